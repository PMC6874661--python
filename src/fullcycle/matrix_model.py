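"""Age-structured matrix projection with stage-level sensitivity analysis.

Annual survival of each life-cycle class j is the product of its stage
survivals, sigma_j = prod_k phi_{j,k}.  These enter a female-based,
birth-pulse, pre-breeding-census Leslie matrix over integer ages 1..28
(ages within a class share parameters): subdiagonal entries carry sigma,
and first-row fertilities F(a) = sigma(a) * b(class of a+1), with b the
expected female offspring per female per year.  The dominant eigenpair
gives the population growth rate lambda, stable age distribution and
reproductive values; sensitivities of lambda to each phi_{j,k} follow the
eigenvector formula d(lambda)/d(a_pq) = v_p w_q / <v, w> summed over the
matrix entries containing phi_{j,k}, optionally chain-ruled onto the daily
mortality scale.  Parameter uncertainty propagates by bootstrap: each of B
replicate matrices draws phi from a logit-normal and b from a log-normal
matched to the estimate and SE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .annual_cycle import (
    AgeClassScheme,
    AnnualCycleCalendar,
    default_calendar,
    default_scheme,
)

__all__ = [
    "DemographicParams",
    "ProjectionModel",
    "DegenerateLifeCycleError",
    "DEFAULT_NATALITY",
    "annual_survival",
    "leslie_matrix",
    "assemble_matrix",
    "growth_rate",
    "eigen_sensitivity_matrix",
    "elasticity_sum",
    "stage_sensitivities",
    "bootstrap_sensitivities",
    "sensitivity_table",
]

#: Placeholder per-class natality (female offspring per female per year);
#: real analyses must supply study-specific values.
DEFAULT_NATALITY: dict[str, tuple[float, float]] = {
    "juvenile": (0.0, 0.0),
    "young_adult": (0.3, 0.05),
    "prime": (0.75, 0.08),
    "senescent": (0.5, 0.07),
}


class DegenerateLifeCycleError(ValueError):
    """Matrix with no positive dominant eigenpair (no reproduction path)."""


@dataclass
class DemographicParams:
    """Stage survivals, natalities and the structures binding them."""

    stage_survivals: Mapping[tuple[str, str], tuple[float, float]]
    natality: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_NATALITY)
    )
    scheme: AgeClassScheme | None = None
    calendar: AnnualCycleCalendar | None = None

    def __post_init__(self) -> None:
        if self.scheme is None:
            self.scheme = default_scheme()
        if self.calendar is None:
            self.calendar = default_calendar(self.scheme)
        for label in self.scheme.labels:
            if label not in self.natality:
                raise ValueError(f"natality missing for class {label!r}")
            for stage in self.calendar.stages_for(label):
                if (label, stage) not in self.stage_survivals:
                    raise ValueError(
                        f"stage survival missing for ({label!r}, {stage!r})"
                    )
                phi = self.stage_survivals[(label, stage)][0]
                if not (0.0 < phi <= 1.0):
                    raise ValueError(f"phi for ({label!r}, {stage!r}) not in (0, 1]")

    @property
    def max_age(self) -> int:
        return self.scheme.max_age

    def phi(self, label: str, stage: str) -> float:
        return self.stage_survivals[(label, stage)][0]

    def combos(self) -> list[tuple[str, str]]:
        return [
            (label, stage)
            for label in self.scheme.labels
            for stage in self.calendar.stages_for(label)
        ]


@dataclass(frozen=True)
class ProjectionModel:
    """Assembled matrix with its dominant eigen-structure."""

    matrix: np.ndarray
    lam: float
    stable_age: np.ndarray  #: right eigenvector, normalised to sum 1
    reproductive_value: np.ndarray  #: left eigenvector, <v, w> = 1


def annual_survival(params: DemographicParams, label: str) -> float:
    """sigma_j: product of phi over the stages in the class's calendar."""
    if label not in params.scheme.labels:
        raise ValueError(f"unknown age class {label!r}")
    stages = params.calendar.stages_for(label)
    return float(np.prod([params.phi(label, s) for s in stages]))


def leslie_matrix(fertilities, survivals) -> np.ndarray:
    """Leslie matrix from explicit top-row fertilities and subdiagonal
    survivals (``len(survivals) == len(fertilities) - 1``)."""
    f = np.asarray(fertilities, dtype=float)
    s = np.asarray(survivals, dtype=float)
    if len(s) != len(f) - 1:
        raise ValueError("need one fewer survival than fertility entries")
    A = np.zeros((len(f), len(f)))
    A[0, :] = f
    A[np.arange(1, len(f)), np.arange(len(f) - 1)] = s
    return A


def _class_of_age(scheme: AgeClassScheme) -> np.ndarray:
    """Class index for each age 1..max_age (index 0 = age 1)."""
    return scheme.index_by_age()


def assemble_matrix(params: DemographicParams) -> np.ndarray:
    """Pre-breeding-census Leslie matrix over ages 1..max_age.

    Subdiagonal: sigma(class of age a), moving age a -> a+1.  First row:
    F(a) = sigma(a) * b(class of a+1) — survive the year, then breed at
    the next birthday; the terminal age has no survival and no fertility.
    """
    scheme = params.scheme
    n = scheme.max_age
    cls = _class_of_age(scheme)
    sigma_by_class = np.array(
        [annual_survival(params, label) for label in scheme.labels]
    )
    b_by_class = np.array([params.natality[label][0] for label in scheme.labels])
    sigma = sigma_by_class[cls]  # per age 1..max
    fert = np.zeros(n)
    fert[:-1] = sigma[:-1] * b_by_class[cls[1:]]
    return leslie_matrix(fert, sigma[:-1])


def growth_rate(A: np.ndarray, check_power_iteration: bool = True) -> ProjectionModel:
    """Dominant eigenpair of a non-negative projection matrix.

    Raises :class:`DegenerateLifeCycleError` when no strictly positive
    real dominant eigenvalue exists.  A power-iteration cross-check must
    agree with the eigendecomposition within 1e-8.
    """
    A = np.asarray(A, dtype=float)
    vals, vecs = np.linalg.eig(A)
    # among eigenvalues at the spectral radius, prefer the (real) one with
    # the smallest imaginary part — imprimitive matrices carry complex
    # companions of equal modulus
    radius = np.abs(vals).max()
    near = np.flatnonzero(np.abs(vals) >= radius * (1 - 1e-12))
    idx = int(near[np.argmax(vals[near].real - np.abs(vals[near].imag))])
    lam = vals[idx]
    if abs(lam.imag) > 1e-9 * max(1.0, abs(lam)) or lam.real <= 0:
        raise DegenerateLifeCycleError(
            "no positive real dominant eigenvalue: degenerate life cycle"
        )
    lam = float(lam.real)
    w = np.real(vecs[:, idx])
    if w.sum() < 0:
        w = -w
    if (w < -1e-9 * np.abs(w).max()).any():
        raise DegenerateLifeCycleError("dominant eigenvector not non-negative")
    w = np.clip(w, 0.0, None)
    w = w / w.sum()

    lvals, lvecs = np.linalg.eig(A.T)
    lidx = int(np.argmin(np.abs(lvals - lam)))
    v = np.real(lvecs[:, lidx])
    if v @ w < 0:
        v = -v
    v = v / (v @ w)

    if check_power_iteration:
        # iterate on A + I (primitive whenever A is irreducible), so
        # imprimitive life cycles (e.g. two-age toys) still converge
        x = np.ones(A.shape[0]) / A.shape[0]
        lam_pi = lam
        for _ in range(10_000):
            y = A @ x + x
            norm = y.sum()
            if norm <= 0:
                raise DegenerateLifeCycleError("power iteration collapsed to zero")
            y = y / norm
            if np.abs(y - x).max() < 1e-13:
                lam_pi = norm - 1.0
                break
            x = y
            lam_pi = norm - 1.0
        if abs(lam_pi - lam) > 1e-8 * max(1.0, lam):
            raise ArithmeticError(
                f"power iteration ({lam_pi}) disagrees with eigendecomposition ({lam})"
            )
    return ProjectionModel(matrix=A, lam=lam, stable_age=w, reproductive_value=v)


def eigen_sensitivity_matrix(model: ProjectionModel) -> np.ndarray:
    """d(lambda)/d(a_pq) = v_p w_q / <v, w> for every matrix entry."""
    v, w = model.reproductive_value, model.stable_age
    return np.outer(v, w) / (v @ w)


def elasticity_sum(model: ProjectionModel) -> float:
    """Sum of entry elasticities (a_pq / lambda) d(lambda)/d(a_pq); equals 1
    for a correct dominant eigenpair."""
    S = eigen_sensitivity_matrix(model)
    return float((model.matrix * S).sum() / model.lam)


def stage_sensitivities(
    params: DemographicParams,
    scale: str = "survival",
    model: ProjectionModel | None = None,
) -> dict[tuple[str, str], float]:
    """d(lambda)/d(phi_{j,k}) for every stage survival (chain rule).

    phi_{j,k} enters every subdiagonal entry of the ages in class j and
    every first-row fertility built from sigma_j, each with
    d(sigma_j)/d(phi_{j,k}) = sigma_j / phi_{j,k}.  With
    ``scale="daily_mortality"`` the derivative is reported with respect to
    the stage's daily mortality 1 - dS (magnitude; lambda falls as
    mortality rises) via the further factor l * dS^(l-1).
    """
    if scale not in ("survival", "daily_mortality"):
        raise ValueError(f"unknown scale {scale!r}")
    scheme, calendar = params.scheme, params.calendar
    if model is None:
        model = growth_rate(assemble_matrix(params), check_power_iteration=False)
    S = eigen_sensitivity_matrix(model)
    cls = _class_of_age(scheme)
    n = scheme.max_age
    b_by_class = np.array([params.natality[label][0] for label in scheme.labels])

    # d(lambda)/d(sigma_j): sum over ages a in class j of the subdiagonal
    # entry plus the fertility entry containing sigma(a)
    dlam_dsigma = np.zeros(len(scheme.labels))
    for i in range(n - 1):  # age index i <-> age i+1; terminal age enters nothing
        j = cls[i]
        dlam_dsigma[j] += S[i + 1, i] + S[0, i] * b_by_class[cls[i + 1]]

    out: dict[tuple[str, str], float] = {}
    for ji, label in enumerate(scheme.labels):
        sigma_j = annual_survival(params, label)
        for stage in calendar.stages_for(label):
            phi = params.phi(label, stage)
            s_phi = dlam_dsigma[ji] * sigma_j / phi
            if scale == "survival":
                out[(label, stage)] = float(s_phi)
            else:
                l = calendar.duration(label, stage)
                dS = phi ** (1.0 / l)
                out[(label, stage)] = float(s_phi * l * dS ** (l - 1))
    return out


def bootstrap_sensitivities(
    params: DemographicParams,
    B: int = 1000,
    seed: int = 0,
    scale: str = "survival",
    max_resample: int = 100,
) -> tuple[dict[tuple[str, str], tuple[float, float]], int]:
    """Bootstrap mean and SE of stage sensitivities over B replicate matrices.

    Each replicate draws every phi from a logit-normal and every b from a
    log-normal matched to its estimate and SE (parameters with SE 0, and
    the zero-death phi = 1 convention, stay fixed).  Replicates whose
    matrix has no positive dominant eigenvalue are redrawn; the count of
    redraws is returned alongside the results.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    combos = params.combos()
    draws: dict[tuple[str, str], list[float]] = {c: [] for c in combos}
    n_resampled = 0

    def draw_params() -> DemographicParams:
        phis = {}
        for c in combos:
            phi, se = params.stage_survivals[c]
            if se <= 0 or phi >= 1.0:
                phis[c] = (phi, se)
            else:
                sd = se / (phi * (1.0 - phi))  # delta method on the logit scale
                phis[c] = (float(expit(rng.normal(logit(phi), sd))), se)
        nat = {}
        for label in params.scheme.labels:
            b, se_b = params.natality[label]
            if se_b <= 0 or b <= 0:
                nat[label] = (b, se_b)
            else:
                sd = se_b / b  # delta method on the log scale
                nat[label] = (float(np.exp(rng.normal(np.log(b), sd))), se_b)
        return DemographicParams(
            stage_survivals=phis,
            natality=nat,
            scheme=params.scheme,
            calendar=params.calendar,
        )

    for _ in range(B):
        for attempt in range(max_resample):
            p = draw_params()
            try:
                model = growth_rate(assemble_matrix(p), check_power_iteration=False)
            except DegenerateLifeCycleError:
                n_resampled += 1
                continue
            sens = stage_sensitivities(p, scale=scale, model=model)
            for c in combos:
                draws[c].append(sens[c])
            break
        else:
            raise DegenerateLifeCycleError(
                f"could not draw a viable matrix in {max_resample} attempts"
            )

    out = {}
    for c, vals in draws.items():
        arr = np.asarray(vals)
        # exact zero when every replicate coincides (all-fixed parameters)
        sd = float(arr.std(ddof=1)) if np.ptp(arr) > 0 else 0.0
        out[c] = (float(arr.mean()), sd)
    return out, n_resampled


def sensitivity_table(
    params: DemographicParams,
    point: Mapping[tuple[str, str], float],
    boot: Mapping[tuple[str, str], tuple[float, float]] | None = None,
    scale: str = "survival",
) -> pd.DataFrame:
    """Tidy sensitivity output (the stage x age-class figure analogue)."""
    rows = []
    for label, stage in params.combos():
        row = {
            "age_class": label,
            "stage": stage,
            "scale": scale,
            "duration_days": params.calendar.duration(label, stage),
            "sensitivity": point[(label, stage)],
        }
        if boot is not None:
            mean_s, se_s = boot[(label, stage)]
            row["boot_mean"] = mean_s
            row["boot_se"] = se_s
        rows.append(row)
    return pd.DataFrame(rows)
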