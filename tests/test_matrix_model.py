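"""Leslie assembly, eigen-analysis, sensitivities and the bootstrap."""

import numpy as np
import pytest

from fullcycle.annual_cycle import (
    AgeClassScheme,
    AnnualCycleCalendar,
    default_calendar,
    default_scheme,
)
from fullcycle.matrix_model import (
    DEFAULT_NATALITY,
    DegenerateLifeCycleError,
    DemographicParams,
    annual_survival,
    assemble_matrix,
    bootstrap_sensitivities,
    eigen_sensitivity_matrix,
    elasticity_sum,
    growth_rate,
    leslie_matrix,
    stage_sensitivities,
)


def default_params(phi_table=None, natality=None, se=0.0):
    scheme = default_scheme()
    calendar = default_calendar(scheme)
    phis = {}
    base = {"breeding": 0.93, "southward_migration": 0.96,
            "wintering": 0.95, "northward_migration": 0.975}
    for label in scheme.labels:
        for stage in calendar.stages_for(label):
            phi = (phi_table or base)[stage]
            if label == "juvenile":
                phi = min(1.0, phi * 0.93)  # harsher first year
            phis[(label, stage)] = (phi, se)
    return DemographicParams(
        stage_survivals=phis,
        natality=natality or dict(DEFAULT_NATALITY),
        scheme=scheme,
        calendar=calendar,
    )


def test_annual_survival_is_product_of_stage_survivals():
    params = default_params()
    sigma = annual_survival(params, "prime")
    assert sigma == pytest.approx(0.93 * 0.96 * 0.95 * 0.975)


def test_annual_survival_product_example():
    phis = dict(zip(
        ("breeding", "southward_migration", "wintering", "northward_migration"),
        (0.9, 0.95, 0.98, 0.99),
    ))
    params = default_params(phi_table=phis)
    assert annual_survival(params, "senescent") == pytest.approx(
        0.9 * 0.95 * 0.98 * 0.99
    )


def test_juvenile_product_spans_only_its_three_stages():
    params = default_params()
    expected = np.prod(
        [params.phi("juvenile", s) for s in params.calendar.stages_for("juvenile")]
    )
    assert len(params.calendar.stages_for("juvenile")) == 3
    assert annual_survival(params, "juvenile") == pytest.approx(expected)


class TestLeslieToys:
    def test_two_age_toy_matrix_and_lambda(self):
        A = leslie_matrix([0.0, 2.0], [0.5])
        assert A.tolist() == [[0.0, 2.0], [0.5, 0.0]]
        model = growth_rate(A)
        assert model.lam == pytest.approx(1.0, abs=1e-12)

    def test_lambda_sqrt_fertility_times_survival(self):
        model = growth_rate(leslie_matrix([0.0, 4.0], [0.25]))
        assert model.lam == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_sensitivity_two_age(self):
        # lambda = sqrt(F2 sigma1): d(lambda)/d(sigma1) = F2/(2 lambda) = 1
        model = growth_rate(leslie_matrix([0.0, 2.0], [0.5]))
        S = eigen_sensitivity_matrix(model)
        assert S[1, 0] == pytest.approx(1.0, abs=1e-10)

    def test_no_reproduction_is_degenerate(self):
        A = leslie_matrix([0.0, 0.0, 0.0], [0.5, 0.6])
        with pytest.raises(DegenerateLifeCycleError):
            growth_rate(A)


def test_assembled_matrix_structure():
    params = default_params()
    A = assemble_matrix(params)
    n = params.scheme.max_age
    assert A.shape == (n, n)
    cls = params.scheme.index_by_age()
    sigmas = [annual_survival(params, lab) for lab in params.scheme.labels]
    bs = {lab: params.natality[lab][0] for lab in params.scheme.labels}
    labels = params.scheme.labels
    # subdiagonal carries sigma(class of age); first row sigma(a) * b(class(a+1))
    for i in range(n - 1):
        assert A[i + 1, i] == pytest.approx(sigmas[cls[i]])
        assert A[0, i] == pytest.approx(sigmas[cls[i]] * bs[labels[cls[i + 1]]])
    assert A[0, n - 1] == 0.0
    # only first row and subdiagonal are populated
    mask = np.zeros_like(A, dtype=bool)
    mask[0, :] = True
    mask[np.arange(1, n), np.arange(n - 1)] = True
    assert (A[~mask] == 0).all()


@pytest.mark.parametrize("seed", range(4))
def test_lambda_matches_characteristic_polynomial(seed):
    """Dominant eigenvalue equals the max real root of the Leslie
    characteristic polynomial lam^n - sum F_a (prod sigma) lam^(n-a)."""
    rng = np.random.default_rng(seed)
    f = np.concatenate(([0.0], rng.uniform(0.5, 3.0, 3)))
    s = rng.uniform(0.2, 0.9, 3)
    A = leslie_matrix(f, s)
    model = growth_rate(A)
    coeffs = np.zeros(5)
    coeffs[0] = 1.0
    cum = np.concatenate(([1.0], np.cumprod(s)))
    for a in range(1, 5):
        coeffs[a] = -f[a - 1] * cum[a - 1]
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-9].real
    assert model.lam == pytest.approx(float(real.max()), abs=1e-8)


def test_elasticities_sum_to_one():
    model = growth_rate(assemble_matrix(default_params()))
    assert elasticity_sum(model) == pytest.approx(1.0, abs=1e-8)


def test_stage_sensitivities_match_finite_differences():
    params = default_params()
    sens = stage_sensitivities(params, scale="survival")
    lam0 = growth_rate(assemble_matrix(params)).lam
    h = 1e-6
    for (label, stage), s in sens.items():
        assert s >= 0.0
        up = default_params()
        down = default_params()
        up.stage_survivals = dict(params.stage_survivals)
        down.stage_survivals = dict(params.stage_survivals)
        phi, se = params.stage_survivals[(label, stage)]
        up.stage_survivals[(label, stage)] = (phi + h, se)
        down.stage_survivals[(label, stage)] = (phi - h, se)
        fd = (
            growth_rate(assemble_matrix(up)).lam
            - growth_rate(assemble_matrix(down)).lam
        ) / (2 * h)
        assert s == pytest.approx(fd, rel=1e-5, abs=1e-9)
    assert lam0 > 0


def test_terminal_single_age_class_has_zero_sensitivity():
    """A survival affecting no matrix entry (terminal age's year) leaves
    lambda unchanged."""
    scheme = AgeClassScheme((("adult", 1, 3), ("last", 4, 4)))
    from fullcycle.annual_cycle import _ADULT_SPANS

    calendar = AnnualCycleCalendar({"adult": _ADULT_SPANS, "last": _ADULT_SPANS})
    phis = {}
    for label in scheme.labels:
        for stage in calendar.stages_for(label):
            phis[(label, stage)] = (0.9, 0.0)
    params = DemographicParams(
        stage_survivals=phis,
        natality={"adult": (0.8, 0.0), "last": (0.1, 0.0)},
        scheme=scheme,
        calendar=calendar,
    )
    sens = stage_sensitivities(params, scale="survival")
    for stage in calendar.stages_for("last"):
        assert sens[("last", stage)] == pytest.approx(0.0, abs=1e-12)
    assert all(sens[("adult", s)] > 0 for s in calendar.stages_for("adult"))


def test_mortality_scale_applies_duration_chain_rule():
    params = default_params()
    s_phi = stage_sensitivities(params, scale="survival")
    s_mort = stage_sensitivities(params, scale="daily_mortality")
    for (label, stage), s in s_phi.items():
        l = params.calendar.duration(label, stage)
        phi = params.phi(label, stage)
        dS = phi ** (1 / l)
        assert s_mort[(label, stage)] == pytest.approx(s * l * dS ** (l - 1))


def test_lambda_monotone_in_stage_survival():
    params = default_params()
    lam0 = growth_rate(assemble_matrix(params)).lam
    worse = default_params()
    worse.stage_survivals = dict(params.stage_survivals)
    worse.stage_survivals[("prime", "breeding")] = (0.80, 0.0)
    lam1 = growth_rate(assemble_matrix(worse)).lam
    assert lam1 < lam0


class TestBootstrap:
    def test_zero_se_collapses_to_point(self):
        natality = {k: (b, 0.0) for k, (b, _) in DEFAULT_NATALITY.items()}
        params = default_params(se=0.0, natality=natality)
        point = stage_sensitivities(params, scale="survival")
        boot, n_resampled = bootstrap_sensitivities(params, B=50, seed=4)
        assert n_resampled == 0
        for key, (mean_s, se_s) in boot.items():
            assert se_s == 0.0
            assert mean_s == pytest.approx(point[key], abs=1e-12)

    def test_doubling_input_se_inflates_output_se(self):
        small = default_params(se=0.01)
        large = default_params(se=0.02)
        b_small, _ = bootstrap_sensitivities(small, B=300, seed=5)
        b_large, _ = bootstrap_sensitivities(large, B=300, seed=5)
        for key in b_small:
            assert b_large[key][1] > b_small[key][1]
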