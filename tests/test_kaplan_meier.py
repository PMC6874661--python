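"""Interval KM estimator: hand oracles, tie/censor conventions, delta method."""

import math
from fractions import Fraction

import numpy as np
import pytest

from fullcycle.kaplan_meier import (
    InsufficientDataError,
    RiskInterval,
    build_risk_intervals,
    combine_daily_survival,
    daily_mortality_table,
    daily_survival,
    estimate_all,
    estimate_km,
    stage_survival,
)

from conftest import make_segments


def test_single_death_hand_computation():
    """10 birds at risk >= 10 days, one dies on within-stage day 3."""
    durations = [10, 12, 15, 20, 11, 30, 25, 14, 18, 3]
    events = [0] * 9 + [1]
    ivs = build_risk_intervals(make_segments(durations, events))
    assert len(ivs) == 1
    iv = ivs[0]
    assert (iv.dt_days, iv.r, iv.n) == (3, 10, 1)
    assert iv.S == pytest.approx(0.9)
    dS, _ = daily_survival(iv)
    assert dS == pytest.approx(0.9 ** (1 / 3))


def test_tied_deaths_share_one_interval():
    durations = [7] * 2 + [20] * 18
    events = [1, 1] + [0] * 18
    ivs = build_risk_intervals(make_segments(durations, events))
    assert len(ivs) == 1
    assert (ivs[0].n, ivs[0].r) == (2, 20)
    assert ivs[0].S == pytest.approx(18 / 20)


def test_censoring_on_death_day_stays_at_risk():
    # one bird censored on day 5, another dies on day 5: deaths-before-losses
    durations = [5, 5, 9, 9]
    events = [0, 1, 0, 0]
    ivs = build_risk_intervals(make_segments(durations, events))
    assert (ivs[0].r, ivs[0].n) == (4, 1)


def test_no_deaths_raises_insufficient_data():
    segs = make_segments([10] * 10, [0] * 10)
    assert build_risk_intervals(segs) == []
    with pytest.raises(InsufficientDataError):
        estimate_km(segs)


def test_all_at_risk_dying_is_an_error():
    segs = make_segments([4, 4], [1, 1])
    with pytest.raises(InsufficientDataError, match="survival 0"):
        build_risk_intervals(segs)


def _interval(S, dt_days, r=100, n=1):
    var_S = S * S * n / (r * (r - n))
    return RiskInterval("a", "b", 0, dt_days, dt_days, r, n, S, var_S, False)


@pytest.mark.parametrize("S,dt,expected", [(1.0, 200, 1.0), (0.5, 1, 0.5),
                                           (0.9, 3, 0.9 ** (1 / 3))])
def test_daily_survival_values(S, dt, expected):
    dS, var = daily_survival(_interval(S, dt))
    assert dS == pytest.approx(expected)
    assert var >= 0


def test_daily_survival_zero_is_undefined():
    iv = RiskInterval("a", "b", 0, 3, 3, 5, 5, 0.0, 0.0, False)
    with pytest.raises(ValueError):
        daily_survival(iv)


def test_combine_single_interval_identity():
    iv = _interval(0.95, 4)
    dS, var = daily_survival(iv)
    dS_hat, se = combine_daily_survival([iv])
    assert dS_hat == pytest.approx(dS)
    assert se == pytest.approx(dS * math.sqrt(var / dS**2))


def test_combine_equal_length_intervals_is_plain_geometric_mean():
    ivs = [_interval(0.99, 5), _interval(0.96, 5)]
    d1, _ = daily_survival(ivs[0])
    d2, _ = daily_survival(ivs[1])
    for weighting in ("days", "intervals"):
        dS_hat, _ = combine_daily_survival(ivs, weighting=weighting)
        assert dS_hat == pytest.approx(math.sqrt(d1 * d2))


def test_combine_interval_weighting_matches_stated_formula():
    """Unweighted mode: dS_hat = (prod dS_t)^(1/m) even with unequal dt."""
    ivs = [_interval(0.99, 2), _interval(0.96, 10)]
    d = [daily_survival(iv)[0] for iv in ivs]
    dS_hat, _ = combine_daily_survival(ivs, weighting="intervals")
    assert dS_hat == pytest.approx(math.sqrt(d[0] * d[1]))


def test_combine_day_weighting_is_per_day_root_of_product():
    ivs = [_interval(0.99, 2), _interval(0.96, 10)]
    dS_hat, _ = combine_daily_survival(ivs, weighting="days")
    assert dS_hat == pytest.approx((0.99 * 0.96) ** (1 / 12))


def test_combine_requires_kept_intervals():
    iv = _interval(0.9, 3, r=4)  # r <= 5 -> dropped
    dropped = RiskInterval(*(list(iv.__dict__.values())[:-1] + [True]))
    with pytest.raises(InsufficientDataError):
        combine_daily_survival([dropped])


@pytest.mark.parametrize(
    "dS,l,expected",
    [(1.0, 180, 1.0), (0.999, 180, 0.999**180), (0.99, 8, 0.99**8)],
)
def test_stage_survival_exponentiation(dS, l, expected):
    phi = stage_survival(dS, 0.001, l)
    assert phi.phi == pytest.approx(expected)
    assert phi.se_phi == pytest.approx(l * dS ** (l - 1) * 0.001)
    assert not phi.assumed_one


def test_stage_survival_zero_death_convention():
    phi = stage_survival(0.99, 0.01, 100, assumed_one=True)
    assert (phi.phi, phi.se_phi, phi.assumed_one) == (1.0, 0.0, True)


def test_phi_monotone_in_duration_and_mortality():
    phis_l = [stage_survival(0.995, 0, l).phi for l in (1, 10, 50, 200)]
    assert phis_l == sorted(phis_l, reverse=True)
    phis_d = [stage_survival(d, 0, 30).phi for d in (0.999, 0.995, 0.98)]
    assert phis_d == sorted(phis_d, reverse=True)


def test_dropping_rule_flags_exactly_small_risk_sets():
    # staggered exits leave <=5 at risk for late deaths
    durations = [3, 10, 10, 10, 10, 10, 18, 18, 18, 25]
    events = [1, 0, 0, 0, 0, 0, 1, 0, 0, 0]
    ivs5 = build_risk_intervals(make_segments(durations, events), min_at_risk=5)
    ivs0 = build_risk_intervals(make_segments(durations, events), min_at_risk=0)
    assert [(iv.r, iv.n) for iv in ivs5] == [(iv.r, iv.n) for iv in ivs0]
    assert [iv.dropped for iv in ivs5] == [iv.r <= 5 for iv in ivs5]
    assert not any(iv.dropped for iv in ivs0)


def test_product_limit_matches_lifelines():
    """Cumulative product of interval survivals equals the KM curve from an
    independent implementation on a censored dataset."""
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(42)
    durations = rng.integers(1, 60, size=120)
    events = rng.random(120) < 0.5
    segs = make_segments(durations, events)
    ivs = build_risk_intervals(segs, min_at_risk=0)
    kmf = lifelines.KaplanMeierFitter().fit(durations, events)
    cumulative = 1.0
    for iv in ivs:
        cumulative *= iv.S
        ours = cumulative
        theirs = float(
            kmf.survival_function_at_times(iv.death_day).iloc[0]
        )
        assert ours == pytest.approx(theirs, abs=1e-12)


def test_exact_rational_product_limit_oracle():
    """Product of S_t in exact arithmetic matches a day-by-day enumeration."""
    durations = [3, 3, 5, 5, 7, 9, 9, 9, 12, 15, 15, 20, 20, 20, 25, 30, 30, 40, 45, 50]
    events = [1, 0, 1, 1, 0, 1, 1, 1, 0, 1, 0, 1, 1, 0, 0, 1, 0, 1, 0, 0]
    ivs = build_risk_intervals(make_segments(durations, events), min_at_risk=0)
    ours = Fraction(1)
    for iv in ivs:
        ours *= Fraction(iv.r - iv.n, iv.r)
    oracle = Fraction(1)
    for day in range(1, max(durations) + 1):
        at_risk = sum(d >= day for d in durations)
        deaths = sum(d == day and e for d, e in zip(durations, events))
        if deaths:
            oracle *= Fraction(at_risk - deaths, at_risk)
    assert ours == oracle


def test_daily_mortality_table_values_and_flags(calendar, scheme):
    # young_adult breeding with deaths; juvenile breeding with none
    segs = make_segments([10] * 9 + [3], [0] * 9 + [1]) + make_segments(
        [30] * 8, [0] * 8, age_class="juvenile", stage="breeding"
    )
    est = estimate_all(segs, calendar, scheme)
    table = daily_mortality_table(est, calendar, scheme)
    ya = table[(table.age_class == "young_adult") & (table.stage == "breeding")].iloc[0]
    dS = 0.9 ** (1 / 3)
    assert ya.daily_mortality_x10 == pytest.approx(10 * (1 - dS))
    juv = table[(table.age_class == "juvenile") & (table.stage == "breeding")].iloc[0]
    assert juv.daily_mortality_x10 == 0.0 and juv.assumed_one
    # juvenile northward is not part of the juvenile calendar
    missing = table[
        (table.age_class == "juvenile") & (table.stage == "northward_migration")
    ].iloc[0]
    assert missing.missing_data and np.isnan(missing.daily_mortality_x10)
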