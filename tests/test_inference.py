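"""Control-resampling GLM, chi-square frequency test and stage ANOVA."""

import datetime as dt

import numpy as np
import pytest
from scipy import stats

from fullcycle.inference import (
    DeathEvent,
    anova_by_stage,
    chisq_death_frequency,
    death_glm_test,
    filter_min_tracking,
    simulate_control_deaths,
)
from fullcycle.simulate import TrackingRecord


def _event(stage, age, simulated=False, lat=None, ident="e"):
    age_class = (
        "juvenile" if age == 1 else "young_adult" if age <= 6
        else "prime" if age <= 11 else "senescent"
    )
    return DeathEvent(ident, age, age_class, stage, lat, simulated)


def _control(ident, tag, days, age=5):
    return TrackingRecord(
        ident, tag, age, "censored", tag + dt.timedelta(days=days - 1)
    )


class TestControlResampling:
    def test_single_day_track_is_chosen_with_certainty(self, calendar, scheme):
        rec = _control("c", dt.date(2010, 6, 1), 1)
        [ev] = simulate_control_deaths([rec], calendar, scheme, seed=0)
        assert ev.stage == "breeding" and ev.age_at_death == 5 and ev.simulated

    def test_seed_reproducibility(self, calendar, scheme):
        controls = [
            _control(f"c{i}", dt.date(2009, 3, 1), 400 + 13 * i) for i in range(52)
        ]
        a = simulate_control_deaths(controls, calendar, scheme, seed=9)
        b = simulate_control_deaths(controls, calendar, scheme, seed=9)
        assert a == b

    def test_stage_frequencies_match_exposure_proportions(self, calendar, scheme):
        """A full adult year of tracking: P(stage) equals the stage's share
        of the 365-day calendar (law of large numbers over 10,000 draws)."""
        controls = [
            _control(f"c{i}", dt.date(2010, 3, 1), 365) for i in range(10_000)
        ]
        events = simulate_control_deaths(controls, calendar, scheme, seed=1)
        frac = np.mean([e.stage == "wintering" for e in events])
        p = 146 / 365
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / len(controls))

    def test_rejects_empty_or_dead_controls(self, calendar, scheme):
        with pytest.raises(ValueError):
            simulate_control_deaths([], calendar, scheme, seed=0)
        dead = TrackingRecord(
            "d", dt.date(2010, 1, 1), 3, "died", dt.date(2010, 2, 1), 30.0, -5.0
        )
        with pytest.raises(ValueError, match="censored"):
            simulate_control_deaths([dead], calendar, scheme, seed=0)


def test_filter_min_tracking_drops_short_histories():
    recs = [_control("a", dt.date(2010, 1, 1), 3), _control("b", dt.date(2010, 1, 1), 30)]
    assert [r.individual_id for r in filter_min_tracking(recs, 7)] == ["b"]


class TestDeathGLM:
    def test_balanced_zero_signal_has_null_lrt(self):
        actual, simulated = [], []
        for stage in ("breeding", "wintering"):
            for age in (3, 10):
                actual += [_event(stage, age)] * 10
                simulated += [_event(stage, age, simulated=True)] * 10
        rep = death_glm_test(actual, simulated)
        for term in ("stage", "age", "interaction"):
            assert rep["terms"][term]["lrt"] == pytest.approx(0.0, abs=1e-8)

    def test_forced_stage_concentration_is_detected(self):
        rng = np.random.default_rng(0)
        stages = ("breeding", "southward_migration", "wintering", "northward_migration")
        actual = [_event("southward_migration", int(a)) for a in rng.integers(2, 20, 50)]
        simulated = [
            _event(stages[i % 4], int(a), simulated=True)
            for i, a in enumerate(rng.integers(2, 20, 50))
        ]
        rep = death_glm_test(actual, simulated)
        assert rep["terms"]["stage"]["p"] < 0.001
        assert any("quasi-separation" in w for w in rep["warnings"])

    def test_four_class_age_coding(self):
        actual = [_event("breeding", a) for a in (1, 3, 9, 20) for _ in range(5)]
        simulated = [
            _event(s, a, simulated=True)
            for s in ("breeding", "wintering")
            for a in (1, 3, 9, 20)
            for _ in range(3)
        ]
        rep = death_glm_test(actual, simulated, age_coding="classes")
        assert rep["age_coding"] == "classes"
        assert rep["terms"]["stage"]["df"] == 1
        assert rep["terms"]["age"]["df"] == 3

    def test_requires_both_arms(self):
        with pytest.raises(ValueError):
            death_glm_test([], [_event("breeding", 3, simulated=True)])


class TestChiSquare:
    def test_proportional_table_is_zero(self):
        deaths = []
        for stage in ("breeding", "wintering"):
            deaths += [_event(stage, 3)] * 6 + [_event(stage, 10)] * 9
        rep = chisq_death_frequency(deaths)
        assert rep["chi2"] == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_table_hand_value(self):
        deaths = [_event("breeding", 3)] * 10 + [_event("wintering", 10)] * 10
        rep = chisq_death_frequency(deaths)
        assert rep["chi2"] == pytest.approx(20.0)
        assert rep["df"] == 1
        assert rep["p"] == pytest.approx(stats.chi2.sf(20.0, 1))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_pearson(self, seed):
        rng = np.random.default_rng(seed)
        stages = ("breeding", "southward_migration", "wintering", "northward_migration")
        counts = rng.integers(1, 30, size=(2, 4))
        deaths = []
        for i, age in enumerate((3, 15)):
            for j, stage in enumerate(stages):
                deaths += [_event(stage, age)] * int(counts[i, j])
        rep = chisq_death_frequency(deaths)
        O = counts.astype(float)
        E = O.sum(1, keepdims=True) * O.sum(0, keepdims=True) / O.sum()
        assert rep["chi2"] == pytest.approx(((O - E) ** 2 / E).sum(), abs=1e-10)

    def test_expected_below_five_flagged(self):
        deaths = [_event("breeding", 3)] * 3 + [_event("wintering", 10)] * 4
        rep = chisq_death_frequency(deaths)
        assert any("expected count < 5" in w for w in rep["warnings"])


class TestAnova:
    def test_equal_group_means_give_zero_f(self):
        deaths = []
        for stage in ("breeding", "wintering", "southward_migration"):
            deaths += [_event(stage, a) for a in (4, 8, 12)]
        rep = anova_by_stage(deaths, "age_at_death")
        assert rep["F"] == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(3)
        a = rng.normal(5, 2, 12)
        b = rng.normal(7, 2, 15)
        deaths = [_event("breeding", 3, lat=float(v)) for v in a] + [
            _event("wintering", 3, lat=float(v)) for v in b
        ]
        rep = anova_by_stage(deaths, "latitude")
        t, _ = stats.ttest_ind(a, b)
        assert rep["F"] == pytest.approx(t**2, rel=1e-10)

    def test_df_structure_for_study_sized_sample(self):
        rng = np.random.default_rng(1)
        stages = ("breeding", "southward_migration", "wintering", "northward_migration")
        deaths = [
            _event(stages[i % 4], int(1 + rng.integers(1, 27))) for i in range(53)
        ]
        rep = anova_by_stage(deaths, "age_at_death")
        assert (rep["df1"], rep["df2"]) == (3, 49)

    def test_singleton_group_warns(self):
        deaths = [_event("breeding", a) for a in (3, 5, 9)] + [_event("wintering", 7)]
        rep = anova_by_stage(deaths, "age_at_death")
        assert any("single observation" in w for w in rep["warnings"])

    def test_latitude_requires_located_events(self):
        deaths = [_event("breeding", 3), _event("wintering", 5)]
        with pytest.raises(ValueError):
            anova_by_stage(deaths, "latitude")
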