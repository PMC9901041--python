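import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutharvest import stats_report as sr
from gutharvest.synthetic_cohort import CohortConfig, generate_cohort, noise_free


def series(wd, mbd):
    return sr.PairedSeries(
        ids=tuple(f"P{i}" for i in range(len(wd))),
        wd=np.asarray(wd, float), mbd=np.asarray(mbd, float),
    )


class TestPairedCrossover:
    def test_identical_arms_null(self):
        r = sr.paired_crossover(series([1, 2, 3], [1, 2, 3]))
        assert r.mean_diff == 0.0 and r.p_value == 1.0

    def test_worked_mean_difference(self):
        r = sr.paired_crossover(series([1, 2, 3], [2, 4, 6]))
        assert r.mean_diff == pytest.approx(2.0)

    def test_arm_swap_negates_difference(self):
        a = sr.paired_crossover(series([1, 2, 3], [2, 5, 7]))
        b = sr.paired_crossover(series([2, 5, 7], [1, 2, 3]))
        assert a.mean_diff == pytest.approx(-b.mean_diff)
        assert a.p_value == pytest.approx(b.p_value)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3 complete pairs"):
            sr.paired_crossover(series([1, 2], [2, 3]))

    def test_incomplete_pairs_excluded_and_logged(self, caplog):
        df = pd.DataFrame({
            "participant_id": ["P1", "P1", "P2", "P2", "P3"],
            "diet": ["WD", "MBD", "WD", "MBD", "WD"],
            "v": [1.0, 2.0, 3.0, 5.0, 9.0],
        })
        with caplog.at_level(logging.INFO, logger="gutharvest.stats_report"):
            ps = sr.PairedSeries.from_frame(df, "v")
        assert ps.ids == ("P1", "P2")
        assert any("excluded" in r.message for r in caplog.records)


class TestBlandAltman:
    def test_self_agreement_collapses(self):
        x = np.array([10.0, 20.0, 30.0])
        ag = sr.bland_altman(x, x)
        assert ag.bias == 0.0 and ag.loa_low == 0.0 and ag.loa_high == 0.0

    def test_constant_offset(self):
        x = np.array([10.0, 20.0, 30.0])
        ag = sr.bland_altman(x, x + 2)
        assert ag.bias == pytest.approx(2.0)
        assert ag.proportional_slope == pytest.approx(0.0, abs=1e-12)

    def test_proportional_bias_matches_closed_form_ols(self):
        # y = 1.1 x: d = 0.1 x, m = 1.05 x -> slope = 0.1/1.05 = 2/21
        x = np.array([10.0, 20.0, 30.0])
        ag = sr.bland_altman(x, 1.1 * x)
        assert ag.proportional_slope == pytest.approx(2 / 21, rel=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            sr.bland_altman([1, 2, 3], [1, 2])


class TestLinCCC:
    def test_perfect_and_inverse_agreement(self):
        x = np.array([-1.0, 0.0, 1.0])
        assert sr.lin_ccc(x, x) == pytest.approx(1.0)
        assert sr.lin_ccc(x, -x) == pytest.approx(-1.0)

    def test_hand_moment_computation(self):
        # x=(1,2,3), y=(2,3,5): cov=1, var_x=2/3, var_y=14/9, dmean=4/3
        # ccc = 2*1 / (2/3 + 14/9 + 16/9) = 0.5
        assert sr.lin_ccc([1, 2, 3], [2, 3, 5]) == pytest.approx(0.5, rel=1e-12)

    def test_undefined_for_two_constants(self):
        with pytest.raises(ValueError, match="constant"):
            sr.lin_ccc([1, 1, 1], [2, 2, 2])

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
                    min_size=3, max_size=30))
    def test_ccc_bounded_by_pearson(self, pairs):
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        if np.var(x) < 1e-6 or np.var(y) < 1e-6:
            return
        ccc = sr.lin_ccc(x, y)
        r = np.corrcoef(x, y)[0, 1]
        assert abs(ccc) <= abs(r) + 1e-9
        assert -1 - 1e-12 <= ccc <= 1 + 1e-12


class TestTrapezoidIAUC:
    def test_constant_series_zero(self):
        assert sr.trapezoid_iauc([-15, 0, 30, 60], [5, 5, 5, 5]) == 0.0

    def test_worked_trapezoid(self):
        iauc = sr.trapezoid_iauc([-15, 0, 30, 60, 90], [0, 0, 10, 10, 0])
        assert iauc == pytest.approx(600.0)

    def test_baseline_subtraction_invariance(self):
        t = [-15, 0, 30, 60, 90]
        v = np.array([0.0, 0.0, 10.0, 10.0, 0.0])
        assert sr.trapezoid_iauc(t, v + 37.2) == pytest.approx(sr.trapezoid_iauc(t, v))

    def test_time_shift_invariance(self):
        t = np.array([-15.0, 0, 30, 60, 90])
        v = [0, 0, 10, 10, 0]
        # shift preserving which samples are pre-meal
        assert sr.trapezoid_iauc(t + 5, v) == pytest.approx(sr.trapezoid_iauc(t, v))

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            sr.trapezoid_iauc([0, 30, 60], [0, 10, 0])

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            sr.trapezoid_iauc([-15, 30, 30], [0, 1, 2])


class TestBuildReport:
    def test_empty_cohort_keeps_schema(self, default_cohort):
        import copy
        empty = copy.copy(default_cohort)
        empty.intake = default_cohort.intake.iloc[0:0]
        report = sr.build_report(empty)
        assert list(report["diet_summary"].columns)[:3] == ["metric", "wd_mean", "wd_sem"]
        assert len(report["diet_summary"]) == 0
        assert len(report["agreement"]) == 0

    def test_measured_ctt_agrees_better_than_fixed(self):
        """Heterogeneous transit drives ME spread, so feeding each participant's
        CTT to the model must improve concordance over a one-size 48 h."""
        ds = generate_cohort(noise_free(CohortConfig(seed=21)))
        report = sr.build_report(ds)
        ag = report["agreement"].set_index("ctt_mode")
        assert ag.loc["measured_ctt", "ccc"] > ag.loc["fixed_48h", "ccc"]

    def test_report_matches_direct_recomputation(self, default_cohort, default_pipeline):
        report = sr.build_report(default_cohort)
        row = report["diet_summary"].set_index("metric").loc["me_pct"]
        wd = default_pipeline[default_pipeline.diet == "WD"].me_pct
        assert row.wd_mean == pytest.approx(wd.mean())
        assert row.wd_sem == pytest.approx(wd.sem())

    def test_summary_text_renders(self, default_cohort):
        text = sr.summary_text(sr.build_report(default_cohort))
        assert "me_pct" in text and "ccc" in text.lower()
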