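"""Statistics: summaries, contrasts, variance components, overlap measures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tractroi.roi_methods import Roi
from tractroi.stats import (
    compare_methods,
    interscan_variability,
    jaccard,
    normality_report,
    reliability_anova,
    section_summaries,
    simulate_method_table,
    simulate_reliability_table,
    startpoint_correct,
    startpoint_correct_table,
)


def _table(rows):
    return pd.DataFrame(rows)


class TestSectionSummaries:
    def _rows(self, values, method="m", section=1):
        rows = []
        for s, v in enumerate(values):
            rows.append({"subject": s, "method": method, "section": section,
                         "side": "left", "slice": 0, "fa": v})
        return rows

    def test_constant_values(self):
        out = section_summaries(_table(self._rows([0.5, 0.5, 0.5])))
        r = out.iloc[0]
        assert (r["mean"], r["sd"], r["cv_percent"]) == (0.5, 0.0, 0.0)

    def test_hand_computed_sd_and_cv(self):
        out = section_summaries(_table(self._rows([0.4, 0.5, 0.6])))
        r = out.iloc[0]
        assert r["mean"] == pytest.approx(0.5)
        assert r["sd"] == pytest.approx(0.1)
        assert r["cv_percent"] == pytest.approx(20.0)

    def test_sides_averaged_within_subject(self):
        rows = [
            {"subject": 0, "method": "m", "section": 1, "side": "left", "fa": 0.6},
            {"subject": 0, "method": "m", "section": 1, "side": "right", "fa": 0.8},
            {"subject": 1, "method": "m", "section": 1, "side": "left", "fa": 0.7},
            {"subject": 1, "method": "m", "section": 1, "side": "right", "fa": 0.7},
        ]
        out = section_summaries(_table(rows))
        assert out.iloc[0]["mean"] == pytest.approx(0.7)


class TestCompareMethods:
    def test_identical_methods_null(self):
        t = simulate_method_table(10, {"A": 0.5}, sigma_noise=0.01, seed=1)
        t2 = t.copy()
        t2["method"] = "B"
        out = compare_methods(pd.concat([t, t2], ignore_index=True))
        assert np.allclose(out["mean_difference"], 0.0)
        assert np.all(out["p_adjusted"] > 0.99)

    def test_known_offset_recovered(self):
        """Method B = A - 0.10 exactly: the estimate lands inside its CI
        around 0.10 for every section."""
        t = simulate_method_table(20, {"A": 0.5, "B": 0.4}, seed=2)
        out = compare_methods(t)
        for _, r in out.iterrows():
            sign = 1.0 if r["method_a"] == "A" else -1.0
            assert sign * r["mean_difference"] == pytest.approx(0.10, abs=0.02)
            assert r["ci_low"] <= r["mean_difference"] <= r["ci_high"]
            assert r["p_adjusted"] < 0.001

    def test_two_groups_reduce_to_unadjusted(self):
        """Tukey-Kramer over two groups degenerates to the plain paired test."""
        t = simulate_method_table(12, {"A": 0.5, "B": 0.45}, seed=3)
        out = compare_methods(t)
        assert np.allclose(out["p_adjusted"], out["p_unadjusted"], atol=1e-6)

    def test_single_method_rejected(self):
        t = simulate_method_table(5, {"A": 0.5}, seed=1)
        with pytest.raises(ValueError):
            compare_methods(t)


class TestReliabilityAnova:
    def test_no_noise_identical_raters(self):
        """With identical raters and no error the repeatability coefficient is
        zero and the limits of agreement collapse onto a zero mean difference."""
        rows = []
        rng = np.random.default_rng(0)
        subj = rng.uniform(0.4, 0.8, 8)
        for s in range(8):
            for r in range(2):
                for side in ("left", "right"):
                    rows.append({"subject": s, "rater": r, "side": side,
                                 "fa": subj[s]})
        vc = reliability_anova(_table(rows))
        assert vc.sigma2_error == pytest.approx(0.0, abs=1e-24)
        assert vc.repeatability_coefficient == pytest.approx(0.0, abs=1e-10)
        assert vc.mean_difference == pytest.approx(0.0, abs=1e-12)
        assert vc.limits_of_agreement[0] == pytest.approx(0.0, abs=1e-10)
        assert vc.limits_of_agreement[1] == pytest.approx(0.0, abs=1e-10)

    def test_repeatability_is_formula_of_error_term(self):
        """RC returned always equals 1.96 * sqrt(2) * sigma_error estimated."""
        t = simulate_reliability_table(50, 0.01, 0.001, 0.004, seed=4)
        vc = reliability_anova(t)
        assert vc.repeatability_coefficient == pytest.approx(
            1.96 * np.sqrt(2.0) * np.sqrt(vc.sigma2_error), rel=1e-12
        )

    def test_component_recovery(self):
        """Known variance components are recovered within 30 % at n = 200;
        the two-level factor's 1-df estimator is unbiased over replicates."""
        true = dict(sigma2_subject=0.010, sigma2_factor=0.002, sigma2_error=0.001)
        t = simulate_reliability_table(200, seed=5, **true)
        vc = reliability_anova(t)
        assert vc.sigma2_subject == pytest.approx(true["sigma2_subject"], rel=0.3)
        assert vc.sigma2_error == pytest.approx(true["sigma2_error"], rel=0.3)
        raws = [
            reliability_anova(
                simulate_reliability_table(200, seed=100 + r, **true)
            ).sigma2_raw["rater"]
            for r in range(150)
        ]
        assert np.mean(raws) == pytest.approx(true["sigma2_factor"], rel=0.3)

    def test_unbiased_across_component_grid(self):
        """Across a small grid of true components the raw estimators average
        to the truth within Monte-Carlo error."""
        for s2s, s2e in [(0.005, 0.001), (0.02, 0.004)]:
            est_s, est_e = [], []
            for r in range(20):
                vc = reliability_anova(simulate_reliability_table(
                    200, s2s, 0.001, s2e, seed=r))
                est_s.append(vc.sigma2_raw["subject"])
                est_e.append(vc.sigma2_raw["error"])
            assert np.mean(est_s) == pytest.approx(s2s, rel=0.2)
            assert np.mean(est_e) == pytest.approx(s2e, rel=0.2)

    def test_loa_uses_rater_interactions_and_error(self):
        t = simulate_reliability_table(
            100, 0.01, 0.002, 0.001,
            sigma2_interactions={"subject:factor": 0.003, "factor:side": 0.002},
            seed=6,
        )
        vc = reliability_anova(t)
        s2 = (vc.sigma2_interactions["subject:rater"]
              + vc.sigma2_interactions["rater:side"] + vc.sigma2_error)
        half = 1.96 * np.sqrt(2.0) * np.sqrt(s2)
        assert vc.limits_of_agreement[1] - vc.mean_difference == pytest.approx(half)
        vc_main = reliability_anova(t, include_main_effect=True)
        assert (vc_main.limits_of_agreement[1] - vc_main.mean_difference
                >= vc.limits_of_agreement[1] - vc.mean_difference)

    def test_structurally_missing_cell_rejected(self):
        t = simulate_reliability_table(10, 0.01, 0.001, 0.001, seed=7)
        with pytest.raises(ValueError, match="unbalanced"):
            reliability_anova(t[~((t.subject == 3) & (t.side == "left")
                                  & (t.rater == 1))])

    def test_missing_slice_drops_subject(self):
        """A NaN FA (missing slice in one rating) removes that subject from
        the balanced ANOVA instead of failing."""
        t = simulate_reliability_table(10, 0.01, 0.001, 0.001, seed=7)
        t.loc[(t.subject == 3) & (t.side == "left") & (t.rater == 1), "fa"] = np.nan
        full = reliability_anova(simulate_reliability_table(
            10, 0.01, 0.001, 0.001, seed=7))
        partial = reliability_anova(t)
        assert partial.sigma2_error != full.sigma2_error  # one subject fewer

    def test_duplicate_cell_rejected(self):
        t = simulate_reliability_table(5, 0.01, 0.001, 0.001, seed=8)
        with pytest.raises(ValueError, match="cell"):
            reliability_anova(pd.concat([t, t.iloc[:1]], ignore_index=True))


class TestInterscan:
    def _scan_table(self, sigma2_scan, sigma2_error, n_scans=6, seed=0):
        rng = np.random.default_rng(seed)
        scan_eff = rng.normal(0, np.sqrt(sigma2_scan), n_scans)
        rows = []
        for sc in range(n_scans):
            for side in ("left", "right"):
                rows.append({
                    "scan": sc, "side": side,
                    "fa": 0.6 + scan_eff[sc] + rng.normal(0, np.sqrt(sigma2_error)),
                })
        return _table(rows)

    def test_total_is_scan_plus_error(self):
        vc = interscan_variability(self._scan_table(0.002, 0.001, seed=1))
        assert vc.total_sigma2 == pytest.approx(
            vc.sigma2_factor + vc.sigma2_error
        )

    def test_interscan_exceeds_intrarater_in_expectation(self):
        """Scan effects add to the error term, so the mean estimated total
        inter-scan variance exceeds the pure error variance."""
        totals, errors = [], []
        for seed in range(100):
            vc = interscan_variability(self._scan_table(0.002, 0.001, seed=seed))
            totals.append(vc.total_sigma2)
            errors.append(vc.sigma2_error)
        assert np.mean(totals) > np.mean(errors)
        assert np.mean(totals) == pytest.approx(0.003, rel=0.4)


class TestStartpointCorrect:
    def _roi(self, start, n):
        return Roi("manual_b0", "left", start,
                   [[(6, start + i, 5)] for i in range(n)])

    def test_alignment_to_latest_start(self):
        a, b = startpoint_correct(self._roi(10, 8), self._roi(12, 8))
        assert a.start_slice == b.start_slice == 12
        assert a.n_slices == 6 and b.n_slices == 8

    def test_identity_for_identical_rois(self):
        r = self._roi(10, 8)
        a, b = startpoint_correct(r, r)
        assert a.start_slice == 10 and a.selections == r.selections

    def test_disjoint_rejected(self):
        with pytest.raises(ValueError, match="no coronal slice"):
            startpoint_correct(self._roi(2, 3), self._roi(10, 3))

    def test_table_repositioning(self):
        rows = []
        for rater, start in (("A", 10), ("B", 12)):
            for i in range(15):
                rows.append({"subject": 0, "method": "m", "side": "left",
                             "rater": rater, "slice": start + i,
                             "position": i + 1, "section": 1 + i // 5,
                             "fa": 0.5})
        out = startpoint_correct_table(_table(rows))
        assert out["slice"].min() == 12
        assert out.groupby("rater")["position"].min().tolist() == [1, 1]


class TestJaccard:
    def _roi(self, voxels, start):
        by_slice = {}
        for v in voxels:
            by_slice.setdefault(v[1], []).append(v)
        n = max(by_slice) - start + 1
        sels = [sorted(by_slice.get(start + i, [])) for i in range(n)]
        return Roi("manual_b0", "left", start, sels)

    def test_identical_is_one(self):
        r = self._roi([(6, 4, 5), (7, 5, 5)], 4)
        assert jaccard(r, r) == 1.0

    def test_disjoint_is_zero(self):
        a = self._roi([(6, 4, 5)], 4)
        b = self._roi([(8, 4, 5)], 4)
        assert jaccard(a, b) == 0.0

    def test_half_overlap(self):
        a = self._roi([(6, 4, 5), (6, 5, 5), (6, 6, 5)], 4)
        b = self._roi([(6, 5, 5), (6, 6, 5), (7, 6, 5)], 4)
        # A = {a,b,c}, B = {b,c,d}: 2 shared of 4 total
        assert jaccard(a, b) == pytest.approx(0.5)

    def test_restricted_to_common_slices(self):
        a = self._roi([(6, 4, 5), (6, 5, 5)], 4)
        b = self._roi([(6, 5, 5), (6, 6, 5)], 5)
        assert jaccard(a, b) == 1.0  # only slice 5 is shared by both ranges

    @settings(deadline=None, max_examples=30)
    @given(st.data())
    def test_symmetric_and_bounded(self, data):
        vox = st.tuples(st.integers(0, 3), st.integers(4, 7), st.integers(0, 3))
        a_v = data.draw(st.sets(vox, min_size=1, max_size=6))
        b_v = data.draw(st.sets(vox, min_size=1, max_size=6))
        a, b = self._roi(sorted(a_v), 4), self._roi(sorted(b_v), 4)
        jab, jba = jaccard(a, b), jaccard(b, a)
        assert jab == jba
        assert 0.0 <= jab <= 1.0


def test_normality_report_behaves():
    rng = np.random.default_rng(0)
    w, p = normality_report(rng.normal(size=200))
    assert 0.9 < w <= 1.0 and p > 0.001
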