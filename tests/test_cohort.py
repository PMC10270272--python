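"""Reference-standard labeling, ischemia criteria and diagnostic metrics."""

import numpy as np
import pytest

from cdgram.cohort import (CohortRecord, ReferenceStandard, confusion,
                           ecg_ischemia_call, evaluate_cohort, label_cad,
                           metrics, roc_auc, spearman_corr)
from cdgram.errors import SchemaError, TrainingError
from cdgram.synth import reference_cohort, confusion_rows

STD1 = ReferenceStandard(50, 0.8)


def _rec(band="25-49", ctffr=0.88, occluded=False):
    return CohortRecord("p", band, ctffr, occluded)


class TestLabeling:
    def test_negative_when_both_arms_clear(self):
        assert label_cad(_rec("25-49", 0.88), STD1) == "negative"

    def test_ctffr_arm_fires(self):
        assert label_cad(_rec("25-49", 0.74), STD1) == "positive"

    def test_occlusion_forces_ctffr_half(self):
        for k in range(1, 5):
            std = ReferenceStandard.by_number(k)
            assert label_cad(_rec("100", 0.95, occluded=True), std) == "positive"

    def test_stenosis_band_edges(self):
        assert label_cad(_rec("50-69", 0.95), STD1) == "positive"
        assert label_cad(_rec("50-69", 0.95), ReferenceStandard(70, 0.8)) == \
            "negative"

    def test_monotone_in_both_arms(self):
        """Lowering CT-FFR or raising stenosis never flips positive->negative."""
        bands = ("0", "1-24", "25-49", "50-69", "70-99", "100")
        for std_k in range(1, 5):
            std = ReferenceStandard.by_number(std_k)
            prev_by_ffr = None
            for ctffr in (0.95, 0.85, 0.75, 0.65, 0.3):
                calls = [label_cad(_rec(b, ctffr), std) == "positive"
                         for b in bands]
                assert calls == sorted(calls)  # monotone in stenosis
                if prev_by_ffr is not None:
                    assert all(not (p and not c)
                               for p, c in zip(prev_by_ffr, calls))
                prev_by_ffr = calls


class TestIschemiaCriteria:
    def test_male_v2v3_elevation(self):
        feats = {"V2": {"st_dev_mv": 0.20}, "V3": {"st_dev_mv": 0.20}}
        assert ecg_ischemia_call(feats, "male") == "positive"

    def test_sex_specific_v2v3_cut(self):
        feats = {"V2": {"st_dev_mv": 0.16}, "V3": {"st_dev_mv": 0.16}}
        assert ecg_ischemia_call(feats, "female") == "positive"
        assert ecg_ischemia_call(feats, "male") == "negative"

    def test_elevation_elsewhere_uses_tenth_mv(self):
        assert ecg_ischemia_call({"II": {"st_dev_mv": 0.11}}) == "positive"
        assert ecg_ischemia_call({"II": {"st_dev_mv": 0.08}}) == "negative"

    def test_depression_needs_two_adjacent_and_slope(self):
        down = {"st_dev_mv": -0.06, "st_slope": "down"}
        assert ecg_ischemia_call({"V4": down, "V5": dict(down)}) == "positive"
        assert ecg_ischemia_call({"V4": down, "V6": dict(down)}) == "negative"
        up = {"st_dev_mv": -0.06, "st_slope": "up"}
        assert ecg_ischemia_call({"V4": up, "V5": dict(up)}) == "negative"

    def test_t_inversion_needs_prominent_r(self):
        inv = {"t_amp_mv": -0.15, "r_amp_mv": 1.0, "s_amp_mv": -0.2}
        assert ecg_ischemia_call({"V4": inv, "V5": dict(inv)}) == "positive"
        small_r = {"t_amp_mv": -0.15, "r_amp_mv": 0.2, "s_amp_mv": -0.4}
        assert ecg_ischemia_call({"V4": small_r, "V5": dict(small_r)}) == \
            "negative"

    def test_all_quiet_is_negative(self):
        feats = {l: {"st_dev_mv": 0.0, "t_amp_mv": 0.2} for l in
                 ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")}
        assert ecg_ischemia_call(feats) == "negative"

    def test_unknown_lead_rejected(self):
        with pytest.raises(ValueError):
            ecg_ischemia_call({"V9": {"st_dev_mv": 1.0}})


class TestConfusionAndMetrics:
    def test_tiny_confusions(self):
        assert confusion(["positive", "negative"],
                         ["positive", "negative"]) == (1, 1, 0, 0)
        assert confusion(["positive"] * 4,
                         ["positive", "positive", "negative", "negative"]) == \
            (2, 0, 2, 0)
        with pytest.raises(SchemaError):
            confusion([1], [1, 0])

    def test_perfect_pair_scores_100(self):
        m = metrics(1, 1, 0, 0)
        assert (m.sensitivity, m.specificity, m.ppv, m.npv, m.accuracy) == \
            (100.0, 100.0, 100.0, 100.0, 100.0)

    def test_undefined_ratio_reported_missing(self):
        m = metrics(0, 5, 0, 0)
        assert m.sensitivity is None and m.ppv is None
        assert m.specificity == 100.0

    @pytest.mark.parametrize("key,expected", [
        (1, (75.60, 82.99, 79.38, 79.70, 79.56)),
        ("ecg", (38.10, 61.34, 46.04, 53.36, 50.55)),
        (4, (83.58, 78.95, 70.00, 89.11, 80.66)),
    ])
    def test_published_rows_reproduce(self, key, expected):
        tp, tn, fp, fn = confusion_rows()[key]
        m = metrics(tp, tn, fp, fn)
        got = (m.sensitivity, m.specificity, m.ppv, m.npv, m.accuracy)
        assert got == expected


class TestROC:
    def test_perfect_separation(self):
        auc, _ = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert auc == 1.0

    def test_constant_scores_give_half(self):
        auc, _ = roc_auc([5.0] * 8, [0, 1] * 4)
        assert auc == 0.5

    def test_matches_mann_whitney_oracle(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.8, 0.2, 0.55, 0.9, 0.15, 0.62,
                  0.5, 0.45, 0.7, 0.05, 0.3, 0.85, 0.25, 0.65, 0.75, 0.6]
        labels = [0, 0, 0, 1, 1, 0, 1, 1, 0, 1, 0, 0, 1, 0, 0, 1, 0, 1, 1, 1]
        auc, (lo, hi) = roc_auc(scores, labels)
        # brute-force normalized Mann-Whitney U with half credit for ties
        pos = [s for s, y in zip(scores, labels) if y]
        neg = [s for s, y in zip(scores, labels) if not y]
        u = sum(1.0 if p > q else 0.5 if p == q else 0.0
                for p in pos for q in neg)
        assert auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)
        assert 0.0 <= lo <= auc <= hi <= 1.0

    def test_bootstrap_ci_brackets_auc(self):
        rng = np.random.default_rng(0)
        scores = np.concatenate([rng.normal(0, 1, 40), rng.normal(1.5, 1, 40)])
        labels = [0] * 40 + [1] * 40
        auc, (lo, hi) = roc_auc(scores, labels, ci="bootstrap", seed=1)
        assert lo < auc < hi

    def test_single_class_rejected(self):
        with pytest.raises(TrainingError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestSpearman:
    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        rho, _ = spearman_corr(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(1000)
        y = rng.permutation(x)
        rho, _ = spearman_corr(x, y)
        assert abs(rho) < 0.08

    def test_tie_heavy_matches_rank_formula(self):
        from scipy.stats import rankdata

        x = [1, 2, 2, 2, 3, 3, 4, 5, 5, 6]
        y = [2, 1, 4, 4, 3, 6, 5, 7, 7, 9]
        rho, _ = spearman_corr(x, y)
        rx, ry = rankdata(x), rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_reported_missing(self):
        assert spearman_corr([1.0] * 5, [1, 2, 3, 4, 5]) == (None, None)


class TestReferenceCohort:
    def test_standard1_counts_from_fixture(self):
        df = reference_cohort()
        std = ReferenceStandard.by_number(1)
        truths = [label_cad(CohortRecord(r.subject_id, r.stenosis_band,
                                         r.ctffr, r.occluded), std)
                  for r in df.itertuples()]
        calls = ["positive" if v >= 0 else "negative" for v in df.cdg_value]
        assert confusion(calls, truths) == (127, 161, 33, 41)

    @pytest.mark.parametrize("std", [1, 2, 3, 4])
    def test_all_standards_reproduce_printed_counts(self, std):
        df = reference_cohort()
        report = evaluate_cohort(df, standard=std)
        tp, tn, fp, fn = confusion_rows()[std]
        assert (report["tp"], report["tn"], report["fp"], report["fn"]) == \
            (tp, tn, fp, fn)
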