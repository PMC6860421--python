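"""ROC curve, AUC/U identity, Youden cut-off and fixed-cut-off classifier."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from foveaq.roc import (
    auc_confidence_interval,
    classify_at_cutoff,
    roc_curve,
    youden_cutoff,
)


def brute_force_youden(scores, labels):
    """Oracle: exhaustive scan over all candidate thresholds by counting.

    J is piecewise-constant between consecutive observed scores, so scanning
    every midpoint (plus outer sentinels) is equivalent to an arbitrarily
    fine grid.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    u = np.unique(scores)
    candidates = [u[0] - 1.0] + [(x + y) / 2 for x, y in zip(u[:-1], u[1:])] + [u[-1] + 1.0]
    best = (-np.inf, -np.inf, np.inf)  # (J, sens, -threshold) maximised
    for th in candidates:
        sens = np.mean(scores[labels] < th)
        spec = np.mean(scores[~labels] >= th)
        j = sens + spec - 1.0
        key = (round(j, 12), sens, -th)
        if key > best:
            best = key
    return -best[2], best[0]


class TestRocCurve:
    def test_perfect_separation(self):
        res = roc_curve([0.6, 0.65, 0.8, 0.9], [True, True, False, False])
        assert res.auc == pytest.approx(1.0)
        # curve passes through (FPR 0, sens 1)
        hit = (res.sensitivity == 1.0) & (res.specificity == 1.0)
        assert hit.any()

    def test_identical_scores_uninformative(self):
        res = roc_curve([0.5] * 6, [True] * 3 + [False] * 3)
        assert res.auc == pytest.approx(0.5)

    def test_single_class_is_error(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve([1.0, 2.0], [True, True])

    def test_auc_equals_one_minus_u_over_n1n2(self, rng):
        """Tie-free algebraic identity AUC = 1 - U/(n_pos * n_neg)."""
        for _ in range(50):
            pos = rng.normal(0.7, 0.05, size=13)
            neg = rng.normal(0.9, 0.08, size=10)
            res = roc_curve(
                np.concatenate([pos, neg]), np.r_[np.ones(13), np.zeros(10)].astype(bool)
            )
            u = sps.mannwhitneyu(pos, neg, alternative="two-sided").statistic
            assert res.auc == pytest.approx(1.0 - u / 130.0, abs=1e-12)

    def test_auc_against_reference_implementation(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=200)
        labels = rng.random(200) < 0.4
        labels[:2] = [True, False]
        res = roc_curve(scores, labels)
        # positive test = low score, so the reference needs negated scores
        assert res.auc == pytest.approx(roc_auc_score(labels, -scores), abs=1e-12)

    def test_label_flip_antisymmetry(self, rng):
        scores = rng.normal(size=40)
        labels = np.r_[np.ones(18), np.zeros(22)].astype(bool)
        auc = roc_curve(scores, labels).auc
        auc_flipped = roc_curve(-scores, ~labels).auc
        assert auc + (1.0 - auc_flipped) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_threshold_sweep(self, rng):
        scores = rng.normal(size=30)
        labels = np.r_[np.ones(12), np.zeros(18)].astype(bool)
        res = roc_curve(scores, labels)
        order = np.argsort(res.thresholds)
        assert np.all(np.diff(res.sensitivity[order]) >= 0)
        assert np.all(np.diff(res.specificity[order]) <= 0)


class TestAucConfidenceInterval:
    def test_perfect_separation_upper_clipped(self):
        lo, hi = auc_confidence_interval(1.0, 5, 5)
        assert hi == 1.0 and lo <= 1.0

    def test_symmetric_about_half(self):
        lo, hi = auc_confidence_interval(0.5, 20, 20)
        assert lo + hi == pytest.approx(1.0)

    def test_interval_contains_point_estimate(self):
        lo, hi = auc_confidence_interval(0.892, 13, 10)
        assert lo <= 0.892 <= hi
        assert 0.0 <= lo and hi <= 1.0


class TestYoudenCutoff:
    def test_midpoint_between_separated_groups(self):
        cutoff, j = youden_cutoff(
            [0.60, 0.65, 0.80, 0.90], [True, True, False, False]
        )
        assert cutoff == pytest.approx(0.725)
        assert j == pytest.approx(1.0)

    def test_complete_overlap_zero_j(self):
        cutoff, j = youden_cutoff([1, 2, 3, 1, 2, 3], [True] * 3 + [False] * 3)
        assert j == pytest.approx(0.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(300):
            n_pos, n_neg = rng.integers(3, 12), rng.integers(3, 12)
            scores = np.round(rng.normal(0.8, 0.1, size=n_pos + n_neg), 3)
            labels = np.r_[np.ones(n_pos), np.zeros(n_neg)].astype(bool)
            cutoff, j = youden_cutoff(scores, labels)
            cutoff_oracle, j_oracle = brute_force_youden(scores, labels)
            assert j == pytest.approx(j_oracle, abs=1e-12)
            if scores.min() < cutoff_oracle < scores.max():
                # interior optimum: both scans share the midpoint candidates
                # (sentinel placement below/above the data range may differ)
                assert cutoff == pytest.approx(cutoff_oracle, abs=1e-9)


class TestClassifyAtCutoff:
    def _table(self, alb, non):
        rows = [
            {"patient_id": f"a{i}", "group": "albinism_fh", "gcl_quotient_II": v}
            for i, v in enumerate(alb)
        ] + [
            {"patient_id": f"n{i}", "group": "non_albinism_fh", "gcl_quotient_II": v}
            for i, v in enumerate(non)
        ]
        return pd.DataFrame(rows)

    def test_published_examples(self):
        table = self._table([0.6667], [0.8887])
        rep = classify_at_cutoff(table, 0.7169)
        assert list(rep.predictions["predicted"]) == ["albinism_fh", "non_albinism_fh"]
        assert rep.tp == 1 and rep.tn == 1

    def test_equality_goes_to_non_albinism(self):
        rep = classify_at_cutoff(self._table([0.7169], [0.9]), 0.7169)
        assert rep.predictions["predicted"][0] == "non_albinism_fh"
        assert rep.fn == 1

    def test_counts_and_rates_consistent(self, quotient_table):
        rep = classify_at_cutoff(quotient_table, 0.7169, "II")
        n_two_class = (
            quotient_table["group"].isin(["albinism_fh", "non_albinism_fh"]).sum()
        )
        assert rep.tp + rep.fp + rep.tn + rep.fn == n_two_class
        assert rep.sensitivity == pytest.approx(rep.tp / (rep.tp + rep.fn))
        assert rep.specificity == pytest.approx(rep.tn / (rep.tn + rep.fp))

    def test_both_orientations_reported(self, quotient_table):
        rep = classify_at_cutoff(quotient_table, 0.7169, "II")
        assert rep.published_wording["printed_specificity"] == rep.sensitivity
        assert rep.published_wording["printed_sensitivity"] == rep.specificity

    def test_missing_quotients_rejected_with_report(self):
        table = self._table([0.66, np.nan], [0.9])
        rep = classify_at_cutoff(table, 0.7169)
        assert len(rep.rejected) == 1
        assert rep.tp + rep.fp + rep.tn + rep.fn == 2

    def test_invalid_cutoff(self, quotient_table):
        with pytest.raises(ValueError, match="cutoff"):
            classify_at_cutoff(quotient_table, -1.0)
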