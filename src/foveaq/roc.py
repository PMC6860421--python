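"""ROC analysis and the fixed-cut-off albinism classifier.

Two-class task: albinism FH (positive class) versus non-albinism FH, scored
by a temporal/nasal thickness quotient.  Albinism thins the temporal ganglion
cell layer, so the test is *positive when the quotient is below the
threshold* (strict "<"; a value exactly at the cut-off is called
non-albinism).

Candidate thresholds are midpoints between consecutive distinct observed
scores plus outer sentinels — the published cut-offs are not observed
values, consistent with this convention.  The optimal cut-off maximises the
Youden index J = sensitivity + specificity - 1, ties broken by higher
sensitivity, then by the lower threshold.  The AUC is trapezoidal, with the
95% CI from the Hanley-McNeil nonparametric standard error, clipped to
[0, 1].

Note on orientation: with sensitivity defined on the positive (albinism)
class, the reference study's printed "specificity 84.6% / sensitivity
100.0%" corresponds to sensitivity 84.6% (11/13 albinism patients below the
cut-off) and specificity 100.0% (10/10 non-albinism above) — the printed
wording swaps the two names relative to the standard convention.
:class:`ClassificationReport` therefore carries both group-wise rates
explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RocResult",
    "ClassificationReport",
    "roc_curve",
    "auc_confidence_interval",
    "youden_cutoff",
    "classify_at_cutoff",
]

ORIENTATION_NOTE = "positive = albinism; test positive <=> score < threshold"


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci_95: tuple[float, float]
    optimal_cutoff: float
    youden_j: float
    n_pos: int
    n_neg: int
    orientation: str = ORIENTATION_NOTE


@dataclass
class ClassificationReport:
    cutoff: float
    quotient_kind: str
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float  # albinism-correct rate, TP / (TP + FN)
    specificity: float  # non-albinism-correct rate, TN / (TN + FP)
    predictions: pd.DataFrame
    rejected: list = field(default_factory=list)
    orientation: str = ORIENTATION_NOTE
    #: the same two rates under the reference study's swapped naming
    published_wording: dict = field(default_factory=dict)


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.all() or not labels.any():
        raise ValueError("ROC analysis needs both classes present")


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0
    span = max(u[-1] - u[0], 1.0)
    return np.concatenate([[u[0] - 0.01 * span], mids, [u[-1] + 0.01 * span]])


def _rates(scores: np.ndarray, labels: np.ndarray, thresholds: np.ndarray):
    pos = scores[labels]
    neg = scores[~labels]
    sens = (pos[None, :] < thresholds[:, None]).mean(axis=1)
    spec = (neg[None, :] >= thresholds[:, None]).mean(axis=1)
    return sens, spec


def roc_curve(scores, labels) -> RocResult:
    """Empirical ROC of the "positive = below threshold" diagnostic rule.

    ``labels`` is boolean (True = albinism).  Returns the full threshold
    table together with the trapezoidal AUC, its Hanley-McNeil 95% CI and
    the Youden-optimal cut-off.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    _check_two_classes(labels)
    thresholds = _candidate_thresholds(scores)
    sens, spec = _rates(scores, labels, thresholds)

    # integrate sensitivity over FPR (both monotone in the threshold sweep)
    fpr = 1.0 - spec
    order = np.argsort(fpr, kind="stable")
    auc = float(np.trapezoid(sens[order], fpr[order]))
    # account for ties between classes: trapezoid over distinct FPR already
    # credits half the tied mass because sens/spec move simultaneously.
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    ci = auc_confidence_interval(auc, n_pos, n_neg)
    cutoff, j = youden_cutoff(scores, labels)
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_ci_95=ci,
        optimal_cutoff=cutoff,
        youden_j=j,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def auc_confidence_interval(
    auc: float, n_pos: int, n_neg: int, level: float = 0.95
) -> tuple[float, float]:
    """Hanley-McNeil nonparametric CI for an empirical AUC, clipped to [0,1]."""
    a = float(auc)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    z = float(sps.norm.ppf(0.5 + level / 2.0))
    return (max(0.0, a - z * se), min(1.0, a + z * se))


def youden_cutoff(scores, labels) -> tuple[float, float]:
    """Cut-off maximising J = sensitivity + specificity - 1.

    Candidates are midpoints of consecutive distinct scores plus outer
    sentinels; ties in J are broken by higher sensitivity, then by the lower
    threshold.  Returns ``(cutoff, J)`` at full precision.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    _check_two_classes(labels)
    thresholds = _candidate_thresholds(scores)
    sens, spec = _rates(scores, labels, thresholds)
    j = sens + spec - 1.0
    best = np.lexsort((thresholds, -sens, -np.round(j, 15)))[0]
    return float(thresholds[best]), float(j[best])


def classify_at_cutoff(
    quotients: pd.DataFrame,
    cutoff: float,
    quotient_kind: str = "II",
    layer: str = "gcl",
) -> ClassificationReport:
    """Apply the fixed diagnostic cut-off to a patient quotient table.

    Only the two-class task is evaluated: albinism FH vs non-albinism FH
    (healthy rows are ignored).  Label albinism iff quotient < cutoff
    (strict; equality is called non-albinism).  Rows with a missing quotient
    are rejected and reported, not silently dropped.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    col = f"{layer}_quotient_{quotient_kind}"
    if col not in quotients.columns:
        raise ValueError(f"quotient column {col!r} not present")
    sub = quotients[quotients["group"].isin(["albinism_fh", "non_albinism_fh"])]
    rejected = [
        {"patient_id": r["patient_id"], "reason": f"missing {col}"}
        for _, r in sub[sub[col].isna()].iterrows()
    ]
    sub = sub.dropna(subset=[col])
    is_pos = (sub["group"] == "albinism_fh").to_numpy()
    pred_pos = (sub[col] < cutoff).to_numpy()
    tp = int((pred_pos & is_pos).sum())
    fp = int((pred_pos & ~is_pos).sum())
    tn = int((~pred_pos & ~is_pos).sum())
    fn = int((~pred_pos & is_pos).sum())
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    preds = pd.DataFrame(
        {
            "patient_id": sub["patient_id"].to_numpy(),
            "group": sub["group"].to_numpy(),
            "quotient": sub[col].to_numpy(),
            "predicted": np.where(pred_pos, "albinism_fh", "non_albinism_fh"),
        }
    )
    return ClassificationReport(
        cutoff=float(cutoff),
        quotient_kind=quotient_kind,
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=float(sens),
        specificity=float(spec),
        predictions=preds,
        rejected=rejected,
        published_wording={
            "printed_specificity": float(sens),
            "printed_sensitivity": float(spec),
        },
    )
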