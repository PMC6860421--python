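"""Temporal/nasal thickness quotients — the primary diagnostic endpoints.

For each patient the parafoveal and perifoveal quotients are

    quotient I  = temporal I  / nasal I
    quotient II = temporal II / nasal II

computed on eye-averaged subfield thicknesses (the mean of the left and
right eye where both were scanned).  Because the two eyes of a patient are
statistically dependent, the patient — not the eye — is the unit of
analysis everywhere downstream.

The order of averaging and ratio formation is ambiguous in principle
(quotient of mean thicknesses vs mean of per-eye quotients); the default is
average-then-divide, the alternative is available via ``order`` and the
absolute discrepancy between the two is reported per patient as a
diagnostic column ``<layer>_q<kind>_order_gap``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .profiles import LAYERS, SUBFIELDS

__all__ = [
    "QuotientError",
    "patient_average",
    "layer_quotient",
    "compute_patient_quotients",
]

QUOTIENT_PAIRS = {"I": ("tI", "nI"), "II": ("tII", "nII")}


class QuotientError(ValueError):
    """Invalid input to quotient computation (e.g. non-positive nasal thickness)."""


def patient_average(eyes: pd.DataFrame, layers=LAYERS) -> pd.Series:
    """Eye-averaged subfield vector for one patient (1 or 2 eyes)."""
    if len(eyes) == 0:
        raise QuotientError("patient has zero eyes")
    if len(eyes) > 2:
        raise QuotientError(f"patient has {len(eyes)} eye records; at most 2 expected")
    if eyes["patient_id"].nunique() != 1:
        raise QuotientError(f"mismatched patient ids: {sorted(eyes['patient_id'].unique())}")
    cols = [f"{layer}_{sf}" for layer in layers for sf in SUBFIELDS]
    out = eyes[cols].mean(axis=0)
    out["eye_count"] = len(eyes)
    return out


def layer_quotient(temporal_um: float, nasal_um: float) -> float:
    """temporal / nasal thickness ratio; nasal must be strictly positive."""
    if nasal_um <= 0:
        raise QuotientError(f"nasal thickness must be > 0, got {nasal_um}")
    return float(temporal_um) / float(nasal_um)


def compute_patient_quotients(
    cohort: pd.DataFrame,
    layers=("gcl",),
    order: str = "average_first",
) -> pd.DataFrame:
    """Per-patient quotient table from a per-eye cohort table.

    One row per patient with eye-averaged subfield thicknesses, the I/II
    quotients per requested layer, and the averaging-order diagnostic.
    Rows whose quotients cannot be formed (non-positive nasal thickness) are
    dropped and reported in the frame's ``attrs["rejected"]``.

    Quotients are scale invariant: multiplying all of a patient's
    thicknesses by k > 0 leaves every quotient unchanged.
    """
    if order not in ("average_first", "quotient_first"):
        raise ValueError(f"unknown averaging order {order!r}")
    cols = [f"{layer}_{sf}" for layer in layers for sf in SUBFIELDS]
    grouped = cohort.groupby(["patient_id", "group"], sort=False)
    counts = grouped.size()
    if (counts > 2).any():
        bad = counts[counts > 2].index[0][0]
        raise QuotientError(f"patient {bad!r} has more than 2 eye records")
    avg = grouped[cols].mean()
    out = avg.reset_index()
    out.insert(2, "eye_count", counts.to_numpy())

    rejected = []
    keep = np.ones(len(out), dtype=bool)
    for layer in layers:
        for kind, (t_sf, n_sf) in QUOTIENT_PAIRS.items():
            nas_avg = out[f"{layer}_{n_sf}"].to_numpy()
            tem_avg = out[f"{layer}_{t_sf}"].to_numpy()
            bad = nas_avg <= 0
            # per-eye quotients for the averaging-order diagnostic
            nas_eye = cohort[f"{layer}_{n_sf}"].to_numpy()
            tem_eye = cohort[f"{layer}_{t_sf}"].to_numpy()
            with np.errstate(divide="ignore", invalid="ignore"):
                per_eye = pd.Series(
                    np.where(nas_eye > 0, tem_eye / nas_eye, np.nan), index=cohort.index
                )
                q_eye_mean = (
                    per_eye.groupby([cohort["patient_id"], cohort["group"]], sort=False)
                    .mean()
                    .to_numpy()
                )
                q_avg_first = np.where(bad, np.nan, tem_avg / np.where(bad, 1.0, nas_avg))
            bad |= np.isnan(q_eye_mean)
            out[f"{layer}_quotient_{kind}"] = (
                q_avg_first if order == "average_first" else q_eye_mean
            )
            out[f"{layer}_q{kind}_order_gap"] = np.abs(q_avg_first - q_eye_mean)
            keep &= ~bad
            for i in np.nonzero(bad)[0]:
                rejected.append(
                    {
                        "patient_id": out.at[i, "patient_id"],
                        "group": out.at[i, "group"],
                        "reason": f"non-positive nasal thickness for {layer} quotient {kind}",
                    }
                )
    out = out[keep].reset_index(drop=True)
    out.attrs["rejected"] = rejected
    return out
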