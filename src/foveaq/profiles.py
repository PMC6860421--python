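"""Generative group profiles for the three study cohorts.

A :class:`GroupProfile` holds everything the synthetic cohort generator needs
for one group: per-layer, per-ETDRS-subfield thickness means and SDs, and the
calibration targets of the two temporal/nasal quotient distributions
(parafoveal "I" and perifoveal "II").

The defaults encode the reference clinical cohort this package models:
15 healthy controls, 10 patients with non-albinism foveal hypoplasia (FH) and
13 with albinism FH.  Ganglion-cell-layer (GCL) means/SDs on the horizontal
meridian and the quotient medians/IQRs are the published group summaries;
superior/inferior GCL and the INL/ONL layers are realistic fill-in values
(see docs/methods.md) and carry no acceptance weight.

Quotient calibration ties the latent distributions to the published
classification behaviour at the fixed diagnostic cut-offs (0.7995 for
quotient I, 0.7169 for quotient II):

* albinism: 11/13 of the mass lies below the cut-off (a truncated-normal
  bulk re-fitted to the printed median/IQR), 2/13 lies in a uniform
  contamination band above it whose width is solved so that the distribution
  mean equals the printed temporal/nasal mean ratio;
* non-albinism quotient II: truncated above the cut-off (10/10 classified
  correctly);
* non-albinism quotient I: a 1/10 near-miss uniform band of width 0.10 just
  below the cut-off (9/10 correct);
* healthy: plain normal (healthy controls are not part of the two-class
  classification task).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .calibration import (
    CalibrationError,
    NormalComponent,
    QuotientModel,
    TruncatedNormalComponent,
    UniformComponent,
    fit_quantile_normal,
    fit_truncated_quantiles,
)

__all__ = [
    "GROUPS",
    "LAYERS",
    "SUBFIELDS",
    "REFERENCE_CUTOFFS",
    "QuotientCalibration",
    "GroupProfile",
    "default_profiles",
    "build_quotient_model",
]

GROUPS = ("healthy", "non_albinism_fh", "albinism_fh")
LAYERS = ("gcl", "inl", "onl")
#: canonical subfield order: central, inner (parafoveal) ring, outer
#: (perifoveal) ring; n/t/s/i = nasal/temporal/superior/inferior.
SUBFIELDS = ("c", "nI", "tI", "sI", "iI", "nII", "tII", "sII", "iII")

#: published Youden-optimal diagnostic cut-offs (albinism below, strict)
REFERENCE_CUTOFFS = {"I": 0.7995, "II": 0.7169}


@dataclass(frozen=True)
class QuotientCalibration:
    """Targets for one latent quotient distribution.

    ``contamination`` is the probability mass placed on the "wrong" side of
    ``cutoff`` (the side named by ``contamination_side``); ``mean_target``,
    when given, pins the distribution mean (used to solve the contamination
    band width); ``contamination_width`` fixes the band width directly.
    ``truncation`` bounds the bulk component.
    """

    median: float
    q1: float
    q3: float
    truncation: tuple[float, float] | None = None
    cutoff: float | None = None
    contamination: float = 0.0
    contamination_side: str = "above"  # side of `cutoff` the contamination sits on
    mean_target: float | None = None
    contamination_width: float | None = None

    def __post_init__(self):
        if not (self.q1 <= self.median <= self.q3):
            raise CalibrationError(
                f"quantile ordering violated: q1={self.q1}, median={self.median}, q3={self.q3}"
            )
        if not (0.0 <= self.contamination <= 1.0):
            raise CalibrationError(f"contamination must be in [0,1], got {self.contamination}")
        if self.contamination > 0 and self.cutoff is None:
            raise CalibrationError("contamination requires a reference cutoff")
        if self.contamination_side not in ("above", "below"):
            raise CalibrationError(f"unknown contamination side {self.contamination_side!r}")


@dataclass(frozen=True)
class GroupProfile:
    """Generative parameters for one study group."""

    group: str
    subfield_mean: dict  # layer -> subfield -> um
    subfield_sd: dict  # layer -> subfield -> um
    quotients: dict  # "I" / "II" -> QuotientCalibration

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        for layer in LAYERS:
            for sf in SUBFIELDS:
                m = self.subfield_mean[layer][sf]
                s = self.subfield_sd[layer][sf]
                if m <= 0:
                    raise ValueError(f"{self.group}: mean must be > 0 for {layer}/{sf}, got {m}")
                if s < 0:
                    raise ValueError(f"{self.group}: sd must be >= 0 for {layer}/{sf}, got {s}")


def _means(c, nI, tI, sI, iI, nII, tII, sII, iII):
    return dict(zip(SUBFIELDS, (c, nI, tI, sI, iI, nII, tII, sII, iII)))


def default_profiles() -> dict[str, GroupProfile]:
    """The calibrated defaults reproducing the reference cohort summaries."""
    healthy = GroupProfile(
        group="healthy",
        subfield_mean={
            "gcl": _means(14.53, 50.9, 47.1, 49.5, 49.0, 37.93, 35.27, 33.5, 32.5),
            "inl": _means(18.0, 40.0, 38.5, 39.5, 39.0, 32.5, 31.0, 32.0, 31.5),
            "onl": _means(93.0, 72.0, 70.0, 71.0, 70.5, 57.0, 55.5, 56.0, 55.5),
        },
        subfield_sd={
            "gcl": _means(3.73, 5.24, 3.76, 4.5, 4.5, 3.23, 3.05, 3.0, 3.0),
            "inl": _means(3.0, 3.5, 3.5, 3.5, 3.5, 3.0, 3.0, 3.0, 3.0),
            "onl": _means(8.0, 6.0, 6.0, 6.0, 6.0, 5.0, 5.0, 5.0, 5.0),
        },
        quotients={
            "I": QuotientCalibration(0.9159, 0.9035, 0.9667),
            "II": QuotientCalibration(0.9452, 0.8642, 0.9765),
        },
    )
    non_albinism = GroupProfile(
        group="non_albinism_fh",
        subfield_mean={
            "gcl": _means(27.75, 41.40, 36.25, 40.0, 39.0, 31.35, 27.50, 28.0, 27.0),
            "inl": _means(30.0, 38.0, 36.5, 37.5, 37.0, 31.0, 29.5, 30.5, 30.0),
            "onl": _means(88.0, 70.0, 68.0, 69.0, 68.5, 56.0, 54.5, 55.0, 54.5),
        },
        subfield_sd={
            "gcl": _means(11.00, 15.30, 12.34, 12.0, 12.0, 8.10, 5.93, 6.0, 6.0),
            "inl": _means(8.0, 7.0, 7.0, 7.0, 7.0, 5.0, 5.0, 5.0, 5.0),
            "onl": _means(12.0, 9.0, 9.0, 9.0, 9.0, 7.0, 7.0, 7.0, 7.0),
        },
        quotients={
            "I": QuotientCalibration(
                0.8759, 0.8234, 0.9500,
                truncation=(REFERENCE_CUTOFFS["I"], np.inf),
                cutoff=REFERENCE_CUTOFFS["I"],
                contamination=1.0 / 10.0,
                contamination_side="below",
                contamination_width=0.10,
            ),
            "II": QuotientCalibration(
                0.8887, 0.7999, 0.9695,
                truncation=(REFERENCE_CUTOFFS["II"], np.inf),
                cutoff=REFERENCE_CUTOFFS["II"],
            ),
        },
    )
    albinism = GroupProfile(
        group="albinism_fh",
        subfield_mean={
            "gcl": _means(38.50, 48.58, 35.2, 44.0, 43.0, 38.27, 26.92, 30.0, 29.0),
            "inl": _means(35.0, 39.0, 36.0, 38.0, 37.5, 31.5, 29.0, 30.5, 30.0),
            "onl": _means(90.0, 71.0, 69.0, 70.0, 69.5, 56.5, 55.0, 55.5, 55.0),
        },
        subfield_sd={
            "gcl": _means(4.67, 2.79, 3.52, 3.5, 3.5, 4.15, 1.90, 3.0, 3.0),
            "inl": _means(5.0, 4.0, 4.0, 4.0, 4.0, 3.5, 3.5, 3.5, 3.5),
            "onl": _means(9.0, 7.0, 7.0, 7.0, 7.0, 6.0, 6.0, 6.0, 6.0),
        },
        quotients={
            "I": QuotientCalibration(
                0.7087, 0.6766, 0.7645,
                truncation=(0.0, REFERENCE_CUTOFFS["I"]),
                cutoff=REFERENCE_CUTOFFS["I"],
                contamination=2.0 / 13.0,
                contamination_side="above",
                mean_target=35.2 / 48.58,
            ),
            "II": QuotientCalibration(
                0.6667, 0.6562, 0.7085,
                truncation=(0.0, REFERENCE_CUTOFFS["II"]),
                cutoff=REFERENCE_CUTOFFS["II"],
                contamination=2.0 / 13.0,
                contamination_side="above",
                mean_target=26.92 / 38.27,
            ),
        },
    )
    return {p.group: p for p in (healthy, non_albinism, albinism)}


@lru_cache(maxsize=None)
def build_quotient_model(calib: QuotientCalibration, label: str = "") -> QuotientModel:
    """Turn calibration targets into a samplable mixture distribution.

    The bulk component is fitted so that the *mixture* median equals the
    target median exactly (quantile probabilities are re-weighted for the
    contamination mass); the quartiles are matched in least squares.  The
    contamination band, when present, is uniform and adjacent to the cut-off;
    its width comes from ``contamination_width`` or is solved so the mixture
    mean hits ``mean_target``.
    """
    c = calib.contamination
    if c == 0.0 and calib.truncation is None:
        mu, sigma = fit_quantile_normal(calib.median, calib.q1, calib.q3, label)
        return QuotientModel((NormalComponent(mu, sigma),), (1.0,), label=label)

    lo, hi = calib.truncation if calib.truncation is not None else (-np.inf, np.inf)
    # map mixture quartile levels to bulk-component levels
    if calib.contamination_side == "above":
        probs = tuple(p / (1.0 - c) for p in (0.25, 0.5, 0.75))
    else:
        probs = tuple((p - c) / (1.0 - c) for p in (0.25, 0.5, 0.75))
        if probs[0] <= 0:
            raise CalibrationError(
                f"contamination {c} on the lower side exceeds the first quartile level"
            )
    mu, sigma, resid = fit_truncated_quantiles(
        (calib.q1, calib.median, calib.q3), probs, (lo, hi)
    )
    bulk = TruncatedNormalComponent(mu, sigma, lo, hi)

    if c == 0.0:
        return QuotientModel((bulk,), (1.0,), label=label, fit_residuals=tuple(resid))

    width = calib.contamination_width
    if width is None:
        if calib.mean_target is None:
            raise CalibrationError(
                f"{label or 'calibration'}: contamination needs a width or a mean target"
            )
        # solve E_mix = (1-c) E_bulk + c E_band for the band centre
        e_band = (calib.mean_target - (1.0 - c) * bulk.mean()) / c
        if calib.contamination_side == "above":
            width = 2.0 * (e_band - calib.cutoff)
        else:
            width = 2.0 * (calib.cutoff - e_band)
        if width <= 0:
            raise CalibrationError(
                f"{label or 'calibration'}: mean target {calib.mean_target} is not "
                f"reachable with contamination on the {calib.contamination_side} side "
                f"of {calib.cutoff} (bulk mean {bulk.mean():.4f})"
            )

    if calib.contamination_side == "above":
        band = UniformComponent(calib.cutoff, calib.cutoff + width)
        comps, weights = (bulk, band), (1.0 - c, c)
    else:
        band = UniformComponent(calib.cutoff - width, calib.cutoff)
        comps, weights = (band, bulk), (c, 1.0 - c)
    return QuotientModel(comps, weights, label=label, fit_residuals=tuple(resid))
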