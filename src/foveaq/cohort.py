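"""Synthetic OCT cohort generation.

Generates per-eye ETDRS subfield thickness tables (and optional en-face
thickness maps) for the three study groups, with the statistical structure
of the reference cohort: bilateral eyes with configurable inter-eye
correlation, group-specific subfield means/SDs, and latent per-patient
temporal/nasal quotients drawn from the calibrated mixture distributions of
:mod:`foveaq.profiles`.

Sampling is two-level: a patient-level latent subfield vector (variance
share ``rho`` of the total) plus eye-level jitter (share ``1 - rho``).  The
patient's GCL temporal subfields are then rescaled so that the eye-averaged
temporal/nasal quotient equals the latent quotient draw *exactly* — this
decouples quotient-level behaviour from subfield noise.  Both quotient kinds
of a patient are driven by one shared uniform (comonotone coupling), so the
atypical albinism patients are atypical on both rings, as in the reference
cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .etdrs import NODATA, ThicknessMap, subfield_masks
from .profiles import (
    GROUPS,
    LAYERS,
    SUBFIELDS,
    GroupProfile,
    QuotientModel,
    build_quotient_model,
    default_profiles,
)

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "generate_thickness_map",
    "write_cohort_csv",
    "read_cohort_csv",
    "COHORT_COLUMNS",
]

_GROUP_INDEX = {g: i for i, g in enumerate(GROUPS)}

#: empirical eye-level metadata frequencies of the reference cohort
_METADATA_FREQS = {
    "healthy": {"fh_grades": {0: 1.0}, "nystagmus": 0.0, "fundus_hypopigmentation": 0.0},
    "non_albinism_fh": {
        "fh_grades": {1: 2 / 18, 2: 11 / 18, 3: 3 / 18, 4: 2 / 18},
        "nystagmus": 4 / 18,
        "fundus_hypopigmentation": 6 / 18,
    },
    "albinism_fh": {
        "fh_grades": {3: 23 / 26, 4: 3 / 26},
        "nystagmus": 16 / 26,
        "fundus_hypopigmentation": 24 / 26,
    },
}

THICKNESS_COLUMNS = [f"{layer}_{sf}" for layer in LAYERS for sf in SUBFIELDS]
COHORT_COLUMNS = (
    ["patient_id", "group", "eye"]
    + THICKNESS_COLUMNS
    + ["fh_grade", "nystagmus", "fundus_hypopigmentation"]
)

_MIN_THICKNESS_UM = 0.5
_MAX_RETRIES = 100


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition; defaults reproduce the reference study cohort."""

    n_patients: dict = field(
        default_factory=lambda: {"healthy": 15, "non_albinism_fh": 10, "albinism_fh": 13}
    )
    unilateral_patients: dict = field(
        default_factory=lambda: {"healthy": 0, "non_albinism_fh": 2, "albinism_fh": 0}
    )
    inter_eye_correlation: float = 0.9
    seed: int = 0

    def __post_init__(self):
        for g, n in self.n_patients.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 0:
                raise ValueError(f"n_patients must be >= 0, got {n} for {g}")
        for g, n in self.unilateral_patients.items():
            if n > self.n_patients.get(g, 0):
                raise ValueError(f"more unilateral than total patients in {g}")
        if not (0.0 <= self.inter_eye_correlation <= 1.0):
            raise ValueError("inter_eye_correlation must be in [0, 1]")

    @property
    def n_eyes(self) -> int:
        return sum(
            2 * n - self.unilateral_patients.get(g, 0) for g, n in self.n_patients.items()
        )


def _build_models(profiles: dict[str, GroupProfile]) -> dict[str, dict[str, QuotientModel]]:
    return {
        g: {k: build_quotient_model(p.quotients[k], label=f"{g}/quotient {k}") for k in ("I", "II")}
        for g, p in profiles.items()
    }


def generate_cohort(
    spec: CohortSpec | None = None,
    profiles: dict[str, GroupProfile] | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one synthetic cohort.

    Returns ``(eyes, latent)``: one row per eye with all layer/subfield
    thicknesses and metadata, and one row per patient with the latent
    quotient draws.  Deterministic given ``(spec, profiles, seed)``; each
    group consumes an independent, fixed random stream, so adding a group
    does not perturb the others.
    """
    spec = spec or CohortSpec()
    profiles = profiles or default_profiles()
    missing = [g for g in spec.n_patients if spec.n_patients[g] > 0 and g not in profiles]
    if missing:
        raise ValueError(f"profiles missing for groups: {missing}")
    models = _build_models(profiles)

    if seed is None:
        seed = spec.seed
    base_ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)

    rho = spec.inter_eye_correlation
    eye_frames: list[pd.DataFrame] = []
    latent_frames: list[pd.DataFrame] = []
    for group in GROUPS:
        n = spec.n_patients.get(group, 0)
        if n == 0:
            continue
        profile = profiles[group]
        rng = np.random.default_rng(
            np.random.SeedSequence(
                entropy=base_ss.entropy, spawn_key=base_ss.spawn_key + (_GROUP_INDEX[group],)
            )
        )
        n_uni = spec.unilateral_patients.get(group, 0)
        pids = [f"{group}_{i + 1:03d}" for i in range(n)]
        bilateral = np.arange(n) >= n_uni  # the first n_uni patients are unilateral

        u = rng.random(n)
        q = {k: models[group][k].ppf(u) for k in ("I", "II")}
        values = _sample_group_eyes(rng, profile, rho, n, bilateral, q)
        meta = _sample_metadata(rng, group, n)

        latent_frames.append(
            pd.DataFrame(
                {"patient_id": pids, "group": group,
                 "quotient_I": q["I"], "quotient_II": q["II"]}
            )
        )
        # expand (n, 2) eye arrays into one row per available eye
        eye_sel = np.stack([np.ones(n, dtype=bool), bilateral], axis=1)  # OD, OS
        rows_idx, eye_idx = np.nonzero(eye_sel)
        frame = {
            "patient_id": np.asarray(pids)[rows_idx],
            "group": group,
            "eye": np.asarray(["OD", "OS"])[eye_idx],
        }
        for col, arr in values.items():
            frame[col] = arr[rows_idx, eye_idx]
        for col, arr in meta.items():
            frame[col] = arr[rows_idx]
        eye_frames.append(pd.DataFrame(frame))

    if eye_frames:
        eyes_df = pd.concat(eye_frames, ignore_index=True)[COHORT_COLUMNS]
        latent_df = pd.concat(latent_frames, ignore_index=True)
    else:
        eyes_df = pd.DataFrame(columns=COHORT_COLUMNS)
        latent_df = pd.DataFrame(columns=["patient_id", "group", "quotient_I", "quotient_II"])
    return eyes_df, latent_df


def _draw_group_values(
    rng: np.random.Generator,
    profile: GroupProfile,
    rho: float,
    n: int,
    bilateral: np.ndarray,
    q: dict[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """One vectorized draw of all (n, 2) per-eye subfield arrays for a group.

    GCL temporal subfields are set from the latent quotients: each patient's
    eye-averaged temporal value is exactly ``quotient * eye-averaged nasal``;
    the per-eye jitter around it sums to zero across the patient's eyes.
    """
    sqrt_rho, sqrt_jit = np.sqrt(rho), np.sqrt(1.0 - rho)
    values: dict[str, np.ndarray] = {}
    for layer in LAYERS:
        for sf in SUBFIELDS:
            mu = profile.subfield_mean[layer][sf]
            sd = profile.subfield_sd[layer][sf]
            patient_level = rng.normal(mu, sd * sqrt_rho, size=n)
            jitter = rng.normal(0.0, sd * sqrt_jit, size=(n, 2))
            values[f"{layer}_{sf}"] = patient_level[:, None] + jitter
    for kind, (t_sf, n_sf) in (("I", ("tI", "nI")), ("II", ("tII", "nII"))):
        nasal = values[f"gcl_{n_sf}"]
        nasal_avg = np.where(bilateral, nasal.mean(axis=1), nasal[:, 0])
        target = q[kind] * nasal_avg
        sd_t = profile.subfield_sd["gcl"][t_sf]
        delta = np.where(bilateral, rng.normal(0.0, sd_t * sqrt_jit, size=n), 0.0)
        values[f"gcl_{t_sf}"] = target[:, None] + np.stack([delta, -delta], axis=1)
    return values


def _sample_group_eyes(
    rng: np.random.Generator,
    profile: GroupProfile,
    rho: float,
    n: int,
    bilateral: np.ndarray,
    q: dict[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Group draw with bounded per-patient resampling of non-positive values."""
    values = _draw_group_values(rng, profile, rho, n, bilateral, q)
    eye_sel = np.stack([np.ones(n, dtype=bool), bilateral], axis=1)
    for _ in range(_MAX_RETRIES):
        bad = np.zeros(n, dtype=bool)
        for arr in values.values():
            bad |= ((arr <= _MIN_THICKNESS_UM) & eye_sel).any(axis=1)
        if not bad.any():
            return values
        redraw = _draw_group_values(
            rng, profile, rho, int(bad.sum()), bilateral[bad], {k: v[bad] for k, v in q.items()}
        )
        for col in values:
            values[col][bad] = redraw[col]
    raise RuntimeError(
        f"could not draw positive thicknesses for group {profile.group!r} "
        f"after {_MAX_RETRIES} retries"
    )


def _sample_metadata(rng: np.random.Generator, group: str, n: int) -> dict[str, np.ndarray]:
    """Per-patient clinical metadata from the reference empirical frequencies."""
    freqs = _METADATA_FREQS[group]
    grades = list(freqs["fh_grades"].items())
    return {
        "fh_grade": rng.choice([g for g, _ in grades], p=[p for _, p in grades], size=n),
        "nystagmus": rng.random(n) < freqs["nystagmus"],
        "fundus_hypopigmentation": rng.random(n) < freqs["fundus_hypopigmentation"],
    }


def generate_thickness_map(
    obs: pd.Series | dict,
    layer: str = "gcl",
    pitch_mm: float = 0.02,
    extent_mm: float = 3.2,
) -> ThicknessMap:
    """Render an eye observation as a piecewise-constant en-face map.

    Every pixel whose centre falls inside ETDRS subfield *s* receives the
    observation's ``<layer>_<s>`` value; pixels outside the 6 mm circle
    carry the no-data sentinel.  ``extent_mm`` is the half-width of the
    square grid and must cover the 3 mm grid radius.
    """
    if pitch_mm <= 0:
        raise ValueError(f"pitch_mm must be > 0, got {pitch_mm}")
    if extent_mm < 3.0:
        raise ValueError(f"grid half-extent {extent_mm} mm does not cover the 6 mm circle")
    laterality = obs["eye"] if "eye" in obs else "OD"
    half = int(round(extent_mm / pitch_mm))
    n = 2 * half + 1
    center = (float(half), float(half))
    masks = subfield_masks((n, n), pitch_mm, center, laterality)
    values = np.full((n, n), NODATA)
    for sf in SUBFIELDS:
        values[masks[sf]] = float(obs[f"{layer}_{sf}"])
    return ThicknessMap(
        values=values, pitch_mm=pitch_mm, center=center, laterality=laterality, layer=layer
    )


def write_cohort_csv(eyes: pd.DataFrame, path: str | Path) -> None:
    """UTF-8 CSV, dot decimal separator, fixed documented column order."""
    eyes.to_csv(path, index=False, columns=COHORT_COLUMNS, float_format="%.6f")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    return df[COHORT_COLUMNS]
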