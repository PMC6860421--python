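"""ETDRS nine-subfield geometry on en-face layer thickness maps.

The ETDRS macular grid consists of three concentric circles of 1, 3 and 6 mm
diameter centred on the fovea.  The central disc is one subfield ("c"); the
inner (parafoveal, 0.5-1.5 mm radius) and outer (perifoveal, 1.5-3 mm) rings
are each split into four quadrants by the 45-degree diagonals: nasal,
temporal, superior, inferior.  Nasal/temporal are anatomical retinal
directions and therefore mirror between right (OD) and left (OS) eyes.

All geometry here works in a canonical fovea-centred frame with
+x = temporal retina and +y = superior retina, regardless of eye; the
image-to-canonical conversion flips x for left eyes (OS).  Thicknesses are in
micrometres, distances in millimetres, subfield volumes in cubic millimetres.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .profiles import SUBFIELDS

__all__ = [
    "ThicknessMap",
    "SubfieldSummary",
    "SUBFIELD_AREAS_MM2",
    "assign_subfield",
    "subfield_masks",
    "subfield_means",
    "subfield_volume",
    "locate_fovea",
    "save_thickness_map",
    "load_thickness_map",
]

NODATA = -1.0

_CENTRAL_R = 0.5
_INNER_R = 1.5
_OUTER_R = 3.0

#: analytic subfield areas (mm^2): central disc and quarter-annuli
SUBFIELD_AREAS_MM2 = {
    "c": np.pi * _CENTRAL_R**2,
    **{
        sf: np.pi * (_INNER_R**2 - _CENTRAL_R**2) / 4.0
        for sf in ("nI", "tI", "sI", "iI")
    },
    **{
        sf: np.pi * (_OUTER_R**2 - _INNER_R**2) / 4.0
        for sf in ("nII", "tII", "sII", "iII")
    },
}


@dataclass
class ThicknessMap:
    """Fovea-centred en-face grid of one layer's thickness in micrometres.

    ``values`` is indexed [row, col]; row increases downward (inferior),
    column increases rightward.  ``center`` is the (row, col) of the fovea.
    Pixels without data carry ``nodata``.
    """

    values: np.ndarray
    pitch_mm: float
    center: tuple[float, float]
    laterality: str
    layer: str = "gcl"
    nodata: float = NODATA

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("thickness map must be a 2-D grid")
        if self.pitch_mm <= 0:
            raise ValueError(f"pitch_mm must be > 0, got {self.pitch_mm}")
        if self.laterality not in ("OD", "OS"):
            raise ValueError(f"laterality must be OD or OS, got {self.laterality!r}")
        r, c = self.center
        nr, nc = self.values.shape
        if not (0 <= r < nr and 0 <= c < nc):
            raise ValueError(f"center {self.center} outside grid {self.values.shape}")
        data = self.values[self.values != self.nodata]
        if data.size and np.any(data < 0):
            raise ValueError("non-sentinel thickness values must be >= 0")


def assign_subfield(
    x_mm: float, y_mm: float, laterality: str = "OD", frame: str = "canonical"
) -> str | None:
    """Subfield id for a fovea-centred point, or None outside the 6 mm circle.

    In the canonical frame (default) +x is the temporal retina and +y the
    superior retina for *either* eye, so the geometry is laterality-free.
    With ``frame="image"`` the coordinates are taken as image axes
    (+x rightward); the x axis is then flipped for left eyes (OS) to reach
    the canonical frame.

    Ring boundaries: r < 0.5 central; 0.5 <= r < 1.5 inner; 1.5 <= r <= 3
    outer.  Quadrants by the 45-degree diagonals; points exactly on a
    diagonal belong to the horizontal (nasal/temporal) wedge.
    """
    if laterality not in ("OD", "OS"):
        raise ValueError(f"laterality must be OD or OS, got {laterality!r}")
    if frame not in ("canonical", "image"):
        raise ValueError(f"frame must be 'canonical' or 'image', got {frame!r}")
    if frame == "image" and laterality == "OS":
        x_mm = -x_mm
    r = float(np.hypot(x_mm, y_mm))
    if r > _OUTER_R:
        return None
    if r < _CENTRAL_R:
        return "c"
    ring = "I" if r < _INNER_R else "II"
    if abs(x_mm) >= abs(y_mm):  # horizontal wedges own the diagonals
        quadrant = "t" if x_mm > 0 else "n"
    else:
        quadrant = "s" if y_mm > 0 else "i"
    return quadrant + ring


_MASK_CACHE: dict = {}


def subfield_masks(
    shape: tuple[int, int],
    pitch_mm: float,
    center: tuple[float, float],
    laterality: str,
) -> dict[str, np.ndarray]:
    """Boolean pixel-membership masks for the nine subfields.

    Membership is decided by the pixel-centre point (no boundary area
    weighting).  Results are cached: the same grid geometry is reused for
    every eye in a simulated cohort.
    """
    key = (shape, float(pitch_mm), tuple(center), laterality)
    if key in _MASK_CACHE:
        return _MASK_CACHE[key]
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    x = (cols - center[1]) * pitch_mm
    y = (center[0] - rows) * pitch_mm  # row down = inferior
    if laterality == "OS":
        x = -x
    r = np.hypot(x, y)
    horizontal = np.abs(x) >= np.abs(y)
    masks: dict[str, np.ndarray] = {"c": r < _CENTRAL_R}
    for ring, ring_mask in (
        ("I", (r >= _CENTRAL_R) & (r < _INNER_R)),
        ("II", (r >= _INNER_R) & (r <= _OUTER_R)),
    ):
        masks["t" + ring] = ring_mask & horizontal & (x > 0)
        masks["n" + ring] = ring_mask & horizontal & (x <= 0)
        masks["s" + ring] = ring_mask & ~horizontal & (y > 0)
        masks["i" + ring] = ring_mask & ~horizontal & (y < 0)
    _MASK_CACHE[key] = masks
    return masks


@dataclass
class SubfieldSummary:
    """Per-subfield mean thickness (um), volume (mm^3) and pixel counts."""

    means_um: dict
    volumes_mm3: dict
    pixel_counts: dict
    laterality: str
    layer: str

    @property
    def horizontal_meridian(self) -> tuple[float, float, float, float, float]:
        """(nII, nI, c, tI, tII) — the meridian of diagnostic interest."""
        m = self.means_um
        return (m["nII"], m["nI"], m["c"], m["tI"], m["tII"])


def subfield_means(tmap: ThicknessMap) -> SubfieldSummary:
    """Arithmetic mean thickness of non-sentinel pixels per ETDRS subfield.

    Raises if the grid does not cover the 6 mm circle or any subfield ends
    up with zero contributing pixels.
    """
    nr, nc = tmap.values.shape
    r0, c0 = tmap.center
    half_extent_mm = min(r0, nr - 1 - r0, c0, nc - 1 - c0) * tmap.pitch_mm
    if half_extent_mm < _OUTER_R:
        raise ValueError(
            f"grid covers only {half_extent_mm:.2f} mm from center; "
            f"the ETDRS grid needs {_OUTER_R} mm"
        )
    masks = subfield_masks(tmap.values.shape, tmap.pitch_mm, tmap.center, tmap.laterality)
    valid = tmap.values != tmap.nodata
    means, volumes, counts = {}, {}, {}
    for sf in SUBFIELDS:
        m = masks[sf] & valid
        n = int(m.sum())
        if n == 0:
            raise ValueError(f"subfield {sf!r} has no contributing pixels")
        mu = float(tmap.values[m].mean())
        means[sf] = mu
        counts[sf] = n
        volumes[sf] = subfield_volume(mu, sf)
    return SubfieldSummary(means, volumes, counts, tmap.laterality, tmap.layer)


def subfield_volume(mean_um: float, subfield: str) -> float:
    """Subfield volume in mm^3 from its mean thickness in um."""
    if subfield not in SUBFIELD_AREAS_MM2:
        raise ValueError(f"unknown subfield {subfield!r}")
    if mean_um < 0:
        raise ValueError(f"mean thickness must be >= 0, got {mean_um}")
    return mean_um * 1e-3 * SUBFIELD_AREAS_MM2[subfield]


def locate_fovea(
    tmap: ThicknessMap,
    search_radius_mm: float = 1.0,
    smooth_mm: float = 0.1,
    flat_tol_um: float = 0.5,
) -> tuple[float, float]:
    """Locate the foveal pit as the centroid of the minimal-thickness region.

    The map is boxcar-smoothed and searched within a central window
    (default +-1 mm, i.e. the central 2 mm).  Intended for maps where the
    central subfield is the thinnest (a depression); if the minimum sits on
    the search-window boundary the map has no central pit — a warning is
    issued and the metadata centre is returned instead (error if the map has
    none).  A flat window raises.
    """
    vals = np.where(tmap.values == tmap.nodata, np.nan, tmap.values)
    size = max(1, int(round(smooth_mm / tmap.pitch_mm)) | 1)  # odd: no half-pixel shift
    smoothed = ndimage.uniform_filter(np.nan_to_num(vals, nan=np.nanmean(vals)), size=size)

    nr, nc = vals.shape
    guess = tmap.center
    half = int(round(search_radius_mm / tmap.pitch_mm))
    r_lo, r_hi = int(max(0, guess[0] - half)), int(min(nr, guess[0] + half + 1))
    c_lo, c_hi = int(max(0, guess[1] - half)), int(min(nc, guess[1] + half + 1))
    window = smoothed[r_lo:r_hi, c_lo:c_hi]
    if window.max() - window.min() < flat_tol_um:
        raise ValueError(
            "thickness map is flat within the search window; "
            "no unique foveal minimum — supply an explicit center"
        )
    min_val = window.min()
    region = window <= min_val + flat_tol_um
    rr, cc = np.nonzero(region)
    on_boundary = (
        rr.min() == 0 or cc.min() == 0 or rr.max() == window.shape[0] - 1 or cc.max() == window.shape[1] - 1
    )
    if on_boundary:
        warnings.warn(
            "minimal-thickness region touches the search-window boundary "
            "(no central depression); falling back to the metadata center",
            stacklevel=2,
        )
        return tmap.center
    return (float(rr.mean()) + r_lo, float(cc.mean()) + c_lo)


# ---------------------------------------------------------------------------
# plain-text map I/O: TSV grid + JSON sidecar


def save_thickness_map(tmap: ThicknessMap, path: str | Path) -> None:
    """Write a map as `<path>.tsv` (grid) + `<path>.json` (metadata)."""
    path = Path(path)
    np.savetxt(path.with_suffix(".tsv"), tmap.values, fmt="%.4f", delimiter="\t")
    meta = {
        "pitch_mm": tmap.pitch_mm,
        "center_row": tmap.center[0],
        "center_col": tmap.center[1],
        "laterality": tmap.laterality,
        "layer": tmap.layer,
        "nodata_value": tmap.nodata,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_thickness_map(path: str | Path) -> ThicknessMap:
    path = Path(path)
    values = np.loadtxt(path.with_suffix(".tsv"), delimiter="\t")
    meta = json.loads(path.with_suffix(".json").read_text())
    return ThicknessMap(
        values=values,
        pitch_mm=meta["pitch_mm"],
        center=(meta["center_row"], meta["center_col"]),
        laterality=meta["laterality"],
        layer=meta.get("layer", "gcl"),
        nodata=meta.get("nodata_value", NODATA),
    )
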