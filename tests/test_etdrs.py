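"""ETDRS grid geometry, subfield extraction and fovea localisation."""

import numpy as np
import pytest

from foveaq.cohort import generate_thickness_map
from foveaq.etdrs import (
    SUBFIELD_AREAS_MM2,
    ThicknessMap,
    assign_subfield,
    load_thickness_map,
    locate_fovea,
    save_thickness_map,
    subfield_masks,
    subfield_means,
    subfield_volume,
)
from foveaq.profiles import SUBFIELDS


def _square_grid(pitch, extent=3.2):
    half = int(round(extent / pitch))
    n = 2 * half + 1
    return (n, n), (float(half), float(half))


class TestAssignSubfield:
    @pytest.mark.parametrize(
        "x,y,lat,expected",
        [
            (0.0, 0.0, "OD", "c"),
            (2.0, 0.0, "OS", "tII"),  # canonical frame: +x temporal either eye
            (0.0, 3.01, "OD", None),
            (1.0, 0.0, "OD", "tI"),
            (-1.0, 0.0, "OD", "nI"),
            (0.0, 2.0, "OD", "sII"),
            (0.0, -2.0, "OD", "iII"),
            (1.0, 1.0, "OD", "tI"),  # diagonal tie goes to the horizontal wedge
            (-2.0, 2.0, "OS", "nII"),
        ],
    )
    def test_canonical_assignment(self, x, y, lat, expected):
        assert assign_subfield(x, y, lat) == expected

    def test_image_frame_flips_for_left_eyes(self):
        assert assign_subfield(2.0, 0.0, "OS", frame="image") == "nII"
        assert assign_subfield(2.0, 0.0, "OD", frame="image") == "tII"

    def test_ring_boundaries(self):
        assert assign_subfield(0.49, 0, "OD") == "c"
        assert assign_subfield(0.5, 0, "OD") == "tI"
        assert assign_subfield(1.5, 0, "OD") == "tII"
        assert assign_subfield(3.0, 0, "OD") == "tII"


class TestPartitionProperties:
    def test_every_inside_pixel_in_exactly_one_subfield(self):
        shape, center = _square_grid(0.05)
        masks = subfield_masks(shape, 0.05, center, "OD")
        total = np.zeros(shape, dtype=int)
        for m in masks.values():
            total += m.astype(int)
        rows = np.arange(shape[0])[:, None]
        cols = np.arange(shape[1])[None, :]
        r = np.hypot((cols - center[1]) * 0.05, (center[0] - rows) * 0.05)
        assert np.all(total[r <= 3.0] == 1)
        assert np.all(total[r > 3.0] == 0)

    def test_rotation_by_90_degrees_permutes_quadrants(self):
        shape, center = _square_grid(0.05)
        masks = subfield_masks(shape, 0.05, center, "OD")
        # rotating the grid 90 deg counter-clockwise maps temporal -> superior
        rotated = np.rot90(masks["tI"])
        overlap = (rotated & masks["sI"]).sum() / masks["sI"].sum()
        assert overlap > 0.99

    @pytest.mark.parametrize("pitches", [(0.05, 0.02, 0.01)])
    def test_pixel_areas_converge_monotonically_to_analytic(self, pitches):
        max_errs = []
        for pitch in pitches:
            shape, center = _square_grid(pitch)
            masks = subfield_masks(shape, pitch, center, "OD")
            errs = [
                abs(masks[sf].sum() * pitch**2 - SUBFIELD_AREAS_MM2[sf])
                for sf in SUBFIELDS
            ]
            max_errs.append(max(errs))
        assert max_errs[0] > max_errs[1] > max_errs[2]
        assert max_errs[-1] < 0.02  # mm^2 at 0.01 mm pitch


class TestSubfieldMeans:
    def test_constant_map_all_means_equal(self):
        shape, center = _square_grid(0.05)
        tmap = ThicknessMap(np.full(shape, 50.0), 0.05, center, "OD")
        summary = subfield_means(tmap)
        assert all(v == pytest.approx(50.0) for v in summary.means_um.values())

    def test_round_trip_error_below_half_micron(self, cohort, rng):
        eyes, _ = cohort
        sample = eyes.sample(20, random_state=12)
        worst = 0.0
        for _, obs in sample.iterrows():
            tmap = generate_thickness_map(obs, pitch_mm=0.02)
            summary = subfield_means(tmap)
            worst = max(
                worst,
                max(abs(summary.means_um[sf] - obs[f"gcl_{sf}"]) for sf in SUBFIELDS),
            )
        assert worst < 0.5

    def test_laterality_mirror_invariance(self, cohort):
        """Mirroring the grid left-right and flipping OD<->OS leaves every
        subfield mean unchanged (nasal/temporal follow the retina, not the
        image)."""
        eyes, _ = cohort
        obs = eyes.iloc[3]
        tmap = generate_thickness_map(obs, pitch_mm=0.05)
        flipped = ThicknessMap(
            tmap.values[:, ::-1].copy(),
            tmap.pitch_mm,
            tmap.center,
            "OD" if tmap.laterality == "OS" else "OS",
            tmap.layer,
        )
        a, b = subfield_means(tmap), subfield_means(flipped)
        for sf in SUBFIELDS:
            assert a.means_um[sf] == pytest.approx(b.means_um[sf], abs=1e-9)

    def test_undersized_grid_rejected(self):
        tmap = ThicknessMap(np.full((41, 41), 30.0), 0.05, (20.0, 20.0), "OD")
        with pytest.raises(ValueError, match="ETDRS"):
            subfield_means(tmap)

    def test_all_nodata_subfield_is_an_error(self):
        shape, center = _square_grid(0.05)
        vals = np.full(shape, 40.0)
        masks = subfield_masks(shape, 0.05, center, "OD")
        vals[masks["tII"]] = -1.0  # knock out one subfield
        tmap = ThicknessMap(vals, 0.05, center, "OD")
        with pytest.raises(ValueError, match="tII"):
            subfield_means(tmap)


class TestVolumes:
    def test_analytic_volume_examples(self):
        assert subfield_volume(100.0, "c") == pytest.approx(0.0785, abs=1e-4)
        assert subfield_volume(0.0, "nII") == 0.0
        assert sum(SUBFIELD_AREAS_MM2.values()) == pytest.approx(np.pi * 9.0, abs=1e-9)

    def test_unknown_subfield_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            subfield_volume(10.0, "xx")


class TestLocateFovea:
    def test_healthy_map_center_found_exactly(self, cohort):
        eyes, _ = cohort
        obs = eyes[eyes["group"] == "healthy"].iloc[0]
        tmap = generate_thickness_map(obs, pitch_mm=0.05)
        assert locate_fovea(tmap) == tmap.center

    def test_albinism_map_falls_back_with_warning(self, cohort):
        # albinism: central subfield is the thickest — no pit to find
        eyes, _ = cohort
        obs = eyes[eyes["group"] == "albinism_fh"].iloc[0]
        tmap = generate_thickness_map(obs, pitch_mm=0.05)
        with pytest.warns(UserWarning, match="metadata center"):
            assert locate_fovea(tmap) == tmap.center

    def test_flat_map_is_an_error(self):
        tmap = ThicknessMap(np.full((129, 129), 42.0), 0.05, (64.0, 64.0), "OD")
        with pytest.raises(ValueError, match="flat"):
            locate_fovea(tmap)


class TestMapIO:
    def test_tsv_json_round_trip(self, cohort, tmp_path):
        eyes, _ = cohort
        tmap = generate_thickness_map(eyes.iloc[5], pitch_mm=0.1)
        save_thickness_map(tmap, tmp_path / "eye")
        back = load_thickness_map(tmp_path / "eye")
        assert back.laterality == tmap.laterality
        assert back.pitch_mm == tmap.pitch_mm
        assert np.allclose(back.values, tmap.values, atol=1e-4)
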