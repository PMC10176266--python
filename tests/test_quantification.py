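"""Per-cell assignment: nearest-stain rule, fallback, nuclear mode, normalization."""

import dataclasses
import math

import numpy as np
import pytest

import trophoquant as tq
from trophoquant.quantification import (
    StainMask,
    assign_nearest_stain,
    build_stain_mask,
    isotype_reference,
    nuclear_intensity,
    quantify_field,
    quantify_isotype_field,
)
from trophoquant.segmentation import Field, NucleusRecord, label_nuclei

from conftest import oracle_nearest_stain, random_assignment_scene


def stain_from_mask(mask: np.ndarray, raster: np.ndarray) -> StainMask:
    records = label_nuclei(mask)
    labels = np.zeros(mask.shape, dtype=int)
    means = {}
    for rec in records:
        labels[tuple(rec.coords.T)] = rec.label
        means[rec.label] = float(raster[tuple(rec.coords.T)].mean())
    return StainMask("green", labels > 0, labels, means, None)


def nucleus_at(label: int, pixels: list[tuple[int, int]]) -> NucleusRecord:
    coords = np.asarray(pixels, dtype=int)
    return NucleusRecord(
        label=label,
        coords=coords,
        centroid=(float(coords[:, 0].mean()), float(coords[:, 1].mean())),
        area_px=len(coords),
    )


class TestBuildStainMask:
    def test_single_blob_component_mean_over_original_values(self, stain_cfg):
        img = np.full((16, 16), 2.0)
        img[4:6, 4:9] = 150.0  # 10-px blob
        field = Field(channels={"blue": np.zeros((16, 16)), "green": img}, um_per_px=1.0)
        stain = build_stain_mask(field, "green", dataclasses.replace(stain_cfg, min_area_px=5))
        assert len(stain.component_means) == 1
        assert stain.component_means[1] == pytest.approx(150.0)

    def test_empty_channel_yields_zero_components(self, stain_cfg):
        field = Field(channels={"blue": np.zeros((8, 8)), "green": np.zeros((8, 8))}, um_per_px=1.0)
        stain = build_stain_mask(field, "green", stain_cfg)
        assert stain.component_means == {}

    def test_two_blobs_keep_separate_means(self, stain_cfg):
        img = np.zeros((20, 20))
        img[2:5, 2:5] = 100.0
        img[12:15, 12:15] = 200.0
        field = Field(channels={"blue": np.zeros((20, 20)), "green": img}, um_per_px=1.0)
        stain = build_stain_mask(field, "green", dataclasses.replace(stain_cfg, min_area_px=5))
        assert sorted(stain.component_means.values()) == [100.0, 200.0]


class TestAssignNearestStain:
    def test_mean_of_nearest_component_assigned(self):
        raster = np.zeros((12, 12))
        mask = np.zeros((12, 12), dtype=bool)
        raster[5, 7], raster[5, 8] = 100.0, 200.0
        mask[5, 7] = mask[5, 8] = True
        stain = stain_from_mask(mask, raster)
        nuc = nucleus_at(1, [(5, 5)])
        (res,) = assign_nearest_stain([nuc], stain, fallback_value=0.0)
        assert res.raw == pytest.approx(150.0)
        assert not res.fallback
        assert res.d_stain == pytest.approx(2.0)
        assert math.isinf(res.d_other_nucleus)

    def test_no_stain_pixels_assigns_fallback_everywhere(self):
        stain = stain_from_mask(np.zeros((10, 10), dtype=bool), np.zeros((10, 10)))
        nuclei = [nucleus_at(1, [(2, 2)]), nucleus_at(2, [(7, 7)])]
        results = assign_nearest_stain(nuclei, stain, fallback_value=12.0)
        assert all(r.raw == 12.0 and r.fallback for r in results)

    def test_neighbor_owned_stain_triggers_fallback(self):
        # nucleus A far from the blob, B adjacent to it; A's nearest stain is
        # farther than B's nucleus pixels, so A falls back and B keeps the blob
        shape = (21, 60)
        raster = np.zeros(shape)
        mask = np.zeros(shape, dtype=bool)
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        blob = (rr - 10) ** 2 + (cc - 36) ** 2 <= 4
        raster[blob] = 80.0
        mask |= blob
        stain = stain_from_mask(mask, raster)
        # A's nearest stain pixel (d=24) is farther than B's nearest nucleus
        # pixel (d=22); B sits on the blob
        disk_a = [(r, c) for r in range(21) for c in range(60)
                  if (r - 10) ** 2 + (c - 10) ** 2 <= 16]
        disk_b = [(r, c) for r in range(21) for c in range(60)
                  if (r - 10) ** 2 + (c - 40) ** 2 <= 64]
        a, b = nucleus_at(1, disk_a), nucleus_at(2, disk_b)
        res_a, res_b = assign_nearest_stain([a, b], stain, fallback_value=5.0)
        oracle = oracle_nearest_stain([a, b], stain, 5.0)
        assert (res_a.raw, res_a.fallback) == (5.0, True)
        assert (res_b.raw, res_b.fallback) == (80.0, False)
        for got, exp in zip((res_a, res_b), oracle):
            assert (got.raw, got.fallback) == (exp[0], exp[1])
            assert got.d_stain == pytest.approx(exp[2])
            assert got.d_other_nucleus == pytest.approx(exp[3])

    def test_matches_exhaustive_pixel_scan_on_random_scenes(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            nuclei, stain = random_assignment_scene(rng)
            got = assign_nearest_stain(nuclei, stain, fallback_value=7.0)
            expected = oracle_nearest_stain(nuclei, stain, 7.0)
            for g, e in zip(got, expected):
                assert g.raw == e[0]
                assert g.fallback == e[1]
                assert g.d_stain == e[2] or g.d_stain == pytest.approx(e[2], abs=1e-12)
                assert g.d_other_nucleus == e[3] or g.d_other_nucleus == pytest.approx(e[3], abs=1e-12)

    def test_any_blue_rule_makes_own_nucleus_compete(self):
        raster = np.zeros((10, 10))
        mask = np.zeros((10, 10), dtype=bool)
        raster[2, 8] = 50.0
        mask[2, 8] = True
        stain = stain_from_mask(mask, raster)
        nuc = nucleus_at(1, [(2, 2), (2, 3)])
        (strict,) = assign_nearest_stain([nuc], stain, 1.0, fallback_rule="any_blue")
        assert strict.fallback  # own nucleus at distance ~0 wins
        (lenient,) = assign_nearest_stain([nuc], stain, 1.0)
        assert not lenient.fallback

    def test_scaling_stain_channel_scales_non_fallback_values(self, stain_cfg):
        spec = tq.FieldSpec(n_colonies=2, cells_per_colony=(4, 6), n_single_cells=3, seed=31)
        field, _ = tq.generate_field(spec)
        nuclei, _, _ = tq.segment_nuclei(field)
        c = 3.0
        base = assign_nearest_stain(
            [r for r in nuclei],
            build_stain_mask(field, "green", stain_cfg),
            fallback_value=8.0,
        )
        scaled_field = Field(
            channels={"blue": field.blue, "green": field.channels["green"] * c},
            um_per_px=field.um_per_px,
        )
        scaled_cfg = dataclasses.replace(stain_cfg, threshold=stain_cfg.threshold * c)
        scaled = assign_nearest_stain(
            nuclei, build_stain_mask(scaled_field, "green", scaled_cfg), fallback_value=8.0
        )
        assert any(not r.fallback for r in base)
        for b, s in zip(base, scaled):
            assert b.fallback == s.fallback
            if not b.fallback:
                assert s.raw == pytest.approx(c * b.raw, rel=1e-12)

    def test_empty_nucleus_list_returns_empty(self):
        stain = stain_from_mask(np.zeros((5, 5), dtype=bool), np.zeros((5, 5)))
        assert assign_nearest_stain([], stain, 1.0) == []


class TestNuclearIntensity:
    def test_mean_over_own_pixels(self):
        img = np.zeros((6, 6))
        img[1, 1], img[1, 2], img[1, 3] = 10.0, 20.0, 30.0
        field = Field(channels={"blue": np.zeros((6, 6)), "red": img}, um_per_px=1.0)
        nuc = nucleus_at(1, [(1, 1), (1, 2), (1, 3)])
        (res,) = nuclear_intensity([nuc], field, "red", fallback_value=0.0)
        assert res.raw == pytest.approx(20.0)
        assert not res.fallback

    def test_zero_channel_gives_zero(self):
        field = Field(channels={"blue": np.zeros((6, 6)), "red": np.zeros((6, 6))}, um_per_px=1.0)
        (res,) = nuclear_intensity([nucleus_at(1, [(2, 2)])], field, "red", 5.0)
        assert res.raw == 0.0

    def test_recovers_known_nuclear_means_exactly_at_zero_noise(self):
        # nuclear-marker layout: signal rendered over the nucleus itself
        spec = tq.FieldSpec(
            n_colonies=0, n_single_cells=8, colony_radius_um=12.0,
            stain_radius_px=4, noise_sd=0.0, seed=19,
        )
        field, gt = tq.generate_field(spec)
        nuclei, _, _ = tq.segment_nuclei(field)
        results = nuclear_intensity(nuclei, field, "green", fallback_value=0.0)
        truth = gt.table[["row", "col"]].to_numpy()
        for rec, res in zip(nuclei, results):
            i = ((truth - rec.centroid) ** 2).sum(axis=1).argmin()
            row = gt.table.iloc[i]
            # blob (radius 4) sits wholly inside the nucleus (radius >= 6);
            # expected nuclear mean mixes blob value and background over the
            # nucleus pixel set, reconstructed from ground-truth geometry
            d2 = ((rec.coords - np.array([row["row"], row["col"]])) ** 2).sum(axis=1)
            in_blob = d2 <= spec.stain_radius_px**2
            expected = (
                in_blob.sum() * row["true_green"]
                + (~in_blob).sum() * spec.background_level
            ) / rec.area_px
            assert res.raw == pytest.approx(expected, abs=1e-9)


class TestIsotypeReference:
    def test_uniform_values_average_to_themselves(self):
        ref = isotype_reference([[10, 10, 10, 10]])
        assert ref.value == 10.0 and ref.n == 4

    def test_pooling_weights_by_cell_count(self):
        ref = isotype_reference([[5, 5], [15, 15]])
        assert ref.value == 10.0
        assert ref.per_field_means == (5.0, 15.0)
        unbalanced = isotype_reference([[5, 5, 5], [20]])
        assert unbalanced.value == pytest.approx(8.75)
        per_field = isotype_reference([[5, 5, 5], [20]], pooling="per_field")
        assert per_field.value == pytest.approx(12.5)

    def test_zero_isotype_cells_is_an_error(self):
        with pytest.raises(ValueError, match="isotype"):
            isotype_reference([[], []])

    def test_nuclear_mode_on_synthetic_isotype_field_returns_background(self, stain_cfg):
        spec = tq.FieldSpec(
            n_colonies=0, n_single_cells=5, colony_radius_um=12.0,
            background_level=9.0, noise_sd=0.0, seed=23,
        )
        iso, _ = tq.generate_isotype_field(spec)
        vals = quantify_isotype_field(iso, ("green",), mode="nuclear", stain_config=stain_cfg)
        ref = isotype_reference([vals["green"]])
        assert ref.value == pytest.approx(9.0, abs=1e-12)


class TestQuantifyField:
    def test_normalization_is_raw_over_reference(self, stain_cfg):
        spec = tq.FieldSpec(n_colonies=0, n_single_cells=4, colony_radius_um=12.0, seed=3)
        field, _ = tq.generate_field(spec)
        ms, _ = quantify_field(field, {"green": 10.0}, stain_config=stain_cfg)
        for m in ms:
            assert m.normalized["green"] == pytest.approx(m.raw["green"] / 10.0)

    def test_fallback_cells_normalize_to_exactly_one(self, stain_cfg):
        spec = tq.FieldSpec(
            n_colonies=2, cells_per_colony=(4, 6), n_single_cells=2,
            stain_offset_px=45.0, seed=29,
        )
        field, _ = tq.generate_field(spec)
        ms, details = quantify_field(field, {"green": 8.0, "red": 8.0}, stain_config=stain_cfg)
        fallbacks = [m for m in ms if m.fallback["green"]]
        assert fallbacks, "offset layout should trigger at least one fallback"
        for m in fallbacks:
            assert m.normalized["green"] == 1.0

    def test_nonpositive_reference_rejected(self, stain_cfg):
        spec = tq.FieldSpec(n_colonies=0, n_single_cells=4, colony_radius_um=12.0, seed=3)
        field, _ = tq.generate_field(spec)
        with pytest.raises(ValueError, match="positive"):
            quantify_field(field, {"green": 0.0}, stain_config=stain_cfg)

    def test_channels_fall_back_independently(self, stain_cfg):
        spec = tq.FieldSpec(n_colonies=2, cells_per_colony=(4, 6), n_single_cells=2, seed=37)
        field, _ = tq.generate_field(spec)
        # remove all red signal so red falls back while green does not
        field.channels["red"] = np.full(field.shape, 8.0)
        ms, _ = quantify_field(field, {"green": 8.0, "red": 8.0}, stain_config=stain_cfg)
        assert all(m.fallback["red"] for m in ms)
        assert any(not m.fallback["green"] for m in ms)

    def test_noise_free_recovery_equals_truth_over_reference(self, stain_cfg):
        spec = tq.FieldSpec(n_colonies=2, cells_per_colony=(5, 8), n_single_cells=5, noise_sd=0.0, seed=7)
        field, gt = tq.generate_field(spec)
        iso, _ = tq.generate_isotype_field(spec)
        refs = {
            ch: isotype_reference([v])
            for ch, v in quantify_isotype_field(iso, ("green", "red"), stain_config=stain_cfg).items()
        }
        ms, _ = quantify_field(field, refs, stain_config=stain_cfg)
        assert len(ms) == gt.n_cells
        truth = gt.table[["row", "col"]].to_numpy()
        for m in ms:
            i = ((truth - m.centroid) ** 2).sum(axis=1).argmin()
            for ch in ("green", "red"):
                expected = gt.table[f"true_{ch}"].iloc[i] / refs[ch].value
                assert m.normalized[ch] == pytest.approx(expected, abs=1e-12)

    def test_isotype_self_normalization_identity(self, stain_cfg):
        spec = tq.FieldSpec(n_colonies=0, n_single_cells=10, colony_radius_um=12.0, noise_sd=0.0, seed=41)
        iso, _ = tq.generate_isotype_field(spec)
        refs = {
            ch: isotype_reference([v])
            for ch, v in quantify_isotype_field(iso, ("green", "red"), stain_config=stain_cfg).items()
        }
        ms, _ = quantify_field(iso, refs, stain_config=stain_cfg)
        vals = [m.normalized["green"] for m in ms]
        assert np.mean(vals) == 1.0
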