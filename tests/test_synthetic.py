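"""Generator contracts: validation, rendering fidelity, determinism,
distributional faithfulness of the sampled plates."""

import math

import numpy as np
import pytest

from conftest import make_cells
from chondroscreen.io import migration_geometry
from chondroscreen.migration import ASSESSMENT_PLANES
from chondroscreen.synthetic import (
    EffectModel,
    GroundTruthCell,
    basal_effect,
    benchmark_effects,
    chondro_effect,
    default_effects,
    dose_plate_spec,
    ellipse_circularity,
    generate_field_stack,
    generate_plate_dataset,
    read_ground_truth,
    sample_truth_cells,
    sample_well_summaries,
    screen_plate_spec,
    trametinib_like_effect,
    write_ground_truth,
)


class TestDomainTypes:
    @pytest.mark.parametrize("kwargs", [
        dict(nominal_area=0.0),
        dict(aspect_ratio=0.5),
        dict(z_plane=-1),
        dict(texture_class="stripes"),
        dict(intensity_scale=0.0),
    ])
    def test_cell_invariants(self, kwargs):
        base = dict(centroid_xyz=(10.0, 10.0, 2.0), nominal_area=200.0,
                    aspect_ratio=2.0, z_plane=2, texture_class="spot")
        with pytest.raises(ValueError):
            GroundTruthCell(**{**base, **kwargs})

    def test_effect_model_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            EffectModel(
                area_um2_mean=200, area_um2_sd=10, aspect_mean=2, aspect_sd=0.1,
                migrated_fraction=0.1, texture_weights={"spot": 0.5, "ridge": 0.4},
            )

    def test_effect_model_fraction_range(self):
        with pytest.raises(ValueError, match="migrated_fraction"):
            EffectModel(
                area_um2_mean=200, area_um2_sd=10, aspect_mean=2, aspect_sd=0.1,
                migrated_fraction=1.2, texture_weights={"spot": 1.0},
            )

    def test_plate_specs_match_design_replicates(self):
        screen = screen_plate_spec(["A"], rng_seed=0)
        per_cond = screen.layout.table.query("role == 'compound'").groupby("concentration_nM").size()
        assert (per_cond == 2).all()
        dose = dose_plate_spec("A", rng_seed=0)
        per_conc = dose.layout.table.query("role == 'compound'").groupby("concentration_nM").size()
        assert (per_conc == 4).all() and len(per_conc) == 8


class TestEllipseCircularity:
    def test_disk_limit(self):
        assert ellipse_circularity(1.0) == pytest.approx(1.0)

    def test_three_to_one(self):
        # Ramanujan closed form: 4r / (3(r+1) - sqrt((3r+1)(r+3)))^2
        assert ellipse_circularity(3.0) == pytest.approx(0.663, abs=0.005)

    def test_monotone_decreasing(self):
        vals = [ellipse_circularity(r) for r in (1.0, 1.5, 2.0, 3.0, 4.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestFieldRendering:
    def test_empty_input_gives_pure_noise(self, migr_geo):
        stack, truth = generate_field_stack([], migr_geo, noise_sd=5.0, rng_seed=1, shape=(64, 64))
        assert truth == []
        nuc = stack.channel("nuclei")
        assert nuc.shape == (102, 64, 64)
        assert nuc.std() > 0  # noise present

    def test_single_cell_peak_at_planted_plane(self, migr_geo):
        cell = GroundTruthCell(
            centroid_xyz=(32.0, 32.0, 20.0), nominal_area=500.0, aspect_ratio=1.5,
            z_plane=20, texture_class="flat",
        )
        stack, truth = generate_field_stack([cell], migr_geo, noise_sd=0.0, shape=(64, 64))
        assert truth == [cell]
        nuc = stack.channel("nuclei")
        z, y, x = np.unravel_index(np.argmax(nuc), nuc.shape)
        assert z == 20 and abs(y - 32) <= 1 and abs(x - 32) <= 1

    def test_out_of_field_centroid_rejected(self, migr_geo):
        cell = GroundTruthCell(
            centroid_xyz=(500.0, 10.0, 5.0), nominal_area=200.0, aspect_ratio=1.0,
            z_plane=5, texture_class="spot",
        )
        with pytest.raises(ValueError, match="outside"):
            generate_field_stack([cell], migr_geo, shape=(64, 64))

    def test_negative_noise_rejected(self, migr_geo):
        with pytest.raises(ValueError):
            generate_field_stack([], migr_geo, noise_sd=-1.0, shape=(32, 32))

    def test_footprint_halfmax_area_matches_nominal(self, morph_geo):
        """Rendered-footprint consistency: area above half-maximum within 10%
        of the nominal µm² footprint for isolated noise-free cells."""
        for seed in range(5):
            cells = make_cells(chondro_effect(), 1, morph_geo, (288, 288), seed=seed)
            stack, (cell,) = generate_field_stack(
                cells, morph_geo, noise_sd=0.0, rng_seed=seed, shape=(288, 288)
            )
            plane = stack.channel("cytoplasm")[cell.z_plane]
            area_px = int((plane > plane.max() / 2).sum())
            area_um2 = area_px * morph_geo.pixel_area_um2
            assert area_um2 == pytest.approx(cell.nominal_area, rel=0.10)


class TestPlateGeneration:
    @pytest.fixture
    def tiny_plate(self):
        spec = screen_plate_spec(
            ["T"], concentrations_nM=(100.0,), replicates=2,
            n_negative=2, n_positive=2, rng_seed=11,
        )
        effects = {**default_effects(), "T": trametinib_like_effect()}
        return spec, effects, migration_geometry(1.0)

    def test_same_seed_is_byte_identical(self, tiny_plate):
        spec, effects, geo = tiny_plate
        s1, t1, _ = generate_plate_dataset(spec, effects, geo, shape=(128, 128), noise_sd=10.0)
        s2, t2, _ = generate_plate_dataset(spec, effects, geo, shape=(128, 128), noise_sd=10.0)
        assert t1 == t2
        for w in s1:
            for c in s1[w].channels:
                np.testing.assert_array_equal(s1[w].channels[c], s2[w].channels[c])

    def test_missing_effect_model_raises(self, tiny_plate):
        spec, _, geo = tiny_plate
        with pytest.raises(KeyError, match="EffectModel"):
            generate_plate_dataset(spec, default_effects(), geo, shape=(128, 128))

    def test_ground_truth_round_trip(self, tiny_plate, tmp_path):
        spec, effects, geo = tiny_plate
        _, truths, _ = generate_plate_dataset(spec, effects, geo, shape=(128, 128))
        p = write_ground_truth(tmp_path / "truth.csv", truths)
        back = read_ground_truth(p)
        assert set(back) == set(truths)
        for w in truths:
            assert len(back[w]) == len(truths[w])
            for a, b in zip(back[w], truths[w]):
                assert a.z_plane == b.z_plane
                assert a.texture_class == b.texture_class
                assert a.nominal_area == pytest.approx(b.nominal_area, rel=1e-4)


class TestSamplingFidelity:
    def test_truth_cell_means_track_effect_model(self, migr_geo):
        """Emulation fidelity: empirical means of sampled fields stay within
        4 SE of the EffectModel means at n >= 200."""
        eff = basal_effect()
        rng = np.random.default_rng(5)
        cells = sample_truth_cells(eff, 300, migr_geo, (2048, 2048), rng)
        areas = np.array([c.nominal_area for c in cells])
        aspects = np.array([c.aspect_ratio for c in cells])
        assert abs(areas.mean() - eff.area_um2_mean) < 4 * eff.area_um2_sd / math.sqrt(len(cells))
        assert abs(aspects.mean() - eff.aspect_mean) < 4 * eff.aspect_sd / math.sqrt(len(cells))
        migrated = np.mean([c.z_plane >= eff.migration_planes[0] for c in cells])
        se = math.sqrt(eff.migrated_fraction * (1 - eff.migrated_fraction) / len(cells))
        assert abs(migrated - eff.migrated_fraction) < 4 * se

    def test_zero_migrated_fraction_stays_at_floor(self, migr_geo):
        from dataclasses import replace
        eff = replace(basal_effect(), migrated_fraction=0.0)
        rng = np.random.default_rng(6)
        cells = sample_truth_cells(eff, 100, migr_geo, (1024, 1024), rng)
        assert all(c.z_plane <= eff.floor_planes[1] for c in cells)
        assert sum(c.z_plane in ASSESSMENT_PLANES for c in cells) == 0

    def test_well_summary_means(self):
        """Per-well mean areas concentrate around the condition mean: the
        Monte-Carlo check against the sampling distribution."""
        spec = screen_plate_spec([], n_negative=24, n_positive=0, rng_seed=3)
        eff = basal_effect()
        summ = sample_well_summaries(spec, {"negative": eff})
        # well means scatter with the well-level CV; their average converges
        se = eff.area_um2_mean * eff.well_cv_area / math.sqrt(len(summ))
        assert abs(summ["mean_area_um2"].mean() - eff.area_um2_mean) < 4 * se
        assert abs(summ["mean_roundness"].mean() - eff.roundness_mean) < 0.02

    def test_summary_migration_scales_with_fraction(self):
        from dataclasses import replace
        spec = screen_plate_spec([], n_negative=8, n_positive=0, rng_seed=4)
        quiet = replace(basal_effect(), migrated_fraction=0.0)
        summ0 = sample_well_summaries(spec, {"negative": quiet})
        assert (summ0["migration_count"] == 0).all()
        summ = sample_well_summaries(spec, {"negative": basal_effect()})
        eff = basal_effect()
        expected = eff.n_cells_mean * eff.migrated_fraction * 5 / 91
        assert summ["migration_count"].mean() == pytest.approx(expected, rel=0.15)

    def test_benchmark_effects_share_modest_cv(self):
        eff = benchmark_effects()
        assert eff["negative"].well_cv_area == eff["positive"].well_cv_area
        assert eff["negative"].area_um2_mean == pytest.approx(231.6)
        assert eff["positive"].area_um2_mean == pytest.approx(694.4)
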