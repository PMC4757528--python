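"""FTV computation vs brute-force enumeration, monotonicity, predictors."""

from __future__ import annotations

import numpy as np
import pytest

from ftvsweep.enhancement import EnhancementMaps
from ftvsweep.ftv import (
    FTVSurface,
    ThresholdGrid,
    build_predictors,
    compute_ftv,
    default_grid,
    enhancing_mask,
    ftv_surface,
)

from .conftest import VOXEL, random_study
from .oracles import bruteforce_ftv_count
from ftvsweep.enhancement import compute_enhancement_maps


def _maps_from_arrays(pe_early, ser, valid=None) -> EnhancementMaps:
    pe_early = np.asarray(pe_early, dtype=float)
    if valid is None:
        valid = np.ones(pe_early.shape, dtype=bool)
    return EnhancementMaps(
        pe_early=pe_early,
        pe_late=np.ones_like(pe_early),
        valid=valid,
        ser=np.asarray(ser, dtype=float),
    )


class TestGrid:
    def test_default_grid_is_the_study_grid(self):
        grid = default_grid()
        assert grid.pe_thresholds == tuple(range(30, 201, 10))
        assert len(grid.pe_thresholds) == 18
        assert grid.ser_thresholds[0] == 0.0 and grid.ser_thresholds[-1] == 2.0
        assert len(grid.ser_thresholds) == 11
        assert np.allclose(np.diff(grid.ser_thresholds), 0.2)
        assert grid.shape == (18, 11)

    def test_non_increasing_thresholds_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            ThresholdGrid(pe_thresholds=(30.0, 30.0), ser_thresholds=(0.0,))

    def test_index_of_rejects_off_grid_cells(self):
        grid = default_grid()
        assert grid.index_of(70.0, 0.0) == (4, 0)
        with pytest.raises(KeyError):
            grid.index_of(75.0, 0.0)


class TestEnhancingMask:
    def test_threshold_above_maximum_gives_empty_mask(self):
        maps = _maps_from_arrays(np.full((4, 4, 4), 80.0), np.ones((4, 4, 4)))
        voi = np.ones((4, 4, 4), dtype=bool)
        assert not enhancing_mask(maps, voi, pe_t=200.0, min_cluster_voxels=1).any()

    def test_small_component_removed_blob_kept(self):
        """A 10-voxel blob survives min_cluster=3; an isolated voxel does not."""
        pe = np.zeros((6, 6, 6))
        blob = [(1, 1, 1), (1, 1, 2), (1, 2, 1), (1, 2, 2), (2, 1, 1),
                (2, 1, 2), (2, 2, 1), (2, 2, 2), (3, 2, 2), (3, 3, 3)]
        for idx in blob:
            pe[idx] = 100.0
        pe[5, 5, 5] = 100.0  # isolated
        maps = _maps_from_arrays(pe, np.ones_like(pe))
        voi = np.ones(pe.shape, dtype=bool)
        mask = enhancing_mask(maps, voi, pe_t=70.0, min_cluster_voxels=3)
        assert mask.sum() == 10
        assert not mask[5, 5, 5]

    def test_min_cluster_one_is_identity_filter(self, rng):
        pe = rng.uniform(0, 200, size=(5, 5, 5))
        maps = _maps_from_arrays(pe, np.ones_like(pe))
        voi = np.ones(pe.shape, dtype=bool)
        mask = enhancing_mask(maps, voi, pe_t=100.0, min_cluster_voxels=1)
        assert np.array_equal(mask, pe >= 100.0)

    def test_connectivity_six_separates_diagonal_voxels(self):
        pe = np.zeros((4, 4, 4))
        pe[0, 0, 0] = pe[1, 1, 1] = 100.0  # diagonal pair
        maps = _maps_from_arrays(pe, np.ones_like(pe))
        voi = np.ones(pe.shape, dtype=bool)
        assert enhancing_mask(maps, voi, 70.0, min_cluster_voxels=2, connectivity=26).sum() == 2
        assert enhancing_mask(maps, voi, 70.0, min_cluster_voxels=2, connectivity=6).sum() == 0


class TestComputeFTV:
    def test_voxel_volume_arithmetic(self, rng):
        """100 passing voxels at 0.7 x 0.94 x 2.0 mm -> 0.1316 cc."""
        pe = np.zeros((10, 10, 4))
        pe.ravel()[:100] = 150.0
        study = random_study(rng, shape=pe.shape)
        maps = _maps_from_arrays(pe, np.ones_like(pe))
        voi = np.ones(pe.shape, dtype=bool)
        ftv = compute_ftv(study, maps, voi, pe_t=100.0, ser_t=0.0, min_cluster_voxels=1)
        assert ftv == pytest.approx(100 * 0.7 * 0.94 * 2.0 / 1000.0)
        assert ftv == pytest.approx(0.1316)

    def test_ser_zero_gates_nothing_nonnegative(self, rng):
        study = random_study(rng, shape=(6, 6, 4))
        maps = compute_enhancement_maps(study, s0_floor=10.0)
        voi = np.ones(study.shape, dtype=bool)
        mask = enhancing_mask(maps, voi, 70.0)
        ftv = compute_ftv(study, maps, voi, 70.0, 0.0)
        assert ftv == pytest.approx(mask.sum() * study.voxel_volume_cc)

    def test_matches_bruteforce_enumeration(self, rng):
        """Exact voxel-count equality with a triple-loop + BFS oracle on
        random maps, including the connectivity step."""
        study = random_study(rng, shape=(12, 12, 6))
        maps = compute_enhancement_maps(study, s0_floor=10.0)
        voi = np.zeros(study.shape, dtype=bool)
        voi[2:10, 1:11, 1:5] = True
        for pe_t, ser_t in [(30.0, 0.0), (70.0, 0.4), (100.0, 1.0), (150.0, 1.8), (60.0, 0.2)]:
            expected = bruteforce_ftv_count(
                maps.pe_early, maps.ser, maps.valid, voi, pe_t, ser_t, min_cluster=4
            )
            got = compute_ftv(study, maps, voi, pe_t, ser_t, min_cluster_voxels=4)
            assert got == pytest.approx(expected * study.voxel_volume_cc)


class TestSurface:
    def test_surface_shape_and_spotcheck(self, rng):
        study = random_study(rng, shape=(10, 10, 5))
        maps = compute_enhancement_maps(study, s0_floor=10.0)
        voi = np.ones(study.shape, dtype=bool)
        surface = ftv_surface(study, maps, voi)
        assert surface.ftv_cc.shape == (18, 11)
        grid = surface.grid
        for _ in range(10):
            i = rng.integers(0, 18)
            j = rng.integers(0, 11)
            direct = compute_ftv(
                study, maps, voi, grid.pe_thresholds[i], grid.ser_thresholds[j]
            )
            assert surface.ftv_cc[i, j] == pytest.approx(direct)

    def test_zero_pe_volume_gives_zero_surface(self, rng):
        study = random_study(rng, shape=(6, 6, 4))
        maps = _maps_from_arrays(np.zeros(study.shape), np.zeros(study.shape))
        voi = np.ones(study.shape, dtype=bool)
        surface = ftv_surface(study, maps, voi)
        assert np.all(surface.ftv_cc == 0.0)

    def test_monotone_non_increasing_both_axes(self, rng):
        study = random_study(rng, shape=(10, 10, 5))
        maps = compute_enhancement_maps(study, s0_floor=10.0)
        voi = np.ones(study.shape, dtype=bool)
        f = ftv_surface(study, maps, voi).ftv_cc
        assert np.all(np.diff(f, axis=0) <= 1e-12)
        assert np.all(np.diff(f, axis=1) <= 1e-12)

    def test_scales_linearly_with_voxel_volume(self, rng):
        from ftvsweep.enhancement import DCEStudy

        study = random_study(rng, shape=(8, 8, 4))
        big = DCEStudy(
            patient_id=study.patient_id, visit=study.visit,
            s0=study.s0, s_early=study.s_early, s_late=study.s_late,
            voxel_size_mm=(1.4, 1.88, 4.0),  # 8x the voxel volume
        )
        maps = compute_enhancement_maps(study, s0_floor=10.0)
        voi = np.ones(study.shape, dtype=bool)
        a = ftv_surface(study, maps, voi).ftv_cc
        b = ftv_surface(big, maps, voi).ftv_cc
        assert np.allclose(b, 8.0 * a)


def test_surfaces_export_long_format(rng):
    from ftvsweep.ftv import surfaces_to_frame

    study = random_study(rng, shape=(6, 6, 4))
    maps = compute_enhancement_maps(study, s0_floor=10.0)
    voi = np.ones(study.shape, dtype=bool)
    surface = ftv_surface(study, maps, voi)
    df = surfaces_to_frame([surface])
    assert list(df.columns) == ["patient_id", "visit", "pe_t", "ser_t", "ftv_cc"]
    assert len(df) == 198
    row = df[(df.pe_t == 70.0) & (df.ser_t == 0.0)].iloc[0]
    assert row.ftv_cc == pytest.approx(surface.at(70.0, 0.0))


def _surface(grid, values, patient="P0", visit="MRI_1") -> FTVSurface:
    arr = np.full(grid.shape, float(values)) if np.isscalar(values) else np.asarray(values)
    return FTVSurface(ftv_cc=arr.astype(float), grid=grid, patient_id=patient, visit=visit)


class TestPredictors:
    def test_percent_change_arithmetic(self):
        grid = default_grid()
        record = build_predictors(
            {"MRI_1": _surface(grid, 40.0), "MRI_f": _surface(grid, 10.0, visit="MRI_f")}
        )
        assert np.allclose(record.delta_ftvf, -75.0)
        assert np.allclose(record.ftv_f, 10.0)

    def test_no_change_gives_zero_delta(self):
        grid = default_grid()
        record = build_predictors(
            {"MRI_1": _surface(grid, 25.0), "MRI_2": _surface(grid, 25.0, visit="MRI_2")}
        )
        assert np.allclose(record.delta_ftv2, 0.0)

    def test_zero_baseline_cell_yields_missing_delta_only(self):
        grid = default_grid()
        base = np.full(grid.shape, 40.0)
        base[0, 0] = 0.0
        record = build_predictors(
            {"MRI_1": _surface(grid, base), "MRI_f": _surface(grid, 10.0, visit="MRI_f")}
        )
        assert np.isnan(record.delta_ftvf[0, 0])
        assert np.isfinite(record.delta_ftvf[1:, :]).all()
        assert record.ftv_f[0, 0] == 10.0  # absolute FTV unaffected

    def test_missing_mri2_yields_all_missing_delta2(self):
        grid = default_grid()
        record = build_predictors(
            {"MRI_1": _surface(grid, 40.0), "MRI_f": _surface(grid, 10.0, visit="MRI_f")}
        )
        assert np.isnan(record.delta_ftv2).all()
        assert np.isfinite(record.delta_ftvf).all()

    def test_missing_baseline_is_structural_error(self):
        grid = default_grid()
        with pytest.raises(ValueError, match="MRI_1"):
            build_predictors({"MRI_f": _surface(grid, 10.0, visit="MRI_f")})
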