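"""Most-invasive FOV search, local density, and tumor-bed estimation."""

import numpy as np
import pytest

from conftest import make_classmap
from stromaratio.errors import (
    EmptyMapError,
    EmptyRomError,
    NoTumorError,
    NoValidFovError,
    ParameterError,
)
from stromaratio.region_of_measurement import (
    brute_force_most_invasive,
    disk_kernel,
    dynamic_threshold,
    estimate_tumor_bed,
    find_most_invasive_fov,
    local_tumor_density,
)
from stromaratio.synthetic_data import MaskSpec, generate_mask
from stromaratio.tissue_model import BACKGROUND, NODATA, STROMA, TUMOR


class TestMostInvasiveFov:
    def test_uniform_tumor_selects_first_grid_center(self, uniform_tumor_map):
        cand, rom = find_most_invasive_fov(uniform_tumor_map, stride_px=8)
        assert cand.tumor_fraction == 1.0
        assert cand.center == (0, 0)  # row-major tie rule
        assert rom.kind == "MI"

    def test_two_blob_map_matches_brute_force(self):
        # one pure-tumor blob, one 50/50 blob; exhaustive search is the oracle
        labels = np.full((64, 64), BACKGROUND, dtype=np.uint8)
        rr, cc = np.mgrid[0:64, 0:64]
        blob1 = ((rr - 20) ** 2 + (cc - 20) ** 2) <= 18**2
        blob2 = ((rr - 44) ** 2 + (cc - 44) ** 2) <= 18**2
        labels[blob1] = TUMOR
        labels[blob2] = np.where(((rr + cc) % 2 == 0), TUMOR, STROMA)[blob2]
        cm = make_classmap(labels, mpp=100.0)
        cand, _ = find_most_invasive_fov(cm, radius_um=1600, stride_px=1)
        oracle = brute_force_most_invasive(cm, radius_um=1600, stride_px=1)
        assert cand.center == oracle.center
        assert cand.tumor_fraction == oracle.tumor_fraction
        assert cand.tissue_fraction == oracle.tissue_fraction

    def test_thin_rim_has_no_valid_fov(self):
        labels = np.full((64, 64), BACKGROUND, dtype=np.uint8)
        labels[0, :] = TUMOR  # thin rim: every disk mostly background
        cm = make_classmap(labels, mpp=100.0)
        with pytest.raises(NoValidFovError):
            find_most_invasive_fov(cm, radius_um=1600, stride_px=4)

    def test_all_nodata_map(self):
        cm = make_classmap(np.full((32, 32), NODATA), mpp=100.0)
        with pytest.raises(EmptyMapError):
            find_most_invasive_fov(cm)

    def test_translation_equivariance(self):
        cm, _ = generate_mask(MaskSpec(width_px=96, height_px=96, mpp=50.0, seed=3))
        cand, _ = find_most_invasive_fov(cm, stride_px=1)
        dr, dc = 5, 3
        shifted = np.full((96 + dr, 96 + dc), NODATA, dtype=np.uint8)
        shifted[dr:, dc:] = cm.labels
        cm2 = make_classmap(shifted, mpp=50.0)
        cand2, _ = find_most_invasive_fov(cm2, stride_px=1)
        assert cand2.center == (cand.center[0] + dr, cand.center[1] + dc)

    def test_mask_is_disk_intersect_valid(self, uniform_tumor_map):
        cand, rom = find_most_invasive_fov(uniform_tumor_map, stride_px=8)
        radius_px = 1600.0 / uniform_tumor_map.meta.mpp
        rr, cc = np.mgrid[0:64, 0:64]
        disk = ((rr - cand.center[0]) ** 2 + (cc - cand.center[1]) ** 2) <= radius_px**2
        assert np.array_equal(rom.mask, disk)


class TestLocalDensity:
    def test_uniform_maps(self, uniform_tumor_map, uniform_stroma_map):
        d = local_tumor_density(uniform_tumor_map, kernel_radius_um=500)
        assert np.all(d.values == 1.0)  # border disks clip-normalized
        d0 = local_tumor_density(uniform_stroma_map, kernel_radius_um=500)
        assert np.all(d0.values == 0.0)

    def test_single_tumor_pixel_density_is_one_over_disk_area(self):
        labels = np.full((41, 41), STROMA, dtype=np.uint8)
        labels[20, 20] = TUMOR
        cm = make_classmap(labels, mpp=100.0)
        d = local_tumor_density(cm, kernel_radius_um=500)  # radius 5 px
        k = int(disk_kernel(5.0).sum())
        assert d.values[20, 20] == pytest.approx(1.0 / k)

    def test_kernel_smaller_than_pixel(self, uniform_tumor_map):
        with pytest.raises(ParameterError):
            local_tumor_density(uniform_tumor_map, kernel_radius_um=50)

    def test_nodata_propagates(self):
        labels = np.full((20, 20), TUMOR, dtype=np.uint8)
        labels[5, 5] = NODATA
        cm = make_classmap(labels, mpp=100.0)
        d = local_tumor_density(cm, kernel_radius_um=300)
        assert np.isnan(d.values[5, 5])
        assert d.values[0, 0] == 1.0

    def test_matches_brute_force_disk_counts(self):
        cm, _ = generate_mask(MaskSpec(width_px=96, height_px=96, mpp=50.0, seed=7))
        d = local_tumor_density(cm, kernel_radius_um=400)
        kernel = disk_kernel(400.0 / 50.0)
        kr = kernel.shape[0] // 2
        rng = np.random.default_rng(0)
        for _ in range(20):
            r, c = rng.integers(0, 96, size=2)
            r0, r1 = max(0, r - kr), min(96, r + kr + 1)
            c0, c1 = max(0, c - kr), min(96, c + kr + 1)
            ksub = kernel[r0 - r + kr : r1 - r + kr, c0 - c + kr : c1 - c + kr]
            win = cm.labels[r0:r1, c0:c1]
            n_tumor = np.count_nonzero(ksub & (win == TUMOR))
            n_valid = np.count_nonzero(ksub & (win != NODATA))
            assert d.values[r, c] == pytest.approx(n_tumor / n_valid)


class TestDynamicThreshold:
    def test_piecewise_linear_form(self):
        assert dynamic_threshold(50.0, 0.2, 0.6, 50.0) == 0.2
        assert dynamic_threshold(0.0, 0.2, 0.6, 50.0) == 0.6
        assert dynamic_threshold(25.0, 0.2, 0.6, 50.0) == pytest.approx(0.4)
        assert dynamic_threshold(100.0, 0.2, 0.6, 50.0) == 0.2

    def test_monotone_non_increasing_in_area(self):
        areas = np.linspace(0, 80, 40)
        taus = [dynamic_threshold(a, 0.15, 0.5, 50.0) for a in areas]
        assert all(t1 >= t2 for t1, t2 in zip(taus, taus[1:]))

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            dynamic_threshold(-1.0)
        with pytest.raises(ParameterError):
            dynamic_threshold(1.0, tau_base=0.6, tau_max=0.5)


class TestTumorBed:
    def test_all_tumor_rom_is_entire_map(self, uniform_tumor_map):
        rom = estimate_tumor_bed(uniform_tumor_map, min_component_mm2=0.0)
        assert rom.mask.all()

    def test_no_tumor_raises(self, uniform_stroma_map):
        with pytest.raises(NoTumorError):
            estimate_tumor_bed(uniform_stroma_map)

    def test_threshold_above_max_density_gives_empty_rom(self):
        # one tumor pixel in stroma: max density 1/k, far below tau ~ 0.9
        labels = np.full((41, 41), STROMA, dtype=np.uint8)
        labels[20, 20] = TUMOR
        cm = make_classmap(labels, mpp=100.0)
        with pytest.raises(EmptyRomError):
            estimate_tumor_bed(cm, tau_base=0.9, tau_max=0.95)

    def test_rom_area_decreases_with_tau(self):
        # 2 mm tumor disk in a stroma field
        h = w = 120
        rr, cc = np.mgrid[0:h, 0:w]
        labels = np.where(
            ((rr - 60) ** 2 + (cc - 60) ** 2) <= 50**2, TUMOR, STROMA
        ).astype(np.uint8)
        cm = make_classmap(labels, mpp=20.0)
        areas = []
        for tau in (0.1, 0.3, 0.5):
            rom = estimate_tumor_bed(
                cm, tau_base=tau, tau_max=tau + 1e-6, min_component_mm2=0.0
            )
            areas.append(rom.area_px)
        assert areas[0] > areas[1] > areas[2]

    def test_monotone_nesting_in_tau(self):
        cm, _ = generate_mask(MaskSpec(width_px=96, height_px=96, mpp=50.0, seed=11))
        prev = None
        for tau in np.linspace(0.05, 0.6, 8):
            try:
                rom = estimate_tumor_bed(
                    cm, tau_base=tau, tau_max=tau + 1e-6, min_component_mm2=0.0
                )
            except EmptyRomError:
                mask = np.zeros(cm.shape, dtype=bool)
            else:
                mask = rom.mask
            if prev is not None:
                assert np.all(prev | ~mask)  # mask subset of previous
            prev = mask

    def test_small_components_removed(self):
        labels = np.full((100, 100), STROMA, dtype=np.uint8)
        rr, cc = np.mgrid[0:100, 0:100]
        labels[((rr - 30) ** 2 + (cc - 30) ** 2) <= 25**2] = TUMOR
        labels[95:97, 95:97] = TUMOR  # speck far away
        cm = make_classmap(labels, mpp=20.0)
        rom = estimate_tumor_bed(cm, tau_base=0.4, tau_max=0.41, min_component_mm2=0.05)
        assert not rom.mask[95:, 95:].any()
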