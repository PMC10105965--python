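import math

import numpy as np
import pytest

from septodg import synthetic_data as synth
from septodg import tracing as tr


def flood_fill_components(mask: np.ndarray) -> list[int]:
    """Brute-force 26-connected component sizes (oracle for small volumes)."""
    visited = np.zeros(mask.shape, dtype=bool)
    sizes = []
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    for idx in np.argwhere(mask):
        idx = tuple(idx)
        if visited[idx]:
            continue
        stack = [idx]
        visited[idx] = True
        size = 0
        while stack:
            z, y, x = stack.pop()
            size += 1
            for dz, dy, dx in offsets:
                nz, ny, nx = z + dz, y + dy, x + dx
                if (
                    0 <= nz < mask.shape[0]
                    and 0 <= ny < mask.shape[1]
                    and 0 <= nx < mask.shape[2]
                    and mask[nz, ny, nx]
                    and not visited[nz, ny, nx]
                ):
                    visited[nz, ny, nx] = True
                    stack.append((nz, ny, nx))
        sizes.append(size)
    return sorted(sizes)


class TestThresholdChannel:
    def test_bimodal_separates_exactly(self):
        img = np.zeros((64, 64))
        img[10:20, 10:20] = 200.0
        mask, _thr = tr.threshold_channel(img)
        assert mask.sum() == 100

    def test_all_zero_channel_empty_mask(self):
        with pytest.warns(UserWarning, match="constant"):
            mask, _ = tr.threshold_channel(np.zeros((8, 8)))
        assert not mask.any()

    def test_noisy_painted_fraction_recovered(self, rng):
        img = rng.normal(0.0, 5.0, (256, 256))
        true = np.zeros((256, 256), dtype=bool)
        true[:44, :44] = True  # ~3% of pixels
        img[true] += 200.0
        mask, _ = tr.threshold_channel(img)
        rec = mask.sum() / true.sum()
        assert rec == pytest.approx(1.0, rel=0.1)

    def test_fixed_and_percentile_methods(self):
        img = np.arange(100.0).reshape(10, 10)
        m1, t1 = tr.threshold_channel(img, method="fixed", value=50.0)
        assert m1.sum() == 49
        m2, t2 = tr.threshold_channel(img, method="percentile", percentile=90.0)
        assert m2.sum() == 10  # values strictly above the 90th percentile (89.1)


class TestConnectivityRatio:
    def _roi(self, shape, sl, name):
        mask = np.zeros(shape, dtype=bool)
        mask[sl] = True
        return tr.RoiMask(name=name, mask=mask)

    def test_simple_ratio(self):
        shape = (1, 100, 100)
        mcherry = np.zeros(shape, dtype=bool)
        mcherry[0, :10, :20] = True  # 200 px in MS
        mcherry[0, 50:60, 50:60] = True  # 100 px in starter
        ms = self._roi(shape, (0, slice(0, 30), slice(0, 30)), "MS")
        starter = self._roi(shape, (0, slice(40, 70), slice(40, 70)), "starter-DG")
        res = tr.connectivity_ratio(mcherry, [ms], starter, (1.0, 1.0))
        assert res.ratios["MS"] == pytest.approx(2.0)

    def test_no_label_all_zero_ratios(self):
        shape = (1, 50, 50)
        mcherry = np.zeros(shape, dtype=bool)
        mcherry[0, 40:45, 40:45] = True  # starter only
        ms = self._roi(shape, (0, slice(0, 20), slice(0, 20)), "MS")
        starter = self._roi(shape, (0, slice(35, 50), slice(35, 50)), "starter-DG")
        res = tr.connectivity_ratio(mcherry, [ms], starter, (1.0, 1.0))
        assert res.ratios["MS"] == 0.0

    def test_zero_starter_flagged(self):
        shape = (1, 50, 50)
        ms = self._roi(shape, (0, slice(0, 20), slice(0, 20)), "MS")
        starter = self._roi(shape, (0, slice(35, 50), slice(35, 50)), "starter-DG")
        res = tr.connectivity_ratio(np.zeros(shape, dtype=bool), [ms], starter, (1.0, 1.0))
        assert res.undefined

    def test_ranking_recovery_over_seeds(self):
        hits = 0
        n_rep = 8
        for seed in range(n_rep):
            cfg = synth.SimConfig(
                seed=seed, imaging=synth.ImagingParams(soma_count=80, section_shape=(600, 600))
            )
            vol, rois, truth = synth.simulate_tracing_volume(cfg, mode="retrograde_sections")
            mask, _ = tr.threshold_channel(vol.channel("mCherry"))
            inputs = [r for n, r in rois.items() if n != "starter-DG"]
            res = tr.connectivity_ratio(mask, inputs, rois["starter-DG"], (1.0, 1.0))
            order = [res.ratios["MS"], res.ratios["DB"], res.ratios["VTA"]]
            hits += order == sorted(order, reverse=True)
        assert hits >= 0.95 * n_rep - 1

    def test_invariant_under_intensity_rescaling(self, rng):
        cfg = synth.SimConfig(seed=3, imaging=synth.ImagingParams(soma_count=40))
        vol, rois, _ = synth.simulate_tracing_volume(cfg, mode="retrograde_sections")
        img = vol.channel("mCherry")
        inputs = [r for n, r in rois.items() if n != "starter-DG"]
        m1, _ = tr.threshold_channel(img)
        m2, _ = tr.threshold_channel(img * 3.0)  # otsu is relative
        r1 = tr.connectivity_ratio(m1, inputs, rois["starter-DG"], (1.0, 1.0))
        r2 = tr.connectivity_ratio(m2, inputs, rois["starter-DG"], (1.0, 1.0))
        for k in r1.ratios:
            assert r1.ratios[k] == pytest.approx(r2.ratios[k], rel=0.02)


class TestColocalization:
    def test_all_positive(self):
        cfg = synth.SimConfig(
            seed=0, imaging=synth.ImagingParams(soma_count=30, colocalization_fraction=1.0)
        )
        vol, rois, truth = synth.simulate_tracing_volume(cfg, mode="retrograde_sections")
        ms = rois["MS"].mask
        res = tr.colocalization_fraction(
            np.where(ms, vol.channel("mCherry"), 0.0), vol.channel("GABA"), (1.0, 1.0)
        )
        assert res["fraction"] == pytest.approx(1.0)

    def test_zero_gaba_channel(self):
        cfg = synth.SimConfig(
            seed=0, imaging=synth.ImagingParams(soma_count=30, colocalization_fraction=0.0,
                                                noise_sd=0.0)
        )
        vol, rois, _ = synth.simulate_tracing_volume(cfg, mode="retrograde_sections")
        ms = rois["MS"].mask
        res = tr.colocalization_fraction(
            np.where(ms, vol.channel("mCherry"), 0.0),
            np.zeros_like(vol.channel("GABA")),
            (1.0, 1.0),
        )
        assert res["fraction"] == 0.0

    def test_binomial_recovery_064(self):
        cfg = synth.SimConfig(
            seed=21, imaging=synth.ImagingParams(soma_count=200, section_shape=(768, 768))
        )
        vol, rois, truth = synth.simulate_tracing_volume(cfg, mode="retrograde_sections")
        ms = rois["MS"].mask
        res = tr.colocalization_fraction(
            np.where(ms, vol.channel("mCherry"), 0.0), vol.channel("GABA"), (1.0, 1.0)
        )
        assert res["n_mcherry"] == 200
        assert res["fraction"] == pytest.approx(truth.colocalized_fraction, abs=0.02)
        assert res["fraction"] == pytest.approx(0.64, abs=0.07)

    def test_no_somata_undefined(self):
        res = tr.colocalization_fraction(
            np.zeros((1, 64, 64)), np.zeros((1, 64, 64)), (1.0, 1.0)
        )
        assert res["undefined"]


class TestCountCells:
    def test_fifty_spheres(self):
        cfg = synth.SimConfig(seed=1, imaging=synth.ImagingParams(soma_count=50))
        vol, rois, truth = synth.simulate_tracing_volume(cfg, mode="anterograde_volume")
        soma_vol = vol.ms_soma_volume
        out = tr.count_cells(soma_vol.channel("YFP_soma"), rois["MS"], (1.0, 1.0))
        assert out["count"] == 50
        expected_density = 50 / (rois["MS"].mask.sum() * 1.0 * 40.0)
        assert out["density"] == pytest.approx(expected_density)

    def test_empty_channel(self):
        roi = tr.RoiMask(name="MS", mask=np.ones((1, 32, 32), dtype=bool))
        with pytest.warns(UserWarning, match="constant"):
            out = tr.count_cells(np.zeros((1, 32, 32)), roi, (1.0, 1.0))
        assert out["count"] == 0

    def test_touching_spheres_split_in_two(self):
        img = np.zeros((1, 64, 64))
        synth.paint_disk(img[0], (30.0, 20.0), 6.0, 200.0)
        synth.paint_disk(img[0], (30.0, 32.0), 6.0, 200.0)  # touching at boundary
        labels = tr.detect_somata(img, (1.0, 1.0), min_diameter_um=8.0)
        assert labels.max() == 2


class TestReconstructProcesses:
    def test_empty_volume(self):
        vol = tr.LabeledVolume(
            channels={"YFP": np.zeros((10, 20, 20))}, voxel_size_um=(1.0, 1.0, 1.0)
        )
        roi = tr.RoiMask(name="hilus", mask=np.ones((10, 20, 20), dtype=bool))
        with pytest.warns(UserWarning, match="constant"):
            res = tr.reconstruct_processes_3d(vol, roi, starter_cell_density=1.0)
        assert res.object_count == 0
        assert res.normalized_density == 0.0

    def test_single_capsule_analytic_volume(self):
        vox = (0.5, 0.5, 0.5)
        arr = np.zeros((120, 24, 24))
        analytic = synth.add_capsule(
            arr, np.array([5.0, 6.0, 6.0]), np.array([55.0, 6.0, 6.0]), 1.0, vox, value=200.0
        )
        assert analytic == pytest.approx(math.pi * 1.0 * 50.0 + 4.0 / 3.0 * math.pi, rel=1e-9)
        vol = tr.LabeledVolume(channels={"YFP": arr}, voxel_size_um=vox)
        roi = tr.RoiMask(name="hilus", mask=np.ones(arr.shape, dtype=bool))
        res = tr.reconstruct_processes_3d(vol, roi, threshold=100.0, starter_cell_density=1.0)
        assert res.object_count == 1
        assert res.summed_volume_um3 == pytest.approx(analytic, rel=0.1)

    def test_capsule_voxelization_converges(self):
        errs = []
        for vox in (1.0, 0.5):
            arr = np.zeros((int(70 / vox), int(12 / vox), int(12 / vox)))
            analytic = synth.add_capsule(
                arr, np.array([10.0, 6.0, 6.0]), np.array([60.0, 6.0, 6.0]), 1.5,
                (vox, vox, vox), value=1.0,
            )
            errs.append(abs(arr.sum() * vox**3 - analytic) / analytic)
        assert errs[1] < errs[0]

    def test_labeling_matches_flood_fill_oracle(self, rng):
        from skimage import measure

        for _ in range(5):
            mask = rng.uniform(size=(32, 32, 32)) < 0.2
            labels = measure.label(mask, connectivity=3)
            sizes = sorted(np.bincount(labels.ravel())[1:].tolist())
            assert sizes == flood_fill_components(mask)

    def test_density_ratio_two_conditions(self):
        ratios = []
        for seed in range(5):
            dens = []
            for count in (15, 30):
                cfg = synth.SimConfig(
                    seed=seed,
                    imaging=synth.ImagingParams(process_count=count, volume_shape=(40, 96, 96)),
                )
                vol, rois, _ = synth.simulate_tracing_volume(cfg, mode="anterograde_volume")
                res = tr.reconstruct_processes_3d(
                    vol, rois["hilus"], threshold=100.0, starter_cell_density=1.0
                )
                dens.append(res.normalized_density)
            ratios.append(dens[1] / dens[0])
        assert np.mean(ratios) == pytest.approx(2.0, abs=0.2)

    def test_summed_volume_invariant_under_translation(self):
        vox = (1.0, 1.0, 1.0)
        a = np.zeros((40, 30, 30))
        b = np.zeros((40, 30, 30))
        synth.add_capsule(a, np.array([5.0, 10.0, 10.0]), np.array([25.0, 10.0, 10.0]), 1.5, vox, 1.0)
        synth.add_capsule(b, np.array([12.0, 14.0, 14.0]), np.array([32.0, 14.0, 14.0]), 1.5, vox, 1.0)
        assert a.sum() == b.sum()

    def test_missing_density_flagged(self):
        arr = np.zeros((10, 20, 20))
        synth.add_capsule(arr, np.array([2.0, 10.0, 10.0]), np.array([8.0, 10.0, 10.0]), 1.0,
                          (1.0, 1.0, 1.0), 200.0)
        vol = tr.LabeledVolume(channels={"YFP": arr}, voxel_size_um=(1.0, 1.0, 1.0))
        roi = tr.RoiMask(name="hilus", mask=np.ones(arr.shape, dtype=bool))
        res = tr.reconstruct_processes_3d(vol, roi, threshold=100.0)
        assert res.unnormalized_flag

    def test_roi_shape_mismatch_raises(self):
        vol = tr.LabeledVolume(channels={"YFP": np.zeros((5, 10, 10))},
                               voxel_size_um=(1.0, 1.0, 1.0))
        roi = tr.RoiMask(name="hilus", mask=np.ones((5, 8, 8), dtype=bool))
        with pytest.raises(ValueError, match="does not fit"):
            tr.reconstruct_processes_3d(vol, roi)
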