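"""Synthetic patches, planted-gradient betas, and forward time series."""

import numpy as np
import pytest

import facegrad as fg
from facegrad import (AnatomicalAxis, CSSParams, GroundTruth, make_patch,
                      make_volume_patch, simulate_betas, simulate_css_voxels,
                      simulate_run_betas, simulate_timeseries)
from facegrad.glm import build_design, fit_glm


class TestMakePatch:
    def test_single_vertex_at_origin(self):
        p = make_patch(1, 1, 1.2)
        assert p.n_vertices == 1
        np.testing.assert_array_equal(p.coords, [[0.0, 0.0]])

    def test_2x3_max_pairwise_distance(self):
        # brute force over all 15 pairs
        p = make_patch(2, 3, 1.0)
        assert p.n_vertices == 6
        dmax = max(
            np.linalg.norm(p.coords[i] - p.coords[j])
            for i in range(6) for j in range(i + 1, 6)
        )
        assert dmax == pytest.approx(np.sqrt(5.0))

    def test_voxel_pitch_grid(self):
        p = make_patch(10, 10, 1.2)
        assert p.n_vertices == 100
        assert p.coords[:, 0].max() == pytest.approx(9 * 1.2)

    def test_deterministic(self):
        a, b = make_patch(4, 5, 1.2), make_patch(4, 5, 1.2)
        np.testing.assert_array_equal(a.coords, b.coords)
        assert a.adjacency == b.adjacency

    def test_adjacency_symmetric_and_grid_like(self):
        p = make_patch(3, 4, 1.0)
        for v, nbs in p.adjacency.items():
            for nb in nbs:
                assert v in p.adjacency[nb]
        # interior vertex has 4 neighbors
        assert len(p.adjacency[1 * 4 + 1]) == 4

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            make_patch(0, 3, 1.0)
        with pytest.raises(ValueError):
            make_patch(2, 2, 0.0)

    def test_volume_patch_face_connectivity(self):
        v = make_volume_patch(3, 3, 3, 1.0)
        center = (1 * 3 + 1) * 3 + 1
        assert len(v.adjacency[center]) == 6


@pytest.fixture()
def patch_axis():
    patch = make_patch(6, 10, 1.0)
    axis = AnatomicalAxis(np.array([[0.0, 2.5], [9.0, 2.5]]))
    return patch, axis


class TestSimulateBetas:
    def test_opposite_slopes_give_strictly_decreasing_difference(self, patch_axis):
        patch, axis = patch_axis
        truth = GroundTruth(
            baseline_pattern=np.zeros(patch.n_vertices),
            gradient_slopes={"eyes": -0.1, "mouth": 0.1},
        )
        bm = simulate_betas(patch, axis, truth, ["eyes", "mouth"])
        pos, _ = fg.project_to_axis(patch.coords, axis)
        diff = bm.get("eyes") - bm.get("mouth")
        order = np.argsort(pos)
        d, q = diff[order], pos[order]
        moved = np.diff(q) > 0
        assert np.all(np.diff(d)[moved] < 0)
        np.testing.assert_allclose(diff, -0.2 * pos, atol=1e-12)

    def test_null_slopes_reproduce_baseline(self, patch_axis):
        patch, axis = patch_axis
        base = np.linspace(0, 1, patch.n_vertices)
        truth = GroundTruth(baseline_pattern=base)
        bm = simulate_betas(patch, axis, truth, ["eyes", "mouth"])
        np.testing.assert_array_equal(bm.get("eyes"), base)
        np.testing.assert_array_equal(bm.get("mouth"), base)

    def test_seeded_determinism_bit_identical(self, patch_axis):
        patch, axis = patch_axis
        truth = GroundTruth(
            baseline_pattern=np.zeros(patch.n_vertices),
            gradient_slopes={"eyes": -0.1}, noise_sd=0.5, seed=42,
        )
        a = simulate_betas(patch, axis, truth, ["eyes"])
        b = simulate_betas(patch, axis, truth, ["eyes"])
        assert a.to_frame().to_csv() == b.to_frame().to_csv()

    def test_unknown_condition_in_slope_map_rejected(self, patch_axis):
        patch, axis = patch_axis
        truth = GroundTruth(
            baseline_pattern=np.zeros(patch.n_vertices),
            gradient_slopes={"nose": 0.1},
        )
        with pytest.raises(ValueError):
            simulate_betas(patch, axis, truth, ["eyes"])

    def test_vein_voxels_exceed_four_percent_psc(self, patch_axis):
        patch, axis = patch_axis
        truth = GroundTruth(
            baseline_pattern=np.full(patch.n_vertices, 1.0),
            vein_ids=np.array([5, 6]),
        )
        bm = simulate_betas(patch, axis, truth, ["face"])
        psc = bm.psc_for("face")
        assert np.all(psc[[5, 6]] > 4.0)

    def test_run_betas_share_truth_but_differ_in_noise(self, patch_axis):
        patch, axis = patch_axis
        truth = GroundTruth(
            baseline_pattern=np.zeros(patch.n_vertices), noise_sd=0.5, seed=3,
        )
        runs = simulate_run_betas(patch, axis, truth, ["eyes"], n_runs=4)
        assert len(runs) == 4
        assert not np.array_equal(runs[0].beta, runs[1].beta)


class TestSimulateTimeseries:
    def _setup(self):
        design = build_design(
            [("eyes", 8.0, 16.0), ("mouth", 40.0, 16.0)], 2.0, 40,
            conditions=["eyes", "mouth"],
        )
        bm = fg.BetaMap(np.arange(3), ["eyes", "mouth"],
                        np.array([[1.0, -0.5], [0.0, 2.0], [0.3, 0.3]]),
                        np.full(3, 100.0))
        return design, bm

    def test_noiseless_inversion_recovers_betas(self):
        design, bm = self._setup()
        Y = simulate_timeseries(design, bm)
        est = fit_glm(Y, design)
        np.testing.assert_allclose(est.beta, bm.beta, atol=1e-10)

    def test_zero_betas_zero_baseline_flat_zero(self):
        design, _ = self._setup()
        bm = fg.BetaMap(np.arange(2), ["eyes", "mouth"],
                        np.zeros((2, 2)), np.zeros(2))
        Y = simulate_timeseries(design, bm)
        np.testing.assert_array_equal(Y, 0.0)

    def test_condition_mismatch_rejected(self):
        design, _ = self._setup()
        bm = fg.BetaMap(np.arange(2), ["eyes", "nose"],
                        np.zeros((2, 2)), np.zeros(2))
        with pytest.raises(ValueError):
            simulate_timeseries(design, bm)

    def test_seeded_determinism(self):
        design, bm = self._setup()
        a = simulate_timeseries(design, bm, noise_sd=1.0, seed=9)
        b = simulate_timeseries(design, bm, noise_sd=1.0, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_glm_unbiased_over_noisy_replicates(self):
        # OLS unbiasedness at the simulator's noise model (500 reps)
        design, bm = self._setup()
        rng = np.random.default_rng(0)
        est = np.empty((500, 2))
        for i in range(500):
            Y = simulate_timeseries(design, bm, noise_sd=1.0,
                                    seed=int(rng.integers(2**31)))
            est[i] = fit_glm(Y, design).beta[0]
        bias = est.mean(axis=0) - bm.beta[0]
        mc_se = est.std(axis=0, ddof=1) / np.sqrt(500)
        assert np.all(np.abs(bias) < 3 * mc_se)

    def test_ar1_noise_option(self):
        design, bm = self._setup()
        Y = simulate_timeseries(design, bm, noise_sd=1.0, seed=1, ar_rho=0.5)
        assert Y.shape == (40, 3)
        with pytest.raises(ValueError):
            simulate_timeseries(design, bm, noise_sd=1.0, ar_rho=1.5)


class TestSimulateCSSVoxels:
    def test_noiseless_equals_forward_model(self):
        ap = fg.make_wedge_apertures(n_cycles=1, n_pix=32)
        p = CSSParams(x=2.0, y=1.0, sigma=1.5, n=0.5)
        series = simulate_css_voxels(ap, [p])
        np.testing.assert_array_equal(series[:, 0], fg.css_response(ap, p))

    def test_zero_gain_flat(self):
        ap = fg.make_wedge_apertures(n_cycles=1, n_pix=32)
        p = CSSParams(x=2.0, y=1.0, sigma=1.5, n=0.5, gain=0.0)
        np.testing.assert_array_equal(simulate_css_voxels(ap, [p]), 0.0)

    def test_center_outside_field_rejected(self):
        ap = fg.make_wedge_apertures(n_cycles=1, n_pix=32)
        with pytest.raises(ValueError):
            simulate_css_voxels(ap, [CSSParams(x=15.0, y=0.0, sigma=1.0, n=1.0)])

    def test_seeded_reproducibility(self):
        ap = fg.make_wedge_apertures(n_cycles=1, n_pix=32)
        p = CSSParams(x=0.0, y=0.0, sigma=2.0, n=1.0)
        a = simulate_css_voxels(ap, [p], noise_sd=0.3, seed=5)
        b = simulate_css_voxels(ap, [p], noise_sd=0.3, seed=5)
        np.testing.assert_array_equal(a, b)


class TestNiftiRoundtrip:
    def test_betamap_volume_roundtrip(self, tmp_path):
        from facegrad.io import read_betamap_nifti, write_betamap_nifti

        patch = make_patch(4, 5, 1.2)
        rng = np.random.default_rng(2)
        bm = fg.BetaMap(patch.vertex_ids, ["eyes", "face"],
                        rng.normal(size=(20, 2)), np.full(20, 100.0))
        write_betamap_nifti(bm, patch, tmp_path)
        back = read_betamap_nifti(tmp_path, ["eyes", "face"])
        np.testing.assert_allclose(back.beta, bm.beta, atol=1e-12)
        np.testing.assert_allclose(back.baseline, bm.baseline, atol=1e-12)

    def test_timeseries_volume_roundtrip(self, tmp_path):
        from facegrad.io import read_timeseries_nifti, write_timeseries_nifti

        patch = make_patch(3, 4, 1.2)
        rng = np.random.default_rng(4)
        series = rng.normal(size=(10, 12))
        path = write_timeseries_nifti(series, patch, tmp_path / "run.nii")
        np.testing.assert_allclose(read_timeseries_nifti(path), series,
                                   atol=1e-12)
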