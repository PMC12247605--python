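import numpy as np
import pytest

from dkiprep import mppca
from dkiprep.io import DWIVolume, GradientTable


def _grad(n):
    bv = np.full(n, 1000.0)
    bv[0] = 0.0
    vecs = np.zeros((n, 3))
    vecs[1:, 0] = 1.0
    return GradientTable(bv, vecs)


class TestMPDenoiseMatrix:
    def test_noiseless_rank1_is_reproduced_exactly(self, rng):
        X = np.outer(rng.standard_normal(100), rng.standard_normal(90))
        for shrink in (False, True):
            Xh, sigma, P = mppca.mp_denoise_matrix(X, shrink=shrink)
            assert P == 1
            assert sigma <= 1e-8 * np.linalg.norm(X)
            assert np.allclose(Xh, X, atol=1e-10 * np.abs(X).max())

    def test_sigma_estimate_on_pure_noise(self, rng):
        """Monte-Carlo oracle: mean sigma-hat over 50 draws within 5% of 1."""
        est = [
            mppca.mp_denoise_matrix(rng.standard_normal((100, 90)))[1]
            for _ in range(50)
        ]
        assert abs(np.mean(est) - 1.0) < 0.05

    def test_denoising_reduces_error_of_low_rank_signal(self, rng):
        S = sum(
            w * np.outer(rng.standard_normal(100), rng.standard_normal(90))
            for w in (30, 20, 10)
        )
        N = rng.standard_normal((100, 90))
        for shrink in (False, True):
            Xh, _, P = mppca.mp_denoise_matrix(S + N, shrink=shrink)
            assert np.linalg.norm(Xh - S) < np.linalg.norm(N)

    def test_nonfinite_input_rejected(self):
        X = np.zeros((10, 5))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            mppca.mp_denoise_matrix(X)


class TestAdaptivePatch:
    def test_homogeneous_volume_selects_nearest_voxels(self):
        data = np.ones((9, 9, 9, 10))
        spec = mppca.PatchSpec(patch_size=7, search_window=3)
        patch = mppca.select_adaptive_patch(data, (4, 4, 4), spec)
        assert len(patch) == 7
        assert tuple(patch[0]) == (4, 4, 4)
        d2 = ((patch - [4, 4, 4]) ** 2).sum(axis=1)
        # centre plus six face neighbours
        assert d2.tolist() == [0, 1, 1, 1, 1, 1, 1]
        # lexicographic tie-break among the distance-1 candidates
        assert patch[1:].tolist() == sorted(patch[1:].tolist())

    def test_two_tissue_volume_stays_within_tissue(self, rng):
        data = np.ones((12, 12, 12, 8))
        data[6:, :, :, :] = 10.0  # second tissue
        spec = mppca.PatchSpec(patch_size=40, search_window=5)
        patch = mppca.select_adaptive_patch(data, (3, 6, 6), spec)
        assert len(patch) == 40
        assert np.all(patch[:, 0] < 6)

    def test_matches_brute_force_bilateral_ranking(self, rng):
        data = rng.random((7, 7, 7, 6))
        spec = mppca.PatchSpec(patch_size=10, search_window=2)
        center = (3, 3, 3)
        patch = mppca.select_adaptive_patch(data, center, spec)
        # independent oracle: rank all window candidates by the documented
        # score (normalized distance + normalized mean |intensity diff|)
        cands = [
            (i, j, k)
            for i in range(1, 6)
            for j in range(1, 6)
            for k in range(1, 6)
        ]
        dist = np.array([np.sqrt(sum((a - b) ** 2 for a, b in zip(c, center)))
                         for c in cands])
        inten = np.array([
            np.abs(data[c] - data[center]).mean() for c in cands
        ])
        score = dist / dist.max() + inten / inten.max()
        best = {cands[i] for i in np.argsort(score, kind="stable")[:10]}
        assert {tuple(p) for p in patch} == best

    def test_requested_hundred_voxels_returned(self):
        data = np.ones((10, 10, 10, 5))
        spec = mppca.PatchSpec(patch_size=100, search_window=7)
        patch = mppca.select_adaptive_patch(data, (5, 5, 5), spec)
        assert len(patch) == 100

    def test_center_outside_mask_rejected(self):
        data = np.ones((5, 5, 5, 4))
        mask = np.zeros((5, 5, 5), bool)
        with pytest.raises(ValueError):
            mppca.select_adaptive_patch(
                data, (2, 2, 2), mppca.PatchSpec(patch_size=5), mask
            )


class TestDenoiseVolume:
    def test_noiseless_input_passes_through(self, small_phantom):
        res = mppca.denoise_volume(
            small_phantom.truth, mppca.PatchSpec(mode="local"), shrink=False
        )
        mask = small_phantom.truth.get_mask()
        rel = np.abs(res.denoised - small_phantom.truth.data)[mask]
        assert rel.max() <= 1e-6 * small_phantom.truth.data.max()
        assert np.all(res.sigma_map[mask] <= 1e-8)

    @pytest.mark.parametrize("mode", ["local", "adaptive"])
    def test_denoising_reduces_rmse_at_snr20(self, small_phantom, small_noisy, mode):
        res = mppca.denoise_volume(small_noisy, mppca.PatchSpec(mode=mode))
        mask = small_phantom.truth.get_mask()
        before = np.sqrt(np.mean((small_noisy.data - small_phantom.truth.data)[mask] ** 2))
        after = np.sqrt(np.mean((res.denoised - small_phantom.truth.data)[mask] ** 2))
        assert after < before

    def test_adaptive_beats_local_on_piecewise_constant_tissue(self, rng):
        """Two-tissue piecewise-constant cube: the adaptive patch avoids
        mixing tissues at the boundary, so its RMSE cannot exceed local."""
        grad = _grad(30)
        truth = np.ones((14, 14, 6, 30))
        truth[7:, :, :, :] = 4.0
        noisy = truth + 0.15 * rng.standard_normal(truth.shape)
        vol = DWIVolume(np.maximum(noisy, 0), grad)
        loc = mppca.denoise_volume(vol, mppca.PatchSpec(mode="local"))
        ada = mppca.denoise_volume(
            vol, mppca.PatchSpec(mode="adaptive", patch_size=100, search_window=4)
        )
        rmse_loc = np.sqrt(np.mean((loc.denoised - truth) ** 2))
        rmse_ada = np.sqrt(np.mean((ada.denoised - truth) ** 2))
        assert rmse_ada <= rmse_loc

    def test_sigma_recovery_across_two_orders_of_magnitude(self, rng):
        """Median of sigma_map within 10% of the generative sigma."""
        grad = _grad(30)
        for sigma in (0.02, 0.2, 2.0):
            data = 10.0 + sigma * rng.standard_normal((12, 12, 6, 30))
            vol = DWIVolume(np.maximum(data, 0), grad)
            res = mppca.denoise_volume(vol, mppca.PatchSpec(mode="local"))
            assert abs(np.median(res.sigma_map) - sigma) < 0.1 * sigma

    def test_empty_mask_rejected(self):
        vol = DWIVolume(np.ones((4, 4, 4, 30)), _grad(30),
                        mask=np.zeros((4, 4, 4), bool))
        with pytest.raises(ValueError):
            mppca.denoise_volume(vol)

    def test_few_volumes_warn(self):
        vol = DWIVolume(np.ones((4, 4, 4, 5)), _grad(5))
        with pytest.warns(UserWarning):
            mppca.denoise_volume(vol, mppca.PatchSpec(mode="local"))


class TestRicianCorrection:
    def test_zero_sigma_is_identity(self, rng):
        m = rng.random((4, 4, 4, 6))
        out = mppca.rician_bias_correct(m, np.zeros((4, 4, 4)))
        assert np.array_equal(out, m)

    def test_direct_formula(self):
        out = mppca.rician_bias_correct(
            np.full((1, 1, 1, 1), 5.0), np.full((1, 1, 1), 3.0)
        )
        assert np.allclose(out, 4.0)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            mppca.rician_bias_correct(np.ones((2, 2, 2, 2)), -np.ones((2, 2, 2)))

    def test_noise_floor_removed_at_zero_signal(self, rng):
        """Analytic Rician moments: E[M^2] = Sr^2 + 2 sigma^2 (so 2 sigma^2
        uncorrected at Sr = 0).  For the clamped estimator max(M^2 - s^2, 0)
        with M^2/s^2 ~ chi^2_2, the exact mean is 2 exp(-1/2) s^2 ~ 1.213:
        most of the floor is removed, the clamp keeps the rest positive."""
        n = 100_000
        m = np.sqrt(rng.standard_normal(n) ** 2 + rng.standard_normal(n) ** 2)
        corr = mppca.rician_bias_correct(m.reshape(1, 1, 1, n),
                                         np.ones((1, 1, 1)))
        uncorrected = np.mean(m**2)
        corrected = np.mean(corr**2)
        assert abs(uncorrected - 2.0) < 0.03
        assert abs(corrected - 2.0 * np.exp(-0.5)) < 0.03
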