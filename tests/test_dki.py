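import numpy as np
import pytest

from dkiprep import dki, phantom
from dkiprep.io import DWIVolume, GradientTable, ScalarMaps


def _closed_form_fa(evals):
    lam = np.asarray(evals, dtype=float)
    md = lam.mean()
    return np.sqrt(1.5 * ((lam - md) ** 2).sum() / (lam**2).sum())


class TestDesignMatrix:
    def test_b0_rows_are_intercept_only(self, clinical_protocol):
        B = dki.build_design_matrix(clinical_protocol)
        b0 = clinical_protocol.bvals == 0
        assert np.allclose(B[b0, 0], 1.0)
        assert np.allclose(B[b0, 1:], 0.0)

    def test_x_direction_unit_b_hits_xx_column_only(self):
        rest = phantom.make_protocol(1, ((2000, 21),))
        bvals = np.r_[1000.0, rest.bvals]
        bvecs = np.vstack([[1.0, 0, 0], rest.bvecs])
        B = dki.build_design_matrix(GradientTable(bvals, bvecs))
        # b = 1 ms/um^2 along x: D block = -1 in the xx column only
        assert np.isclose(B[0, 1], -1.0)
        assert np.allclose(B[0, 2:7], 0.0)

    def test_full_rank_for_clinical_protocol(self, clinical_protocol):
        B = dki.build_design_matrix(clinical_protocol)
        assert B.shape == (89, 22)
        assert np.linalg.matrix_rank(B) == 22

    def test_single_shell_dki_rejected(self):
        n = 30
        vecs = phantom.make_protocol(2, ((1000, 28),)).bvecs
        grad = GradientTable(np.r_[0, 0, np.full(28, 1000.0)], vecs)
        with pytest.raises(dki.ModelError):
            dki.build_design_matrix(grad)
        assert dki.build_design_matrix(grad, model="dti").shape == (30, 7)

    def test_dti_needs_seven_volumes(self):
        grad = GradientTable(np.zeros(5), np.zeros((5, 3)))
        with pytest.raises(dki.ModelError):
            dki.build_design_matrix(grad, model="dti")


class TestWLLSFit:
    def test_isotropic_monoexponential_recovered(self, clinical_protocol):
        dt = np.array([1.0, 0, 0, 1.0, 0, 1.0])
        sig = dki.forward_signal(clinical_protocol, np.array(100.0), dt, np.zeros(15))
        vol = DWIVolume(np.tile(sig, (2, 2, 2, 1)), clinical_protocol)
        maps = dki.scalar_maps(dki.wlls_fit(vol))
        for name, want in [("md", 1.0), ("ad", 1.0), ("rd", 1.0),
                           ("fa", 0.0), ("mk", 0.0), ("ak", 0.0), ("rk", 0.0)]:
            assert np.allclose(maps[name], want, atol=1e-8), name

    def test_forward_inverse_roundtrip_100_random_tensors(self, clinical_protocol, rng):
        """Noiseless forward signals refit to <= 1e-8 relative error."""
        n = 100
        evals = rng.uniform(0.3, 2.5, (n, 3))
        dts, kts = [], []
        for i in range(n):
            q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
            D = q @ np.diag(evals[i]) @ q.T
            dts.append([D[0, 0], D[0, 1], D[0, 2], D[1, 1], D[1, 2], D[2, 2]])
            kts.append(0.5 * rng.uniform(-0.3, 1.0, 15))
        dts, kts = np.array(dts), np.array(kts)
        s0 = rng.uniform(0.5, 2.0, n)
        sig = dki.forward_signal(clinical_protocol, s0, dts, kts)
        vol = DWIVolume(sig.reshape(n, 1, 1, -1), clinical_protocol)
        fit = dki.wlls_fit(vol)
        got = np.concatenate(
            [fit.lnS0.reshape(n, 1), fit.dt.reshape(n, 6), fit.kt.reshape(n, 15)],
            axis=1,
        )
        want = np.concatenate([np.log(s0)[:, None], dts, kts], axis=1)
        scale = np.abs(want).max()
        assert np.abs(got - want).max() <= 1e-8 * scale

    def test_anisotropic_fa_matches_closed_form(self, clinical_protocol):
        evals = (1.7, 0.3, 0.3)
        dt = np.array([evals[1], 0, 0, evals[1], 0, evals[0]])  # axis along z
        sig = dki.forward_signal(clinical_protocol, np.array(1.0), dt, np.zeros(15))
        vol = DWIVolume(sig.reshape(1, 1, 1, -1), clinical_protocol)
        maps = dki.scalar_maps(dki.wlls_fit(vol))
        assert np.isclose(maps.fa[0, 0, 0], _closed_form_fa(evals), atol=1e-6)
        assert np.isclose(_closed_form_fa(evals), 0.799, atol=1e-3)
        assert np.isclose(maps.md[0, 0, 0], np.mean(evals), atol=1e-8)
        assert np.isclose(np.mean(evals), 0.7667, atol=1e-4)

    def test_weighting_improves_on_noisy_phantom(self, small_phantom):
        noisy = phantom.add_rician_noise(
            small_phantom.truth, phantom.NoiseModel.from_truth(small_phantom, 15, 9)
        )
        tm = phantom.truth_scalar_maps(small_phantom)
        wm = small_phantom.wm_mask
        rmse = {}
        for weighted in (True, False):
            maps = dki.scalar_maps(dki.wlls_fit(noisy, weighted=weighted))
            rmse[weighted] = np.sqrt(np.nanmean((maps.md - tm.md)[wm] ** 2))
        assert rmse[True] <= rmse[False]


class TestScalarMaps:
    def test_isotropic_kurtosis_phantom_mk_is_one(self):
        """W_iso = 1 means K(n) = 1 along every direction; the 256-point
        directional average must agree to the discretization tolerance."""
        md = 0.8
        dt = np.array([md, 0, 0, md, 0, md])
        kt = np.zeros(15)
        kt[[0, 10, 14]] = md**2
        kt[[3, 5, 12]] = md**2 / 3.0
        fit = dki.TensorFit(
            np.zeros((1, 1, 1)),
            dt.reshape(1, 1, 1, 6),
            kt.reshape(1, 1, 1, 15),
            np.ones((1, 1, 1), bool),
        )
        maps = dki.scalar_maps(fit)
        for name in ("mk", "ak", "rk"):
            assert np.isclose(maps[name][0, 0, 0], 1.0, atol=1e-3), name

    def test_rotation_equivariance(self, clinical_protocol, rng):
        """Rotating bvecs and ground-truth tensors together leaves every
        scalar unchanged."""
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        from dkiprep.phantom import _axisym_tensors, _rotate_tensors

        dt, kt = _axisym_tensors(1.7, 0.45, 0.8, 1.8)
        sig = dki.forward_signal(clinical_protocol, np.array(1.0), dt, kt)
        vol = DWIVolume(sig.reshape(1, 1, 1, -1), clinical_protocol)
        maps = dki.scalar_maps(dki.wlls_fit(vol))

        grad_rot = GradientTable(
            clinical_protocol.bvals, clinical_protocol.bvecs @ q.T
        )
        dt_r, kt_r = _rotate_tensors(dt, kt, q)
        sig_r = dki.forward_signal(grad_rot, np.array(1.0), dt_r, kt_r)
        assert np.allclose(sig, sig_r, atol=1e-10)  # model equivariance
        vol_r = DWIVolume(sig_r.reshape(1, 1, 1, -1), clinical_protocol)
        maps_r = dki.scalar_maps(dki.wlls_fit(vol_r))
        for name in ("md", "ad", "rd", "fa", "mk", "ak", "rk"):
            assert np.isclose(maps[name][0, 0, 0], maps_r[name][0, 0, 0],
                              atol=1e-6), name


class TestOutlierStats:
    def _maps(self, **over):
        base = {n: np.full((5, 5, 4), v) for n, v in
                [("md", 0.8), ("ad", 1.2), ("rd", 0.6), ("fa", 0.5),
                 ("mk", 0.9), ("ak", 0.7), ("rk", 1.4)]}
        base.update(over)
        return ScalarMaps(**base)

    def test_all_physical_maps_have_zero_outliers(self):
        stats = dki.outlier_stats(self._maps(), np.ones((5, 5, 4), bool))
        assert all(v == 0.0 for v in stats.values())

    def test_single_violating_voxel_is_one_percent(self):
        md = np.full((5, 5, 4), 0.8)
        md[0, 0, 0] = -0.1
        stats = dki.outlier_stats(self._maps(md=md), np.ones((5, 5, 4), bool))
        assert np.isclose(stats["md"], 1.0)
        assert np.isclose(stats["average"], 1.0 / 7.0)

    def test_kurtosis_bound_is_minus_two(self):
        mk = np.full((5, 5, 4), 0.9)
        mk[0, 0, 0] = -2.5   # outlier
        mk[0, 0, 1] = -1.9   # not an outlier
        stats = dki.outlier_stats(self._maps(mk=mk), np.ones((5, 5, 4), bool))
        assert np.isclose(stats["mk"], 1.0)

    def test_fa_above_one_is_outlier(self):
        fa = np.full((5, 5, 4), 0.5)
        fa[0, 0, 0] = 1.2
        stats = dki.outlier_stats(self._maps(fa=fa), np.ones((5, 5, 4), bool))
        assert np.isclose(stats["fa"], 1.0)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            dki.outlier_stats(self._maps(), np.zeros((5, 5, 4), bool))
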