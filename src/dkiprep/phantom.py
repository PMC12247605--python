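"""Ground-truth phantom generators for denoising and Gibbs experiments.

Two simulators are provided:

* a parametric multi-shell brain phantom: a piecewise-constant label field
  (CSF, cortical ribbon, white-matter tracts of varying orientation) whose
  noiseless signals follow the DKI forward model exactly, with Rician noise
  added at a chosen SNR via the magnitude of a complex Gaussian channel;
* a Shepp-Logan-style diffusion phantom for Gibbs ringing: ellipses with
  differing signal intensities and diffusion parameters are rendered at
  high resolution, Fourier transformed, centrally truncated to the target
  grid, and (optionally) zero-filled to a 6/8 or 7/8 partial-Fourier
  sampling along the horizontal axis before magnitude reconstruction.

SNR is defined against the mean white-matter b0 truth signal:
sigma = mean(WM b0)/SNR, one global noise level.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .dki import TensorFit, build_design_matrix, forward_signal, scalar_maps
from .io import DWIVolume, GradientTable, ScalarMaps

__all__ = [
    "NoiseModel",
    "PhantomTruth",
    "make_protocol",
    "make_multishell_phantom",
    "add_rician_noise",
    "make_shepp_logan_dmri",
    "truth_scalar_maps",
]

#: SNR grid used in the denoising experiments
SNR_LEVELS = (10, 15, 20, 25, 30, 60)


@dataclass(frozen=True)
class NoiseModel:
    """Rician noise at a target SNR: sigma = reference b0 signal / SNR."""

    snr: float
    sigma: float
    seed: int

    def __post_init__(self):
        if self.snr <= 0 or self.sigma <= 0:
            raise ValueError("snr and sigma must be positive")

    @classmethod
    def from_truth(cls, truth: "PhantomTruth", snr: float, seed: int):
        b0 = truth.truth.mean_b0()
        ref = float(b0[truth.wm_mask].mean())
        return cls(snr=snr, sigma=ref / snr, seed=seed)


@dataclass
class PhantomTruth:
    """Noiseless ground truth plus the region assignments behind it."""

    truth: DWIVolume
    region_labels: np.ndarray
    region_params: dict[int, tuple[float, np.ndarray, np.ndarray]]
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    ringing_rois: list[np.ndarray] | None = None


# --------------------------------------------------------------------------
# gradient scheme

def _spread_directions(n: int, offset: int = 0) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * (i + offset)
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(1.0 - z**2, 0.0))
    v = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def make_protocol(
    n_b0: int = 5,
    shells: tuple[tuple[float, int], ...] = ((250, 4), (1000, 20), (2000, 60)),
) -> GradientTable:
    """Clinical multi-shell scheme: 5 b0, b250 x 4, b1000 x 20, b2000 x 60."""
    bvals = [0.0] * n_b0
    bvecs = [np.zeros(3)] * n_b0
    for k, (b, n) in enumerate(shells):
        bvals += [float(b)] * n
        bvecs += list(_spread_directions(n, offset=7 * k))
    return GradientTable(np.array(bvals), np.array(bvecs))


# --------------------------------------------------------------------------
# tensor construction helpers

def _iso_kt(md: float, k: float) -> np.ndarray:
    """15 kt coefficients of an isotropic apparent kurtosis K(n) = k."""
    v = np.zeros(15)
    w = k * md**2
    v[[0, 10, 14]] = w          # xxxx, yyyy, zzzz
    v[[3, 5, 12]] = w / 3.0     # xxyy, xxzz, yyzz
    return v


def _axisym_tensors(
    ad: float, rd: float, ak: float, rk: float
) -> tuple[np.ndarray, np.ndarray]:
    """dt/kt of an axially symmetric fibre along z (radial plane x-y)."""
    dt = np.array([rd, 0, 0, rd, 0, ad], dtype=float)
    v = np.zeros(15)
    v1111 = rk * rd**2
    v3333 = ak * ad**2
    v[0] = v[10] = v1111
    v[14] = v3333
    v[3] = v1111 / 3.0          # planar isotropy: V_xxyy = V_xxxx / 3
    # set the oblique coefficient so K at 45 deg is the AK/RK midpoint
    d45 = 0.5 * (ad + rd)
    k45 = 0.5 * (ak + rk)
    v[5] = v[12] = (4.0 * k45 * d45**2 - v1111 - v3333) / 6.0
    return dt, v


_KT_FULL_IDX = [
    (0, 0, 0, 0), (0, 0, 0, 1), (0, 0, 0, 2), (0, 0, 1, 1), (0, 0, 1, 2),
    (0, 0, 2, 2), (0, 1, 1, 1), (0, 1, 1, 2), (0, 1, 2, 2), (0, 2, 2, 2),
    (1, 1, 1, 1), (1, 1, 1, 2), (1, 1, 2, 2), (1, 2, 2, 2), (2, 2, 2, 2),
]


def _rotate_tensors(
    dt: np.ndarray, kt: np.ndarray, R: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    D = np.array(
        [[dt[0], dt[1], dt[2]], [dt[1], dt[3], dt[4]], [dt[2], dt[4], dt[5]]]
    )
    Dr = R @ D @ R.T
    dt_r = np.array(
        [Dr[0, 0], Dr[0, 1], Dr[0, 2], Dr[1, 1], Dr[1, 2], Dr[2, 2]]
    )
    W = np.zeros((3, 3, 3, 3))
    for c, idx in enumerate(_KT_FULL_IDX):
        for perm in set(itertools.permutations(idx)):
            W[perm] = kt[c]
    Wr = np.einsum("ia,jb,kc,ld,abcd->ijkl", R, R, R, R, W)
    kt_r = np.array([Wr[idx] for idx in _KT_FULL_IDX])
    return dt_r, kt_r


def _rot_from_z_to(v: np.ndarray) -> np.ndarray:
    """Rotation taking e_z onto unit vector v."""
    v = np.asarray(v, dtype=float)
    v = v / np.linalg.norm(v)
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(z, v)
    s = np.linalg.norm(axis)
    c = float(z @ v)
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    axis = axis / s
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + s * K + (1 - c) * (K @ K)


# --------------------------------------------------------------------------
# multi-shell phantom

# region parameter table: label -> (name, S0, builder)
_WM_FIBRES = {
    3: np.array([1.0, 0.0, 0.0]),          # along x
    4: np.array([0.0, 1.0, 0.0]),          # along y
    5: np.array([0.0, 0.0, 1.0]),          # through-plane
    6: np.array([1.0, 1.0, 0.0]) / np.sqrt(2.0),  # oblique in-plane
}


def _default_region_params() -> dict[int, tuple[float, np.ndarray, np.ndarray]]:
    params: dict[int, tuple[float, np.ndarray, np.ndarray]] = {}
    # CSF: fast isotropic diffusion, Gaussian (zero kurtosis)
    params[1] = (2.0, np.array([3.0, 0, 0, 3.0, 0, 3.0]), np.zeros(15))
    # cortical grey matter: slow isotropic diffusion, moderate kurtosis
    params[2] = (0.9, np.array([0.9, 0, 0, 0.9, 0, 0.9]), _iso_kt(0.9, 0.7))
    # white-matter tracts: axially symmetric fibres, varying orientation
    dt0, kt0 = _axisym_tensors(ad=1.7, rd=0.45, ak=0.8, rk=1.8)
    for label, fibre in _WM_FIBRES.items():
        R = _rot_from_z_to(fibre)
        params[label] = (1.0, *_rotate_tensors(dt0, kt0, R))
    return params


def _multishell_labels(grid_shape: tuple[int, int, int]) -> np.ndarray:
    nx, ny, nz = grid_shape
    x, y, z = np.meshgrid(
        np.linspace(-1, 1, nx), np.linspace(-1, 1, ny),
        np.linspace(-1, 1, nz), indexing="ij",
    )
    labels = np.zeros(grid_shape, dtype=int)
    head = (x**2 + y**2) / 0.9**2 + z**2 / 0.95**2 <= 1.0
    labels[head] = 2  # cortical ribbon by default
    inner = (x**2 + y**2) / 0.72**2 + z**2 / 0.8**2 <= 1.0
    # white matter quadrants with distinct fibre orientations
    labels[inner & (x >= 0) & (y >= 0)] = 3
    labels[inner & (x < 0) & (y >= 0)] = 4
    labels[inner & (x >= 0) & (y < 0)] = 5
    labels[inner & (x < 0) & (y < 0)] = 6
    ventricle = (x**2) / 0.18**2 + (y**2) / 0.3**2 + z**2 / 0.5**2 <= 1.0
    labels[ventricle] = 1
    return labels


_WM_ANGLE_STD = 0.25   # radians; smooth fibre-orientation dispersion (tract)
_WM_ANGLE_WHITE = 0.08  # radians; voxel-scale orientation micro-variation
_WM_PARAM_STD = 0.12   # fractional smooth spread of tensor magnitudes
_WM_PARAM_WHITE = 0.12  # fractional voxel-scale magnitude micro-variation
_WM_S0_STD = 0.03      # fractional spread of per-voxel S0
_WM_CORR_VOX = 2.5     # correlation length (voxels) of the smooth component


def _smooth_unit_field(
    rng: np.random.Generator, grid_shape, n_fields: int, corr: float
) -> np.ndarray:
    """Spatially correlated Gaussian fields, unit marginal variance."""
    from scipy.ndimage import gaussian_filter

    f = rng.standard_normal((n_fields,) + tuple(grid_shape))
    f = np.stack([gaussian_filter(x, corr, mode="wrap") for x in f])
    f /= f.reshape(n_fields, -1).std(axis=1)[:, None, None, None]
    return f


def _axisym_tensors_batch(ad, rd, ak, rk):
    """Vectorized :func:`_axisym_tensors` for arrays of magnitudes."""
    b = ad.shape[0]
    dt = np.zeros((b, 6))
    dt[:, 0] = dt[:, 3] = rd
    dt[:, 5] = ad
    v = np.zeros((b, 15))
    v1111 = rk * rd**2
    v3333 = ak * ad**2
    v[:, 0] = v[:, 10] = v1111
    v[:, 14] = v3333
    v[:, 3] = v1111 / 3.0
    d45 = 0.5 * (ad + rd)
    k45 = 0.5 * (ak + rk)
    v[:, 5] = v[:, 12] = (4.0 * k45 * d45**2 - v1111 - v3333) / 6.0
    return dt, v


def _rotvec_to_matrix(rv: np.ndarray) -> np.ndarray:
    """Rodrigues formula for a batch of rotation vectors (B, 3)."""
    theta = np.linalg.norm(rv, axis=1)
    axis = np.where(theta[:, None] > 1e-12, rv / np.maximum(theta, 1e-12)[:, None], 0.0)
    K = np.zeros((rv.shape[0], 3, 3))
    K[:, 0, 1], K[:, 0, 2] = -axis[:, 2], axis[:, 1]
    K[:, 1, 0], K[:, 1, 2] = axis[:, 2], -axis[:, 0]
    K[:, 2, 0], K[:, 2, 1] = -axis[:, 1], axis[:, 0]
    s = np.sin(theta)[:, None, None]
    c = (1.0 - np.cos(theta))[:, None, None]
    return np.eye(3)[None] + s * K + c * (K @ K)


def _rotate_tensors_batch(dt: np.ndarray, kt: np.ndarray, R: np.ndarray):
    """Rotate batches of symmetric 2nd/4th-order tensor coefficients."""
    b = dt.shape[0]
    D = np.zeros((b, 3, 3))
    for c, (i, j) in enumerate([(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]):
        D[:, i, j] = D[:, j, i] = dt[:, c]
    Dr = R @ D @ np.swapaxes(R, 1, 2)
    dt_r = np.stack(
        [Dr[:, 0, 0], Dr[:, 0, 1], Dr[:, 0, 2], Dr[:, 1, 1], Dr[:, 1, 2], Dr[:, 2, 2]],
        axis=1,
    )
    W = np.zeros((b, 3, 3, 3, 3))
    for c, idx in enumerate(_KT_FULL_IDX):
        for perm in set(itertools.permutations(idx)):
            W[(slice(None),) + perm] = kt[:, c]
    Wr = np.einsum("bpi,bqj,brk,bsl,bijkl->bpqrs", R, R, R, R, W, optimize=True)
    kt_r = np.stack([Wr[(slice(None),) + idx] for idx in _KT_FULL_IDX], axis=1)
    return dt_r, kt_r


def make_multishell_phantom(
    grid_shape: tuple[int, int, int] = (64, 64, 16),
    protocol: GradientTable | None = None,
    seed: int = 0,
    voxel_size: tuple[float, float, float] = (2.5, 2.5, 2.5),
) -> PhantomTruth:
    """Anatomical multi-region phantom with exact DKI truth signals.

    Labels: 1 CSF, 2 grey matter; every white-matter voxel is its own
    region whose fibre orientation and tensor magnitudes are drawn around
    one of four tract orientations (x / y / z / oblique) from seeded,
    spatially correlated random fields.  The dispersion emulates the
    voxelwise heterogeneity of real tissue -- without it, patches would be
    exactly low rank and denoising unrealistically lossless -- while the
    spatial correlation keeps neighbouring voxels similar, as in real
    tracts.  Every labelled voxel's truth signal equals the DKI forward
    model of its region parameters.
    """
    protocol = protocol or make_protocol()
    if len(protocol) < 22:
        raise ValueError("protocol must contain at least 22 volumes")
    rng = np.random.default_rng(seed)
    base = _multishell_labels(grid_shape)
    params = _default_region_params()
    labels = np.where(np.isin(base, list(_WM_FIBRES)), 0, base)

    wm_sel = np.isin(base, list(_WM_FIBRES))
    nwm = int(wm_sel.sum())
    fields = _smooth_unit_field(rng, grid_shape, 8, _WM_CORR_VOX)[:, wm_sel]
    white = rng.standard_normal((7, nwm))
    mag = (
        1.0 + _WM_PARAM_STD * fields[:4] + _WM_PARAM_WHITE * white[:4]
    )
    dt0, kt0 = _axisym_tensors_batch(
        1.7 * mag[0], 0.45 * mag[1], 0.8 * mag[2], 1.8 * mag[3]
    )
    rotvec = (
        _WM_ANGLE_STD * fields[4:7] + _WM_ANGLE_WHITE * white[4:7]
    ).T
    R_jit = _rotvec_to_matrix(rotvec)
    R_base = np.zeros((nwm, 3, 3))
    quad_of = base[wm_sel]
    for quad, fibre in _WM_FIBRES.items():
        R_base[quad_of == quad] = _rot_from_z_to(fibre)
    dt_wm, kt_wm = _rotate_tensors_batch(dt0, kt0, R_jit @ R_base)
    s0_wm = 1.0 + _WM_S0_STD * fields[7]

    wm_labels = 10 + np.arange(nwm)
    labels[wm_sel] = wm_labels
    for quad in _WM_FIBRES:
        params.pop(quad, None)
    for i in range(nwm):
        params[10 + i] = (float(s0_wm[i]), dt_wm[i], kt_wm[i])

    # one vectorized forward evaluation for all regions
    B = build_design_matrix(protocol)
    nvol = len(protocol)
    data = np.zeros(grid_shape + (nvol,))
    for label in (1, 2):
        s0, dt, kt = params[label]
        data[labels == label] = forward_signal(protocol, np.array(s0), dt, kt)
    beta_wm = np.concatenate([np.log(s0_wm)[:, None], dt_wm, kt_wm], axis=1)
    data[wm_sel] = np.exp(beta_wm @ B.T)
    mask = labels > 0
    truth = DWIVolume(
        data, protocol, voxel_size=np.array(voxel_size), mask=mask
    )
    return PhantomTruth(
        truth=truth,
        region_labels=labels,
        region_params=params,
        wm_mask=labels >= 10,
        csf_mask=labels == 1,
    )


def truth_scalar_maps(truth: PhantomTruth) -> ScalarMaps:
    """Exact scalar maps from the per-region tensors (no fitting)."""
    labels = truth.region_labels
    nmax = labels.max() + 1
    lut_dt = np.full((nmax, 6), np.nan)
    lut_kt = np.full((nmax, 15), np.nan)
    lut_s0 = np.full(nmax, np.nan)
    for label, (s0, d, k) in truth.region_params.items():
        lut_dt[label] = d
        lut_kt[label] = k
        lut_s0[label] = np.log(s0)
    fit = TensorFit(lut_s0[labels], lut_dt[labels], lut_kt[labels], labels > 0)
    return scalar_maps(fit)


def add_rician_noise(truth: DWIVolume, noise: NoiseModel) -> DWIVolume:
    """Sm = sqrt((Sr + sigma e1)^2 + (sigma e2)^2), e1/e2 iid standard normal.

    The imaginary channel of the noiseless signal is zero; the draw is
    reproducible from ``noise.seed``.
    """
    rng = np.random.default_rng(noise.seed)
    shape = truth.data.shape
    e1 = rng.standard_normal(shape)
    e2 = rng.standard_normal(shape)
    sm = np.sqrt(
        (truth.data + noise.sigma * e1) ** 2 + (noise.sigma * e2) ** 2
    )
    return truth.with_data(sm)


# --------------------------------------------------------------------------
# Shepp-Logan Gibbs phantom

# (cx, cy, a, b, angle_deg, label) -- painted in order, later overwrites
_SL_ELLIPSES = [
    (0.0, 0.0, 0.72, 0.95, 0.0, 1),      # outer rim (skull/scalp-like)
    (0.0, 0.0, 0.655, 0.87, 0.0, 2),     # brain interior (GM-like)
    (0.22, 0.0, 0.11, 0.31, -18.0, 3),   # right ventricle (CSF)
    (-0.22, 0.0, 0.16, 0.41, 18.0, 3),   # left ventricle (CSF)
    (0.0, 0.35, 0.21, 0.25, 0.0, 4),     # superior WM region (fibre x)
    (0.0, -0.48, 0.23, 0.16, 0.0, 5),    # inferior WM region (fibre y)
    (0.38, -0.38, 0.08, 0.08, 0.0, 6),   # small bright lesion-like inclusion
]


def _sl_region_params() -> dict[int, tuple[float, np.ndarray, np.ndarray]]:
    params: dict[int, tuple[float, np.ndarray, np.ndarray]] = {}
    params[1] = (1.5, np.array([0.8, 0, 0, 0.8, 0, 0.8]), _iso_kt(0.8, 0.5))
    # brain interior: mildly anisotropic through-plane so FA and all
    # kurtosis scalars have nonzero truth inside the ringing ROIs
    dt2, kt2 = _axisym_tensors(ad=1.2, rd=0.75, ak=0.6, rk=1.0)
    params[2] = (0.9, dt2, kt2)
    params[3] = (2.0, np.array([3.0, 0, 0, 3.0, 0, 3.0]), np.zeros(15))
    dt0, kt0 = _axisym_tensors(ad=1.7, rd=0.45, ak=0.8, rk=1.8)
    params[4] = (1.0, *_rotate_tensors(dt0, kt0, _rot_from_z_to([1, 0, 0])))
    params[5] = (1.0, *_rotate_tensors(dt0, kt0, _rot_from_z_to([0, 1, 0])))
    params[6] = (1.8, np.array([1.2, 0, 0, 1.2, 0, 1.2]), _iso_kt(1.2, 0.9))
    return params


def _sl_labels(n: int) -> np.ndarray:
    # FFT sample convention (no half-voxel offset) so that the k-space
    # truncated reconstruction stays aligned with the target-grid truth
    x, y = np.meshgrid(
        np.linspace(-1, 1, n, endpoint=False),
        np.linspace(-1, 1, n, endpoint=False),
        indexing="ij",
    )
    labels = np.zeros((n, n), dtype=int)
    for cx, cy, a, b, ang, label in _SL_ELLIPSES:
        t = np.deg2rad(ang)
        xr = (x - cx) * np.cos(t) + (y - cy) * np.sin(t)
        yr = -(x - cx) * np.sin(t) + (y - cy) * np.cos(t)
        inside = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
        labels[inside] = label
    return labels


def _truncate_kspace(
    image: np.ndarray, n_out: int, pf: float, pe_axis: int
) -> np.ndarray:
    """Central k-space truncation + zero-filled PF reconstruction (2D)."""
    h = image.shape[0]
    spec = np.fft.fftshift(np.fft.fft2(image)) / image.size
    c = h // 2
    lo, hi = c - n_out // 2, c + n_out // 2
    spec = spec[lo:hi, lo:hi].copy()
    if pf < 1.0:
        # acquired lines cover the full positive side and a truncated
        # negative side: zero-fill k < -(pf - 1/2) * n
        n_keep = int(round(pf * n_out))
        spec_ax = np.moveaxis(spec, pe_axis, 0)
        spec_ax[: n_out - n_keep, :] = 0.0
        spec = np.moveaxis(spec_ax, 0, pe_axis)
    img = np.fft.ifft2(np.fft.ifftshift(spec)) * n_out**2
    return np.abs(img)


def _sl_ringing_rois(n: int) -> list[np.ndarray]:
    """Four rectangular ROIs straddling high-contrast ventricle edges."""

    def band(x0, x1, y0, y1):
        roi = np.zeros((n, n), dtype=bool)
        i0, i1 = int((x0 + 1) / 2 * n), int((x1 + 1) / 2 * n)
        j0, j1 = int((y0 + 1) / 2 * n), int((y1 + 1) / 2 * n)
        roi[i0:i1, j0:j1] = True
        return roi

    # boxes straddle ringing from the high-contrast near-vertical
    # (PE-perpendicular) ventricle edges and sit >= 2 voxels (at 128
    # resolution) away from any region edge so partial-volume voxels do
    # not drown the ringing signal
    return [
        band(0.40, 0.52, -0.12, 0.12),    # right of right ventricle
        band(-0.56, -0.44, -0.14, 0.14),  # left of left ventricle
        band(0.42, 0.54, 0.14, 0.26),     # right of right ventricle, upper
        band(-0.54, -0.42, -0.28, -0.14),  # left of left ventricle, lower
    ]


def make_shepp_logan_dmri(
    resolution: int = 128,
    protocol: GradientTable | None = None,
    pf_fraction: float = 6.0 / 8.0,
    pe_axis: int = 0,
    oversample: int = 4,
) -> tuple[PhantomTruth, DWIVolume]:
    """Shepp-Logan-style diffusion slice with simulated Gibbs ringing.

    Returns ``(clean, ringing)``: the target-resolution ground truth and
    the magnitude reconstruction after central k-space truncation from the
    ``oversample``-times finer grid plus zero-filled partial Fourier along
    ``pe_axis`` (the horizontal image axis by default).
    """
    protocol = protocol or make_protocol()
    if not any(abs(pf_fraction - p) < 1e-9 for p in (1.0, 7 / 8, 6 / 8)):
        raise ValueError("pf_fraction must be one of 1, 7/8, 6/8")
    if oversample < 1:
        raise ValueError("oversample must be >= 1")
    n = resolution
    params = _sl_region_params()
    labels = _sl_labels(n)
    labels_hi = _sl_labels(n * oversample)
    nvol = len(protocol)

    lut = np.zeros((max(params) + 1, nvol))
    for label, (s0, dt, kt) in params.items():
        lut[label] = forward_signal(protocol, np.array(s0), dt, kt)

    clean_data = lut[labels][:, :, None, :]  # (n, n, 1, nvol)
    ringing_data = np.empty_like(clean_data)
    for v in range(nvol):
        hi_img = lut[labels_hi, v]
        ringing_data[:, :, 0, v] = _truncate_kspace(hi_img, n, pf_fraction, pe_axis)

    grad = protocol
    mask3 = (labels > 0)[:, :, None]
    clean_vol = DWIVolume(
        clean_data, grad, voxel_size=np.array([1.7, 1.7, 3.0]),
        pf_fraction=1.0, pe_axis=pe_axis, mask=mask3,
    )
    ringing_vol = DWIVolume(
        ringing_data, grad, voxel_size=np.array([1.7, 1.7, 3.0]),
        pf_fraction=pf_fraction, pe_axis=pe_axis, mask=mask3,
    )
    rois = [r[:, :, None] for r in _sl_ringing_rois(n)]
    clean = PhantomTruth(
        truth=clean_vol,
        region_labels=labels[:, :, None],
        region_params=params,
        wm_mask=np.isin(labels, [4, 5])[:, :, None],
        csf_mask=(labels == 3)[:, :, None],
        ringing_rois=rois,
    )
    return clean, ringing_vol
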