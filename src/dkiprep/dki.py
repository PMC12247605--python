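"""Weighted linear least squares DTI/DKI fitting and scalar-map derivation.

The log-signal model is

    ln S(b, n) = ln S0 - b D(n) + (b^2/6) V(n),

with b internally in ms/µm² so diffusivities emerge in µm²/ms.
D(n) = sum_ij n_i n_j D_ij is the apparent diffusivity along unit direction
n; V(n) = sum_ijkl n_i n_j n_k n_l V_ijkl carries the conventional MD²·W
kurtosis scaling, so the apparent kurtosis is K(n) = V(n)/D(n)².

Fitting is two-pass weighted linear least squares on log-signals: an
unweighted pass predicts the signal, the second pass weights every row by
the squared predicted signal.  No positivity constraints and no outlier
rejection are applied during fitting: physically implausible estimates are
the subject of the outlier statistic, not of the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DWIVolume, GradientTable, ScalarMaps

__all__ = [
    "DT_ORDER",
    "KT_ORDER",
    "TensorFit",
    "OutlierSpec",
    "build_design_matrix",
    "forward_signal",
    "wlls_fit",
    "scalar_maps",
    "outlier_stats",
]

#: symmetric diffusion-tensor coefficient order and multiplicities
DT_ORDER = ["xx", "xy", "xz", "yy", "yz", "zz"]
_DT_IDX = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]
_DT_MULT = np.array([1, 2, 2, 1, 2, 1], dtype=float)

#: symmetric kurtosis-tensor coefficient order and multinomial multiplicities
KT_ORDER = [
    "xxxx", "xxxy", "xxxz", "xxyy", "xxyz", "xxzz",
    "xyyy", "xyyz", "xyzz", "xzzz",
    "yyyy", "yyyz", "yyzz", "yzzz", "zzzz",
]
_KT_IDX = [
    (0, 0, 0, 0), (0, 0, 0, 1), (0, 0, 0, 2), (0, 0, 1, 1), (0, 0, 1, 2),
    (0, 0, 2, 2), (0, 1, 1, 1), (0, 1, 1, 2), (0, 1, 2, 2), (0, 2, 2, 2),
    (1, 1, 1, 1), (1, 1, 1, 2), (1, 1, 2, 2), (1, 2, 2, 2), (2, 2, 2, 2),
]
_KT_MULT = np.array([1, 4, 4, 6, 12, 6, 4, 12, 12, 4, 1, 4, 6, 4, 1], dtype=float)

S_PER_MM2_TO_MS_PER_UM2 = 1.0 / 1000.0


class ModelError(ValueError):
    """Raised when the acquisition cannot support the requested model."""


@dataclass
class TensorFit:
    """Per-voxel WLLS coefficients: lnS0, 6 dt (µm²/ms), 15 kt (MD²·W)."""

    lnS0: np.ndarray
    dt: np.ndarray
    kt: np.ndarray
    fit_ok: np.ndarray


@dataclass(frozen=True)
class OutlierSpec:
    """Physical plausibility bounds; the upper diffusivity bound is
    intentionally absent (D < 3 is rarely violated)."""

    d_lo: float = 0.0
    fa_lo: float = 0.0
    fa_hi: float = 1.0
    k_lo: float = -2.0


def quadratic_form_rows(dirs: np.ndarray) -> np.ndarray:
    """Rows evaluating D(n) against the 6 dt coefficients."""
    dirs = np.asarray(dirs, dtype=float)
    cols = [dirs[..., i] * dirs[..., j] for i, j in _DT_IDX]
    return np.stack(cols, axis=-1) * _DT_MULT


def quartic_form_rows(dirs: np.ndarray) -> np.ndarray:
    """Rows evaluating V(n) against the 15 kt coefficients."""
    dirs = np.asarray(dirs, dtype=float)
    cols = [
        dirs[..., i] * dirs[..., j] * dirs[..., k] * dirs[..., l]
        for i, j, k, l in _KT_IDX
    ]
    return np.stack(cols, axis=-1) * _KT_MULT


def build_design_matrix(grad: GradientTable, model: str = "dki") -> np.ndarray:
    """Design matrix for the log-linear model: n_volumes x 22 (or x 7 DTI).

    Columns: intercept, -b * (n n^T) terms with symmetric multiplicities,
    then +(b²/6) quartic terms; b converted to ms/µm².
    """
    b = grad.bvals * S_PER_MM2_TO_MS_PER_UM2
    n = grad.bvecs
    ones = np.ones((len(grad), 1))
    d_block = -b[:, None] * quadratic_form_rows(n)
    if model == "dti":
        if len(grad) < 7:
            raise ModelError("DTI fit needs at least 7 volumes")
        return np.hstack([ones, d_block])
    if model != "dki":
        raise ValueError(f"unknown model {model!r}")
    nonzero_shells = np.unique(grad.shell_index[grad.bvals > 0])
    if len(grad) < 22 or nonzero_shells.size < 2:
        raise ModelError(
            "DKI fit needs >= 22 volumes spanning >= 2 nonzero shells"
        )
    k_block = (b[:, None] ** 2 / 6.0) * quartic_form_rows(n)
    return np.hstack([ones, d_block, k_block])


def forward_signal(
    grad: GradientTable, S0: np.ndarray, dt: np.ndarray, kt: np.ndarray
) -> np.ndarray:
    """Noiseless DKI signal for coefficients (..., 6) and (..., 15)."""
    B = build_design_matrix(grad)
    beta = np.concatenate(
        [np.log(np.asarray(S0, dtype=float))[..., None], dt, kt], axis=-1
    )
    return np.exp(beta @ B.T)


def wlls_fit(
    vol: DWIVolume,
    mask: np.ndarray | None = None,
    model: str = "dki",
    weighted: bool = True,
) -> TensorFit:
    """Two-pass WLLS fit of every in-mask voxel.

    Non-positive signals are clamped to a small floor before the log and
    the voxel is flagged in ``fit_ok``; voxels with singular normal
    equations are likewise flagged rather than fatal.  ``weighted=False``
    stops after the first (unweighted log-linear) pass.
    """
    B = build_design_matrix(vol.grad, model=model)
    ncoef = B.shape[1]
    mask = vol.get_mask() if mask is None else np.asarray(mask, dtype=bool)
    grid = vol.data.shape[:3]
    S = vol.data[mask]  # (nvox, nvol)
    s0_est = np.maximum(S.max(axis=1, keepdims=True), 1e-300)
    floor = 1e-8 * s0_est
    clean = np.all(np.isfinite(S), axis=1) & np.all(S > 0, axis=1)
    y = np.log(np.maximum(S, floor))

    # pass 1: unweighted LLS (shared design -> one solve)
    beta = np.linalg.lstsq(B, y.T, rcond=None)[0].T  # (nvox, ncoef)
    if not weighted:
        beta2 = beta
        ok = clean & np.all(np.isfinite(beta2), axis=1)
        return _pack_fit(beta2, ok, mask, grid, model)
    # pass 2: weight rows by squared predicted signal
    w = np.exp(2.0 * (beta @ B.T))  # (nvox, nvol)
    w = np.clip(w, 0.0, np.finfo(float).max)
    BB = B[:, :, None] * B[:, None, :]  # (nvol, ncoef, ncoef)
    A = np.tensordot(w, BB, axes=(1, 0))  # (nvox, ncoef, ncoef)
    rhs = np.einsum("vi,ic,vi->vc", w, B, y, optimize=True)
    ok = clean.copy()
    try:
        beta2 = np.linalg.solve(A, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        beta2 = np.empty_like(rhs)
        for v in range(A.shape[0]):
            try:
                beta2[v] = np.linalg.solve(A[v], rhs[v])
            except np.linalg.LinAlgError:
                beta2[v] = np.nan
                ok[v] = False
    ok &= np.all(np.isfinite(beta2), axis=1)
    return _pack_fit(beta2, ok, mask, grid, model)


def _pack_fit(beta, ok, mask, grid, model) -> TensorFit:
    def to_grid(arr):
        out = np.full(grid + arr.shape[1:], np.nan, dtype=arr.dtype)
        out[mask] = arr
        return out

    lnS0 = to_grid(beta[:, :1])[..., 0]
    dt = to_grid(beta[:, 1:7])
    if model == "dki":
        kt = to_grid(beta[:, 7:22])
    else:
        kt = np.zeros(grid + (15,))
        kt[~mask] = np.nan
    fit_ok = np.zeros(grid, dtype=bool)
    fit_ok[mask] = ok
    return TensorFit(lnS0, dt, kt, fit_ok)


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit directions (n, 3)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(1.0 - z**2, 0.0))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


_MK_DIRS = fibonacci_sphere(256)
_RK_ANGLES = np.linspace(0.0, np.pi, 64, endpoint=False)


def _dt_to_matrix(dt: np.ndarray) -> np.ndarray:
    out = np.empty(dt.shape[:-1] + (3, 3))
    for c, (i, j) in enumerate(_DT_IDX):
        out[..., i, j] = dt[..., c]
        out[..., j, i] = dt[..., c]
    return out


def scalar_maps(fit: TensorFit) -> ScalarMaps:
    """Derive MD/AD/RD/FA and MK/AK/RK from the fitted tensors.

    Eigenvalues are sorted descending; AK is the apparent kurtosis along
    the principal eigenvector, RK the average over 64 directions in the
    radial plane, MK the average over a 256-point spherical set.
    """
    grid = fit.lnS0.shape
    ok = fit.fit_ok & np.all(np.isfinite(fit.dt), axis=-1) \
        & np.all(np.isfinite(fit.kt), axis=-1)
    dt = fit.dt[ok]
    kt = fit.kt[ok]

    D = _dt_to_matrix(dt)
    evals, evecs = np.linalg.eigh(D)  # ascending
    lam = evals[:, ::-1]  # descending: lam1 >= lam2 >= lam3
    e1 = evecs[:, :, 2]
    e2 = evecs[:, :, 1]
    e3 = evecs[:, :, 0]

    md = lam.mean(axis=1)
    ad = lam[:, 0]
    rd = 0.5 * (lam[:, 1] + lam[:, 2])
    num = ((lam - md[:, None]) ** 2).sum(axis=1)
    den = (lam**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5 * num / den)

    with np.errstate(divide="ignore", invalid="ignore"):
        # MK: lab-frame directional average
        d_app = quadratic_form_rows(_MK_DIRS) @ dt.T  # (ndir, nvox)
        v_app = quartic_form_rows(_MK_DIRS) @ kt.T
        mk = (v_app / d_app**2).mean(axis=0)
        # AK: along the principal axis (apparent diffusivity = lam1)
        v_ax = np.einsum("vc,vc->v", quartic_form_rows(e1), kt)
        ak = v_ax / lam[:, 0] ** 2
        # RK: average over the radial plane
        cos, sin = np.cos(_RK_ANGLES), np.sin(_RK_ANGLES)
        dirs_r = cos[None, :, None] * e2[:, None, :] + \
            sin[None, :, None] * e3[:, None, :]  # (nvox, 64, 3)
        d_r = lam[:, 1][:, None] * cos[None, :] ** 2 + \
            lam[:, 2][:, None] * sin[None, :] ** 2
        v_r = np.einsum("vdc,vc->vd", quartic_form_rows(dirs_r), kt)
        rk = (v_r / d_r**2).mean(axis=1)

    def to_grid(arr):
        out = np.full(grid, np.nan)
        out[ok] = arr
        return out

    return ScalarMaps(
        md=to_grid(md), ad=to_grid(ad), rd=to_grid(rd), fa=to_grid(fa),
        mk=to_grid(mk), ak=to_grid(ak), rk=to_grid(rk),
    )


def outlier_stats(
    maps: ScalarMaps, roi: np.ndarray, spec: OutlierSpec | None = None
) -> dict[str, float]:
    """Percent of ROI voxels violating physical bounds, per map + average.

    Bounds: D > 0 for MD/AD/RD, 0 < FA < 1, K > -2 for MK/AK/RK.  Non-finite
    voxels (invalid fits) count as outliers.
    """
    spec = spec or OutlierSpec()
    roi = np.asarray(roi, dtype=bool)
    nroi = roi.sum()
    if nroi == 0:
        raise ValueError("ROI is empty")
    out: dict[str, float] = {}
    with np.errstate(invalid="ignore"):
        for name in ("md", "ad", "rd"):
            v = maps[name][roi]
            out[name] = 100.0 * np.mean(~(v > spec.d_lo))
        v = maps["fa"][roi]
        out["fa"] = 100.0 * np.mean(~((v > spec.fa_lo) & (v < spec.fa_hi)))
        for name in ("mk", "ak", "rk"):
            v = maps[name][roi]
            out[name] = 100.0 * np.mean(~(v > spec.k_lo))
    out["average"] = float(np.mean([out[k] for k in
                                    ("md", "ad", "rd", "fa", "mk", "ak", "rk")]))
    return out
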