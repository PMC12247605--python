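"""Marchenko-Pastur PCA denoising with local and adaptive patches.

Each voxel's diffusion signal across volumes is stacked with neighbouring
voxels into a Casorati matrix (patch voxels x volumes).  Random-matrix
theory separates the singular spectrum into signal components and a bulk of
noise components whose eigenvalues follow the Marchenko-Pastur (MP)
distribution; the bulk yields a per-voxel noise level sigma and the number
of retained components P.  Noise components are either discarded (hard
truncation) or all singular values are passed through the optimal
Frobenius-loss shrinker.

Patches are either a fixed local box around each voxel or an adaptive
selection: the ``patch_size`` voxels in a search window that minimise a
bilateral score combining spatial distance and mean absolute intensity
difference over all diffusion volumes, so that patches stay within one
tissue type and signal redundancy is maximal.

Rician bias correction (method of moments) removes the noise-floor bias of
magnitude images using the MP noise map: S = sqrt(max(M^2 - sigma^2, 0)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import DWIVolume

__all__ = [
    "PatchSpec",
    "DenoiseResult",
    "select_adaptive_patch",
    "mp_denoise_matrix",
    "denoise_volume",
    "denoise_volume_multi",
    "rician_bias_correct",
]


@dataclass(frozen=True)
class PatchSpec:
    """How to form the Casorati matrix around each voxel.

    mode 'local' uses a box of ``local_box`` voxels per side (clipped at the
    volume edge); mode 'adaptive' picks the ``patch_size`` best-matching
    voxels in a window of half-width ``search_window`` by the bilateral
    score.  The centre voxel is always part of its own patch.
    """

    mode: str = "adaptive"
    patch_size: int = 100
    search_window: int = 7
    local_box: int = 5

    def __post_init__(self):
        if self.mode not in ("local", "adaptive"):
            raise ValueError(f"unknown patch mode {self.mode!r}")
        if self.patch_size < 2:
            raise ValueError("patch_size must be >= 2")
        if self.local_box < 1 or self.local_box % 2 == 0:
            raise ValueError("local_box must be a positive odd integer")


@dataclass
class DenoiseResult:
    denoised: np.ndarray
    sigma_map: np.ndarray
    ncomponents_map: np.ndarray


def _mp_components(lam: np.ndarray, m_rows: int) -> tuple[np.ndarray, np.ndarray]:
    """Number of signal components and noise variance from MP consistency.

    ``lam``: (..., N) eigenvalues of X^T X / M, sorted descending.  For each
    candidate P, the trailing N-P eigenvalues are averaged into a variance
    estimate; P is the smallest value for which the largest trailing
    eigenvalue sits below the MP bulk edge sigma^2 (1 + sqrt((N-P)/M))^2.
    Returns (P, sigma^2) broadcast over the leading axes.
    """
    lam = np.asarray(lam)
    n = lam.shape[-1]
    # tail_mean[..., p] = mean(lam[p:]) for p = 0..n-1
    rev_csum = np.cumsum(lam[..., ::-1], axis=-1)[..., ::-1]
    counts = np.arange(n, 0, -1, dtype=float)
    tail_mean = rev_csum / counts
    edge = tail_mean * (1.0 + np.sqrt(counts / m_rows)) ** 2
    ok = lam <= edge  # lam[..., p] is the largest of the trailing block
    # smallest p with ok; fall back to n-1 if none
    any_ok = ok.any(axis=-1)
    p_first = np.where(any_ok, np.argmax(ok, axis=-1), n - 1)
    sigma2 = np.take_along_axis(tail_mean, p_first[..., None], axis=-1)[..., 0]
    return p_first, sigma2


def _shrink_singular_values(
    s: np.ndarray, sigma: np.ndarray, m_rows: int, n_cols: int
) -> np.ndarray:
    """Optimal Frobenius-loss shrinker on normalized singular values.

    y = s / (sigma sqrt(M)), beta = N/M; values inside the MP bulk
    (y <= 1 + sqrt(beta)) map to zero, the rest to
    sigma sqrt(M) sqrt((y^2 - beta - 1)^2 - 4 beta) / y.
    """
    sigma = np.asarray(sigma)[..., None]
    beta = n_cols / m_rows
    scale = sigma * np.sqrt(m_rows)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = s / scale
        inner = (y**2 - beta - 1.0) ** 2 - 4.0 * beta
        s_new = scale * np.sqrt(np.maximum(inner, 0.0)) / y
    s_new = np.where(y > 1.0 + np.sqrt(beta), s_new, 0.0)
    # noiseless patch: all components are signal, keep them
    return np.where(np.broadcast_to(sigma > 0, s.shape), s_new, s)


def _denoise_batch_multi(
    X: np.ndarray,
    shrinks: tuple[bool, ...],
    center_rows: np.ndarray | None = None,
):
    """Denoise a batch of Casorati matrices X (B, M, N) for one SVD pass.

    Returns ({shrink_flag: X_hat}, sigma, P).  If ``center_rows`` is given,
    only that row of each reconstruction is computed (B, N) -- the
    centre-voxel writeback.
    """
    b, m, n = X.shape
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    lam = (s**2) / m
    P, sigma2 = _mp_components(lam, m)
    sigma = np.sqrt(sigma2)
    recs: dict[bool, np.ndarray] = {}
    for shrink in shrinks:
        if shrink:
            s_new = _shrink_singular_values(s, sigma, m, n)
        else:
            keep = np.arange(min(m, n))[None, :] < P[:, None]
            s_new = np.where(keep, s, 0.0)
            # noiseless matrices: every component is signal
            s_new = np.where((sigma2 <= 0)[:, None], s, s_new)
        if center_rows is not None:
            u_c = U[np.arange(b), center_rows, :]  # (B, N)
            recs[shrink] = np.einsum("bi,bij->bj", u_c * s_new, Vt)
        else:
            recs[shrink] = np.einsum("bik,bk,bkj->bij", U, s_new, Vt)
    return recs, sigma, P


def mp_denoise_matrix(X: np.ndarray, shrink: bool = False):
    """Denoise one Casorati matrix; returns (X_hat, sigma, P).

    The matrix is oriented internally so rows >= columns; the MP criterion
    is evaluated on the eigenvalues of X^T X / rows.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or min(X.shape) < 2:
        raise ValueError("X must be 2D with both dimensions >= 2")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite entries")
    transposed = X.shape[0] < X.shape[1]
    Xw = X.T if transposed else X
    recs, sigma, P = _denoise_batch_multi(Xw[None], (shrink,))
    rec = recs[shrink]
    out = rec[0].T if transposed else rec[0]
    return out, float(sigma[0]), int(P[0])


def select_adaptive_patch(
    data: np.ndarray,
    center: tuple[int, int, int],
    spec: PatchSpec,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Bilateral patch selection around ``center``.

    Candidates in the clipped search window are ranked by the sum of the
    max-normalized spatial distance and the max-normalized mean absolute
    intensity difference (over all volumes) to the centre voxel; ties break
    in lexicographic voxel-index order.  Returns an (n, 3) index array with
    the centre first, n = min(patch_size, available candidates).
    """
    data = np.asarray(data)
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    ci, cj, ck = (int(c) for c in center)
    if not mask[ci, cj, ck]:
        raise ValueError(f"centre voxel {center} lies outside the mask")
    w = spec.search_window
    lo = (max(ci - w, 0), max(cj - w, 0), max(ck - w, 0))
    hi = (
        min(ci + w + 1, data.shape[0]),
        min(cj + w + 1, data.shape[1]),
        min(ck + w + 1, data.shape[2]),
    )
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    sub_mask = mask[sl]
    idx = np.argwhere(sub_mask)  # lexicographic order within window
    abs_idx = idx + np.array(lo)
    d2 = ((abs_idx - np.array([ci, cj, ck])) ** 2).sum(axis=1).astype(float)
    dist = np.sqrt(d2)
    block = data[sl][sub_mask]  # (n_cand, n_vol)
    center_sig = data[ci, cj, ck]
    inten = np.abs(block - center_sig).mean(axis=1)
    d_max = dist.max() if dist.size and dist.max() > 0 else 1.0
    i_max = inten.max() if inten.size and inten.max() > 0 else 1.0
    score = dist / d_max + inten / i_max
    order = np.argsort(score, kind="stable")
    chosen = abs_idx[order[: spec.patch_size]]
    # centre always first
    is_center = np.all(chosen == [ci, cj, ck], axis=1)
    if is_center.any():
        pos = int(np.argmax(is_center))
        chosen = np.concatenate([chosen[pos:pos + 1], chosen[:pos], chosen[pos + 1:]])
    else:
        chosen = np.concatenate([[[ci, cj, ck]], chosen[:-1]])
    return chosen


def _local_patch(shape, center, spec, mask):
    half = spec.local_box // 2
    ci, cj, ck = center
    sl = tuple(
        slice(max(c - half, 0), min(c + half + 1, s))
        for c, s in zip(center, shape)
    )
    idx = np.argwhere(mask[sl]) + np.array([s.start for s in sl])
    is_center = np.all(idx == [ci, cj, ck], axis=1)
    pos = int(np.argmax(is_center))
    return np.concatenate([idx[pos:pos + 1], idx[:pos], idx[pos + 1:]])


def denoise_volume_multi(
    vol: DWIVolume,
    spec: PatchSpec | None = None,
    shrinks: tuple[bool, ...] = (False,),
    chunk: int = 256,
) -> dict[bool, DenoiseResult]:
    """Denoise every in-mask voxel, once per shrinkage setting.

    Patch selection and the SVD of each Casorati matrix are shared between
    the requested shrinkage settings; only the singular-value treatment and
    the centre-row writeback differ.  Returns {shrink_flag: DenoiseResult}.
    """
    spec = spec or PatchSpec()
    shrinks = tuple(dict.fromkeys(shrinks))
    data = vol.data
    nvol = data.shape[3]
    mask = vol.get_mask()
    if not mask.any():
        raise ValueError("mask is empty")
    if nvol < 8:
        warnings.warn("fewer than 8 volumes: MP noise estimate is unreliable")
    outs = {f: data.copy() for f in shrinks}
    sigma_map = np.zeros(data.shape[:3])
    ncomp_map = np.zeros(data.shape[:3], dtype=int)
    flat = data.reshape(-1, nvol)
    strides = np.array(
        [data.shape[1] * data.shape[2], data.shape[2], 1], dtype=np.int64
    )

    centers = np.argwhere(mask)
    # group patches by size so SVDs batch cleanly
    groups: dict[int, list[tuple[np.ndarray, np.ndarray]]] = {}
    for c in centers:
        if spec.mode == "adaptive":
            p = select_adaptive_patch(data, tuple(c), spec, mask)
        else:
            p = _local_patch(data.shape[:3], tuple(c), spec, mask)
        groups.setdefault(len(p), []).append((c, p @ strides))

    for size, items in groups.items():
        if size < 2:
            continue
        for start in range(0, len(items), chunk):
            part = items[start:start + chunk]
            cen = np.array([c for c, _ in part])
            rows = np.stack([r for _, r in part])  # (B, size)
            X = flat[rows]  # (B, size, nvol)
            ii, jj, kk = cen.T
            if size < nvol:  # orient rows >= columns for the MP criterion
                recs, sig, P = _denoise_batch_multi(
                    np.swapaxes(X, 1, 2), shrinks, center_rows=None
                )
                for f in shrinks:
                    outs[f][ii, jj, kk, :] = recs[f][:, :, 0]
            else:
                recs, sig, P = _denoise_batch_multi(
                    X, shrinks, center_rows=np.zeros(len(part), dtype=int)
                )
                for f in shrinks:
                    outs[f][ii, jj, kk, :] = recs[f]
            sigma_map[ii, jj, kk] = sig
            ncomp_map[ii, jj, kk] = P
    return {
        f: DenoiseResult(np.maximum(outs[f], 0.0), sigma_map.copy(), ncomp_map.copy())
        for f in shrinks
    }


def denoise_volume(
    vol: DWIVolume,
    spec: PatchSpec | None = None,
    shrink: bool = False,
    chunk: int = 256,
) -> DenoiseResult:
    """Denoise every in-mask voxel from its own patch (centre writeback).

    Each voxel receives the centre row of its patch reconstruction together
    with that patch's noise level and component count, populating
    ``sigma_map`` and ``ncomponents_map``.
    """
    return denoise_volume_multi(vol, spec, (shrink,), chunk)[shrink]


def rician_bias_correct(denoised: np.ndarray, sigma_map: np.ndarray) -> np.ndarray:
    """Method-of-moments noise-floor removal: sqrt(max(M^2 - sigma^2, 0))."""
    denoised = np.asarray(denoised, dtype=float)
    sigma_map = np.asarray(sigma_map, dtype=float)
    if np.any(sigma_map < 0):
        raise ValueError("sigma map must be non-negative")
    sig2 = sigma_map[..., None] ** 2 if sigma_map.ndim == denoised.ndim - 1 else sigma_map**2
    return np.sqrt(np.maximum(denoised**2 - sig2, 0.0))
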