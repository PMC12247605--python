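"""Gibbs-ringing removal by subvoxel shifts, with a partial-Fourier stage.

Finite k-space sampling turns sharp edges into sinc oscillations with a
2-voxel period.  The subvoxel-shift (SuShi) corrector re-interpolates each
line at the shift that minimises local total variation: sampling exactly
half-way between the original grid points lands on the zero crossings of
the ringing pattern.  The two in-plane axes are handled with the standard
pair of complementary spectral weighting filters so each axis' unringing
only acts on ringing oriented along it.

Partial-Fourier (PF) acquisitions zero-fill one side of k-space, adding a
second ringing pattern whose period is 2/(2*pf - 1) voxels (4 voxels for
6/8 PF).  The RPG corrector removes the symmetric-truncation ringing on the
original grid, then resamples the image along the phase-encode axis so the
PF ringing acquires a 2-voxel period (interleaved line sets for 6/8; x3
upsampling plus stride-4 phases for 7/8), runs a second subvoxel-shift pass
on each phase, and recombines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import resample as _fourier_resample

from .io import SUPPORTED_PF, DWIVolume

__all__ = ["UnringParams", "sushi_unring", "rpg_unring", "unring_volume"]


@dataclass(frozen=True)
class UnringParams:
    """Subvoxel-shift search parameters.

    ``nshifts`` shifts on each side of zero are tested (step 1/(2*nshifts)
    voxel); total variation is measured over neighbour differences at
    offsets ``k1``..``k2`` on each side of the voxel.  ``slice_axis`` is the
    through-slice axis of 3D input, left untouched.
    """

    nshifts: int = 20
    k1: int = 1
    k2: int = 3
    pf_fraction: float = 1.0
    pe_axis: int = 0
    slice_axis: int = 2

    def __post_init__(self):
        if self.nshifts < 2:
            raise ValueError("nshifts must be >= 2")
        if not (1 <= self.k1 < self.k2):
            raise ValueError("require 1 <= k1 < k2")
        if not any(abs(self.pf_fraction - p) < 1e-9 for p in SUPPORTED_PF):
            raise ValueError(
                "correcting for 5/8 (or other) partial Fourier is unsupported: "
                "it may result in unreasonably smoothed maps"
            )


def _shift_values(nshifts: int) -> np.ndarray:
    steps = np.arange(1, nshifts + 1) / (2.0 * nshifts)
    return np.concatenate([[0.0], steps, -steps])  # zero shift first (ties)


def _unring_lines(lines: np.ndarray, params: UnringParams) -> np.ndarray:
    """Subvoxel-shift unringing of a batch of periodic lines (L, N)."""
    lines = np.asarray(lines, dtype=float)
    L, N = lines.shape
    shifts = _shift_values(params.nshifts)
    c = np.fft.fft(lines, axis=1)
    freqs = np.fft.fftfreq(N) * N  # signed integer frequencies
    phase = np.exp(2j * np.pi * freqs[None, :] * shifts[:, None] / N)
    shifted = np.fft.ifft(c[None, :, :] * phase[:, None, :], axis=2).real  # (S,L,N)

    d = np.roll(shifted, -1, axis=2) - shifted  # d(x) = sh(x+1) - sh(x)
    ad = np.abs(d)
    tv_r = np.zeros_like(ad)
    tv_l = np.zeros_like(ad)
    for t in range(params.k1, params.k2 + 1):
        # right window |sh(x+t) - sh(x+t-1)|, left window |sh(x-t) - sh(x-t+1)|
        tv_r += np.roll(ad, -(t - 1), axis=2)
        tv_l += np.roll(ad, t, axis=2)
    measure = np.minimum(tv_l, tv_r)
    opt = np.argmin(measure, axis=0)  # (L, N); ties -> zero shift

    s_opt = shifts[opt]
    sel = opt[None, :, :]
    sh_opt = np.take_along_axis(shifted, sel, axis=0)[0]  # (L, N)
    # neighbours must come from the SAME shifted signal chosen at x
    left = np.take_along_axis(np.roll(shifted, 1, axis=2), sel, axis=0)[0]
    right = np.take_along_axis(np.roll(shifted, -1, axis=2), sel, axis=0)[0]
    a = np.abs(s_opt)
    neighbour = np.where(s_opt > 0, left, right)
    return sh_opt * (1.0 - a) + neighbour * a


def _unring_along_axis(image: np.ndarray, axis: int, params: UnringParams):
    moved = np.moveaxis(image, axis, -1)
    flat = moved.reshape(-1, moved.shape[-1])
    out = _unring_lines(flat, params).reshape(moved.shape)
    return np.moveaxis(out, -1, axis)


def _axis_filters(shape2d: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Complementary spectral weights (Ga, Gb) for the two in-plane axes.

    Ga passes components varying slowly along axis b (its ringing is along
    axis a); Ga + Gb = 1 everywhere so constant images are preserved.
    """
    na, nb = shape2d
    ca = np.cos(2 * np.pi * np.fft.fftfreq(na))[:, None]
    cb = np.cos(2 * np.pi * np.fft.fftfreq(nb))[None, :]
    denom = 2.0 + ca + cb
    with np.errstate(divide="ignore", invalid="ignore"):
        ga = np.where(denom > 1e-12, (1.0 + cb) / denom, 0.5)
    return ga, 1.0 - ga


def _sushi_2d(image: np.ndarray, params: UnringParams) -> np.ndarray:
    spec = np.fft.fft2(image)
    ga, gb = _axis_filters(image.shape)
    part_a = np.fft.ifft2(spec * ga).real
    part_b = np.fft.ifft2(spec * gb).real
    return (
        _unring_along_axis(part_a, 0, params)
        + _unring_along_axis(part_b, 1, params)
    )


def sushi_unring(image: np.ndarray, params: UnringParams | None = None):
    """Subvoxel-shift Gibbs removal for symmetric k-space truncation.

    2D input is corrected in-plane; 3D input is corrected slice-wise in the
    plane orthogonal to ``params.slice_axis``.
    """
    params = params or UnringParams()
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    if image.ndim == 2:
        return _sushi_2d(image, params)
    if image.ndim != 3:
        raise ValueError("image must be 2D or 3D")
    moved = np.moveaxis(image, params.slice_axis, 0)
    out = np.stack([_sushi_2d(sl, params) for sl in moved])
    return np.moveaxis(out, 0, params.slice_axis)


def _pf_phases(pf: float) -> tuple[int, int]:
    """(upsample factor, decimation stride) mapping the PF ringing period
    2/(2*pf - 1) onto 2 samples: 6/8 -> (1, 2), 7/8 -> (3, 4)."""
    if abs(pf - 6.0 / 8.0) < 1e-9:
        return 1, 2
    if abs(pf - 7.0 / 8.0) < 1e-9:
        return 3, 4
    raise ValueError(f"no partial-Fourier stage for pf = {pf}")


def rpg_unring(image: np.ndarray, params: UnringParams | None = None):
    """Two-stage Gibbs removal for zero-filled partial-Fourier data.

    Full-Fourier input delegates to :func:`sushi_unring`.  Otherwise a
    SuShi pass removes the symmetric-truncation ringing; then the image is
    resampled along the phase-encode axis so the partial-Fourier ringing
    (period 2/(2*pf - 1) voxels) acquires the 2-voxel period the shift
    search assumes: each interleaved subsampled line set is unrung
    separately and the phases recombined, so no samples are discarded.
    For 7/8 the grid is first Fourier-upsampled x3 (period 8/3 -> 8) and
    decimated with stride 4; for 6/8 the stride-2 phases are used directly.
    """
    params = params or UnringParams()
    image = np.asarray(image, dtype=float)
    if abs(params.pf_fraction - 1.0) < 1e-9:
        return sushi_unring(image, params)

    out = sushi_unring(image, params)
    pe = params.pe_axis if image.ndim == 3 else min(params.pe_axis, 1)
    n = image.shape[pe]
    up, stride = _pf_phases(params.pf_fraction)
    work = _fourier_resample(out, up * n, axis=pe) if up > 1 else out.copy()
    for phase in range(stride):
        sl = [slice(None)] * work.ndim
        sl[pe] = slice(phase, None, stride)
        work[tuple(sl)] = _unring_along_axis(work[tuple(sl)], pe, params)
    if up > 1:
        work = _fourier_resample(work, n, axis=pe)
    return work


def unring_volume(
    vol: DWIVolume, params: UnringParams | None = None, method: str = "auto"
) -> DWIVolume:
    """Unring every diffusion volume of a 4D series.

    ``method`` 'auto' selects RPG for partial-Fourier data and SuShi for
    full Fourier, mirroring the pipeline's corrector choice; 'sushi' or
    'rpg' force one corrector.  Geometry defaults come from the volume.
    """
    if params is None:
        params = UnringParams(pf_fraction=vol.pf_fraction, pe_axis=vol.pe_axis)
    if method == "auto":
        method = "rpg" if params.pf_fraction < 1.0 else "sushi"
    if method not in ("sushi", "rpg"):
        raise ValueError(f"unknown unring method {method!r}")
    fn = sushi_unring if method == "sushi" else rpg_unring
    out = np.empty_like(vol.data)
    for v in range(vol.data.shape[3]):
        out[..., v] = fn(vol.data[..., v], params)
    new = vol.with_data(np.maximum(out, 0.0))
    new.pf_fraction = 1.0 if method == "rpg" else vol.pf_fraction
    return new
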