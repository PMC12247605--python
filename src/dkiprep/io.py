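"""Data model and NIfTI / FSL bval-bvec I/O for diffusion-weighted series.

A diffusion acquisition is represented as a :class:`DWIVolume`: a 4D
magnitude image (x, y, z, volume), its gradient table, voxel geometry, and
the partial-Fourier factor / phase-encode axis needed by the Gibbs
corrector.  b-vectors are interpreted in image-index space; no scanner-frame
reorientation is attempted.  Voxel coordinates are 0-based array indices
throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = [
    "GradientTable",
    "DWIVolume",
    "ScalarMaps",
    "FormatError",
    "read_dwi",
    "write_dwi",
    "write_map",
]

#: partial-Fourier factors the Gibbs corrector supports
SUPPORTED_PF = (1.0, 7.0 / 8.0, 6.0 / 8.0)

SCALAR_NAMES = ("md", "ad", "rd", "fa", "mk", "ak", "rk")


class FormatError(ValueError):
    """Raised when an input file pair is structurally inconsistent."""


@dataclass(frozen=True)
class GradientTable:
    """Per-volume diffusion weighting: b-values (s/mm^2) and unit directions.

    ``shell_index`` labels each volume with the index of its nominal shell
    (0 = b0, then ascending b).  Directions for b = 0 volumes may be zero.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    shell_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.shape == (3, bvals.size):
            bvecs = bvecs.T
        if bvecs.shape != (bvals.size, 3):
            raise FormatError(
                f"bvecs shape {bvecs.shape} does not match {bvals.size} b-values"
            )
        if np.any(bvals < 0):
            raise ValueError("b-values must be non-negative")
        norms = np.linalg.norm(bvecs, axis=1)
        dwi = bvals > 0
        if np.any(np.abs(norms[dwi] - 1.0) > 1e-6):
            raise ValueError("b-vectors for b > 0 volumes must be unit length")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        if self.shell_index is None:
            object.__setattr__(self, "shell_index", _shell_labels(bvals))
        else:
            object.__setattr__(
                self, "shell_index", np.asarray(self.shell_index, dtype=int).ravel()
            )

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.shell_index == 0

    @property
    def shells(self) -> np.ndarray:
        """Nominal b-value of each shell (median of member b-values)."""
        return np.array(
            [np.median(self.bvals[self.shell_index == s])
             for s in range(self.shell_index.max() + 1)]
        )


def _shell_labels(bvals: np.ndarray, tol: float = 100.0) -> np.ndarray:
    """Snap b-values to nominal shells within ``tol`` (s/mm^2) and label them."""
    order = np.argsort(bvals)
    labels = np.empty(bvals.size, dtype=int)
    shell_centers: list[float] = []
    for i in order:
        b = bvals[i]
        for s, c in enumerate(shell_centers):
            if abs(b - c) <= tol:
                labels[i] = s
                break
        else:
            shell_centers.append(b)
            labels[i] = len(shell_centers) - 1
    # shell 0 must be the b0 shell if one exists
    return labels


@dataclass
class DWIVolume:
    """4D magnitude diffusion series plus acquisition geometry."""

    data: np.ndarray
    grad: GradientTable
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))
    pf_fraction: float = 1.0
    pe_axis: int = 1
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise FormatError(f"expected a 4D image, got {self.data.ndim}D")
        if self.data.shape[3] != len(self.grad):
            raise FormatError(
                f"image has {self.data.shape[3]} volumes but gradient table "
                f"has {len(self.grad)}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image contains non-finite values")
        if np.any(self.data < 0):
            raise ValueError("magnitude data must be non-negative")
        if not any(abs(self.pf_fraction - p) < 1e-9 for p in SUPPORTED_PF):
            raise ValueError(
                f"unsupported partial-Fourier fraction {self.pf_fraction}; "
                f"supported: 1, 7/8, 6/8"
            )
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).ravel()
        if self.voxel_size.shape != (3,):
            raise ValueError("voxel_size must be a 3-vector")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError("mask shape does not match image grid")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def get_mask(self) -> np.ndarray:
        """Return the brain mask, defaulting to all voxels."""
        if self.mask is not None:
            return self.mask
        return np.ones(self.data.shape[:3], dtype=bool)

    def mean_b0(self) -> np.ndarray:
        """Mean over the b = 0 volumes (3D)."""
        return self.data[..., self.grad.b0_mask].mean(axis=3)

    def with_data(self, data: np.ndarray) -> "DWIVolume":
        """Copy of this volume with new image data (same geometry/table)."""
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class ScalarMaps:
    """The seven DTI/DKI scalar maps on the 3D grid of the source volume.

    Diffusivities (md, ad, rd) are in µm²/ms; fa and the kurtosis scalars
    (mk, ak, rk) are dimensionless.  Voxels where the fit failed are NaN.
    """

    md: np.ndarray
    ad: np.ndarray
    rd: np.ndarray
    fa: np.ndarray
    mk: np.ndarray
    ak: np.ndarray
    rk: np.ndarray

    def __getitem__(self, name: str) -> np.ndarray:
        return getattr(self, name.lower())

    def items(self):
        for name in SCALAR_NAMES:
            yield name, getattr(self, name)


def read_dwi(
    image_path,
    bval_path,
    bvec_path,
    pf_fraction: float = 1.0,
    pe_axis: int = 1,
    shell_tol: float = 100.0,
) -> DWIVolume:
    """Load a 4D NIfTI with FSL-style .bval/.bvec files.

    b-values are snapped to nominal shells within ``shell_tol`` s/mm^2.
    Raises :class:`FormatError` on dimension mismatches.
    """
    img = nib.load(str(image_path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 4:
        raise FormatError(f"{image_path}: expected 4D image, got {data.ndim}D")
    bvals = np.loadtxt(str(bval_path), ndmin=1).ravel()
    bvecs = np.loadtxt(str(bvec_path), ndmin=2)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    if bvals.size != data.shape[3] or bvecs.shape[0] != data.shape[3]:
        raise FormatError(
            f"gradient files describe {bvals.size} volumes but image has "
            f"{data.shape[3]}"
        )
    grad = GradientTable(bvals, bvecs, _shell_labels(bvals, tol=shell_tol))
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return DWIVolume(data, grad, voxel_size, pf_fraction, pe_axis)


def write_dwi(vol: DWIVolume, image_path, bval_path, bvec_path) -> None:
    """Write a DWIVolume as NIfTI + FSL bval/bvec (one row / three rows)."""
    affine = np.diag(list(vol.voxel_size) + [1.0])
    img = nib.Nifti1Image(vol.data, affine)
    img.header.set_zooms(tuple(vol.voxel_size) + (1.0,))
    nib.save(img, str(image_path))
    np.savetxt(str(bval_path), vol.grad.bvals[None, :], fmt="%.6g")
    np.savetxt(str(bvec_path), vol.grad.bvecs.T, fmt="%.9g")


def write_map(map3d: np.ndarray, voxel_size, path) -> None:
    """Write a 3D scalar map as NIfTI (viewable in standard viewers)."""
    voxel_size = np.asarray(voxel_size, dtype=float).ravel()
    affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(map3d, dtype=np.float64), affine)
    img.header.set_zooms(tuple(voxel_size))
    nib.save(img, str(path))
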