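"""End-to-end preprocessing orchestration.

The canonical step order is (a) MPPCA denoising, (b) Gibbs removal (RPG
when the acquisition used partial Fourier, SuShi otherwise), (c)+(d) an
external hook where EPI-distortion / eddy-current / motion correction
tools would run (never re-implemented here), (e) b0 normalization between
the two acquisition series, (f) Rician bias correction, then the WLLS
tensor fit.  Configurations requesting steps out of this order are
rejected: the steps do not commute and the executed order is part of the
provenance report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.ndimage import gaussian_filter

from . import __version__
from .dki import scalar_maps, wlls_fit
from .evaluate import gaussian_smooth_csf_excluded
from .gibbs import UnringParams, unring_volume
from .io import DWIVolume, GradientTable, ScalarMaps
from .mppca import PatchSpec, denoise_volume, rician_bias_correct

__all__ = ["PipelineConfig", "ConfigError", "b0_normalize", "run_pipeline", "PRESETS"]

CANONICAL_ORDER = (
    "denoise", "degibbs", "external_hook", "b0_normalize", "rician", "fit"
)

PRESETS: dict[str, tuple[str, ...]] = {
    "none": ("fit",),
    "em": ("external_hook", "b0_normalize", "fit"),
    "em-smooth": ("external_hook", "b0_normalize", "fit"),
    "dv1": CANONICAL_ORDER,
    "dv2": CANONICAL_ORDER,
}


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Which steps run and with what options.

    ``steps`` must be an ordered subset of the canonical order.  Presets:
    'none' (fit only), 'em' (hook + b0 normalization + fit), 'em-smooth'
    (em + CSF-excluded smoothing), 'dv1' (local patch, SuShi), 'dv2'
    (adaptive patch + shrinkage, RPG for partial Fourier).
    """

    steps: tuple[str, ...] = CANONICAL_ORDER
    denoise_mode: str = "adaptive"
    shrinkage: bool = True
    patch_size: int = 100
    search_window: int = 7
    smoothing: float | None = None  # FWHM factor, e.g. 1.2; None = off
    csf_mask: np.ndarray | None = None
    b0_sigma_mm: float = 3.0
    seed: int = 0
    external_hook: Callable[[DWIVolume], DWIVolume] | None = None
    unring: UnringParams | None = None

    def __post_init__(self):
        unknown = set(self.steps) - set(CANONICAL_ORDER)
        if unknown:
            raise ConfigError(f"unknown steps: {sorted(unknown)}")
        order = [CANONICAL_ORDER.index(s) for s in self.steps]
        if order != sorted(order) or len(set(order)) != len(order):
            raise ConfigError(
                f"steps must follow the canonical order {CANONICAL_ORDER}"
            )
        if "rician" in self.steps and "denoise" not in self.steps:
            raise ConfigError(
                "Rician bias correction needs the noise map from denoising"
            )

    @classmethod
    def preset(cls, name: str, **kwargs) -> "PipelineConfig":
        if name not in PRESETS:
            raise ConfigError(f"unknown preset {name!r}")
        opts: dict = {"steps": PRESETS[name]}
        if name == "em-smooth":
            opts["smoothing"] = 1.2
        if name == "dv1":
            opts.update(denoise_mode="local", shrinkage=False)
        if name == "dv2":
            opts.update(denoise_mode="adaptive", shrinkage=True)
        opts.update(kwargs)
        return cls(**opts)


def b0_normalize(
    series_a: DWIVolume, series_b: DWIVolume, sigma_mm: float = 3.0
) -> DWIVolume:
    """Rescale series_b onto series_a's intensity level and concatenate.

    The mean b = 0 image of each series is smoothed with an isotropic
    Gaussian of ``sigma_mm`` (mm, truncated at 4 sigma); series_b is
    multiplied voxelwise by the ratio smoothed-b0_a / smoothed-b0_b.
    """
    if series_a.data.shape[:3] != series_b.data.shape[:3]:
        raise ValueError("series grids do not match")
    if not np.allclose(series_a.voxel_size, series_b.voxel_size):
        raise ValueError("series voxel sizes do not match")
    sigma_vox = sigma_mm / series_a.voxel_size
    sm_a = gaussian_filter(series_a.mean_b0(), sigma_vox, truncate=4.0)
    sm_b = gaussian_filter(series_b.mean_b0(), sigma_vox, truncate=4.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = sm_a / sm_b
    mask = series_a.get_mask()
    bad = (sm_b == 0) & mask
    scale[sm_b == 0] = 1.0
    if bad.any():
        import warnings

        warnings.warn(f"{int(bad.sum())} zero-valued smoothed b0 voxels in mask")
    data = np.concatenate(
        [series_a.data, series_b.data * scale[..., None]], axis=3
    )
    grad = GradientTable(
        np.concatenate([series_a.grad.bvals, series_b.grad.bvals]),
        np.concatenate([series_a.grad.bvecs, series_b.grad.bvecs]),
    )
    return replace(series_a, data=data, grad=grad)


def _series_list(vols) -> list[DWIVolume]:
    if isinstance(vols, DWIVolume):
        return [vols]
    vols = list(vols)
    if not 1 <= len(vols) <= 2:
        raise ConfigError("run_pipeline takes one or two series")
    return vols


def run_pipeline(vols, config: PipelineConfig | None = None):
    """Execute the configured steps; returns (volume, maps, sigma, report).

    Denoising and Gibbs removal run per input series; b0 normalization
    (when enabled, requiring two series) merges them.  The report records
    the executed order and parameters for provenance.
    """
    config = config or PipelineConfig()
    series = _series_list(vols)
    if ("b0_normalize" in config.steps) != (len(series) == 2):
        raise ConfigError(
            "b0_normalize requires exactly two input series (and two series "
            "require b0_normalize)"
        )
    executed: list[dict] = []
    sigma_maps: list[np.ndarray] = []

    if "denoise" in config.steps:
        spec = PatchSpec(
            mode=config.denoise_mode, patch_size=config.patch_size,
            search_window=config.search_window,
        )
        new_series = []
        for s in series:
            res = denoise_volume(s, spec, shrink=config.shrinkage)
            new_series.append(s.with_data(res.denoised))
            sigma_maps.append(res.sigma_map)
        series = new_series
        executed.append(
            dict(step="denoise", mode=config.denoise_mode,
                 shrinkage=config.shrinkage, patch_size=config.patch_size)
        )

    if "degibbs" in config.steps:
        new_series = []
        methods = []
        for s in series:
            params = config.unring or UnringParams(
                pf_fraction=s.pf_fraction, pe_axis=s.pe_axis
            )
            method = "rpg" if params.pf_fraction < 1.0 else "sushi"
            new_series.append(unring_volume(s, params, method=method))
            methods.append(method)
        series = new_series
        executed.append(dict(step="degibbs", method=methods))

    if "external_hook" in config.steps:
        if config.external_hook is not None:
            series = [config.external_hook(s) for s in series]
            executed.append(dict(step="external_hook", enabled=True))
        else:
            executed.append(dict(step="external_hook", enabled=False))

    if "b0_normalize" in config.steps:
        vol = b0_normalize(series[0], series[1], sigma_mm=config.b0_sigma_mm)
        if sigma_maps:
            sigma_map = np.mean(sigma_maps, axis=0)
        else:
            sigma_map = np.zeros(vol.data.shape[:3])
        executed.append(dict(step="b0_normalize", sigma_mm=config.b0_sigma_mm))
    else:
        vol = series[0]
        sigma_map = sigma_maps[0] if sigma_maps else np.zeros(vol.data.shape[:3])

    if "rician" in config.steps:
        vol = vol.with_data(rician_bias_correct(vol.data, sigma_map))
        executed.append(dict(step="rician"))

    if config.smoothing is not None:
        vol = gaussian_smooth_csf_excluded(vol, config.smoothing, config.csf_mask)
        executed.append(dict(step="smooth", fwhm_factor=config.smoothing))

    maps: ScalarMaps | None = None
    if "fit" in config.steps:
        fit = wlls_fit(vol)
        maps = scalar_maps(fit)
        executed.append(dict(step="fit", model="dki"))

    report = dict(
        version=__version__,
        seed=config.seed,
        steps=executed,
        order=[e["step"] for e in executed],
    )
    return vol, maps, sigma_map, report


def save_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
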