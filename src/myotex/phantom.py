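"""Synthetic left-ventricle perfusion phantoms.

The cohort this package analyses — myocardial perfusion SPECT volumes with a
three-level post-revascularization outcome label — is emulated with geometric
phantoms: an ellipsoidal myocardial shell (open at the base) in a 64x64xS
grid, a reduced-uptake perfusion defect, a multiplicative log-Gaussian
heterogeneity field whose strength varies by outcome class (the hypothesized
discriminating signal: heterogeneous uptake from mixed hibernating / scarred
tissue), Gaussian PSF blur and intensity-dependent Gaussian noise as a
count-noise surrogate.

Everything is deterministic under a seed; per-sample seeds are derived as
``cohort_seed + sample_index`` so individual phantoms can be regenerated in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .images import ROIMask, SliceImage, VolumeImage


@dataclass
class PhantomConfig:
    """Geometry, signal and noise parameters of a single LV phantom.

    Parameters
    ----------
    grid_shape : voxel grid, axial slices on the last axis.
    voxel_spacing : mm; the clinical acquisitions this emulates used a
        64x64 matrix with ~6.6 mm pixels.
    shell_radii_inner / shell_radii_outer : ellipsoid semi-axes in voxels.
    base_uptake : nominal tracer uptake of healthy myocardium.
    defect_fraction : fraction of shell voxels inside the perfusion defect.
    defect_contrast : multiplicative uptake inside the defect (1 = none).
    texture_corr_length : Gaussian correlation length (voxels) of the
        heterogeneity field.
    texture_sd : log-scale standard deviation of the heterogeneity field.
    psf_sigma : Gaussian PSF blur in voxels.
    noise_scale : noise sd = noise_scale * sqrt(intensity).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 32)
    voxel_spacing: tuple[float, float, float] = (6.6, 6.6, 6.6)
    shell_radii_inner: tuple[float, float, float] = (13.0, 13.0, 8.0)
    shell_radii_outer: tuple[float, float, float] = (22.0, 22.0, 13.0)
    base_uptake: float = 100.0
    defect_fraction: float = 0.15
    defect_contrast: float = 0.6
    texture_corr_length: float = 2.0
    texture_sd: float = 0.10
    psf_sigma: float = 1.0
    noise_scale: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if any(g <= 0 for g in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        ri, ro = self.shell_radii_inner, self.shell_radii_outer
        if any(r <= 0 for r in ri) or any(r <= 0 for r in ro):
            raise ValueError("shell radii must be positive")
        if not all(a < b for a, b in zip(ri, ro)):
            raise ValueError("inner radii must be strictly smaller than outer radii")
        if not (0 <= self.defect_fraction < 1):
            raise ValueError("defect_fraction must lie in [0, 1)")
        if not (0 < self.defect_contrast <= 1):
            raise ValueError("defect_contrast must lie in (0, 1]")
        if self.texture_sd < 0 or self.noise_scale < 0 or self.psf_sigma < 0:
            raise ValueError("texture_sd, noise_scale and psf_sigma must be >= 0")
        scalars = (self.base_uptake, self.texture_corr_length, self.texture_sd,
                   self.psf_sigma, self.noise_scale)
        if not all(np.isfinite(s) for s in scalars):
            raise ValueError("all scalar parameters must be finite")


# Class-dependent offsets added to (texture_corr_length, texture_sd,
# defect_contrast).  Class 1 (no EF improvement) is the baseline; classes 2
# and 3 carry increasingly strong uptake heterogeneity, the planted
# discriminating signal.
DEFAULT_CLASS_EFFECT: dict[int, tuple[float, float, float]] = {
    1: (0.0, 0.00, 0.0),
    2: (1.0, 0.15, 0.0),
    3: (2.0, 0.35, 0.0),
}

NULL_CLASS_EFFECT: dict[int, tuple[float, float, float]] = {
    1: (0.0, 0.0, 0.0),
    2: (0.0, 0.0, 0.0),
    3: (0.0, 0.0, 0.0),
}


@dataclass
class CohortConfig:
    """A labeled phantom cohort; default class sizes mirror the 24/12/16 split."""

    n_per_class: tuple[int, int, int] = (24, 12, 16)
    effect: dict[int, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_EFFECT)
    )
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    seed: int = 0

    def validate(self) -> None:
        if any(n < 0 for n in self.n_per_class):
            raise ValueError("class sizes must be non-negative")
        self.phantom.validate()


@dataclass
class LabeledVolume:
    volume: VolumeImage
    truth_mask: ROIMask
    label: int

    def __post_init__(self) -> None:
        if self.label not in (1, 2, 3):
            raise ValueError("label must be 1, 2 or 3")
        if self.truth_mask.shape != self.volume.shape:
            raise ValueError("mask shape must equal volume shape")
        if self.truth_mask.count() == 0:
            raise ValueError("truth mask is empty")


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------

def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return q <= 1.0


def _shell_mask(cfg: PhantomConfig) -> np.ndarray:
    """Myocardial shell: outer minus inner ellipsoid, open at the base.

    The base (valve plane) is modelled by removing the top ~30% of the long
    axis; exact geometry is cosmetic — the shell only has to be a thick,
    connected, roughly LV-shaped ROI.
    """
    center = tuple((s - 1) / 2.0 for s in cfg.grid_shape)
    outer = _ellipsoid(cfg.grid_shape, center, cfg.shell_radii_outer)
    inner = _ellipsoid(cfg.grid_shape, center, cfg.shell_radii_inner)
    shell = outer & ~inner
    z = np.arange(cfg.grid_shape[2])
    base_cut = center[2] + 0.7 * cfg.shell_radii_outer[2]
    shell[:, :, z > base_cut] = False
    return shell


def _defect_mask(shell: np.ndarray, cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """A contiguous angular sector of the shell covering ``defect_fraction``."""
    if cfg.defect_fraction <= 0:
        return np.zeros_like(shell)
    idx = np.argwhere(shell)
    center = (np.array(shell.shape) - 1) / 2.0
    phi = np.arctan2(idx[:, 1] - center[1], idx[:, 0] - center[0])
    phi0 = rng.uniform(-np.pi, np.pi)
    d = np.abs(np.angle(np.exp(1j * (phi - phi0))))
    cut = np.quantile(d, cfg.defect_fraction)
    sel = idx[d <= cut]
    out = np.zeros_like(shell)
    out[tuple(sel.T)] = True
    return out


def _heterogeneity_field(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Positive multiplicative field: exp of a smoothed Gaussian random field.

    White noise is smoothed with a Gaussian kernel of width
    ``texture_corr_length``, re-standardized to unit variance, scaled to
    ``texture_sd`` and exponentiated so the field stays positive.
    """
    g = rng.standard_normal(cfg.grid_shape)
    if cfg.texture_corr_length > 0:
        g = ndimage.gaussian_filter(g, cfg.texture_corr_length)
        sd = g.std()
        if sd > 0:
            g = g / sd
    return np.exp(cfg.texture_sd * g)


def generate_lv_phantom(config: PhantomConfig) -> tuple[VolumeImage, ROIMask]:
    """Generate one LV phantom volume and its ground-truth shell mask.

    Uptake = base_uptake x heterogeneity field x defect map, blurred by a
    Gaussian PSF, plus Gaussian noise with variance proportional to intensity.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    shell = _shell_mask(config)
    if not shell.any():
        raise ValueError("configuration produces an empty shell")

    uptake = np.zeros(config.grid_shape)
    uptake[shell] = config.base_uptake
    uptake[shell] *= _heterogeneity_field(config, rng)[shell]
    defect = _defect_mask(shell, config, rng)
    uptake[defect] *= config.defect_contrast

    if config.psf_sigma > 0:
        uptake = ndimage.gaussian_filter(uptake, config.psf_sigma)
    if config.noise_scale > 0:
        noise = rng.standard_normal(config.grid_shape)
        uptake = uptake + config.noise_scale * np.sqrt(np.clip(uptake, 0, None)) * noise
        uptake = np.clip(uptake, 0, None)

    vol = VolumeImage(uptake, spacing=config.voxel_spacing)
    return vol, ROIMask(shell)


def generate_cohort(config: CohortConfig) -> list[LabeledVolume]:
    """Generate the labeled cohort; exactly ``n_per_class`` phantoms per class.

    Class effects offset (texture_corr_length, texture_sd, defect_contrast);
    per-sample seeds are ``config.seed + sample_index``.
    """
    config.validate()
    out: list[LabeledVolume] = []
    index = 0
    for label, n in zip((1, 2, 3), config.n_per_class):
        d_corr, d_sd, d_contrast = config.effect.get(label, (0.0, 0.0, 0.0))
        for _ in range(n):
            pcfg = replace(
                config.phantom,
                texture_corr_length=config.phantom.texture_corr_length + d_corr,
                texture_sd=config.phantom.texture_sd + d_sd,
                defect_contrast=float(
                    np.clip(config.phantom.defect_contrast + d_contrast, 1e-6, 1.0)
                ),
                seed=config.seed + index,
            )
            vol, mask = generate_lv_phantom(pcfg)
            out.append(LabeledVolume(vol, mask, label))
            index += 1
    return out


# ---------------------------------------------------------------------------
# Deterministic 2D texture fixtures (oracle inputs for the texture operators)
# ---------------------------------------------------------------------------

def make_texture_fixture(kind: str, size: tuple[int, int] = (32, 32), **params) -> SliceImage:
    """Small deterministic 2D images for exercising texture operators.

    kinds: ``constant`` (value), ``checkerboard`` (cell), ``grating``
    (wavelength, orientation_deg) and ``white_noise`` (seed, sd).
    """
    ny, nx = size
    if ny < 8 or nx < 8:
        raise ValueError("fixture size must be at least 8x8")
    if kind == "constant":
        img = np.full(size, float(params.get("value", 1.0)))
    elif kind == "checkerboard":
        cell = int(params.get("cell", 1))
        yy, xx = np.indices(size)
        img = (((yy // cell) + (xx // cell)) % 2).astype(float)
    elif kind == "grating":
        lam = float(params.get("wavelength", 8.0))
        theta = np.deg2rad(float(params.get("orientation_deg", 0.0)))
        yy, xx = np.indices(size)
        # phase advances along the direction theta (0 deg = along x)
        img = 0.5 + 0.5 * np.sin(2 * np.pi * (xx * np.cos(theta) + yy * np.sin(theta)) / lam)
    elif kind == "white_noise":
        rng = np.random.default_rng(int(params.get("seed", 0)))
        img = rng.normal(0.5, float(params.get("sd", 0.15)), size)
    else:
        raise ValueError(f"unknown fixture kind: {kind!r}")
    return SliceImage(img)
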