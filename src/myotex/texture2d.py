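"""In-house 2D texture extractor: per-pixel Haralick GLCM, LAWS energy and
Gabor filter-bank features.

Per-pixel features are computed with a square kernel sliding over the image
(sizes 3/5/7); the resulting feature maps are reduced over the ROI by five
statistics (average, variance, median, skewness, kurtosis).  Gabor features
are per-image: each filter's response-magnitude image is reduced by the same
five statistics.  Feature names follow the ``<Family>_<Stat>_<Descriptor>``
convention (``Gabor_Median_W5O135``, ``LAWS_Skewness_R5E5``,
``Haralick_Kurtosis_DiffAvg``, ``FO_Variance_ImgMed``).

Conventions fixed here (documented in docs/methods.md):

* GLCM offsets for orientations 0/45/90/135 degrees at distance d are
  (0,d), (d,d), (d,0), (d,-d) in (row, col); the four orientation matrices
  are accumulated into one symmetric matrix before Haralick statistics
  (rotation pooling).
* Quantization for the per-pixel GLCM is fixed-bin-number over the whole
  slice, so neighbouring windows share a common gray-level scale.
* Aggregation statistics use population variance, Fisher-Pearson skewness
  g1 and non-excess kurtosis (normal -> 3); a constant sample reports
  skewness 0 and kurtosis 0 by convention.
* Entropies use the natural logarithm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .images import SliceImage, as_array, as_bool_mask
from .preprocess import quantize

HARALICK_NAMES = (
    "Energy", "Contrast", "Correlation", "Variance", "IDM",
    "SumAvg", "SumVar", "SumEntropy", "Entropy",
    "DiffAvg", "DiffVar", "DiffEntropy", "IMC1", "IMC2",
)

AGG_STATS = ("Average", "Variance", "Median", "Skewness", "Kurtosis")


@dataclass
class GLCMConfig:
    distance: int = 1
    orientations: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    n_levels: int = 8
    symmetric: bool = True

    def validate(self) -> None:
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if not self.orientations:
            raise ValueError("orientations must be nonempty")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")

    def offsets(self) -> list[tuple[int, int]]:
        d = self.distance
        out = []
        for theta in self.orientations:
            t = math.radians(theta)
            out.append((int(round(d * math.sin(t))), int(round(d * math.cos(t)))))
        return out


@dataclass
class CooccurrenceMatrix:
    probs: np.ndarray
    config: GLCMConfig

    def __post_init__(self) -> None:
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("co-occurrence probabilities must sum to 1")


@dataclass
class AggregationStats:
    average: float
    variance: float
    median: float
    skewness: float
    kurtosis: float

    def as_dict(self) -> dict[str, float]:
        return {
            "Average": self.average, "Variance": self.variance,
            "Median": self.median, "Skewness": self.skewness,
            "Kurtosis": self.kurtosis,
        }


@dataclass
class PixelFeatureMap:
    """A per-pixel feature image defined on ``support`` (where the kernel fits
    and, for masked extraction, the center pixel is in the ROI)."""

    values: np.ndarray
    support: np.ndarray
    kernel_size: int
    feature_name: str


@dataclass
class GaborBankConfig:
    """Default bank: 6 wavelengths on a sqrt(2)-spaced ladder x 8 orientations."""

    wavelengths: tuple[float, ...] = (2.0, 5.66, 8.0, 11.31, 22.63, 45.25)
    orientations: tuple[float, ...] = (0.0, 22.5, 45.0, 67.5, 90.0, 112.5, 135.0, 157.5)
    bandwidth: float = 1.0
    aspect: float = 1.0
    max_kernel_radius: int = 31

    def validate(self) -> None:
        if any(w < 2 for w in self.wavelengths):
            raise ValueError("wavelengths below 2 px violate the Nyquist limit")

    def n_filters(self) -> int:
        return len(self.wavelengths) * len(self.orientations)


# ---------------------------------------------------------------------------
# GLCM and Haralick statistics
# ---------------------------------------------------------------------------

def glcm(window, config: GLCMConfig, levels=None, mask=None
         ) -> CooccurrenceMatrix:
    """Co-occurrence matrix of a (quantized) 2D window, pooled over the
    configured orientations, optionally symmetrized, normalized.

    ``window`` may be a raw image (quantized here to ``config.n_levels``) or
    an integer level image in 1..L when ``levels`` is "given".  With a
    ``mask`` only pairs whose both pixels lie inside the ROI are counted
    (per-image use); per-pixel kernels pass the full window.
    """
    config.validate()
    arr = as_array(window)
    if arr.ndim != 2:
        raise ValueError("glcm expects a 2D window")
    if min(arr.shape) <= config.distance:
        raise ValueError("window smaller than the GLCM offset")
    m = np.ones(arr.shape, bool) if mask is None else as_bool_mask(mask, arr.shape)
    if levels == "given":
        lev = arr.astype(np.int64)
    else:
        lev = quantize(arr, m if mask is not None else None,
                       config.n_levels).levels
    L = config.n_levels
    counts = np.zeros((L, L), dtype=float)
    for dr, dc in config.offsets():
        a, b = _offset_pairs(lev, dr, dc)
        ma, mb = _offset_pairs(m.astype(np.int64), dr, dc)
        ok = (ma > 0) & (mb > 0)
        np.add.at(counts, (a[ok] - 1, b[ok] - 1), 1.0)
    if config.symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no gray-level pairs at the requested offset")
    return CooccurrenceMatrix(counts / total, config)


def _offset_pairs(lev: np.ndarray, dr: int, dc: int) -> tuple[np.ndarray, np.ndarray]:
    H, W = lev.shape
    r0, r1 = max(0, -dr), H - max(0, dr)
    c0, c1 = max(0, -dc), W - max(0, dc)
    a = lev[r0:r1, c0:c1]
    b = lev[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    return a.ravel(), b.ravel()


def _plogp(p: np.ndarray) -> np.ndarray:
    return np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)


def _haralick_from_probs(P: np.ndarray) -> dict[str, np.ndarray]:
    """The 14 Haralick statistics, vectorized over a leading batch axis.

    ``P``: (..., L, L) normalized co-occurrence matrices.  The roster replaces
    the numerically unstable maximal correlation coefficient with the
    difference average.
    """
    P = np.asarray(P, dtype=float)
    L = P.shape[-1]
    k = np.arange(1, L + 1, dtype=float)
    px = P.sum(axis=-1)
    py = P.sum(axis=-2)
    mu_x = (px * k).sum(axis=-1)
    mu_y = (py * k).sum(axis=-1)
    var_x = (px * (k - mu_x[..., None]) ** 2).sum(axis=-1)
    var_y = (py * (k - mu_y[..., None]) ** 2).sum(axis=-1)

    ii = k[:, None] * np.ones((L, L))
    jj = ii.T
    energy = (P ** 2).sum(axis=(-2, -1))
    contrast = (P * (ii - jj) ** 2).sum(axis=(-2, -1))
    cov = (P * ii * jj).sum(axis=(-2, -1)) - mu_x * mu_y
    sd = np.sqrt(var_x * var_y)
    # degenerate single-level matrices correlate perfectly by convention
    correlation = np.where(sd > 1e-12, cov / np.where(sd > 1e-12, sd, 1.0), 1.0)
    variance = (P * (ii - mu_x[..., None, None]) ** 2).sum(axis=(-2, -1))
    idm = (P / (1.0 + (ii - jj) ** 2)).sum(axis=(-2, -1))

    s = (ii + jj).astype(int)
    d = np.abs(ii - jj).astype(int)
    p_sum = np.stack(
        [(P * (s == v)).sum(axis=(-2, -1)) for v in range(2, 2 * L + 1)], axis=-1
    )
    p_diff = np.stack(
        [(P * (d == v)).sum(axis=(-2, -1)) for v in range(0, L)], axis=-1
    )
    ks = np.arange(2, 2 * L + 1, dtype=float)
    kd = np.arange(0, L, dtype=float)
    sum_avg = (p_sum * ks).sum(axis=-1)
    sum_var = (p_sum * (ks - sum_avg[..., None]) ** 2).sum(axis=-1)
    sum_entropy = -_plogp(p_sum).sum(axis=-1)
    entropy = -_plogp(P).sum(axis=(-2, -1))
    diff_avg = (p_diff * kd).sum(axis=-1)
    diff_var = (p_diff * (kd - diff_avg[..., None]) ** 2).sum(axis=-1)
    diff_entropy = -_plogp(p_diff).sum(axis=-1)

    hx = -_plogp(px).sum(axis=-1)
    hy = -_plogp(py).sum(axis=-1)
    pxpy = px[..., :, None] * py[..., None, :]
    log_pxpy = np.where(pxpy > 0, np.log(np.where(pxpy > 0, pxpy, 1.0)), 0.0)
    hxy1 = -(P * log_pxpy).sum(axis=(-2, -1))
    hxy2 = -(pxpy * log_pxpy).sum(axis=(-2, -1))
    hmax = np.maximum(hx, hy)
    imc1 = np.where(hmax > 1e-12, (entropy - hxy1) / np.where(hmax > 1e-12, hmax, 1.0), 0.0)
    imc2 = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - entropy)), 0.0, None))

    return {
        "Energy": energy, "Contrast": contrast, "Correlation": correlation,
        "Variance": variance, "IDM": idm, "SumAvg": sum_avg, "SumVar": sum_var,
        "SumEntropy": sum_entropy, "Entropy": entropy, "DiffAvg": diff_avg,
        "DiffVar": diff_var, "DiffEntropy": diff_entropy, "IMC1": imc1,
        "IMC2": imc2,
    }


def haralick14(m: CooccurrenceMatrix) -> dict[str, float]:
    """The 14 named Haralick statistics of one normalized co-occurrence matrix."""
    if abs(m.probs.sum() - 1.0) > 1e-9:
        raise ValueError("matrix is not normalized")
    return {name: float(v) for name, v in _haralick_from_probs(m.probs).items()}


# ---------------------------------------------------------------------------
# Sliding-kernel machinery
# ---------------------------------------------------------------------------

def perpixel_map(image, mask, feature_fn, kernel_size: int = 5,
                 feature_name: str = "feature") -> PixelFeatureMap:
    """Evaluate ``feature_fn`` on the kernel neighbourhood of every in-mask
    pixel whose kernel fits inside the image.

    The kernel uses raw image pixels even where they fall outside the ROI;
    the mask gates only which center pixels contribute.
    """
    if kernel_size % 2 == 0 or kernel_size < 3:
        raise ValueError("kernel_size must be odd and >= 3")
    arr = as_array(image)
    if kernel_size > min(arr.shape):
        raise ValueError("kernel larger than image")
    m = np.ones(arr.shape, bool) if mask is None else as_bool_mask(mask, arr.shape)
    h = kernel_size // 2
    support = np.zeros(arr.shape, bool)
    support[h:arr.shape[0] - h, h:arr.shape[1] - h] = True
    support &= m
    if not support.any():
        raise ValueError("no in-mask pixel has a fully interior kernel")
    values = np.full(arr.shape, np.nan)
    for r, c in np.argwhere(support):
        values[r, c] = feature_fn(arr[r - h:r + h + 1, c - h:c + h + 1])
    return PixelFeatureMap(values, support, kernel_size, feature_name)


def haralick_maps(image, mask, config: GLCMConfig | None = None,
                  kernel_size: int = 5) -> dict[str, PixelFeatureMap]:
    """Fast per-pixel Haralick maps for a whole slice.

    The slice is quantized once (fixed bin number over the full slice), then
    per-window co-occurrence counts for each orientation are accumulated via
    integral images over the pair-code one-hot cube, pooled and symmetrized,
    and the 14 statistics are evaluated for all window centers at once.
    Matches :func:`perpixel_map` + :func:`glcm` + :func:`haralick14` exactly.
    """
    config = config or GLCMConfig()
    config.validate()
    if kernel_size % 2 == 0 or kernel_size < 3:
        raise ValueError("kernel_size must be odd and >= 3")
    arr = as_array(image)
    H, W = arr.shape
    if kernel_size > min(H, W):
        raise ValueError("kernel larger than image")
    m = np.ones(arr.shape, bool) if mask is None else as_bool_mask(mask, arr.shape)
    L = config.n_levels
    lev = quantize(arr, None, L).levels  # whole-slice FBN quantization
    h = kernel_size // 2

    ncodes = L * L
    out_h, out_w = H - 2 * h, W - 2 * h
    counts = np.zeros((out_h, out_w, ncodes))
    for dr, dc in config.offsets():
        code = _pair_code_image(lev, dr, dc, L)
        cum = _integral_cube(code, ncodes)
        # first-pixel rows of an in-window pair span
        # [i - h + max(0,-dr), i + h - max(0,dr)] for window center i
        r0 = np.arange(out_h) + max(0, -dr)
        r1 = np.arange(out_h) + kernel_size - max(0, dr)
        c0 = np.arange(out_w) + max(0, -dc)
        c1 = np.arange(out_w) + kernel_size - max(0, dc)
        box = (cum[r1][:, c1] - cum[r1][:, c0] - cum[r0][:, c1] + cum[r0][:, c0])
        counts += box

    mats = counts.reshape(out_h * out_w, L, L)
    if config.symmetric:
        mats = mats + mats.transpose(0, 2, 1)
    totals = mats.sum(axis=(1, 2), keepdims=True)
    mats = mats / np.where(totals > 0, totals, 1.0)
    feats = _haralick_from_probs(mats)

    support = np.zeros((H, W), bool)
    support[h:H - h, h:W - h] = True
    support &= m
    maps: dict[str, PixelFeatureMap] = {}
    for name in HARALICK_NAMES:
        values = np.full((H, W), np.nan)
        values[h:H - h, h:W - h] = feats[name].reshape(out_h, out_w)
        values[~support] = np.nan
        maps[name] = PixelFeatureMap(values, support, kernel_size, f"Haralick_{name}")
    return maps


def _pair_code_image(lev: np.ndarray, dr: int, dc: int, L: int) -> np.ndarray:
    """Pair code (a-1)*L + (b-1) at each first-pixel position; -1 where the
    offset leaves the image."""
    H, W = lev.shape
    code = np.full((H, W), -1, dtype=np.int64)
    r0, r1 = max(0, -dr), H - max(0, dr)
    c0, c1 = max(0, -dc), W - max(0, dc)
    a = lev[r0:r1, c0:c1]
    b = lev[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    code[r0:r1, c0:c1] = (a - 1) * L + (b - 1)
    return code


def _integral_cube(code: np.ndarray, ncodes: int) -> np.ndarray:
    """(H+1, W+1, ncodes) integral images of the one-hot pair-code cube."""
    H, W = code.shape
    onehot = np.zeros((H, W, ncodes))
    valid = code >= 0
    onehot[(*np.nonzero(valid), code[valid])] = 1.0
    cum = np.zeros((H + 1, W + 1, ncodes))
    cum[1:, 1:] = onehot.cumsum(axis=0).cumsum(axis=1)
    return cum


# ---------------------------------------------------------------------------
# Aggregation statistics
# ---------------------------------------------------------------------------

def aggregate(values, mask=None) -> AggregationStats:
    """Average, population variance, median, skewness g1 and (non-excess)
    kurtosis of the in-support values of a feature map or image."""
    if isinstance(values, PixelFeatureMap):
        v = values.values[values.support]
        if mask is not None:
            v = values.values[values.support & as_bool_mask(mask, values.values.shape)]
    else:
        arr = as_array(values)
        m = np.ones(arr.shape, bool) if mask is None else as_bool_mask(mask, arr.shape)
        v = arr[m]
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("aggregation needs at least 2 values")
    mean = float(v.mean())
    var = float(v.var())
    med = float(np.median(v))
    if var <= 0:
        warnings.warn("constant sample: skewness and kurtosis set to 0", stacklevel=2)
        return AggregationStats(mean, 0.0, med, 0.0, 0.0)
    sd = math.sqrt(var)
    skew = float(((v - mean) ** 3).mean() / sd ** 3)
    kurt = float(((v - mean) ** 4).mean() / var ** 2)
    return AggregationStats(mean, var, med, skew, kurt)


# ---------------------------------------------------------------------------
# LAWS texture energy
# ---------------------------------------------------------------------------

LAWS_VECTORS = {
    "L5": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
    "E5": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),
    "S5": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),
    "R5": np.array([1.0, -4.0, 6.0, -4.0, 1.0]),
    "W5": np.array([-1.0, 2.0, 0.0, -2.0, 1.0]),
}


def laws_kernels() -> dict[str, np.ndarray]:
    """The 25 5x5 LAWS masks: outer products of L5/E5/S5/R5/W5."""
    names = list(LAWS_VECTORS)
    return {
        f"{a}{b}": np.outer(LAWS_VECTORS[a], LAWS_VECTORS[b])
        for a in names for b in names
    }


def laws_features(image, mask=None, energy_window: int = 15
                  ) -> tuple[dict[str, PixelFeatureMap], dict[str, float]]:
    """25 LAWS texture-energy maps and their aggregated statistics.

    Each mask is convolved with the image (reflect boundary); the texture
    energy map is the moving average of the absolute response over
    ``energy_window``; the five statistics are taken over the ROI.
    """
    arr = as_array(image)
    if min(arr.shape) < 5:
        raise ValueError("image must be at least 5x5")
    m = np.ones(arr.shape, bool) if mask is None else as_bool_mask(mask, arr.shape)
    support = m
    maps: dict[str, PixelFeatureMap] = {}
    feats: dict[str, float] = {}
    for name, ker in laws_kernels().items():
        resp = ndimage.correlate(arr, ker, mode="reflect")
        energy = ndimage.uniform_filter(np.abs(resp), size=energy_window, mode="reflect")
        fmap = PixelFeatureMap(energy, support, 5, f"LAWS_{name}")
        maps[name] = fmap
        stats = aggregate(energy, m)
        for stat, val in stats.as_dict().items():
            feats[f"LAWS_{stat}_{name}"] = val
    return maps, feats


# ---------------------------------------------------------------------------
# Gabor filter bank
# ---------------------------------------------------------------------------

def gabor_kernels(bank: GaborBankConfig) -> dict[str, np.ndarray]:
    """Complex Gabor kernels named ``W<int(wavelength)>O<int(orientation)>``.

    sigma follows the one-octave-bandwidth relation sigma ~= 0.56 * wavelength;
    kernels are truncated at 2.5 sigma (capped at ``max_kernel_radius``) and
    the real (cosine) part is DC-corrected to zero mean so constant images
    give zero response.
    """
    bank.validate()
    out: dict[str, np.ndarray] = {}
    for lam in bank.wavelengths:
        sigma = lam * (1.0 / math.pi) * math.sqrt(math.log(2) / 2) * \
            (2 ** bank.bandwidth + 1) / (2 ** bank.bandwidth - 1)
        radius = min(int(math.ceil(2.5 * sigma)), bank.max_kernel_radius)
        radius = max(radius, 2)
        y, x = np.mgrid[-radius:radius + 1, -radius:radius + 1].astype(float)
        for theta_deg in bank.orientations:
            t = math.radians(theta_deg)
            rotx = x * math.cos(t) + y * math.sin(t)
            roty = -x * math.sin(t) + y * math.cos(t)
            envelope = np.exp(-(rotx ** 2 + (bank.aspect * roty) ** 2) / (2 * sigma ** 2))
            carrier = np.exp(1j * 2 * np.pi * rotx / lam)
            ker = envelope * carrier
            ker = ker - ker.real.mean()  # DC-correct the cosine part
            out[f"W{int(lam)}O{int(theta_deg)}"] = ker
    return out


def gabor_features(image, mask=None, bank: GaborBankConfig | None = None
                   ) -> dict[str, float]:
    """Aggregated response magnitudes of the Gabor bank over the ROI.

    Returns ``Gabor_<Stat>_W<lam>O<theta>`` for the five statistics and every
    filter (default bank: 48 filters -> 240 values).
    """
    bank = bank or GaborBankConfig()
    arr = as_array(image)
    m = np.ones(arr.shape, bool) if mask is None else as_bool_mask(mask, arr.shape)
    feats: dict[str, float] = {}
    for name, ker in gabor_kernels(bank).items():
        mag = gabor_response(arr, ker)
        stats = aggregate(mag, m)
        for stat, val in stats.as_dict().items():
            feats[f"Gabor_{stat}_{name}"] = val
    return feats


def gabor_response(arr: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Response magnitude |image * kernel| with reflect-padded FFT convolution."""
    pad = (kernel.shape[0] // 2, kernel.shape[1] // 2)
    padded = np.pad(arr, ((pad[0], pad[0]), (pad[1], pad[1])), mode="reflect")
    re = signal.fftconvolve(padded, kernel.real[::-1, ::-1], mode="valid")
    im = signal.fftconvolve(padded, kernel.imag[::-1, ::-1], mode="valid")
    return np.hypot(re, im)


# ---------------------------------------------------------------------------
# Median-image first-order features
# ---------------------------------------------------------------------------

def median_image_features(image, mask=None, kernel: int = 3) -> dict[str, float]:
    """Five statistics of the 3x3 running-median image (``FO_<Stat>_ImgMed``)."""
    arr = as_array(image)
    if min(arr.shape) < kernel:
        raise ValueError(f"image must be at least {kernel}x{kernel}")
    m = np.ones(arr.shape, bool) if mask is None else as_bool_mask(mask, arr.shape)
    med = ndimage.median_filter(arr, size=kernel, mode="reflect")
    stats = aggregate(med, m)
    return {f"FO_{stat}_ImgMed": val for stat, val in stats.as_dict().items()}


# ---------------------------------------------------------------------------
# Whole-slice / whole-volume in-house battery
# ---------------------------------------------------------------------------

@dataclass
class Texture2DConfig:
    glcm: GLCMConfig = field(default_factory=GLCMConfig)
    kernel_size: int = 5
    laws_energy_window: int = 15
    gabor: GaborBankConfig = field(default_factory=GaborBankConfig)
    median_kernel: int = 3
    min_slice_pixels: int = 25


def extract_slice_features(image, mask=None, config: Texture2DConfig | None = None
                           ) -> dict[str, float]:
    """The full in-house battery for one 2D slice.

    14 Haralick maps x 5 stats + 25 LAWS masks x 5 stats + 48 Gabor filters
    x 5 stats + 5 median-image stats = 440 named features.
    """
    config = config or Texture2DConfig()
    feats: dict[str, float] = {}
    hmaps = haralick_maps(image, mask, config.glcm, config.kernel_size)
    for name, fmap in hmaps.items():
        stats = aggregate(fmap)
        for stat, val in stats.as_dict().items():
            feats[f"Haralick_{stat}_{name}"] = val
    _, lfeats = laws_features(image, mask, config.laws_energy_window)
    feats.update(lfeats)
    feats.update(gabor_features(image, mask, config.gabor))
    feats.update(median_image_features(image, mask, config.median_kernel))
    return feats


def extract_volume_features_2d(volume, mask, config: Texture2DConfig | None = None
                               ) -> dict[str, float]:
    """Slice-wise in-house battery averaged over in-mask axial slices.

    Slices with fewer than ``min_slice_pixels`` ROI pixels are skipped; the
    per-slice feature vectors are averaged with equal weight.
    """
    config = config or Texture2DConfig()
    arr = as_array(volume)
    m = as_bool_mask(mask, arr.shape)
    rows: list[dict[str, float]] = []
    for z in range(arr.shape[2]):
        msl = m[:, :, z]
        if msl.sum() < config.min_slice_pixels:
            continue
        rows.append(extract_slice_features(arr[:, :, z], msl, config))
    if not rows:
        raise ValueError("no axial slice has enough ROI pixels")
    return {k: float(np.mean([r[k] for r in rows])) for k in rows[0]}
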