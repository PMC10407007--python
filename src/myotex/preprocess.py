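"""Gray-level normalization, intensity quantization and LV segmentation.

Normalization rescales each image to [0, 1] by its own min/max.  Quantization
uses a fixed bin number (FBN) over the in-mask intensity range — the standard
choice when images have been min-max normalized.  Automatic segmentation
follows the two-stage scheme used for perfusion SPECT: k-means intensity
clustering to seed the myocardium, then an active-contour (snake) refinement
of the boundary, applied slice by slice along the axial axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.segmentation import morphological_chan_vese

from .images import ROIMask, SliceImage, VolumeImage, as_array, as_bool_mask


@dataclass
class QuantizedImage:
    """Integer gray levels in 1..n_levels inside the mask, 0 outside."""

    levels: np.ndarray
    n_levels: int
    mask: np.ndarray

    def __post_init__(self) -> None:
        inmask = self.levels[self.mask]
        if inmask.size and (inmask.min() < 1 or inmask.max() > self.n_levels):
            raise ValueError("in-mask levels must lie in [1, n_levels]")


def normalize_gray_levels(image):
    """Min-max normalize to [0, 1]: I' = (I - min I) / (max I - min I).

    A constant image maps to all zeros (with a warning) rather than raising,
    so batch processing never aborts on a degenerate slice.
    """
    arr = as_array(image)
    if arr.size == 0:
        raise ValueError("empty image")
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        warnings.warn("constant image: normalization returns all zeros", stacklevel=2)
        out = np.zeros_like(arr, dtype=float)
    else:
        out = (arr - lo) / (hi - lo)
    if isinstance(image, VolumeImage):
        return VolumeImage(out, spacing=image.spacing, origin=image.origin)
    if isinstance(image, SliceImage):
        return SliceImage(out, spacing=image.spacing)
    return out


def quantize(image, mask=None, n_levels: int = 16) -> QuantizedImage:
    """Discretize in-mask intensities into ``n_levels`` equal-width bins.

    Fixed-bin-number dialect: v -> min(floor(L * (v - min) / (max - min)) + 1, L)
    over the in-mask range, so the in-mask maximum maps to level L.  A
    constant region maps entirely to level 1.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    arr = as_array(image)
    m = np.ones(arr.shape, bool) if mask is None else as_bool_mask(mask, arr.shape)
    if not m.any():
        raise ValueError("empty mask")
    vals = arr[m]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(arr.shape, dtype=np.int64)
    if hi == lo:
        levels[m] = 1
    else:
        lv = np.floor(n_levels * (arr[m] - lo) / (hi - lo)).astype(np.int64) + 1
        levels[m] = np.minimum(lv, n_levels)
    return QuantizedImage(levels, n_levels, m)


def kmeans_initial_mask(volume, k: int = 3, seed: int = 0) -> ROIMask:
    """Seed mask = voxels of the highest-intensity k-means cluster.

    k = 3 separates background, blood pool / soft tissue, and myocardium in
    a normalized perfusion volume.
    """
    from sklearn.cluster import KMeans

    if k < 2:
        raise ValueError("k must be >= 2")
    arr = as_array(volume)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(arr.reshape(-1, 1))
    top = int(np.argmax(km.cluster_centers_.ravel()))
    return ROIMask((labels == top).reshape(arr.shape))


def refine_contour(image, init_mask, iterations: int = 20, smoothing: int = 1,
                   lambda1: float = 1.0, lambda2: float = 1.0) -> ROIMask:
    """Active-contour (morphological snake) refinement of an initial mask.

    Runs morphological Chan-Vese for a fixed iteration budget; with zero
    iterations the initial mask is returned unchanged.  Works on 2D slices
    and 3D volumes alike.
    """
    arr = as_array(image)
    init = as_bool_mask(init_mask, arr.shape)
    if not init.any():
        raise ValueError("empty initial mask")
    if iterations <= 0:
        return ROIMask(init.copy())
    out = morphological_chan_vese(
        arr, num_iter=iterations, init_level_set=init.astype(np.int8),
        smoothing=smoothing, lambda1=lambda1, lambda2=lambda2,
    )
    out = out.astype(bool)
    if not out.any():  # contour collapsed; keep the seed
        return ROIMask(init.copy())
    return ROIMask(out)


def segment_lv(volume, seed: int = 0, k: int = 3, iterations: int = 10,
               smoothing: int = 1) -> ROIMask:
    """Automatic LV delineation: k-means seeding + per-slice snake refinement.

    The volume is min-max normalized, the top-intensity k-means cluster forms
    the initial mask, and each axial slice with a nonempty seed is refined by
    the active contour; slices are restacked into a 3D mask.
    """
    arr = as_array(normalize_gray_levels(volume))
    if arr.max() == 0:
        raise ValueError("volume has no foreground signal")
    init = kmeans_initial_mask(arr, k=k, seed=seed).voxels
    out = np.zeros_like(init)
    for z in range(arr.shape[2]):
        sl = init[:, :, z]
        if not sl.any():
            continue
        out[:, :, z] = refine_contour(
            arr[:, :, z], sl, iterations=iterations, smoothing=smoothing
        ).voxels
    if not out.any():
        raise ValueError("segmentation produced an empty mask")
    return ROIMask(out)


def dice(a, b) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|)."""
    a = as_array(a).astype(bool)
    b = as_array(b).astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
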