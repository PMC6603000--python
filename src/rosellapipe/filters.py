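"""Deterministic image-processing primitives shared by every pipeline stage.

All convolution and grayscale-morphology filters operate plane-by-plane on
each z-plane of a stack (the acquisitions are strongly anisotropic: 5 or 11
planes at 400 nm spacing versus 0.2152 um laterally), while connected
components and size statistics are three-dimensional (26-connectivity by
default).  Raw inputs are 16-bit graytones; filtered outputs are signed
floats on the same scale.

Kernel semantics: "size s, standard deviation sd" denotes a square s x s
truncated Gaussian normalised to unit sum.  The border policy for spatial
convolution is symmetric (edge-repeating) padding.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.signal import fftconvolve
from skimage.morphology import disk, white_tophat

__all__ = [
    "GaussianSpec",
    "gaussian_kernel",
    "log_kernel",
    "gaussian_convolve",
    "difference_of_gaussians",
    "laplacian_of_gaussian",
    "tophat_gray",
    "butterworth_highpass_plane",
    "butterworth_highpass",
    "ratio_image",
    "complement_image",
    "threshold_components",
    "morphological_reconstruct",
    "label_volume",
    "structure_3d",
]

#: physical voxel volume in um^3 (0.2152 um pixels, 400 nm z-step)
PIXEL_PITCH_UM = 0.2152
Z_STEP_UM = 0.4
VOXEL_VOLUME_UM3 = PIXEL_PITCH_UM**2 * Z_STEP_UM


@dataclass(frozen=True)
class GaussianSpec:
    """Square truncated Gaussian kernel: side length ``size`` px, std ``sd`` px."""

    size: int
    sd: float

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"kernel size must be >= 1, got {self.size}")
        if self.sd <= 0:
            raise ValueError(f"kernel sd must be > 0, got {self.sd}")


def gaussian_kernel(spec: GaussianSpec) -> np.ndarray:
    """Unit-sum square truncated Gaussian kernel."""
    offsets = np.arange(spec.size) - (spec.size - 1) / 2.0
    g = np.exp(-(offsets**2) / (2.0 * spec.sd**2))
    kernel = np.outer(g, g)
    return kernel / kernel.sum()


def log_kernel(size: int, sd: float) -> np.ndarray:
    """Zero-sum Laplacian-of-Gaussian kernel (negative centre, positive ring).

    Convolving a bright blob yields a strongly negative interior response,
    which is why the edge masks threshold on large *negative* values.
    """
    if size < 3:
        raise ValueError(f"LoG kernel size must be >= 3, got {size}")
    if sd <= 0:
        raise ValueError(f"LoG sd must be > 0, got {sd}")
    offsets = np.arange(size) - (size - 1) / 2.0
    xx, yy = np.meshgrid(offsets, offsets)
    r2 = xx**2 + yy**2
    g = np.exp(-r2 / (2.0 * sd**2))
    g /= g.sum()
    kernel = g * (r2 - 2.0 * sd**2) / sd**4
    return kernel - kernel.mean()


def _convolve_plane(plane: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Same-size 2D convolution with symmetric (edge-repeating) padding.

    Even-sized kernels are anchored so that the output voxel at (y, x)
    aggregates rows/cols [y - (s-1)//2, y + s//2].
    """
    s = kernel.shape[0]
    lo, hi = (s - 1) // 2, s // 2
    padded = np.pad(plane.astype(np.float64), ((lo, hi), (lo, hi)), mode="symmetric")
    return fftconvolve(padded, kernel[::-1, ::-1], mode="valid")


def _apply_planewise(volume: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim == 2:
        return _convolve_plane(volume, kernel)
    return np.stack([_convolve_plane(p, kernel) for p in volume])


def gaussian_convolve(image: np.ndarray, spec: GaussianSpec) -> np.ndarray:
    """Plane-wise Gaussian blur with a unit-sum square truncated kernel."""
    return _apply_planewise(image, gaussian_kernel(spec))


def difference_of_gaussians(
    image: np.ndarray, fg: GaussianSpec, bg: GaussianSpec
) -> np.ndarray:
    """Spatial band-pass: narrow (foreground) blur minus wide (background) blur."""
    if fg.sd >= bg.sd:
        raise ValueError(
            f"foreground sd ({fg.sd}) must be smaller than background sd ({bg.sd})"
        )
    return gaussian_convolve(image, fg) - gaussian_convolve(image, bg)


def laplacian_of_gaussian(image: np.ndarray, size: int, sd: float) -> np.ndarray:
    """Plane-wise convolution with the zero-sum LoG kernel."""
    return _apply_planewise(image, log_kernel(size, sd))


def tophat_gray(image: np.ndarray, radius: int) -> np.ndarray:
    """White top-hat (image minus grayscale opening) with a disk, plane-wise.

    Extracts bright structures smaller than the structuring element; the
    output is non-negative everywhere.
    """
    if radius < 1:
        raise ValueError(f"structuring-element radius must be >= 1, got {radius}")
    footprint = disk(radius)
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        return white_tophat(image, footprint=footprint)
    return np.stack([white_tophat(p, footprint=footprint) for p in image])


def butterworth_highpass_plane(
    plane: np.ndarray, cutoff: float, order: int
) -> np.ndarray:
    """Butterworth high-pass in the Fourier domain, H(D) = 1 / (1 + (D0/D)^2n).

    D is the centred frequency radius in FFT-bin units; the DC bin gets
    H = 0 exactly, and the gain at D = D0 is exactly 0.5.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    plane = np.asarray(plane, dtype=np.float64)
    if not np.all(np.isfinite(plane)):
        raise ValueError("plane contains non-finite values")
    h, w = plane.shape
    fy = np.fft.fftfreq(h) * h
    fx = np.fft.fftfreq(w) * w
    d = np.hypot(fy[:, None], fx[None, :])
    with np.errstate(divide="ignore"):
        transfer = 1.0 / (1.0 + (cutoff / np.where(d > 0, d, np.inf)) ** (2 * order))
    transfer[0, 0] = 0.0
    return np.real(np.fft.ifft2(np.fft.fft2(plane) * transfer))


def butterworth_highpass(volume: np.ndarray, cutoff: float, order: int) -> np.ndarray:
    """Apply :func:`butterworth_highpass_plane` to every z-plane."""
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim == 2:
        return butterworth_highpass_plane(volume, cutoff, order)
    return np.stack([butterworth_highpass_plane(p, cutoff, order) for p in volume])


def ratio_image(
    green_raw: np.ndarray,
    red_raw: np.ndarray,
    blur: GaussianSpec = GaussianSpec(5, 2),
    eps: float = 1.0,
) -> np.ndarray:
    """Green:red pH ratio image.

    Both raw channels are blurred with ``blur`` before the element-wise
    division; the red denominator is clamped at ``eps`` (graytones) so empty
    background cannot blow up the ratio.
    """
    green_raw = np.asarray(green_raw)
    red_raw = np.asarray(red_raw)
    if green_raw.shape != red_raw.shape:
        raise ValueError(
            f"channel shapes differ: {green_raw.shape} vs {red_raw.shape}"
        )
    bg = gaussian_convolve(green_raw, blur)
    br = gaussian_convolve(red_raw, blur)
    return bg / np.maximum(br, eps)


def complement_image(image: np.ndarray) -> np.ndarray:
    """Graytone complement: (per-field maximum) - image.

    Reverses the intensity ordering so that dark (low-ratio, acidified)
    vesicles become the brightest objects.
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    return image.max() - image


_COMPARATORS = {
    ">": operator.gt,
    "<": operator.lt,
    ">=": operator.ge,
    "<=": operator.le,
}


def structure_3d(connectivity: int = 26) -> np.ndarray:
    """3D labelling structure for 6-, 18- or 26-connectivity."""
    rank = {6: 1, 18: 2, 26: 3}
    if connectivity not in rank:
        raise ValueError(f"3D connectivity must be one of 6/18/26, got {connectivity}")
    return ndi.generate_binary_structure(3, rank[connectivity])


def label_volume(mask: np.ndarray, connectivity: int = 26):
    """Label a boolean volume (or plane); returns (labels, n_components)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim == 2:
        rank = {4: 1, 8: 2}
        structure = ndi.generate_binary_structure(2, rank.get(connectivity, 2))
    else:
        structure = structure_3d(connectivity)
    return ndi.label(mask, structure=structure)


def threshold_components(
    image: np.ndarray,
    comparator: str,
    value: float,
    min_size: int = 1,
    max_size: float = np.inf,
    connectivity: int = 26,
) -> np.ndarray:
    """Threshold an image and drop connected components outside a size window.

    Bounds are inclusive: components of exactly ``min_size`` or ``max_size``
    voxels are retained.  Border-touching components are kept here (border
    exclusion happens once, during classification).
    """
    if comparator not in _COMPARATORS:
        raise ValueError(f"comparator must be one of {sorted(_COMPARATORS)}")
    if min_size > max_size:
        raise ValueError(f"min_size ({min_size}) exceeds max_size ({max_size})")
    mask = _COMPARATORS[comparator](np.asarray(image, dtype=np.float64), value)
    if min_size <= 1 and np.isinf(max_size):
        return mask
    labels, n = label_volume(mask, connectivity)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = (sizes >= min_size) & (sizes <= max_size)
    keep[0] = False
    return keep[labels]


def morphological_reconstruct(
    seed: np.ndarray, limit: np.ndarray, connectivity: int = 26
) -> np.ndarray:
    """Binary reconstruction: components of ``limit`` that intersect ``seed``.

    The seed is intersected with the limiting mask first, so the result is
    always a subset of ``limit`` and a superset of ``seed & limit``.
    """
    seed = np.asarray(seed, dtype=bool)
    limit = np.asarray(limit, dtype=bool)
    if seed.shape != limit.shape:
        raise ValueError(f"shape mismatch: seed {seed.shape} vs limit {limit.shape}")
    seed = seed & limit
    if not seed.any():
        return np.zeros_like(limit)
    labels, n = label_volume(limit, connectivity)
    if n == 0:
        return np.zeros_like(limit)
    hit = np.zeros(n + 1, dtype=bool)
    hit[np.unique(labels[seed])] = True
    hit[0] = False
    return hit[labels]
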