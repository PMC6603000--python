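"""Flatfield correction, PSF modelling and Richardson-Lucy deconvolution.

The restored (*Deconvolved*) volumes produced here are the inputs to every
segmentation stage.  The point-spread function is a scalar Gaussian
approximation to the widefield/confocal PSF (lateral FWHM 0.51 lambda/NA,
axial FWHM 1.77 n lambda/NA^2); it only serves as the initial estimate for
deconvolution, whose downstream consumers are threshold-based masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filters import GaussianSpec, gaussian_convolve

__all__ = ["PsfModel", "FlatfieldReference", "generate_psf", "flatfield_correct", "deconvolve"]

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class PsfModel:
    """Optical parameters for the Gaussian-approximation PSF.

    Wavelength in nm, pitch/z-step in um.  Emission-side defaults follow the
    instrument bandpass filters: 520 nm (pHluorin), 600 nm (DsRed), 690 nm
    (lysotracker deep red); NA 1.2 water-immersion objective, n = 1.33.
    """

    wavelength_em: float = 520.0
    numerical_aperture: float = 1.2
    pixel_pitch: float = 0.2152
    z_step: float = 0.4
    refractive_index: float = 1.33
    support: tuple[int, int, int] = (7, 17, 17)

    def __post_init__(self) -> None:
        if self.numerical_aperture <= 0 or self.wavelength_em <= 0:
            raise ValueError("wavelength and NA must be positive")
        if self.numerical_aperture > self.refractive_index:
            raise ValueError(
                f"NA ({self.numerical_aperture}) cannot exceed the refractive "
                f"index ({self.refractive_index})"
            )
        if self.pixel_pitch <= 0 or self.z_step <= 0:
            raise ValueError("pixel pitch and z-step must be positive")

    @property
    def lateral_fwhm_um(self) -> float:
        return 0.51 * (self.wavelength_em * 1e-3) / self.numerical_aperture

    @property
    def axial_fwhm_um(self) -> float:
        return (
            1.77
            * self.refractive_index
            * (self.wavelength_em * 1e-3)
            / self.numerical_aperture**2
        )


def generate_psf(model: PsfModel) -> np.ndarray:
    """Sample the Gaussian-approximation PSF on the voxel grid.

    Returns a unit-sum volume of shape ``model.support`` that is radially
    symmetric in-plane and mirror-symmetric in z.  Doubling the z-step halves
    the number of z-samples covering a fixed physical extent.
    """
    nz, ny, nx = model.support
    sigma_lat_px = model.lateral_fwhm_um / _FWHM_PER_SIGMA / model.pixel_pitch
    sigma_ax_px = model.axial_fwhm_um / _FWHM_PER_SIGMA / model.z_step
    z = np.arange(nz) - (nz - 1) / 2.0
    y = np.arange(ny) - (ny - 1) / 2.0
    x = np.arange(nx) - (nx - 1) / 2.0
    gz = np.exp(-(z**2) / (2.0 * sigma_ax_px**2))
    gy = np.exp(-(y**2) / (2.0 * sigma_lat_px**2))
    gx = np.exp(-(x**2) / (2.0 * sigma_lat_px**2))
    psf = gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    return psf / psf.sum()


@dataclass
class FlatfieldReference:
    """Per-channel illumination reference from an adjustment plate.

    The reference is Gaussian-smoothed (sigma 20 px by default) before the
    division so that shot noise in the reference does not imprint on the
    corrected data.
    """

    reference_image: np.ndarray
    smoothing: GaussianSpec = field(default_factory=lambda: GaussianSpec(81, 20.0))

    def smoothed(self) -> np.ndarray:
        ref = gaussian_convolve(np.asarray(self.reference_image, dtype=np.float64), self.smoothing)
        if np.any(ref <= 0):
            raise ValueError("flatfield reference is non-positive after smoothing")
        return ref


def flatfield_correct(raw: np.ndarray, ref: FlatfieldReference) -> np.ndarray:
    """Divide out the illumination profile, preserving the field mean.

    ``corrected(z, y, x) = raw(z, y, x) * mean(ref) / ref(y, x)``; a uniform
    reference therefore leaves the input untouched.
    """
    raw = np.asarray(raw, dtype=np.float64)
    smoothed = ref.smoothed()
    plane_shape = raw.shape[-2:]
    if smoothed.shape != plane_shape:
        raise ValueError(
            f"reference plane {smoothed.shape} does not match field planes {plane_shape}"
        )
    gain = smoothed.mean() / smoothed
    return raw * gain


def deconvolve(
    image: np.ndarray,
    psf_init: np.ndarray,
    iterations: int = 10,
    blind: bool = False,
) -> np.ndarray:
    """Richardson-Lucy restoration of a 3D stack.

    The default is fixed-PSF Richardson-Lucy (reproducible bit-for-bit);
    ``blind=True`` alternates a multiplicative PSF update with each image
    update, mirroring blind deconvolution with the supplied PSF as the
    initial estimate.  Output is non-negative and approximately flux
    conserving for interior-supported objects.
    """
    if iterations < 1:
        raise ValueError(f"iterations must be >= 1, got {iterations}")
    psf_init = np.asarray(psf_init, dtype=np.float64)
    if not np.isclose(psf_init.sum(), 1.0, atol=1e-6):
        raise ValueError("PSF must be normalised to unit sum")
    image = np.asarray(image, dtype=np.float64)
    # mirror-double every axis: the tiling is exactly periodic, so the
    # circular FFT convolutions see no boundary discontinuity and a
    # constant image is an exact fixed point
    shape = image.shape
    mirrored = np.pad(image, tuple((0, s) for s in shape), mode="symmetric")
    crop = tuple(slice(0, s) for s in shape)
    eps = 1e-12

    def _otf(psf: np.ndarray) -> np.ndarray:
        kernel = np.zeros(mirrored.shape)
        slices = tuple(slice(0, p) for p in psf.shape)
        kernel[slices] = psf
        for axis, p in enumerate(psf.shape):
            kernel = np.roll(kernel, -((p - 1) // 2), axis=axis)
        return np.fft.rfftn(kernel)

    def _conv(arr: np.ndarray, otf: np.ndarray) -> np.ndarray:
        return np.fft.irfftn(np.fft.rfftn(arr) * otf, s=mirrored.shape, axes=(0, 1, 2))

    psf = psf_init.copy()
    otf = _otf(psf)
    est = mirrored.copy() if not blind else np.full_like(mirrored, max(image.mean(), eps))
    for _ in range(iterations):
        if blind:
            # multiplicative PSF refinement with the image estimate fixed
            ratio = mirrored / np.maximum(_conv(est, otf), eps)
            corr = np.fft.irfftn(
                np.fft.rfftn(ratio) * np.conj(np.fft.rfftn(est)),
                s=mirrored.shape, axes=(0, 1, 2),
            )
            for axis, p in enumerate(psf.shape):
                corr = np.roll(corr, (p - 1) // 2, axis=axis)
            window = tuple(slice(0, p) for p in psf.shape)
            update = np.maximum(corr[window], 0.0)
            psf = psf * update
            psf = psf / max(psf.sum(), eps)
            otf = _otf(psf)
        blurred = _conv(est, otf)
        ratio = mirrored / np.maximum(blurred, eps)
        est = est * _conv(ratio, np.conj(otf))
        est = np.maximum(est, 0.0)
    return est[crop]
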