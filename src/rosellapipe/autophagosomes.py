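"""Hollow-vesicle (autophagosome) detection.

Autophagosomes are closed, not-yet-acidified double-membrane vesicles that
image as bright rings in both channels.  Two complementary detectors find
them: a Fourier/Euler route (high-pass filtering, z-maximum projection and
Euler-number topology selection of one-hole components) and a circle Hough
route on the raw green channel, validated by intensity statistics.
Candidates from either route are then shape-filtered by size and two
sphericity indices.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import canny
from skimage.measure import euler_number, regionprops
from skimage.morphology import disk
from skimage.transform import hough_circle, hough_circle_peaks

from .config import PipelineConfig
from .filters import (
    GaussianSpec,
    butterworth_highpass,
    gaussian_convolve,
    label_volume,
)

__all__ = [
    "fourier_euler_detect",
    "hough_detect",
    "sphericity_indices",
    "shape_filter_autophagosomes",
]


def _remove_small_2d(mask: np.ndarray, min_area: int) -> np.ndarray:
    labels, n = label_volume(mask, 8)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_area
    keep[0] = False
    return keep[labels]


def fourier_euler_detect(
    green_dog: np.ndarray, cfg: PipelineConfig | None = None
) -> np.ndarray:
    """Topology route: select one-hole (Euler number 0) ring components.

    The green band-pass image is Butterworth high-pass filtered plane by
    plane, thresholded (> 150), maximum-projected along z, despeckled
    (area >= 20, 3x3 median, opening radius 1), and its connected components
    are kept when their Euler number is 0 (exactly one hole).  A proportion
    filter (filled/area > 1.01 and filled - area > 20) discards spurious
    pinholes, holes are recovered by inverting and dropping the > 10000 px
    background, and each surviving component is filled via reconstruction
    from its hole, opened with a radius-5 disk, and restored to 3D on the
    planes where the thresholded mask was already positive.
    """
    cfg = cfg or PipelineConfig()
    ftb = butterworth_highpass(green_dog, cfg.butterworth_cutoff, cfg.butterworth_order)
    m150 = ftb > cfg.euler_threshold
    proj = m150.any(axis=0)
    proj = _remove_small_2d(proj, cfg.euler_min_area)
    proj = ndi.median_filter(proj.astype(np.uint8), size=3).astype(bool)
    proj = ndi.binary_opening(proj, structure=disk(cfg.euler_opening_radius))

    labels, n = label_volume(proj, cfg.connectivity_2d)
    select_mask = np.zeros_like(proj)
    filled_mask = np.zeros_like(proj)
    for idx in range(1, n + 1):
        comp = labels == idx
        if euler_number(comp, connectivity=2) != 0:
            continue
        filled = ndi.binary_fill_holes(comp)
        area = int(comp.sum())
        filled_area = int(filled.sum())
        if filled_area / area <= cfg.euler_proportion_ratio:
            continue
        if filled_area - area <= cfg.euler_proportion_difference:
            continue
        select_mask |= comp
        filled_mask |= filled

    # hole extraction: invert the selected mask and drop the big background
    inverted = ~select_mask
    lab_inv, n_inv = label_volume(inverted, cfg.connectivity_2d)
    holes = np.zeros_like(proj)
    if n_inv:
        sizes = np.bincount(lab_inv.ravel())
        small = sizes <= cfg.euler_background_size
        small[0] = False
        holes = small[lab_inv] & inverted
    holes &= filled_mask

    # reconstruction: filled components that contain a hole
    lab_fill, n_fill = label_volume(filled_mask, cfg.connectivity_2d)
    recon = np.zeros_like(proj)
    if n_fill and holes.any():
        hit = np.zeros(n_fill + 1, dtype=bool)
        hit[np.unique(lab_fill[holes])] = True
        hit[0] = False
        recon = hit[lab_fill]
    recon = ndi.binary_opening(recon, structure=disk(cfg.euler_restore_opening_radius))

    # 3D restoration: a plane of a component is kept when the thresholded
    # Butterworth mask was already positive there
    out = np.zeros(green_dog.shape, dtype=bool)
    lab_rec, n_rec = label_volume(recon, cfg.connectivity_2d)
    for idx in range(1, n_rec + 1):
        comp2d = lab_rec == idx
        for z in range(out.shape[0]):
            if (m150[z] & comp2d).any():
                out[z] |= comp2d
    return out


def _mad(values: np.ndarray) -> float:
    med = np.median(values)
    return float(np.median(np.abs(values - med)))


def hough_detect(
    phluorin_raw: np.ndarray,
    known_vesicles: np.ndarray,
    dsred_raw: np.ndarray,
    cfg: PipelineConfig | None = None,
) -> np.ndarray:
    """Circle-Hough route on the raw green channel.

    Already-identified vesicle pixels are replaced by low-pass filtered
    values so they cannot re-trigger, the plane is graytone-eroded (disk
    radius 2) to sharpen the remaining rings, and circles with radii
    3-30 px are detected in two radius sweeps.  A circle is accepted only
    when the raw green pixels inside it are textured (MAD > 20) and the
    raw red pixels are dim (0.9-quantile < 300); accepted circles are
    rasterised as filled disks on their plane of detection.
    """
    cfg = cfg or PipelineConfig()
    phluorin_raw = np.asarray(phluorin_raw, dtype=np.float64)
    dsred_raw = np.asarray(dsred_raw, dtype=np.float64)
    known = np.asarray(known_vesicles, dtype=bool)
    out = np.zeros(phluorin_raw.shape, dtype=bool)
    nz, ny, nx = phluorin_raw.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    footprint = disk(cfg.hough_erosion_radius)
    for z in range(nz):
        plane = phluorin_raw[z]
        lowpass = gaussian_convolve(plane, GaussianSpec(*cfg.ratio_blur))
        prepared = np.where(known[z], lowpass, plane)
        prepared = ndi.grey_erosion(prepared, footprint=footprint)
        scale = prepared.max()
        if scale <= 0:
            continue
        edges = canny(prepared / scale, sigma=cfg.hough_canny_sigma)
        if not edges.any():
            continue
        for rmin, rmax in cfg.hough_radius_stages:
            radii = np.arange(rmin, rmax + 1)
            accum = hough_circle(edges, radii)
            _, cxs, cys, rads = hough_circle_peaks(
                accum,
                radii,
                total_num_peaks=cfg.hough_max_circles_per_stage,
                threshold=cfg.hough_accumulator_threshold,
            )
            for cx, cy, r in zip(cxs, cys, rads):
                if not (0 <= cy < ny and 0 <= cx < nx):
                    continue
                inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
                green_vals = plane[inside]
                if green_vals.size == 0:
                    continue
                if _mad(green_vals) <= cfg.hough_mad_threshold:
                    continue
                red_q = np.quantile(dsred_raw[z][inside], cfg.hough_red_quantile)
                if red_q >= cfg.hough_red_quantile_threshold:
                    continue
                out[z] |= inside
    return out


def sphericity_indices(
    component: np.ndarray, green_deconvolved: np.ndarray
) -> tuple[float, float]:
    """Shape and hollowness indices for one candidate component.

    ``idx1`` is projected circularity scaled so an ideal rendered sphere
    scores about 1.2: ``1.2 * 4 pi A / P^2`` on the z-maximum projection
    with the Crofton perimeter.  Compact round bodies score above 1,
    filaments and ragged sheets well below.

    ``idx2`` captures the hollow-ring intensity profile -- the ratio
    between vesicle border and vesicle centre intensities: mean deconvolved
    green in the border band (in-plane distance-to-edge <= 2 px) over the
    mean in the core (around the in-plane distance maximum).  A bright rim
    around a dim lumen scores well above 1.5; solid bright bodies and flat
    background disks score at or below 1.
    """
    component = np.asarray(component, dtype=bool)
    volume = int(component.sum())
    if volume == 0:
        return 0.0, 0.0
    proj = component.any(axis=0)
    props = regionprops(proj.astype(np.uint8))[0]
    perimeter = props.perimeter_crofton
    idx1 = 0.0 if perimeter == 0 else 1.2 * 4.0 * np.pi * props.area / perimeter**2

    green = np.asarray(green_deconvolved, dtype=np.float64)
    edt = np.stack([ndi.distance_transform_edt(p) for p in component])
    border = component & (edt <= 2.0)
    core = component & (edt >= max(0.6 * edt.max(), 2.5))
    if not core.any():
        core = component & (edt == edt.max())
    core_mean = green[core].mean()
    idx2 = float(green[border].mean() / core_mean) if core_mean > 0 else 0.0
    return float(idx1), idx2


def shape_filter_autophagosomes(
    candidates: np.ndarray,
    green_deconvolved: np.ndarray,
    cfg: PipelineConfig | None = None,
) -> np.ndarray:
    """Retain candidates of 50-10000 voxels with Idx1 > 1 and Idx2 > 1.5."""
    cfg = cfg or PipelineConfig()
    labels, n = label_volume(candidates, cfg.connectivity_3d)
    out = np.zeros_like(np.asarray(candidates, dtype=bool))
    if n == 0:
        return out
    green = np.asarray(green_deconvolved, dtype=np.float64)
    for sl, idx in zip(ndi.find_objects(labels), range(1, n + 1)):
        if sl is None:
            continue
        comp = labels[sl] == idx
        volume = int(comp.sum())
        if not (cfg.autophagosome_min_volume <= volume <= cfg.autophagosome_max_volume):
            continue
        idx1, idx2 = sphericity_indices(comp, green[sl])
        if idx1 > cfg.sphericity_idx1_threshold and idx2 > cfg.sphericity_idx2_threshold:
            out[sl][comp] = True
    return out
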