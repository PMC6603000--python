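"""Channel masks for the autophagy staging pipeline.

Builds the DsRed vesicle mask (band-pass + top-hat + watershed-confirmed
pool), the pHluorin mask (large-vesicle band-pass OR LoG edges) and the
ratio-derived autolysosome rescue mask from the deconvolved channels, i.e.
the dsRedMask / pHluorinMask / AutoLysoMask stages of the workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk
from skimage.segmentation import watershed

from .config import PipelineConfig
from .filters import (
    GaussianSpec,
    complement_image,
    difference_of_gaussians,
    label_volume,
    laplacian_of_gaussian,
    threshold_components,
    tophat_gray,
)

__all__ = [
    "ChannelMasks",
    "build_dsred_dog_mask",
    "build_dsred_tophat_split",
    "build_dsred_mask",
    "build_phluorin_mask",
    "build_autolyso_mask",
    "build_channel_masks",
]


@dataclass
class ChannelMasks:
    """All intermediate and final masks of the red/green segmentation stage."""

    dsred_dog_mask: np.ndarray | None = None
    dsred_tophat_split: np.ndarray | None = None
    dsred_mask1: np.ndarray | None = None
    dsred_dog2_mask: np.ndarray | None = None
    dsred_stencil1: np.ndarray | None = None
    dsred_stencil2: np.ndarray | None = None
    dsred_mask: np.ndarray | None = None
    green_dog: np.ndarray | None = None
    green_dog_mask: np.ndarray | None = None
    green_log_mask: np.ndarray | None = None
    phluorin_mask: np.ndarray | None = None
    autolyso_candidates: np.ndarray | None = None
    autolyso_mask: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


def build_dsred_dog_mask(
    dsred_deconvolved: np.ndarray, cfg: PipelineConfig | None = None
) -> np.ndarray:
    """Small red vesicles: DoG (20,1)-(20,7) band-pass thresholded > 400."""
    cfg = cfg or PipelineConfig()
    dog = difference_of_gaussians(
        dsred_deconvolved,
        GaussianSpec(*cfg.dsred_dog_fg),
        GaussianSpec(*cfg.dsred_dog_bg),
    )
    return dog > cfg.dsred_dog_threshold


def build_dsred_tophat_split(
    dsred_deconvolved: np.ndarray,
    dog_mask: np.ndarray,
    cfg: PipelineConfig | None = None,
) -> np.ndarray:
    """Top-hat red mask, refined by substitution against the DoG mask.

    Every connected component larger than 500 voxels whose voxel overlap
    with the DoG mask exceeds 10% is replaced by the DoG-mask pattern inside
    it, which restores the splits the top-hat merged away.
    """
    cfg = cfg or PipelineConfig()
    tophat = tophat_gray(dsred_deconvolved, cfg.dsred_tophat_radius)
    mask = tophat > cfg.dsred_tophat_threshold
    labels, n = label_volume(mask, cfg.connectivity_3d)
    if n == 0:
        return mask
    out = mask.copy()
    dog_mask = np.asarray(dog_mask, dtype=bool)
    for idx in range(1, n + 1):
        comp = labels == idx
        size = int(comp.sum())
        if size <= cfg.dsred_substitution_min_size:
            continue
        overlap = np.count_nonzero(comp & dog_mask) / size
        if overlap > cfg.dsred_substitution_overlap:
            out[comp] = dog_mask[comp]
    return out


def build_dsred_mask(
    dsred_deconvolved: np.ndarray, cfg: PipelineConfig | None = None
) -> ChannelMasks:
    """Full DsRed-positive vesicle pool (dsRedMask).

    Combines the DoG and refined top-hat masks (dsRedMask1), splits them via
    a distance-transform watershed seeded from dsRedMask1, gates the
    watershed regions with a confirmatory second DoG mask (dsRedStencil2),
    and pools voxels present in either dsRedMask1 or dsRedStencil2.  The
    final mask is therefore always a superset of dsRedMask1.
    """
    cfg = cfg or PipelineConfig()
    masks = ChannelMasks()
    masks.dsred_dog_mask = build_dsred_dog_mask(dsred_deconvolved, cfg)
    masks.dsred_tophat_split = build_dsred_tophat_split(
        dsred_deconvolved, masks.dsred_dog_mask, cfg
    )
    mask1 = masks.dsred_dog_mask | masks.dsred_tophat_split
    masks.dsred_mask1 = mask1

    dog2 = difference_of_gaussians(
        dsred_deconvolved,
        GaussianSpec(*cfg.dsred_dog2_fg),
        GaussianSpec(*cfg.dsred_dog2_bg),
    )
    masks.dsred_dog2_mask = threshold_components(
        dog2,
        ">",
        cfg.dsred_dog2_threshold,
        min_size=cfg.dsred_dog2_min_size,
        max_size=cfg.dsred_dog2_max_size,
        connectivity=cfg.connectivity_3d,
    )

    if mask1.any():
        markers, _ = label_volume(mask1, cfg.connectivity_3d)
        distance = ndi.distance_transform_edt(~mask1)
        regions = watershed(distance, markers=markers, watershed_line=True)
        masks.dsred_stencil1 = regions > 0
    else:
        masks.dsred_stencil1 = np.zeros_like(mask1)
    masks.dsred_stencil2 = masks.dsred_stencil1 & masks.dsred_dog2_mask
    masks.dsred_mask = mask1 | masks.dsred_stencil2
    return masks


def build_phluorin_mask(
    phluorin_deconvolved: np.ndarray,
    cfg: PipelineConfig | None = None,
    masks: ChannelMasks | None = None,
) -> ChannelMasks:
    """Green vesicle mask: large-vesicle DoG OR LoG edge mask, despeckled.

    Connected components below 10 voxels are removed from the merged mask.
    The intermediate GreenDoG image is kept on the result because the
    hollow-vesicle detector consumes it.
    """
    cfg = cfg or PipelineConfig()
    masks = masks or ChannelMasks()
    green_dog = difference_of_gaussians(
        phluorin_deconvolved,
        GaussianSpec(*cfg.green_dog_fg),
        GaussianSpec(*cfg.green_dog_bg),
    )
    masks.green_dog = green_dog
    masks.green_dog_mask = green_dog > cfg.green_dog_threshold
    green_log = laplacian_of_gaussian(
        phluorin_deconvolved, cfg.green_log_size, cfg.green_log_sd
    )
    masks.green_log_mask = green_log < cfg.green_log_threshold
    merged = masks.green_dog_mask | masks.green_log_mask
    labels, n = label_volume(merged, cfg.connectivity_3d)
    if n:
        sizes = np.bincount(labels.ravel())
        keep = sizes >= cfg.phluorin_min_size
        keep[0] = False
        merged = keep[labels]
    masks.phluorin_mask = merged
    return masks


def build_autolyso_mask(
    ratio: np.ndarray,
    green_raw: np.ndarray,
    cfg: PipelineConfig | None = None,
    masks: ChannelMasks | None = None,
) -> np.ndarray:
    """Ratio-derived rescue mask for acidified vesicles missed elsewhere.

    Candidates are bright spots of the top-hat filtered *complemented* ratio
    image (acidified vesicles are ratio-dark, hence complement-bright).  A
    candidate survives only if its green neighbourhood -- an in-plane
    dilation ring of radius 7 px -- is at least 50% brighter (mean raw
    green) than the vesicle itself, and the candidate exceeds 100 voxels.
    """
    cfg = cfg or PipelineConfig()
    comp = complement_image(ratio)
    tophat = tophat_gray(comp, cfg.autolyso_tophat_radius)
    candidates = tophat > cfg.autolyso_threshold
    if masks is not None:
        masks.autolyso_candidates = candidates
    labels, n = label_volume(candidates, cfg.connectivity_3d)
    out = np.zeros_like(candidates)
    if n == 0:
        if masks is not None:
            masks.autolyso_mask = out
        return out
    green_raw = np.asarray(green_raw, dtype=np.float64)
    footprint = disk(cfg.autolyso_dilation_radius)[None, :, :]
    objects = ndi.find_objects(labels)
    for idx, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        # pad the bounding box so the dilation ring fits
        r = cfg.autolyso_dilation_radius
        zsl = sl[0]
        ysl = slice(max(sl[1].start - r, 0), min(sl[1].stop + r, labels.shape[1]))
        xsl = slice(max(sl[2].start - r, 0), min(sl[2].stop + r, labels.shape[2]))
        window = (zsl, ysl, xsl)
        comp_mask = labels[window] == idx
        size = int(comp_mask.sum())
        if size <= cfg.autolyso_min_volume:
            continue
        ring = ndi.binary_dilation(comp_mask, structure=footprint) & ~comp_mask
        if not ring.any():
            continue
        green_win = green_raw[window]
        if green_win[ring].mean() >= cfg.autolyso_brightness_factor * green_win[comp_mask].mean():
            out[window][comp_mask] = True
    if masks is not None:
        masks.autolyso_mask = out
    return out


def build_channel_masks(
    phluorin_deconvolved: np.ndarray,
    dsred_deconvolved: np.ndarray,
    ratio: np.ndarray,
    green_raw: np.ndarray,
    cfg: PipelineConfig | None = None,
) -> ChannelMasks:
    """Run the red, green and ratio mask builders on one field."""
    cfg = cfg or PipelineConfig()
    masks = build_dsred_mask(dsred_deconvolved, cfg)
    build_phluorin_mask(phluorin_deconvolved, cfg, masks)
    build_autolyso_mask(ratio, green_raw, cfg, masks)
    return masks
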