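"""Mitochondrial network segmentation and mitophagy event detection.

ATP5C1-Rosella fields (11 planes) carry the reporter on mitochondria:
healthy mitochondria are bright in both channels, while mitochondria
delivered to acidic compartments (mitophagy events) keep DsRed but lose the
pHluorin signal, collapsing their green:red ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .config import PipelineConfig
from .filters import (
    GaussianSpec,
    difference_of_gaussians,
    label_volume,
    morphological_reconstruct,
)

__all__ = [
    "MitoMasks",
    "MitophagySummary",
    "segment_mitochondria",
    "detect_mitophagy",
    "mito_volumes",
    "resource_split",
]


@dataclass
class MitoMasks:
    mito_dog: np.ndarray | None = None
    mito_mask: np.ndarray | None = None
    mitophagy_seed: np.ndarray | None = None
    mitophagy_limit: np.ndarray | None = None
    mitophagy_mask: np.ndarray | None = None


@dataclass
class MitophagySummary:
    field_id: str = ""
    condition: str = ""
    mito_volume_um3: float = 0.0
    mitophagy_volume_um3: float = 0.0
    mitophagy_event_count: int = 0
    mito_component_count: int = 0
    resource_split: dict = field(default_factory=dict)


def segment_mitochondria(
    dsred_raw: np.ndarray, cfg: PipelineConfig | None = None
) -> MitoMasks:
    """Mitochondrial mask: DoG (50,1)-(50,2) of the DsRed channel > 12.

    The narrow band-pass follows tubular cross-sections; a local reduction
    in tubule cross-section can split the network into several components,
    which is expected behaviour rather than a defect.
    """
    cfg = cfg or PipelineConfig()
    masks = MitoMasks()
    masks.mito_dog = difference_of_gaussians(
        dsred_raw, GaussianSpec(*cfg.mito_dog_fg), GaussianSpec(*cfg.mito_dog_bg)
    )
    masks.mito_mask = masks.mito_dog > cfg.mito_threshold
    return masks


def detect_mitophagy(
    masks: MitoMasks,
    ratio: np.ndarray,
    dsred_raw: np.ndarray,
    cfg: PipelineConfig | None = None,
) -> MitoMasks:
    """Mitophagy events: ratio-quenched seeds grown inside a red DoG limit.

    26-connected components of the mitochondrial mask whose mean green:red
    ratio falls below 0.6 seed the events; the limiting mask is a wider
    DsRed band-pass (50,1)-(50,5) thresholded > 50, and the event mask is
    the morphological reconstruction of the limit from the seeds.
    """
    cfg = cfg or PipelineConfig()
    if masks.mito_mask is None:
        raise ValueError("segment_mitochondria must run first")
    ratio = np.asarray(ratio, dtype=np.float64)
    labels, n = label_volume(masks.mito_mask, cfg.connectivity_3d)
    seed = np.zeros_like(masks.mito_mask)
    if n:
        means = ndi.mean(ratio, labels=labels, index=np.arange(1, n + 1))
        low = np.concatenate([[False], means < cfg.mitophagy_ratio_threshold])
        seed = low[labels]
    masks.mitophagy_seed = seed
    limit_dog = difference_of_gaussians(
        dsred_raw,
        GaussianSpec(*cfg.mitophagy_dog_fg),
        GaussianSpec(*cfg.mitophagy_dog_bg),
    )
    masks.mitophagy_limit = limit_dog > cfg.mitophagy_limit_threshold
    masks.mitophagy_mask = morphological_reconstruct(
        seed, masks.mitophagy_limit, cfg.connectivity_3d
    )
    return masks


def mito_volumes(
    masks: MitoMasks,
    field_id: str = "",
    condition: str = "",
    cfg: PipelineConfig | None = None,
) -> MitophagySummary:
    """Physical volumes and event counts (voxels x 0.2152^2 x 0.4 um^3)."""
    cfg = cfg or PipelineConfig()
    voxel = cfg.pixel_pitch_um**2 * cfg.z_step_um
    mito_mask = masks.mito_mask if masks.mito_mask is not None else np.zeros((1, 1, 1), bool)
    event_mask = (
        masks.mitophagy_mask if masks.mitophagy_mask is not None else np.zeros_like(mito_mask)
    )
    _, n_mito = label_volume(mito_mask, cfg.connectivity_3d)
    _, n_events = label_volume(event_mask, cfg.connectivity_3d)
    return MitophagySummary(
        field_id=field_id,
        condition=condition,
        mito_volume_um3=float(np.count_nonzero(mito_mask)) * voxel,
        mitophagy_volume_um3=float(np.count_nonzero(event_mask)) * voxel,
        mitophagy_event_count=int(n_events),
        mito_component_count=int(n_mito),
    )


def resource_split(
    lc3_vacuole_frequency: float,
    atp5c1_mitophagy_frequency: float,
    basal_lc3_vacuole_frequency: float,
    basal_atp5c1_mitophagy_frequency: float,
) -> dict:
    """Autophagy-resource distribution relative to the basal reference.

    Non-mitochondrial autophagy is modelled by subtracting the mitophagy
    frequency (ATP5C1 reporter) from the total autophagic-vacuole frequency
    (LC3 reporter); both quantities are then expressed as percentages of
    their basal values.  A negative post-subtraction frequency is clamped to
    zero with a warning; a zero basal denominator flags the percentage as
    undefined (NaN).
    """
    import warnings

    non_mito = lc3_vacuole_frequency - atp5c1_mitophagy_frequency
    basal_non_mito = basal_lc3_vacuole_frequency - basal_atp5c1_mitophagy_frequency
    if non_mito < 0:
        warnings.warn("negative non-mitochondrial autophagy frequency clamped to 0", stacklevel=2)
        non_mito = 0.0
    if basal_non_mito < 0:
        warnings.warn("negative basal non-mitochondrial frequency clamped to 0", stacklevel=2)
        basal_non_mito = 0.0
    mitophagy_pct = (
        100.0 * atp5c1_mitophagy_frequency / basal_atp5c1_mitophagy_frequency
        if basal_atp5c1_mitophagy_frequency > 0
        else float("nan")
    )
    non_mito_pct = (
        100.0 * non_mito / basal_non_mito if basal_non_mito > 0 else float("nan")
    )
    return {
        "mitophagy_pct": mitophagy_pct,
        "non_mito_autophagy_pct": non_mito_pct,
        "non_mito_frequency": non_mito,
        "basal_non_mito_frequency": basal_non_mito,
    }
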