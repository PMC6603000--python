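"""Vesicle pooling, progressive-exclusion classification and field summaries.

Every detected vesicle is assigned exactly one of four stages by a
progressive exclusion tree evaluated in the order autophagosome ->
phagophore -> late autolysosome -> early autolysosome; vesicles failing
every rule are kept as "unclassified" rather than silently dropped.

Stage logic (Rosella reporter): phagophores are bright in both channels
with a high green:red ratio; autophagosomes are hollow rings caught by the
dedicated detectors; autolysosomes are acidified (green-quenched) so their
ratio collapses while DsRed persists, with early autolysosomes retaining
partial green signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import regionprops
from skimage.morphology import ball, disk

from .config import PipelineConfig
from .filters import VOXEL_VOLUME_UM3, label_volume
from .segmentation import ChannelMasks

__all__ = [
    "CLASS_NAMES",
    "VesicleRecord",
    "FieldSummary",
    "pool_vesicles",
    "compute_noncircular_mask",
    "classify_features",
    "classify_vesicles",
    "records_to_frame",
    "summarize_field",
    "normalize_wells",
]

CLASS_NAMES = (
    "phagophore",
    "autophagosome",
    "early_autolysosome",
    "late_autolysosome",
    "unclassified",
)


@dataclass
class VesicleRecord:
    label: int
    vesicle_class: str
    volume_voxels: int
    volume_um3: float
    centroid: tuple
    mean_red_raw: float
    mean_green_raw: float
    q3_green: float
    q3_red: float
    median_ratio: float
    overlap_phluorin: float
    overlap_dsred: float
    overlap_autolyso: float
    overlap_autophagosome: float
    overlap_noncircular: float
    center_green: float
    surface_green: float
    eccentricity: float
    touches_border: bool
    major_axis_um: float


@dataclass
class FieldSummary:
    field_id: str = ""
    well_id: str = ""
    condition: str = ""
    n_phagophore: int = 0
    n_autophagosome: int = 0
    n_early_autolysosome: int = 0
    n_late_autolysosome: int = 0
    n_unclassified: int = 0
    autophagic_vacuoles: int = 0
    autophagy_rate: float = 0.0
    rate_defined: bool = True
    n_vesicles_total: int = 0
    counts: dict = field(default_factory=dict)


def pool_vesicles(
    all_masks: np.ndarray,
    autophagosome_mask: np.ndarray,
    dsred_raw: np.ndarray,
    cfg: PipelineConfig | None = None,
) -> np.ndarray:
    """Pool all detections into a label volume of classifiable vesicles.

    The in-plane perimeter of the autophagosome mask is carved out of the
    pooled mask before labelling so that vesicles separated only by a ring
    stay split.  Components with mean raw DsRed <= 300 or touching the
    lateral (y, x) image border are discarded; survivors are relabelled
    1..n.
    """
    cfg = cfg or PipelineConfig()
    pooled = np.asarray(all_masks, dtype=bool).copy()
    ap = np.asarray(autophagosome_mask, dtype=bool)
    if ap.any():
        eroded = np.stack([ndi.binary_erosion(p, structure=disk(1)) for p in ap])
        perimeter = ap & ~eroded
        pooled &= ~perimeter
    labels, n = label_volume(pooled, cfg.connectivity_3d)
    if n == 0:
        return labels
    dsred_raw = np.asarray(dsred_raw, dtype=np.float64)
    means = ndi.mean(dsred_raw, labels=labels, index=np.arange(1, n + 1))
    border = np.zeros(labels.shape, dtype=bool)
    border[:, 0, :] = border[:, -1, :] = True
    border[:, :, 0] = border[:, :, -1] = True
    touches = np.zeros(n + 1, dtype=bool)
    touches[np.unique(labels[border])] = True
    keep = np.zeros(n + 1, dtype=np.int32)
    nxt = 0
    for idx in range(1, n + 1):
        if means[idx - 1] > cfg.vesicle_min_mean_red and not touches[idx]:
            nxt += 1
            keep[idx] = nxt
    return keep[labels]


def compute_noncircular_mask(
    labels: np.ndarray, cfg: PipelineConfig | None = None
) -> np.ndarray:
    """Mask of components with projected eccentricity > 0.9.

    Eccentricity is measured on the z-maximum projection of each component
    (five-plane stacks are too thin for 3D ellipsoid fits).
    """
    cfg = cfg or PipelineConfig()
    out = np.zeros(labels.shape, dtype=bool)
    for idx in range(1, int(labels.max()) + 1):
        comp = labels == idx
        proj = comp.any(axis=0)
        props = regionprops(proj.astype(np.uint8))
        if props and props[0].eccentricity > cfg.noncircular_eccentricity:
            out |= comp
    return out


def classify_features(f: dict, cfg: PipelineConfig | None = None) -> str:
    """Progressive-exclusion decision tree on one vesicle's feature dict.

    Expected keys: overlap_autophagosome, overlap_noncircular,
    overlap_phluorin, overlap_dsred, overlap_autolyso, median_ratio,
    q3_green, q3_red, center_green, surface_green.
    """
    cfg = cfg or PipelineConfig()
    if f["overlap_autophagosome"] > 0 and f["overlap_noncircular"] == 0:
        return "autophagosome"
    # phagophore: three alternative condition sets
    if (
        f["overlap_phluorin"] >= cfg.overlap_threshold
        and f["overlap_dsred"] >= cfg.overlap_threshold
        and f["median_ratio"] > cfg.phagophore_median_ratio
        and f["overlap_autolyso"] == 0
    ):
        return "phagophore"
    if f["q3_green"] > cfg.phagophore_q3_green and f["q3_red"] > cfg.phagophore_q3_red:
        return "phagophore"
    if f["center_green"] >= cfg.phagophore_center_factor * f["surface_green"]:
        return "phagophore"
    # late autolysosome
    if f["overlap_dsred"] >= cfg.overlap_threshold and (
        f["overlap_phluorin"] < cfg.late_phluorin_overlap
        or f["median_ratio"] <= cfg.late_median_ratio
    ):
        return "late_autolysosome"
    if f["center_green"] < f["surface_green"]:
        return "late_autolysosome"
    # early autolysosome
    if (
        f["overlap_dsred"] >= cfg.overlap_threshold
        and f["overlap_phluorin"] <= cfg.overlap_threshold
    ) or f["overlap_autolyso"] > 0:
        return "early_autolysosome"
    return "unclassified"


def _overlap(comp: np.ndarray, mask: np.ndarray | None) -> float:
    if mask is None:
        return 0.0
    return float(np.count_nonzero(comp & mask) / comp.sum())


def _center_surface(comp: np.ndarray, green: np.ndarray) -> tuple[float, float]:
    """Mean raw green in the 1-voxel-eroded interior vs the surface shell.

    Falls back to per-plane disk(1) erosion on thin components; if that is
    empty too, both values equal the component mean (no strict comparison
    can then fire).
    """
    interior = ndi.binary_erosion(comp, structure=ball(1))
    if not interior.any():
        interior = np.stack([ndi.binary_erosion(p, structure=disk(1)) for p in comp])
    shell = comp & ~interior
    if not interior.any() or not shell.any():
        mean = float(green[comp].mean())
        return mean, mean
    return float(green[interior].mean()), float(green[shell].mean())


def classify_vesicles(
    labels: np.ndarray,
    masks: ChannelMasks,
    autophagosome_mask: np.ndarray,
    noncircular_mask: np.ndarray,
    ratio: np.ndarray,
    green_raw: np.ndarray,
    red_raw: np.ndarray,
    cfg: PipelineConfig | None = None,
) -> list[VesicleRecord]:
    """Measure features and classify every pooled vesicle."""
    cfg = cfg or PipelineConfig()
    green_raw = np.asarray(green_raw, dtype=np.float64)
    red_raw = np.asarray(red_raw, dtype=np.float64)
    ratio = np.asarray(ratio, dtype=np.float64)
    records: list[VesicleRecord] = []
    n = int(labels.max())
    objects = ndi.find_objects(labels)
    border_y = labels.shape[1] - 1
    border_x = labels.shape[2] - 1
    for idx in range(1, n + 1):
        sl = objects[idx - 1]
        if sl is None:
            continue
        comp = labels[sl] == idx
        volume = int(comp.sum())
        g = green_raw[sl]
        r = red_raw[sl]
        rat = ratio[sl]
        center_green, surface_green = _center_surface(comp, g)
        feats = {
            "overlap_phluorin": _overlap(comp, None if masks.phluorin_mask is None else masks.phluorin_mask[sl]),
            "overlap_dsred": _overlap(comp, None if masks.dsred_mask is None else masks.dsred_mask[sl]),
            "overlap_autolyso": _overlap(comp, None if masks.autolyso_mask is None else masks.autolyso_mask[sl]),
            "overlap_autophagosome": _overlap(comp, np.asarray(autophagosome_mask, dtype=bool)[sl]),
            "overlap_noncircular": _overlap(comp, np.asarray(noncircular_mask, dtype=bool)[sl]),
            "median_ratio": float(np.median(rat[comp])),
            "q3_green": float(np.quantile(g[comp], 0.75)),
            "q3_red": float(np.quantile(r[comp], 0.75)),
            "center_green": center_green,
            "surface_green": surface_green,
        }
        cls = classify_features(feats, cfg)
        zc, yc, xc = ndi.center_of_mass(comp)
        proj = comp.any(axis=0)
        props = regionprops(proj.astype(np.uint8))
        ecc = float(props[0].eccentricity) if props else 0.0
        major = float(props[0].axis_major_length) * cfg.pixel_pitch_um if props else 0.0
        touches = bool(
            np.any(labels[:, [0, border_y], :] == idx)
            or np.any(labels[:, :, [0, border_x]] == idx)
        )
        records.append(
            VesicleRecord(
                label=idx,
                vesicle_class=cls,
                volume_voxels=volume,
                volume_um3=volume * VOXEL_VOLUME_UM3,
                centroid=(zc + sl[0].start, yc + sl[1].start, xc + sl[2].start),
                mean_red_raw=float(r[comp].mean()),
                mean_green_raw=float(g[comp].mean()),
                q3_green=feats["q3_green"],
                q3_red=feats["q3_red"],
                median_ratio=feats["median_ratio"],
                overlap_phluorin=feats["overlap_phluorin"],
                overlap_dsred=feats["overlap_dsred"],
                overlap_autolyso=feats["overlap_autolyso"],
                overlap_autophagosome=feats["overlap_autophagosome"],
                overlap_noncircular=feats["overlap_noncircular"],
                center_green=center_green,
                surface_green=surface_green,
                eccentricity=ecc,
                touches_border=touches,
                major_axis_um=major,
            )
        )
    return records


def records_to_frame(records: list[VesicleRecord]) -> pd.DataFrame:
    """Per-vesicle records as a tidy DataFrame (one row per vesicle)."""
    if not records:
        return pd.DataFrame(
            columns=[f.name for f in VesicleRecord.__dataclass_fields__.values()]
        )
    return pd.DataFrame([vars(rec) for rec in records])


def summarize_field(
    records: list[VesicleRecord],
    field_id: str = "",
    well_id: str = "",
    condition: str = "",
) -> FieldSummary:
    """Per-field counts, autophagic-vacuole sum and autophagy rate-constant.

    Autophagic vacuoles = autophagosomes + early autolysosomes + late
    autolysosomes; the rate-constant is phagophores / autophagic vacuoles
    (0 and flagged undefined when there are no vacuoles).
    """
    counts = {name: 0 for name in CLASS_NAMES}
    for rec in records:
        counts[rec.vesicle_class] += 1
    vacuoles = (
        counts["autophagosome"]
        + counts["early_autolysosome"]
        + counts["late_autolysosome"]
    )
    defined = vacuoles > 0
    rate = counts["phagophore"] / vacuoles if defined else 0.0
    return FieldSummary(
        field_id=field_id,
        well_id=well_id,
        condition=condition,
        n_phagophore=counts["phagophore"],
        n_autophagosome=counts["autophagosome"],
        n_early_autolysosome=counts["early_autolysosome"],
        n_late_autolysosome=counts["late_autolysosome"],
        n_unclassified=counts["unclassified"],
        autophagic_vacuoles=vacuoles,
        autophagy_rate=rate,
        rate_defined=defined,
        n_vesicles_total=len(records),
        counts=counts,
    )


def normalize_wells(
    per_well_counts: pd.DataFrame,
    clip: tuple[float, float] = (0.0, 2.0),
    mode: str = "clip",
) -> pd.DataFrame:
    """Category-mean normalised per-well frequencies on a 0-2 scale.

    Each column (category) is divided by its across-well mean; the result is
    clipped to ``clip`` (default) or min-max rescaled into it when
    ``mode='rescale'``.  Categories with zero mean are dropped with a
    warning.
    """
    import warnings

    out = {}
    for col in per_well_counts.columns:
        mean = per_well_counts[col].mean()
        if mean == 0:
            warnings.warn(f"category {col!r} has zero mean; excluded", stacklevel=2)
            continue
        scaled = per_well_counts[col] / mean
        if mode == "rescale":
            lo, hi = scaled.min(), scaled.max()
            span = hi - lo
            scaled = (
                pd.Series(np.full(len(scaled), clip[0]), index=scaled.index)
                if span == 0
                else clip[0] + (scaled - lo) / span * (clip[1] - clip[0])
            )
        else:
            scaled = scaled.clip(*clip)
        out[col] = scaled
    return pd.DataFrame(out, index=per_well_counts.index)
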