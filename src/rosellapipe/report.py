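"""Condition-level aggregation: per-well means, heatmap matrix, resource split."""

from __future__ import annotations

import pandas as pd

from .classify import normalize_wells
from .config import PipelineConfig
from .mitophagy import resource_split

__all__ = ["summaries_to_frame", "per_well_counts", "heatmap_matrix", "condition_resource_split"]

_COUNT_COLUMNS = [
    "n_phagophore",
    "n_autophagosome",
    "n_early_autolysosome",
    "n_late_autolysosome",
    "autophagic_vacuoles",
]


def summaries_to_frame(summaries) -> pd.DataFrame:
    """Field summaries (dataclasses) as one tidy DataFrame."""
    rows = []
    for s in summaries:
        row = {k: v for k, v in vars(s).items() if k != "counts"}
        rows.append(row)
    return pd.DataFrame(rows)


def per_well_counts(field_frame: pd.DataFrame) -> pd.DataFrame:
    """Mean per-field class counts per well (wells as rows)."""
    if field_frame.empty:
        raise ValueError("no field summaries to aggregate")
    return field_frame.groupby("well_id")[_COUNT_COLUMNS].mean()


def heatmap_matrix(field_frame: pd.DataFrame, cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Category-mean normalised per-well frequencies scaled to 0-2."""
    cfg = cfg or PipelineConfig()
    counts = per_well_counts(field_frame)
    return normalize_wells(counts, clip=cfg.heatmap_clip, mode=cfg.heatmap_mode)


def condition_resource_split(
    lc3_frame: pd.DataFrame,
    mito_frame: pd.DataFrame,
    basal_condition: str = "basal",
) -> pd.DataFrame:
    """Resource distribution per condition, relative to the basal reference.

    ``lc3_frame`` needs columns condition + autophagic_vacuoles;
    ``mito_frame`` needs condition + mitophagy_event_count.  Frequencies are
    per-field means within each condition.
    """
    lc3 = lc3_frame.groupby("condition")["autophagic_vacuoles"].mean()
    mito = mito_frame.groupby("condition")["mitophagy_event_count"].mean()
    if basal_condition not in lc3.index or basal_condition not in mito.index:
        raise ValueError(f"basal condition {basal_condition!r} missing from inputs")
    rows = []
    for condition in lc3.index:
        if condition not in mito.index:
            continue
        split = resource_split(
            lc3[condition], mito[condition], lc3[basal_condition], mito[basal_condition]
        )
        rows.append({"condition": condition, **split})
    return pd.DataFrame(rows)
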