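"""Field-level orchestration of the autophagy, mitophagy and lysotracker workflows."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autophagosomes import fourier_euler_detect, hough_detect, shape_filter_autophagosomes
from .classify import (
    FieldSummary,
    VesicleRecord,
    classify_vesicles,
    compute_noncircular_mask,
    pool_vesicles,
    records_to_frame,
    summarize_field,
)
from .config import PipelineConfig
from .filters import GaussianSpec, ratio_image
from .lysotracker import lysosome_sizes, segment_lysosomes
from .lysotracker import records_to_frame as lyso_frame
from .mitophagy import MitoMasks, MitophagySummary, detect_mitophagy, mito_volumes, segment_mitochondria
from .preprocessing import FlatfieldReference, PsfModel, deconvolve, flatfield_correct, generate_psf
from .segmentation import ChannelMasks, build_channel_masks
from .simulate import FieldStack

__all__ = [
    "FieldStack",
    "AutophagyResult",
    "MitophagyResult",
    "LysotrackerResult",
    "run_autophagy_field",
    "run_mitophagy_field",
    "run_lysotracker_field",
]

log = logging.getLogger("rosellapipe")


@dataclass
class AutophagyResult:
    records: list[VesicleRecord]
    summary: FieldSummary
    masks: ChannelMasks
    autophagosome_mask: np.ndarray
    noncircular_mask: np.ndarray
    labels: np.ndarray
    ratio: np.ndarray
    stage_log: dict = field(default_factory=dict)

    @property
    def vesicle_table(self) -> pd.DataFrame:
        return records_to_frame(self.records)


@dataclass
class MitophagyResult:
    masks: MitoMasks
    summary: MitophagySummary
    ratio: np.ndarray


@dataclass
class LysotrackerResult:
    mask: np.ndarray
    records: list
    deconvolved: np.ndarray

    @property
    def lysosome_table(self) -> pd.DataFrame:
        return lyso_frame(self.records)


def _psf_for(cfg: PipelineConfig, wavelength: float, nz: int) -> np.ndarray:
    model = PsfModel(
        wavelength_em=wavelength,
        numerical_aperture=cfg.psf_numerical_aperture,
        pixel_pitch=cfg.pixel_pitch_um,
        z_step=cfg.z_step_um,
        refractive_index=cfg.psf_refractive_index,
        support=(min(nz, 7), 17, 17),
    )
    return generate_psf(model)


def _preprocess(
    raw: np.ndarray,
    cfg: PipelineConfig,
    wavelength: float,
    flatfield: FlatfieldReference | None,
) -> np.ndarray:
    img = np.asarray(raw, dtype=np.float64)
    if flatfield is not None:
        img = flatfield_correct(img, flatfield)
    psf = _psf_for(cfg, wavelength, img.shape[0])
    return deconvolve(img, psf, iterations=cfg.deconvolution_iterations,
                      blind=cfg.deconvolution_blind)


def run_autophagy_field(
    stack: FieldStack,
    cfg: PipelineConfig | None = None,
    flatfield_green: FlatfieldReference | None = None,
    flatfield_red: FlatfieldReference | None = None,
    well_id: str = "",
    condition: str = "",
) -> AutophagyResult:
    """Full staging workflow on one dual-channel Rosella-LC3 field."""
    cfg = cfg or PipelineConfig()
    if stack.red is None:
        raise ValueError("autophagy staging needs both green and red channels")
    if stack.green.shape[0] != 5:
        log.warning("expected 5 z-planes for Rosella-LC3 fields, got %d",
                    stack.green.shape[0])
    green_raw = np.asarray(stack.green, dtype=np.float64)
    red_raw = np.asarray(stack.red, dtype=np.float64)
    if flatfield_green is not None:
        green_raw = flatfield_correct(green_raw, flatfield_green)
    if flatfield_red is not None:
        red_raw = flatfield_correct(red_raw, flatfield_red)

    green_dec = deconvolve(green_raw, _psf_for(cfg, cfg.psf_wavelength_green_nm, green_raw.shape[0]),
                           iterations=cfg.deconvolution_iterations, blind=cfg.deconvolution_blind)
    red_dec = deconvolve(red_raw, _psf_for(cfg, cfg.psf_wavelength_red_nm, red_raw.shape[0]),
                         iterations=cfg.deconvolution_iterations, blind=cfg.deconvolution_blind)

    ratio = ratio_image(green_raw, red_raw, GaussianSpec(*cfg.ratio_blur), cfg.ratio_eps)
    masks = build_channel_masks(green_dec, red_dec, ratio, green_raw, cfg)

    euler_mask = fourier_euler_detect(masks.green_dog, cfg)
    known = masks.dsred_mask | masks.phluorin_mask | masks.autolyso_mask | euler_mask
    hough_mask = hough_detect(green_raw, known, red_raw, cfg)
    autophagosome_mask = shape_filter_autophagosomes(
        euler_mask | hough_mask, green_dec, cfg
    )

    all_masks = masks.dsred_mask | masks.phluorin_mask | masks.autolyso_mask | autophagosome_mask
    labels = pool_vesicles(all_masks, autophagosome_mask, red_raw, cfg)
    noncircular = compute_noncircular_mask(labels, cfg)
    records = classify_vesicles(
        labels, masks, autophagosome_mask, noncircular, ratio, green_raw, red_raw, cfg
    )
    summary = summarize_field(records, field_id=stack.field_id,
                              well_id=well_id, condition=condition)
    stage_log = {
        "dsred_mask_voxels": int(np.count_nonzero(masks.dsred_mask)),
        "phluorin_mask_voxels": int(np.count_nonzero(masks.phluorin_mask)),
        "autolyso_mask_voxels": int(np.count_nonzero(masks.autolyso_mask)),
        "euler_candidate_voxels": int(np.count_nonzero(euler_mask)),
        "hough_candidate_voxels": int(np.count_nonzero(hough_mask)),
        "autophagosome_voxels": int(np.count_nonzero(autophagosome_mask)),
        "n_vesicles": len(records),
    }
    return AutophagyResult(
        records=records, summary=summary, masks=masks,
        autophagosome_mask=autophagosome_mask, noncircular_mask=noncircular,
        labels=labels, ratio=ratio, stage_log=stage_log,
    )


def run_mitophagy_field(
    stack: FieldStack,
    cfg: PipelineConfig | None = None,
    flatfield_green: FlatfieldReference | None = None,
    flatfield_red: FlatfieldReference | None = None,
    condition: str = "",
) -> MitophagyResult:
    """Mitochondrial network + mitophagy events on one ATP5C1-Rosella field."""
    cfg = cfg or PipelineConfig()
    if stack.red is None:
        raise ValueError("mitophagy staging needs both green and red channels")
    if stack.green.shape[0] != 11:
        log.warning("expected 11 z-planes for ATP5C1-Rosella fields, got %d",
                    stack.green.shape[0])
    green_raw = np.asarray(stack.green, dtype=np.float64)
    red_raw = np.asarray(stack.red, dtype=np.float64)
    if flatfield_green is not None:
        green_raw = flatfield_correct(green_raw, flatfield_green)
    if flatfield_red is not None:
        red_raw = flatfield_correct(red_raw, flatfield_red)
    ratio = ratio_image(green_raw, red_raw, GaussianSpec(*cfg.ratio_blur), cfg.ratio_eps)
    masks = segment_mitochondria(red_raw, cfg)
    detect_mitophagy(masks, ratio, red_raw, cfg)
    summary = mito_volumes(masks, field_id=stack.field_id, condition=condition, cfg=cfg)
    return MitophagyResult(masks=masks, summary=summary, ratio=ratio)


def run_lysotracker_field(
    stack: FieldStack,
    cfg: PipelineConfig | None = None,
    flatfield: FlatfieldReference | None = None,
) -> LysotrackerResult:
    """Lysotracker vesicle segmentation + sizing on a single-channel field."""
    cfg = cfg or PipelineConfig()
    raw = np.asarray(stack.green, dtype=np.float64)
    if flatfield is not None:
        raw = flatfield_correct(raw, flatfield)
    dec = deconvolve(raw, _psf_for(cfg, cfg.psf_wavelength_lysotracker_nm, raw.shape[0]),
                     iterations=cfg.deconvolution_iterations, blind=cfg.deconvolution_blind)
    mask = segment_lysosomes(dec, cfg)
    records = lysosome_sizes(mask, cfg)
    return LysotrackerResult(mask=mask, records=records, deconvolved=dec)
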