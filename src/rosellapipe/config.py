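"""Pipeline configuration: every numeric parameter of every stage.

Default values are the platform's reference analysis parameters; each field
name is prefixed with the mask it feeds.  Gaussian kernels are given as
``(size_px, sd_px)`` pairs.  The config round-trips losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # --- geometry -------------------------------------------------------
    pixel_pitch_um: float = 0.2152
    z_step_um: float = 0.4
    connectivity_3d: int = 26
    connectivity_2d: int = 8

    # --- preprocessing --------------------------------------------------
    deconvolution_iterations: int = 10
    deconvolution_blind: bool = False
    psf_wavelength_green_nm: float = 520.0
    psf_wavelength_red_nm: float = 600.0
    psf_wavelength_lysotracker_nm: float = 690.0
    psf_numerical_aperture: float = 1.2
    psf_refractive_index: float = 1.33
    flatfield_smoothing_sigma: float = 20.0

    # --- dsRedMask ------------------------------------------------------
    dsred_dog_fg: tuple = (20, 1.0)
    dsred_dog_bg: tuple = (20, 7.0)
    dsred_dog_threshold: float = 400.0
    dsred_tophat_radius: int = 25
    dsred_tophat_threshold: float = 1200.0
    dsred_substitution_min_size: int = 500
    dsred_substitution_overlap: float = 0.10
    dsred_dog2_fg: tuple = (11, 1.0)
    dsred_dog2_bg: tuple = (25, 6.0)
    dsred_dog2_threshold: float = 1000.0
    dsred_dog2_min_size: int = 200
    dsred_dog2_max_size: int = 2000

    # --- pHluorinMask ---------------------------------------------------
    green_dog_fg: tuple = (100, 1.0)
    green_dog_bg: tuple = (100, 5.0)
    green_dog_threshold: float = 1000.0
    green_log_size: int = 20
    green_log_sd: float = 1.0
    green_log_threshold: float = -2000.0
    phluorin_min_size: int = 10

    # --- RatioIm / AutoLysoMask ----------------------------------------
    ratio_blur: tuple = (5, 2.0)
    ratio_eps: float = 1.0
    autolyso_tophat_radius: int = 15
    autolyso_threshold: float = 1.5
    autolyso_dilation_radius: int = 7
    autolyso_brightness_factor: float = 1.5
    autolyso_min_volume: int = 100

    # --- hollow-vesicle (autophagosome) detection ----------------------
    butterworth_cutoff: float = 10.0
    butterworth_order: int = 5
    euler_threshold: float = 150.0
    euler_min_area: int = 20
    euler_opening_radius: int = 1
    euler_proportion_ratio: float = 1.01
    euler_proportion_difference: int = 20
    euler_background_size: int = 10000
    euler_restore_opening_radius: int = 5
    hough_erosion_radius: int = 2
    hough_radius_stages: tuple = ((3, 15), (16, 30))
    hough_max_circles_per_stage: int = 20
    hough_accumulator_threshold: float = 0.35
    hough_canny_sigma: float = 2.0
    hough_mad_threshold: float = 20.0
    hough_red_quantile: float = 0.9
    hough_red_quantile_threshold: float = 300.0
    autophagosome_min_volume: int = 50
    autophagosome_max_volume: int = 10000
    sphericity_idx1_threshold: float = 1.0
    sphericity_idx2_threshold: float = 1.5

    # --- classification -------------------------------------------------
    vesicle_min_mean_red: float = 300.0
    noncircular_eccentricity: float = 0.9
    overlap_threshold: float = 0.25
    phagophore_median_ratio: float = 2.0
    phagophore_q3_green: float = 7500.0
    phagophore_q3_red: float = 4000.0
    phagophore_center_factor: float = 1.25
    late_phluorin_overlap: float = 0.10
    late_median_ratio: float = 2.0

    # --- mitophagy ------------------------------------------------------
    mito_dog_fg: tuple = (50, 1.0)
    mito_dog_bg: tuple = (50, 2.0)
    mito_threshold: float = 12.0
    mitophagy_ratio_threshold: float = 0.6
    mitophagy_dog_fg: tuple = (50, 1.0)
    mitophagy_dog_bg: tuple = (50, 5.0)
    mitophagy_limit_threshold: float = 50.0

    # --- lysotracker ----------------------------------------------------
    lyso_dog_fg: tuple = (100, 1.0)
    lyso_dog_bg: tuple = (100, 5.0)
    lyso_dog_threshold: float = 2000.0
    lyso_log_size: int = 20
    lyso_log_sd: float = 1.0
    lyso_log_threshold: float = -2000.0
    lyso_min_size: int = 10

    # --- reporting ------------------------------------------------------
    heatmap_clip: tuple = (0.0, 2.0)
    heatmap_mode: str = "clip"  # "clip" or "rescale"

    def to_yaml(self, path=None) -> str:
        def _plain(value):
            if isinstance(value, tuple):
                return [_plain(v) for v in value]
            return value

        data = {k: _plain(v) for k, v in asdict(self).items()}
        text = yaml.safe_dump(data, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        import os

        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        elif os.path.exists(str(source)):
            with open(source) as fh:
                data = yaml.safe_load(fh)
        else:
            data = yaml.safe_load(str(source))
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")

        def _restore(name, value):
            if isinstance(value, list):
                return tuple(
                    tuple(v) if isinstance(v, list) else v for v in value
                )
            return value

        return cls(**{k: _restore(k, v) for k, v in data.items()})
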