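pixel_pitch_um: 0.2152
z_step_um: 0.4
connectivity_3d: 26
connectivity_2d: 8
deconvolution_iterations: 10
deconvolution_blind: false
psf_wavelength_green_nm: 520.0
psf_wavelength_red_nm: 600.0
psf_wavelength_lysotracker_nm: 690.0
psf_numerical_aperture: 1.2
psf_refractive_index: 1.33
flatfield_smoothing_sigma: 20.0
dsred_dog_fg:
- 20
- 1.0
dsred_dog_bg:
- 20
- 7.0
dsred_dog_threshold: 400.0
dsred_tophat_radius: 25
dsred_tophat_threshold: 1200.0
dsred_substitution_min_size: 500
dsred_substitution_overlap: 0.1
dsred_dog2_fg:
- 11
- 1.0
dsred_dog2_bg:
- 25
- 6.0
dsred_dog2_threshold: 1000.0
dsred_dog2_min_size: 200
dsred_dog2_max_size: 2000
green_dog_fg:
- 100
- 1.0
green_dog_bg:
- 100
- 5.0
green_dog_threshold: 1000.0
green_log_size: 20
green_log_sd: 1.0
green_log_threshold: -2000.0
phluorin_min_size: 10
ratio_blur:
- 5
- 2.0
ratio_eps: 1.0
autolyso_tophat_radius: 15
autolyso_threshold: 1.5
autolyso_dilation_radius: 7
autolyso_brightness_factor: 1.5
autolyso_min_volume: 100
butterworth_cutoff: 10.0
butterworth_order: 5
euler_threshold: 150.0
euler_min_area: 20
euler_opening_radius: 1
euler_proportion_ratio: 1.01
euler_proportion_difference: 20
euler_background_size: 10000
euler_restore_opening_radius: 5
hough_erosion_radius: 2
hough_radius_stages:
- - 3
  - 15
- - 16
  - 30
hough_max_circles_per_stage: 20
hough_accumulator_threshold: 0.35
hough_canny_sigma: 2.0
hough_mad_threshold: 20.0
hough_red_quantile: 0.9
hough_red_quantile_threshold: 300.0
autophagosome_min_volume: 50
autophagosome_max_volume: 10000
sphericity_idx1_threshold: 1.0
sphericity_idx2_threshold: 1.5
vesicle_min_mean_red: 300.0
noncircular_eccentricity: 0.9
overlap_threshold: 0.25
phagophore_median_ratio: 2.0
phagophore_q3_green: 7500.0
phagophore_q3_red: 4000.0
phagophore_center_factor: 1.25
late_phluorin_overlap: 0.1
late_median_ratio: 2.0
mito_dog_fg:
- 50
- 1.0
mito_dog_bg:
- 50
- 2.0
mito_threshold: 12.0
mitophagy_ratio_threshold: 0.6
mitophagy_dog_fg:
- 50
- 1.0
mitophagy_dog_bg:
- 50
- 5.0
mitophagy_limit_threshold: 50.0
lyso_dog_fg:
- 100
- 1.0
lyso_dog_bg:
- 100
- 5.0
lyso_dog_threshold: 2000.0
lyso_log_size: 20
lyso_log_sd: 1.0
lyso_log_threshold: -2000.0
lyso_min_size: 10
heatmap_clip:
- 0.0
- 2.0
heatmap_mode: clip
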