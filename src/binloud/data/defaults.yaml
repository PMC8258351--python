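# Default configuration of the binloud loudness model.
# Pass a (partial) copy of this file to `binloud <cmd> --config` to override.

# ---- excitation front end -------------------------------------------------
n_segments: 1000            # basilar-membrane segments (equidistant place axis)
place_fmin_hz: 40.0         # apical corner of the place-frequency map
place_fmax_hz: 20000.0      # basal corner of the place-frequency map
tau_s: 0.025                # temporal-integration time constant (25 ms)
frame_rate_hz: 200.0        # frame rate after temporal integration
compression_exponent: 0.3   # dB/dB growth of the normal-hearing I/O function
compression_rejoin_db: 100.0  # sensation level where impaired I/O rejoins NH
max_cochlear_gain_db: 35.0  # cap on the OHC-loss share of an audiogram
spread_lower_db_per_oct: 27.0
spread_upper_db_per_oct_base: 27.0
spread_upper_level_coeff: 0.2
spread_upper_db_per_oct_min: 6.0
internal_floor_db: -100.0
specific_loudness_exponent: 0.5  # compresses the supra-threshold excitation

# ---- gain stages ----------------------------------------------------------
w_max: 1000.0               # cap of the bandwidth estimator (uniform vectors)
alpha_b_default: -0.273     # average normal-hearing binaural gain
alpha_b_bounds: [-0.5, 1.0] # fitting bounds for alpha_B (lower bound -0.5)
beta_bounds: [-0.5, 2.0]    # fitting bounds for beta_L, beta_R, beta_B

# ---- loudness-function fitting --------------------------------------------
fixed_upper_slope: 0.7      # CU/dB when < 5 data points lie in 35-50 CU
min_points_upper: 5
slope_bounds: [0.01, 10.0]

# ---- CU <-> sone transform (log10-cubic around 25 CU) -----------------------
sone_transform_coeffs: [0.60206, 0.09, -0.0016, 1.8e-05, 25.0]

# ---- internal loudness -> sone power law (set by calibration) ---------------
sone_scale: 1.0
sone_exponent: 1.0
calibrated: false

# ---- fitting / simulation ---------------------------------------------------
level_grid_db: [0.0, 115.0, 1.5]
aided_gain_cap_db: 60.0
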