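# Cultivar coefficient presets for wheat cv. PBW343.
# The two presets differ ONLY in tt_floral_initiation (400 vs 450 degC d):
# mulch lowers soil temperature and delays anthesis by roughly a week, an
# effect the model represents through this single coefficient rather than
# mechanistically.  All other values are shared calibration constants.
pbw343_bare:
  startgf_to_mat: 750.0        # degC d, anthesis to physiological maturity
  tt_floral_initiation: 400.0  # degC d, emergence to floral initiation
  vern_sens: 1.7
  photop_sens: 3.8
  trap_x: [0.0, 26.0, 30.0, 40.0]   # cardinal temperatures, degC
  trap_y: [0.0, 26.0, 26.0, 0.0]    # thermal time response, degC d per day
  rue: 1.24                    # g biomass per MJ intercepted
  extinction_k: 0.50
  grains_per_g_stem: 37.5      # grains per g stem biomass at anthesis
  max_grain_wt_mg: 41.0
  grain_fill_rate_mg_degday: 0.050   # mg per grain per degC d, unstressed
  stem_frac_at_anthesis: 0.60
  tt_emergence_base: 80.0      # degC d plus 10 per cm sowing depth
  tt_per_cm_sowing_depth: 10.0
  tt_floral_to_anthesis: 550.0 # stem elongation through heading, degC d
  lai_expansion_per_degday: 0.012  # logistic canopy expansion rate, per degC d
  lai_max: 6.0
  lai_at_emergence: 0.05
  root_front_velocity_mm_day: 15.0
  max_root_depth_mm: 1800.0
  rue_temp_threshold: 26.0     # degC; RUE declines linearly above this
  rue_temp_cut: 40.0           # degC; RUE reaches zero here
  fill_heat_threshold: 34.0    # degC; grain filling penalised above this
  fill_heat_slope: 0.04        # f_fill = 1 - slope*(tmax - 34)
  senescence_accel: 0.08       # extra fractional thermal time per degC > 34
  stay_green_frac: 0.4         # fraction of grain fill with full green canopy
  max_harvest_index: 0.55
pbw343_mulch:
  inherits: pbw343_bare
  tt_floral_initiation: 450.0
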