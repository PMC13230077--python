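# Default model inputs for the cost-utility comparison of ezetimibe added to
# moderate-intensity statin therapy versus moderate-intensity statin therapy
# alone, for secondary prevention after acute coronary syndrome (ACS) in a
# Thai cohort intolerant to high-intensity statins.
#
# Costs are 2024 Thai baht (THB). Annual drug costs are daily acquisition
# prices x 365 (see metadata). Intervals are 95% uncertainty intervals used
# both for one-way sensitivity ranges and for fitting sampling distributions.
metadata:
  description: >
    Four-state Markov cohort model inputs: annual event probabilities per
    treatment arm, mortality adjustments, annual costs in 2024 THB, and
    EQ-5D-based utilities.
  currency: "THB (2024)"
  statin_daily_cost_thb: 0.80
  ezetimibe_daily_cost_thb: 4.74

parameters:
  # --- Annual event probabilities, moderate-intensity statin alone ---
  p_mi_statin:      {base: 0.016900, low: 0.0152, high: 0.0186, dist: beta, role: probability}
  p_stroke_statin:  {base: 0.005415, low: 0.0049, high: 0.0060, dist: beta, role: probability}
  # --- Annual event probabilities, ezetimibe + moderate-intensity statin ---
  p_mi_ez:          {base: 0.014779, low: 0.0133, high: 0.0163, dist: beta, role: probability}
  p_stroke_ez:      {base: 0.004653, low: 0.0042, high: 0.0051, dist: beta, role: probability}
  # --- Annual case fatality in the post-event states (both arms) ---
  p_death_mi:       {base: 0.090263, low: 0.0812, high: 0.0993, dist: beta, role: probability}
  p_death_stroke:   {base: 0.071593, low: 0.0644, high: 0.0788, dist: beta, role: probability}
  # --- Mortality adjustments ---
  # ln(HR) for post-ACS excess mortality in the no-further-event state
  # (HR = 2.0); the interval is on the log scale.
  log_hr_excess:    {base: 0.693, low: 0.62, high: 0.76, dist: lognormal, role: log_hazard_ratio}
  rr_death_mi:      {base: 0.840, low: 0.55, high: 1.07, dist: lognormal, role: relative_risk}
  rr_death_stroke:  {base: 0.900, low: 0.84, high: 0.96, dist: lognormal, role: relative_risk}
  rr_death_any:     {base: 0.990, low: 0.91, high: 1.07, dist: lognormal, role: relative_risk}
  # --- Annual drug costs (THB/year) ---
  cost_statin_annual: {base: 292,   low: 234,    high: 350,    dist: gamma, role: cost}
  cost_ez_annual:     {base: 1730,  low: 1384,   high: 2075,   dist: gamma, role: cost}
  # --- Annual treatment costs (THB/year) ---
  cost_acs_y1:        {base: 65507, low: 45174,  high: 67762,  dist: gamma, role: cost}
  cost_acs_y2plus:    {base: 39617, low: 27320,  high: 40980,  dist: gamma, role: cost}
  cost_mi_y1:         {base: 148366, low: 102314, high: 153472, dist: gamma, role: cost}
  cost_mi_y2plus:     {base: 15924, low: 10982,  high: 16472,  dist: gamma, role: cost}
  cost_stroke_y1:     {base: 73440, low: 50645,  high: 75967,  dist: gamma, role: cost}
  cost_stroke_y2plus: {base: 11634, low: 8023,   high: 12035,  dist: gamma, role: cost}
  # --- Direct non-medical costs (THB/year, societal perspective only) ---
  cost_dnm_y1:        {base: 3730,  low: 2572,   high: 3858,   dist: gamma, role: cost}
  cost_dnm_y2plus:    {base: 5394,  low: 3720,   high: 5580,   dist: gamma, role: cost}
  # --- Utilities ---
  u_acs:            {base: 0.82,    low: 0.738,  high: 0.902,  dist: beta,  role: utility}
  dec_mi:           {base: 0.41635, low: 0.3747, high: 0.458,  dist: gamma, role: utility_decrement}
  dec_stroke:       {base: 0.2259,  low: 0.2033, high: 0.2485, dist: gamma, role: utility_decrement}

settings:
  start_age: 62
  max_age: 100
  cycle_length: 1.0
  discount_rate_costs: 0.03
  discount_rate_outcomes: 0.03
  wtp: 160000
  perspective: societal
  psa_iterations: 1000
  rng_seed: 12345
  half_cycle: true
  exchange_rate_thb_per_usd: 35.2952
  post_event_mortality: max
  acs_cost_states: no_event_only
  discount_timing: mid
  psa_link_arms: false
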