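# Default model configuration: published inputs for the Italian SPMS
# cost-effectiveness and budget-impact analyses, with synthetic stand-ins
# for the inputs that were never published (natural-history transition
# matrix, background life table, baseline discontinuation, adverse-event
# costs, market shares).  All numbers use plain-dot decimal notation.
locale: dot

cohort:
  start_age: 48.0
  male_fraction: 0.399
  baseline_distribution_pct:
    edss0: 0.0
    edss1: 0.0
    edss2: 0.49
    edss3: 9.32
    edss4: 18.59
    edss5: 16.09
    edss6: 55.33
    edss7: 0.18
    edss8: 0.0
    edss9: 0.0

clinical:
  relapse_probability:
    edss0: 0.0
    edss1: 0.0
    edss2: 0.465
    edss3: 0.161
    edss4: 0.218
    edss5: 0.168
    edss6: 0.126
    edss7: 0.276
    edss8: 0.276
    edss9: 0.276
  mortality_multipliers:
    edss0: {value: 1.00, low: 0.80, high: 1.20}
    edss1: {value: 1.43, low: 1.14, high: 1.72}
    edss2: {value: 1.60, low: 1.28, high: 1.92}
    edss3: {value: 1.64, low: 1.31, high: 1.97}
    edss4: {value: 1.67, low: 1.34, high: 2.00}
    edss5: {value: 1.84, low: 1.47, high: 2.21}
    edss6: {value: 2.27, low: 1.82, high: 2.72}
    edss7: {value: 3.10, low: 2.48, high: 3.72}
    edss8: {value: 4.45, low: 3.56, high: 5.34}
    edss9: {value: 6.45, low: 5.16, high: 7.74}

utilities:
  edss0: {value: 0.832, low: 0.646, high: 0.957}
  edss1: {value: 0.791, low: 0.620, high: 0.920}
  edss2: {value: 0.737, low: 0.583, high: 0.866}
  edss3: {value: 0.651, low: 0.520, high: 0.771}
  edss4: {value: 0.582, low: 0.467, high: 0.693}
  edss5: {value: 0.501, low: 0.403, high: 0.598}
  edss6: {value: 0.412, low: 0.333, high: 0.494}
  edss7: {value: 0.300, low: 0.243, high: 0.360}
  edss8: {value: -0.041, low: -0.049, high: -0.033}
  edss9: {value: -0.214, low: -0.257, high: -0.174}

costs:
  management:
    edss0_3: {value: 2102.0, low: 1720.0, high: 2543.0}
    edss4_6: {value: 4822.0, low: 3946.0, high: 5834.0}
    edss7_9: {value: 8052.0, low: 6589.0, high: 9742.0}
  relapse: 405.0

arms:
  reference:
    name: interferon beta-1b
    hr_cdp6: {value: 0.93, low: 0.71, high: 1.20}
    rr_arr: {value: 0.65, low: 0.48, high: 0.88}
    hr_cdp3: {value: 0.74, low: 0.60, high: 0.91}
    # Extavia ex-factory price; Betaferon's per-vial price differs by <0.01 EUR.
    drug: {price_ex_factory: 285.3, pack_size: 5, annual_units: 182.625}
    admin_monitoring: {year1: 1137.0, later: 412.0}
  intervention:
    name: siponimod
    hr_cdp6: {value: 0.50, low: 0.35, high: 0.74}
    rr_arr: {value: 0.59, low: 0.35, high: 0.99}
    hr_discontinuation: {value: 0.87, low: 0.64, high: 1.18}
    hr_cdp3: {value: 0.61, low: 0.32, high: 1.16}
    drug: {price_ex_factory: 1890.9, pack_size: 28, annual_units: 365.25}
    admin_monitoring: {year1: 1272.0, later: 309.0}

settings:
  discount_rate: 0.03
  wtp: 40000.0
  max_age: 100.0
  stop_edss: 7

# Natural-history matrix and life table: synthetic by default; point "csv"
# at files (relative to this config) to load external inputs instead.
transition_matrix: {synthetic: true}
life_table: {synthetic: true}

# Synthetic-input generator settings; every value here is a stand-in with
# no published provenance (see docs/methods.md for the calibration).
synthetic:
  seed: 0
  progression_intensity: 0.30
  improvement_intensity: 0.04
  progression_gradient: 0.97
  jump_fraction: 0.15
  jitter_sd: 0.05
  gompertz_a: 1.65e-5
  gompertz_b: 0.10
  male_mortality_factor: 1.6
  baseline_discontinuation: 0.10
  uptake_rate: 1.0
  uptake_ceiling: 0.42
  sipo_count_year1: 405
  sipo_count_year3: 2236
  calibration_eligible: 5827
  ifn_displacement: [0.012, 0.016, 0.0]

funnel:
  national_population: 59641488
  ms_prevalence: 0.002
  spms_share: 0.137
  age_edss_share: 0.918
  active_share: 0.60
  treated_share: 0.65
  eligible_share: 0.996

bia:
  horizon: 3
  dmts:
    # 600 mg every 6 months priced per 330 mg vial: 2 vials per
    # administration, 4 vials per year.
    ocrelizumab:
      drug: {price_ex_factory: 6250.0, pack_size: 1, annual_units: 4}
      admin_monitoring: {year1: 1150.0, later: 363.0}
      ae_cost_annual: 200.0
    untreated: {}
  scenarios: {synthetic: true}
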