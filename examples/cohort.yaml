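# Example run configuration for `ffcrelax run`.
# Every key shown with its default; remove a line to keep the default.

acquisition:
  n_fields: 70          # evolution fields per profile
  f_lo: 1.0e+4           # Hz, lowest proton Larmor frequency
  f_hi: 1.0e+7           # Hz, highest
  dense_lo: 4.0e+5       # Hz, dense-band start (quadrupole-peak region)
  dense_hi: 3.5e+6       # Hz, dense-band end
  n_dense_extra: 30     # extra points inside the dense band
  noise_lo: 0.01        # per-profile relative noise, lower bound
  noise_hi: 0.04        # upper bound

cohort:
  n_patients: 10
  n_tumour: 2           # tumour samples per patient
  n_adjacent_muscle: 1  # muscle directly next to the tumour
  n_muscle: 1           # muscle >= 3 cm away (remote)
  n_fat: 1
  myxoid_prob: 0.4            # probability a patient's tumour is myxoid
  effect_myxoid: -0.71        # additive shift of myxoid tumour factors
  effect_proximity: 1.21      # multiplier on adjacent-muscle factors
  tumour_factor_mean: 1.5     # baseline tumour factor (longer T1)
  scaling_factor_sd: 0.15     # patient-level log-normal spread

scaling:
  f_min_hz: 4.0e+6       # high-field cut-off, inclusive
  reference: null       # null = first muscle sample of the cohort

fit:
  n_starts: 5
  error_floor: 0.01     # relative sigma floor for zero-error points
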