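# Example study configuration: 14-day evaluation scenario with four
# daily meals (07:00 breakfast 30-50 g, 13:00 lunch 50-70 g, 17:00 snack
# 30-50 g, 20:00 dinner 60-80 g), +/-30 min meal-time jitter, circadian
# insulin-sensitivity variability, random meal absorption rates, and
# CGM sensor noise.
#
#   faidsim train    --config examples/experiment.yaml --mode faid --out banks
#   faidsim simulate --arm FAID --config examples/experiment.yaml --banks banks
#   faidsim simulate --arm HAID_SBC_MCHO --config examples/experiment.yaml
#   faidsim report   --compare FAID HAID_SBC_MCHO

arm: FAID
n_patients: 3
days: 14
seed: 1

detector_mode: trade_off     # highest_sensitivity | trade_off | lowest_fp

# carbohydrate misestimation of the SBC baseline arm (multiplicative
# Gaussian error on the announced CHO)
cho_mu: 0.0
cho_sigma: 0.2

# intra-patient variability
si_amplitude: 0.3            # fractional circadian swing of insulin sensitivity
absorption_cv: 0.2           # CV of the per-meal absorption-rate multiplier
cgm_noise_sd: 2.0            # mg/dL

train:
  gamma: 0.9
  alpha: 0.001
  epsilon_start: 1.0
  epsilon_end: 0.05
  batch_size: 32
  target_sync_period: 15
  memory_days: 300           # random-action days filling the replay memories
  train_iterations: 600      # epsilon-greedy training days
  k_bob: 1.0
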