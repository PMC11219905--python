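# Methods

`faidsim` simulates fully automatic insulin delivery (FAID) for type 1
diabetes at desk scale: a virtual patient, a PD controller with an
insulin-on-board (IOB) safety layer, an unscented-Kalman-filter (UKF)
meal detector, and a bank of deep Q-networks (DQNs) that size meal
boluses without carbohydrate information. This note records the models,
the parameter choices, and the limits of what the synthetic experiments
can show.

## Virtual patient

The plant is an extended Bergman minimal model with states
(G_pl, G_s, X, I, S1, S2, M1, M2):

- **Glucose.** dG_pl/dt = −(p1 + X)·G_pl + p1·G_bl + D/V_g, where D is
  the meal appearance flux. The subcutaneous (sensor) glucose G_s tracks
  G_pl through a first-order lag (τ_s = 10 min, unit gain).
- **Insulin.** A two-compartment subcutaneous chain S1 → S2 (time
  constant t_maxI = 55 min) feeds plasma insulin I, which decays at
  k_f = 0.138 min⁻¹. Remote insulin action follows
  dX/dt = −p2·X + p3·(I − I_b), with I_b the plasma insulin sustained by
  the basal rate. Using the *deviation* from basal insulin (rather than
  absolute insulin) makes the pair (G_bl, u_bl) an exact equilibrium of
  the closed loop, which anchors every steady-state test; withdrawing
  insulin entirely sends glucose to the hyperglycemic fixed point
  p1·G_bl/(p1 − p3·I_b/p2) ≈ 370 mg/dL.
- **Meals.** A two-compartment absorption chain with time-to-peak
  40 min and bioavailability 0.8; the per-meal absorption-rate
  multiplier rescales the chain's time constant.

Default parameters (p1 = 0.015 min⁻¹, p2 = 0.028 min⁻¹,
p3 = 4·10⁻⁵ min⁻¹ per mU/L, V_g = 110 dL, G_bl = 130 mg/dL, TDI = 40 U,
u_bl = 0.9 U/h) were fixed once against three plausibility targets for
an adult with type 1 diabetes: an unannounced 60 g meal from basal peaks
near 280–300 mg/dL; a guideline meal bolus (500-rule) holds the peak
near 200 mg/dL with a trough well above 70; and a 2× bolus overdose
produces frank hypoglycemia (trough ≈ 55 mg/dL) under open-loop basal.
A cohort is generated by log-normal jitter (CV 15%) of the rate and
volume parameters around these defaults, with the basal rate re-derived
as half the jittered TDI.

Intra-patient variability: sinusoidal circadian modulation of p3
(default amplitude 30%, sensitivity minimum near 06:00), log-normal
per-meal absorption multipliers (CV 20%), and additive Gaussian CGM
noise (SD 2 mg/dL, the MARD ≤ 10% sensor class). CGM samples arrive
every 5 min; the ODEs integrate with 1-min fixed-step RK4 (halving the
step changes 24-h trajectories by < 0.1%).

What the generator does **not** emulate: exercise, stress, medication,
sensor dropouts/drift, pump occlusions, protein/fat meal effects, and
the day-scale parameter drift of real physiology. Passing tests
demonstrate internal consistency of the control and learning machinery
under the stated variability — not clinical performance.

## Controller

- **PD law** on the CGM error with derivative time τ_d = 90 min and
  gain k_p = 60·TDI/(τ_d·1500) U/h per mg/dL; the glucose derivative is
  a one-sample (5-min) backward difference. A bolus is injected as a
  one-step impulse added to the infusion command.
- **IOB model**: dc1/dt = u − k_dia·c1, dc2/dt = k_dia·(c1 − c2),
  IOB = c1 + c2, advanced with the exact linear-system discretisation.
  k_dia = 0.02 min⁻¹ gives ≈ 4 h duration of insulin action.
- **SAFE layer** (sliding-mode reference conditioning): surface
  s = (IOB − IOB_max) + τ_sm·dIOB/dt with a constant bound
  (IOB_max = 1.5 × hourly-basal × 4 h by default, so its derivative is
  zero), switching amplitude ν⁺ = 100 mg/dL, first-order filter rate
  λ = 0.05 min⁻¹. The filtered signal raises the reference from
  G_ref = 120 mg/dL to a virtual reference, which suspends dosing.
- **Insulin feedback**: the command is reduced by η·(î_p − î_pss) where
  î_p is propagated through the same insulin submodel driven by the
  delivered dose; η = 0.05 U/h per mU/L by default.

## Meal detector

A UKF (scaled unscented transform, α = 10⁻³, β = 2, κ = 0) estimates
the seven-state augmented model [G_pl, G_s, X, I, S1, S2, D] in which
the disturbance D — the unknown meal flux — is a random walk (per-step
SD 15 mg/min). The estimate is floored at zero: meals only add glucose.
The trigger computes the raw (biased, mean-removed) cross-covariance
between the buffered CGM sequence and the forward-differenced
disturbance estimate over an 18-sample (90-min) window, maximised over
non-negative lags; a meal is flagged after three consecutive
above-threshold samples with a rising disturbance and a positive 15-min
CGM difference, outside the night window [23:00, 06:00), with a 2-h
refractory hold-off per flag.

The three named tunings map to thresholds calibrated on clean synthetic
traces (a separate `faidsim calibrate-detector` sweep):
`highest_sensitivity` T = 40, `trade_off` T = 110, `lowest_fp` T = 250.
At the trade-off point the detector finds essentially all 60 g meals of
the default patient with ≈ 0–0.2 false positives/day and a median delay
of ~35 min; harder cohort members detect later and less completely, as
real detectors do.

## DRL bolus calculator

24 DQNs per patient — 3 meals × 8 subaction spaces (SAS) banded by the
pre-meal CGM value. Each network is a fully connected 15-28-28-28-15
ReLU net over the state (window maximum, minimum, the last hour's 12
CGM samples, and the out-of-range AUC of the 4-h window; inputs scaled
by fixed constants 200 mg/dL and 5000 mg/dL·min). The 15 discrete
actions per SAS span 0 to 1.8× the patient's 500-rule meal bolus,
shifted upward in the hyperglycemic bands by half a 1800-rule
correction. Chosen boluses pass through the bolus-on-board adjustment
(subtract the BOB ratio when hyperglycemic, trim 5/10/20% otherwise per
the banded rules) with k_BOB = 1 by default.

Training is classic DQN: per-network replay memories filled by a
uniform-random simulation, epsilon-greedy acting (linear anneal
1.0 → 0.05), one uniform mini-batch (32) squared-Bellman-error update
per meal event with Adam at α = 10⁻³, γ = 0.9, and target networks
synchronised every 15 iterations (one iteration = one simulated day).
Two numerical choices matter:

- **Zero-initialised output layers.** An agent that has never been
  updated returns identical Q-values, and the greedy tie-break (lowest
  index = smallest bolus) then makes untrained agents maximally
  conservative. This is the single most important safety choice in the
  package: rarely visited (meal, SAS) pairs — e.g. the dinner-bank
  networks that field snack detections — otherwise dose arbitrarily
  from their random initialisation.
- **Reward windows.** The 4-h postprandial window is truncated at the
  next bolus event; windows shorter than 65 min are not graded.
  Hypoglycemia anywhere in the window takes precedence over the
  hyperglycemia branches, exactly as the reward table prescribes.

Hybrid-mode (announced) agents are trained with boluses at true meal
times; fully-automatic agents are trained with the detector in the
loop, so they learn from the elevated-glucose states that detection
latency actually produces. Detections are routed to meal banks by
time-of-day bins ([05, 11) / [11, 17) / [17, 23) h, with night hours to
the nearest meal); the 17:00 snack therefore uses the dinner bank —
with the conservative initialisation its boluses stay small and the PD
loop absorbs most of the snack, mirroring how small meals are handled
when detection is unavailable.

A hypoglycemia *event* is ≥ 15 consecutive minutes of CGM < 70 mg/dL
(ADA convention).

## Study arms and problem sizes

Three arms share the PD+SAFE+IFB loop: `HAID_SBC_MCHO` (announced
meals, standard bolus calculator CHO/CR + (BG−BG_T)/CF − IOB with CR =
500/TDI, CF = 1800/TDI, BG_T = 120, and Gaussian CHO misestimation of
20% CV), `HAID_DRL` (announced meals, DQN bolus), and `FAID`
(detector-triggered DQN bolus; true meal times visible only to the
scorer). Evaluation runs 14 days of the four-meal jittered protocol.

Desk-scale problem sizes, chosen so the whole suite runs on one CPU:
scaled training studies use 100 memory-days and 300 iterations; the
fully automatic arm trains with 300 memory-days and 600 iterations per
patient and is evaluated on a two-patient cohort. Patients whose
training diverges (non-finite loss) are flagged and excluded from
cohort reports, never silently.

## Known limitations

- The detector and the plant share model structure; real model mismatch
  is limited to noise, variability, and the unknown disturbance. This
  flatters the detector relative to clinical data.
- Per-patient outcome spread is real and visible even in the two-patient
  cohort (time-below-range differs several-fold between cohort members
  and training seeds); population-level claims need the full-cohort,
  full-length runs.
- The dominant failure mode of the fully automatic arm is *snack
  aliasing*: agents train on the three-meal protocol, so a detected
  17:00 snack is dosed by the dinner bank, whose learned boluses are
  sized for 60–80 g dinners. The conservative initialisation and the
  tapered low-glucose menus bound the damage, but a well-trained dinner
  agent remains the wrong expert for a 30–50 g snack. (The detector
  here finds nearly all snacks; a detector that misses small meals
  side-steps the issue at the cost of sensitivity, since the PD loop
  compensates small meals adequately on its own.)
- The learned policies are conservative by construction; they
  under-bolus relative to an oracle and leave more time above range
  than an announced-meal system. That ordering (hybrid better than
  fully automatic, both far better than no bolus) is the qualitative
  result the package reproduces.
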