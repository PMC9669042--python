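# Methods

## The analysis in one paragraph

A regression surrogate f maps per-visit records x (age, sex, height,
weight, BMI, plain water, total fluid intake, total water intake, food
variables) to 24 h urine osmolality y (mOsm/kg). Advice is generated by
inverting f over the single actionable coordinate, plain water intake w:
minimize (f(x(w)) − 500)² over w ∈ [0, 4050] mL subject to
375 ≤ f(x(w)) ≤ 625 mOsm/kg, where x(w) shifts plain water, total fluid
intake and total water intake together by w − w₀ and holds everything else
fixed. Advice quality is scored by a 2×2 contingency scheme on the sign of
(actual TFI − reference TFI) against hydration status (y < 500), for both
the algorithm's optimized TFI and EFSA fluid thresholds.

## Synthetic cohort and forward model

The generator emulates a pooled hydration-trial population; real data of
this kind are access-restricted, so all development and testing run on
synthetic cohorts with the same statistical structure.

Forward model (osmolar clearance):

    U_Osm = load / V_net,
    load  = 10 mOsm/kg/day × weight + 0.087 × sodium_mg + 1.5 × protein_g,
    V_net = max(TWI + metabolic_water − insensible_loss, 300 mL),

followed by multiplicative lognormal noise (σ_log = 0.15) and clipping to
[50, 1400] mOsm/kg. Defaults: metabolic water 300 mL/day (physiologic range
0.25–0.35 L/day), insensible loss 900 mL/day. The 300 mL urine-volume floor
keeps the ratio bounded; anuria is outside the healthy-adult scope. This is
the simplest mechanism that yields the inverse monotone water → U_Osm
relationship the analysis rests on, and it doubles as the independent
ground truth for closed-loop tests: advice is validated by pushing the
optimized water back through the *noise-free* forward model.

Cohort structure: 1–3 visits per participant; sex (63% female), height and
habitual water intake are participant-level; age 19–51 y and BMI
18–30 kg/m² uniform; plain water a truncated normal (mean 1300, sd 850,
bounds 0–4050 mL); other beverages ~700 mL; food moisture scales with
energy intake (not with fluids — see below); TWI = TFI + food moisture.
Realized urine volume is the exact clearance counterpart of the noisy
U_Osm, and micturition count is volume / 250 mL plus rounding noise, so the
feature-ranking stage has dominant urine-derived features to discover and
then exclude, as a deployable model must. 19% of participants have all
fluid-intake fields missing (participant-level missingness, matching how
intake diaries fail). Seeding is hierarchical
(cohort → participant → visit), so enlarging a cohort never perturbs
existing participants.

Design note — food moisture: an earlier draft tied food moisture to TFI.
That made every fluid feature collinear, and the inversion's coupled shift
(water, TFI and TWI move; moisture stays) then stepped off the training
manifold, biasing the 1-D slice. Food moisture now scales with energy
intake, which is both more physiologic (food water comes from food, not
from how much one drinks) and keeps counterfactual records inside the
training distribution's support.

What the generator does **not** emulate: thermoregulation, exercise,
seasonality, pregnancy physiology, multi-study heterogeneity, and the real
107-variable codebook. Passing tests therefore demonstrate that the
pipeline recovers structure it is pointed at, not that it would achieve any
particular error on real clinical data.

## Preprocessing

Eligibility: age 18–65 y and BMI 18–30 kg/m² (healthy-adult conventions,
configurable), plasma osmolality ≤ 310 mOsm/kg (dehydration threshold),
total fluid intake ≥ 200 mL/day, and a complete core (response +
anthropometrics). Rows with missing fluid intake are retained — tree
learners route missing values natively — and missingness never triggers the
plasma/fluid filters. Each removal is attributed to the first violated
criterion in a fixed order so the filter report reconciles exactly.

Split: participants (not rows) are partitioned 75:25, rounding toward
train; the sorted unique ID list is shuffled with the seed, making the
assignment stable under row reordering. With two or more participants the
test side is never left empty.

## Surrogate

Feature importance is fraction-of-total split gain (sums to 1); a
max-normalized column is kept for display parity with importance plots
scaled to the top feature. The deployable feature policy excludes urine
volume and micturition count — measurements the general population cannot
supply — and ships as configuration.

Learners: XGBoost (primary), random forest and
`HistGradientBoostingRegressor` (the scikit-learn gradient boosting machine)
as comparators. All three route NaN through tree splits natively, so no
sentinel encoding or imputation exists anywhere. Hyperparameters come from
seeded random search (default 50 draws in library use; smaller in the
bundled scripts) over depth 3–8, learning rate 0.03–0.3 (log-uniform),
100–600 rounds, subsample 0.7–1.0, scored by mean MAE over
participant-grouped CV folds (GroupKFold — no participant ever spans a
fold boundary). Stability is assessed by repeating the whole
split→tune→fit→score cycle five times with distinct split seeds.

## Interpretation

PDP/ICE overwrite the feature with each grid value in every record and
average; the default water grid is 0–4050 mL in 150 mL steps, deliberately
the same axis the optimizer searches. ALE uses 20 quantile bins by default
(the standard equi-count construction), accumulates within-bin prediction
differences between bin edges, and centers by the count-weighted mean;
empty bins from ties merge with neighbors. Both implementations are tested
against naive double-loop oracles written directly from the definitions.
`largest_drop_interval` scans the PDP for the window of a given width with
the steepest decrease and reports "no decrease" on non-decreasing curves.
All ICE curves are computed (no subsampling); callers with > 10³ rows
should subset.

## Inversion

Tree responses are piecewise constant, so a raw gradient method is
undefined. The solver therefore:

1. precomputes the 1-D water slice at 10 mL resolution (one batched
   predict) and smooths it with a 100 mL moving average;
2. runs an augmented-Lagrangian outer loop (penalty 1.0, ×10 per outer
   iteration, max 8; converged when band violation < 1 mOsm/kg and the
   water step < 1 mL) whose inner problem is solved by SLSQP on the
   smoothed slice with 50 mL finite-difference steps, multi-started from
   the original water, 1500 mL and both bounds;
3. arbitrates all candidates — outer iterates, starts, and the argmin of
   the penalized objective over the precomputed raw slice (a coarse global
   scan; standard safeguard against plateaus) — on the **raw** unsmoothed
   model response, with ties broken toward the smallest behavior change
   |w − w₀|.

The reported prediction always comes from the raw model at the returned
water value. The objective is squared deviation from the 500 mOsm/kg target
(the absolute-deviation alternative changes nothing for a band-symmetric
target) plus quadratic band-violation penalties at final weight ρ = 100;
the brute-force grid oracle minimizes exactly this objective, which is what
makes solver-vs-oracle agreement a meaningful test. If no water in bounds
reaches the band, the best bound-respecting water is returned with status
`infeasible`. Rows missing plain water or TFI are skipped, not imputed: the
coupling rule is undefined for them.

## Evaluation

Cell rule: Δ = actual TFI − reference TFI; Δ ≥ 0 with U_Osm < 500 is a true
positive, Δ ≥ 0 with U_Osm ≥ 500 a false positive, Δ < 0 with U_Osm < 500 a
false negative, Δ < 0 with U_Osm ≥ 500 a true negative. The Δ = 0 tie
belongs to the "≥ 0" row by the table's inequality. Accuracy is
(TP+TN)/total; acceptable classification is (TP+FN+TN)/total, penalizing
only the harmful cell (too little water advised to an underhydrated
person); their gap is exactly FN/total. EFSA references are 80% of the
2.5/2.0 L adequate intakes: 2000/1600 mL. Both comparators are scored on
the identical row set (rows lacking a recommendation or actuals are
excluded from both), and percentages print to one decimal.

## Problem sizes and numerical choices

The bundled tests and the acceptance script use a 600-participant synthetic
study (≈1100 train rows, ≈300 test rows), 3-fold grouped CV with 8 random
search draws, and a 50 mL oracle grid — sizes at which every stage's
behavior is already asymptotic while a full run stays around a minute.
Closed-loop recovery is evaluated on the noise-free generator only for
records whose acceptable band is reachable inside the water bounds
(the forward response is non-increasing in water, so reachability is a
two-endpoint check). Degenerate inputs fail loudly: constant response in
ranking, empty feature lists, empty contingency tables, non-positive
classification inputs.

## Known limitations

- The surrogate extrapolates poorly beyond the observed water/TWI support;
  recommendations at the 4050 mL bound for extreme records inherit that
  flatness (they are flagged `boundary`/`infeasible`).
- The advice modulates plain water only; no multi-beverage reallocation or
  intra-day timing.
- Contingency metrics depend on the reference TFI being comparable across
  rows; participants with missing intake contribute nothing to scoring.
- The synthetic food set (energy, sodium, protein, moisture) is a stand-in;
  its realism is untested against any dietary survey.
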