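# Methods

## Problem and setting

A pneumatically assisted rehabilitation device for the wrist or ankle
streams joint angle (degrees from a rest midpoint; flexion negative,
extension positive) and actuator pressure (PSI) at 30 Hz while a stroke
survivor plays therapeutic video games at home. Each patient carries a
clinician-assigned residual-severity class — "no", "low" or "high" range
of motion (ROM) — and the task is to recover that class automatically from
activity-level summaries of the session telemetry. The pipeline has five
stages: synthetic cohort generation, feature extraction, dataset assembly,
exploratory diagnostics, and model comparison.

## Synthetic cohort generator

No dataset of this kind is publicly deposited, so the generator is a
first-class part of the package: it defines the conditions under which
every end-to-end claim is tested.

**Signal model.** The angle signal of one activity is

    angle(t) = rest + A·sin(2πf·t + φ) + k·P·sin(2πf_a·t + ψ) + j(t) + ε(t)

with `A` the patient's volitional amplitude, `f` half the patient's
movement rate (a sinusoid at `f` reverses direction `2f` times per
second), `k` a per-patient assistance coupling (deg/PSI), `P` the
assistance pressure, `f_a = 0.05 Hz` the air muscle's slow stretch cycle,
`j` a smooth AR(1) jitter process (pole 0.99, scaled by the sensor-noise
SD) and `ε` white sensor noise. With probability 10⁻³ per sample the
angle is replaced by `rest ± 6·(A + kP)` — the sensor faults that motivate
winsorization. `rest` is redrawn per activity (SD 4°) because the
peripheral is re-donned; pressure is the assistance level modulated
anti-phase with the stretch cycle at a per-activity depth U(0.15, 0.6)
plus noise. Scores arrive as a Poisson event stream whose increment unit
varies by orders of magnitude between games (scores are deliberately not
standardized across games).

**Class structure.** Default per-class conditions (between-patient mean ± SD):

| class | volitional amplitude (deg) | assistance (PSI) | movement rate (Hz) |
|-------|---------------------------|------------------|--------------------|
| no    | 3 ± 2                     | 8.0 ± 1.5        | 0.12               |
| low   | 12 ± 6                    | 3.0 ± 1.0 or 7.5 ± 1.5 (50/50 mixture) | 0.30 |
| high  | 32 ± 10                   | 2.0 ± 0.8        | 0.50               |

Assistance coupling is 2.0 ± 0.6 deg/PSI for every class, so a no-ROM
patient at 8 PSI shows ~16° of machine-driven excursion — observed ROM
confounds volitional ability with assistance, by design. The "low" class
mixes two clinically motivated phenotypes (patients who barely use
assistance versus patients with large machine-assisted excursions), and
adjacent classes overlap in every single marginal. Mean ROM still orders
no < low < high, but severity is recoverable only through feature
interactions (ROM relative to pressure, movement count relative to
duration), which is what gives tree ensembles their edge over a linear
classifier here. Each patient also carries a distinctive fingerprint
(own amplitude, pressure level, movement rate, coupling; within-patient
SDs are much smaller than between-patient SDs).

Cohort scale defaults: 33 patients, uniform class mix, 10–15 sessions per
patient, 5–60 min per session split over 1–10 activities (Dirichlet
proportions, 5 s floor), 80 % hand / 20 % foot peripherals (foot ROM
scaled by 0.7). This yields ≈2 200 activities — large enough for stable
holdout estimates while a full experiment (generation, features, 10-fold
CV for four models, holdout scoring) runs in well under a minute.

**Assessments.** The clinician-style record draws min/max angles from
class-conditional passive-range distributions (stretched range is largely
independent of volitional ability); the assessment type follows the
protocol: "no" patients complete only the passive assessment, all "high"
patients the assisted one, "low" patients either.

**Reproducibility.** One master seed; patient draws, assessments and each
activity stream use dedicated `SeedSequence([master, channel, p, s, g])`
streams, so any single stream can be regenerated in isolation and a rerun
is byte-identical.

**What the generator does not emulate.** Real pneumatic actuation
dynamics, game-specific movement patterns, fatigue and learning trends
within or across sessions, missing data, and the empirical correlation
structure of real telemetry (e.g. the pressure summaries are more
collinear here than the ~0.8 correlation seen in practice). Passing tests
therefore demonstrate that the pipeline is correct and that the models
behave as designed under the stated class structure — not that the
reported synthetic accuracies transfer to any particular device's data.

## Feature extraction

Dropped sensor readings (missing samples) are sanitized first: the default
forward-fills the last valid reading within the stream (a drop variant is
available). Cleaning order is then winsorize → smooth. Winsorization clips each activity's
series to its own 1st/99th-percentile band; the bounds are the
nearest-outer order statistics (floor index for the lower bound, ceil for
the upper) rather than interpolated percentiles, which makes the operation
exactly idempotent — re-cleaning cleaned data is a no-op. Smoothing is a
centered moving average (default 5 samples ≈ 0.17 s at 30 Hz) with edge
shrinkage; window 1 is the identity.

A *movement* is a direction change of the smoothed angle counted with a
hysteresis band (default 2°): a reversal counts only once the signal has
retreated at least the band width from the running extremum, so residual
noise cannot inflate the count. The counter operates on the sequence of
strict turning points, which is equivalent to scanning every sample.

The centripetal-force features use F = c·ω², with ω from central
differences of the angle (degrees converted to radians first) and
c = 1 N·s²/rad² by default — an effective mass × lever-arm constant whose
absolute scale is irrelevant downstream because features are z-scored.
F_ext is the maximum over upward-moving samples; F_flex the maximum over
downward-moving samples, reported negative by convention. For a pure
sinusoid A·sin(2πft) both magnitudes equal (2πfA·π/180)²·c; at 30 Hz the
discrete estimate lands within 1 % (the dominant error is the
sinc factor of the central difference, ~0.4 % at f = 0.5 Hz).

Remaining summaries are direct: R/P min/max/mean from the cleaned
channels, t_game as the timestamp span, Score as the maximum cumulative
score (0 when a game emitted no events), h ∈ {0 hand, 1 foot}. R_mean is
computed and carried but excluded from the default modeling feature set,
whose canonical order is F_flex, F_ext, N_mov, R_min, R_max, t_game,
P_min, P_max, P_mean, Score, h. Winsorization percentiles are
per-activity: each game is its own sensor context.

## Dataset assembly

Rows with fewer than 3 movements are removed (no meaningful therapeutic
exercise). Labels join on patient; exactly one assessment per patient is
required, and violations name the offending patient. The class coding is
ordinal in severity: no=0, low=1, high=2.

The split unit is one activity row, matching a design in which tens of
thousands of activities from a few dozen patients are split 80:20; one
patient's rows can therefore appear on both sides, and holdout scores
partially reflect patient memorization rather than generalization to new
patients. This leakage is deliberate (it mirrors the study design being
implemented) and documented; a patient-grouped split is available behind
`group_by_patient=True` for stricter estimates. Splits are stratified on
the class label by default (largest-remainder apportionment keeps every
class within one row of the target fraction); |train| = round(fraction·n).
Normalization is z-scoring with train-fitted mean and SD per feature
(population SD; zero-variance features get SD 1 so they map to 0), applied
unchanged to the holdout partition.

## Exploratory diagnostics

Pearson correlations (the standard default; nothing in the data demands a
rank estimator); zero-variance features yield a flagged 0 rather than NaN.
The redundancy rule drops one member of each pair with |r| strictly
above 0.9 — strict, so a pair at exactly 0.9 survives — visiting pairs in
canonical feature order and dropping the later member (deterministic
tie-break). The F_flex/F_ext pair ships as a default keep-override:
flexion and extension strength recover independently after stroke, so both
are clinically informative despite strong anti-correlation. PCA explained
variance uses all components on z-scored rows; ratios are nonnegative,
nonincreasing and sum to 1.

## Models and evaluation

Four classifiers on the z-scored features: multiclass logistic regression
(C = 1, the minimal linear baseline); extra trees with entropy splits,
42 trees, max 8 717 leaf nodes and 100 % of features per split; LightGBM
with 200 boosting rounds, 127 max leaves, learning rate 0.1 and early
stopping (20 rounds) on a 10 % inner validation split — settings chosen so
the fitted ensemble lands in the same order of magnitude (≈100 trees,
≤127 leaves) as the consensus model this pipeline is patterned on; and a
feed-forward network with ReLU hidden layers (8, 5, 8) trained with Adam,
cross-entropy loss and early stopping. A grid-tuning helper for the
network (layer sizes × learning rate × batch size × epochs, inner
stratified CV, ties to the smaller network, full evaluation log) is
provided. One experiment seed drives cohort, split, folds and model seeds;
tree-model runs are bit-reproducible.

Model selection uses stratified 10-fold cross-validated accuracy
(mean and sample SD over folds); the final comparison uses the holdout
confusion matrix. Per-class precision is TP over the predicted-class
column sum, recall TP over the true-class row sum, F1 their harmonic
mean; macro averages weight classes equally, weighted averages by
support, and both are always reported (displays default to weighted).
All metrics are percentages; zero denominators yield 0 with an explicit
flag. Confusion matrices expose both counts and a row-percentage view.
The comparison tables rank models by weighted holdout F1.

The reference per-class precision/recall/F1 values from the motivating
33-patient clinical study are embedded as constants for
arithmetic-consistency checks (the published per-class F1 equals the
harmonic mean of the published precision and recall to within one unit in
the last printed digit); they are inputs to those checks, never outputs of
this pipeline.

## Numerical and edge-case conventions

- Empty series, empty training sets, empty holdout sets, single-class
  training data, sub-3-sample streams and invalid fractions raise
  `ValueError` with a specific message rather than propagating NaNs.
- t_game is the timestamp span (last − first); simulated streams sample at
  i/rate, so a d-second activity spans d − 1/rate seconds.
- Percentile bounds, split apportionment and the movement counter are
  exactly deterministic; no tolerance hides in the data path. Displayed
  percentages round to 2 decimals; stored values keep full precision.

## Known limitations

- Synthetic accuracies are optimistic relative to new-patient deployment
  because of the row-level split (see above); the patient-grouped split
  quantifies the difference.
- The generator's class structure is stylized; its purpose is pipeline
  validation under known ground truth, not clinical realism.
- The extra-trees-versus-linear margin varies with the cohort seed (the
  gradient-boosted margin is consistently larger); the packaged
  experiment seed is a representative fixed condition, and the ordering
  has been observed at every seed exercised.
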