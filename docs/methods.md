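# Methods

## Problem and model

Motor imagery (MI) modulates sensorimotor EEG rhythms: imagining a
movement desynchronizes the contralateral mu (~8–12 Hz) and beta
(~13–30 Hz) oscillations (event-related desynchronization, ERD). The
classical decoder for this signal is filter-bank common spatial patterns
(FBCSP): band-pass the epoched EEG through a bank of sub-bands, fit CSP
spatial filters per band, concatenate log-variance features, and classify.
Fixed, uniformly spaced sub-bands ignore inter-subject variability in
rhythm location, so this package treats the sub-band boundaries themselves
as decision variables.

A sparrow search algorithm (SSA) optimizes a vector of `2 n_bands` band
edges in [4, 40] Hz. The fitness of a candidate bank is the mean
stratified k-fold cross-validated accuracy of the full FBCSP + classifier
pipeline on the training session. After the search, features and the
classifier are refitted on the whole training session under the best bank
and evaluated on a held-out session.

### CSP

For a binary problem with trace-normalized average class covariances
`C1`, `C2`, CSP solves the symmetric-definite generalized eigenproblem
`C1 w = λ (C1 + C2) w`, giving `Wᵀ(C1+C2)W = I` and `WᵀC1W = Λ` with
eigenvalues in [0, 1]. The `m` largest- and `m` smallest-eigenvalue
filters (default `m = 2`) are retained. The problem for `C2` has
eigenvalues `1 − λ` with the same eigenvectors, so one decomposition
serves both classes. Multi-class data uses one-vs-rest binary problems
(the original FBCSP multi-class scheme); pairwise problems are available
behind `scheme="pairwise"`.

Per-trial covariances are computed from channel-centered data and
normalized by their trace before averaging, controlling inter-trial
amplitude variation. When `C1 + C2` is ill-conditioned (condition number
> 1e10 — guaranteed after common average referencing, which removes one
rank), a ridge of `1e-6 · trace/channels` is added.

The log-variance feature of component `i` is
`log(Var(Zᵢ) / Σⱼ Var(Zⱼ))`, the reference variance being the sum over
the 2m retained components of the same problem, so each problem's
features sum to one in the exponential domain. This is the most common
FBCSP normalization; alternatives (per-band reference, baseline-interval
variance) exist in the literature, and the choice matters little because
downstream classifiers are affine-invariant to a shared offset.

### Sparrow search

Each individual is a flat vector of band edges (`low₁, high₁, …`); the
equivalent (center, bandwidth) parametrization differs only by an affine
bijection, and edges are the natural coordinates for constraint repair.
Population roles per iteration (defaults follow the published operating
point: N = 15, T = 30, 10 bands, ST = 0.8, 20% producers, 30% watchers):

* **producers** (top 20% by fitness): multiplicative shrink
  `x·exp(−t/(αT))` with `α ~ U(0,1]` while the warning draw `R₂ < ST`,
  otherwise an additive scalar standard-normal jump `x + Q·1`;
* **followers** (the rest): `x + step·(x_best − x) + Q` with
  per-coordinate Gaussian `Q` and step
  `R·exp(−j/dim) + β_explore·(1 − t/T)` (`R ~ U[0,1]`, 1-based
  coordinate `j`, `β_explore = 0.5`). The dimension index in the decay
  term is read as the coordinate index so that each band edge attenuates
  independently — the constant-dimension reading would make the term a
  single global constant, defeating its stated purpose;
* **watchers** (30%, resampled uniformly without replacement each
  iteration): non-best individuals move to
  `x_best + β·|x − x_best| + noise` with `β ~ N(0,1)` and
  `noise ~ (1 − t/T)·N(0, σ²)`, `σ = f_max − f_min = 36 Hz`; the current
  best individual is instead displaced along `(x − x_best)` scaled by the
  inverse fitness gap to the worst (plus `ε = 1e-8` against division by
  zero). σ = 36 Hz is a very large perturbation even damped; it is kept
  as specified because the repair step absorbs out-of-range jumps.

The classic follower and watcher rules of the original SSA are available
behind `use_classic_follower` / `use_classic_watcher`. In the classic
follower rule the pseudo-inverse of the random sign vector `A` is
`Aᵀ(AAᵀ)⁻¹ = Aᵀ/dim`, and followers are ranked from the worst (= rank 1)
so the worst half explores.

After every update, **repair** projects the vector back into the feasible
set: per pair, swap if reversed, clip into [4, 40] Hz, enforce a minimum
width of 0.5 Hz (pushing down from the upper bound when needed), then
sort pairs by low edge. Repair is total: any real vector becomes a valid
bank. Optimized bands may overlap or leave gaps — nothing in the feature
pipeline requires a partition, and individually optimized banks routinely
overlap in practice.

Elitism retains the best position ever evaluated, making the fitness
history monotone non-decreasing. Individual 0 of the initial population
is the uniform bank (warm start), so the search can never return a bank
with worse training fitness than the uniform baseline it is meant to
improve upon. Fitness evaluations are cached on the position rounded to
0.01 Hz; band edges closer than that are indistinguishable after
filtering at 250 Hz. Cross-validation folds are drawn once per run from
the run seed, independent of the candidate, so fitness is a deterministic
function of the position and the whole experiment is reproducible from
the base seed.

## Preprocessing

Continuous recordings are epoched per cue event; the chain is broadband
band-pass (0.5–40 Hz), common average reference, baseline correction
against the pre-cue fixation interval (0–2 s), then cropping to the
imagery window (2–6 s) and optional peak-amplitude artifact rejection
(±100 µV when enabled; off by default since synthetic data contains no
artifacts). Because the baseline window precedes the imagery window, the
chain cuts the union window first, corrects there, then crops. All
filters are 4th-order Butterworth applied forward–backward (zero phase):
standard EEG practice, and zero phase keeps band-power latencies — the
quantity ERD analysis cares about — undelayed. Amplitude-threshold
rejection replaces visual inspection, which is not reproducible.

## Synthetic ERD data

The generator plants the class contrast that CSP exploits, without
simulating a head model. Per trial:

* each class's planted band contributes a narrow-band oscillation
  (3 sinusoids, frequencies uniform in the band, uniform phases, 10 µV
  rms total) on the source channels in *all* trials, attenuated in
  amplitude by `(1 − erd_depth)` in trials of that class — ERD as a tonic
  power reduction over the whole epoch, since the extracted 2–6 s window
  already isolates the imagery period;
* every oscillation's amplitude is additionally multiplied by a per-trial
  log-normal draw (log-std 0.4, unit mean square, shared across source
  channels — one cortical source per rhythm). This models the strong
  trial-to-trial variability of single-trial rhythm power. It is
  essential, not cosmetic: with a fixed amplitude the variance contrast
  over a 1000-sample epoch is essentially noise-free, any classifier
  separates the classes perfectly, and the band search loses its
  gradient — a regime no recorded EEG exhibits. The unit-mean-square
  normalization leaves the expected `(1 − erd_depth)²` power ratio
  unchanged. Log-std 0.4 puts the log band-power spread at 0.8, within
  the range reported for single-trial mu power, and puts within-session
  decodability in the realistic 80–95 % range;
* class-independent *distractor rhythms* (defaults: theta 4–8 Hz and
  beta-range 15–19 and 25–30 Hz, 10 µV rms each, same per-trial jitter,
  same sources and mixing) occupy the spectrum outside the planted bands.
  These are what make sub-band selection matter: stationary noise alone
  never penalizes a classifier for covering extra bandwidth, so without
  task-irrelevant fluctuating rhythms the optimal bank is simply "all of
  4–40 Hz" and no band-selection method could be validated. Because the
  distractors share the sources' spatial pattern, only spectral — not
  spatial — filtering can remove them;
* a 1/f-shaped Gaussian background (8 µV rms per channel, independent
  across channels and trials) models ongoing broadband EEG; source
  activity leaks into the other channels through a fixed seeded mixing
  matrix with gains up to ±0.2, giving CSP a spatial pattern to find.
  The 8 µV level makes rhythm and background comparable in magnitude, as
  at the scalp.

Two different seeds produce sessions that differ in every random draw,
including the mixing matrix — cross-session transfer in the tests is
therefore conservative (as after a full cap repositioning).

What the generator does *not* emulate: head-model topographies, ocular
and muscle artifacts, within-epoch ERD time courses, slow drifts of
rhythm frequency, or imbalanced classes. Passing tests therefore show
that the pipeline recovers planted spectral structure under realistic
SNR and trial variability — not that it reaches any particular accuracy
on recorded EEG.

## Evaluation

Accuracy is the exact-match fraction. Cohen's kappa is
`(Acc − p_e)/(1 − p_e)` with `p_e = 1/n_classes` by default (the
balanced-design convention, 0.25 for four classes); the marginal-product
estimate is available behind `chance="marginal"`. Aggregates are mean ±
sample standard deviation (n − 1). Classifier backends: LDA (default),
linear SVM (C = 1), kNN (k = 5, Euclidean); when all training feature
rows are identical, prediction falls back to the majority class with ties
broken toward the lowest label.

## Problem sizes

Unit tests run on reduced configurations (6–8 channels, 10–40 trials per
class, 2–4 bands, populations of 4–10, a handful of iterations) chosen so
the full suite exercises every code path at desk scale. The validation
experiments (`scripts/acceptance.py`) use the planted-band recovery task
at 8 channels, 40 trials/class, 4 bands, N = 10, T = 15 over 5 seeds —
large enough for the search dynamics to matter, small enough to run on
one CPU in minutes.

## Known limitations

* One-vs-rest CSP is an assumption; the binary theory does not prescribe
  a unique multi-class extension.
* The fitness is a noisy, piecewise-constant function of the band edges
  (finite trials, discrete CV folds); the search can plateau on wide
  bands when the task is easy.
* The GDF import adapter maps only the four cue annotations of the
  BCI Competition IV-2a layout and requires the optional `mne`
  dependency.
* No artifact modelling beyond a peak-amplitude threshold.
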