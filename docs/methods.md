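# Methods

This note documents the models, conventions, numerical choices and
limitations of `megdenoise`, in the order the pipeline runs.

## Data model and conventions

Event-locked MEG for N subjects is stored as aligned tensors
`n_events x n_sensors x n_time`; all subjects saw the identical stimulus
stream, so event axes correspond one-to-one, and sensors are assumed
index-aligned (same helmet layout). Time bins are labelled by the **start**
offset of the bin from event onset in ms, and bins are half-open intervals
`[t, t + bin_ms)`; a 300–500 ms window at 25 ms resolution is therefore the
eight bins labelled 300…475. Flattening to the per-event matrix `X_i`
(`n_events x d`, `d = n_sensors * n_time`) is **sensor-major** (all bins of
sensor 0, then sensor 1, …); the convention is arbitrary but fixing it makes
weight matrices interpretable and round-trips bit-exact. Region labels are
supplied sensor metadata, not derived from hardware geometry.

## Cross-validation structure

Event streams are time series: adjacent events carry correlated noise, so
folds are contiguous blocks (acquisition runs by default) and the first and
last `n_edge_drop = 60` events of each fold (30 s at one event per 500 ms)
are excluded from *test* evaluation. Edge events remain usable as training
data for other folds — the leakage concern is test events sitting next to
training events, not the reverse. Inner CV for penalty selection re-splits
the training events into 3 contiguous sub-blocks with the same edge logic
(automatic edge size when training sets are small).

## Pairwise mapping

One multivariate ridge per (fold, predictor group) maps the source subject's
predictors to all response columns that share that predictor set — one model
for `SGTG`, one per time bin for `SGTL`, one per sensor for `SLTG`, one per
sensor-time pair for `SLTL`. Ridge decouples across outputs, so grouping is
exact, not an approximation. Defaults for the local settings: spatial
neighborhood = 9 nearest sensors in layout coordinates (ties broken by
sensor index), temporal half-width = 2 bins (±50 ms), both always containing
the response's own sensor/bin and clipped at epoch edges.

Numerics: predictors and responses are z-scored per column on training
statistics (constant columns are left as centred zeros) and predictions are
un-scaled afterwards, which absorbs the intercept; the penalty path
λ ∈ {10⁰ … 10⁶} is evaluated through one eigendecomposition of the
standardised Gram matrix per training set; penalty ties prefer the largest λ.
The X-side decompositions are cached per (source, fold, predictor group) and
shared across targets, which makes the all-pairs denoiser roughly N times
cheaper than naive refitting.

Held-out predictions are concatenated across folds and averaged over the
N−1 sources; the denoised tensor is defined only at test-usable events (NaN
at dropped edges, which downstream analyses mask out).

## Evaluation: Kv(2K) and the per-fold convention

The Kv(2K) statistic draws K distinct positive rows and K distinct
negatives (2K distinct rows per comparison), scores the summed Euclidean
distance comparison, and averages over 1,000 sampled comparisons by default.
Exact distance ties score 0.5, which is unbiased under the null. Constrained
(attribute-matched) negatives are drawn without replacement; events with no
same-attribute partner are excluded from the positive pool with a logged
warning. Permutation p-values use the add-one estimator
`(1 + #{perm ≥ obs}) / (1 + n_perms)`, which cannot return zero.

All held-out accuracies and encoding correlations are computed **within each
test fold and averaged over folds**. This matches the definition
`Acc = 1/k Σ_j 20v40(·^{(j)}, ·^{(j)})` and is not cosmetic: predictions of
different folds come from different models whose intercepts differ by the
training-fold means, and pooling folds before comparing converts those
coherent offsets into systematic bias (we observed below-chance accuracies
and strongly negative encoding correlations under pooling; both artifacts
vanish under per-fold evaluation). A related caveat: at K = 20 on small test
folds the statistic amplifies whatever in-sample covariance the realisation
happened to contain, so a *single* null dataset can score 0.4 or 0.6; null
calibration statements hold in expectation over datasets or permutations.

## Shared Response Model

Deterministic SRM: bases are initialised by QR of a seeded Gaussian matrix;
each iteration solves an orthogonal Procrustes problem per subject
(`W_i = U V'` from the SVD of `Z' X_i`) and re-estimates `Z` as the
all-subject mean of `X_i W_i'`, which is the exact minimiser given the
orthonormality constraint. The objective is monotone non-increasing; default
10 iterations with a relative-change tolerance of 1e-6 (tests use more
iterations where exact recovery is asserted). Row-orthonormality holds to
1e-8 after every step. The latent dimension L is chosen by inner CV on the
Kv(2K) accuracy of the leave-one-subject-out reconstruction, ties preferring
the smaller L. At train time the shared response averages all subjects; the
leave-one-out exclusion applies at test time only.

## Validation analyses

* **Power gradation**: data squared → mean over selected sensors → mean over
  events of each word-length group → mean over subjects.
* **N400m**: per event, temporal mean over the 300–500 ms window per region
  sensor, then max across the region's sensors on signed values (MEG field
  polarity is sensor-dependent, so an absolute-value variant is exposed by
  flag). Correlation with surprisal is Pearson; the permutation test is
  one-sided (greater), permuting surprisal over events.
* **Encoding**: one ridge per (sensor, bin) from word length, log-frequency
  and surprisal, penalty per column; held-out Pearson correlation per column
  within fold, averaged over folds. The unique contribution of surprisal is
  the drop in sensor-averaged correlation after refitting without it;
  per-bin significance uses an exact sign-flip test over folds (all 2^k
  patterns when feasible), whose attainable p is floored at 2^-k — with
  four folds the floor is 0.0625, so significance claims need six or more
  folds.

## The simulator

The generator emulates a fixed-rate (RSVP) multi-subject reading session:
a word stream with Zipf-flavoured lengths (2–12 letters), log-frequency
negatively correlated with length, positive surprisal negatively correlated
with frequency, and unit-norm embeddings with a 1/k² variance spectrum drawn
independently of the three scalars (so the semantic component carries no
length shortcut). The shared response sums three components:

* visual: amplitude ∝ word length, Gaussian kernel peaking at 150 ms
  (sd 40 ms), occipital sensors;
* N400-like: amplitude ∝ surprisal, kernel supported on 300–500 ms
  (peak 400 ms, sd 50 ms), temporal/parietal sensors with left-temporal
  loading strongest;
* semantic: each embedding coordinate drives a fixed random topography with
  a smooth Gaussian time course (energy-normalised per dimension).

Each subject observes an orthonormal spatial mixing of the shared response
(QR of `I + 0.25·G`, sign-fixed so it tends to the identity) plus AR(1)
Gaussian noise (ρ = 0.3) generated along the *continuous* recording within
each run, so adjacent events are correlated — the situation the edge-drop
logic exists for. Optional integer latency jitter (off by default)
demonstrates why temporally local settings underperform under latency
differences.

**Noise calibration.** `snr` is defined as the ratio of the *event-varying*
shared variance to the noise variance, default 0.008. Two deliberate choices
here. First, the static evoked pattern (identical for every event)
contributes most of the shared tensor's raw variance but no event-level
information, so scaling noise against total variance would let an
uninformative component mask the planted effects. Second, the default was
calibrated once so that cross-subject predictive accuracy on the reference
preset (8 subjects, 2,000 events, 30 sensors, 20 bins) lands in the band
reported for real single-trial MEG — single-source 20v40 around 0.6–0.9 and
averaged estimates around 0.9, rather than saturating the metric at 1.0,
where averaging improvements and denoising gains would be unmeasurable ties.
The effect sizes (γ_length = 1.0, γ_surprisal = 1.7, γ_semantic = 2.5) were
chosen together so that each planted direction's event-variance clears the
ridge transfer threshold (≈ √(d/n) relative to noise): directions below that
threshold are not recoverable by cross-subject regression at this sample
size, and a component that real denoising demonstrably preserves should be
transferable in the emulation too.

**What passing tests do and do not show.** The simulator is linear and
Gaussian with index-aligned sensors and exactly shared timing; real MEG has
non-linear responses, anatomical variability, artifacts, and session-level
nonstationarities. Tests on this generator validate the machinery (fold
discipline, estimator correctness, the direction of denoising effects under
shared structure), not the magnitude of gains on any real recording.

## Reference problem sizes

The shipped validation suite runs the reference preset (8 subjects, 2,000
events in 4 runs, 30 sensors, 20 bins) for the averaging/decoding/encoding/
gradation properties, a 4-subject, 600-event configuration across 20 seeds
for the surprisal null calibration, and small exact-recovery problems
(e.g. N=8, L=5, n=500, d=60 for the SRM) elsewhere; these sizes keep the
whole suite within a few minutes on one CPU while leaving every assertion
at conventional statistical strength.

## Known limitations

* Variable-duration events are supported only through fixed-window epoching
  (pad/truncate upstream).
* Index alignment of sensors across subjects is assumed; no anatomical
  co-registration.
* The PM denoiser is linear; genuinely non-linear shared structure is out of
  scope.
* Denoised values exist only at test-usable events; analyses on denoised
  data lose the 2·60 edge events per fold.
* Absence of an effect in denoised data is not evidence of absence in the
  underlying recordings: the transformation may simply not have retained it.
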