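# Methods

`bcistate` simulates and analyzes a two-class active EEG brain-computer
interface (BCI) operated in a maze-navigation task, with the goal of
studying how a user's mental state — self-reported fatigue, frustration
and attention, each on a [0, 1] slider — relates to classification
accuracy. Because no recorded EEG accompanies the emulated study, all
inputs come from a synthetic generator with a fully known planted
structure; every analysis is therefore testable against ground truth.

## The BCI

**Features.** Each 5-s task period (15 channels, 256 Hz) is band-pass
filtered at 2–30 Hz (4th-order Butterworth, applied forward–backward so
the filter is zero-phase) and summarized by spectral power in 1-Hz bands
from 0–1 to 29–30 Hz per electrode: 30 bands × 15 electrodes = 450
features. Band power is the sum of squared DFT coefficients of the full
trial with frequency in the half-open interval [b, b+1) Hz, scaled so
that the coefficient powers sum to the signal's mean square (Parseval);
the DC coefficient is excluded. No windowing or segment averaging is
applied — the estimate is the raw periodogram mass of the band. A tone
exactly between DFT bins therefore leaks ~8% of its power to
neighbouring bands (rectangular-window scalloping); the generator avoids
this by planting oscillations on exact DFT bins. Bands 0 and 1 Hz fall
inside the filter's stop band and are attenuated but retained, keeping
the 450-column layout fixed.

**Feature selection.** Two paths reduce 450 features to k ∈ 1..12:

* *FCBF* — the fast correlation-based filter. Features are ranked by
  symmetrical uncertainty with the class label, SU(x, y) =
  2·I(x;y)/(H(x)+H(y)); a feature f is removed when an already-kept, more
  relevant feature g *predominates* it, i.e. SU(g, f) ≥ SU(f, class).
  SU is computed on equal-frequency discretizations (10 bins; FCBF is
  defined for discrete variables and the binning choice is ours). FCBF
  does not natively return an exact feature count, so the survivors are
  truncated to k or topped up from the removed features in class-SU
  order, ties always breaking toward the lower feature index. SU values
  are rounded to 12 decimals before comparisons so that mathematically
  exact ties (e.g. a feature identical to the class) are resolved by the
  tie rule rather than floating-point summation order.
* *cluster-PCA + FCBF* — features are clustered by average-linkage
  hierarchical clustering under the distance 1 − |Pearson r| (sign-blind,
  since band powers can be anti-correlated), the tree is cut at 75
  clusters, and the first principal component of each cluster's
  standardized members becomes an intermediate feature (sign fixed so the
  largest-magnitude loading is positive); FCBF then selects k of the 75.
  We read "75 intermediate features" as 75 clusters × 1 PC; fewer
  clusters with several PCs each would be an alternative reading.

**Classifier.** Two-class Fisher LDA: w = Σ⁻¹(μ_active − μ_rest) with the
pooled within-class covariance, bias placing the midpoint of the
projected class means at score 0 (equal priors — training classes are
balanced by design). A small ridge (10⁻⁶·trace/k by default) keeps the
solve stable; k ≤ 12 with 120 trials is rarely singular.

**Model selection.** The menu crosses both selection paths with k = 1..12
(24 candidates). Each is scored by ten runs of stratified ten-fold
cross-validation; selection maps are refit inside each training fold, so
the fitted reduction never sees test-fold statistics. Because the FCBF
ordering and the cluster-PCA stage are k-independent, they are fitted
once per fold and shared across all k. Accuracy is raw (not balanced);
with balanced classes the distinction is minor. The winner is the
highest mean accuracy, ties toward smaller k, then the direct FCBF path.

**Online decisions.** At each maze intersection, K ∈ {2, 3, 4} candidate
directions are probed with one task period each; exactly one (the
intended direction) carries the active task. The intersection decision is
the argmax of the LDA discriminant score over the K periods (ties to the
lowest index) — under the equal-covariance Gaussian model the score is
monotone in the active-class posterior. Two accuracies are reported:
*balanced individual* accuracy, (sensitivity + specificity)/2 over
per-period binary predictions (score > 0 ⇒ active, independent of the
collective argmax), and *collective* accuracy, the fraction of
intersections decided correctly. With uninformative scores the former
sits at 1/2 and the latter at mean(1/K).

## The synthetic cohort

The generator emulates the study protocol: 10 participants; two training
sessions of 150 cued trials each (30 per class over rest + four candidate
tasks, so two sessions give 60 per task); three online sessions of ~50
intersections. Only the 5-s task period of each trial is materialized.

* **Background EEG** is per-channel AR(1) noise (coefficient 0.95,
  innovation 1 µV) — the simplest process with a realistic 1/f-like
  spectral decay.
* **Active-class effect**: sinusoids with random per-trial phase at the
  centers of the 1-Hz bins inside the base band (default 10–12 Hz,
  snapped to exact DFT bins of the 5-s window), added on five central
  channels. The planted discriminative signal is thus exactly a
  band-power contrast. The default amplitude (0.27 µV at multiplier 1)
  is calibrated once so that two-class training CV accuracy falls in the
  low-70% range, the operating point typical of active mental-task BCIs —
  deliberately far from ceiling, since near-perfect accuracy would leave
  the state analyses nothing to resolve.
* **Heterogeneity**: each participant draws a lognormal effect factor
  (σ = 0.35, clipped to [0.3, 2.5]) once, so expected-accuracy weighting
  has real work to do; the four candidate tasks have fixed relative
  strengths with word generation strongest.
* **Online drift**: online amplitudes are attenuated by 0.8, emulating
  the common finding that training-fit classifiers degrade in later
  sessions.
* **Mental state**: ratings follow a reflected random walk in [0, 1]
  (step sd 0.08 per intersection, uniform start), sampled once per
  intersection and inherited by its task periods. The true rating
  dynamics of the emulated study are unknown; the walk is a stand-in
  chosen to give smooth within-session trajectories with good coverage.
* **Response surface**: a configurable map from (fatigue, frustration,
  attention) to a separability multiplier in [0, 2] scales the active
  amplitude online. `ConstantSurface` is the null; `GaussianBumpSurface`
  (center, width, floor, peak) plants a localized optimum;
  `LinearSurface` plants a monotone single-state effect.

What the generator does *not* emulate: ocular/muscle artifacts (hence no
artifact-removal stage), volume conduction or any head-model forward
physics, the 5-s preparation/cool-down periods, non-stationarity within a
session other than through the state walk, and participant-specific task
choice (all participants use word generation). Passing tests therefore
show that the pipeline recovers the structure this model plants — not
that real EEG contains such structure.

## State–accuracy analyses

All analyses run on outcome records at a chosen granularity (task period
by default; intersection available).

**Quantization + chi-squared.** Ratings are rank-median-split into
low/high *within each participant-session* (lower ⌈n/2⌉ records are
"low"; ties resolved by record order so counts differ by at most one).
Splitting within sessions both varies the cut per participant and keeps
every session equally represented at both levels, controlling for
learning effects. Constant-rating sessions are excluded with a warning.
The pooled 2×2 correct-by-level table is tested with Pearson's
chi-squared (1 df, no continuity correction — n is large in all uses).

**Smoothed curves.** Per session and state, ratings are z-scored
(population sd). Records are sorted by normalized rating (stable sort)
and the binary correctness sequence is smoothed with a centered moving
average (default window 51, odd; windows shrink at the edges), giving
C_actual. Replacing each record's correctness with its session-mean
accuracy and smoothing identically gives C_expected, which absorbs
participant- and session-level accuracy differences. The 90% band for
the deviation C_actual − C_expected comes from permutation: correctness
is shuffled *within* each participant-session (exactly preserving every
session mean and hence C_expected), and the 5th/95th percentiles of the
pooled pointwise deviations over 200 resamples are returned as a
symmetric halfwidth. Bootstrap or a parametric normal fit would be
alternatives; permutation makes the null ("no rating–accuracy link,
session accuracies as observed") explicit.

**Bivariate grid.** On a 0.01-resolution grid over the raw [0,1]² plane
of a state pair, each cell takes the Euclidean-nearest m = 500 records
(ties at the boundary broken by record index; raw ratings, not
normalized, so between-participant anchoring differences remain part of
the map). C_actual is the neighbors' mean correctness and C_expected =
Σ_p w_p C_{p,s}, with w_p the share of neighbors from participant p and
C_{p,s} the accuracy of the originating session — computed as the
neighbor mean of per-record session accuracy. Cells with |C_actual −
C_expected| beyond a CI halfwidth are masked significant, and connected
components (4-neighborhood) of the mask are summarized by size, centroid
and peak. Because a cell averages m records while the curves average a
51-record window, the curve-derived band would be far too wide for the
grid; the grid band is instead computed by the same permutation scheme
with the smoothing window set to ≈ m (501), matching the effective
sample size of a neighborhood. On cohorts of ~4 800 periods this yields
a halfwidth close to ±0.03. Neighborhoods of adjacent cells overlap
heavily, so significant cells are strongly spatially correlated; the
*fraction* of cells beyond the band still calibrates near the nominal
10% under the null, which the test suite checks loosely (≤ 15%).

**Separability.** The trained LDA projects each period to w·φ(x) (bias
dropped; the Fisher score is translation-invariant). The Fisher score
J = |μ₁ − μ₂|²/(s₁² + s₂²) uses population (1/n) variances — the scatter
convention of the Fisher criterion; `ddof` is configurable. Scores are
computed per participant within each low/high level and then averaged,
so projection scales from different classifiers never mix. Class
ellipses in a two-feature plane (the two top-ranked selected features by
default) are drawn along the covariance eigenvectors with half-axes
√(λᵢ·q), q the χ²(2 df) quantile at 0.67 — the 67% probability contour
of the fitted Gaussian, not 1-σ axes.

## Numerical and degenerate-input conventions

* Half-open band intervals: a coefficient at exactly b+1 Hz belongs to
  band b+1.
* SU of a constant sequence is defined as 0; zero within-class variance
  gives J = 0 when means agree and +∞ (with a warning) otherwise.
* Constant features are dropped before clustering; constant-rating
  sessions are excluded per state; m > n in the grid shrinks m to n —
  each with a warning rather than an error.
* Determinism: every stream is a `numpy` PCG64 generator keyed by
  (seed, stage, participant, session); a fixed seed reproduces
  byte-identical signals, fold splits and reports.

## Experiment problem sizes

The calibration and recovery experiments (`bcistate.experiments`) use the
smallest sizes at which their statistical checks are stable: oracle
equivalence on 200 random ≤8-feature/≤30-trial instances; closed-form
checks at n = 10⁴–10⁵ samples; chi-squared null calibration on 1 000
replicates of 10⁴ records; full-stack null calibration on a 4-participant
cohort (~1 500 periods); planted-surface recovery on the emulated study's
own scale (10 participants × 3 sessions × 50 intersections, ~4 800
periods, 10 seeded replicates), where the nearest-500 neighborhoods are
small enough relative to the rating plane to resolve the bump's location.
These experiments fix a selection spec (FCBF, k = 6) instead of running
the 24-entry menu, which is exercised separately: the menu selects the
model, it is not what the state analyses measure.

## Known limitations

* The planted effect is a stationary narrow-band amplitude change; real
  task-related EEG modulation is broader-band, non-stationary and
  spatially diffuse.
* The response surface acts only on the active class; rest-period
  statistics are state-independent, so state effects on specificity are
  absent by construction and period-level effect sizes are diluted by
  the rest periods.
* Ratings are noiseless reflections of the latent state the surface
  reads; real self-reports add reporting noise and anchoring effects the
  normalization only partly addresses.
* The chi-squared test treats records as independent; periods within an
  intersection share ratings (though not correctness, given the state).
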