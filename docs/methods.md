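# Methods

This note documents the models and procedures implemented in `assemblage`,
the choices made where the design was genuinely open, and what the
synthetic-data benchmarks do and do not establish.

## Task and data model

A session couples spike trains of simultaneously recorded dorsal CA1 (dCA1)
and medial prefrontal (mPFC) single units with the event table of a delayed
non-match to sample (DNMTS) task: cue light, sample lever press, a 4/8/16 s
delay terminated by a 500 ms tone, nose-poke, and choice press. Sessions
hold 150 trials by default (50 per delay, equal left/right counts per delay,
order shuffled in blocks). All times are absolute seconds from session
start; binned series use half-open 50 ms bins timestamped by their left
edge, and alignment to an event is done by subtraction so the event always
falls on a bin edge. Units below 0.5 Hz average rate are excluded; miss
trials are excluded from all analyses.

## Firing-rate estimation

Instantaneous rates are kernel density estimates: the spike train convolved
with a Gaussian kernel whose width minimizes the unbiased least-squares
cross-validation error

    CVE(h) = ∫ f̂_h² − (2/n) Σᵢ f̂_h^(−i)(tᵢ).

For Gaussian kernels both terms reduce to sums of Gaussians over pairwise
spike-time differences, so the CVE is evaluated in closed form on a 60-point
log-spaced grid from 1 ms to 2 s (ties break toward the smaller width;
fewer than 5 spikes falls back to 100 ms). The closed form is verified
against a quadrature + explicit leave-one-out oracle to ~1e-13 relative
error. One bandwidth is selected per unit over the whole session and reused
for every alignment so tensors stay comparable across events. Trains with
predictable temporal structure select narrower kernels than flat trains of
the same rate; an essentially homogeneous train selects a width near the
grid cap, and the CVE landscape there is nearly flat, so the *selected
width* of an unstructured train is not a stable quantity (the argmin is,
per grid, and is what we test).

Event responsiveness uses the ±3 SD convention: the trial-averaged rate is
z-scored against the 500 ms pre-event baseline, with the scale set to the
standard error of the trial mean (across-trial baseline SD / √trials).
This peak-based criterion is not an exact 5% test — baseline-mean
uncertainty and the skew of low-rate KDE values inflate its family-wise
false-positive rate above the per-bin 0.27% × bins estimate — and the
tests bound it at what the statistic actually delivers.

## Single-unit coding

Per 50 ms bin, left/right discrimination is the pooled-SD two-sample t
statistic; at the typical ~54 trials per side-condition the p < 0.05
criterion is t > 1.67. Significance is pointwise against a label-shuffle
null (permutations shared across bins) with Bonferroni correction over
bins; "informative" units carry more than 50 ms (≥ 2 bins) of significant
coding within ±4 s of the sample or choice press. Encoding duration is the
total significant time, not the longest run. Coding distance between
t-profiles removes each profile's mean, scales by the pooled SD of the
pair, and takes the Euclidean norm, so offset-identical profiles are at
distance 0.

## Population decoding

The decoder is a two-class linear discriminant on trials × units rate
vectors per bin with the pooled covariance regularized toward the identity,
Σ_reg = Σ + λI, λ = 0.05 (not optimized), evaluated by leave-one-out
cross-validation; CP = 1 − CVE. Features are raw KDE rates without per-unit
standardization (the regularization is stated on the covariance, not the
correlation). Area comparisons equalize population size by drawing K =
min(n_dCA1, n_mPFC) units with replacement from the larger area ten times
and averaging; CP differences are tested against a Beta(k+1, n−k+1)
reference built from the smaller CP. Correct→error generalization fits the
decoder on all correct trials and scores the error trials; its null
permutes the correct/error split (cue labels kept), so a significant drop
reflects degraded error-trial activity rather than the smaller test set.
Hotelling's T² with the same regularized covariance gives the parametric
counterpart; its F approximation is exact only at λ = 0 and n > p + 1.

LOOCV with balanced classes is pessimistically biased below 0.5 on null
data at small trial counts (the held-out trial's class is underrepresented
in training). Chance calibration is therefore checked against the 95%
binomial band at the per-session trial count — the chance band one would
draw on a decoding figure — rather than a pooled band across hundreds of
sessions that no leave-one-out estimator could satisfy.

## Cross-temporal decoding

Code stability is probed by training at t₁ and testing at t₂ on a 50 ms
grid. Each grid is an average over repeated draws of eight trials per cue
side; within a draw, a leave-one-pair-out split (train 7+7, test 1+1, every
pair held out in turn) keeps training and testing trials disjoint. The
spec's sources do not state the within-draw partition; leave-one-pair-out
was chosen because it uses every drawn trial for testing exactly once.
Per-cell significance thresholds at the 95th percentile of label-shuffled
grids. The 250 ms Gaussian display smoothing is applied after significance
testing (σ = 250/2.355 ms, reading the stated width as FWHM) and never to
the significance mask.

## Factor-analysis assembly detection

Task-epoch rates (cue −5 s to choice +5 s per completed trial, overlaps
merged) are modelled as v_t = μ + Γz_t + ε with isotropic-factor prior
z ~ N(0, I) and diagonal noise Ψ. EM runs on the sufficient statistics
(mean and covariance), so fit cost is independent of the number of time
bins; initialization is principal-axis, convergence at 1e-6 relative
objective gain, max 500 iterations, Heywood variances floored at 1e-6 of
the unit variance.

Model order uses a trial-shuffle bootstrap: per unit, whole-trial rate
segments are exchanged across trials within (delay, cue side, outcome)
groups, preserving every unit's autocorrelation and its stimulus- and
outcome-locked rate profile while destroying trial-by-trial co-fluctuation
between units. Because response-latency jitter makes segment lengths
unequal, a segment landing in a slightly longer slot is wrap-extended
around its own start; with equal lengths this is a plain permutation.
Grouping by side and outcome matters: a null that scrambles side labels
leaves genuine side-locked signal covariance outside the null, and the
ladder then (correctly, but unhelpfully) reports extra factors for it.
The number of assemblies is the longest initial run of incremental
log-likelihood-ratio gains exceeding the upper 1% confidence limit of the
same statistic on 500 (tests: 100) shuffled data sets.

Membership calibration needed three choices beyond the basic recipe, each
forced by an identifiability property of ML factor analysis:

- **Varimax before thresholding.** The likelihood is invariant under
  orthogonal rotation of Γ, so raw EM loadings can mix two genuine
  assemblies depending on initialization. Varimax (applied identically to
  real and bootstrap fits) aligns each factor with one assembly.
- **A small loading ridge (0.01 per observation).** When surplus factors
  are forced onto data with no cross-unit correlation — exactly the
  bootstrap situation — the ML solution is degenerate: a factor can split
  a single unit's variance arbitrarily between loading and noise at equal
  likelihood, parking large spurious loadings on high-variance units and
  inflating their bootstrap thresholds. The ridge breaks this flat
  direction (convergence tracks the penalized objective, which still moves
  along it) while shrinking correlation-anchored loadings negligibly.
- **Per-unit bootstrap thresholds.** Loading magnitudes scale with each
  unit's rate and variance, so a pooled 99th-percentile threshold is set by
  the most active, most task-modulated units and misses low-rate members;
  each unit's |loading| is compared with the 99th percentile of its own
  bootstrap loadings (pooled across factors; pooled and per-factor modes
  remain available).

The FA input uses a common 100 ms kernel for all units (per-unit CV
bandwidths remain the default elsewhere): a shared latent smoothed by
*different* kernels is no longer exactly low-rank, which blurs the factor
count. Factors with ≥ 2 significantly loading units become assemblies,
typed by member areas; a within-area assembly whose member set is contained
in an inter-area assembly is reported as part of the larger one. Factor
scores (posterior means) give each assembly's activation; activation
significance thresholds scores at the (1−α) quantile of scores obtained by
projecting trial-shuffled data through the fitted model.

The independent cross-check detects assemblies from z-scored raw 50 ms
spike counts (not KDE rates — the Marchenko–Pastur bound assumes
unsmoothed samples): component count from correlation-matrix eigenvalues
above (1+√(N/M))², FastICA on the retained subspace, membership where a
component weight exceeds the background by 2.5 SD. The background spread is
estimated robustly (median + 2.5 × 1.4826 MAD) because the members
themselves inflate a plain mean/SD whenever the assembly is a non-trivial
fraction of the population. ICA assemblies need ≥ 3 members. Agreement with
FA is the mean best-pair Jaccard overlap O = |A∩B|/|A∪B| over ICA
assemblies.

Rank-ordered synthetic assemblies benchmark FA assemblies against the best
achievable unit groups: units ranked by individual peak LOOCV CP, blocks of
s consecutive ranked units decoded jointly for each size s and rank r, and
each FA assembly assigned the rank of the closest-performing size-matched
block. Noise-correlation contributions are measured by permuting trial
order within cue class — per unit independently (destroys all noise
correlations) or with one common permutation per area (spares within-area,
destroys inter-area correlations) — and re-decoding.

## Rhythmic physiology

Autocorrelograms count spike pairs per lag bin, normalized by the
edge-corrected homogeneous-Poisson expectation (flat ≈ 1; a cosine
modulation of depth m appears as 1 + (m²/2)cos 2πfτ). The modulation index
is the fraction of mean-removed ACG spectral power (lags ≤ 1 s) in
3.5–5.5 Hz relative to 1–15 Hz; this band-fraction definition is this
package's own, and a peak−trough variant over 150–300 ms lags is provided.
Pair coherence is multitaper (DPSS, NW = 3, 5 tapers) on mean-subtracted
10 ms counts over concatenated task epochs; its floor for independent
trains is ≈ 1/(tapers × epochs). Cross-correlograms rate-match the two
trains per draw (the higher-count train subsampled to the lower count, 100
draws), tally target-minus-reference lags (positive = dCA1 leads), and
normalize by the per-draw total spike count. CCG spectra are compared
between conditions with paired sign-flip permutations, Bonferroni over
frequencies; lead/lag balance is (Σ₊ − Σ₋)/Σ of CCG mass with a paired t
test across pairs. Spike-phase locking band-passes the LFP (zero-phase
4th-order Butterworth), interpolates the analytic-signal phase at spike
times, and reports the mean resultant length with Rayleigh's test
(≥ 50 spikes).

## Synthetic sessions

The generator emulates the study's structure with planted ground truth.
Unit baselines are log-normal (median 2 Hz, σ_log 0.5). Half the dCA1
units carry side-selective Gaussian bumps at the sample press (amplitude
1.0 × baseline, width 0.6 s); 20% of mPFC units carry weaker sample bumps
(0.8) and 50% carry side-selective bumps whose centres tile the delay in
proportion to its length. Tuning amplitudes were set so peak single-unit
t-scores land in the 3–6 range with dCA1 above mPFC, matching the scale
seen in real recordings of this preparation. Planted assemblies (default:
two 3+3 inter-area and one 4-unit within-dCA1, disjoint, recruited from
the more active half of the cells) share a binary on/off Markov latent
(dwell ≈ 0.2 s, on-probability 0.3, on-multiplier 4×). The binary form of
the gain matters: a log-normal multiplicative gain carries a strong
quadratic latent component that a linear factor model legitimately reports
as extra factors, whereas a binary latent is exactly rank-1 per assembly.
Inter-area members additionally carry (1 + m·cos 2πft + φ) with f = 4.5 Hz,
m = 0.3, and a per-(trial, assembly) common phase, confined to the 4 s
before the sample press. On error trials the mPFC delay-tuning amplitude
and the rhythm depth are multiplied by 0.25; rates are attenuated, labels
never flipped, and dCA1 sample coding is untouched. Spikes are exact
inhomogeneous Poisson over 50 ms piecewise-constant intensities; latencies
are log-normal and independent of delay and outcome.

What the generator does not emulate: refractoriness and bursting, theta
phase precession, behavioral state drift, electrode drift or sorting
errors, reward-magnitude effects, and spatial/behavioral covariates.
Passing benchmarks therefore demonstrate that each detector recovers the
structure it claims to detect under Poisson variability at realistic rates
and trial counts — not that real recordings contain that structure.

## Benchmark problem sizes

The validation suite runs at desk scale: null-decoder calibration uses 100
ten-unit, 48-trial sessions; assembly recovery uses twenty 24-unit,
150-trial sessions with 100 bootstrap datasets; cross-temporal signatures
use 24 trials per side on a 4 s delay with 100 resamples; rhythm detection
uses twenty 12-unit, 50-trial sessions; error-trial checks use five
20-unit, 80-trial sessions with 30% errors. These sizes keep each
benchmark's expected outcome stable under its own sampling variability
while completing in minutes.

## Known limitations

- The factor-count ladder measures departures from the (delay, side,
  outcome)-grouped null; correlation structure time-locked more finely than
  those groups would count as assemblies.
- The Beta-reference CP comparison treats per-bin CP values as independent
  binomials, ignoring LOOCV fold correlation.
- The F approximation for regularized Hotelling's T² is heuristic for
  λ > 0; only the λ = 0 case is calibrated.
- ACG/CCG normalizations assume within-epoch stationarity; strong
  within-epoch rate trends bias the Poisson expectation.
- The |z| > 3 responsiveness rule is a convention, not a calibrated test;
  see above.
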