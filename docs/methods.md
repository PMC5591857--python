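# Methods

This note documents the models, conventions and numerical choices behind
`songmem`, and what the synthetic validation does and does not establish.

## Response magnitude

Multiunit activity is treated as an analog signal, not as sorted spikes.
For each stimulus presentation the response magnitude is

    max(0, RMS_stim − RMS_baseline)

where each RMS is taken about its own window mean. Demeaning makes the
statistic exactly invariant to a DC offset common to both windows (the
traces this models are bandpass filtered 0.5–5 kHz and hence zero-mean, so
demeaning is a no-op on clean data) and it scales linearly with amplifier
gain. The clamp at zero keeps the downstream normalization defined; window
boundaries are configuration parameters, since no universal convention
exists for them.

## Adaptation (SSA) rate

For one site × stimulus, with magnitudes m_t indexed by 1-based trial t,
the rate is the OLS slope over the inclusive window [6, 25] (20 points)
divided by the window mean and expressed in percent per trial:

    rate = 100 · slope_OLS(m_t ~ t, t = 6…25) / mean(m_6…m_25)

Choices worth making explicit:

* **Fit window.** Trials 1–5 carry a fast, non-linear component of
  adaptation; the window starts at trial 6 where the profile is
  approximately linear. The window is a parameter (`fit_window`).
* **Denominator.** The normalization that makes rates comparable across
  sites could use the window mean, the fitted value at the first window
  trial, or the first-trial magnitude; the literature's wording does not
  pin this down. The window mean is the default (it makes the rate exactly
  invariant to site gain, the property the tests verify); the alternatives
  sit behind `denominator=`.
* **Degenerate series.** A series whose denominator is ≤ `epsilon`
  (default 1e-9 magnitude units) has no defined rate. Batch fitting flags
  such series `near_zero_mean` with a NaN rate and logs the count; they are
  never silently dropped.
* r² of the window fit is reported for diagnostics; a constant series has
  rate 0 and r² defined as 0.

## Familiarity Index

FI = (mean of the test set's novel rates) / (familiar rate), one record per
site × test set × familiar song. Using same-set novels as the denominator
controls for slow drift in responsiveness across the session. Both
components must be negative: adaptation rates with the wrong sign admit no
familiarity interpretation, so such records are excluded with reason codes
(`nonnegative_rate` for the familiar component, `nonnegative_novel_mean`
for the denominator, `undefined_*` when an upstream rate was flagged).
Exclusion rules are this package's own; pooled sample sizes therefore
depend on noise level, which mirrors how reported pooled n's in this
literature fall short of the combinatorial maximum.

Pooling reports n, median and IQR (q75 − q25, linear interpolation) per
cell; the median of an even count is the mean of the central pair.
Requested cells with no usable records appear explicitly with n = 0.

## Statistics

* **Sign test** against FI = 1: ties with the null are dropped and counted.
  n ≤ 100 uses the exact two-sided binomial p (minimum-likelihood
  convention); n > 100 uses the continuity-corrected normal approximation
  Z = (k − n/2 − sign(k − n/2)/2) / √(n/4), reporting Z — the convention of
  the statistical packages this analysis chain descends from, and the one
  that reproduces the canonical Z → p pairings (Z = 3.85 → 2.4e-4 and
  Z = 2.25 → 0.049 after Bonferroni m = 2). Near the switch point
  (n = 90–100) the two forms agree within 10% relative for p ≥ 0.01.
* **Kolmogorov–Smirnov**: d = sup |ECDF_a − ECDF_b| with the asymptotic
  two-sided p; invariant under common monotone transforms.
* **t tests**: one-sample (df = n − 1) and pooled two-sample
  (df = n_a + n_b − 2).
* **Bonferroni**: p′ = min(1, m·p) with m defaulting to 2 for the
  left/right hemisphere pair.
* Rejection decisions always use α = 0.05 on the corrected p where a
  correction applies; the report carries both raw and corrected values and
  leaves boundary calls (p = α) to the reader.

## ΔΔCT expression analysis

Per sample: ΔCT = CT_target − CT_housekeeping; ΔΔCT subtracts the mean ΔCT
of the reference (vehicle) group within the same gene × region × hemisphere
cell; relative expression is 100 · 2^(−ΔΔCT) percent. This assumes 100%
amplification efficiency (exact doubling per cycle) and makes the reference
group's geometric mean 100% in every cell by construction. Group contrasts
default to a pooled two-sample t of treated vs reference percent values
(df = 8 for 5 + 5 birds, matching the degrees of freedom this design
reports); a one-sample form against 100% is exposed as well because the
two conventions coexist in the literature and are not equivalent — the
one-sample form ignores reference-group variance.

## Synthetic-data generator

The generator is the package's test bed and defines its study conditions:

* **Design**: groups `hdac3i` (8 birds), `vehicle` (6), `x200` (6); 4
  electrodes per hemisphere in NCM and non-NCM (either region can be
  omitted by setting its electrode count to 0); 4 test sets × (2 F + 2 N)
  songs × 25 trials.
* **Adaptation shape**: piecewise — a geometric fast phase over trials 1–5
  (`fast_phase_drop_frac`, default 0.3 of baseline amplitude at trial 1,
  halving each trial and truncated at trial 5) on top of a decline exactly
  linear in trial number. The linear ramp is anchored at the centre of the
  fit window, so the true normalized rate equals the configured slope
  exactly, making ground truth exact rather than approximate.
* **Effect structure**: novel songs decline at `novel_slope_pct` (default
  −1.5 %/trial, i.e. ≈30% decline across the linear window — a realistic
  magnitude for NCM multiunit adaptation to conspecific song); familiar
  songs at `novel_slope_pct / fi_true(group, hemisphere, region)`, so the
  true FI is the configured ratio by construction.
* **Amplitude and noise**: per-site baseline amplitudes are lognormal
  (log-mean ln 100, log-sd 0.4, arbitrary units — FI is provably invariant
  to them); trial noise is multiplicative lognormal with coefficient of
  variation `noise_cv` (default 0.15), keeping magnitudes positive.
* **Seeding**: each site draws from an independent substream keyed by
  (seed, group, bird, hemisphere, region, site); enlarging a cohort never
  perturbs existing sites, and identical config + seed is bit-identical.
* **Epoch synthesis** scales the stimulus-window samples so their demeaned
  RMS is exactly `magnitude + noise_sd`; extraction then recovers the
  series up to the baseline-window RMS sampling fluctuation,
  O(noise_sd/√(2·n_baseline)).
* The qPCR generator writes CT = base CT − log2(fold-change) + N(0, σ),
  with housekeeping CT independent of group (default σ = 0.25 cycles).

**What the generator does not emulate**: spike-train point-process
structure, song acoustics, session-order and electrode-depth effects,
within-bird correlation of site noise (sites are independent here, whereas
real sites within a bird share state — pooled-site inference is therefore
anti-conservative on real data, a known limitation of the pooling design
this reproduces), non-stationary drift, and pharmacokinetics. Passing
parameter-recovery tests therefore demonstrates the correctness of the
estimators under the stated noise model, not the adequacy of that model
for any particular real dataset.

## Sampling behaviour of the FI estimator

With trial-noise CV c, the OLS slope over the 20-point window has standard
error 100·c/√665 ≈ 0.58 %/trial at c = 0.15, independent of site
amplitude. At the default novel slope of −1.5 %/trial this makes each FI
record a ratio of two noisy negative numbers with ~40–50% CV, with a small
downward bias of the median of the ratio relative to the true ratio
(≈ −0.02 at FI 1.25). A median over ~250 records consequently has a spread
of ≈0.05 around its target, and two-sample K-S tests between cells whose
true medians differ by ≈0.13 (e.g. 1.28 vs 1.15 at ~250 records a side)
have power well below 1 (≈0.4; measured, not asserted, in the validation
suite). These are properties of the estimator under the stated noise
conditions, not implementation defects: at noise 0 recovery is exact, and
recovery tightens as c shrinks or |slope| grows.

## Validation problem sizes

The validation suite simulates: 100 replicate 8-bird NCM-only cohorts for
parameter recovery; 500 null 4-bird cohorts (2000 group × hemisphere ×
region cells, ≥120 records each, exercising the large-n sign-test branch)
for the type-I error rate; and 100 seeds of the three-group scenario for
the qualitative pattern — sizes chosen to estimate proportions to a few
percent while keeping the default test run fast. Oracle checks
(normal-equation OLS, binomial enumeration for all n ≤ 30, ECDF sweeps for
all sample-size pairs ≤ 8, hand-computed ΔΔCT) are exhaustive at small n
and agree to 1e-10 or better.
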