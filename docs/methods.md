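# Methods

## The channel model

A receptor→NF-κB→GFP reporter pathway is treated as a discrete memoryless
channel. The input alphabet X is the measured dose series, including the
unstimulated control (dose 0); the output Y is per-cell fluorescence after a
variance-stabilizing transform (log10 by default — reporter GFP spans
decades and both binning and the noise decomposition behave poorly on raw
linear intensities). Cells are assumed independent and exchangeable within a
dose, and one capacity/SNR/EC50 value is estimated per biological replicate;
replicates, not cells, are the units of all between-condition tests, so the
per-cell independence assumption affects estimator precision but not test
validity.

Capacity is the maximum of I(X;Y) over distributions on the *measured* dose
set. It is therefore a property of the experiment's dose ladder as well as of
the pathway — which is the point of the capacity-versus-maximum-dose curve,
and the reason estimates are bounded by log2(#doses).

## Capacity estimation

1. **Binning.** Output values are pooled across doses and split into
   equal-frequency bins (default; equal-width available). Bins are defined by
   interior cut points: (−∞, c₁), [c₁, c₂), …, [c_k, ∞). Using open outer
   bins keeps bin membership well defined for subsampled, bootstrapped or
   truncated data and keeps discrete-valued outputs separable; duplicate
   quantile cuts are collapsed, so the effective bin count can fall below the
   request (degenerate outputs raise an error when fewer than 2 effective
   bins remain). Empty bins are dropped before maximization; 0·log 0 = 0
   throughout.

2. **Maximization.** Capacity of the empirical conditional P(j|i) = N_ij/N_i
   is computed by Blahut–Arimoto, iterated until the standard upper bound
   max_i D(Q_i ‖ q_Y) and lower bound I(r;Q) agree within tolerance (1e-5
   bits inside the estimator — far below its statistical noise; 1e-12 bits
   for the analytic `true_capacity` oracle). The alternating update is exact
   for this objective and deterministic, so no random trial input
   distributions are needed.

3. **Bias correction.** The plug-in estimator is biased upward at finite N.
   Each dose is subsampled without replacement at fractions
   {0.5, 0.625, 0.75, 0.875, 1.0} of its cells (10 repeats each), a straight
   line of capacity vs 1/N_total is fitted by least squares, and the
   intercept (1/N → 0) is reported, clipped at 0. The (1/N, capacity) points
   are kept in `bias_curve` for inspection. On dose-independent data this
   removes essentially all of the apparent information (see the independence
   tests), at the cost of extra variance at small N.

4. **Confidence interval.** Cells are resampled with replacement within each
   dose B times (default 100) and the 2.5/97.5 percentiles reported. By
   default each resample is evaluated with the plug-in estimator and the
   interval is shifted by the estimated bias (corrected minus plug-in
   estimate on the full data) — the bias is nearly constant across resamples
   of the same N, and this costs B plug-in fits instead of B × 50.
   `nested_bootstrap=True` runs the full extrapolation inside every resample
   instead. A flag is raised if the point estimate escapes its own interval
   (possible under extreme resampling noise).

5. **Bin-count selection.** `select_bin_count` runs the bias-corrected
   estimator over candidate bin counts (default {10, 15, 20, 30, 40}) and
   returns the smallest candidate within 0.02 bits of the median — a plateau
   rule: the estimate should be insensitive to binning resolution. If the
   profile spreads over more than 0.2 bits there is no plateau; a warning is
   emitted and the median candidate used.

Minimum data requirements: ≥ 2 doses and ≥ 50 cells per dose (errors
otherwise). The capacity-vs-maximum-dose curve estimates capacity on every
prefix of the ascending dose ladder (length ≥ 2), always anchored at the
lowest dose, so each point answers "how much information could cells extract
if doses never exceeded D_max?".

## Signal and noise power

On the transformed scale, signal power is the variance across doses of the
per-dose means and noise power the mean across doses of the per-dose
variances; SNR is their ratio. Conventions: per-dose variances use ddof=1
(they estimate within-dose population variance from a sample of cells);
the across-dose variance divides by the number of doses D (ddof=0), because
the dose ladder is the complete input alphabet, not a sample from one. Doses
are unweighted in both averages — weighting by the capacity-achieving input
distribution would entangle the decomposition with the capacity estimate, and
the unweighted form is exposed precisely so the two analyses stay
independent. Powers are computed on the same transform used for capacity so
SNR and capacity comparisons align.

## Dose–response fitting

The 4PL curve y = bottom + (top − bottom)/(1 + (EC50/x)^hill) is fitted by
least squares, parameterized internally in log10(EC50) and evaluated through
a logistic in log dose for numerical stability. The unstimulated control
(x = 0) stays in the fit: for hill > 0 the model's zero-dose limit is
`bottom`, so control points anchor the lower asymptote. Initialization takes
bottom/top from the response range and EC50 from the dose nearest the
half-range crossing, with multi-start over hill ∈ {0.5, 1, 2} and best-RSS
selection; bounds hill ∈ [0.1, 10] and EC50 within [min positive dose/100,
max dose×100] prevent runaway fits on flat data. Non-convergence is reported
as a flagged fit with diagnostics, not an exception. The default response per
dose is the geometric mean of the per-cell fluorescence (back-transformed
from the log10 scale); the arithmetic mean of transformed values is available.

EC50 equality between two datasets is tested with the extra-sum-of-squares F
test: full model = separate 4PL per dataset (8 parameters), null model =
shared EC50 with separate bottom/top/hill (7 parameters), Δdf = 1,
F = ((RSS_null − RSS_full)/1)/(RSS_full/df_full). With noiseless identical
data both RSS vanish; that degenerate case returns F = 0, p = 1 (identical
curves) or p → 0 (different curves) explicitly.

## Comparison statistics

Wilcoxon rank-sum: for pooled sample size ≤ 12 the null distribution is
enumerated over all C(n_a+n_b, n_a) rank assignments using midranks, and the
two-sided p is 2·min(lower tail, upper tail) capped at 1; larger samples use
the tie- and continuity-corrected normal approximation. Student's t is the
pooled-variance unpaired two-tailed test; zero pooled variance is flagged
degenerate (p = 1 for equal means, p → 0 otherwise). Tests are two-sided and
uncorrected for multiplicity, matching per-comparison reporting; the
comparison layer is config-driven, so a Benjamini–Hochberg step can be added
downstream of the tidy CSV.

## Synthetic data

`simulate_mixture_reporter` emulates the statistical structure of NF-κB
reporter data: at dose d a cell activates with probability p(d) following a
4PL in dose (floor p_min at dose 0), and log10 fluorescence is drawn from a
basal or an activated normal component. Defaults (basal 2.0 ± 0.35, active
3.2 ± 0.45 log10 units, p from 0.05 to 0.95, 12 half-log doses, 5000
cells/dose) give broad, heavily overlapping populations with no clean
two-state separation — the regime where plug-in information estimates are
least trustworthy and bias correction matters. Draw order is fixed (per
dose: one uniform vector, one normal vector) under `numpy.random.default_rng`,
so a seed determines the dataset bit-for-bit across platforms.

What the generator does *not* emulate: graded within-population intensity
shifts (component means are dose-independent, so with full separation the
output is effectively binary and capacity saturates near 1 bit — real
reporter channels exceed this via graded expression); temporal reporter
dynamics; cell-cycle and size covariates; instrument artifacts
(autofluorescence, spillover, saturation); correlations between cells.
Passing the recovery tests therefore demonstrates estimator correctness on
mixture-structured data, not end-to-end validity of any particular gating or
compensation choice on an acquired dataset.

`simulate_known_channel` draws output symbols from an explicit row-stochastic
Q(j|i) and emits well-separated centers plus small Gaussian jitter (centers
must be > 6 jitter SDs apart so symbols stay recoverable). Its true capacity
from `true_capacity` (Blahut–Arimoto at 1e-12 bits) is the oracle for all
parameter-recovery tests: the estimator recovers binary-symmetric-channel
capacities for ε ∈ {0, 0.11, 0.25, 0.5} within 0.03 bits at 5000 cells/input.

## Flow-data handling

The FCS reader supports FCS 3.0/3.1 list-mode files with float (F), double
(D) and uniform 16/32-bit integer (I) data segments; log-amplified parameters
($PnE = d,f with d > 0) are converted to linear scale as f·10^(d·x/$PnR).
No compensation or gating is applied beyond channel selection — the analysis
operates on whichever channel the sample sheet names. Non-positive
intensities under the log10 transform are floored at half the smallest
positive value in the dataset (deterministic and scale-free). Population
summaries report the geometric mean with a robust SD defined as the scaled
median absolute deviation (×1.4826) of ln-values, exponentiated to a
multiplicative factor. Bead calibration fits a least-squares line of
log10(molecules) on log10(FI) from ≥ 2 standards.

## Problem sizes

The test suite and acceptance script run entirely on synthetic data sized for
precision at interactive runtimes: 5000 cells/input for channel-recovery
checks, 12 doses × 1000 cells over 20 seeds for the independence null and
monotonicity checks, 100 000 cells/dose for closed-form moment checks, and
20-seed ensembles for EC50 recovery. The analysis drivers use 12 doses ×
1000 cells × 3 replicates per condition.

## Known limitations

- Capacity is estimated per replicate on the measured dose ladder; it is not
  an estimate of the pathway's capacity over a continuum of doses.
- The linear 1/N bias extrapolation is first-order; at very small N per dose
  (near the 50-cell floor) residual bias and extrapolation variance grow.
- The bias-shifted bootstrap CI assumes the finite-sample bias is roughly
  constant across resamples; the nested bootstrap relaxes this at ~50× cost.
- Equal-frequency binning on pooled outputs is robust to heavy tails but ties
  all conditions to a common grid; strongly multimodal outputs may deserve a
  hand-chosen grid via the `bin_output` primitives.
- The 4PL fit assumes a monotone response with hill ∈ [0.1, 10]; asymmetric
  (5PL) responses and competitive-inhibition models are out of scope.
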