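# Methods

## Model

A bin's mRNA concentration (in RPKM) follows a linear birth–death ODE
whose synthesis rate switches once, at the bin's onset delay `T_d`:

    dx/dt = s_b + Θ(t − T_d)·s_a − k·x,      k = μ + γ.

`Θ` takes its post-switch value at `t = T_d` exactly.  Upregulated bins
start from the basal steady state `s_b/k` and relax toward
`(s_b + s_a)/k`; downregulated bins are the mirror image (step
`1 − Θ`), starting from the high state.  The initial condition is the
pre-shift steady state because the culture is in balanced growth when
the stimulus arrives.  The closed form is used everywhere (tests verify
it against adaptive numerical integration to a relative tolerance of
1e−6); no ODE solver runs inside the objective.

Assumptions worth making explicit: a single rate change per bin within
the fitted window; first-order mRNA decay with a known or co-fitted
rate; dilution `μ` negligible against turnover on a 10-minute scale
(default `μ = 0`, overridable); and a constant elongation speed within
an operon, so bin onsets are affine in position.

## Per-bin estimation

For fixed `k` and `T_d` the model is *linear* in `(s_b, s_a)`.  The
default fitter exploits this: for each delay on a dense grid (121
points over `[0, t_max]`) the optimal nonnegative rates come from an
exact two-variable nonnegative least-squares solution, and the best
grid point is refined by bounded Brent search.  This profile search is
deterministic and globally optimal for fixed `γ` up to grid refinement;
ties in the profile (e.g. a constant series, where any delay fits
equally) are broken toward the smallest delay.  A seeded
simulated-annealing backend (`method="anneal"`, scipy
`dual_annealing` with restarts) is provided as an alternative global
optimizer over the full parameter vector; both satisfy the same
objective contract (summed squared residuals over window × replicates),
and the fit-objective test asserts the returned optimum is never worse
than the generating truth.

When a literature degradation rate is available it is fixed
(`γ = ln 2 / half-life`); otherwise `γ` is co-fitted by an outer
bounded search over half-lives of 0.5–60 min.

**Time-point windows.**  Transiently regulated bins (rise then fall)
violate the single-switch model beyond the turning point, so the fit
uses the minimal prefix of timepoints ending at the first local
extremum of the replicate-mean trajectory, with a minimum of three
points; monotone series keep the full design.  A turning point only
counts when the reversal after the extremum exceeds 25% of the series
range: with three replicates and a biological CV around 22%, smaller
reversals are indistinguishable from noise, and truncating a monotone
bin's window costs far more than tolerating a late wobble.  Manual
per-(operon, bin) windows are honoured when supplied.

**Confidence intervals.**  95% CIs for `T_d` come from a parametric
residual bootstrap (default B = 200).  Count noise has a scale roughly
proportional to the mean, so raw residuals are standardised by the
fitted value (floored at 5% of the median fitted level), pooled across
replicates *and* timepoints, inflated by `sqrt(n/(n−3))` to restore the
variance absorbed by the three-parameter fit, then resampled, rescaled
and refitted.  Pooling matters: with only three replicates per
timepoint, resampling within a timepoint underestimates the noise space
badly (empirical coverage ≈ 80%), while the standardised pool achieves
≈ 94% coverage on 500 simulated bins — inside the 90–98% band the
package holds itself to.  The fraction of bootstrap delays pinned to
the `[0, t_max]` search boundary is recorded per bin
(`boundary_frac`); values near 1 mark onsets the data cannot localise.

## Operon regression

Bin delays are regressed on bin midpoints (`midpoint = (start − 1 +
end)/2`, matching the "1–300 nt → 150" convention) by weighted least
squares, weight `w = 1/(CI half-width)²` — the standard
inverse-variance reading of "weighted by the 95% confidence
intervals".  TER is the inverse slope; the operon's initiation delay is
the intercept at position 0, reported as-is even when slightly
negative (clipping to zero happens only in cohort summaries and
histograms).  Quantiles in summaries use linear interpolation.

Three robustness layers guard the regression, each recorded in the
result's flags:

- bins with `boundary_frac > 0.5` are excluded as non-identifiable;
- weights are floored (CI half-width ≥ 0.5 s, since onsets are not
  resolvable below a fraction of the 30-s sampling resolution) and
  capped at 50× the median weight, so one spuriously narrow interval
  cannot dominate;
- a Huber-regression prepass drops bins whose residual exceeds 2.0
  robust standard deviations (`trim=None` disables this and recovers
  plain WLS, which is what the algebra tests exercise).  The bin-delay
  error distribution is heavy-tailed — an occasional fit lands a
  hundred seconds off — and with at most ~15 bins per operon a single
  such outlier otherwise corrupts the slope.

A fitted slope that is not positive means no 5'→3' wave (`no_wave`,
TER undefined); a positive slope with t-statistic below 2 is reported
but flagged `weak_wave`.  Cohort-level summaries and recovery metrics
use the confident (unflagged) set, mirroring how a real study reports
TERs only for operons whose wave is resolvable.

## Synthetic data generator

The generator emulates the aerobic-shift design: samples at 0, 30, 60,
120, 300 and 600 s, three biological replicates, per-sample library
sizes drawn uniformly from the observed 5.6–11.0 million mapped reads.
Each operon gets a ground-truth TER and operon delay; bin *i*'s onset
is `delay + midpoint_i/TER`; expected RPKM follows the closed-form
model; counts are drawn negative-binomial with variance
`m + φ·m²` (default dispersion φ = 0.05, a typical RNA-seq biological
CV of ~22%); RPKM is then recomputed from the counts, exactly as a real
pipeline would.  With φ = 0 the counts are the rounded
(half-to-even) means, giving a deterministic dataset on which the
pipeline must be nearly exact (worst-case TER error < 2%, delay < 1 s).

Cohort defaults describe operons with a *detectable* wave — the kind a
TER analysis would actually report: lengths U(1500, 4500) nt (at least
five bins, as in the multi-gene respiratory operons such analyses
feature), basal expression U(10, 50) RPKM, steady-state fold change
U(5, 20), mRNA half-lives U(2, 5) min (bracketing published
genome-wide *E. coli* medians at 37 °C), TER U(21.5, 63.6) nt/s and
operon delay U(4, 43) s (the cohort's 10–90% spans), 62/89 of operons
upregulated, `μ = 0`.

What the generator does **not** emulate: positional biases of library
preparation, non-uniform coverage within bins, polymerase pausing or
within-operon TER variation, regulatory cascades (each operon switches
once, independently), rRNA contamination, and mapping artefacts.
Passing recovery tests therefore demonstrates the estimator's
correctness under the stated noise model, not robustness to every
failure mode of real libraries.

## What the design can and cannot resolve

With six timepoints, three replicates and a 22% CV, a single bin's
onset delay carries an irreducible uncertainty of roughly 12–45 s
(Monte-Carlo measurement across fold changes of 5–20 and half-lives of
2–5 min; a local-information argument gives the same order).  The
estimator is median-unbiased but right-skewed, which is why the
robust layers above exist.  Propagated through the delay–position
regression of a 1.5–4.5 kb operon this yields a median relative TER
error around 15–25% and a median absolute operon-delay error around
5–10 s for the cohort defaults; longer operons, larger fold changes and
faster turnover all tighten the estimate.  These figures are the
recovery numbers `scripts/acceptance.py` recomputes; they should be
read as a property of the sampling design as much as of the estimator.

## Sequence features and associations

CAI is the geometric mean (computed in log space) of each sense
codon's relative adaptiveness `w_c = f_c / max(f)` within its
synonymous family, from a Kazusa-style usage table (an *E. coli* K-12
table ships with the package; any `(codon, count)` TSV can be
substituted).  Stop codons are excluded; ATG and TGG contribute
`w = 1`; codons containing ambiguous bases are skipped with a warning;
unobserved codons receive half the smallest observed family frequency
rather than zero so the geometric mean stays finite.  ITE uses the
identical geometric-mean contract over an externally supplied weight
set (the published ITE weights are input data, not recomputed; the
analysis script substitutes a clearly-labelled synthetic stand-in).
RNA folding energies are accepted from an external file only — no
thermodynamic computation happens in-repo.

Spearman correlations use average ranks (tie-corrected).  P-values are
exact by full permutation enumeration for n ≤ 8 and asymptotic
(t approximation) otherwise; the two agree to within 0.02 at the
boundary.  No multiple-testing correction is applied across the
association table; significance is marked at raw p < 0.05.  Binary
covariates (regulator and sigma-factor membership, upregulation) are
encoded 0/1 and join from an annotation table — regulatory network
membership is input, not inferred.

## Problem sizes

The test suite fits 50-operon noisy cohorts (≈500 bins, B = 200
bootstrap), a 10-operon noise-free cohort, a 500-bin coverage
simulation and a 2000-replicate correlation calibration; the acceptance
script runs the same computations at 50 operons / 300 coverage bins.
Each completes in minutes on one CPU thanks to the profile fitter.
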