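# Methods

This note records the models behind `lbstock`, the assumptions they make,
the numerical choices that were genuinely open, and what the synthetic-data
tests do and do not demonstrate about real fishery data.

## Population model and observation conventions

All length-based machinery assumes a stock in demographic equilibrium whose
individuals grow along the von Bertalanffy curve and die at rate
M + F·S(L), where S(L) = 1/(1+e^(−α(L−Lc))) is the gear's logistic
retention ogive. In length coordinates the survivors attaining bin edge
L_{i+1} follow

    N_{i+1} = N_i · ((Linf − L_{i+1})/(Linf − L_i))^(M/K + F/K·S(L_i)),

which is exact for constant rates within a bin because
(Linf − L) ∝ e^(−Kt).

Two observation conventions connect this population to a catch sample, and
they are *not* interchangeable:

1. **Master-equation convention** (used by LBB): the expected catch in bin i
   is proportional to N_i·S(L_i) — no correction for the time a fish spends
   in the bin. This is the form the LBB literature fits, and the default
   convention of `simulate_length_frequency`.
2. **Snapshot (pile-up) convention** (assumed by the length-converted catch
   curve): a standing-stock census accumulates fish in proportion to the
   time spent per bin, adding a factor Δt_i ∝ ln((Linf−L_i)/(Linf−L_{i+1})).
   `simulate_length_frequency(pile_up=True)` generates it.

The difference matters exactly one growth coefficient: regressing a
master-equation sample through the catch curve recovers Z + K rather than Z
(we measure 1.76 vs 1.2 at K = 0.6), while the snapshot sample recovers Z
itself (1.14 vs 1.2). This is the published "pile-up" controversy about the
LBB master equation, reproduced here as a property of the generator. Each
estimator is therefore validated against data simulated under its own
observation model; mixing them quantifies the structural bias rather than
the estimator's quality. Applied to one real dataset, the two estimators
inherit whichever mismatch the real sampling process has — a caveat no
length-based assessment escapes.

Individual variability: each simulated fish receives its own asymptotic
length Linf_i ~ Normal(linf_mean, cv·linf_mean) (default cv 0.05), which
smooths simulated tables the way real ones are smooth. The fitted models
assume a single Linf; at cv = 0.05 this misspecification biases the
posterior Linf and M/K upward along their shared ridge (about +6% and +26%
in our checks) while leaving B/B0 essentially unbiased (±0.01) — the
biomass ratio depends mainly on Lc/Linf and F/M, which the ridge preserves.
Recovery tests are run at cv = 0.02 ("noise-controlled") so that parameter
recovery, not misspecification, is what they measure.

A second generator, `simulate_cohort_length_frequency`, produces an annual
pulse-recruitment snapshot: cohorts aged τ, 1+τ, 2+τ, … with abundances
decayed by the age-integrated mortality, lengths spread by individual Linf
variability and a recruitment-timing jitter (sd 0.1 yr by default). Modal
structure of this kind is what measured biological samples show and what
ELEFAN requires; the equilibrium generator cannot produce it because
continuous recruitment erases modes by construction.

## ELEFAN

Restructuring uses the classical 5-bin moving-average scheme: relative
deviation count/MA − 1 per bin, runs of adjacent positive bins down-weighted
by run length, zero-count bins adjacent to a peak scored −1, positives
rescaled so the maximum is 1. A candidate (Linf, K) curve with within-year
anchor τ predicts cohort lengths Linf(1−e^(−K(τ+j))); ESP sums the scores of
the bins these predictions hit (each peak run counted once, via its best hit
bin), ASP sums all positive scores, Rn = 10^(ESP/ASP)/10.

Two identification safeguards, both adopted after studying failure modes on
synthetic data with known truth:

* **Separability stop.** Cohorts are projected only while the annual growth
  increment is at least one bin width. Beyond that point cohorts pile into
  the same bins; their restructured scores reflect exponential decay, not
  modal signal, and counting them lets fast-growing curves that saturate
  *above* the table escape tail penalties and win spuriously (single-sample
  aliasing).
* **Robust Linf floor.** The grid search skips Linf candidates below the
  99.5% count-weighted length quantile rather than below the literal largest
  occupied bin: a stock's *mean* asymptotic length legitimately lies below
  the largest individual when Linf varies between individuals, and one or
  two stragglers must not veto the true value. (The single-curve scorer
  `score_growth_curve` keeps the strict "Linf above the largest non-empty
  bin" precondition as an API guard.)

Defaults: 60×60 grid, anchor step 1/24 yr (finer than monthly), ties broken
by the first-encountered optimum (Linf ascending, then K). With these rules
the grid search recovers Linf within ~1% and K within ~7% from 50k-fish
noise-controlled cohort samples (tolerances in the tests: 5%/10%).
Bootstrap uncertainty for ELEFAN is out of scope.

## Catch curve and empirical rates

Bins are converted to relative ages via t(L) = t₀ − ln(1 − L/Linf)/K at bin
midpoints. Descending-limb selection, the part of the procedure no
convention fixes: drop bins up to and including the modal ln(N/Δt) point
plus one further bin (incomplete selection), and bins with midpoint above
0.95·Linf (unstable age conversion); both thresholds are arguments. Z is
minus the OLS slope; it is invariant to rescaling all counts, to t₀, and
needs at least three usable points. Negative F = Z − M is reported with a
warning, never clipped — transparency over silent correction.

The empirical natural-mortality regression takes the mean habitat water
temperature T (°C) as input; it is a between-stock life-history correlation,
not a within-stock estimate, so M and the catch-curve Z need not be
mutually consistent on any given dataset (real assessments show the same
tension).

## LBB

Likelihood: multinomial over observed bin counts with expected proportions
from the master recursion; trailing all-zero bins are dropped so they do
not artificially truncate the Linf support (the recursion needs Linf above
the top *occupied* edge). Priors are log-normal on all five parameters;
default CVs 10% for Linf and Lc, 30% for α, M/K, F/K; a CV of zero pins a
parameter. When no priors are supplied, data-driven defaults are derived
and logged: Linf prior at (largest occupied length)/0.95, Lc prior at the
sample mode, M/K prior 1.5 (the near-universal life-history default), F/K
0.5 and α 10 as weak generic centers. An external growth estimate can
centre the Linf prior (`use_elefan_linf` in the pipeline config) — the
recommended practice when a reliable independent Linf exists.

Sampling is adaptive random-walk Metropolis–Hastings on log-parameters.
During burn-in the proposal first tunes a diagonal scale toward 30%
acceptance, then switches to the empirical covariance of the burn-in draws
scaled by 2.38/√d (the posterior has a strong Linf–M/K ridge that diagonal
proposals cannot traverse; effective sample sizes were ~6 before this
change, 380–1400 after). The proposal is frozen at the end of burn-in, so
the retained chain is a valid fixed-kernel sampler. Defaults: 3 chains ×
20,000 iterations, 5,000 burn-in, thinning 5, all driven by one seeded
generator per fit — identical seeds give identical posteriors. Point
estimates are posterior medians, intervals central 95%; a fit whose minimum
effective sample size (computed with arviz) falls below 200 is returned
flagged `converged=False` with a warning, never silently.

Per-recruit reference points use the Beverton–Holt relative forms with
x = 1 − Lc/Linf:

    CPUE′/R = x^(M/K)/(1+F/M) · [1 − 3x/(1+1/(Z/K)) + 3x²/(1+2/(Z/K)) − x³/(1+3/(Z/K))]
    B0′/R   = x^(M/K) · [same bracket with M/K in place of Z/K]
    Y′/R    = (F/M)·CPUE′/R,   B/B0 = CPUE′/R ÷ B0′/R

so B/B0 = 1 holds identically when F = 0 (no special-casing needed). The
Bmsy/B0 proxy evaluates the same chain at F = M and Lc = Lc-opt, where
Lc-opt reduces to 5·Linf/(2(3+M/K)). Status: healthy if B/Bmsy ≥ 1 and
F/M ≤ 1 (boundaries inclusive); B/Bmsy ≥ 1 with F/M > 1 is reported as
fully exploited (biomass high, pressure above the proxy MSY level); then
fully exploited ≥ 0.5, overfished ≥ 0.2, collapsed below — all thresholds
configurable.

Length indicators: L95th is the count-weighted 95th percentile with linear
interpolation within bins; Lmean averages bin midpoints above Lc. Annual
fits are independent — no hierarchical pooling across years.

## Spatial analytics

CPUE is catch per net deployment (t/net); cell CPUE is total catch over
total nets (total-ratio, not mean-of-ratios — both are exported since
logbook conventions differ). Cells are half-open and indexed by their
lower-left corner so every position belongs to exactly one cell, and
aggregation conserves totals exactly. Gravity centers are planar
catch-weighted means — adequate over a 10°×15° box and standard practice.
Spearman correlations use scipy's mid-rank implementation; a brute-force
Pearson-on-midranks oracle pins the tie convention in the tests.

## Synthetic data: what passing tests show

The generators reproduce the *assumed* structure: equilibrium age/length
composition, logistic selection, allometric weight with lognormal noise,
log-normally distributed catches around annually drifting centroids inside
the 35–45° N / 145–160° E study box with a declining median (default 30 t
median, −15%/yr, σ = 0.5, 1+Poisson(2) nets). Passing recovery tests shows
the estimators are correct *under their own assumptions* at realistic
sample sizes (5,000 fish/yr for LBB, 50,000 for noise-controlled ELEFAN
checks, matching sample sizes where the estimators' asymptotics apply).
They do not show robustness to what real data add: time-varying
recruitment and mortality, size-dependent catchability drift, spatial
sampling bias, measurement error, or ageing structure that violates the
"length reflects age" premise. The pipeline demo on cohort-structured data
deliberately exhibits one such effect — LBB's Linf and M/K drift upward when
recruitment is pulsed rather than continuous — as a reminder that the
equilibrium assumption, not the sampler, is usually the binding constraint.

## Problem sizes and defaults used in checks

Recovery checks run at: LBB 3×20,000 MCMC on 5,000 fish (~3 s); ELEFAN
49×36 grid × 24 anchors on 50,000 fish (~0.5 s); catch curve on 100,000
fish (instant); gravity centers on 5,000 operations/yr. The end-to-end
pipeline check uses two years, 2,000 fish and 300 operations per year with
a reduced ELEFAN grid and 2×3,000 MCMC — sizes chosen so the full suite
stays interactive while keeping every estimator in its asymptotic regime.

## Known limitations

* Annual LF tables only; no seasonal growth oscillation, no monthly ELEFAN
  sample linking.
* Single-species, single-fleet; no environmental covariates or habitat
  modelling.
* The empirical t₀ and M regressions are inter-specific averages; their
  outputs are conventional reporting quantities, not stock-specific
  estimates.
* LBB inherits the master-equation (no pile-up) convention of its
  literature; see the observation-convention discussion above.
* Gravity centers are unprojected means; do not use them across wide
  latitude spans.
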