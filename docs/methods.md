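# Methods

## Model and estimator

A community sample is a vector of abundances ranked non-increasing,
`A_1 >= ... >= A_S > 0`. The fractal SAD model asserts
`A_r/A_1 = r^(-p)` for a single exponent `p = 1/d`, where `d > 0` is the
fractal dimension of a stepwise accumulation process: at each step `K = k^d`
new species appear, each `k` times less abundant than the previous wave.
`p = 1` is Zipf's law; `p = 0` a perfectly even community.

With `F_r = ln(A_r/A_1)` and `D_r = ln r`, the model is a line through the
origin in log-log space. Minimising `sum_r (-p*D_r - F_r)^2` gives the
closed form `p = -sum(D_r F_r) / sum(D_r^2)`. The `r = 1` term contributes
zero to both sums, so at least two ranks are required; samples with `S < 2`
are rejected (and counted, not silently dropped, in batch runs). The
estimator is scale invariant — multiplying all abundances by a constant
changes neither `p` nor R² — and it is returned as computed: inverted or
ultra-even communities can legitimately yield `p <= 0`, and surveys report
whatever the formula gives rather than clamping, since empirical surveys do
observe sub-zero and near-zero exponents.

## Goodness of fit

R² on the log-transformed variables is `1 - SS_res/SS_tot` with
`SS_res = sum (F_r + p*D_r)^2`. The total sum of squares is centered
(about the mean of `F_r`) by default: this bounds R² above by 1 and matches
the usual regression convention, at the cost of admitting negative values
when the through-origin power law fits worse than a flat line. Because some
published analyses use the uncentered alternative (`SS_tot = sum F_r^2`),
both variants are exposed (`r_squared_log(..., centered=False)`; the survey
CLI's `--r2-variant both` emits both columns), so a summary table computed
either way can be checked against archived results. A flat SAD fitted at
`p = 0` has `SS_tot = SS_res = 0` and is defined as R² = 1 (zero residuals
are a perfect fit); a flat SAD at any other exponent returns `-inf` rather
than a 0/0 artifact.

## Effective species numbers

Summing the model gives the dominance ratio
`A_T/A_1 = sum_{r=1}^S r^(-p)`, a partial generalized harmonic sum
(`effective_species_finite`). In Hill's framework the quantity
`(sum w_i^a)^(1/(1-a))` over relative abundances is the effective number of
species of order `a`; the order-infinity limit is `1/max(w_i) = A_T/A_1`,
which ties the model's sum directly to diversity theory. Order 1 is handled
by the analytic Shannon limit (`exp(-sum w ln w)`) rather than by
numerically approaching 1, and infinity is an explicit sentinel
(`math.inf`), never a large finite order — both choices remove tolerance
knobs from what are exact statements. Rényi entropy is `ln` of the Hill
number of the same order.

As `S -> inf` the sum converges exactly when `p > 1`, to `zeta(p)`
(`effective_species_infinite`); for `p <= 1` the function raises a
divergence signal — that is the contract, since the effective species number
does not exist there. The zeta value is computed as a partial sum to `N`
plus the integral tail `N^(1-p)/(p-1)` refined by two Euler–Maclaurin
corrections (`-N^(-p)/2 + p*N^(-p-1)/12`); `N` is doubled until the first
neglected term `p(p+1)(p+2)/720 * N^(-p-3)` falls below the requested
tolerance (default 1e-10). The corrections keep `N` small even for `p`
slightly above 1, and the result is verified against arbitrary-precision
zeta in the tests. `harmonic_gap(S) = H_S - ln S` exposes the `p = 1`
boundary behaviour: non-increasing in `S`, bounded below by and converging
to the Euler–Mascheroni constant at the known `1/(2S)` rate.

## Synthetic communities

The generator module produces the structures the analysis assumes, so the
whole pipeline is testable without any external data.

- **exact_power_law** — the noise-free forward model; the estimator must
  recover the generating exponent to machine precision.
- **multinomial_power_law** — `N` individuals drawn multinomially from `S`
  species with expected relative abundances `∝ r^(-p_true)`; unobserved
  species are dropped (zero-truncation, as in real surveys where only
  detected species are recorded) and the counts re-ranked with stable ties.
  Defaults (`p_true = 1`, `S = 100`, `N = 1e5`) are the standard
  recovery-experiment condition used throughout the tests.
- **fractal_accumulation** — the stepwise process itself: step 0 holds one
  species of abundance 1; after step `j` the community holds `ceil(K^j)`
  species (`K = k^d`), the newcomers having abundance `k^(-j)`. Non-integer
  `K^j` is ceiled and the newcomer count at step `j` is
  `ceil(K^j) - ceil(K^(j-1))`, a stated rounding rule that keeps outputs
  exact for fractal (non-integer) dimensions. The multiplicative reading —
  richness multiplied by `K` each step, rather than `K` species added — is
  the one that reproduces `A_r ∝ r^(-1/d)`, which is what the rank model
  asserts; the resulting staircase brackets the ideal power law within a
  factor `k` on either side, and the fitted exponent lands within ±0.1 of
  `1/d` for the default doubling process.

One integer seed fully determines any stochastic output (numpy's PCG64
generator); identical specs give identical communities.

What the generators do **not** emulate: spatial or temporal autocorrelation
between samples, detection bias varying by species, abundance measured as
biomass with its own error structure, or competing SAD families (log-series,
lognormal). Passing recovery tests therefore show that the estimator is
consistent under multinomial noise and staircase discretisation — not that
real communities follow the power law.

## Data handling

Abundance tables are long-format delimited text (sample, species, count).
Column names and delimiter vary across survey archives, so they are carried
by a dialect object; a sniffer guesses a dialect from common ecological
header names, and explicit dialects always override it. Duplicate
(sample, species) rows are summed — archives often split records by subplot
or period — zero-abundance rows are dropped before ranking, negative or
unparseable values are errors carrying the file row, and abundances are
accepted as non-negative reals (densities and biomass, not only counts).
Ties in abundance are ranked stably by species label, so ranks are
reproducible; ranks are always `1..S` with no midranks. Samples reduced to
zero species are omitted and counted. Abundance tables are written with 17
significant digits (exact double round trip); fit tables with 12.

Model-generated vectors with a negative exponent are increasing in the rank
index by construction; `predict_sad` marks these as unranked rather than
re-sorting, so the generating exponent (including its sign) remains
recoverable, while every empirical ingestion path sorts.

## Survey reductions

Batch fitting preserves input order and records an exclusion entry per
unfittable sample. Summary rows report max, min, median (midpoint
convention for even n), mean, and standard error `sd/sqrt(n)` with the
`n-1` denominator (0 for a single fit). Histograms of `p` use right-open
bins `[j*w, (j+1)*w)` anchored at 0 with default width `w = 1/3` — the
thirds in which the exponent's mode is conventionally reported
(0.67–1, 1–1.33, 1.33–1.67) — with negative exponents in an explicit
underflow bin so counts always total n. Width and anchor are configurable
because archived figures do not always state their binning exactly.

## Problem sizes and numerical choices

The recovery experiments run 100–500 seeds at `S = 100`, `N = 1e5`
(multinomial) and 10 accumulation steps, sizes at which the whole suite
completes in a few seconds while the Monte-Carlo means are stable to well
inside the ±0.05 and ±0.1 bands asserted. The estimator-vs-minimizer
cross-check uses 500 log-normally perturbed power laws (richness 2–200,
sigma 0.5) against a dense-grid plus bounded scalar minimization oracle at
1e-8. Harmonic sums are chunked at 1e6 terms to keep memory flat; numpy's
pairwise summation keeps the `S = 1e6` harmonic-gap error far below the
asserted `1/(2S)` envelope.

## Limitations

- The reproduction of the published eight-archive survey (19,833 samples)
  requires the archived CSVs, which cannot be redistributed with the
  package; the corresponding test states where to place them and fails
  visibly in their absence rather than passing vacuously.
- The estimator weights all ranks equally on the log scale; no
  heteroscedasticity correction or rank truncation is attempted, matching
  the plain least-squares definition it implements.
- No alternative SAD families are fitted or compared; the package measures
  one model's exponent and fit quality, deliberately.
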