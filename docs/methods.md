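# Methods

## Model

For a fixed transcription factor (TF) profile `TF`, every candidate
modulator M and target T over J samples is fit by ordinary least
squares:

    T_j = a1 + a2·M_j + b1·TF_j + b2·TF_j·M_j + ε_j,   j = 1..J

with M dichotomized at its median (`1` iff strictly above the median,
so ties at the median go to the low group; a modulator whose
dichotomization is constant is reported as degenerate and skipped).
Each of a2, b1, b2 receives a two-sided t-test on J − 4 degrees of
freedom. The *correlation indicator* of a coefficient is `+` if
p < α and the coefficient is positive, `-` if p < α and negative, and
`0` otherwise (a coefficient exactly 0 is `0` regardless of p). The
ordered triple (a2, b1, b2) of indicators maps bijectively onto 27
labelled regulation classes (`modnet.classes`); 22 of these "involve
the modulator", defined by the rule *b2 ≠ 0, or both a2 ≠ 0 and
b1 ≠ 0*. Saturated fits (zero residual degrees of freedom cannot occur
at J ≥ 5, which the loader enforces, but an exactly-zero residual can):
p-values are set to 0 and the fit flagged `saturated`.

Assumptions: Gaussian, homoscedastic, sample-independent errors; a
non-constant TF profile; expression already on a log2-like scale.
Samples are treated as exchangeable — the time ordering is not used by
the model itself, only by the binding-evidence timepoints.

## Pipeline stages and parameter defaults

1. **Preprocess** (`io_prep`): optional probe→gene mapping, absent-call
   filtering (drop probes absent in *all* samples), duplicate-probe
   collapse by mean, and a coefficient-of-variation filter
   (`cv_threshold`, default 0.15). The CV is computed on the *linear*
   scale (2^value) by default because CV on log data understates
   variation of highly expressed genes; `cv_scale: log-abs` is
   available for data that is not log-transformed.
2. **Targets** (`binding`): peaks from each (caller, timepoint) file
   are assigned to genes by interval overlap with a strand-aware
   upstream window (`upstream_window`, default 10 kb). A gene is
   **genomic** iff it has a qualifying peak (score ≥ cutoff) from
   *every* required caller at *every* required timepoint (defaults: 4
   callers × timepoints {0, 0.5, 1, 24} h); **non-genomic** iff it has
   no peak anywhere; **ambiguous** otherwise. The score cutoff comes
   from `mcs_mode`: `quantile` (default, the `mcs_value`-quantile —
   default 0.95 — of all pooled scores), `absolute` (use `mcs_value`
   directly), or `none` (presence only). The quantile mode is
   self-calibrating on real score distributions; the absolute mode is
   the right choice when scores already carry an absolute meaning, as
   in the synthetic generator (see below).
3. **Triplets** (`triplets`): all (modulator, target) pairs with
   M ≠ T and TF on neither side, scanned in deterministic lexicographic
   order at significance level `alpha` (default 0.05). Fits are
   vectorized per modulator (one shared design matrix across targets).
   Per-class FDRs are estimated by permutation: each target's profile
   is permuted across samples independently (`n_perm`, default 100),
   and `fdr = min(1, mean null connection count / observed count)`,
   blank when the observed count is 0. This estimator is conservative
   and simple; it controls the *expected* false/observed ratio per
   class rather than a per-edge q-value.
4. **Network** (`network`): edges are (M, T) pairs whose class is in
   `keep_classes` (default: the 22 modulator-involving classes).
   The degree null rewires the same number of edges uniformly over the
   |M|×|T| bipartite grid without multi-edges, `n_shuffles` times
   (default 1000), pools all null modulator degrees (zeros included)
   and takes the `quantile` (default 0.95) as a threshold, rounded up
   to an integer; modulators with observed degree ≥ threshold are
   kept, and orphaned targets dropped. Uniform rewiring is the correct
   null for "is this modulator's degree surprising given the edge
   budget"; it deliberately does not condition on the observed degree
   sequence, which would make every degree unsurprising by
   construction.

All randomness flows from a single integer `seed` through
`numpy.random.default_rng`; stage-specific streams are derived from it,
so reruns of an identical config are bit-identical (verified by test).
Output tables carry a header with a 12-hex config hash, the seed and
the package version.

## Synthetic data generator

`modnet.simulate` emulates the *statistical structure* of such a study,
not its biology: a standardized degree-3 polynomial TF trajectory over
a default 12-point time grid (0–32 h); independent Gaussian gene noise;
optional planted triplets with chosen (a1, a2, b1, b2) and noise SD; a
modulator catalog allocated over seven function classes by
largest-remainder quotas (reference composition: 162 protein kinases,
43 phosphatases, 8 acetyltransferases, 1 deacetylase, 57
methyltransferases, 156 TFs, 58 cofactors; total 485); and peak files
in which true genomic genes get high-score peaks (scores in
[0.96, 1.0]) from all callers/timepoints subject to a dropout rate,
while decoy "ambiguous" genes get peaks from a strict subset of
callers with uniform scores. It does **not** model probe-level
artifacts, temporal autocorrelation, batch effects, or realistic peak
shapes/widths. Because the synthetic genomic scores live in a narrow
high band, the pooled 95% score quantile can land *inside* that band
and evict true genomic genes — synthetic configs therefore use
`mcs_mode: absolute, mcs_value: 0.95`; both modes are exercised by
tests.

## Numerical choices

- OLS via the normal equations on a 4-column design (J ≈ 12); this is
  numerically safe at this size and verified against an independent
  implementation (statsmodels) to 1e-8 on coefficients and p-values.
- p-values from the t survival function (`scipy.stats.t.sf`).
- Degree-null shuffles drawn with `rng.choice(n_m·n_t, n_e,
  replace=False)` and `bincount`; the pooled-quantile threshold uses
  `numpy.quantile` then `ceil`.
- Table floats are written with `%.10g`, which round-trips the
  quantities of interest and keeps files diff-stable.

## Verified statistical properties (test suite)

- Type-I error of the interaction test at α = 0.05, J = 12: 5% ± 1%
  over 10,000 null simulations.
- Joint probability that all three indicators are `0` under the global
  null: ≈ 0.886 (the tests are positively dependent through the shared
  design, so this exceeds the independence value 0.95³ ≈ 0.857).
- Recovery of the interaction sign at standardized effect
  |b2|·sd(TF)/σ = 4: ≥ 95% (point estimate ≈ 0.97 over 800 planted
  triplets).
- Degree-null filter passing fraction on complete-random networks
  (100 × 100 nodes, 500 edges): ≈ 5–7%, within 5% ± 3%.
- Zero-dropout consensus partition recovers planted truth exactly.

Fixture and problem sizes in the tests (e.g. 10 modulators × 250
targets for FDR behaviour, 100×100/500-edge random networks for null
calibration) are the package's own choices, selected so each property
is measurable with small Monte Carlo error inside the suite's time
budget.

## Limitations

- Dichotomizing M discards within-group variation and halves power
  relative to a continuous-interaction model; it is retained because
  the class taxonomy is defined on the dichotomized model.
- The per-class permutation FDR is a category-level summary, not an
  edge-level q-value, and is noisy for rare classes (its null count is
  itself small-sample); it also scales with scan size.
- The genomic definition (every caller × every timepoint) is strict by
  design; real data with caller dropout will push genes into the
  ambiguous bin, which is reported but not modelled further.
- With J = 12 samples, only large effects are reliably signed; class
  assignments for marginal p-values near α are unstable under
  resampling.
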