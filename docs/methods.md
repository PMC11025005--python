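# Methods

This note documents the statistical procedures, the modelling choices
behind them, and what the synthetic-data validation does and does not
demonstrate.

## Data model and boundary cohorts

An analysis is framed by an ordered stage sequence with a focal boundary
between positions `b` and `b+1` (for the Permian-Triassic case,
Changhsingian | Induan). Genus fates are read off sampled stratigraphic
ranges:

- **extinct** — last appearance at or before the boundary stage;
- **survivor** — sampled both at/before and after the boundary;
- **undefined** — first appearance after the boundary (excluded from all
  extinction tallies).

Two cohort rules decide who enters the denominator. The default
(`boundary_interval`) counts only genera actually sampled in the boundary
stage, which matches tallying "the boundary stage's genera" directly. The
`range_through` option additionally counts genera sampled before and
after the boundary but not in the boundary stage itself (necessarily
survivors); it is the standard boundary-crosser alternative and lowers
apparent extinction under incomplete sampling. Both are exposed because
published tabulations differ and the choice matters at low sampling
rates.

Geographic range defaults to the count of distinct localities, which
works without coordinates and enters regressions log₁₀-transformed; the
maximum great-circle distance (spherical Earth, R = 6371 km) is available
when paleocoordinates exist. Locality counts and great-circle spans are
both common proxies; neither is asserted to be "the" correct one, and the
regression machinery accepts either.

## Trait table

Clades are mapped to four respiratory-protein groups — diffusion,
hemerythrin, hemocyanin, hemoglobin — with capacity ordered
diffusion < hemerythrin < hemocyanin < hemoglobin. The default capacity
covariate is the ordinal rank 0–3: the ordering is physiologically
well-supported (pigment concentration and Hill cooperativity are far
lower for hemerythrin than for hemocyanin/hemoglobin, and absent for
diffusion), whereas any particular quantitative spacing is not, so the
package ships the ranking and lets users supply quantitative capacities,
validated to respect the same ordering.

The packaged table codes 14 clades (bivalves split into protobranch =
hemocyanin and non-protobranch = hemoglobin). Circulatory system is
closed for cephalopods, conodonts and fish, open for the other
coelomates, none for the diffusion group. Motility and a binary
physiological-buffering flag follow the usual clade-level coding in the
extinction-selectivity literature (buffered ≈ motile taxa with advanced
circulatory/respiratory anatomy; echinoderms are coded motile but
unbuffered). Echinoderm coelomocyte pigments are heterogeneous; binning
them as hemoglobin follows the convention adopted by the classification
this package implements, without endorsing the physiology. The table is
an ordinary CSV and fully overridable — it is data, not code.

Trait assignment assumes phylogenetic bracketing: extinct members of a
clade carry the protein type of its modern members.

## Extinction estimators

Proportional extinction per group uses exact Clopper-Pearson intervals by
default (Beta-quantile bounds; conservative, never under-covering), with
Wilson score intervals as the alternative. Multi-clade headline means are
unweighted averages of clade proportions, not pooled-genus proportions;
both are available.

On sequences of ≥ 4 stages the package computes, per interior interval
*i*:

- Foote's boundary-crosser per-capita rate
  `q_i = −ln(N_bt / (N_bt + N_bL))`, undefined (reported as such, not ∞)
  when no taxon ranges through;
- Alroy's three-timer rate `μ_i = ln(2t_i / 3t_i) + ln(p_s)` with pooled
  completeness `p_s = Σ3t / (Σ3t + Σpt)`;
- Alroy's gap-filler rate
  `μ_i = ln((2t_i + pt_i) / (3t_i + pt_i + gf_i))`.

These are the canonical literature forms of the three named estimators.
Negative three-timer/gap-filler values (estimator noise when sampling is
good) are floored at zero and flagged rather than dropped, so downstream
averages are not biased by silent deletion. On a two-stage dataset only
proportional extinction is computable and the CLI says so explicitly.

The stratified comparisons hold one trait fixed while binning by another:
open vs. closed circulation within the hemocyanin group (ostracods,
gastropods, protobranch bivalves vs. cephalopods), and
hemerythrin/hemocyanin/hemoglobin bins within open-circulatory taxa.

## Body-size reduction

The statistic is `(1 − median_post / median_pre) · 100` on raw-mm
medians (midpoint rule at even n); log₁₀ medians are reported alongside
for audit. Species are the sampling unit — one maximum length per
species per cohort, which avoids juvenile specimens — with a genus-level
toggle (max over species).

Uncertainty comes from resampling the pre- and post-boundary cohorts
independently, with replacement, at their own sizes (B = 1000 default):
the two cohorts are distinct faunas, so paired resampling would be
wrong. The reported `boot_sd` is the SD of the statistic over
replicates. Validation shows it is close to unbiased for the true
sampling SD of the median-ratio statistic but has a ~20% coefficient of
variation at n = 200 on a single dataset — a caveat for interpreting any
one group's error bar.

Significance uses the two-sided Mann-Whitney U test with midranks. The
p-value is exact by full enumeration when `n_pre · n_post ≤ 400` with no
ties, otherwise a normal approximation with tie and continuity
corrections. Because the test is rank-based, log-transforming sizes
would not change it.

Seeding: the pipeline seed spawns one substream per group (keyed by a
stable hash of the group label), so adding or removing a group never
changes another group's bootstrap result.

## Selectivity regressions

Group-level OLS (extinction proportion or size reduction vs. capacity)
is unweighted by default — each clade/group is one point, mirroring
scatter-of-group fitting — with group-size weights optional. Slope
inference is the two-sided t test on n−2 df.

The genus-level logistic regression maximizes the binomial likelihood by
Newton iteration (statsmodels backend). Continuous covariates (capacity,
log₁₀ range, log₁₀(occurrences+1) — counts are right-skewed) are
z-scored for comparable coefficients; binaries are 0/1; categorical
capacity is dummy-coded against the diffusion reference. Columns that
are constant, or exact linear combinations of earlier columns, are
dropped with a warning — clade-level covariates can coincide on a given
clade set (e.g. motility and buffering differ only via echinoderms), and
a silent singular fit would be worse than an explicit drop.
Non-convergence and (quasi-)separation — detected via the statsmodels
separation check, non-finite standard errors, or runaway coefficients —
yield a flagged, estimate-withheld result rather than silent output.
Wald per-coefficient p-values are reported without multiple-testing
correction (noted in the report); stars follow the *** p<0.001 /
** p<0.01 / NS convention. Clade fixed effects are available but off by
default, treating genera as exchangeable.

## Synthetic-data generator

The generator is the validation instrument: it produces datasets whose
true group extinction probabilities, sampling rate and size shifts are
known exactly.

Each genus draws an origin stage (uniform over pre-boundary stages, or
post-boundary for a configurable fraction, default 0.15, which populates
the later intervals), then terminates at the end of each alive interval
with probability π_g at the boundary stage (its protein group's
parameter) and the background turnover (default 0.2/interval) elsewhere.
Using π_g alone at the boundary makes realized boundary survival exactly
Bernoulli(1 − π_g), so recovery checks have clean targets. True
presences are thinned by i.i.d. Bernoulli sampling per (genus, interval)
with probability r; the thinning uniforms come from per-genus substreams
independent of r, so lowering r removes occurrences monotonically.
Species sizes are log-normal per clade; the post-boundary location
shifts by log₁₀(m_g), so the true median reduction is (1 − m_g)·100%.

The study-scale scenario fixes the study conditions at the scale of the
Permian-Triassic compilation: 13 clades, ~1,150 genera, ~1,575 size
species over six stages, π = 0.95/0.90/0.85/0.65 and m = 0.5/0.6/0.9/0.95
ordered by capacity, r = 0.8. The probabilities are illustrative values
chosen to produce severe, trait-ordered extinction; they are conditions
of the simulation, not measurements.

What the generator does **not** emulate: spatially clustered sampling
(thinning is i.i.d. per genus-interval, whereas real sampling is
locality-structured), correlated trait evolution, within-lineage size
change, taxonomic error, or stage-length differences (rates are per
interval, not per Myr). Passing recovery tests therefore shows the
estimators are correct under idealized sampling, not that real-data
biases are overcome.

## Numerical and validation choices

- Validation problem sizes: 2,000 genera for the estimator-consistency
  check (tolerance 0.05), 4 × 300 genera at r = 0.8 for extinction
  recovery, 100 replicates of n = 200 cohorts for size recovery (3
  percentage points on the mean), 2,000 null replicates for rank-test
  calibration (5% ± 1.5%), 1,000 draws for CI coverage, and 100
  replicates at n = 2,000 for logistic ±2 SE coverage (≥ 93%).
- The bootstrap-vs-outer-Monte-Carlo agreement (within 25%) is checked on
  the mean bootstrap SD over 30 replicate datasets, because a single
  dataset's bootstrap SD of a median is itself ~20%-noisy at n = 200.
- Logistic log-likelihoods are cross-checked against a derivative-free
  Nelder-Mead maximization of an independently coded likelihood (1e-4),
  and the 2×2 closed form ln(ad/bc) (1e-8).
- Exact Mann-Whitney enumeration is cross-checked against a full
  combinatorial enumeration oracle (1e-12).
- Determinism: all randomness flows from numpy `SeedSequence`s derived
  from a single integer seed; identical config + seed gives byte-identical
  pipeline CSVs.

## Known limitations

- Ordinal capacity ranks impose equal spacing between protein groups in
  continuous-capacity regressions; use quantitative capacities where
  defensible.
- Clade-level trait assignment ignores within-clade physiological
  variation (some taxa express multiple carrier proteins).
- The rate estimators need ≥ 4 stages; two-stage datasets support only
  proportional extinction.
- No phylogenetic non-independence correction: genera are treated as
  exchangeable (clade fixed effects are the only control offered).
- No origination rates, diversity curves, or subsampling standardization
  (SQS/rarefaction) — this package is extinction-side only.
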