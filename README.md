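# paleoselect

Extinction-selectivity and body-size-reduction analysis for fossil
occurrence data, built around clade-level physiological covariates.

Mass extinctions do not remove taxa at random. Across the Permian-Triassic
boundary — the largest marine extinction of the Phanerozoic — clades
differed sharply in how much diversity and body size they lost, and one
candidate driver is respiratory physiology: marine animals move O₂ with
simple diffusion (protozoans, sponges, corals), hemerythrin (brachiopods,
bryozoans), hemocyanin (ostracods, gastropods, cephalopods, protobranch
bivalves), or hemoglobin (other bivalves, echinoderms, conodonts, fish),
and these carriers differ strongly in O₂-carrying capacity. `paleoselect`
is a toolkit for testing that kind of trait-based selectivity hypothesis
on genus-level occurrence and body-size tables: it classifies clades by
respiratory-protein group, estimates extinction magnitudes and
sampling-standardized rates, quantifies size reduction with bootstrap
uncertainty, and fits selectivity regressions — plus a synthetic-data
generator with known ground truth so every stage can be validated.

Intended users are paleobiologists and macroevolution researchers working
with PBDB-style occurrence exports or comparable compilations.

## Statistics implemented

**Extinction magnitude.** For a boundary between stages (e.g.
Changhsingian | Induan), each genus sampled in the boundary stage is
extinct if it has no later occurrences. Per group, the proportion
`n_extinct / n_total` carries an exact Clopper-Pearson (default) or
Wilson binomial confidence interval. A range-through cohort option adds
survivors not sampled in the boundary stage itself.

**Sampling-standardized rates** on sequences of ≥ 4 stages, from
occurrence-pattern counts per interval *i* (2tᵢ: sampled in *i−1* and
*i*; 3tᵢ: in *i−1, i, i+1*; part-timers ptᵢ: in *i−1* and *i+1* but not
*i*; gap-fillers gfᵢ: in *i−1* and *i+2* but not *i+1*; boundary
crossers N_bt, N_bL):

- per-capita rate  `q = −ln(N_bt / (N_bt + N_bL))`
- three-timer rate `μ = ln(2tᵢ/3tᵢ) + ln(p_s)`,
  with completeness `p_s = Σ3t / (Σ3t + Σpt)`
- gap-filler rate  `μ = ln((2tᵢ + ptᵢ) / (3tᵢ + ptᵢ + gfᵢ))`

**Body-size reduction.** Per group,
`reduction = (1 − median_post / median_pre) · 100` on species maximum
lengths, with a standard deviation from 1,000 independent bootstrap
replicates of both cohorts and a two-sided Mann-Whitney U test (exact by
enumeration for small tie-free samples, tie-and-continuity-corrected
normal approximation otherwise).

**Selectivity regressions.** Group-level OLS of extinction or size
reduction on O₂-carrying capacity (ordinal ranks 0–3 by default, or
user-supplied quantitative values with the same ordering), and
genus-level multiple logistic regression of extinction status on
capacity (continuous or 4-level categorical vs. the diffusion
reference), log₁₀ geographic range, motility, physiological buffering, a
carbonate-shell flag, and log₁₀ occurrence count.

## Worked example

```python
import paleoselect as ps

cfg = ps.scenario_permian_triassic(seed=1)          # 13 clades, ~1,100 genera
occ, truth = ps.generate_occurrences(cfg)
summ = ps.build_genus_summaries(occ, cfg.stages)
annotated, _ = ps.assign_traits(summ)

for est in ps.proportional_extinction(annotated, group_by="protein_group"):
    print(f"{est.group:12s} {est.value:6.1%}  CI [{est.ci_low:.1%}, {est.ci_high:.1%}]"
          f"  ({est.n_extinct}/{est.n_total} genera)")
```

```
diffusion     96.3%  CI [92.6%, 98.5%]  (184/191 genera)
hemerythrin   93.9%  CI [88.4%, 97.3%]  (124/132 genera)
hemocyanin    84.6%  CI [78.4%, 89.6%]  (148/175 genera)
hemoglobin    64.8%  CI [55.9%, 73.1%]  (83/128 genera)
```

The scenario imposes boundary extinction probabilities of
0.95/0.90/0.85/0.65 across the four protein groups; each pooled estimate
recovers its group's truth within the binomial interval. Regressing the
13 clade-level proportions on their groups' capacity ranks gives

```
OLS extinction ~ capacity: slope=-0.085, R^2=0.756, p=0.0001
```

i.e. extinction declines by about 8.5 percentage points per capacity
rank in this synthetic fauna — a negative capacity-extinction
relationship of the kind the selectivity hypothesis predicts.

The same analyses run from the shell:

```sh
paleoselect simulate --out data/ --seed 1
paleoselect extinction data/occurrences.csv \
    --stages Capitanian,Wuchiapingian,Changhsingian,Induan,Olenekian,Anisian \
    --boundary 2 --group-by protein_group
paleoselect run config.yaml       # full pipeline from a YAML config
```

## Layout

- `paleoselect.data_model` — stage sequences, occurrence/size records,
  CSV/TSV readers with reject reports, genus summaries, geographic range.
- `paleoselect.traits` — respiratory-protein trait table and capacity
  values.
- `paleoselect.extinction` — proportions, binomial CIs, interval counts
  and rate estimators, stratified comparisons.
- `paleoselect.size_reduction` — median reduction, bootstrap, rank tests.
- `paleoselect.selectivity` — OLS and logistic fits, coefficient report.
- `paleoselect.simulate` — ground-truth synthetic datasets.
- `paleoselect.pipeline` / `paleoselect.cli` — orchestration and the
  `paleoselect` command.

See `docs/methods.md` for the modelling assumptions, parameter choices
and known limitations.
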