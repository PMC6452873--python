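# undermet

Tools for predicting and dissecting bacterial adaptation to non-native
carbon sources via promiscuous ("underground") enzyme activities.  The
package is aimed at systems-biology and experimental-evolution groups who
run adaptive laboratory evolution (ALE) on *E. coli*-like organisms and
want, in one place:

* **growth-innovation prediction** — constraint-based simulation of a
  genome-scale metabolic network augmented, one reaction at a time, with
  underground activities, to find which single promiscuous reaction (and
  hence which gene) makes a non-native substrate growth-sustaining;
* **mutation–prediction matching** — scoring those gene predictions
  against mutations observed in evolved clones, with direct regulatory
  elements credited to their target genes, and an exact Fisher test for the
  aggregate association;
* **ALE growth analytics** — per-flask growth rates from OD600 series with
  the standard QC rejection rules, generations and cumulative cell
  divisions (CCD), and monotone piecewise-cubic fitness trajectories;
* **duplication detection** — a read-depth caller for large segmental
  amplifications (and optionally deletions) in bacterial genomes.

## The models and statistics at the core

**Flux balance analysis.** A metabolic network with stoichiometric matrix
*S* is assumed at steady state: maximize the biomass flux *c·v* subject to
*S v = 0* and bounds *l ≤ v ≤ u* (fluxes in mmol gDW⁻¹ h⁻¹; the biomass
flux proxies growth rate in h⁻¹).  Growth on a substrate is simulated by
setting its exchange lower bound to −10 mmol gDW⁻¹ h⁻¹.  All growth
simulations can use parsimonious FBA (pFBA): among solutions achieving the
FBA optimum, minimize Σᵢ|vᵢ|.  Flux variability analysis (FVA) reports each
reaction's min/max flux subject to biomass ≥ 99% of optimum; gene deletions
act through boolean gene–protein–reaction (GPR) rules.

**Underground prediction.** A substrate is *predicted growth-sustaining*
if the wild-type network's optimum on it is zero but adding a single
underground reaction makes it positive (growth threshold 10⁻⁶ h⁻¹ — the
prediction is qualitative, depending only on network structure).  The
predicted genes are the enabling reactions' catalyzing genes.

**ALE analytics.** Growth rate is the OLS slope of ln OD600 vs time;
estimates are rejected if fewer than 3 points were sampled, the OD range is
outside [0.2, 0.4], or R² < 0.98.  Generations per flask are
log₂(OD_final/OD_initial); CCD accumulates net cell-count increase across
serial flasks.  Trajectories are fitted by isotonic regression followed by
monotone piecewise-cubic (PCHIP) interpolation.

**Duplication calling.** Per-position depth is binned (default 100 bp);
with per-contig mean μ and standard deviation σ, bins with depth strictly
greater than 2μ − σ are flagged, runs are merged across gaps ≤ 1 kb, and
runs ≥ 5 kb are reported with their mean fold (region mean ÷ μ).

## Worked example

```bash
python examples/match_study_mutations.py
```

```
HIT  D-lyxose               predicted=['yihS'] mutated=['yihS', 'yihW']
HIT  D-2-deoxyribose        predicted=['rbsK'] mutated=['rbsK', 'rbsR']
miss D-arabinose            predicted=['rbsK'] mutated=['fucR']
HIT  m-tartrate             predicted=['dmlA'] mutated=['dmlA', 'dmlR/dmlA-intergenic']
HIT  monomethyl-succinate   predicted=['ybfF'] mutated=['ybfF/seqA-intergenic']

4 of 5 conditions show a mutation in the predicted
gene or its direct regulator; D-arabinose misses because its
promiscuous fuc-operon route was absent from the underground database.
```

Each line is one ALE substrate condition: the enzyme gene predicted by
single-underground-reaction addition, and the genes or regulatory elements
actually mutated in evolved clones.  A regulatory element (e.g. the *rbsR*
repressor, or a promoter-region intergenic mutation) counts as a hit for
the gene it directly regulates.  The D-arabinose miss is informative: the
evolved clones used the *fuc* operon's promiscuous route, which the
underground reaction database did not contain.

Other runnable walk-throughs in `examples/`: `predict_underground_growth.py`
(planted-scenario prediction), `lp_analyses.py` (FBA/pFBA/FVA/scan/
deletions on a readable toy), `ale_growth_rates.py` (QC'd rates, CCD,
trajectory), `call_duplications.py` (a 20 kb fold-2 event recovered from
simulated 100× coverage).

There is also a thin CLI over the same functions:

```bash
undermet sim model --branches 2 --plantings 1 --seed 5 --out toy.json
undermet predict --model toy.json --substrate novel0_e
undermet dup call --depth depth.tsv --bin 100 --min-len 5000 --out amp.bed
undermet run --config run.cfg --out-dir results/run1
```

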