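# Methods

This note documents the models, conventions, and numerical choices behind
`undermet`, and what the synthetic-data-based tests do and do not
demonstrate.

## Constraint-based engine

The flux polytope is {v : S v = 0, l ≤ v ≤ u}.  All analyses are linear
programs over it, assembled by the package and solved with scipy's HiGHS
bindings; the LP construction is owned by `undermet.engine`, so the solver
backend is swappable without touching any analysis.

* **FBA** maximizes the biomass flux.  Solver statuses are reported
  faithfully (`optimal` / `infeasible` / `unbounded`); fluxes with
  magnitude below 10⁻⁹ are reported as exactly 0 to stabilize downstream
  comparisons.
* **pFBA** splits each flux into nonnegative forward/backward parts
  (v = p − q) and minimizes Σ(p + q) subject to the original constraints
  plus c·v ≥ fraction·opt.  The fraction defaults to 1.0 — full optimality —
  and is configurable; the objective floor is an inequality rather than an
  equality to avoid numerical infeasibility at tight tolerances.  Alternate
  optima are not resolved further: among degenerate minimal-flux solutions
  any one may be returned, so callers (and tests) should rely on the
  objective and Σ|v|, not on individual fluxes of degenerate arms.
* **FVA** minimizes and maximizes each reaction's flux subject to biomass
  ≥ fraction·optimum; the default fraction is 0.99, the conventional
  growth-rate cutoff for deletion-impact analyses.
* **flux scans** pin both bounds of one reaction to each grid value and
  re-optimize biomass, recording infeasible points as such; the value
  function of such a bound parameter is concave, which the tests assert.
* **Gene deletions** evaluate each reaction's GPR rule (case-insensitive
  AND/OR with parentheses, no NOT; empty rule = always active) with the
  knockout set inactive and close the reactions whose rules are false.
  Genes absent from every rule are inert and only logged — deliberate, so
  whole genomic deletion-region gene lists (mostly non-metabolic genes)
  can be passed directly.

Verification is dual-route throughout: a brute-force vertex-enumeration
oracle (basic feasible solutions by direct linear algebra) on ≤ 6-reaction
toys, and cross-validation against an independent constraint-based
implementation (cobra) on serialized fixtures, both to 10⁻⁶ relative.

## Model representation and edits

Models are stoichiometric networks in the BiGG JSON dialect (reactions
with `lower_bound`/`upper_bound`/`gene_reaction_rule`, objective marked by
`objective_coefficient`); SBML Level 3 + FBC is imported through
python-libsbml.  Reaction roles (exchange / demand / underground /
biomass) round-trip through the JSON `notes` field and are inferred from
`EX_`/`DM_` id prefixes on plain files.  Conventions:

* negative exchange flux = uptake; opening a substrate sets its exchange
  lower bound to −10 mmol gDW⁻¹ h⁻¹ (positive-growth predictions are
  robust to the exact value within a physiological range);
* the "unconstrained" bound magnitude is 1000 mmol gDW⁻¹ h⁻¹, the
  dialect's conventional default — also used for added demand sinks, whose
  upper bound is not otherwise specified;
* demand reactions (`DM_<met>`, bounds [0, 1000]) drain one unit of a
  metabolite; they exist to keep dead-end products (e.g. glyceraldehyde in
  deoxyribose catabolism simulations) from masking knockout phenotypes;
* isozyme registration rewrites a rule to `(old) or (gene)`.

All edits are functional (copy-and-return), so scans and deletion screens
cannot corrupt a shared model.

## Underground growth prediction

Underground reactions are tested strictly one at a time — the question is
whether a *single* promiscuous activity suffices for growth — and a
substrate counts as growth-sustaining when the biomass optimum exceeds
10⁻⁶ h⁻¹.  The threshold is far above LP tolerance (10⁻⁹) and far below
any real growth value, making the binary call robust; the prediction is
qualitative and depends only on network structure.  Wild-type growth is
always computed on the base network, never the augmented one.  Candidate
substrates are evaluated as sole carbon source: callers shut the
growth-supporting uptakes (`close_uptake`) before testing.

Mutation matching expands each condition's mutated elements through an
explicit regulator map (element → directly regulated genes): a mutated
repressor, activator, or promoter-region intergenic site counts as a hit
for its target gene.  No regulon inference is performed — the map is an
input, which keeps the credit assignment auditable.

The aggregate association is a two-sided Fisher exact test computed by
exhaustive hypergeometric enumeration in exact rational arithmetic
(`fractions.Fraction`), summing the probabilities of all tables with the
observed margins that are no more probable than the observed table; the
only rounding is the final conversion to float, so agreement with the
enumeration definition is exact to ≈10⁻¹⁶.  Degenerate margins return
p = 1 with a warning.  The 2×2 construction (which gene universe, which
aggregation across conditions) is not canonical; `build_contingency_table`
implements one defensible choice — predicted × mutated gene sets over an
explicit universe — and is labeled as such.

## ALE growth analytics

* Growth rate: OLS slope of ln OD600 vs time, in h⁻¹ (natural log for the
  regression; base-2 only in the generations calculation).  R² is the
  squared Pearson correlation of ln OD with time.
* QC: reject if n < 3 points (exactly 3 is allowed), OD range < 0.2 or
  > 0.4, or R² < 0.98.  The flags are independent and can co-occur.
* Generations = log₂(OD_final / OD_initial); negative when a culture
  shrinks.
* **CCD is a parameterized convention.**  Divisions per flask are the net
  cell-count increase N_final − N_initial with N = OD × volume ×
  cells_per_od_ml, defaults 15 ml and 10⁹ cells OD⁻¹ ml⁻¹.  The prior
  literature's exact CCD formula is not restated in the sources this
  package follows; anyone needing absolute CCD values comparable to
  published trajectories must check these two constants against their own
  calibration.  Relative trajectory shape is insensitive to them (both are
  multiplicative).
* Trajectories: isotonic regression (pool-adjacent-violators) of rate vs
  CCD, then a shape-preserving piecewise-cubic Hermite interpolant (PCHIP)
  through the isotonic values.  PCHIP through non-decreasing knots is
  non-decreasing everywhere, so the fitted curve is monotone by
  construction and uniquely defined; evaluation outside the data range
  clamps to the end values.  Duplicate CCD values are averaged before
  fitting.

## Duplication calling

The threshold is depth > 2μ − σ, read as "twice the mean, backed off by
one standard deviation".  The alternative reading 2(μ − σ) is a laxer
threshold whenever σ > 0 and is exposed as `alt_threshold` rather than
silently chosen.  μ and σ are computed per contig by default (plasmids and
chromosomes differ in copy number); `global_stats` pools them.  Defaults —
100 bp bins, 5 kb minimum length, 1 kb merge gap — target multi-kilobase
segmental events; a strict-less-than μ/2 mirror (`deletions=True`, off by
default) flags large deletions with the same machinery.  Positions absent
from the input depth table count as depth 0; the trailing partial bin is
averaged over its true width.

A structural caveat: the rule's μ and σ include the amplified bins
themselves, so sensitivity falls as the amplified fraction of the genome
grows (at fold 2, the threshold crosses the event depth when roughly a
quarter of the genome is amplified).  For bacterial-genome-scale inputs
with events of tens to hundreds of kilobases this is immaterial, but the
caller should not be pointed at tiny contigs dominated by one event.

## Synthetic data: what it emulates, and what passing tests show

The generators produce inputs with the *statistical structure* each stage
assumes, chosen to mirror the study conditions they stand in for:

* toy networks: one native carbon exchange (uptake bound −10), parallel
  two-step conversion routes, one-gene GPRs, biomass yield drawn from
  {1, 2} per seed;
* planted scenarios: the planted reaction is the only route from the novel
  substrate into metabolism, verified at generation time by FBA (base
  model must not grow; the planted reaction must enable; previously
  planted reactions must not leak into the new substrate) — so recovery
  tests cannot pass vacuously;
* OD series: OD(t) = OD₀·e^{μt} plus additive Gaussian noise on the
  absorbance scale (plate-reader error model; sd 0.005 in the recovery
  benchmarks, four time points as in automated ALE platforms), truncated
  below at 10⁻⁴;
* coverage: per-position Poisson (or negative-binomial with size
  parameter r) around mean_depth × fold(position); benchmark genomes are
  200 kb at 100× with one 20 kb fold-2 event — a deliberately scaled-down
  genome that preserves the event-to-genome depth contrast of real
  bacterial data;
* mutation tables: per condition, a predicted gene with probability
  hit_rate, otherwise a decoy.

Every generator is deterministic under its seed.  What passing recovery
tests show: the estimators implement their definitions correctly and have
the expected statistical behavior under the assumed noise.  What they do
not show: robustness to structure real data has and these generators lack —
GC-bias and mapping artifacts in coverage, non-exponential growth phases
and evaporation drift in OD series, genetic hitchhiking and multi-mutation
epistasis in mutation tables, and the combinatorial pathway redundancy of
genome-scale networks.  Genome-scale claims therefore rest on running
`undermet.reproduce` against the real augmented iJO1366 model (supplied by
the user as `data/model_ev1.json`; a multi-megabyte file distributed with
the underground-metabolism *E. coli* reconstruction, not redistributed
here) rather than on the toys.

## Degenerate inputs and tie-breaks

* LP ties (alternate optima): unspecified beyond the objective and, for
  pFBA, Σ|v|.
* FVA min/max at the same vertex can invert by < 10⁻⁹; the interval is
  reordered.
* All-zero coverage: warning, no calls.  Bins exactly at the threshold:
  not called (strict inequality, matching "more than").
* Fisher with an empty margin: p = 1 with a warning.
* GPR parse errors carry the character position; unknown knockout genes
  warn and are ignored.
* Trajectory fitting needs ≥ 2 distinct CCD values; constant input yields
  a constant curve.
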