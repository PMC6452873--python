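"""Underground-metabolism growth prediction and mutation matching.

The headline procedure: take a wild-type genome-scale network that cannot
grow on a candidate carbon source, add promiscuous ("underground") enzyme
reactions one at a time, and ask which single added activity turns the
biomass optimum positive.  The genes catalyzing the enabling activities are
the predicted mutational targets of adaptive evolution on that substrate;
agreement with mutations actually observed in evolved clones is scored per
condition and, in aggregate, with a two-sided Fisher exact test.

Growth is treated as binary (optimum above ``GROWTH_THRESHOLD``): the
prediction depends only on network structure, not on the exact uptake rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
import warnings

from .engine import fba
from .model import MetabolicModel, Reaction, add_reaction, gpr_genes, set_exchange

#: Minimum biomass flux (h^-1) counted as growth; robust to LP tolerance.
GROWTH_THRESHOLD = 1e-6


@dataclass
class UndergroundReaction:
    """A promiscuous side activity: the reaction plus its catalyzing gene(s)."""

    reaction: Reaction
    catalyzing_genes: set[str] = field(default_factory=set)
    native_reaction_id: str = ""

    def __post_init__(self):
        self.reaction.tags.add("underground")
        if not self.catalyzing_genes:
            self.catalyzing_genes = gpr_genes(self.reaction.gpr)
        if not self.catalyzing_genes:
            raise ValueError(
                f"underground reaction {self.reaction.id}: no catalyzing genes"
            )


@dataclass
class SubstrateTest:
    substrate_metabolite: str
    wt_growth: float
    enabling: list[tuple[str, float]]  # (underground reaction id, growth)
    predicted_genes: set[str]


@dataclass
class PredictionMatch:
    condition: str
    predicted_genes: set[str]
    mutated_genes: set[str]
    hit: bool


@dataclass
class ContingencyTable2x2:
    """Counts: a = predicted∧mutated, b = predicted only, c = mutated only, d = neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")


def augment(
    model: MetabolicModel, underground: list[UndergroundReaction]
) -> MetabolicModel:
    """Add every underground reaction to the model (tagged, base untouched)."""
    out = model
    for ug in underground:
        out = add_reaction(out, ug.reaction)
    return out


def test_substrate(
    model: MetabolicModel,
    underground: list[UndergroundReaction],
    substrate: str,
    uptake: float = 10.0,
) -> SubstrateTest:
    """Which single underground reaction enables growth on a substrate?

    The exchange for ``substrate`` is opened to ``uptake`` (lower bound
    ``-uptake``, i.e. 10 mmol gDW^-1 h^-1 by default).  Wild-type growth is
    computed on the base network alone; if the wild type already grows the
    test short-circuits with an empty enabling list.  Otherwise each
    underground reaction is added individually — never in combination — and
    those that lift the optimum above ``GROWTH_THRESHOLD`` are collected.
    ``predicted_genes`` is the union of catalyzing genes over enabling
    reactions.
    """
    base = set_exchange(model, substrate, -abs(uptake), 0.0)
    wt = fba(base)
    wt_growth = wt.objective_value if wt.optimal else 0.0
    if wt_growth > GROWTH_THRESHOLD:
        return SubstrateTest(substrate, wt_growth, [], set())
    enabling: list[tuple[str, float]] = []
    predicted: set[str] = set()
    for ug in underground:
        sol = fba(add_reaction(base, ug.reaction))
        growth = sol.objective_value if sol.optimal else 0.0
        if growth > GROWTH_THRESHOLD:
            enabling.append((ug.reaction.id, growth))
            predicted |= ug.catalyzing_genes
    return SubstrateTest(substrate, wt_growth, enabling, predicted)


def match_mutations(
    tests: list[SubstrateTest] | dict[str, set[str]],
    mutations: dict[str, set[str]],
    regulator_map: dict[str, set[str]] | None = None,
) -> list[PredictionMatch]:
    """Score predicted genes against mutated elements, condition by condition.

    ``tests`` maps a condition either through a list of :class:`SubstrateTest`
    (condition = substrate metabolite) or directly as condition ->
    predicted-gene set.  ``mutations`` lists the mutated genes or regulatory
    elements per condition.  A mutated element that is a direct regulator of
    a predicted gene counts as a hit for it, via the explicit
    ``regulator_map`` (element -> genes it regulates); no regulon inference
    is performed.  A condition is a hit iff the (expanded) mutated set
    intersects the predicted set.
    """
    regulator_map = regulator_map or {}
    if isinstance(tests, dict):
        predicted_by_condition = {c: set(g) for c, g in tests.items()}
    else:
        predicted_by_condition = {t.substrate_metabolite: set(t.predicted_genes) for t in tests}
    out = []
    for condition in mutations:
        if condition not in predicted_by_condition:
            raise KeyError(f"no substrate test for condition {condition!r}")
        predicted = predicted_by_condition[condition]
        mutated = set(mutations[condition])
        expanded = set(mutated)
        for element in mutated:
            expanded |= regulator_map.get(element, set())
        out.append(
            PredictionMatch(
                condition=condition,
                predicted_genes=predicted,
                mutated_genes=mutated,
                hit=bool(predicted & expanded),
            )
        )
    return out


def build_contingency_table(
    matches: list[PredictionMatch], gene_universe: set[str]
) -> ContingencyTable2x2:
    """One defensible 2x2 construction: predicted × mutated over a gene universe.

    Genes predicted in any condition versus genes mutated (after no
    regulator expansion — raw mutated ids intersected with the universe) in
    any condition, counted over ``gene_universe`` (typically the model's
    genes).  This is a helper, not a canonical definition: other
    constructions of the table are equally defensible.
    """
    predicted = set().union(*(m.predicted_genes for m in matches)) & gene_universe
    mutated = set().union(*(m.mutated_genes for m in matches)) & gene_universe
    a = len(predicted & mutated)
    b = len(predicted - mutated)
    c = len(mutated - predicted)
    d = len(gene_universe) - a - b - c
    return ContingencyTable2x2(a, b, c, d)


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value by exact hypergeometric enumeration.

    Enumerates every 2x2 table with the observed margins, sums the
    hypergeometric probabilities of tables no more probable than the
    observed one, and returns the sum.  Computed in exact rational
    arithmetic, so the result is the enumeration definition itself up to
    one final float conversion.  Degenerate margins (an empty row or
    column) give p = 1 with a warning.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if min(r1, r2, c1, c2) == 0:
        warnings.warn("degenerate 2x2 margins; Fisher exact p = 1", stacklevel=2)
        return 1.0
    denom = comb(n, c1)

    def weight(x: int) -> Fraction:
        # P(A = x) given the margins, times denom (integer weight)
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    observed = weight(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = Fraction(0)
    for x in range(lo, hi + 1):
        w = weight(x)
        if w <= observed:
            total += w
    return float(min(total, Fraction(1)))
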