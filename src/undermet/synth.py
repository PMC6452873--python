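"""Synthetic inputs with the statistical structure each analysis stage assumes.

Four generators, all deterministic under a fixed seed:

* toy stoichiometric networks with a biomass objective and one-gene GPRs;
* planted underground scenarios — a novel substrate the base network cannot
  use, reachable only through a planted promiscuous reaction (the planting
  is verified by FBA at generation time, so downstream recovery tests
  cannot pass vacuously);
* exponential OD600 series with additive Gaussian plate-reader noise;
* per-base coverage profiles with planted fold-change segments under
  Poisson or negative-binomial noise.

These emulate the *structure* of real study inputs (growth screens, ALE
flask series, WGS depth), not their biology; see the methods note for what
that does and does not validate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ale import FlaskSeries, ODMeasurement
from .engine import fba
from .model import LARGE_BOUND, MetabolicModel, Metabolite, Reaction, add_reaction, set_exchange
from .underground import GROWTH_THRESHOLD, UndergroundReaction

NATIVE_SUBSTRATE = "nat_e"


@dataclass
class PlantedScenario:
    """A base model plus planted underground reactions and their ground truth."""

    model: MetabolicModel
    underground: list[UndergroundReaction]
    novel_substrates: list[tuple[str, str]]  # (metabolite id, planted gene id)
    seed: int = 0


def make_toy_model(n_branches: int = 1, seed: int = 0) -> MetabolicModel:
    """A small growing network: uptake -> conversion route(s) -> biomass.

    One native carbon exchange (``EX_nat_e``, lower bound −10), a transport
    step, ``n_branches`` parallel two-step conversion routes to a biomass
    precursor, and a biomass sink as objective.  Every enzymatic reaction
    carries a one-gene GPR.  The seed picks the biomass yield (precursor
    units per biomass unit) so property tests see varied but reproducible
    stoichiometry; the FBA optimum is uptake-bound / yield-coefficient > 0.
    """
    if n_branches < 1:
        raise ValueError("n_branches >= 1")
    rng = np.random.default_rng(seed)
    y = float(rng.choice([1.0, 2.0]))  # precursor units per unit biomass

    mets = [
        Metabolite("nat_e", "native carbon (extracellular)", "e"),
        Metabolite("nat_c", "native carbon (cytosol)", "c"),
        Metabolite("prec_c", "biomass precursor", "c"),
    ]
    rxns = [
        Reaction("EX_nat_e", {"nat_e": -1.0}, lower_bound=-10.0,
                 upper_bound=LARGE_BOUND, tags={"exchange"}),
        Reaction("TPT_nat", {"nat_e": -1.0, "nat_c": 1.0}, lower_bound=0.0,
                 upper_bound=LARGE_BOUND, gpr="g_tpt"),
    ]
    genes = {"g_tpt"}
    for b in range(1, n_branches + 1):
        mid = f"int{b}_c"
        mets.append(Metabolite(mid, f"branch {b} intermediate", "c"))
        for suffix, stoich in (("a", {"nat_c": -1.0, mid: 1.0}),
                               ("b", {mid: -1.0, "prec_c": 1.0})):
            gene = f"g_b{b}{suffix}"
            rxns.append(Reaction(f"CNV_{b}{suffix}", stoich, lower_bound=0.0,
                                 upper_bound=LARGE_BOUND, gpr=gene))
            genes.add(gene)
    rxns.append(Reaction("BIOMASS", {"prec_c": -y}, lower_bound=0.0,
                         upper_bound=LARGE_BOUND, tags={"biomass"}))
    return MetabolicModel(metabolites=mets, reactions=rxns, genes=genes,
                          objective_id="BIOMASS", id=f"toy_b{n_branches}_s{seed}")


def plant_underground(
    model: MetabolicModel,
    substrate_id: str,
    gene_id: str,
    seed: int = 0,
    existing: list[UndergroundReaction] | None = None,
    close_uptake: tuple[str, ...] = (NATIVE_SUBSTRATE,),
) -> PlantedScenario:
    """Plant an underground reaction that alone enables growth on a new substrate.

    The growth-supporting carbon uptakes named in ``close_uptake`` are shut
    (exchange lower bound 0) so the novel substrate is tested as the sole
    carbon source, mirroring a minimal-medium growth screen.  The substrate
    metabolite and a closed exchange are added to the base model if absent;
    the planted underground reaction converts the substrate to the native
    cytosolic carbon under a single catalyzing gene.  Generation verifies by
    FBA that (i) the base model cannot grow on the substrate, (ii) the
    planted reaction enables growth, and (iii) no previously planted
    reaction in ``existing`` provides an unintended alternative route; any
    violation aborts with an error.
    """
    base = model.copy()
    for met in close_uptake:
        ex = base.exchange_for(met)
        if ex is not None and ex.lower_bound < 0:
            ex.lower_bound = 0.0
    if substrate_id not in base.metabolite_ids:
        compartment = substrate_id.rsplit("_", 1)[-1] if "_" in substrate_id else "e"
        base.metabolites.append(Metabolite(substrate_id, compartment=compartment))
        base.validate()
    if base.exchange_for(substrate_id) is None:
        base = set_exchange(base, substrate_id, 0.0, LARGE_BOUND)

    open_model = set_exchange(base, substrate_id, -10.0, 0.0)
    wt = fba(open_model)
    if wt.optimal and wt.objective_value > GROWTH_THRESHOLD:
        raise ValueError(
            f"cannot plant on {substrate_id}: base model already grows "
            f"({wt.objective_value:.4g} h^-1)"
        )

    existing = list(existing or [])
    for ug in existing:
        sol = fba(add_reaction(open_model, ug.reaction))
        # a second planting on the SAME substrate is intended; anything else
        # that unlocks growth here is an unintended alternative route
        if (sol.optimal and sol.objective_value > GROWTH_THRESHOLD
                and substrate_id not in ug.reaction.stoichiometry):
            raise ValueError(
                f"unintended alternative route: {ug.reaction.id} enables "
                f"growth on {substrate_id}"
            )

    planted = UndergroundReaction(
        reaction=Reaction(
            id=f"UG_{substrate_id}_{gene_id}",
            stoichiometry={substrate_id: -1.0, "nat_c": 1.0},
            lower_bound=0.0,
            upper_bound=LARGE_BOUND,
            gpr=gene_id,
            tags={"underground"},
        ),
        catalyzing_genes={gene_id},
    )
    sol = fba(add_reaction(open_model, planted.reaction))
    if not (sol.optimal and sol.objective_value > GROWTH_THRESHOLD):
        raise ValueError(f"planting failed: {planted.reaction.id} does not enable growth")

    underground = existing + [planted]
    pairs = [(substrate_id, gene_id)]
    return PlantedScenario(model=base, underground=underground,
                           novel_substrates=pairs, seed=seed)


def make_planted_scenario(
    n_branches: int = 2, n_substrates: int = 1, seed: int = 0
) -> PlantedScenario:
    """Toy model with ``n_substrates`` independently planted novel substrates."""
    model = make_toy_model(n_branches=n_branches, seed=seed)
    underground: list[UndergroundReaction] = []
    pairs: list[tuple[str, str]] = []
    for k in range(n_substrates):
        sub, gene = f"novel{k}_e", f"g_ug{k}"
        scen = plant_underground(model, sub, gene, seed=seed, existing=underground)
        model, underground = scen.model, scen.underground
        pairs.extend(scen.novel_substrates)
    return PlantedScenario(model=model, underground=underground,
                           novel_substrates=pairs, seed=seed)


def simulate_od_series(
    mu: float,
    od0: float,
    times: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    flask_id: str = "flask",
) -> FlaskSeries:
    """Exponential growth OD(t) = od0·e^{mu·t} plus additive Gaussian noise.

    Noise is on the absorbance scale (plate-reader error model); values are
    truncated below at 1e-4 so the log transform stays defined.
    """
    if od0 <= 0 or noise_sd < 0:
        raise ValueError("od0 > 0 and noise_sd >= 0 required")
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    od = od0 * np.exp(mu * t) + rng.normal(0.0, noise_sd, size=t.shape)
    od = np.maximum(od, 1e-4)
    return FlaskSeries(
        flask_id=flask_id,
        measurements=[ODMeasurement(float(ti), float(oi)) for ti, oi in zip(t, od)],
    )


def simulate_coverage(
    genome_length: int,
    mean_depth: float,
    events: list[tuple[int, int, float]] = (),
    noise: str = "poisson",
    dispersion: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-base depth with planted fold-change segments.

    ``events`` are (start, end, fold) in 1-based inclusive coordinates and
    must lie within the genome and not overlap.  Depth at each position is
    drawn with mean mean_depth × fold(position) from a Poisson or a
    negative-binomial (``noise="negbin"``, with ``dispersion`` the NB size
    parameter r, variance m + m²/r).
    """
    rng = np.random.default_rng(seed)
    fold = np.ones(genome_length)
    occupied = np.zeros(genome_length, dtype=bool)
    for start, end, f in events:
        if not (1 <= start <= end <= genome_length):
            raise ValueError(f"event ({start}, {end}) outside genome")
        if f <= 0:
            raise ValueError("event fold must be positive")
        sl = slice(start - 1, end)
        if occupied[sl].any():
            raise ValueError(f"event ({start}, {end}) overlaps a previous event")
        occupied[sl] = True
        fold[sl] = f
    mean = mean_depth * fold
    if noise == "poisson":
        return rng.poisson(mean).astype(float)
    if noise == "negbin":
        if dispersion is None or dispersion <= 0:
            raise ValueError("negbin noise requires a positive dispersion")
        p = dispersion / (dispersion + mean)
        return rng.negative_binomial(dispersion, p).astype(float)
    raise ValueError(f"unknown noise model {noise!r}")


def write_depth_tsv(path, depths: np.ndarray, contig: str = "chromosome") -> None:
    """Write per-base depth as the (contig, 1-based pos, depth) TSV the caller reads."""
    import pandas as pd

    pd.DataFrame(
        {
            "contig": contig,
            "pos": np.arange(1, len(depths) + 1),
            "depth": np.asarray(depths),
        }
    ).to_csv(path, sep="\t", header=False, index=False)


def simulate_mutation_table(
    tests,
    hit_rate: float,
    decoy_genes: set[str],
    seed: int = 0,
) -> dict[str, set[str]]:
    """Mutation tables with a tunable hit rate against predictions.

    For each substrate test, with probability ``hit_rate`` the mutated set
    contains one of the predicted genes, otherwise one decoy gene drawn
    from ``decoy_genes`` (which must not intersect the predictions).
    """
    if not 0 <= hit_rate <= 1:
        raise ValueError("hit_rate in [0, 1]")
    rng = np.random.default_rng(seed)
    decoys = sorted(decoy_genes)
    out: dict[str, set[str]] = {}
    for test in tests:
        predicted = sorted(test.predicted_genes)
        usable_decoys = [g for g in decoys if g not in test.predicted_genes]
        if not usable_decoys and hit_rate < 1:
            raise ValueError("decoy_genes empty (or all predicted) with hit_rate < 1")
        if predicted and rng.random() < hit_rate:
            out[test.substrate_metabolite] = {predicted[rng.integers(len(predicted))]}
        else:
            out[test.substrate_metabolite] = {
                usable_decoys[rng.integers(len(usable_decoys))]
            }
    return out
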