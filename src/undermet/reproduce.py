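"""Genome-scale reproduction workflows for the full *E. coli* model.

These functions run the published genome-scale analyses when pointed at the
underground-augmented iJO1366 model (distributed as study supplementary
material; multi-megabyte, so not bundled here):

* enumerate carbon sources that only grow with a single underground
  reaction added;
* intersect a genomic deletion-region gene list with the model's genes;
* test each intersected gene for individual essentiality at the 99% FVA
  growth cutoff, and all of them deleted as a group.

Each function takes explicit inputs (model path or object, gene lists) and
computes everything at call time.
"""

from __future__ import annotations

from .engine import fba, group_deletion, single_gene_deletions
from .io import load_model
from .model import MetabolicModel, set_exchange
from .underground import GROWTH_THRESHOLD, UndergroundReaction, test_substrate


def split_underground(model: MetabolicModel) -> tuple[MetabolicModel, list[UndergroundReaction]]:
    """Separate a combined model into its base network and underground reactions.

    Underground reactions are identified by their ``underground`` tag (set
    from the JSON ``notes`` on load) or by a ``u`` id suffix convention.
    """
    base = model.copy()
    underground = []
    keep = []
    for rxn in base.reactions:
        if "underground" in rxn.tags:
            underground.append(UndergroundReaction(reaction=rxn.copy()))
        else:
            keep.append(rxn)
    base.reactions = keep
    base.validate()
    return base, underground


def enumerate_enabled_sources(
    model_or_path,
    substrates: list[str],
    uptake: float = 10.0,
    close_uptake: tuple[str, ...] = ("glc__D_e",),
) -> dict[str, list[str]]:
    """Substrate -> enabling underground reaction ids, over a candidate list.

    The default-medium carbon uptakes named in ``close_uptake`` (glucose by
    default) are shut first, so each candidate is tested as the sole carbon
    source.  A substrate appears in the result only if the base network
    cannot grow on it and at least one single underground reaction addition
    can.
    """
    model = _as_model(model_or_path)
    for met in close_uptake:
        ex = model.exchange_for(met)
        if ex is not None and ex.lower_bound < 0:
            model = set_exchange(model, met, 0.0, ex.upper_bound)
    base, underground = split_underground(model)
    out: dict[str, list[str]] = {}
    for substrate in substrates:
        test = test_substrate(base, underground, substrate, uptake=uptake)
        if test.wt_growth <= GROWTH_THRESHOLD and test.enabling:
            out[substrate] = [rid for rid, _ in test.enabling]
    return out


def intersect_deletion_region(model_or_path, region_genes: list[str]) -> list[str]:
    """Genes from a genomic deletion region that are present in the model."""
    model = _as_model(model_or_path)
    return sorted(set(region_genes) & model.genes)


def deletion_region_impact(
    model_or_path,
    region_genes: list[str],
    substrate: str | None = None,
    uptake: float = 10.0,
    essentiality_fraction: float = 0.99,
) -> dict:
    """Essentiality of a deletion region's model genes, singly and as a group.

    Optionally sets the growth substrate first.  A gene is called
    individually dispensable if its knockout retains at least
    ``essentiality_fraction`` of the wild-type optimum (the 99% cutoff used
    in FVA-style deletion screens).  Returns the per-gene optima, the list
    of individually essential genes, the group-deletion optimum, and
    whether the group deletion leaves the optimum unchanged (within 1e-6
    relative).
    """
    model = _as_model(model_or_path)
    if substrate is not None:
        model = set_exchange(model, substrate, -abs(uptake), 0.0)
    model_genes = intersect_deletion_region(model, region_genes)
    wt = fba(model)
    if not wt.optimal or wt.objective_value <= GROWTH_THRESHOLD:
        raise ValueError("wild-type model does not grow; check substrate setup")
    per_gene = single_gene_deletions(model, model_genes)
    cutoff = essentiality_fraction * wt.objective_value
    essential = sorted(g for g, v in per_gene.items() if v < cutoff)
    group = group_deletion(model, set(model_genes))
    group_opt = group.objective_value if group.optimal else 0.0
    return {
        "wild_type_growth": wt.objective_value,
        "model_genes": model_genes,
        "n_model_genes": len(model_genes),
        "per_gene_growth": per_gene,
        "individually_essential": essential,
        "n_individually_essential": len(essential),
        "group_deletion_growth": group_opt,
        "group_deletion_unchanged": abs(group_opt - wt.objective_value)
        <= 1e-6 * max(1.0, abs(wt.objective_value)),
    }


def _as_model(model_or_path) -> MetabolicModel:
    if isinstance(model_or_path, MetabolicModel):
        return model_or_path
    return load_model(model_or_path)
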