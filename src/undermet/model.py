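"""Genome-scale metabolic model container and the edits applied before simulation.

A :class:`MetabolicModel` is a stoichiometric network: metabolites, reactions
with flux bounds (mmol gDW^-1 h^-1) and gene-protein-reaction (GPR) boolean
rules, and one biomass objective reaction whose flux proxies growth rate
(h^-1).  The editing operations here are the ones a growth-prediction study
needs before solving any linear program: opening an exchange for a carbon
source, adding a reaction (e.g. a promiscuous "underground" activity), adding
a demand sink for a dead-end metabolite, registering an isozyme on a GPR, and
knocking out genes.

All editing functions are functional: they return a modified copy and leave
the input model untouched.
"""

from __future__ import annotations

import copy as _copy
import logging
import re
from dataclasses import dataclass, field

log = logging.getLogger("undermet.model")

#: Conventional "unconstrained" flux bound magnitude, mmol gDW^-1 h^-1.
LARGE_BOUND = 1000.0


class ModelValidationError(ValueError):
    """A model or model file violates a structural invariant."""


class GPRSyntaxError(ValueError):
    """A gene-protein-reaction rule failed to parse."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""

    def __post_init__(self):
        if not self.id:
            raise ModelValidationError("metabolite id must be non-empty")


@dataclass
class Reaction:
    """A reaction: stoichiometry maps metabolite id -> coefficient (< 0 consumed)."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -LARGE_BOUND
    upper_bound: float = LARGE_BOUND
    gpr: str = ""
    tags: set[str] = field(default_factory=set)
    name: str = ""

    def __post_init__(self):
        if not self.id:
            raise ModelValidationError("reaction id must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        zeros = [m for m, c in self.stoichiometry.items() if c == 0]
        if zeros:
            raise ModelValidationError(
                f"reaction {self.id}: zero stoichiometric coefficient for {zeros}"
            )

    @property
    def genes(self) -> set[str]:
        return gpr_genes(self.gpr)

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            gpr=self.gpr,
            tags=set(self.tags),
            name=self.name,
        )


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    genes: set[str]
    objective_id: str
    id: str = "model"

    def __post_init__(self):
        self.validate()

    # -- lookups -----------------------------------------------------------

    @property
    def metabolite_ids(self) -> set[str]:
        return {m.id for m in self.metabolites}

    @property
    def reaction_ids(self) -> set[str]:
        return {r.id for r in self.reactions}

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(f"no reaction {rxn_id!r} in model {self.id!r}")

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(f"no metabolite {met_id!r} in model {self.id!r}")

    def exchange_for(self, metabolite_id: str) -> Reaction | None:
        """The exchange reaction touching exactly this metabolite, if any."""
        for r in self.reactions:
            if "exchange" in r.tags and set(r.stoichiometry) == {metabolite_id}:
                return r
        return None

    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(met_ids) != len(set(met_ids)):
            dup = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(rxn_ids) != len(set(rxn_ids)):
            dup = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dup}")
        if self.objective_id not in set(rxn_ids):
            raise ModelValidationError(
                f"objective reaction {self.objective_id!r} not in model"
            )
        declared = set(met_ids)
        for r in self.reactions:
            undeclared = set(r.stoichiometry) - declared
            if undeclared:
                raise ModelValidationError(
                    f"reaction {r.id} references undeclared metabolites: "
                    f"{sorted(undeclared)}"
                )
            missing = r.genes - self.genes
            if missing:
                # register rather than fail: GPR is the authoritative gene source
                log.info("registering genes from gpr of %s: %s", r.id, sorted(missing))
                self.genes |= missing
            if ("exchange" in r.tags or "demand" in r.tags) and len(r.stoichiometry) != 1:
                raise ModelValidationError(
                    f"boundary reaction {r.id} must touch exactly one metabolite"
                )

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=[_copy.copy(m) for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            genes=set(self.genes),
            objective_id=self.objective_id,
            id=self.id,
        )


# ---------------------------------------------------------------------------
# GPR parsing and evaluation
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(\(|\)|[A-Za-z0-9_.\-]+)")


def _tokenize_gpr(expr: str) -> list[tuple[str, int]]:
    tokens, pos = [], 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if m is None:
            raise GPRSyntaxError(f"unexpected character {expr[pos]!r}", pos)
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse_gpr(expr: str):
    """Parse a GPR rule into an AST of ('and'|'or', [children]) / ('gene', id).

    Grammar: case-insensitive AND/OR with parentheses; OR binds looser than
    AND; empty string means "always active" (AST ``None``).
    """
    tokens = _tokenize_gpr(expr)
    if not tokens:
        return None
    idx = 0

    def peek():
        return tokens[idx][0] if idx < len(tokens) else None

    def parse_or():
        nonlocal idx
        node = parse_and()
        children = [node]
        while peek() is not None and peek().lower() == "or":
            idx += 1
            children.append(parse_and())
        return children[0] if len(children) == 1 else ("or", children)

    def parse_and():
        nonlocal idx
        node = parse_atom()
        children = [node]
        while peek() is not None and peek().lower() == "and":
            idx += 1
            children.append(parse_atom())
        return children[0] if len(children) == 1 else ("and", children)

    def parse_atom():
        nonlocal idx
        tok = peek()
        if tok is None:
            raise GPRSyntaxError("unexpected end of expression", len(expr))
        pos = tokens[idx][1]
        if tok == "(":
            idx += 1
            node = parse_or()
            if peek() != ")":
                raise GPRSyntaxError("unbalanced parenthesis", pos)
            idx += 1
            return node
        if tok == ")":
            raise GPRSyntaxError("unexpected ')'", pos)
        if tok.lower() in ("and", "or"):
            raise GPRSyntaxError(f"unexpected operator {tok!r}", pos)
        idx += 1
        return ("gene", tok)

    ast = parse_or()
    if idx != len(tokens):
        raise GPRSyntaxError(f"trailing token {tokens[idx][0]!r}", tokens[idx][1])
    return ast


def gpr_genes(expr: str) -> set[str]:
    """All gene ids appearing in a GPR rule."""
    ast = parse_gpr(expr)
    out: set[str] = set()

    def walk(node):
        if node is None:
            return
        kind = node[0]
        if kind == "gene":
            out.add(node[1])
        else:
            for child in node[1]:
                walk(child)

    walk(ast)
    return out


def eval_gpr(expr: str, inactive_genes: set[str]) -> bool:
    """Evaluate a GPR rule with the given genes knocked out (set to False).

    Empty rules are always active (spontaneous / orphan reactions).
    """
    ast = parse_gpr(expr)

    def ev(node) -> bool:
        if node is None:
            return True
        kind = node[0]
        if kind == "gene":
            return node[1] not in inactive_genes
        if kind == "and":
            return all(ev(c) for c in node[1])
        return any(ev(c) for c in node[1])

    return ev(ast)


# ---------------------------------------------------------------------------
# Model edits
# ---------------------------------------------------------------------------

def set_exchange(
    model: MetabolicModel, metabolite_id: str, lb: float, ub: float
) -> MetabolicModel:
    """Open (or create) the exchange reaction for a metabolite with given bounds.

    Negative lower bound = uptake allowed.  Idempotent in the resulting
    bounds: calling twice with the same arguments yields the same model.
    """
    if lb > ub:
        raise ModelValidationError(f"exchange bounds inverted: {lb} > {ub}")
    out = model.copy()
    out.metabolite(metabolite_id)  # raises KeyError if unknown
    rxn = out.exchange_for(metabolite_id)
    if rxn is None:
        rxn = Reaction(
            id=f"EX_{metabolite_id}",
            stoichiometry={metabolite_id: -1.0},
            lower_bound=lb,
            upper_bound=ub,
            tags={"exchange"},
        )
        out.reactions.append(rxn)
        out.validate()
    else:
        rxn.lower_bound = lb
        rxn.upper_bound = ub
    return out


def add_reaction(model: MetabolicModel, rxn: Reaction) -> MetabolicModel:
    """Add a reaction column; undeclared metabolites are registered as new.

    Adding a column can only enlarge the feasible flux set, so the FBA
    optimum never decreases.
    """
    if rxn.id in model.reaction_ids:
        raise ModelValidationError(f"reaction id {rxn.id!r} already in model")
    out = model.copy()
    known = out.metabolite_ids
    for met_id in rxn.stoichiometry:
        if met_id not in known:
            compartment = met_id.rsplit("_", 1)[-1] if "_" in met_id else ""
            out.metabolites.append(Metabolite(id=met_id, compartment=compartment))
    out.reactions.append(rxn.copy())
    out.genes |= rxn.genes
    out.validate()
    return out


def add_demand(model: MetabolicModel, metabolite_id: str) -> MetabolicModel:
    """Add an irreversible sink ``DM_<met>`` draining one unit of the metabolite.

    Used to keep a dead-end product (e.g. glyceraldehyde) from blocking flux
    through upstream reactions in knockout simulations.
    """
    model.metabolite(metabolite_id)
    dm_id = f"DM_{metabolite_id}"
    if dm_id in model.reaction_ids:
        raise ModelValidationError(f"demand reaction {dm_id!r} already in model")
    rxn = Reaction(
        id=dm_id,
        stoichiometry={metabolite_id: -1.0},
        lower_bound=0.0,
        upper_bound=LARGE_BOUND,
        tags={"demand"},
    )
    return add_reaction(model, rxn)


def add_isozyme(model: MetabolicModel, reaction_id: str, gene_id: str) -> MetabolicModel:
    """Register an additional catalyzing gene: gpr becomes ``(old) or (gene)``."""
    out = model.copy()
    rxn = out.reaction(reaction_id)
    rxn.gpr = f"({rxn.gpr}) or ({gene_id})" if rxn.gpr else f"({gene_id})"
    out.genes.add(gene_id)
    return out


def knock_out_genes(model: MetabolicModel, genes: set[str]) -> MetabolicModel:
    """Close every reaction whose GPR evaluates false with ``genes`` inactive.

    Genes absent from every GPR (e.g. non-metabolic genes from a genomic
    deletion list) are inert and only logged, so whole deletion-region gene
    lists can be passed directly.
    """
    unknown = set(genes) - model.genes
    if unknown:
        log.warning("knockout genes not in model (ignored): %s", sorted(unknown))
    out = model.copy()
    for rxn in out.reactions:
        if rxn.gpr and not eval_gpr(rxn.gpr, set(genes)):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out
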