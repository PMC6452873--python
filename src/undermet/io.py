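"""Model I/O: BiGG-dialect JSON (read/write) and SBML Level 3 + FBC (read).

The JSON dialect is the one genome-scale *E. coli* models are distributed
in: ``metabolites`` / ``reactions`` / ``genes`` arrays, with per-reaction
``lower_bound`` / ``upper_bound`` / ``gene_reaction_rule`` and the objective
marked by ``objective_coefficient``.  Reaction tags (exchange / demand /
underground / biomass) round-trip through the reaction ``notes`` field and
are additionally inferred from conventional id prefixes (``EX_``, ``DM_``)
on load so stock BiGG files work unmodified.
"""

from __future__ import annotations

import json
from pathlib import Path

from .model import LARGE_BOUND, MetabolicModel, Metabolite, ModelValidationError, Reaction

KNOWN_TAGS = ("exchange", "demand", "underground", "biomass")


class ModelParseError(ValueError):
    """A model file could not be parsed; the message names the offending record."""


def _infer_tags(rxn_id: str, explicit: list[str] | None) -> set[str]:
    tags = set(explicit or ())
    if rxn_id.startswith("EX_"):
        tags.add("exchange")
    elif rxn_id.startswith("DM_"):
        tags.add("demand")
    return {t for t in tags if t in KNOWN_TAGS}


def load_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Load a metabolic model from JSON (BiGG dialect) or SBML L3+FBC.

    ``format`` is ``"json"`` or ``"sbml"``; by default it is inferred from the
    file suffix (``.xml``/``.sbml`` -> SBML, anything else JSON).
    """
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "json"
    if format == "json":
        return _load_json(path)
    if format == "sbml":
        return _load_sbml(path)
    raise ValueError(f"unknown model format {format!r}")


def _load_json(path: Path) -> MetabolicModel:
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ModelParseError(f"{path}: not valid JSON: {e}") from e
    for key in ("metabolites", "reactions"):
        if key not in raw:
            raise ModelParseError(f"{path}: missing top-level {key!r} array")

    metabolites = []
    for rec in raw["metabolites"]:
        try:
            metabolites.append(
                Metabolite(
                    id=rec["id"],
                    name=rec.get("name", ""),
                    compartment=rec.get("compartment", ""),
                )
            )
        except (KeyError, TypeError) as e:
            raise ModelParseError(f"{path}: malformed metabolite record {rec!r}") from e

    reactions, objective_id = [], None
    for rec in raw["reactions"]:
        try:
            stoich = {m: float(c) for m, c in rec["metabolites"].items() if float(c) != 0}
            rxn = Reaction(
                id=rec["id"],
                name=rec.get("name", ""),
                stoichiometry=stoich,
                lower_bound=float(rec.get("lower_bound", -LARGE_BOUND)),
                upper_bound=float(rec.get("upper_bound", LARGE_BOUND)),
                gpr=rec.get("gene_reaction_rule", ""),
                tags=_infer_tags(rec["id"], (rec.get("notes") or {}).get("tags")),
            )
        except (KeyError, TypeError, ValueError) as e:
            if isinstance(e, ModelValidationError):
                raise
            raise ModelParseError(
                f"{path}: malformed reaction record {rec.get('id', rec)!r}"
            ) from e
        if float(rec.get("objective_coefficient", 0)) != 0:
            objective_id = rxn.id
            rxn.tags.add("biomass")
        reactions.append(rxn)

    if objective_id is None:
        # fall back to a biomass-tagged or biomass-named reaction
        for rxn in reactions:
            if "biomass" in rxn.tags or "biomass" in rxn.id.lower():
                objective_id = rxn.id
                break
    if objective_id is None:
        raise ModelValidationError(f"{path}: no objective reaction declared")

    genes = {g["id"] for g in raw.get("genes", [])}
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        objective_id=objective_id,
        id=raw.get("id", Path(path).stem),
    )


def save_model(model: MetabolicModel, path: str | Path) -> None:
    """Write a model as BiGG-dialect JSON (stable key order, round-trip safe)."""
    raw = {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": dict(sorted(r.stoichiometry.items())),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gpr,
                "objective_coefficient": 1.0 if r.id == model.objective_id else 0.0,
                "notes": {"tags": sorted(r.tags)},
            }
            for r in model.reactions
        ],
        "genes": [{"id": g} for g in sorted(model.genes)],
    }
    Path(path).write_text(json.dumps(raw, indent=1, sort_keys=False) + "\n")


def _load_sbml(path: Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelParseError(f"{path}: SBML parse error: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelParseError(f"{path}: no <model> element")
    fbc = sbml_model.getPlugin("fbc")

    def strip(sid: str, prefixes=("M_", "R_", "G_")) -> str:
        for p in prefixes:
            if sid.startswith(p):
                return sid[len(p):]
        return sid

    metabolites = [
        Metabolite(
            id=strip(s.getId()),
            name=s.getName() or "",
            compartment=s.getCompartment() or "",
        )
        for s in sbml_model.getListOfSpecies()
    ]

    objective_id = None
    if fbc is not None and fbc.getActiveObjective() is not None:
        obj = fbc.getActiveObjective()
        for fo in obj.getListOfFluxObjectives():
            if fo.getCoefficient() != 0:
                objective_id = strip(fo.getReaction())
                break

    def param_value(pid: str, default: float) -> float:
        p = sbml_model.getParameter(pid) if pid else None
        return p.getValue() if p is not None else default

    reactions = []
    for r in sbml_model.getListOfReactions():
        stoich: dict[str, float] = {}
        for sr in r.getListOfReactants():
            stoich[strip(sr.getSpecies())] = stoich.get(strip(sr.getSpecies()), 0.0) - sr.getStoichiometry()
        for sr in r.getListOfProducts():
            stoich[strip(sr.getSpecies())] = stoich.get(strip(sr.getSpecies()), 0.0) + sr.getStoichiometry()
        stoich = {m: c for m, c in stoich.items() if c != 0}

        rfbc = r.getPlugin("fbc")
        if rfbc is not None and rfbc.getLowerFluxBound():
            lb = param_value(rfbc.getLowerFluxBound(), -LARGE_BOUND)
            ub = param_value(rfbc.getUpperFluxBound(), LARGE_BOUND)
        else:
            lb = -LARGE_BOUND if r.getReversible() else 0.0
            ub = LARGE_BOUND

        gpr = ""
        if rfbc is not None and rfbc.getGeneProductAssociation() is not None:
            gpr = _gpa_to_string(rfbc.getGeneProductAssociation().getAssociation(), fbc, strip)

        rxn_id = strip(r.getId())
        reactions.append(
            Reaction(
                id=rxn_id,
                name=r.getName() or "",
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                tags=_infer_tags(rxn_id, None),
            )
        )

    if objective_id is None:
        for rxn in reactions:
            if "biomass" in rxn.id.lower():
                objective_id = rxn.id
                break
    if objective_id is None:
        raise ModelValidationError(f"{path}: no active FBC objective")

    genes: set[str] = set()
    if fbc is not None:
        genes = {
            strip(gp.getLabel() or gp.getId())
            for gp in fbc.getListOfGeneProducts()
        }

    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        objective_id=objective_id,
        id=sbml_model.getId() or Path(path).stem,
    )


def _gpa_to_string(assoc, fbc, strip) -> str:
    """Render an FBC gene-product association tree as an AND/OR rule string."""
    import libsbml

    if assoc is None:
        return ""
    if assoc.isGeneProductRef():
        ref = assoc.getGeneProduct()
        sbml_model = assoc.getSBMLDocument().getModel()
        gp = sbml_model.getPlugin("fbc").getGeneProduct(ref)
        label = gp.getLabel() if gp is not None and gp.getLabel() else ref
        return strip(label)
    parts = [
        _gpa_to_string(assoc.getAssociation(i), fbc, strip)
        for i in range(assoc.getNumAssociations())
    ]
    op = " and " if assoc.getTypeCode() == libsbml.SBML_FBC_AND else " or "
    return "(" + op.join(parts) + ")"
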