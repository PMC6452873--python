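"""End-to-end run orchestration: predict -> match -> optional LP analyses.

A run is directory-isolated: every stage writes its outputs (tidy CSV /
JSON / BED) under the run directory and a machine-readable ``manifest.json``
records inputs with content hashes, the seed, package version, and
per-stage status.  Configuration is a flat key=value text file mirroring
the CLI flags; CLI flags override file values.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .engine import fva
from .io import load_model
from .model import MetabolicModel
from .reproduce import split_underground
from .underground import UndergroundReaction, match_mutations, test_substrate

log = logging.getLogger("undermet.pipeline")


@dataclass
class RunConfig:
    model_path: str
    substrates: list[str] = field(default_factory=list)
    underground_path: str | None = None  # sidecar CSV: reaction_id,gene_ids,native_reaction_id
    mutations_path: str | None = None    # CSV: condition,gene
    regulators_path: str | None = None   # CSV: element,gene
    close_uptake: list[str] = field(default_factory=list)
    uptake: float = 10.0
    fva_fraction: float = 0.99
    run_fva: bool = False
    seed: int = 0

    def validate(self) -> None:
        for p in (self.model_path, self.underground_path, self.mutations_path,
                  self.regulators_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        if not 0 < self.fva_fraction <= 1:
            raise ValueError("fva_fraction must be in (0, 1]")


def read_config(path) -> dict[str, str]:
    """Flat key=value config; '#' comments and blank lines ignored."""
    out: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{i}: expected key=value, got {line!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def config_from_mapping(raw: dict[str, str]) -> RunConfig:
    def split_list(s: str) -> list[str]:
        return [x.strip() for x in s.split(",") if x.strip()]

    return RunConfig(
        model_path=raw["model_path"],
        substrates=split_list(raw.get("substrates", "")),
        underground_path=raw.get("underground_path") or None,
        mutations_path=raw.get("mutations_path") or None,
        regulators_path=raw.get("regulators_path") or None,
        close_uptake=split_list(raw.get("close_uptake", "")),
        uptake=float(raw.get("uptake", 10.0)),
        fva_fraction=float(raw.get("fva_fraction", 0.99)),
        run_fva=raw.get("run_fva", "false").lower() in ("1", "true", "yes"),
        seed=int(raw.get("seed", 0)),
    )


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def load_underground_sidecar(model: MetabolicModel, path) -> list[UndergroundReaction]:
    """Underground reactions named by a sidecar CSV over reactions in the model.

    Columns: reaction_id, gene_ids (semicolon-separated), native_reaction_id.
    """
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        rxn = model.reaction(str(row["reaction_id"])).copy()
        genes = {g.strip() for g in str(row["gene_ids"]).split(";") if g.strip()}
        out.append(
            UndergroundReaction(
                reaction=rxn,
                catalyzing_genes=genes,
                native_reaction_id=str(row.get("native_reaction_id", "") or ""),
            )
        )
    return out


def read_mutation_csv(path) -> dict[str, set[str]]:
    df = pd.read_csv(path)
    return {
        str(cond): set(grp["gene"].astype(str))
        for cond, grp in df.groupby("condition", sort=False)
    }


def read_regulator_csv(path) -> dict[str, set[str]]:
    df = pd.read_csv(path)
    return {
        str(el): set(grp["gene"].astype(str))
        for el, grp in df.groupby("element", sort=False)
    }


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the configured stages, write outputs + manifest, return manifest.

    Stages: ``predict`` (per-substrate underground enabling test), ``match``
    (if a mutation table is configured), ``fva`` (if requested).  Any stage
    failure is recorded in the manifest and re-raised.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in (
                ("model", config.model_path),
                ("underground", config.underground_path),
                ("mutations", config.mutations_path),
                ("regulators", config.regulators_path),
            )
            if p is not None
        },
        "stages": {},
    }

    def finish(stage: str, status: str, **info):
        manifest["stages"][stage] = {"status": status, **info}
        log.info("stage %s: %s %s", stage, status, json.dumps(info, default=str))
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    try:
        model = load_model(config.model_path)
        if config.underground_path:
            underground = load_underground_sidecar(model, config.underground_path)
            ug_ids = {u.reaction.id for u in underground}
            base = model.copy()
            base.reactions = [r for r in base.reactions if r.id not in ug_ids]
            base.validate()
        else:
            base, underground = split_underground(model)
        for met in config.close_uptake:
            ex = base.exchange_for(met)
            if ex is not None:
                ex.lower_bound = 0.0

        rows = []
        tests = []
        for substrate in config.substrates:
            t = test_substrate(base, underground, substrate, uptake=config.uptake)
            tests.append(t)
            if t.enabling:
                for rid, growth in t.enabling:
                    rows.append({"substrate": substrate, "wt_growth": t.wt_growth,
                                 "enabling_reaction": rid, "growth": growth,
                                 "predicted_genes": ";".join(sorted(t.predicted_genes))})
            else:
                rows.append({"substrate": substrate, "wt_growth": t.wt_growth,
                             "enabling_reaction": "", "growth": float("nan"),
                             "predicted_genes": ""})
        pred_df = pd.DataFrame(rows)
        pred_df.to_csv(out_dir / "predictions.csv", index=False)
        finish("predict", "ok", n_substrates=len(config.substrates),
               output="predictions.csv")
    except Exception as e:
        finish("predict", "failed", error=str(e))
        raise

    if config.mutations_path:
        try:
            mutations = read_mutation_csv(config.mutations_path)
            regulators = (read_regulator_csv(config.regulators_path)
                          if config.regulators_path else {})
            predicted = {t.substrate_metabolite: t.predicted_genes for t in tests}
            matches = match_mutations(predicted, mutations, regulators)
            pd.DataFrame(
                {
                    "condition": [m.condition for m in matches],
                    "predicted_genes": [";".join(sorted(m.predicted_genes)) for m in matches],
                    "mutated_genes": [";".join(sorted(m.mutated_genes)) for m in matches],
                    "hit": [m.hit for m in matches],
                }
            ).to_csv(out_dir / "matches.csv", index=False)
            finish("match", "ok", hits=int(sum(m.hit for m in matches)),
                   n_conditions=len(matches), output="matches.csv")
        except Exception as e:
            finish("match", "failed", error=str(e))
            raise

    if config.run_fva:
        try:
            intervals = fva(base, fraction=config.fva_fraction)
            pd.DataFrame(
                {
                    "reaction_id": [i.reaction_id for i in intervals],
                    "min": [i.min_flux for i in intervals],
                    "max": [i.max_flux for i in intervals],
                    "fraction": [i.fraction for i in intervals],
                }
            ).to_csv(out_dir / "fva.csv", index=False)
            finish("fva", "ok", n_reactions=len(intervals), output="fva.csv")
        except Exception as e:
            finish("fva", "failed", error=str(e))
            raise

    return manifest
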