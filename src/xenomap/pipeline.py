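"""End-to-end pipeline: build, annotate, score, filter, signatures, sweep.

Every stage reads and writes files so any stage can be re-run in
isolation; a run manifest records package/backend versions and every
threshold and seed that influenced an artifact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import __version__
from .annotate import SomTable, SorTable, annotate_reactivity, annotate_som
from .bayes import filter_map, score_map
from .core import ChemistryError, MetabolicMap, canonicalize
from .rules import EnzymeDictionary, Ruleset, apply_enzyme_dictionary, predict_map
from .signatures import optimal_signatures, threshold_sweep, default_grid
from .synth import FixtureSpec, synthesize_tables

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def map_summary(m: MetabolicMap) -> dict:
    """Map characteristics: metabolite/reaction counts and the
    percentage of metabolites reactive to DNA (None until reactivity
    is annotated).  Counts include the parent compound."""
    n_nodes = len(m.nodes)
    n_edges = len(m.edges)
    flags = [n.dna_reactive for n in m.nodes.values()]
    if any(f is None for f in flags):
        n_reactive = None
        ratio = None
    else:
        n_reactive = sum(flags)
        ratio = round(100.0 * n_reactive / n_nodes, 1) if n_nodes else 0.0
    return {
        "n_metabolites": n_nodes,
        "n_reactions": n_edges,
        "n_reactive": n_reactive,
        "ratio_reactive_percent": ratio,
    }


@dataclass
class RecoveryReport:
    recovered: list[str]  # reference names found in the map
    missed: list[str]  # reference names absent from the map
    n_extra: int  # predicted metabolites not in the reference

    @property
    def n_recovered(self) -> int:
        return len(self.recovered)


def compare_to_reference(
    m: MetabolicMap,
    reference: Sequence[Union[str, tuple[str, str]]],
) -> RecoveryReport:
    """Match map nodes against a reference list by canonical SMILES.

    ``reference`` entries are SMILES strings or (name, smiles) pairs.
    """
    named = [
        (entry, entry) if isinstance(entry, str) else (entry[0], entry[1])
        for entry in reference
    ]
    canon = []
    for name, smiles in named:
        try:
            c, _ = canonicalize(smiles)
        except ChemistryError as exc:
            raise ChemistryError(f"reference entry {name!r}: {exc}") from exc
        canon.append((name, c))
    map_smiles = {n.smiles for n in m.nodes.values()}
    recovered = [name for name, c in canon if c in map_smiles]
    missed = [name for name, c in canon if c not in map_smiles]
    ref_set = {c for _, c in canon}
    n_extra = sum(1 for s in map_smiles if s not in ref_set)
    return RecoveryReport(recovered, missed, n_extra)


def write_scores_tsv(m: MetabolicMap, scores: dict, path) -> None:
    rows = [
        {
            "node_id": nid,
            "smiles": m.nodes[nid].smiles or "",
            "production_score": f"{scores[nid]:.12g}",
        }
        for nid in sorted(m.nodes, key=lambda n: (-scores[n], n))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


DEFAULT_CONFIG = {
    "cycles": 2,
    "ruleset": "builtin",
    "enzyme_dict": "builtin",
    "som": None,  # list of TSV paths, or {"synthetic": {"seed": N}}
    "sor": None,  # TSV path, or {"synthetic": {"seed": N}}
    "policy": "rank",
    "sor_threshold": 0.85,
    "filter_threshold": 0.10,
    "tie_tolerance": 1e-9,
    "sweep_step": 0.01,
    "reduction_mode": "figure10",
}


def run_pipeline(config: dict, outdir) -> dict:
    """Run every stage in order, writing one artifact per stage.

    Returns the manifest (also written to ``manifest.json``).
    Artifacts: map.json, annotated.json, scores.tsv, filtered.json,
    report.tsv, sweep.tsv.
    """
    cfg = {**DEFAULT_CONFIG, **config}
    if "parent_smiles" not in cfg:
        raise PipelineError("build", "config lacks 'parent_smiles'")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg, "stages": {}, "versions": _versions()}

    # -- build ---------------------------------------------------------
    try:
        ruleset = (
            Ruleset.builtin() if cfg["ruleset"] == "builtin"
            else Ruleset.from_tsv(cfg["ruleset"])
        )
        m = predict_map(
            cfg["parent_smiles"], ruleset, n_cycles=int(cfg["cycles"]),
            display_name=cfg.get("display_name"),
        )
        dictionary = (
            EnzymeDictionary.builtin() if cfg["enzyme_dict"] == "builtin"
            else EnzymeDictionary.from_tsv(cfg["enzyme_dict"])
        )
        m = apply_enzyme_dictionary(m, dictionary)
        m.to_json(outdir / "map.json")
        manifest["stages"]["build"] = {
            "artifact": "map.json", **map_summary(m)
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("build", str(exc)) from exc

    # -- annotate ------------------------------------------------------
    try:
        som_cfg, sor_cfg = cfg["som"], cfg["sor"]
        if isinstance(som_cfg, dict) and "synthetic" in som_cfg:
            synth_seed = int(som_cfg["synthetic"].get("seed", 0))
            som_tables = [synthesize_tables(m, seed=synth_seed)[0]]
        elif som_cfg:
            som_tables = [SomTable.from_tsv(p) for p in som_cfg]
        else:
            raise PipelineError(
                "annotate",
                "no SOM source configured: set config['som'] to a list of "
                "TSV paths or to {'synthetic': {'seed': N}}",
            )
        if isinstance(sor_cfg, dict) and "synthetic" in sor_cfg:
            sor_table = synthesize_tables(
                m, seed=int(sor_cfg["synthetic"].get("seed", 0))
            )[1]
        elif sor_cfg:
            sor_table = SorTable.from_tsv(sor_cfg)
        else:
            raise PipelineError(
                "annotate",
                "no SOR source configured: set config['sor'] to a TSV path "
                "or to {'synthetic': {'seed': N}}",
            )
        annotated = annotate_som(m, som_tables, policy=cfg["policy"])
        annotated = annotate_reactivity(
            annotated, sor_table, threshold=float(cfg["sor_threshold"])
        )
        annotated.to_json(outdir / "annotated.json")
        manifest["stages"]["annotate"] = {
            "artifact": "annotated.json", **map_summary(annotated)
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("annotate", str(exc)) from exc

    # -- score ---------------------------------------------------------
    try:
        scores = score_map(annotated, mode=cfg["reduction_mode"])
        write_scores_tsv(annotated, scores, outdir / "scores.tsv")
        for nid, s in scores.items():
            annotated.nodes[nid].production_score = s
        manifest["stages"]["score"] = {"artifact": "scores.tsv"}
    except Exception as exc:
        raise PipelineError("score", str(exc)) from exc

    # -- filter --------------------------------------------------------
    try:
        filtered = filter_map(annotated, scores, float(cfg["filter_threshold"]))
        filtered.to_json(outdir / "filtered.json")
        manifest["stages"]["filter"] = {
            "artifact": "filtered.json",
            "threshold": float(cfg["filter_threshold"]),
            **map_summary(filtered),
        }
    except Exception as exc:
        raise PipelineError("filter", str(exc)) from exc

    # -- signatures ----------------------------------------------------
    try:
        report = optimal_signatures(
            annotated,
            sor_threshold=float(cfg["sor_threshold"]),
            tolerance=float(cfg["tie_tolerance"]),
            mode=cfg["reduction_mode"],
        )
        report.to_frame().to_csv(outdir / "report.tsv", sep="\t", index=False)
        manifest["stages"]["signatures"] = {
            "artifact": "report.tsv",
            "max_score": report.max_score,
            "optimal": ["+".join(sorted(c)) for c in report.optimal_contexts],
        }
    except Exception as exc:
        raise PipelineError("signatures", str(exc)) from exc

    # -- sweep ---------------------------------------------------------
    try:
        sweep = threshold_sweep(
            annotated,
            grid=default_grid(float(cfg["sweep_step"])),
            tolerance=float(cfg["tie_tolerance"]),
            mode=cfg["reduction_mode"],
        )
        sweep.to_frame().to_csv(outdir / "sweep.tsv", sep="\t", index=False)
        manifest["stages"]["sweep"] = {
            "artifact": "sweep.tsv", "n_thresholds": len(sweep.grid)
        }
    except Exception as exc:
        raise PipelineError("sweep", str(exc)) from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def _versions() -> dict:
    import rdkit

    return {"xenomap": __version__, "rdkit": rdkit.__version__}
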