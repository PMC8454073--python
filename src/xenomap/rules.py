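"""Rule-based metabolite prediction.

Biotransformations are expressed as SMIRKS transforms applied with
RDKit.  The shipped catalogue (``data/rules.tsv``) is a curated set of
phase I oxidations (CYP chemistry: hydroxylations, dealkylations,
N-/S-oxidations) and phase II conjugations (glucuronidation,
acetylation, sulfation, glutathione conjugation), written so that atom
map number 1 marks the substrate atom on which the reaction occurs
(the receiving atom for conjugations/oxidations, the heteroatom losing
its substituent for dealkylations).  The catalogue is data, not code:
users can extend or replace it with their own TSV.

Map construction applies every rule to every node first created in the
previous cycle (the parent is cycle 0); products are deduplicated by
canonical SMILES and back-edges are dropped, so maps are DAGs by
construction.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional

from rdkit import Chem
from rdkit.Chem import AllChem

from .core import (
    ENZYME_FAMILIES,
    ChemistryError,
    MetabolicMap,
    mol_from_canonical,
)

logger = logging.getLogger(__name__)

EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class Rule:
    name: str
    phase: str  # "I" or "II"
    smirks: str


class Ruleset:
    """An ordered collection of named SMIRKS biotransformation rules."""

    def __init__(self, rules: Iterable[Rule]):
        self.rules = list(rules)
        names = [r.name for r in self.rules]
        if len(names) != len(set(names)):
            raise ValueError("duplicate rule names in ruleset")
        self._rxns = {}
        for r in self.rules:
            if r.phase not in ("I", "II"):
                raise ValueError(f"rule {r.name}: phase must be I or II")
            try:
                rxn = AllChem.ReactionFromSmarts(r.smirks)
            except Exception as exc:  # noqa: BLE001 - RDKit parser errors
                raise ChemistryError(
                    f"rule {r.name}: invalid SMIRKS {r.smirks!r}: {exc}"
                ) from exc
            if rxn is None or rxn.GetNumReactantTemplates() != 1:
                raise ChemistryError(
                    f"rule {r.name}: SMIRKS does not parse as a "
                    f"single-reactant transform: {r.smirks!r}"
                )
            rxn.Initialize()
            self._rxns[r.name] = rxn

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    def reaction(self, name: str):
        return self._rxns[name]

    @classmethod
    def from_tsv(cls, path) -> "Ruleset":
        rules = []
        with open(path) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                rules.append(Rule(row["rule_name"], row["phase"], row["smirks"]))
        return cls(rules)

    @classmethod
    def builtin(cls) -> "Ruleset":
        with resources.as_file(
            resources.files("xenomap.data") / "rules.tsv"
        ) as p:
            return cls.from_tsv(p)


class EnzymeDictionary:
    """Maps rule names to enzyme families (or EXCLUDED)."""

    VALID = set(ENZYME_FAMILIES) | {EXCLUDED}

    def __init__(self, entries: dict[str, str]):
        bad = {v for v in entries.values()} - self.VALID
        if bad:
            raise ValueError(f"unknown enzyme families in dictionary: {sorted(bad)}")
        self.entries = dict(entries)

    def __getitem__(self, rule_name: str) -> str:
        return self.entries[rule_name]

    def __contains__(self, rule_name: str) -> bool:
        return rule_name in self.entries

    @classmethod
    def from_tsv(cls, path) -> "EnzymeDictionary":
        entries = {}
        with open(path) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                entries[row["rule_name"]] = row["enzyme_family"]
        return cls(entries)

    @classmethod
    def builtin(cls) -> "EnzymeDictionary":
        with resources.as_file(
            resources.files("xenomap.data") / "enzyme_dict.tsv"
        ) as p:
            return cls.from_tsv(p)


def _apply_rule(rxn, mol: Chem.Mol) -> list[tuple[str, int]]:
    """Apply one transform to one molecule.

    Returns ``[(product_canonical_smiles, reaction_atom_index), ...]``
    deduplicated per product (keeping the lowest reaction-atom index,
    which resolves symmetry-equivalent sites deterministically).  The
    reaction atom is the substrate atom carrying map number 1, reported
    in the substrate's atom order (call with a molecule parsed from its
    canonical SMILES so indices are in canonical order).  Products that
    fail sanitization are skipped.
    """
    found: dict[str, int] = {}
    for prods in rxn.RunReactants((mol,)):
        for prod in prods:
            atom_idx = None
            for atom in prod.GetAtoms():
                if (
                    atom.HasProp("old_mapno")
                    and atom.GetIntProp("old_mapno") == 1
                    and atom.HasProp("react_atom_idx")
                ):
                    atom_idx = atom.GetIntProp("react_atom_idx")
                    break
            try:
                Chem.SanitizeMol(prod)
                smi = Chem.MolToSmiles(prod)
            except Exception:  # noqa: BLE001 - RDKit raises many types
                continue
            if atom_idx is None:
                continue
            if smi not in found or atom_idx < found[smi]:
                found[smi] = atom_idx
    return sorted(found.items())


def predict_map(
    parent_smiles: str,
    ruleset: Ruleset,
    n_cycles: int = 2,
    display_name: Optional[str] = None,
) -> MetabolicMap:
    """Build a map of metabolism by iterating the ruleset.

    Cycle ``k`` applies every rule to every node first created at cycle
    ``k - 1`` (the parent is cycle 0); each successful application adds
    a rank-``k`` edge and its product node, deduplicated by canonical
    SMILES.  Cycle-creating edges (products identical to an ancestor)
    are dropped.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    m = MetabolicMap()
    root = m.add_metabolite(parent_smiles, is_original=True, display_name=display_name)
    frontier = [root.node_id]
    for cycle in range(1, n_cycles + 1):
        created: list[str] = []
        for src_id in frontier:
            src = m.nodes[src_id]
            mol = mol_from_canonical(src.smiles)
            for rule in ruleset:
                rxn = ruleset.reaction(rule.name)
                try:
                    products = _apply_rule(rxn, mol)
                except Exception as exc:  # noqa: BLE001
                    logger.warning(
                        "rule %s failed on %s: %s", rule.name, src.smiles, exc
                    )
                    continue
                for smi, atom_idx in products:
                    known = m.node_for_smiles(smi)
                    if known is None:
                        dst = m.add_metabolite(smi)
                        created.append(dst.node_id)
                    else:
                        dst = known
                    m.new_edge(
                        src_id,
                        dst.node_id,
                        rule.name,
                        rank=cycle,
                        reaction_atom=atom_idx,
                    )
        frontier = created
    m.validate()
    return m


def apply_enzyme_dictionary(m: MetabolicMap, dictionary: EnzymeDictionary) -> MetabolicMap:
    """Label every edge with its enzyme family; drop EXCLUDED chemistry.

    Edges whose rule maps to EXCLUDED are removed, and nodes thereby
    left unreachable from the original compound are cascade-removed.
    Raises ``KeyError`` listing rules absent from the dictionary.
    """
    missing = sorted({e.rule_name for e in m.edges if e.rule_name not in dictionary})
    if missing:
        raise KeyError(f"rules missing from enzyme dictionary: {missing}")
    out = m.copy()
    doomed = []
    for e in out.edges:
        family = dictionary[e.rule_name]
        if family == EXCLUDED:
            doomed.append(e)
        else:
            e.enzyme_family = family
    out.remove_edges(doomed)
    if doomed:
        logger.info("removed %d edge(s) mapped to EXCLUDED", len(doomed))
    out.prune_unreachable()
    out.validate()
    return out


def ruleset_summary(ruleset: Ruleset, dictionary: EnzymeDictionary) -> dict:
    """Count rules per phase and per enzyme family."""
    per_family = {fam: 0 for fam in ENZYME_FAMILIES}
    n_phase1 = n_phase2 = n_excluded = 0
    for rule in ruleset:
        if rule.phase == "I":
            n_phase1 += 1
        else:
            n_phase2 += 1
        fam = dictionary[rule.name] if rule.name in dictionary else None
        if fam == EXCLUDED:
            n_excluded += 1
        elif fam is not None:
            per_family[fam] += 1
    return {
        "n_phase1": n_phase1,
        "n_phase2": n_phase2,
        "per_family": per_family,
        "n_excluded": n_excluded,
    }
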