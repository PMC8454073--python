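"""Attach site-of-metabolism and DNA-reactivity annotations to a map.

Site-of-metabolism (SOM) predictors score substrate atoms with the
probability that a given enzyme transforms them; site-of-reactivity
(SOR) predictors score atoms of a metabolite with the probability of
covalent binding to DNA.  Both kinds of prediction enter this package
only as tables (TSV), so maps can be annotated offline from any
provider's output, or from the synthetic generator.

The default annotation policy is keyed by rank, reflecting the
two-phase structure of xenobiotic metabolism: first-rank reactions are
mostly phase I and are matched against CYP-isoform (plus family-level
UGT) records; second-rank reactions are matched against family-level
records for all five families.  A by-enzyme policy is also provided,
which matches on the edge's enzyme family regardless of rank; it
avoids the known blind spot of the rank policy, where a genuine
rank-1 conjugation (e.g. an arylamine N-sulfamate) can never receive a
score because the rank-1 provider only covers CYPs and UGTs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFMCS

from .core import (
    CYP_ISOFORMS,
    ENZYME_FAMILIES,
    ChemistryError,
    MetabolicMap,
    ReactionEdge,
    mol_from_canonical,
)

logger = logging.getLogger(__name__)

#: Sentinel returned when the reaction atom cannot be resolved.
AMBIGUOUS = "AMBIGUOUS"

_SOM_COLUMNS = ["smiles", "atom_index", "enzyme", "score", "source", "applicable_rank"]
_SOR_COLUMNS = ["smiles", "atom_index", "sor_score"]


@dataclass(frozen=True)
class SomRecord:
    smiles: str  # canonical SMILES of the substrate
    atom_index: int  # 0-based canonical heavy-atom index
    enzyme: str  # family or CYP isoform label
    score: float
    source: str = "table"
    applicable_rank: str = "any"  # "1" | "2" | "any"


class SomTable:
    """A collection of per-atom, per-enzyme site-of-metabolism scores."""

    def __init__(self, records: Iterable[SomRecord]):
        self.records = list(records)
        valid_enzymes = set(ENZYME_FAMILIES) | set(CYP_ISOFORMS)
        seen = set()
        for r in self.records:
            if not 0.0 <= r.score <= 1.0:
                raise ValueError(f"SOM score outside [0,1]: {r}")
            if r.applicable_rank not in ("1", "2", "any"):
                raise ValueError(f"bad applicable_rank: {r}")
            if r.enzyme not in valid_enzymes:
                raise ValueError(f"unknown enzyme label: {r}")
            key = (r.smiles, r.atom_index, r.enzyme, r.source)
            if key in seen:
                raise ValueError(f"duplicate SOM record for {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_tsv(cls, path) -> "SomTable":
        df = pd.read_csv(path, sep="\t", dtype={"applicable_rank": str})
        missing = set(_SOM_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"SOM table {path}: missing columns {sorted(missing)}")
        return cls(
            SomRecord(
                str(r.smiles), int(r.atom_index), str(r.enzyme),
                float(r.score), str(r.source), str(r.applicable_rank),
            )
            for r in df.itertuples()
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame([r.__dict__ for r in self.records])[_SOM_COLUMNS].to_csv(
            path, sep="\t", index=False
        )


class SorTable:
    """Per-atom DNA-reactivity (SOR) scores, one record per atom."""

    def __init__(self, records: Iterable[tuple[str, int, float]]):
        self.by_smiles: dict[str, dict[int, float]] = {}
        for smiles, atom_index, score in records:
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"SOR score outside [0,1]: {smiles} {atom_index}")
            atoms = self.by_smiles.setdefault(smiles, {})
            if atom_index in atoms:
                raise ValueError(f"duplicate SOR record: {smiles} atom {atom_index}")
            atoms[int(atom_index)] = float(score)

    def __contains__(self, smiles: str) -> bool:
        return smiles in self.by_smiles

    def vector(self, smiles: str, n_atoms: int) -> list[float]:
        """Full-length per-atom vector; atoms without a record score 0."""
        atoms = self.by_smiles[smiles]
        bad = [i for i in atoms if i >= n_atoms or i < 0]
        if bad:
            raise ValueError(f"SOR atom index out of range for {smiles}: {bad}")
        return [atoms.get(i, 0.0) for i in range(n_atoms)]

    @classmethod
    def from_tsv(cls, path) -> "SorTable":
        df = pd.read_csv(path, sep="\t")
        missing = set(_SOR_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"SOR table {path}: missing columns {sorted(missing)}")
        return cls(
            (str(r.smiles), int(r.atom_index), float(r.sor_score))
            for r in df.itertuples()
        )

    def to_tsv(self, path) -> None:
        rows = [
            {"smiles": s, "atom_index": i, "sor_score": v}
            for s, atoms in self.by_smiles.items()
            for i, v in sorted(atoms.items())
        ]
        pd.DataFrame(rows, columns=_SOR_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Atom-of-reaction detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReactionAtom:
    """Result of reaction-atom detection.

    ``atom_index`` is in the canonical atom order of the substrate.
    ``symmetric`` flags a site chosen among symmetry-equivalent
    candidates (lowest index wins); ``ambiguous`` is True when two or
    more symmetry-*inequivalent* candidates tie, in which case
    ``atom_index`` is None and a manual override is required.
    """

    atom_index: Optional[int]
    symmetric: bool = False
    ambiguous: bool = False


def detect_reaction_atom(src_smiles: str, dst_smiles: str) -> ReactionAtom:
    """Locate the substrate atom transformed by src -> dst.

    A maximum-common-substructure alignment of the two molecules is
    computed; the reaction atom is the substrate heavy atom at the
    modification boundary: the matched atom adjacent to atoms present
    only in the product (an added substituent) or only in the
    substrate (a leaving group).  Symmetry-equivalent candidates are
    collapsed to the lowest canonical index; symmetry-inequivalent
    ties give :data:`AMBIGUOUS` (``ambiguous=True``).
    """
    src = mol_from_canonical(src_smiles)
    dst = mol_from_canonical(dst_smiles)
    res = rdFMCS.FindMCS(
        [src, dst],
        bondCompare=rdFMCS.BondCompare.CompareAny,
        atomCompare=rdFMCS.AtomCompare.CompareElements,
        timeout=10,
    )
    if res.numAtoms == 0:
        raise ChemistryError(
            f"no common substructure between {src_smiles!r} and {dst_smiles!r}"
        )
    query = Chem.MolFromSmarts(res.smartsString)
    src_match = src.GetSubstructMatch(query)
    dst_match = dst.GetSubstructMatch(query)
    if not src_match or not dst_match:
        raise ChemistryError(
            f"MCS does not embed in both molecules: {src_smiles!r}, {dst_smiles!r}"
        )
    src_in = set(src_match)
    dst_in = set(dst_match)
    dst_to_src = {d: s for s, d in zip(src_match, dst_match)}

    candidates: set[int] = set()
    # Substrate atoms losing a substituent (atoms matched, neighbour not).
    for atom in src.GetAtoms():
        if atom.GetIdx() in src_in and any(
            nb.GetIdx() not in src_in for nb in atom.GetNeighbors()
        ):
            candidates.add(atom.GetIdx())
    # Substrate atoms gaining a substituent (their image in the product
    # has a neighbour outside the common substructure).
    for atom in dst.GetAtoms():
        if atom.GetIdx() in dst_in and any(
            nb.GetIdx() not in dst_in for nb in atom.GetNeighbors()
        ):
            candidates.add(dst_to_src[atom.GetIdx()])
    if not candidates:
        # Identical heavy-atom skeleton (e.g. a pure bond-order change):
        # fall back to atoms whose degree or H-count differs.
        for s_idx, d_idx in zip(src_match, dst_match):
            sa, da = src.GetAtomWithIdx(s_idx), dst.GetAtomWithIdx(d_idx)
            if sa.GetTotalNumHs() != da.GetTotalNumHs() or sa.GetFormalCharge() != da.GetFormalCharge():
                candidates.add(s_idx)
    if not candidates:
        return ReactionAtom(None, ambiguous=True)

    ranks = list(Chem.CanonicalRankAtoms(src, breakTies=False))
    classes = {ranks[i] for i in candidates}
    if len(classes) > 1:
        return ReactionAtom(None, ambiguous=True)
    # all candidates are symmetry-equivalent: report the lowest member
    # of their class and flag when the site had equivalent alternatives
    cls = classes.pop()
    members = [i for i in range(src.GetNumAtoms()) if ranks[i] == cls]
    return ReactionAtom(min(members), symmetric=len(members) > 1)


def fill_reaction_atoms(
    m: MetabolicMap, overrides: Optional[dict[str, int]] = None
) -> list[str]:
    """Detect missing reaction atoms on every edge of a chemical map.

    ``overrides`` maps edge_id -> atom_index and takes precedence over
    detection (the manual-curation escape hatch).  Returns edge ids
    left ambiguous.
    """
    if m.abstract:
        raise ChemistryError("cannot detect reaction atoms on an abstract map")
    overrides = overrides or {}
    ambiguous = []
    for e in m.edges:
        if e.edge_id in overrides:
            e.reaction_atom = int(overrides[e.edge_id])
            continue
        if e.reaction_atom is not None:
            continue
        res = detect_reaction_atom(m.nodes[e.src].smiles, m.nodes[e.dst].smiles)
        if res.ambiguous:
            ambiguous.append(e.edge_id)
        else:
            e.reaction_atom = res.atom_index
    return ambiguous


def load_overrides(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return {str(r.edge_id): int(r.atom_index) for r in df.itertuples()}


# ---------------------------------------------------------------------------
# SOM annotation
# ---------------------------------------------------------------------------

def _merge_records(tables: Sequence[SomTable]) -> list[SomRecord]:
    """Concatenate provider tables; first occurrence of a key wins."""
    merged: dict[tuple, SomRecord] = {}
    for table in tables:
        for r in table.records:
            key = (r.smiles, r.atom_index, r.enzyme, r.applicable_rank)
            merged.setdefault(key, r)
    return list(merged.values())


def annotate_som(
    m: MetabolicMap,
    tables: Union[SomTable, Sequence[SomTable]],
    policy: str = "rank",
) -> MetabolicMap:
    """Attach SOM scores to edges; duplicate per matching enzyme.

    Matching key is ``(src canonical SMILES, reaction_atom, enzyme)``.
    Under the default rank policy, rank-1 CYPs edges match CYP-isoform
    records and rank-1 UGTs edges match family records (records with
    applicable_rank in {"1", "any"}); rank-2 edges match family-level
    records (applicable_rank in {"2", "any"}).  A CYPs edge matching k
    isoform records becomes k parallel edges, one per isoform, each
    with its own score.  A score of 0 is a valid annotation; edges
    with *no* matching record are removed, and nodes left unreachable
    are cascade-removed.
    """
    if policy not in ("rank", "enzyme"):
        raise ValueError(f"unknown annotation policy: {policy!r}")
    if m.abstract:
        raise ChemistryError("annotate_som needs a chemical map")
    if isinstance(tables, SomTable):
        tables = [tables]
    records = _merge_records(tables)

    for e in m.edges:
        if e.enzyme_family is None:
            raise ValueError(f"edge {e.edge_id} has no enzyme family")
        if e.reaction_atom is None:
            raise ValueError(f"edge {e.edge_id} has no reaction atom")
    for r in records:
        mol = Chem.MolFromSmiles(r.smiles)
        if mol is not None and r.atom_index >= mol.GetNumAtoms():
            raise ValueError(
                f"SOM record atom index {r.atom_index} outside molecule {r.smiles}"
            )

    index: dict[tuple[str, int, str], list[SomRecord]] = {}
    for r in records:
        index.setdefault((r.smiles, r.atom_index, r.enzyme), []).append(r)

    def lookup(smiles: str, atom: int, enzyme: str, ranks: tuple[str, ...]):
        for r in index.get((smiles, atom, enzyme), ()):
            if r.applicable_rank in ranks:
                return r
        return None

    out = m.copy()
    new_edges: list[ReactionEdge] = []
    removed = 0
    for e in out.edges:
        src_smiles = out.nodes[e.src].smiles
        matches: list[tuple[Optional[str], SomRecord]] = []
        if policy == "rank":
            if e.rank == 1:
                ranks = ("1", "any")
                if e.enzyme_family == "CYPs":
                    for iso in CYP_ISOFORMS:
                        rec = lookup(src_smiles, e.reaction_atom, iso, ranks)
                        if rec is not None:
                            matches.append((iso, rec))
                elif e.enzyme_family == "UGTs":
                    rec = lookup(src_smiles, e.reaction_atom, "UGTs", ranks)
                    if rec is not None:
                        matches.append((None, rec))
                # rank-1 NATs/SULTs/GSTs: no rank-1 provider covers them
            else:
                rec = lookup(src_smiles, e.reaction_atom, e.enzyme_family, ("2", "any"))
                if rec is not None:
                    matches.append((None, rec))
        else:  # by-enzyme policy, rank-independent
            any_rank = ("1", "2", "any")
            if e.enzyme_family == "CYPs":
                for iso in CYP_ISOFORMS:
                    rec = lookup(src_smiles, e.reaction_atom, iso, any_rank)
                    if rec is not None:
                        matches.append((iso, rec))
                if not matches:
                    rec = lookup(src_smiles, e.reaction_atom, "CYPs", any_rank)
                    if rec is not None:
                        matches.append((None, rec))
            else:
                rec = lookup(src_smiles, e.reaction_atom, e.enzyme_family, any_rank)
                if rec is not None:
                    matches.append((None, rec))
        if not matches:
            removed += 1
            continue
        for i, (iso, rec) in enumerate(matches):
            edge = ReactionEdge(
                edge_id=e.edge_id if i == 0 else f"{e.edge_id}.{i}",
                src=e.src,
                dst=e.dst,
                rule_name=e.rule_name,
                rank=e.rank,
                reaction_atom=e.reaction_atom,
                enzyme_family=e.enzyme_family,
                isoform=iso,
                som_score=rec.score,
                som_source=rec.source,
            )
            new_edges.append(edge)
    if removed:
        logger.info("annotate_som: removed %d unannotated edge(s)", removed)
    out.edges = new_edges
    out._edge_keys = {e.identity() for e in new_edges}
    out.prune_unreachable()
    out.validate()
    return out


def annotate_reactivity(
    m: MetabolicMap,
    sor: SorTable,
    threshold: float = 0.85,
    strict: bool = False,
) -> MetabolicMap:
    """Fill per-atom SOR vectors and set the DNA-reactivity flag.

    A node is DNA-reactive when its maximal atom SOR score reaches the
    threshold (>= by default; > with ``strict=True``).  Nodes absent
    from the table are flagged non-reactive with a warning.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0,1]")
    out = m.copy()
    for node in out.nodes.values():
        key = node.smiles if not out.abstract else node.node_id
        if key in sor:
            if out.abstract:
                atoms = sor.by_smiles[key]
                vec = [atoms.get(i, 0.0) for i in range(max(atoms) + 1)]
            else:
                n_atoms = mol_from_canonical(node.smiles).GetNumAtoms()
                vec = sor.vector(key, n_atoms)
            node.atom_sor = vec
            peak = max(vec)
            node.dna_reactive = peak > threshold if strict else peak >= threshold
        else:
            logger.warning("no SOR record for node %s; assuming non-reactive", node.node_id)
            node.dna_reactive = False
    out.validate()
    return out


def is_reactive(node, threshold: float, strict: bool = False) -> bool:
    """Recompute a node's reactivity from its SOR vector at a threshold."""
    if node.atom_sor is None:
        return False
    peak = max(node.atom_sor)
    return peak > threshold if strict else peak >= threshold
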