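"""Core domain model for enriched maps of metabolism.

An enriched map of metabolism is a rooted directed acyclic graph whose
nodes are chemical compounds (metabolites) and whose edges are
biotransformation reactions.  Nodes carry a canonical SMILES, per-atom
DNA-reactivity (SOR) scores and a production probability score; edges
carry the biotransformation rule, the rank (rule-application cycle at
which the reaction was first predicted), the atom of reaction, the
catalysing enzyme family/isoform and a site-of-metabolism (SOM) score.

Scoring-stage fixtures may use *abstract* maps whose nodes have no
SMILES; chemistry-dependent operations refuse such maps.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional

import networkx as nx
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: The five enzyme families of the phase I / phase II universe.
ENZYME_FAMILIES = ("CYPs", "UGTs", "NATs", "SULTs", "GSTs")

#: CYP isoforms resolved by rank-1 site-of-metabolism annotation.
CYP_ISOFORMS = ("CYP1A2", "CYP2C19", "CYP2C9", "CYP2D6", "CYP3A4")


class ChemistryError(ValueError):
    """Raised for unparsable SMILES/SMIRKS or abstract-map misuse."""


def canonicalize(smiles: str) -> tuple[str, list[int]]:
    """Canonicalize a SMILES string.

    Returns ``(canonical_smiles, perm)`` where ``perm[i]`` is the
    position in canonical atom order of heavy atom ``i`` of the input
    (atoms in SMILES parse order).  Canonical atom order is defined as
    the parse order of the canonical SMILES string, so annotation
    tables keyed to canonical order can be built by parsing the
    canonical form directly.

    Raises :class:`ChemistryError` on unparsable input.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemistryError(f"unparsable SMILES: {smiles!r}")
    canonical = Chem.MolToSmiles(mol)
    # Writing the canonical SMILES records the atom output order:
    # output position k holds input atom order[k].
    order = list(
        map(int, mol.GetProp("_smilesAtomOutputOrder").strip("[],").split(","))
    )
    perm = [0] * mol.GetNumAtoms()
    for pos, inp in enumerate(order):
        perm[inp] = pos
    return canonical, perm


def mol_from_canonical(smiles: str) -> Chem.Mol:
    """Parse a canonical SMILES; atom indices then follow canonical order."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemistryError(f"unparsable SMILES: {smiles!r}")
    return mol


@dataclass
class MetaboliteNode:
    """A compound in a map of metabolism.

    Optional labels are ``None`` until the corresponding pipeline stage
    fills them; ``None`` is distinct from a legitimate value of 0.
    """

    node_id: str
    smiles: Optional[str] = None  # canonical; None only in abstract maps
    is_original: bool = False
    atom_sor: Optional[list[float]] = None
    dna_reactive: Optional[bool] = None
    production_score: Optional[float] = None
    display_name: Optional[str] = None

    def validate(self) -> None:
        if self.atom_sor is not None:
            if not all(0.0 <= s <= 1.0 for s in self.atom_sor):
                raise ValueError(
                    f"node {self.node_id}: atom_sor values outside [0,1]"
                )
            if self.smiles is not None:
                n_heavy = mol_from_canonical(self.smiles).GetNumAtoms()
                if len(self.atom_sor) != n_heavy:
                    raise ValueError(
                        f"node {self.node_id}: atom_sor length "
                        f"{len(self.atom_sor)} != heavy-atom count {n_heavy}"
                    )
        if self.production_score is not None and not (
            0.0 <= self.production_score <= 1.0
        ):
            raise ValueError(f"node {self.node_id}: production_score not in [0,1]")


@dataclass
class ReactionEdge:
    """A directed biotransformation between two metabolites."""

    edge_id: str
    src: str
    dst: str
    rule_name: str
    rank: int
    reaction_atom: Optional[int] = None  # 0-based, canonical order of src
    enzyme_family: Optional[str] = None
    isoform: Optional[str] = None
    som_score: Optional[float] = None  # 0.0 is a valid annotation
    som_source: Optional[str] = None

    @property
    def enzyme(self) -> Optional[str]:
        """The most specific enzyme label (isoform if present)."""
        return self.isoform if self.isoform is not None else self.enzyme_family

    def validate(self) -> None:
        if self.src == self.dst:
            raise ValueError(f"edge {self.edge_id}: src == dst")
        if self.rank not in (1, 2):
            raise ValueError(f"edge {self.edge_id}: rank {self.rank} not in {{1,2}}")
        if self.isoform is not None and self.enzyme_family != "CYPs":
            raise ValueError(
                f"edge {self.edge_id}: isoform set on non-CYPs family "
                f"{self.enzyme_family}"
            )
        if self.som_score is not None and not 0.0 <= self.som_score <= 1.0:
            raise ValueError(f"edge {self.edge_id}: som_score not in [0,1]")

    def identity(self) -> tuple:
        """Fields that make two edges distinct within a map."""
        return (
            self.src,
            self.dst,
            self.rule_name,
            self.reaction_atom,
            self.enzyme_family,
            self.isoform,
        )


class MetabolicMap:
    """Rooted DAG of metabolites and reactions.

    Node identity within a map is the canonical SMILES (one node per
    compound); edges are deduplicated on
    ``(src, dst, rule_name, reaction_atom, enzyme_family, isoform)``.
    Mutation preserves acyclicity: edges that would create a cycle are
    dropped (and logged), never added.
    """

    def __init__(self, abstract: bool = False):
        self.nodes: dict[str, MetaboliteNode] = {}
        self.edges: list[ReactionEdge] = []
        self.original: Optional[str] = None
        self.abstract = abstract
        self._by_smiles: dict[str, str] = {}
        self._edge_keys: set[tuple] = set()
        self._next_node = 0
        self._next_edge = 0
        self.rejected_edges: list[ReactionEdge] = []

    # -- construction -------------------------------------------------

    def _new_node_id(self) -> str:
        while (nid := f"n{self._next_node}") in self.nodes:
            self._next_node += 1
        self._next_node += 1
        return nid

    def _new_edge_id(self) -> str:
        eid = f"e{self._next_edge}"
        self._next_edge += 1
        return eid

    def add_metabolite(
        self,
        smiles: Optional[str] = None,
        *,
        node_id: Optional[str] = None,
        is_original: bool = False,
        display_name: Optional[str] = None,
    ) -> MetaboliteNode:
        """Add a compound, deduplicating by canonical SMILES.

        Returns the (possibly pre-existing) node.  Abstract maps take
        explicit ``node_id`` and no SMILES.
        """
        if self.abstract:
            if node_id is None:
                raise ValueError("abstract maps require explicit node ids")
            if node_id in self.nodes:
                return self.nodes[node_id]
            node = MetaboliteNode(node_id, None, is_original, display_name=display_name)
        else:
            if smiles is None:
                raise ChemistryError("chemical maps require a SMILES per node")
            canonical, _ = canonicalize(smiles)
            if canonical in self._by_smiles:
                return self.nodes[self._by_smiles[canonical]]
            node = MetaboliteNode(
                node_id or self._new_node_id(),
                canonical,
                is_original,
                display_name=display_name,
            )
            self._by_smiles[canonical] = node.node_id
        if node.node_id in self.nodes:
            raise ValueError(f"duplicate node id {node.node_id}")
        self.nodes[node.node_id] = node
        if is_original:
            if self.original is not None and self.original != node.node_id:
                raise ValueError("map already has an original compound")
            self.original = node.node_id
        return node

    def node_for_smiles(self, smiles: str) -> Optional[MetaboliteNode]:
        if self.abstract:
            raise ChemistryError("abstract map has no SMILES index")
        canonical, _ = canonicalize(smiles)
        nid = self._by_smiles.get(canonical)
        return self.nodes[nid] if nid else None

    def add_edge_acyclic(self, edge: ReactionEdge) -> bool:
        """Add an edge unless it would create a cycle.

        Back-edges (dst an ancestor of src, dst == src, or dst the
        original compound) arise from rule inversions; they are logged
        and dropped, leaving the map unchanged.  Returns whether the
        edge was added.  Raises ``KeyError`` on a dangling src.
        """
        if edge.src not in self.nodes:
            raise KeyError(f"edge {edge.edge_id}: unknown src node {edge.src!r}")
        if edge.dst not in self.nodes:
            raise KeyError(f"edge {edge.edge_id}: unknown dst node {edge.dst!r}")
        if (
            edge.dst == edge.src
            or edge.dst == self.original
            or edge.dst in self.ancestors(edge.src)
        ):
            logger.info(
                "dropping cycle-creating edge %s -> %s (rule %s)",
                edge.src, edge.dst, edge.rule_name,
            )
            self.rejected_edges.append(edge)
            return False
        key = edge.identity()
        if key in self._edge_keys:
            return False
        edge.validate()
        self._edge_keys.add(key)
        self.edges.append(edge)
        return True

    def new_edge(self, src: str, dst: str, rule_name: str, rank: int, **kw) -> bool:
        """Convenience constructor + :meth:`add_edge_acyclic`."""
        return self.add_edge_acyclic(
            ReactionEdge(self._new_edge_id(), src, dst, rule_name, rank, **kw)
        )

    # -- graph queries -------------------------------------------------

    def in_edges(self, node_id: str) -> list[ReactionEdge]:
        return [e for e in self.edges if e.dst == node_id]

    def out_edges(self, node_id: str) -> list[ReactionEdge]:
        return [e for e in self.edges if e.src == node_id]

    def parents(self, node_id: str) -> list[str]:
        seen: list[str] = []
        for e in self.edges:
            if e.dst == node_id and e.src not in seen:
                seen.append(e.src)
        return seen

    def ancestors(self, node_id: str) -> set[str]:
        """All nodes with a directed path to ``node_id`` (excl. itself)."""
        out: set[str] = set()
        stack = [node_id]
        while stack:
            cur = stack.pop()
            for e in self.edges:
                if e.dst == cur and e.src not in out:
                    out.add(e.src)
                    stack.append(e.src)
        return out

    def reachable_from_original(self) -> set[str]:
        if self.original is None:
            return set()
        out = {self.original}
        stack = [self.original]
        adj: dict[str, list[str]] = {}
        for e in self.edges:
            adj.setdefault(e.src, []).append(e.dst)
        while stack:
            cur = stack.pop()
            for nxt in adj.get(cur, ()):
                if nxt not in out:
                    out.add(nxt)
                    stack.append(nxt)
        return out

    def prune_unreachable(self) -> list[str]:
        """Drop nodes not reachable from the original (cascading).

        Returns the ids of removed nodes.
        """
        keep = self.reachable_from_original()
        removed = [nid for nid in self.nodes if nid not in keep]
        for nid in removed:
            node = self.nodes.pop(nid)
            if node.smiles is not None:
                self._by_smiles.pop(node.smiles, None)
        kept_edges = []
        for e in self.edges:
            if e.src in keep and e.dst in keep:
                kept_edges.append(e)
            else:
                self._edge_keys.discard(e.identity())
        self.edges = kept_edges
        if removed:
            logger.info("pruned %d unreachable node(s): %s", len(removed), removed)
        return removed

    def remove_edges(self, edges: Iterable[ReactionEdge]) -> None:
        doomed = {id(e) for e in edges}
        for e in self.edges:
            if id(e) in doomed:
                self._edge_keys.discard(e.identity())
        self.edges = [e for e in self.edges if id(e) not in doomed]

    def topological_order(self) -> list[str]:
        """Topological node order; raises on a cycle."""
        g = self.to_networkx()
        return list(nx.topological_sort(g))

    def validate(self) -> None:
        """Check all structural invariants; raise ``ValueError`` on breach."""
        if self.original is None or self.original not in self.nodes:
            raise ValueError("map has no original compound")
        for node in self.nodes.values():
            node.validate()
        seen_ids = set()
        for e in self.edges:
            e.validate()
            if e.src not in self.nodes or e.dst not in self.nodes:
                raise ValueError(f"edge {e.edge_id}: dangling endpoint")
            if e.edge_id in seen_ids:
                raise ValueError(f"duplicate edge id {e.edge_id}")
            seen_ids.add(e.edge_id)
            if e.rank == 1 and e.src != self.original:
                raise ValueError(f"edge {e.edge_id}: rank-1 src is not the original")
        if not self.abstract:
            smi = [n.smiles for n in self.nodes.values()]
            if len(smi) != len(set(smi)):
                raise ValueError("two nodes share a canonical SMILES")
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise ValueError("map contains a cycle")
        unreachable = set(self.nodes) - self.reachable_from_original()
        if unreachable:
            raise ValueError(f"nodes unreachable from original: {sorted(unreachable)}")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "xenomap/1",
            "abstract": self.abstract,
            "original": self.original,
            "nodes": [asdict(n) for n in self.nodes.values()],
            "edges": [asdict(e) for e in self.edges],
        }

    @classmethod
    def from_dict(cls, doc: dict, check: bool = True) -> "MetabolicMap":
        for key in ("original", "nodes", "edges"):
            if key not in doc:
                raise ValueError(f"map document: missing field {key!r}")
        m = cls(abstract=bool(doc.get("abstract", False)))
        node_fields = {f for f in MetaboliteNode.__dataclass_fields__}
        for i, nd in enumerate(doc["nodes"]):
            bad = set(nd) - node_fields
            if bad or "node_id" not in nd:
                raise ValueError(f"nodes[{i}]: unexpected or missing fields {bad}")
            node = MetaboliteNode(**nd)
            node.validate()
            m.nodes[node.node_id] = node
            if node.smiles is not None:
                m._by_smiles[node.smiles] = node.node_id
        m.original = doc["original"]
        edge_fields = {f for f in ReactionEdge.__dataclass_fields__}
        for i, ed in enumerate(doc["edges"]):
            bad = set(ed) - edge_fields
            if bad or "edge_id" not in ed:
                raise ValueError(f"edges[{i}]: unexpected or missing fields {bad}")
            edge = ReactionEdge(**ed)
            edge.validate()
            m.edges.append(edge)
            m._edge_keys.add(edge.identity())
        if check:
            m.validate()
        return m

    @classmethod
    def from_dict_unchecked(cls, doc: dict) -> "MetabolicMap":
        """Deserialize without invariant checks (for internal surgery)."""
        return cls.from_dict(doc, check=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MetabolicMap":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for nid, node in self.nodes.items():
            g.add_node(nid)
        for e in self.edges:
            g.add_edge(e.src, e.dst, key=e.edge_id)
        return g

    def to_graphml(self, path) -> None:
        """GraphML export readable by generic graph tools.

        GraphML cannot express nulls, so absent labels are simply
        omitted per element (the JSON document is the lossless format).
        """
        g = nx.MultiDiGraph()
        for nid, node in self.nodes.items():
            attrs = {"is_original": node.is_original}
            if node.smiles is not None:
                attrs["smiles"] = node.smiles
            if node.dna_reactive is not None:
                attrs["dna_reactive"] = node.dna_reactive
            if node.production_score is not None:
                attrs["production_score"] = node.production_score
            if node.display_name is not None:
                attrs["display_name"] = node.display_name
            g.add_node(nid, **attrs)
        for e in self.edges:
            attrs = {"rule": e.rule_name, "rank": e.rank}
            if e.reaction_atom is not None:
                attrs["atom"] = e.reaction_atom
            if e.enzyme_family is not None:
                attrs["enzyme"] = e.enzyme_family
            if e.isoform is not None:
                attrs["isoform"] = e.isoform
            if e.som_score is not None:
                attrs["som"] = e.som_score
            g.add_edge(e.src, e.dst, key=e.edge_id, **attrs)
        nx.write_graphml(g, path)

    # -- misc ----------------------------------------------------------

    def copy(self) -> "MetabolicMap":
        return MetabolicMap.from_dict(self.to_dict())

    def __eq__(self, other) -> bool:
        if not isinstance(other, MetabolicMap):
            return NotImplemented
        return (
            self.abstract == other.abstract
            and self.original == other.original
            and self.nodes == other.nodes
            and sorted(self.edges, key=lambda e: e.edge_id)
            == sorted(other.edges, key=lambda e: e.edge_id)
        )

    def __repr__(self) -> str:
        return (
            f"<MetabolicMap {len(self.nodes)} nodes, {len(self.edges)} edges, "
            f"original={self.original}>"
        )
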