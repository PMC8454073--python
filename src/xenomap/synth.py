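"""Synthetic fixtures: random annotated maps, provider-style tables,
the published toy reduction network, and the curated caffeine
reference list.

The random generator emulates the statistical shape of an annotated
two-rank map — SOM scores in [0,1] with a point mass at exactly 0
(reactions a provider scored as impossible), per-atom SOR scores with
a minority of metabolites carrying a high-reactivity atom — without
any chemistry: scoring-stage maps are *abstract* (node ids, no
SMILES), because the Bayesian and signature machinery is
chemistry-agnostic.  For chemical maps, :func:`synthesize_tables`
fabricates SOM/SOR tables keyed to the map's real SMILES and reaction
atoms, so the full pipeline runs end-to-end without any web service.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .annotate import SomRecord, SomTable, SorTable
from .core import CYP_ISOFORMS, MetabolicMap, mol_from_canonical
from .signatures import ENZYME_UNIVERSE


@dataclass
class FixtureSpec:
    """Parameters of the random annotated-map generator.

    Defaults mirror the shape of a small two-rank xenobiotic map:
    a handful of first-rank reactions, a couple of second-rank
    products each, ~15% of SOM annotations exactly 0, and a bit under
    half of the metabolites carrying a DNA-reactive atom.
    """

    n_rank1: int = 6
    branching: float = 2.0  # mean number of rank-2 products per rank-1 node
    enzyme_universe: Sequence[str] = ENZYME_UNIVERSE
    score_distribution: tuple = ("beta", 2.0, 2.0)
    sor_distribution: tuple = ("beta", 1.5, 6.0)
    p_zero: float = 0.15  # probability a SOM annotation is exactly 0
    p_reactive: float = 0.45  # probability a node gets one high-SOR atom
    n_atoms: int = 8  # heavy-atom count of abstract nodes
    seed: int = 0

    def validate(self) -> None:
        if self.n_rank1 < 1:
            raise ValueError("n_rank1 must be >= 1")
        for p in (self.p_zero, self.p_reactive):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0,1]")


def _draw(rng: np.random.Generator, dist: tuple, size: int) -> np.ndarray:
    kind, *params = dist
    if kind == "beta":
        return rng.beta(params[0], params[1], size=size)
    if kind == "uniform":
        return rng.uniform(params[0], params[1], size=size)
    if kind == "constant":
        return np.full(size, float(params[0]))
    raise ValueError(f"unknown distribution: {dist!r}")


def _som_score(rng: np.random.Generator, spec: FixtureSpec) -> float:
    if rng.random() < spec.p_zero:
        return 0.0
    return float(np.clip(_draw(rng, spec.score_distribution, 1)[0], 0.0, 1.0))


def _family_of(enzyme: str) -> str:
    return "CYPs" if enzyme in CYP_ISOFORMS else enzyme


def generate_random_map(spec: FixtureSpec) -> tuple[MetabolicMap, SomTable, SorTable]:
    """Deterministic (per seed) random annotated two-rank map.

    Returns the map plus the SOM/SOR tables it was annotated from;
    for abstract maps the tables' ``smiles`` column carries node ids.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    universe = list(spec.enzyme_universe)
    m = MetabolicMap(abstract=True)
    root = m.add_metabolite(node_id="root", is_original=True)
    som_records: list[SomRecord] = []
    # abstract nodes have no real sites: give every reaction on a given
    # substrate its own pseudo-atom so table keys stay unique
    atom_counter: dict[str, int] = {}

    def next_atom(src: str) -> int:
        atom_counter[src] = atom_counter.get(src, -1) + 1
        return atom_counter[src]

    def annotate_edge(src: str, dst: str, rank: int, enzyme: str, atom: int) -> None:
        family = _family_of(enzyme)
        score = _som_score(rng, spec)
        m.new_edge(
            src, dst, rule_name=f"synthetic_r{rank}", rank=rank,
            reaction_atom=atom,
            enzyme_family=family,
            isoform=enzyme if family == "CYPs" and enzyme != "CYPs" else None,
            som_score=score, som_source="synthetic",
        )
        som_records.append(
            SomRecord(src, atom, enzyme, score, "synthetic", str(rank))
        )

    rank1_ids = []
    for i in range(spec.n_rank1):
        node = m.add_metabolite(node_id=f"m1_{i}")
        rank1_ids.append(node.node_id)
        n_parallel = min(3, 1 + rng.poisson(0.5))
        enzymes = rng.choice(universe, size=n_parallel, replace=False)
        for enz in sorted(enzymes):
            annotate_edge(root.node_id, node.node_id, 1, str(enz),
                          atom=next_atom(root.node_id))

    pool_size = max(1, int(round(spec.n_rank1 * spec.branching * 0.7)))
    created: set[str] = set()
    for src in rank1_ids:
        n_children = min(pool_size, rng.poisson(spec.branching))
        children = rng.choice(pool_size, size=n_children, replace=False)
        for c in sorted(children):
            dst = f"m2_{c}"
            if dst not in created:
                m.add_metabolite(node_id=dst)
                created.add(dst)
            enz = str(rng.choice(universe))
            annotate_edge(src, dst, 2, enz, atom=next_atom(src))
    m.prune_unreachable()

    sor_records = []
    for nid, node in m.nodes.items():
        vec = np.clip(_draw(rng, spec.sor_distribution, spec.n_atoms), 0.0, 1.0)
        if nid != root.node_id and rng.random() < spec.p_reactive:
            vec[rng.integers(spec.n_atoms)] = rng.uniform(0.85, 1.0)
        if nid == root.node_id:
            vec = np.zeros(spec.n_atoms)  # fixtures keep the parent inert
        node.atom_sor = [float(v) for v in vec]
        node.dna_reactive = max(node.atom_sor) >= 0.85
        sor_records.extend((nid, i, float(v)) for i, v in enumerate(vec))

    m.validate()
    return m, SomTable(som_records), SorTable(sor_records)


def figure10_fixture() -> MetabolicMap:
    """The published worked example of the Bayesian reduction.

    Abstract map with enzymes E1..E4: the root A feeds B, C and D;
    A -> C is annotated by three different enzymes (E1 0.2, E2 0.35,
    E3 0.5), and F is produced both from D (E1 0.77, E2 0.70) and
    from C (E1 0.75, E2 0.60).  The correct reduction keeps A -> C
    via E3 at 0.5, D -> F via E1 at 0.77 and C -> F via E2 at 0.60.
    """
    m = MetabolicMap(abstract=True)
    m.add_metabolite(node_id="A", is_original=True)
    for nid in ("B", "C", "D", "F"):
        m.add_metabolite(node_id=nid)

    def edge(src, dst, enzyme, score, rank):
        m.new_edge(
            src, dst, rule_name="toy", rank=rank, reaction_atom=0,
            enzyme_family=enzyme, som_score=score, som_source="toy",
        )

    edge("A", "B", "E4", 0.9, 1)
    edge("A", "C", "E1", 0.2, 1)
    edge("A", "C", "E2", 0.35, 1)
    edge("A", "C", "E3", 0.5, 1)
    edge("A", "D", "E4", 0.8, 1)
    edge("D", "F", "E1", 0.77, 2)
    edge("D", "F", "E2", 0.70, 2)
    edge("C", "F", "E1", 0.75, 2)
    edge("C", "F", "E2", 0.60, 2)

    for nid, node in m.nodes.items():
        node.atom_sor = [0.9] if nid == "F" else [0.1]
        node.dna_reactive = nid == "F"
    m.nodes["A"].atom_sor = [0.0]
    m.validate()
    return m


def caffeine_reference() -> tuple[str, list[tuple[str, str]]]:
    """Parent SMILES and the curated list of known caffeine metabolites.

    Returns ``(caffeine_smiles, [(name, smiles), ...])`` with 16
    entries including caffeine itself: the three dimethylxanthines,
    three monomethylxanthines, four methyluric acids reachable in two
    reactions, plus the further demethylated uric acids and the two
    NAT-derived uracil metabolites that two cycles of rule
    application cannot reach.
    """
    with resources.as_file(
        resources.files("xenomap.data") / "caffeine_reference.tsv"
    ) as p:
        with open(p) as fh:
            rows = [(r["name"], r["smiles"]) for r in csv.DictReader(fh, delimiter="\t")]
    parent = next(smiles for name, smiles in rows if name == "caffeine")
    return parent, rows


def synthesize_tables(
    m: MetabolicMap,
    seed: int = 0,
    spec: Optional[FixtureSpec] = None,
) -> tuple[SomTable, SorTable]:
    """Fabricate provider-style SOM/SOR tables for a chemical map.

    Emulates the provider landscape the rank policy assumes: rank-1
    CYPs edges receive 1-3 CYP-isoform records and rank-1 UGTs edges a
    family record (rank-1 conjugations by other families stay
    uncovered, as with real rank-1 providers); rank-2 edges receive
    family-level records.  SOR vectors cover every heavy atom of every
    node.  Deterministic per seed.
    """
    if m.abstract:
        raise ValueError("synthesize_tables needs a chemical map")
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(seed)
    seen: set[tuple] = set()
    som_records: list[SomRecord] = []

    def add(smiles, atom, enzyme, rank_tag, source):
        key = (smiles, atom, enzyme, rank_tag)
        if key in seen:
            return
        seen.add(key)
        som_records.append(
            SomRecord(smiles, atom, enzyme, _som_score(rng, spec), source, rank_tag)
        )

    for e in sorted(m.edges, key=lambda e: e.edge_id):
        src_smiles = m.nodes[e.src].smiles
        if e.reaction_atom is None or e.enzyme_family is None:
            raise ValueError(f"edge {e.edge_id} lacks enzyme/reaction atom")
        if e.rank == 1:
            if e.enzyme_family == "CYPs":
                k = int(rng.integers(1, 4))
                isoforms = rng.choice(CYP_ISOFORMS, size=k, replace=False)
                for iso in sorted(isoforms):
                    add(src_smiles, e.reaction_atom, str(iso), "1", "synthetic-rank1")
            elif e.enzyme_family == "UGTs":
                add(src_smiles, e.reaction_atom, "UGTs", "1", "synthetic-rank1")
        else:
            add(src_smiles, e.reaction_atom, e.enzyme_family, "2", "synthetic-rank2")

    sor_records = []
    for nid, node in sorted(m.nodes.items()):
        n_atoms = mol_from_canonical(node.smiles).GetNumAtoms()
        vec = np.clip(_draw(rng, spec.sor_distribution, n_atoms), 0.0, 1.0)
        if nid != m.original and rng.random() < spec.p_reactive:
            vec[rng.integers(n_atoms)] = rng.uniform(0.85, 1.0)
        sor_records.extend((node.smiles, i, float(v)) for i, v in enumerate(vec))
    return SomTable(som_records), SorTable(sor_records)
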