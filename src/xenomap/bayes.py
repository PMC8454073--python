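"""Production probability scores by exact inference on a reduced DAG.

An annotated map is first *reduced* so that each target metabolite is
produced by at most one reaction per enzyme family and at most one
reaction per source compound (enzyme-recruitment exclusivity).  Each
retained edge then fires independently with its SOM score as
probability, and a metabolite is produced when at least one incoming
edge fires from a produced source (noisy-OR semantics).  The
production probability score of a metabolite is the exact probability
of that event, with the original compound present with probability 1.

Exact inference enumerates joint states of the (small) ancestor set of
each query node, which accounts for correlation through shared
ancestors; a 2^|E| edge-state enumeration is provided as an
independent brute-force oracle.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Optional

from .core import CYP_ISOFORMS, MetabolicMap

logger = logging.getLogger(__name__)

#: Mapping node_id -> production probability.
ScoreVector = dict[str, float]

_ANCESTOR_LIMIT = 22
_ORACLE_EDGE_LIMIT = 25


def edge_available(edge, context: Optional[frozenset]) -> bool:
    """Is an annotated edge usable under an enzymatic context?

    Context labels are the most specific enzyme names (CYP isoforms,
    family labels otherwise).  An isoform-labelled edge needs its
    isoform; a family-level CYPs edge (as produced by rank-2
    annotation) is available when *any* CYP isoform is in the context;
    other families need their family label.
    """
    if context is None:
        return True
    if edge.isoform is not None:
        return edge.isoform in context
    if edge.enzyme_family == "CYPs":
        return any(iso in context for iso in CYP_ISOFORMS)
    return edge.enzyme_family in context


@dataclass(frozen=True)
class RetainedEdge:
    src: str
    dst: str
    enzyme_family: str
    enzyme: str  # most specific label (isoform when known)
    prob: float


@dataclass
class ReducedNetwork:
    """The Bayesian DAG obtained from an annotated map."""

    root: str
    nodes: list[str]
    edges: list[RetainedEdge]
    #: False for the textual-rule variant, which relaxes source exclusivity
    source_exclusive: bool = True

    def in_edges(self, node_id: str) -> list[RetainedEdge]:
        return [e for e in self.edges if e.dst == node_id]

    def parents(self, node_id: str) -> list[str]:
        out = []
        for e in self.edges:
            if e.dst == node_id and e.src not in out:
                out.append(e.src)
        return out

    def validate(self) -> None:
        for t in self.nodes:
            incoming = self.in_edges(t)
            fams = [e.enzyme_family for e in incoming]
            srcs = [e.src for e in incoming]
            if len(fams) != len(set(fams)):
                raise ValueError(f"target {t}: two retained edges share a family")
            if self.source_exclusive and len(srcs) != len(set(srcs)):
                raise ValueError(f"target {t}: two retained edges share a source")


def reduce_network(
    m: MetabolicMap,
    context: Optional[Iterable[str]] = None,
    mode: str = "figure10",
) -> ReducedNetwork:
    """Reduce an annotated map to the Bayesian DAG.

    Steps: (0) drop edges whose enzyme is outside the context;
    (1) within each (src, dst, family) group keep only the top-scoring
    edge (isoform collapse); (2) per target, greedily retain the
    highest-scoring candidate and discard remaining candidates sharing
    its enzyme family or its source; (3) cascade-remove nodes
    unreachable from the root.  Ties break deterministically on
    (lower enzyme label, lower src id).

    ``mode="methods-text"`` applies family exclusivity only (no
    source exclusivity) in step 2, the literal reading of the textual
    reduction rule; the default follows the stricter published worked
    example, which both rules generalize.
    """
    if mode not in ("figure10", "methods-text"):
        raise ValueError(f"unknown reduction mode: {mode!r}")
    ctx = frozenset(context) if context is not None else None
    for e in m.edges:
        if e.som_score is None or e.enzyme_family is None:
            raise ValueError(f"edge {e.edge_id} lacks annotation; annotate first")

    candidates = [e for e in m.edges if edge_available(e, ctx)]

    # (1) isoform collapse within (src, dst, family)
    groups: dict[tuple, list] = {}
    for e in candidates:
        groups.setdefault((e.src, e.dst, e.enzyme_family), []).append(e)
    collapsed = []
    for group in groups.values():
        group.sort(key=lambda e: (-e.som_score, e.enzyme or "", e.src))
        collapsed.append(group[0])

    # (2) greedy per-target selection under exclusivity
    by_target: dict[str, list] = {}
    for e in collapsed:
        by_target.setdefault(e.dst, []).append(e)
    retained: list[RetainedEdge] = []
    for target in sorted(by_target):
        pool = sorted(
            by_target[target], key=lambda e: (-e.som_score, e.enzyme or "", e.src)
        )
        while pool:
            best = pool.pop(0)
            retained.append(
                RetainedEdge(
                    best.src, best.dst, best.enzyme_family,
                    best.enzyme or best.enzyme_family, best.som_score,
                )
            )
            if mode == "figure10":
                pool = [
                    e for e in pool
                    if e.enzyme_family != best.enzyme_family and e.src != best.src
                ]
            else:
                pool = [e for e in pool if e.enzyme_family != best.enzyme_family]

    # (3) reachability cascade
    adj: dict[str, list[str]] = {}
    for e in retained:
        adj.setdefault(e.src, []).append(e.dst)
    keep = {m.original}
    stack = [m.original]
    while stack:
        cur = stack.pop()
        for nxt in adj.get(cur, ()):
            if nxt not in keep:
                keep.add(nxt)
                stack.append(nxt)
    reduced = ReducedNetwork(
        root=m.original,
        nodes=[nid for nid in m.nodes if nid in keep],
        edges=[e for e in retained if e.src in keep and e.dst in keep],
        source_exclusive=(mode == "figure10"),
    )
    reduced.validate()
    return reduced


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def _ancestors(reduced: ReducedNetwork, node_id: str) -> set[str]:
    out: set[str] = set()
    stack = [node_id]
    while stack:
        cur = stack.pop()
        for e in reduced.edges:
            if e.dst == cur and e.src not in out:
                out.add(e.src)
                stack.append(e.src)
    return out


def _topo(reduced: ReducedNetwork, subset: list[str]) -> list[str]:
    order: list[str] = []
    pending = set(subset)
    parents = {n: set(reduced.parents(n)) & pending for n in subset}
    while pending:
        ready = sorted(n for n in pending if not (parents[n] & pending))
        if not ready:
            raise ValueError("cycle detected in reduced network")
        order.extend(ready)
        pending -= set(ready)
    return order


def production_scores(reduced: ReducedNetwork) -> ScoreVector:
    """Exact production probability of every node of the reduced DAG.

    For each query node the joint states of its ancestor set are
    enumerated (the set is closed under taking parents, so the Bayes
    factorization over it is exact); each ancestor's conditional
    probability is noisy-OR over its produced parents.  Complexity is
    2^|ancestors| per node, which stays small on two-rank maps.
    """
    scores: ScoreVector = {reduced.root: 1.0}
    for node in reduced.nodes:
        if node == reduced.root:
            continue
        anc = _ancestors(reduced, node)
        anc.discard(reduced.root)
        if len(anc) > _ANCESTOR_LIMIT:
            raise ValueError(
                f"ancestor set of {node} too large for exact enumeration "
                f"({len(anc)} > {_ANCESTOR_LIMIT})"
            )
        order = _topo(reduced, sorted(anc))
        in_edges = {u: reduced.in_edges(u) for u in order + [node]}
        total = 0.0
        for bits in itertools.product((False, True), repeat=len(order)):
            state = dict(zip(order, bits))
            state[reduced.root] = True
            p_config = 1.0
            for u in order:
                p_on = 1.0
                for e in in_edges[u]:
                    if state.get(e.src, False):
                        p_on *= 1.0 - e.prob
                p_on = 1.0 - p_on
                p_config *= p_on if state[u] else 1.0 - p_on
                if p_config == 0.0:
                    break
            if p_config == 0.0:
                continue
            p_node = 1.0
            for e in in_edges[node]:
                if state.get(e.src, False):
                    p_node *= 1.0 - e.prob
            total += p_config * (1.0 - p_node)
        scores[node] = min(1.0, total)
    return scores


def brute_force_scores(reduced: ReducedNetwork) -> ScoreVector:
    """Oracle: enumerate all 2^|E| edge-firing states.

    For each state, the produced set is computed by reachability from
    the root through fired edges; state probabilities accumulate per
    node.  Exact by construction; refuses networks with more than
    25 edges.
    """
    n_edges = len(reduced.edges)
    if n_edges > _ORACLE_EDGE_LIMIT:
        raise ValueError(
            f"brute force limited to {_ORACLE_EDGE_LIMIT} edges, got {n_edges}"
        )
    scores = {n: 0.0 for n in reduced.nodes}
    for fired in itertools.product((False, True), repeat=n_edges):
        p_state = 1.0
        for e, f in zip(reduced.edges, fired):
            p_state *= e.prob if f else 1.0 - e.prob
        if p_state == 0.0:
            continue
        adj: dict[str, list[str]] = {}
        for e, f in zip(reduced.edges, fired):
            if f:
                adj.setdefault(e.src, []).append(e.dst)
        produced = {reduced.root}
        stack = [reduced.root]
        while stack:
            cur = stack.pop()
            for nxt in adj.get(cur, ()):
                if nxt not in produced:
                    produced.add(nxt)
                    stack.append(nxt)
        for n in produced:
            scores[n] += p_state
    return scores


def score_map(
    m: MetabolicMap,
    context: Optional[Iterable[str]] = None,
    mode: str = "figure10",
) -> ScoreVector:
    """Reduce and score; nodes dropped by the reduction score 0."""
    reduced = reduce_network(m, context=context, mode=mode)
    scores = production_scores(reduced)
    return {nid: scores.get(nid, 0.0) for nid in m.nodes}


def filter_map(
    m: MetabolicMap,
    scores: ScoreVector,
    threshold: float,
    strict: bool = False,
) -> MetabolicMap:
    """Keep nodes whose production score reaches the threshold.

    The original compound is kept unconditionally.  Edges survive only
    when both endpoints are kept; nodes cut off from the root by the
    filtration are cascade-removed (and logged).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0,1]")
    missing = [nid for nid in m.nodes if nid not in scores]
    if missing:
        raise ValueError(f"scores missing for nodes: {missing}")

    def keeps(nid: str) -> bool:
        if nid == m.original:
            return True
        s = scores[nid]
        return s > threshold if strict else s >= threshold

    doc = m.to_dict()
    kept_ids = {nd["node_id"] for nd in doc["nodes"] if keeps(nd["node_id"])}
    doc["nodes"] = [nd for nd in doc["nodes"] if nd["node_id"] in kept_ids]
    doc["edges"] = [
        ed for ed in doc["edges"] if ed["src"] in kept_ids and ed["dst"] in kept_ids
    ]
    out = MetabolicMap.from_dict_unchecked(doc)
    removed = out.prune_unreachable()
    if removed:
        logger.info("filter_map: cascade-removed %s (unreachable after filtering)", removed)
    out.validate()
    return out
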