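"""Enzymatic contexts, global reactivity scores and optimal signatures.

An *enzymatic context* is the subset of the enzyme universe declared
available; reactions catalysed by unavailable enzymes are excluded
before the Bayesian reduction, so production probability scores are
context-conditioned.  The default universe resolves CYPs at isoform
level and the conjugating families at family level:

    CYP1A2, CYP2C19, CYP2C9, CYP2D6, CYP3A4, UGTs, NATs, SULTs, GSTs

giving 2^9 = 512 contexts.  The *global reactivity score* of a map in
a context is the sum of the production probability scores of its
DNA-reactive metabolites; an *optimal enzymatic signature* is a
context of minimal cardinality attaining the maximal global
reactivity score.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .annotate import is_reactive
from .bayes import ScoreVector, edge_available, production_scores, reduce_network
from .core import CYP_ISOFORMS, MetabolicMap

#: The 9-enzyme universe of the study.
ENZYME_UNIVERSE = ("CYP1A2", "CYP2C19", "CYP2C9", "CYP2D6", "CYP3A4",
                   "UGTs", "NATs", "SULTs", "GSTs")

Context = frozenset


def enumerate_contexts(universe: Sequence[str] = ENZYME_UNIVERSE) -> list[Context]:
    """All subsets of the universe, by cardinality then lexicographic."""
    if not universe:
        raise ValueError("universe must be non-empty")
    if len(set(universe)) != len(universe):
        raise ValueError("duplicate labels in enzyme universe")
    ordered = sorted(universe)
    out: list[Context] = []
    for k in range(len(ordered) + 1):
        for combo in itertools.combinations(ordered, k):
            out.append(frozenset(combo))
    return out


class ContextScorer:
    """Caches per-context production scores for one annotated map.

    Two contexts admitting the same set of edges yield the same
    reduction, so score vectors are memoized on the admitted edge set;
    with 9 enzymes and a small map this collapses most of the 512
    contexts onto a few distinct reductions.
    """

    def __init__(self, m: MetabolicMap, mode: str = "figure10"):
        self.map = m
        self.mode = mode
        self._cache: dict[frozenset, ScoreVector] = {}

    def scores(self, context: Context) -> ScoreVector:
        admitted = frozenset(
            e.edge_id for e in self.map.edges if edge_available(e, context)
        )
        if admitted not in self._cache:
            reduced = reduce_network(self.map, context=context, mode=self.mode)
            scores = production_scores(reduced)
            self._cache[admitted] = {
                nid: scores.get(nid, 0.0) for nid in self.map.nodes
            }
        return self._cache[admitted]


def global_reactivity(
    m: MetabolicMap,
    context: Iterable[str],
    sor_threshold: float = 0.85,
    strict: bool = False,
    scorer: Optional[ContextScorer] = None,
) -> float:
    """Sum of production scores over DNA-reactive metabolites.

    Reactivity is recomputed from each node's SOR vector at the given
    threshold (the stored flag is ignored), so the same annotated map
    can be scanned over thresholds.  The root contributes only if it
    is itself reactive.
    """
    scorer = scorer or ContextScorer(m)
    scores = scorer.scores(frozenset(context))
    return sum(
        scores[nid]
        for nid, node in m.nodes.items()
        if is_reactive(node, sor_threshold, strict)
    )


@dataclass
class SignatureReport:
    """Exhaustive context scan results for one annotated map."""

    sor_threshold: float
    rows: list[tuple[Context, float]]  # one row per context, scan order
    max_score: float
    optimal_contexts: list[Context]
    tolerance: float = 1e-9

    def to_frame(self):
        import pandas as pd

        universe = sorted({e for ctx, _ in self.rows for e in ctx} |
                          set().union(*[set(c) for c in self.optimal_contexts or [frozenset()]]))
        opt = set(map(frozenset, self.optimal_contexts))
        recs = []
        for ctx, score in self.rows:
            recs.append(
                {
                    "context": "+".join(sorted(ctx)) if ctx else "(none)",
                    "n_enzymes": len(ctx),
                    "score": score,
                    "is_optimal": frozenset(ctx) in opt,
                }
            )
        return pd.DataFrame(recs)


def optimal_signatures(
    m: MetabolicMap,
    sor_threshold: float = 0.85,
    tolerance: float = 1e-9,
    universe: Sequence[str] = ENZYME_UNIVERSE,
    strict: bool = False,
    mode: str = "figure10",
    scorer: Optional[ContextScorer] = None,
) -> SignatureReport:
    """Scan every context; report score-maximal contexts of minimal size."""
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    scorer = scorer or ContextScorer(m, mode=mode)
    contexts = enumerate_contexts(universe)
    rows = [
        (ctx, global_reactivity(m, ctx, sor_threshold, strict, scorer))
        for ctx in contexts
    ]
    max_score = max(score for _, score in rows)
    near = [(ctx, s) for ctx, s in rows if s >= max_score - tolerance]
    min_card = min(len(ctx) for ctx, _ in near)
    optimal = [ctx for ctx, _ in near if len(ctx) == min_card]
    return SignatureReport(sor_threshold, rows, max_score, optimal, tolerance)


@dataclass
class SweepReport:
    """Optimal signatures recomputed along a grid of SOR thresholds."""

    grid: list[float]
    reactive_counts: list[int]
    signatures: list[list[Context]]  # optimal contexts per threshold
    max_scores: list[float]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sor_threshold": self.grid,
                "n_reactive": self.reactive_counts,
                "max_score": self.max_scores,
                "optimal_signatures": [
                    ";".join("+".join(sorted(c)) if c else "(none)" for c in sigs)
                    for sigs in self.signatures
                ],
            }
        )


def default_grid(step: float = 0.01) -> list[float]:
    """Thresholds 0.00, step, ..., 1.00 inclusive (101 points at 0.01)."""
    n = int(round(1.0 / step))
    return [round(i * step, 10) for i in range(n + 1)]


def threshold_sweep(
    m: MetabolicMap,
    grid: Optional[Sequence[float]] = None,
    tolerance: float = 1e-9,
    universe: Sequence[str] = ENZYME_UNIVERSE,
    mode: str = "figure10",
) -> SweepReport:
    """Recompute the reactive set and optimal signatures per threshold.

    Context-conditioned production scores do not depend on the SOR
    threshold, so they are computed once and re-summed per threshold.
    """
    if grid is None:
        grid = default_grid()
    grid = list(grid)
    if any(not 0.0 <= t <= 1.0 for t in grid) or sorted(grid) != grid:
        raise ValueError("grid must be sorted values in [0,1]")
    scorer = ContextScorer(m, mode=mode)
    counts, sigs, maxes = [], [], []
    for t in grid:
        counts.append(sum(1 for n in m.nodes.values() if is_reactive(n, t)))
        report = optimal_signatures(
            m, sor_threshold=t, tolerance=tolerance,
            universe=universe, mode=mode, scorer=scorer,
        )
        sigs.append(report.optimal_contexts)
        maxes.append(report.max_score)
    return SweepReport(list(grid), counts, sigs, maxes)
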