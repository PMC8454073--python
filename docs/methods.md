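# Methods

## Overview

`xenomap` builds *enriched maps of metabolism* for xenobiotics
(drugs, food-borne contaminants such as heterocyclic aromatic amines,
pollutants): rooted directed acyclic graphs whose nodes are predicted
metabolites and whose edges are biotransformation reactions.  The map
is decorated in stages —

1. **Prediction** — SMIRKS biotransformation rules are applied for two
   cycles (phase I oxidations, then any rule again on the first-cycle
   products), deduplicating metabolites by canonical SMILES.
2. **Enzyme labelling** — a rule→enzyme-family dictionary assigns each
   reaction to CYPs, UGTs, NATs, SULTs or GSTs; rules outside that
   universe (the two methyltransferase rules) are excluded and the
   orphaned metabolites pruned.
3. **SOM annotation** — site-of-metabolism tables (per substrate atom,
   per enzyme, score in [0,1]) attach a probability to each reaction;
   reactions scored by several CYP isoforms are duplicated, one edge
   per isoform.  Unscorable reactions are removed.
4. **Reactivity labelling** — per-atom site-of-reactivity (SOR) tables
   flag a metabolite as DNA-reactive when any atom reaches the
   threshold (default 0.85, inclusive).
5. **Scoring** — a Bayesian reduction turns the annotated map into a
   DAG on which each metabolite's *production probability score* is
   computed exactly.
6. **Context search** — production is re-scored under all 2^9 = 512
   *enzymatic contexts* (subsets of {CYP1A2, CYP2C19, CYP2C9, CYP2D6,
   CYP3A4, UGTs, NATs, SULTs, GSTs}) to find *optimal signatures*:
   smallest contexts maximizing the summed score of DNA-reactive
   metabolites.

## The rule catalogue

The shipped catalogue (`data/rules.tsv`) contains 43 transforms
authored for this package from standard xenobiotic biotransformation
chemistry: 16 phase I CYP reactions (aromatic and benzylic/aliphatic
hydroxylation, a dedicated xanthine C8 → uric-acid oxidation, N-/O-
dealkylations, azine and tertiary-amine N-oxidation, arylamine
N-hydroxylation — the canonical bioactivation step of heterocyclic
aromatic amines — alcohol/aldehyde oxidation, epoxidation, S-oxidation)
and 27 phase II conjugations structured as 13 glucuronidations, 5
N-acetylations, 6 sulfations and 1 glutathione conjugation, plus 2
methylation rules that the enzyme dictionary marks EXCLUDED because
methyltransferases fall outside the five-family universe.

Rules are written so that atom-map number 1 marks the *atom of
reaction*: the substrate atom receiving the new substituent
(conjugations, oxidations) or the heteroatom losing its alkyl group
(dealkylations).  The engine records that atom directly from the
transform match, in the canonical atom order of the substrate;
`detect_reaction_atom` recovers the same atom from a
maximum-common-substructure alignment of substrate and product for
maps produced without the engine, returning an AMBIGUOUS sentinel when
symmetry-inequivalent candidate sites tie (a manual override table,
edge_id → atom index, takes precedence in `fill_reaction_atoms`).

The catalogue is deliberately a *data* artifact: practitioners extend
it by editing the TSV (for instance adding the N-acetoxy and
N-sulfonyloxy activation chemistry of arylhydroxylamines — O-sulfation
of N-hydroxy groups is already included).  Two caveats follow.  First,
published map sizes obtained with other catalogues are reproducible
only with those catalogues; with this one, the caffeine map contains
21 metabolites and 29 reactions whose qualitative content matches the
published caffeine map closely (the three N-demethylations,
trimethyluric acid, the imidazole N-oxide as the sole unknown
first-rank metabolite, xanthine N-glucuronides, and the convergent
re-demethylation of trimethyluric acid toward all three dimethyluric
acids).  Second, recovery against curated references is catalogue-
dependent; the shipped rules recover 11 of the 16 known caffeine
metabolites (including caffeine), missing exactly the two
NAT-dependent uracils (no xanthine-opening N-acetylation rule exists
in the catalogue) and the three monomethyluric acids (three reactions
away from caffeine, beyond two cycles).

## Annotation policy

Rank-based by default, reflecting the two-phase structure of
xenobiotic metabolism: first-rank reactions are matched against
CYP-isoform records (five isoforms) plus family-level UGT records;
second-rank reactions against family-level records of all five
families.  The key is `(substrate canonical SMILES, reaction atom,
enzyme)`; a score of 0 is a *valid* annotation distinct from "no
record".  This policy has a known blind spot — a genuine first-rank
conjugation (e.g. an arylamine N-sulfamate) can never be scored, and
its product inherits a null production probability — so a by-`enzyme`
policy is provided that matches on the edge's family regardless of
rank.

Scores from different providers are used as-is; no cross-provider
rescaling is attempted (no principled mapping between provider score
scales exists, and the rank policy keeps scores homogeneous within a
rank).

## Bayesian reduction and production probability

SOM scores are read as conditional probabilities: the probability of
the product given the substrate.  Before inference the map is reduced
under two recruitment-exclusivity principles:

1. one enzyme catalyzes a reaction — per (substrate, product) pair
   only the top-scoring enzyme survives (within CYPs, the best isoform;
   across families, the best family);
2. an enzyme family recruited for one reaction into a target cannot be
   recruited for a second reaction into the same target — greedily,
   the highest-scoring candidate into each target is retained and all
   remaining candidates sharing its family *or* its substrate are
   discarded.

Ties break deterministically (higher score, then lexicographically
lower enzyme label, then lower substrate id).  The textual variant of
the rule (family exclusivity only, no per-substrate exclusivity) is
available as `reduction="methods-text"`; the default `"figure10"`
follows the published worked example, which the textual rule does not
fully determine.  Enzymatic contexts are applied *before* reduction,
so removing an enzyme lets the next-best candidate take over rather
than deleting the reaction outright.  A family-level CYPs edge (from
rank-2 annotation, which cannot name an isoform) counts as available
when any CYP isoform is in the context.

On the reduced DAG every retained edge fires independently with its
score as probability; a metabolite is produced when at least one
incoming edge fires from a produced substrate (noisy-OR), and the
root is produced with probability 1.  `production_scores` computes
each node's marginal exactly by enumerating joint states of its
ancestor set (which is closed under taking parents, so the Bayes
factorization over it is exact and correlations through shared
ancestors are respected).  Complexity is 2^|ancestors| per node —
negligible on two-rank maps; a guard refuses ancestor sets above 22.
`brute_force_scores` enumerates all 2^|E| edge states (limit 25
edges) and serves as the independent oracle; the suite checks
agreement to 1e-12 on 200 seeded random maps.

Filtration keeps metabolites whose score reaches the threshold
(default 0.10, inclusive; a strict flag exists because published
boundary phrasing is mixed), always keeps the root, and cascade-
removes metabolites disconnected by the filtering.

## Signature search and threshold sweep

The global reactivity score of a context is the sum of production
probabilities over DNA-reactive metabolites (the root counts only if
itself reactive).  All 512 contexts are scanned; contexts admitting
the same edge set share one reduction/inference pass (memoized).
Optimal signatures are the contexts within 1e-9 of the maximal score
having minimal cardinality — all of them are reported, so exact ties
(e.g. two isoforms with identical records) surface as distinct
signatures.  The SOR-threshold sweep re-derives the reactive set and
the optimal signatures at 101 thresholds (0.00–1.00, step 0.01);
since production scores do not depend on the SOR threshold they are
computed once and re-summed.

## Synthetic data

The generator (`FixtureSpec`, `generate_random_map`) emulates the
statistical shape of an annotated two-rank map without chemistry:
abstract node ids behind the same graph interface (chemistry-dependent
operations refuse such maps).  Defaults: 6 first-rank metabolites
(the caffeine map has 5 first-rank reactions), mean 2 second-rank
products per first-rank metabolite with a shared product pool (so
multi-parent targets exercise the exclusivity rules), 1–3 parallel
enzymes per first-rank reaction, SOM scores Beta(2,2) with a 15%
point mass at exactly 0 (the caffeine map has 5 null-scored reactions
of 31), per-atom SOR scores Beta(1.5,6) with a 45% chance of one
high-reactivity atom in U(0.85,1) (published reactive ratios cluster
at 40–50%).  For chemical maps, `synthesize_tables` fabricates
provider-style SOM/SOR tables keyed to the map's real SMILES and
reaction atoms, reproducing the rank-policy provider landscape
(isoform records at rank 1, family records at rank 2, no rank-1
records for NATs/SULTs/GSTs).

What passing on synthetic data does *not* show: real SOM providers
produce correlated isoform scores and systematic biases absent here;
synthetic SOR vectors are i.i.d. per atom, whereas real reactivity
concentrates on exocyclic nitrogens and activated ring positions; and
no statement about any real compound's metabolism follows from
fixture-level correctness.

## Numerical choices

- Tie-breaking everywhere is deterministic; two runs of any stage are
  byte-identical.
- Signature tie tolerance 1e-9 (floating-point sums of ≤ hundreds of
  terms); oracle agreement asserted at 1e-12.
- Reactivity and filtration comparisons are inclusive (≥) by default
  with strict (>) flags.
- Cycle-creating edges (rule inversions such as
  demethylation/methylation pairs) are dropped, not errors: maps are
  DAGs by construction.
- Degenerate inputs: an empty ruleset yields the one-node map; an
  empty context reduces to the root alone; score-0 annotations
  propagate exactly (a metabolite all of whose pathways contain a
  null-scored reaction scores exactly 0).

## Known limitations

- Two cycles cannot reach third-generation metabolites (e.g. the
  monomethyluric acids of caffeine).
- Node identity is canonical-SMILES equality: tautomers and charge
  states are distinct nodes (the xanthine-oxidation rule emits the
  oxo tautomer directly to avoid an 8-hydroxy/8-oxo split); no
  neutralization or tautomer canonicalization is applied, and
  stereochemistry-aware identity is out of scope.
- Exact inference is designed for shallow (two-rank) maps; deep or
  dense DAGs would need variable elimination or sampling.
- The greedy reduction is order-deterministic but not globally
  optimal in any variational sense; enlarging a context is not
  guaranteed to raise scores, though no violation occurs on the
  seeded fixture suite (tested as a diagnostic).
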