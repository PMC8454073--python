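# xenomap

Enriched maps of xenobiotic metabolism: predict the metabolites of a
parent compound with SMIRKS biotransformation rules, annotate each
reaction with site-of-metabolism (SOM) probabilities and each
metabolite with per-atom DNA-reactivity (SOR) scores, rank metabolites
by an exact Bayesian *production probability*, and search enzymatic
contexts for the smallest enzyme combinations that maximize the
production of DNA-reactive metabolites.

The package is aimed at predictive-toxicology work on compounds whose
bioactivation cannot be fully characterized experimentally — the
motivating case being heterocyclic aromatic amines (HAA), food-borne
contaminants whose CYP-mediated N-hydroxylation and subsequent
O-conjugation yield nitrenium ions that form DNA adducts.

## The model

A map of metabolism is a DAG rooted at the parent compound; an edge
carries the rule that produced it, its rank (rule-application cycle,
1 or 2), the atom of reaction, an enzyme family or CYP isoform, and a
SOM score `p ∈ [0, 1]`.  After a reduction that enforces enzyme
recruitment exclusivity (per target: at most one reaction per enzyme
family and per substrate; per reaction: one enzyme), each retained
edge `u → v` is treated as firing independently with probability
`p_uv`, and

    P(v produced) = P( ∃ u → v : u produced ∧ edge fires ),
    P(root) = 1,

a noisy-OR Bayesian network whose marginals are computed exactly
(shared-ancestor correlations included).  For an enzymatic context
`C ⊆ {CYP1A2, CYP2C19, CYP2C9, CYP2D6, CYP3A4, UGTs, NATs, SULTs,
GSTs}`, edges of unavailable enzymes are removed before reduction; the
*global reactivity score* of `C` is `Σ P(v | C)` over DNA-reactive
metabolites `v` (max atom SOR ≥ 0.85 by default), and an *optimal
enzymatic signature* is a cardinality-minimal `C` attaining the
maximal score over all 512 contexts.

SOM and SOR predictions enter only as TSV tables (from any provider,
or from the built-in synthetic generator); no web service is called.
See `docs/methods.md` for the full method description.

## Worked example

Run the whole pipeline on caffeine with synthetic annotation tables
(deterministic at a given seed):

```python
from xenomap import run_pipeline

manifest = run_pipeline(
    {
        "parent_smiles": "CN1C=NC2=C1C(=O)N(C)C(=O)N2C",  # caffeine
        "som": {"synthetic": {"seed": 7}},
        "sor": {"synthetic": {"seed": 7}},
    },
    "out/",
)
for stage, info in manifest["stages"].items():
    print(stage, info)
```

prints (abridged):

```
build      {'artifact': 'map.json', 'n_metabolites': 20, 'n_reactions': 28, ...}
annotate   {'artifact': 'annotated.json', 'n_metabolites': 20, 'n_reactions': 34, 'n_reactive': 9, 'ratio_reactive_percent': 45.0}
filter     {'artifact': 'filtered.json', 'threshold': 0.1, 'n_metabolites': 13, 'n_reactions': 22, ...}
signatures {'artifact': 'report.tsv', 'max_score': 2.098499938315877, 'optimal': ['CYP2D6+CYP3A4']}
sweep      {'artifact': 'sweep.tsv', 'n_thresholds': 101}
```

Reading: two rule cycles predict 20 caffeine metabolites linked by 28
reactions; SOM annotation duplicates CYP reactions per isoform (34
edges) and the synthetic SOR tables flag 9 metabolites as
DNA-reactive (45%).  Filtering at production probability ≥ 0.10 keeps
13 metabolites.  Under these synthetic annotations the smallest
enzyme combination maximizing reactive-metabolite production is
{CYP2D6, CYP3A4} with a global reactivity score of 2.098, stable
across the 101-point SOR-threshold sweep.  The top of `scores.tsv`:

```
node_id  smiles                              production_score
n0       Cn1c(=O)c2c(ncn2C)n(C)c1=O          1
n1       Cn1c(=O)c2c([nH]c(=O)n2C)n(C)c1=O   0.778359759936
n2       Cn1c(=O)[nH]c2ncn(C)c2c1=O          0.69303940201
```

(n0 is caffeine, n1 its trimethyluric acid, n2 theophylline.)

The same stages are available as a CLI:

```
xenomap build --smiles 'CN1C=NC2=C1C(=O)N(C)C(=O)N2C' --out map.json
xenomap annotate --map map.json --som som.tsv --sor sor.tsv --out annotated.json
xenomap score --map annotated.json --context all --out scores.tsv
xenomap filter --map annotated.json --scores scores.tsv --threshold 0.10 --out filtered.json
xenomap signatures --map annotated.json --sor-threshold 0.85 --out report.tsv
xenomap sweep --map annotated.json --step 0.01 --out sweep.tsv
xenomap simulate --seed 1 --out fixture/     # synthetic map + tables
xenomap summary --map map.json
xenomap compare --map map.json               # vs the caffeine reference list
```

The built caffeine map recovers 11 of the 16 known caffeine
metabolites (including caffeine itself): the three dimethylxanthines,
the three monomethylxanthines, and the four uric acids reachable in
two reactions.  The misses are the two NAT-derived uracils (chemistry
absent from the catalogue) and the three monomethyluric acids (three
reactions from caffeine).

## Layout

- `src/xenomap/core.py` — graph model, canonicalization, JSON/GraphML
- `src/xenomap/rules.py` — SMIRKS engine, ruleset, enzyme dictionary
- `src/xenomap/annotate.py` — SOM/SOR tables, reaction-atom detection
- `src/xenomap/bayes.py` — reduction, exact inference, oracle, filter
- `src/xenomap/signatures.py` — contexts, reactivity, sweep
- `src/xenomap/synth.py` — synthetic fixtures and reference data
- `src/xenomap/pipeline.py`, `cli.py` — orchestration and CLI
- `src/xenomap/data/` — rule catalogue, enzyme dictionary, caffeine
  reference list (editable TSVs)
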