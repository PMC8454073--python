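import pytest

from xenomap import (
    EnzymeDictionary,
    MetabolicMap,
    Ruleset,
    annotate_reactivity,
    annotate_som,
    apply_enzyme_dictionary,
    predict_map,
    synthesize_tables,
)

CAFFEINE = "CN1C=NC2=C1C(=O)N(C)C(=O)N2C"


@pytest.fixture(scope="session")
def ruleset():
    return Ruleset.builtin()


@pytest.fixture(scope="session")
def enzyme_dict():
    return EnzymeDictionary.builtin()


@pytest.fixture(scope="session")
def caffeine_raw(ruleset):
    """Two-cycle caffeine map straight from the rule engine."""
    return predict_map(CAFFEINE, ruleset, n_cycles=2, display_name="caffeine")


@pytest.fixture(scope="session")
def caffeine_map(caffeine_raw, enzyme_dict):
    """Caffeine map with enzyme families applied."""
    return apply_enzyme_dictionary(caffeine_raw, enzyme_dict)


@pytest.fixture(scope="session")
def caffeine_annotated(caffeine_map):
    """Caffeine map annotated from synthetic SOM/SOR tables."""
    som, sor = synthesize_tables(caffeine_map, seed=7)
    m = annotate_som(caffeine_map, som)
    return annotate_reactivity(m, sor, threshold=0.85)


def abstract_map(edges, sor=None):
    """Build a small annotated abstract map from edge tuples.

    ``edges``: iterable of (src, dst, enzyme, prob, rank); the first
    edge's src is the original compound.  ``sor`` maps node_id -> peak
    SOR value (default 0.1, root 0.0).
    """
    m = MetabolicMap(abstract=True)
    root = edges[0][0]
    m.add_metabolite(node_id=root, is_original=True)
    atom = {}
    for src, dst, enzyme, prob, rank in edges:
        for nid in (src, dst):
            if nid not in m.nodes:
                m.add_metabolite(node_id=nid)
        atom[src] = atom.get(src, -1) + 1
        family = "CYPs" if enzyme.startswith("CYP") and enzyme != "CYPs" else enzyme
        m.new_edge(
            src, dst, rule_name="toy", rank=rank, reaction_atom=atom[src],
            enzyme_family=family,
            isoform=enzyme if family == "CYPs" and enzyme != "CYPs" else None,
            som_score=prob, som_source="toy",
        )
    sor = sor or {}
    for nid, node in m.nodes.items():
        peak = 0.0 if nid == root else 0.1
        node.atom_sor = [sor.get(nid, peak)]
        node.dna_reactive = node.atom_sor[0] >= 0.85
    m.validate()
    return m
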