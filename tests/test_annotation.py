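"""SOM/SOR annotation: atom detection, rank policy, reactivity."""

import pytest

from xenomap import (
    ChemistryError,
    Rule,
    Ruleset,
    SomRecord,
    SomTable,
    SorTable,
    annotate_reactivity,
    annotate_som,
    apply_enzyme_dictionary,
    detect_reaction_atom,
    fill_reaction_atoms,
    predict_map,
    EnzymeDictionary,
    MetabolicMap,
)

from conftest import abstract_map


class TestDetectReactionAtom:
    def test_toluene_benzylic_oxidation(self):
        res = detect_reaction_atom("Cc1ccccc1", "OCc1ccccc1")
        assert res.atom_index == 0 and not res.ambiguous  # the methyl carbon

    def test_phenol_glucuronidation_on_oxygen(self):
        res = detect_reaction_atom(
            "Oc1ccccc1", "O=C(O)C1OC(Oc2ccccc2)C(O)C(O)C1O"
        )
        assert res.atom_index == 0 and not res.ambiguous  # phenolic oxygen

    def test_symmetric_methyls_flagged(self):
        res = detect_reaction_atom("Cc1ccc(C)cc1", "Cc1ccc(CO)cc1")
        assert res.symmetric and not res.ambiguous
        assert res.atom_index == 0  # lowest member of the equivalence class

    def test_no_common_substructure_errors(self):
        with pytest.raises(ChemistryError, match="common substructure"):
            detect_reaction_atom("O", "C")

    def test_agrees_with_engine_recorded_atoms(self, caffeine_raw):
        """MCS detection reproduces the transform-recorded sites."""
        checked = 0
        for e in caffeine_raw.edges:
            if e.rank != 1:
                continue
            res = detect_reaction_atom(
                caffeine_raw.nodes[e.src].smiles, caffeine_raw.nodes[e.dst].smiles
            )
            if res.ambiguous or res.symmetric:
                continue
            assert res.atom_index == e.reaction_atom, e.rule_name
            checked += 1
        assert checked >= 4

    def test_override_takes_precedence(self):
        m = predict_map(
            "Cc1ccccc1",
            Ruleset([Rule("bh", "I", "[C;X4;H3:1][c:2]>>[C:1](O)[c:2]")]),
            n_cycles=1,
        )
        (edge,) = m.edges
        edge.reaction_atom = None
        left = fill_reaction_atoms(m, overrides={edge.edge_id: 3})
        assert left == [] and edge.reaction_atom == 3


def toluene_cyp_map():
    """toluene -> benzyl alcohol, a single rank-1 CYPs edge."""
    m = predict_map(
        "Cc1ccccc1",
        Ruleset([Rule("benzylic_hydroxylation", "I",
                      "[C;X4;H3:1][c:2]>>[C:1](O)[c:2]")]),
        n_cycles=1,
    )
    return apply_enzyme_dictionary(
        m, EnzymeDictionary({"benzylic_hydroxylation": "CYPs"})
    )


class TestAnnotateSom:
    def test_single_isoform_record(self):
        m = toluene_cyp_map()
        table = SomTable([SomRecord("Cc1ccccc1", 0, "CYP3A4", 0.714, "w2d", "1")])
        out = annotate_som(m, table)
        (edge,) = out.edges
        assert (edge.enzyme_family, edge.isoform, edge.som_score) == (
            "CYPs", "CYP3A4", 0.714,
        )

    def test_two_isoforms_duplicate_edge(self):
        m = toluene_cyp_map()
        table = SomTable(
            [
                SomRecord("Cc1ccccc1", 0, "CYP1A2", 0.9, "w2d", "1"),
                SomRecord("Cc1ccccc1", 0, "CYP3A4", 0.4, "w2d", "1"),
            ]
        )
        out = annotate_som(m, table)
        assert len(out.edges) == 2
        assert {(e.src, e.dst, e.rule_name, e.reaction_atom) for e in out.edges} == {
            (out.edges[0].src, out.edges[0].dst, "benzylic_hydroxylation", 0)
        }
        assert {(e.isoform, e.som_score) for e in out.edges} == {
            ("CYP1A2", 0.9), ("CYP3A4", 0.4),
        }

    def test_zero_score_record_is_kept(self):
        m = toluene_cyp_map()
        out = annotate_som(
            m, SomTable([SomRecord("Cc1ccccc1", 0, "CYP2D6", 0.0, "w2d", "1")])
        )
        assert len(out.edges) == 1 and out.edges[0].som_score == 0.0

    def test_unannotated_rank2_edge_cascades_away(self):
        """aniline -> N-hydroxy (rank 1 CYPs) -> hydroxamic acid
        (rank 2 NATs); with no rank-2 record the NAT product must
        disappear with its edge."""
        rules = Ruleset(
            [
                Rule("n_hydroxylation_arylamine", "I",
                     "[N;X3;H2;$(Nc):1]>>[N:1]O"),
                Rule("n_acetylation_arylhydroxylamine", "II",
                     "[N;X3;H1;$(N(c)O):1]>>[N:1]C(C)=O"),
            ]
        )
        m = predict_map("Nc1ccccc1", rules, n_cycles=2)
        m = apply_enzyme_dictionary(
            m,
            EnzymeDictionary(
                {"n_hydroxylation_arylamine": "CYPs",
                 "n_acetylation_arylhydroxylamine": "NATs"}
            ),
        )
        assert len(m.nodes) == 3
        (r1_edge,) = [e for e in m.edges if e.rank == 1]
        table = SomTable(
            [SomRecord("Nc1ccccc1", r1_edge.reaction_atom, "CYP1A2", 0.8, "w2d", "1")]
        )
        out = annotate_som(m, table)
        assert len(out.nodes) == 2 and len(out.edges) == 1

    def test_split_tables_equal_concatenated(self):
        m = toluene_cyp_map()
        records = [
            SomRecord("Cc1ccccc1", 0, "CYP1A2", 0.9, "w2d", "1"),
            SomRecord("Cc1ccccc1", 0, "CYP3A4", 0.4, "w2d", "1"),
        ]
        one = annotate_som(m, SomTable(records))
        split = annotate_som(m, [SomTable(records[:1]), SomTable(records[1:])])
        assert {(e.isoform, e.som_score) for e in one.edges} == {
            (e.isoform, e.som_score) for e in split.edges
        }

    def test_atom_index_outside_molecule_rejected(self):
        m = toluene_cyp_map()
        with pytest.raises(ValueError, match="outside"):
            annotate_som(
                m, SomTable([SomRecord("Cc1ccccc1", 99, "CYP3A4", 0.5, "w2d", "1")])
            )

    def test_abstract_map_refused(self):
        m = abstract_map([("r", "a", "UGTs", 0.5, 1)])
        with pytest.raises(ChemistryError):
            annotate_som(m, SomTable([]))

    def test_enzyme_policy_scores_rank1_conjugation(self):
        """The by-enzyme policy fixes the rank-policy blind spot: a
        rank-1 sulfation can be scored from a family-level record."""
        rules = Ruleset(
            [Rule("n_sulfation_arylamine", "II",
                  "[N;X3;H2;$(Nc):1]>>[N:1]S(=O)(=O)O")]
        )
        m = predict_map("Nc1ccccc1", rules, n_cycles=1)
        m = apply_enzyme_dictionary(
            m, EnzymeDictionary({"n_sulfation_arylamine": "SULTs"})
        )
        (edge,) = m.edges
        table = SomTable(
            [SomRecord("Nc1ccccc1", edge.reaction_atom, "SULTs", 0.6, "fame", "2")]
        )
        under_rank = annotate_som(m, table, policy="rank")
        assert len(under_rank.edges) == 0  # rank policy cannot score it
        under_enzyme = annotate_som(m, table, policy="enzyme")
        assert len(under_enzyme.edges) == 1
        assert under_enzyme.edges[0].som_score == 0.6


class TestAnnotateReactivity:
    def make_map(self, peaks):
        m = MetabolicMap(abstract=True)
        m.add_metabolite(node_id="root", is_original=True)
        sor_records = [("root", 0, 0.0)]
        for i, p in enumerate(peaks):
            m.add_metabolite(node_id=f"m{i}")
            m.new_edge("root", f"m{i}", "toy", 1, enzyme_family="CYPs",
                       som_score=0.5, som_source="toy")
            sor_records += [(f"m{i}", 0, p), (f"m{i}", 1, p / 2)]
        return m, SorTable(sor_records)

    def test_threshold_boundary_inclusive(self):
        m, sor = self.make_map([0.84, 0.85, 0.86])
        out = annotate_reactivity(m, sor, threshold=0.85)
        flags = [out.nodes[f"m{i}"].dna_reactive for i in range(3)]
        assert flags == [False, True, True]

    def test_strict_flag(self):
        m, sor = self.make_map([0.84, 0.85, 0.86])
        out = annotate_reactivity(m, sor, threshold=0.85, strict=True)
        flags = [out.nodes[f"m{i}"].dna_reactive for i in range(3)]
        assert flags == [False, False, True]

    def test_zero_threshold_boundary(self):
        m, sor = self.make_map([0.0])
        out = annotate_reactivity(m, sor, threshold=0.0)
        assert out.nodes["m0"].dna_reactive  # >= convention at the boundary

    def test_monotone_in_threshold(self):
        m, sor = self.make_map([0.1, 0.3, 0.5, 0.7, 0.9])
        previous = None
        for t in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
            out = annotate_reactivity(m, sor, threshold=t)
            reactive = {n for n, node in out.nodes.items() if node.dna_reactive}
            if previous is not None:
                assert reactive <= previous
            previous = reactive

    def test_missing_node_defaults_non_reactive(self):
        m, sor = self.make_map([0.9])
        m.add_metabolite(node_id="orphan")
        m.new_edge("root", "orphan", "toy", 1, enzyme_family="CYPs",
                   som_score=0.5, som_source="toy")
        out = annotate_reactivity(m, sor, threshold=0.85)
        assert out.nodes["orphan"].dna_reactive is False
        assert out.nodes["orphan"].atom_sor is None

    def test_fills_full_atom_vector(self, caffeine_annotated):
        for node in caffeine_annotated.nodes.values():
            assert node.atom_sor is not None
            assert all(0.0 <= v <= 1.0 for v in node.atom_sor)
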