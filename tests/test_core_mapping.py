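import random

import pytest

from rgcore import MoleculeRecord, RunConfig, assemble_rg, assign_all, extract_cores
from rgcore.core_extraction import RGCore, canonical_graph_smiles, rg_mcs
from rgcore.core_mapping import (
    ResolutionStage,
    aggregate_reference_maps,
    enumerate_mappings,
    node_distance_map,
    resolve_mapping,
    substituent_distance_map,
)
from rgcore.fixtures import make_ambiguous_pair_series
from rgcore.rg_builder import rg_to_nx


def rg_of(smiles, cid="t"):
    return assemble_rg(MoleculeRecord(cid, smiles, 5.0))


def whole_rg_core(rg, core_id=1):
    return RGCore(core_id, rg_to_nx(rg), rg.rg_smiles, [rg.compound_id])


def label_of(core, node):
    return core.graph.nodes[node]["label"]


@pytest.fixture(scope="module")
def ambiguous_setup():
    series = make_ambiguous_pair_series()
    cfg = RunConfig(similarity_threshold=0.5, min_core_size=3)
    rgs = [assemble_rg(r, cfg) for r in series.records]
    cores = extract_cores(rgs, cfg)
    core = next(c for c in cores if c.core_smarts == series.expected_core_smarts)
    return series, rgs, core


class TestEnumerateMappings:
    def test_isomorphic_molecule_single_mapping(self, toy_rgs):
        rg = toy_rgs[0]
        assert len(enumerate_mappings(rg, whole_rg_core(rg))) == 1

    def test_two_like_nodes_two_mappings(self, ambiguous_setup):
        series, rgs, core = ambiguous_setup
        amb = next(r for r in rgs if r.compound_id == series.ambiguous_id)
        assert len(enumerate_mappings(amb, core)) == 2

    def test_absent_label_no_mappings(self, toy_rgs):
        cyclohexane = rg_of("C1CCCCC1")
        assert enumerate_mappings(toy_rgs[0], whole_rg_core(cyclohexane)) == []

    def test_automorphic_embeddings_collapse(self):
        # two equivalent Hg positions: core automorphism, one atom image
        rg = rg_of("NC(=O)Cc1ccc(Cl)c(Cl)c1")
        assert len(enumerate_mappings(rg, whole_rg_core(rg))) == 1


class TestNodeDistanceMap:
    def test_adjacent_and_seven_bond_pairs(self):
        # amide and phenyl separated by a hexamethylene linker: 7 bonds
        rg = rg_of("NC(=O)CCCCCCc1ccc(Cl)cc1")
        core = whole_rg_core(rg)
        (m,) = enumerate_mappings(rg, core)
        nd = node_distance_map(rg, m)
        by_labels = {
            frozenset((label_of(core, i), label_of(core, j))): d
            for (i, j), d in nd.entries.items()
        }
        assert by_labels[frozenset(("Ge", "Li"))] == 1
        assert by_labels[frozenset(("Li", "No"))] == 1
        assert by_labels[frozenset(("Ge", "No"))] == 7

    def test_all_pairs_present(self):
        rg = rg_of("NC(=O)Cc1ccc(Cl)cc1")
        (m,) = enumerate_mappings(rg, whole_rg_core(rg))
        nd = node_distance_map(rg, m)
        n = len(rg)
        assert len(nd.entries) == n * (n - 1) // 2

    def test_single_node_core_empty_map(self):
        rg = rg_of("c1ccncc1")
        (m,) = enumerate_mappings(rg, whole_rg_core(rg))
        assert node_distance_map(rg, m).entries == {}


class TestSubstituentDistanceMap:
    def test_sorted_three_site_encoding(self):
        # benzylic alcohol, halogens ortho/meta/meta to the linker: the
        # linker node sees its three substitution sites at 3, 4 and 4 bonds
        rg = rg_of("OCc1c(F)c(Cl)cc(Cl)c1")
        template = rg_of("OCc1ccccc1")
        core_graph = rg_mcs(rg, template)
        core = RGCore(1, core_graph, canonical_graph_smiles(core_graph), [])
        (m,) = enumerate_mappings(rg, core)
        sd = substituent_distance_map(rg, m)
        by_label = {label_of(core, c): v for c, v in sd.entries.items()}
        assert by_label["Li"] == (3, 4, 4)
        assert by_label["No"] == (1, 1, 1)
        assert by_label["Ge"] == (4, 5, 5)

    def test_molecule_equal_to_core_has_no_sites(self):
        rg = rg_of("NC(=O)Cc1ccc(Cl)cc1")
        (m,) = enumerate_mappings(rg, whole_rg_core(rg))
        sd = substituent_distance_map(rg, m)
        assert all(v == () for v in sd.entries.values())

    def test_one_site_gives_length_one_lists(self):
        rg = rg_of("CNC(=O)Cc1ccc(Cl)cc1")  # N-methyl outside a 4-node core
        template = rg_of("NC(=O)Cc1ccc(Cl)cc1")
        core_graph = rg_mcs(rg, template)
        core = RGCore(1, core_graph, canonical_graph_smiles(core_graph), [])
        (m,) = enumerate_mappings(rg, core)
        sd = substituent_distance_map(rg, m)
        assert all(len(v) == 1 for v in sd.entries.values())


class TestAggregation:
    def test_identical_maps_increment_count(self, ambiguous_setup):
        series, rgs, core = ambiguous_setup
        by_id = {rg.compound_id: rg for rg in rgs}
        unique = [
            enumerate_mappings(rg, core)[0]
            for rg in rgs
            if rg.compound_id != series.ambiguous_id
        ]
        node_refs, sub_refs = aggregate_reference_maps(by_id, unique)
        assert len(node_refs) == 1 and node_refs[0].count == 4
        assert len(sub_refs) == 1 and sub_refs[0].count == 4

    def test_distinct_maps_kept_separately(self):
        a = rg_of("NC(=O)Cc1ccc(Cl)cc1", "a")
        b = rg_of("NC(=O)CCCCCCc1ccc(Cl)cc1", "b")  # stretched analogue
        core = whole_rg_core(a)
        ma = enumerate_mappings(a, core)[0]
        (mb,) = enumerate_mappings(b, core)
        node_refs, _ = aggregate_reference_maps({"a": a, "b": b}, [ma, mb])
        assert len(node_refs) == 2
        assert [r.count for r in node_refs] == [1, 1]

    def test_no_unique_mappings_empty_references(self):
        assert aggregate_reference_maps({}, []) == ([], [])


class TestResolution:
    def test_ambiguous_molecule_resolves_to_ground_truth(self, ambiguous_setup):
        series, rgs, core = ambiguous_setup
        assignments = assign_all(rgs, core and [core])[core.core_id]
        amb = next(m for m in assignments if m.compound_id == series.ambiguous_id)
        assert amb.ambiguous
        assert amb.resolution_stage is ResolutionStage.NODE_MAP
        rg = next(r for r in rgs if r.compound_id == series.ambiguous_id)
        nd = node_distance_map(rg, amb)
        by_labels = {
            frozenset((label_of(core, i), label_of(core, j))): d
            for (i, j), d in nd.entries.items()
        }
        assert by_labels[frozenset(("Ge", "No"))] == series.expected_node_map["Ge-No"]

    def test_resolution_permutation_invariant(self, ambiguous_setup):
        series, rgs, core = ambiguous_setup
        by_id = {rg.compound_id: rg for rg in rgs}
        amb_rg = by_id[series.ambiguous_id]
        unique = [
            enumerate_mappings(rg, core)[0]
            for rg in rgs
            if rg.compound_id != series.ambiguous_id
        ]
        refs = aggregate_reference_maps(by_id, unique)
        candidates = enumerate_mappings(amb_rg, core)
        chosen = resolve_mapping(amb_rg, list(candidates), refs).correspondence
        for seed in range(5):
            shuffled = list(candidates)
            random.Random(seed).shuffle(shuffled)
            assert resolve_mapping(amb_rg, shuffled, refs).correspondence == chosen

    def test_no_references_falls_back_deterministically(self, ambiguous_setup):
        series, rgs, core = ambiguous_setup
        amb_rg = next(r for r in rgs if r.compound_id == series.ambiguous_id)
        candidates = enumerate_mappings(amb_rg, core)
        chosen = resolve_mapping(amb_rg, candidates, ([], []))
        assert chosen.resolution_stage is ResolutionStage.FALLBACK
        assert chosen.correspondence in [c.correspondence for c in candidates]

    def test_chosen_mapping_is_always_a_candidate(self, ambiguous_setup):
        series, rgs, core = ambiguous_setup
        assignments = assign_all(rgs, [core])[core.core_id]
        for m in assignments:
            rg = next(r for r in rgs if r.compound_id == m.compound_id)
            cands = [c.correspondence for c in enumerate_mappings(rg, core)]
            assert m.correspondence in cands


class TestAssignAll:
    def test_union_of_members_covers_dataset(self, many_rgs, config):
        cores = extract_cores(many_rgs, config)
        assignments = assign_all(many_rgs, cores)
        assigned = {m.compound_id for ms in assignments.values() for m in ms}
        assert assigned == {rg.compound_id for rg in many_rgs}

    def test_molecule_under_every_core_it_contains(self, many_rgs, config):
        cores = extract_cores(many_rgs, config)
        assignments = assign_all(many_rgs, cores)
        for core in cores:
            members = {m.compound_id for m in assignments[core.core_id]}
            for rg in many_rgs:
                contains = bool(enumerate_mappings(rg, core))
                assert (rg.compound_id in members) == contains

    def test_second_pass_supersets_extraction_members(self, many_rgs, config):
        cores = extract_cores(many_rgs, config)
        assignments = assign_all(many_rgs, cores)
        for core in cores:
            members = {m.compound_id for m in assignments[core.core_id]}
            assert set(core.member_ids) <= members

    def test_mapping_preserves_labels(self, toy_rgs, config):
        cores = extract_cores(toy_rgs, config)
        assignments = assign_all(toy_rgs, cores)
        by_id = {rg.compound_id: rg for rg in toy_rgs}
        for core in cores:
            for m in assignments[core.core_id]:
                rg = by_id[m.compound_id]
                for cnode, rnode in m.correspondence.items():
                    assert core.graph.nodes[cnode]["label"] == rg.nodes[rnode].label
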