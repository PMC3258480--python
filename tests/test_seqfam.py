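"""Sequence-family clustering: graph, single linkage, profiles, merging."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

from eck.records import Dataset, select_complete_ec
from eck.seqfam import (
    ClusterSet,
    SequenceFamilyClusterer,
    build_profile,
    families_per_node,
    identity_graph,
    merge_singletons,
    profile_score,
    single_linkage_partition,
)
from eck.synthetic import GeneratorConfig, generate

SEQ = "ACDEFGHIKLMNPQRSTVWY" * 3


def closure_partition(ids, edges):
    """Brute-force transitive closure of the similarity relation (oracle)."""
    blocks = [{i} for i in ids]
    for a, b in edges:
        block_a = next(blk for blk in blocks if a in blk)
        block_b = next(blk for blk in blocks if b in blk)
        if block_a is not block_b:
            blocks.remove(block_b)
            block_a.update(block_b)
    return sorted(tuple(sorted(blk)) for blk in blocks)


class TestIdentityGraph:
    def test_identical_sequences_complete_graph(self):
        graph = identity_graph({f"r{i}": SEQ for i in range(4)})
        assert graph.number_of_edges() == 6

    def test_dissimilar_set_edgeless(self):
        rng = np.random.default_rng(0)
        seqs = {
            f"r{i}": "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=80))
            for i in range(4)
        }
        assert identity_graph(seqs).number_of_edges() == 0

    def test_planted_two_family_node_is_bipartitioned(self):
        cfg = GeneratorConfig(n_ec_nodes=1, families_per_node=[2], rng_seed=5)
        dataset, truth = generate(cfg)
        seqs = {r.record_id: r.concatenated_sequence for r in dataset}
        graph = identity_graph(seqs)
        for a, b in itertools.combinations(seqs, 2):
            same_family = truth.family_of[a] == truth.family_of[b]
            assert graph.has_edge(a, b) == same_family

    def test_threshold_bounds_checked(self):
        with pytest.raises(ValueError):
            identity_graph({"a": SEQ}, identity_threshold=150)


class TestSingleLinkage:
    def test_chain_of_edges_is_one_cluster(self):
        graph = nx.Graph()
        graph.add_nodes_from("ABC")
        graph.add_edges_from([("A", "B"), ("B", "C")])
        partition = single_linkage_partition(graph)
        assert partition.as_blocks() == [("A", "B", "C")]
        assert partition.as_blocks() == closure_partition("ABC", [("A", "B"), ("B", "C")])

    def test_edgeless_graph_gives_singletons(self):
        graph = nx.Graph()
        graph.add_nodes_from(range(5))
        assert single_linkage_partition(graph).n_clusters == 5

    def test_empty_graph_gives_empty_partition(self):
        assert single_linkage_partition(nx.Graph()).n_clusters == 0

    @given(
        n=st.integers(2, 12),
        edge_bits=st.lists(st.booleans(), min_size=66, max_size=66),
    )
    def test_matches_transitive_closure_oracle(self, n, edge_bits):
        ids = [f"s{i}" for i in range(n)]
        pairs = list(itertools.combinations(ids, 2))
        edges = [p for p, keep in zip(pairs, edge_bits) if keep]
        graph = nx.Graph()
        graph.add_nodes_from(ids)
        graph.add_edges_from(edges)
        assert single_linkage_partition(graph).as_blocks() == closure_partition(ids, edges)


class TestProfiles:
    def test_pseudocount_arithmetic_two_identical_members(self):
        profile = build_profile({"a": "ACD", "b": "ACD"})
        # (2 + 0.1) / (2 + 20 * 0.1) per observed letter
        assert profile.columns[0, 0] == pytest.approx(2.1 / 4.0)
        assert profile.consensus == "ACD"

    def test_columns_sum_to_one_and_length_is_center(self):
        profile = build_profile({"x": SEQ, "y": SEQ[:50], "z": SEQ[5:]})
        assert profile.columns.shape == (len(SEQ), 20)
        assert np.allclose(profile.columns.sum(axis=1), 1.0)

    def test_singleton_input_rejected(self):
        with pytest.raises(ValueError):
            build_profile({"a": SEQ})


class TestMergeSingletons:
    def test_no_singletons_unchanged(self):
        raw = ClusterSet(None, {"a": frozenset({"a", "b"})}, stage="raw")
        merged = merge_singletons(raw, {"a": SEQ, "b": SEQ})
        assert merged.stage == "merged"
        assert merged.as_blocks() == raw.as_blocks()

    def test_singleton_identical_to_consensus_is_merged(self):
        sequences = {"a1": SEQ, "a2": SEQ, "zz": SEQ}
        raw = ClusterSet(
            None,
            {"a1": frozenset({"a1", "a2"}), "zz": frozenset({"zz"})},
            stage="raw",
        )
        merged = merge_singletons(raw, sequences, tau=-1.0)
        assert merged.as_blocks() == [("a1", "a2", "zz")]

    def test_symmetric_tie_merges_into_smaller_label(self):
        sequences = {"a1": SEQ, "a2": SEQ, "b1": SEQ, "b2": SEQ, "zz": SEQ}
        raw = ClusterSet(
            None,
            {
                "a1": frozenset({"a1", "a2"}),
                "b1": frozenset({"b1", "b2"}),
                "zz": frozenset({"zz"}),
            },
            stage="raw",
        )
        profiles_equal = build_profile({"a1": SEQ, "a2": SEQ})
        assert profile_score(profiles_equal, SEQ) == profile_score(
            build_profile({"b1": SEQ, "b2": SEQ}), SEQ
        )
        merged = merge_singletons(raw, sequences, tau=-1.0)
        assert merged.as_blocks() == [("a1", "a2", "zz"), ("b1", "b2")]

    def test_unrelated_singleton_not_merged(self):
        rng = np.random.default_rng(2)
        other = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
        raw = ClusterSet(
            None, {"a1": frozenset({"a1", "a2"}), "zz": frozenset({"zz"})}, stage="raw"
        )
        merged = merge_singletons(raw, {"a1": SEQ, "a2": SEQ, "zz": other}, tau=-1.0)
        assert merged.n_clusters == 2

    def test_merge_never_increases_cluster_count(self, small_synthetic):
        dataset, _ = small_synthetic
        counts, _ = families_per_node(select_complete_ec(dataset))
        assert (counts["merged"] <= counts["raw"]).all()


class TestFamiliesPerNode:
    def test_single_sequence_node_is_one_family(self):
        cfg = GeneratorConfig(
            n_ec_nodes=1, families_per_node=[1], members_per_family=1, rng_seed=0
        )
        dataset, _ = generate(cfg)
        counts, _ = families_per_node(dataset)
        assert counts["raw"].tolist() == [1]

    def test_planted_counts_recovered(self, small_synthetic):
        dataset, truth = small_synthetic
        clusterer = SequenceFamilyClusterer().fit(select_complete_ec(dataset))
        estimates = clusterer.counts_["merged"].to_dict()
        assert estimates == truth.node_family_counts

    def test_permutation_invariance(self, small_synthetic):
        dataset, _ = small_synthetic
        reversed_ds = Dataset(records=list(reversed(dataset.records)))
        a = SequenceFamilyClusterer().fit(dataset)
        b = SequenceFamilyClusterer().fit(reversed_ds)
        assert a.counts_.sort_index().equals(b.counts_.sort_index())
        for node in a.cluster_sets_:
            assert (
                a.cluster_sets_[node].as_blocks() == b.cluster_sets_[node].as_blocks()
            )

    def test_cluster_count_monotone_in_identity_threshold(self, small_synthetic):
        dataset, _ = small_synthetic
        totals = []
        for threshold in (10.0, 30.0, 95.0):
            counts, _ = families_per_node(dataset, identity_threshold=threshold, merge=False)
            totals.append(int(counts["raw"].sum()))
        assert totals == sorted(totals)

    def test_separability_seed_sweep(self):
        """Planted families recovered exactly on >= 95% of nodes (5 seeds x 40 nodes)."""
        hits = total = 0
        for seed in range(5):
            dataset, truth = generate(GeneratorConfig(n_ec_nodes=40, rng_seed=seed))
            clusterer = SequenceFamilyClusterer().fit(select_complete_ec(dataset))
            for node, estimate in clusterer.counts_["merged"].items():
                total += 1
                hits += int(estimate == truth.node_family_counts[node])
        assert total == 200
        assert hits / total >= 0.95
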