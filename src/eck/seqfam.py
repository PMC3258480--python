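"""Evolutionary families per EC node from sequences.

The pipeline mirrors the classic identity-threshold family estimate: build a
graph over the records of one EC node with an edge wherever global percent
identity and coverage clear their thresholds, take connected components
(single-linkage clustering, the behaviour of ``blastclust``), then absorb
singleton clusters into multi-member clusters whenever they score well
against a position-frequency profile of the cluster — a lightweight analogue
of placing singletons with profile HMMs.  Records belonging to several EC
nodes are clustered independently within each node; sequences are never
compared across nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .alignment import AlignmentParams, DEFAULT_PARAMS, get_aligner, global_identity
from .records import AMINO_ACIDS, Dataset, ECNode

__all__ = [
    "ClusterSet",
    "SequenceProfile",
    "identity_graph",
    "single_linkage_partition",
    "build_profile",
    "merge_singletons",
    "families_per_node",
    "SequenceFamilyClusterer",
]

logger = logging.getLogger(__name__)

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Pseudocount added per residue type to every profile column.
PROFILE_PSEUDOCOUNT = 0.1


@dataclass
class ClusterSet:
    """A partition of record ids within one EC node into families.

    Clusters are labelled by their lexicographically smallest member, which
    makes labels deterministic and order-independent.  ``stage`` is ``"raw"``
    after single-linkage clustering and ``"merged"`` after singleton merging.
    """

    node: Optional[ECNode]
    clusters: Dict[str, frozenset]
    stage: str = "raw"

    def __post_init__(self) -> None:
        members: List[str] = [m for block in self.clusters.values() for m in block]
        if len(members) != len(set(members)):
            raise ValueError("cluster blocks must be disjoint")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def members(self) -> frozenset:
        return frozenset(m for block in self.clusters.values() for m in block)

    def as_blocks(self) -> List[Tuple[str, ...]]:
        """Sorted tuple-of-tuples form, convenient for equality checks."""
        return sorted(tuple(sorted(block)) for block in self.clusters.values())


def _labelled(blocks: Iterable[Iterable[str]]) -> Dict[str, frozenset]:
    return {min(block): frozenset(block) for block in blocks if block}


def identity_graph(
    sequences: Mapping[str, str],
    identity_threshold: float = 30.0,
    coverage_threshold: float = 0.8,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> nx.Graph:
    """Build the undirected similarity graph over record ids.

    An edge joins two ids iff global identity >= ``identity_threshold`` (in
    percent) and coverage >= ``coverage_threshold``; no self loops.
    """
    if not 0 <= identity_threshold <= 100:
        raise ValueError("identity_threshold must be in [0, 100]")
    if not 0 <= coverage_threshold <= 1:
        raise ValueError("coverage_threshold must be in [0, 1]")
    graph = nx.Graph()
    ids = sorted(sequences)
    graph.add_nodes_from(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            identity, coverage = global_identity(sequences[a], sequences[b], params)
            if identity >= identity_threshold and coverage >= coverage_threshold:
                graph.add_edge(a, b)
    return graph


def single_linkage_partition(
    graph: nx.Graph, node: Optional[ECNode] = None
) -> ClusterSet:
    """Connected components of the similarity graph as a raw ClusterSet."""
    blocks = list(nx.connected_components(graph))
    return ClusterSet(node=node, clusters=_labelled(blocks), stage="raw")


@dataclass
class SequenceProfile:
    """Per-position residue frequencies of a cluster (center-star alignment).

    The profile has one column per residue of the center sequence (the
    longest member; ties broken toward the lexicographically smallest id);
    every other member is globally aligned to the center and its letters are
    tallied into the center's columns (insertions relative to the center are
    dropped).  Columns get a pseudocount of 0.1 per residue type and are
    renormalized, so each column sums to 1.
    """

    columns: np.ndarray  # shape (L, 20)
    consensus: str
    source_cluster: str
    n_members: int

    def __post_init__(self) -> None:
        sums = self.columns.sum(axis=1)
        if not np.allclose(sums, 1.0):
            raise ValueError("profile columns must sum to 1")


def build_profile(
    sequences: Mapping[str, str],
    source_cluster: str = "",
    params: AlignmentParams = DEFAULT_PARAMS,
) -> SequenceProfile:
    """Build a position-frequency profile from >= 2 cluster members."""
    if len(sequences) < 2:
        raise ValueError("a profile needs at least two member sequences")
    center_id = min(sequences, key=lambda i: (-len(sequences[i]), i))
    center = sequences[center_id]
    counts = np.zeros((len(center), 20))
    for pos, letter in enumerate(center):
        if letter in _AA_INDEX:
            counts[pos, _AA_INDEX[letter]] += 1
    aligner = get_aligner(params)
    for member_id, seq in sequences.items():
        if member_id == center_id:
            continue
        alignment = aligner.align(center, seq)[0]
        for (c_start, c_end), (m_start, _m_end) in zip(*alignment.aligned):
            for offset in range(c_end - c_start):
                letter = seq[m_start + offset]
                if letter in _AA_INDEX:
                    counts[c_start + offset, _AA_INDEX[letter]] += 1
    smoothed = counts + PROFILE_PSEUDOCOUNT
    columns = smoothed / smoothed.sum(axis=1, keepdims=True)
    consensus = "".join(
        min(  # highest frequency, alphabetical tie-break
            AMINO_ACIDS, key=lambda a: (-col[_AA_INDEX[a]], a)
        )
        for col in columns
    )
    return SequenceProfile(
        columns=columns,
        consensus=consensus,
        source_cluster=source_cluster,
        n_members=len(sequences),
    )


def profile_score(
    profile: SequenceProfile, seq: str, params: AlignmentParams = DEFAULT_PARAMS
) -> float:
    """Mean natural-log column frequency of ``seq`` along a global alignment
    of the sequence to the profile consensus; ``-inf`` if nothing aligns."""
    alignment = get_aligner(params).align(profile.consensus, seq)[0]
    total = 0.0
    n_columns = 0
    for (c_start, c_end), (s_start, _s_end) in zip(*alignment.aligned):
        for offset in range(c_end - c_start):
            letter = seq[s_start + offset]
            if letter in _AA_INDEX:
                total += float(
                    np.log(profile.columns[c_start + offset, _AA_INDEX[letter]])
                )
                n_columns += 1
    if n_columns == 0:
        return float("-inf")
    return total / n_columns


def merge_singletons(
    cluster_set: ClusterSet,
    sequences: Mapping[str, str],
    tau: float = -1.0,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> ClusterSet:
    """Absorb singleton clusters into multi-member clusters by profile score.

    Each singleton is scored against the profile of every multi-member
    cluster; it joins the best-scoring cluster if the score reaches ``tau``
    (ties broken toward the lexicographically smallest cluster label).
    Profiles are built once from the raw multi-member clusters, so merge
    results do not depend on the order in which singletons are considered.
    The result never has more clusters than the input.
    """
    if cluster_set.stage != "raw":
        raise ValueError("merge_singletons expects a raw ClusterSet")
    singles = sorted(l for l, b in cluster_set.clusters.items() if len(b) == 1)
    multis = {l: b for l, b in cluster_set.clusters.items() if len(b) > 1}
    if not singles or not multis:
        return ClusterSet(cluster_set.node, dict(cluster_set.clusters), stage="merged")
    profiles = {
        label: build_profile({m: sequences[m] for m in block}, label, params)
        for label, block in sorted(multis.items())
    }
    merged = {label: set(block) for label, block in cluster_set.clusters.items()}
    for single in singles:
        scores = {
            label: profile_score(profiles[label], sequences[single], params)
            for label in sorted(profiles)
        }
        best_label = min(scores, key=lambda l: (-scores[l], l))
        if scores[best_label] >= tau:
            merged[best_label].update(merged.pop(single))
    return ClusterSet(cluster_set.node, _labelled(merged.values()), stage="merged")


def families_per_node(
    dataset: Dataset,
    identity_threshold: float = 30.0,
    coverage_threshold: float = 0.8,
    tau: float = -1.0,
    merge: bool = True,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> Tuple[pd.DataFrame, Dict[str, ClusterSet]]:
    """Run the full per-node chain over all complete EC nodes.

    Returns a per-node count table (columns ``raw`` and, when merging is on,
    ``merged``) indexed by EC-node string, plus the final ClusterSet per
    node.  A record belonging to several complete nodes is clustered
    independently within each.
    """
    rows = []
    cluster_sets: Dict[str, ClusterSet] = {}
    for node in dataset.complete_nodes:
        node_records = dataset.records_of_node(node)
        sequences = {r.record_id: r.concatenated_sequence for r in node_records}
        if not sequences:
            logger.info("EC node %s has no sequences; skipped", node)
            continue
        graph = identity_graph(sequences, identity_threshold, coverage_threshold, params)
        raw = single_linkage_partition(graph, node)
        row = {"node": str(node), "raw": raw.n_clusters}
        final = raw
        if merge:
            final = merge_singletons(raw, sequences, tau, params)
            row["merged"] = final.n_clusters
        cluster_sets[str(node)] = final
        rows.append(row)
    counts = pd.DataFrame(rows).set_index("node") if rows else pd.DataFrame()
    return counts, cluster_sets


class SequenceFamilyClusterer(BaseEstimator):
    """Estimate evolutionary families per EC node from chain sequences.

    Parameters
    ----------
    identity_threshold : float, default 30.0
        Percent identity above which two records of one node are linked.
    coverage_threshold : float, default 0.8
        Minimum aligned fraction of the shorter sequence.
    tau : float, default -1.0
        Per-column log-frequency acceptance threshold for singleton merging.
    merge : bool, default True
        Whether to run the profile-based singleton merge stage.

    Attributes (after :meth:`fit`)
    ------------------------------
    counts_ : pandas.DataFrame
        Per-node family counts (columns ``raw`` and optionally ``merged``).
    cluster_sets_ : dict
        Final :class:`ClusterSet` per EC-node string.
    mean_raw_, mean_merged_ : float
        Mean families per node at each stage.
    singleton_node_fraction_ : float
        Fraction of nodes represented by a single family (final stage).
    """

    def __init__(
        self,
        identity_threshold: float = 30.0,
        coverage_threshold: float = 0.8,
        tau: float = -1.0,
        merge: bool = True,
        alignment_params: AlignmentParams = DEFAULT_PARAMS,
    ) -> None:
        self.identity_threshold = identity_threshold
        self.coverage_threshold = coverage_threshold
        self.tau = tau
        self.merge = merge
        self.alignment_params = alignment_params

    def fit(self, X: Dataset, y=None) -> "SequenceFamilyClusterer":
        if not isinstance(X, Dataset):
            raise TypeError("X must be an eck Dataset")
        counts, cluster_sets = families_per_node(
            X,
            self.identity_threshold,
            self.coverage_threshold,
            self.tau,
            self.merge,
            self.alignment_params,
        )
        self.counts_ = counts
        self.cluster_sets_ = cluster_sets
        self.n_nodes_ = len(counts)
        final_column = "merged" if self.merge and "merged" in counts else "raw"
        if len(counts):
            self.mean_raw_ = float(counts["raw"].mean())
            self.mean_merged_ = (
                float(counts["merged"].mean()) if "merged" in counts else None
            )
            self.singleton_node_fraction_ = float((counts[final_column] == 1).mean())
        else:
            self.mean_raw_ = float("nan")
            self.mean_merged_ = None
            self.singleton_node_fraction_ = float("nan")
        return self

    def fit_predict(self, X: Dataset, y=None) -> pd.DataFrame:
        return self.fit(X).counts_
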