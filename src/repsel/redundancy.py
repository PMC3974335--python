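"""Greedy identity clustering: candidate seeds and the non-redundant set.

Sequences are processed in order of decreasing length (ties by id) and
each joins the first existing cluster whose representative it matches at
or above the identity threshold, else founds a new cluster (CD-HIT-style
greedy incremental clustering). Because input is length-sorted, every
cluster's representative is automatically its longest member.

Two instantiations matter downstream: clustering at 25% yields the
candidate seeds (one longest sequence per cluster), and clustering at 50%
yields the non-redundant search set used for profile construction.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .pairwise import IdentityMatrix
from .seqio import FamilyDataset, ProteinSequence

CANDIDATE_THRESHOLD = 25.0
NONREDUNDANT_THRESHOLD = 50.0


@dataclass
class ClusterSet:
    """Clusters at a given identity threshold; first member = representative."""

    threshold: float
    clusters: list[list[str]]

    @property
    def representatives(self) -> list[str]:
        return [c[0] for c in self.clusters]

    def to_tsv(self, path: str | Path) -> Path:
        rows = [
            {"member_id": m, "representative_id": c[0]}
            for c in self.clusters
            for m in c
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        return Path(path)


def greedy_cluster(
    dataset: FamilyDataset, matrix: IdentityMatrix, threshold: float
) -> ClusterSet:
    if not 0.0 < threshold <= 100.0:
        raise ValueError("threshold must be in (0, 100]")
    order = sorted(dataset.members, key=lambda s: (-s.length, s.id))
    clusters: list[list[str]] = []
    for seq in order:
        for cluster in clusters:
            if matrix.value(cluster[0], seq.id) >= threshold:
                cluster.append(seq.id)
                break
        else:
            clusters.append([seq.id])
    return ClusterSet(threshold, clusters)


def candidate_seeds(
    dataset: FamilyDataset,
    matrix: IdentityMatrix,
    threshold: float = CANDIDATE_THRESHOLD,
) -> list[ProteinSequence]:
    """Longest member of each cluster at the candidate threshold (default 25%)."""
    if len(dataset) < 2:
        raise ValueError("candidate selection needs at least 2 sequences")
    clusters = greedy_cluster(dataset, matrix, threshold)
    return [dataset.get(rep) for rep in clusters.representatives]


def nonredundant_set(
    dataset: FamilyDataset,
    matrix: IdentityMatrix,
    threshold: float = NONREDUNDANT_THRESHOLD,
) -> FamilyDataset:
    """Cluster representatives at the non-redundancy threshold (default 50%)."""
    clusters = greedy_cluster(dataset, matrix, threshold)
    return dataset.subset(clusters.representatives)
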