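"""MID grouping, edit-distance sub-clustering, and consensus building.

Reads sharing a 12-nt MID usually descend from one RNA molecule, but two
molecules can draw the same MID by chance.  Building one consensus per MID
group would then fuse distinct receptor sequences into a chimera.  Each MID
group is therefore split into *sub-clusters* — sets of reads within a
Levenshtein-distance threshold (15% of the read length) of a seed read —
and one quality-weighted consensus is built per sub-cluster.  Each retained
sub-cluster is the unit of digital molecule counting.

The clustering is greedy and deterministic: the unassigned read with the
highest summed quality seeds each cluster (ties broken by read id), and all
unassigned reads within the threshold of the seed join it.  On molecules
separated by more than twice the threshold this is equivalent to quality
threshold clustering.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .preprocess import PreparedRead

__all__ = [
    "MIDGroup",
    "ClusterParams",
    "SubCluster",
    "levenshtein",
    "group_by_mid",
    "qt_subcluster",
    "build_consensus",
    "subcluster_all",
    "fraction_mids_with_subclusters",
    "subclusters_to_frame",
]

_BASE_ORDER = b"ACGT"  # fixed tie-break order for consensus voting


@dataclass
class MIDGroup:
    """All prepared reads sharing one MID."""

    mid: str
    reads: list[PreparedRead]

    def __post_init__(self) -> None:
        if not self.reads:
            raise ValueError("MIDGroup must contain at least one read")


@dataclass(frozen=True)
class ClusterParams:
    """Sub-clustering knobs.

    ``distance_fraction`` — Levenshtein threshold as a fraction of the seed
    read length (0.15, i.e. 22 edits for 150-nt payloads).
    ``min_reads`` — minimum reads per retained sub-cluster (2; singletons
    cannot be error-checked and are discarded).
    """

    distance_fraction: float = 0.15
    min_reads: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.distance_fraction < 1:
            raise ValueError("distance_fraction must be in (0, 1)")
        if self.min_reads < 2:
            raise ValueError("min_reads must be >= 2")


@dataclass
class SubCluster:
    """Reads inferred to descend from one RNA molecule, plus their consensus."""

    mid: str
    members: list[PreparedRead]
    consensus: str

    @property
    def read_count(self) -> int:
        return len(self.members)


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions)."""
    if a == b:
        return 0
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def _within(a: str, b: str, k: int) -> bool:
    """True when levenshtein(a, b) <= k (banded, early-exit)."""
    if a == b:
        return True
    return edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"] != -1


def group_by_mid(reads: Iterable[PreparedRead]) -> dict[str, MIDGroup]:
    """Partition prepared reads into MID groups keyed by MID sequence."""
    buckets: dict[str, list[PreparedRead]] = {}
    for read in reads:
        buckets.setdefault(read.mid, []).append(read)
    return {mid: MIDGroup(mid=mid, reads=members) for mid, members in buckets.items()}


def build_consensus(members: Sequence[PreparedRead]) -> str:
    """Quality-weighted per-position consensus of a sub-cluster.

    The consensus length is the modal member length (ties: shortest);
    members of non-modal length do not vote.  At each position the base with
    the largest summed quality wins, ties broken A < C < G < T.  N bases
    carry weight 0.
    """
    if not members:
        raise ValueError("cannot build a consensus of zero reads")
    lengths = Counter(len(r.payload) for r in members)
    top = max(lengths.values())
    modal_len = min(length for length, c in lengths.items() if c == top)
    voters = [r for r in members if len(r.payload) == modal_len]
    first = voters[0].payload
    if all(v.payload == first for v in voters):
        return first
    mat = np.frombuffer("".join(v.payload for v in voters).encode("ascii"), dtype=np.uint8)
    mat = mat.reshape(len(voters), modal_len)
    quals = np.vstack([v.qual for v in voters]).astype(np.int64)
    weights = np.empty((4, modal_len), dtype=np.int64)
    for i, code in enumerate(_BASE_ORDER):
        weights[i] = ((mat == code) * quals).sum(axis=0)
    winners = weights.argmax(axis=0)  # argmax returns the first max: A<C<G<T
    return np.frombuffer(_BASE_ORDER, dtype=np.uint8)[winners].tobytes().decode("ascii")


def qt_subcluster(
    group: MIDGroup, params: ClusterParams = ClusterParams()
) -> tuple[list[SubCluster], list[PreparedRead]]:
    """Split one MID group into sub-clusters; return (retained, discarded).

    Greedy seeded clustering: the highest-summed-quality unassigned read
    seeds a cluster of all unassigned reads within
    round(distance_fraction × seed length) edits of it.  Clusters with fewer
    than ``min_reads`` members are discarded, and a 2-read cluster is kept
    only when both reads are identical (a disagreeing pair cannot be
    error-corrected).  Retained sub-clusters carry their consensus.
    """
    reads = group.reads
    if len(reads) < params.min_reads:
        return [], list(reads)

    payloads = [r.payload for r in reads]
    if len(set(payloads)) == 1:
        cluster = SubCluster(mid=group.mid, members=list(reads), consensus=payloads[0])
        return [cluster], []

    order = sorted(range(len(reads)), key=lambda i: (-reads[i].qual_sum(), reads[i].id))
    taken = [False] * len(reads)
    raw_clusters: list[list[PreparedRead]] = []
    for seed_idx in order:
        if taken[seed_idx]:
            continue
        seed = reads[seed_idx]
        threshold = int(round(params.distance_fraction * len(seed.payload)))
        cache: dict[str, bool] = {seed.payload: True}
        members: list[PreparedRead] = []
        for j in order:
            if taken[j]:
                continue
            pj = reads[j].payload
            hit = cache.get(pj)
            if hit is None:
                hit = _within(pj, seed.payload, threshold)
                cache[pj] = hit
            if hit:
                members.append(reads[j])
                taken[j] = True
        raw_clusters.append(members)

    clusters: list[SubCluster] = []
    discarded: list[PreparedRead] = []
    for members in raw_clusters:
        if len(members) < params.min_reads:
            discarded.extend(members)
        elif len(members) == 2 and members[0].payload != members[1].payload:
            discarded.extend(members)
        else:
            clusters.append(
                SubCluster(mid=group.mid, members=members, consensus=build_consensus(members))
            )
    return clusters, discarded


def subcluster_all(
    groups: Mapping[str, MIDGroup] | Iterable[MIDGroup],
    params: ClusterParams = ClusterParams(),
) -> tuple[list[SubCluster], list[PreparedRead]]:
    """Sub-cluster every MID group; returns all retained sub-clusters and
    all discarded reads (singletons and unverifiable pairs)."""
    if isinstance(groups, Mapping):
        groups = groups.values()
    clusters: list[SubCluster] = []
    discarded: list[PreparedRead] = []
    for group in groups:
        c, d = qt_subcluster(group, params)
        clusters.extend(c)
        discarded.extend(d)
    return clusters, discarded


def fraction_mids_with_subclusters(
    groups: Mapping[str, MIDGroup] | Iterable[MIDGroup],
    params: ClusterParams = ClusterParams(),
) -> float:
    """Fraction of usable MID groups that split into 2 or more sub-clusters.

    The denominator counts MID groups yielding at least one retained
    sub-cluster; the numerator those yielding at least two.  Raises
    ``ValueError`` when no group yields a sub-cluster (the fraction is then
    undefined).
    """
    if isinstance(groups, Mapping):
        groups = groups.values()
    eligible = 0
    multi = 0
    for group in groups:
        clusters, _ = qt_subcluster(group, params)
        if clusters:
            eligible += 1
            if len(clusters) >= 2:
                multi += 1
    if eligible == 0:
        raise ValueError("no MID group yielded a retained sub-cluster")
    return multi / eligible


def subclusters_to_frame(clusters: Iterable[SubCluster]) -> pd.DataFrame:
    """Sub-cluster table: mid, subcluster_index (within MID), read_count,
    consensus."""
    rows = []
    index: Counter[str] = Counter()
    for c in clusters:
        rows.append(
            {
                "mid": c.mid,
                "subcluster_index": index[c.mid],
                "read_count": c.read_count,
                "consensus": c.consensus,
            }
        )
        index[c.mid] += 1
    return pd.DataFrame(rows, columns=["mid", "subcluster_index", "read_count", "consensus"])
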