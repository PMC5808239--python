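"""End-to-end driver: prepared reads -> sub-clusters -> filtered clonotypes.

Kept deliberately thin: each stage lives in its own module; this wires the
default chain (group by MID -> sub-cluster -> consensus -> merge -> filters)
and exposes the summary statistics the rarefaction analyses consume.  A
``subcluster=False`` mode builds a single consensus per MID group, which is
the error-prone variant that sub-clustering exists to fix: it lets chimera
formation be measured directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .filters import Clonotype, ConsensusRecord, apply_filters
from .preprocess import PreparedRead
from .subcluster import ClusterParams, build_consensus, group_by_mid, subcluster_all

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "total_molecules", "unique_sequences", "single_copy_clones"]


@dataclass(frozen=True)
class PipelineConfig:
    """Default processing chain parameters.

    ``frame_offset`` of ``None`` skips functionality flagging; the payload
    starts at the constant-region anchor, so with the bundled anchor frame 0
    is in frame.  ``mid_filter``/``collapse`` toggle the MID read-count
    filter and the one-edit neighbor collapse; ``subcluster=False`` selects
    the naive one-consensus-per-MID variant.
    """

    cluster: ClusterParams = field(default_factory=ClusterParams)
    frame_offset: int | None = 0
    threshold_fraction: float = 0.2
    collapse: bool = True
    mid_filter: bool = True
    subcluster: bool = True


@dataclass
class PipelineResult:
    clonotypes: list[Clonotype]
    stats: dict


def _records_without_subclustering(
    groups, params: ClusterParams
) -> list[ConsensusRecord]:
    """One consensus per MID group with >= min_reads reads (naive mode)."""
    records = []
    for group in groups.values():
        if len(group.reads) < params.min_reads:
            continue
        records.append(
            ConsensusRecord(
                seq=build_consensus(group.reads),
                mid=group.mid,
                read_count=len(group.reads),
            )
        )
    return records


def run_pipeline(
    reads: Sequence[PreparedRead], config: PipelineConfig = PipelineConfig()
) -> PipelineResult:
    """Run the molecule-counting chain on prepared reads."""
    groups = group_by_mid(reads)
    if config.subcluster:
        clusters, discarded = subcluster_all(groups, config.cluster)
        records = [
            ConsensusRecord(seq=c.consensus, mid=c.mid, read_count=c.read_count)
            for c in clusters
        ]
        n_discarded = len(discarded)
    else:
        records = _records_without_subclustering(groups, config.cluster)
        n_discarded = sum(
            len(g.reads) for g in groups.values() if len(g.reads) < config.cluster.min_reads
        )
    clonotypes, audit = apply_filters(
        records,
        frame_offset=config.frame_offset,
        threshold_fraction=config.threshold_fraction,
        do_collapse=config.collapse,
        do_mid_filter=config.mid_filter,
    )
    stats = {
        "n_reads": len(reads),
        "n_mid_groups": len(groups),
        "n_subclusters": len(records),
        "n_discarded_reads": n_discarded,
        **audit,
    }
    return PipelineResult(clonotypes=clonotypes, stats=stats)


def _select(clonotypes: Iterable[Clonotype], productive_only: bool):
    return [c for c in clonotypes if c.functional or not productive_only]


def total_molecules(clonotypes: Iterable[Clonotype], productive_only: bool = False) -> int:
    """Sum of molecule counts (surviving MID sub-clusters) over clonotypes."""
    return sum(c.molecule_count for c in _select(clonotypes, productive_only))


def unique_sequences(clonotypes: Iterable[Clonotype], productive_only: bool = False) -> int:
    """Number of distinct consensus sequences."""
    return len(_select(clonotypes, productive_only))


def single_copy_clones(clonotypes: Iterable[Clonotype], productive_only: bool = False) -> int:
    """Clonotypes backed by exactly one molecule (itself backed by >= 2 reads)."""
    return sum(
        1
        for c in _select(clonotypes, productive_only)
        if c.molecule_count == 1 and c.total_reads >= 2
    )
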