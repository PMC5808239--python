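"""Subsampling analyses: saturation, reproducibility, and clonal expansion.

Rarefaction reruns the full molecule-counting pipeline on nested read
subsamples of increasing depth.  With MID error correction enabled the
molecule count plateaus at the true molecule number once every molecule is
covered by enough reads; without correction, erroneous MIDs keep accruing
with depth and the count rises without saturating.  Adjacent-subsample
overlap of single-copy clones measures how reproducibly the rarest clones
are detected at a given depth, and the expansion summary quantifies how
much of the molecule mass sits in clones above a copy-number threshold.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .filters import Clonotype
from .pipeline import PipelineConfig, run_pipeline, single_copy_clones, total_molecules, unique_sequences
from .preprocess import PreparedRead

__all__ = [
    "RarefactionPoint",
    "ExpansionSummary",
    "DEFAULT_FRACTIONS",
    "subsample_reads",
    "nested_subsamples",
    "rarefaction_curve",
    "overlap_percentage",
    "single_copy_overlap_curve",
    "clone_size_distribution",
    "expansion_summary",
]

DEFAULT_FRACTIONS: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 11))

_STATISTICS = {
    "molecules": total_molecules,
    "unique_sequences": unique_sequences,
    "single_copy_clones": single_copy_clones,
}


@dataclass(frozen=True)
class RarefactionPoint:
    fraction: float
    depth: int  # number of reads subsampled
    statistic: str
    value: int


@dataclass(frozen=True)
class ExpansionSummary:
    """Expanded-clone tally at a molecule-count threshold (default 20 RNA
    copies): how many clones exceed it and what fraction of all molecules
    they hold."""

    threshold: int
    expanded_clone_count: int
    expanded_molecule_fraction: float


def subsample_reads(
    reads: Sequence[PreparedRead],
    fraction: float,
    rng: np.random.Generator | int | None = None,
) -> list[PreparedRead]:
    """Uniform without-replacement subsample of round(fraction x n) reads."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1:
        return list(reads)
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    k = round(fraction * len(reads))
    idx = rng.choice(len(reads), size=k, replace=False)
    return [reads[i] for i in idx]


def nested_subsamples(
    reads: Sequence[PreparedRead],
    fractions: Sequence[float],
    rng: np.random.Generator | int | None = None,
) -> dict[float, list[PreparedRead]]:
    """Nested subsamples: each shallower sample is a subset of every deeper
    one (one shuffled order, prefix per fraction).  Preferred for overlap
    curves, where the deeper sample must contain the shallower one's reads."""
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must be in (0, 1]")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    order = rng.permutation(len(reads))
    return {
        float(f): [reads[i] for i in order[: round(f * len(reads))]]
        for f in fractions
    }


def rarefaction_curve(
    reads: Sequence[PreparedRead],
    statistic: str = "molecules",
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    seed: int = 0,
    config: PipelineConfig = PipelineConfig(),
    nested: bool = True,
) -> list[RarefactionPoint]:
    """Run the pipeline at each depth fraction and record one statistic.

    ``statistic`` is one of ``molecules``, ``unique_sequences``, or
    ``single_copy_clones``.  Fractions must be sorted ascending.  With
    ``nested`` (default) subsamples form a chain under inclusion; otherwise
    each fraction is drawn independently.
    """
    if list(fractions) != sorted(fractions):
        raise ValueError("fractions must be sorted ascending")
    stat_fn = _STATISTICS[statistic]
    rng = np.random.default_rng(seed)
    if nested:
        samples = nested_subsamples(reads, fractions, rng)
    else:
        samples = {float(f): subsample_reads(reads, f, rng) for f in fractions}
    points = []
    for f in fractions:
        sample = samples[float(f)]
        value = stat_fn(run_pipeline(sample, config).clonotypes) if sample else 0
        points.append(
            RarefactionPoint(
                fraction=float(f), depth=len(sample), statistic=statistic, value=int(value)
            )
        )
    return points


def overlap_percentage(shallower: set[str], deeper: set[str]) -> float:
    """|shallow ∩ deep| / |deep| — clone overlap between adjacent depths,
    normalised by the deeper subsample's clone count."""
    if not deeper:
        raise ValueError("overlap undefined: deeper clone set is empty")
    return len(shallower & deeper) / len(deeper)


def single_copy_overlap_curve(
    reads: Sequence[PreparedRead],
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    seed: int = 0,
    config: PipelineConfig = PipelineConfig(),
) -> list[tuple[float, float]]:
    """Overlap of single-copy clone sets between adjacent nested depths.

    For n fractions, n-1 overlap values are produced, each keyed by the
    deeper fraction of the pair.
    """
    if list(fractions) != sorted(fractions):
        raise ValueError("fractions must be sorted ascending")
    rng = np.random.default_rng(seed)
    samples = nested_subsamples(reads, fractions, rng)
    clone_sets = {}
    for f in fractions:
        clonotypes = run_pipeline(samples[float(f)], config).clonotypes
        clone_sets[float(f)] = {
            c.seq for c in clonotypes if c.molecule_count == 1 and c.total_reads >= 2
        }
    out = []
    for shallow, deep in zip(fractions, fractions[1:]):
        out.append(
            (float(deep), overlap_percentage(clone_sets[float(shallow)], clone_sets[float(deep)]))
        )
    return out


def clone_size_distribution(clonotypes: Iterable[Clonotype]) -> pd.Series:
    """Frequency table of clonotype molecule counts (index: molecule count,
    value: number of clonotypes).  Total mass equals the clonotype count."""
    counts = Counter(c.molecule_count for c in clonotypes)
    return pd.Series(dict(sorted(counts.items())), dtype=np.int64, name="n_clonotypes")


def expansion_summary(
    clonotypes: Sequence[Clonotype], threshold: int = 20
) -> ExpansionSummary:
    """Tally clones with more than ``threshold`` molecules and the fraction
    of the molecule mass they carry."""
    expanded = [c for c in clonotypes if c.molecule_count > threshold]
    all_molecules = sum(c.molecule_count for c in clonotypes)
    frac = (
        sum(c.molecule_count for c in expanded) / all_molecules if all_molecules else 0.0
    )
    return ExpansionSummary(
        threshold=threshold,
        expanded_clone_count=len(expanded),
        expanded_molecule_fraction=frac,
    )
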