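"""Clonotype assembly and post-clustering error filters.

Identical sub-cluster consensus sequences are merged into clonotypes; a
clonotype's molecule count is the number of its surviving MID sub-clusters.
Three filters then remove the dominant artifact classes:

* **non-functional flagging** — sequences whose in-frame translation
  (relative to the constant-region reading frame) contains a stop codon are
  flagged; they stay in raw output but are excluded from productive tallies.
* **one-edit neighbor collapse** — a clonotype at Levenshtein distance
  exactly 1 from a clonotype with strictly more molecules is a PCR/sequencing
  satellite of it and is removed.  Decisions are made against the pre-filter
  state, so genuine 1-edit clone pairs of equal abundance both survive and
  no chain collapse occurs.
* **MID read-count filter** — within a clonotype, MID entries supported by
  fewer than 20% of the maximum per-MID read count are erroneous MIDs
  (PCR errors on the barcode itself) and are dropped.  The 20% threshold is
  the operating rule; a two-component negative-binomial mixture fit of the
  read-count distribution is provided as the diagnostic that justifies it
  and can supply a data-driven crossover threshold instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import optimize, stats

__all__ = [
    "ConsensusRecord",
    "Clonotype",
    "NBMixtureFit",
    "merge_identical",
    "flag_nonfunctional",
    "collapse_neighbors",
    "fit_nb_mixture",
    "mid_readcount_filter",
    "apply_filters",
    "clonotypes_to_frame",
]


@dataclass(frozen=True, slots=True)
class ConsensusRecord:
    """One retained sub-cluster: consensus sequence, its MID, its read count."""

    seq: str
    mid: str
    read_count: int


@dataclass
class Clonotype:
    """A unique consensus sequence and its supporting MID sub-clusters.

    ``mids`` maps (MID, occurrence index) -> read count; the occurrence
    index keeps two same-MID sub-clusters with the same consensus as
    distinct countable molecules.  The molecule count is the number of
    entries; the keys are canonicalised (per-MID read counts sorted
    descending) so equality is independent of input order.
    """

    seq: str
    mids: dict[tuple[str, int], int] = field(default_factory=dict)
    functional: bool = True

    @property
    def molecule_count(self) -> int:
        return len(self.mids)

    @property
    def total_reads(self) -> int:
        return sum(self.mids.values())


def merge_identical(records: Iterable[ConsensusRecord]) -> list[Clonotype]:
    """Merge identical consensus sequences into clonotypes.

    Returns clonotypes sorted by sequence; output is invariant under
    permutation of the input records.
    """
    by_seq: dict[str, dict[str, list[int]]] = {}
    for rec in records:
        by_seq.setdefault(rec.seq, {}).setdefault(rec.mid, []).append(rec.read_count)
    out: list[Clonotype] = []
    for seq in sorted(by_seq):
        mids: dict[tuple[str, int], int] = {}
        for mid in sorted(by_seq[seq]):
            for i, count in enumerate(sorted(by_seq[seq][mid], reverse=True)):
                mids[(mid, i)] = count
        out.append(Clonotype(seq=seq, mids=mids))
    return out


def flag_nonfunctional(
    clonotype: Clonotype, frame_offset: int, require_frame_length: bool = False
) -> bool:
    """Flag a clonotype as non-functional; returns True when flagged.

    A sequence is non-functional when its translation in the reading frame
    given by ``frame_offset`` (0, 1 or 2 — derived from the constant-region
    anchor's known frame) contains a stop codon, or, optionally, when its
    length is inconsistent with that frame.  The flag is recorded on the
    clonotype; flagged clonotypes are kept in raw output.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1, or 2")
    coding = clonotype.seq[frame_offset:]
    if require_frame_length and len(coding) % 3 != 0:
        clonotype.functional = False
        return True
    trimmed = coding[: len(coding) - len(coding) % 3]
    aa = str(Seq(trimmed).translate())
    nonfunctional = "*" in aa
    clonotype.functional = not nonfunctional
    return nonfunctional


def _distance_one_pairs(seqs: Sequence[str]) -> list[tuple[int, int]]:
    """Indices of sequence pairs at Levenshtein distance exactly 1.

    A single edit leaves either the first h or the last h characters intact
    (h = half the shortest sequence length), so candidate pairs are found by
    bucketing on prefix and suffix keys and verified with a banded
    alignment.  Exact for distance-1 pairs; near-linear on typical inputs.
    """
    n = len(seqs)
    if n < 2:
        return []
    h = max(1, min(len(s) for s in seqs) // 2)
    candidates: set[tuple[int, int]] = set()
    for key_fn in (lambda s: s[:h], lambda s: s[-h:]):
        buckets: dict[str, list[int]] = {}
        for i, s in enumerate(seqs):
            buckets.setdefault(key_fn(s), []).append(i)
        for members in buckets.values():
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    candidates.add((members[a], members[b]))
    pairs = []
    for i, j in candidates:
        if seqs[i] == seqs[j]:
            continue
        d = edlib.align(seqs[i], seqs[j], mode="NW", task="distance", k=1)["editDistance"]
        if d == 1:
            pairs.append((i, j))
    return pairs


def collapse_neighbors(clonotypes: Sequence[Clonotype]) -> list[Clonotype]:
    """Remove clonotypes one edit away from a strictly more abundant one.

    Abundance is the molecule count; ties retain both sequences.  All
    removal decisions are evaluated against the pre-filter state in a single
    pass, so removals do not cascade through already-removed sequences.
    """
    seqs = [c.seq for c in clonotypes]
    counts = [c.molecule_count for c in clonotypes]
    removed = [False] * len(clonotypes)
    for i, j in _distance_one_pairs(seqs):
        if counts[i] > counts[j]:
            removed[j] = True
        elif counts[j] > counts[i]:
            removed[i] = True
    return [c for c, r in zip(clonotypes, removed) if not r]


@dataclass(frozen=True)
class NBMixtureFit:
    """Two-component negative-binomial mixture fit of per-MID read counts.

    Components are ordered so the low-mean component comes first; ``weight_low``
    is its mixture weight.  ``crossover_count`` is the smallest count at which
    the high component's posterior exceeds the low component's — the
    data-driven analogue of the 20%-of-maximum rule.  ``degenerate`` marks an
    all-equal input (single-component result); ``boundary`` marks a fit whose
    weight collapsed to 0 or 1 (the data support a single component).
    """

    weight_low: float
    mean_low: float
    size_low: float
    mean_high: float
    size_high: float
    crossover_count: int | None
    degenerate: bool = False
    boundary: bool = False
    loglik: float = float("nan")


def _nb_logpmf(counts: np.ndarray, mean: float, size: float) -> np.ndarray:
    p = size / (size + mean)
    return stats.nbinom.logpmf(counts, size, p)


def _fit_component(counts: np.ndarray, resp: np.ndarray, mean: float) -> float:
    """Weighted MLE of the NB size (dispersion) parameter at fixed mean."""

    def nll(log_size: float) -> float:
        return -float((resp * _nb_logpmf(counts, mean, math.exp(log_size))).sum())

    res = optimize.minimize_scalar(nll, bounds=(math.log(1e-3), math.log(1e4)), method="bounded")
    return math.exp(res.x)


def fit_nb_mixture(read_counts: Sequence[int] | np.ndarray, max_iter: int = 200) -> NBMixtureFit:
    """EM fit of a two-component negative-binomial mixture.

    Deterministic: the low component is initialised at the 10th percentile
    of the counts, the high at the 90th, dispersions at 1, weights at 1/2.
    Requires at least 20 counts; an all-equal input yields a degenerate
    single-component result rather than an error.
    """
    counts = np.asarray(read_counts, dtype=np.int64)
    if counts.size < 20:
        raise ValueError("need at least 20 read counts")
    if np.any(counts < 1):
        raise ValueError("read counts must be positive")
    if np.unique(counts).size == 1:
        c = float(counts[0])
        return NBMixtureFit(
            weight_low=1.0, mean_low=c, size_low=float("inf"),
            mean_high=c, size_high=float("inf"),
            crossover_count=None, degenerate=True,
        )

    mean_low = max(float(np.percentile(counts, 10)), 0.1)
    mean_high = max(float(np.percentile(counts, 90)), mean_low * 1.5)
    size_low = size_high = 1.0
    w = 0.5
    loglik = -np.inf
    for _ in range(max_iter):
        log_lo = math.log(w) + _nb_logpmf(counts, mean_low, size_low)
        log_hi = math.log1p(-w) + _nb_logpmf(counts, mean_high, size_high)
        norm = np.logaddexp(log_lo, log_hi)
        new_loglik = float(norm.sum())
        resp_lo = np.exp(log_lo - norm)
        resp_hi = 1.0 - resp_lo
        w = float(np.clip(resp_lo.mean(), 1e-9, 1 - 1e-9))
        mean_low = max(float((resp_lo * counts).sum() / max(resp_lo.sum(), 1e-12)), 1e-3)
        mean_high = max(float((resp_hi * counts).sum() / max(resp_hi.sum(), 1e-12)), 1e-3)
        size_low = _fit_component(counts, resp_lo, mean_low)
        size_high = _fit_component(counts, resp_hi, mean_high)
        if abs(new_loglik - loglik) < 1e-8 * max(abs(new_loglik), 1.0):
            loglik = new_loglik
            break
        loglik = new_loglik

    if mean_low > mean_high:
        mean_low, mean_high = mean_high, mean_low
        size_low, size_high = size_high, size_low
        w = 1.0 - w
    boundary = w < 1e-3 or w > 1 - 1e-3

    crossover: int | None = None
    grid = np.arange(0, int(counts.max()) + 1)
    post_lo = math.log(max(w, 1e-300)) + _nb_logpmf(grid, mean_low, size_low)
    post_hi = math.log(max(1 - w, 1e-300)) + _nb_logpmf(grid, mean_high, size_high)
    above = np.nonzero(post_hi > post_lo)[0]
    if above.size:
        crossover = int(above[0])
    return NBMixtureFit(
        weight_low=w, mean_low=mean_low, size_low=size_low,
        mean_high=mean_high, size_high=size_high,
        crossover_count=crossover, boundary=boundary, loglik=loglik,
    )


def mid_readcount_filter(
    clonotype: Clonotype,
    threshold_fraction: float = 0.2,
    threshold_count: int | None = None,
) -> Clonotype | None:
    """Drop erroneous-MID entries with low read counts from a clonotype.

    Within the clonotype, MID entries with read_count <
    threshold_fraction × max(read_count) are removed (an absolute
    ``threshold_count``, e.g. an NB-mixture crossover, takes precedence when
    given).  Molecule and read totals follow from the surviving entries.
    Returns ``None`` if no entry survives.
    """
    if not clonotype.mids:
        raise ValueError("clonotype has no MID entries")
    if threshold_count is not None:
        cut = float(threshold_count)
    else:
        cut = threshold_fraction * max(clonotype.mids.values())
    kept = {k: v for k, v in clonotype.mids.items() if v >= cut}
    if not kept:
        return None
    return replace(clonotype, mids=kept)


def apply_filters(
    records: Iterable[ConsensusRecord],
    frame_offset: int | None = None,
    threshold_fraction: float = 0.2,
    do_collapse: bool = True,
    do_mid_filter: bool = True,
) -> tuple[list[Clonotype], dict]:
    """Run the full filter chain: merge -> non-functional flag -> one-edit
    neighbor collapse -> MID read-count filter.

    Returns the surviving clonotypes and an audit log of per-filter removal
    counts.
    """
    clonotypes = merge_identical(records)
    audit: dict = {"merged_clonotypes": len(clonotypes)}
    if frame_offset is not None:
        flagged = sum(flag_nonfunctional(c, frame_offset) for c in clonotypes)
        audit["flagged_nonfunctional"] = int(flagged)
    if do_collapse:
        before = len(clonotypes)
        clonotypes = collapse_neighbors(clonotypes)
        audit["removed_neighbor_collapse"] = before - len(clonotypes)
    if do_mid_filter:
        molecules_before = sum(c.molecule_count for c in clonotypes)
        filtered = [mid_readcount_filter(c, threshold_fraction) for c in clonotypes]
        clonotypes = [c for c in filtered if c is not None]
        audit["removed_mid_entries"] = molecules_before - sum(
            c.molecule_count for c in clonotypes
        )
    audit["final_clonotypes"] = len(clonotypes)
    return clonotypes, audit


def clonotypes_to_frame(clonotypes: Iterable[Clonotype]) -> pd.DataFrame:
    """Clonotype table: seq, molecule_count, total_reads, functional, n_mids."""
    rows = [
        {
            "seq": c.seq,
            "molecule_count": c.molecule_count,
            "total_reads": c.total_reads,
            "functional": c.functional,
            "n_mids": len({mid for mid, _ in c.mids}),
        }
        for c in clonotypes
    ]
    return pd.DataFrame(
        rows, columns=["seq", "molecule_count", "total_reads", "functional", "n_mids"]
    )
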