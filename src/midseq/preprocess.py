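"""FASTQ parsing, anchor filtering, and MID extraction.

Reads are expected to carry a molecular identifier (MID) at a fixed offset
(default: the first 12 nt), followed by the receptor constant-region anchor
and the V(D)J-proximal variable sequence.  Only reads containing an exact
occurrence of the constant-region anchor are kept; kept reads are trimmed to
a fixed payload length starting at the anchor so that the error-prone read
tail never enters consensus building.
"""

from __future__ import annotations

import gzip
import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "RawRead",
    "PreprocessConfig",
    "PreparedRead",
    "RejectedRead",
    "ParseError",
    "ParseResult",
    "PrepareResult",
    "parse_fastq",
    "read_fastq",
    "locate_anchor",
    "prepare_read",
    "prepare_reads",
    "prepared_to_frame",
    "frame_to_prepared",
]


@dataclass(slots=True)
class RawRead:
    """One sequencing read: identifier, sequence over {A,C,G,T,N}, and
    per-base Phred qualities (uint8 array, same length as seq)."""

    id: str
    seq: str
    qual: np.ndarray


@dataclass(frozen=True)
class PreprocessConfig:
    """Read-layout and filtering parameters.

    ``anchor`` is the constant-region sequence that must occur exactly
    (``max_anchor_mismatches`` defaults to 0).  The MID occupies
    ``mid_length`` bases starting at ``mid_offset``; the payload is cut to
    ``payload_length`` nt starting at the anchor, and reads whose post-anchor
    sequence is shorter than ``min_payload`` are rejected.
    """

    anchor: str
    mid_length: int = 12
    payload_length: int = 150
    mid_offset: int = 0
    min_payload: int = 100
    max_anchor_mismatches: int = 0

    def __post_init__(self) -> None:
        if not self.anchor:
            raise ValueError("anchor must be non-empty")
        if self.mid_length < 1 or self.payload_length < 1:
            raise ValueError("mid_length and payload_length must be >= 1")
        if not 0 < self.min_payload <= self.payload_length:
            raise ValueError("require 0 < min_payload <= payload_length")


@dataclass(slots=True)
class PreparedRead:
    """An anchored, trimmed read: its MID, its payload (starting with the
    anchor), and payload-aligned qualities."""

    id: str
    mid: str
    payload: str
    qual: np.ndarray

    def qual_sum(self) -> int:
        return int(self.qual.sum())

    def mean_quality(self) -> float:
        return float(self.qual.mean())


@dataclass(frozen=True, slots=True)
class RejectedRead:
    id: str
    reason: str  # one of: no_anchor, ambiguous_mid, short_payload


@dataclass(frozen=True, slots=True)
class ParseError:
    record_index: int
    message: str


@dataclass
class ParseResult:
    reads: list[RawRead]
    errors: list[ParseError] = field(default_factory=list)


@dataclass
class PrepareResult:
    prepared: list[PreparedRead]
    rejected: list[RejectedRead]

    @property
    def stats(self) -> dict:
        by_reason = Counter(r.reason for r in self.rejected)
        return {
            "parsed": len(self.prepared) + len(self.rejected),
            "accepted": len(self.prepared),
            "rejected": dict(sorted(by_reason.items())),
        }


def _decode_quality(qual_line: str) -> np.ndarray:
    return np.frombuffer(qual_line.encode("ascii"), dtype=np.uint8) - 33


def parse_fastq(stream: Iterable[str] | io.TextIOBase) -> ParseResult:
    """Parse 4-line-per-record FASTQ text into :class:`RawRead` objects.

    Qualities are decoded from Phred+33.  Malformed records (missing '@'
    header, missing '+' separator, sequence/quality length mismatch,
    truncated final record) are skipped and reported with their record
    index.
    """
    reads: list[RawRead] = []
    errors: list[ParseError] = []
    it: Iterator[str] = iter(stream)
    index = 0
    while True:
        try:
            header = next(it)
        except StopIteration:
            break
        lines = [header.rstrip("\n")]
        for _ in range(3):
            try:
                lines.append(next(it).rstrip("\n"))
            except StopIteration:
                errors.append(ParseError(index, "truncated record"))
                return ParseResult(reads, errors)
        header, seq, sep, qual = lines
        if not header.startswith("@"):
            errors.append(ParseError(index, "header does not start with '@'"))
        elif not sep.startswith("+"):
            errors.append(ParseError(index, "separator does not start with '+'"))
        elif len(seq) != len(qual):
            errors.append(ParseError(index, "sequence/quality length mismatch"))
        elif not seq:
            errors.append(ParseError(index, "empty sequence"))
        else:
            rid = header[1:].split()[0] if len(header) > 1 else ""
            reads.append(RawRead(id=rid, seq=seq, qual=_decode_quality(qual)))
        index += 1
    return ParseResult(reads, errors)


def read_fastq(path: str | Path) -> ParseResult:
    """Parse a FASTQ file, transparently handling gzip compression."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:  # type: ignore[operator]
        return parse_fastq(handle)


def locate_anchor(read: RawRead, config: PreprocessConfig) -> int | None:
    """0-based position of the first anchor occurrence at or after the MID.

    Exact substring match by default; with ``max_anchor_mismatches`` > 0 a
    Hamming-tolerant scan is used.  Returns ``None`` when absent.
    """
    start = config.mid_offset + config.mid_length
    if config.max_anchor_mismatches == 0:
        pos = read.seq.find(config.anchor, start)
        return pos if pos >= 0 else None
    anchor = config.anchor
    la = len(anchor)
    for pos in range(start, len(read.seq) - la + 1):
        window = read.seq[pos : pos + la]
        mismatches = sum(a != b for a, b in zip(anchor, window))
        if mismatches <= config.max_anchor_mismatches:
            return pos
    return None


def prepare_read(
    read: RawRead, config: PreprocessConfig
) -> PreparedRead | RejectedRead:
    """Anchor, trim, and MID-extract a single read.

    Rejections are categorised: ``no_anchor`` (no exact anchor occurrence),
    ``ambiguous_mid`` (an N inside the MID makes grouping impossible), or
    ``short_payload`` (post-anchor sequence shorter than ``min_payload``).
    N bases in the payload are tolerated; consensus voting scores them with
    quality 0.
    """
    pos = locate_anchor(read, config)
    if pos is None:
        return RejectedRead(read.id, "no_anchor")
    mid = read.seq[config.mid_offset : config.mid_offset + config.mid_length]
    if "N" in mid:
        return RejectedRead(read.id, "ambiguous_mid")
    payload = read.seq[pos : pos + config.payload_length]
    if len(payload) < config.min_payload:
        return RejectedRead(read.id, "short_payload")
    qual = read.qual[pos : pos + len(payload)]
    return PreparedRead(id=read.id, mid=mid, payload=payload, qual=qual)


def prepare_reads(
    reads: Iterable[RawRead], config: PreprocessConfig
) -> PrepareResult:
    """Prepare a batch of reads; accepted + rejected == parsed always."""
    prepared: list[PreparedRead] = []
    rejected: list[RejectedRead] = []
    for read in reads:
        out = prepare_read(read, config)
        if isinstance(out, PreparedRead):
            prepared.append(out)
        else:
            rejected.append(out)
    return PrepareResult(prepared, rejected)


def prepared_to_frame(reads: Iterable[PreparedRead]) -> pd.DataFrame:
    """Tabular read manifest: id, mid, payload, Phred+33 quality string,
    mean quality."""
    rows = [
        {
            "id": r.id,
            "mid": r.mid,
            "payload": r.payload,
            "qual": (r.qual + 33).tobytes().decode("ascii"),
            "mean_quality": round(r.mean_quality(), 3),
        }
        for r in reads
    ]
    return pd.DataFrame(rows, columns=["id", "mid", "payload", "qual", "mean_quality"])


def frame_to_prepared(frame: pd.DataFrame) -> list[PreparedRead]:
    """Inverse of :func:`prepared_to_frame` (mean_quality is recomputed)."""
    return [
        PreparedRead(
            id=str(row.id),
            mid=str(row.mid),
            payload=str(row.payload),
            qual=_decode_quality(str(row.qual)),
        )
        for row in frame.itertuples(index=False)
    ]
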