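"""Synthetic MID-tagged repertoire reads with full ground truth.

The generator emulates the data-generating process the pipeline corrects:

1. **Clone structure** — K clones with cell counts drawn from a discrete
   power law (exponent ``alpha``); every cell contributes exactly ``m``
   transcript molecules, so clone i carries m·x_i molecules.
2. **MID tagging** — each molecule independently draws a uniform random
   MID of ``mid_length`` nt, so MID collisions arise at the Poisson rate the
   occupancy model predicts.
3. **PCR** — each sequenced read descends from its molecule through
   ``pcr_cycles`` of stochastic duplication.  Substitution errors strike the
   MID and the payload alike; errors in the first ``pcr_founder_cycles``
   cycles are shared by all reads descending from the same early amplicon
   (this is what creates multi-read erroneous-MID satellites), later errors
   are private to a read lineage.  The genealogy is simulated at the level
   of the sampled reads rather than the full amplicon pool.
4. **Sequencing** — per-read Poisson(``reads_per_molecule_mean``) coverage,
   per-base substitution errors at ``seq_error_rate``, and a declining
   positional quality profile.

Spike-in sequences with fixed copy numbers model control-RNA sensitivity
experiments.  Every read is linked to its source molecule and every molecule
to its clone, so recovery, inflation, and chimera rates are all measurable
exactly.
"""

from __future__ import annotations

import gzip
from dataclasses import asdict, dataclass
from pathlib import Path

import edlib
import numpy as np
import pandas as pd
import yaml

from .models import sample_clone_sizes
from .preprocess import RawRead

__all__ = [
    "DEFAULT_ANCHOR",
    "SimConfig",
    "CloneTruth",
    "SimTruth",
    "SimReads",
    "simulate_repertoire",
    "amplify_and_sequence",
    "simulate_reads",
    "random_payload",
    "write_fixture",
    "load_fixture",
]

# 21-nt stand-in for a receptor constant-region primer landing site; stop-free
# in frame 0 so translation-based functionality calls start cleanly.
DEFAULT_ANCHOR = "GAGGACCTGAAAAACGTGTTC"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOP_CODONS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOP_CODONS
)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic repertoire.

    Defaults describe a small naive-like T cell library: power-law clone
    sizes (alpha 2.5), 3 transcripts per cell, 12-nt MIDs, 150-nt payloads,
    20 PCR cycles at 80% per-cycle efficiency with 1e-4 substitutions per
    base per duplication, 1e-3 per-base sequencing error, and ~30x read
    coverage per molecule.
    """

    K: int = 500
    alpha: float = 2.5
    m: int = 3
    mid_length: int = 12
    anchor: str = DEFAULT_ANCHOR
    payload_length: int = 150
    max_clone_cells: int = 100_000
    min_clone_separation: int = 25
    separation_check_max_clones: int = 3000
    pcr_cycles: int = 20
    pcr_efficiency: float = 0.8
    pcr_error_rate: float = 1e-4
    pcr_founder_cycles: int = 3
    seq_error_rate: float = 1e-3
    reads_per_molecule_mean: float = 30.0
    nonproductive_fraction: float = 0.0
    spike_ins: tuple[tuple[str, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1 or self.m < 1:
            raise ValueError("K and m must be >= 1")
        for name in ("pcr_efficiency", "pcr_error_rate", "seq_error_rate",
                     "nonproductive_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if len(self.anchor) >= self.payload_length:
            raise ValueError("anchor must be shorter than payload_length")

    @property
    def variable_region_length(self) -> int:
        return self.payload_length - len(self.anchor)


@dataclass(frozen=True)
class CloneTruth:
    """One true clone: payload sequence (anchor + variable region), cell
    count, productivity, and its molecule tally (m x cells, or the spike-in
    copy number)."""

    clone_id: int
    sequence: str
    cell_count: int
    productive: bool
    n_molecules: int
    is_spike: bool = False


@dataclass
class SimTruth:
    """Generative ground truth: clones, molecule->clone and molecule->MID
    assignments, and (after sequencing) read->molecule links."""

    config: SimConfig
    clones: list[CloneTruth]
    molecule_clone: np.ndarray  # clone id per molecule
    molecule_mid_codes: np.ndarray  # (n_molecules, mid_length) uint8 in 0..3
    read_molecule: np.ndarray | None = None

    @property
    def n_molecules(self) -> int:
        return int(self.molecule_clone.size)

    def molecule_mids(self) -> list[str]:
        """MID strings per molecule, decoded on demand."""
        ascii_codes = _BASES[self.molecule_mid_codes]
        w = self.config.mid_length
        raw = ascii_codes.tobytes()
        return [raw[i * w : (i + 1) * w].decode("ascii") for i in range(self.n_molecules)]

    def clone_sequences(self) -> set[str]:
        return {c.sequence for c in self.clones}


@dataclass
class SimReads:
    """Sequenced reads plus the read->molecule ground-truth map."""

    reads: list[RawRead]
    read_molecule: np.ndarray

    def read_to_molecule(self) -> dict[str, int]:
        return {r.id: int(m) for r, m in zip(self.reads, self.read_molecule)}


def _encode(seq: str) -> np.ndarray:
    """ACGT string -> uint8 codes 0..3."""
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    codes = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if np.any(codes == 255):
        raise ValueError("sequence contains characters outside ACGT")
    return codes


def random_payload(config: SimConfig, rng: np.random.Generator) -> str:
    """One random stop-free payload under ``config``'s layout (for spike-ins)."""
    mat = _random_variable_regions(1, config, rng)
    var = _BASES[mat[0]].tobytes().decode("ascii")
    return config.anchor + var


def _random_variable_regions(
    n: int, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """(n, variable_region_length) uint8 code matrix of stop-free sequence.

    Codons are drawn from the 61 sense codons so productive clones never
    carry an in-frame stop; a non-codon-sized remainder is filled with
    stop-free suffix bases.
    """
    vlen = config.variable_region_length
    n_codons, rem = divmod(vlen, 3)
    codon_codes = np.stack([_encode(c) for c in _SENSE_CODONS])  # (61, 3)
    picks = rng.integers(0, len(_SENSE_CODONS), size=(n, n_codons))
    mat = codon_codes[picks].reshape(n, n_codons * 3)
    if rem:
        # a trailing partial codon is never translated; any bases do
        tail = rng.integers(0, 4, size=(n, rem), dtype=np.uint8)
        mat = np.concatenate([mat, tail], axis=1)
    return mat.astype(np.uint8)


def _insert_stop(var_codes: np.ndarray, rng: np.random.Generator) -> None:
    """Overwrite one random in-frame codon with a random stop codon."""
    n_codons = var_codes.size // 3
    pos = int(rng.integers(0, n_codons)) * 3
    stop = _encode(_STOP_CODONS[int(rng.integers(0, len(_STOP_CODONS)))])
    var_codes[pos : pos + 3] = stop


def _check_separation(
    payloads: list[str], min_sep: int, skip_indices: set[int]
) -> list[int]:
    """Indices of payloads closer than ``min_sep`` edits to an earlier one."""
    offenders: list[int] = []
    for i in range(1, len(payloads)):
        for j in range(i):
            if j in skip_indices or i in skip_indices:
                continue
            d = edlib.align(
                payloads[i], payloads[j], mode="NW", task="distance", k=min_sep - 1
            )["editDistance"]
            if d != -1:
                offenders.append(i)
                break
    return offenders


def simulate_repertoire(
    config: SimConfig, rng: np.random.Generator | None = None
) -> SimTruth:
    """Generate the pre-sequencing ground truth: clones, molecules, MIDs.

    Clone payloads are random stop-free sequences behind the shared anchor;
    for repertoires up to ``separation_check_max_clones`` clones, pairwise
    Levenshtein separation >= ``min_clone_separation`` is verified and
    offending clones are regenerated (failure after bounded retries raises).
    Beyond that size the check is skipped: random variable regions of 100+
    nt concentrate at edit distances far above the threshold.  Cell counts
    follow the power law, each cell contributes exactly ``m`` molecules, and
    every molecule draws an independent uniform MID.  Spike-ins are appended
    with their stated copy numbers.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    x = sample_clone_sizes(
        config.alpha, config.K, xmax=config.max_clone_cells, rng=rng
    )
    var = _random_variable_regions(config.K, config, rng)

    n_nonprod = int(round(config.nonproductive_fraction * config.K))
    nonprod_ids = set(rng.choice(config.K, size=n_nonprod, replace=False).tolist()) if n_nonprod else set()
    for i in nonprod_ids:
        _insert_stop(var[i], rng)

    anchor_codes = _encode(config.anchor)
    payload_codes = np.concatenate(
        [np.tile(anchor_codes, (config.K, 1)), var], axis=1
    ).astype(np.uint8)

    def payload_str(i: int) -> str:
        return _BASES[payload_codes[i]].tobytes().decode("ascii")

    payloads = [payload_str(i) for i in range(config.K)]
    if config.min_clone_separation and config.K <= config.separation_check_max_clones:
        for _attempt in range(20):
            offenders = _check_separation(payloads, config.min_clone_separation, set())
            if not offenders:
                break
            for i in offenders:
                fresh = _random_variable_regions(1, config, rng)[0]
                if i in nonprod_ids:
                    _insert_stop(fresh, rng)
                payload_codes[i, len(config.anchor):] = fresh
                payloads[i] = payload_str(i)
        else:
            raise RuntimeError(
                "could not achieve pairwise clone separation "
                f">= {config.min_clone_separation} after bounded retries"
            )

    clones = [
        CloneTruth(
            clone_id=i,
            sequence=payloads[i],
            cell_count=int(x[i]),
            productive=i not in nonprod_ids,
            n_molecules=config.m * int(x[i]),
        )
        for i in range(config.K)
    ]
    mol_per_clone = [config.m * int(xi) for xi in x]

    for s, (seq, copies) in enumerate(config.spike_ins):
        if len(seq) != config.payload_length or not seq.startswith(config.anchor):
            raise ValueError(
                "spike-in sequences must be full payloads starting with the anchor"
            )
        clones.append(
            CloneTruth(
                clone_id=config.K + s,
                sequence=seq,
                cell_count=0,
                productive=True,
                n_molecules=int(copies),
                is_spike=True,
            )
        )
        payload_codes = np.concatenate([payload_codes, _encode(seq)[None, :]], axis=0)
        mol_per_clone.append(int(copies))

    molecule_clone = np.repeat(
        np.arange(len(clones), dtype=np.int64), np.asarray(mol_per_clone, dtype=np.int64)
    )
    n_mol = molecule_clone.size
    mid_codes = rng.integers(0, 4, size=(n_mol, config.mid_length), dtype=np.uint8)

    truth = SimTruth(
        config=config,
        clones=clones,
        molecule_clone=molecule_clone,
        molecule_mid_codes=mid_codes,
    )
    truth._payload_codes = payload_codes  # type: ignore[attr-defined]
    return truth


def _apply_point_errors(
    mat: np.ndarray, rows: np.ndarray, pos: np.ndarray, delta: np.ndarray
) -> None:
    """Substitute mat[rows, pos] by shifting 1..3 places in base space."""
    mat[rows, pos] = (mat[rows, pos] + delta) % 4


def amplify_and_sequence(
    truth: SimTruth, config: SimConfig | None = None, rng: np.random.Generator | None = None
) -> SimReads:
    """PCR-amplify and sequence the simulated molecules.

    Per molecule, Poisson-distributed reads are drawn.  Each read is
    assigned to one of 2^``pcr_founder_cycles`` founder lineages; founder
    lineages carry Poisson-distributed early-PCR substitutions shared by all
    their reads (MID and payload bases alike), later PCR substitutions are
    private per read, and sequencing substitutions plus a declining quality
    profile are applied last.  Read layout is MID + payload.
    """
    config = config or truth.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    payload_codes: np.ndarray = truth._payload_codes  # type: ignore[attr-defined]
    n_mol = truth.n_molecules
    w = config.mid_length
    read_len = w + config.payload_length

    per_mol = rng.poisson(config.reads_per_molecule_mean, n_mol)
    read_mol = np.repeat(np.arange(n_mol, dtype=np.int64), per_mol)
    n_reads = read_mol.size
    if n_reads == 0:
        return SimReads(reads=[], read_molecule=read_mol)

    mat = np.empty((n_reads, read_len), dtype=np.uint8)
    mat[:, :w] = truth.molecule_mid_codes[read_mol]
    mat[:, w:] = payload_codes[truth.molecule_clone[read_mol]]

    # --- shared early-PCR (founder) errors
    s = min(config.pcr_founder_cycles, config.pcr_cycles)
    if s > 0 and config.pcr_error_rate > 0:
        n_founders = 2**s
        founder = rng.integers(0, n_founders, n_reads)
        key = read_mol * n_founders + founder
        order = np.argsort(key, kind="stable")
        sorted_keys = key[order]
        starts = np.nonzero(np.r_[True, sorted_keys[1:] != sorted_keys[:-1]])[0]
        ends = np.r_[starts[1:], n_reads]
        lam_founder = s * config.pcr_efficiency * read_len * config.pcr_error_rate
        n_mut = rng.poisson(lam_founder, starts.size)
        for g in np.nonzero(n_mut)[0]:
            rows = order[starts[g] : ends[g]]
            for _ in range(n_mut[g]):
                p = int(rng.integers(0, read_len))
                delta = int(rng.integers(1, 4))
                mat[rows, p] = (mat[rows, p] + delta) % 4

    # --- private late-PCR errors
    late = max(config.pcr_cycles - s, 0)
    if late > 0 and config.pcr_error_rate > 0:
        lam_late = late * config.pcr_efficiency * read_len * config.pcr_error_rate
        k = rng.poisson(lam_late, n_reads)
        rows = np.repeat(np.arange(n_reads), k)
        if rows.size:
            pos = rng.integers(0, read_len, rows.size)
            delta = rng.integers(1, 4, rows.size)
            _apply_point_errors(mat, rows, pos, delta)

    # --- sequencing errors
    if config.seq_error_rate > 0:
        k = rng.poisson(config.seq_error_rate * read_len, n_reads)
        rows = np.repeat(np.arange(n_reads), k)
        if rows.size:
            pos = rng.integers(0, read_len, rows.size)
            delta = rng.integers(1, 4, rows.size)
            _apply_point_errors(mat, rows, pos, delta)

    # --- qualities: high at the start, declining toward the read end
    profile = np.clip(38.0 - 12.0 * np.arange(read_len) / read_len, 2, 40)
    quals = (
        profile[None, :].astype(np.int16)
        + rng.integers(-3, 4, size=(n_reads, read_len), dtype=np.int16)
    )
    quals = np.clip(quals, 2, 40).astype(np.uint8)

    raw = _BASES[mat].tobytes()
    reads = [
        RawRead(
            id=f"r{i}",
            seq=raw[i * read_len : (i + 1) * read_len].decode("ascii"),
            qual=quals[i],
        )
        for i in range(n_reads)
    ]
    truth.read_molecule = read_mol
    return SimReads(reads=reads, read_molecule=read_mol)


def simulate_reads(config: SimConfig) -> tuple[SimTruth, SimReads]:
    """Full simulation under one seeded generator: repertoire + sequencing."""
    rng = np.random.default_rng(config.seed)
    truth = simulate_repertoire(config, rng)
    sim_reads = amplify_and_sequence(truth, config, rng)
    return truth, sim_reads


def write_fixture(truth: SimTruth, sim_reads: SimReads, out_dir: str | Path) -> None:
    """Write reads.fastq.gz, truth tables (TSV), and the config echo (YAML)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with gzip.open(out / "reads.fastq.gz", "wt") as fq:
        for r in sim_reads.reads:
            fq.write(f"@{r.id}\n{r.seq}\n+\n{(r.qual + 33).tobytes().decode('ascii')}\n")
    pd.DataFrame(
        [
            {
                "clone_id": c.clone_id,
                "sequence": c.sequence,
                "cell_count": c.cell_count,
                "productive": c.productive,
                "n_molecules": c.n_molecules,
                "is_spike": c.is_spike,
            }
            for c in truth.clones
        ]
    ).to_csv(out / "truth_clones.tsv", sep="\t", index=False)
    mids = truth.molecule_mids()
    pd.DataFrame(
        {
            "molecule_id": np.arange(truth.n_molecules),
            "clone_id": truth.molecule_clone,
            "mid": mids,
        }
    ).to_csv(out / "truth_molecules.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "read_id": [r.id for r in sim_reads.reads],
            "molecule_id": sim_reads.read_molecule,
        }
    ).to_csv(out / "truth_reads.tsv", sep="\t", index=False)
    cfg = asdict(truth.config)
    cfg["spike_ins"] = [list(s) for s in cfg["spike_ins"]]
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))


def load_fixture(out_dir: str | Path) -> tuple[SimTruth, SimReads]:
    """Read back a fixture written by :func:`write_fixture`."""
    from .preprocess import read_fastq

    out = Path(out_dir)
    cfg = yaml.safe_load((out / "config.yaml").read_text())
    cfg["spike_ins"] = tuple(tuple(s) for s in cfg.get("spike_ins", ()))
    config = SimConfig(**cfg)
    clones_df = pd.read_csv(out / "truth_clones.tsv", sep="\t")
    clones = [
        CloneTruth(
            clone_id=int(r.clone_id),
            sequence=str(r.sequence),
            cell_count=int(r.cell_count),
            productive=bool(r.productive),
            n_molecules=int(r.n_molecules),
            is_spike=bool(r.is_spike),
        )
        for r in clones_df.itertuples(index=False)
    ]
    mol_df = pd.read_csv(out / "truth_molecules.tsv", sep="\t")
    mid_codes = np.stack([_encode(m) for m in mol_df["mid"].astype(str)])
    truth = SimTruth(
        config=config,
        clones=clones,
        molecule_clone=mol_df["clone_id"].to_numpy(dtype=np.int64),
        molecule_mid_codes=mid_codes,
    )
    truth._payload_codes = np.stack(  # type: ignore[attr-defined]
        [_encode(c.sequence) for c in clones]
    )
    reads_df = pd.read_csv(out / "truth_reads.tsv", sep="\t")
    truth.read_molecule = reads_df["molecule_id"].to_numpy(dtype=np.int64)
    parsed = read_fastq(out / "reads.fastq.gz")
    return truth, SimReads(reads=parsed.reads, read_molecule=truth.read_molecule)
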