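"""Artificial-genome and paired-end read simulation.

Builds a mutated genome by injecting non-overlapping deletions and
insertions into a reference at uniformly sampled positions, records the
ground truth in reference coordinates, and emits 100-bp paired-end reads
with a Normal(350, 50) insert-size model and a 0.1% per-base substitution
error (all configurable).  Reads are drawn from the mutated genome, so
deletions show up downstream as discordant inserts / split alignments —
exactly what deletion callers consume.

SV sizes default to a synthetic mixture over 1 bp – 1 Mb: mostly
log-uniform, with excess mass near 300 bp and 6,000 bp emulating the Alu
and LINE peaks of human deletion spectra.  An empirical size table can
replace the mixture entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .model import GenomicInterval, TruthRecord

__all__ = [
    "SimulationConfig",
    "ReadPair",
    "random_reference",
    "sample_sv_sizes",
    "inject_svs",
    "simulate_reads",
]

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# byte -> 0..3 base index, 4 for anything else (N, lowercase folded first)
_BASE_INDEX = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i
    _BASE_INDEX[_b + 32] = _i  # lowercase

_COMPLEMENT = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTNacgtn", b"TGCANtgcan"):
    _COMPLEMENT[_a] = _b


@dataclass
class SimulationConfig:
    """Parameters of SV injection and read generation.

    ``size_table`` — optional empirical ``[(size, weight), ...]`` replacing
    the default mixture sampler.  ``depth`` is fold coverage; the paper-style
    series is 5/10/20/30x.  All randomness flows from ``seed``.
    """

    n_sv: int = 500
    del_fraction: float = 0.5
    min_size: int = 1
    max_size: int = 1_000_000
    size_table: Optional[Sequence[Tuple[int, float]]] = None
    read_length: int = 100
    insert_mean: float = 350.0
    insert_sd: float = 50.0
    error_rate: float = 0.001
    depth: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must lie in [0, 1]")
        if not 0.0 <= self.del_fraction <= 1.0:
            raise ValueError("del_fraction must lie in [0, 1]")
        if self.read_length < 1 or self.depth < 0:
            raise ValueError("read_length must be >= 1 and depth >= 0")
        if self.min_size < 1 or self.min_size > self.max_size:
            raise ValueError("need 1 <= min_size <= max_size")


@dataclass(frozen=True)
class ReadPair:
    """One FR-oriented read pair; read2 is reverse-complemented."""

    name: str
    seq1: str
    seq2: str
    quality: str


def random_reference(
    length: int,
    seed: int = 0,
    contig: str = "chr1",
    gc: float = 0.41,
) -> Dict[str, str]:
    """A single-contig i.i.d. reference at human-like GC content."""
    rng = np.random.default_rng(seed)
    p_at, p_gc = (1.0 - gc) / 2.0, gc / 2.0
    seq = rng.choice(_BASES, size=length, p=[p_at, p_gc, p_gc, p_at])
    return {contig: seq.tobytes().decode("ascii")}


def sample_sv_sizes(n: int, cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Sample ``n`` SV sizes from the configured distribution.

    Default mixture: 60% log-uniform over [min_size, max_size), 25% rounded
    Normal(300, 30), 15% rounded Normal(6000, 600); clamped into range.
    """
    if cfg.size_table is not None:
        sizes = np.asarray([s for s, _ in cfg.size_table], dtype=np.int64)
        weights = np.asarray([w for _, w in cfg.size_table], dtype=float)
        if (sizes < 1).any() or (weights < 0).any() or weights.sum() <= 0:
            raise ValueError("size_table needs sizes >= 1 and non-negative weights")
        return rng.choice(sizes, size=n, p=weights / weights.sum())
    component = rng.choice(3, size=n, p=[0.60, 0.25, 0.15])
    out = np.empty(n, dtype=np.int64)
    lo, hi = np.log10(cfg.min_size), np.log10(cfg.max_size)
    lu = component == 0
    out[lu] = np.floor(10.0 ** rng.uniform(lo, hi, lu.sum())).astype(np.int64)
    alu = component == 1
    out[alu] = np.rint(rng.normal(300.0, 30.0, alu.sum())).astype(np.int64)
    line = component == 2
    out[line] = np.rint(rng.normal(6000.0, 600.0, line.sum())).astype(np.int64)
    return np.clip(out, cfg.min_size, cfg.max_size - 1)


def _has_n(seq: str, start: int, end: int) -> bool:
    window = seq[start:end]
    return "N" in window or "n" in window


def inject_svs(
    reference: Mapping[str, str],
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Dict[str, str], List[TruthRecord]]:
    """Place ``cfg.n_sv`` non-overlapping SVs and apply them to the reference.

    Positions are uniform over the genome; a placement is rejected and
    resampled when the event (plus a 1-bp guard) would overlap a previous
    event, cross a contig boundary, or land in an N-run.  Deletions remove
    their span; insertions add a random A/C/G/T string after an anchor base.
    Truth coordinates are *reference* coordinates (pre-mutation), because
    caller output is mapped back against the original reference.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if not reference:
        raise ValueError("reference must contain at least one contig")
    contigs = list(reference)
    lengths = np.array([len(reference[c]) for c in contigs], dtype=np.int64)
    total = int(lengths.sum())

    sizes = sample_sv_sizes(cfg.n_sv, cfg, rng)
    is_del = rng.random(cfg.n_sv) < cfg.del_fraction

    placed: Dict[str, List[Tuple[int, int]]] = {c: [] for c in contigs}
    events: List[TruthRecord] = []
    max_attempts = min(max(10_000, 50 * cfg.n_sv), 1_000_000)
    attempts = 0
    max_contig = int(lengths.max())
    for size, deletion in zip(sizes.tolist(), is_del.tolist()):
        footprint = size if deletion else 1  # INS occupies only its anchor base
        if footprint + 2 > max_contig:
            raise RuntimeError(
                f"an SV of {size} bp cannot fit on any contig (longest: {max_contig} bp); "
                "use fewer or smaller SVs, or a larger reference"
            )
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"could not place {cfg.n_sv} SVs after {max_attempts} attempts; "
                    "use fewer or smaller SVs, or a larger reference"
                )
            ci = int(rng.choice(len(contigs), p=lengths / total))
            contig = contigs[ci]
            clen = int(lengths[ci])
            if footprint + 2 > clen:
                continue
            start = int(rng.integers(1, clen - footprint))  # keep 1-bp contig guard
            end = start + footprint
            if _has_n(reference[contig], start, end):
                continue
            if any(start - 1 < e and s < end + 1 for s, e in placed[contig]):
                continue  # 1-bp guard between events
            placed[contig].append((start, end))
            break
        interval = GenomicInterval(contig, start, end)
        if deletion:
            events.append(TruthRecord(interval=interval, sv_type="DEL"))
        else:
            ins_seq = rng.choice(_BASES, size=size).tobytes().decode("ascii")
            events.append(
                TruthRecord(interval=interval, sv_type="INS", inserted_sequence=ins_seq)
            )

    mutated: Dict[str, str] = {}
    by_contig: Dict[str, List[TruthRecord]] = {c: [] for c in contigs}
    for ev in events:
        by_contig[ev.interval.contig].append(ev)
    for contig in contigs:
        seq = reference[contig]
        parts: List[str] = []
        cursor = 0
        for ev in sorted(by_contig[contig], key=lambda e: e.interval.start):
            if ev.sv_type == "DEL":
                parts.append(seq[cursor : ev.interval.start])
                cursor = ev.interval.end
            else:  # insert after the anchor base
                parts.append(seq[cursor : ev.interval.end])
                parts.append(ev.inserted_sequence or "")
                cursor = ev.interval.end
        parts.append(seq[cursor:])
        mutated[contig] = "".join(parts)

    events.sort(key=lambda e: (e.interval.contig, e.interval.start))
    return mutated, events


def _apply_errors(
    reads: np.ndarray, error_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Substitute each base with probability ``error_rate`` to a different base."""
    if error_rate <= 0.0:
        return reads
    n_reads, read_len = reads.shape
    counts = rng.binomial(read_len, error_rate, size=n_reads)
    for i in np.nonzero(counts)[0]:
        pos = rng.choice(read_len, size=counts[i], replace=False)
        idx = _BASE_INDEX[reads[i, pos]]
        idx = np.where(idx > 3, rng.integers(0, 4, idx.size), idx)  # N -> random base
        shift = rng.integers(1, 4, size=counts[i])
        reads[i, pos] = _BASES[(idx + shift) % 4]
    return reads


def simulate_reads(
    genome: Mapping[str, str],
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    chunk_size: int = 50_000,
) -> Iterator[ReadPair]:
    """Generate FR paired-end reads at ``cfg.depth`` fold coverage.

    The pair count is ``round(depth * genome_length / (2 * read_length))``,
    allocated across contigs in proportion to length.  Fragment lengths are
    drawn from Normal(insert_mean, insert_sd), rounded, redrawn below
    2*read_length (clamped after a bounded number of redraws) and capped at
    the contig length; fragment starts are uniform.  Read names encode the
    true fragment coordinates: ``frag:<contig>:<start>-<end>:<pair index>``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    rl = cfg.read_length
    contigs = [c for c in genome]
    lengths = np.array([len(genome[c]) for c in contigs], dtype=np.int64)
    total = int(lengths.sum())
    n_pairs = int(round(cfg.depth * total / (2.0 * rl)))
    if n_pairs == 0:
        return

    feasible = lengths >= 2 * rl
    for c, ok in zip(contigs, feasible):
        if not ok:
            logger.warning("contig %s shorter than one fragment; skipped", c)
    if not feasible.any():
        raise ValueError("no contig is long enough for a single fragment")
    probs = np.where(feasible, lengths, 0).astype(float)
    per_contig = rng.multinomial(n_pairs, probs / probs.sum())

    quality = "I" * rl
    pair_index = 0
    for contig, n_c in zip(contigs, per_contig.tolist()):
        if n_c == 0:
            continue
        seq = np.frombuffer(genome[contig].encode("ascii"), dtype=np.uint8)
        clen = seq.size
        for offset in range(0, n_c, chunk_size):
            m = min(chunk_size, n_c - offset)
            frags = np.rint(rng.normal(cfg.insert_mean, cfg.insert_sd, m)).astype(np.int64)
            for _ in range(100):
                bad = frags < 2 * rl
                if not bad.any():
                    break
                frags[bad] = np.rint(
                    rng.normal(cfg.insert_mean, cfg.insert_sd, int(bad.sum()))
                ).astype(np.int64)
            np.clip(frags, 2 * rl, clen, out=frags)
            starts = rng.integers(0, clen - frags + 1)
            ends = starts + frags

            cols = np.arange(rl)
            fwd = seq[starts[:, None] + cols]
            rev = seq[(ends - rl)[:, None] + cols]
            rev = _COMPLEMENT[rev][:, ::-1]
            fwd = _apply_errors(np.ascontiguousarray(fwd), cfg.error_rate, rng)
            rev = _apply_errors(np.ascontiguousarray(rev), cfg.error_rate, rng)

            for k in range(m):
                name = f"frag:{contig}:{starts[k]}-{ends[k]}:{pair_index}"
                yield ReadPair(
                    name=name,
                    seq1=fwd[k].tobytes().decode("ascii"),
                    seq2=rev[k].tobytes().decode("ascii"),
                    quality=quality,
                )
                pair_index += 1
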