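"""Statistical caller emulator.

Stands in for real deletion callers (read-pair, split-read, assembly
types) by deriving noisy call sets directly from a truth set: each truth
deletion is recovered with a per-size-bin probability, breakpoints and
sizes are jittered, and false calls are sprinkled at a per-bin Poisson
rate.  This gives the filtering / merging / evaluation stages end-to-end
inputs with *known* generative parameters, so the whole metric stack can
be checked by parameter recovery.

False calls are rejection-sampled away from truth effective regions (a
"false" call that matched a truth would not be false), and their sizes
are drawn within their bin, so per-bin precision is controlled exactly
by the recall / false-call rates.

``emulate_depth_series`` produces a coverage series (e.g. 5/10/20/30x)
with noise scaled inversely with depth, using common random numbers: a
truth detected at one depth stays detected at every higher depth, and
false calls are thinned as depth grows.  Per-bin performance is then
monotone in depth by construction, mirroring how added coverage can only
help a caller that consumes more evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from intervaltree import IntervalTree

from .model import DeletionCall, GenomicInterval, SizeBin, TruthRecord, find_bin

__all__ = ["EmulatorProfile", "emulate_calls", "emulate_depth_series"]

# false calls keep this distance (bp) from truth spans: twice the default
# evaluation margin, so their effective regions cannot touch a truth's
TRUTH_GUARD = 100


@dataclass(frozen=True)
class EmulatorProfile:
    """Generative parameters of one emulated caller.

    ``recall_by_bin`` — probability of emitting each truth deletion whose
    size falls in the bin (unlisted bins: 0).  ``fp_per_mb`` — expected
    false calls per megabase per bin, with sizes uniform within the bin.
    Jitter standard deviations are in bp.
    """

    caller: str
    recall_by_bin: Mapping[SizeBin, float]
    fp_per_mb: Mapping[SizeBin, float] = field(default_factory=dict)
    breakpoint_jitter_sd: float = 0.0
    size_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.caller:
            raise ValueError("caller must be non-empty")
        for p in self.recall_by_bin.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("recall probabilities must lie in [0, 1]")
        for r in self.fp_per_mb.values():
            if r < 0:
                raise ValueError("fp_per_mb must be non-negative")
        if self.breakpoint_jitter_sd < 0 or self.size_jitter_sd < 0:
            raise ValueError("jitter sds must be non-negative")

    @classmethod
    def from_rows(
        cls,
        caller: str,
        recall_rows: Sequence[Tuple[int, int, float]],
        fp_rows: Sequence[Tuple[int, int, float]] = (),
        breakpoint_jitter_sd: float = 0.0,
        size_jitter_sd: float = 0.0,
    ) -> "EmulatorProfile":
        """Build from ``(low, high, value)`` rows (half-open bins)."""
        return cls(
            caller=caller,
            recall_by_bin={SizeBin(l, h): p for l, h, p in recall_rows},
            fp_per_mb={SizeBin(l, h): r for l, h, r in fp_rows},
            breakpoint_jitter_sd=breakpoint_jitter_sd,
            size_jitter_sd=size_jitter_sd,
        )


def _jittered_call(
    truth: TruthRecord,
    profile: EmulatorProfile,
    start_z: float,
    size_z: float,
) -> DeletionCall:
    shift = int(round(start_z * profile.breakpoint_jitter_sd))
    dsize = int(round(size_z * profile.size_jitter_sd))
    start = max(0, truth.interval.start + shift)
    size = max(1, truth.size + dsize)
    return DeletionCall(
        interval=GenomicInterval(truth.interval.contig, start, start + size),
        caller=profile.caller,
    )


def _truth_blocklist(truths: Sequence[TruthRecord], contig: str) -> IntervalTree:
    tree = IntervalTree()
    for t in truths:
        if t.interval.contig == contig:
            tree.addi(max(0, t.interval.start - TRUTH_GUARD), t.interval.end + TRUTH_GUARD)
    return tree


def _fp_call(
    contig: str,
    genome_length: int,
    size_bin: SizeBin,
    caller: str,
    blocked: IntervalTree,
    rng: np.random.Generator,
) -> Optional[DeletionCall]:
    hi = min(size_bin.high, genome_length + 1)
    if hi <= size_bin.low:
        return None
    for _ in range(200):
        size = int(rng.integers(size_bin.low, hi))
        if size > genome_length:
            return None
        start = int(rng.integers(0, genome_length - size + 1))
        if not blocked.overlap(start, start + size):
            return DeletionCall(
                interval=GenomicInterval(contig, start, start + size), caller=caller
            )
    return None  # genome too crowded for this bin; drop the false call


def _default_contig(truths: Sequence[TruthRecord], contig: Optional[str]) -> str:
    if contig is not None:
        return contig
    contigs = {t.interval.contig for t in truths}
    if len(contigs) == 1:
        return next(iter(contigs))
    if not contigs:
        return "chr1"
    raise ValueError("truths span several contigs; pass contig= for false-call placement")


def emulate_calls(
    truths: Sequence[TruthRecord],
    genome_length: int,
    profile: EmulatorProfile,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
    contig: Optional[str] = None,
) -> List[DeletionCall]:
    """Derive one caller's noisy deletion call set from the truth set.

    Insertion truths are never called (deletion callers only).  False calls
    are placed uniformly on ``contig`` (inferred when the truth set lives on
    a single contig), with per-bin Poisson counts at ``fp_per_mb``.
    Deterministic for a given seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    fp_contig = _default_contig(truths, contig)
    blocked = _truth_blocklist(truths, fp_contig)
    calls: List[DeletionCall] = []
    for truth in truths:
        if truth.sv_type != "DEL":
            continue
        b = find_bin(list(profile.recall_by_bin), truth.size)
        p = profile.recall_by_bin.get(b, 0.0) if b else 0.0
        u, z1, z2 = rng.random(), rng.standard_normal(), rng.standard_normal()
        if u < p:
            calls.append(_jittered_call(truth, profile, z1, z2))
    for size_bin, rate in profile.fp_per_mb.items():
        n_fp = int(rng.poisson(rate * genome_length / 1e6))
        for _ in range(n_fp):
            call = _fp_call(fp_contig, genome_length, size_bin, profile.caller, blocked, rng)
            if call is not None:
                calls.append(call)
    calls.sort(key=lambda c: (c.interval.contig, c.interval.start, c.interval.end))
    return calls


def emulate_depth_series(
    truths: Sequence[TruthRecord],
    genome_length: int,
    profile: EmulatorProfile,
    depths: Sequence[float],
    reference_depth: float = 30.0,
    seed: int = 0,
    contig: Optional[str] = None,
) -> Dict[float, List[DeletionCall]]:
    """Coverage series with noise inversely proportional to depth.

    At depth ``d`` the miss probability per bin is
    ``min(1, (1 - recall) * reference_depth / d)``, the false-call rate is
    ``fp_per_mb * reference_depth / d`` and the jitter sd scales with
    ``sqrt(reference_depth / d)``.  All depths share one set of random draws
    (common random numbers): detections are nested across depths and false
    calls are thinned as depth grows, so per-bin precision and recall — and
    hence F-measure — are non-decreasing in depth.
    """
    if any(d <= 0 for d in depths):
        raise ValueError("depths must be positive")
    rng = np.random.default_rng(seed)
    fp_contig = _default_contig(truths, contig)
    blocked = _truth_blocklist(truths, fp_contig)

    dels = [t for t in truths if t.sv_type == "DEL"]
    draws = [(rng.random(), rng.standard_normal(), rng.standard_normal()) for _ in dels]

    # false-call superset at the noisiest depth, each with a thinning mark
    d_min = min(depths)
    max_scale = reference_depth / d_min
    fp_pool: List[Tuple[float, DeletionCall]] = []
    for size_bin, rate in profile.fp_per_mb.items():
        n_max = int(rng.poisson(rate * max_scale * genome_length / 1e6))
        for _ in range(n_max):
            call = _fp_call(fp_contig, genome_length, size_bin, profile.caller, blocked, rng)
            if call is not None:
                fp_pool.append((rng.random(), call))

    series: Dict[float, List[DeletionCall]] = {}
    for depth in depths:
        scale = reference_depth / depth
        jitter = math.sqrt(scale)
        scaled = EmulatorProfile(
            caller=profile.caller,
            recall_by_bin={
                b: max(0.0, 1.0 - min(1.0, (1.0 - p) * scale))
                for b, p in profile.recall_by_bin.items()
            },
            fp_per_mb=profile.fp_per_mb,
            breakpoint_jitter_sd=profile.breakpoint_jitter_sd * jitter,
            size_jitter_sd=profile.size_jitter_sd * jitter,
        )
        calls: List[DeletionCall] = []
        for truth, (u, z1, z2) in zip(dels, draws):
            b = find_bin(list(scaled.recall_by_bin), truth.size)
            p = scaled.recall_by_bin.get(b, 0.0) if b else 0.0
            if u < p:
                calls.append(_jittered_call(truth, scaled, z1, z2))
        keep_fraction = scale / max_scale  # == d_min / depth
        for mark, call in fp_pool:
            if mark < keep_fraction:
                calls.append(call)
        calls.sort(key=lambda c: (c.interval.contig, c.interval.start, c.interval.end))
        series[depth] = calls
    return series
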