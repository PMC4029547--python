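"""Post-calling stages: per-caller size filtering and duplicate-removing merge.

Call sets from complementary callers (assembly-type callers for short
deletions, split-read for mid-range, read-pair for long) are first trimmed
to the size range in which each caller is trusted, then pooled.  Any pair of
pooled calls that reciprocally overlap by more than a fixed fraction of both
called regions (default 2/3) is treated as a duplicate, and the member with
the lower precision prior is discarded; what remains is a unified,
duplicate-free deletion list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .model import DeletionCall, PrecisionProfile, SizeBin, intersect_size

__all__ = [
    "FilterSpec",
    "MergeConfig",
    "UnknownCallerError",
    "default_filter_spec",
    "default_precision_profile",
    "filter_calls",
    "mutual_overlap_exceeds",
    "precision_of",
    "merge_callsets",
]

# Trusted size ranges (bp, inclusive) per caller, reflecting where each
# algorithm family keeps precision above ~90%: assembly (HC) below 100 bp,
# split-read (Pindel) 100 bp - 30 kb, read-pair (BD) above 1 kb.
DEFAULT_RANGES: Dict[str, Tuple[int, int]] = {
    "HC": (1, 100),
    "Pindel": (100, 30_000),
    "BD": (1_000, 1_000_000),
}

DEFAULT_CALLER_PRIORITY: Tuple[str, ...] = ("HC", "Pindel", "BD")

DEFAULT_OVERLAP_FRACTION = 2.0 / 3.0


class UnknownCallerError(KeyError):
    """A call's caller has no configured size range and unlisted callers are rejected."""


@dataclass(frozen=True)
class FilterSpec:
    """caller -> (min_size, max_size) inclusive; unlisted callers are rejected
    unless ``allow_unlisted`` is set (then they pass unfiltered)."""

    ranges: Dict[str, Tuple[int, int]]
    allow_unlisted: bool = False

    def __post_init__(self) -> None:
        for caller, (lo, hi) in self.ranges.items():
            if lo < 1 or lo > hi:
                raise ValueError(f"bad size range for {caller}: [{lo}, {hi}]")


def default_filter_spec() -> FilterSpec:
    return FilterSpec(ranges=dict(DEFAULT_RANGES))


def default_precision_profile() -> PrecisionProfile:
    """Simulation-calibrated priors for the default caller trio (configurable)."""
    return PrecisionProfile.from_rows(
        [
            ("HC", 1, 101, 0.97),
            ("Pindel", 100, 30_001, 0.95),
            ("BD", 1_000, 1_000_001, 0.93),
        ],
        default=0.0,
    )


@dataclass(frozen=True)
class MergeConfig:
    """Duplicate-removal parameters.

    ``overlap_fraction`` is the reciprocal-overlap threshold (strict: both
    calls must be covered by the intersection for *more* than this fraction).
    ``reciprocal=False`` switches to an either-side interpretation.  Ties in
    precision are broken by ``caller_priority`` order, then smaller start,
    then larger size, so merging is fully deterministic.
    """

    precision_profile: PrecisionProfile
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION
    caller_priority: Tuple[str, ...] = DEFAULT_CALLER_PRIORITY
    reciprocal: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in (0, 1]")


def filter_calls(calls: Sequence[DeletionCall], spec: FilterSpec) -> List[DeletionCall]:
    """Keep calls whose size lies in their caller's trusted range (inclusive)."""
    kept: List[DeletionCall] = []
    for call in calls:
        rng = spec.ranges.get(call.caller)
        if rng is None:
            if spec.allow_unlisted:
                kept.append(call)
                continue
            raise UnknownCallerError(
                f"caller {call.caller!r} has no configured size range "
                "(set allow_unlisted to pass such calls through)"
            )
        lo, hi = rng
        if lo <= call.size <= hi:
            kept.append(call)
    return kept


def mutual_overlap_exceeds(
    a: DeletionCall,
    b: DeletionCall,
    fraction: float = DEFAULT_OVERLAP_FRACTION,
    reciprocal: bool = True,
) -> bool:
    """True iff the calls overlap each other by strictly more than ``fraction``
    of their called regions (both regions when reciprocal, either otherwise)."""
    inter = intersect_size(a.interval, b.interval)
    if inter == 0:
        return False
    frac_a = inter > fraction * a.size
    frac_b = inter > fraction * b.size
    return (frac_a and frac_b) if reciprocal else (frac_a or frac_b)


def precision_of(call: DeletionCall, profile: PrecisionProfile) -> float:
    """Precision prior for the call's (caller, size) — profile default if unmapped."""
    return profile.lookup(call.caller, call.size)


def _canonical_key(c: DeletionCall):
    # total over all fields so pooling order cannot leak into the result
    return (
        c.interval.contig,
        c.interval.start,
        c.interval.end,
        c.caller,
        c.score if c.score is not None else float("-inf"),
        c.ploidy or "",
    )


def _keep_rank(c: DeletionCall, cfg: MergeConfig, pool_index: int):
    """Total order: the smaller rank of a duplicated pair survives."""
    try:
        prio = cfg.caller_priority.index(c.caller)
    except ValueError:
        prio = len(cfg.caller_priority)
    return (
        -precision_of(c, cfg.precision_profile),
        prio,
        c.caller,
        c.interval.start,
        -c.size,
        pool_index,
    )


def merge_callsets(
    callsets: Sequence[Sequence[DeletionCall]],
    cfg: MergeConfig,
) -> List[DeletionCall]:
    """Pool call sets and remove duplicated entries.

    Candidate pairs (those satisfying the overlap predicate) are processed in
    a fixed order — descending overlap size, then coordinates — and for each
    pair still alive the lower-precision member is discarded.  A discarded
    call takes part in no further comparisons.  The output therefore contains
    no pair satisfying the predicate, is sorted by (contig, start, end), and
    is independent of the order in which call sets (or calls) were supplied.
    """
    pool = sorted((c for cs in callsets for c in cs), key=_canonical_key)
    trees: dict[str, IntervalTree] = {}
    for i, c in enumerate(pool):
        trees.setdefault(c.interval.contig, IntervalTree()).addi(
            c.interval.start, c.interval.end, i
        )

    pairs = []  # (-overlap, key_i, key_j, i, j)
    for i, c in enumerate(pool):
        for hit in trees[c.interval.contig].overlap(c.interval.start, c.interval.end):
            j = hit.data
            if j <= i:
                continue
            other = pool[j]
            if mutual_overlap_exceeds(c, other, cfg.overlap_fraction, cfg.reciprocal):
                overlap = intersect_size(c.interval, other.interval)
                pairs.append((-overlap, _canonical_key(c), _canonical_key(other), i, j))
    pairs.sort(key=lambda p: p[:3])

    alive = [True] * len(pool)
    for _neg_overlap, _ka, _kb, i, j in pairs:
        if not (alive[i] and alive[j]):
            continue
        loser = max(i, j, key=lambda k: _keep_rank(pool[k], cfg, k))
        alive[loser] = False

    survivors = [c for c, ok in zip(pool, alive) if ok]
    survivors.sort(key=lambda c: (c.interval.contig, c.interval.start, c.interval.end))
    return survivors
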