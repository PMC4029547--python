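"""Independent brute-force oracles used to cross-check the implementation.

Everything here works by materializing position sets or enumerating all
pairs — deliberately naive, sharing no code with the library's indexed
paths.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Set, Tuple

from svunify.model import DeletionCall, GenomicInterval, SizeBin, TruthRecord


def positions(interval: GenomicInterval) -> Set[Tuple[str, int]]:
    return {(interval.contig, p) for p in range(interval.start, interval.end)}


def brute_intersect(a: GenomicInterval, b: GenomicInterval) -> int:
    return len(positions(a) & positions(b))


def brute_union(a: GenomicInterval, b: GenomicInterval) -> int:
    return len(positions(a) | positions(b))


def brute_effective(interval: GenomicInterval, margin: int) -> Set[Tuple[str, int]]:
    return {
        (interval.contig, p)
        for p in range(max(0, interval.start - margin), interval.end + margin)
    }


def brute_quality(a: GenomicInterval, b: GenomicInterval, margin: int) -> float:
    ea, eb = brute_effective(a, margin), brute_effective(b, margin)
    inter = len(ea & eb)
    return inter / len(ea | eb) if inter else 0.0


def brute_precision_recall(
    calls: Sequence[DeletionCall],
    truths: Sequence[TruthRecord],
    margin: int,
    bins: Sequence[SizeBin],
) -> Tuple[Dict[SizeBin, float], Dict[SizeBin, float]]:
    """All-pairs per-bin precision and recall (missing bins omitted)."""
    dels = [t for t in truths if t.sv_type == "DEL"]
    eff_call = [brute_effective(c.interval, margin) for c in calls]
    eff_del = [brute_effective(t.interval, margin) for t in dels]

    def jac(a: Set[Tuple[str, int]], b: Set[Tuple[str, int]]) -> float:
        inter = len(a & b)
        return inter / len(a | b) if inter else 0.0

    precision: Dict[SizeBin, float] = {}
    recall: Dict[SizeBin, float] = {}
    for size_bin in bins:
        in_bin = [i for i, c in enumerate(calls) if size_bin.contains(c.size)]
        if in_bin:
            total = sum(
                max((jac(eff_call[i], e) for e in eff_del), default=0.0) for i in in_bin
            )
            precision[size_bin] = total / len(in_bin)
        t_in_bin = [j for j, t in enumerate(dels) if size_bin.contains(t.size)]
        if t_in_bin:
            total = sum(
                max((jac(eff_del[j], e) for e in eff_call), default=0.0) for j in t_in_bin
            )
            recall[size_bin] = total / len(t_in_bin)
    return precision, recall


def brute_merge(
    pool: Sequence[DeletionCall],
    overlap_fraction: float,
    precision_lookup,
    caller_priority: Sequence[str],
) -> List[DeletionCall]:
    """Fixed-point duplicate removal by naive pair enumeration.

    Re-scans all alive pairs each round in the canonical order (largest
    overlap first, then coordinates), removing the lower-precision member,
    until no pair satisfies the predicate.
    """

    def overlap(a: DeletionCall, b: DeletionCall) -> int:
        if a.interval.contig != b.interval.contig:
            return 0
        return max(
            0, min(a.interval.end, b.interval.end) - max(a.interval.start, b.interval.start)
        )

    def is_dup(a: DeletionCall, b: DeletionCall) -> bool:
        ov = overlap(a, b)
        return ov > overlap_fraction * a.size and ov > overlap_fraction * b.size

    def sort_key(c: DeletionCall):
        return (
            c.interval.contig,
            c.interval.start,
            c.interval.end,
            c.caller,
            c.score if c.score is not None else float("-inf"),
            c.ploidy or "",
        )

    def keep_rank(c: DeletionCall, idx: int):
        try:
            prio = list(caller_priority).index(c.caller)
        except ValueError:
            prio = len(caller_priority)
        return (-precision_lookup(c), prio, c.caller, c.interval.start, -c.size, idx)

    alive = sorted(pool, key=sort_key)
    while True:
        pairs = []
        for i in range(len(alive)):
            for j in range(i + 1, len(alive)):
                if is_dup(alive[i], alive[j]):
                    pairs.append(
                        (-overlap(alive[i], alive[j]), sort_key(alive[i]), sort_key(alive[j]), i, j)
                    )
        if not pairs:
            break
        pairs.sort(key=lambda p: p[:3])
        _, _, _, i, j = pairs[0]
        loser = max((i, j), key=lambda k: keep_rank(alive[k], k))
        alive = [c for k, c in enumerate(alive) if k != loser]
    alive.sort(key=lambda c: (c.interval.contig, c.interval.start, c.interval.end))
    return alive
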