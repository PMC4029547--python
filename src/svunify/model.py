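"""Core domain types and exact interval arithmetic.

All coordinates are 0-based half-open (BED convention); VCF's 1-based
inclusive positions are converted at the I/O boundary.  A 1-bp deletion is a
length-1 interval — zero-length intervals are invalid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

__all__ = [
    "GenomicInterval",
    "DeletionCall",
    "TruthRecord",
    "SizeBin",
    "PrecisionProfile",
    "EvaluationReport",
    "BinStats",
    "DEFAULT_BIN_EDGES",
    "make_bins",
    "intersect_size",
    "union_size",
]

DEFAULT_BIN_EDGES: Tuple[int, ...] = (1, 10, 100, 1_000, 10_000, 100_000, 1_000_000)


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A contig-anchored half-open span ``[start, end)`` in base pairs."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end}): "
                "zero-length intervals are rejected"
            )

    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.contig}:{self.start}-{self.end}"


def intersect_size(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of base pairs covered by both intervals (0 across contigs)."""
    if a.contig != b.contig:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def union_size(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of base pairs covered by either interval.

    Cross-contig unions are defined as ``len(a) + len(b)`` (the intervals
    cannot overlap), so inclusion–exclusion holds unconditionally.
    """
    return a.length() + b.length() - intersect_size(a, b)


@dataclass(frozen=True, slots=True)
class DeletionCall:
    """One caller's assertion that ``interval`` is deleted from the sample.

    ``size`` always equals the interval length; ``score`` is the caller-native
    confidence when available, and ``ploidy`` a genotype tag for assembly-type
    callers that estimate it.
    """

    interval: GenomicInterval
    caller: str
    size: int = -1  # -1 sentinel: filled from the interval in __post_init__
    score: Optional[float] = None
    ploidy: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.caller:
            raise ValueError("caller must be non-empty")
        if self.size == -1:
            object.__setattr__(self, "size", self.interval.length())
        elif self.size != self.interval.length():
            raise ValueError(
                f"size {self.size} != interval length {self.interval.length()}"
            )


@dataclass(frozen=True, slots=True)
class TruthRecord:
    """A prepared (ground-truth) SV in reference coordinates.

    Deletions span their deleted region.  Insertions are anchored at a single
    reference base (length-1 interval) and carry the inserted sequence; their
    ``size`` is the inserted length.
    """

    interval: GenomicInterval
    sv_type: str
    size: int = -1
    inserted_sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sv_type not in ("DEL", "INS"):
            raise ValueError(f"sv_type must be DEL or INS, got {self.sv_type!r}")
        if self.sv_type == "DEL":
            if self.inserted_sequence is not None:
                raise ValueError("DEL records carry no inserted sequence")
            if self.size == -1:
                object.__setattr__(self, "size", self.interval.length())
            elif self.size != self.interval.length():
                raise ValueError("DEL size must equal interval length")
        else:
            if self.inserted_sequence is None:
                raise ValueError("INS records require inserted_sequence")
            if self.interval.length() != 1:
                raise ValueError("INS anchor must be a length-1 interval")
            if self.size == -1:
                object.__setattr__(self, "size", len(self.inserted_sequence))
            elif self.size != len(self.inserted_sequence):
                raise ValueError("INS size must equal inserted sequence length")


@dataclass(frozen=True, slots=True)
class SizeBin:
    """Half-open size range ``[low, high)`` in bp."""

    low: int
    high: int

    def __post_init__(self) -> None:
        if self.low < 1:
            raise ValueError("bin low bound must be >= 1")
        if self.low >= self.high:
            raise ValueError(f"invalid bin [{self.low}, {self.high})")

    def contains(self, size: int) -> bool:
        return self.low <= size < self.high

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.low},{self.high})"


def make_bins(edges: Sequence[int] = DEFAULT_BIN_EDGES) -> Tuple[SizeBin, ...]:
    """Build a gap-free, overlap-free bin scheme from ascending edges."""
    if len(edges) < 2:
        raise ValueError("need at least two bin edges")
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError(f"bin edges must be strictly ascending: {edges}")
    return tuple(SizeBin(a, b) for a, b in zip(edges, edges[1:]))


def find_bin(bins: Sequence[SizeBin], size: int) -> Optional[SizeBin]:
    """The unique bin containing ``size``, or None if outside the scheme."""
    for b in bins:
        if b.contains(size):
            return b
    return None


class PrecisionProfile:
    """Per-caller, per-size-bin precision estimates used as merge priors.

    The values play the role of prior beliefs, calibrated from simulation,
    about how trustworthy a call of a given size from a given caller is; the
    merge step keeps the higher-precision member of a duplicated pair.
    """

    def __init__(
        self,
        entries: Mapping[str, Mapping[SizeBin, float]] | None = None,
        default: float = 0.0,
    ) -> None:
        if not 0.0 <= default <= 1.0:
            raise ValueError("default precision must lie in [0, 1]")
        self.default = default
        self._entries: dict[str, dict[SizeBin, float]] = {}
        if entries:
            for caller, by_bin in entries.items():
                for b, p in by_bin.items():
                    self.set(caller, b, p)

    def set(self, caller: str, size_bin: SizeBin, precision: float) -> None:
        if not 0.0 <= precision <= 1.0:
            raise ValueError(f"precision {precision} outside [0, 1]")
        by_bin = self._entries.setdefault(caller, {})
        for existing in by_bin:
            if existing is not size_bin and (
                existing.low < size_bin.high and size_bin.low < existing.high
            ):
                if existing != size_bin:
                    raise ValueError(
                        f"overlapping bins for {caller}: {existing} vs {size_bin}"
                    )
        by_bin[size_bin] = precision

    def lookup(self, caller: str, size: int) -> float:
        """Precision for a call of ``size`` bp from ``caller`` (default if unmapped)."""
        if size < 1:
            raise ValueError("size must be >= 1")
        for b, p in self._entries.get(caller, {}).items():
            if b.contains(size):
                return p
        return self.default

    @property
    def callers(self) -> Tuple[str, ...]:
        return tuple(self._entries)

    @classmethod
    def from_rows(
        cls,
        rows: Iterable[Tuple[str, int, int, float]],
        default: float = 0.0,
    ) -> "PrecisionProfile":
        """Build from ``(caller, low, high, precision)`` rows (half-open bins)."""
        profile = cls(default=default)
        for caller, low, high, precision in rows:
            profile.set(caller, SizeBin(int(low), int(high)), float(precision))
        return profile


@dataclass(frozen=True, slots=True)
class BinStats:
    """Per-bin evaluation numbers; precision/recall are None for empty denominators."""

    bin: SizeBin
    n_called: int
    n_prepared: int
    precision: Optional[float]
    recall: Optional[float]
    f_measure: Optional[float]


class EvaluationReport:
    """Size-stratified precision / recall / F-measure with call counts."""

    def __init__(self, rows: Sequence[BinStats]):
        self.rows: Tuple[BinStats, ...] = tuple(rows)
        for r in self.rows:
            if (r.precision is None) != (r.n_called == 0):
                raise ValueError("precision undefined iff no calls in bin")
            if (r.recall is None) != (r.n_prepared == 0):
                raise ValueError("recall undefined iff no truths in bin")

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def row(self, size_bin: SizeBin) -> BinStats:
        for r in self.rows:
            if r.bin == size_bin:
                return r
        raise KeyError(str(size_bin))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "bin_low": [r.bin.low for r in self.rows],
                "bin_high": [r.bin.high for r in self.rows],
                "n_called": [r.n_called for r in self.rows],
                "n_prepared": [r.n_prepared for r in self.rows],
                "precision": [r.precision for r in self.rows],
                "recall": [r.recall for r in self.rows],
                "f_measure": [r.f_measure for r in self.rows],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, na_rep="NA")
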