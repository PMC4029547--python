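"""Readers and writers normalizing caller output and pipeline artifacts.

Internal coordinates are 0-based half-open throughout; VCF's 1-based,
padding-base convention is converted here and nowhere else.  Contig names
are taken verbatim (no "chr" normalization): a contig-name mismatch
between call sets is the user's to resolve, and silently coercing names
would hide it.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import DeletionCall, GenomicInterval, TruthRecord
from .simulator import ReadPair

__all__ = [
    "CallsetSource",
    "VcfReadStats",
    "read_callset",
    "read_deletions_vcf",
    "read_deletions_bed",
    "read_truth_bed",
    "write_calls_bed",
    "write_truth_bed",
    "write_merged_bed",
    "write_deletions_vcf",
    "read_fasta",
    "write_fasta",
    "write_paired_fastq",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CallsetSource:
    """One caller's output file; format by extension unless given explicitly."""

    path: Union[str, Path]
    caller: str
    format: Optional[str] = None  # "vcf" | "bed" | None -> by extension

    def __post_init__(self) -> None:
        if not self.caller:
            raise ValueError("caller must be non-empty")
        if self.format is not None and self.format.lower() not in ("vcf", "bed"):
            raise ValueError(f"unsupported format {self.format!r}")

    def resolved_format(self) -> str:
        if self.format:
            return self.format.lower()
        name = str(self.path).lower()
        for suffix in (".gz", ".bgz"):
            if name.endswith(suffix):
                name = name[: -len(suffix)]
        if name.endswith(".vcf"):
            return "vcf"
        if name.endswith(".bed") or name.endswith(".tsv"):
            return "bed"
        raise ValueError(f"cannot infer format of {self.path}; pass format=")


def read_callset(source: CallsetSource) -> List[DeletionCall]:
    if source.resolved_format() == "vcf":
        calls, _ = read_deletions_vcf(source.path, source.caller)
        return calls
    return read_deletions_bed(source.path, caller=source.caller)


@dataclass
class VcfReadStats:
    """Per-file counters of records kept and why others were dropped."""

    kept: int = 0
    non_deletion: int = 0
    filtered: int = 0
    svlen_end_mismatch: int = 0


def _vcf_deletion_from_allele(
    rec, alt: str, caller: str, line_hint: str
) -> Optional[DeletionCall]:
    """One ALT allele -> DeletionCall, or None for a non-deletion allele."""
    pos0 = rec.start  # pysam: 0-based position of POS
    svlen = rec.info.get("SVLEN", None)
    if isinstance(svlen, (tuple, list)):
        svlen = svlen[0]

    if alt == "<DEL>":
        end0 = rec.stop  # pysam: END as 0-based exclusive
        if end0 <= pos0 + 1:
            raise ValueError(f"END before POS at {line_hint}")
        size = int(abs(svlen)) if svlen is not None else end0 - (pos0 + 1)
        if svlen is not None and size != end0 - (pos0 + 1):
            # SVLEN wins; rebuild the end from it
            end0 = pos0 + 1 + size
        interval = GenomicInterval(rec.contig, pos0 + 1, end0)
        call = DeletionCall(
            interval=interval,
            caller=caller,
            size=size,
            score=rec.qual if rec.qual is not None else None,
        )
        return call
    if alt.startswith("<"):
        return None  # other symbolic SV type
    ref = rec.ref or ""
    if len(ref) <= len(alt):
        return None  # SNV, insertion, or MNV
    if ref[0].upper() != alt[0].upper():
        return None  # no shared padding base: complex substitution
    # padding-base convention: the retained prefix is len(alt) bases long,
    # the remainder of REF is the deleted span
    size = len(ref) - len(alt)
    interval = GenomicInterval(rec.contig, pos0 + len(alt), pos0 + len(ref))
    return DeletionCall(
        interval=interval,
        caller=caller,
        size=size,
        score=rec.qual if rec.qual is not None else None,
    )


def read_deletions_vcf(
    path: Union[str, Path], caller: str
) -> Tuple[List[DeletionCall], VcfReadStats]:
    """Deletion records from a VCF (plain or bgzip).

    Keeps symbolic ``<DEL>`` records and sequence-resolved deletions (REF
    longer than ALT, shared leading base).  Multi-allelic records are split
    and non-deletion alleles dropped.  Records failing FILTER (anything but
    PASS or missing) are dropped and counted.
    """
    stats = VcfReadStats()
    calls: List[DeletionCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            line_hint = f"{rec.contig}:{rec.pos}"
            filters = list(rec.filter.keys())
            if filters and filters != ["PASS"]:
                stats.filtered += 1
                continue
            emitted = False
            for alt in rec.alts or ():
                try:
                    call = _vcf_deletion_from_allele(rec, alt, caller, line_hint)
                except ValueError as exc:
                    raise ValueError(f"malformed VCF record at {line_hint}: {exc}") from exc
                if call is not None:
                    svlen = rec.info.get("SVLEN", None)
                    if isinstance(svlen, (tuple, list)):
                        svlen = svlen[0]
                    if (
                        alt == "<DEL>"
                        and svlen is not None
                        and int(abs(svlen)) != rec.stop - (rec.start + 1)
                    ):
                        stats.svlen_end_mismatch += 1
                        logger.warning(
                            "SVLEN and END disagree at %s; using SVLEN", line_hint
                        )
                    calls.append(call)
                    emitted = True
            if emitted:
                stats.kept += 1
            else:
                stats.non_deletion += 1
    return calls, stats


def _parse_bed_line(line: str, lineno: int, path) -> Optional[List[str]]:
    line = line.rstrip("\n")
    if not line or line.startswith(("#", "track", "browser")):
        return None
    fields = line.split("\t")
    if len(fields) < 3:
        raise ValueError(f"{path}:{lineno}: BED line needs >= 3 columns")
    return fields


def _bed_interval(fields: Sequence[str], lineno: int, path) -> GenomicInterval:
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
    if start < 0 or start >= end:
        raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
    return GenomicInterval(fields[0], start, end)


def read_deletions_bed(
    path: Union[str, Path], caller: Optional[str] = None
) -> List[DeletionCall]:
    """Deletion calls from a BED file (column 4 caller/label, column 5 score).

    ``caller`` overrides column 4 (and is required when the column is absent).
    """
    calls: List[DeletionCall] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            fields = _parse_bed_line(line, lineno, path)
            if fields is None:
                continue
            interval = _bed_interval(fields, lineno, path)
            name = caller or (fields[3] if len(fields) > 3 else "")
            if not name:
                raise ValueError(f"{path}:{lineno}: no caller column; pass caller=")
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            ploidy = fields[6] if len(fields) > 6 and fields[6] != "." else None
            calls.append(
                DeletionCall(interval=interval, caller=name, score=score, ploidy=ploidy)
            )
    return calls


def write_calls_bed(calls: Sequence[DeletionCall], path: Union[str, Path]) -> None:
    """contig, start, end, caller, score, size [, ploidy]."""
    with open(path, "w") as out:
        for c in calls:
            row = [
                c.interval.contig,
                str(c.interval.start),
                str(c.interval.end),
                c.caller,
                "." if c.score is None else f"{c.score:g}",
                str(c.size),
            ]
            if c.ploidy is not None:
                row.append(c.ploidy)
            out.write("\t".join(row) + "\n")


def write_merged_bed(
    calls: Sequence[DeletionCall],
    path: Union[str, Path],
    precision_lookup=None,
) -> None:
    """Unified extended BED: contig, start, end, caller, precision prior, size.

    ``precision_lookup(call) -> float`` supplies the prior column (written to
    3 decimals; "." when no lookup is given).  A ploidy column is appended
    when any call carries one.
    """
    any_ploidy = any(c.ploidy is not None for c in calls)
    with open(path, "w") as out:
        for c in calls:
            prior = "." if precision_lookup is None else f"{precision_lookup(c):.3f}"
            row = [
                c.interval.contig,
                str(c.interval.start),
                str(c.interval.end),
                c.caller,
                prior,
                str(c.size),
            ]
            if any_ploidy:
                row.append(c.ploidy if c.ploidy is not None else ".")
            out.write("\t".join(row) + "\n")


def write_truth_bed(truths: Sequence[TruthRecord], path: Union[str, Path]) -> None:
    """contig, start, end, sv_type, size, inserted sequence ("." for DEL)."""
    with open(path, "w") as out:
        for t in truths:
            out.write(
                "\t".join(
                    [
                        t.interval.contig,
                        str(t.interval.start),
                        str(t.interval.end),
                        t.sv_type,
                        str(t.size),
                        t.inserted_sequence or ".",
                    ]
                )
                + "\n"
            )


def read_truth_bed(path: Union[str, Path]) -> List[TruthRecord]:
    truths: List[TruthRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            fields = _parse_bed_line(line, lineno, path)
            if fields is None:
                continue
            interval = _bed_interval(fields, lineno, path)
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: truth BED needs an sv_type column")
            sv_type = fields[3]
            seq = fields[5] if len(fields) > 5 and fields[5] != "." else None
            truths.append(
                TruthRecord(interval=interval, sv_type=sv_type, inserted_sequence=seq)
            )
    return truths


def read_fasta(path: Union[str, Path]) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: Union[str, Path]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_paired_fastq(
    pairs: Iterable[ReadPair], prefix: Union[str, Path]
) -> Tuple[Path, Path]:
    """Write mates to ``<prefix>_1.fastq.gz`` / ``<prefix>_2.fastq.gz`` in lockstep."""
    prefix = Path(prefix)
    path1 = prefix.parent / (prefix.name + "_1.fastq.gz")
    path2 = prefix.parent / (prefix.name + "_2.fastq.gz")
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with gzip.open(path1, "wt", compresslevel=2) as out1, gzip.open(
        path2, "wt", compresslevel=2
    ) as out2:
        for pair in pairs:
            out1.write(f"@{pair.name}/1\n{pair.seq1}\n+\n{pair.quality}\n")
            out2.write(f"@{pair.name}/2\n{pair.seq2}\n+\n{pair.quality}\n")
    return path1, path2


def write_deletions_vcf(
    calls: Sequence[DeletionCall],
    contig_lengths: Mapping[str, int],
    path: Union[str, Path],
) -> None:
    """Symbolic ``<DEL>`` VCF with END and SVLEN, for interchange with SV tools."""
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">')
    header.add_line(
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length (negative for deletions)">'
    )
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    header.add_line('##INFO=<ID=CALLER,Number=1,Type=String,Description="Source caller">')
    header.add_line('##ALT=<ID=DEL,Description="Deletion">')
    for contig, length in contig_lengths.items():
        header.add_line(f"##contig=<ID={contig},length={length}>")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in sorted(calls, key=lambda x: (x.interval.contig, x.interval.start)):
            # padding base sits just before the deleted span
            rec = out.new_record(
                contig=c.interval.contig,
                start=c.interval.start - 1 if c.interval.start > 0 else 0,
                alleles=("N", "<DEL>"),
            )
            rec.stop = c.interval.end
            rec.info["SVTYPE"] = "DEL"
            rec.info["SVLEN"] = -c.size
            rec.info["CALLER"] = c.caller
            if c.score is not None:
                rec.qual = c.score
            out.write(rec)
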