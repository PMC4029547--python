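"""End-to-end orchestration: simulate -> emulate -> filter -> merge -> evaluate.

One TOML/INI-style config drives every stage; a global seed feeds a
hierarchy of stage-salted generators, so adding a stage never shifts
another stage's random stream.  Every run writes a manifest (config
snapshot, seeds, output checksums) sufficient to reproduce it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from . import __version__
from .emulator import EmulatorProfile, emulate_calls
from .evaluation import EvaluationConfig, evaluate
from .filter_merge import (
    FilterSpec,
    MergeConfig,
    default_filter_spec,
    default_precision_profile,
    filter_calls,
    merge_callsets,
    precision_of,
)
from .io import (
    read_fasta,
    write_calls_bed,
    write_fasta,
    write_merged_bed,
    write_paired_fastq,
    write_truth_bed,
)
from .model import (
    DEFAULT_BIN_EDGES,
    DeletionCall,
    EvaluationReport,
    PrecisionProfile,
    TruthRecord,
    make_bins,
)
from .simulator import SimulationConfig, inject_svs, random_reference, simulate_reads

__all__ = [
    "PipelineResult",
    "StageError",
    "default_run_config",
    "stage_rng",
    "run_end_to_end",
]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Stage-name-salted generator: independent streams per stage under one seed."""
    salt = zlib.crc32(stage.encode()) & 0x7FFFFFFF
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, salt])


def default_run_config() -> Dict:
    """A complete, runnable configuration (the defaults of every stage).

    Three emulated callers mirror the algorithm families the pipeline
    integrates: an assembly-type caller strong below 100 bp, a split-read
    caller covering 100 bp – 30 kb, and a read-pair caller above 1 kb.
    """
    return {
        "seed": 0,
        "simulation": {
            "reference_length": 5_000_000,
            "n_sv": 300,
            "max_size": 100_000,
            "del_fraction": 0.5,
            "depth": 30.0,
            "read_length": 100,
            "insert_mean": 350.0,
            "insert_sd": 50.0,
            "error_rate": 0.001,
            "write_reads": False,
            "write_genomes": True,
        },
        "evaluation": {"margin": 50, "bin_edges": list(DEFAULT_BIN_EDGES)},
        "filter": {
            "allow_unlisted": False,
            "ranges": {"HC": [1, 100], "Pindel": [100, 30_000], "BD": [1_000, 1_000_000]},
        },
        "merge": {
            "overlap_fraction": 2.0 / 3.0,
            "caller_priority": ["HC", "Pindel", "BD"],
            "reciprocal": True,
            "precision_default": 0.0,
            "precision_table": [
                ["HC", 1, 101, 0.97],
                ["Pindel", 100, 30_001, 0.95],
                ["BD", 1_000, 1_000_001, 0.93],
            ],
        },
        "callers": {
            "HC": {
                "recall": [[1, 101, 0.95]],
                "fp_per_mb": [[1, 101, 0.5]],
                "breakpoint_jitter_sd": 0.0,
                "size_jitter_sd": 0.0,
            },
            "Pindel": {
                "recall": [[100, 30_001, 0.92]],
                "fp_per_mb": [[100, 30_001, 0.3]],
                "breakpoint_jitter_sd": 2.0,
                "size_jitter_sd": 2.0,
            },
            "BD": {
                "recall": [[1_000, 1_000_001, 0.90]],
                "fp_per_mb": [[1_000, 1_000_001, 0.3]],
                "breakpoint_jitter_sd": 10.0,
                "size_jitter_sd": 10.0,
            },
        },
    }


def _simulation_config(section: Mapping, seed: int) -> SimulationConfig:
    return SimulationConfig(
        n_sv=int(section.get("n_sv", 300)),
        del_fraction=float(section.get("del_fraction", 0.5)),
        min_size=int(section.get("min_size", 1)),
        max_size=int(section.get("max_size", 1_000_000)),
        size_table=[tuple(row) for row in section["size_table"]]
        if "size_table" in section
        else None,
        read_length=int(section.get("read_length", 100)),
        insert_mean=float(section.get("insert_mean", 350.0)),
        insert_sd=float(section.get("insert_sd", 50.0)),
        error_rate=float(section.get("error_rate", 0.001)),
        depth=float(section.get("depth", 30.0)),
        seed=seed,
    )


def filter_spec_from_config(section: Mapping) -> FilterSpec:
    if "ranges" not in section:
        return default_filter_spec()
    return FilterSpec(
        ranges={c: (int(lo), int(hi)) for c, (lo, hi) in section["ranges"].items()},
        allow_unlisted=bool(section.get("allow_unlisted", False)),
    )


def merge_config_from_config(section: Mapping) -> MergeConfig:
    if "precision_table" in section:
        profile = PrecisionProfile.from_rows(
            [tuple(row) for row in section["precision_table"]],
            default=float(section.get("precision_default", 0.0)),
        )
    else:
        profile = default_precision_profile()
    return MergeConfig(
        precision_profile=profile,
        overlap_fraction=float(section.get("overlap_fraction", 2.0 / 3.0)),
        caller_priority=tuple(section.get("caller_priority", ("HC", "Pindel", "BD"))),
        reciprocal=bool(section.get("reciprocal", True)),
    )


def evaluation_config_from_config(section: Mapping) -> EvaluationConfig:
    return EvaluationConfig(
        margin=int(section.get("margin", 50)),
        bins=make_bins(section.get("bin_edges", DEFAULT_BIN_EDGES)),
    )


def emulator_profile_from_config(caller: str, section: Mapping) -> EmulatorProfile:
    return EmulatorProfile.from_rows(
        caller=caller,
        recall_rows=[tuple(row) for row in section.get("recall", [])],
        fp_rows=[tuple(row) for row in section.get("fp_per_mb", [])],
        breakpoint_jitter_sd=float(section.get("breakpoint_jitter_sd", 0.0)),
        size_jitter_sd=float(section.get("size_jitter_sd", 0.0)),
    )


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for block in iter(lambda: handle.read(1 << 20), b""):
            digest.update(block)
    return digest.hexdigest()


@dataclass
class PipelineResult:
    truths: List[TruthRecord]
    callsets: Dict[str, List[DeletionCall]]
    filtered: Dict[str, List[DeletionCall]]
    merged: List[DeletionCall]
    report: EvaluationReport
    out_dir: Path
    manifest_path: Path


def run_end_to_end(
    config: Mapping,
    out_dir: Path,
    seed: Optional[int] = None,
) -> PipelineResult:
    """Run simulate -> emulate-per-caller -> filter -> merge -> evaluate.

    Writes, under ``out_dir``: reference/mutated FASTA (optional), truth BED,
    raw and filtered per-caller BEDs, the unified merged BED, the evaluation
    TSV and a JSON run manifest.  ``seed`` overrides the config's seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0)) if seed is None else int(seed)
    outputs: Dict[str, Path] = {}
    inputs: Dict[str, str] = {}
    stage_seeds: Dict[str, str] = {}

    sim_section = config.get("simulation", {})
    stage = "simulate"
    try:
        rng = stage_rng(seed, stage)
        stage_seeds[stage] = f"{seed}:{stage}"
        sim_cfg = _simulation_config(sim_section, seed)
        if "reference" in sim_section:
            ref_path = Path(sim_section["reference"])
            reference = read_fasta(ref_path)
            inputs[str(ref_path)] = _sha256(ref_path)
        else:
            length = int(sim_section.get("reference_length", 2_000_000))
            reference = random_reference(length, seed=int(rng.integers(0, 2**31)))
        mutated, truths = inject_svs(reference, sim_cfg, rng=rng)
        truth_path = out_dir / "truth.bed"
        write_truth_bed(truths, truth_path)
        outputs["truth_bed"] = truth_path
        if bool(sim_section.get("write_genomes", True)):
            ref_out = out_dir / "reference.fa"
            mut_out = out_dir / "mutated.fa"
            write_fasta(reference, ref_out)
            write_fasta(mutated, mut_out)
            outputs["reference_fasta"] = ref_out
            outputs["mutated_fasta"] = mut_out
        if bool(sim_section.get("write_reads", False)):
            reads_rng = stage_rng(seed, "simulate-reads")
            pairs = simulate_reads(mutated, sim_cfg, rng=reads_rng)
            fq1, fq2 = write_paired_fastq(pairs, out_dir / "reads")
            outputs["fastq_1"], outputs["fastq_2"] = fq1, fq2
        genome_length = sum(len(s) for s in reference.values())
    except Exception as exc:  # noqa: BLE001 - wrap with stage context
        raise StageError(stage, exc) from exc

    stage = "emulate"
    callsets: Dict[str, List[DeletionCall]] = {}
    try:
        for caller, section in config.get("callers", {}).items():
            profile = emulator_profile_from_config(caller, section)
            rng = stage_rng(seed, f"emulate:{caller}")
            stage_seeds[f"emulate:{caller}"] = f"{seed}:emulate:{caller}"
            calls = emulate_calls(truths, genome_length, profile, rng=rng)
            callsets[caller] = calls
            raw_path = out_dir / f"calls.{caller}.bed"
            write_calls_bed(calls, raw_path)
            outputs[f"calls_{caller}"] = raw_path
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "filter"
    try:
        spec = filter_spec_from_config(config.get("filter", {}))
        filtered = {caller: filter_calls(calls, spec) for caller, calls in callsets.items()}
        for caller, calls in filtered.items():
            path = out_dir / f"filtered.{caller}.bed"
            write_calls_bed(calls, path)
            outputs[f"filtered_{caller}"] = path
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "merge"
    try:
        merge_cfg = merge_config_from_config(config.get("merge", {}))
        merged = merge_callsets(list(filtered.values()), merge_cfg)
        merged_path = out_dir / "merged.bed"
        write_merged_bed(
            merged,
            merged_path,
            precision_lookup=lambda c: precision_of(c, merge_cfg.precision_profile),
        )
        outputs["merged_bed"] = merged_path
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "evaluate"
    try:
        eval_cfg = evaluation_config_from_config(config.get("evaluation", {}))
        report = evaluate(merged, truths, eval_cfg)
        report_path = out_dir / "report.tsv"
        report.write_tsv(report_path)
        outputs["report_tsv"] = report_path
    except Exception as exc:
        raise StageError(stage, exc) from exc

    manifest = {
        "tool": "svunify",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "stage_seeds": stage_seeds,
        "config": json.loads(json.dumps(config, default=str)),
        "inputs": inputs,
        "outputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in outputs.items()},
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")

    return PipelineResult(
        truths=truths,
        callsets=callsets,
        filtered=filtered,
        merged=merged,
        report=report,
        out_dir=out_dir,
        manifest_path=manifest_path,
    )
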