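"""End-to-end pipeline: trim -> demux -> merge -> classify -> (calibrate)
-> normalise, driven by a single config with one global seed.

The global seed is expanded deterministically into per-stage substreams via
``numpy.random.SeedSequence``, so a config re-run reproduces byte-identical
count tables and manifests.  Every stage logs its read conservation (input
= output + discarded) into the run manifest; no reads are dropped silently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .calibrate import apply_bias_correction, estimate_bias
from .classify import build_diagnostics, count_splice_forms
from .core import (
    AmpliconDesign,
    ReadPair,
    SpliceForm,
    SpliceFormCountTable,
    default_design,
    read_fastq,
)
from .demux import demultiplex, trim_pairs
from .merge import merge_batch
from .quantify import pool_normalize
from .simulate import (
    MixtureManifest,
    PcrBiasSpec,
    default_spikein_manifests,
    simulate_readset,
    simulate_spikein_run,
)

logger = logging.getLogger("splicequant")

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    design: AmpliconDesign
    # either simulate parameters or FASTQ inputs
    simulate: dict | None = None
    fastq_r1: str | None = None
    fastq_r2: str | None = None
    single_end: bool = False
    # stage parameters
    quality_cutoff: int = 0
    adapters: list[str] = field(default_factory=list)
    trim_error_rate: float = 0.1
    demux_error_rate: float = 0.15
    # anchored barcode search window (slack around the expected offset);
    # None searches whole reads, which in 300-nt reads is tie-prone
    demux_window: int | None = 2
    barcode_read: str = "r2"
    min_overlap: int = 10
    max_mismatch_ratio: float = 0.25
    classify_error_rate: float = 0.10
    flank: int = 10
    both_strands: bool = True
    calibrate_spikein: bool = False
    spikein_reads_per_mixture: int = 20000
    pool_assignment: dict[str, str] | None = None
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        for name, rate in (
            ("trim_error_rate", self.trim_error_rate),
            ("demux_error_rate", self.demux_error_rate),
            ("classify_error_rate", self.classify_error_rate),
        ):
            if not (0.0 <= rate < 1.0):
                raise PipelineError("config", f"{name} must be in [0, 1), got {rate}")
        if not (0.0 <= self.max_mismatch_ratio <= 1.0):
            raise PipelineError("config", "max_mismatch_ratio must be in [0, 1]")
        if self.quality_cutoff < 0:
            raise PipelineError("config", "quality_cutoff must be >= 0")
        if self.simulate is None and self.fastq_r1 is None:
            raise PipelineError(
                "config", "either a simulate block or FASTQ inputs are required"
            )
        for p in (self.fastq_r1, self.fastq_r2):
            if p is not None and not Path(p).exists():
                raise PipelineError("config", f"input path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        design_spec = raw.pop("design", "default")
        if design_spec in (None, "default"):
            design = default_design()
        elif isinstance(design_spec, dict):
            design = AmpliconDesign.from_dict(design_spec)
        else:
            design = AmpliconDesign.from_yaml(design_spec)
        return cls(design=design, **raw)


def _simulate_input(
    config: PipelineConfig, rng_seed_seq: np.random.SeedSequence
) -> tuple[list[ReadPair], dict]:
    sim = dict(config.simulate or {})
    proportions = {
        SpliceForm(k): float(v) for k, v in sim.get("proportions", {}).items()
    }
    n = int(sim.get("n_read_pairs", 10000))
    samples = sim.get("samples", list(range(config.design.n_samples)))
    err = float(sim.get("seq_error_rate", 0.005))
    read_length = int(sim.get("read_length", 300))
    bias = sim.get("bias")
    bias_spec = (
        PcrBiasSpec(
            {SpliceForm(k): float(v) for k, v in bias["per_cycle_efficiency"].items()},
            int(bias.get("n_cycles", 32)),
        )
        if bias
        else None
    )
    children = rng_seed_seq.spawn(len(samples))
    reads: list[ReadPair] = []
    truth = {}
    for sample_index, child in zip(samples, children):
        reads.extend(
            simulate_readset(
                config.design,
                proportions,
                n,
                seq_error_rate=err,
                bias=bias_spec,
                read_length=read_length,
                seed=int(child.generate_state(1)[0] % (2**31)),
                sample_index=sample_index,
                single_end=config.single_end,
            )
        )
        truth[f"S{sample_index:02d}"] = {str(k): v for k, v in proportions.items()}
    return reads, {"n_samples": len(samples), "n_read_pairs_per_sample": n}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the pipeline; returns the run manifest.

    The manifest records versions, parameters, the seed, per-stage read
    conservation, and paths of every artefact written to
    ``config.output_dir`` (count tables as TSV, manifest as JSON).
    """
    config.validate()
    design = config.design
    manifest: dict = {
        "tool": "splicequant",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "quality_cutoff": config.quality_cutoff,
            "adapters": config.adapters,
            "trim_error_rate": config.trim_error_rate,
            "demux_error_rate": config.demux_error_rate,
            "demux_window": config.demux_window,
            "barcode_read": config.barcode_read,
            "min_overlap": config.min_overlap,
            "max_mismatch_ratio": config.max_mismatch_ratio,
            "classify_error_rate": config.classify_error_rate,
            "flank": config.flank,
            "both_strands": config.both_strands,
            "single_end": config.single_end,
        },
        "stages": [],
    }
    root_ss = np.random.SeedSequence(config.seed)
    sim_ss, spike_ss = root_ss.spawn(2)

    # ---- input ---------------------------------------------------------
    if config.simulate is not None:
        reads, sim_info = _simulate_input(config, sim_ss)
        manifest["input"] = {"source": "simulated", **sim_info}
    else:
        r1 = read_fastq(config.fastq_r1)
        if config.fastq_r2:
            r2 = read_fastq(config.fastq_r2)
            if len(r1) != len(r2):
                raise PipelineError("input", "R1/R2 read counts differ")
            reads = [ReadPair(a, b) for a, b in zip(r1, r2)]
        else:
            reads = [ReadPair(a) for a in r1]
        manifest["input"] = {"source": config.fastq_r1, "n_read_pairs": len(reads)}
    n_input = len(reads)

    def record(stage: str, n_in: int, n_out: int, n_discarded: int, **extra) -> None:
        if n_in != n_out + n_discarded:
            raise PipelineError(
                stage, f"conservation violated: {n_in} != {n_out} + {n_discarded}"
            )
        entry = {
            "stage": stage,
            "n_in": n_in,
            "n_out": n_out,
            "n_discarded": n_discarded,
            **extra,
        }
        manifest["stages"].append(entry)
        logger.info("%s: %d in, %d out, %d discarded", stage, n_in, n_out, n_discarded)

    # ---- trim ----------------------------------------------------------
    reads = trim_pairs(
        reads, config.quality_cutoff, config.adapters, config.trim_error_rate
    )
    record("trim", n_input, len(reads), 0)

    # ---- demux ---------------------------------------------------------
    demux_res = demultiplex(
        reads,
        design,
        max_error_rate=config.demux_error_rate,
        barcode_read=config.barcode_read,
        window=config.demux_window,
    )
    n_assigned = sum(len(b) for b in demux_res.batches.values())
    record(
        "demux",
        len(reads),
        n_assigned,
        len(demux_res.unassigned),
        per_sample={i: len(b) for i, b in demux_res.batches.items()},
    )

    # ---- merge ---------------------------------------------------------
    diagnostics = build_diagnostics(design, flank=config.flank)
    merged_batches: dict[str, list] = {}
    n_merge_in = n_merged = n_unmerged = 0
    for idx, batch in demux_res.batches.items():
        if not batch:
            # barcode unused in this run; an empty sample would only poison
            # downstream normalisation
            logger.info("sample S%02d: no reads assigned, dropped", idx)
            continue
        merged, unmerged, _ = merge_batch(
            batch,
            config.min_overlap,
            config.max_mismatch_ratio,
            single_end=config.single_end,
        )
        merged_batches[f"S{idx:02d}"] = merged
        n_merge_in += len(batch)
        n_merged += len(merged)
        n_unmerged += len(unmerged)
    record("merge", n_merge_in, n_merged, n_unmerged)

    # ---- classify ------------------------------------------------------
    counts = count_splice_forms(
        merged_batches,
        diagnostics,
        max_error_rate=config.classify_error_rate,
        both_strands=config.both_strands,
        design=design,
    )
    record("classify", n_merged, int(counts.df["raw_count"].sum()), 0)

    # ---- calibrate (optional) -----------------------------------------
    bias_model = None
    if config.calibrate_spikein:
        manifests = default_spikein_manifests()
        sim = config.simulate or {}
        bias = sim.get("bias")
        bias_spec = (
            PcrBiasSpec(
                {
                    SpliceForm(k): float(v)
                    for k, v in bias["per_cycle_efficiency"].items()
                },
                int(bias.get("n_cycles", 32)),
            )
            if bias
            else None
        )
        readsets, _ = simulate_spikein_run(
            design,
            manifests,
            bias_spec,
            n_reads_per_mixture=config.spikein_reads_per_mixture,
            seed=int(spike_ss.generate_state(1)[0] % (2**31)),
        )
        spike_batches = {}
        for mixture_id, pairs in readsets.items():
            pairs = trim_pairs(
                pairs, config.quality_cutoff, config.adapters, config.trim_error_rate
            )
            merged, _, _ = merge_batch(
                [
                    ReadPair(
                        p.r1,
                        None
                        if p.r2 is None
                        else _strip_tail(p.r2, design),
                    )
                    for p in pairs
                ],
                config.min_overlap,
                config.max_mismatch_ratio,
            )
            spike_batches[mixture_id] = merged
        spike_counts = count_splice_forms(
            spike_batches,
            diagnostics,
            max_error_rate=config.classify_error_rate,
            both_strands=config.both_strands,
            design=design,
        )
        bias_model = estimate_bias(
            spike_counts, manifests, species_lengths=design.species_lengths
        )
        counts = apply_bias_correction(counts, bias_model)
        manifest["bias_factors"] = {
            str(sp): f for sp, f in bias_model.factors.items()
        }

    # ---- normalise -----------------------------------------------------
    if config.pool_assignment:
        counts = pool_normalize(counts, config.pool_assignment)
        manifest["pool_assignment"] = config.pool_assignment

    # ---- outputs -------------------------------------------------------
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        counts.to_tsv(outdir / "counts.tsv")
        demux_res.report().to_csv(outdir / "demux_report.tsv", sep="\t", index=False)
        if bias_model is not None:
            bias_model.to_tsv(outdir / "bias_model.tsv")
        (outdir / "run_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        manifest["outputs"] = {
            "counts": str(outdir / "counts.tsv"),
            "manifest": str(outdir / "run_manifest.json"),
        }
    manifest["counts"] = counts
    return manifest


def _strip_tail(read, design: AmpliconDesign):
    """Remove quatromer+barcode prefix from a spike-in mate (the spike-in
    mixtures are one sample each, so no demultiplexing pass is run)."""
    from .core import Read

    drop = design.quatromer_length + design.barcode_length
    return Read(read.id, read.seq[drop:], read.qual[drop:])
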