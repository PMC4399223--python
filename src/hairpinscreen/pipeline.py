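"""Pipeline orchestration: simulate -> count -> test -> call -> filter.

A single YAML config names the inputs, outputs, thresholds and simulation
block; stages run in order and every output file is recorded in a
manifest (``manifest.json`` in the output directory) carrying the tool
version, a hash of the config and the seed, so partial reruns can detect
stale intermediates instead of silently reusing them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .calls import classify_hits
from .counting import count_reads, read_counts, write_counts
from .datasets import load_table1
from .expression import cpm, expressed_calls, cross_reference, tmm_factors
from .nbtest import screen_exact_test
from .records import read_library, read_samples, write_library, write_samples
from .synthetic import (
    SimulationConfig,
    emit_fastq,
    simulate_counts,
    simulate_truth,
    synthetic_library,
    synthetic_samples,
)

log = logging.getLogger("hairpinscreen")

STAGES = ("simulate", "count", "test", "call", "expression-filter")


@dataclass
class PipelineConfig:
    """Everything a run needs; mirrors the YAML layout."""

    outdir: str = "screen_out"
    library: str | None = None
    samples: str | None = None
    fastq: str | None = None
    counts: str | None = None
    results: str | None = None
    gene_counts: str | None = None

    fdr_max: float = 0.01
    fold_min: float = 1.5
    cpm_min: float = 0.5
    prior_count: float = 0.5
    fdr_scope: str = "per_pool"  # or "global"

    seed: int = 1
    n_pools: int = 2
    hairpins_per_pool: int = 88
    replicates: int = 3
    error_rate: float = 0.0
    read_len: int = 50
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    primary_pops: tuple[str, ...] = ()
    sphere_pop: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.fdr_max <= 1 or not self.fold_min > 1 or self.cpm_min < 0:
            raise ValueError("thresholds out of range")
        if self.fdr_scope not in ("per_pool", "global"):
            raise ValueError(f"fdr_scope must be per_pool or global, got {self.fdr_scope}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        flat: dict = {}
        for block in ("paths", "thresholds", "test", "simulation", "expression"):
            flat.update(raw.pop(block, {}) or {})
        flat.update(raw)
        flat.update({k: v for k, v in overrides.items() if v is not None})
        sim_keys = {f.name for f in dataclasses.fields(SimulationConfig)}
        sim = {k: flat.pop(k) for k in list(flat) if k in sim_keys}
        for k in ("fold_enriched", "fold_depleted"):
            if k in sim and isinstance(sim[k], (list, tuple)):
                sim[k] = tuple(float(x) for x in sim[k])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "primary_pops" in flat:
            flat["primary_pops"] = tuple(flat["primary_pops"])
        return cls(simulation=SimulationConfig(**sim), **flat)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class Manifest:
    """Maps output files to (sha256, version, config hash, seed, stage)."""

    def __init__(self, outdir: Path, config: PipelineConfig):
        self.path = outdir / "manifest.json"
        self.config = config
        self.entries: dict = (
            json.loads(self.path.read_text()) if self.path.exists() else {}
        )

    def record(self, path: Path, stage: str) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.entries[path.name] = {
            "sha256": digest,
            "version": __version__,
            "config_hash": self.config.hash(),
            "seed": self.config.seed,
            "stage": stage,
        }
        self.path.write_text(json.dumps(self.entries, indent=1, sort_keys=True))

    def check_fresh(self, path: Path) -> None:
        """Refuse to consume an intermediate produced under another config."""
        entry = self.entries.get(path.name)
        if entry is None:
            return  # externally supplied input: caller's responsibility
        if entry["config_hash"] != self.config.hash():
            raise ValueError(
                f"stale intermediate {path}: written under config "
                f"{entry['config_hash']}, current is {self.config.hash()}"
            )
        if hashlib.sha256(path.read_bytes()).hexdigest() != entry["sha256"]:
            raise ValueError(f"intermediate {path} was modified after it was written")


def _need(path: str | None, what: str) -> Path:
    if path is None:
        raise FileNotFoundError(f"config names no {what}")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"missing {what}: {p}")
    return p


def run(config: PipelineConfig, stages: Sequence[str] = STAGES) -> dict:
    """Execute the requested stages in canonical order.

    Returns a dict of the main in-memory artifacts (counts, results, calls
    summary, ...) keyed by stage for programmatic use; files land under
    ``config.outdir``.
    """
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stages: {bad} (choose from {STAGES})")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(outdir, config)
    artifacts: dict = {}
    t0 = time.time()
    log.info("run start: seed=%d config=%s stages=%s",
             config.seed, config.hash(), ",".join(stages))

    lib_path = Path(config.library) if config.library else outdir / "library.tsv"
    smp_path = Path(config.samples) if config.samples else outdir / "samples.tsv"
    fastq_path = Path(config.fastq) if config.fastq else outdir / "reads.fastq.gz"
    counts_path = Path(config.counts) if config.counts else outdir / "counts.tsv"
    results_path = Path(config.results) if config.results else outdir / "results.tsv"

    if "simulate" in stages:
        if lib_path.exists():
            library = read_library(lib_path)
        else:
            library = synthetic_library(
                config.n_pools, config.hairpins_per_pool, seed=config.seed
            )
            write_library(library, lib_path)
            manifest.record(lib_path, "simulate")
        if smp_path.exists():
            samples = read_samples(smp_path)
        else:
            samples = synthetic_samples(
                sorted({h.pool_id for h in library}), config.replicates, seed=config.seed
            )
            write_samples(samples, smp_path)
            manifest.record(smp_path, "simulate")
        truth = simulate_truth(library, samples, config.simulation, seed=config.seed)
        counts = simulate_counts(truth, library, samples, seed=config.seed + 1)
        from .records import ReadStructure

        structure = ReadStructure(read_len=config.read_len)
        emit_fastq(counts, library, samples, structure, config.error_rate,
                   seed=config.seed + 2, path=fastq_path)
        manifest.record(fastq_path, "simulate")
        truth_path = outdir / "truth.tsv"
        pd.DataFrame(
            {"baseline_prop": truth.baseline_prop, "fold": truth.fold,
             "pool_id": truth.pool_of_hairpin}
        ).to_csv(truth_path, sep="\t", index_label="hairpin_id")
        manifest.record(truth_path, "simulate")
        artifacts["simulate"] = {"truth": truth, "counts": counts}
        log.info("simulate: %d hairpins, %d samples, %d planted hits",
                 len(library), len(samples), len(truth.hits))

    if "count" in stages:
        library = read_library(_need(str(lib_path), "library table"))
        samples = read_samples(_need(str(smp_path), "sample sheet"))
        fq = _need(str(fastq_path), "FASTQ input")
        manifest.check_fresh(fq)
        from .records import ReadStructure

        structure = ReadStructure(read_len=config.read_len)
        matrix, report = count_reads(fq, library, samples, structure)
        write_counts(matrix, counts_path)
        manifest.record(counts_path, "count")
        (outdir / "counting_report.json").write_text(
            json.dumps(dataclasses.asdict(report), indent=1)
        )
        manifest.record(outdir / "counting_report.json", "count")
        artifacts["count"] = {"matrix": matrix, "report": report}
        log.info("count: %d/%d reads matched", report.matched_reads, report.total_reads)

    if "test" in stages:
        cpath = _need(str(counts_path), "count matrix")
        manifest.check_fresh(cpath)
        samples = read_samples(_need(str(smp_path), "sample sheet"))
        matrix = read_counts(cpath).attach_samples(samples)
        library = read_library(_need(str(lib_path), "library table"))
        by_id = {h.hairpin_id: h for h in library}
        missing = [i for i in matrix.counts.index if i not in by_id]
        if missing:
            raise ValueError(f"count matrix rows absent from library: {missing[:5]}")
        matrix = type(matrix)(
            matrix.counts, hairpins=[by_id[i] for i in matrix.counts.index],
            samples=matrix.samples,
        )
        results = screen_exact_test(
            matrix, prior_count=config.prior_count,
            per_pool_fdr=config.fdr_scope == "per_pool",
        )
        results.to_csv(results_path, sep="\t")
        manifest.record(results_path, "test")
        artifacts["test"] = {"results": results}
        log.info("test: %d hairpins across %d pools",
                 len(results), results["pool_id"].nunique())

    if "call" in stages:
        rpath = _need(str(results_path), "test results")
        manifest.check_fresh(rpath)
        results = pd.read_csv(rpath, sep="\t", index_col=0)
        calls, summary = classify_hits(results, config.fdr_max, config.fold_min)
        calls_path = outdir / "calls.tsv"
        calls.to_csv(calls_path, sep="\t")
        manifest.record(calls_path, "call")
        (outdir / "call_summary.json").write_text(json.dumps(summary, indent=1))
        manifest.record(outdir / "call_summary.json", "call")
        artifacts["call"] = {"calls": calls, "summary": summary}
        log.info("call: %(n_significant)d significant, %(n_enriched)d enriched, "
                 "%(n_depleted)d depleted, %(n_unique_genes)d genes", summary)

    if "expression-filter" in stages:
        gpath = _need(config.gene_counts, "gene-level count table")
        gcounts = pd.read_csv(gpath, sep="\t", index_col=0)
        factors = tmm_factors(gcounts)
        lin = cpm(gcounts, log=False, norm_factors=factors)
        calls_tab = expressed_calls(lin, threshold=config.cpm_min)
        exp_path = outdir / "expressed_calls.tsv"
        calls_tab.to_csv(exp_path, sep="\t")
        manifest.record(exp_path, "expression-filter")
        artifacts["expression-filter"] = {"expressed": calls_tab, "tmm": factors}
        if config.primary_pops and config.sphere_pop:
            calls_path = outdir / "calls.tsv"
            if "call" in artifacts:
                hit_rows = artifacts["call"]["calls"]
            elif calls_path.exists():
                hit_rows = pd.read_csv(calls_path, sep="\t", index_col=0)
            else:
                raise FileNotFoundError("expression cross-reference needs calls.tsv")
            hits = hit_rows.loc[hit_rows["call"] != "not_significant", "gene"]
            xref = cross_reference(
                hits, calls_tab, list(config.primary_pops), config.sphere_pop
            )
            (outdir / "cross_reference.json").write_text(json.dumps(xref, indent=1))
            manifest.record(outdir / "cross_reference.json", "expression-filter")
            artifacts["expression-filter"]["cross_reference"] = xref
            log.info("expression-filter: %(n_primary)d/%(n_hit_genes)d hit genes "
                     "expressed in primary populations", xref)

    log.info("run done in %.1fs", time.time() - t0)
    return artifacts
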