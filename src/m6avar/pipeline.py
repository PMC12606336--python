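"""End-to-end pipeline: simulate -> build-sets -> classify -> VSEA -> overlap
-> permutation tests -> QTL triage, with a reproducibility manifest.

Every stage consumes the on-disk tables through io_formats (even for
simulated studies, which are written to ``<out>/inputs/`` first), so a run
exercises the same code paths as a run on externally produced files. The
manifest records the configuration, seed, per-stage row counts, wall times
and SHA-256 digests of all outputs; replaying the same configuration and
seed reproduces all digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import __version__
from .annotation import SnpAnnotator, overlap_snps_with_peaks, write_overlap_table
from .io_formats import (
    read_chrom_sizes,
    read_deg_table,
    read_gtf,
    read_ld_table,
    read_peak_table,
    read_qtl_table,
    read_snp_table,
    read_splice_table,
    write_peak_table,
    write_snp_table,
)
from .peak_analysis import drach_fraction, label_dmps, metagene_profile
from .permutation_tests import (
    annotation_enrichment,
    chromosome_enrichment,
    write_category_table,
)
from .qtl_integration import (
    build_candidates,
    filter_degs,
    filter_splice_events,
    write_candidate_table,
)
from .synthetic_data import SimConfig, simulate_study
from .types import ConfigurationError, ValidationError
from .variant_sets import expand_ld, summarize_sets
from .vsea import vsea_batch, write_vsea_table

logger = logging.getLogger(__name__)

SPLICE_TYPES = ("SE", "RI", "A5SS", "A3SS", "MXE")


@dataclass
class PipelineConfig:
    out_dir: str = "m6avar_run"
    seed: int = 0
    simulate: bool = True
    input_dir: Optional[str] = None  # required when simulate is False
    sim: SimConfig = None
    r2_min: float = 0.8
    dmp_alpha: float = 0.05
    dmp_use_adjusted: bool = True
    deg_alpha: float = 0.05
    deg_lfc_min: float = 0.58
    splice_fdr_max: float = 0.05
    n_perm: int = 1000
    n_iter: int = 100_000
    n_bins: int = 90
    threads: int = 1
    force: bool = False

    def __post_init__(self):
        if self.sim is None:
            self.sim = SimConfig(seed=self.seed)


@dataclass
class RunManifest:
    version: str
    config: dict
    seed: int
    stages: List[dict] = field(default_factory=list)
    digests: Dict[str, str] = field(default_factory=dict)

    def add_stage(self, name: str, n_rows: int, seconds: float) -> None:
        self.stages.append({"stage": name, "rows": n_rows, "seconds": round(seconds, 3)})

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _discover_traits(input_dir: Path) -> List[str]:
    traits = sorted(p.stem.replace("snps_", "", 1) for p in input_dir.glob("snps_*.tsv"))
    if not traits:
        raise ConfigurationError(f"no snps_<trait>.tsv tables found in {input_dir}")
    return traits


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages in dependency order; returns the output directory."""
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()) and not config.force:
        existing = [p for p in out.iterdir() if p.name != "inputs"]
        if existing:
            raise ConfigurationError(f"{out} is not empty; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)

    manifest = RunManifest(version=__version__, config=_config_dict(config), seed=config.seed)
    master = np.random.SeedSequence(config.seed)
    rng_vsea, rng_chrom, rng_annot = (np.random.default_rng(s) for s in master.spawn(3))

    # --- stage 0: inputs -----------------------------------------------------
    t0 = time.perf_counter()
    if config.simulate:
        sim_cfg = config.sim
        if sim_cfg.seed != config.seed:
            sim_cfg = SimConfig(**{**asdict(sim_cfg), "seed": config.seed})
        bundle = simulate_study(sim_cfg)
        inputs = out / "inputs"
        bundle.write(inputs)
    else:
        if config.input_dir is None:
            raise ConfigurationError("input_dir is required when simulate is False")
        inputs = Path(config.input_dir)
    required = [inputs / "peaks.tsv", inputs / "annotation.gtf",
                inputs / "genome.sizes", inputs / "deg.tsv", inputs / "qtl.tsv"]
    missing = [str(p) for p in required if not p.exists()]
    if missing:
        raise ConfigurationError(f"missing pipeline inputs: {missing}")
    traits = _discover_traits(inputs)
    manifest.add_stage("inputs", len(traits), time.perf_counter() - t0)

    # --- load ---------------------------------------------------------------
    peaks = read_peak_table(inputs / "peaks.tsv")
    transcripts = read_gtf(inputs / "annotation.gtf")
    chrom_sizes = read_chrom_sizes(inputs / "genome.sizes")
    genome_fa = inputs / "genome.fa"

    # --- build-sets ---------------------------------------------------------
    t0 = time.perf_counter()
    sets = []
    for trait in traits:
        leads = read_snp_table(inputs / f"snps_{trait}.tsv")
        ld_path = inputs / f"ld_{trait}.tsv"
        ld = read_ld_table(ld_path) if ld_path.exists() else []
        sets.append(expand_ld(leads, ld, r2_min=config.r2_min, trait=trait))
    summary = summarize_sets(sets)
    sets_path = out / "sets.tsv"
    with open(sets_path, "w") as fh:
        fh.write(f"# m6avar v{__version__} | variant sets; columns: trait n_lead n_total\n")
        summary.to_csv(fh, sep="\t", index=False)
    manifest.add_stage("build-sets", len(summary), time.perf_counter() - t0)

    # --- classify-dmps ------------------------------------------------------
    t0 = time.perf_counter()
    labeled = label_dmps(peaks, alpha=config.dmp_alpha, use_adjusted=config.dmp_use_adjusted)
    increased = [p for p in labeled if p.direction == "increased"]
    decreased = [p for p in labeled if p.direction == "decreased"]
    write_peak_table(labeled, out / "dmps.tsv")
    manifest.add_stage("classify-dmps", len(labeled), time.perf_counter() - t0)

    # --- metagene + drach ---------------------------------------------------
    t0 = time.perf_counter()
    profile = metagene_profile(peaks, transcripts, n_bins=config.n_bins)
    profile.write_tsv(out / "metagene.tsv")
    manifest.add_stage("metagene", profile.n_mapped, time.perf_counter() - t0)

    t0 = time.perf_counter()
    if genome_fa.exists():
        frac = drach_fraction(peaks, genome_fa)
        with open(out / "drach.tsv", "w") as fh:
            fh.write(f"# m6avar v{__version__} | fraction of peaks with >= 1 DRACH match\n")
            fh.write(f"n_peaks\tdrach_fraction\n{len(peaks)}\t{frac:.6g}\n")
        manifest.add_stage("drach", len(peaks), time.perf_counter() - t0)
    else:
        logger.info("genome.fa absent; DRACH stage skipped")

    # --- vsea ---------------------------------------------------------------
    t0 = time.perf_counter()
    inc_regions = [p.interval for p in increased]
    dec_regions = [p.interval for p in decreased]
    dmp_sets = {s.trait: (inc_regions, dec_regions) for s in sets}
    results = vsea_batch(sets, dmp_sets, chrom_sizes, n_perm=config.n_perm,
                         rng=rng_vsea, threads=config.threads)
    write_vsea_table(results, out / "vsea.tsv")
    manifest.add_stage("vsea", len(results), time.perf_counter() - t0)

    # --- overlap for the top trait x direction ------------------------------
    t0 = time.perf_counter()
    top = results[0]
    top_set = next(s for s in sets if s.trait == top.trait)
    top_regions = [p for p in (increased if top.direction == "increased" else decreased)]
    pairs, dedup = overlap_snps_with_peaks(top_set, top_regions)
    write_overlap_table(pairs, out / "pairs.tsv")
    write_snp_table(dedup, out / "overlap_snps.tsv", trait=top.trait)
    manifest.add_stage("overlap", len(pairs), time.perf_counter() - t0)

    # --- permutation tests --------------------------------------------------
    t0 = time.perf_counter()
    if dedup:
        chrom_res = chromosome_enrichment(dedup, list(top_set), n_iter=config.n_iter, rng=rng_chrom)
        write_category_table(chrom_res, out / "chrom_test.tsv", "chromosome")
        annot_res = annotation_enrichment(dedup, list(top_set), transcripts,
                                          n_iter=config.n_iter, rng=rng_annot)
        write_category_table(annot_res, out / "annot_test.tsv", "annotation")
        n_tests = len(chrom_res) + len(annot_res)
    else:
        logger.warning("no overlapping SNPs; permutation-test stage writes empty tables")
        for name, mode in (("chrom_test.tsv", "chromosome"), ("annot_test.tsv", "annotation")):
            write_category_table([], out / name, mode)
        n_tests = 0
    manifest.add_stage("permtest", n_tests, time.perf_counter() - t0)

    # --- qtl triage ---------------------------------------------------------
    t0 = time.perf_counter()
    degs = read_deg_table(inputs / "deg.tsv")
    up, down = filter_degs(degs, alpha=config.deg_alpha, lfc_min=config.deg_lfc_min)
    events = []
    splice_dir = inputs / "splice"
    if splice_dir.is_dir():
        for etype in SPLICE_TYPES:
            p = splice_dir / f"{etype}.tsv"
            if p.exists():
                events.extend(read_splice_table(p, event_type=etype))
    sig_events = filter_splice_events(events, fdr_max=config.splice_fdr_max)
    qtls = read_qtl_table(inputs / "qtl.tsv")
    candidates = build_candidates(dedup, qtls, up, down, sig_events)
    write_candidate_table(candidates, out / "candidates.tsv")
    manifest.add_stage("qtl-triage", len(candidates), time.perf_counter() - t0)

    for p in sorted(out.glob("*.tsv")):
        manifest.digests[p.name] = _sha256(p)
    manifest.write(out / "manifest.json")
    return out


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    return d
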