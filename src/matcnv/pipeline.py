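"""End-to-end orchestration: simulate (optional) -> normalize ->
segment -> call -> cohort statistics, with every artifact on disk.

Stage order is fixed — GC LOESS before PCA, segmentation on the fully
normalized profile — and every source of randomness is derived from the
config seed, so a re-run with the same config is byte-identical.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calling import CNVCall, call_maternal_cnvs
from .cohort import (CohortSummary, DensityRow, MOVCluster,
                     chromosome_density, cluster_movs, compare_to_db,
                     summarize_cohort)
from .config import PipelineConfig
from .genome import GenomeModel
from .normalize import NormalizedProfile, normalize_cohort
from .segment import Segment, segment_profile
from .simulate import BinnedSample, simulate_cohort
from . import io as mio

log = logging.getLogger("matcnv")


@dataclass
class PipelineResult:
    model: GenomeModel
    samples: list[BinnedSample]
    profiles: list[NormalizedProfile]
    segments: dict[str, list[Segment]]
    calls: list[CNVCall]
    clusters: list[MOVCluster]
    summary: CohortSummary
    density: list[DensityRow]
    out_dir: Path


def _stage(name: str, t0: float, n_in: int, n_out: int, **params) -> None:
    kv = " ".join(f"{k}={v}" for k, v in params.items())
    log.info("stage=%s %s n_in=%d n_out=%d wall=%.2fs",
             name, kv, n_in, n_out, time.perf_counter() - t0)


def run_pipeline(config: PipelineConfig,
                 samples: list[BinnedSample] | None = None) -> PipelineResult:
    """Execute the full pipeline per the config.

    If ``samples`` is None a cohort is simulated from
    ``config.simulate``; otherwise the provided binned samples are
    analyzed.  All stage outputs (counts, profiles, segments, calls,
    MOV/density/comparison tables) are written under
    ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    sim_seed, seg_seed = (int(s.generate_state(1)[0] % (2 ** 31))
                          for s in root.spawn(2))

    t0 = time.perf_counter()
    model = config.genome.build()
    _stage("genome", t0, 0, model.n_bins, preset=config.genome.preset,
           bin_size=model.bin_size)

    if samples is None:
        t0 = time.perf_counter()
        spec = config.simulate.to_spec(seed=sim_seed)
        samples = simulate_cohort(model, spec)
        counts_dir = out / "counts"
        counts_dir.mkdir(exist_ok=True)
        paths = []
        for s in samples:
            p = counts_dir / f"{s.sample_id}.counts.tsv"
            mio.write_counts_tsv(p, s, model)
            paths.append(str(p))
        mio.write_manifest_tsv(out / "manifest.tsv", samples, paths)
        mio.write_truth_bed(out / "truth.bed", samples)
        _stage("simulate", t0, 0, len(samples), n_samples=spec.n_samples,
               seed=sim_seed)

    t0 = time.perf_counter()
    profiles = normalize_cohort(
        samples, model, span=config.normalize.span, k=config.normalize.k,
        leave_one_out=config.normalize.leave_one_out)
    prof_dir = out / "profiles"
    prof_dir.mkdir(exist_ok=True)
    for p in profiles:
        mio.write_profile_tsv(prof_dir / f"{p.sample_id}.profile.tsv",
                              p, model)
    _stage("normalize", t0, len(samples), len(profiles),
           span=config.normalize.span, k=config.normalize.k)

    t0 = time.perf_counter()
    seg_dir = out / "segments"
    seg_dir.mkdir(exist_ok=True)
    segments: dict[str, list[Segment]] = {}
    all_calls: list[CNVCall] = []
    seg_ss = np.random.SeedSequence(seg_seed)
    child_seeds = seg_ss.generate_state(len(profiles)) % (2 ** 31)
    for prof, s_seed in zip(profiles, child_seeds):
        segs = segment_profile(
            prof, model, alpha=config.segment.alpha,
            n_perm=config.segment.n_perm,
            min_width=config.segment.min_width, seed=int(s_seed))
        segments[prof.sample_id] = segs
        mio.write_segments_tsv(
            seg_dir / f"{prof.sample_id}.segments.tsv", segs)
        all_calls.extend(call_maternal_cnvs(
            segs, sample_id=prof.sample_id,
            min_length_bp=config.call.min_length_bp,
            deviation_threshold=config.call.deviation_threshold))
    mio.write_calls_bed(out / "calls.bed", all_calls)
    n_segs = sum(len(v) for v in segments.values())
    _stage("segment+call", t0, len(profiles), n_segs,
           alpha=config.segment.alpha, n_perm=config.segment.n_perm,
           n_calls=len(all_calls))

    t0 = time.perf_counter()
    clusters = cluster_movs(
        all_calls, cohort_size=len(samples),
        min_reciprocal_overlap=config.cohort.min_reciprocal_overlap)
    summary = summarize_cohort(clusters, all_calls, len(samples))
    mio.write_mov_table_tsv(out / "mov_table.tsv", clusters)
    _stage("cohort", t0, len(all_calls), len(clusters),
           n_mov=summary.n_mov)

    t0 = time.perf_counter()
    counts_per_chrom = {c: 0 for c in model.chrom_names}
    for cl in clusters:
        counts_per_chrom[cl.chrom] += 1
    density = chromosome_density(counts_per_chrom,
                                 model.effective_lengths())
    mio.write_density_tsv(out / "density.tsv", density)
    _stage("density", t0, len(clusters), len(density))

    if config.cohort.db_path:
        t0 = time.perf_counter()
        db = mio.read_db_frequencies_tsv(config.cohort.db_path)
        comps = []
        for cl in clusters:
            if not cl.is_mov:
                continue
            hit = db[db["locus"] == cl.label]
            for _, row in hit.iterrows():
                comps.append(compare_to_db(
                    cl.n_occurrences, len(samples),
                    float(row["freq_pct"]), int(row["cohort_size"]),
                    locus=cl.label))
        mio.write_comparisons_tsv(out / "db_comparisons.tsv", comps)
        _stage("db_compare", t0, summary.n_mov, len(comps))

    return PipelineResult(
        model=model, samples=samples, profiles=profiles, segments=segments,
        calls=all_calls, clusters=clusters, summary=summary,
        density=density, out_dir=out)
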