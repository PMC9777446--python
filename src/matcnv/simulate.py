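"""Synthetic cfDNA cohort generator with a known CNV truth set.

Emulates the bin-count signal of low-coverage (0.12–0.5×) NIPT
sequencing of maternal plasma: per-bin expected counts are shaped by a
smooth GC bias curve, low-rank batch artifacts shared across samples,
and the copy ratio of any CNVs carried.  cfDNA is a maternal/fetal
mixture, so a bin's copy ratio is

    c_b = (1 - ff) * maternal_copies / 2 + ff * fetal_copies / 2

with ``ff`` the fetal fraction.  A maternal heterozygous gain therefore
shifts the diploid ratio by +0.5 regardless of ff (the fetus inherits
the maternal allele in this model), while a fetal-only event shifts it
by only ±ff/2 — the physical basis for the maternal/fetal calling
threshold downstream.

Counts are negative-binomially overdispersed (Poisson in the limit
``dispersion -> 0``); a multinomial mode partitions the read total
exactly when strict conservation is wanted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .genome import GenomeModel

Carrier = Literal["maternal", "fetal"]


@dataclass(frozen=True)
class TruthVariant:
    """An injected CNV with its population frequency.

    ``copy_state`` is the carried copy number of the interval in the
    carrier genome: 1 = heterozygous loss, 3 = heterozygous gain
    (0 and 4 = homozygous states, rare but allowed).
    """

    chrom: str
    start_bp: int
    end_bp: int
    copy_state: int
    carrier: Carrier = "maternal"
    population_frequency: float = 0.0

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise ValueError("end_bp must exceed start_bp")
        if self.copy_state not in (0, 1, 3, 4):
            raise ValueError(f"copy_state {self.copy_state} not in {{0,1,3,4}}")
        if not 0.0 <= self.population_frequency <= 1.0:
            raise ValueError("population_frequency must be in [0, 1]")
        if self.carrier not in ("maternal", "fetal"):
            raise ValueError(f"unknown carrier {self.carrier!r}")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a simulated cohort.

    Defaults mirror the real-assay regime: 5–20 M reads per sample
    (0.12–0.5× depth at genome scale), fetal fraction ~N(0.10, 0.04)
    truncated to [0.01, 0.30], a unimodal GC bias peaked near GC 0.42,
    two low-rank batch components, and mild negative-binomial
    overdispersion.  On a toy genome pass an explicit ``reads_range``
    scaled to hold mean reads-per-bin, i.e. coverage, fixed.
    """

    n_samples: int
    reads_range: tuple[int, int] = (5_000_000, 20_000_000)
    fetal_fraction_mean: float = 0.10
    fetal_fraction_sd: float = 0.04
    fetal_fraction_max: float = 0.30
    gc_bias_strength: float = 8.0     # curvature of log-bias quadratic
    gc_bias_peak: float = 0.42
    batch_rank: int = 2
    batch_scale: float = 0.08         # per-component score SD (log scale)
    dispersion: float = 0.01          # NB: var = mu + dispersion * mu^2
    variant_catalog: tuple[TruthVariant, ...] = ()
    count_model: Literal["nb", "poisson", "multinomial"] = "nb"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        lo, hi = self.reads_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid reads_range {self.reads_range}")
        for v in (self.fetal_fraction_mean, self.fetal_fraction_max):
            if not 0.0 <= v <= 1.0:
                raise ValueError("fetal fraction parameters must be in [0, 1]")
        if self.batch_rank < 0:
            raise ValueError("batch_rank must be >= 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        object.__setattr__(self, "variant_catalog",
                           tuple(self.variant_catalog))


@dataclass
class BinnedSample:
    """One sample's raw counts over the mappable-bin grid."""

    sample_id: str
    counts: np.ndarray                  # int, length = n mappable bins
    total_reads: int
    fetal_fraction: float | None = None
    truth: list[TruthVariant] = field(default_factory=list)


def gc_bias_curve(gc: np.ndarray, strength: float, peak: float) -> np.ndarray:
    """Unimodal quadratic-in-log GC bias, 1.0 at the peak."""
    return np.exp(-strength * (gc - peak) ** 2)


def _variant_bin_mask(model: GenomeModel, v: TruthVariant,
                      chrom_arr: np.ndarray, start_arr: np.ndarray,
                      end_arr: np.ndarray) -> np.ndarray:
    try:
        ci = model.chrom_names.index(v.chrom)
    except ValueError:
        raise ValueError(f"variant chromosome {v.chrom!r} not in genome")
    centers = (start_arr + end_arr) / 2.0
    return (chrom_arr == ci) & (centers >= v.start_bp) & (centers < v.end_bp)


def _smooth_loadings(rng: np.random.Generator, rank: int,
                     n_bins: int) -> np.ndarray:
    """Low-rank batch loadings: smoothed white noise, unit RMS per row.

    The 5-bin (100 kb) smoothing window reflects the local coherence of
    flow-cell/library artifacts — correlated over a few bins, not over
    megabases (megabase-coherent artifacts would be indistinguishable
    from CNVs and make the assay unusable).
    """
    if rank == 0:
        return np.zeros((0, n_bins))
    raw = rng.standard_normal((rank, n_bins))
    win = np.hanning(5)
    win /= win.sum()
    sm = np.apply_along_axis(lambda r: np.convolve(r, win, mode="same"),
                             1, raw)
    rms = np.sqrt((sm ** 2).mean(axis=1, keepdims=True))
    return sm / rms


def simulate_cohort(model: GenomeModel, spec: CohortSpec) -> list[BinnedSample]:
    """Draw a cohort of binned samples with recorded CNV truth.

    Expected count of mappable bin b for a sample with read total R is
    ``mu_b = R * w_b / sum(w)`` with
    ``w_b = g(GC_b) * exp(sum_k s_k L_kb) * c_b`` — GC bias, per-sample
    low-rank batch effect and copy ratio.  Carriers are assigned per
    variant by independent Bernoulli(population_frequency) draws.
    Identical ``spec`` (including seed) reproduces the cohort bit for
    bit.
    """
    rng = np.random.default_rng(spec.seed)
    mb = model.mappable_view()
    n = mb.n
    if n == 0:
        raise ValueError("genome model has no mappable bins")

    gbias = gc_bias_curve(mb.gc, spec.gc_bias_strength, spec.gc_bias_peak)
    loadings = _smooth_loadings(rng, spec.batch_rank, n)

    # carrier matrix: (n_variants, n_samples)
    carry = np.zeros((len(spec.variant_catalog), spec.n_samples), dtype=bool)
    for vi, v in enumerate(spec.variant_catalog):
        carry[vi] = rng.random(spec.n_samples) < v.population_frequency
    var_masks = [
        _variant_bin_mask(model, v, mb.chrom, mb.start, mb.end)
        for v in spec.variant_catalog
    ]

    samples: list[BinnedSample] = []
    lo, hi = spec.reads_range
    for si in range(spec.n_samples):
        total = int(rng.integers(lo, hi + 1))
        ff = float(np.clip(
            rng.normal(spec.fetal_fraction_mean, spec.fetal_fraction_sd),
            0.01, spec.fetal_fraction_max,
        ))
        copy_ratio = np.ones(n)
        truth: list[TruthVariant] = []
        for vi, v in enumerate(spec.variant_catalog):
            if not carry[vi, si]:
                continue
            truth.append(v)
            if v.carrier == "maternal":
                # fetus co-inherits the maternal allele: shift is ff-free
                c = v.copy_state / 2.0
            else:
                c = (1.0 - ff) + ff * v.copy_state / 2.0
            copy_ratio[var_masks[vi]] *= c

        scores = rng.standard_normal(spec.batch_rank) * spec.batch_scale
        w = gbias * copy_ratio
        if spec.batch_rank:
            w = w * np.exp(scores @ loadings)
        p = w / w.sum()
        mu = total * p

        if spec.count_model == "multinomial":
            counts = rng.multinomial(total, p)
        elif spec.count_model == "poisson" or spec.dispersion == 0:
            counts = rng.poisson(mu)
        else:
            shape = 1.0 / spec.dispersion
            lam = rng.gamma(shape, mu * spec.dispersion)
            counts = rng.poisson(lam)

        samples.append(BinnedSample(
            sample_id=f"S{si:04d}",
            counts=counts.astype(np.int64),
            total_reads=int(counts.sum()),
            fetal_fraction=ff,
            truth=truth,
        ))
    return samples
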