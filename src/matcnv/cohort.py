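"""Cohort-level statistics over per-sample maternal CNV calls.

Three analyses mirror how a population screening cohort is summarised:

* **MOV clustering** — calls of the same type whose reciprocal overlap
  is at least 0.75 are linked into connected components; a component
  seen in two or more samples is a *multiple occurring variant* (MOV)
  with cohort frequency ``100 * n / N`` percent.
* **Database comparison** — a variant's cohort frequency is tested
  against a published population frequency with a 2x2 Pearson
  chi-squared test (no continuity correction), reconstructing the
  database carrier count as ``round(freq% * N_db)``.
* **Chromosome density outliers** — distinct variants per megabase of
  effective (mappable) chromosome length; assuming this rate is
  normally distributed across chromosomes, each chromosome gets a
  lower-tail p-value, flagging chromosomes with significantly depleted
  variation.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import CNVCall


@dataclass
class MOVCluster:
    """A cluster of equivalent calls across samples.

    The representative interval is the modal exact interval of the
    member calls (ties: leftmost, then shortest).  ``n_occurrences``
    counts distinct carrier samples.
    """

    chrom: str
    start_bp: int
    end_bp: int
    type: str
    n_occurrences: int
    member_sample_ids: tuple[str, ...]
    frequency_pct: float

    @property
    def is_mov(self) -> bool:
        return self.n_occurrences >= 2

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.start_bp:,}–{self.end_bp:,}"


@dataclass(frozen=True)
class DbComparison:
    """2x2 chi-squared contrast of cohort vs database frequency."""

    locus: str
    cohort_n: int
    cohort_N: int
    db_freq_pct: float
    db_N: int
    chi2_stat: float
    p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class DensityRow:
    """One chromosome's variants-per-megabase and its lower-tail
    normal p-value."""

    chrom: str
    effective_length_bp: int
    n_variants: int
    per_mb: float
    p_value: float
    significant: bool


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(|A∩B|/|A|, |A∩B|/|B|) for half-open intervals."""
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_movs(
    calls: Sequence[CNVCall],
    cohort_size: int,
    min_reciprocal_overlap: float = 0.75,
) -> list[MOVCluster]:
    """Link same-type calls with reciprocal overlap >= threshold into
    connected components.

    Returns every component (singletons included) sorted by genome
    position; filter on ``is_mov`` for recurrent variants.  Clustering
    is invariant to the input order of calls.
    """
    if cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")
    groups: dict[tuple[str, str], list[CNVCall]] = defaultdict(list)
    for c in calls:
        groups[(c.chrom, c.type)].append(c)

    clusters: list[MOVCluster] = []
    for (chrom, ctype), group in groups.items():
        # canonical order makes components order-invariant
        group = sorted(group, key=lambda c: (c.start_bp, c.end_bp,
                                             c.sample_id))
        uf = _UnionFind(len(group))
        for i, a in enumerate(group):
            for j in range(i + 1, len(group)):
                b = group[j]
                if b.start_bp >= a.end_bp:
                    break  # sorted by start: no further overlap with a
                if reciprocal_overlap(a.interval,
                                      b.interval) >= min_reciprocal_overlap:
                    uf.union(i, j)
        comp: dict[int, list[CNVCall]] = defaultdict(list)
        for i in range(len(group)):
            comp[uf.find(i)].append(group[i])
        for members in comp.values():
            counts = Counter(m.interval for m in members)
            top = max(counts.values())
            rep = min((iv for iv, c in counts.items() if c == top),
                      key=lambda iv: (iv[0], iv[1] - iv[0]))
            sample_ids = tuple(sorted({m.sample_id for m in members}))
            n = len(sample_ids)
            clusters.append(MOVCluster(
                chrom=chrom,
                start_bp=rep[0],
                end_bp=rep[1],
                type=ctype,
                n_occurrences=n,
                member_sample_ids=sample_ids,
                frequency_pct=round(100.0 * n / cohort_size, 3),
            ))
    clusters.sort(key=lambda c: (c.chrom, c.start_bp, c.end_bp, c.type))
    return clusters


def mov_frequency_pct(n_occurrences: int, cohort_size: int) -> float:
    """Cohort frequency in percent, rounded to 3 decimals for reporting."""
    if cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")
    return round(100.0 * n_occurrences / cohort_size, 3)


def compare_to_db(
    cohort_n: int,
    cohort_N: int,
    db_freq_pct: float,
    db_N: int,
    locus: str = "",
) -> DbComparison:
    """Pearson chi-squared (1 df, no continuity correction) on the 2x2
    carriers-by-source table.

    The database carrier count is reconstructed as
    ``round(db_freq_pct/100 * db_N)`` since databases publish
    frequencies, not counts.  A table with an expected zero cell (both
    frequencies zero) is flagged degenerate with an undefined p.
    """
    if cohort_N < 1 or db_N < 1:
        raise ValueError("cohort sizes must be >= 1")
    if not 0.0 <= db_freq_pct <= 100.0:
        raise ValueError("db_freq_pct must be in [0, 100]")
    if not 0 <= cohort_n <= cohort_N:
        raise ValueError("cohort_n must be in [0, cohort_N]")
    db_n = int(round(db_freq_pct / 100.0 * db_N))
    table = np.array([[cohort_n, cohort_N - cohort_n],
                      [db_n, db_N - db_n]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return DbComparison(locus, cohort_n, cohort_N, db_freq_pct, db_N,
                            chi2_stat=float("nan"), p_value=float("nan"),
                            degenerate=True)
    res = stats.chi2_contingency(table, correction=False)
    return DbComparison(locus, cohort_n, cohort_N, db_freq_pct, db_N,
                        chi2_stat=float(res.statistic),
                        p_value=float(res.pvalue))


def chromosome_density(
    variant_counts: Mapping[str, int],
    effective_lengths: Mapping[str, int],
    alpha: float = 0.05,
    two_sided: bool = False,
) -> list[DensityRow]:
    """Variants-per-megabase outlier test across chromosomes.

    The per-Mb rate is assumed normal across chromosomes; its mean and
    sample (n-1) standard deviation are estimated from the rates
    themselves and each chromosome receives the lower-tail probability
    ``Phi((rate - mean)/sd)`` (two-sided optionally).  Chromosomes with
    p < alpha are flagged as significantly variant-poor.
    """
    chroms = list(variant_counts)
    if len(chroms) < 3:
        raise ValueError("need >= 3 chromosomes")
    lengths = np.array([effective_lengths[c] for c in chroms], dtype=float)
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    counts = np.array([variant_counts[c] for c in chroms], dtype=float)
    per_mb = counts / (lengths / 1e6)
    mu = per_mb.mean()
    sd = per_mb.std(ddof=1)
    if sd == 0:
        warnings.warn("all chromosomes have identical density; "
                      "p-values are uninformative")
        p = np.full(per_mb.size, 0.5)
    else:
        z = (per_mb - mu) / sd
        p = stats.norm.cdf(z)
        if two_sided:
            p = 2.0 * np.minimum(p, 1.0 - p)
    return [
        DensityRow(
            chrom=c,
            effective_length_bp=int(effective_lengths[c]),
            n_variants=int(variant_counts[c]),
            per_mb=float(r),
            p_value=float(pv),
            significant=bool(sd != 0 and pv < alpha),
        )
        for c, r, pv in zip(chroms, per_mb, p)
    ]


@dataclass
class CohortSummary:
    """Counts of distinct CNVs, MOVs, gains/losses and per-chromosome
    totals, plus a frequency table of recurrent variants."""

    n_calls: int
    n_distinct: int
    n_mov: int
    n_distinct_gain: int
    n_distinct_loss: int
    per_chromosome: dict[str, int]
    mov_table: pd.DataFrame = field(repr=False, default=None)


def summarize_cohort(
    clusters: Sequence[MOVCluster],
    calls: Sequence[CNVCall],
    cohort_size: int,
) -> CohortSummary:
    """Aggregate clusters into the cohort's headline numbers and a
    frequency table (locus label, size, coordinates, n, frequency %)."""
    per_chrom: dict[str, int] = defaultdict(int)
    for cl in clusters:
        per_chrom[cl.chrom] += 1
    movs = [cl for cl in clusters if cl.is_mov]
    rows = [{
        "cnv": f"{'dup' if cl.type == 'gain' else 'del'} {cl.label}",
        "size_bp": cl.end_bp - cl.start_bp,
        "chrom": cl.chrom,
        "start_bp": cl.start_bp,
        "end_bp": cl.end_bp,
        "type": cl.type,
        "n": cl.n_occurrences,
        "frequency_pct": cl.frequency_pct,
    } for cl in sorted(movs, key=lambda c: -c.n_occurrences)]
    table = pd.DataFrame(
        rows, columns=["cnv", "size_bp", "chrom", "start_bp", "end_bp",
                       "type", "n", "frequency_pct"])
    return CohortSummary(
        n_calls=len(calls),
        n_distinct=len(clusters),
        n_mov=len(movs),
        n_distinct_gain=sum(1 for c in clusters if c.type == "gain"),
        n_distinct_loss=sum(1 for c in clusters if c.type == "loss"),
        per_chromosome=dict(per_chrom),
        mov_table=table,
    )
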