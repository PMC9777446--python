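"""Binned genome model: fixed bin grid, GC track, mappability mask.

All downstream stages (counting, normalization, segmentation, calling)
operate on a fixed grid of ``bin_size`` bp bins.  A trailing partial bin
at a chromosome end is kept on the grid but flagged unmappable, so every
mappable bin has exactly ``bin_size`` bp.  The effective length of a
chromosome is the total mappable span — the denominator of the
variants-per-megabase statistic.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np

DEFAULT_BIN_SIZE = 20_000

#: Chromosome sizes of the GRCh37/hg19 reference, for genome-scale runs.
HG19_CHROM_LENGTHS: dict[str, int] = {
    "chr1": 249_250_621, "chr2": 243_199_373, "chr3": 198_022_430,
    "chr4": 191_154_276, "chr5": 180_915_260, "chr6": 171_115_067,
    "chr7": 159_138_663, "chr8": 146_364_022, "chr9": 141_213_431,
    "chr10": 135_534_747, "chr11": 135_006_516, "chr12": 133_851_895,
    "chr13": 115_169_878, "chr14": 107_349_540, "chr15": 102_531_392,
    "chr16": 90_354_753, "chr17": 81_195_210, "chr18": 78_077_248,
    "chr19": 59_128_983, "chr20": 63_025_520, "chr21": 48_129_895,
    "chr22": 51_304_566, "chrX": 155_270_560,
}

X_NAMES = frozenset({"X", "chrX"})


@dataclass(frozen=True)
class GenomeModel:
    """Fixed bin grid with per-bin GC fraction and mappability.

    Parameters are normally produced by :func:`build_genome_model`.

    Attributes
    ----------
    chrom_names
        Ordered chromosome labels.
    chrom_lengths
        Length in bp of each chromosome, same order as ``chrom_names``.
    bin_size
        Bin width in bp.
    bin_chrom
        Per-bin chromosome index (into ``chrom_names``), full grid.
    bin_start, bin_end
        Per-bin genomic coordinates, 0-based half-open, full grid.
    gc
        Per-bin GC fraction in [0, 1], full grid (NaN allowed on
        unmappable bins).
    mappable
        Per-bin boolean mask, full grid.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_size: int
    bin_chrom: np.ndarray
    bin_start: np.ndarray
    bin_end: np.ndarray
    gc: np.ndarray
    mappable: np.ndarray

    # ---- derived views -------------------------------------------------

    @property
    def n_bins(self) -> int:
        return self.bin_start.size

    @property
    def n_mappable(self) -> int:
        return int(self.mappable.sum())

    def is_autosome(self, name: str) -> bool:
        return name not in X_NAMES

    @property
    def autosomal(self) -> np.ndarray:
        """Full-grid boolean mask of autosomal bins."""
        auto_idx = np.array(
            [self.is_autosome(c) for c in self.chrom_names], dtype=bool
        )
        return auto_idx[self.bin_chrom]

    def mappable_view(self) -> "MappableBins":
        """Arrays restricted to mappable bins, the working coordinate
        system for counts, ratios and segments."""
        m = self.mappable
        return MappableBins(
            chrom=self.bin_chrom[m],
            start=self.bin_start[m],
            end=self.bin_end[m],
            gc=self.gc[m],
            autosomal=self.autosomal[m],
            chrom_names=self.chrom_names,
        )

    def effective_lengths(self) -> dict[str, int]:
        """Mappable span (bp) per chromosome."""
        out: dict[str, int] = {}
        for i, name in enumerate(self.chrom_names):
            sel = (self.bin_chrom == i) & self.mappable
            out[name] = int(sel.sum()) * self.bin_size
        return out


@dataclass(frozen=True)
class MappableBins:
    """Grid arrays restricted to mappable bins."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    gc: np.ndarray
    autosomal: np.ndarray
    chrom_names: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.start.size

    def chrom_slices(self) -> list[tuple[str, slice]]:
        """Contiguous slice of mappable bins per chromosome, in order."""
        out = []
        for i, name in enumerate(self.chrom_names):
            idx = np.flatnonzero(self.chrom == i)
            if idx.size:
                out.append((name, slice(int(idx[0]), int(idx[-1]) + 1)))
        return out


GCProfile = Callable[[str, np.ndarray], np.ndarray]


def default_gc_track(chrom: str, centers: np.ndarray) -> np.ndarray:
    """Smooth deterministic GC landscape for synthetic genomes.

    A slow sinusoidal isochore-like structure around GC 0.42 with a
    chromosome-specific phase, clipped to [0.30, 0.60].
    """
    phase = (zlib.crc32(chrom.encode()) % 7) * 0.9
    x = centers / 1e6
    gc = (
        0.42
        + 0.07 * np.sin(x / 11.0 + phase)
        + 0.04 * np.sin(x / 2.3 + 2.0 * phase)
    )
    return np.clip(gc, 0.30, 0.60)


def build_genome_model(
    chrom_lengths: Mapping[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    gc_profile: GCProfile | None = None,
    unmappable_intervals: Iterable[tuple[str, int, int]] = (),
) -> GenomeModel:
    """Lay out the bin grid and flag unmappable bins.

    Parameters
    ----------
    chrom_lengths
        Ordered mapping of chromosome name to length in bp.
    bin_size
        Bin width in bp (> 0).
    gc_profile
        Callable ``f(chrom_name, bin_center_bp) -> gc array``; defaults
        to :func:`default_gc_track`.
    unmappable_intervals
        ``(chrom, start, end)`` half-open bp intervals; any bin
        overlapping one is flagged unmappable (centromeres, repetitive
        regions).

    Raises
    ------
    ValueError
        On non-positive bin size or a zero/negative chromosome length.
    """
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    gc_profile = gc_profile or default_gc_track

    names: list[str] = []
    lengths: list[int] = []
    chrom_idx: list[np.ndarray] = []
    starts: list[np.ndarray] = []
    ends: list[np.ndarray] = []
    gcs: list[np.ndarray] = []
    mapp: list[np.ndarray] = []

    masks_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in unmappable_intervals:
        if e <= s:
            raise ValueError(f"empty unmappable interval {c}:{s}-{e}")
        masks_by_chrom.setdefault(c, []).append((int(s), int(e)))

    for ci, (name, length) in enumerate(chrom_lengths.items()):
        if length <= 0:
            raise ValueError(
                f"chromosome {name!r} has non-positive length {length}"
            )
        names.append(name)
        lengths.append(int(length))
        n_full, rem = divmod(int(length), bin_size)
        n = n_full + (1 if rem else 0)
        start = np.arange(n, dtype=np.int64) * bin_size
        end = np.minimum(start + bin_size, length)
        m = np.ones(n, dtype=bool)
        if rem:
            m[-1] = False  # trailing partial bin never enters analysis
        for s, e in masks_by_chrom.get(name, ()):
            m &= ~((start < e) & (end > s))
        centers = (start + end) / 2.0
        gc = np.asarray(gc_profile(name, centers), dtype=float)
        if gc.shape != start.shape:
            raise ValueError("gc_profile returned wrong-shaped array")
        if np.any((gc[m] < 0) | (gc[m] > 1)):
            raise ValueError("gc_profile must yield values in [0, 1]")
        chrom_idx.append(np.full(n, ci, dtype=np.int32))
        starts.append(start)
        ends.append(end)
        gcs.append(gc)
        mapp.append(m)

    return GenomeModel(
        chrom_names=tuple(names),
        chrom_lengths=tuple(lengths),
        bin_size=bin_size,
        bin_chrom=np.concatenate(chrom_idx),
        bin_start=np.concatenate(starts),
        bin_end=np.concatenate(ends),
        gc=np.concatenate(gcs),
        mappable=np.concatenate(mapp),
    )


def toy_genome(
    bin_size: int = DEFAULT_BIN_SIZE,
    with_centromeres: bool = True,
) -> GenomeModel:
    """Desk-scale genome: four autosomes plus X, 30–40 Mb each.

    Small enough that a full cohort simulation, normalization and
    segmentation run in seconds to minutes, while keeping per-chromosome
    bin counts (1,500–2,000) in the regime where circular binary
    segmentation behaves as it does genome-wide.  Each chromosome gets a
    2 Mb centromere-like unmappable band at its midpoint.
    """
    lengths = {
        "chr1": 40_000_000,
        "chr2": 35_000_000,
        "chr3": 30_000_000,
        "chr4": 30_000_000,
        "chrX": 30_000_000,
    }
    masks = []
    if with_centromeres:
        for name, ln in lengths.items():
            mid = ln // 2
            masks.append((name, mid - 1_000_000, mid + 1_000_000))
    return build_genome_model(lengths, bin_size=bin_size,
                              unmappable_intervals=masks)
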