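"""On-disk formats: counts/profile/segments TSV, calls BED, cohort
tables, and the packaged reference-cohort fixtures.

Coordinates are 0-based half-open everywhere on disk (BED convention
and the internal bin grid).  Human-readable locus labels are rendered
exactly as screening reports print them — ``chr6:168,340,000–168,580,000``
— which are the grid-aligned half-open coordinates with thousands
separators (end minus start equals the variant size).
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calling import CNVCall
from .cohort import DbComparison, DensityRow, MOVCluster
from .genome import GenomeModel
from .normalize import NormalizedProfile
from .segment import Segment
from .simulate import BinnedSample, TruthVariant

#: Size of the reference screening cohort behind the packaged tables.
REFERENCE_COHORT_SIZE = 6422
#: Sizes of the population databases the reference cohort was
#: contrasted with (non-Finnish European subsets).
DGV_DBVAR_COHORT_SIZE = 11_222
GNOMAD_COHORT_SIZE = 7_624

_LOCUS_RE = re.compile(
    r"^(?P<chrom>\w+)\s*:\s*(?P<start>[\d,]+)\s*[–—-]\s*(?P<end>[\d,]+)$")


def format_locus_label(chrom: str, start_bp: int, end_bp: int) -> str:
    """Render half-open coordinates the way report tables print them."""
    return f"{chrom}:{start_bp:,}–{end_bp:,}"


def parse_locus_label(label: str) -> tuple[str, int, int]:
    """Parse ``chr6:168,340,000–168,580,000`` to (chrom, start, end).

    Accepts en/em dash or hyphen as the range separator.  Raises
    ``ValueError`` on malformed labels or start >= end.
    """
    m = _LOCUS_RE.match(label.strip())
    if not m:
        raise ValueError(f"malformed locus label: {label!r}")
    start = int(m["start"].replace(",", ""))
    end = int(m["end"].replace(",", ""))
    if end <= start:
        raise ValueError(f"locus label has start >= end: {label!r}")
    return m["chrom"], start, end


# ---------------------------------------------------------------------------
# counts / profiles / segments / calls
# ---------------------------------------------------------------------------

_COUNTS_HEADER = (
    "# per-bin read counts; coordinates 0-based half-open; "
    "gc = GC fraction of the bin\n"
)


def write_counts_tsv(path: Path | str, sample: BinnedSample,
                     model: GenomeModel) -> None:
    mb = model.mappable_view()
    df = pd.DataFrame({
        "chrom": [mb.chrom_names[i] for i in mb.chrom],
        "start": mb.start,
        "end": mb.end,
        "gc": np.round(mb.gc, 6),
        "count": sample.counts,
    })
    with open(path, "w") as fh:
        fh.write(_COUNTS_HEADER)
        fh.write(f"# sample_id={sample.sample_id} "
                 f"total_reads={sample.total_reads}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_counts_tsv(path: Path | str) -> pd.DataFrame:
    """Read a counts table; returns columns chrom/start/end/gc/count."""
    df = _read_tsv(path, required={"chrom", "start", "end", "gc", "count"})
    if (df["end"] <= df["start"]).any():
        bad = int(np.argmax((df["end"] <= df["start"]).values)) + 1
        raise ValueError(f"{path}: record {bad} has start >= end")
    if (df["count"] < 0).any():
        raise ValueError(f"{path}: negative counts")
    return df


def counts_to_sample(df: pd.DataFrame, sample_id: str) -> BinnedSample:
    counts = df["count"].to_numpy(dtype=np.int64)
    return BinnedSample(sample_id=sample_id, counts=counts,
                        total_reads=int(counts.sum()))


def write_profile_tsv(path: Path | str, profile: NormalizedProfile,
                      model: GenomeModel) -> None:
    mb = model.mappable_view()
    df = pd.DataFrame({
        "chrom": [mb.chrom_names[i] for i in mb.chrom],
        "start": mb.start,
        "end": mb.end,
        "ratio": profile.ratio,
    })
    with open(path, "w") as fh:
        fh.write("# normalized copy ratio per bin; diploid expectation 1.0; "
                 "coordinates 0-based half-open\n")
        fh.write(f"# sample_id={profile.sample_id} "
                 f"noise_sd={profile.noise_sd!r}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_profile_tsv(path: Path | str) -> tuple[pd.DataFrame, str, float]:
    """Returns (table, sample_id, noise_sd)."""
    sample_id, noise_sd = "", float("nan")
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            m = re.search(r"sample_id=(\S+) noise_sd=(\S+)", line)
            if m:
                sample_id, noise_sd = m[1], float(m[2])
    df = _read_tsv(path, required={"chrom", "start", "end", "ratio"})
    return df, sample_id, noise_sd


def write_segments_tsv(path: Path | str, segments: Sequence[Segment]) -> None:
    df = pd.DataFrame([{
        "chrom": s.chrom, "start_bp": s.start_bp, "end_bp": s.end_bp,
        "n_bins": s.n_bins, "mean_ratio": s.mean_ratio, "z": s.z_score,
    } for s in segments])
    with open(path, "w") as fh:
        fh.write("# equal-level segments; coordinates 0-based half-open bp; "
                 "mean_ratio diploid=1; z approximated segment z-score\n")
        df.to_csv(fh, sep="\t", index=False)


def read_segments_tsv(path: Path | str) -> pd.DataFrame:
    return _read_tsv(path, required={"chrom", "start_bp", "end_bp",
                                     "n_bins", "mean_ratio", "z"})


def write_calls_bed(path: Path | str, calls: Sequence[CNVCall]) -> None:
    """BED5+ : chrom, start, end, name=type, score=z, deviation,
    sample_id."""
    with open(path, "w") as fh:
        fh.write("# maternal CNV calls; BED 0-based half-open; "
                 "name=gain|loss score=z extra: deviation, sample_id\n")
        for c in calls:
            fh.write(f"{c.chrom}\t{c.start_bp}\t{c.end_bp}\t{c.type}\t"
                     f"{c.z_score:.4f}\t{c.deviation:.4f}\t{c.sample_id}\n")


def read_calls_bed(path: Path | str) -> list[CNVCall]:
    calls: list[CNVCall] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 7:
                raise ValueError(f"{path}: line {ln}: expected 7 fields, "
                                 f"got {len(parts)}")
            chrom, start, end, ctype, z, dev, sid = parts
            start, end = int(start), int(end)
            if end <= start:
                raise ValueError(f"{path}: line {ln}: start >= end")
            if ctype not in ("gain", "loss"):
                raise ValueError(f"{path}: line {ln}: bad type {ctype!r}")
            dev = float(dev)
            calls.append(CNVCall(
                sample_id=sid, chrom=chrom, start_bp=start, end_bp=end,
                type=ctype, length_bp=end - start, deviation=dev,
                z_score=float(z),
                mean_ratio=1.0 + (dev if ctype == "gain" else -dev) * 0.5,
            ))
    return calls


# ---------------------------------------------------------------------------
# cohort-level tables
# ---------------------------------------------------------------------------

def write_mov_table_tsv(path: Path | str, clusters: Sequence[MOVCluster],
                        movs_only: bool = True) -> None:
    rows = [{
        "cnv": ("dup" if c.type == "gain" else "del"),
        "size_bp": c.end_bp - c.start_bp,
        "coordinates": c.label,
        "n": c.n_occurrences,
        "frequency_pct": c.frequency_pct,
    } for c in clusters if c.is_mov or not movs_only]
    df = pd.DataFrame(rows, columns=["cnv", "size_bp", "coordinates",
                                     "n", "frequency_pct"])
    with open(path, "w") as fh:
        fh.write("# recurrent variants; coordinates 0-based half-open; "
                 "frequency_pct = 100*n/N\n")
        df.to_csv(fh, sep="\t", index=False)


def write_density_tsv(path: Path | str, rows: Sequence[DensityRow]) -> None:
    df = pd.DataFrame([{
        "chrom": r.chrom, "effective_length_bp": r.effective_length_bp,
        "n_variants": r.n_variants, "per_mb": r.per_mb,
        "p_value": r.p_value, "significant": r.significant,
    } for r in rows])
    with open(path, "w") as fh:
        fh.write("# variants per megabase of effective (mappable) length; "
                 "lower-tail normal p\n")
        df.to_csv(fh, sep="\t", index=False)


def write_comparisons_tsv(path: Path | str,
                          comps: Sequence[DbComparison]) -> None:
    df = pd.DataFrame([{
        "locus": c.locus, "cohort_n": c.cohort_n, "cohort_N": c.cohort_N,
        "db_freq_pct": c.db_freq_pct, "db_N": c.db_N,
        "chi2": c.chi2_stat, "p_value": c.p_value,
        "degenerate": c.degenerate,
    } for c in comps])
    with open(path, "w") as fh:
        fh.write("# cohort vs database frequency, Pearson chi-squared "
                 "(1 df, no continuity correction)\n")
        df.to_csv(fh, sep="\t", index=False)


def read_db_frequencies_tsv(path: Path | str) -> pd.DataFrame:
    """Population frequency table: locus, freq_pct, cohort_size, source."""
    df = _read_tsv(path, required={"locus", "freq_pct", "cohort_size",
                                   "source"})
    if ((df["freq_pct"] < 0) | (df["freq_pct"] > 100)).any():
        raise ValueError(f"{path}: freq_pct outside [0, 100]")
    return df


# ---------------------------------------------------------------------------
# truth / manifest
# ---------------------------------------------------------------------------

def write_truth_bed(path: Path | str, samples: Sequence[BinnedSample]) -> None:
    with open(path, "w") as fh:
        fh.write("# injected truth variants; chrom start end copy_state "
                 "carrier sample_id\n")
        for s in samples:
            for v in s.truth:
                fh.write(f"{v.chrom}\t{v.start_bp}\t{v.end_bp}\t"
                         f"{v.copy_state}\t{v.carrier}\t{s.sample_id}\n")


def read_truth_bed(path: Path | str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}: line {ln}: expected 6 fields")
            rows.append({
                "chrom": parts[0], "start_bp": int(parts[1]),
                "end_bp": int(parts[2]), "copy_state": int(parts[3]),
                "carrier": parts[4], "sample_id": parts[5],
            })
    return pd.DataFrame(rows)


def write_manifest_tsv(path: Path | str, samples: Sequence[BinnedSample],
                       paths: Sequence[str]) -> None:
    df = pd.DataFrame({
        "sample_id": [s.sample_id for s in samples],
        "counts_path": list(paths),
        "total_reads": [s.total_reads for s in samples],
        "fetal_fraction": [s.fetal_fraction for s in samples],
    })
    with open(path, "w") as fh:
        fh.write("# cohort manifest\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# packaged reference-cohort fixtures
# ---------------------------------------------------------------------------

def _fixture_path(name: str):
    return resources.files("matcnv.fixtures").joinpath(name)


def load_reference_mov_table() -> pd.DataFrame:
    """Most frequent recurrent maternal CNVs of the reference screening
    cohort (N=6,422): occurrence counts, cohort frequencies and the
    matched population-database frequencies (non-Finnish European)."""
    with resources.as_file(_fixture_path("reference_mov_table.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    parsed = df["coordinates"].map(parse_locus_label)
    df["chrom"] = [t[0] for t in parsed]
    df["start_bp"] = [t[1] for t in parsed]
    df["end_bp"] = [t[2] for t in parsed]
    return df


def load_reference_density_table() -> pd.DataFrame:
    """Per-chromosome distinct-variant counts and effective (mappable)
    lengths of the reference screening cohort."""
    with resources.as_file(
            _fixture_path("reference_chromosome_density.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#",
                           dtype={"chrom": str})


# ---------------------------------------------------------------------------

def _read_tsv(path: Path | str, required: set[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # noqa: BLE001 - annotate file context
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax()) + 2  # +header +1-based
        raise ValueError(f"{path}: malformed row at line ~{bad}")
    return df
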