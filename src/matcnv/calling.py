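"""Maternal CNV calling from segmented copy-ratio profiles.

A heterozygous one-copy maternal gain or loss shifts the diploid ratio
by +/-0.5 irrespective of fetal fraction, while a fetal-only event
shifts it by only +/-ff/2 (ff rarely exceeds 0.25 in practice).  A
segment is therefore designated a maternal CNV when

* it is at least ``min_length_bp`` long (default 200 kb, the detection
  resolution of 20 kb-binned low-coverage data), and
* its signal deviation ``|mean_ratio - 1| / 0.5`` — the observed shift
  as a fraction of the heterozygous single-copy shift — exceeds
  ``deviation_threshold`` (default 0.75, i.e. ratio <= 0.625 or
  >= 1.375).

Maternal het events sit at deviation ~1.0 and pass; fetal events at
realistic fetal fractions sit at deviation ~ff and are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .segment import Segment

HET_SHIFT = 0.5  # ratio shift of a one-copy change on a diploid background


@dataclass(frozen=True)
class CNVCall:
    """A maternal copy-number call (bin-aligned, 0-based half-open)."""

    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    type: Literal["gain", "loss"]
    length_bp: int
    deviation: float
    z_score: float
    mean_ratio: float

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start_bp, self.end_bp)


def signal_deviation(mean_ratio: float) -> float:
    """|mean_ratio - 1| as a fraction of the heterozygous shift 0.5."""
    return abs(mean_ratio - 1.0) / HET_SHIFT


def call_maternal_cnvs(
    segments: list[Segment],
    sample_id: str = "",
    min_length_bp: int = 200_000,
    deviation_threshold: float = 0.75,
) -> list[CNVCall]:
    """Threshold segments into maternal gain/loss calls.

    A segment qualifies iff its span is >= ``min_length_bp`` AND its
    signal deviation strictly exceeds ``deviation_threshold``.  Adjacent
    qualifying segments are never merged: one segment, one call.
    """
    if min_length_bp <= 0 or deviation_threshold <= 0:
        raise ValueError("thresholds must be positive")
    calls: list[CNVCall] = []
    for seg in segments:
        length = seg.end_bp - seg.start_bp
        dev = signal_deviation(seg.mean_ratio)
        if length < min_length_bp or dev <= deviation_threshold:
            continue
        calls.append(CNVCall(
            sample_id=sample_id,
            chrom=seg.chrom,
            start_bp=seg.start_bp,
            end_bp=seg.end_bp,
            type="gain" if seg.mean_ratio > 1.0 else "loss",
            length_bp=length,
            deviation=dev,
            z_score=seg.z_score,
            mean_ratio=seg.mean_ratio,
        ))
    return calls
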