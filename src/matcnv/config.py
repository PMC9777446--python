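"""Pipeline configuration: one dataclass per stage, YAML round-trip.

Every threshold defaults to the values the analysis is anchored to:
20 kb bins, LOESS span 0.3 with k=3 panel components, CBS at
alpha 0.01 with 1,000 permutations and min width 2, maternal calls at
>= 200 kb and signal deviation > 0.75, MOV clustering at reciprocal
overlap >= 0.75.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .genome import DEFAULT_BIN_SIZE, HG19_CHROM_LENGTHS, GenomeModel, \
    build_genome_model, toy_genome
from .simulate import CohortSpec, TruthVariant


@dataclass
class GenomeConfig:
    preset: str = "toy"                   # "toy" | "hg19" | "custom"
    bin_size: int = DEFAULT_BIN_SIZE
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    unmappable_intervals: list[list[Any]] = field(default_factory=list)

    def build(self) -> GenomeModel:
        if self.preset == "toy":
            return toy_genome(bin_size=self.bin_size)
        if self.preset == "hg19":
            return build_genome_model(HG19_CHROM_LENGTHS,
                                      bin_size=self.bin_size)
        if self.preset == "custom":
            if not self.chrom_lengths:
                raise ValueError("custom genome requires chrom_lengths")
            masks = [tuple(iv) for iv in self.unmappable_intervals]
            return build_genome_model(self.chrom_lengths,
                                      bin_size=self.bin_size,
                                      unmappable_intervals=masks)
        raise ValueError(f"unknown genome preset {self.preset!r}")


@dataclass
class SimulateConfig:
    n_samples: int = 20
    reads_min: int = 5_000_000
    reads_max: int = 20_000_000
    fetal_fraction_mean: float = 0.10
    fetal_fraction_sd: float = 0.04
    fetal_fraction_max: float = 0.30
    gc_bias_strength: float = 8.0
    gc_bias_peak: float = 0.42
    batch_rank: int = 2
    batch_scale: float = 0.08
    dispersion: float = 0.01
    count_model: str = "nb"
    # each: {chrom, start_bp, end_bp, copy_state, carrier, frequency}
    variants: list[dict[str, Any]] = field(default_factory=list)

    def to_spec(self, seed: int) -> CohortSpec:
        catalog = tuple(
            TruthVariant(
                chrom=v["chrom"], start_bp=int(v["start_bp"]),
                end_bp=int(v["end_bp"]), copy_state=int(v["copy_state"]),
                carrier=v.get("carrier", "maternal"),
                population_frequency=float(v.get("frequency", 0.0)),
            ) for v in self.variants)
        return CohortSpec(
            n_samples=self.n_samples,
            reads_range=(self.reads_min, self.reads_max),
            fetal_fraction_mean=self.fetal_fraction_mean,
            fetal_fraction_sd=self.fetal_fraction_sd,
            fetal_fraction_max=self.fetal_fraction_max,
            gc_bias_strength=self.gc_bias_strength,
            gc_bias_peak=self.gc_bias_peak,
            batch_rank=self.batch_rank,
            batch_scale=self.batch_scale,
            dispersion=self.dispersion,
            count_model=self.count_model,
            variant_catalog=catalog,
            seed=seed,
        )


@dataclass
class NormalizeConfig:
    span: float = 0.3
    k: int = 3
    leave_one_out: bool = True


@dataclass
class SegmentConfig:
    alpha: float = 0.01
    n_perm: int = 1000
    min_width: int = 2


@dataclass
class CallConfig:
    min_length_bp: int = 200_000
    deviation_threshold: float = 0.75


@dataclass
class CohortStageConfig:
    min_reciprocal_overlap: float = 0.75
    db_path: str | None = None


@dataclass
class PipelineConfig:
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    normalize: NormalizeConfig = field(default_factory=NormalizeConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    call: CallConfig = field(default_factory=CallConfig)
    cohort: CohortStageConfig = field(default_factory=CohortStageConfig)
    seed: int = 0
    out_dir: str = "matcnv_out"

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        return cls(
            genome=GenomeConfig(**d.get("genome", {})),
            simulate=SimulateConfig(**d.get("simulate", {})),
            normalize=NormalizeConfig(**d.get("normalize", {})),
            segment=SegmentConfig(**d.get("segment", {})),
            call=CallConfig(**d.get("call", {})),
            cohort=CohortStageConfig(**d.get("cohort", {})),
            seed=int(d.get("seed", 0)),
            out_dir=str(d.get("out_dir", "matcnv_out")),
        )

    def to_yaml(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
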