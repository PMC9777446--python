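"""Simulate a small cfDNA screening cohort with a known injected CNV.

Builds the desk-scale toy genome (4 autosomes + X, 20 kb bins), injects
a 400 kb maternal heterozygous duplication at 10% population frequency,
and draws 12 samples at ~0.25x-equivalent depth.
"""

import numpy as np

from matcnv import CohortSpec, TruthVariant, simulate_cohort, toy_genome

model = toy_genome()
dup = TruthVariant("chr1", 5_000_000, 5_400_000, copy_state=3,
                   carrier="maternal", population_frequency=0.10)
spec = CohortSpec(n_samples=12, reads_range=(380_000, 520_000),
                  variant_catalog=(dup,), seed=42)
samples = simulate_cohort(model, spec)

mb = model.mappable_view()
inside = (mb.chrom == 0) & (mb.start >= dup.start_bp) & (mb.end <= dup.end_bp)
print(f"genome: {model.n_bins} bins ({model.n_mappable} mappable), "
      f"bin size {model.bin_size:,} bp")
for s in samples:
    carrier = "carrier" if s.truth else "diploid"
    ratio = s.counts[inside].mean() / np.median(s.counts)
    print(f"{s.sample_id}: {s.total_reads:>7,} reads  ff={s.fetal_fraction:.2f}"
          f"  mean bin ratio in dup locus = {ratio:4.2f}  ({carrier})")
print("\nCarriers show a bin-count ratio near 1.5 over the duplicated "
      "interval (one extra maternal copy of two); non-carriers sit near "
      "1.0.  The fetal fraction does not move maternal signal.")
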