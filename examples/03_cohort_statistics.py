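"""Cohort-level statistics on the packaged reference tables.

Uses the shipped reference-cohort summary (N=6,422 screening samples):
recomputes each locus's cohort frequency, contrasts two loci against
their population-database frequencies with the 2x2 chi-squared test,
and runs the chromosome variants-per-megabase outlier analysis.
"""

from matcnv import (GNOMAD_COHORT_SIZE, REFERENCE_COHORT_SIZE,
                    chromosome_density, compare_to_db,
                    load_reference_density_table, load_reference_mov_table,
                    mov_frequency_pct)

mov = load_reference_mov_table()
print("most frequent recurrent variants (top 5):")
for _, r in mov.head(5).iterrows():
    freq = mov_frequency_pct(r["n"], REFERENCE_COHORT_SIZE)
    print(f"  {r['cnv']:<14s} {r['coordinates']:<32s} "
          f"n={r['n']:>3d}  {freq:.3f}%")

print("\ndatabase contrasts (vs gnomAD non-Finnish European, "
      f"N={GNOMAD_COHORT_SIZE:,}):")
for label in ("dup 15q13.3", "del 15q11.2"):
    r = mov[mov["cnv"] == label].iloc[0]
    res = compare_to_db(int(r["n"]), REFERENCE_COHORT_SIZE,
                        float(r["gnomad_nf_pct"]), GNOMAD_COHORT_SIZE,
                        locus=label)
    verdict = "different" if res.p_value < 0.05 else "compatible"
    print(f"  {label:<14s} cohort {mov_frequency_pct(int(r['n']), REFERENCE_COHORT_SIZE):.3f}% "
          f"vs db {r['gnomad_nf_pct']}%  chi2={res.chi2_stat:6.2f} "
          f"p={res.p_value:.2e}  -> {verdict}")

dens = load_reference_density_table()
rows = chromosome_density(
    dict(zip(dens["chrom"], dens["n_variants"])),
    dict(zip(dens["chrom"], dens["effective_length_bp"])))
print("\nvariants per megabase of effective chromosome length:")
for r in rows:
    flag = "  <-- significantly variant-poor" if r.significant else ""
    if r.chrom in ("2", "19", "X") or r.significant:
        print(f"  chr{r.chrom:<3s} {r.per_mb:.9f} per Mb  "
              f"p={r.p_value:.6f}{flag}")
print("\nOnly chromosome 19 falls in the lower 5% tail of the "
      "across-chromosome density distribution: it carries far fewer "
      "large CNVs than its mappable size predicts.")
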