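"""Age-corrected anticipation analysis of a small pedigree.

Measured telomere lengths are projected back to birth ("initial telomere
length") with a linear shortening rate; shrinking per-generation means
indicate genetic anticipation.
"""

from gelquant import PedigreeRecord, summarize_anticipation

records = [
    PedigreeRecord("III-1", 3, age_years=52, measured_tl_kb=6.74,
                   genotype="carrier"),
    PedigreeRecord("III-2", 3, age_years=47, measured_tl_kb=6.89,
                   genotype="carrier"),
    PedigreeRecord("IV-1", 4, age_years=21, measured_tl_kb=7.11,
                   genotype="affected"),
    PedigreeRecord("IV-2", 4, age_years=16, measured_tl_kb=7.26,
                   genotype="carrier"),
]
links = [("III-1", "IV-1"), ("III-2", "IV-2")]

summary = summarize_anticipation(records, rate_bp_per_year=30.0, links=links)
for g, n, mean in summary.per_generation:
    print(f"generation {g}: n={n}, mean initial TL {mean:.3f} kb")
for (g1, g2), delta in summary.deltas.items():
    print(f"delta {g1}->{g2}: {delta:+.0f} bp")
print(f"per year of age gap: {summary.per_year_delta_bp:+.1f} bp/yr")
print(f"monotone anticipation: {summary.monotone_anticipation}")
# a positive delta means the later generation started life with shorter
# telomeres even after removing the aging effect.
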