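"""Load a panel manifest, apply the design filter, and summarize gene categories.

The synthetic generator's default panel mirrors the study shape: 326 curated
SNPs of which 15 were dropped by the assay designer and 2 are duplicate
entries, leaving 309 analyzable variants (94.7%, truncated).
"""

from adrnet.panel import filter_panel, gene_category_summary
from adrnet.simulate import SimulationConfig, build_panel

manifest, _ = build_panel(SimulationConfig(seed=17))
filtered, report = filter_panel(manifest)

print(f"input variants:      {report.n_input}")
print(f"design-excluded:     {report.n_design_excluded}")
print(f"duplicates:          {report.n_duplicates}")
print(f"retained:            {report.n_retained} ({report.retained_fraction}%)")
print()
print("genes per functional category (each gene counted once):")
for category, count in gene_category_summary(filtered).items():
    print(f"  {category:<24} {count}")
# The retained fraction is truncated, not rounded: 309/326 = 94.78..% prints
# as 94.7%, matching the truncation convention used for all cohort percentages.
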