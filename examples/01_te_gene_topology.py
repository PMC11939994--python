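"""Classify TE copies against their nearest genes and summarize the mix.

Generates a small synthetic genome with a known relation-category mix,
runs the classifier, and prints the category-by-superfamily summary.
"""

from telandscape.synthetic import SimConfig, gen_annotation
from telandscape.topology import classify_all, relation_summary, distance_profile

cfg = SimConfig(seed=1, n_tes=2000)
genes, tes, chrom_sizes, truth = gen_annotation(cfg)

records = classify_all(tes, genes)
summary = relation_summary(records)
print(summary)
print()
prof = distance_profile(records)
print(prof.groupby("side").sum())

# The Proportion_pct column is the share of mapped TEs per category; the
# generator targeted ~45% upstream / ~42% downstream / ~10% nested / ~3%
# boundary-overlapping, and the distance profile splits proximal TEs at the
# 5 kb bin (closed at exactly 5000 bp).
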