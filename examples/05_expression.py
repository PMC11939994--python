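"""Expression thresholds: CPM, a naive two-group test, and DE filtering.

Simulates a 3-vs-3 ecotype count matrix with a planted DE fraction, then
applies the standard threshold set (baseMean > 10, |log2FC| >= 2,
padj < 0.05).
"""

from telandscape.expression import cpm, de_filter, naive_de
from telandscape.synthetic import SimConfig, gen_counts

cfg = SimConfig(seed=5, n_features=2000, de_fraction=0.05, effect_size=8.0,
                nb_dispersion=200)
counts, groups, truth = gen_counts(cfg)

norm = cpm(counts)
stats = naive_de(norm, groups)
up, down = de_filter(stats, base_min=10, lfc_min=2, alpha=0.05)

planted = set(truth.index[truth["is_de"]])
print(f"planted DE features: {len(planted)}")
print(f"called up: {len(up)}, down: {len(down)}")
print(f"recovered: {len((up | down) & planted)} of {len(planted)}")
print(f"false calls: {len((up | down) - planted)}")

# With an 8-fold planted effect the estimated |log2FC| clears the >= 2
# threshold comfortably; the filter's inequalities are exactly as printed
# (strict baseMean > 10, non-strict |log2FC| >= 2, strict padj < 0.05).
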