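"""Quantify retrograde-tracing cell counts.

Loads the packaged reference count table (presynaptic neurons of ventral CA1
in four afferent regions, five brains), normalizes each region by the
per-brain four-region total (controlling for injection variability), and
reports the across-brain medians. Also shows the antero-posterior axis
distribution on simulated soma coordinates.
"""

import numpy as np

from recogmem.anatomy import (
    axis_distribution,
    double_label_fraction,
    load_reference_counts,
    normalized_fractions,
)

table = load_reference_counts()
fractions, medians = normalized_fractions(table)

print("region            median normalized fraction")
for region in table.regions:
    print(f"  {region:15s} {medians[region]:.2f}")
print(f"per-brain fractions sum to {fractions.sum(axis=0).iloc[0]:.9f}")

# axis distribution of simulated somata: two density peaks, more posterior
rng = np.random.default_rng(1)
coords = np.concatenate([rng.normal(1.0, 0.6, 150), rng.normal(-2.0, 0.8, 250)])
dist = axis_distribution(coords, bin_mm=1.0, split_at_mm=0.0)
print(f"anterior fraction:  {dist.anterior_fraction:.2f}")
print(f"posterior fraction: {dist.posterior_fraction:.2f}")

print(f"double-labeled example: {double_label_fraction(15, 52):.1f}% of tracer-positive cells")

# The endopiriform nucleus carries the largest normalized share of ventral-CA1
# afferents among the four regions (~0.45 of the pooled count), and labeled
# somata concentrate posterior to bregma.
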