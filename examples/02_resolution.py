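"""Source-resolution statistics: how small a fertilizer contribution is detectable.

The quotient of isotope enrichment (labeled minus unlabeled source 67:66
ratio) and experimental precision (2sd over treatment replicates) counts the
statistically distinguishable ratios between the sources; its reciprocal
(x100) is the smallest detectable source share of plant Zn.
"""

from zntrace import (
    detectable_contribution,
    distinguishable_ratios,
    enrichment,
    resolution_within_range,
)

cases = {
    "direct (labeled compost)": (1.5552, 0.1463, 0.0034),
    "indirect, acidic soil": (0.3052, 0.1473, 0.0027),
    "indirect, alkaline soil": (0.2175, 0.1473, 0.0027),
}

for name, (labeled, unlabeled, precision) in cases.items():
    e = enrichment(labeled, unlabeled)
    n = distinguishable_ratios(e, precision)
    print(
        f"{name}: enrichment {e:.4f}, n = {n}, "
        f"detectable contribution {detectable_contribution(n):.2f}%"
    )

# Organic fertilizers rarely supply over half of plant Zn, so the resolution
# over the 0-50% sub-range is what matters in practice:
for name, (labeled, unlabeled, precision) in cases.items():
    if "indirect" in name:
        n50 = resolution_within_range(enrichment(labeled, unlabeled), precision, 0.5)
        print(f"{name}: {n50} distinguishable ratios within the 0-50% range")
# Direct labeling resolves contributions of ~0.24%; indirect labeling is
# coarser (1.7-3.9%) because the label is diluted by resident soil Zn.
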