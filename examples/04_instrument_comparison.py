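"""Bland-Altman comparison of a quadrupole vs a multicollector profile.

Simulates the same samples measured on both instruments and summarizes
their agreement: the bias (mean difference) and the limits of agreement
(bias +/- 1.96 sd of the differences).
"""

import numpy as np

from zntrace import AbundanceVector, bland_altman
from zntrace.compare import simulate_paired_ratio_means
from zntrace.simulate import InstrumentProfile

q = InstrumentProfile.quadrupole()  # 1.3% RSD per ratio, 12 repeats
mc = InstrumentProfile.multicollector()  # 0.05% RSD, 3 blocks x 20 cycles

true_ratio = AbundanceVector.natural().ratio()
rng = np.random.default_rng(42)
q_means, mc_means = simulate_paired_ratio_means(true_ratio, q, mc, n_pairs=57, rng=rng)

res = bland_altman(q_means, mc_means, shapiro=True)
rng_width = q_means.max() - q_means.min()
print(f"n pairs            = {res.n}")
print(f"bias               = {res.bias:+.6f} ratio units")
print(f"limits of agreement= [{res.loa_low:+.6f}, {res.loa_high:+.6f}]")
print(f"Shapiro-Wilk p     = {res.shapiro_p:.3f}")
# With no systematic offset between the instruments the bias hovers near
# zero; the width of the limits is set almost entirely by the quadrupole's
# replicate-mean noise (1.3%/sqrt(12) ~ 0.38% of the ratio), since the
# multicollector is ~25x more precise.
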