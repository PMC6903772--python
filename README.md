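# zntrace

Enriched stable-isotope source tracing for zinc in soil–fertilizer–plant
systems.

## The problem

Organic fertilizers can raise Zn concentrations in crops, but quantifying
*how much* of a plant's Zn actually came from the fertilizer (as opposed to
the soil) requires an isotope tracer.  Enriched stable-isotope tracing labels
either the fertilizer itself (**direct** labeling) or the soil-available Zn
pool (**indirect** labeling, used for complex organic fertilizers that cannot
be labeled homogeneously), then reads the mixture in the plant by ICP-MS
isotope-ratio measurement.  `zntrace` implements the full computational side
of this workflow for researchers in plant nutrition and soil science:

- isotope abundance ↔ ratio algebra for the five stable Zn isotopes
  (⁶⁴Zn, ⁶⁶Zn, ⁶⁷Zn, ⁶⁸Zn, ⁷⁰Zn);
- the two-source mass-balance mixing model and its inverse;
- mass-bias correction of raw ratios by standard-sample-standard bracketing
  with a power-law fractionation model;
- a synthetic ICP-MS generator (quadrupole and multicollector noise
  profiles, mass-bias drift, replicate schemes, matrix interference) so the
  whole chain is testable without instrument access;
- source-resolution statistics (distinguishable ratios, detectable
  contribution) and amendment dose arithmetic;
- Bland–Altman instrument comparison and paired t-tests;
- spike-size planning for indirect soil labeling.

## The model

Plant Zn is a two-source molar mixture.  With `f` the fraction of plant Zn
derived from the fertilizer and ⁶⁶Zn/⁶⁷Zn abundances (mole %, subscripts
`fert`, `soil`) of the two sources, the plant's ⁶⁷Zn:⁶⁶Zn ratio is

```
R_plant(f) = (f·⁶⁷Zn_fert + (1−f)·⁶⁷Zn_soil) / (f·⁶⁶Zn_fert + (1−f)·⁶⁶Zn_soil)
```

and inverting for `f` given a measured plant ratio `R` gives the
fertilizer-derived fraction in percent:

```
Zndf_fert% = 100 · (⁶⁶Zn_soil·R − ⁶⁷Zn_soil)
           / ((⁶⁷Zn_fert − ⁶⁷Zn_soil) − R·(⁶⁶Zn_fert − ⁶⁶Zn_soil))
```

Whether a contribution is *detectable* depends on the isotope enrichment
`E` (labeled minus unlabeled source ratio) relative to the experimental
precision `p` (2 sd of the ratio over independent treatment replicates):
`n = ⌊E/p⌋` ratios are statistically distinguishable between the sources,
and `100/n` % is the smallest resolvable source share.

## Worked example

```python
from zntrace import (AbundanceVector, SourcePair, labeled_abundances,
                     zndf_fertilizer, summarize_treatment,
                     enrichment, distinguishable_ratios, detectable_contribution)

soil = AbundanceVector.natural()          # reference plants read ~natural Zn
compost = labeled_abundances(31.0)        # 67Zn-labeled compost, A67 = 31%
pair = SourcePair(soil, compost)

ratios = [0.2698, 0.2731, 0.2705, 0.2722]     # four replicate plant 67:66 ratios
zndfs = [zndf_fertilizer(r, pair)[0] for r in ratios]
s = summarize_treatment(zndfs)
print(f"Zndf_fertilizer% = {s.zndf_fertilizer_pct:.2f} +/- {s.ci95_half_width:.2f}")
# Zndf_fertilizer% = 11.99 +/- 0.22

e = enrichment(0.3052, 0.1473)            # indirectly labeled acidic soil
n = distinguishable_ratios(e, 0.0027)     # at 2sd experimental precision
print(e, n, detectable_contribution(n))
# 0.1579  58  1.72
```

The first block says ~12% of the plant's Zn came from the compost, with a
replicate-based 95% CI of ±0.22 percentage points.  The second says the
indirect label separates the sources by 0.1579 ratio units, which at a
2sd precision of 0.0027 resolves 58 distinct ratio values — contributions
down to ~1.72% of plant Zn are detectable.

The `examples/` directory holds one short script per capability
(mixing model, resolution, calibration, instrument comparison, spike
planning, full pipeline).  A thin CLI exposes the same stages:
`zntrace run-all --seed 1 --out out/` runs the default virtual experiment
end to end.

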