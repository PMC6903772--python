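# Methods

## Isotope frame and representations

All computations use the five stable Zn isotopes (mass numbers 64, 66, 67,
68, 70) with AME atomic masses and IUPAC natural abundances
(49.17 / 27.73 / 4.04 / 18.45 / 0.61 mole %).  A composition is carried
either as an `AbundanceVector` (mole fractions in percent, renormalized to
exactly 100 on construction; inputs must already sum to 100 within 1e-6
relative) or as a `RatioSet` of ⁶⁷Zn:ˣˣZn molar ratios.  The conversions are
closed-form: with reference abundance `A_ref` and ratios `R_x = A_ref/A_x`,
closure gives `A_ref = 100/(1 + Σ 1/R_x)`.  The round trip is an identity to
1e-12 relative, which the suite verifies on random vectors.

⁶⁷Zn is the reference isotope throughout (configurable in `IsotopeSystem`),
because enriched-⁶⁷Zn labeling makes ⁶⁷Zn:⁶⁶Zn the natural reporting ratio.
Measured source ratios are treated as authoritative inputs even where they
differ slightly from the IUPAC-derived value (measured natural ⁶⁷Zn:⁶⁶Zn
values of ~0.146–0.148 versus the IUPAC-derived 0.1457 reflect real
instrument- and sample-level offsets, not errors to be reconciled).

## Two-source mixing model

Plant Zn is a molar mixture of soil-available Zn and fertilizer Zn; the
mass balance over ⁶⁶Zn and ⁶⁷Zn yields the forward model `plant_ratio(f)`
and its closed-form inverse `zndf_fertilizer(R)` (see README for the
formulas).  Properties maintained:

- the inverse composed with the forward map is the identity on [0, 1]
  (checked to 1e-10 on a 101-point grid over random source pairs);
- `Zndf_fert% + Zndf_soil% = 100` exactly (the soil share is defined as the
  complement, never computed independently);
- estimates outside a configurable admissible interval (default
  [−10, 110] %) are **flagged, not rejected** — replicate noise on
  near-endpoint mixtures legitimately produces small excursions past 0% or
  100%, and discarding them would bias treatment means;
- source pairs whose ⁶⁷Zn:⁶⁶Zn ratios are closer than a minimum separation
  raise an unresolvable-mixture error.  The constructor default is a pure
  numerical floor (1e-12); `SourcePair.with_precision` ties the threshold to
  10× a supplied experimental precision, the point at which fewer than a
  handful of ratio steps separate the endmembers.

Treatment summaries use the sample mean, sample sd, and a Student-t 95% CI
with n−1 degrees of freedom over independent treatment replicates (n ≥ 2
required; the study design this emulates uses n = 4).

## Mass-bias correction

Instrument mass discrimination is modeled by a power law factorized per
atomic mass unit: `R_meas = R_true · b(t)^Δm`, with Δm the *atomic-mass*
difference (u) between reference and denominator isotope (atomic masses
rather than mass-number differences; the distinction is ~0.1% per amu and
free to get right).  Bracketing standards of known composition pin `b` at
their acquisition times via `b = (R_meas/R_true)^(1/Δm)` from the 67:66
ratio (a joint per-ratio geometric-mean estimate is available behind a
flag); between standards `b` is interpolated linearly in time.

Interpolating the bias factor itself (rather than its reciprocal, the
correction factor) makes bracketing the **exact** inverse of a linearly
drifting instrument: the suite checks recovery of true ratios to 1e-10
relative under linear drift with noise off.  Samples outside the standard
envelope raise an error rather than extrapolate.

The isobaric interference of ⁶⁴Ni on mass 64 is not corrected; mass-64
ratios from unpurified simulations simply carry the run's interference
flag.  No exponential/Russell-law alternative or double-spike deconvolution
is provided.

## Synthetic measurement model

Noise is applied **multiplicatively at the ratio level** — each measured
ratio is the biased true ratio times (1 + ε), ε ~ N(0, RSD), independent per
ratio per acquisition — because precision specifications for these
instruments are quoted as per-ratio RSDs.  Defaults:

| profile | RSD per ratio | scheme |
|---|---|---|
| Q (quadrupole) | 1.3% (67:64, 67:66, 67:68), 2.7% (67:70) | 12 repeats per sample |
| MC (multicollector) | 0.05% | 3 blocks × 20 cycles, block means retained |

RSDs are treated as per-acquisition, so a sample's 12-repeat (or 60-cycle)
mean is correspondingly more precise.  MC standards are acquired as one
block of 20 cycles per bracketing event; Q standards as a single
acquisition.  The generator's empirical RSDs converge to the configured
values (checked at 10⁴ repeats within 5% relative).

Matrix interference for non-purified samples is additive in signal space:
each replicate's ratios imply relative channel intensities (closure to
100), channel *m* gains `matrix_level · fraction_m · total`, and ratios are
re-formed.  A zero profile or zero level returns the identical object, so
the purified path and the interference-off path are literally the same
code.  Interference magnitudes are free parameters; the default profile
(0.6% of total signal on mass 64, 0.4% on mass 67) produces unpurified
67:66 shifts of roughly +0.01 ratio units at natural composition — the
order observed when plant matrices are measured without ion-exchange
purification.

Randomness is hierarchical (`numpy` `SeedSequence`: experiment → treatment →
replicate), so identical seed + config reproduce byte-identical CSVs.

The generator emulates the statistical structure of real measurement
campaigns — replicate schemes, drift, per-ratio noise, an additive matrix
effect — but not plasma chemistry, concentration-dependent detector
nonlinearity, digestion/processing losses, or biological variability beyond
the treatment-replicate scatter implied by the noise model.  Passing tests
therefore demonstrate the correctness and statistical calibration of the
*analysis chain*, not the field accuracy of any particular instrument.

## Resolution statistics

`n = ⌊enrichment / precision⌋` with precision the 2sd itself (not sd).
Truncation (floor) rather than rounding implements the conservative reading
of "statistically distinguishable" — a partial step is not a resolvable
step; both conventions reproduce the printed reference values, and floor is
documented as this package's choice.  A relative guard of 1e-9 is applied
before truncation because quotients that are exact in real arithmetic
(0.0702/0.0027 = 26) can fall a half-ulp below the integer in binary
floating point; without the guard the count would lose a full unit to
representation error.  Negative enrichments floor at 0.  The within-range
variant scales the enrichment by the fraction of the mixing range of
practical interest (default 0.5, since organic-fertilizer contributions
rarely exceed half of plant Zn).

Dose arithmetic: `zn_input = content × rate / 1000` (mg Zn per kg soil);
`field_rate = rate × 10000·depth·density / 1000` (t amendment per ha),
defaults 0.2 m ploughing depth and 1.3 t m⁻³ bulk density.

## Method comparison

Bland–Altman: differences `d = x − y`, bias = mean(d), limits of agreement
= bias ± 1.96·sd(d).  The 95% band is interpreted as limits of agreement
(the standard output of the approach); k is configurable.  Shapiro–Wilk
normality checking and the paired t statistic are delegated to
`scipy.stats`; the Bland–Altman computation itself is authored here (no
installed package exposes it as a function).  Bonferroni adjustment
multiplies each raw p by the number of comparisons, capped at 1; a
zero-variance difference with nonzero mean is reported as p = 0 with a
degenerate-variance flag.  Significance letters share a letter between the
two members of a non-significant pair — adequate for pairwise
instrument-vs-instrument tables; no full compact-letter-display clique
algorithm is attempted.

## Spike planning

Mixing for spike design is computed in **molar space**: masses convert to
moles through each component's abundance-weighted atomic mass before
isotope amounts add.  This matters at percent level because enriched spikes
(e.g. A67 = 90%) have atomic weights ~2% above natural Zn.  The spike mass
for a target 67:66 ratio is the closed-form solution of the one-unknown
molar mixing equation, verified in the suite against a bisection oracle on
the mixing function; targets outside the [pool, spike) ratio interval are
infeasible (the spike's own ratio requires infinite addition).  The "pool"
is the plant-available soil Zn pool as probed by reference treatments
(e.g. DTPA-extractable as a proxy); exchange kinetics between soil Zn
compartments are out of scope, and the maximum tolerable pool increase is a
user constraint with no universal default — it must come from pretests on
the soil at hand.

## Pipeline and simulation sizes

`run_pipeline` is a pure function of (config, seed): simulate → bracket-
correct → mixing model → resolution report → Bland–Altman (Q vs MC on
identical samples; purified vs unpurified by re-simulating the same design
with interference on, Q only).  The experimental precision entering the
pipeline's resolution report is the mean 2sd over the Q instrument's
treatments (measured, not assumed); noise-free runs have zero spread and
report zero resolvable steps rather than dividing by zero.

The Monte-Carlo studies use sizes chosen to bound sampling error well below
the effects examined: parameter recovery runs 200 simulated experiments per
true fraction (5, 10, 30%) per instrument profile with 4 replicates each;
agreement coverage uses 1000 runs of 400 pairs (bias-vs-zero check) and one
run of 10⁴ pairs (limits-of-agreement coverage).  The recovery check uses a
3-standard-error band: the estimator's nonlinearity bias (second-order in
the ratio noise) is orders of magnitude below the Q profile's sampling
error at these sizes.

## Known limitations

- Strictly two sources, one sink; no three-source unmixing.
- No vendor raw-file readers; inputs are tabular CSV exports.
- The interference model is a phenomenological additive signal fraction,
  not species-specific plasma chemistry.
- Significance lettering is pairwise, not a general multi-group CLD.
- Mass-bias drift is linear within a bracketing interval by construction;
  strongly nonlinear drift between standards is not modeled and would not
  be exactly inverted.
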