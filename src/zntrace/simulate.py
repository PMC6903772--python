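"""Synthetic ICP-MS measurement generator.

Produces raw isotope-ratio data with the statistical structure the analysis
assumes, so every downstream stage (calibration, mixing model, resolution,
method comparison) is testable without instrument access:

* multiplicative per-ratio noise — each measured ratio is the true ratio
  times ``(1 + eps)`` with ``eps ~ N(0, rsd)`` drawn independently per ratio
  per repeat (precision specs for these instruments are quoted as per-ratio
  RSD, so noise is applied at ratio level, not per isotope channel);
* per-amu mass bias with slow linear drift, applied as
  ``R_meas = R_true * b(t)**dm`` (see :mod:`zntrace.calibration`);
* replicate schemes: a quadrupole (Q) profile measures each sample 12 times;
  a multicollector (MC) profile acquires 3 blocks x 20 cycles and retains
  block means;
* an additive matrix interference for non-purified samples, modeled at the
  signal level: the implied intensity of each isotope channel is augmented
  by a fraction of the total signal before ratios are re-formed.

Randomness is hierarchical: an experiment seed spawns per-treatment, then
per-replicate streams, so any sub-unit is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .calibration import BracketingSequence, SequenceEvent, apply_mass_bias
from .core import (
    DEFAULT_SYSTEM,
    ZN_MASS_NUMBERS,
    AbundanceVector,
    IsotopeSystem,
    RatioSet,
    SourcePair,
    abundances_from_ratios,
    plant_ratio,
    ratios_from_abundances,
)
from .errors import ConfigError, DomainError

#: Default per-ratio relative standard deviations (fractions, not percent).
Q_RSD: dict[int, float] = {64: 0.013, 66: 0.013, 68: 0.013, 70: 0.027}
MC_RSD: dict[int, float] = {64: 0.0005, 66: 0.0005, 68: 0.0005, 70: 0.0005}


@dataclass(frozen=True)
class InstrumentProfile:
    """Noise, replicate scheme, and mass-bias drift of one instrument."""

    name: str  # "Q" or "MC"
    ratio_rsd: Mapping[int, float]
    repeats: int = 12  # Q: repeats per sample; MC: ignored (blocks*cycles used)
    blocks: int | None = None  # MC only
    cycles: int | None = None  # MC only
    mass_bias_b0: float = 1.0  # per-amu bias factor at t = 0
    mass_bias_drift: float = 0.0  # linear drift of b per time unit

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.ratio_rsd.values()):
            raise DomainError("RSDs must be >= 0")
        if self.blocks is not None:
            if self.blocks < 1 or (self.cycles or 0) < 1:
                raise DomainError("blocks and cycles must be >= 1")
        elif self.repeats < 1:
            raise DomainError("repeats must be >= 1")

    def bias_at(self, t: float) -> float:
        b = self.mass_bias_b0 + self.mass_bias_drift * t
        if b <= 0:
            raise DomainError(f"mass-bias factor {b} <= 0 at t={t}")
        return b

    @classmethod
    def quadrupole(cls, **kw) -> "InstrumentProfile":
        return cls(name="Q", ratio_rsd=dict(Q_RSD), repeats=12, **kw)

    @classmethod
    def multicollector(cls, **kw) -> "InstrumentProfile":
        return cls(name="MC", ratio_rsd=dict(MC_RSD), blocks=3, cycles=20, **kw)


@dataclass(frozen=True)
class InterferenceProfile:
    """Additive spectral interference as a fraction of total signal per mass.

    ``fractions[m]`` is the interference intensity landing on mass ``m``,
    expressed as a fraction of the total Zn-channel signal, at unit matrix
    level; an all-zero profile is the purified (no interference) case.
    """

    fractions: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.fractions.values()):
            raise DomainError("interference fractions must be >= 0")
        object.__setattr__(self, "fractions", dict(self.fractions))

    @property
    def is_zero(self) -> bool:
        return all(v == 0 for v in self.fractions.values())


@dataclass(frozen=True)
class MeasurementRun:
    """Replicate raw ratio measurements of one sample on one instrument.

    ``times[i]`` is the acquisition time of replicate ``i``; the mass bias
    applied to that replicate was evaluated at that time.
    """

    sample_id: str
    instrument: str
    times: tuple[float, ...]
    replicates: tuple[RatioSet, ...]
    interference_flag: bool = False

    def mean_ratios(self) -> RatioSet:
        denominators = self.replicates[0].ratios.keys()
        return RatioSet(
            {
                m: float(np.mean([r[m] for r in self.replicates]))
                for m in denominators
            },
            reference=self.replicates[0].reference,
        )


def _noisy_ratios(
    true_rs: RatioSet,
    profile: InstrumentProfile,
    bias: float,
    n: int,
    rng: np.random.Generator,
    system: IsotopeSystem,
) -> list[RatioSet]:
    biased = apply_mass_bias(true_rs, bias, system)
    out = []
    for _ in range(n):
        out.append(
            RatioSet(
                {
                    m: r * (1.0 + rng.normal(0.0, profile.ratio_rsd.get(m, 0.0)))
                    for m, r in biased.ratios.items()
                },
                reference=biased.reference,
            )
        )
    return out


def simulate_measurement(
    true_av: AbundanceVector,
    profile: InstrumentProfile,
    t: float,
    rng: np.random.Generator,
    system: IsotopeSystem = DEFAULT_SYSTEM,
    sample_id: str = "sample",
    dt: float = 1.0,
) -> MeasurementRun:
    """Simulate one sample's raw replicate ratio measurements.

    Q profiles emit ``repeats`` independent ratio sets; MC profiles emit
    ``blocks`` ratio sets, each the mean of ``cycles`` noisy acquisitions.
    Replicate ``i`` (or block ``i``) is acquired at time ``t + i*dt`` with
    the mass bias evaluated at that time.
    """
    true_rs = ratios_from_abundances(true_av, system.reference_isotope)
    reps, times = [], []
    if profile.blocks is not None:
        for i in range(profile.blocks):
            ti = t + i * dt
            cycles = _noisy_ratios(
                true_rs, profile, profile.bias_at(ti), profile.cycles, rng, system
            )
            reps.append(
                RatioSet(
                    {
                        m: float(np.mean([c[m] for c in cycles]))
                        for m in true_rs.ratios
                    },
                    reference=true_rs.reference,
                )
            )
            times.append(ti)
    else:
        for i in range(profile.repeats):
            ti = t + i * dt
            reps.append(
                _noisy_ratios(true_rs, profile, profile.bias_at(ti), 1, rng, system)[0]
            )
            times.append(ti)
    return MeasurementRun(
        sample_id=sample_id,
        instrument=profile.name,
        times=tuple(times),
        replicates=tuple(reps),
    )


def apply_interference(
    run: MeasurementRun,
    ip: InterferenceProfile,
    matrix_level: float,
) -> MeasurementRun:
    """Add matrix interference to a run's implied signals and re-form ratios.

    Each replicate's ratios imply relative channel signals (via closure);
    channel ``m`` is augmented by ``matrix_level * fractions[m] * total``,
    then ratios are recomputed.  Zero profile or zero level is the identity
    (same objects, no recomputation).
    """
    if matrix_level < 0:
        raise DomainError("matrix_level must be >= 0")
    if matrix_level == 0 or ip.is_zero:
        return run
    new_reps = []
    for rs in run.replicates:
        signals = abundances_from_ratios(rs).abundance  # proportions summing to 100
        total = 100.0
        bumped = {
            m: signals[m] + matrix_level * ip.fractions.get(m, 0.0) * total
            for m in ZN_MASS_NUMBERS
        }
        new_reps.append(
            RatioSet(
                {m: bumped[rs.reference] / bumped[m] for m in rs.ratios},
                reference=rs.reference,
            )
        )
    return replace(run, replicates=tuple(new_reps), interference_flag=True)


@dataclass(frozen=True)
class Treatment:
    """One growth-trial treatment: a source pair, a true fertilizer fraction,
    and the replicate/purification scheme."""

    name: str
    soil_source: str
    fertilizer_source: str
    true_zndf: float  # fraction in [0, 1]; 0 for reference treatments
    n_replicates: int = 4
    purified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_zndf <= 1.0:
            raise DomainError(f"true_zndf={self.true_zndf} outside [0, 1]")
        if self.n_replicates < 2:
            raise ConfigError("each treatment needs >= 2 replicates")


@dataclass(frozen=True)
class VirtualExperiment:
    """Sources and treatments of a simulated growth trial."""

    sources: Mapping[str, AbundanceVector]
    treatments: tuple[Treatment, ...]
    standard: AbundanceVector = field(default_factory=AbundanceVector.natural)

    def __post_init__(self) -> None:
        for tr in self.treatments:
            for ref in (tr.soil_source, tr.fertilizer_source):
                if ref not in self.sources:
                    raise ConfigError(
                        f"treatment {tr.name!r} references undefined source {ref!r}"
                    )

    def true_plant_ratio(self, tr: Treatment) -> float:
        soil = self.sources[tr.soil_source]
        if tr.true_zndf == 0.0:
            return soil.ratio()
        pair = SourcePair(soil, self.sources[tr.fertilizer_source])
        return plant_ratio(tr.true_zndf, pair)

    def true_plant_abundances(self, tr: Treatment) -> AbundanceVector:
        soil = self.sources[tr.soil_source]
        fert = self.sources[tr.fertilizer_source]
        f = tr.true_zndf
        mixed = {
            m: f * fert[m] + (1.0 - f) * soil[m] for m in ZN_MASS_NUMBERS
        }
        return AbundanceVector(mixed)


@dataclass
class ExperimentDataset:
    """Simulated raw dataset: one bracketed sequence per
    (instrument, treatment, replicate), plus the generating truth."""

    sequences: dict[tuple[str, str, int], BracketingSequence]
    truth: dict[str, float]  # treatment name -> true zndf fraction
    experiment: VirtualExperiment


def _bracketed_sequence(
    run: MeasurementRun,
    standard_av: AbundanceVector,
    profile: InstrumentProfile,
    rng: np.random.Generator,
    system: IsotopeSystem,
) -> BracketingSequence:
    """Wrap a sample run in standard measurements: standard, repeats, standard."""
    std_rs = ratios_from_abundances(standard_av, system.reference_isotope)

    def measure_standard(t: float) -> RatioSet:
        # standards are acquired like a sample block: MC averages one block
        # of cycles, Q takes a single acquisition per bracketing event
        n = profile.cycles if profile.blocks is not None else 1
        acqs = _noisy_ratios(std_rs, profile, profile.bias_at(t), n, rng, system)
        return RatioSet(
            {m: float(np.mean([a[m] for a in acqs])) for m in std_rs.ratios},
            reference=std_rs.reference,
        )

    t_before = run.times[0] - 1.0
    t_after = run.times[-1] + 1.0
    events: list[SequenceEvent] = [
        SequenceEvent(t_before, "standard", "std", measure_standard(t_before))
    ]
    for i, (ti, rs) in enumerate(zip(run.times, run.replicates)):
        events.append(SequenceEvent(ti, "sample", f"{run.sample_id}/{i}", rs))
    events.append(SequenceEvent(t_after, "standard", "std", measure_standard(t_after)))
    return BracketingSequence(events=events, standard_true=standard_av)


def simulate_experiment(
    ve: VirtualExperiment,
    profiles: Sequence[InstrumentProfile],
    ip: InterferenceProfile | None = None,
    matrix_level: float = 1.0,
    seed: int = 0,
    system: IsotopeSystem = DEFAULT_SYSTEM,
) -> ExperimentDataset:
    """Simulate the full virtual experiment.

    For every treatment x replicate x instrument a bracketed sequence is
    emitted whose underlying truth is the treatment's mixed plant
    composition.  Non-purified treatments get the interference profile
    applied to their sample measurements (standards are clean solutions and
    stay interference-free).
    """
    ip = ip or InterferenceProfile()
    root = np.random.SeedSequence(seed)
    treat_seeds = root.spawn(len(ve.treatments))
    sequences: dict[tuple[str, str, int], BracketingSequence] = {}
    truth: dict[str, float] = {}
    for tr, tr_seed in zip(ve.treatments, treat_seeds):
        truth[tr.name] = tr.true_zndf
        true_av = ve.true_plant_abundances(tr)
        rep_seeds = tr_seed.spawn(tr.n_replicates * len(profiles))
        k = 0
        for profile in profiles:
            for rep in range(tr.n_replicates):
                rng = np.random.default_rng(rep_seeds[k])
                k += 1
                run = simulate_measurement(
                    true_av, profile, t=1.0, rng=rng, system=system,
                    sample_id=f"{tr.name}/r{rep}",
                )
                if not tr.purified:
                    run = apply_interference(run, ip, matrix_level)
                sequences[(profile.name, tr.name, rep)] = _bracketed_sequence(
                    run, ve.standard, profile, rng, system
                )
    return ExperimentDataset(sequences=sequences, truth=truth, experiment=ve)
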