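"""Mass-bias correction by standard-sample-standard bracketing.

ICP-MS instruments transmit heavier isotopes slightly differently from
lighter ones (mass discrimination), so a measured ratio deviates from the
true one by a smooth, slowly drifting factor.  Under a power-law
fractionation model the deviation factorizes per atomic mass unit:

    R_meas = R_true * b(t)**dm

where ``b(t)`` is the per-amu bias factor at time ``t`` and ``dm`` is the
atomic-mass difference (u) between the reference and denominator isotope
(from true atomic masses, not mass numbers).  Bracketing a standard of known
composition before and after each block of samples pins ``b`` at the
standard events; between standards it is interpolated linearly in time,
which makes the correction the exact inverse of a linearly drifting bias.

The bias is estimated from the 67:66 standard ratio by default; a joint
estimate (geometric mean over all four ratios) is available via
``joint=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .core import DEFAULT_SYSTEM, AbundanceVector, IsotopeSystem, RatioSet, ratios_from_abundances
from .errors import DomainError, UnbracketedSampleError


@dataclass(frozen=True)
class SequenceEvent:
    """One timed acquisition in a measurement sequence."""

    time: float
    kind: Literal["standard", "sample"]
    sample_id: str
    ratios: RatioSet


@dataclass
class BracketingSequence:
    """Ordered standard/sample events plus the standard's assumed composition.

    Every sample event must have at least one standard event before and one
    after it, and event times must strictly increase.
    """

    events: list[SequenceEvent]
    standard_true: AbundanceVector

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise DomainError("event times must be strictly increasing")
        std_times = [e.time for e in self.events if e.kind == "standard"]
        if not std_times:
            raise UnbracketedSampleError("sequence contains no standard events")
        lo, hi = min(std_times), max(std_times)
        for e in self.events:
            if e.kind == "sample" and not (lo <= e.time <= hi):
                raise UnbracketedSampleError(
                    f"sample {e.sample_id!r} at t={e.time} outside standard envelope [{lo}, {hi}]"
                )

    @property
    def standards(self) -> list[SequenceEvent]:
        return [e for e in self.events if e.kind == "standard"]

    @property
    def samples(self) -> list[SequenceEvent]:
        return [e for e in self.events if e.kind == "sample"]


@dataclass(frozen=True)
class CorrectionModel:
    """Piecewise-linear per-amu bias factor ``b(t)`` fitted at standards.

    ``correct_ratios`` divides each measured ratio by ``b(t)**dm``.
    """

    standard_times: np.ndarray
    standard_bias: np.ndarray
    envelope: tuple[float, float]

    def bias_at(self, t: float) -> float:
        lo, hi = self.envelope
        if not (lo <= t <= hi):
            raise UnbracketedSampleError(f"t={t} outside standard envelope [{lo}, {hi}]")
        return float(np.interp(t, self.standard_times, self.standard_bias))


def fit_bracketing(
    seq: BracketingSequence,
    system: IsotopeSystem = DEFAULT_SYSTEM,
    joint: bool = False,
) -> CorrectionModel:
    """Fit the per-amu bias factor at each standard event.

    At a standard event the bias is ``b = (R_meas / R_true)**(1/dm)`` from
    the 67:66 ratio (``dm = m67 - m66``); with ``joint=True`` the geometric
    mean of the per-ratio estimates over all four denominators is used.
    """
    std_true_ratios = ratios_from_abundances(seq.standard_true, system.reference_isotope)
    times, biases = [], []
    for ev in seq.standards:
        if joint:
            logs = []
            for m in system.denominators:
                dm = system.mass_difference(m)
                logs.append(np.log(ev.ratios[m] / std_true_ratios[m]) / dm)
            b = float(np.exp(np.mean(logs)))
        else:
            dm = system.mass_difference(66)
            b = float((ev.ratios[66] / std_true_ratios[66]) ** (1.0 / dm))
        if b <= 0:
            raise DomainError("non-positive bias factor")
        times.append(ev.time)
        biases.append(b)
    t = np.asarray(times)
    return CorrectionModel(
        standard_times=t,
        standard_bias=np.asarray(biases),
        envelope=(float(t.min()), float(t.max())),
    )


def correct_ratios(
    raw: RatioSet,
    model: CorrectionModel,
    t: float,
    system: IsotopeSystem = DEFAULT_SYSTEM,
) -> RatioSet:
    """Remove mass bias from a raw ratio set measured at time ``t``."""
    b = model.bias_at(t)
    factors = {m: b ** (-system.mass_difference(m)) for m in raw.ratios}
    return raw.scaled(factors)


def apply_mass_bias(
    true_ratios: RatioSet,
    bias_per_amu: float,
    system: IsotopeSystem = DEFAULT_SYSTEM,
) -> RatioSet:
    """Forward bias model used by the simulator: ``R_meas = R_true * b**dm``."""
    if bias_per_amu <= 0:
        raise DomainError("bias factor must be > 0")
    factors = {m: bias_per_amu ** system.mass_difference(m) for m in true_ratios.ratios}
    return true_ratios.scaled(factors)


def correct_sequence(
    seq: BracketingSequence,
    system: IsotopeSystem = DEFAULT_SYSTEM,
    joint: bool = False,
) -> list[tuple[SequenceEvent, RatioSet]]:
    """Fit the bracketing model and correct every sample event in one pass."""
    model = fit_bracketing(seq, system, joint=joint)
    return [(ev, correct_ratios(ev.ratios, model, ev.time, system)) for ev in seq.samples]
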