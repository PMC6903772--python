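"""Isotope data model and the two-source mixing model.

Zinc has five stable isotopes (mass numbers 64, 66, 67, 68, 70).  A sample's
isotopic composition is carried either as an :class:`AbundanceVector` (mole
fractions in percent, summing to 100) or as a :class:`RatioSet` of molar
ratios of a reference isotope (by default :sup:`67`Zn) over each of the other
four.  The two representations are exactly interconvertible.

Source tracing rests on a two-source, one-sink mass balance: the Zn in a
plant is a molar mixture of Zn taken up from the soil-available pool and Zn
taken up from the fertilizer.  Writing ``f`` for the fraction of plant Zn
derived from the fertilizer, the plant's 67:66 ratio is

    R_plant(f) = (f * A67_fert + (1-f) * A67_soil)
               / (f * A66_fert + (1-f) * A66_soil)

and inverting for ``f`` given a measured plant ratio yields the
fertilizer-derived fraction (reported in percent as ``Zndf_fertilizer%``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateSourceError,
    DomainError,
    IncompleteRatioSetError,
    InsufficientReplicationError,
    UnresolvableMixtureError,
)

#: Mass numbers of the five stable Zn isotopes, in increasing order.
ZN_MASS_NUMBERS: tuple[int, ...] = (64, 66, 67, 68, 70)

#: Atomic masses (u) of the stable Zn isotopes (AME2020 values).
ZN_ATOMIC_MASSES: dict[int, float] = {
    64: 63.9291420,
    66: 65.9260339,
    67: 66.9271277,
    68: 67.9248446,
    70: 69.9253192,
}

#: IUPAC natural abundances, mole fraction in percent.
IUPAC_ABUNDANCES: dict[int, float] = {
    64: 49.17,
    66: 27.73,
    67: 4.04,
    68: 18.45,
    70: 0.61,
}


@dataclass(frozen=True)
class AbundanceVector:
    """Isotopic composition as mole fractions in percent.

    Entries are renormalized to sum to exactly 100 on construction; the
    pre-normalization sum must already be 100 within ``rel_tol`` (default
    1e-6 relative) or a :class:`DomainError` is raised.
    """

    abundance: Mapping[int, float]
    rel_tol: float = 1e-6

    def __post_init__(self) -> None:
        ab = dict(self.abundance)
        if set(ab) != set(ZN_MASS_NUMBERS):
            raise DomainError(
                f"abundance vector must cover isotopes {ZN_MASS_NUMBERS}, got {sorted(ab)}"
            )
        if any(v < 0 for v in ab.values()):
            raise DomainError(f"negative abundance in {ab}")
        total = sum(ab.values())
        if total <= 0 or abs(total - 100.0) > 100.0 * self.rel_tol:
            raise DomainError(f"abundances sum to {total}, not 100 within rel_tol")
        object.__setattr__(
            self, "abundance", {m: 100.0 * ab[m] / total for m in ZN_MASS_NUMBERS}
        )

    def __getitem__(self, mass_number: int) -> float:
        return self.abundance[mass_number]

    def as_array(self) -> np.ndarray:
        return np.array([self.abundance[m] for m in ZN_MASS_NUMBERS])

    def atomic_mass(self) -> float:
        """Abundance-weighted atomic mass (u) of this composition."""
        return sum(self.abundance[m] * ZN_ATOMIC_MASSES[m] for m in ZN_MASS_NUMBERS) / 100.0

    def ratio(self, numerator: int = 67, denominator: int = 66) -> float:
        den = self.abundance[denominator]
        if den <= 0:
            raise DomainError(f"zero abundance of isotope {denominator}")
        return self.abundance[numerator] / den

    @classmethod
    def natural(cls) -> "AbundanceVector":
        return cls(IUPAC_ABUNDANCES)


@dataclass(frozen=True)
class IsotopeSystem:
    """The fixed frame for all conversions: Zn isotope masses, natural
    abundances, and the reference isotope used to express ratios."""

    isotope_masses: Mapping[int, float] = field(
        default_factory=lambda: dict(ZN_ATOMIC_MASSES)
    )
    natural_abundance: AbundanceVector = field(
        default_factory=AbundanceVector.natural
    )
    reference_isotope: int = 67

    def __post_init__(self) -> None:
        masses = [self.isotope_masses[m] for m in sorted(self.isotope_masses)]
        if any(b <= a for a, b in zip(masses, masses[1:])):
            raise DomainError("isotope masses must increase strictly with mass number")
        if self.reference_isotope not in self.isotope_masses:
            raise DomainError(f"unknown reference isotope {self.reference_isotope}")

    def mass_difference(self, denominator: int) -> float:
        """Mass difference (u) between reference and denominator isotope."""
        return self.isotope_masses[self.reference_isotope] - self.isotope_masses[denominator]

    @property
    def denominators(self) -> tuple[int, ...]:
        return tuple(m for m in ZN_MASS_NUMBERS if m != self.reference_isotope)


#: Module-level default system (67 reference, IUPAC abundances).
DEFAULT_SYSTEM = IsotopeSystem()


@dataclass(frozen=True)
class RatioSet:
    """Molar isotope ratios reference:denominator for the four non-reference
    isotopes, e.g. 67:64, 67:66, 67:68, 67:70."""

    ratios: Mapping[int, float]
    reference: int = 67

    def __post_init__(self) -> None:
        expected = {m for m in ZN_MASS_NUMBERS if m != self.reference}
        missing = expected - set(self.ratios)
        if missing:
            raise IncompleteRatioSetError(f"missing denominator isotopes {sorted(missing)}")
        extra = set(self.ratios) - expected
        if extra:
            raise DomainError(f"unexpected denominator isotopes {sorted(extra)}")
        if any(v <= 0 for v in self.ratios.values()):
            raise DomainError("all ratios must be > 0")
        object.__setattr__(self, "ratios", dict(self.ratios))

    def __getitem__(self, denominator: int) -> float:
        return self.ratios[denominator]

    def scaled(self, factors: Mapping[int, float]) -> "RatioSet":
        """Return a copy with each ratio multiplied by its factor."""
        return RatioSet(
            {m: r * factors.get(m, 1.0) for m, r in self.ratios.items()},
            reference=self.reference,
        )


@dataclass(frozen=True)
class SourcePair:
    """Abundance vectors of the two Zn sources entering the mixing model.

    ``min_separation`` is the smallest admissible difference between the two
    sources' 67:66 ratios; closer sources are declared unresolvable.  The
    Table-5 logic (distinguishable ratios = enrichment / experimental
    precision) implies that sources closer than ~10x the experimental
    precision resolve fewer than one step, hence the default tying the
    separation to a supplied precision belongs to the caller; here the
    default is a pure numerical floor.
    """

    soil: AbundanceVector
    fertilizer: AbundanceVector
    min_separation: float = 1e-12

    def __post_init__(self) -> None:
        if abs(self.fertilizer.ratio() - self.soil.ratio()) <= self.min_separation:
            raise UnresolvableMixtureError(
                "soil and fertilizer 67:66 ratios are separated by "
                f"{abs(self.fertilizer.ratio() - self.soil.ratio()):.3e} <= "
                f"min_separation {self.min_separation:.3e}"
            )

    @classmethod
    def with_precision(
        cls,
        soil: AbundanceVector,
        fertilizer: AbundanceVector,
        experimental_precision: float,
        factor: float = 10.0,
    ) -> "SourcePair":
        """Build a pair requiring separation >= ``factor`` x the supplied
        experimental precision (2sd of the 67:66 ratio)."""
        return cls(soil, fertilizer, min_separation=factor * experimental_precision)


@dataclass(frozen=True)
class MixingResult:
    """Fertilizer-derived Zn fraction for a treatment, in percent."""

    zndf_fertilizer_pct: float
    per_replicate: tuple[float, ...]
    sd: float
    ci95_half_width: float
    out_of_range: bool = False

    @property
    def zndf_soil_pct(self) -> float:
        return 100.0 - self.zndf_fertilizer_pct

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            self.zndf_fertilizer_pct - self.ci95_half_width,
            self.zndf_fertilizer_pct + self.ci95_half_width,
        )


def abundances_from_ratios(rs: RatioSet) -> AbundanceVector:
    """Convert a complete ratio set to mole-fraction abundances.

    With reference abundance ``A_ref`` and ratios ``R_x = A_ref / A_x``,
    closure (sum = 100%) gives ``A_ref = 100 / (1 + sum_x 1/R_x)``.
    """
    inv_sum = sum(1.0 / r for r in rs.ratios.values())
    a_ref = 100.0 / (1.0 + inv_sum)
    ab = {m: a_ref / r for m, r in rs.ratios.items()}
    ab[rs.reference] = a_ref
    return AbundanceVector(ab, rel_tol=1e-9)


def ratios_from_abundances(av: AbundanceVector, reference: int = 67) -> RatioSet:
    """Inverse of :func:`abundances_from_ratios`: ``R_x = A_ref / A_x``."""
    a_ref = av[reference]
    if a_ref <= 0:
        raise DomainError(f"reference isotope {reference} has zero abundance")
    ratios = {}
    for m in ZN_MASS_NUMBERS:
        if m == reference:
            continue
        if av[m] <= 0:
            raise DomainError(f"zero abundance of denominator isotope {m}")
        ratios[m] = a_ref / av[m]
    return RatioSet(ratios, reference=reference)


def plant_ratio(zndf_fert: float, sources: SourcePair) -> float:
    """Forward mixing model: plant 67:66 ratio for a fertilizer fraction.

    ``zndf_fert`` is the fraction (0..1) of plant Zn derived from the
    fertilizer; the remainder comes from the soil-available pool.
    """
    if not 0.0 <= zndf_fert <= 1.0:
        raise DomainError(f"zndf_fert={zndf_fert} outside [0, 1]")
    f = zndf_fert
    num = f * sources.fertilizer[67] + (1.0 - f) * sources.soil[67]
    den = f * sources.fertilizer[66] + (1.0 - f) * sources.soil[66]
    if den <= 0:
        raise DegenerateSourceError("mixture has non-positive 66Zn abundance")
    return num / den


def zndf_fertilizer(
    plant_ratio_67_66: float,
    sources: SourcePair,
    admissible_pct: tuple[float, float] = (-10.0, 110.0),
) -> tuple[float, bool]:
    """Invert the mixing model: percent of plant Zn from the fertilizer.

    Solving the two-isotope mass balance for the fertilizer fraction gives

        Zndf% = 100 * (A66_soil * R - A67_soil)
              / ((A67_fert - A67_soil) - R * (A66_fert - A66_soil))

    with ``R`` the measured plant 67:66 ratio.  Returns ``(zndf_pct, flag)``
    where ``flag`` is True when the estimate falls outside ``admissible_pct``
    (measurement noise can legitimately push endpoint mixtures slightly past
    0% or 100%; such values are flagged, not rejected).
    """
    r = plant_ratio_67_66
    soil, fert = sources.soil, sources.fertilizer
    den = (fert[67] - soil[67]) - r * (fert[66] - soil[66])
    if abs(den) < 1e3 * np.finfo(float).eps * max(abs(fert[67]), abs(soil[67]), 1.0):
        raise UnresolvableMixtureError("mixing-model denominator is numerically zero")
    zndf = 100.0 * (soil[66] * r - soil[67]) / den
    flagged = not (admissible_pct[0] <= zndf <= admissible_pct[1])
    return zndf, flagged


def summarize_treatment(per_replicate_zndf: Sequence[float]) -> MixingResult:
    """Mean, sample sd, and Student-t 95% CI over treatment replicates."""
    vals = np.asarray(per_replicate_zndf, dtype=float)
    n = vals.size
    if n < 2:
        raise InsufficientReplicationError(f"need >= 2 replicates, got {n}")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    tcrit = float(stats.t.ppf(0.975, df=n - 1))
    half = tcrit * sd / math.sqrt(n)
    return MixingResult(
        zndf_fertilizer_pct=mean,
        per_replicate=tuple(float(v) for v in vals),
        sd=sd,
        ci95_half_width=half,
    )
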