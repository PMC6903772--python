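"""Experimental precision and source-resolution statistics.

Whether a two-source tracing experiment can resolve a fertilizer
contribution depends on the ratio of two numbers:

* **isotope enrichment** — the difference between the labeled and unlabeled
  source's 67:66 ratio, i.e. how far apart the two endmembers sit;
* **experimental precision** — twice the standard deviation (2sd) of the
  67:66 ratio across independent treatment replicates, i.e. how finely a
  ratio can be pinned down in practice.

Their quotient ``n = enrichment / precision`` counts how many statistically
distinguishable ratio values fit between the sources; ``100/n`` is then the
smallest detectable source contribution in percent of plant Zn.  If only a
sub-interval of the mixing range is of practical interest (most organic
fertilizers contribute under half of plant Zn), the count scales by that
fraction.

Also provided: the dose arithmetic connecting amendment Zn content and
application rate to Zn input per kg soil and to field application rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InsufficientReplicationError

#: Relative guard applied before truncation so that quotients that are exact
#: in real arithmetic (e.g. 0.0702 / 0.0027 = 26) are not floored to n - 1 by
#: binary floating-point representation error.
_FLOOR_GUARD = 1e-9


@dataclass(frozen=True)
class ResolutionReport:
    """One labeled/unlabeled source pairing's resolution summary."""

    labeled_ratio: float
    unlabeled_ratio: float
    experimental_precision: float  # 2sd of the 67:66 ratio
    range_fraction: float = 1.0

    @property
    def enrichment(self) -> float:
        return enrichment(self.labeled_ratio, self.unlabeled_ratio)

    @property
    def n_distinguishable(self) -> int:
        return distinguishable_ratios(self.enrichment, self.experimental_precision)

    @property
    def detectable_contribution_pct(self) -> float:
        return detectable_contribution(self.n_distinguishable)

    @property
    def n_within_range(self) -> int:
        return resolution_within_range(
            self.enrichment, self.experimental_precision, self.range_fraction
        )


def experimental_precision(replicate_ratios) -> float:
    """2sd of the ratio across independent treatment replicates (n >= 2)."""
    vals = np.asarray(replicate_ratios, dtype=float)
    if vals.size < 2:
        raise InsufficientReplicationError(f"need >= 2 replicates, got {vals.size}")
    return 2.0 * float(vals.std(ddof=1))


def enrichment(labeled: float, unlabeled: float) -> float:
    """Isotope enrichment: labeled-source minus unlabeled-source ratio."""
    return labeled - unlabeled


def distinguishable_ratios(enrichment_value: float, precision: float) -> int:
    """Count of statistically distinguishable ratios between the sources.

    ``floor(enrichment / precision)``, floored at 0 for negative enrichment.
    Truncation is the conservative reading of "statistically
    distinguishable" (a partial step is not a resolvable step); a tiny
    relative guard keeps exact real-arithmetic quotients from losing a unit
    to floating-point representation.
    """
    if precision <= 0:
        raise DomainError(f"precision must be > 0, got {precision}")
    q = enrichment_value / precision
    return max(0, math.floor(q * (1.0 + _FLOOR_GUARD)))


def detectable_contribution(n: int) -> float:
    """Smallest resolvable source contribution, percent: 100/n (2 decimals)."""
    if n < 1:
        raise DomainError(f"need n >= 1 distinguishable ratios, got {n}")
    return round(100.0 / n, 2)


def resolution_within_range(
    enrichment_value: float, precision: float, range_fraction: float = 1.0
) -> int:
    """Distinguishable ratios within a sub-interval of the mixing range.

    ``range_fraction = 1`` reduces to :func:`distinguishable_ratios`.
    """
    if not 0.0 < range_fraction <= 1.0:
        raise DomainError(f"range_fraction must be in (0, 1], got {range_fraction}")
    return distinguishable_ratios(range_fraction * enrichment_value, precision)


def zn_input(content_mg_per_kg_amendment: float, rate_g_per_kg_soil: float) -> float:
    """Zn input to soil (mg Zn per kg soil) from amendment content and rate."""
    if content_mg_per_kg_amendment < 0 or rate_g_per_kg_soil < 0:
        raise DomainError("content and rate must be >= 0")
    return content_mg_per_kg_amendment * rate_g_per_kg_soil / 1000.0


def field_rate(
    rate_g_per_kg_soil: float,
    depth_m: float = 0.2,
    density_t_per_m3: float = 1.3,
) -> float:
    """Field application rate (t amendment per ha) for a pot-scale rate.

    One hectare to ploughing depth holds ``10000 * depth * density`` tonnes
    of soil; ``rate`` g amendment per kg soil equals ``rate`` kg per tonne.
    Defaults: 20 cm depth, 1.3 t m^-3 bulk density.
    """
    if rate_g_per_kg_soil <= 0 or depth_m <= 0 or density_t_per_m3 <= 0:
        raise DomainError("rate, depth and density must be > 0")
    soil_mass_t_per_ha = 10000.0 * depth_m * density_t_per_m3
    return rate_g_per_kg_soil * soil_mass_t_per_ha / 1000.0
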