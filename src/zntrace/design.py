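"""Spike planning for indirect labeling.

Indirect source tracing labels the soil-available Zn pool by adding an
isotopically enriched spike.  The planning trade-off: enough spike must be
added that the labeled pool's 67:66 ratio is well separated from natural
composition (resolution), but not so much Zn that the size of the
plant-available pool itself changes materially.

Mixing is computed in molar space.  Enriched spikes have an atomic weight
materially different from natural Zn (a pure-67 spike weighs ~66.93 u vs
~65.4 u for natural Zn), so masses are converted to moles via each
component's abundance-weighted atomic mass before isotope amounts are
added.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import ZN_MASS_NUMBERS, AbundanceVector
from .errors import DomainError, InfeasibleTargetError
from .resolution import detectable_contribution, distinguishable_ratios, enrichment


@dataclass(frozen=True)
class SpikePlan:
    """A computed spike addition for one soil pool and target ratio."""

    pool_zn_mg_per_kg: float
    pool_av: AbundanceVector
    spike_av: AbundanceVector
    target_ratio_67_66: float
    spike_mass_mg_per_kg: float
    pool_increase_pct: float
    max_increase_pct: float | None = None

    @property
    def feasible(self) -> bool:
        if self.max_increase_pct is None:
            return True
        return self.pool_increase_pct <= self.max_increase_pct

    def mixed_composition(self) -> AbundanceVector:
        return mix_abundances(
            self.pool_zn_mg_per_kg, self.pool_av,
            self.spike_mass_mg_per_kg, self.spike_av,
        )


def mix_abundances(
    mass_a: float,
    av_a: AbundanceVector,
    mass_b: float,
    av_b: AbundanceVector,
) -> AbundanceVector:
    """Isotope composition of a mass mixture of two Zn components.

    Each component's mass is converted to moles via its abundance-weighted
    atomic mass; per-isotope mole amounts add; the result is renormalized to
    percent.
    """
    if mass_a < 0 or mass_b < 0:
        raise DomainError("masses must be >= 0")
    if mass_a == 0 and mass_b == 0:
        raise DomainError("at least one component mass must be > 0")
    mol_a = mass_a / av_a.atomic_mass()
    mol_b = mass_b / av_b.atomic_mass()
    total = mol_a + mol_b
    mixed = {
        m: (mol_a * av_a[m] + mol_b * av_b[m]) / total for m in ZN_MASS_NUMBERS
    }
    return AbundanceVector(mixed)


def spike_mass_for_target(
    pool_zn_mg_per_kg: float,
    pool_av: AbundanceVector,
    spike_av: AbundanceVector,
    target_ratio_67_66: float,
    max_increase_pct: float | None = None,
) -> SpikePlan:
    """Solve for the spike mass that brings the pool to a target 67:66 ratio.

    The one-unknown molar mixing equation

        R_t = (P*a67_pool + S*a67_spike) / (P*a66_pool + S*a66_spike)

    is solved for the spike mole amount ``S`` given the pool amount ``P``;
    the target must lie strictly between the pool's and the spike's 67:66
    ratios (the spike's own ratio would require an infinite addition).
    """
    if pool_zn_mg_per_kg <= 0:
        raise DomainError("pool size must be > 0")
    r_pool = pool_av.ratio()
    r_spike = spike_av.ratio()
    r_t = target_ratio_67_66
    lo, hi = sorted((r_pool, r_spike))
    if r_t == r_pool:
        spike_mass = 0.0
    elif not (lo <= r_t < hi if r_spike > r_pool else lo < r_t <= hi):
        raise InfeasibleTargetError(
            f"target {r_t} outside the reachable interval between pool ({r_pool:.6g}) "
            f"and spike ({r_spike:.6g}) ratios"
        )
    elif r_t == r_spike:
        raise InfeasibleTargetError("target equals the spike ratio (infinite spike)")
    else:
        p_mol = pool_zn_mg_per_kg / pool_av.atomic_mass()
        s_mol = p_mol * (pool_av[67] - r_t * pool_av[66]) / (
            r_t * spike_av[66] - spike_av[67]
        )
        spike_mass = s_mol * spike_av.atomic_mass()
    return SpikePlan(
        pool_zn_mg_per_kg=pool_zn_mg_per_kg,
        pool_av=pool_av,
        spike_av=spike_av,
        target_ratio_67_66=r_t,
        spike_mass_mg_per_kg=spike_mass,
        pool_increase_pct=100.0 * spike_mass / pool_zn_mg_per_kg,
        max_increase_pct=max_increase_pct,
    )


def design_report(plans, precision: float) -> pd.DataFrame:
    """Tabulate resolution and feasibility for a list of spike plans.

    ``precision`` is the anticipated experimental precision (2sd of the
    67:66 ratio over treatment replicates).  Enrichment is the labeled pool's
    target ratio minus the unlabeled pool's ratio.
    """
    rows = []
    for plan in plans:
        e = enrichment(plan.target_ratio_67_66, plan.pool_av.ratio())
        n = distinguishable_ratios(e, precision)
        rows.append(
            {
                "pool_zn_mg_per_kg": plan.pool_zn_mg_per_kg,
                "target_ratio_67_66": plan.target_ratio_67_66,
                "spike_mass_mg_per_kg": plan.spike_mass_mg_per_kg,
                "pool_increase_pct": plan.pool_increase_pct,
                "enrichment": e,
                "n_distinguishable": n,
                "detectable_contribution_pct": (
                    detectable_contribution(n) if n >= 1 else float("nan")
                ),
                "feasible": plan.feasible,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pool_zn_mg_per_kg", "target_ratio_67_66", "spike_mass_mg_per_kg",
            "pool_increase_pct", "enrichment", "n_distinguishable",
            "detectable_contribution_pct", "feasible",
        ],
    )
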