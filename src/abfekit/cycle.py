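"""Two-state disorder-order population cycle.

A protein segment (here, the lid of a p53-pathway target) interconverts
between a "closed and disordered" and an "open and ordered" macrostate. In
the apo protein the ordered state sits ``dG_conf_apo`` above the disordered
one (sign convention: ``dG_conf = G_ordered - G_disordered``, positive when
order is disfavoured). A ligand that binds the two macrostates with
different affinities shifts this equilibrium in the complex:

    dG_conf_complex = dG_conf_apo - (dG_bind_disordered - dG_bind_ordered)

The bracketed term is the ligand's *preference* for the ordered state
(positive when the ordered complex binds more tightly). Populations follow
from the two-state Boltzmann factor, and the apparent (state-averaged)
binding free energy from the population-weighted mixture of the two
state-specific binding constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from scipy.special import expit, logsumexp

from .thermo import ThermoConditions, kd_from_dg

__all__ = [
    "CycleSpec",
    "two_state_population",
    "population_to_dg",
    "complex_population",
    "apparent_binding_dg",
    "cycle_table",
]


def two_state_population(dg_conf: float, cond: ThermoConditions | None = None) -> float:
    """Equilibrium probability of the ordered state.

    ``p = exp(-dG/RT) / (1 + exp(-dG/RT))``, i.e. a logistic function of
    the conformational gap; dG = 0 gives 0.5 and large positive gaps give
    vanishing ordered populations.
    """
    cond = cond or ThermoConditions()
    if not math.isfinite(dg_conf):
        raise ValueError(f"dG_conf must be finite, got {dg_conf}")
    return float(expit(-dg_conf / cond.rt))


def population_to_dg(p: float, cond: ThermoConditions | None = None) -> float:
    """Inverse of :func:`two_state_population`: ``dG = -RT ln(p/(1-p))``."""
    cond = cond or ThermoConditions()
    if not (0.0 < p < 1.0):
        raise ValueError(f"population must lie strictly in (0, 1), got {p}")
    return -cond.rt * math.log(p / (1.0 - p))


@dataclass(frozen=True)
class CycleSpec:
    """Inputs of the conformational-selection cycle.

    Parameters
    ----------
    dg_conf_apo : float
        Apo conformational gap G_ordered - G_disordered, kcal/mol.
    dg_bind_ordered, dg_bind_disordered : float
        Standard binding free energies of the ligand to each macrostate,
        kcal/mol (negative = favourable).
    """

    dg_conf_apo: float
    dg_bind_ordered: float
    dg_bind_disordered: float
    conditions: ThermoConditions = field(default_factory=ThermoConditions)

    def __post_init__(self) -> None:
        for name in ("dg_conf_apo", "dg_bind_ordered", "dg_bind_disordered"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")

    @property
    def preference(self) -> float:
        """Ligand preference for the ordered state, kcal/mol (positive = prefers order)."""
        return self.dg_bind_disordered - self.dg_bind_ordered

    @property
    def dg_conf_complex(self) -> float:
        """Conformational gap in the protein-ligand complex (cycle closure)."""
        return self.dg_conf_apo - self.preference


def complex_population(spec: CycleSpec) -> float:
    """Ordered-state population in the protein-ligand complex."""
    return two_state_population(spec.dg_conf_complex, spec.conditions)


def apparent_binding_dg(spec: CycleSpec) -> float:
    """Apparent (state-averaged) standard binding free energy, kcal/mol.

    The observable binding constant of a conformationally heterogeneous
    receptor is the apo-population-weighted average of the state-specific
    binding constants:

        dG_app = -RT ln[ p_ord exp(-dG_ord/RT) + p_dis exp(-dG_dis/RT) ]

    which reduces to ``dG_bind_ordered`` when the apo ensemble is fully
    ordered, and is always at least as favourable as the weighted state
    free energies because binding selects the better-binding state.
    """
    rt = spec.conditions.rt
    p_ord = two_state_population(spec.dg_conf_apo, spec.conditions)
    p_dis = 1.0 - p_ord
    val = logsumexp(
        [-spec.dg_bind_ordered / rt, -spec.dg_bind_disordered / rt],
        b=[p_ord, p_dis],
    )
    return float(-rt * val)


def cycle_table(spec: CycleSpec) -> pd.DataFrame:
    """One-row summary of the cycle: populations, gaps and apparent affinity.

    Populations are reported both as probabilities and percentages rounded
    to the nearest percent (matching how such shifts are usually quoted).
    """
    p_apo = two_state_population(spec.dg_conf_apo, spec.conditions)
    p_cpx = complex_population(spec)
    dg_app = apparent_binding_dg(spec)
    row = {
        "dG_conf_apo": spec.dg_conf_apo,
        "dG_conf_complex": spec.dg_conf_complex,
        "preference": spec.preference,
        "p_ordered_apo": p_apo,
        "p_ordered_apo_pct": round(100.0 * p_apo),
        "p_ordered_complex": p_cpx,
        "p_ordered_complex_pct": round(100.0 * p_cpx),
        "dG_bind_apparent": dg_app,
        "kd_apparent_M": kd_from_dg(dg_app, spec.conditions),
        "temperature_K": spec.conditions.temperature,
    }
    return pd.DataFrame([row])
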