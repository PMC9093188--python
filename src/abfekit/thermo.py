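"""Scalar binding thermodynamics.

Conversions between dissociation constants and standard free energies of
binding, enthalpy/entropy decomposition of calorimetric data, and the
thermodynamic conditions object shared across the package.

Sign and unit conventions
-------------------------
All energies are in kcal/mol. The standard free energy of binding is
``dG = RT ln(Kd / c0)`` with the standard concentration ``c0 = 1 M``, so a
picomolar binder has a large negative ``dG``. The entropic term is carried
as ``-T dS`` so that the identity ``dG = dH + (-T dS)`` is a plain sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "GAS_CONSTANT_KCAL",
    "STANDARD_CONCENTRATION_M",
    "STANDARD_VOLUME_A3",
    "ThermoConditions",
    "BindingMeasurement",
    "dg_from_kd",
    "kd_from_dg",
    "fold_change_to_ddg",
    "ddg_to_fold_change",
    "decompose",
]

#: Molar gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 0.0019872

#: Standard-state concentration, mol L^-1.
STANDARD_CONCENTRATION_M = 1.0

#: Volume per molecule at the 1 M standard state, cubic angstroms.
STANDARD_VOLUME_A3 = 1660.54


@dataclass(frozen=True)
class ThermoConditions:
    """Temperature and reference-state constants.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin. Defaults to 298.15 K, the ambient
        condition assumed for all population and Kd arithmetic.
    """

    temperature: float = 298.15
    gas_constant: float = GAS_CONSTANT_KCAL
    standard_concentration: float = STANDARD_CONCENTRATION_M

    def __post_init__(self) -> None:
        if not (self.temperature > 0 and math.isfinite(self.temperature)):
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if self.gas_constant <= 0:
            raise ValueError("gas constant must be positive")
        if self.standard_concentration <= 0:
            raise ValueError("standard concentration must be positive")

    @property
    def rt(self) -> float:
        """Thermal energy RT in kcal/mol."""
        return self.gas_constant * self.temperature


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value}")


def dg_from_kd(kd: float, cond: ThermoConditions | None = None) -> float:
    """Standard binding free energy (kcal/mol) from a dissociation constant.

    ``dG = RT ln(Kd / c0)``; strictly increasing in Kd (weaker binding,
    less negative free energy).
    """
    cond = cond or ThermoConditions()
    if not (kd > 0 and math.isfinite(kd)):
        raise ValueError(f"kd must be a positive finite concentration, got {kd}")
    return cond.rt * math.log(kd / cond.standard_concentration)


def kd_from_dg(dg: float, cond: ThermoConditions | None = None) -> float:
    """Inverse of :func:`dg_from_kd`: ``Kd = c0 exp(dG / RT)``."""
    cond = cond or ThermoConditions()
    _require_finite("dG", dg)
    return cond.standard_concentration * math.exp(dg / cond.rt)


def fold_change_to_ddg(fold: float, cond: ThermoConditions | None = None) -> float:
    """Free-energy penalty (kcal/mol) of an x-fold increase in Kd.

    A 250-fold loss in affinity corresponds to ``RT ln 250`` of binding
    free energy at the given temperature.
    """
    cond = cond or ThermoConditions()
    if not (fold > 0 and math.isfinite(fold)):
        raise ValueError(f"fold change must be positive, got {fold}")
    return cond.rt * math.log(fold)


def ddg_to_fold_change(ddg: float, cond: ThermoConditions | None = None) -> float:
    """Inverse of :func:`fold_change_to_ddg`."""
    cond = cond or ThermoConditions()
    _require_finite("ddG", ddg)
    return math.exp(ddg / cond.rt)


def decompose(dg: float, dh: float, cond: ThermoConditions | None = None) -> float:
    """Entropic component ``-T dS = dG - dH`` of a binding free energy."""
    _require_finite("dG", dg)
    _require_finite("dH", dh)
    return dg - dh


@dataclass(frozen=True)
class BindingMeasurement:
    """A calorimetric binding measurement with its derived quantities.

    Constructed from the directly measured pair (Kd, dH); dG and -T dS are
    derived so the invariants ``dG = RT ln(Kd/c0)`` and
    ``dG = dH + (-T dS)`` hold by construction.
    """

    kd: float
    dh: float
    conditions: ThermoConditions = field(default_factory=ThermoConditions)

    def __post_init__(self) -> None:
        if not (self.kd > 0 and math.isfinite(self.kd)):
            raise ValueError(f"kd must be positive and finite, got {self.kd}")
        _require_finite("dH", self.dh)

    @property
    def dg(self) -> float:
        return dg_from_kd(self.kd, self.conditions)

    @property
    def minus_tds(self) -> float:
        return decompose(self.dg, self.dh, self.conditions)

    def as_dict(self) -> dict[str, float]:
        return {
            "kd_M": self.kd,
            "dG_kcal_mol": self.dg,
            "dH_kcal_mol": self.dh,
            "minus_TdS_kcal_mol": self.minus_tds,
            "temperature_K": self.conditions.temperature,
        }
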