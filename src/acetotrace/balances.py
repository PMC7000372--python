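"""Chemostat rate → yield conversion and carbon/electron recovery balances.

Biomass-specific conversion rates q (mmol per g biomass per h, substrate
uptake negative) are converted to yields on a carbon-mole basis:

    Y_i = q_i · C_i / (|q_s| · C_s)        [Cmol (Cmol substrate)⁻¹]
    Y_H2 = q_H2 / (|q_s| · C_s)            [mol (Cmol substrate)⁻¹]

Carbon recovery is the summed carbon yields; electron recovery weighs each
yield with its degree of reduction per Cmol (2 electrons per mol H₂) and
divides by the substrate's γ per Cmol. Recoveries near 100% indicate that
all major fermentation products were captured by the measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .formulas import Compound

__all__ = [
    "RateSet",
    "YieldSet",
    "BalanceError",
    "yields_from_rates",
    "carbon_recovery",
    "electron_recovery",
    "acetyl_coa_derivative_yield",
    "yields_to_mol_per_mol",
    "round_half_away",
]

CMOL_PER_CMOL = "cmol_per_cmol"
MOL_PER_CMOL = "mol_per_cmol"


class BalanceError(ValueError):
    """Raised for inconsistent rate or yield inputs."""


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used for reported recoveries)."""
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


@dataclass
class RateSet:
    """Biomass-specific conversion rates, mmol (g biomass)⁻¹ h⁻¹, signed."""

    values: dict[str, float]
    sd: dict[str, float] = field(default_factory=dict)
    substrate: str = "galacturonate"

    def __post_init__(self) -> None:
        for name, q in self.values.items():
            if name == self.substrate:
                if q >= 0:
                    raise BalanceError(
                        f"substrate uptake rate must be negative, got q_{name} = {q}"
                    )
            elif q < 0:
                raise BalanceError(f"product rate must be non-negative, got q_{name} = {q}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def get(self, name: str, default: float = 0.0) -> float:
        return self.values.get(name, default)


@dataclass
class YieldSet:
    """Product yields per Cmol substrate with per-entry units.

    Carbon-containing products are in Cmol (Cmol substrate)⁻¹, H₂ in
    mol (Cmol substrate)⁻¹, mirroring the mixed units of chemostat yield
    tables; converters between bases are explicit.
    """

    values: dict[str, float]
    units: dict[str, str] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    substrate: str = "galacturonate"

    def __post_init__(self) -> None:
        for name, y in self.values.items():
            if y < 0:
                raise BalanceError(f"yield must be non-negative, got Y_{name} = {y}")
            unit = self.units.setdefault(
                name, MOL_PER_CMOL if name == "h2" else CMOL_PER_CMOL
            )
            if unit == CMOL_PER_CMOL and y > 1.0 + 1e-12:
                raise BalanceError(
                    f"carbon yield Y_{name} = {y} exceeds 1 Cmol/Cmol"
                )

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def get(self, name: str, default: float = 0.0) -> float:
        return self.values.get(name, default)

    def carbon_entries(self) -> dict[str, float]:
        return {
            n: y for n, y in self.values.items() if self.units[n] == CMOL_PER_CMOL
        }


def yields_from_rates(rates: RateSet, registry: dict[str, Compound]) -> YieldSet:
    """Convert biomass-specific rates to yields on the substrate carbon basis."""
    substrate = registry[rates.substrate]
    q_s = rates.get(rates.substrate)
    if q_s == 0:
        raise BalanceError(f"substrate rate q_{rates.substrate} is zero; yields undefined")
    denom = abs(q_s) * substrate.carbons
    values: dict[str, float] = {}
    units: dict[str, str] = {}
    sd: dict[str, float] = {}
    for name, q in rates.values.items():
        if name == rates.substrate:
            continue
        compound = registry[name]
        if compound.carbons > 0:
            values[name] = q * compound.carbons / denom
            units[name] = CMOL_PER_CMOL
            scale = compound.carbons / denom
        else:
            values[name] = q / denom
            units[name] = MOL_PER_CMOL
            scale = 1.0 / denom
        if name in rates.sd:
            sd[name] = rates.sd[name] * scale
    return YieldSet(values=values, units=units, sd=sd, substrate=rates.substrate)


def rates_from_yields(
    yields: YieldSet, q_substrate: float, registry: dict[str, Compound]
) -> RateSet:
    """Inverse of :func:`yields_from_rates` given the substrate uptake rate."""
    if q_substrate >= 0:
        raise BalanceError("substrate uptake rate must be negative")
    substrate = registry[yields.substrate]
    denom = abs(q_substrate) * substrate.carbons
    values = {yields.substrate: q_substrate}
    for name, y in yields.values.items():
        compound = registry[name]
        if yields.units[name] == CMOL_PER_CMOL:
            values[name] = y * denom / compound.carbons
        else:
            values[name] = y * denom
    return RateSet(values=values, substrate=yields.substrate)


def carbon_recovery(yields: YieldSet) -> float:
    """Percent of substrate carbon recovered in products (H₂ excluded)."""
    return 100.0 * sum(yields.carbon_entries().values())


def electron_recovery(yields: YieldSet, registry: dict[str, Compound]) -> float:
    """Percent of substrate electron equivalents recovered in products.

    Carbon products contribute Y_i·γ_cmol,i; H₂ contributes Y_H2·2.
    """
    substrate = registry[yields.substrate]
    if substrate.gamma_cmol is None:
        raise BalanceError(f"substrate {yields.substrate} has no carbon")
    total = 0.0
    missing: list[str] = []
    for name, y in yields.values.items():
        if y == 0:
            continue
        compound = registry.get(name)
        if compound is None:
            missing.append(name)
            continue
        if yields.units[name] == CMOL_PER_CMOL:
            if compound.gamma_cmol is None:
                missing.append(name)
                continue
            total += y * compound.gamma_cmol
        else:
            total += y * compound.gamma_mol
    if missing:
        raise BalanceError(
            "degree of reduction unavailable for species with nonzero yield: "
            + ", ".join(sorted(missing))
        )
    return 100.0 * total / substrate.gamma_cmol


def acetyl_coa_derivative_yield(yields: YieldSet) -> float:
    """Mol acetyl-CoA-derived product per Cmol substrate.

    Acetate (2 carbons) is the only acetyl-CoA-derived product in these
    cultures, so this is the acetate carbon yield divided by 2.
    """
    return yields.get("acetate") / 2.0


def yields_to_mol_per_mol(
    yields: YieldSet, registry: dict[str, Compound]
) -> dict[str, float]:
    """Convert yields to mol product per mol substrate (biomass stays in Cmol).

    Used when comparing measured yields with network stoichiometries written
    per mol of substrate.
    """
    substrate = registry[yields.substrate]
    out: dict[str, float] = {}
    for name, y in yields.values.items():
        compound = registry[name]
        if yields.units[name] == CMOL_PER_CMOL and compound.carbons > 0 and name != "biomass":
            out[name] = y * substrate.carbons / compound.carbons
        else:
            # H₂ (mol/Cmol) and biomass (kept per Cmol) scale with substrate carbons
            out[name] = y * substrate.carbons
    return out
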