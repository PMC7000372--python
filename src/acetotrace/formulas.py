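"""Elemental formulas and degree-of-reduction arithmetic.

The degree of reduction γ of a compound counts electron equivalents per mole
relative to the reference redox states CO₂, H₂O and NH₃ (ammonia nitrogen
source):

    γ_mol = 4·C + 1·H − 2·O − 3·N

Dividing by the carbon count gives γ per Cmol, the quantity used in electron
balances over fermentation products. CO₂ has γ = 0 by construction; H₂
carries 2 electron equivalents.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "ElementalFormula",
    "Compound",
    "FormulaError",
    "parse_formula",
    "degree_of_reduction",
]

#: electrons contributed per atom relative to the CO₂/H₂O/NH₃ reference
_VALENCE = {"C": 4.0, "H": 1.0, "O": -2.0, "N": -3.0}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


class FormulaError(ValueError):
    """Raised for formula strings that cannot be interpreted."""


@dataclass(frozen=True)
class ElementalFormula:
    """Per-element atom counts; fractional counts allowed (biomass formulas)."""

    C: float = 0.0
    H: float = 0.0
    O: float = 0.0
    N: float = 0.0

    def __post_init__(self) -> None:
        for el in ("C", "H", "O", "N"):
            if getattr(self, el) < 0:
                raise FormulaError(f"negative {el} count in formula {self}")

    def as_dict(self) -> dict[str, float]:
        return {el: getattr(self, el) for el in ("C", "H", "O", "N") if getattr(self, el)}


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-style formula string such as ``C6H10O7`` or ``CH1.8O0.5N0.2``.

    Counts default to 1 when omitted.  Only C, H, O and N are accepted; any
    other symbol raises :class:`FormulaError` naming the offending token.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    counts: dict[str, float] = {}
    pos = 0
    for m in _TOKEN.finditer(text.strip()):
        if m.start() != pos:
            raise FormulaError(f"unparseable token at {text[pos:]!r} in formula {text!r}")
        pos = m.end()
        symbol, count = m.group(1), m.group(2)
        if symbol not in _VALENCE:
            raise FormulaError(f"unknown element symbol {symbol!r} in formula {text!r}")
        counts[symbol] = counts.get(symbol, 0.0) + (float(count) if count else 1.0)
    if pos != len(text.strip()):
        raise FormulaError(f"unparseable token at {text[pos:]!r} in formula {text!r}")
    return ElementalFormula(**counts)


def degree_of_reduction(
    formula: ElementalFormula, nitrogen_source: str = "ammonia"
) -> tuple[float, float | None]:
    """Return ``(γ per mol, γ per Cmol)`` for a formula.

    With ammonia as nitrogen source each N contributes −3.  For carbon-free
    species (H₂) the per-Cmol value is undefined and returned as ``None``.
    """
    if nitrogen_source != "ammonia":
        raise ValueError(f"unsupported nitrogen source: {nitrogen_source!r}")
    gamma = sum(_VALENCE[el] * getattr(formula, el) for el in _VALENCE)
    if formula.C > 0:
        return gamma, gamma / formula.C
    return gamma, None


@dataclass(frozen=True)
class Compound:
    """A chemical species with formula, carbon count and degree of reduction."""

    name: str
    formula: ElementalFormula
    carbons: float = field(init=False)
    gamma_mol: float = field(init=False)
    gamma_cmol: float | None = field(init=False)

    def __post_init__(self) -> None:
        gamma_mol, gamma_cmol = degree_of_reduction(self.formula)
        object.__setattr__(self, "carbons", self.formula.C)
        object.__setattr__(self, "gamma_mol", gamma_mol)
        object.__setattr__(self, "gamma_cmol", gamma_cmol)

    @classmethod
    def from_string(cls, name: str, formula: str) -> "Compound":
        return cls(name=name, formula=parse_formula(formula))


def default_registry() -> dict[str, Compound]:
    """Registry of the species occurring in galacturonate fermentation balances.

    Biomass uses the generic composition CH₁.₈O₀.₅N₀.₂ (γ per Cmol = 4.2).
    """
    specs = {
        "galacturonate": "C6H10O7",
        "pyruvate": "C3H4O3",
        "acetate": "C2H4O2",
        "formate": "CH2O2",
        "co2": "CO2",
        "h2": "H2",
        "biomass": "CH1.8O0.5N0.2",
    }
    return {name: Compound.from_string(name, f) for name, f in specs.items()}
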