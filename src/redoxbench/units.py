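"""Unit-tagged energies and potentials.

Every energy handled by this package carries an explicit unit. Arithmetic
between mismatched units is an error rather than a silent bug: the pipeline
mixes hartree-scale absolute energies (hundreds of hartree) with kcal/mol
report values, and a missed conversion would be invisible in the output.

Supported units: ``hartree``, ``kcal_per_mol``, ``eV`` (energies, freely
interconvertible) and ``volt`` (a potential — convertible to an energy only
through an explicit electron count, see
:func:`redoxbench.benchmark.volts_to_kcal`).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass


class Unit(str, enum.Enum):
    HARTREE = "hartree"
    KCAL_PER_MOL = "kcal_per_mol"
    EV = "eV"
    VOLT = "volt"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: kcal/mol per hartree (CODATA-style conversion used in quantum chemistry).
HARTREE_TO_KCAL = 627.509474
#: kcal/mol per eV: N_A * e / (4184 J/kcal).
EV_TO_KCAL = 23.060548

# Conversion factors to the internal canonical energy unit (hartree).
_TO_HARTREE = {
    Unit.HARTREE: 1.0,
    Unit.KCAL_PER_MOL: 1.0 / HARTREE_TO_KCAL,
    Unit.EV: EV_TO_KCAL / HARTREE_TO_KCAL,
}


class UnitError(ValueError):
    """Raised on unsupported conversions or mixed-unit arithmetic."""


@dataclass(frozen=True)
class Quantity:
    """A number tagged with an energy/potential unit.

    Addition and subtraction require identical units; multiplication and
    division by plain scalars are allowed. Use :meth:`to` to convert.
    """

    value: float
    unit: Unit

    def __post_init__(self) -> None:
        if not isinstance(self.unit, Unit):
            object.__setattr__(self, "unit", Unit(self.unit))

    def to(self, target: Unit | str) -> "Quantity":
        return convert(self, target)

    # -- arithmetic ------------------------------------------------------
    def _check(self, other: "Quantity") -> None:
        if not isinstance(other, Quantity):
            raise UnitError(
                f"cannot combine Quantity with {type(other).__name__}; "
                "wrap plain numbers in a Quantity with an explicit unit"
            )
        if other.unit is not self.unit:
            raise UnitError(
                f"unit mismatch: {self.unit.value} vs {other.unit.value}"
            )

    def __add__(self, other: "Quantity") -> "Quantity":
        self._check(other)
        return Quantity(self.value + other.value, self.unit)

    def __sub__(self, other: "Quantity") -> "Quantity":
        self._check(other)
        return Quantity(self.value - other.value, self.unit)

    def __neg__(self) -> "Quantity":
        return Quantity(-self.value, self.unit)

    def __mul__(self, scalar: float) -> "Quantity":
        if isinstance(scalar, Quantity):
            raise UnitError("cannot multiply two Quantities")
        return Quantity(self.value * scalar, self.unit)

    __rmul__ = __mul__

    def __truediv__(self, scalar: float) -> "Quantity":
        if isinstance(scalar, Quantity):
            raise UnitError("cannot divide two Quantities")
        return Quantity(self.value / scalar, self.unit)

    def isclose(self, other: "Quantity", *, abs_tol: float = 0.0,
                rel_tol: float = 1e-9) -> bool:
        self._check(other)
        return math.isclose(self.value, other.value,
                            rel_tol=rel_tol, abs_tol=abs_tol)


def hartree(value: float) -> Quantity:
    return Quantity(value, Unit.HARTREE)


def kcal(value: float) -> Quantity:
    return Quantity(value, Unit.KCAL_PER_MOL)


def convert(q: Quantity, target: Unit | str) -> Quantity:
    """Convert ``q`` to ``target`` unit.

    Energy units interconvert freely; ``volt`` converts only to itself
    (turning a potential into a molar energy needs an electron count and is
    handled by :func:`redoxbench.benchmark.volts_to_kcal`).
    """
    try:
        target = Unit(target)
    except ValueError as exc:
        raise UnitError(f"unknown unit: {target!r}") from exc
    if q.unit is target:
        return Quantity(q.value, target)
    if q.unit is Unit.VOLT or target is Unit.VOLT:
        raise UnitError(
            "volt is a potential, not a molar energy; conversion requires "
            "an electron count (see benchmark.volts_to_kcal)"
        )
    in_hartree = q.value * _TO_HARTREE[q.unit]
    return Quantity(in_hartree / _TO_HARTREE[target], target)
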