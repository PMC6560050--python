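"""Species, basis-set and energy data model, redox differencing, spin checks.

The chemistry being modelled: mononuclear iron coordination complexes whose
ligands mimic amino-acid side chains (water, methoxide for Ser, formate for
Asp/Glu, methanethiolate for Cys, methylamine for Lys). Each complex exists
in two oxidation states, Fe(II) and Fe(III); the electronic component of the
reduction energy is the energy of the reduced species minus the oxidized
one, which for these gas-phase cations is a large negative number (electron
attachment to a cation is strongly downhill).

Both oxidation states are high-spin in their ground state: quintet (2S+1=5)
for Fe(II) d6 and sextet (2S+1=6) for Fe(III) d5. The spin diagnostics here
compare a reported UHF-style <S^2> against the pure-state value S(S+1).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from .units import Quantity, Unit

# ---------------------------------------------------------------------------
# Canonical complexes
# ---------------------------------------------------------------------------

#: The 12 canonical model complexes, in report order (water-only complexes of
#: increasing coordination number, then tetrahedral and octahedral complexes
#: carrying one amino-acid-mimicking ligand).
CANONICAL_COMPLEXES: tuple[str, ...] = (
    "Fe(H2O)",
    "Fe(H2O)2",
    "Fe(H2O)4",
    "Fe(H2O)6",
    "Fe(H2O)3(CH3O-)",
    "Fe(H2O)3(CH3S-)",
    "Fe(H2O)3(NH2CH3)",
    "Fe(H2O)3(HCOO-)",
    "Fe(H2O)5(CH3O-)",
    "Fe(H2O)5(CH3S-)",
    "Fe(H2O)5(NH2CH3)",
    "Fe(H2O)5(HCOO-)",
)

#: Report groups: A = water-only, B = tetrahedral (3 waters + side chain),
#: C = octahedral (5 waters + side chain). Four complexes each.
COMPLEX_GROUPS: dict[str, tuple[str, ...]] = {
    "A": CANONICAL_COMPLEXES[0:4],
    "B": CANONICAL_COMPLEXES[4:8],
    "C": CANONICAL_COMPLEXES[8:12],
}

#: Net charge carried by the ligand shell of each canonical complex.
LIGAND_CHARGES: dict[str, int] = {
    name: (-1 if name.endswith(("(CH3O-)", "(CH3S-)", "(HCOO-)")) else 0)
    for name in CANONICAL_COMPLEXES
}


def canonical_order_index(complex_id: str) -> int:
    """Position of ``complex_id`` in the canonical report order.

    Unknown complexes sort after the canonical twelve, alphabetically.
    """
    try:
        return CANONICAL_COMPLEXES.index(complex_id)
    except ValueError:
        return len(CANONICAL_COMPLEXES)


def complex_sort_key(complex_id: str) -> tuple[int, str]:
    return (canonical_order_index(complex_id), complex_id)


# ---------------------------------------------------------------------------
# Basis sets
# ---------------------------------------------------------------------------

_CARDINAL_LETTERS = {"D": 2, "T": 3, "Q": 4, "5": 5, "6": 6}
_BASIS_RE = re.compile(r"p?V(D|T|Q|5|6)Z", re.IGNORECASE)


@dataclass(frozen=True, order=True)
class BasisLevel:
    """A correlation-consistent basis identified by its cardinal number X.

    X = 2 is double-zeta (aug-cc-pVDZ), 3 triple-zeta, 4 quadruple-zeta.
    """

    cardinal: int
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.cardinal < 2:
            raise ValueError(f"cardinal must be >= 2, got {self.cardinal}")
        if not self.label:
            letter = {v: k for k, v in _CARDINAL_LETTERS.items()}.get(
                self.cardinal, str(self.cardinal)
            )
            object.__setattr__(self, "label", f"aug-cc-pV{letter}Z")

    @classmethod
    def from_label(cls, label: str) -> "BasisLevel":
        """Resolve a basis label like ``aug-cc-pVTZ`` (or a bare cardinal
        number) to a :class:`BasisLevel`."""
        text = label.strip()
        if text.isdigit():
            return cls(int(text), label=text)
        m = _BASIS_RE.search(text)
        if not m:
            raise ValueError(f"cannot resolve basis label {label!r} to a cardinal")
        return cls(_CARDINAL_LETTERS[m.group(1).upper()], label=text)


# ---------------------------------------------------------------------------
# Species
# ---------------------------------------------------------------------------


class OxState(str, enum.Enum):
    II = "II"
    III = "III"

    @property
    def iron_charge(self) -> int:
        return 2 if self is OxState.II else 3

    @property
    def high_spin_multiplicity(self) -> int:
        # d6 quintet for Fe(II), d5 sextet for Fe(III)
        return 5 if self is OxState.II else 6


@dataclass(frozen=True)
class SpeciesState:
    """One complex in one oxidation/spin state — the object energies attach to."""

    complex_id: str
    oxidation_state: OxState
    spin_multiplicity: int
    ligand_charge_sum: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.oxidation_state, OxState):
            object.__setattr__(
                self, "oxidation_state", OxState(self.oxidation_state)
            )
        allowed = {OxState.II: (1, 5), OxState.III: (2, 6)}[self.oxidation_state]
        if self.spin_multiplicity not in allowed:
            raise ValueError(
                f"spin multiplicity {self.spin_multiplicity} not considered for "
                f"Fe({self.oxidation_state.value}); allowed: {allowed}"
            )

    @property
    def total_charge(self) -> int:
        return self.oxidation_state.iron_charge + self.ligand_charge_sum

    @property
    def key(self) -> tuple[str, str]:
        return (self.complex_id, self.oxidation_state.value)

    @classmethod
    def high_spin(cls, complex_id: str, oxidation_state: OxState | str,
                  ligand_charge_sum: int | None = None) -> "SpeciesState":
        ox = OxState(oxidation_state)
        if ligand_charge_sum is None:
            ligand_charge_sum = LIGAND_CHARGES.get(complex_id, 0)
        return cls(complex_id, ox, ox.high_spin_multiplicity, ligand_charge_sum)


@dataclass(frozen=True)
class RedoxCouple:
    """An Fe(III)/Fe(II) pair of the same complex (one-electron couple)."""

    oxidized: SpeciesState
    reduced: SpeciesState

    def __post_init__(self) -> None:
        if self.oxidized.complex_id != self.reduced.complex_id:
            raise ValueError(
                "redox couple must pair states of the same complex: "
                f"{self.oxidized.complex_id!r} vs {self.reduced.complex_id!r}"
            )
        dq = self.oxidized.total_charge - self.reduced.total_charge
        if dq != 1:
            raise ValueError(
                f"oxidized minus reduced charge must be 1, got {dq}"
            )

    @property
    def complex_id(self) -> str:
        return self.oxidized.complex_id

    @classmethod
    def high_spin(cls, complex_id: str,
                  ligand_charge_sum: int | None = None) -> "RedoxCouple":
        return cls(
            oxidized=SpeciesState.high_spin(complex_id, OxState.III,
                                            ligand_charge_sum),
            reduced=SpeciesState.high_spin(complex_id, OxState.II,
                                           ligand_charge_sum),
        )


# ---------------------------------------------------------------------------
# Energies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComponentEnergy:
    """HF + correlation split of an electronic energy.

    The two components converge to the basis-set limit at different rates
    (HF roughly exponentially in the cardinal number, correlation as an
    inverse power), which is why they are stored and extrapolated separately.
    """

    hf: Quantity
    corr: Quantity

    def __post_init__(self) -> None:
        if self.hf.unit is not self.corr.unit:
            raise ValueError(
                f"hf and corr must share a unit: {self.hf.unit} vs {self.corr.unit}"
            )

    @property
    def total(self) -> Quantity:
        return self.hf + self.corr

    @property
    def unit(self) -> Unit:
        return self.hf.unit


@dataclass(frozen=True)
class EnergyRecord:
    species: SpeciesState
    method: str
    basis: BasisLevel
    energy: ComponentEnergy

    @property
    def key(self) -> tuple[tuple[str, str], str, int]:
        return (self.species.key, self.method, self.basis.cardinal)


class MissingRecordError(KeyError):
    """A lookup for an absent (species, method, basis) combination."""

    def __init__(self, species_key, method, cardinal):
        self.species_key = species_key
        self.method = method
        self.cardinal = cardinal
        super().__init__(
            f"no energy record for species={species_key}, method={method!r}, "
            f"basis cardinal {cardinal}"
        )


class EnergyTable:
    """Keyed collection of :class:`EnergyRecord`; duplicate keys rejected."""

    def __init__(self, records: Iterable[EnergyRecord] = ()) -> None:
        self._records: dict[tuple, EnergyRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: EnergyRecord) -> None:
        if record.key in self._records:
            raise ValueError(f"duplicate energy record for key {record.key}")
        self._records[record.key] = record

    def get(self, species: SpeciesState, method: str,
            basis: BasisLevel | int) -> EnergyRecord:
        cardinal = basis.cardinal if isinstance(basis, BasisLevel) else int(basis)
        try:
            return self._records[(species.key, method, cardinal)]
        except KeyError:
            raise MissingRecordError(species.key, method, cardinal) from None

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[EnergyRecord]:
        return iter(self._records.values())

    def species_states(self) -> list[SpeciesState]:
        seen: dict[tuple, SpeciesState] = {}
        for rec in self._records.values():
            seen.setdefault(rec.species.key, rec.species)
        return list(seen.values())

    def complex_ids(self) -> list[str]:
        ids = {rec.species.complex_id for rec in self._records.values()}
        return sorted(ids, key=complex_sort_key)


# ---------------------------------------------------------------------------
# Spin diagnostics
# ---------------------------------------------------------------------------

#: Default |<S^2> - S(S+1)| tolerance: passes clean pre-annihilation values
#: (deviations of order 1e-2) while flagging genuinely contaminated
#: wavefunctions.
DEFAULT_S2_TOLERANCE = 0.05


def expected_s2(multiplicity: int) -> float:
    """Pure-spin-state <S^2> = S(S+1) for spin multiplicity 2S+1.

    Quintet (5) gives 6.0, sextet (6) gives 8.75.
    """
    if multiplicity < 1:
        raise ValueError(f"multiplicity must be >= 1, got {multiplicity}")
    s = (multiplicity - 1) / 2.0
    return s * (s + 1.0)


def contamination_flag(observed_s2: float, multiplicity: int,
                       tol: float = DEFAULT_S2_TOLERANCE) -> bool:
    """True iff the observed <S^2> deviates from S(S+1) by more than ``tol``."""
    if tol <= 0:
        raise ValueError(f"tolerance must be positive, got {tol}")
    return abs(observed_s2 - expected_s2(multiplicity)) > tol


def select_ground_multiplicity(candidates: Mapping[int, Quantity]) -> int:
    """Multiplicity of the lowest-energy candidate state.

    Ties break toward the higher multiplicity (the high-spin state is the
    ground state throughout the systems this package models).
    """
    if not candidates:
        raise ValueError("no candidate spin states supplied")
    units = {q.unit for q in candidates.values()}
    if len(units) > 1:
        raise ValueError(f"candidate energies mix units: {sorted(u.value for u in units)}")
    return min(candidates, key=lambda m: (candidates[m].value, -m))


# ---------------------------------------------------------------------------
# Redox differencing
# ---------------------------------------------------------------------------


def delta_e_redox(e_reduced: Quantity, e_oxidized: Quantity) -> Quantity:
    """Electronic reduction energy: E(reduced) - E(oxidized).

    Negative for gas-phase electron attachment to a cationic complex.
    """
    return e_reduced - e_oxidized
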