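"""Composite CCSD(T)/CBS reference values.

The reference energy for each redox couple is assembled as a composite:
the MP2 energy extrapolated to the complete-basis-set limit, plus a
higher-level correction ``E_CCSD(T) - E_MP2`` evaluated in a small basis
(double-zeta by default). The approximation rests on the near basis-set
independence of the CCSD(T)-minus-MP2 correlation difference; enlarging
the correction basis from double- to triple-zeta is known to move the
result by under 0.1 kcal/mol for comparable systems.
"""

from __future__ import annotations

from dataclasses import dataclass

from .extrapolation import (
    CbsResult,
    ExtrapolationParams,
    Scheme,
    scheme1_cbs,
    scheme2_cbs,
)
from .model import (
    BasisLevel,
    EnergyTable,
    RedoxCouple,
    SpeciesState,
    complex_sort_key,
    delta_e_redox,
)
from .units import Quantity, Unit

MP2 = "MP2"
CCSDT = "CCSD(T)"

#: Basis used for the coupled-cluster correction (the largest basis at which
#: both MP2 and CCSD(T) energies are available: double-zeta here).
DEFAULT_CORRECTION_BASIS = BasisLevel(2)


@dataclass(frozen=True)
class CompositeCorrection:
    """``E_CCSD(T) - E_MP2`` at a stated basis."""

    value: Quantity
    basis: BasisLevel


@dataclass(frozen=True)
class ReferenceValue:
    """Reference reduction energy for one couple, with provenance."""

    couple: RedoxCouple
    delta_e: Quantity  # kcal/mol at the reporting boundary
    scheme: Scheme
    correction_basis: BasisLevel

    @property
    def complex_id(self) -> str:
        return self.couple.complex_id


def composite_cbs(mp2_cbs: Quantity, correction: CompositeCorrection) -> Quantity:
    """CCSD(T)/CBS estimate: MP2/CBS plus the coupled-cluster correction."""
    return mp2_cbs + correction.value


def species_mp2_cbs(energies: EnergyTable, species: SpeciesState,
                    scheme: Scheme | str,
                    params: ExtrapolationParams | None = None) -> CbsResult:
    """Extrapolate one species' MP2 energy to the CBS limit."""
    scheme = Scheme(scheme)
    e_dz = energies.get(species, MP2, 2).energy
    e_tz = energies.get(species, MP2, 3).energy
    if scheme is Scheme.SCHEME1:
        return scheme1_cbs(e_dz, e_tz, params)
    e_qz = energies.get(species, MP2, 4).energy
    return scheme2_cbs(e_dz, e_tz, e_qz, params)


def species_correction(energies: EnergyTable, species: SpeciesState,
                       basis: BasisLevel = DEFAULT_CORRECTION_BASIS,
                       ) -> CompositeCorrection:
    """CCSD(T) minus MP2 total energy for one species at ``basis``."""
    e_cc = energies.get(species, CCSDT, basis).energy.total
    e_mp2 = energies.get(species, MP2, basis).energy.total
    return CompositeCorrection(value=e_cc - e_mp2, basis=basis)


def couple_reference(energies: EnergyTable, couple: RedoxCouple,
                     scheme: Scheme | str = Scheme.SCHEME2,
                     correction_basis: BasisLevel = DEFAULT_CORRECTION_BASIS,
                     params: ExtrapolationParams | None = None,
                     ) -> ReferenceValue:
    """CCSD(T)/CBS reduction energy for one redox couple.

    Extrapolation and correction are applied per species (absolute
    energies) and then differenced: reduced minus oxidized.
    """
    scheme = Scheme(scheme)
    per_species: dict[str, Quantity] = {}
    for role, species in (("reduced", couple.reduced),
                          ("oxidized", couple.oxidized)):
        mp2_cbs = species_mp2_cbs(energies, species, scheme, params).cbs_total
        corr = species_correction(energies, species, correction_basis)
        per_species[role] = composite_cbs(mp2_cbs, corr)
    delta = delta_e_redox(per_species["reduced"], per_species["oxidized"])
    return ReferenceValue(
        couple=couple,
        delta_e=delta.to(Unit.KCAL_PER_MOL),
        scheme=scheme,
        correction_basis=correction_basis,
    )


def couple_mp2_cbs_delta(energies: EnergyTable, couple: RedoxCouple,
                         scheme: Scheme | str = Scheme.SCHEME2,
                         params: ExtrapolationParams | None = None) -> Quantity:
    """MP2/CBS reduction energy (no coupled-cluster correction), kcal/mol."""
    scheme = Scheme(scheme)
    red = species_mp2_cbs(energies, couple.reduced, scheme, params).cbs_total
    ox = species_mp2_cbs(energies, couple.oxidized, scheme, params).cbs_total
    return delta_e_redox(red, ox).to(Unit.KCAL_PER_MOL)


def build_reference_table(energies: EnergyTable,
                          scheme: Scheme | str = Scheme.SCHEME2,
                          correction_basis: BasisLevel = DEFAULT_CORRECTION_BASIS,
                          params: ExtrapolationParams | None = None,
                          ) -> list[ReferenceValue]:
    """One reference value per redox couple found in ``energies``.

    Couples are formed from species sharing a complex id with both
    oxidation states present; output follows the canonical complex order.
    A missing record fails loudly, naming the (species, method, basis) key.
    """
    by_complex: dict[str, dict[str, SpeciesState]] = {}
    for species in energies.species_states():
        by_complex.setdefault(species.complex_id, {})[
            species.oxidation_state.value] = species
    out: list[ReferenceValue] = []
    for complex_id in sorted(by_complex, key=complex_sort_key):
        states = by_complex[complex_id]
        if set(states) != {"II", "III"}:
            missing = {"II", "III"} - set(states)
            raise ValueError(
                f"complex {complex_id!r} lacks oxidation state(s) "
                f"{sorted(missing)}; cannot form a redox couple"
            )
        couple = RedoxCouple(oxidized=states["III"], reduced=states["II"])
        out.append(couple_reference(energies, couple, scheme,
                                    correction_basis, params))
    return out
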