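import pytest

from redoxbench import (
    RedoxCouple,
    gen_species_energies,
    kcal,
)


@pytest.fixture()
def planted_couple_table():
    """Noiseless synthetic energy table for one couple, planted at -380 kcal/mol."""
    couple = RedoxCouple.high_spin("Fe(H2O)6")
    return couple, gen_species_energies(couple, kcal(-380.0), seed=7)
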