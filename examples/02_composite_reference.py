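"""Build a composite CCSD(T)/CBS reference for one redox couple.

Generates a synthetic energy table with a planted reduction energy of
-380 kcal/mol (the realistic magnitude for an octahedral iron aquo
complex), then recovers it through the full pipeline: per-species MP2/CBS
extrapolation, double-zeta coupled-cluster correction, redox differencing.
"""

from redoxbench import (
    RedoxCouple,
    build_reference_table,
    gen_species_energies,
    kcal,
)

couple = RedoxCouple.high_spin("Fe(H2O)6")
print(f"couple: {couple.complex_id}  "
      f"Fe(III) multiplicity {couple.oxidized.spin_multiplicity}, "
      f"Fe(II) multiplicity {couple.reduced.spin_multiplicity}")

table = gen_species_energies(couple, kcal(-380.0), seed=0)
print(f"energy records: {len(table)} "
      "(MP2 at X=2,3,4 and CCSD(T) at X=2, both oxidation states)")

ref = build_reference_table(table)[0]
print(f"reference delta_E_elec: {ref.delta_e.value:.6f} kcal/mol "
      f"(scheme {ref.scheme.value}, correction basis X="
      f"{ref.correction_basis.cardinal})")
# The recovered value equals the planted -380 kcal/mol to ~1e-10: with
# noiseless series matching the assumed convergence forms the composite
# pipeline is exact.
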