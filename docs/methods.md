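# Methods

## Scope and model

`redoxbench` computes the electronic component of the Fe(III)/Fe(II)
reduction energy at 0 K, ΔE_elec = E(reduced) − E(oxidized), for
mononuclear iron coordination complexes, assembles CCSD(T)/CBS-quality
reference values for it from finite-basis single-point energies, and scores
density-functional predictions against those references. Everything that
requires an electronic-structure engine — geometries, single points,
wavefunctions — is outside scope: energies enter as tabulated inputs (real
or synthetic). Solvation, thermal, zero-point and entropic contributions
are likewise excluded by design; the electronic term dominates the redox
potential and is the one that discriminates between functionals.

Both oxidation states are treated as high spin (quintet Fe(II) d⁶, sextet
Fe(III) d⁵), the ground states for these complexes;
`select_ground_multiplicity` picks the lowest-energy state and breaks exact
ties toward the higher multiplicity, consistent with that regime. Spin
contamination is diagnosed by comparing a reported ⟨S²⟩ against the pure
value S(S+1) (6.0 for the quintet, 8.75 for the sextet) with a default
tolerance of 0.05 — loose enough to pass clean pre-annihilation UHF-style
values (deviations ~10⁻²), tight enough to flag a genuinely contaminated
wavefunction, where deviations are typically ≥ 0.1.

## Units

All arithmetic is unit-checked (`hartree`, `kcal_per_mol`, `eV`, `volt`).
Conversion constants: 627.509474 kcal/mol per hartree and 23.060548 kcal/mol
per eV. The internal canonical unit is hartree; report-facing output is
kcal/mol. `volt` converts to a molar energy only through an explicit
electron count (`volts_to_kcal`), never silently.

## Basis-set extrapolation

HF and correlation components converge to the basis-set limit at different
rates and are extrapolated separately.

**Scheme I** (two-point, cardinals 2 and 3) assumes
E(X) = E_CBS + A·X⁻ᵖ with p = α = 4.93 for HF and p = β = 2.13 for
correlation (literature exponents, the package defaults). The limit is the
closed form (X_hi^p·E_hi − X_lo^p·E_lo)/(X_hi^p − X_lo^p); the two weights
sum to one, so a constant series is its own limit. One code path serves any
(p, X_lo, X_hi): the correlation part of scheme II is the same formula with
p = 3 on cardinals 3 and 4.

**Scheme II** extrapolates correlation with the inverse-cube two-point
formula on TZ/QZ and HF with a three-point exponential model
E(X) = E_CBS + A·e^(−BX) through DZ/TZ/QZ. With consecutive cardinals the
three-parameter fit has the closed-form Aitken Δ² solution
E_CBS = E_QZ − d₂²/(d₁ − d₂), d₁ = E_DZ − E_TZ, d₂ = E_TZ − E_QZ — a unique
interpolant, no optimizer, no nondeterminism. The series must be monotone
and contracting (d₁d₂ > 0, |d₂| < |d₁|, with a 10⁻⁹ relative guard against
a vanishing denominator); anything else has no B > 0 interpolant and is
rejected with the offending differences named.

The two textual descriptions of scheme II's HF treatment conflict in the
source material (exponential three-point fit vs reusing the scheme I
power law). The package makes the exponential fit the default and exposes
`hf_cbs_mode ∈ {exponential, eq2}` so both readings are reproducible.
Whether the double-zeta point entered the original HF fits cannot be
verified from published numbers alone; the default uses all three points,
which the closed form requires.

Extrapolation is applied to per-species absolute energies and then
differenced. For the two-point schemes the order is immaterial (fixed
linear weights — a property test certifies that extrapolating a difference
equals differencing extrapolations); the exponential fit is nonlinear and a
test documents a nonzero discrepancy on a constructed pair.

## Composite references

The reference for each couple is MP2/CBS plus the CCSD(T) − MP2 total-energy
difference at a stated basis (default cardinal 2, the largest basis where
both methods are affordable for these systems). The approximation rests on
the near basis-set independence of that difference; published comparisons
put the double- vs triple-zeta change below 0.1 kcal/mol, so the correction
basis is configurable but defaults to 2. Scheme II is the default for
references; scheme I remains available for comparison columns. The scheme
affects only the MP2/CBS term: reference minus MP2/CBS equals the
correction identically, which a test asserts.

## Benchmark statistics

Signed errors are prediction − reference in kcal/mol. MSE is their mean,
MUE the mean magnitude, MaxE the largest magnitude together with the
complex where it occurs (ties broken by canonical complex order). Accuracy
groups bin functionals by MUE at 0.1 and 0.2 V per electron transferred.
The boundaries are applied unrounded (2.3061, 4.6121 kcal/mol) to avoid
classifying on a display artifact; a strict mode uses the conventional
printed 2.31/4.62. Rankings sort ascending by MUE with ties broken by
smaller MaxE, then name. Report tables round to 2 dp (round-half-even)
and are deterministic.

The canonical 12-complex roster and its A/B/C partition (water-only;
tetrahedral with one side-chain mimic; octahedral with one side-chain
mimic — four complexes each) ship as constants. No significance testing is
performed between functionals: the references themselves carry ~1 kcal/mol
uncertainty, so distinctions below that are not meaningful.

## Synthetic data

The generator plants ground truth in the two places the pipeline needs it:

* **Convergence series** follow the forms the schemes assume — HF
  exponential (default amplitude 0.05 hartree, decay B = 1.4) or power-law,
  correlation A·X⁻ᵖ (default amplitude 0.1 hartree, p = 3) — around planted
  CBS components at realistic magnitudes (total energies ~−1260 hartree,
  reduction energies in the −600 to −240 kcal/mol range, basis-set
  increments of a few kcal/mol per cardinal step, matching the regime of
  real iron complexes so tests exercise realistic cancellation). The
  synthetic CCSD(T) record shifts the double-zeta correlation energy by a
  basis-independent constant, so the composite correction is exact by
  construction. On noiseless input the full pipeline returns the planted
  reduction energy to ≤ 10⁻⁸ kcal/mol.
* **Benchmark datasets** give each synthetic functional a fixed bias plus
  independent Gaussian noise (default sd 1 kcal/mol) around uniformly drawn
  references. MSE then estimates the bias with sampling error sd/√n;
  parameter-recovery tests run 200 seeded replicates against the 3σ bound
  with a binomial allowance.

Noise is Gaussian and independent per record; no correlated-error
structure is modelled (none is known for these data). With component noise
of 10⁻⁴ hartree, first-order propagation through the scheme II weights
(correlation: 64/37 and 27/37; HF: Aitken partials evaluated at the
noiseless differences) gives a reduction-energy standard deviation of
≈ 0.24 kcal/mol under the default amplitudes; the test suite checks the
Monte-Carlo spread against that independent computation rather than a fixed
constant, since the figure scales with the chosen decay amplitudes.

All randomness flows through `numpy.random.default_rng(seed)`: same seed,
bit-identical output, platform-independent.

What the generator does **not** emulate: real basis-set series contain
non-asymptotic structure (the DZ point especially), method errors are
correlated across complexes and oxidation states, and functional errors
are far from independent Gaussians. Passing the synthetic round-trip
therefore certifies the algebra and plumbing, not the physical adequacy of
the extrapolation forms for real wavefunctions.

## Fixtures and the reproduction regression

The published per-complex tables ship as CSV fixtures: MP2 reduction
energies at three basis sets, both schemes' CBS values with difference
columns, the composite references, the top-ten functional tables for the
three complex groups and overall, the 44-functional roster, and the
printed MSE/MUE footers. Absolute reference energies are *fixtures only* —
recomputing them needs per-species HF/correlation components that were
never published — but every derivable quantity is recomputed:
difference columns, footer statistics, per-group MUE/MaxE from the
per-complex errors, overall MUE/MaxE and ranking for the five functionals
whose errors are printed for all twelve complexes (BB1K, mPWB1K, mPW1B95,
B3LYP, M06-2X).

`reproduce_paper(tolerance)` compares each recomputed value, rounded to the
printed precision, against the printed one. The default allowance of
0.01 kcal/mol absorbs half-ulp rounding ambiguity (e.g. a true 0.675
printing as 0.67); `tolerance=0` surfaces exactly those cases — eight in
the stock fixtures, all last-digit rounding artifacts. Percent-HF-exchange
values printed as two-part strings ("22.20/100.00") are stored verbatim as
text. Fixture labels use ASCII hyphen-minus throughout.

## Problem sizes and determinism

All computations are closed-form or O(n) statistics; the full test suite
runs in seconds. Monte-Carlo checks use 100–200 seeded replicates of
12-complex datasets, ample for the 3σ/binomial bounds they assert. CLI runs
with identical inputs and seeds are byte-identical.

## Known limitations

* The exponential HF fit is exact only for exactly exponential series; on
  real HF energies it is an approximation whose error is not estimated here.
* Only cardinal-labelled correlation-consistent series are supported; no
  other basis families or extrapolation schemes.
* Dispersion corrections are not computed; published evidence puts their
  aggregate effect (~0.15 kcal/mol MUE shift) below the reference
  uncertainty.
* The 12-complex roster models single side-chain substitutions; real
  protein sites coordinate several side chains at once.
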