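# fpcc

Vertical ionization potentials from pCCD-tailored coupled-cluster methods,
for quantum chemists studying closed-shell molecules whose static correlation
makes a single Hartree–Fock determinant a poor starting point.

## What it computes

**pCCD reference.** Pair coupled cluster doubles restricts the cluster
operator to closed-shell electron-pair excitations,

    |pCCD> = exp(T_p) |Phi_0>,    T_p = sum_ia c_i^a  a+_a a+_abar a_ibar a_i ,

i.e. the seniority-zero sector.  The orbitals are optimized variationally
(via the pCCD Lagrangian and its response densities), which restores size
consistency and lets the orbitals localize and break symmetry; the reference
determinant is re-selected from the pCCD natural occupation numbers after
every rotation.

**Dynamical correlation.** Broken-pair excitations are added on top of the
frozen pCCD pair amplitudes — the frozen-pair (tailored) flavors fpCCD and
fpCCSD, their linearized variants fpLCCD and fpLCCSD (equations linear in
the broken-pair amplitudes while the pair exponential is kept intact), and
conventional CCD/CCSD in the same pCCD-optimized orbital basis.

**Ionization.** For each flavor, ionized states are parametrized by a linear
1h + 2h1p operator `R = sum r_i a_i + 1/2 sum r_ij^a a+_a a_j a_i` and the
ionization energies `omega` are right eigenvalues of the flavor's
similarity-transformed Hamiltonian, found by nonsymmetric Davidson iteration
with Koopmans seeding.  Both spin-dependent (spin-orbital) and spin-summed
(spatial-orbital) sigma equations are implemented and agree identically.

**Benchmark layer.** ME/MAE/RMSE/MPE/SD error statistics, box-plot
distribution summaries, and two-point complete-basis-set extrapolation
`E_X = E_CBS + a X^-3` of total energies and IPs.

Every stage is verified against brute-force determinant-space oracles
(dense FCI, seniority-zero CI, and the explicit finite-BCH matrix
`exp(-T) H exp(T)`) that ship as a first-class module.

## Worked example

Ionize a seeded two-electron fixture Hamiltonian with IP-EOM-fpCCSD:

```python
from fpcc import FixtureSpec, generate_fixture, ip_spectrum, fci_ground_energy

ham = generate_fixture(FixtureSpec("two-electron", {"K": 3, "scale": 0.3}, seed=6))
table, info = ip_spectrum(ham, flavor="fpCCSD", n_roots=2, davidson_tol=1e-9)
print(table[["state", "omega_ev", "weight_1h", "hole_character"]].to_string(index=False))
print(f"pCCD energy:   {info['pccd'].energy:.10f} Ha")
print(f"fpCCSD energy: {info['ground'].energy:.10f} Ha")
```

prints

```
 state   omega_ev  weight_1h hole_character
     0  48.266095   0.999591             0b
     1 122.522356   0.000343             0b
pCCD energy:   -2.7364711478 Ha
fpCCSD energy: -2.7364711478 Ha
```

State 0 is the Koopmans-like main line (99.96% 1h character, a beta hole in
orbital 0); state 1 is a 2h1p satellite.  For two electrons the 1h + 2h1p
space is complete, so the lowest root reproduces the FCI ionization energy
`E_FCI(N-1) - E_FCI(N)` (here to 2e-11 Ha), and because a two-electron
singlet is exactly seniority-zero in its natural orbitals, the broken-pair
correction vanishes: the fpCCSD energy equals the orbital-optimized pCCD
energy.

The same pipeline is scriptable from the shell:

```bash
fpcc run --config config.yaml     # pCCD -> flavors -> IP tables (TSV) + run log
fpcc stats --computed a.tsv --reference b.tsv   # ME/MAE/RMSE/MPE/SD report
fpcc cbs --input cbs.yaml         # two-point CBS extrapolation
fpcc oracle --config config.yaml  # brute-force cross-checks, nonzero exit on failure
```

## Scope

Active spaces are folded to a frozen-core effective Hamiltonian before any
correlated stage.  The package targets small molecular and model
Hamiltonians (FCIDUMP input, built-in reduced-pairing and random fixture
families); production-scale basis sets and geometry sets are out of scope,
as are perturbative triples, EA/spin-flip variants and 3h2p extensions.
See `docs/methods.md` for the model assumptions, numerical choices and
limitations.
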