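# Methods

## Model overview

The package implements a family of coupled-cluster (CC) methods built on a
pair coupled cluster doubles (pCCD) reference, and extracts vertical
ionization potentials (IPs) by equation-of-motion (EOM) diagonalization in
the 1h + 2h1p manifold.  All Hamiltonians are restricted closed-shell
molecular-orbital Hamiltonians: a core energy, one-electron integrals `h`,
and two-electron integrals in the chemist convention `(pq|rs)` with full
8-fold permutational symmetry (the FCIDUMP convention; orbital indices are
0-based in memory, 1-based on disk).

### pCCD and its working equations

pCCD keeps only closed-shell pair excitations, so the wave function lives in
the seniority-zero sector and the energy depends on the integrals only
through the classes `h_pp`, `J_pq = (pp|qq)` and `K_pq = (pq|pq)`.  The
amplitude equations used here were derived directly from the projection
conditions `<Phi_i^a| exp(-T_p) H exp(T_p) |Phi_0> = 0` by expanding the
pair-excited bra through the seniority-zero determinant couplings:

    R_ia = K_ia
         + c_ia [E(Phi_i^a) - E(Phi_0)]
         + sum_{j != i} K_ij c_ja + sum_{b != a} K_ab c_ib
         + sum_{jb} K_jb c_ib c_ja            (j != i, b != a)
         - c_ia [ sum_b K_ib c_ib + sum_j K_ja c_ja - c_ia K_ia ]

with `E(Phi_i^a)` the mean-field energy of the pair-excited determinant.
After cancellation the residual is at most quadratic in `c` — the generic
quartic CC bound collapses because the pair algebra closes.  Correctness is
anchored to two independent oracles rather than to transcribed literature
formulas: dense seniority-zero CI (DOCI), and the explicit determinant-basis
matrix of `exp(-T_p) H exp(T_p)`.

The amplitude solver is quasi-Newton on the pair energy denominators
`E(Phi_i^a) - E(Phi_0)` with DIIS (history 6), initial guess
`c = -K_ov / denominator` (zero where the denominator is below 1e-6),
residual max-norm tolerance 1e-10, at most 200 iterations.  Non-convergence
sets an honest flag and logs the largest residual; it never raises silently.

### Adjoint system and response densities

The orbital optimization needs densities that make the (non-variational)
projected energy stationary.  The adjoint amplitudes solve the linear system
`J^T lam = -dE/dc` where `J` is the amplitude Jacobian; because the residual
is quadratic, Jacobian columns are obtained *exactly* as symmetric unit-step
differences of the residual, and the dense system is solved directly (the
tool targets small active spaces; an iterative solver would gain nothing
here).  A condition number above 1e12 raises a diagnostic — that is the
degenerate-pair-spectrum failure mode.

The Lagrangian `L = E + lam . R` is affine in each integral class, so the
response densities are computed by exact unit-step differentiation of `L`
with respect to `h_pp`, `J_pq` and `K_pq`.  This yields the diagonal 1-RDM
(the natural occupations; their trace equals the electron count by
construction and is asserted to 1e-5) and a seniority-structured 2-RDM with
nonzeros `Gamma_ppqq` and `Gamma_pqpq` only.

### Orbital optimization

Orbitals are parametrized as `U = exp(-kappa)` with antisymmetric `kappa`;
orthogonality of the evaluated exponential is re-asserted to 1e-10.  The
energy gradient is assembled from the response densities through the
generalized Fock matrix (`g = F^T - F`, verified against finite differences
of the re-solved pCCD energy).  Far from stationarity the step is a damped
diagonal-Hessian (Levenberg-style trust region: steps are accepted only if
the re-solved energy does not increase, the damping adapts by factors of
4 and 0.5); once the gradient max-norm falls below 1e-2 the optimizer
switches to Newton steps on a finite-difference orbital Hessian, solved in
the Hessian eigenbasis with curvature clipped at 1e-6 so that redundant
(energy-invariant) rotations receive no step, and with the step capped at
0.3 radians.  Convergence: gradient max-norm 1e-7.  After every accepted
rotation the natural occupations re-select the reference determinant (ties
broken toward the lowest orbital index, with a logged warning) and the
orbitals are permuted so the occupied block leads.  No symmetry projector
exists anywhere, so symmetry breaking and localization are permitted by
construction.  The default optimization is deterministic; no stochastic
saddle-point escape is used.

### Broken-pair ground states

Six flavors share one spin-orbital CCSD residual engine (Fock and
antisymmetrized-integral blocks over interleaved alpha/beta spin orbitals):
CCD and CCSD (pair channel relaxed), fpCCD and fpCCSD (diagonal-pair channel
of T2 frozen to the pCCD amplitudes, never updated, its residual rows not
part of the equations), and fpLCCD/fpLCCSD.  The linearized flavors are
defined operationally: every term of combined order >= 2 in the broken-pair
amplitudes is dropped while the pair exponential is retained in full.  This
is implemented *exactly* — the residual is a polynomial of degree <= 4 in a
formal scaling `alpha` of the broken-pair amplitudes, so evaluating it at
`alpha = 0, +-1, +-2` and contracting with the inverse-Vandermonde weights
isolates the constant-plus-linear part with no truncation error.  The same
rule defines the linearized energy functional and (below) the linearized
effective Hamiltonian, so the fast route and the dense oracle truncate
identically by construction.  Solver: quasi-Newton with Moller-Plesset-style
denominators in the pCCD orbital basis, DIIS history 6, residual max-norm
1e-8, 200 iterations; T1 starts at zero, broken-pair T2 at the first-order
guess.  Exact antisymmetry and the frozen pair channel are re-imposed after
every DIIS extrapolation, which keeps the frozen channel bit-identical to
the pCCD amplitudes at every iterate.

The ground-state amplitude equations are solved in the spin-orbital
formulation (the form the determinant-basis oracle checks channel by
channel); the spin-summed spatial formulation is exercised where it matters
physically, in the IP-EOM sigma equations.

### IP-EOM

Ionized states live in the doublet-hole sector: `r1` over beta-spin holes,
`r2` over the `{i_a j_b a_a}` and `{i_b j_b a_b}` spin cases (2h1p).  The
sigma equations act with the normal-ordered one- and two-body blocks of the
flavor's `Hbar` (`Foo`, `Fov`, `Fvv`, `Woooo`, `Wooov`, `Wovvo`, `Wovoo`,
`Woovv`) plus one explicit three-body contraction through T2 — per two-body
contraction the cost is bounded by o^2 v^2 work.  Two evaluation engines
share a single declarative term list: a spin-dependent engine contracting
spin-orbital tensors directly, and a spin-summed engine that performs the
algebraic spin summation programmatically, emitting contractions over
spatial-orbital blocks only.  Their spectra are identical by construction of
the sector and are asserted equal in the tests.

One structural point deserves emphasis: the `2h1p <- 1h` coupling of `Hbar`
contains a disconnected term proportional to the ground-state *singles
projection* `<Phi_i^a|Hbar|Phi_0>`.  It vanishes for converged CCSD but not
for doubles-only or frozen-pair flavors, whose equations never set that
projection to zero; it is carried as a separate intermediate (`R1g`, which
reduces to the bare `f_ov` block at zero amplitudes) and is required for
exact agreement with the dense similarity-transformed matrix.

Flavor content of the intermediates: full and frozen-pair flavors keep all
nonvanishing nonlinear terms; linearized flavors keep only the nonlinear
terms associated with the pair operator, realized by the same exact
polynomial truncation as the ground state.  Because each sigma term is
linear in exactly one intermediate (and the three-body term is linear in
T2), truncating each intermediate truncates the projected matrix — the fast
route and the dense oracle therefore agree term-for-term, not just at
convergence.

The eigensolver is a nonsymmetric Davidson: Koopmans-type unit vectors on
the 1h block seed the subspace, the preconditioner is the Koopmans diagonal,
the subspace collapses onto the Ritz vectors at 20 roots x n_roots columns,
and stalled preconditioned directions fall back to raw residuals.  Roots are
returned ascending in omega; degeneracies within 1e-9 are ordered by
descending 1h weight, then lowest hole index.  Complex subspace eigenvalue
pairs (possible in principle for a non-Hermitian matrix) trigger a logged
diagnostic; arithmetic stays real, and only right eigenvectors are computed.
Hartree-to-eV conversion uses 27.211386245988.  A 1h-only mode exists behind
the sector bookkeeping but is not a default, since 2h1p relaxation is what
makes the method family accurate.

### Frozen core

The frozen-core approximation folds the leading `n_frozen` doubly occupied
orbitals into an effective Hamiltonian (core Coulomb/exchange into `h`, core
mean-field energy into the core constant) before any correlated stage, and
is validated against frozen-core dense CI.  Which orbitals to freeze is the
caller's decision (for second-row elements the 1s core, for third-row
1s2s2p), expressed as a count of leading orbitals.

### Statistics and CBS extrapolation

Error statistics over IP sets: ME (mean signed), MAE, RMSE, MPE (mean of
|error|/|reference| in percent — the absolute convention keeps MPE positive
even when ME is negative, and zero-reference entries are excluded with a
logged count), SD (n-1 denominator).  Distribution summaries follow the
box-plot convention: quartiles by linear interpolation, 1.5 IQR whiskers,
points beyond them flagged as outliers.  The CBS limit uses the standard
two-point inverse-cubic model `E_X = E_CBS + a X^-3` over cardinal numbers
X; the model string is recorded in every extrapolation's output metadata.
The two-point formula is linear, so extrapolating an energy difference
equals differencing the extrapolations — asserted in the tests.

## Oracles and what the tests show

The `oracles` module realizes Hamiltonians, cluster operators and
`exp(-T) H exp(T)` as explicit matrices over bitmask determinant bases
(lexicographic ordering, so oracle matrices are platform-reproducible), with
dimension caps of 50,000 (CI) and 5,000 (similarity transformation).  The
oracles are cross-validated among themselves: DOCI is bounded below by FCI,
FCI is invariant under orbital rotation, and the similarity transformation
preserves trace and spectrum.

The synthetic fixtures emulate what the verification needs from real
integrals — full 8-fold symmetry, a gapped mean-field reference, a tunable
interaction scale, seniority-conserving pairing models, block-diagonal
noninteracting composites — and are deterministic under their seed.  They do
not emulate basis-set structure, point-group symmetry, Coulomb singularity
cusps or realistic integral decay.  Passing tests therefore demonstrate that
the implemented equations are *exactly* the stated models (to the printed
tolerances) on small Hamiltonians; they do not by themselves certify
accuracy claims on production molecular basis sets, which require external
geometry and reference data outside desk scope.

Problem sizes used throughout the suite and the acceptance script — up to 6
spatial orbitals, 2-3 electron pairs, 20-fixture panels — were chosen so the
dense oracles remain exact references and the full battery runs in minutes
on one CPU.

## Known limitations

- The amplitude-level Jacobian and orbital Hessian are built densely; fine
  for the intended active-space sizes, wasteful beyond ~20 orbitals.
- The linearized-flavor residual costs five residual evaluations per
  iteration (the exact polynomial truncation); a hand-expanded term list
  would be faster but would reintroduce transcription risk.
- Only right EOM eigenvectors are computed; properties needing
  biorthogonal left vectors (Dyson intensities) are out of scope.
- Complex-pair eigenvalues of the non-Hermitian effective Hamiltonian are
  detected and reported, not resolved.
- No point-group symmetry is exploited anywhere, by design (symmetry
  breaking is a feature of the orbital optimization, not a bug).
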