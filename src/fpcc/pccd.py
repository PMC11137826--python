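"""Orbital-optimized pair coupled cluster doubles (pCCD).

pCCD restricts the cluster operator to closed-shell electron-pair
excitations ``T_p = sum_ia c_i^a a+_a a+_abar a_ibar a_i``, i.e. to the
seniority-zero sector.  Because the pair algebra closes, the projected
amplitude equations can be written entirely in terms of the seniority
integral classes

    hd_p = h_pp,   J_pq = (pp|qq),   K_pq = (pq|pq),

and are at most quadratic in the amplitudes ``c``.  The equations used here
are derived directly from the projection conditions
``<Phi_i^a| exp(-T_p) H exp(T_p) |Phi_0> = 0`` (see docs/methods.md) and are
validated against dense seniority-zero CI, never against transcribed
literature formulas.

The adjoint (Lambda) system makes the energy stationary with respect to
``c``; response densities then follow by exact differentiation of the
Lagrangian with respect to the integral classes (the Lagrangian is affine in
each class, so unit-step finite differences are exact), and drive the
variational orbital optimization, which also re-selects the reference
determinant from the pCCD natural occupations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .diis import DIIS
from .hamiltonian import (
    MolecularHamiltonian,
    ReferenceDeterminant,
    RotationGenerator,
    fock_matrix,
    reference_energy,
    transform_orbitals,
)

__all__ = [
    "PairAmplitudes",
    "PairAdjoint",
    "PCCDResult",
    "OrbitalOptimizationResult",
    "pccd_residual",
    "pccd_energy",
    "solve_pccd",
    "solve_pccd_lambda",
    "natural_occupations",
    "select_reference",
    "orbital_gradient",
    "optimize_orbitals",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairAmplitudes:
    """Pair-excitation amplitudes ``c[i, a]`` (occupied x virtual, spatial)."""

    c: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.c, dtype=float)
        object.__setattr__(self, "c", c)
        if c.ndim != 2 or not np.all(np.isfinite(c)):
            raise ValueError("pair amplitudes must be a finite o x v matrix")


@dataclass(frozen=True)
class PairAdjoint:
    """Adjoint (Lambda) amplitudes, same shape as the pair amplitudes."""

    lam: np.ndarray

    def __post_init__(self):
        lam = np.asarray(self.lam, dtype=float)
        object.__setattr__(self, "lam", lam)
        if lam.ndim != 2 or not np.all(np.isfinite(lam)):
            raise ValueError("adjoint amplitudes must be a finite o x v matrix")


@dataclass(frozen=True)
class PCCDResult:
    energy: float
    c: PairAmplitudes
    lam: PairAdjoint
    natural_occupations: np.ndarray
    converged: bool
    n_iter: int


@dataclass(frozen=True)
class OrbitalOptimizationResult:
    ham: MolecularHamiltonian
    pccd: PCCDResult
    kappas: list  # accepted RotationGenerator steps, in order
    U_total: np.ndarray  # accumulated orthogonal transformation (incl. permutations)
    gradient_norm: float
    converged: bool
    n_iter: int


# ---------------------------------------------------------------------------
# Seniority integral classes
# ---------------------------------------------------------------------------

def _seniority_classes(ham: MolecularHamiltonian):
    if ham.n_frozen != 0:
        raise ValueError("fold the frozen core before running pCCD")
    hd = np.diag(ham.h).copy()
    Jm = np.einsum("ppqq->pq", ham.eri)
    Km = np.einsum("pqpq->pq", ham.eri)
    return hd, Jm, Km


def _residual_blocks(hd, Jm, Km, o: int):
    """Precompute the c-independent blocks entering the residual."""
    K = hd.size
    G = 2.0 * Jm - Km
    occ = np.arange(o)
    virt = np.arange(o, K)
    S = G[:, occ].sum(axis=1)  # S[p] = sum_{j occ} G_pj
    # Delta E_ia = E(Phi_ii->aa) - E(Phi_0)
    dE = (
        2.0 * (hd[virt][None, :] - hd[occ][:, None])
        + 2.0 * (S[virt][None, :] - G[np.ix_(occ, virt)])
        - 2.0 * (S[occ][:, None] - np.diag(G)[occ][:, None])
        + np.diag(G)[virt][None, :]
        - np.diag(G)[occ][:, None]
    )
    Kov = Km[np.ix_(occ, virt)]
    Koo = Km[np.ix_(occ, occ)].copy()
    np.fill_diagonal(Koo, 0.0)
    Kvv = Km[np.ix_(virt, virt)].copy()
    np.fill_diagonal(Kvv, 0.0)
    return dE, Kov, Koo, Kvv


def _residual(c, dE, Kov, Koo, Kvv):
    rowK = np.sum(Kov * c, axis=1, keepdims=True)  # sum_b K_ib c_ib
    colK = np.sum(Kov * c, axis=0, keepdims=True)  # sum_j K_ja c_ja
    Q = (c @ Kov.T) @ c  # sum_jb K_jb c_ib c_ja
    return (
        Kov
        + c * dE
        + Koo @ c
        + c @ Kvv
        + Q
        - 2.0 * c * rowK
        - 2.0 * c * colK
        + 2.0 * Kov * c * c
    )


def pccd_residual(ham: MolecularHamiltonian, c: PairAmplitudes) -> np.ndarray:
    """Projection of ``exp(-T_p) H exp(T_p)`` on the pair-excited determinants.

    Zero at the pCCD solution; entry ``(i, a)`` couples the pair excitation
    ``i, ibar -> a, abar``.
    """
    hd, Jm, Km = _seniority_classes(ham)
    o = ham.n_pairs
    if c.c.shape != (o, ham.n_orb - o):
        raise ValueError("amplitude shape inconsistent with the active space")
    return _residual(c.c, *_residual_blocks(hd, Jm, Km, o))


def pccd_energy(ham: MolecularHamiltonian, c: PairAmplitudes) -> float:
    """``E_ref + sum_ia c_ia K_ia`` with the pair-coupling exchange integrals."""
    _, _, Km = _seniority_classes(ham)
    o = ham.n_pairs
    Kov = Km[:o, o:]
    return reference_energy(ham) + float(np.sum(Kov * c.c))


def _initial_guess(dE, Kov):
    denom = np.where(np.abs(dE) < 1e-6, np.inf, dE)
    return -Kov / denom


def solve_pccd(
    ham: MolecularHamiltonian,
    guess: PairAmplitudes | None = None,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> PCCDResult:
    """Solve the pCCD amplitude and adjoint equations.

    Quasi-Newton iteration on the pair energy denominators with DIIS
    (history 6).  Raises no exception on non-convergence; the ``converged``
    flag and residual history are honest.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    hd, Jm, Km = _seniority_classes(ham)
    o, K = ham.n_pairs, ham.n_orb
    dE, Kov, Koo, Kvv = _residual_blocks(hd, Jm, Km, o)
    c = _initial_guess(dE, Kov) if guess is None else guess.c.copy()
    denom = np.where(np.abs(dE) < 1e-6, np.copysign(1.0, dE) * 1.0, dE)
    diis = DIIS(6)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        R = _residual(c, dE, Kov, Koo, Kvv)
        if np.max(np.abs(R)) < tol:
            converged = True
            break
        c = diis.update((c - R / denom).ravel(), (R / denom).ravel()).reshape(o, K - o)
    if not converged:
        logger.warning(
            "pCCD did not converge in %d iterations (max residual %.2e)",
            max_iter,
            float(np.max(np.abs(_residual(c, dE, Kov, Koo, Kvv)))),
        )
    amps = PairAmplitudes(c)
    lam = solve_pccd_lambda(ham, amps) if converged else PairAdjoint(np.zeros_like(c))
    occs = natural_occupations(ham, amps, lam) if converged else None
    if occs is None:
        occs = np.concatenate([2.0 * np.ones(o), np.zeros(K - o)])
    energy = reference_energy(ham) + float(np.sum(Kov * c))
    return PCCDResult(energy, amps, lam, occs, converged, n_iter)


def _jacobian(ham, c):
    """Dense amplitude Jacobian by exact symmetric differences (the residual
    is quadratic, so the odd part at unit step is the exact linear map)."""
    hd, Jm, Km = _seniority_classes(ham)
    o = ham.n_pairs
    blocks = _residual_blocks(hd, Jm, Km, o)
    n = c.size
    J = np.empty((n, n))
    for k in range(n):
        x = np.zeros_like(c).ravel()
        x[k] = 1.0
        x = x.reshape(c.shape)
        J[:, k] = 0.5 * (_residual(c + x, *blocks) - _residual(c - x, *blocks)).ravel()
    return J


def solve_pccd_lambda(
    ham: MolecularHamiltonian, c: PairAmplitudes, tol: float = 1e-10
) -> PairAdjoint:
    """Solve the linear adjoint system ``J^T lam = -dE/dc``."""
    _, _, Km = _seniority_classes(ham)
    o = ham.n_pairs
    Kov = Km[:o, o:]
    J = _jacobian(ham, c.c)
    cond = np.linalg.cond(J)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "singular pCCD adjoint system (degenerate pair spectrum)"
        )
    lam = np.linalg.solve(J.T, -Kov.ravel())
    return PairAdjoint(lam.reshape(c.c.shape))


# ---------------------------------------------------------------------------
# Response densities
# ---------------------------------------------------------------------------

def _lagrangian(core, hd, Jm, Km, c, lam, o):
    dE, Kov, Koo, Kvv = _residual_blocks(hd, Jm, Km, o)
    occ = np.arange(o)
    G = 2.0 * Jm - Km
    e_ref = core + 2.0 * hd[occ].sum() + G[np.ix_(occ, occ)].sum()
    energy = e_ref + float(np.sum(Kov * c))
    return energy + float(np.sum(lam * _residual(c, dE, Kov, Koo, Kvv)))


def response_densities(ham: MolecularHamiltonian, c: PairAmplitudes, lam: PairAdjoint):
    """Seniority-structured response densities ``(gamma, A, B)``.

    ``gamma`` is the (diagonal) 1-RDM; the 2-RDM has the seniority-zero
    sparsity ``Gamma_ppqq = A_pq`` (pair block) and ``Gamma_pqpq = B_pq``
    (number block), chemist indexing.  Obtained by exact unit-step
    differentiation of the Lagrangian, which is affine in each integral class.
    """
    hd, Jm, Km = _seniority_classes(ham)
    o, K = ham.n_pairs, ham.n_orb
    base = _lagrangian(0.0, hd, Jm, Km, c.c, lam.lam, o)
    gamma = np.empty(K)
    for p in range(K):
        hp = hd.copy()
        hp[p] += 1.0
        gamma[p] = _lagrangian(0.0, hp, Jm, Km, c.c, lam.lam, o) - base
    A = np.zeros((K, K))
    B = np.zeros((K, K))
    for p in range(K):
        for q in range(p + 1):
            if p == q:
                Jp, Kp = Jm.copy(), Km.copy()
                Jp[p, p] += 1.0
                Kp[p, p] += 1.0
                A[p, p] = _lagrangian(0.0, hd, Jp, Kp, c.c, lam.lam, o) - base
            else:
                Jp = Jm.copy()
                Jp[p, q] += 1.0
                Jp[q, p] += 1.0
                A[p, q] = A[q, p] = 0.5 * (
                    _lagrangian(0.0, hd, Jp, Km, c.c, lam.lam, o) - base
                )
                Kp = Km.copy()
                Kp[p, q] += 1.0
                Kp[q, p] += 1.0
                B[p, q] = B[q, p] = 0.5 * (
                    _lagrangian(0.0, hd, Jm, Kp, c.c, lam.lam, o) - base
                )
    return gamma, A, B


def natural_occupations(
    ham: MolecularHamiltonian, c: PairAmplitudes, lam: PairAdjoint
) -> np.ndarray:
    """Diagonal of the pCCD response 1-RDM; values in [0, 2], trace = N."""
    gamma, _, _ = response_densities(ham, c, lam)
    trace = gamma.sum()
    if abs(trace - ham.n_electrons) > 1e-5:
        raise ValueError(
            f"response 1-RDM trace {trace:.8f} violates the electron count"
        )
    return gamma


def select_reference(occupations: np.ndarray, n_pairs: int) -> ReferenceDeterminant:
    """The ``n_pairs`` orbitals of largest occupation; ties to the lowest index."""
    occ = np.asarray(occupations, dtype=float)
    order = np.lexsort((np.arange(occ.size), -occ))  # stable: lowest index wins ties
    chosen = np.sort(order[:n_pairs])
    if n_pairs < occ.size:
        edge_in = occ[order[n_pairs - 1]]
        edge_out = occ[order[n_pairs]]
        if abs(edge_in - edge_out) < 1e-12:
            logger.warning(
                "natural-occupation tie at the Fermi edge (%.12f); "
                "keeping the lowest-index orbital",
                edge_in,
            )
    return ReferenceDeterminant(tuple(int(i) for i in chosen))


# ---------------------------------------------------------------------------
# Orbital optimization
# ---------------------------------------------------------------------------

def _two_rdm_tensor(A, B):
    K = A.shape[0]
    G = np.zeros((K, K, K, K))
    idx = np.arange(K)
    G[idx[:, None], idx[:, None], idx[None, :], idx[None, :]] += A
    off = B.copy()
    np.fill_diagonal(off, 0.0)
    G[idx[:, None], idx[None, :], idx[:, None], idx[None, :]] += off
    return G


def orbital_gradient(ham: MolecularHamiltonian, c: PairAmplitudes, lam: PairAdjoint):
    """Antisymmetric energy gradient w.r.t. the rotation generator kappa.

    Built from the response densities through the generalized Fock matrix;
    the sign convention matches ``rotate_orbitals`` (U = exp(-kappa)), i.e.
    ``E(kappa) ~ E(0) + sum_pq g_pq kappa_pq / ...`` with g returned here.
    """
    gamma, A, B = response_densities(ham, c, lam)
    Gamma = _two_rdm_tensor(A, B)
    F = ham.h * gamma[None, :] + 2.0 * np.einsum(
        "mqrs,nqrs->mn", ham.eri, Gamma, optimize=True
    )
    return F.T - F


@dataclass
class OrbitalOptions:
    tol: float = 1e-7  # gradient max-norm
    energy_tol: float = 1e-10
    max_iter: int = 200
    mu0: float = 1.0  # initial Levenberg-style damping of the diagonal Hessian
    newton_threshold: float = 1e-2  # gradient norm below which FD-Newton kicks in


def _kappa_params(K):
    return [(p, q) for p in range(K) for q in range(p + 1, K)]


def _pack_kappa(mat, pairs):
    return np.array([mat[p, q] for p, q in pairs])


def _unpack_kappa(vec, pairs, K):
    kappa = np.zeros((K, K))
    for x, (p, q) in zip(vec, pairs):
        kappa[p, q] = x
        kappa[q, p] = -x
    return kappa


def _newton_step(ham, result, grad, pairs, eps=1e-5):
    """Full orbital Hessian by central differences of the analytic gradient;
    returns the (regularized) Newton step in kappa form."""
    K = ham.n_orb
    n = len(pairs)
    H = np.empty((n, n))
    for k, (p, q) in enumerate(pairs):
        d = np.zeros((K, K))
        d[p, q], d[q, p] = eps, -eps
        up = transform_orbitals(ham, RotationGenerator(d).matrix())
        dn = transform_orbitals(ham, RotationGenerator(-d).matrix())
        ru = solve_pccd(up, guess=result.c)
        rd = solve_pccd(dn, guess=result.c)
        if not (ru.converged and rd.converged):
            return None
        gu = _pack_kappa(orbital_gradient(up, ru.c, ru.lam), pairs)
        gd = _pack_kappa(orbital_gradient(dn, rd.c, rd.lam), pairs)
        H[:, k] = (gu - gd) / (2 * eps)
    H = 0.5 * (H + H.T)
    g = _pack_kappa(grad, pairs)
    # solve in the Hessian eigenbasis with clipped curvature: redundant
    # (energy-invariant) rotation directions get no step instead of noise
    w, V = np.linalg.eigh(H)
    curv = np.maximum(np.abs(w), 1e-6)
    step = -V @ ((V.T @ g) / curv)
    big = np.abs(step).max()
    if big > 0.3:
        step *= 0.3 / big
    return _unpack_kappa(step, pairs, K)


def optimize_orbitals(
    ham: MolecularHamiltonian, opts: OrbitalOptions | None = None
) -> OrbitalOptimizationResult:
    """Variationally optimize the orbitals of the pCCD energy.

    Exponential parametrization with a damped diagonal-Hessian (trust-region
    style) step; the reference determinant is re-selected from the natural
    occupations after every accepted rotation, so symmetry breaking and
    occupied/virtual reordering are permitted by construction.
    """
    opts = opts or OrbitalOptions()
    K = ham.n_orb
    o = ham.n_pairs
    current = ham
    result = solve_pccd(current)
    if not result.converged:
        raise RuntimeError("pCCD failed to converge at the starting orbitals")
    kappas: list[RotationGenerator] = []
    U_total = np.eye(K)
    mu = opts.mu0
    grad = orbital_gradient(current, result.c, result.lam)
    gnorm = float(np.max(np.abs(grad)))
    converged = gnorm < opts.tol
    n_iter = 0
    pairs = _kappa_params(K)
    while not converged and n_iter < opts.max_iter:
        n_iter += 1
        accepted = False
        if gnorm < opts.newton_threshold:
            # quadratic local convergence: Newton on the FD orbital Hessian
            kappa = _newton_step(current, result, grad, pairs)
            if kappa is not None:
                gen = RotationGenerator(kappa)
                trial = transform_orbitals(current, gen.matrix())
                trial_res = solve_pccd(trial, guess=result.c)
                if trial_res.converged:
                    trial_grad = orbital_gradient(trial, trial_res.c, trial_res.lam)
                    if (
                        trial_res.energy <= result.energy + 1e-12
                        or np.max(np.abs(trial_grad)) < 0.5 * gnorm
                    ):
                        accepted = True
        if not accepted:
            f = fock_matrix(current)
            gamma = result.natural_occupations
            hess = np.abs(
                2.0
                * (gamma[:, None] - gamma[None, :])
                * (np.diag(f)[None, :] - np.diag(f)[:, None])
            )
            hess = np.maximum(hess, 0.1)
            for _ in range(40):
                kappa = -grad / (hess + mu)
                kappa = 0.5 * (kappa - kappa.T)
                gen = RotationGenerator(kappa)
                trial = transform_orbitals(current, gen.matrix())
                trial_res = solve_pccd(trial, guess=result.c)
                if trial_res.converged and trial_res.energy <= result.energy + 1e-12:
                    accepted = True
                    mu = max(mu * 0.5, 1e-8)
                    break
                mu *= 4.0
        if not accepted:
            logger.warning(
                "orbital optimization: no downhill step found (gradient %.2e); "
                "returning last stable state",
                gnorm,
            )
            break
        current, result = trial, trial_res
        kappas.append(gen)
        U_total = U_total @ gen.matrix()
        # re-select the reference determinant from the natural occupations
        ref = select_reference(result.natural_occupations, o)
        if ref.occupied_pairs != tuple(range(o)):
            order = list(ref.occupied_pairs) + [
                p for p in range(K) if p not in ref.occupied_pairs
            ]
            P = np.eye(K)[:, order]
            current = transform_orbitals(current, P)
            U_total = U_total @ P
            result = solve_pccd(current)
            logger.info("reference determinant re-selected: %s", ref.occupied_pairs)
        grad = orbital_gradient(current, result.c, result.lam)
        gnorm = float(np.max(np.abs(grad)))
        converged = gnorm < opts.tol
    return OrbitalOptimizationResult(
        current, result, kappas, U_total, gnorm, converged, n_iter
    )
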