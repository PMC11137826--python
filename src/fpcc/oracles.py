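"""Brute-force determinant-space oracles.

Everything here trades scaling for transparency: Hamiltonians, cluster
operators and similarity transformations are realized as explicit matrices
over bitmask determinant bases, so the polynomial-scaling production code in
:mod:`fpcc.ground_state` and :mod:`fpcc.ipeom` can be checked against exact
linear algebra on small systems.

Determinants are integers whose bit ``s`` marks occupation of interleaved
spin orbital ``s = 2p + sigma`` (``sigma = 0`` alpha, ``1`` beta); bases are
ordered lexicographically (ascending integers), which makes every oracle
matrix reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .hamiltonian import MolecularHamiltonian
from .spinorb import spin_orbital_eri, spin_orbital_h

__all__ = [
    "DeterminantBasis",
    "hamiltonian_matrix",
    "excitation_matrix",
    "fci_ground_energy",
    "doci_ground_energy",
    "cc_residual_dense",
    "dense_hbar",
    "dense_ip_matrix",
    "linear_order_weights",
]

FCI_DIM_CAP = 50_000
HBAR_DIM_CAP = 5_000


@dataclass(frozen=True)
class DeterminantBasis:
    """All determinants of ``n_elec`` electrons in ``n_spin`` spin orbitals
    with fixed ``2 Sz = sz2``; optionally with a frozen (always occupied) core."""

    n_spin: int
    n_elec: int
    sz2: int = 0
    frozen_bits: int = 0

    @property
    def states(self) -> list[int]:
        return self._build()

    def _build(self) -> list[int]:
        if not hasattr(self, "_states"):
            K = self.n_spin // 2
            na = (self.n_elec + self.sz2) // 2
            nb = self.n_elec - na
            if na - nb != self.sz2 or na < 0 or nb < 0 or na > K or nb > K:
                object.__setattr__(self, "_states", [])
                return []
            alphas = [sum(1 << (2 * p) for p in combo) for combo in combinations(range(K), na)]
            betas = [sum(1 << (2 * p + 1) for p in combo) for combo in combinations(range(K), nb)]
            states = sorted(
                a | b
                for a in alphas
                for b in betas
                if (a | b) & self.frozen_bits == self.frozen_bits
            )
            object.__setattr__(self, "_states", states)
        return self._states

    @property
    def index(self) -> dict[int, int]:
        if not hasattr(self, "_index"):
            object.__setattr__(
                self, "_index", {d: i for i, d in enumerate(self.states)}
            )
        return self._index

    def __len__(self) -> int:
        return len(self.states)


def _apply_string(bits: int, ops: tuple[tuple[int, bool], ...]) -> tuple[int, int] | None:
    """Apply a second-quantized operator string (rightmost first).

    ``ops`` is a sequence of ``(spin_orbital, dagger)``; returns the resulting
    determinant and fermionic phase, or ``None`` if the string annihilates it.
    """
    phase = 1
    for s, dagger in reversed(ops):
        mask = 1 << s
        occupied = bits & mask
        if dagger:
            if occupied:
                return None
            if (bits & (mask - 1)).bit_count() % 2:
                phase = -phase
            bits |= mask
        else:
            if not occupied:
                return None
            if (bits & (mask - 1)).bit_count() % 2:
                phase = -phase
            bits &= ~mask
    return bits, phase


def _occ_list(bits: int) -> list[int]:
    out = []
    s = 0
    while bits:
        if bits & 1:
            out.append(s)
        bits >>= 1
        s += 1
    return out


def hamiltonian_matrix(ham: MolecularHamiltonian, basis: DeterminantBasis) -> np.ndarray:
    """Dense matrix of H over the basis, by Slater-Condon enumeration."""
    h = spin_orbital_h(ham)
    g = spin_orbital_eri(ham)
    n_spin = 2 * ham.n_orb
    states = basis.states
    index = basis.index
    dim = len(states)
    H = np.zeros((dim, dim))
    for col, ket in enumerate(states):
        occ = _occ_list(ket)
        virt = [s for s in range(n_spin) if not (ket >> s) & 1]
        diag = ham.core_energy + sum(h[s, s] for s in occ)
        diag += 0.5 * sum(g[s, t, s, t] for s in occ for t in occ)
        H[col, col] += diag
        for s in occ:
            for u in virt:
                coeff = h[u, s] + sum(g[u, t, s, t] for t in occ if t != s)
                res = _apply_string(ket, ((u, True), (s, False)))
                if res is not None:
                    row = index.get(res[0])  # outside rows = projection on the sector
                    if row is not None:
                        H[row, col] += res[1] * coeff
        for s, t in combinations(occ, 2):
            for u, v in combinations(virt, 2):
                res = _apply_string(
                    ket, ((u, True), (v, True), (t, False), (s, False))
                )
                if res is not None:
                    row = index.get(res[0])
                    if row is not None:
                        H[row, col] += res[1] * g[u, v, s, t]
    return H


def excitation_matrix(
    basis: DeterminantBasis,
    t1: np.ndarray | None,
    t2: np.ndarray | None,
    occ_so: np.ndarray,
    virt_so: np.ndarray,
) -> np.ndarray:
    """Matrix of ``T = sum t1 a+_a a_i + (1/4) sum t2 a+_a a+_b a_j a_i``.

    ``t1``/``t2`` are indexed over the positions of ``occ_so``/``virt_so``;
    ``t2`` must be antisymmetric in (ij) and (ab).
    """
    states = basis.states
    index = basis.index
    dim = len(states)
    T = np.zeros((dim, dim))
    no, nv = len(occ_so), len(virt_so)
    terms: list[tuple[float, tuple[tuple[int, bool], ...]]] = []
    if t1 is not None:
        for i in range(no):
            for a in range(nv):
                if t1[i, a] != 0.0:
                    terms.append(
                        (t1[i, a], ((int(virt_so[a]), True), (int(occ_so[i]), False)))
                    )
    if t2 is not None:
        for i in range(no):
            for j in range(i + 1, no):
                for a in range(nv):
                    for b in range(a + 1, nv):
                        val = t2[i, j, a, b]
                        if val != 0.0:
                            terms.append(
                                (
                                    val,
                                    (
                                        (int(virt_so[a]), True),
                                        (int(virt_so[b]), True),
                                        (int(occ_so[j]), False),
                                        (int(occ_so[i]), False),
                                    ),
                                )
                            )
    for col, ket in enumerate(states):
        for coeff, ops in terms:
            res = _apply_string(ket, ops)
            if res is not None:
                row = index.get(res[0])  # images outside the sector are projected out
                if row is not None:
                    T[row, col] += res[1] * coeff
    return T


def _nilpotent_expm(T: np.ndarray) -> np.ndarray:
    """exp(T) for a nilpotent excitation matrix, by the terminating series."""
    out = np.eye(T.shape[0])
    term = np.eye(T.shape[0])
    for k in range(1, T.shape[0] + 1):
        term = term @ T / k
        if not term.any():
            break
        out += term
    return out


# ---------------------------------------------------------------------------
# Ground-state oracles
# ---------------------------------------------------------------------------

def fci_ground_energy(
    ham: MolecularHamiltonian,
    n_elec: int | None = None,
    sz2: int = 0,
    frozen_core: int = 0,
    return_rdm1: bool = False,
):
    """Lowest eigenvalue (and optional spin-summed 1-RDM) of the dense
    Hamiltonian in the ``(n_elec, sz2)`` sector."""
    if n_elec is None:
        n_elec = ham.n_electrons
    frozen_bits = 0
    for p in range(frozen_core):
        frozen_bits |= 1 << (2 * p) | 1 << (2 * p + 1)
    basis = DeterminantBasis(2 * ham.n_orb, n_elec, sz2, frozen_bits)
    if len(basis) == 0:
        raise ValueError("empty determinant sector")
    if len(basis) > FCI_DIM_CAP:
        raise ValueError(f"determinant space dimension {len(basis)} exceeds cap")
    H = hamiltonian_matrix(ham, basis)
    w, V = np.linalg.eigh(H)
    e0 = float(w[0])
    if not return_rdm1:
        return e0
    psi = V[:, 0]
    K = ham.n_orb
    rdm1 = np.zeros((K, K))
    index = basis.index
    for col, ket in enumerate(basis.states):
        if abs(psi[col]) < 1e-14:
            continue
        for s in _occ_list(ket):
            p, sig = divmod(s, 2)
            for q in range(K):
                res = _apply_string(ket, ((2 * q + sig, True), (s, False)))
                if res is not None:
                    rdm1[q, p] += res[1] * psi[index[res[0]]] * psi[col]
    return e0, rdm1


def doci_ground_energy(ham: MolecularHamiltonian):
    """Seniority-zero (doubly occupied) CI: ground energy, pair-CI vector in
    the lexicographic pair basis, and natural occupations (length K, in [0,2])."""
    K, npair = ham.n_orb, ham.n_pairs
    from math import comb

    if comb(K, npair) > FCI_DIM_CAP:
        raise ValueError("pair-space dimension exceeds cap")
    states = [sum(1 << p for p in combo) for combo in combinations(range(K), npair)]
    states.sort()
    index = {d: i for i, d in enumerate(states)}
    hd = np.diag(ham.h)
    Jm = np.einsum("ppqq->pq", ham.eri)
    Km = np.einsum("pqpq->pq", ham.eri)
    dim = len(states)
    H = np.zeros((dim, dim))
    for col, ket in enumerate(states):
        occ = _occ_list(ket)
        occ_arr = np.array(occ)
        e = ham.core_energy + 2.0 * hd[occ_arr].sum()
        e += (2.0 * Jm - Km)[np.ix_(occ_arr, occ_arr)].sum()
        H[col, col] = e
        for p in occ:
            for q in range(K):
                if (ket >> q) & 1:
                    continue
                H[index[ket ^ (1 << p) ^ (1 << q)], col] += Km[p, q]
    w, V = np.linalg.eigh(H)
    psi = V[:, 0]
    occs = np.zeros(K)
    for col, ket in enumerate(states):
        for p in _occ_list(ket):
            occs[p] += 2.0 * psi[col] ** 2
    return float(w[0]), psi, occs


# ---------------------------------------------------------------------------
# Similarity-transformed Hamiltonian oracles
# ---------------------------------------------------------------------------

def linear_order_weights(degree: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Nodes and weights extracting the order-0 plus order-1 part of a
    polynomial of the given degree from its values at integer nodes."""
    nodes = np.array([0, 1, -1, 2, -2][: degree + 1], dtype=float)
    V = np.vander(nodes, degree + 1, increasing=True)
    A = np.linalg.inv(V)
    return nodes, A[0] + A[1]


def dense_hbar(
    ham: MolecularHamiltonian,
    t1: np.ndarray | None,
    t2: np.ndarray,
    n_elec: int,
    sz2: int,
    pair_t2: np.ndarray | None = None,
):
    """Explicit ``exp(-T) H exp(T)`` over the ``(n_elec, sz2)`` determinant
    basis.

    When ``pair_t2`` is given, the amplitudes are split into the electron-pair
    channel (kept to all orders) and the broken-pair remainder ``t - t_pair``
    (kept to first order only): the matrix polynomial in a formal scaling of
    the broken-pair amplitudes is truncated exactly after the linear term,
    which realizes the linearized (fpLCC-type) similarity transformation.
    """
    from .spinorb import occ_virt_spin_orbitals

    occ_so, virt_so = occ_virt_spin_orbitals(ham)
    basis = DeterminantBasis(2 * ham.n_orb, n_elec, sz2)
    if len(basis) > HBAR_DIM_CAP:
        raise ValueError(f"sector dimension {len(basis)} exceeds cap")
    H = hamiltonian_matrix(ham, basis)

    def hbar(t1x, t2x):
        T = excitation_matrix(basis, t1x, t2x, occ_so, virt_so)
        return _nilpotent_expm(-T) @ H @ _nilpotent_expm(T)

    if pair_t2 is None:
        return basis, hbar(t1, t2)
    broken_t2 = t2 - pair_t2
    nodes, weights = linear_order_weights(4)
    out = None
    for x, w in zip(nodes, weights):
        t1x = None if t1 is None else x * t1
        M = hbar(t1x, pair_t2 + x * broken_t2)
        out = w * M if out is None else out + w * M
    return basis, out


def cc_residual_dense(
    ham: MolecularHamiltonian,
    t1: np.ndarray | None,
    t2: np.ndarray,
    pair_t2: np.ndarray | None = None,
):
    """Project ``Hbar |Phi_0>`` on the reference, singles and doubles.

    Returns ``(energy, R1, R2)`` with amplitude-shaped residuals; the
    independent oracle for every ground-state flavor (``pair_t2`` switches on
    the linearized truncation as in :func:`dense_hbar`).
    """
    from .spinorb import occ_virt_spin_orbitals

    occ_so, virt_so = occ_virt_spin_orbitals(ham)
    no, nv = len(occ_so), len(virt_so)
    basis, Hbar = dense_hbar(ham, t1, t2, ham.n_electrons, 0, pair_t2=pair_t2)
    ref = int(sum(1 << int(s) for s in occ_so))
    index = basis.index
    y = Hbar[:, index[ref]]
    energy = float(y[index[ref]])
    R1 = np.zeros((no, nv))
    for i in range(no):
        for a in range(nv):
            res = _apply_string(ref, ((int(virt_so[a]), True), (int(occ_so[i]), False)))
            if res is not None and res[0] in index:  # spin-allowed only
                R1[i, a] = res[1] * y[index[res[0]]]
    R2 = np.zeros((no, no, nv, nv))
    for i in range(no):
        for j in range(i + 1, no):
            for a in range(nv):
                for b in range(a + 1, nv):
                    res = _apply_string(
                        ref,
                        (
                            (int(virt_so[a]), True),
                            (int(virt_so[b]), True),
                            (int(occ_so[j]), False),
                            (int(occ_so[i]), False),
                        ),
                    )
                    if res is not None and res[0] in index:
                        val = res[1] * y[index[res[0]]]
                        R2[i, j, a, b] = val
                        R2[j, i, a, b] = -val
                        R2[i, j, b, a] = -val
                        R2[j, i, b, a] = val
    return energy, R1, R2


def ionization_vector_to_dets(
    ham: MolecularHamiltonian, r1: np.ndarray, r2: np.ndarray, dets: list[int]
) -> np.ndarray:
    """Coefficients of ``R |Phi_0>`` on the given (N-1)-electron determinants.

    Phase conventions follow the operator-application engine, so amplitude
    vectors and dense-matrix vectors can be compared element-wise.
    """
    from .spinorb import occ_virt_spin_orbitals

    occ_so, virt_so = occ_virt_spin_orbitals(ham)
    ref = int(sum(1 << int(s) for s in occ_so))
    index = {d: k for k, d in enumerate(dets)}
    vec = np.zeros(len(dets))
    no, nv = len(occ_so), len(virt_so)
    for i in range(no):
        if r1[i] != 0.0:
            res = _apply_string(ref, ((int(occ_so[i]), False),))
            if res is not None and res[0] in index:
                vec[index[res[0]]] += res[1] * r1[i]
    for i in range(no):
        for j in range(i + 1, no):
            for a in range(nv):
                if r2[i, j, a] != 0.0:
                    res = _apply_string(
                        ref,
                        (
                            (int(virt_so[a]), True),
                            (int(occ_so[j]), False),
                            (int(occ_so[i]), False),
                        ),
                    )
                    if res is not None and res[0] in index:
                        vec[index[res[0]]] += res[1] * r2[i, j, a]
    return vec


def dense_ip_matrix(
    ham: MolecularHamiltonian,
    t1: np.ndarray | None,
    t2: np.ndarray,
    pair_t2: np.ndarray | None = None,
    sz2_ion: int = 1,
):
    """The explicit 1h+2h1p block of ``Hbar - E0`` in the (N-1)-electron
    sector; the central oracle for the IP-EOM engine.

    Returns ``(dets, M)`` where ``dets`` lists the retained determinants in
    lexicographic order and ``M`` is the projected non-Hermitian matrix whose
    eigenvalues are ionization energies ``omega`` (Hartree).
    """
    from .spinorb import occ_virt_spin_orbitals

    occ_so, virt_so = occ_virt_spin_orbitals(ham)
    ref = int(sum(1 << int(s) for s in occ_so))
    n_elec = ham.n_electrons
    basis_ion, Hbar_ion = dense_hbar(ham, t1, t2, n_elec - 1, sz2_ion, pair_t2=pair_t2)
    # E0 from the N-electron sector with identical amplitudes/truncation
    E0, _, _ = cc_residual_dense(ham, t1, t2, pair_t2=pair_t2)
    keep = [
        i for i, d in enumerate(basis_ion.states) if (d & ~ref).bit_count() <= 1
    ]
    dets = [basis_ion.states[i] for i in keep]
    M = Hbar_ion[np.ix_(keep, keep)] - E0 * np.eye(len(keep))
    return dets, M
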