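"""Spin-orbital views of a restricted Hamiltonian.

Spin orbitals are interleaved: spin orbital ``s = 2p + sigma`` with
``sigma = 0`` for alpha and ``1`` for beta, so lexicographic determinant
orderings are stable under this convention.
"""

from __future__ import annotations

import numpy as np

from .hamiltonian import MolecularHamiltonian, fock_matrix

__all__ = [
    "spin_orbital_h",
    "spin_orbital_eri",
    "spin_orbital_fock",
    "occ_virt_spin_orbitals",
]


def spin_orbital_h(ham: MolecularHamiltonian) -> np.ndarray:
    """One-electron integrals over 2K interleaved spin orbitals."""
    return np.kron(ham.h, np.eye(2))


def spin_orbital_eri(ham: MolecularHamiltonian) -> np.ndarray:
    """Antisymmetrized physicist integrals ``<PQ||RS>`` over spin orbitals."""
    K = ham.n_orb
    tmp = ham.eri.transpose(0, 2, 1, 3)  # (pr|qs) -> [p, q, r, s] physicist
    eye = np.eye(2)
    g = np.einsum("pqrs,ac,bd->paqbrcsd", tmp, eye, eye).reshape(
        2 * K, 2 * K, 2 * K, 2 * K
    )
    return g - g.transpose(0, 1, 3, 2)


def spin_orbital_fock(ham: MolecularHamiltonian) -> np.ndarray:
    """Closed-shell Fock matrix expanded to spin orbitals."""
    return np.kron(fock_matrix(ham), np.eye(2))


def occ_virt_spin_orbitals(ham: MolecularHamiltonian) -> tuple[np.ndarray, np.ndarray]:
    """Occupied and virtual spin-orbital index lists of the leading-pair reference."""
    no = 2 * ham.n_pairs
    return np.arange(no), np.arange(no, 2 * ham.n_orb)


def pair_channel_t2(c: np.ndarray) -> np.ndarray:
    """Embed spatial pair amplitudes ``c[i, a]`` into an antisymmetric
    spin-orbital ``t2[I, J, A, B]`` (the i=j, a=b diagonal-pair channel)."""
    o, v = c.shape
    t2 = np.zeros((2 * o, 2 * o, 2 * v, 2 * v))
    for i in range(o):
        for a in range(v):
            val = c[i, a]
            t2[2 * i, 2 * i + 1, 2 * a, 2 * a + 1] = val
            t2[2 * i + 1, 2 * i, 2 * a, 2 * a + 1] = -val
            t2[2 * i, 2 * i + 1, 2 * a + 1, 2 * a] = -val
            t2[2 * i + 1, 2 * i, 2 * a + 1, 2 * a] = val
    return t2


def spin_conserving_masks(no: int, nv: int) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks of Sz-conserving t1/t2 entries (interleaved spins)."""
    so = np.arange(no) % 2
    sv = np.arange(nv) % 2
    m1 = so[:, None] == sv[None, :]
    m2 = (
        so[:, None, None, None] + so[None, :, None, None]
        == sv[None, None, :, None] + sv[None, None, None, :]
    )
    return m1, m2


def pair_channel_mask(no: int, nv: int) -> np.ndarray:
    """Boolean mask of the diagonal-pair channel in a spin-orbital t2."""
    mask = np.zeros((no, no, nv, nv), dtype=bool)
    for i in range(no // 2):
        for a in range(nv // 2):
            for pi, pj in ((2 * i, 2 * i + 1), (2 * i + 1, 2 * i)):
                for pa, pb in ((2 * a, 2 * a + 1), (2 * a + 1, 2 * a)):
                    mask[pi, pj, pa, pb] = True
    return mask
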