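"""Restricted molecular-orbital Hamiltonians: data model, FCIDUMP I/O, rotations.

The package works throughout with spin-free (spatial-orbital) integrals in the
chemist ``(pq|rs)`` index convention, the same convention FCIDUMP files use.
Orbital indices are 0-based internally and 1-based on disk.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

__all__ = [
    "MolecularHamiltonian",
    "RotationGenerator",
    "ReferenceDeterminant",
    "read_fcidump",
    "write_fcidump",
    "rotate_orbitals",
    "transform_orbitals",
    "fold_frozen_core",
    "make_pairing_hamiltonian",
    "reference_energy",
    "fock_matrix",
]

#: default numerical tolerance for integral-symmetry invariants
SYMMETRY_TOL = 1e-10

# generators of the 8-fold permutational symmetry group of real (pq|rs)
_ERI_PERMS = (
    (1, 0, 2, 3),  # p <-> q
    (0, 1, 3, 2),  # r <-> s
    (2, 3, 0, 1),  # (pq) <-> (rs)
    (1, 0, 3, 2),
    (3, 2, 0, 1),
    (2, 3, 1, 0),
    (3, 2, 1, 0),
)


@dataclass(frozen=True)
class MolecularHamiltonian:
    """Closed-shell restricted Hamiltonian in a molecular-orbital basis.

    Parameters
    ----------
    core_energy:
        Scalar energy offset in Hartree (nuclear repulsion plus any folded
        frozen-core contribution).
    h:
        ``(K, K)`` one-electron integral matrix, Hartree.
    eri:
        ``(K, K, K, K)`` two-electron integrals ``(pq|rs)`` (chemist
        convention), Hartree.
    n_pairs:
        Number of doubly occupied orbitals in the closed-shell reference.
    n_frozen:
        Number of frozen-core spatial orbitals (always the leading orbitals).
    basis_tag:
        Provenance label: ``"canonical-HF"``, ``"pCCD-natural"`` or ``"model"``.
    """

    core_energy: float
    h: np.ndarray
    eri: np.ndarray
    n_pairs: int
    n_frozen: int = 0
    basis_tag: str = "model"

    def __post_init__(self) -> None:
        h = np.ascontiguousarray(np.asarray(self.h, dtype=float))
        eri = np.ascontiguousarray(np.asarray(self.eri, dtype=float))
        object.__setattr__(self, "h", h)
        object.__setattr__(self, "eri", eri)
        self.validate()

    # -- basic views ------------------------------------------------------
    @property
    def n_orb(self) -> int:
        """Number of spatial orbitals K."""
        return self.h.shape[0]

    @property
    def n_electrons(self) -> int:
        return 2 * self.n_pairs

    def validate(self, tol: float = SYMMETRY_TOL) -> None:
        """Check the structural invariants; raise ``ValueError`` on failure."""
        K = self.h.shape[0]
        if self.h.shape != (K, K):
            raise ValueError("h must be a square matrix")
        if self.eri.shape != (K, K, K, K):
            raise ValueError("eri must have shape (K, K, K, K)")
        if not np.allclose(self.h, self.h.T, atol=tol):
            raise ValueError("one-electron integrals must be symmetric")
        for perm in _ERI_PERMS:
            if not np.allclose(self.eri, self.eri.transpose(perm), atol=tol):
                raise ValueError(
                    "two-electron integrals violate 8-fold permutational symmetry"
                )
        if self.n_frozen < 0 or self.n_frozen >= self.n_pairs:
            raise ValueError("require 0 <= n_frozen < n_pairs")
        if not (self.n_pairs <= K):
            raise ValueError("n_pairs cannot exceed the number of orbitals")


@dataclass(frozen=True)
class RotationGenerator:
    """Real antisymmetric generator ``kappa``; the rotation is ``exp(-kappa)``."""

    kappa: np.ndarray

    def __post_init__(self) -> None:
        kappa = np.asarray(self.kappa, dtype=float)
        object.__setattr__(self, "kappa", kappa)
        if kappa.ndim != 2 or kappa.shape[0] != kappa.shape[1]:
            raise ValueError("kappa must be square")
        if not np.allclose(kappa, -kappa.T, atol=1e-12):
            raise ValueError("kappa must be antisymmetric")

    def matrix(self) -> np.ndarray:
        """Orthogonal matrix ``U = exp(-kappa)``, orthogonality re-asserted."""
        U = expm(-self.kappa)
        if not np.allclose(U.T @ U, np.eye(U.shape[0]), atol=1e-10):
            raise ValueError("exp(-kappa) failed the orthogonality check")
        return U


@dataclass(frozen=True)
class ReferenceDeterminant:
    """Closed-shell determinant given by its doubly occupied spatial orbitals."""

    occupied_pairs: tuple[int, ...]

    def __post_init__(self) -> None:
        occ = tuple(int(i) for i in self.occupied_pairs)
        object.__setattr__(self, "occupied_pairs", occ)
        if len(set(occ)) != len(occ):
            raise ValueError("occupied orbitals must be unique")
        if any(i < 0 for i in occ):
            raise ValueError("orbital indices must be non-negative")


def aufbau_reference(ham: MolecularHamiltonian) -> ReferenceDeterminant:
    """The leading-orbital reference |Phi_0> = first ``n_pairs`` orbitals."""
    return ReferenceDeterminant(tuple(range(ham.n_pairs)))


# ---------------------------------------------------------------------------
# FCIDUMP (Knowles-Handy layout)
# ---------------------------------------------------------------------------

#: integrals smaller than this magnitude are not written to disk
WRITE_FLOOR = 1e-16


def read_fcidump(path) -> MolecularHamiltonian:
    """Read a restricted closed-shell Hamiltonian from an FCIDUMP file.

    Point-group labels (ORBSYM/ISYM) are parsed but ignored.  Only ``MS2=0``
    with an even electron count is accepted.  All integrals that are not
    listed are zero; listed integrals are expanded to full 8-fold symmetry.
    """
    text = open(path).read()
    m = re.search(r"&FCI(.*?)(?:&END|/)", text, re.DOTALL | re.IGNORECASE)
    if m is None:
        raise ValueError(f"{path}: missing &FCI ... &END namelist header")
    header, body = m.group(1), text[m.end():]

    def _get(key, default=None):
        mm = re.search(rf"{key}\s*=\s*(-?\d+)", header, re.IGNORECASE)
        if mm is None:
            if default is None:
                raise ValueError(f"{path}: header lacks {key}")
            return default
        return int(mm.group(1))

    norb = _get("NORB")
    nelec = _get("NELEC")
    ms2 = _get("MS2", 0)
    if nelec % 2 != 0:
        raise ValueError("restricted closed-shell reader requires even NELEC")
    if ms2 != 0:
        raise ValueError("restricted closed-shell reader requires MS2 = 0")

    core = 0.0
    h = np.zeros((norb, norb))
    eri = np.zeros((norb, norb, norb, norb))
    for line in body.splitlines():
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 5:
            raise ValueError(f"{path}: malformed integral record {line!r}")
        val = float(parts[0].replace("D", "E").replace("d", "e"))
        p, q, r, s = (int(x) for x in parts[1:])
        if max(p, q, r, s) > norb:
            raise ValueError(f"{path}: orbital index exceeds NORB in {line!r}")
        if p == 0 and q == 0 and r == 0 and s == 0:
            core = val
        elif r == 0 and s == 0:
            h[p - 1, q - 1] = h[q - 1, p - 1] = val
        else:
            p, q, r, s = p - 1, q - 1, r - 1, s - 1
            eri[p, q, r, s] = val
            for perm in _ERI_PERMS:
                idx = tuple(np.array([p, q, r, s])[list(perm)])
                eri[idx] = val
    return MolecularHamiltonian(core, h, eri, n_pairs=nelec // 2)


def write_fcidump(ham: MolecularHamiltonian, path, floor: float = WRITE_FLOOR) -> None:
    """Write ``ham`` in FCIDUMP form (symmetry-unique integrals only)."""
    K = ham.n_orb
    with open(path, "w") as fh:
        fh.write(f"&FCI NORB={K},NELEC={ham.n_electrons},MS2=0,\n")
        fh.write(" ORBSYM=" + "1," * K + "\n ISYM=1,\n&END\n")

        def rec(val, p, q, r, s):
            fh.write(f" {val:23.16E} {p:4d} {q:4d} {r:4d} {s:4d}\n")

        seen = set()
        for p in range(K):
            for q in range(p + 1):
                for r in range(p + 1):
                    for s in range(K):
                        if (p, q, r, s) in seen:
                            continue
                        val = ham.eri[p, q, r, s]
                        idx = (p, q, r, s)
                        group = {idx} | {
                            tuple(np.array(idx)[list(perm)]) for perm in _ERI_PERMS
                        }
                        seen |= group
                        if abs(val) > floor:
                            rec(val, p + 1, q + 1, r + 1, s + 1)
        for p in range(K):
            for q in range(p + 1):
                if abs(ham.h[p, q]) > floor:
                    rec(ham.h[p, q], p + 1, q + 1, 0, 0)
        rec(ham.core_energy, 0, 0, 0, 0)


# ---------------------------------------------------------------------------
# Orbital transformations
# ---------------------------------------------------------------------------

def transform_orbitals(ham: MolecularHamiltonian, U: np.ndarray) -> MolecularHamiltonian:
    """Transform all integrals by an orthogonal matrix ``U`` (columns = new MOs)."""
    U = np.asarray(U, dtype=float)
    if U.shape != (ham.n_orb, ham.n_orb):
        raise ValueError("dimension mismatch between U and the Hamiltonian")
    h = U.T @ ham.h @ U
    eri = np.einsum("tuvw,tp,uq,vr,ws->pqrs", ham.eri, U, U, U, U, optimize=True)
    return replace(ham, h=h, eri=eri)


def rotate_orbitals(ham: MolecularHamiltonian, kappa: RotationGenerator) -> MolecularHamiltonian:
    """Apply the orbital rotation ``U = exp(-kappa)`` to all integrals."""
    if kappa.kappa.shape[0] != ham.n_orb:
        raise ValueError("dimension mismatch between kappa and the Hamiltonian")
    return transform_orbitals(ham, kappa.matrix())


def fold_frozen_core(ham: MolecularHamiltonian) -> MolecularHamiltonian:
    """Fold the ``n_frozen`` leading doubly occupied orbitals into an
    effective Hamiltonian over the remaining ``K - n_frozen`` orbitals.

    The core Coulomb/exchange field enters the one-electron integrals and the
    core's mean-field energy is absorbed into ``core_energy``.
    """
    nc = ham.n_frozen
    if nc < 1:
        raise ValueError("fold_frozen_core requires n_frozen >= 1")
    if nc >= ham.n_pairs:
        raise ValueError("cannot freeze all (or more) occupied pairs")
    core = np.arange(nc)
    act = np.arange(nc, ham.n_orb)
    # core Coulomb (2J - K) field over active orbitals
    j_field = 2.0 * np.einsum("pqcc->pq", ham.eri[np.ix_(act, act, core, core)])
    k_field = np.einsum("pccq->pq", ham.eri[np.ix_(act, core, core, act)])
    h_eff = ham.h[np.ix_(act, act)] + j_field - k_field
    e_core = (
        ham.core_energy
        + 2.0 * np.trace(ham.h[np.ix_(core, core)])
        + 2.0 * np.einsum("ccdd->", ham.eri[np.ix_(core, core, core, core)])
        - np.einsum("cddc->", ham.eri[np.ix_(core, core, core, core)])
    )
    return MolecularHamiltonian(
        e_core,
        h_eff,
        ham.eri[np.ix_(act, act, act, act)],
        n_pairs=ham.n_pairs - nc,
        n_frozen=0,
        basis_tag=ham.basis_tag,
    )


# ---------------------------------------------------------------------------
# Model Hamiltonians
# ---------------------------------------------------------------------------

def make_pairing_hamiltonian(levels, g: float, n_pairs: int | None = None) -> MolecularHamiltonian:
    """Reduced (BCS-like) pairing Hamiltonian in molecular-Hamiltonian form.

    ``H = sum_p eps_p (n_pa + n_pb) - g sum_pq P+_p P_q`` realized through
    the exchange-type integrals ``(pq|pq) = -g``.  The 8-fold symmetry of a
    real two-electron tensor then also carries the diagonal spin-exchange
    partner of the pair-hop term; the model remains seniority-conserving, so
    its ground state is reachable by dense seniority-zero CI.
    """
    levels = np.asarray(levels, dtype=float)
    K = levels.size
    if K < 2:
        raise ValueError("need at least two single-pair levels")
    if n_pairs is None:
        n_pairs = K // 2
    h = np.diag(levels)
    eri = np.zeros((K, K, K, K))
    for p in range(K):
        for q in range(K):
            eri[p, q, p, q] = -g
            eri[p, q, q, p] = -g
    return MolecularHamiltonian(0.0, h, eri, n_pairs=n_pairs, basis_tag="model")


# ---------------------------------------------------------------------------
# Mean-field quantities
# ---------------------------------------------------------------------------

def reference_energy(ham: MolecularHamiltonian, ref: ReferenceDeterminant | None = None) -> float:
    """Energy of the closed-shell determinant: ``core + 2 sum h_ii + sum (2J - K)``."""
    if ref is None:
        ref = aufbau_reference(ham)
    occ = np.asarray(ref.occupied_pairs, dtype=int)
    if occ.size and occ.max() >= ham.n_orb:
        raise IndexError("reference orbital index out of range")
    e1 = 2.0 * ham.h[occ, occ].sum()
    Jb = ham.eri[np.ix_(occ, occ, occ, occ)]
    e2 = 2.0 * np.einsum("iijj->", Jb) - np.einsum("ijji->", Jb)
    return float(ham.core_energy + e1 + e2)


def fock_matrix(ham: MolecularHamiltonian, ref: ReferenceDeterminant | None = None) -> np.ndarray:
    """Closed-shell Fock matrix ``f = h + sum_i [2 (pq|ii) - (pi|iq)]``."""
    if ref is None:
        ref = aufbau_reference(ham)
    occ = np.asarray(ref.occupied_pairs, dtype=int)
    f = ham.h.copy()
    if occ.size:
        f += 2.0 * np.einsum("pqii->pq", ham.eri[:, :, occ][:, :, :, occ])
        f -= np.einsum("piiq->pq", ham.eri[:, occ][:, :, occ, :])
    return f
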