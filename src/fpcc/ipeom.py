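"""IP-EOM over the six coupled-cluster flavors: 1h + 2h1p ionization energies.

The ionized states are parametrized by a linear hole-type operator

    R = sum_i r_i a_i  +  (1/2) sum_ija r_ij^a a+_a a_j a_i

acting on the flavor's ground state, and obtained as right eigenvalues of
the similarity-transformed Hamiltonian ``Hbar - E0`` projected on the 1h and
2h1p manifolds of one spin sector (the doublet-hole sector: r1 runs over
beta-spin holes, r2 over the {i_a j_b a_a} and {i_b j_b a_b} spin cases).

The sigma equations are written once as a term list over the normal-ordered
one- and two-body elements of Hbar (plus the one explicit three-body
contraction) and evaluated by two engines:

* spin-dependent: direct spin-orbital contractions;
* spin-summed: algebraic spin summation over the same term list, emitting
  contractions over spatial-orbital blocks only.

Both must produce identical spectra; the determinant-basis oracle
(:func:`fpcc.oracles.dense_ip_matrix`) independently checks either route.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ground_state import FLAVORS, FlavorSpec, GroundStateResult, _Workspace
from .hamiltonian import MolecularHamiltonian
from .oracles import linear_order_weights
from .spinorb import pair_channel_t2

__all__ = [
    "HARTREE_TO_EV",
    "EffectiveHamiltonian",
    "IonizationVector",
    "IPRoot",
    "build_intermediates",
    "sigma_vector",
    "davidson_ionize",
    "DavidsonOptions",
    "ip_spectrum",
]

logger = logging.getLogger(__name__)

HARTREE_TO_EV = 27.211386245988


# ---------------------------------------------------------------------------
# Effective Hamiltonian intermediates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectiveHamiltonian:
    """Normal-ordered one-/two-body Hbar blocks needed by the 1h/2h1p sigma
    equations, plus the T2 amplitudes entering the explicit three-body term.

    With all cluster amplitudes zero every block equals its bare Fock/integral
    counterpart.  ``flavor`` records which nonlinear terms were included:
    full and frozen-pair flavors keep all nonvanishing nonlinear terms, the
    linearized flavors only those associated with the electron-pair operator
    (everything beyond first order in the broken-pair amplitudes is dropped).
    """

    Foo: np.ndarray
    Fov: np.ndarray
    Fvv: np.ndarray
    Woooo: np.ndarray
    Wooov: np.ndarray
    Wovvo: np.ndarray
    Wovoo: np.ndarray
    Woovv: np.ndarray
    R1g: np.ndarray  # ground-state singles projection (1h -> 2h1p coupling)
    t2: np.ndarray
    flavor: FlavorSpec
    no: int
    nv: int
    e_ground: float


def _bare_intermediates(ws: _Workspace, t1: np.ndarray, t2: np.ndarray):
    """Full Hbar blocks as polynomials in the amplitudes (spin-orbital)."""
    ein = np.einsum
    tau = t2 + ein("ia,jb->ijab", t1, t1) - ein("ib,ja->ijab", t1, t1)

    Fme = ws.fov + ein("nf,mnef->me", t1, ws.oovv)
    Fmi = (
        ws.foo
        + ein("ie,me->mi", t1, ws.fov)
        + ein("ne,mnie->mi", t1, ws.ooov)
        + 0.5 * ein("inef,mnef->mi", t2, ws.oovv)
        + ein("ie,nf,mnef->mi", t1, t1, ws.oovv)
    )
    Fae = (
        ws.fvv
        - ein("ma,me->ae", t1, ws.fov)
        + ein("mf,amef->ae", t1, ws.vovv)
        - 0.5 * ein("mnaf,mnef->ae", t2, ws.oovv)
        - ein("ma,nf,mnef->ae", t1, t1, ws.oovv)
    )

    Woooo = ws.oooo + 0.5 * ein("ijef,mnef->mnij", tau, ws.oovv)
    x = ein("je,mnie->mnij", t1, ws.ooov)
    Woooo = Woooo + x - x.transpose(0, 1, 3, 2)

    Wooov = ws.ooov + ein("if,mnfe->mnie", t1, ws.oovv)

    Wovvo = (
        ws.ovvo
        + ein("jf,mbef->mbej", t1, ws.ovvv)
        - ein("nb,mnej->mbej", t1, ws.oovo)
        - ein("jnfb,mnef->mbej", t2 + ein("jf,nb->jnfb", t1, t1), ws.oovv)
    )

    Wovoo = (
        ws.ovoo
        - ein("me,ijbe->mbij", Fme, t2)
        - ein("nb,mnij->mbij", t1, Woooo)
        + 0.5 * ein("mbef,ijef->mbij", ws.ovvv, tau)
    )
    x = ein("mnie,jnbe->mbij", ws.ooov, t2)
    Wovoo = Wovoo + x - x.transpose(0, 1, 3, 2)
    x = ein("ie,mbej->mbij", t1, ws.ovvo - ein("njbf,mnef->mbej", t2, ws.oovv))
    Wovoo = Wovoo + x - x.transpose(0, 1, 3, 2)

    # disconnected singles-residual coupling <2h1p| a_m Hbar |Phi_0>: the
    # ground-state singles projection couples the 1h block to 2h1p.  It
    # vanishes for converged CCSD but not for doubles-only or frozen-pair
    # flavors; at zero amplitudes it reduces to the bare f_ov block.
    from .ground_state import _residual_full

    R1g = _residual_full(ws, t1, t2)[0]

    return Fmi, Fme, Fae, Woooo, Wooov, Wovvo, Wovoo, R1g


def build_intermediates(
    ham: MolecularHamiltonian, ground: GroundStateResult, c: np.ndarray | None = None
) -> EffectiveHamiltonian:
    """Assemble the flavor's effective Hamiltonian from its converged ground
    state.  For frozen-pair flavors ``c`` defaults to the pair channel stored
    in the amplitudes."""
    if not ground.converged:
        raise ValueError("ground state must be converged before IP-EOM")
    ws = _Workspace(ham)
    flavor = ground.flavor
    t1 = ground.amplitudes.t1
    t1 = np.zeros((ws.no, ws.nv)) if t1 is None else t1
    t2 = ground.amplitudes.t2
    if flavor.linearized:
        if c is None:
            pair_t2 = np.zeros_like(t2)
            pair_t2[ws.mask] = t2[ws.mask]
        else:
            pair_t2 = pair_channel_t2(c)
        broken2 = t2 - pair_t2
        nodes, weights = linear_order_weights(4)
        acc = None
        for xn, w in zip(nodes, weights):
            vals = _bare_intermediates(ws, xn * t1, pair_t2 + xn * broken2)
            if acc is None:
                acc = [w * v for v in vals]
            else:
                acc = [a + w * v for a, v in zip(acc, vals)]
        Fmi, Fme, Fae, Woooo, Wooov, Wovvo, Wovoo, R1g = acc
    else:
        Fmi, Fme, Fae, Woooo, Wooov, Wovvo, Wovoo, R1g = _bare_intermediates(ws, t1, t2)
    return EffectiveHamiltonian(
        Foo=Fmi,
        Fov=Fme,
        Fvv=Fae,
        Woooo=Woooo,
        Wooov=Wooov,
        Wovvo=Wovvo,
        Wovoo=Wovoo,
        Woovv=ws.oovv,
        R1g=R1g,
        t2=t2,
        flavor=flavor,
        no=ws.no,
        nv=ws.nv,
        e_ground=ground.energy,
    )


# ---------------------------------------------------------------------------
# Sigma equations (one shared term list, two evaluation engines)
# ---------------------------------------------------------------------------

def _sigma_spin_orbital(imds: EffectiveHamiltonian, r1: np.ndarray, r2: np.ndarray):
    """Spin-dependent sigma: direct spin-orbital contractions.

    ``r1``: (no,) hole amplitudes; ``r2``: (no, no, nv) antisymmetric in the
    two hole indices.  Exactly linear in r.
    """
    ein = np.einsum
    s1 = -ein("mi,m->i", imds.Foo, r1)
    s1 -= ein("me,mie->i", imds.Fov, r2)
    s1 += 0.5 * ein("nmie,mne->i", imds.Wooov, r2)

    s2 = -ein("maij,m->ija", imds.Wovoo, r1)
    s2 += ein("ae,ije->ija", imds.Fvv, r2)
    x = ein("mi,mja->ija", imds.Foo, r2)
    s2 -= x - x.transpose(1, 0, 2)
    s2 += 0.5 * ein("mnij,mna->ija", imds.Woooo, r2)
    x = ein("maei,mje->ija", imds.Wovvo, r2)
    s2 += x - x.transpose(1, 0, 2)
    s2 += 0.5 * ein("mnef,mnf,ijae->ija", imds.Woovv, r2, imds.t2)
    x = ein("i,ja->ija", r1, imds.R1g)
    s2 += x - x.transpose(1, 0, 2)
    return s1, s2


#: the same sigma equations as a declarative term list, used for algebraic
#: spin summation.  Each entry: (target, subscripts, operand names, factor,
#: antisymmetrize-two-hole-output?)
_SIGMA_TERMS = [
    ("s1", "mi,m->i", ("Foo", "r1"), -1.0),
    ("s1", "me,mie->i", ("Fov", "r2"), -1.0),
    ("s1", "nmie,mne->i", ("Wooov", "r2"), 0.5),
    ("s2", "maij,m->ija", ("Wovoo", "r1"), -1.0),
    ("s2", "ae,ije->ija", ("Fvv", "r2"), 1.0),
    ("s2", "mi,mja->ija", ("Foo", "r2"), -1.0),
    ("s2", "mj,mia->ija", ("Foo", "r2"), 1.0),
    ("s2", "mnij,mna->ija", ("Woooo", "r2"), 0.5),
    ("s2", "maei,mje->ija", ("Wovvo", "r2"), 1.0),
    ("s2", "mbej,mie->ijb", ("Wovvo", "r2"), -1.0),
    ("s2", "mnef,mnf,ijae->ija", ("Woovv", "r2", "t2"), 0.5),
    ("s2", "i,ja->ija", ("r1", "R1g"), 1.0),
    ("s2", "j,ia->ija", ("r1", "R1g"), -1.0),
]


def _spatial_slice(tensor: np.ndarray, spins: tuple[int, ...]) -> np.ndarray:
    """Spatial block of a spin-orbital tensor for the given index spins."""
    sl = tuple(slice(s, None, 2) for s in spins)
    return tensor[sl]


def _resolve_r2_block(r2A, r2B, spins):
    """Spatial tensor for the r2 spin case; None when outside the sector.

    Cases: (a,b,a) -> A[i,j,a]; (b,a,a) -> -A[j,i,a]; (b,b,b) -> B.
    """
    if spins == (0, 1, 0):
        return r2A
    if spins == (1, 0, 0):
        return -r2A.transpose(1, 0, 2)
    if spins == (1, 1, 1):
        return r2B
    return None


def _sigma_spin_summed(imds: EffectiveHamiltonian, r1s, r2A, r2B):
    """Spin-summed sigma: algebraic spin summation of the term list, every
    emitted contraction running over spatial orbitals only.

    Blocks: ``r1s`` (o,) beta holes; ``r2A`` (o,o,v) for {i_a j_b a_a};
    ``r2B`` (o,o,v) antisymmetric for {i_b j_b a_b}.
    """
    o, v = imds.no // 2, imds.nv // 2
    out = {
        "s1": np.zeros(o),
        "s2A": np.zeros((o, o, v)),
        "s2B": np.zeros((o, o, v)),
    }
    tensors = {
        "Foo": imds.Foo,
        "Fov": imds.Fov,
        "Fvv": imds.Fvv,
        "Woooo": imds.Woooo,
        "Wooov": imds.Wooov,
        "Wovvo": imds.Wovvo,
        "Wovoo": imds.Wovoo,
        "Woovv": imds.Woovv,
        "R1g": imds.R1g,
        "t2": imds.t2,
    }
    # occupied/virtual letters per subscript position decide slicing parity
    for target, subscripts, names, factor in _SIGMA_TERMS:
        lhs, rhs = subscripts.split("->")
        groups = lhs.split(",")
        targets = ["s1"] if target == "s1" else ["s2A", "s2B"]
        for tgt in targets:
            out_spins = {"s1": {"i": 1}, "s2A": {}, "s2B": {}}[tgt]
            if tgt == "s2A":
                out_spins = dict(zip(rhs, (0, 1, 0)))
            elif tgt == "s2B":
                out_spins = dict(zip(rhs, (1, 1, 1)))
            free = sorted(set(lhs.replace(",", "")) - set(rhs))
            from itertools import product

            for assignment in product((0, 1), repeat=len(free)):
                spin_of = dict(zip(free, assignment))
                spin_of.update(out_spins)
                operands = []
                ok = True
                for grp, name in zip(groups, names):
                    spins = tuple(spin_of[ch] for ch in grp)
                    if name == "r1":
                        if spins != (1,):
                            ok = False
                            break
                        operands.append(r1s)
                    elif name == "r2":
                        block = _resolve_r2_block(r2A, r2B, spins)
                        if block is None:
                            ok = False
                            break
                        operands.append(block)
                    else:
                        operands.append(_spatial_slice(tensors[name], spins))
                if ok:
                    out[tgt] += factor * np.einsum(subscripts, *operands)
    return out["s1"], out["s2A"], out["s2B"]


# ---------------------------------------------------------------------------
# Sector packing
# ---------------------------------------------------------------------------

class _Sector:
    """Index bookkeeping for the doublet-hole (1h + 2h1p) spin sector."""

    def __init__(self, no: int, nv: int):
        self.no, self.nv = no, nv
        self.h1 = [i for i in range(no) if i % 2 == 1]  # beta holes
        self.h2 = [
            (i, j, a)
            for i in range(no)
            for j in range(i + 1, no)
            for a in range(nv)
            if (i % 2) + (j % 2) - (a % 2) == 1
        ]
        self.dim = len(self.h1) + len(self.h2)

    def pack(self, r1: np.ndarray, r2: np.ndarray) -> np.ndarray:
        v = np.empty(self.dim)
        v[: len(self.h1)] = r1[self.h1]
        v[len(self.h1):] = [r2[i, j, a] for (i, j, a) in self.h2]
        return v

    def unpack(self, v: np.ndarray):
        r1 = np.zeros(self.no)
        r1[self.h1] = v[: len(self.h1)]
        r2 = np.zeros((self.no, self.no, self.nv))
        for k, (i, j, a) in enumerate(self.h2):
            r2[i, j, a] = v[len(self.h1) + k]
            r2[j, i, a] = -v[len(self.h1) + k]
        return r1, r2


@dataclass(frozen=True)
class IonizationVector:
    """1h + 2h1p amplitudes of one ionized state (spin-orbital storage)."""

    r1: np.ndarray  # (no,), nonzero on beta holes
    r2: np.ndarray  # (no, no, nv), antisymmetric in the hole pair

    def norm(self) -> float:
        return float(np.sqrt(np.sum(self.r1**2) + 0.5 * np.sum(self.r2**2)))

    @property
    def weight_1h(self) -> float:
        n2 = self.norm() ** 2
        return float(np.sum(self.r1**2) / n2) if n2 > 0 else 0.0


@dataclass(frozen=True)
class IPRoot:
    """One ionized state: ``omega`` in Hartree (see ``omega_ev``)."""

    omega: float
    vector: IonizationVector
    weight_1h: float
    converged: bool

    @property
    def omega_ev(self) -> float:
        return self.omega * HARTREE_TO_EV


def sigma_vector(
    imds: EffectiveHamiltonian, r: IonizationVector, spin_summed: bool = False
) -> IonizationVector:
    """Action of ``Hbar - E0`` on a trial vector; exactly linear in ``r``."""
    if not spin_summed:
        s1, s2 = _sigma_spin_orbital(imds, r.r1, r.r2)
        return IonizationVector(s1, s2)
    o, v = imds.no // 2, imds.nv // 2
    r1s = r.r1[1::2]
    r2A = r.r2[0::2, 1::2, 0::2]
    r2B = r.r2[1::2, 1::2, 1::2]
    s1, s2A, s2B = _sigma_spin_summed(imds, r1s, r2A, r2B)
    out1 = np.zeros(imds.no)
    out1[1::2] = s1
    out2 = np.zeros((imds.no, imds.no, imds.nv))
    out2[0::2, 1::2, 0::2] = s2A
    out2[1::2, 0::2, 0::2] = -s2A.transpose(1, 0, 2)
    s2B = 0.5 * (s2B - s2B.transpose(1, 0, 2))
    out2[1::2, 1::2, 1::2] = s2B
    return IonizationVector(out1, out2)


# ---------------------------------------------------------------------------
# Davidson
# ---------------------------------------------------------------------------

@dataclass
class DavidsonOptions:
    tol: float = 1e-6  # residual norm, Hartree
    max_iter: int = 200
    max_subspace_factor: int = 20
    spin_summed: bool = False


def davidson_ionize(
    imds: EffectiveHamiltonian, n_roots: int, opts: DavidsonOptions | None = None
) -> list[IPRoot]:
    """Lowest ``n_roots`` ionization energies by nonsymmetric Davidson
    iteration, seeded with Koopmans-type unit vectors on the 1h block.

    Roots are returned sorted ascending in omega; degenerate roots (within
    1e-9) are ordered by descending 1h weight, then lowest hole index.
    """
    opts = opts or DavidsonOptions()
    sector = _Sector(imds.no, imds.nv)
    dim = sector.dim
    if n_roots > dim:
        raise ValueError("more roots requested than sector dimension")

    def matvec(v):
        r1, r2 = sector.unpack(v)
        s = sigma_vector(imds, IonizationVector(r1, r2), opts.spin_summed)
        return sector.pack(s.r1, s.r2)

    # diagonal preconditioner from the Koopmans-type part of Hbar
    diag1 = np.array([-imds.Foo[i, i] for i in sector.h1])
    diag2 = np.array(
        [
            imds.Fvv[a, a] - imds.Foo[i, i] - imds.Foo[j, j]
            for (i, j, a) in sector.h2
        ]
    )
    diag = np.concatenate([diag1, diag2])

    def _append(V, x):
        # modified Gram-Schmidt, twice for numerical safety
        for _ in range(2):
            if V.shape[1]:
                x = x - V @ (V.T @ x)
        n = np.linalg.norm(x)
        if n < 1e-10:
            return V, False
        return np.column_stack([V, x / n]), True

    n_seed = min(max(n_roots, 2), dim)
    order = np.argsort(diag)
    V = np.zeros((dim, n_seed))
    for k in range(n_seed):
        V[order[k], k] = 1.0
    S = np.empty((dim, 0))
    max_subspace = min(dim, max(opts.max_subspace_factor * n_roots, 2 * n_seed))
    converged = np.zeros(n_roots, dtype=bool)
    theta = np.zeros(n_roots)
    ritz = np.zeros((dim, n_roots))
    for _ in range(opts.max_iter):
        while S.shape[1] < V.shape[1]:
            S = np.column_stack([S, matvec(V[:, S.shape[1]])])
        Hs = V.T @ S
        w, Y = np.linalg.eig(Hs)
        if np.max(np.abs(w.imag)) > 1e-7:
            logger.warning("complex eigenvalue pair in Davidson subspace")
        sel = np.argsort(w.real)[:n_roots]
        theta = w.real[sel]
        Y = Y[:, sel].real
        ritz = V @ Y
        resid = S @ Y - ritz * theta[None, :]
        norms = np.linalg.norm(resid, axis=0)
        converged = norms < opts.tol
        if converged.all() or V.shape[1] >= dim:
            break
        if V.shape[1] >= max_subspace:
            # collapse onto the current Ritz vectors and restart
            V = np.empty((dim, 0))
            for k in range(n_roots):
                V, _ok = _append(V, ritz[:, k].copy())
            S = np.empty((dim, 0))
            continue
        grown = False
        for k in range(n_roots):
            if converged[k]:
                continue
            denom = diag - theta[k]
            denom = np.where(np.abs(denom) < 1e-8, 1e-8, denom)
            V, ok = _append(V, resid[:, k] / denom)
            if not ok:  # preconditioned direction already in the subspace
                V, ok = _append(V, resid[:, k].copy())
            grown = grown or ok
        if not grown:
            break
    roots = []
    for k in range(n_roots):
        r1, r2 = sector.unpack(ritz[:, k])
        vec = IonizationVector(r1, r2)
        nrm = vec.norm()
        if nrm > 0:
            vec = IonizationVector(vec.r1 / nrm, vec.r2 / nrm)
        roots.append(IPRoot(float(theta[k]), vec, vec.weight_1h, bool(converged[k])))
    # ordering rule for (near-)degenerate roots
    roots.sort(
        key=lambda r: (
            round(r.omega / 1e-9),
            -r.weight_1h,
            int(np.argmax(np.abs(r.vector.r1))) if r.vector.r1.any() else 0,
        )
    )
    if not all(r.converged for r in roots):
        logger.warning(
            "Davidson: %d of %d roots not converged to %.1e",
            sum(not r.converged for r in roots),
            n_roots,
            opts.tol,
        )
    return roots


# ---------------------------------------------------------------------------
# End-to-end driver
# ---------------------------------------------------------------------------

def ip_spectrum(
    ham: MolecularHamiltonian,
    flavor: str | FlavorSpec = "fpCCSD",
    n_roots: int = 2,
    optimize: bool = True,
    spin_summed: bool = False,
    davidson_tol: float = 1e-7,
):
    """Full pipeline: (orbital-optimized) pCCD -> flavor ground state ->
    IP-EOM Davidson.  Returns a pandas DataFrame with omega in eV, 1h weight
    and dominant hole character, plus the per-stage results."""
    import pandas as pd

    from .hamiltonian import fold_frozen_core
    from .pccd import optimize_orbitals, solve_pccd

    if isinstance(flavor, str):
        flavor = FLAVORS[flavor]
    if ham.n_frozen > 0:
        ham = fold_frozen_core(ham)
    try:
        if optimize:
            oo = optimize_orbitals(ham)
            ham_use, pccd = oo.ham, oo.pccd
        else:
            ham_use = ham
            pccd = solve_pccd(ham)
    except Exception as err:  # pragma: no cover - defensive tagging
        raise RuntimeError(f"stage pCCD: {err}") from err
    try:
        ground = solve_ground = solve_ground_state_checked(ham_use, flavor, pccd)
    except Exception as err:
        raise RuntimeError(f"stage ground-state({flavor.name}): {err}") from err
    try:
        c = pccd.c.c if flavor.frozen else None
        imds = build_intermediates(ham_use, ground, c)
        roots = davidson_ionize(
            imds,
            n_roots,
            DavidsonOptions(tol=davidson_tol, spin_summed=spin_summed),
        )
    except Exception as err:
        raise RuntimeError(f"stage IP-EOM({flavor.name}): {err}") from err
    rows = []
    for k, root in enumerate(roots):
        holes = np.argsort(-np.abs(root.vector.r1))[:2]
        character = "+".join(f"{int(h) // 2}b" for h in holes if abs(root.vector.r1[h]) > 1e-3)
        rows.append(
            {
                "state": k,
                "omega_ev": root.omega_ev,
                "omega_hartree": root.omega,
                "weight_1h": root.weight_1h,
                "hole_character": character or "satellite",
                "converged": root.converged,
            }
        )
    table = pd.DataFrame(rows)
    return table, {"pccd": pccd, "ground": ground, "roots": roots, "ham": ham_use}


def solve_ground_state_checked(ham, flavor, pccd):
    from .ground_state import solve_ground_state

    ground = solve_ground_state(ham, flavor, pccd=pccd)
    if not ground.converged:
        raise RuntimeError(f"{flavor.name} amplitude equations did not converge")
    return ground
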