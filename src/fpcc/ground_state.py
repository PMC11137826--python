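"""Ground-state coupled-cluster solvers over a pCCD (or external) orbital basis.

Six flavors share one residual engine:

========  =======  ==========  ============
flavor    singles  linearized  pair channel
========  =======  ==========  ============
CCD       no       no          relaxed
CCSD      yes      no          relaxed
fpCCD     no       no          frozen to pCCD
fpCCSD    yes      no          frozen to pCCD
fpLCCD    no       yes         frozen to pCCD
fpLCCSD   yes      yes         frozen to pCCD
========  =======  ==========  ============

Frozen-pair (tailored) flavors keep the diagonal-pair channel of T2 fixed to
the pCCD amplitudes ``c`` and never update it.  Linearized (fpLCC) flavors
additionally drop every term of combined order >= 2 in the broken-pair
amplitudes while retaining the full pair exponential: this is realized
exactly by evaluating the (quartic) residual polynomial at integer scalings
of the broken-pair amplitudes and truncating after the linear term, so the
retained disconnected pair couplings are inherited from the full equations
rather than transcribed from term lists.

Amplitudes are spin-orbital tensors (interleaved spins); closed-shell spin
symmetry is carried by the integrals.  The dense determinant-basis route in
:mod:`fpcc.oracles` provides the independent check of every projection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .diis import DIIS
from .hamiltonian import MolecularHamiltonian, reference_energy
from .oracles import linear_order_weights
from .pccd import PCCDResult
from .spinorb import (
    occ_virt_spin_orbitals,
    pair_channel_mask,
    pair_channel_t2,
    spin_orbital_eri,
    spin_orbital_fock,
)

__all__ = [
    "FlavorSpec",
    "ClusterAmplitudes",
    "GroundStateResult",
    "FLAVORS",
    "cc_residual",
    "cc_energy",
    "solve_ground_state",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FlavorSpec:
    """One of the six supported coupled-cluster flavors."""

    name: str
    singles: bool
    linearized: bool
    pair_channel: str  # "frozen-to-pCCD" | "relaxed"

    def __post_init__(self):
        if self.linearized and self.pair_channel != "frozen-to-pCCD":
            raise ValueError("linearized flavors require the frozen pair channel")
        if self.pair_channel not in ("frozen-to-pCCD", "relaxed"):
            raise ValueError(f"unknown pair channel {self.pair_channel!r}")

    @property
    def frozen(self) -> bool:
        return self.pair_channel == "frozen-to-pCCD"


FLAVORS: dict[str, FlavorSpec] = {
    "CCD": FlavorSpec("CCD", False, False, "relaxed"),
    "CCSD": FlavorSpec("CCSD", True, False, "relaxed"),
    "fpCCD": FlavorSpec("fpCCD", False, False, "frozen-to-pCCD"),
    "fpCCSD": FlavorSpec("fpCCSD", True, False, "frozen-to-pCCD"),
    "fpLCCD": FlavorSpec("fpLCCD", False, True, "frozen-to-pCCD"),
    "fpLCCSD": FlavorSpec("fpLCCSD", True, True, "frozen-to-pCCD"),
}


@dataclass(frozen=True)
class ClusterAmplitudes:
    """Spin-orbital T1/T2; ``pair_mask`` marks the diagonal-pair channel."""

    t1: np.ndarray | None
    t2: np.ndarray
    pair_mask: np.ndarray
    flavor: FlavorSpec

    def __post_init__(self):
        t2 = self.t2
        if not np.allclose(t2, -t2.transpose(1, 0, 2, 3), atol=1e-10) or not np.allclose(
            t2, -t2.transpose(0, 1, 3, 2), atol=1e-10
        ):
            raise ValueError("t2 must be antisymmetric in (ij) and (ab)")


@dataclass(frozen=True)
class GroundStateResult:
    energy: float
    amplitudes: ClusterAmplitudes
    flavor: FlavorSpec
    residual_norm: float
    converged: bool
    n_iter: int = 0


class _Workspace:
    """Cached spin-orbital Fock/integral blocks for one Hamiltonian."""

    def __init__(self, ham: MolecularHamiltonian):
        occ, virt = occ_virt_spin_orbitals(ham)
        self.no, self.nv = len(occ), len(virt)
        f = spin_orbital_fock(ham)
        g = spin_orbital_eri(ham)
        o, v = slice(0, self.no), slice(self.no, self.no + self.nv)
        self.foo, self.fov, self.fvv = f[o, o], f[o, v], f[v, v]
        self.oooo = g[o, o, o, o]
        self.ooov = g[o, o, o, v]
        self.oovo = g[o, o, v, o]
        self.oovv = g[o, o, v, v]
        self.ovoo = g[o, v, o, o]
        self.ovov = g[o, v, o, v]
        self.ovvo = g[o, v, v, o]
        self.ovvv = g[o, v, v, v]
        self.vovv = g[v, o, v, v]
        self.vvvo = g[v, v, v, o]
        self.vvvv = g[v, v, v, v]
        self.e_ref = reference_energy(ham)
        self.mask = pair_channel_mask(self.no, self.nv)
        eo, ev = np.diag(self.foo), np.diag(self.fvv)
        self.d1 = eo[:, None] - ev[None, :]
        self.d2 = (
            eo[:, None, None, None]
            + eo[None, :, None, None]
            - ev[None, None, :, None]
            - ev[None, None, None, :]
        )


def _residual_full(ws: _Workspace, t1: np.ndarray, t2: np.ndarray):
    """Singles/doubles projections of ``exp(-T) H exp(T)`` on the reference
    manifold (full CCSD form, spin-orbital antisymmetrized)."""
    ein = np.einsum
    tau = t2 + ein("ia,jb->ijab", t1, t1) - ein("ib,ja->ijab", t1, t1)
    tau_t = t2 + 0.5 * (ein("ia,jb->ijab", t1, t1) - ein("ib,ja->ijab", t1, t1))

    Fae = (
        ws.fvv
        - 0.5 * ein("me,ma->ae", ws.fov, t1)
        + ein("mf,amef->ae", t1, ws.vovv)
        - 0.5 * ein("mnaf,mnef->ae", tau_t, ws.oovv)
    )
    Fmi = (
        ws.foo
        + 0.5 * ein("ie,me->mi", t1, ws.fov)
        + ein("ne,mnie->mi", t1, ws.ooov)
        + 0.5 * ein("inef,mnef->mi", tau_t, ws.oovv)
    )
    Fme = ws.fov + ein("nf,mnef->me", t1, ws.oovv)

    Wmnij = ws.oooo + 0.25 * ein("ijef,mnef->mnij", tau, ws.oovv)
    x = ein("je,mnie->mnij", t1, ws.ooov)
    Wmnij = Wmnij + x - x.transpose(0, 1, 3, 2)
    Wabef = ws.vvvv + 0.25 * ein("mnab,mnef->abef", tau, ws.oovv)
    x = ein("mb,amef->abef", t1, ws.vovv)
    Wabef = Wabef - x + x.transpose(1, 0, 2, 3)
    Wmbej = (
        ws.ovvo
        + ein("jf,mbef->mbej", t1, ws.ovvv)
        - ein("nb,mnej->mbej", t1, ws.oovo)
        - ein(
            "jnfb,mnef->mbej",
            0.5 * t2 + ein("jf,nb->jnfb", t1, t1),
            ws.oovv,
        )
    )

    r1 = (
        ws.fov
        + ein("ie,ae->ia", t1, Fae)
        - ein("ma,mi->ia", t1, Fmi)
        + ein("imae,me->ia", t2, Fme)
        - ein("nf,naif->ia", t1, ws.ovov)
        - 0.5 * ein("imef,maef->ia", t2, ws.ovvv)
        - 0.5 * ein("mnae,nmei->ia", t2, ws.oovo)
    )

    r2 = ws.oovv.copy()
    x = ein("ijae,be->ijab", t2, Fae - 0.5 * ein("mb,me->be", t1, Fme))
    r2 += x - x.transpose(0, 1, 3, 2)
    x = ein("imab,mj->ijab", t2, Fmi + 0.5 * ein("je,me->mj", t1, Fme))
    r2 -= x - x.transpose(1, 0, 2, 3)
    r2 += 0.5 * ein("mnab,mnij->ijab", tau, Wmnij)
    r2 += 0.5 * ein("ijef,abef->ijab", tau, Wabef)
    x = ein("imae,mbej->ijab", t2, Wmbej) - ein(
        "ie,ma,mbej->ijab", t1, t1, ws.ovvo
    )
    r2 += x - x.transpose(1, 0, 2, 3) - x.transpose(0, 1, 3, 2) + x.transpose(1, 0, 3, 2)
    x = ein("ie,abej->ijab", t1, ws.vvvo)
    r2 += x - x.transpose(1, 0, 2, 3)
    x = ein("ma,mbij->ijab", t1, ws.ovoo)
    r2 -= x - x.transpose(0, 1, 3, 2)
    return r1, r2


def _energy_full(ws: _Workspace, t1: np.ndarray, t2: np.ndarray) -> float:
    ein = np.einsum
    return float(
        ws.e_ref
        + ein("ia,ia->", ws.fov, t1)
        + 0.25 * ein("ijab,ijab->", ws.oovv, t2)
        + 0.5 * ein("ijab,ia,jb->", ws.oovv, t1, t1)
    )


def _zeros_t1(ws: _Workspace) -> np.ndarray:
    return np.zeros((ws.no, ws.nv))


def _flavor_eval(ws, flavor, t1, t2, pair_t2, func):
    """Evaluate ``func(t1, t2)`` with the flavor's term content.

    For linearized flavors the broken-pair amplitudes are scaled by integer
    nodes and the exact order-0 + order-1 part of the polynomial is taken.
    """
    if not flavor.linearized:
        return func(t1, t2)
    broken2 = t2 - pair_t2
    nodes, weights = linear_order_weights(4)
    out = None
    for xn, w in zip(nodes, weights):
        val = func(xn * t1, pair_t2 + xn * broken2)
        contr = tuple(w * v for v in val) if isinstance(val, tuple) else w * val
        if out is None:
            out = contr
        elif isinstance(out, tuple):
            out = tuple(a + b for a, b in zip(out, contr))
        else:
            out = out + contr
    return out


def cc_residual(
    ham_or_ws,
    amps: ClusterAmplitudes,
    c: np.ndarray | None = None,
) -> tuple[np.ndarray | None, np.ndarray]:
    """Flavor-resolved residuals ``(R1, R2)``.

    ``R1`` is ``None`` for doubles-only flavors.  For frozen-pair flavors the
    diagonal-pair rows of ``R2`` are identically zero (the channel is not an
    equation), and ``c`` (spatial pair amplitudes) must be supplied.
    """
    ws = ham_or_ws if isinstance(ham_or_ws, _Workspace) else _Workspace(ham_or_ws)
    flavor = amps.flavor
    t1 = amps.t1 if amps.t1 is not None else _zeros_t1(ws)
    if flavor.frozen:
        if c is None:
            raise ValueError("frozen-pair flavors require the pCCD amplitudes c")
        pair_t2 = pair_channel_t2(c)
        if not np.array_equal(amps.t2[ws.mask], pair_t2[ws.mask]):
            raise ValueError("t2 pair channel deviates from the frozen pCCD amplitudes")
    else:
        pair_t2 = None
    r1, r2 = _flavor_eval(
        ws, flavor, t1, amps.t2, pair_t2, lambda a, b: _residual_full(ws, a, b)
    )
    if flavor.frozen:
        r2 = r2.copy()
        r2[ws.mask] = 0.0
    if not flavor.singles:
        r1 = None
    return r1, r2


def cc_energy(ham_or_ws, amps: ClusterAmplitudes, c: np.ndarray | None = None) -> float:
    """Flavor-consistent energy functional (linearized flavors keep only the
    retained orders of the broken-pair amplitudes)."""
    ws = ham_or_ws if isinstance(ham_or_ws, _Workspace) else _Workspace(ham_or_ws)
    t1 = amps.t1 if amps.t1 is not None else _zeros_t1(ws)
    pair_t2 = pair_channel_t2(c) if (amps.flavor.frozen and c is not None) else None
    return _flavor_eval(
        ws, amps.flavor, t1, amps.t2, pair_t2, lambda a, b: _energy_full(ws, a, b)
    )


def solve_ground_state(
    ham: MolecularHamiltonian,
    flavor: FlavorSpec | str,
    pccd: PCCDResult | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> GroundStateResult:
    """Converge the flavor's amplitude equations by quasi-Newton + DIIS.

    Frozen flavors require a converged pCCD result; the pair channel of T2 is
    set to the pCCD amplitudes once and never updated.  Non-convergence is
    reported through the ``converged`` flag and a warning with diagnostics,
    never silently.
    """
    if isinstance(flavor, str):
        flavor = FLAVORS[flavor]
    ws = _Workspace(ham)
    c = None
    if flavor.frozen:
        if pccd is None or not pccd.converged:
            raise ValueError("frozen-pair flavors need a converged pCCD reference")
        c = pccd.c.c
        pair_t2 = pair_channel_t2(c)
    else:
        pair_t2 = np.zeros((ws.no, ws.no, ws.nv, ws.nv))

    d2 = np.where(np.abs(ws.d2) < 1e-8, -1.0, ws.d2)
    d1 = np.where(np.abs(ws.d1) < 1e-8, -1.0, ws.d1)
    t2 = ws.oovv / d2  # first-order guess with pCCD-orbital denominators
    if flavor.frozen:
        t2[ws.mask] = pair_t2[ws.mask]
    t1 = _zeros_t1(ws)

    diis = DIIS(6)
    converged = False
    res_norm = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        amps = ClusterAmplitudes(t1 if flavor.singles else None, t2, ws.mask, flavor)
        r1, r2 = cc_residual(ws, amps, c)
        res_norm = float(np.max(np.abs(r2)))
        if r1 is not None:
            res_norm = max(res_norm, float(np.max(np.abs(r1))))
        if res_norm < tol:
            converged = True
            break
        dt2 = r2 / d2
        if flavor.frozen:
            dt2[ws.mask] = 0.0
        new_t2 = t2 + dt2
        new_t1 = t1 + (r1 / d1 if r1 is not None else 0.0)
        flat = np.concatenate([new_t1.ravel(), new_t2.ravel()])
        step = np.concatenate([(new_t1 - t1).ravel(), (new_t2 - t2).ravel()])
        ext = diis.update(flat, step)
        t1 = ext[: t1.size].reshape(t1.shape)
        t2 = ext[t1.size :].reshape(t2.shape)
        # re-impose exact antisymmetry and the frozen pair channel
        t2 = 0.25 * (
            t2
            - t2.transpose(1, 0, 2, 3)
            - t2.transpose(0, 1, 3, 2)
            + t2.transpose(1, 0, 3, 2)
        )
        if flavor.frozen:
            t2[ws.mask] = pair_t2[ws.mask]
        if not flavor.singles:
            t1 = _zeros_t1(ws)
    if not converged:
        logger.warning(
            "%s did not converge in %d iterations (max residual %.2e, DIIS depth %d)",
            flavor.name,
            max_iter,
            res_norm,
            len(diis.history),
        )
    amps = ClusterAmplitudes(t1 if flavor.singles else None, t2, ws.mask, flavor)
    energy = cc_energy(ws, amps, c)
    return GroundStateResult(energy, amps, flavor, res_norm, converged, n_iter)
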