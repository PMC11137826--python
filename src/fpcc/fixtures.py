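"""Seeded fixture Hamiltonians standing in for external molecular data.

The benchmark geometries behind the published applications live in external
supporting information; desk-scale verification instead runs on synthetic
closed-shell Hamiltonians with full 8-fold integral symmetry: reduced pairing
models, random two-electron systems, random symmetric Hamiltonians with a
tunable interaction scale, and noninteracting block-diagonal composites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hamiltonian import MolecularHamiltonian, make_pairing_hamiltonian, read_fcidump

__all__ = ["FixtureSpec", "generate_fixture", "compose_noninteracting"]

FAMILIES = (
    "pairing-model",
    "two-electron",
    "random-symmetric",
    "noninteracting-composite",
    "fcidump-file",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative recipe for a fixture Hamiltonian; same seed, same fixture."""

    family: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown fixture family {self.family!r}")


def _symmetrize_eri(raw: np.ndarray) -> np.ndarray:
    perms = [
        (0, 1, 2, 3), (1, 0, 2, 3), (0, 1, 3, 2), (1, 0, 3, 2),
        (2, 3, 0, 1), (3, 2, 0, 1), (2, 3, 1, 0), (3, 2, 1, 0),
    ]
    return sum(raw.transpose(p) for p in perms) / 8.0


def _random_symmetric(rng: np.random.Generator, K: int, n_pairs: int, scale: float) -> MolecularHamiltonian:
    if n_pairs > K:
        raise ValueError("n_pairs cannot exceed the number of orbitals")
    # well-gapped diagonal one-electron part keeps the reference dominant
    occ_levels = np.sort(rng.uniform(-2.5, -1.0, n_pairs))
    virt_levels = np.sort(rng.uniform(0.5, 2.0, K - n_pairs))
    h = np.diag(np.concatenate([occ_levels, virt_levels]))
    noise = rng.normal(0.0, 0.05 * scale, (K, K))
    h = h + 0.5 * (noise + noise.T)
    eri = scale * _symmetrize_eri(rng.normal(0.0, 0.3, (K, K, K, K)))
    core = float(rng.uniform(0.0, 1.0))
    return MolecularHamiltonian(core, h, eri, n_pairs=n_pairs, basis_tag="model")


def compose_noninteracting(*hams: MolecularHamiltonian) -> MolecularHamiltonian:
    """Block-diagonal composite of noninteracting fragments.

    Orbitals are reordered so that all fragment occupied orbitals come first:
    the composite's leading-pair reference is the product of the fragment
    references, and there are no inter-fragment integrals at all.
    """
    K = sum(m.n_orb for m in hams)
    h = np.zeros((K, K))
    eri = np.zeros((K, K, K, K))
    order: list[tuple[int, int]] = []  # (fragment, local orbital) per slot
    for frag, m in enumerate(hams):
        order.extend((frag, p) for p in range(m.n_pairs))
    for frag, m in enumerate(hams):
        order.extend((frag, p) for p in range(m.n_pairs, m.n_orb))
    for P, (fp, p) in enumerate(order):
        for Q, (fq, q) in enumerate(order):
            if fp == fq:
                h[P, Q] = hams[fp].h[p, q]
            for R, (fr, r) in enumerate(order):
                for S, (fs, s) in enumerate(order):
                    if fp == fq == fr == fs:
                        eri[P, Q, R, S] = hams[fp].eri[p, q, r, s]
    return MolecularHamiltonian(
        sum(m.core_energy for m in hams),
        h,
        eri,
        n_pairs=sum(m.n_pairs for m in hams),
        basis_tag="model",
    )


def generate_fixture(spec: FixtureSpec) -> MolecularHamiltonian:
    """Materialize a fixture Hamiltonian; deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    par = dict(spec.parameters)
    if spec.family == "pairing-model":
        levels = par.get("levels")
        if levels is None:
            levels = np.arange(1, par.get("n_levels", 4) + 1, dtype=float)
        return make_pairing_hamiltonian(
            levels, g=par.get("g", 0.5), n_pairs=par.get("n_pairs")
        )
    if spec.family == "two-electron":
        return _random_symmetric(
            rng, K=par.get("K", 3), n_pairs=1, scale=par.get("scale", 0.3)
        )
    if spec.family == "random-symmetric":
        return _random_symmetric(
            rng,
            K=par.get("K", 4),
            n_pairs=par.get("n_pairs", 2),
            scale=par.get("scale", 0.2),
        )
    if spec.family == "noninteracting-composite":
        sub = FixtureSpec(
            par.get("sub_family", "random-symmetric"),
            par.get("sub_parameters", {}),
            seed=spec.seed,
        )
        monomer = generate_fixture(sub)
        return compose_noninteracting(*[monomer] * par.get("copies", 2))
    if spec.family == "fcidump-file":
        return read_fcidump(par["path"])
    raise ValueError(spec.family)
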