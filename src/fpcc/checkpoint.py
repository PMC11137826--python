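"""JSON checkpoints carrying pipeline state between stages.

Structured, human-readable containers: rotated integrals, pair amplitudes,
adjoint, natural occupations after the pCCD stage; flavor, energy and cluster
amplitudes after a ground-state stage.  Arrays are stored as nested lists
(the tool targets small active spaces where readability beats compactness).
"""

from __future__ import annotations

import json
from typing import Any

import numpy as np

from .hamiltonian import MolecularHamiltonian

__all__ = ["save_checkpoint", "load_checkpoint", "ham_to_dict", "ham_from_dict"]


def _encode(obj: Any):
    if isinstance(obj, np.ndarray):
        return {"__ndarray__": obj.tolist(), "shape": list(obj.shape)}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _decode(d):
    if isinstance(d, dict) and "__ndarray__" in d:
        return np.asarray(d["__ndarray__"], dtype=float).reshape(d["shape"])
    return d


def ham_to_dict(ham: MolecularHamiltonian) -> dict:
    return {
        "core_energy": ham.core_energy,
        "h": ham.h,
        "eri": ham.eri,
        "n_pairs": ham.n_pairs,
        "n_frozen": ham.n_frozen,
        "basis_tag": ham.basis_tag,
    }


def ham_from_dict(d: dict) -> MolecularHamiltonian:
    return MolecularHamiltonian(
        float(d["core_energy"]),
        np.asarray(d["h"]),
        np.asarray(d["eri"]),
        n_pairs=int(d["n_pairs"]),
        n_frozen=int(d.get("n_frozen", 0)),
        basis_tag=str(d.get("basis_tag", "model")),
    )


def save_checkpoint(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, default=_encode, indent=1)


def load_checkpoint(path) -> dict:
    def hook(d):
        return {k: _decode(v) for k, v in d.items()} if "__ndarray__" not in d else _decode(d)

    with open(path) as fh:
        return json.load(fh, object_hook=hook)
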