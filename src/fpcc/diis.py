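"""DIIS (direct inversion of the iterative subspace) convergence acceleration."""

from __future__ import annotations

import numpy as np

__all__ = ["DIIS", "diis_step"]


def diis_step(history: list[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    """Least-squares extrapolation over ``(amplitudes, residual)`` snapshots.

    A single snapshot is returned unchanged.  A singular B-matrix drops the
    oldest snapshot and retries.
    """
    if not history:
        raise ValueError("need at least one snapshot")
    if len(history) == 1:
        return history[0][0].copy()
    m = len(history)
    B = np.empty((m + 1, m + 1))
    B[-1, :] = -1.0
    B[:, -1] = -1.0
    B[-1, -1] = 0.0
    for i in range(m):
        for j in range(m):
            B[i, j] = float(history[i][1] @ history[j][1])
    rhs = np.zeros(m + 1)
    rhs[-1] = -1.0
    try:
        coeff = np.linalg.solve(B, rhs)[:m]
    except np.linalg.LinAlgError:
        return diis_step(history[1:])
    if not np.all(np.isfinite(coeff)):
        return diis_step(history[1:])
    return sum(c * amps for c, (amps, _) in zip(coeff, history))


class DIIS:
    """Rolling-window DIIS accelerator over flattened amplitude vectors."""

    def __init__(self, max_vectors: int = 6):
        self.max_vectors = max_vectors
        self.history: list[tuple[np.ndarray, np.ndarray]] = []

    def update(self, amps: np.ndarray, resid: np.ndarray) -> np.ndarray:
        self.history.append((amps.copy(), resid.copy()))
        if len(self.history) > self.max_vectors:
            self.history.pop(0)
        return diis_step(self.history)

    def reset(self) -> None:
        self.history.clear()
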