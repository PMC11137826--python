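"""Benchmark error statistics and two-point complete-basis-set extrapolation.

Error measures over a set of computed vs reference ionization energies (eV):
ME (mean signed error), MAE (mean absolute error), RMSE, MPE (mean absolute
relative error in percent, relative to the reference) and SD (standard
deviation of the signed errors, n-1 denominator).

The CBS limit of a total energy is estimated from two cardinal numbers X
with the inverse-cubic model ``E_X = E_CBS + a * X**-3`` (the standard
two-point correlation-energy extrapolation); the closed form follows by
eliminating ``a`` between the two points.  Which model is used is recorded in
the output metadata of every extrapolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ipeom import HARTREE_TO_EV

__all__ = [
    "ErrorStats",
    "CBSPoint",
    "error_stats",
    "cbs_extrapolate",
    "cbs_ip",
    "summarize_distribution",
]

logger = logging.getLogger(__name__)

CBS_MODEL = "E_X = E_CBS + a * X**-3"


@dataclass(frozen=True)
class ErrorStats:
    me: float
    mae: float
    rmse: float
    mpe: float  # percent
    sd: float
    n: int
    n_mpe_excluded: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("need at least one sample")
        if not all(
            np.isfinite(v) for v in (self.me, self.mae, self.rmse, self.sd)
        ):
            raise ValueError("non-finite error statistic")

    def as_dict(self) -> dict:
        return {
            "ME": self.me,
            "MAE": self.mae,
            "RMSE": self.rmse,
            "MPE": self.mpe,
            "SD": self.sd,
            "n": self.n,
        }


@dataclass(frozen=True)
class CBSPoint:
    """Total energy at basis cardinal number X (2 = double zeta, ...)."""

    X: int
    E: float

    def __post_init__(self):
        if self.X not in (2, 3, 4, 5):
            raise ValueError("cardinal number must be in {2, 3, 4, 5}")


def error_stats(computed, reference) -> ErrorStats:
    """ME/MAE/RMSE/MPE/SD of ``computed - reference`` (both in eV).

    Entries with zero reference are excluded from MPE (with a logged count);
    MPE uses absolute relative errors, so it is positive even when ME < 0.
    """
    computed = np.asarray(computed, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if computed.shape != reference.shape or computed.ndim != 1:
        raise ValueError("computed and reference must be equal-length vectors")
    err = computed - reference
    nonzero = reference != 0.0
    excluded = int(np.sum(~nonzero))
    if excluded:
        logger.warning("MPE: %d entries with zero reference excluded", excluded)
    if nonzero.any():
        mpe = float(np.mean(np.abs(err[nonzero] / reference[nonzero])) * 100.0)
    else:
        mpe = float("nan")
    sd = float(np.std(err, ddof=1)) if err.size > 1 else 0.0
    return ErrorStats(
        me=float(np.mean(err)),
        mae=float(np.mean(np.abs(err))),
        rmse=float(np.sqrt(np.mean(err**2))),
        mpe=mpe,
        sd=sd,
        n=err.size,
        n_mpe_excluded=excluded,
    )


def cbs_extrapolate(lo: CBSPoint, hi: CBSPoint) -> tuple[float, float]:
    """Two-point CBS limit: returns ``(E_CBS, a)`` for the inverse-cubic model."""
    if lo.X >= hi.X:
        raise ValueError("need lo.X < hi.X")
    wl, wh = lo.X ** -3, hi.X ** -3
    a = (lo.E - hi.E) / (wl - wh)
    return hi.E - a * wh, a


def cbs_ip(
    neutral: dict[int, float], omega: dict[int, float], X_pair=(2, 3)
) -> dict:
    """Extrapolate an ionization potential to the CBS limit.

    ``neutral`` maps cardinal number to the neutral ground-state total energy
    (Hartree); ``omega`` maps cardinal number to the ionization energy
    (Hartree) at the same basis.  Both state energies are extrapolated
    separately and differenced; by linearity of the two-point formula this
    equals extrapolating omega directly.
    """
    lo, hi = X_pair
    for X in X_pair:
        if X not in neutral or X not in omega:
            raise KeyError(f"missing cardinal number {X}")
    e_n, a_n = cbs_extrapolate(CBSPoint(lo, neutral[lo]), CBSPoint(hi, neutral[hi]))
    e_i, a_i = cbs_extrapolate(
        CBSPoint(lo, neutral[lo] + omega[lo]), CBSPoint(hi, neutral[hi] + omega[hi])
    )
    return {
        "ip_hartree": e_i - e_n,
        "ip_ev": (e_i - e_n) * HARTREE_TO_EV,
        "E_cbs_neutral": e_n,
        "E_cbs_ionized": e_i,
        "a_neutral": a_n,
        "a_ionized": a_i,
        "model": CBS_MODEL,
    }


def summarize_distribution(errors) -> dict:
    """Quartiles, median, 1.5*IQR whiskers and outliers (box-plot convention;
    quartiles by linear interpolation)."""
    err = np.sort(np.asarray(errors, dtype=float))
    if err.size < 1:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(err, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = err[(err >= lo_fence) & (err <= hi_fence)]
    outliers = err[(err < lo_fence) | (err > hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "outliers": [float(x) for x in outliers],
        "mean": float(err.mean()),
        "skew_sign": float(np.sign(err.mean() - med)),
    }
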