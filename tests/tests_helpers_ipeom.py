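"""Shared helpers for IP-EOM tests: amplitude-basis matrices of the sigma
engine and of the dense determinant oracle."""

import numpy as np

from fpcc.ipeom import IonizationVector, _Sector, build_intermediates, sigma_vector
from fpcc.oracles import dense_ip_matrix, ionization_vector_to_dets
from fpcc.spinorb import pair_channel_t2


def sigma_matrix(imds, sector, spin_summed=False):
    n = sector.dim
    out = np.empty((n, n))
    for k in range(n):
        e = np.zeros(n)
        e[k] = 1.0
        r1, r2 = sector.unpack(e)
        s = sigma_vector(imds, IonizationVector(r1, r2), spin_summed)
        out[:, k] = sector.pack(s.r1, s.r2)
    return out


def dense_matrix_in_amplitude_basis(ham, imds, t1, t2, pair_t2=None):
    dets, M = dense_ip_matrix(ham, t1, t2, pair_t2=pair_t2)
    sector = _Sector(imds.no, imds.nv)
    A = np.zeros((len(dets), sector.dim))
    for k in range(sector.dim):
        e = np.zeros(sector.dim)
        e[k] = 1.0
        r1, r2 = sector.unpack(e)
        A[:, k] = ionization_vector_to_dets(ham, r1, r2, dets)
    return sector, A.T @ M @ A


def dense_vs_sigma_difference(ham, gs_full, gs_lin, c):
    """Compare the fpCC-vs-fpLCC effective-Hamiltonian difference of the fast
    route against the dense truncation oracle at identical amplitudes.

    Returns ``(max deviation between the two difference matrices,
    max magnitude of the difference itself)``.
    """
    imds_full = build_intermediates(ham, gs_full, c)
    imds_lin = build_intermediates(ham, gs_lin, c)
    amps = gs_full.amplitudes
    pair = pair_channel_t2(c)
    sector, M_full = dense_matrix_in_amplitude_basis(ham, imds_full, amps.t1, amps.t2)
    _, M_lin = dense_matrix_in_amplitude_basis(
        ham, imds_lin, amps.t1, amps.t2, pair_t2=pair
    )
    S_full = sigma_matrix(imds_full, sector)
    S_lin = sigma_matrix(imds_lin, sector)
    dev = np.abs((S_full - S_lin) - (M_full - M_lin)).max()
    magnitude = np.abs(S_full - S_lin).max()
    return dev, magnitude
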