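"""IP-EOM engine: intermediates, sigma equations, Davidson and the driver,
all against the dense 1h+2h1p block of the similarity-transformed
Hamiltonian."""

import numpy as np
import pytest

from fpcc.fixtures import FixtureSpec, compose_noninteracting, generate_fixture
from fpcc.ground_state import (
    FLAVORS,
    ClusterAmplitudes,
    GroundStateResult,
    solve_ground_state,
)
from fpcc.ground_state import _Workspace
from fpcc.hamiltonian import MolecularHamiltonian
from fpcc.ipeom import (
    DavidsonOptions,
    IonizationVector,
    build_intermediates,
    davidson_ionize,
    ip_spectrum,
    sigma_vector,
)
from fpcc.ipeom import _Sector
from fpcc.oracles import (
    dense_ip_matrix,
    fci_ground_energy,
    ionization_vector_to_dets,
)
from fpcc.pccd import solve_pccd
from fpcc.spinorb import pair_channel_mask, pair_channel_t2


def _fake_ground(ham, t1, t2, flavor="CCSD"):
    ws = _Workspace(ham)
    amps = ClusterAmplitudes(t1, t2, ws.mask, FLAVORS[flavor])
    return GroundStateResult(0.0, amps, FLAVORS[flavor], 0.0, True)


def _sigma_matrix(imds, sector, spin_summed=False):
    n = sector.dim
    out = np.empty((n, n))
    for k in range(n):
        e = np.zeros(n)
        e[k] = 1.0
        r1, r2 = sector.unpack(e)
        s = sigma_vector(imds, IonizationVector(r1, r2), spin_summed)
        out[:, k] = sector.pack(s.r1, s.r2)
    return out


def _dense_matrix_in_amplitude_basis(ham, imds, t1, t2, pair_t2=None):
    dets, M = dense_ip_matrix(ham, t1, t2, pair_t2=pair_t2)
    sector = _Sector(imds.no, imds.nv)
    A = np.zeros((len(dets), sector.dim))
    for k in range(sector.dim):
        e = np.zeros(sector.dim)
        e[k] = 1.0
        r1, r2 = sector.unpack(e)
        A[:, k] = ionization_vector_to_dets(ham, r1, r2, dets)
    return sector, A.T @ M @ A


class TestIntermediates:
    def test_zero_amplitudes_give_bare_blocks(self, ham_two_pair):
        ws = _Workspace(ham_two_pair)
        zero2 = np.zeros((ws.no,) * 2 + (ws.nv,) * 2)
        imds = build_intermediates(
            ham_two_pair, _fake_ground(ham_two_pair, np.zeros((ws.no, ws.nv)), zero2)
        )
        assert np.abs(imds.Foo - ws.foo).max() < 1e-12
        assert np.abs(imds.Fvv - ws.fvv).max() < 1e-12
        assert np.abs(imds.Woooo - ws.oooo).max() < 1e-12
        assert np.abs(imds.Wovvo - ws.ovvo).max() < 1e-12
        assert np.abs(imds.Wovoo - ws.ovoo).max() < 1e-12

    def test_requires_converged_ground_state(self, ham_two_pair):
        ws = _Workspace(ham_two_pair)
        bad = GroundStateResult(
            0.0,
            ClusterAmplitudes(None, np.zeros((ws.no,) * 2 + (ws.nv,) * 2), ws.mask, FLAVORS["CCD"]),
            FLAVORS["CCD"],
            1.0,
            False,
        )
        with pytest.raises(ValueError):
            build_intermediates(ham_two_pair, bad)

    def test_dense_equivalence_at_random_amplitudes(
        self, ham_two_pair, random_spin_amplitudes
    ):
        t1, t2 = random_spin_amplitudes
        imds = build_intermediates(ham_two_pair, _fake_ground(ham_two_pair, t1, t2))
        sector, Mamp = _dense_matrix_in_amplitude_basis(ham_two_pair, imds, t1, t2)
        assert np.abs(_sigma_matrix(imds, sector) - Mamp).max() < 1e-12

    def test_linearized_truncation_difference_matches_dense(self, ham_two_pair):
        # at identical amplitudes, the fpCCSD-vs-fpLCCSD effective-Hamiltonian
        # difference contains exactly the dropped broken-pair nonlinearities:
        # block-wise the fast-route difference must equal the dense difference
        pccd = solve_pccd(ham_two_pair)
        gs = solve_ground_state(ham_two_pair, "fpCCSD", pccd=pccd)
        amps = gs.amplitudes
        lin = ClusterAmplitudes(amps.t1, amps.t2, amps.pair_mask, FLAVORS["fpLCCSD"])
        gs_lin = GroundStateResult(gs.energy, lin, FLAVORS["fpLCCSD"], 0.0, True)
        imds_full = build_intermediates(ham_two_pair, gs, pccd.c.c)
        imds_lin = build_intermediates(ham_two_pair, gs_lin, pccd.c.c)
        pair = pair_channel_t2(pccd.c.c)
        sector, M_full = _dense_matrix_in_amplitude_basis(
            ham_two_pair, imds_full, amps.t1, amps.t2
        )
        _, M_lin = _dense_matrix_in_amplitude_basis(
            ham_two_pair, imds_lin, amps.t1, amps.t2, pair_t2=pair
        )
        S_full = _sigma_matrix(imds_full, sector)
        S_lin = _sigma_matrix(imds_lin, sector)
        assert np.abs((S_full - S_lin) - (M_full - M_lin)).max() < 1e-10
        # the deletions do change the operator (nontrivial difference)
        assert np.abs(S_full - S_lin).max() > 1e-6


class TestSigma:
    def test_zero_vector_maps_to_zero(self, ham_two_pair, random_spin_amplitudes):
        t1, t2 = random_spin_amplitudes
        imds = build_intermediates(ham_two_pair, _fake_ground(ham_two_pair, t1, t2))
        s = sigma_vector(
            imds,
            IonizationVector(np.zeros(imds.no), np.zeros((imds.no, imds.no, imds.nv))),
        )
        assert s.r1.any() == False and s.r2.any() == False  # noqa: E712

    def test_linearity(self, ham_two_pair, random_spin_amplitudes):
        t1, t2 = random_spin_amplitudes
        imds = build_intermediates(ham_two_pair, _fake_ground(ham_two_pair, t1, t2))
        sector = _Sector(imds.no, imds.nv)
        rng = np.random.default_rng(1)
        v, w = rng.normal(0, 1, (2, sector.dim))
        a, b = 0.7, -1.3

        def sig(x):
            r1, r2 = sector.unpack(x)
            s = sigma_vector(imds, IonizationVector(r1, r2))
            return sector.pack(s.r1, s.r2)

        assert np.abs(sig(a * v + b * w) - a * sig(v) - b * sig(w)).max() < 1e-12

    def test_spin_summed_equals_spin_dependent(
        self, ham_two_pair, random_spin_amplitudes
    ):
        t1, t2 = random_spin_amplitudes
        imds = build_intermediates(ham_two_pair, _fake_ground(ham_two_pair, t1, t2))
        sector = _Sector(imds.no, imds.nv)
        S1 = _sigma_matrix(imds, sector, spin_summed=False)
        S2 = _sigma_matrix(imds, sector, spin_summed=True)
        assert np.abs(S1 - S2).max() < 1e-12


class TestDavidson:
    def test_koopmans_limit(self, ham_diagonal):
        pccd = solve_pccd(ham_diagonal)
        for name, flavor in FLAVORS.items():
            gs = solve_ground_state(ham_diagonal, name, pccd=pccd)
            imds = build_intermediates(
                ham_diagonal, gs, pccd.c.c if flavor.frozen else None
            )
            roots = davidson_ionize(imds, 2, DavidsonOptions(tol=1e-11))
            assert np.allclose(
                [r.omega for r in roots], [0.8, 1.2], atol=1e-12
            ), name

    def test_two_electron_ip_equals_delta_fci(self, ham_one_pair):
        gs = solve_ground_state(ham_one_pair, "CCSD")
        imds = build_intermediates(ham_one_pair, gs)
        root = davidson_ionize(imds, 1, DavidsonOptions(tol=1e-9))[0]
        dfci = fci_ground_energy(ham_one_pair, n_elec=1, sz2=1) - fci_ground_energy(
            ham_one_pair
        )
        assert root.omega == pytest.approx(dfci, abs=1e-8)

    @pytest.mark.parametrize("name", list(FLAVORS))
    def test_all_roots_match_dense_diagonalization(self, ham_two_pair, name):
        flavor = FLAVORS[name]
        pccd = solve_pccd(ham_two_pair)
        gs = solve_ground_state(ham_two_pair, name, pccd=pccd)
        imds = build_intermediates(ham_two_pair, gs, pccd.c.c if flavor.frozen else None)
        t1 = gs.amplitudes.t1
        t1 = np.zeros((imds.no, imds.nv)) if t1 is None else t1
        pair = pair_channel_t2(pccd.c.c) if flavor.linearized else None
        _, M = dense_ip_matrix(ham_two_pair, t1, gs.amplitudes.t2, pair_t2=pair)
        dense = np.sort(np.linalg.eigvals(M).real)
        roots = davidson_ionize(imds, 3, DavidsonOptions(tol=1e-9))
        assert np.abs(np.array([r.omega for r in roots]) - dense[:3]).max() < 1e-8
        assert all(r.converged for r in roots)

    def test_left_right_eigenvalues_agree(self, ham_two_pair):
        gs = solve_ground_state(ham_two_pair, "CCSD")
        t1, t2 = gs.amplitudes.t1, gs.amplitudes.t2
        _, M = dense_ip_matrix(ham_two_pair, t1, t2)
        wr = np.sort(np.linalg.eigvals(M).real)
        wl = np.sort(np.linalg.eigvals(M.T).real)
        assert np.abs(wr - wl).max() < 1e-9

    def test_too_many_roots_rejected(self, ham_one_pair):
        gs = solve_ground_state(ham_one_pair, "CCSD")
        imds = build_intermediates(ham_one_pair, gs)
        with pytest.raises(ValueError):
            davidson_ionize(imds, 10_000)


class TestSpectrumDriver:
    def test_zero_interaction_spectrum_is_koopmans_in_ev(self, ham_diagonal):
        from fpcc.ipeom import HARTREE_TO_EV

        table, _ = ip_spectrum(ham_diagonal, "CCSD", n_roots=2, optimize=False)
        assert np.allclose(
            table["omega_ev"].to_numpy(), np.array([0.8, 1.2]) * HARTREE_TO_EV, atol=1e-10
        )

    def test_noninteracting_dimer_spectrum_matches_monomer(self):
        mono = generate_fixture(FixtureSpec("two-electron", {"K": 2, "scale": 0.3}, seed=7))
        dimer = compose_noninteracting(mono, mono)
        t_m, _ = ip_spectrum(mono, "CCSD", n_roots=1, davidson_tol=1e-9)
        t_d, _ = ip_spectrum(dimer, "CCSD", n_roots=2, davidson_tol=1e-9)
        omega_m = t_m["omega_hartree"].to_numpy()
        omega_d = t_d["omega_hartree"].to_numpy()
        # doubled degeneracy: both dimer roots equal the monomer root
        assert np.abs(omega_d - omega_m[0]).max() < 1e-7

    def test_spin_summed_spectrum_identical(self, ham_two_pair):
        t_a, _ = ip_spectrum(
            ham_two_pair, "fpCCSD", n_roots=3, optimize=False, davidson_tol=1e-9
        )
        t_b, _ = ip_spectrum(
            ham_two_pair,
            "fpCCSD",
            n_roots=3,
            optimize=False,
            spin_summed=True,
            davidson_tol=1e-9,
        )
        assert np.abs(
            t_a["omega_hartree"].to_numpy() - t_b["omega_hartree"].to_numpy()
        ).max() < 1e-8

    def test_stage_errors_are_tagged(self, ham_two_pair):
        with pytest.raises(Exception, match="stage"):
            ip_spectrum(ham_two_pair, "CCSD", n_roots=10_000, optimize=False)
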