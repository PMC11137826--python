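"""pCCD amplitudes, adjoint, response densities and orbital optimization,
checked against dense seniority-zero CI and the determinant-basis
similarity-transformation oracle."""

import numpy as np
import pytest

from fpcc.fixtures import FixtureSpec, compose_noninteracting, generate_fixture
from fpcc.hamiltonian import (
    MolecularHamiltonian,
    RotationGenerator,
    make_pairing_hamiltonian,
    reference_energy,
    transform_orbitals,
)
from fpcc.oracles import cc_residual_dense, doci_ground_energy, fci_ground_energy
from fpcc.pccd import (
    OrbitalOptions,
    PairAdjoint,
    PairAmplitudes,
    natural_occupations,
    optimize_orbitals,
    orbital_gradient,
    pccd_energy,
    pccd_residual,
    select_reference,
    solve_pccd,
    solve_pccd_lambda,
)
from fpcc.spinorb import pair_channel_t2


def _zero_eri_ham():
    h = np.diag([-1.0, -0.6, 0.5, 1.0])
    return MolecularHamiltonian(0.0, h, np.zeros((4, 4, 4, 4)), 2)


class TestResidual:
    def test_noninteracting_zero_residual(self):
        ham = _zero_eri_ham()
        r = pccd_residual(ham, PairAmplitudes(np.zeros((2, 2))))
        assert np.abs(r).max() == 0.0

    def test_exact_one_pair_solution_has_zero_residual(self, ham_one_pair):
        # for one pair the exponential truncates, so pCCD == DOCI and the
        # DOCI coefficient ratios solve the amplitude equations exactly
        _, psi, _ = doci_ground_energy(ham_one_pair)
        c = (psi[1:] / psi[0]).reshape(1, -1)
        r = pccd_residual(ham_one_pair, PairAmplitudes(c))
        assert np.abs(r).max() < 1e-10

    def test_matches_dense_operator_oracle(self, ham_two_pair):
        rng = np.random.default_rng(5)
        c = rng.normal(0, 0.05, (2, 2))
        _, _, R2 = cc_residual_dense(ham_two_pair, None, pair_channel_t2(c))
        dense = np.array(
            [[R2[2 * i, 2 * i + 1, 2 * a, 2 * a + 1] for a in range(2)] for i in range(2)]
        )
        fast = pccd_residual(ham_two_pair, PairAmplitudes(c))
        assert np.abs(fast - dense).max() < 1e-12

    def test_energy_matches_dense_projection(self, ham_two_pair):
        c = np.full((2, 2), 0.03)
        e_dense, _, _ = cc_residual_dense(ham_two_pair, None, pair_channel_t2(c))
        assert pccd_energy(ham_two_pair, PairAmplitudes(c)) == pytest.approx(
            e_dense, abs=1e-12
        )


class TestSolve:
    def test_zero_eri_reference_energy(self):
        ham = _zero_eri_ham()
        res = solve_pccd(ham)
        assert res.converged
        assert res.energy == pytest.approx(reference_energy(ham), abs=1e-12)
        assert np.abs(res.c.c).max() == 0.0

    def test_one_pair_equals_doci(self, ham_one_pair):
        res = solve_pccd(ham_one_pair)
        e_doci, _, occs = doci_ground_energy(ham_one_pair)
        assert res.converged
        assert res.energy == pytest.approx(e_doci, abs=1e-9)
        assert np.abs(res.natural_occupations - occs).max() < 1e-8

    def test_weak_pairing_close_to_doci(self):
        ham = make_pairing_hamiltonian([1.0, 2.0, 3.0, 4.0], g=0.1, n_pairs=2)
        res = solve_pccd(ham)
        e_doci, _, _ = doci_ground_energy(ham)
        assert res.converged and res.n_iter < 50
        assert abs(res.energy - e_doci) < 1e-4

    def test_invalid_tolerance(self, ham_one_pair):
        with pytest.raises(ValueError):
            solve_pccd(ham_one_pair, tol=0.0)


class TestLambdaAndDensities:
    def test_zero_eri_lambda_zero(self):
        ham = _zero_eri_ham()
        lam = solve_pccd_lambda(ham, PairAmplitudes(np.zeros((2, 2))))
        assert np.abs(lam.lam).max() == 0.0

    def test_one_pair_rdm_equals_doci(self, ham_one_pair):
        res = solve_pccd(ham_one_pair)
        _, _, occs = doci_ground_energy(ham_one_pair)
        gamma = natural_occupations(ham_one_pair, res.c, res.lam)
        assert np.abs(gamma - occs).max() < 1e-8

    def test_lagrangian_stationarity(self, ham_two_pair):
        # with converged (c, lambda) the Lagrangian is stationary in c, so a
        # finite perturbation changes E + lam.R only at second order
        res = solve_pccd(ham_two_pair)
        rng = np.random.default_rng(2)
        dc = rng.normal(0, 1.0, res.c.c.shape)
        eps = 1e-5

        def lagr(c):
            amps = PairAmplitudes(c)
            r = pccd_residual(ham_two_pair, amps)
            return pccd_energy(ham_two_pair, amps) + float(np.sum(res.lam.lam * r))

        slope = (lagr(res.c.c + eps * dc) - lagr(res.c.c - eps * dc)) / (2 * eps)
        assert abs(slope) < 1e-6

    def test_occupations_zero_eri(self):
        ham = _zero_eri_ham()
        res = solve_pccd(ham)
        assert np.allclose(res.natural_occupations, [2, 2, 0, 0], atol=1e-12)

    def test_occupation_gap_shrinks_with_pairing_strength(self):
        gaps = []
        for g in [0.1, 0.3, 0.5, 0.7]:
            ham = make_pairing_hamiltonian([1.0, 2.0, 3.0, 4.0], g=g, n_pairs=2)
            res = solve_pccd(ham, tol=1e-11, max_iter=500)
            assert res.converged
            occ = res.natural_occupations
            gaps.append(occ[:2].min() - occ[2:].max())
        assert all(a > b for a, b in zip(gaps, gaps[1:]))


class TestSelectReference:
    def test_clean_gap(self):
        ref = select_reference(np.array([2.0, 2.0, 0.0, 0.0]), 2)
        assert ref.occupied_pairs == (0, 1)

    def test_sorting_definition(self):
        ref = select_reference(np.array([1.9, 0.6, 1.2, 0.3]), 2)
        assert ref.occupied_pairs == (0, 2)

    def test_tie_goes_to_lowest_index(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="fpcc.pccd"):
            ref = select_reference(np.array([2.0, 1.0, 1.0, 0.0]), 2)
        assert ref.occupied_pairs == (0, 1)
        assert any("tie" in rec.message for rec in caplog.records)

    def test_idempotent(self):
        occ = np.array([1.7, 0.2, 1.1, 0.9])
        assert select_reference(occ, 2) == select_reference(occ, 2)


class TestOrbitalOptimization:
    def test_two_electron_oo_pccd_is_full_ci(self):
        ham = generate_fixture(FixtureSpec("two-electron", {"K": 2, "scale": 0.3}, seed=2))
        oo = optimize_orbitals(ham)
        assert oo.converged
        assert oo.pccd.energy == pytest.approx(fci_ground_energy(ham), abs=1e-8)

    def test_fci_invariant_under_accumulated_rotation(self):
        ham = generate_fixture(FixtureSpec("two-electron", {"K": 3, "scale": 0.3}, seed=4))
        oo = optimize_orbitals(ham)
        rotated = transform_orbitals(ham, oo.U_total)
        assert fci_ground_energy(rotated) == pytest.approx(
            fci_ground_energy(ham), abs=1e-9
        )

    def test_stationary_start_returns_zero_rotation(self):
        ham = generate_fixture(FixtureSpec("two-electron", {"K": 2, "scale": 0.3}, seed=2))
        oo = optimize_orbitals(ham)
        again = optimize_orbitals(oo.ham)
        assert again.n_iter == 0 and not again.kappas
        assert np.allclose(again.U_total, np.eye(2), atol=1e-12)

    def test_size_consistency_noninteracting_dimer(self):
        mono = generate_fixture(FixtureSpec("two-electron", {"K": 2, "scale": 0.3}, seed=7))
        dimer = compose_noninteracting(mono, mono)
        e_mono = optimize_orbitals(mono).pccd.energy
        oo = optimize_orbitals(dimer)
        assert oo.pccd.energy == pytest.approx(2 * e_mono, abs=1e-7)

    def test_gradient_matches_finite_difference(self, ham_two_pair):
        res = solve_pccd(ham_two_pair)
        g = orbital_gradient(ham_two_pair, res.c, res.lam)
        rng = np.random.default_rng(0)
        d = rng.normal(0, 1, (4, 4))
        d -= d.T
        eps = 1e-6
        up = solve_pccd(
            transform_orbitals(ham_two_pair, RotationGenerator(eps * d).matrix()),
            guess=res.c,
        ).energy
        dn = solve_pccd(
            transform_orbitals(ham_two_pair, RotationGenerator(-eps * d).matrix()),
            guess=res.c,
        ).energy
        assert (up - dn) / (2 * eps) == pytest.approx(float(np.sum(g * d)), abs=1e-5)

    def test_energy_non_increasing(self, ham_two_pair):
        oo = optimize_orbitals(ham_two_pair, OrbitalOptions(tol=1e-6))
        start = solve_pccd(ham_two_pair).energy
        assert oo.pccd.energy <= start + 1e-12
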