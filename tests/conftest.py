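import numpy as np
import pytest

from fpcc.fixtures import FixtureSpec, generate_fixture
from fpcc.hamiltonian import MolecularHamiltonian


@pytest.fixture(scope="session")
def ham_two_pair():
    """Moderately interacting 4-orbital, 2-pair random Hamiltonian."""
    return generate_fixture(
        FixtureSpec("random-symmetric", {"K": 4, "n_pairs": 2, "scale": 0.2}, seed=11)
    )


@pytest.fixture(scope="session")
def ham_one_pair():
    """One-pair (two-electron), 4-orbital Hamiltonian."""
    return generate_fixture(FixtureSpec("two-electron", {"K": 4, "scale": 0.3}, seed=1))


@pytest.fixture(scope="session")
def ham_diagonal():
    """Noninteracting Hamiltonian (zero eri, diagonal h): Koopmans regime."""
    h = np.diag([-1.2, -0.8, 0.4, 0.9])
    return MolecularHamiltonian(0.3, h, np.zeros((4, 4, 4, 4)), n_pairs=2)


@pytest.fixture(scope="session")
def random_spin_amplitudes(ham_two_pair):
    """Random spin-conserving (t1, t2) for residual/oracle comparisons."""
    from fpcc.spinorb import spin_conserving_masks

    no, nv = 2 * ham_two_pair.n_pairs, 2 * (ham_two_pair.n_orb - ham_two_pair.n_pairs)
    rng = np.random.default_rng(3)
    m1, m2 = spin_conserving_masks(no, nv)
    t1 = rng.normal(0, 0.1, (no, nv)) * m1
    t2 = rng.normal(0, 0.1, (no, no, nv, nv))
    t2 = 0.25 * (
        t2
        - t2.transpose(1, 0, 2, 3)
        - t2.transpose(0, 1, 3, 2)
        + t2.transpose(1, 0, 3, 2)
    )
    return t1, t2 * m2
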