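import pytest

from hdxcp.model import FitData, Hyperparameters, Peptide
from hdxcp.sampler import SamplerConfig, run_rjmcmc
from hdxcp.synthetic import (
    realistic_hyperparameters,
    simulate_peptide_map,
    simulate_truth,
    simulate_uptake_data,
)

TIMES = (15.0, 150.0, 1500.0, 15000.0)


def make_dataset(n_residues=40, n_peptides=35, sigma=0.005, seed=7,
                 truth_seed=None, replicates=3, min_redundancy=3,
                 times=TIMES, state="apo"):
    """Small synthetic experiment used across the suite."""
    truth = simulate_truth(n_residues,
                           realistic_hyperparameters(n_residues, times),
                           seed=truth_seed if truth_seed is not None
                           else seed)
    peptides = simulate_peptide_map(n_residues, n_peptides, seed=seed + 1,
                                    min_redundancy=min_redundancy)
    table = simulate_uptake_data(truth, peptides, times, replicates, sigma,
                                 seed=seed + 2, state=state,
                                 n_residues=n_residues)
    return truth, table


@pytest.fixture(scope="session")
def small_dataset():
    return make_dataset()


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """A short but converged fit on the small dataset (shared)."""
    truth, table = small_dataset
    fd = FitData(table)
    hyper = Hyperparameters.default_for(fd.n_residues)
    cfg = SamplerConfig(n_iter=2500, burn_in=1000, thin=5, seed=123)
    samples = run_rjmcmc(fd, hyper, cfg)
    return truth, table, fd, samples


@pytest.fixture
def toy_peptides():
    return [
        Peptide(id="a", sequence="AAAAAA", start=1, end=6),   # exch {3..5}
        Peptide(id="b", sequence="AAAA", start=4, end=7),     # exch {6}
    ]
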