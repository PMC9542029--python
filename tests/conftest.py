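import numpy as np
import pandas as pd
import pytest

from hybriddom import RunConfig, SimConfig, run_pipeline


@pytest.fixture(scope="session")
def null_run():
    """All-conserved simulation (5/5/5, 5000 genes) through the full
    pipeline: the calibration scenario with no true signal."""
    sim = SimConfig(
        n_genes=5000,
        mode_proportions={"conserved": 1.0},
        mean_log_mu=6.0,
        sd_log_mu=1.0,
        seed=2024,
    )
    return run_pipeline(RunConfig(sim=sim, seed=2024))


@pytest.fixture(scope="session")
def recovery_run():
    """Default mode mixture (20% transgressive truth) at effect_lfc=2:
    the signal-recovery scenario."""
    sim = SimConfig(
        n_genes=5000, effect_lfc=2.0, mean_log_mu=6.0, sd_log_mu=1.0, seed=515
    )
    return run_pipeline(RunConfig(sim=sim, seed=515))


@pytest.fixture()
def small_experiment():
    """A quick 400-gene experiment with strong effects for unit tests."""
    from hybriddom import simulate_experiment

    sim = SimConfig(
        n_genes=400, effect_lfc=2.0, mean_log_mu=6.0, sd_log_mu=0.8, seed=99
    )
    return simulate_experiment(sim)


def make_counts(rng, n_genes=30, n_samples=6, mu=200.0):
    """Random positive CountMatrix for round-trip style tests."""
    from hybriddom import CountMatrix

    counts = rng.poisson(mu, size=(n_genes, n_samples))
    genes = np.array([f"g{i}" for i in range(n_genes)], dtype=object)
    samples = np.array([f"s{j}" for j in range(n_samples)], dtype=object)
    return CountMatrix(genes, samples, counts)
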