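import pytest

from regstate.pipeline import run_state_pipeline
from regstate.simdata import SimulationConfig, simulate


@pytest.fixture(scope="session")
def noiseless_sim(tmp_path_factory):
    """One synthetic dataset with zero jitter, dropout and spurious peaks."""
    cfg = SimulationConfig(seed=11, jitter_sd=0.0, dropout_prob=0.0, spurious_rate=0.0)
    outdir = tmp_path_factory.mktemp("noiseless_sim")
    truth = simulate(cfg, outdir)
    return truth, outdir


@pytest.fixture(scope="session")
def noiseless_result(noiseless_sim):
    truth, outdir = noiseless_sim
    return truth, run_state_pipeline(outdir)


@pytest.fixture(scope="session")
def default_sims(tmp_path_factory):
    """Twenty datasets at the generator's default noise settings."""
    sims = []
    for seed in range(20):
        outdir = tmp_path_factory.mktemp(f"default_sim_{seed}")
        sims.append((simulate(SimulationConfig(seed=seed), outdir), outdir))
    return sims
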