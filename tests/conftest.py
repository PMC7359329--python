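import numpy as np
import pytest

from mapkinfo import EnsembleConfig, default_parameters, run_ensemble


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def wt_ensemble():
    """Wild-type population at the study conditions (100 cells, 15 doses)."""
    return run_ensemble(EnsembleConfig(n_cells=100, seed=1, genotype="wt"))


@pytest.fixture(scope="session")
def msg5d_ensemble():
    return run_ensemble(EnsembleConfig(n_cells=100, seed=1, genotype="msg5d"))


@pytest.fixture
def frozen_cycle_params(params):
    """Parameters with all feedback synthesis frozen: beta=0 and beta0 chosen
    so each total sits exactly at its wild-type basal level, reducing the
    model to independent push-pull cycles with closed-form steady states."""
    from mapkinfo import basal_state

    p = params.copy()
    b = basal_state(p)
    targets = {"STE2": b.Rtot, "FUS3": b.Ftot, "SST2": b.Sst2,
               "MSG5": b.Msg5, "FUS1": b.Rep}
    for gene, level in targets.items():
        p.genes[gene].beta = 0.0
        p.genes[gene].beta0 = p.genes[gene].gamma * level
    return p


def rng(seed=0):
    return np.random.default_rng(seed)
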