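import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from thirststate import sc_qc
from thirststate.synthetic_data import SimConfig, gen_counts

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sc_sim():
    """1,000-cell simulation with 50 planted QC violators and 40 planted
    class doublets (4% of 1,000), shared across QC tests."""
    cfg = SimConfig(seed=11, n_cells=1000, doublet_rate=0.04, n_qc_violators=50)
    adata, cells, truth = gen_counts(cfg)
    sc_qc.compute_qc_metrics(adata)
    sc_qc.lognormalize(adata)
    return adata, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
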