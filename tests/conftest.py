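import numpy as np
import pandas as pd
import pytest

from adiponet import SimConfig, simulate_genotypes, simulate_expression, \
    simulate_traits


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(n_individuals=300, n_variants=200, seed=3)


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return simulate_genotypes(small_cfg)


@pytest.fixture(scope="session")
def small_cohort(small_cfg, small_panel):
    """Panel + expression + truth + traits for one small synthetic cohort."""
    expr, truth = simulate_expression(small_panel, small_cfg)
    quant, binary, sex, ttruth = simulate_traits(small_panel, truth,
                                                 small_cfg)
    return {"cfg": small_cfg, "panel": small_panel, "expr": expr,
            "truth": truth, "quant": quant, "binary": binary, "sex": sex,
            "trait_truth": ttruth}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
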