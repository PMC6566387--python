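import numpy as np
import pandas as pd
import pytest

from pahtox.simulate import (
    default_expression_config,
    default_screen_config,
    generate_expression_study,
    generate_phenotype_screen,
)


@pytest.fixture(scope="session")
def small_study():
    """A reduced synthetic expression study shared across unit tests."""
    cfg = default_expression_config(n_genes=800, seed=7)
    counts, meta, truth = generate_expression_study(cfg)
    return counts, meta, truth


@pytest.fixture(scope="session")
def small_screen():
    cfg = default_screen_config(n_chemicals=16, seed=3)
    return generate_phenotype_screen(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
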