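import numpy as np
import pytest

import supmap as sm


@pytest.fixture(scope="session")
def small_genetic_map() -> sm.GeneticMap:
    """Two 400 kb chromosomes with a marker every 10 kb."""
    return sm.GeneticMap.default(n_chromosomes=2, length_bp=400_000,
                                 marker_spacing=10_000)


@pytest.fixture(scope="session")
def noise_free_screen() -> sm.ScreenTable:
    params = sm.ScreenSimParams(
        n_queries=40, n_strains=2, technical_sd=0.0, biological_sd=0.0,
        missing_rate=0.0,
        suppression_effects={("q0001", "W01"): 1.5},
        insensitive_queries=frozenset({f"q{i:04d}" for i in range(25, 40)}),
    )
    return sm.simulate_screen(params, seed=11)


@pytest.fixture()
def random_matrix():
    """60 alleles (2 per gene) x 8 strains of iid scores."""
    import pandas as pd
    rng = np.random.default_rng(5)
    alleles = [f"g{i:03d}-ts{j}" for i in range(30) for j in (1, 2)]
    mat = pd.DataFrame(rng.normal(size=(len(alleles), 8)), index=alleles,
                       columns=[f"W{k:02d}" for k in range(8)])
    genes = pd.Series({a: a.split("-")[0] for a in alleles})
    return mat, genes
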