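import numpy as np
import pandas as pd
import pytest

import barseqtools as bt
from barseqtools.simulate import simulate_counts, simulate_effects


@pytest.fixture(scope="session")
def small_experiment():
    """A small 2x2x2 experiment with catalog, sheet, truth and counts."""
    params = bt.SimParams(n_mutants=120, seed=11)
    return bt.simulate_experiment(params, bt.DesignSpec(2, 2, 2), depth_per_sample=30_000)


@pytest.fixture(scope="session")
def medium_counts():
    """A 2x4x2 count matrix (800 mutants) used by several statistics tests."""
    params = bt.SimParams(n_mutants=800, seed=21, effect_magnitude=1.0)
    effects = simulate_effects(params, np.random.default_rng(21))
    matrix = simulate_counts(
        params, effects, bt.DesignSpec(2, 4, 2), depth_per_sample=800 * 150, seed=22
    )
    return params, effects, matrix


def toy_matrix(values, samples=None, mutants=None, tags=False):
    """Small helper to build CountMatrix objects from plain arrays."""
    values = np.asarray(values)
    n, p = values.shape
    cols = [f"s{i}" for i in range(p)] if samples is None else list(samples.index)
    if tags:
        idx = pd.MultiIndex.from_product(
            [[f"m{i}" for i in range(n // 2)], ["UPTAG", "DNTAG"]],
            names=["mutant_id", "tag"],
        )
    else:
        ids = mutants or [f"m{i}" for i in range(n)]
        idx = pd.Index(ids, name="mutant_id")
    df = pd.DataFrame(values, index=idx, columns=cols)
    return bt.CountMatrix(df, samples)
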