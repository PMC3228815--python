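import numpy as np
import pandas as pd
import pytest

from hierglm.data_io import drop_non_segregating
from hierglm.multiplicative import GroupedVariants
from hierglm.simulate import Scenario, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def small_dataset():
    """A small two-group simulated dataset with a real group effect."""
    sc = Scenario(n=400, group_sizes=(6, 8), h=(0.05, 0.0), p_neg=(0.0, 0.0),
                  common_groups=(0,))
    ds = simulate_dataset(sc, 42)
    return ds


@pytest.fixture(scope="session")
def small_grouped(small_dataset):
    ds = small_dataset
    gm = drop_non_segregating(ds.genotypes)
    grouped = [v for v in gm.variant_ids if isinstance(gm.groups.get(v), str)]
    gmap = {k: [v for v in grouped if gm.groups[v] == k]
            for k in sorted(set(gm.groups[grouped]))}
    gmap = {k: v for k, v in gmap.items() if len(v) >= 2}
    keep = [v for ids in gmap.values() for v in ids]
    gv = GroupedVariants(gm.dosages[keep], gmap)
    cov = ds.pheno[["age", "sex", "bmi"]].astype(float)
    singles = [s for s in ds.singletons if s in gm.variant_ids]
    cov = pd.concat([cov, gm.dosages[singles]], axis=1)
    return ds.pheno["y"].to_numpy(), cov, gv
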