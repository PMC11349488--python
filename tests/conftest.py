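import dendropy
import numpy as np
import pandas as pd
import pytest

# Fixed six-species tree used by the exhaustive diversity oracles.
SIX_SPECIES_NEWICK = (
    "((A:1.0,B:1.0):2.0,((C:0.5,D:0.5):1.5,(E:1.2,F:1.2):0.8):1.0):0.0;"
)


@pytest.fixture
def six_tree() -> dendropy.Tree:
    return dendropy.Tree.get(data=SIX_SPECIES_NEWICK, schema="newick",
                             rooting="force-rooted")


@pytest.fixture(scope="session")
def six_traits() -> pd.DataFrame:
    """Fixed mixed-type trait table for the six-species fixture."""
    return pd.DataFrame(
        {
            "sla": [200.0, 240.0, 110.0, 130.0, 300.0, 280.0],
            "height": [0.3, 0.5, 12.0, 9.0, 0.8, 1.1],
            "seed_mass": [1.2, 0.8, 40.0, 25.0, 0.2, 0.4],
            "woody": ["no", "no", "yes", "yes", "no", "no"],
        },
        index=list("ABCDEF"),
    )


@pytest.fixture(scope="session")
def six_abundances() -> pd.Series:
    return pd.Series([0.4, 0.1, 0.25, 0.05, 0.15, 0.3], index=list("ABCDEF"))


def make_group_sizes_community(
    sizes: dict[int, int],
    present: dict[int, int],
    cover: float = 0.2,
    extra_species: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Toy plots x species matrix: one focal species present in ``present[g]``
    plots of each group g, plus optional random filler species."""
    rng = np.random.default_rng(seed)
    plots, groups = [], []
    for g, n in sizes.items():
        for i in range(n):
            plots.append(f"g{g}p{i}")
            groups.append(g)
    comm = pd.DataFrame(0.0, index=plots, columns=["focal"]
                        + [f"filler{j}" for j in range(extra_species)])
    pos = 0
    for g, n in sizes.items():
        k = present.get(g, 0)
        comm.iloc[pos:pos + k, 0] = cover
        pos += n
    for j in range(extra_species):
        mask = rng.random(len(plots)) < 0.3
        comm.loc[mask, f"filler{j}"] = rng.uniform(0.05, 0.6, mask.sum())
    return comm, pd.Series(groups, index=plots)


@pytest.fixture
def table3_sizes() -> dict[int, int]:
    """Observed plot counts per cluster in the survey design the indicator
    worked examples assume."""
    return {1: 15, 2: 62, 3: 93, 4: 72, 5: 130}


from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")
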