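import dendropy
import numpy as np
import pandas as pd
import pytest

from betafacet.data_io import (
    DIET_COLUMNS,
    STRATUM_COLUMNS,
    IncidenceMatrix,
)


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


@pytest.fixture
def small_tree() -> dendropy.Tree:
    """((A:1,B:1):1,C:2); — total branch length 5."""
    return tree_from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def incidence_abc() -> IncidenceMatrix:
    df = pd.DataFrame(
        [[1, 1, 0], [1, 0, 1]],
        index=["s1", "s2"],
        columns=["A", "B", "C"],
    )
    return IncidenceMatrix(df)


def random_incidence(
    rng: np.random.Generator, n_sites: int, n_species: int
) -> IncidenceMatrix:
    """Random binary matrix with no empty sites or absent species."""
    while True:
        m = (rng.random((n_sites, n_species)) < 0.5).astype(int)
        if (m.sum(axis=1) > 0).all() and (m.sum(axis=0) > 0).all():
            df = pd.DataFrame(
                m,
                index=[f"s{i}" for i in range(n_sites)],
                columns=[f"sp{j}" for j in range(n_species)],
            )
            return IncidenceMatrix(df)


def make_traits(
    species: list[str],
    body_mass: np.ndarray,
    diet_p: np.ndarray | None = None,
) -> pd.DataFrame:
    """Valid trait table; diet fraction 1 split (p, 1-p, 0...), stratum uniform."""
    n = len(species)
    p = np.full(n, 0.5) if diet_p is None else np.asarray(diet_p, float)
    data = {"body_mass": body_mass}
    for k, c in enumerate(DIET_COLUMNS):
        if k == 0:
            data[c] = p
        elif k == 1:
            data[c] = 1 - p
        else:
            data[c] = np.zeros(n)
    for c in STRATUM_COLUMNS:
        data[c] = np.full(n, 1 / len(STRATUM_COLUMNS))
    return pd.DataFrame(data, index=pd.Index(species, name="species_id"))
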