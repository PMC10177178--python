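"""Generator oracles: constructed assembly modes have known beta
structure; trees are ultrametric binary; traits carry the requested
phylogenetic signal; environment is gradient-monotone."""

import numpy as np
import pytest

from betafacet.phylo_beta import EdgeTable
from betafacet.synthetic_data import (
    SimulationSpec,
    bm_covariance,
    simulate_communities,
    simulate_dataset,
    simulate_environment,
    simulate_traits,
    simulate_tree,
)
from betafacet.taxonomic_beta import pairwise_taxonomic


def test_nestedness_mode_is_pure_nestedness():
    spec = SimulationSpec(
        n_sites=3,
        pool_size=10,
        richness_per_site=(5, 3, 2),
        assembly_mode="nestedness",
        rng_seed=4,
    )
    inc, _ = simulate_communities(spec)
    sets = [inc.site_species(s) for s in inc.site_ids]
    order = sorted(range(3), key=lambda k: -len(sets[k]))
    assert sets[order[2]] <= sets[order[1]] <= sets[order[0]]
    bs = pairwise_taxonomic(inc)
    assert np.allclose(bs.turnover.to_numpy(), 0.0)
    np.testing.assert_allclose(
        bs.nestedness.to_numpy(), bs.total.to_numpy(), atol=1e-12
    )


def test_turnover_mode_disjoint_ranges():
    """niche_breadth=1 with enough species: every species sits in one
    band only, so distinct bands share nothing."""
    spec = SimulationSpec(
        n_sites=3,
        pool_size=30,
        assembly_mode="turnover",
        niche_breadth=1,
        rng_seed=0,
    )
    inc, _ = simulate_communities(spec)
    bs = pairwise_taxonomic(inc)
    off = ~np.eye(3, dtype=bool)
    assert np.allclose(bs.turnover.to_numpy()[off], 1.0)
    assert np.allclose(bs.total.to_numpy()[off], 1.0)
    assert np.allclose(bs.nestedness.to_numpy()[off], 0.0)


def test_turnover_adjacent_share_more_than_distant():
    spec = SimulationSpec(rng_seed=2)  # default 8 bands, breadth 3
    inc, _ = simulate_communities(spec)
    m = inc.matrix.astype(int)
    shared = m @ m.T
    assert shared[0, 1] > shared[0, 7]


def test_modes_deterministic_under_seed():
    for mode in ("random", "turnover", "filtered", "limiting"):
        spec = SimulationSpec(
            n_sites=4,
            pool_size=25,
            richness_per_site=(10, 8, 6, 5),
            assembly_mode=mode,
            rng_seed=11,
        )
        a, _ = simulate_communities(spec)
        b, _ = simulate_communities(spec)
        assert a == b


def test_infeasible_richness_rejected():
    with pytest.raises(ValueError, match="richness"):
        SimulationSpec(
            n_sites=2, pool_size=5, richness_per_site=(6, 2), assembly_mode="random"
        )


def test_tree_shape_and_determinism():
    tree = simulate_tree(2, seed=0)
    lengths = [l.edge.length for l in tree.leaf_node_iter()]
    assert lengths[0] == pytest.approx(lengths[1])  # a cherry, equal tips
    big = simulate_tree(132, seed=1)
    n_leaves = sum(1 for _ in big.leaf_node_iter())
    n_edges = sum(1 for e in big.preorder_edge_iter() if e.length is not None)
    assert n_leaves == 132
    assert n_edges == 2 * 132 - 2  # rooted binary tree identity
    s1 = simulate_tree(20, seed=5).as_string(schema="newick")
    s2 = simulate_tree(20, seed=5).as_string(schema="newick")
    assert s1 == s2


def test_tree_is_ultrametric():
    tree = simulate_tree(30, seed=3)
    depths = []
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length
            node = node.parent_node
        depths.append(d)
    assert np.ptp(depths) < 1e-9


def test_traits_lambda_controls_sister_correlation():
    """On a cherry with a long shared stem, latent traits are strongly
    correlated at lambda=1 and uncorrelated at lambda=0 (Monte-Carlo
    over 500 replicates)."""
    import dendropy

    tree = dendropy.Tree.get(data="((A:0.1,B:0.1):10,C:10.1);", schema="newick")
    vals = {0.0: [], 1.0: []}
    for lam in vals:
        for rep in range(500):
            tr = simulate_traits(tree, lam, seed=rep)
            x = np.log10(tr["body_mass"])
            vals[lam].append((x["A"], x["B"]))
    for lam, pairs in vals.items():
        r = np.corrcoef(np.array(pairs).T)[0, 1]
        if lam == 0.0:
            assert abs(r) < 0.15
        else:
            assert r > 0.9  # shared stem is ~99% of the tip variance


def test_traits_valid_fractions():
    tree = simulate_tree(40, seed=7)
    tr = simulate_traits(tree, 0.5, seed=1)
    diet = [c for c in tr.columns if c.startswith("diet")]
    strat = [c for c in tr.columns if c.startswith("stratum")]
    assert tr[diet].sum(axis=1).to_numpy() == pytest.approx(np.ones(40))
    assert tr[strat].sum(axis=1).to_numpy() == pytest.approx(np.ones(40))
    assert (tr["body_mass"] > 0).all()


def test_bm_covariance_matches_shared_paths(small_tree):
    cov = bm_covariance(small_tree, ["A", "B", "C"])
    expected = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
    np.testing.assert_allclose(cov, expected)


def test_environment_monotone_and_deterministic():
    spec = SimulationSpec(rng_seed=0)
    meta = simulate_dataset(spec).metadata
    env0 = simulate_environment(meta, noise_sd=0.0, seed=1)
    assert (np.diff(env0["Bio1"]) < 0).all()
    assert (np.diff(env0["PET"]) < 0).all()
    # noiseless Bio1 is perfectly rank-anticorrelated with elevation
    from scipy.stats import spearmanr

    rho = spearmanr(env0["Bio1"], meta["elevation_mid"]).statistic
    assert rho == pytest.approx(-1.0)
    env_a = simulate_environment(meta, noise_sd=0.3, seed=9)
    env_b = simulate_environment(meta, noise_sd=0.3, seed=9)
    assert env_a.equals(env_b)


def test_single_variable_distance_matches_elevation():
    """With no noise and one monotone variable, the environmental and
    elevational distance matrices are perfectly Mantel-correlated."""
    from betafacet.gradient_stats import (
        elevational_distance,
        environmental_distance,
        mantel,
    )

    spec = SimulationSpec(rng_seed=0)
    meta = simulate_dataset(spec).metadata
    env0 = simulate_environment(meta, noise_sd=0.0, seed=1)
    d_env = environmental_distance(env0, ["Bio1"])
    d_elev = elevational_distance(meta)
    res = mantel(d_env, d_elev, n_perm=99, seed=0)
    assert res.r == pytest.approx(1.0, abs=1e-9)


def test_dataset_reproducible():
    a = simulate_dataset(SimulationSpec(rng_seed=42))
    b = simulate_dataset(SimulationSpec(rng_seed=42))
    assert a.incidence == b.incidence
    assert a.traits.equals(b.traits)
    assert a.environment.equals(b.environment)
    ta = EdgeTable(a.tree, a.incidence.species_ids)
    tb = EdgeTable(b.tree, b.incidence.species_ids)
    np.testing.assert_allclose(np.sort(ta.lengths), np.sort(tb.lengths))
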