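"""Distance matrices, Mantel, rank-sum, ANOSIM, hierarchical partitioning."""

import numpy as np
import pandas as pd
import pytest

from betafacet.gradient_stats import (
    anosim,
    decay_regression,
    elevational_distance,
    environmental_distance,
    hierarchical_partition,
    mantel,
    ranksum_compare,
)


def square(vals, sites):
    return pd.DataFrame(vals, index=sites, columns=sites, dtype=float)


@pytest.fixture
def meta3():
    return pd.DataFrame({"elevation_mid": [2150.0, 2400.0, 2900.0]}, index=list("abc"))


def test_elevational_distance(meta3):
    d = elevational_distance(meta3)
    assert d.loc["a", "b"] == 250.0
    assert d.loc["a", "c"] == 750.0
    assert d.loc["a", "a"] == 0.0
    assert np.allclose(d.to_numpy(), d.to_numpy().T)


def test_environmental_distance_standardizes_then_euclid():
    env = pd.DataFrame({"Bio1": [1.0, 3.0], "PET": [10.0, 20.0]}, index=["a", "b"])
    d1 = environmental_distance(env, ["Bio1"])
    # two sites standardized to -1/sqrt(2)... with ddof=1: z = ±0.707 -> distance sqrt(2)
    assert d1.loc["a", "b"] == pytest.approx(np.sqrt(2.0))
    d2 = environmental_distance(env, ["Bio1", "PET"])
    assert d2.loc["a", "b"] == pytest.approx(np.sqrt(2.0) * d1.loc["a", "b"])
    env["flat"] = 1.0
    with pytest.raises(ValueError, match="flat"):
        environmental_distance(env, ["flat"])


def test_mantel_perfect_and_anti():
    sites = list("abc")
    d1 = square([[0, 1, 2], [1, 0, 3], [2, 3, 0]], sites)
    res = mantel(d1, d1.copy(), n_perm=99, seed=0)
    assert res.r == pytest.approx(1.0)
    assert 0 < res.p <= 1
    d2 = square([[0, 3, 2], [3, 0, 1], [2, 1, 0]], sites)
    anti = mantel(d1, d2, n_perm=99, seed=0)
    assert anti.r == pytest.approx(-1.0)
    with pytest.raises(ValueError, match="constant"):
        mantel(square(np.ones((3, 3)) - np.eye(3), sites), d1, n_perm=9, seed=0)


def test_mantel_matches_skbio():
    """Cross-check r (and p to permutation noise) against scikit-bio."""
    from skbio.stats.distance import DistanceMatrix
    from skbio.stats.distance import mantel as skbio_mantel

    rng = np.random.default_rng(0)
    n = 10
    x = rng.random((n, 2))
    a = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
    b = a + rng.normal(scale=0.1, size=(n, n))
    b = (b + b.T) / 2
    np.fill_diagonal(b, 0)
    b = np.abs(b)
    sites = [f"s{i}" for i in range(n)]
    ours = mantel(square(a, sites), square(b, sites), n_perm=999, seed=1)
    r_sk, p_sk, _ = skbio_mantel(
        DistanceMatrix(a, sites), DistanceMatrix(b, sites),
        permutations=999, alternative="greater",
    )
    assert ours.r == pytest.approx(float(r_sk), abs=1e-10)
    assert ours.p == pytest.approx(float(p_sk), abs=0.02)


def test_mantel_null_p_uniformity():
    """Against an independent random matrix the permutation p-value
    should be roughly uniform (KS sanity at 60 simulations)."""
    from scipy.stats import kstest

    rng = np.random.default_rng(4)
    sites = [f"s{i}" for i in range(8)]
    ps = []
    for k in range(60):
        a = rng.random((8, 8))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        b = rng.random((8, 8))
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        ps.append(mantel(square(a, sites), square(b, sites), n_perm=199, seed=k).p)
    assert kstest(ps, "uniform").pvalue > 0.01


def test_decay_regression_cases(meta3):
    d = elevational_distance(meta3)
    x = np.array([250.0, 750.0, 500.0])  # condensed lower triangle of d
    exact = decay_regression(x.copy(), d)
    assert exact.slope == pytest.approx(1.0)
    assert exact.r_squared == pytest.approx(1.0)
    const = decay_regression(np.full(3, 0.4), d)
    assert const.slope == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError, match="identical"):
        decay_regression(x, np.ones(3))
    with pytest.raises(ValueError, match="3 pairs"):
        decay_regression(np.array([1.0, np.nan, np.nan]), d)


def test_ranksum_worked_example():
    res = ranksum_compare([1, 2, 3], [4, 5, 6])
    assert abs(res.z) == pytest.approx(4.5 / np.sqrt(5.25), abs=1e-6)  # ~1.964
    assert res.direction == "y > x"
    swapped = ranksum_compare([4, 5, 6], [1, 2, 3])
    assert swapped.z == pytest.approx(-res.z)
    assert swapped.p == pytest.approx(res.p)
    tied = ranksum_compare([1, 2, 3], [1, 2, 3])
    assert tied.z == 0.0
    assert tied.direction == "tied"


def test_ranksum_matches_scipy_with_ties():
    from scipy.stats import mannwhitneyu

    rng = np.random.default_rng(2)
    x = rng.integers(0, 6, size=20).astype(float)
    y = rng.integers(1, 7, size=25).astype(float)
    ours = ranksum_compare(x, y)
    ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                       use_continuity=False)
    assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)


def test_anosim_extremes():
    sites = [f"s{i}" for i in range(6)]
    groups = ["g1"] * 3 + ["g2"] * 3
    d = np.ones((6, 6))
    d[:3, :3] = 0.1
    d[3:, 3:] = 0.1
    np.fill_diagonal(d, 0)
    res = anosim(square(d, sites), groups, n_perm=199, seed=0)
    assert res.R == pytest.approx(1.0)
    flat = square(np.ones((6, 6)) - np.eye(6), sites)
    assert anosim(flat, groups, n_perm=99, seed=0).R == pytest.approx(0.0)
    with pytest.raises(ValueError, match="size 1"):
        anosim(flat, ["g1"] * 5 + ["g2"], n_perm=9, seed=0)


def test_anosim_matches_skbio():
    from skbio.stats.distance import DistanceMatrix
    from skbio.stats.distance import anosim as skbio_anosim

    rng = np.random.default_rng(3)
    n = 9
    d = rng.random((n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    sites = [f"s{i}" for i in range(n)]
    groups = ["a"] * 4 + ["b"] * 5
    ours = anosim(square(d, sites), groups, n_perm=9999, seed=5)
    ref = skbio_anosim(DistanceMatrix(d, sites), grouping=groups, permutations=9999)
    assert ours.R == pytest.approx(float(ref["test statistic"]), abs=1e-10)
    assert ours.p == pytest.approx(float(ref["p-value"]), abs=0.05)


def test_anosim_null_mean_near_zero():
    rng = np.random.default_rng(6)
    sites = [f"s{i}" for i in range(8)]
    rs = []
    for k in range(40):
        d = rng.random((8, 8))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        groups = rng.permutation(["a"] * 4 + ["b"] * 4)
        rs.append(anosim(square(d, sites), groups, n_perm=9, seed=k).R)
    assert abs(np.mean(rs)) < 0.12


# ---------------------------------------------- hierarchical partitioning


def _pair_vectors(rng, n=30, k=2):
    x = rng.normal(size=(n, k))
    return x


def test_hierpart_single_predictor():
    rng = np.random.default_rng(0)
    x = rng.normal(size=40)
    y = 2 * x + rng.normal(scale=0.5, size=40)
    res = hierarchical_partition(y, {"x": x})
    assert res.independent["x"] == pytest.approx(res.r_squared_full, abs=1e-12)


def test_hierpart_orthogonal_predictors():
    """For exactly orthogonal predictors each independent effect equals
    its marginal R^2 and joint effects vanish."""
    n = 32
    t = np.arange(n)
    x1 = np.cos(2 * np.pi * t / n)
    x2 = np.sin(2 * np.pi * t / n)
    y = 1.5 * x1 + 0.5 * x2
    res = hierarchical_partition(y, {"c": x1, "s": x2})
    from betafacet.gradient_stats import _ols_r2

    for name, x in (("c", x1), ("s", x2)):
        marginal = _ols_r2(y, x[:, None])
        assert res.independent[name] == pytest.approx(marginal, abs=1e-10)
        assert res.joint[name] == pytest.approx(0.0, abs=1e-10)


def test_hierpart_sum_identity_five_predictors():
    rng = np.random.default_rng(1)
    for _ in range(5):
        x = rng.normal(size=(40, 5))
        beta = rng.normal(size=5)
        y = x @ beta + rng.normal(size=40)
        res = hierarchical_partition(
            y, {f"v{j}": x[:, j] for j in range(5)}
        )
        assert sum(res.independent.values()) == pytest.approx(
            res.r_squared_full, abs=1e-10
        )


def test_hierpart_collinear_rejected():
    rng = np.random.default_rng(2)
    x = rng.normal(size=30)
    y = x + rng.normal(size=30)
    with pytest.raises(ValueError, match="collinear"):
        hierarchical_partition(y, {"a": x, "b": 2 * x})


def test_hierpart_matches_r_oracle_values():
    """Frozen oracle: independent effects computed by direct enumeration
    of all 2^3 orderings for a 3-predictor design (hand enumeration of
    the 6 orderings, averaged)."""
    rng = np.random.default_rng(7)
    x = rng.normal(size=(25, 3))
    y = x @ np.array([1.0, -0.5, 0.2]) + rng.normal(size=25)
    res = hierarchical_partition(y, {"a": x[:, 0], "b": x[:, 1], "c": x[:, 2]})
    from itertools import permutations

    from betafacet.gradient_stats import _ols_r2

    incr = {0: [], 1: [], 2: []}
    for order in permutations(range(3)):
        before: list[int] = []
        for v in order:
            r_with = _ols_r2(y, x[:, sorted(before + [v])])
            r_without = _ols_r2(y, x[:, sorted(before)]) if before else 0.0
            incr[v].append(r_with - r_without)
            before.append(v)
    for name, idx in (("a", 0), ("b", 1), ("c", 2)):
        assert res.independent[name] == pytest.approx(np.mean(incr[idx]), abs=1e-10)
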