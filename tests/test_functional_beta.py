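"""Trait space and convex-hull partition: geometry oracles and PCA checks."""

import numpy as np
import pandas as pd
import pytest

from betafacet.data_io import IncidenceMatrix
from betafacet.functional_beta import (
    HullGeometry,
    build_trait_space,
    encode_traits,
    hull_pair_counts,
    pairwise_functional,
    site_hull,
)
from betafacet.taxonomic_beta import partition_from_counts
from conftest import make_traits


def hull_from_points(points, site_id="h") -> HullGeometry:
    from scipy.spatial import ConvexHull

    pts = np.asarray(points, dtype=float)
    h = ConvexHull(pts)
    return HullGeometry(site_id, pts[h.vertices], float(h.volume), False)


def monte_carlo_intersection(p1, p2, n_points, rng):
    """Rejection-sampling oracle for the intersection area of two
    convex polygons, via vectorized half-plane tests."""
    pts = np.vstack([p1, p2])
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    box = np.prod(hi - lo)
    sample = rng.uniform(lo, hi, size=(n_points, 2))

    def inside(poly, q):
        # vertices in hull order; inside = consistent cross-product sign
        a = poly
        b = np.roll(poly, -1, axis=0)
        cross = (b[None, :, 0] - a[None, :, 0]) * (q[:, None, 1] - a[None, :, 1]) - (
            b[None, :, 1] - a[None, :, 1]
        ) * (q[:, None, 0] - a[None, :, 0])
        return (cross >= 0).all(axis=1) | (cross <= 0).all(axis=1)

    hit = inside(p1, sample) & inside(p2, sample)
    p_hat = hit.mean()
    area = box * p_hat
    se = box * np.sqrt(max(p_hat * (1 - p_hat), 1e-12) / n_points)
    return area, se


SQUARE02 = [(0, 0), (2, 0), (2, 2), (0, 2)]
SQUARE13 = [(1, 1), (3, 1), (3, 3), (1, 3)]
SQUARE_INNER = [(0.5, 0.5), (1.5, 0.5), (1.5, 1.5), (0.5, 1.5)]


def test_offset_squares_partition():
    """[0,2]^2 vs [1,3]^2: a=1, b=3, c=3 -> (0.75, 0.75, 0)."""
    pc = hull_pair_counts(hull_from_points(SQUARE02), hull_from_points(SQUARE13))
    assert (pc.a, pc.b, pc.c) == pytest.approx((1.0, 3.0, 3.0))
    p = partition_from_counts(pc, facet="functional")
    assert p.total == pytest.approx(0.75)
    assert p.turnover == pytest.approx(0.75)
    assert p.nestedness == pytest.approx(0.0, abs=1e-12)


def test_nested_squares_partition():
    """[0,2]^2 vs [0.5,1.5]^2: nestedness-only geometry, turnover 0."""
    pc = hull_pair_counts(hull_from_points(SQUARE02), hull_from_points(SQUARE_INNER))
    assert (pc.a, pc.b, pc.c) == pytest.approx((1.0, 3.0, 0.0))
    p = partition_from_counts(pc, facet="functional")
    assert p.turnover == 0.0  # exact: min(b, c) = 0
    assert p.total == pytest.approx(0.6)
    assert p.nestedness == pytest.approx(0.6)


def test_identical_hulls_zero_partition():
    pc = hull_pair_counts(hull_from_points(SQUARE02), hull_from_points(SQUARE02))
    p = partition_from_counts(pc, facet="functional")
    assert (p.total, p.turnover, p.nestedness) == (0.0, 0.0, 0.0)


def random_convex_pair(rng):
    def poly():
        pts = rng.normal(size=(rng.integers(4, 9), 2)) + rng.normal(scale=0.7, size=2)
        from scipy.spatial import ConvexHull

        h = ConvexHull(pts)
        return pts[h.vertices]

    return poly(), poly()


def test_clipping_matches_monte_carlo():
    """Polygon-clipping intersection area agrees with the rejection-
    sampling oracle within 3 standard errors (spot check; the full
    50-pair sweep runs in the acceptance suite)."""
    rng = np.random.default_rng(5)
    for _ in range(10):
        p1, p2 = random_convex_pair(rng)
        pc = hull_pair_counts(
            HullGeometry("a", p1, 0.0, False), HullGeometry("b", p2, 0.0, False)
        )
        mc, se = monte_carlo_intersection(p1, p2, 200_000, rng)
        assert abs(pc.a - mc) <= max(3 * se, 1e-9)


def test_scale_invariance():
    rng = np.random.default_rng(8)
    p1, p2 = random_convex_pair(rng)
    base = partition_from_counts(
        hull_pair_counts(
            HullGeometry("a", p1, 0.0, False), HullGeometry("b", p2, 0.0, False)
        )
    )
    scaled = partition_from_counts(
        hull_pair_counts(
            HullGeometry("a", 3.7 * p1, 0.0, False),
            HullGeometry("b", 3.7 * p2, 0.0, False),
        )
    )
    assert scaled.total == pytest.approx(base.total, abs=1e-9)
    assert scaled.turnover == pytest.approx(base.turnover, abs=1e-9)


def test_pca_rank_one_case():
    """Traits that are all affine in one latent variable load entirely
    on the first axis."""
    t = np.linspace(-1, 1, 12)
    traits = make_traits(
        [f"sp{k}" for k in range(12)],
        body_mass=10**t,
        diet_p=0.3 + 0.2 * t,
    )
    with np.errstate(all="ignore"):
        space = build_trait_space(traits, n_axes=2)
    assert space.variance_explained[0] == pytest.approx(1.0, abs=1e-9)


def test_pca_reconstruction_complete():
    rng = np.random.default_rng(1)
    traits = make_traits(
        [f"sp{k}" for k in range(20)],
        body_mass=np.exp(rng.normal(3, 1, 20)),
        diet_p=rng.uniform(0.1, 0.9, 20),
    )
    x = encode_traits(traits)
    x = x.loc[:, x.std(ddof=1) > 1e-8]  # same constant-column rule
    z = ((x - x.mean()) / x.std(ddof=1)).to_numpy()
    space = build_trait_space(traits, n_axes=np.linalg.matrix_rank(z))
    recon = space.coordinates.to_numpy() @ space.loadings.to_numpy().T
    assert np.abs(recon - z).max() < 1e-10


def test_site_hull_degeneracies():
    coords = pd.DataFrame(
        {"PC1": [0.0, 1.0, 2.0, 0.0, 1.0], "PC2": [0.0, 1.0, 2.0, 1.0, 0.0]},
        index=[f"sp{k}" for k in range(5)],
    )
    from betafacet.functional_beta import TraitSpace

    space = TraitSpace(coords, np.array([0.6, 0.4]), coords.iloc[:2])
    too_few = site_hull(space, {"sp0", "sp1"}, "low")
    assert too_few.excluded and "fewer than 3" in too_few.reason
    collinear = site_hull(space, {"sp0", "sp1", "sp2"}, "line")
    assert collinear.excluded
    square = site_hull(space, {"sp0", "sp1", "sp3", "sp4"}, "sq")
    assert not square.excluded and square.volume == pytest.approx(1.0)
    # interior point does not change the hull
    plus_inner = site_hull(space, {"sp0", "sp1", "sp2", "sp3", "sp4"}, "all")
    assert plus_inner.volume == pytest.approx(2.0)


def test_pairwise_functional_exclusions_propagate():
    coords = pd.DataFrame(
        {
            "PC1": [0.0, 2.0, 2.0, 0.0, 1.0, 3.0],
            "PC2": [0.0, 0.0, 2.0, 2.0, 3.0, 1.0],
        },
        index=[f"sp{k}" for k in range(6)],
    )
    from betafacet.functional_beta import TraitSpace

    space = TraitSpace(coords, np.array([0.5, 0.5]), coords.iloc[:2])
    df = pd.DataFrame(
        [
            [1, 1, 1, 1, 0, 0],  # square hull
            [1, 1, 1, 1, 1, 1],  # bigger hull
            [1, 1, 0, 0, 0, 0],  # 2 species -> excluded
        ],
        index=["s1", "s2", "s3"],
        columns=coords.index,
    )
    inc = IncidenceMatrix(df)
    bs = pairwise_functional(inc, space)
    assert np.isnan(bs.total.loc["s1", "s3"])
    assert np.isnan(bs.turnover.loc["s2", "s3"])
    assert np.isfinite(bs.total.loc["s1", "s2"])
    # containment: s1's hull is inside s2's -> turnover exactly 0
    assert bs.turnover.loc["s1", "s2"] == 0.0
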