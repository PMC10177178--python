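"""Phylogenetic beta diversity by shared/unique branch lengths.

For each site pair, every branch of the tree is classified by the sites
its subtended tips occur in: both sites (shared length ``a``), exactly
one (unique lengths ``b``, ``c``), or neither (ignored).  Feeding the
summed lengths through the Sørensen partition yields the PhyloSor
family (total / turnover / nestedness on branch lengths).

Classification is confined to the minimal spanning subtree of the two
communities: the root stem and any branch subtending the entire union
of the two sites (the path from the union's most recent common ancestor
up to the root) are excluded.  Such branches are unavoidably "shared"
in every comparison, and excluding them makes the computation invariant
under pruning the tree to the union of the pair — the property that
lets a regional tree and a pair-pruned tree give identical answers.
Zero-length branches are allowed and contribute 0.
"""

from __future__ import annotations

from typing import Sequence

import dendropy
import numpy as np

from .data_io import IncidenceMatrix, prune_tree
from .taxonomic_beta import (
    BetaPartition,
    PairCounts,
    PairwiseBetaSet,
    _as_beta_set,
    _partition_arrays,
    partition_from_counts,
)


class EdgeTable:
    """Branch lengths with per-branch tip-membership masks.

    ``masks`` is (n_edges, n_species) boolean: masks[e, s] is True when
    species ``s`` is a tip subtended by edge ``e``.  Built in one
    post-order traversal; the root stem is not included.  Species in
    ``species_order`` that are not tips of the tree simply never appear
    in any mask.
    """

    def __init__(self, tree: dendropy.Tree, species_order: Sequence[str]):
        index = {label: k for k, label in enumerate(species_order)}
        n = len(species_order)
        lengths: list[float] = []
        masks: list[np.ndarray] = []
        node_mask: dict[int, np.ndarray] = {}
        for node in tree.postorder_node_iter():
            mask = np.zeros(n, dtype=bool)
            if node.is_leaf():
                label = node.taxon.label
                if label in index:
                    mask[index[label]] = True
            else:
                for child in node.child_nodes():
                    mask |= node_mask[id(child)]
            node_mask[id(node)] = mask
            if node is tree.seed_node:
                continue  # exclude the root stem
            lengths.append(float(node.edge.length or 0.0))
            masks.append(mask)
        self.lengths = np.asarray(lengths, dtype=float)
        self.masks = (
            np.vstack(masks) if masks else np.zeros((0, n), dtype=bool)
        )
        self._masks_int = self.masks.astype(np.int64)
        self.species_order = list(species_order)

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())

    def tip_counts(self, occupancy: np.ndarray) -> np.ndarray:
        """(n_edges, n_sites) counts |mask_e ∩ site_i| for boolean site
        rows (n_sites, n_species)."""
        occ = np.atleast_2d(np.asarray(occupancy)).astype(np.int64)
        return self._masks_int @ occ.T


def _pair_abc_matrices(
    table: EdgeTable, occupancy: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized a/b/c branch-length matrices over all site pairs.

    Works from the rooted accounting (every edge intersecting a site)
    and then subtracts, per pair, the length of edges subtending the
    whole union — exactly the root-to-MRCA(union) path.
    """
    occ = np.atleast_2d(np.asarray(occupancy, dtype=bool))
    counts = table.tip_counts(occ)  # (n_edges, n_sites)
    pres = (counts > 0).astype(float)
    w = table.lengths
    a_rooted = (pres * w[:, None]).T @ pres
    pd_rooted = (w[:, None] * pres).sum(axis=0)
    # edge subtends all of site i  <=>  count == site richness
    rich = occ.sum(axis=1)
    full = (counts == rich[None, :]).astype(float)
    above_mrca = (full * w[:, None]).T @ full  # length subtending both full sites
    a = a_rooted - above_mrca
    b = pd_rooted[:, None] - a_rooted
    c = pd_rooted[None, :] - a_rooted
    return a, b, c


def classify_branches(
    tree: dendropy.Tree,
    site1: set[str] | Sequence[str],
    site2: set[str] | Sequence[str],
) -> PairCounts:
    """Summed shared / unique branch lengths for one site pair."""
    site1, site2 = set(site1), set(site2)
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    unknown = (site1 | site2) - tips
    if unknown:
        raise ValueError(f"species not on tree: {sorted(unknown)}")
    order = sorted(tips)
    table = EdgeTable(tree, order)
    occ = np.array(
        [[sp in site for sp in order] for site in (site1, site2)], dtype=bool
    )
    a, b, c = _pair_abc_matrices(table, occ)
    return PairCounts(a=float(a[0, 1]), b=float(b[0, 1]), c=float(c[0, 1]))


def phylo_pair_partition(
    tree: dendropy.Tree, site1: set[str], site2: set[str]
) -> BetaPartition:
    return partition_from_counts(
        classify_branches(tree, site1, site2), facet="phylogenetic"
    )


def pairwise_phylogenetic(
    inc: IncidenceMatrix, tree: dendropy.Tree, table: EdgeTable | None = None
) -> PairwiseBetaSet:
    """PhyloSor-family partition for all unordered site pairs.

    A prebuilt :class:`EdgeTable` may be supplied to amortize the
    traversal across many incidence matrices (the null model loop).
    """
    if inc.n_sites < 2:
        raise ValueError("need at least 2 sites")
    if table is None:
        table = EdgeTable(tree, inc.species_ids)
    a, b, c = _pair_abc_matrices(table, inc.matrix)
    total, turnover, nestedness = _partition_arrays(a, b, c)
    return _as_beta_set("phylogenetic", inc.site_ids, total, turnover, nestedness)


def faith_pd(tree: dendropy.Tree, species: set[str] | Sequence[str]) -> float:
    """Faith's PD: summed branch length of the minimal subtree spanning
    the species set and the root (root stem excluded)."""
    species = set(species)
    if not species:
        raise ValueError("empty species set")
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    unknown = species - tips
    if unknown:
        raise ValueError(f"species not on tree: {sorted(unknown)}")
    order = sorted(tips)
    table = EdgeTable(tree, order)
    occ = np.array([[sp in species for sp in order]], dtype=bool)
    pres = table.tip_counts(occ)[:, 0] > 0
    return float(table.lengths[pres].sum())


def average_over_trees(
    inc: IncidenceMatrix, trees: Sequence[dendropy.Tree]
) -> tuple[PairwiseBetaSet, PairwiseBetaSet]:
    """Mean and SD of the phylogenetic partition across a tree sample.

    Accommodates topological uncertainty (e.g. a pseudo-posterior sample
    of trees); with a single tree the SD matrices are all zero.
    """
    if len(trees) < 1:
        raise ValueError("need at least one tree")
    tip_sets = [
        frozenset(leaf.taxon.label for leaf in t.leaf_node_iter()) for t in trees
    ]
    if len(set(tip_sets)) != 1:
        raise ValueError("trees have mismatched tip sets")
    if not set(inc.species_ids) <= tip_sets[0]:
        raise ValueError("incidence species missing from trees")
    stacks: dict[str, list[np.ndarray]] = {
        comp: [] for comp in ("total", "turnover", "nestedness")
    }
    for tree in trees:
        bs = pairwise_phylogenetic(inc, tree)
        for comp in stacks:
            stacks[comp].append(bs.component(comp).to_numpy())
    means, sds = {}, {}
    for comp, mats in stacks.items():
        arr = np.stack(mats)
        means[comp] = arr.mean(axis=0)
        sds[comp] = arr.std(axis=0, ddof=0)
    mean_set = _as_beta_set(
        "phylogenetic",
        inc.site_ids,
        means["total"],
        means["turnover"],
        means["nestedness"],
    )
    sd_set = _as_beta_set(
        "phylogenetic", inc.site_ids, sds["total"], sds["turnover"], sds["nestedness"]
    )
    return mean_set, sd_set


def prune_to_union(
    tree: dendropy.Tree, site1: set[str], site2: set[str]
) -> dendropy.Tree:
    """Restrict the tree to the species occurring in either site."""
    return prune_tree(tree, sorted(set(site1) | set(site2)))
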