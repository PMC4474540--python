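"""Cancer-type clustering by fold-change correlation, globally and within
pathway gene sets.

The distance between two cohorts is 1 minus the Spearman correlation of
their log2 fold-change vectors over the shared genes (all shared genes by
default, optionally DE-only).  Cohorts are clustered agglomeratively with
average linkage and a deterministic tie rule, and each tree is exported as
a newick string with UPGMA-style branch lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .attribution import spearman_rho
from .diffexpr import DETable
from .io import GeneCatalog

logger = logging.getLogger(__name__)

LINKAGES = ("average", "complete", "single")


def fold_change_distance(
    de_tables: list[DETable],
    gene_subset: set[str] | None = None,
    de_only: bool = False,
    min_shared: int = 10,
    subset_name: str = "gene subset",
) -> tuple[pd.DataFrame, int]:
    """Pairwise 1 - Spearman distance of cohort log2fc profiles.

    Genes used are the intersection of all cohorts' universes with
    ``gene_subset`` (all genes when None); with ``de_only`` the
    intersection is further restricted to genes DE in at least one cohort.
    Returns (symmetric distance DataFrame, number of shared genes).
    """
    if len(de_tables) < 2:
        raise ValueError("need at least 2 cohorts")
    ids = [de.cohort_id for de in de_tables]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate cohort ids")
    shared: set[str] = set(de_tables[0].universe())
    for de in de_tables[1:]:
        shared &= de.universe()
    if gene_subset is not None:
        shared &= set(gene_subset)
    if de_only:
        any_de: set[str] = set()
        for de in de_tables:
            any_de |= de.de_genes()
        shared &= any_de
    if len(shared) < min_shared:
        raise ValueError(
            f"only {len(shared)} shared genes for {subset_name}; "
            f"need at least {min_shared}"
        )
    genes = sorted(shared)
    fc = np.column_stack([de.table["log2fc"].loc[genes].to_numpy() for de in de_tables])
    k = len(ids)
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = 1.0 - spearman_rho(fc[:, i], fc[:, j])
            dist[i, j] = dist[j, i] = d
    return pd.DataFrame(dist, index=ids, columns=ids), len(genes)


@dataclass
class CohortDendrogram:
    """Agglomerative tree over cohorts for one gene subset.

    ``merges`` lists (left members, right members, height) in merge order;
    heights are non-decreasing for average/complete/single linkage on a
    proper distance matrix.
    """

    name: str
    cohort_ids: list[str]
    n_shared_genes: int
    distance: pd.DataFrame
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]
    newick: str

    def first_merge(self) -> tuple[str, ...]:
        left, right, _ = self.merges[0]
        return tuple(sorted(left + right))


def _newick(node, heights) -> str:
    """Recursive newick with branch length = parent height/2 - node height/2."""

    def render(members: tuple[str, ...], parent_h: float) -> str:
        h = heights[members]
        branch = (parent_h - h) / 2.0
        if len(members) == 1:
            return f"{members[0]}:{branch:.6f}"
        left, right = node[members]
        inner = f"({render(left, h)},{render(right, h)})"
        return f"{inner}:{branch:.6f}"

    root = max(heights, key=len)
    h = heights[root]
    if len(root) == 1:
        return f"{root[0]};"
    left, right = node[root]
    return f"({render(left, h)},{render(right, h)});"


def cluster_cohorts(
    dist: pd.DataFrame,
    linkage: str = "average",
    name: str = "all_genes",
    n_shared_genes: int = 0,
) -> CohortDendrogram:
    """Agglomerative clustering with a deterministic tie rule.

    At each step the pair of clusters with the smallest distance is merged;
    exact ties are broken by the lexicographically smallest pair of sorted
    member tuples.  Average linkage uses size-weighted means; complete and
    single linkage take the max / min.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}")
    ids = [str(c) for c in dist.columns]
    arr = dist.to_numpy(dtype=float)
    if list(dist.index) != list(dist.columns):
        raise ValueError("distance matrix index and columns differ")
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0.0):
        raise ValueError("distance matrix diagonal must be zero")

    clusters: dict[tuple[str, ...], dict[tuple[str, ...], float]] = {}
    members = [(c,) for c in ids]
    for i, a in enumerate(members):
        clusters[a] = {}
    for i, a in enumerate(members):
        for j, b in enumerate(members):
            if i != j:
                clusters[a][b] = float(arr[i, j])
    sizes = {m: 1 for m in members}
    heights: dict[tuple[str, ...], float] = {m: 0.0 for m in members}
    children: dict[tuple[str, ...], tuple[tuple[str, ...], tuple[str, ...]]] = {}
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []

    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in clusters[a]:
                if a < b:
                    key = (clusters[a][b], a, b)
                    if best is None or key < best:
                        best = key
        d, a, b = best
        left, right = (a, b) if a <= b else (b, a)
        new = tuple(sorted(left + right))
        merges.append((left, right, d))
        heights[new] = d
        children[new] = (left, right)
        na, nb = sizes[a], sizes[b]
        new_d: dict[tuple[str, ...], float] = {}
        for other in clusters:
            if other in (a, b):
                continue
            if linkage == "average":
                nd = (na * clusters[a][other] + nb * clusters[b][other]) / (na + nb)
            elif linkage == "complete":
                nd = max(clusters[a][other], clusters[b][other])
            else:
                nd = min(clusters[a][other], clusters[b][other])
            new_d[other] = nd
        del clusters[a]
        del clusters[b]
        for other in list(clusters):
            clusters[other].pop(a, None)
            clusters[other].pop(b, None)
            clusters[other][new] = new_d[other]
        clusters[new] = new_d
        sizes[new] = na + nb

    newick = _newick(children, heights)
    return CohortDendrogram(
        name=name,
        cohort_ids=ids,
        n_shared_genes=n_shared_genes,
        distance=dist,
        merges=merges,
        newick=newick,
    )


def pathway_panel(
    de_tables: list[DETable],
    catalog: GeneCatalog | None,
    pathways: list[str] | None = None,
    linkage: str = "average",
    de_only: bool = False,
) -> tuple[dict[str, CohortDendrogram], dict[str, str]]:
    """One dendrogram for all genes plus one per pathway.

    Per-pathway failures (e.g. too few shared genes) are collected in the
    returned error map; the panel continues.
    """
    panel: dict[str, CohortDendrogram] = {}
    errors: dict[str, str] = {}
    dist, n_shared = fold_change_distance(de_tables, None, de_only=de_only)
    panel["all_genes"] = cluster_cohorts(
        dist, linkage=linkage, name="all_genes", n_shared_genes=n_shared
    )
    if pathways is None:
        pathways = catalog.sets_of_kind("pathway") if catalog is not None else []
    for pw in pathways:
        if catalog is None or pw not in catalog.sets:
            errors[pw] = "unknown pathway"
            continue
        if catalog.set_kind.get(pw) != "pathway":
            errors[pw] = "set is not of kind pathway"
            continue
        try:
            dist, n_shared = fold_change_distance(
                de_tables, catalog.sets[pw], de_only=de_only, subset_name=pw
            )
        except ValueError as exc:
            errors[pw] = str(exc)
            logger.warning("pathway %r skipped: %s", pw, exc)
            continue
        panel[pw] = cluster_cohorts(
            dist, linkage=linkage, name=pw, n_shared_genes=n_shared
        )
    return panel, errors
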