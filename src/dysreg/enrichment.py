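"""Hypergeometric enrichment/depletion of gene categories in DE sets,
and the tissue-specific-gene direction analysis.

For a cohort with universe size N (its measured genes), a category of size
K and a DE set of size n overlapping the category in k genes, the
enrichment p-value is the upper tail P(X >= k) and the depletion p-value
the lower tail P(X <= k) of X ~ Hypergeometric(N, K, n).  Both tails
include the observed count, so they overlap in P(X = k).  No correction is
applied across the category x cohort matrix; cells are labeled enriched /
depleted / neither at a display threshold (default 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DETable
from .io import GeneCatalog

logger = logging.getLogger(__name__)


def hypergeom_enrichment(N: int, K: int, n: int, k: int) -> tuple[float, float]:
    """Upper and lower tail probabilities of the hypergeometric overlap.

    Returns ``(p_enrich, p_deplete)`` = (P(X >= k), P(X <= k)) for
    X ~ Hypergeometric(N, K, n).  Validates the support bounds.
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if K > N:
        raise ValueError(f"K={K} exceeds N={N}")
    if n > N:
        raise ValueError(f"n={n} exceeds N={N}")
    lo, hi = max(0, n + K - N), min(K, n)
    if not lo <= k <= hi:
        raise ValueError(f"k={k} outside support [{lo}, {hi}] for N={N}, K={K}, n={n}")
    dist = stats.hypergeom(N, K, n)
    p_enrich = float(dist.sf(k - 1))
    p_deplete = float(dist.cdf(k))
    return min(1.0, p_enrich), min(1.0, p_deplete)


@dataclass
class EnrichmentCell:
    """One category x cohort enrichment/depletion result."""

    cohort_id: str
    set_name: str
    N: int
    K: int
    n: int
    k: int
    p_enrich: float
    p_deplete: float
    direction: str  # enriched | depleted | neither

    @staticmethod
    def direction_at(p_enrich: float, p_deplete: float, threshold: float) -> str:
        if p_enrich <= threshold and p_enrich <= p_deplete:
            return "enriched"
        if p_deplete <= threshold:
            return "depleted"
        return "neither"


def enrichment_cell(
    de: DETable, catalog: GeneCatalog, set_name: str, threshold: float = 0.05
) -> EnrichmentCell:
    if set_name not in catalog.sets:
        raise KeyError(f"unknown set {set_name!r}")
    universe = de.universe()
    members = catalog.sets[set_name] & universe
    de_genes = de.de_genes()
    N, K, n = len(universe), len(members), len(de_genes)
    k = len(members & de_genes)
    p_enrich, p_deplete = hypergeom_enrichment(N, K, n, k)
    return EnrichmentCell(
        cohort_id=de.cohort_id,
        set_name=set_name,
        N=N, K=K, n=n, k=k,
        p_enrich=p_enrich,
        p_deplete=p_deplete,
        direction=EnrichmentCell.direction_at(p_enrich, p_deplete, threshold),
    )


def enrichment_matrix(
    de_tables: list[DETable],
    catalog: GeneCatalog,
    sets: list[str],
    threshold: float = 0.05,
) -> pd.DataFrame:
    """One row per (cohort, set) with counts, both tail p-values and the
    direction at ``threshold``.  Overlaps are counted on each cohort's own
    universe (restrict the catalog with ``intersect_universe`` upstream if
    it contains unmeasured genes)."""
    rows = []
    for de in de_tables:
        for s in sets:
            cell = enrichment_cell(de, catalog, s, threshold)
            rows.append(
                {
                    "cohort_id": cell.cohort_id,
                    "set_name": cell.set_name,
                    "N": cell.N, "K": cell.K, "n": cell.n, "k": cell.k,
                    "p_enrich": cell.p_enrich,
                    "p_deplete": cell.p_deplete,
                    "direction": cell.direction,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class TissueReport:
    """Direction analysis of a cohort's matched tissue-specific gene set.

    Among the DE tissue genes: ``frac_under`` is the under-expressed
    fraction, ``sign_test_p`` an exact two-sided binomial test of that
    fraction against 0.5, and ``ranksum_p`` a one-sided rank-sum test that
    the signed log2 fold changes of DE tissue genes lie below those of the
    other DE genes.
    """

    cohort_id: str
    tissue_set: str
    cell: EnrichmentCell
    n_de_tissue: int
    n_under: int
    frac_under: float
    sign_test_p: float
    ranksum_p: float

    def to_dict(self) -> dict:
        return {
            "cohort_id": self.cohort_id,
            "tissue_set": self.tissue_set,
            "N": self.cell.N, "K": self.cell.K,
            "n": self.cell.n, "k": self.cell.k,
            "p_enrich": self.cell.p_enrich,
            "p_deplete": self.cell.p_deplete,
            "direction": self.cell.direction,
            "n_de_tissue": self.n_de_tissue,
            "n_under": self.n_under,
            "frac_under": self.frac_under,
            "sign_test_p": self.sign_test_p,
            "ranksum_p": self.ranksum_p,
        }


def tissue_specificity(
    de: DETable, catalog: GeneCatalog, cohort_id: str | None = None,
    threshold: float = 0.05,
) -> TissueReport | None:
    """Tissue-specific-gene report for the cohort's matched tissue set.

    Returns None (with a log message) when the catalog maps no tissue set
    to the cohort.
    """
    cid = cohort_id if cohort_id is not None else de.cohort_id
    set_name = catalog.tissue_set_for(cid)
    if set_name is None:
        logger.warning("no tissue set mapped to cohort %r; report skipped", cid)
        return None
    cell = enrichment_cell(de, catalog, set_name, threshold)
    de_tissue = sorted(catalog.sets[set_name] & de.de_genes())
    fc = de.table["log2fc"]
    n_de_tissue = len(de_tissue)
    n_under = int((fc.loc[de_tissue] < 0).sum())
    frac_under = n_under / n_de_tissue if n_de_tissue else float("nan")
    if n_de_tissue:
        sign_p = float(stats.binomtest(n_under, n_de_tissue, 0.5).pvalue)
    else:
        sign_p = float("nan")
    other_de = sorted(de.de_genes() - set(de_tissue))
    if n_de_tissue and other_de:
        ranksum_p = float(
            stats.mannwhitneyu(
                fc.loc[de_tissue], fc.loc[other_de], alternative="less"
            ).pvalue
        )
    else:
        ranksum_p = float("nan")
    return TissueReport(
        cohort_id=cid,
        tissue_set=set_name,
        cell=cell,
        n_de_tissue=n_de_tissue,
        n_under=n_under,
        frac_under=frac_under,
        sign_test_p=sign_p,
        ranksum_p=ranksum_p,
    )
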