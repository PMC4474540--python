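"""RBP cascade analysis: top fold-change RBPs whose direct PPI partners
are jointly enriched for DE genes and cancer-related (allOnco) genes.

Ranking keeps DE RBPs only, ordered by |log2fc| descending with ties broken
by adjusted p ascending then symbol.  For each ranked RBP two one-sided
hypergeometric tests are run over the universe of cohort-measured genes
that are network nodes: DE genes among the RBP's first neighbors, and
allOnco genes among them.  An RBP is a cascade RBP when both enrichment
p-values fall below the threshold; the exported subnetwork keeps the
selected RBPs and their neighbors that are both DE and allOnco.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .diffexpr import DETable
from .enrichment import hypergeom_enrichment
from .io import GeneCatalog, PPINetwork

logger = logging.getLogger(__name__)


def rank_rbps(
    de: DETable,
    catalog: GeneCatalog,
    top_k: int = 20,
    rbp_set: str = "RBP",
    de_only: bool = True,
) -> list[str]:
    """DE RBPs sorted by |log2fc| descending, truncated to ``top_k``.

    Ties are broken by adjusted p ascending, then symbol lexicographic.
    With ``de_only=False`` all RBPs are ranked regardless of significance.
    """
    if rbp_set not in catalog.sets:
        raise KeyError(f"unknown set {rbp_set!r}")
    pool = catalog.sets[rbp_set] & de.universe()
    if de_only:
        pool = pool & de.de_genes()
    tab = de.table.loc[sorted(pool)]
    order = sorted(
        tab.index,
        key=lambda g: (-abs(tab.at[g, "log2fc"]), tab.at[g, "p_adj"], g),
    )
    if len(order) < top_k:
        logger.warning(
            "only %d ranked RBPs available for top_k=%d", len(order), top_k
        )
    return order[:top_k]


def neighborhood(network: PPINetwork, gene: str) -> set[str]:
    """First neighbors of ``gene`` (excluding itself); empty with a warning
    when the gene is not a network node."""
    if gene not in network.nodes:
        logger.warning("gene %r absent from the network", gene)
        return set()
    return network.neighbors(gene)


@dataclass
class CascadeResult:
    cohort_id: str
    stats: pd.DataFrame  # per ranked RBP: rank, n_neighbors, k_de, k_onco, p values, selected
    selected: list[str]
    subnetwork: PPINetwork
    node_roles: dict[str, str]  # gene -> "rbp" | "allOnco-target"
    universe_size: int

    def stats_tsv(self, path: str) -> None:
        out = self.stats.copy()
        out.index.name = "rbp"
        out.to_csv(path, sep="\t")


def cascade_select(
    de: DETable,
    catalog: GeneCatalog,
    network: PPINetwork,
    top_k: int = 20,
    threshold: float = 0.05,
    rbp_set: str = "RBP",
    onco_set: str = "allOnco",
    de_only: bool = True,
) -> CascadeResult:
    """Run the dual-enrichment cascade selection on one cohort."""
    if onco_set not in catalog.sets:
        raise KeyError(f"unknown set {onco_set!r}")
    universe = de.universe() & network.nodes
    N = len(universe)
    de_in_u = de.de_genes() & universe
    onco_in_u = catalog.sets[onco_set] & universe
    ranked = rank_rbps(de, catalog, top_k=top_k, rbp_set=rbp_set, de_only=de_only)

    rows = []
    selected: list[str] = []
    sub_edges: set[tuple[str, str]] = set()
    node_roles: dict[str, str] = {}
    for rank, rbp in enumerate(ranked, start=1):
        neigh = neighborhood(network, rbp) & universe
        n = len(neigh)
        k_de = len(neigh & de_in_u)
        k_onco = len(neigh & onco_in_u)
        if n == 0:
            p_de = p_onco = 1.0
        else:
            p_de, _ = hypergeom_enrichment(N, len(de_in_u), n, k_de)
            p_onco, _ = hypergeom_enrichment(N, len(onco_in_u), n, k_onco)
        sel = bool(p_de < threshold and p_onco < threshold)
        rows.append(
            {
                "rank": rank,
                "log2fc": float(de.table.at[rbp, "log2fc"]),
                "p_adj": float(de.table.at[rbp, "p_adj"]),
                "n_neighbors": n,
                "k_de": k_de,
                "k_onco": k_onco,
                "p_enrich_de": p_de,
                "p_enrich_onco": p_onco,
                "selected": sel,
            }
        )
        if sel:
            selected.append(rbp)
            node_roles[rbp] = "rbp"
            for partner in sorted(neigh & de_in_u & onco_in_u):
                node_roles.setdefault(partner, "allOnco-target")
                sub_edges.add((rbp, partner) if rbp <= partner else (partner, rbp))
    stats = pd.DataFrame(rows, index=pd.Index(ranked, name="rbp"))
    subnetwork = PPINetwork(nodes=set(node_roles), edges=sub_edges)
    return CascadeResult(
        cohort_id=de.cohort_id,
        stats=stats,
        selected=selected,
        subnetwork=subnetwork,
        node_roles=node_roles,
        universe_size=N,
    )
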