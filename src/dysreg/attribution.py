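"""Genetic vs epigenetic attribution of RBP expression changes.

For each RBP, the per-patient log2 expression change (tumor vs matched
normal, with pseudocount) is correlated with the gene's value in the
tumor-sample CNV or methylation matrix using Spearman's rank correlation;
R^2 is the squared correlation.  DE and non-DE RBPs are then compared with
a one-sided Wilcoxon rank-sum test of the alternative that DE RBPs have
larger R^2 — the contrast that separates a genetically driven expression
change (CNV coupled) from an epigenetically neutral one.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DETable
from .io import GeneCatalog, MolecularMatrix, PairedCohort


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman correlation (Pearson on average ranks; tie-robust).

    Returns NaN when either vector has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


@dataclass
class AttributionResult:
    cohort_id: str
    assay: str
    rows: pd.DataFrame  # per RBP: n_samples, rho, r_squared, de_status
    excluded: dict[str, int]  # reason -> count

    def to_tsv(self, path: str) -> None:
        out = self.rows.copy()
        out.index.name = "rbp"
        out.to_csv(path, sep="\t")


def per_gene_attribution(
    cohort: PairedCohort,
    mat: MolecularMatrix,
    de: DETable,
    catalog: GeneCatalog,
    min_samples: int = 8,
    rbp_set: str = "RBP",
    pseudocount: float = 1.0,
) -> AttributionResult:
    """Spearman rho / R^2 of expression change vs assay value per RBP.

    RBPs absent from the matrix, with fewer than ``min_samples`` matched
    tumor samples, or with zero variance in either vector are excluded and
    counted in ``excluded``.
    """
    if rbp_set not in catalog.sets:
        raise KeyError(f"unknown set {rbp_set!r}")
    gene_idx = cohort.gene_index()
    mat_idx = mat.gene_index()
    mat_samples = {s: j for j, s in enumerate(mat.samples)}
    # match pairs to assay columns via the tumor sample id
    matched = [
        (pi, mat_samples[tcol])
        for pi, (_, tcol, _) in enumerate(cohort.pairs)
        if tcol in mat_samples
    ]
    tumor = cohort.tumor_matrix()
    normal = cohort.normal_matrix()
    pair_idx = [pi for pi, _ in matched]
    col_idx = [cj for _, cj in matched]
    rbps = sorted(catalog.sets[rbp_set] & set(cohort.genes))
    de_genes = de.de_genes()
    rows = []
    kept: list[str] = []
    excluded = {"absent_from_matrix": 0, "too_few_samples": 0, "degenerate": 0}
    for g in rbps:
        if g not in mat_idx:
            excluded["absent_from_matrix"] += 1
            continue
        if len(matched) < min_samples:
            excluded["too_few_samples"] += 1
            continue
        gi = gene_idx[g]
        x = np.log2(
            (tumor[gi, pair_idx] + pseudocount)
            / (normal[gi, pair_idx] + pseudocount)
        )
        y = mat.values[mat_idx[g], col_idx]
        rho = spearman_rho(x, y)
        if np.isnan(rho):
            excluded["degenerate"] += 1
            continue
        kept.append(g)
        rows.append(
            {
                "n_samples": len(matched),
                "spearman_rho": rho,
                "r_squared": rho * rho,
                "de_status": g in de_genes,
            }
        )
    frame = pd.DataFrame(rows, index=pd.Index(kept, name="rbp"))
    if frame.empty:
        frame = pd.DataFrame(
            columns=["n_samples", "spearman_rho", "r_squared", "de_status"],
            index=pd.Index([], name="rbp"),
        )
    return AttributionResult(
        cohort_id=cohort.cohort_id, assay=mat.assay, rows=frame, excluded=excluded
    )


def _exact_ranksum_p(de_vals: np.ndarray, other_vals: np.ndarray) -> tuple[float, float]:
    """Exact one-sided rank-sum p by enumerating all rank assignments.

    Uses midranks for ties; p = P(W >= w_obs) under the permutation null.
    """
    pooled = np.concatenate([de_vals, other_vals])
    ranks = stats.rankdata(pooled)
    n1 = de_vals.size
    w_obs = float(ranks[:n1].sum())
    total = 0
    ge = 0
    idx = range(pooled.size)
    for comb in combinations(idx, n1):
        total += 1
        if ranks[list(comb)].sum() >= w_obs - 1e-9:
            ge += 1
    return w_obs, ge / total


def compare_groups(
    result: AttributionResult | pd.DataFrame, alternative: str = "greater"
) -> tuple[float, float]:
    """Rank-sum comparison of R^2 between DE and non-DE RBPs.

    Returns ``(W, p)`` with W the rank-sum statistic of the DE group.
    Exact null enumeration when both groups have <= 10 members, normal
    approximation with tie correction otherwise.
    """
    rows = result.rows if isinstance(result, AttributionResult) else result
    de_vals = rows.loc[rows["de_status"], "r_squared"].to_numpy()
    other_vals = rows.loc[~rows["de_status"], "r_squared"].to_numpy()
    if de_vals.size == 0:
        raise ValueError("DE group is empty")
    if other_vals.size == 0:
        raise ValueError("non-DE group is empty")
    if alternative not in ("greater", "two-sided", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if de_vals.size <= 10 and other_vals.size <= 10 and alternative == "greater":
        return _exact_ranksum_p(de_vals, other_vals)
    res = stats.mannwhitneyu(
        de_vals, other_vals, alternative=alternative, method="asymptotic"
    )
    w = float(res.statistic) + de_vals.size * (de_vals.size + 1) / 2.0
    return w, float(res.pvalue)
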