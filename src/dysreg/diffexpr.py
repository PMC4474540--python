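"""Paired differential expression per cohort.

A gene is tested with a paired two-sided t-test on log2(x + pseudocount)
transformed values of the matched tumor/normal pairs; p-values are
Bonferroni-adjusted over all genes tested in the cohort and a gene is
called differentially expressed (DE) when the adjusted p falls below
``alpha``.  The per-gene fold change is the mean over pairs of the log2
ratio (tumor + c) / (normal + c), which for log-transformed data is exactly
the mean paired difference the t-test examines.

Genes whose tumor and normal vectors are identical are retained with
p = 1 (never DE), so the tested universe is stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import FormatError, GeneCatalog, PairedCohort

DE_COLUMNS = [
    "mean_normal", "mean_tumor", "log2fc", "t_stat", "p_raw", "p_adj", "is_de",
]


@dataclass
class DETable:
    """Per-gene paired-test results for one cohort.

    ``table`` is indexed by gene symbol with columns ``mean_normal``,
    ``mean_tumor``, ``log2fc``, ``t_stat`` (NaN when the paired differences
    are all zero), ``p_raw``, ``p_adj`` and boolean ``is_de``.
    """

    cohort_id: str
    table: pd.DataFrame
    alpha: float = 0.05
    pseudocount: float = 1.0

    def de_genes(self) -> set[str]:
        return set(self.table.index[self.table["is_de"]])

    def universe(self) -> set[str]:
        return set(self.table.index)

    def log2fc(self) -> pd.Series:
        return self.table["log2fc"]

    def to_tsv(self, path: str) -> None:
        from .io import _float_repr

        out = self.table.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format=_float_repr)

    @classmethod
    def from_tsv(cls, path: str, cohort_id: str | None = None,
                 alpha: float = 0.05, pseudocount: float = 1.0) -> "DETable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        missing = [c for c in DE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"DE table {path} missing columns {missing}")
        df["is_de"] = df["is_de"].astype(bool)
        if cohort_id is None:
            import os

            cohort_id = os.path.basename(path).split("_")[0]
        return cls(cohort_id=cohort_id, table=df, alpha=alpha,
                   pseudocount=pseudocount)


def paired_log2fc(
    tumor: np.ndarray, normal: np.ndarray, pseudocount: float = 1.0
) -> float:
    """Mean over pairs of log2((T_i + c) / (N_i + c))."""
    tumor = np.asarray(tumor, dtype=float)
    normal = np.asarray(normal, dtype=float)
    if tumor.shape != normal.shape or tumor.ndim != 1 or tumor.size < 1:
        raise ValueError("tumor and normal must be equal-length vectors")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return float(np.mean(np.log2(tumor + pseudocount) - np.log2(normal + pseudocount)))


def paired_t_test(
    tumor: np.ndarray, normal: np.ndarray, pseudocount: float = 1.0
) -> tuple[float, float]:
    """Two-sided paired t-test on log2(x + pseudocount) values.

    Returns ``(t_stat, p_raw)``; ``t_stat`` is NaN with p = 1 when every
    paired difference is exactly zero, and +/-inf with p = 0 when the
    differences are constant but non-zero.
    """
    tumor = np.asarray(tumor, dtype=float)
    normal = np.asarray(normal, dtype=float)
    if tumor.shape != normal.shape or tumor.ndim != 1:
        raise ValueError("tumor and normal must be equal-length vectors")
    n = tumor.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    diffs = np.log2(tumor + pseudocount) - np.log2(normal + pseudocount)
    sd = float(np.std(diffs, ddof=1))
    mean = float(np.mean(diffs))
    if sd == 0.0:
        if mean == 0.0:
            return float("nan"), 1.0
        return float(np.sign(mean)) * float("inf"), 0.0
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return float(t), min(1.0, p)


def bonferroni(p_raw: np.ndarray) -> np.ndarray:
    """Bonferroni adjustment: p_adj_i = min(1, p_i * m)."""
    p = np.asarray(p_raw, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


def call_de(
    cohort: PairedCohort,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> DETable:
    """Run the paired test and fold-change computation for every gene."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    tumor = cohort.tumor_matrix()
    normal = cohort.normal_matrix()
    n = cohort.n_pairs
    diffs = np.log2(tumor + pseudocount) - np.log2(normal + pseudocount)
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    # degenerate rows: constant differences
    const = sd == 0.0
    zero_const = const & (mean == 0.0)
    shift_const = const & (mean != 0.0)
    t = np.where(zero_const, np.nan, t)
    p = np.where(zero_const, 1.0, p)
    t = np.where(shift_const, np.where(mean > 0, np.inf, -np.inf), t)
    p = np.where(shift_const, 0.0, p)
    p = np.minimum(1.0, p)
    p_adj = bonferroni(p)
    table = pd.DataFrame(
        {
            "mean_normal": normal.mean(axis=1),
            "mean_tumor": tumor.mean(axis=1),
            "log2fc": mean,
            "t_stat": t,
            "p_raw": p,
            "p_adj": p_adj,
            "is_de": p_adj < alpha,
        },
        index=pd.Index(cohort.genes, name="gene"),
    )
    return DETable(cohort_id=cohort.cohort_id, table=table, alpha=alpha,
                   pseudocount=pseudocount)


@dataclass
class AmplitudeProfile:
    """|log2fc| distributions of DE genes per gene set (the CDF comparison).

    ``values`` maps set name -> sorted array of |log2fc| of that set's DE
    genes; sets with zero DE genes are present with an empty array and
    listed in ``empty_sets``.
    """

    cohort_id: str
    values: dict[str, np.ndarray]
    empty_sets: list[str]

    def ecdf(self, set_name: str, x: float) -> float:
        v = self.values[set_name]
        if v.size == 0:
            raise ValueError(f"set {set_name!r} has no DE genes")
        return float(np.searchsorted(v, x, side="right") / v.size)

    def compare(
        self, larger: str, smaller: str, alternative: str = "greater"
    ) -> tuple[float, float]:
        """One-sided rank-sum test that ``larger``'s |log2fc| exceed
        ``smaller``'s; returns (U statistic, p)."""
        a, b = self.values[larger], self.values[smaller]
        if a.size == 0 or b.size == 0:
            raise ValueError("both sets need at least one DE gene")
        res = stats.mannwhitneyu(a, b, alternative=alternative)
        return float(res.statistic), float(res.pvalue)


def amplitude_profiles(
    de: DETable, catalog: GeneCatalog, sets: list[str]
) -> AmplitudeProfile:
    """Collect |log2fc| of DE genes per set and expose ECDF / comparisons."""
    for s in sets:
        if s not in catalog.sets:
            raise KeyError(f"unknown set {s!r}")
    de_set = de.de_genes()
    abs_fc = de.table["log2fc"].abs()
    values: dict[str, np.ndarray] = {}
    empty: list[str] = []
    for s in sets:
        members = sorted(catalog.sets[s] & de_set)
        v = np.sort(abs_fc.loc[members].to_numpy()) if members else np.array([])
        values[s] = v
        if v.size == 0:
            empty.append(s)
    return AmplitudeProfile(cohort_id=de.cohort_id, values=values, empty_sets=empty)
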