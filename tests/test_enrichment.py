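"""Hypergeometric tails against exhaustive enumeration, the enrichment
matrix, and the tissue-specific direction report."""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from dysreg import (
    call_de,
    enrichment_cell,
    enrichment_matrix,
    hypergeom_enrichment,
    tissue_specificity,
)
from dysreg.diffexpr import DETable
from dysreg.io import GeneCatalog
from dysreg.simulate import generate
from conftest import tiny_config


def enumeration_tails(N, K, n, k):
    """Exact tail probabilities by counting all C(N, n) draws (Fractions)."""
    ge = le = 0
    for draw in combinations(range(N), n):
        overlap = sum(1 for x in draw if x < K)
        if overlap >= k:
            ge += 1
        if overlap <= k:
            le += 1
    total = comb(N, n)
    return Fraction(ge, total), Fraction(le, total)


class TestHypergeomTails:
    def test_worked_case(self):
        # N=10, K=5, n=4, k=4: C(5,4)C(5,0)/C(10,4) = 5/210
        p_enr, _ = hypergeom_enrichment(10, 5, 4, 4)
        assert p_enr == pytest.approx(5 / 210, abs=1e-12)

    def test_symmetric_case(self):
        # N=20, K=10, n=10, k=5: p_enrich = (1 + P(X=5)) / 2
        p_enr, p_dep = hypergeom_enrichment(20, 10, 10, 5)
        p5 = comb(10, 5) ** 2 / comb(20, 10)
        assert p_enr == pytest.approx((1 + p5) / 2, abs=1e-10)
        assert p_enr == pytest.approx(0.67186, abs=5e-6)
        assert p_dep == pytest.approx((1 + p5) / 2, abs=1e-10)

    def test_zero_overlap_boundary(self):
        p_enr, p_dep = hypergeom_enrichment(30, 10, 5, 0)
        assert p_enr == 1.0
        assert p_dep == pytest.approx(
            comb(20, 5) / comb(30, 5), abs=1e-12
        )

    def test_support_violation_names_bound(self):
        with pytest.raises(ValueError, match="support"):
            hypergeom_enrichment(10, 5, 4, 5)
        with pytest.raises(ValueError, match="K=11 exceeds N=10"):
            hypergeom_enrichment(10, 11, 4, 2)

    def test_matches_enumeration_on_small_grid(self):
        # spot grid here; the exhaustive N <= 12 sweep lives in acceptance
        for N, K, n, k in [(8, 3, 4, 2), (9, 4, 5, 1), (10, 5, 5, 5),
                           (7, 7, 3, 3), (12, 6, 6, 3)]:
            p_enr, p_dep = hypergeom_enrichment(N, K, n, k)
            e_ge, e_le = enumeration_tails(N, K, n, k)
            assert p_enr == pytest.approx(float(e_ge), abs=1e-12)
            assert p_dep == pytest.approx(float(e_le), abs=1e-12)

    def test_complementarity_and_monotonicity(self):
        N, K, n = 40, 12, 15
        pmf = lambda k: comb(K, k) * comb(N - K, n - k) / comb(N, n)
        prev = None
        for k in range(0, min(K, n) + 1):
            p_enr, p_dep = hypergeom_enrichment(N, K, n, k)
            assert p_enr + p_dep - pmf(k) == pytest.approx(1.0, abs=1e-10)
            if prev is not None:
                assert p_enr <= prev + 1e-12
            prev = p_enr


def _de_table(universe, de_genes):
    table = pd.DataFrame(
        {
            "mean_normal": 1.0, "mean_tumor": 1.0, "log2fc": 0.5,
            "t_stat": 1.0, "p_raw": 0.5, "p_adj": 1.0,
            "is_de": [g in de_genes for g in universe],
        },
        index=pd.Index(universe, name="gene"),
    )
    return DETable(cohort_id="X", table=table)


def _catalog(universe, **sets):
    return GeneCatalog(
        universe=set(universe),
        sets={k: set(v) for k, v in sets.items()},
        set_kind={k: "category" for k in sets},
    )


class TestEnrichmentMatrix:
    def test_maximal_overlap(self):
        universe = [f"G{i}" for i in range(20)]
        de = _de_table(universe, set(universe[:5]))
        cat = _catalog(universe, S=universe[:5])
        cell = enrichment_cell(de, cat, "S")
        assert (cell.k, cell.n, cell.K) == (5, 5, 5)
        assert cell.p_enrich == pytest.approx(1 / comb(20, 5), abs=1e-12)
        assert cell.direction == "enriched"

    def test_disjoint_set_depleted(self):
        universe = [f"G{i}" for i in range(30)]
        de = _de_table(universe, set(universe[:15]))
        cat = _catalog(universe, S=universe[20:30])
        cell = enrichment_cell(de, cat, "S")
        assert cell.k == 0
        assert cell.direction == "depleted"

    def test_unknown_set_errors(self):
        universe = ["A", "B"]
        de = _de_table(universe, {"A"})
        with pytest.raises(KeyError):
            enrichment_matrix([de], _catalog(universe, S=["A"]), ["nope"])

    def test_matrix_shape_and_counts(self, tiny_sim):
        des = [call_de(c) for c in tiny_sim.cohorts]
        sets = sorted(tiny_sim.catalog.sets_of_kind("category"))
        mat = enrichment_matrix(des, tiny_sim.catalog, sets)
        assert len(mat) == len(des) * len(sets)
        row = mat.iloc[0]
        assert row["N"] == len(tiny_sim.cohorts[0].genes)
        assert 0 <= row["k"] <= min(row["K"], row["n"])

    def test_null_category_p_values_roughly_uniform(self):
        # calibration: a category independent of DE status gives a
        # Kolmogorov-consistent enrichment p distribution
        rng = np.random.default_rng(0)
        universe = [f"G{i}" for i in range(400)]
        ps = []
        for _ in range(200):
            de_genes = set(rng.choice(universe, size=80, replace=False))
            members = set(rng.choice(universe, size=50, replace=False))
            de = _de_table(universe, de_genes)
            cat = _catalog(universe, S=members)
            ps.append(enrichment_cell(de, cat, "S").p_enrich)
        from scipy import stats

        # discrete p-values are super-uniform; test only the one-sided
        # "too many small p" direction
        ecdf = np.mean(np.asarray(ps)[:, None] <= np.linspace(0.05, 0.95, 19), axis=0)
        assert np.all(ecdf <= np.linspace(0.05, 0.95, 19) + 1.36 / np.sqrt(200))


class TestTissueSpecificity:
    def _with_tissue(self, universe, tissue_genes, cohort_id="X"):
        cat = GeneCatalog(
            universe=set(universe),
            sets={"tissue_X": set(tissue_genes)},
            set_kind={"tissue_X": "tissue"},
            tissue_to_cohort={"tissue_X": cohort_id},
        )
        return cat

    def test_counting(self):
        universe = [f"G{i}" for i in range(20)]
        de_genes = {"G0", "G1", "G2"}
        table = pd.DataFrame(
            {
                "mean_normal": 1.0, "mean_tumor": 1.0,
                "log2fc": [-1.0, -2.0, 0.5] + [0.0] * 17,
                "t_stat": 1.0, "p_raw": 0.5, "p_adj": 1.0,
                "is_de": [g in de_genes for g in universe],
            },
            index=pd.Index(universe, name="gene"),
        )
        de = DETable(cohort_id="X", table=table)
        rep = tissue_specificity(de, self._with_tissue(universe, de_genes))
        assert rep.n_de_tissue == 3 and rep.n_under == 2
        assert rep.frac_under == pytest.approx(2 / 3)

    def test_all_negative_sign_test(self):
        universe = [f"G{i}" for i in range(40)]
        tissue = universe[:10]
        fc = [-1.0] * 10 + [1.0] * 30
        table = pd.DataFrame(
            {
                "mean_normal": 1.0, "mean_tumor": 1.0, "log2fc": fc,
                "t_stat": 1.0, "p_raw": 0.5, "p_adj": 1.0, "is_de": True,
            },
            index=pd.Index(universe, name="gene"),
        )
        de = DETable(cohort_id="X", table=table)
        rep = tissue_specificity(de, self._with_tissue(universe, tissue))
        assert rep.sign_test_p == pytest.approx(2 * 0.5**10, rel=1e-9)
        assert rep.ranksum_p < 1e-4

    def test_missing_tissue_set_skipped(self, caplog):
        universe = ["A", "B", "C"]
        de = _de_table(universe, {"A"})
        cat = _catalog(universe, S=["A"])
        with caplog.at_level("WARNING"):
            assert tissue_specificity(de, cat, "X") is None

    def test_planted_under_fraction_recovered(self):
        cfg = tiny_config(seed=17, n_genes=1000, tissue_set_size=200,
                          n_pairs=30)
        res = generate(cfg)
        de = call_de(res.cohorts[0])
        rep = tissue_specificity(de, res.catalog, "C1")
        assert rep.cell.p_enrich < 1e-6
        assert rep.frac_under == pytest.approx(cfg.tissue_under_frac, abs=0.1)
        assert rep.sign_test_p < 1e-6
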