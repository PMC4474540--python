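"""Paired t-test, fold change, Bonferroni and amplitude profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from dysreg import (
    amplitude_profiles,
    bonferroni,
    call_de,
    null_cohort,
    paired_log2fc,
    paired_t_test,
)
from dysreg.simulate import generate
from conftest import tiny_config


def from_log2_diffs(diffs):
    """Tumor/normal vectors whose log2(x+1) paired differences equal diffs."""
    diffs = np.asarray(diffs, dtype=float)
    normal = np.ones_like(diffs)  # log2(N+1) = 1
    tumor = 2.0 ** (1.0 + diffs) - 1.0
    return tumor, normal


class TestPairedLog2FC:
    def test_identity(self):
        assert paired_log2fc([3.0, 5.0], [3.0, 5.0]) == 0.0

    def test_exact_arithmetic(self):
        assert paired_log2fc([3.0, 3.0], [1.0, 1.0], pseudocount=1.0) == 1.0

    def test_matches_elementwise_recomputation(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 30))
            t = rng.gamma(2, 30, n)
            m = rng.gamma(2, 30, n)
            expected = np.mean([np.log2((a + 1) / (b + 1)) for a, b in zip(t, m)])
            assert paired_log2fc(t, m) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_log2fc([1.0], [1.0, 2.0])


class TestPairedTTest:
    def test_worked_case_df2(self):
        # differences (1, 2, 3): t = 2*sqrt(3), two-sided p from the exact
        # df=2 CDF, F(t) = (1 + t / sqrt(t^2 + 2)) / 2
        t_obs, p = paired_t_test(*from_log2_diffs([1.0, 2.0, 3.0]))
        assert t_obs == pytest.approx(2 * np.sqrt(3), rel=1e-9)
        p_closed = 1.0 - 2 * np.sqrt(3) / np.sqrt(12 + 2)
        assert p == pytest.approx(p_closed, rel=1e-9)
        assert p == pytest.approx(0.074180, abs=5e-7)

    def test_all_zero_differences(self):
        t_obs, p = paired_t_test([4.0, 4.0, 4.0], [4.0, 4.0, 4.0])
        assert np.isnan(t_obs) and p == 1.0

    def test_matches_quadrature_oracle(self, rng):
        # high-precision numerical integration of the t density
        for _ in range(100):
            n = int(rng.integers(3, 15))
            t_vec, n_vec = rng.gamma(2, 30, n), rng.gamma(2, 30, n)
            t_obs, p = paired_t_test(t_vec, n_vec)
            df = n - 1
            from scipy.special import gammaln

            const = np.exp(
                gammaln((df + 1) / 2) - gammaln(df / 2)
            ) / np.sqrt(df * np.pi)

            def density(u, df=df, const=const):
                return const * (1 + u * u / df) ** (-(df + 1) / 2)

            tail, _ = integrate.quad(density, abs(t_obs), np.inf)
            assert p == pytest.approx(2 * tail, abs=1e-8)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0], [2.0])


class TestBonferroni:
    def test_definition(self):
        np.testing.assert_allclose(bonferroni([0.01, 0.5]), [0.02, 1.0])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bonferroni([0.3]), [0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.5, 1.2])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_properties(self, ps):
        adj = bonferroni(ps)
        assert np.all(adj >= np.asarray(ps))
        assert np.all(adj <= 1.0)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestCallDE:
    def test_gene_order_invariance(self, tiny_sim):
        cohort = tiny_sim.cohorts[0]
        de = call_de(cohort)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(cohort.genes))
        from dysreg.io import PairedCohort

        shuffled = PairedCohort(
            cohort.cohort_id,
            [cohort.genes[i] for i in perm],
            cohort.samples,
            cohort.expr[perm, :],
            cohort.pairs,
        )
        de_shuffled = call_de(shuffled)
        joined = de.table.join(de_shuffled.table, rsuffix="_s")
        np.testing.assert_allclose(joined["p_raw"], joined["p_raw_s"])
        np.testing.assert_allclose(joined["log2fc"], joined["log2fc_s"])

    def test_planted_four_fold_shift_detected(self):
        # analytic power ~1 for a 4-fold shift at low noise
        c = null_cohort(200, 20, seed=3, noise_sd=0.1)
        expr = c.expr.copy()
        tumor_cols = [c.samples.index(t) for t in c.tumor_columns]
        expr[0, tumor_cols] *= 4.0
        from dysreg.io import PairedCohort

        boosted = PairedCohort(c.cohort_id, c.genes, c.samples, expr, c.pairs)
        de = call_de(boosted)
        assert de.table.iloc[0]["is_de"]
        assert de.table.iloc[0]["log2fc"] == pytest.approx(2.0, abs=0.2)

    def test_constant_gene_never_de(self):
        c = null_cohort(50, 5, seed=1)
        expr = c.expr.copy()
        expr[3, :] = 7.0
        from dysreg.io import PairedCohort

        flat = PairedCohort(c.cohort_id, c.genes, c.samples, expr, c.pairs)
        de = call_de(flat)
        row = de.table.iloc[3]
        assert np.isnan(row["t_stat"]) and row["p_raw"] == 1.0 and not row["is_de"]

    def test_scaling_tumor_raises_log2fc(self, tiny_sim):
        cohort = tiny_sim.cohorts[0]
        base = call_de(cohort).table["log2fc"].iloc[5]
        expr = cohort.expr.copy()
        tumor_cols = [cohort.samples.index(t) for t in cohort.tumor_columns]
        expr[5, tumor_cols] *= 3.0
        from dysreg.io import PairedCohort

        scaled = PairedCohort(
            cohort.cohort_id, cohort.genes, cohort.samples, expr, cohort.pairs
        )
        assert call_de(scaled).table["log2fc"].iloc[5] > base


class TestAmplitudeProfiles:
    def _profile_from_values(self, values_by_set):
        """Build a DETable-like scenario with prescribed DE |log2fc|."""
        from dysreg.io import GeneCatalog
        import pandas as pd
        from dysreg.diffexpr import DETable

        genes, fc, sets = [], [], {}
        for sname, vals in values_by_set.items():
            members = []
            for i, v in enumerate(vals):
                g = f"{sname}_{i}"
                genes.append(g)
                fc.append(v)
                members.append(g)
            sets[sname] = set(members)
        table = pd.DataFrame(
            {
                "mean_normal": 1.0, "mean_tumor": 1.0, "log2fc": fc,
                "t_stat": 5.0, "p_raw": 1e-9, "p_adj": 1e-6, "is_de": True,
            },
            index=pd.Index(genes, name="gene"),
        )
        catalog = GeneCatalog(
            universe=set(genes), sets=sets,
            set_kind={n: "category" for n in sets},
        )
        de = DETable(cohort_id="X", table=table)
        return amplitude_profiles(de, catalog, list(sets)), catalog

    def test_ecdf_definition(self):
        prof, _ = self._profile_from_values({"S": [1.0, 2.0, 3.0]})
        assert prof.ecdf("S", 2.0) == pytest.approx(2 / 3)

    def test_identical_sets_not_distinguishable(self):
        prof, _ = self._profile_from_values(
            {"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0]}
        )
        _, p = prof.compare("A", "B", alternative="two-sided")
        assert p > 0.9

    def test_planted_scale_separation_detected(self):
        cfg = tiny_config(
            seed=31, n_genes=2000, n_pairs=30,
            category_sizes={"RBP": 300, "allOnco": 300},
            de_prob={"other": 0.0, "RBP": 0.5, "allOnco": 0.5},
            effect_scale={"other": 1.0, "RBP": 1.0, "allOnco": 2.6},
            n_hub_rbps=0, tissue_set_size=0,
            similar_cohort_pairs=[], pathway_sizes={},
        )
        res = generate(cfg)
        de = call_de(res.cohorts[0])
        prof = amplitude_profiles(de, res.catalog, ["allOnco", "RBP"])
        _, p = prof.compare("allOnco", "RBP")
        assert p < 0.01
        # stochastic dominance of the ECDFs at a mid amplitude
        assert prof.ecdf("allOnco", 1.5) < prof.ecdf("RBP", 1.5)

    def test_empty_set_flagged(self):
        prof, _ = self._profile_from_values({"A": [1.0], "B": []})
        assert prof.empty_sets == ["B"]
        with pytest.raises(ValueError):
            prof.ecdf("B", 1.0)
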