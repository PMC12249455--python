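"""Correlations, reference-gene partition, pathway score, Mann-Whitney."""

import numpy as np
import pandas as pd
import pytest

from bimodalsurv import (
    correlation_matrix,
    group_compare,
    partition_by_reference,
    pathway_average_survival,
    pearson_correlation,
    univariate_cox,
    median_dichotomize,
)


class TestPearson:
    def test_perfect_correlation(self, rng):
        x = rng.normal(size=20)
        assert pearson_correlation(x, x)["r"] == pytest.approx(1.0)

    def test_affine_anticorrelation(self, rng):
        x = rng.normal(size=20)
        res = pearson_correlation(x, -2 * x + 7)
        assert res["r"] == pytest.approx(-1.0)

    def test_symmetry_and_missing_pairs(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        x[3] = np.nan
        a, b = pearson_correlation(x, y), pearson_correlation(y, x)
        assert a["r"] == pytest.approx(b["r"])
        assert a["n"] == 29

    def test_degenerate_inputs(self, rng):
        with pytest.raises(ValueError):
            pearson_correlation(np.ones(10), rng.normal(size=10))
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 2.0], [3.0, 4.0])

    def test_null_rejection_rate(self, rng):
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            if pearson_correlation(rng.normal(size=112), rng.normal(size=112))["p"] < 0.05:
                hits += 1
        assert 0.02 <= hits / n_rep <= 0.08


class TestPartition:
    def _matrix(self, rng):
        ref = rng.normal(4, 1, 112)
        data = {
            "MKI67": ref,
            "CLONE": ref + rng.normal(0, 0.3, 112),
            "INDEP": rng.normal(4, 1, 112),
        }
        return pd.DataFrame(data).T

    def test_partition_is_disjoint_and_complete(self, rng):
        m = self._matrix(rng)
        part = partition_by_reference(["CLONE", "INDEP"], m, "MKI67", 0.3)
        assert set(part["low_correlated"]) | set(part["high_correlated"]) == {
            "CLONE",
            "INDEP",
        }
        assert not set(part["low_correlated"]) & set(part["high_correlated"])
        assert part["low_correlated"] == ["INDEP"]
        assert part["high_correlated"] == ["CLONE"]

    def test_identical_gene_always_high(self, rng):
        m = self._matrix(rng)
        m.loc["SAME"] = m.loc["MKI67"]
        part = partition_by_reference(["SAME"], m, "MKI67", 0.99)
        assert part["high_correlated"] == ["SAME"]

    def test_zero_threshold_empties_low_set(self, rng):
        m = self._matrix(rng)
        part = partition_by_reference(["CLONE", "INDEP"], m, "MKI67", 0.0)
        assert part["low_correlated"] == []

    def test_missing_reference_rejected(self, rng):
        with pytest.raises(ValueError, match="reference"):
            partition_by_reference(["A"], self._matrix(rng), "NOPE", 0.3)


class TestPathwayScore:
    def test_single_gene_set_equals_gene_result(self, small_cohort):
        c = small_cohort
        gene = "BIM0000"
        res = pathway_average_survival(c.expression, c.clinical, [gene])
        lab = median_dichotomize(c.expression.loc[gene].to_numpy())
        direct = univariate_cox(lab, c.clinical["os_time"], c.clinical["os_event"])
        assert res["hr"] == pytest.approx(direct["hr"])
        assert res["p_logrank"] == pytest.approx(direct["p_logrank"])

    def test_score_is_mean_and_order_invariant(self, small_cohort):
        c = small_cohort
        genes = ["BIM0000", "BIM0001", "BIM0002"]
        r1 = pathway_average_survival(c.expression, c.clinical, genes)
        r2 = pathway_average_survival(c.expression, c.clinical, genes[::-1])
        assert r1["hr"] == pytest.approx(r2["hr"])
        s = r1["pathway_score"]
        lo = c.expression.loc[genes].min()
        hi = c.expression.loc[genes].max()
        assert ((s >= lo - 1e-12) & (s <= hi + 1e-12)).all()

    def test_averaging_coregulated_genes_strengthens_signal(self, small_cohort):
        # planted genes share one membership: averaging cancels noise
        c = small_cohort
        genes = [f"BIM{i:04d}" for i in range(10)]
        avg = pathway_average_survival(c.expression, c.clinical, genes)
        single = pathway_average_survival(c.expression, c.clinical, [genes[0]])
        assert avg["hr"] > 1
        assert avg["p_logrank"] <= single["p_logrank"] * 10

    def test_noise_gene_set_is_null(self, null_cohort):
        c = null_cohort
        res = pathway_average_survival(
            c.expression, c.clinical, ["BG00000", "BG00001", "BG00002"]
        )
        assert res["ci_low"] <= 1.0 <= res["ci_high"]

    def test_absent_gene_named_in_error(self, small_cohort):
        with pytest.raises(ValueError, match="GHOST"):
            pathway_average_survival(
                small_cohort.expression, small_cohort.clinical, ["BIM0000", "GHOST"]
            )


class TestGroupCompare:
    def test_exact_extreme_configuration(self):
        # {1,2,3} vs {4,5,6}: U = 0 for group 1, p = 2 / C(6,3) = 0.1
        u, p = group_compare([1, 2, 3, 4, 5, 6], [1, 1, 1, 0, 0, 0])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_label_swap_symmetry(self, rng):
        v = rng.normal(size=10)
        lab = np.r_[np.ones(5, int), np.zeros(5, int)]
        u1, p1 = group_compare(v, lab)
        u2, p2 = group_compare(v, 1 - lab)
        assert u1 + u2 == pytest.approx(25.0)  # n1 * n2
        assert p1 == pytest.approx(p2)

    def test_identical_groups(self):
        v = np.r_[np.arange(5.0), np.arange(5.0)]
        lab = np.r_[np.ones(5, int), np.zeros(5, int)]
        _, p = group_compare(v, lab)
        assert p > 0.9

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1.0, 2.0], [1, 1])


class TestCorrelationMatrix:
    def test_diagonal_and_symmetry(self, rng):
        m = pd.DataFrame(rng.normal(size=(3, 40)), index=["a", "b", "c"])
        tab = correlation_matrix(m, ["a", "b", "c"])
        piv = tab.pivot(index="gene_a", columns="gene_b", values="r")
        assert np.allclose(np.diag(piv), 1.0)
        assert np.allclose(piv.to_numpy(), piv.to_numpy().T)

    def test_equicorrelated_factor_model(self, rng):
        # x_g = f + noise(sigma): E[r] = 1 / (1 + sigma^2)
        sigma = 0.7
        f = rng.normal(size=4000)
        m = pd.DataFrame(
            [f + rng.normal(0, sigma, 4000) for _ in range(6)],
            index=[f"g{i}" for i in range(6)],
        )
        tab = correlation_matrix(m, list(m.index))
        off = tab[tab["gene_a"] != tab["gene_b"]]["r"]
        assert off.mean() == pytest.approx(1 / (1 + sigma**2), abs=0.03)
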