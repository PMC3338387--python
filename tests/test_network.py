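import numpy as np
import pandas as pd
import pytest

from vbnetrec.network import (
    Dataset,
    EdgeScoreTable,
    average_directions,
    build_union_graph,
    expression_pcs,
    phase1_phenotypes,
    phase2_expression,
    refit_ols_ci,
)


def make_dataset(rng, n=150, p_expr=8, m=3, q=2, planted=None):
    E = rng.standard_normal((n, p_expr))
    G = rng.binomial(2, 0.5, size=(n, m)).astype(float)
    P = rng.standard_normal((n, q))
    if planted:
        for qi, cols, sizes in planted:
            for c, s in zip(cols, sizes):
                src = E[:, c] if isinstance(c, int) else G[:, int(c[1:])]
                P[:, qi] += s * (src - src.mean()) / src.std()
    idx = [f"S{i}" for i in range(n)]
    return Dataset(
        expression=pd.DataFrame(E, index=idx, columns=[f"expr_{i}" for i in range(p_expr)]),
        genotypes=pd.DataFrame(G, index=idx, columns=[f"geno_{i}" for i in range(m)]),
        phenotypes=pd.DataFrame(P, index=idx, columns=[f"pheno_{i}" for i in range(q)]),
    )


class TestDataset:
    def test_complete_case_filter(self, rng):
        ds = make_dataset(rng, n=20)
        expr = ds.expression.copy()
        expr.iloc[3, 0] = np.nan
        filtered = Dataset(expression=expr, genotypes=ds.genotypes, phenotypes=ds.phenotypes)
        assert filtered.n == 19 and filtered.n_dropped == 1

    def test_alignment_order_insensitive(self, rng):
        ds = make_dataset(rng, n=15)
        shuffled = ds.genotypes.sample(frac=1.0, random_state=1)
        ds2 = Dataset(expression=ds.expression, genotypes=shuffled, phenotypes=ds.phenotypes)
        assert list(ds2.genotypes.index) == list(ds2.expression.index)
        pd.testing.assert_frame_equal(ds2.genotypes, ds.genotypes)

    def test_rejects_duplicate_ids(self, rng):
        ds = make_dataset(rng, n=10)
        bad = ds.expression.copy()
        bad.index = ["S0"] * 10
        with pytest.raises(ValueError, match="duplicated"):
            Dataset(expression=bad, genotypes=ds.genotypes, phenotypes=ds.phenotypes)

    def test_rejects_empty_intersection(self, rng):
        ds = make_dataset(rng, n=10)
        other = ds.genotypes.copy()
        other.index = [f"T{i}" for i in range(10)]
        with pytest.raises(ValueError, match="shared"):
            Dataset(expression=ds.expression, genotypes=other, phenotypes=ds.phenotypes)


class TestExpressionPCs:
    def test_rank_one_table(self, rng):
        u = rng.standard_normal(30)
        v = rng.standard_normal(10)
        E = np.outer(u, v)
        pcs = expression_pcs(E, k=2)
        uc = u - u.mean()
        corr = abs(np.corrcoef(pcs[:, 0], uc)[0, 1])
        assert corr > 1 - 1e-10

    def test_orthonormal(self, rng):
        pcs = expression_pcs(rng.standard_normal((40, 25)), k=5)
        assert pcs.T @ pcs == pytest.approx(np.eye(5), abs=1e-8)

    def test_variance_ordering(self, rng):
        E = rng.standard_normal((60, 30)) * np.linspace(5, 0.5, 30)
        pcs = expression_pcs(E, k=6)
        Ec = E - E.mean(0)
        var = [(pcs[:, i] @ Ec) @ (pcs[:, i] @ Ec) for i in range(6)]
        assert all(var[i] >= var[i + 1] - 1e-9 for i in range(5))

    def test_sign_convention_deterministic(self, rng):
        E = rng.standard_normal((30, 12))
        a = expression_pcs(E, k=3)
        b = expression_pcs(E.copy(), k=3)
        assert np.array_equal(a, b)
        for i in range(3):
            assert a[np.abs(a[:, i]).argmax(), i] > 0

    def test_rejects_k_too_large(self, rng):
        with pytest.raises(ValueError, match="smaller"):
            expression_pcs(rng.standard_normal((10, 5)), k=10)


class TestAverageDirections:
    def test_equal_scores_pass_through(self):
        t = EdgeScoreTable(roles={"a": "expression", "b": "expression"})
        t.add("a", "b", 0.7)
        t.add("b", "a", 0.7)
        sym = average_directions(t).symmetric()
        assert sym[frozenset({"a", "b"})] == pytest.approx(0.7)

    def test_paper_cutoff_arithmetic(self):
        t = EdgeScoreTable(roles={"a": "expression", "b": "expression"})
        t.add("a", "b", 1.00)
        t.add("b", "a", 0.981)
        sym = average_directions(t).symmetric()
        assert sym[frozenset({"a", "b"})] == pytest.approx(0.9905)
        assert sym[frozenset({"a", "b"})] > 0.99

    def test_half_score_dropped_at_both_cutoffs(self):
        t = EdgeScoreTable(roles={"a": "expression", "b": "expression"})
        t.add("a", "b", 1.0)
        t.add("b", "a", 0.0)
        s = average_directions(t).symmetric()[frozenset({"a", "b"})]
        assert s == pytest.approx(0.5)
        assert not s > 0.99 and not s > 0.5  # strict inequality rule

    def test_single_direction_pass_through(self):
        t = EdgeScoreTable(roles={"p": "phenotype", "g": "genotype"})
        t.add("p", "g", 0.995)
        assert average_directions(t).symmetric()[frozenset({"p", "g"})] == 0.995

    def test_genotype_response_rejected(self):
        t = EdgeScoreTable(roles={"g": "genotype", "e": "expression"})
        with pytest.raises(ValueError, match="genotype"):
            t.add("g", "e", 0.5)


class TestBuildUnionGraph:
    def _table(self, roles, entries):
        t = EdgeScoreTable(roles=roles)
        for a, b, s in entries:
            t.add(a, b, s)
        return t

    def test_disjoint_union_counts(self):
        roles = {"p1": "phenotype", "e1": "expression", "e2": "expression", "e3": "expression"}
        t1 = self._table(roles, [("p1", "e1", 0.999)])
        t2 = self._table(roles, [("e2", "e3", 0.995), ("e3", "e2", 0.997)])
        g = build_union_graph(t1, t2, threshold=0.99)
        assert g.number_of_edges() == 2

    def test_duplicate_edge_both_provenance_max_score(self):
        roles = {"p1": "phenotype", "e1": "expression", "e2": "expression"}
        t1 = self._table(roles, [("e1", "e2", 0.995)])
        t2 = self._table(roles, [("e1", "e2", 0.999), ("e2", "e1", 0.993)])
        g = build_union_graph(t1, t2, threshold=0.99)
        assert g.number_of_edges() == 1
        d = g.edges["e1", "e2"]
        assert d["provenance"] == "both"
        assert d["p_hat_sym"] == pytest.approx(max(0.995, 0.996))

    def test_empty_inputs_phenotype_vertices(self):
        roles = {"p1": "phenotype", "p2": "phenotype", "e1": "expression"}
        t1 = self._table(roles, [("p1", "e1", 0.3)])
        g = build_union_graph(t1, None, threshold=0.99)
        assert g.number_of_edges() == 0
        assert set(g.nodes) == {"p1", "p2"}

    def test_threshold_monotonicity(self):
        roles = {"e%d" % i: "expression" for i in range(6)}
        entries = [("e0", "e1", 0.999), ("e2", "e3", 0.7), ("e4", "e5", 0.3)]
        t = self._table(roles, entries)
        strict = set(build_union_graph(t, None, threshold=0.99).edges)
        loose = set(build_union_graph(t, None, threshold=0.5).edges)
        assert {frozenset(e) for e in strict} <= {frozenset(e) for e in loose}


class TestPhases:
    def test_phase1_planted_recovery(self, rng):
        ds = make_dataset(rng, n=250, p_expr=10, m=4, q=1,
                          planted=[(0, [1, 4, "g0"], [3.0, 3.0, 3.0])])
        table = phase1_phenotypes(ds, n_restarts=3, seed=0, n_pcs=2)
        hits = {f for (r, f), s in table.scores.items() if s > 0.99}
        assert {"expr_1", "expr_4", "geno_0"} <= hits
        others = {f for (r, f), s in table.scores.items()
                  if s > 0.99 and f not in {"expr_1", "expr_4", "geno_0"}}
        assert not others

    def test_phase1_null_empty(self, rng):
        ds = make_dataset(rng, n=200, p_expr=10, m=3, q=1)
        table = phase1_phenotypes(ds, n_restarts=3, seed=1, n_pcs=2)
        assert all(s <= 0.99 for s in table.scores.values())

    def test_phase1_deterministic(self, rng):
        ds = make_dataset(rng, n=100, p_expr=6, m=2, q=1)
        t1 = phase1_phenotypes(ds, n_restarts=2, seed=5, n_pcs=2)
        t2 = phase1_phenotypes(ds, n_restarts=2, seed=5, n_pcs=2)
        assert t1.scores == t2.scores

    def test_phase2_no_self_and_no_genotype_response(self, rng):
        ds = make_dataset(rng, n=120, p_expr=5, m=2, q=1)
        table = phase2_expression(ds, n_restarts=1, seed=0, n_pcs=2)
        for resp, feat in table.scores:
            assert resp != feat
            assert table.roles[resp] == "expression"
        responses = {r for r, _ in table.scores}
        assert responses == set(ds.expression.columns)


class TestRefitOlsCi:
    def test_strong_effect_tight_interval(self, rng):
        ds = make_dataset(rng, n=300, p_expr=5, m=2, q=1)
        x = ds.expression["expr_0"].to_numpy()
        ds.phenotypes["pheno_0"] = 2.0 * x + 0.01 * rng.standard_normal(300)
        res = refit_ols_ci(ds, "pheno_0", ["expr_0"], n_pcs=0)
        row = res.iloc[0]
        assert row["estimate"] == pytest.approx(2.0, abs=0.01)
        assert not row["covers_zero"]
        assert row["ci_high"] - row["ci_low"] < 0.02

    def test_null_feature_covers_zero(self, rng):
        covered = 0
        for s in range(40):
            r = np.random.default_rng(s)
            ds = make_dataset(r, n=80, p_expr=4, m=1, q=1)
            res = refit_ols_ci(ds, "pheno_0", ["expr_2"], n_pcs=0)
            covered += bool(res.iloc[0]["covers_zero"])
        assert covered >= 33  # ~95% coverage, generous slack

    def test_aliased_column_dropped(self, rng):
        ds = make_dataset(rng, n=100, p_expr=4, m=1, q=1)
        ds.expression["expr_3"] = 2.0 * ds.expression["expr_1"]
        res = refit_ols_ci(ds, "pheno_0", ["expr_1", "expr_3"], n_pcs=0)
        assert list(res["feature"]) == ["expr_1"]

    def test_too_many_features_rejected(self, rng):
        ds = make_dataset(rng, n=20, p_expr=25, m=1, q=1)
        with pytest.raises(ValueError, match="< n"):
            refit_ols_ci(ds, "pheno_0", [f"expr_{i}" for i in range(22)], n_pcs=0)
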