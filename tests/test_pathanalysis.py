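import itertools
import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from nucleotype.comparative import LambdaGLS
from nucleotype.pathanalysis import (
    AveragedModel,
    CausalModel,
    PathModelResult,
    average_models,
    basis_set,
    cicc,
    evaluate_model,
    fisher_c,
    fit_paths,
    model_registry,
    parse_dag_spec,
    rank_models,
    run_path_analysis,
)
from nucleotype.pathanalysis import test_claim as dsep_claim_pvalue
from nucleotype.phylo import phylo_covariance
from nucleotype.simulate import sim_traits_dag, sim_tree

DIRECT4_COEFS = {
    ("GS", "CV"): 0.6, ("GS", "DT"): 0.5, ("TEMP", "GS"): -0.4,
    ("TEMP", "DT"): -0.5, ("GC", "GS"): 0.3,
}


def brute_force_d_separated(g: nx.DiGraph, x: str, y: str, z: set) -> bool:
    """Path-blocking oracle: every undirected path from x to y is blocked.

    A path is blocked by z if it contains a chain or fork whose middle
    vertex is in z, or a collider whose middle vertex has no descendant
    (including itself) in z.
    """
    skel = g.to_undirected()
    desc = {v: nx.descendants(g, v) | {v} for v in g.nodes}
    for path in nx.all_simple_paths(skel, x, y):
        blocked = False
        for a, b, c in zip(path, path[1:], path[2:]):
            collider = g.has_edge(a, b) and g.has_edge(c, b)
            if collider:
                if not (desc[b] & z):
                    blocked = True
                    break
            elif b in z:
                blocked = True
                break
        if not blocked:
            return False
    return True


class TestRegistry:
    def test_default_has_fourteen_acyclic_models(self):
        reg = model_registry()
        assert len(reg) == 14
        names = [m.name for m in reg]
        assert len(set(names)) == 14
        for m in reg:
            assert nx.is_directed_acyclic_graph(m.graph())

    def test_structural_constraints(self):
        reg = {m.name: set(m.edges) for m in model_registry()}
        assert reg["direct4"] >= {("GS", "CV"), ("GS", "DT"),
                                  ("TEMP", "GS"), ("TEMP", "DT")}
        # direct2 swaps the genome-size/cell-volume arrow
        assert reg["direct2"] == (reg["direct4"] - {("GS", "CV"), ("GC", "GS")}) | {
            ("CV", "GS")}
        # direct1 and direct2 lack the GC -> GS edge
        assert ("GC", "GS") not in reg["direct1"]
        assert ("GC", "GS") not in reg["direct2"]
        # indirect models reach DT from GS only through CV
        for name, edges in reg.items():
            if name.startswith("indirect"):
                assert ("GS", "DT") not in edges
                assert ("GS", "CV") in edges and ("CV", "DT") in edges
            if name.startswith("null"):
                g = nx.DiGraph(list(edges))
                g.add_nodes_from(["GS", "DT"])
                assert not nx.has_path(g, "GS", "DT")

    def test_spec_file_parsing(self, tmp_path):
        text = "[toy]\nGS -> CV\n# comment\nCV -> DT\n"
        models = parse_dag_spec(text)
        assert len(models) == 1
        assert models[0].edges == (("GS", "CV"), ("CV", "DT"))

    def test_cyclic_spec_rejected(self):
        with pytest.raises(ValueError, match="cycl"):
            parse_dag_spec("[bad]\nGS -> CV\nCV -> GS\n")


class TestBasisSet:
    def test_chain_single_claim(self):
        m = CausalModel("chain", edges=(("A", "B"), ("B", "C")),
                        vertices=("A", "B", "C"))
        claims = basis_set(m)
        assert len(claims) == 1
        cl = claims[0]
        assert {cl.x, cl.y} == {"A", "C"}
        assert cl.conditioning_set == ("B",)
        assert cl.child == "C"  # A is an ancestor of C

    def test_complete_dag_empty_basis(self):
        m = CausalModel("full", edges=(("A", "B"), ("A", "C"), ("B", "C")),
                        vertices=("A", "B", "C"))
        assert basis_set(m) == []

    def test_all_enumerated_dags_claims_d_separated(self):
        """Across every DAG on 5 vertices with <= 6 edges, each basis claim
        is d-separated per the brute-force path-blocking oracle and the
        claim count equals the non-adjacent-pair count."""
        verts = ("A", "B", "C", "D", "E")
        pairs = list(itertools.combinations(verts, 2))
        for states in itertools.product((0, 1, 2), repeat=len(pairs)):
            edges = []
            for (u, v), s in zip(pairs, states):
                if s == 1:
                    edges.append((u, v))
                elif s == 2:
                    edges.append((v, u))
            if len(edges) > 6:
                continue
            g = nx.DiGraph()
            g.add_nodes_from(verts)
            g.add_edges_from(edges)
            if not nx.is_directed_acyclic_graph(g):
                continue
            m = CausalModel("m", edges=tuple(edges), vertices=verts)
            claims = basis_set(m)
            nonadj = sum(
                1 for (u, v) in pairs
                if not (g.has_edge(u, v) or g.has_edge(v, u))
            )
            assert len(claims) == nonadj
            for cl in claims:
                assert brute_force_d_separated(
                    g, cl.x, cl.y, set(cl.conditioning_set)), (edges, cl)

    def test_oracle_agrees_with_networkx(self):
        """Sanity-check the hand-rolled oracle against networkx on one DAG."""
        g = nx.DiGraph([("A", "B"), ("B", "C"), ("D", "B")])
        g.add_nodes_from("ABCDE")
        for x, y in itertools.combinations("ABCDE", 2):
            for z in ([], ["B"], ["B", "D"]):
                if x in z or y in z:
                    continue
                assert brute_force_d_separated(g, x, y, set(z)) == \
                    nx.is_d_separator(g, {x}, {y}, set(z))


class TestClaimTesting:
    def test_deterministic(self, tree50):
        data = sim_traits_dag(tree50, _direct4(), DIRECT4_COEFS, seed=5)
        claims = basis_set(_direct4())
        p1 = dsep_claim_pvalue(tree50, data, claims[0])
        p2 = dsep_claim_pvalue(tree50, data, claims[0])
        assert p1 == p2

    def test_power_against_misspecified_claim(self):
        """Regressing a child on its direct cause must reject often."""
        from nucleotype.pathanalysis import DSepClaim

        m = CausalModel("one_edge", edges=(("GS", "DT"),))
        bogus = DSepClaim(x="GS", y="DT", conditioning_set=(), child="DT")
        hits = 0
        for rep in range(25):
            tree = sim_tree(100, seed=300 + rep)
            data = sim_traits_dag(tree, m, {("GS", "DT"): 0.8}, seed=400 + rep)
            hits += dsep_claim_pvalue(tree, data, bogus) < 0.05
        assert hits >= 22  # >= ~90% power


def _direct4():
    return [m for m in model_registry() if m.name == "direct4"][0]


class TestFisherC:
    def test_closed_form_df4(self):
        c, df, p = fisher_c([0.5, 0.5])
        assert c == pytest.approx(-2 * 2 * math.log(0.5), abs=1e-4)
        assert df == 4
        # chi-square df=4 upper tail has closed form e^(-C/2) (1 + C/2)
        assert p == pytest.approx(math.exp(-c / 2) * (1 + c / 2), abs=1e-10)
        assert p == pytest.approx(0.5966, abs=1e-4)

    def test_empty_list_vacuous(self):
        assert fisher_c([]) == (0.0, 0, 1.0)

    def test_monotone_in_p(self):
        base = fisher_c([0.5, 0.5])[0]
        assert fisher_c([0.4, 0.5])[0] > base
        assert fisher_c([0.5, 0.6])[0] < base

    def test_zero_p_raises_with_guidance(self):
        with pytest.raises(ValueError, match="floor"):
            fisher_c([0.5, 0.0])


class TestCICc:
    def test_arithmetic(self):
        assert cicc(2.7726, 5, 20) == pytest.approx(2.7726 + 200 / 14, abs=1e-3)

    def test_monotone_in_q(self):
        assert cicc(2.0, 6, 30) > cicc(2.0, 5, 30)

    def test_guard(self):
        with pytest.raises(ValueError):
            cicc(2.0, 19, 20)


class TestRanking:
    def _results(self, ciccs):
        out = []
        for i, c in enumerate(ciccs):
            r = PathModelResult(
                model=CausalModel(f"m{i}", edges=()), claims=[], p_values=[],
                C=0.0, df=0, p_model=1.0, q=5, n=50, CICc=c)
            out.append(r)
        return out

    def test_best_delta_zero_and_weights_norm(self):
        ranked = rank_models(self._results([12.0, 10.0, 11.0]))
        assert ranked[0].delta_CICc == 0.0
        assert sum(r.weight for r in ranked) == pytest.approx(1.0, abs=1e-12)
        assert [r.CICc for r in ranked] == sorted([r.CICc for r in ranked])

    def test_equal_cicc_equal_weights(self):
        ranked = rank_models(self._results([10.0, 10.0]))
        assert ranked[0].weight == pytest.approx(ranked[1].weight)

    def test_weights_invariant_to_constant_shift(self):
        w1 = [r.weight for r in rank_models(self._results([10.0, 12.0, 15.0]))]
        w2 = [r.weight for r in rank_models(self._results([110.0, 112.0, 115.0]))]
        assert w1 == pytest.approx(w2, abs=1e-12)


class TestFitPaths:
    def test_single_edge_equals_direct_regression(self, tree50):
        m = CausalModel("one", edges=(("GS", "DT"),))
        data = sim_traits_dag(tree50, m, {("GS", "DT"): 0.6}, seed=8)
        paths = fit_paths(m, tree50, data)
        from nucleotype.comparative import pgls_fit

        z = (data - data.mean()) / data.std(ddof=1)
        direct = pgls_fit(tree50, z, "DT", ["GS"])
        beta, se = paths[("GS", "DT")]
        assert beta == pytest.approx(direct.params["GS"], abs=1e-10)
        assert se == pytest.approx(direct.bse["GS"], abs=1e-10)

    def test_scale_invariance(self, tree50):
        data = sim_traits_dag(tree50, _direct4(), DIRECT4_COEFS, seed=9)
        p1 = fit_paths(_direct4(), tree50, data)
        scaled = data.copy()
        scaled["GS"] = scaled["GS"] * 1000.0
        p2 = fit_paths(_direct4(), tree50, scaled)
        for e in p1:
            assert p1[e][0] == pytest.approx(p2[e][0], abs=1e-10)

    def test_parameter_recovery(self):
        """Mean standardized path estimates stay near the generating values."""
        sums = {e: 0.0 for e in DIRECT4_COEFS}
        n_rep = 20
        for rep in range(n_rep):
            tree = sim_tree(100, seed=700 + rep)
            data = sim_traits_dag(tree, _direct4(), DIRECT4_COEFS, seed=800 + rep)
            paths = fit_paths(_direct4(), tree, data)
            for e in sums:
                sums[e] += paths[e][0]
        for e, true_val in DIRECT4_COEFS.items():
            assert sums[e] / n_rep == pytest.approx(true_val, abs=0.1)


class TestAveraging:
    def _two_model_setup(self):
        m1 = CausalModel("m1", edges=(("GS", "DT"),))
        m2 = CausalModel("m2", edges=())
        r1 = PathModelResult(model=m1, claims=[], p_values=[], C=0.0, df=0,
                             p_model=1.0, q=6, n=50, CICc=10.0)
        r2 = PathModelResult(model=m2, claims=[], p_values=[], C=0.0, df=0,
                             p_model=1.0, q=5, n=50, CICc=10.0)
        fits = {"m1": {("GS", "DT"): (0.4, 0.1)}, "m2": {}}
        return [r1, r2], fits

    def test_full_vs_conditional(self):
        results, fits = self._two_model_setup()
        full = average_models(results, fits, mode="full")
        cond = average_models(results, fits, mode="conditional")
        assert full.coefficients[("GS", "DT")] == pytest.approx(0.2)
        assert cond.coefficients[("GS", "DT")] == pytest.approx(0.4)

    def test_single_model_identity(self):
        results, fits = self._two_model_setup()
        avg = average_models(results[:1], {"m1": fits["m1"]})
        assert avg.coefficients[("GS", "DT")] == pytest.approx(0.4)
        assert avg.standard_errors[("GS", "DT")] == pytest.approx(0.1)

    def test_order_invariance(self):
        results, fits = self._two_model_setup()
        a1 = average_models(results, fits)
        a2 = average_models(results[::-1], fits)
        assert a1.coefficients == a2.coefficients


class TestEndToEnd:
    def test_run_path_analysis_smoke(self, tree50):
        data = sim_traits_dag(tree50, _direct4(), DIRECT4_COEFS, seed=12)
        ranked, avg = run_path_analysis(tree50, data)
        assert len(ranked) == 14
        assert ranked[0].delta_CICc == 0.0
        assert sum(r.weight for r in ranked) == pytest.approx(1.0)
        assert all(np.isfinite(list(avg.coefficients.values())))
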