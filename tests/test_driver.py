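import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crcnet.driver import (binarize_cnv, binarize_mutations,
                           extract_driver_subnetwork, geneset_enrichment,
                           permutation_significance, random_walk,
                           start_probabilities)


class TestBinarize:
    def test_repeated_calls_stay_binary(self):
        calls = pd.DataFrame({"sample": ["s1", "s1"], "gene": ["A", "A"],
                              "variant_class": ["Missense_Mutation"] * 2})
        mat = binarize_mutations(calls, ["A", "B"], ["s1", "s2"])
        assert mat.at["A", "s1"] == 1
        assert mat.to_numpy().sum() == 1

    def test_silent_only_scores_zero(self):
        calls = pd.DataFrame({"sample": ["s1"], "gene": ["A"],
                              "variant_class": ["Silent"]})
        mat = binarize_mutations(calls, ["A"], ["s1"])
        assert mat.at["A", "s1"] == 0

    def test_empty_sample_column_retained(self):
        calls = pd.DataFrame({"sample": ["s1"], "gene": ["A"],
                              "variant_class": ["Nonsense_Mutation"]})
        mat = binarize_mutations(calls, ["A"], ["s1", "s2"])
        assert "s2" in mat.columns
        assert mat["s2"].sum() == 0

    def test_cnv_thresholds_inclusive(self):
        ratios = pd.DataFrame([[1.2, 1.0, 0.8, 1.19]], index=["A"],
                              columns=["s1", "s2", "s3", "s4"])
        mat = binarize_cnv(ratios)
        assert list(mat.loc["A"]) == [1, 0, 1, 0]

    def test_nonpositive_ratio_errors(self):
        ratios = pd.DataFrame([[0.0]], index=["A"], columns=["s1"])
        with pytest.raises(ValueError):
            binarize_cnv(ratios)


class TestStartProbabilities:
    def test_single_alteration_gets_all_mass(self):
        mut = pd.DataFrame([[1, 0], [0, 0]], index=["A", "B"],
                           columns=["s1", "s2"])
        sp = start_probabilities(mut)
        assert sp.p0["A"] == pytest.approx(1.0)

    def test_hand_example(self):
        # s1 alters A and B, s2 alters only A:
        # S(A) = 1/2 + 1 = 1.5, S(B) = 1/2 -> p0 = (0.75, 0.25)
        mut = pd.DataFrame([[1, 1], [1, 0]], index=["A", "B"],
                           columns=["s1", "s2"])
        sp = start_probabilities(mut)
        assert sp.s_mut["A"] == pytest.approx(1.5)
        assert sp.s_mut["B"] == pytest.approx(0.5)
        assert sp.p0["A"] == pytest.approx(0.75)
        assert sp.p0["B"] == pytest.approx(0.25)

    def test_sample_duplication_invariance(self):
        rng = np.random.default_rng(0)
        for rep in range(10):
            mut = pd.DataFrame(rng.integers(0, 2, size=(10, 5)),
                               index=[f"g{i}" for i in range(10)],
                               columns=[f"s{j}" for j in range(5)])
            cnv = pd.DataFrame(rng.integers(0, 2, size=(10, 5)),
                               index=mut.index, columns=mut.columns)
            if mut.to_numpy().sum() + cnv.to_numpy().sum() == 0:
                continue
            doubled_m = pd.concat([mut, mut.add_suffix("_dup")], axis=1)
            doubled_c = pd.concat([cnv, cnv.add_suffix("_dup")], axis=1)
            a = start_probabilities(mut, cnv).p0
            b = start_probabilities(doubled_m, doubled_c).p0
            assert np.allclose(a, b, atol=1e-12)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(1)
        mut = pd.DataFrame(rng.integers(0, 2, size=(10, 5)),
                           index=[f"g{i}" for i in range(10)],
                           columns=[f"s{j}" for j in range(5)])
        sp = start_probabilities(mut)
        # brute force: explicit loops over the definition
        s = np.zeros(10)
        M = mut.to_numpy()
        for j in range(5):
            colsum = M[:, j].sum()
            if colsum:
                s += M[:, j] / colsum
        expected = s / s.sum()
        assert np.allclose(sp.p0.to_numpy(), expected, atol=1e-12)
        assert sp.p0.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_errors(self):
        mut = pd.DataFrame(0, index=["A"], columns=["s1"])
        with pytest.raises(ValueError, match="all-zero"):
            start_probabilities(mut)


def path_graph():
    g = nx.Graph()
    g.add_edge("A", "B")
    return g


class TestRandomWalk:
    def test_full_restart_returns_p0(self):
        g = nx.cycle_graph(6)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        p0 = pd.Series(np.ones(6) / 6.0, index=sorted(g.nodes))
        p0.iloc[0] = 0.5
        p0 /= p0.sum()
        res = random_walk(g, p0, r=1.0)
        assert np.allclose(res.scores, p0.loc[res.scores.index], atol=1e-12)

    def test_two_node_closed_form(self):
        # p = (1-r) W^T p + r p0 with p0=(1,0), r=0.5 -> p = (2/3, 1/3)
        res = random_walk(path_graph(), pd.Series([1.0, 0.0],
                                                  index=["A", "B"]), r=0.5,
                          epsilon=1e-12)
        assert res.scores["A"] == pytest.approx(2 / 3, abs=1e-9)
        assert res.scores["B"] == pytest.approx(1 / 3, abs=1e-9)

    def test_uniform_p0_on_regular_graph_stays_uniform(self):
        g = nx.cycle_graph(8)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        p0 = pd.Series(1 / 8, index=sorted(g.nodes))
        res = random_walk(g, p0, r=0.5)
        assert np.allclose(res.scores, 1 / 8, atol=1e-8)

    def test_agrees_with_direct_linear_solve(self):
        rng = np.random.default_rng(2)
        for rep in range(5):
            g = nx.gnp_random_graph(50, 0.15, seed=int(rng.integers(1e6)))
            if not nx.is_connected(g):
                g = g.subgraph(max(nx.connected_components(g), key=len))
            g = nx.relabel_nodes(g, {n: f"n{n:02d}" for n in g.nodes})
            nodes = sorted(g.nodes)
            raw = rng.random(len(nodes))
            p0 = pd.Series(raw / raw.sum(), index=nodes)
            res = random_walk(g, p0, r=0.5, epsilon=1e-12)
            A = nx.to_numpy_array(g, nodelist=nodes)
            W = A / A.sum(axis=0, keepdims=True)
            direct = 0.5 * np.linalg.solve(np.eye(len(nodes)) - 0.5 * W,
                                           p0.to_numpy())
            assert np.allclose(res.scores.to_numpy(), direct, atol=1e-8)
            assert res.scores.sum() == pytest.approx(1.0, abs=1e-12)

    def test_score_monotone_in_start_probability(self):
        rng = np.random.default_rng(3)
        g = nx.gnp_random_graph(30, 0.2, seed=5)
        g = g.subgraph(max(nx.connected_components(g), key=len))
        g = nx.relabel_nodes(g, {n: f"n{n:02d}" for n in g.nodes})
        nodes = sorted(g.nodes)
        raw = rng.random(len(nodes))
        p0 = pd.Series(raw / raw.sum(), index=nodes)
        base = random_walk(g, p0, r=0.5, epsilon=1e-12).scores
        for gene in nodes[:5]:
            bumped = p0.copy()
            bumped[gene] += 0.5
            bumped /= bumped.sum()
            up = random_walk(g, bumped, r=0.5, epsilon=1e-12).scores
            assert up[gene] >= base[gene] - 1e-12

    def test_restart_range_validated(self):
        with pytest.raises(ValueError):
            random_walk(path_graph(), pd.Series([1.0, 0.0],
                                                index=["A", "B"]), r=0.0)


class TestPermutationSignificance:
    def test_uniform_p0_on_vertex_transitive_graph(self):
        g = nx.cycle_graph(20)
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        p0 = pd.Series(1 / 20, index=sorted(g.nodes))
        sig = permutation_significance(g, p0, n_perm=50, seed=0)
        # permuting a uniform vector changes nothing: every permutation
        # reproduces the observed score
        assert (sig.table["local_p"] == 1.0).all()

    def test_planted_hub_minimal_local_p(self):
        g = nx.star_graph(49)
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        hub = "n00"
        p0 = pd.Series(0.0, index=sorted(g.nodes))
        p0[hub] = 1.0
        sig = permutation_significance(g, p0, n_perm=99, seed=1)
        # every permutation that moves the mass off the hub scores below
        # the observed walk; only permutations fixing the hub tie it.
        rng = np.random.default_rng(1)
        hub_idx = sorted(g.nodes).index(hub)
        n_fix = sum(rng.permutation(50)[hub_idx] == hub_idx
                    for _ in range(99))
        assert sig.table.loc[hub, "local_p"] == pytest.approx((1 + n_fix) / 100)
        assert sig.table["local_p"].idxmin() == hub

    def test_seed_reproducibility(self):
        g = nx.gnp_random_graph(30, 0.2, seed=7)
        g = g.subgraph(max(nx.connected_components(g), key=len))
        g = nx.relabel_nodes(g, {n: f"n{n:02d}" for n in g.nodes})
        rng = np.random.default_rng(8)
        nodes = sorted(g.nodes)
        raw = rng.random(len(nodes))
        p0 = pd.Series(raw / raw.sum(), index=nodes)
        a = permutation_significance(g, p0, n_perm=50, seed=9)
        b = permutation_significance(g, p0, n_perm=50, seed=9)
        assert a.table.equals(b.table)

    def test_local_p_uniform_under_null(self):
        # observed start probabilities themselves drawn from the
        # permutation null -> local p approximately uniform
        g = nx.barabasi_albert_graph(100, 3, seed=10)
        g = nx.relabel_nodes(g, {i: f"n{i:03d}" for i in g.nodes})
        rng = np.random.default_rng(11)
        nodes = sorted(g.nodes)
        raw = rng.exponential(size=len(nodes)) * (rng.random(len(nodes)) < 0.3)
        raw[0] = max(raw[0], 0.1)
        values = raw / raw.sum()
        p0 = pd.Series(values[rng.permutation(len(nodes))], index=nodes)
        sig = permutation_significance(g, p0, n_perm=200, seed=12)
        ks = stats.kstest(sig.table["local_p"], "uniform")
        assert ks.pvalue > 0.01


class TestExtractSubnetwork:
    def _sig_table(self, graph, sig_genes):
        from crcnet.driver import SignificanceResult
        nodes = sorted(graph.nodes)
        table = pd.DataFrame({
            "p0": 0.0, "score": 0.0,
            "local_p": [0.01 if n in sig_genes else 0.9 for n in nodes],
            "global_p": [0.01 if n in sig_genes else 0.9 for n in nodes],
        }, index=pd.Index(nodes, name="gene"))
        return SignificanceResult(table)

    def test_no_significant_genes_empty_result(self):
        g = nx.path_graph(5)
        g = nx.relabel_nodes(g, str)
        sub = extract_driver_subnetwork(g, self._sig_table(g, set()))
        assert sub.number_of_nodes() == 0

    def test_largest_component_returned(self):
        g = nx.Graph()
        nx.add_path(g, ["a1", "a2", "a3", "a4", "a5"])
        nx.add_path(g, ["b1", "b2", "b3"])
        g.add_edge("a5", "b1")    # connect; significance will split them
        sig = self._sig_table(g, {"a1", "a2", "a3", "a4", "a5",
                                  "b2", "b3"})
        sub = extract_driver_subnetwork(g, sig)
        assert set(sub.nodes) == {"a1", "a2", "a3", "a4", "a5"}

    def test_end_to_end_planted_driver_recovery(self):
        from crcnet.pipeline import run_driver_inference
        from crcnet.synthetic import (SyntheticCohortSpec,
                                      gen_alteration_data,
                                      gen_expression_cohort,
                                      gen_signaling_network,
                                      plant_driver_genes)
        spec = SyntheticCohortSpec(seed=21)
        expr, truth = gen_expression_cohort(spec)
        net = gen_signaling_network(300, 3, seed=22, genes=list(expr.genes))
        truth = plant_driver_genes(net, truth, 12, seed=23)
        mut, cnv = gen_alteration_data(net, truth, 0.01, 0.6, seed=24)
        res = run_driver_inference(net, mut, cnv, truth.sample_subtype,
                                   n_perm=200, seed=25)
        for k, r in res.items():
            found = set(r["subnetwork"].nodes)
            planted = truth.driver_genes[k]
            assert len(found & planted) / len(planted) >= 0.8


class TestEnrichment:
    def test_disjoint_set_p_one(self):
        out = geneset_enrichment({"A", "B"}, {"A", "B", "C", "D", "E"},
                                 {"other": ["C", "D"]})
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_identical_set_matches_exact_tail(self):
        subnet = {f"g{i}" for i in range(5)}
        background = {f"g{i}" for i in range(50)}
        out = geneset_enrichment(subnet, background, {"hit": sorted(subnet)})
        # exact enumeration: P(drawing all 5 of the 5 set genes in 5 draws)
        from math import comb
        expected = comb(5, 5) * comb(45, 0) / comb(50, 5)
        assert out["p"].iloc[0] == pytest.approx(expected, rel=1e-10)

    def test_bh_stepup_hand_example(self):
        adjusted = stats.false_discovery_control([0.01, 0.02, 0.03],
                                                 method="bh")
        assert np.allclose(adjusted, [0.03, 0.03, 0.03])
        subnet = {"A"}
        bg = {"A", "B", "C", "D"}
        out = geneset_enrichment(subnet, bg, {"s1": ["A"], "s2": ["A", "B"],
                                              "s3": ["B"]})
        assert (out["fdr"] >= out["p"] - 1e-15).all()

    def test_empty_collection_errors(self):
        with pytest.raises(ValueError):
            geneset_enrichment({"A"}, {"A", "B"}, {})
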