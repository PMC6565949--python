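"""Pearson edges, permutation p-values, bipartite degrees and exports."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lncnet as L


def pearson_definitional(x, y):
    """Direct covariance / sigma oracle, independent of the implementation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    return cov / (x.std() * y.std())


class TestPearson:
    def test_identity_and_affine(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert L.pearson_r(x, x) == pytest.approx(1.0)
        assert L.pearson_r(x, -2 * x + 7) == pytest.approx(-1.0)

    def test_matches_definitional_oracle(self):
        x = [1, 2, 3, 4, 5, 6]
        y = [2, 1, 4, 3, 6, 5]
        assert L.pearson_r(x, y) == pytest.approx(pearson_definitional(x, y))

    def test_constant_vector_is_undefined(self):
        assert math.isnan(L.pearson_r([1, 1, 1], [1, 2, 3]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            L.pearson_r([1, 2, 3], [1, 2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        xs=st.lists(
            st.floats(-100, 100, allow_nan=False), min_size=4, max_size=8
        ),
        a=st.floats(0.1, 10),
        b=st.floats(-5, 5),
    )
    def test_symmetry_bounds_affine_invariance(self, xs, a, b):
        rng = np.random.default_rng(0)
        x = np.asarray(xs)
        y = rng.normal(size=len(x))
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        r = L.pearson_r(x, y)
        assert -1.0 - 1e-9 <= r <= 1.0 + 1e-9
        assert r == pytest.approx(L.pearson_r(y, x))
        assert r == pytest.approx(L.pearson_r(a * x + b, y), abs=1e-9)


def exact_p_bruteforce(x, y):
    """Exhaustive enumeration oracle over all n! shuffles of y."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    r_obs = abs(pearson_definitional(x, y))
    perms = list(itertools.permutations(range(len(y))))
    hits = sum(
        1
        for p in perms
        if abs(pearson_definitional(x, y[list(p)])) >= r_obs - 1e-12
    )
    return hits / len(perms)


class TestPermutationPvalue:
    def test_perfect_correlation_n4(self):
        """Only the identity and the full reversal of (1,2,3,4) reach |r|=1."""
        x = np.array([1.0, 2.0, 3.0, 4.0])
        p = L.permutation_pvalue(x, x, L.PermutationScheme(mode="exact"))
        assert p == pytest.approx(2 / 24)

    def test_zero_correlation_gives_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([-1.0, 1.0, 1.0, -1.0])  # r exactly 0
        assert L.pearson_r(x, y) == pytest.approx(0.0)
        p = L.permutation_pvalue(x, y, L.PermutationScheme(mode="exact"))
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=5), rng.normal(size=5)
        p = L.permutation_pvalue(x, y, L.PermutationScheme(mode="exact"))
        assert p == pytest.approx(exact_p_bruteforce(x, y))

    def test_monte_carlo_converges_to_exact(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        exact = 2 / 24
        scheme = L.PermutationScheme(mode="monte_carlo", n_draws=10_000, seed=5)
        p_mc = L.permutation_pvalue(x, x, scheme)
        se = math.sqrt(exact * (1 - exact) / 10_000)
        assert abs(p_mc - exact) <= 3 * se + 1 / 10_001  # add-one offset slack

    def test_monte_carlo_reproducible(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=10), rng.normal(size=10)
        scheme = L.PermutationScheme(mode="monte_carlo", n_draws=500, seed=42)
        assert L.permutation_pvalue(x, y, scheme) == L.permutation_pvalue(x, y, scheme)

    def test_monte_carlo_p_strictly_positive(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=9)
        scheme = L.PermutationScheme(mode="monte_carlo", n_draws=200, seed=0)
        assert L.permutation_pvalue(x, x, scheme) > 0

    def test_auto_resolution_threshold(self):
        scheme = L.PermutationScheme(mode="auto", small_n_threshold=8)
        assert scheme.resolve(6) == "exact"
        assert scheme.resolve(9) == "monte_carlo"

    def test_constant_input_propagates_nan(self):
        p = L.permutation_pvalue(
            np.ones(4), np.array([1.0, 2, 3, 4]), L.PermutationScheme(mode="exact")
        )
        assert math.isnan(p)

    def test_exact_p_superuniform_under_null(self):
        """P(p <= t) <= t (small slack) for exchangeable null draws at n=6."""
        rng = np.random.default_rng(123)
        scheme = L.PermutationScheme(mode="exact")
        pvals = np.array(
            [
                L.permutation_pvalue(rng.normal(size=6), rng.normal(size=6), scheme)
                for _ in range(300)
            ]
        )
        for t in (0.01, 0.05, 0.1, 0.25):
            frac = (pvals <= t).mean()
            tol = 3 * math.sqrt(t * (1 - t) / len(pvals))
            assert frac <= t + tol


def expr_frame(rows, prefix):
    return pd.DataFrame(
        rows, index=[f"{prefix}{i}" for i in range(len(rows))],
        columns=[f"s{j}" for j in range(len(rows[0]))],
    )


class TestBuildNetwork:
    def test_pair_count_exhaustive(self):
        rng = np.random.default_rng(0)
        lnc = expr_frame(rng.random((2, 6)) * 100, "lnc")
        mrna = expr_frame(rng.random((3, 6)) * 100, "m")
        edges, summary = L.build_network(lnc, mrna)
        assert len(edges) == 6
        assert summary.edges["retained"].all() if len(summary.edges) else True

    def test_sample_axis_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        lnc = expr_frame(rng.random((2, 6)), "lnc")
        mrna = expr_frame(rng.random((2, 6)), "m")
        with pytest.raises(ValueError):
            L.build_network(lnc, mrna[reversed(list(mrna.columns))])

    def test_planted_pairs_retained(self, default_fixture, default_groups):
        _, counts, annotation, truth = default_fixture
        rpkm = L.compute_rpkm(counts, annotation)
        passed = L.filter_de(L.differential_expression(rpkm, default_groups))
        ids = set(passed["transcript_id"])
        lnc = sorted(t for t in ids if t.startswith("lnc"))
        mrna = sorted(t for t in ids if t.startswith("mrna"))
        edges, summary = L.build_network(rpkm.loc[lnc], rpkm.loc[mrna])
        retained = edges[edges["retained"]]
        got = set(zip(retained["lncrna_id"], retained["mrna_id"]))
        planted = set(
            zip(truth.correlated_pairs["lncrna_id"], truth.correlated_pairs["mrna_id"])
        )
        assert planted <= got
        assert retained["r"].abs().min() >= 0.95
        assert (retained["p_perm"] < 0.05).all()

    def test_null_fixture_retains_almost_nothing(self):
        total_pairs, total_retained = 0, 0
        for seed in range(3):
            config = L.SimulationConfig(seed=800 + seed, frac_de=0.0, n_planted_pairs=0)
            counts, annotation, _ = L.simulate_fixture(config)
            rpkm = L.compute_rpkm(counts, annotation)
            edges, _ = L.build_network(rpkm.iloc[:20], rpkm.iloc[20:])
            total_pairs += len(edges)
            total_retained += int(edges["retained"].sum())
        assert total_retained / total_pairs <= 0.02

    def test_constant_transcript_never_retained(self):
        lnc = expr_frame([[5.0] * 6, [1, 4, 2, 8, 5, 7]], "lnc")
        mrna = expr_frame([[1, 4, 2, 8, 5, 7]], "m")
        edges, _ = L.build_network(lnc, mrna)
        flat = edges[edges["lncrna_id"] == "lnc0"]
        assert flat["r"].isna().all()
        assert not flat["retained"].any()


class TestDegrees:
    def test_empty_edges_all_zero(self):
        summary = L.node_degrees(
            pd.DataFrame(columns=["lncrna_id", "mrna_id", "r", "p_perm", "sign", "retained"]),
            lnc_ids=["l1"],
            mrna_ids=["m1", "m2"],
        )
        assert (summary.nodes["degree"] == 0).all()
        assert summary.n_edges == 0

    def test_star_graph(self):
        edges = pd.DataFrame(
            {
                "lncrna_id": ["hub"] * 5,
                "mrna_id": [f"m{i}" for i in range(5)],
                "r": [0.99] * 5,
                "p_perm": [0.01] * 5,
                "sign": ["positive"] * 5,
                "retained": [True] * 5,
            }
        )
        summary = L.node_degrees(edges)
        deg = summary.nodes.set_index("id")["degree"]
        assert deg["hub"] == 5
        assert all(deg[f"m{i}"] == 1 for i in range(5))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_random_bipartite_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        pairs = [
            (f"l{i}", f"m{j}")
            for i in range(4)
            for j in range(6)
            if rng.random() < 0.4
        ]
        edges = pd.DataFrame(
            {
                "lncrna_id": [p[0] for p in pairs],
                "mrna_id": [p[1] for p in pairs],
                "r": 0.99,
                "p_perm": 0.01,
                "sign": "positive",
                "retained": True,
            }
        )
        summary = L.node_degrees(edges)
        deg = summary.nodes.set_index("id")["degree"]
        for node in deg.index:
            expected = sum(1 for p in pairs if node in p)
            assert deg[node] == expected
        # bipartite handshake
        lnc_sum = deg[[i for i in deg.index if i.startswith("l")]].sum()
        mrna_sum = deg[[i for i in deg.index if i.startswith("m")]].sum()
        assert lnc_sum == mrna_sum == summary.n_edges == len(pairs)


class TestExport:
    @pytest.fixture()
    def small_summary(self, default_fixture, default_groups):
        _, counts, annotation, _ = default_fixture
        rpkm = L.compute_rpkm(counts, annotation)
        passed = L.filter_de(L.differential_expression(rpkm, default_groups))
        ids = set(passed["transcript_id"])
        lnc = sorted(t for t in ids if t.startswith("lnc"))
        mrna = sorted(t for t in ids if t.startswith("mrna"))
        return L.build_network(rpkm.loc[lnc], rpkm.loc[mrna])[1]

    def test_sif_line_count(self, small_summary, tmp_path):
        paths = L.export_network(small_summary, tmp_path)
        lines = paths["sif"].read_text().strip().splitlines()
        assert len(lines) == small_summary.n_edges

    def test_graphml_round_trip(self, small_summary, tmp_path):
        paths = L.export_network(small_summary, tmp_path)
        g = nx.read_graphml(paths["graphml"])
        roles = sorted(d["role"] for _, d in g.nodes(data=True))
        assert roles == sorted(small_summary.nodes["role"])
        rs = sorted(round(d["r"], 9) for _, _, d in g.edges(data=True))
        assert rs == sorted(round(v, 9) for v in small_summary.edges["r"])

    def test_node_table_handshake(self, small_summary, tmp_path):
        paths = L.export_network(small_summary, tmp_path)
        nodes = pd.read_csv(paths["nodes"], sep="\t")
        assert nodes["degree"].sum() == 2 * small_summary.n_edges
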