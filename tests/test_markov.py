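"""Centrality ranking, Graphical Lasso (with an independent first-order
convex solver as oracle), and the key-biomarker rule."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cohortsig.markov import (
    MarkovNetwork,
    eigenvector_centrality,
    graphical_lasso,
    impute_and_transform,
    select_central_features,
    select_key_biomarkers,
)
from cohortsig.preprocess import rank_int


def glasso_oracle(s: np.ndarray, lam: float,
                  max_iter: int = 200_000) -> tuple[np.ndarray, float]:
    """Independent solver: monotone proximal-gradient descent on the primal
    objective -logdet(Theta) + tr(S Theta) + lam * |offdiag(Theta)|_1, with
    backtracking (the -logdet term rejects any step leaving the PD cone)."""
    p = s.shape[0]
    off = ~np.eye(p, dtype=bool)

    def obj(th):
        sign, logdet = np.linalg.slogdet(th)
        if sign <= 0:
            return np.inf
        return -logdet + np.trace(s @ th) + lam * np.abs(th[off]).sum()

    theta = np.linalg.inv(s + 0.1 * np.eye(p))
    f = obj(theta)
    step = 1.0
    stall = 0
    for _ in range(max_iter):
        grad = s - np.linalg.inv(theta)
        while step > 1e-14:
            cand = theta - step * grad
            cand = np.where(
                off,
                np.sign(cand) * np.maximum(np.abs(cand) - step * lam, 0.0),
                cand,
            )
            cand = 0.5 * (cand + cand.T)
            fc = obj(cand)
            if np.isfinite(fc) and fc <= f:
                break
            step *= 0.5
        else:
            break
        if f - fc < 1e-14:
            stall += 1
            if stall > 20:
                theta, f = cand, fc
                break
        else:
            stall = 0
        theta, f = cand, fc
        step *= 1.2
    return theta, float(f)


def _objective(s, theta, lam):
    off = ~np.eye(s.shape[0], dtype=bool)
    return (-np.linalg.slogdet(theta)[1] + np.trace(s @ theta)
            + lam * np.abs(theta[off]).sum())


class TestEigenvectorCentrality:
    def test_star_center_and_leaves(self):
        g = nx.star_graph(4)  # node 0 center, leaves 1..4
        ranking = eigenvector_centrality(g, weighted=False)
        assert ranking.scores[0] == pytest.approx(1.0)
        for leaf in range(1, 5):
            assert ranking.scores[leaf] == pytest.approx(0.5, abs=1e-8)
        assert ranking.order[0] == 0

    def test_cycle_all_equal(self):
        g = nx.cycle_graph(6)
        ranking = eigenvector_centrality(g, weighted=False)
        assert np.allclose(list(ranking.scores.values()), 1.0, atol=1e-8)

    def test_largest_component_rule(self):
        g = nx.complete_graph(5)
        g = nx.union(g, nx.relabel_nodes(nx.complete_graph(3),
                                         {i: i + 10 for i in range(3)}))
        ranking = eigenvector_centrality(g, weighted=False)
        assert all(ranking.scores[i] > 0 for i in range(5))
        assert all(ranking.scores[i + 10] == 0.0 for i in range(3))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            eigenvector_centrality(nx.Graph())


class TestSelectCentral:
    def test_top_k_and_bounds(self):
        from cohortsig.markov import CentralityRanking

        ranking = CentralityRanking(
            scores={"a": 1.0, "b": 0.9, "c": 0.9, "d": 0.2},
            order=["a", "b", "c", "d"],
        )
        assert select_central_features(ranking, 2) == ["a", "b"]
        assert select_central_features(ranking, 4) == ["a", "b", "c", "d"]
        with pytest.raises(ValueError):
            select_central_features(ranking, 1)
        with pytest.raises(ValueError):
            select_central_features(ranking, 5)

    def test_tie_broken_lexicographically(self):
        g = nx.Graph()
        g.add_edges_from([("hub", "bb"), ("hub", "aa")])
        ranking = eigenvector_centrality(g, weighted=False)
        assert select_central_features(ranking, 2) == ["hub", "aa"]


class TestImputeAndTransform:
    def test_mean_fill_then_int(self):
        df = pd.DataFrame({"f": [1.0, np.nan, 3.0]})
        out, frac = impute_and_transform(df)
        expected = rank_int(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out["f"], expected, atol=1e-12)
        assert frac == pytest.approx(1 / 3)

    def test_no_missing_equals_rank_int(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.normal(size=20)})
        out, frac = impute_and_transform(df)
        assert frac == 0.0
        np.testing.assert_allclose(out["a"], rank_int(df["a"].to_numpy()))

    def test_imputed_fraction_counting(self):
        rng = np.random.default_rng(1)
        arr = rng.normal(size=(10, 10))
        flat = [(i, j) for i in range(10) for j in range(10)]
        for k in rng.choice(100, 10, replace=False):
            arr[flat[k]] = np.nan
        # keep every column partially observed
        df = pd.DataFrame(arr)
        if df.isna().all().any():
            pytest.skip("degenerate draw")
        _, frac = impute_and_transform(df)
        assert frac == pytest.approx(0.10)

    def test_all_missing_feature_errors(self):
        df = pd.DataFrame({"a": [np.nan, np.nan, np.nan], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            impute_and_transform(df)


class TestGraphicalLasso:
    def _data(self, seed=0, n=400):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, 3))
        y = x[:, 0] + 0.8 * rng.normal(size=n)
        z = y + 0.8 * rng.normal(size=n)
        return pd.DataFrame({"x": x[:, 0], "y": y, "z": z})

    def test_identity_covariance_yields_no_edges(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(300, 4)),
                          columns=list("abcd"))
        # decorrelate exactly so the empirical covariance is the identity
        x = df.to_numpy()
        x = x - x.mean(0)
        u, _, vt = np.linalg.svd(x, full_matrices=False)
        df = pd.DataFrame(u @ vt * np.sqrt(len(x)), columns=df.columns)
        net = graphical_lasso(df, penalty=0.1)
        assert net.edges == []

    def test_lambda_zero_matches_inverse(self):
        df = self._data()
        net = graphical_lasso(df, penalty=0.0)
        x = df.to_numpy()
        x = (x - x.mean(0)) / x.std(0, ddof=1)
        s = x.T @ x / len(x)
        np.testing.assert_allclose(net.precision.to_numpy(), np.linalg.inv(s),
                                   atol=1e-6)

    def test_chain_conditional_independence(self):
        # data whose sample covariance is exactly the chain model's
        # population covariance (x - y - z, x independent of z given y)
        a = b = 0.4
        c = np.array([[1, a, a * b], [a, 1, b], [a * b, b, 1]])
        rng = np.random.default_rng(2)
        g = rng.normal(size=(500, 3))
        g = g - g.mean(0)
        u, _, vt = np.linalg.svd(g, full_matrices=False)
        white = u @ vt * np.sqrt(len(g))
        df = pd.DataFrame(white @ np.linalg.cholesky(c).T,
                          columns=["x", "y", "z"])
        net = graphical_lasso(df, penalty=0.05)
        pairs = {frozenset((a_, b_)) for a_, b_, _ in net.edges}
        assert pairs == {frozenset(("x", "y")), frozenset(("y", "z"))}
        # the independent solver sees the same structure on the same S
        theta_oracle, _ = glasso_oracle(c, 0.05)
        assert abs(theta_oracle[0, 2]) <= 1e-6
        assert min(abs(theta_oracle[0, 1]), abs(theta_oracle[1, 2])) > 0.1

    @pytest.mark.parametrize("seed,p", [(0, 3), (1, 4), (2, 5)])
    def test_agrees_with_independent_solver(self, seed, p):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(200, p)) @ rng.normal(size=(p, p))
        df = pd.DataFrame(x, columns=[f"v{i}" for i in range(p)])
        for lam in (0.05, 0.2):
            net = graphical_lasso(df, penalty=lam)
            z = df.to_numpy()
            z = (z - z.mean(0)) / z.std(0, ddof=1)
            s = z.T @ z / len(z)
            theta_oracle, f_oracle = glasso_oracle(s, lam)
            f_ours = _objective(s, net.precision.to_numpy(), lam)
            assert f_ours == pytest.approx(f_oracle, abs=1e-4)
            np.testing.assert_allclose(net.precision.to_numpy(), theta_oracle,
                                       atol=1e-3)

    def test_edge_count_monotone_in_lambda(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(150, 6)) @ rng.normal(size=(6, 6))
        df = pd.DataFrame(x, columns=[f"v{i}" for i in range(6)])
        counts = [
            len(graphical_lasso(df, penalty=lam).edges)
            for lam in (0.01, 0.05, 0.1, 0.2, 0.4, 0.8)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_precision_symmetric_positive_definite(self):
        df = self._data(seed=4)
        net = graphical_lasso(df, penalty="ebic")
        theta = net.precision.to_numpy()
        np.testing.assert_allclose(theta, theta.T, atol=1e-10)
        assert np.linalg.eigvalsh(theta).min() > 0

    def test_requires_complete_matrix(self):
        df = self._data()
        df.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            graphical_lasso(df, penalty=0.1)


class TestKeyBiomarkers:
    def _net(self) -> MarkovNetwork:
        # hand-built conditional-independence structure:
        #   micro_a -- met_a (cross-modality)   -> both kept
        #   lab_a  -- lab_b (within-modality only) -> both dropped
        #   met_b  -- met_a (within, but met_a kept via micro_a)
        #   iso    isolated -> dropped
        nodes = ["met_a", "met_b", "micro_a", "lab_a", "lab_b", "iso"]
        theta = np.eye(6)
        pairs = {(0, 2): 0.4, (3, 4): 0.5, (0, 1): 0.3}
        for (i, j), v in pairs.items():
            theta[i, j] = theta[j, i] = v
        mods = pd.Series(
            ["metabolome", "metabolome", "microbiome", "clinical_labs",
             "clinical_labs", "vitals"],
            index=nodes,
        )
        return MarkovNetwork(
            nodes=nodes, modality_of=mods,
            precision=pd.DataFrame(theta, index=nodes, columns=nodes),
            penalty=0.1,
        )

    def test_cross_modality_rule(self):
        key = select_key_biomarkers(self._net())
        assert key.biomarkers == ["met_a", "micro_a"]
        assert "lab_a" not in key.biomarkers and "iso" not in key.biomarkers

    def test_override_replacement(self):
        key = select_key_biomarkers(
            self._net(), overrides={"met_a": "met_b"},
            available_features=["met_a", "met_b", "micro_a"],
        )
        assert key.biomarkers == ["met_b", "micro_a"]
        assert key.pre_override == ["met_a", "micro_a"]
        with pytest.raises(KeyError):
            select_key_biomarkers(
                self._net(), overrides={"met_a": "ghost"},
                available_features=["met_a"],
            )

    def test_rule_idempotent_and_order_independent(self):
        net = self._net()
        first = select_key_biomarkers(net).biomarkers
        reordered = MarkovNetwork(
            nodes=list(reversed(net.nodes)),
            modality_of=net.modality_of,
            precision=net.precision.iloc[::-1, ::-1],
            penalty=net.penalty,
        )
        assert select_key_biomarkers(reordered).biomarkers == first
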