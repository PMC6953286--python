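"""Fisher enrichment, logistic subset-vs-rest associations, transitions,
replication concordance and cross-module overlap."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

from cohortsig.enrich import (
    adjusted_incidence_test,
    bonferroni,
    cross_module_overlap,
    fisher_exact_mc,
    logistic_enrichment,
    replication_concordance,
    transition_analysis,
)


def exact_fisher_rxc(table: np.ndarray) -> float:
    """Enumeration oracle: exact two-sided Fisher p for a small RxC table
    (sum over all tables with the observed margins that are at most as
    probable as the observed one)."""
    table = np.asarray(table, dtype=np.int64)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)

    def log_prob(t):
        return (gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
                - gammaln(t.sum() + 1) - gammaln(t + 1).sum())

    obs = log_prob(table)
    r, c = table.shape

    def tables(row_idx, remaining_cols):
        if row_idx == r - 1:
            last = remaining_cols
            if (last >= 0).all():
                yield last[None, :]
            return
        ranges = [range(min(rows[row_idx], remaining_cols[j]) + 1)
                  for j in range(c)]
        for combo in itertools.product(*ranges):
            combo = np.asarray(combo)
            if combo.sum() != rows[row_idx]:
                continue
            for rest in tables(row_idx + 1, remaining_cols - combo):
                yield np.vstack([combo[None, :], rest])

    total = 0.0
    for t in tables(0, cols.copy()):
        lp = log_prob(t)
        if lp <= obs + 1e-9:
            total += np.exp(lp)
    return float(total)


class TestFisherExactMC:
    def test_2x2_auto_uses_exact(self):
        table = [[8, 2], [2, 8]]
        p = fisher_exact_mc(table, seed=1)
        assert p == pytest.approx(stats.fisher_exact(table)[1], abs=1e-12)
        assert p == pytest.approx(0.0230, abs=2e-4)

    def test_mc_close_to_exact_on_2x2(self):
        table = [[8, 2], [2, 8]]
        exact = stats.fisher_exact(table)[1]
        reps = 20_000
        p = fisher_exact_mc(table, n_replicates=reps, seed=2, method="mc")
        se = np.sqrt(exact * (1 - exact) / reps)
        assert abs(p - exact) <= 3 * se

    def test_mc_matches_enumeration_on_3x2(self):
        table = np.array([[6, 1], [2, 5], [1, 6]])
        exact = exact_fisher_rxc(table)
        reps = 30_000
        p = fisher_exact_mc(table, n_replicates=reps, seed=3)
        se = np.sqrt(exact * (1 - exact) / reps)
        assert abs(p - exact) <= 3 * se

    def test_no_association_large_p(self):
        p = fisher_exact_mc([[50, 50], [50, 50]], seed=4)
        assert p >= 0.5

    def test_same_seed_same_p(self):
        table = np.array([[5, 2, 1], [2, 5, 2], [1, 2, 6]])
        p1 = fisher_exact_mc(table, n_replicates=5000, seed=7)
        p2 = fisher_exact_mc(table, n_replicates=5000, seed=7)
        assert p1 == p2

    def test_degenerate_margins_error(self):
        with pytest.raises(ValueError):
            fisher_exact_mc([[0, 0], [3, 4]], seed=1)


class TestLogisticEnrichment:
    def test_null_type_one_error_rate(self):
        rng = np.random.default_rng(11)
        n, p = 400, 150
        values = pd.DataFrame(rng.normal(size=(n, p)),
                              columns=[f"f{j}" for j in range(p)],
                              index=[f"S{i}" for i in range(n)])
        labels = pd.Series(rng.integers(1, 3, n), index=values.index)
        res = logistic_enrichment(values, labels, subset=1)
        rate = (res["p"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / p)
        assert abs(rate - 0.05) <= 3 * se

    def test_separation_triggers_firth_flag(self):
        rng = np.random.default_rng(12)
        n = 100
        labels = pd.Series([1] * 50 + [2] * 50,
                           index=[f"S{i}" for i in range(n)])
        x = (labels == 1).astype(float) + 1e-4 * rng.normal(size=n)
        values = pd.DataFrame({"sep": x}, index=labels.index)
        res = logistic_enrichment(values, labels, subset=1)
        assert res.loc[0, "flag"] == "separation_firth"
        assert np.isfinite(res.loc[0, "z"]) and abs(res.loc[0, "z"]) > 3

    def test_constant_feature_skipped(self):
        labels = pd.Series([1, 1, 2, 2, 1, 2] * 5,
                           index=[f"S{i}" for i in range(30)])
        values = pd.DataFrame({"const": np.ones(30)}, index=labels.index)
        res = logistic_enrichment(values, labels, subset=1)
        assert res.loc[0, "flag"] == "skipped_degenerate"

    def test_whole_cohort_subset_errors(self):
        labels = pd.Series([1, 1, 1], index=list("abc"))
        values = pd.DataFrame({"f": [1.0, 2.0, 3.0]}, index=list("abc"))
        with pytest.raises(ValueError):
            logistic_enrichment(values, labels, subset=1)


class TestBonferroni:
    def test_threshold_arithmetic(self):
        flags, adj = bonferroni(np.linspace(0.001, 0.5, 10), alpha=0.05)
        assert adj == pytest.approx(0.005)

    def test_examples(self):
        flags, _ = bonferroni(np.array([0.004, 0.006] + [0.5] * 8), alpha=0.05)
        assert flags.tolist()[:2] == [True, False]
        flags, _ = bonferroni(np.ones(5))
        assert not flags.any()


class TestReplicationConcordance:
    def _disc(self):
        return pd.DataFrame(
            {
                "subset": [1, 1, 2, 2],
                "trait": list("abab"),
                "effect": [2.0, -1.0, 0.5, -3.0],
                "p": [0.001, 0.2, 0.04, 1e-6],
            }
        )

    def test_copy_gives_full_direction_concordance(self):
        disc = self._disc()
        same_dir, _ = replication_concordance(disc, disc.copy())
        assert same_dir == 1.0

    def test_negated_effects_zero_concordance(self):
        rep = self._disc()
        rep["effect"] = -rep["effect"]
        same_dir, _ = replication_concordance(self._disc(), rep)
        assert same_dir == 0.0

    def test_empty_intersection_errors(self):
        rep = self._disc()
        rep["subset"] = [9, 9, 9, 9]
        with pytest.raises(ValueError):
            replication_concordance(self._disc(), rep)


class TestTransitions:
    def test_hand_fixture(self):
        b = pd.Series([1, 1, 2, 2], index=list("wxyz"))
        f = pd.Series([1, 2, 2, 2], index=list("wxyz"))
        tm = transition_analysis(b, f)
        np.testing.assert_allclose(tm.rates.to_numpy(),
                                   [[0.5, 0.5], [0.0, 1.0]])
        assert tm.stay_rate == pytest.approx(0.75)

    def test_identity(self):
        b = pd.Series([1, 2, 3, 1], index=list("wxyz"))
        tm = transition_analysis(b, b)
        np.testing.assert_allclose(tm.rates.to_numpy(), np.eye(3))
        assert tm.stay_rate == 1.0

    def test_rows_stochastic_and_relabel_invariant(self):
        rng = np.random.default_rng(13)
        idx = [f"S{i}" for i in range(300)]
        b = pd.Series(rng.integers(1, 5, 300), index=idx)
        f = pd.Series(rng.integers(1, 5, 300), index=idx)
        tm = transition_analysis(b, f)
        np.testing.assert_allclose(tm.rates.sum(axis=1), 1.0, atol=1e-12)
        relabel = {1: 4, 2: 3, 3: 2, 4: 1}
        tm2 = transition_analysis(b.map(relabel), f.map(relabel))
        assert tm2.stay_rate == pytest.approx(tm.stay_rate)

    def test_no_shared_samples_errors(self):
        with pytest.raises(ValueError):
            transition_analysis(pd.Series([1], index=["a"]),
                                pd.Series([1], index=["b"]))


class TestAdjustedIncidence:
    def test_strong_subset_effect_detected(self):
        hits = 0
        n_reps = 20
        for rep in range(n_reps):
            rng = np.random.default_rng(100 + rep)
            n = 800
            idx = [f"S{i}" for i in range(n)]
            member = pd.Series(rng.integers(0, 2, n), index=idx)
            cov = pd.DataFrame(rng.normal(size=(n, 3)),
                               columns=["bp", "bmi", "age"], index=idx)
            logit = -2.5 + np.log(5.0) * member + 0.3 * cov["bp"]
            y = pd.Series(
                (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int),
                index=idx,
            )
            p, beta = adjusted_incidence_test(y, member, cov)
            hits += (p < 0.05) and (beta > 0)
        assert hits / n_reps >= 0.8

    def test_null_type_one_error(self):
        hits = 0
        n_reps = 100
        for rep in range(n_reps):
            rng = np.random.default_rng(300 + rep)
            n = 400
            idx = [f"S{i}" for i in range(n)]
            member = pd.Series(rng.integers(0, 2, n), index=idx)
            cov = pd.DataFrame(rng.normal(size=(n, 3)),
                               columns=["bp", "bmi", "age"], index=idx)
            y = pd.Series((rng.random(n) < 0.15).astype(int), index=idx)
            p, _ = adjusted_incidence_test(y, member, cov)
            hits += p < 0.05
        se = np.sqrt(0.05 * 0.95 / n_reps)
        assert abs(hits / n_reps - 0.05) <= 3 * se

    def test_zero_incident_cases_error(self):
        idx = list("abcd")
        with pytest.raises(ValueError):
            adjusted_incidence_test(
                pd.Series([0, 0, 0, 0], index=idx),
                pd.Series([0, 1, 0, 1], index=idx),
                pd.DataFrame({"age": [1.0, 2.0, 3.0, 4.0]}, index=idx),
            )


class TestCrossModuleOverlap:
    def test_identical_assignments_full_overlap(self):
        idx = [f"S{i}" for i in range(200)]
        rng = np.random.default_rng(14)
        a = pd.Series(rng.integers(1, 4, 200), index=idx)
        overlap, reciprocal, p = cross_module_overlap(a, a, 1, 1,
                                                      n_permutations=200,
                                                      seed=0)
        assert overlap == 1.0 and reciprocal == 1.0
        assert p < 0.05

    def test_independent_assignments_match_base_rate(self):
        rng = np.random.default_rng(15)
        idx = [f"S{i}" for i in range(2000)]
        a = pd.Series(rng.integers(1, 5, 2000), index=idx)
        b = pd.Series(rng.integers(1, 5, 2000), index=idx)
        overlap, _, _ = cross_module_overlap(a, b, 1, 1,
                                             n_permutations=200, seed=1)
        base = (b == 1).mean()
        assert abs(overlap - base) <= 3 * np.sqrt(base * (1 - base) / (a == 1).sum())

    def test_determinism_and_empty_subset_error(self):
        idx = list("abcdef")
        a = pd.Series([1, 1, 2, 2, 1, 2], index=idx)
        b = pd.Series([1, 2, 1, 2, 2, 1], index=idx)
        r1 = cross_module_overlap(a, b, 1, 1, n_permutations=500, seed=5)
        r2 = cross_module_overlap(a, b, 1, 1, n_permutations=500, seed=5)
        assert r1 == r2
        with pytest.raises(ValueError):
            cross_module_overlap(a, b, 9, 1, seed=5)
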