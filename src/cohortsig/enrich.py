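"""Subset characterization and outcome statistics.

Fisher's exact test (exact for 2x2, Monte-Carlo with fixed-margin table
sampling otherwise) with Bonferroni correction for disease/medication
enrichment across subsets; subset-vs-rest logistic regressions per feature
(Wald z, with a Firth-penalized fallback under perfect separation);
replication concordance between discovery and validation; baseline ->
follow-up subset transition matrices with the overall stay-rate; a
covariate-adjusted logistic check of incident disease; and a permutation
test for membership overlap between the subsets of two different modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, gammaln
import statsmodels.api as sm

DEFAULT_MC_REPLICATES = 1_000_000


@dataclass
class TransitionMatrix:
    counts: pd.DataFrame
    rates: pd.DataFrame
    stay_rate: float
    empty_rows: list = field(default_factory=list)


def _log_table_prob(table: np.ndarray) -> float:
    """Log-probability of an RxC table under fixed margins (multivariate
    hypergeometric)."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
        - gammaln(n + 1) - gammaln(table + 1).sum()
    )


def fisher_exact_mc(
    table,
    n_replicates: int = DEFAULT_MC_REPLICATES,
    seed: int = 0,
    method: str = "auto",
) -> float:
    """Fisher's exact test p-value for an RxC contingency table.

    ``method="auto"`` uses the exact two-sided hypergeometric test for 2x2
    tables and Monte-Carlo otherwise; ``"mc"`` forces Monte-Carlo. The MC
    estimator samples tables with the observed margins (Patefield-style)
    and applies the add-one rule
    p = (1 + #{simulated tables at most as probable}) / (n_replicates + 1).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or np.any(t < 0):
        raise ValueError("table must be a 2-D array of non-negative counts")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("degenerate margins: zero row or column")
    if method not in {"auto", "mc", "exact"}:
        raise ValueError("method must be auto, mc or exact")
    if method in {"auto", "exact"} and t.shape == (2, 2):
        return float(stats.fisher_exact(t, alternative="two-sided")[1])
    if method == "exact":
        raise ValueError("exact mode supports only 2x2 tables")
    if n_replicates < 1_000:
        raise ValueError("n_replicates must be >= 1000")
    rng = np.random.default_rng(seed)
    obs_logp = _log_table_prob(t)
    sampler = stats.random_table(rows, cols)
    at_most = 0
    remaining = int(n_replicates)
    batch = 100_000
    while remaining > 0:
        k = min(batch, remaining)
        sims = sampler.rvs(size=k, random_state=rng)
        logp = (
            gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
            - gammaln(t.sum() + 1) - gammaln(sims + 1).sum(axis=(1, 2))
        )
        at_most += int(np.sum(logp <= obs_logp + 1e-9))
        remaining -= k
    return float((1 + at_most) / (n_replicates + 1))


def _firth_logit(x: np.ndarray, y: np.ndarray, max_iter: int = 200,
                 tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Firth-penalized logistic fit; returns (beta, standard errors)."""
    beta = np.zeros(x.shape[1])
    for _ in range(max_iter):
        mu = expit(x @ beta)
        w = mu * (1 - mu)
        info = x.T @ (x * w[:, None])
        info_inv = np.linalg.inv(info)
        h = np.einsum("ij,jk,ik->i", x, info_inv, x) * w
        score = x.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    mu = expit(x @ beta)
    w = mu * (1 - mu)
    info = x.T @ (x * w[:, None])
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return beta, se


def logistic_enrichment(values: pd.DataFrame, assignment: pd.Series,
                        subset) -> pd.DataFrame:
    """Per-feature subset-vs-rest logistic regression.

    For each feature, membership in ``subset`` (1/0) is regressed on the
    single feature over its non-missing samples; the Wald z-statistic and
    two-sided p are reported. Perfect separation triggers a Firth-penalized
    refit (flagged). Constant features are skipped with a reason.
    """
    labels = assignment.loc[values.index]
    y_all = (labels == subset).astype(float).to_numpy()
    if y_all.sum() == 0 or y_all.sum() == len(y_all):
        raise ValueError("subset must be non-empty and not the whole cohort")
    rows = []
    for fid in values.columns:
        col = values[fid].to_numpy(dtype=float)
        obs = ~np.isnan(col)
        xv, yv = col[obs], y_all[obs]
        if xv.size < 10 or np.all(xv == xv[0]) or yv.sum() in (0, yv.size):
            rows.append((fid, np.nan, np.nan, int(xv.size), "skipped_degenerate"))
            continue
        design = np.column_stack([np.ones(xv.size), xv])
        flag = ""
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(yv, design).fit(disp=0, maxiter=200)
            if not fit.mle_retvals.get("converged", False) or np.abs(fit.params).max() > 50:
                raise sm.tools.sm_exceptions.PerfectSeparationError
            z = float(fit.tvalues[1])
            p = float(fit.pvalues[1])
        except Exception:
            beta, se = _firth_logit(design, yv)
            z = float(beta[1] / se[1])
            p = float(2 * stats.norm.sf(abs(z)))
            flag = "separation_firth"
        rows.append((fid, z, p, int(xv.size), flag))
    return pd.DataFrame(rows, columns=["feature", "z", "p", "n", "flag"])


def bonferroni(p_values, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Significance flags and the adjusted threshold alpha/m (m = tests run)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    m = int(np.sum(~np.isnan(p)))
    if m == 0:
        return np.zeros(p.shape, dtype=bool), np.nan
    adjusted = alpha / m
    flags = np.zeros(p.shape, dtype=bool)
    ok = ~np.isnan(p)
    flags[ok] = p[ok] < adjusted
    return flags, adjusted


def replication_concordance(discovery: pd.DataFrame, replication: pd.DataFrame,
                            keys=("subset", "trait"), effect_col: str = "effect",
                            p_col: str = "p", alpha: float = 0.05
                            ) -> tuple[float, float]:
    """(fraction of shared effects with the same sign, fraction significant
    in replication after Bonferroni at the replication test count)."""
    keys = list(keys)
    merged = discovery.merge(replication, on=keys, suffixes=("_disc", "_rep"))
    if merged.empty:
        raise ValueError("no shared (subset, trait) keys")
    same_dir = float(
        (np.sign(merged[f"{effect_col}_disc"]) == np.sign(merged[f"{effect_col}_rep"]))
        .mean()
    )
    flags, _ = bonferroni(merged[f"{p_col}_rep"].to_numpy(), alpha=alpha)
    return same_dir, float(flags.mean())


def transition_analysis(baseline: pd.Series, followup: pd.Series) -> TransitionMatrix:
    """Baseline -> follow-up subset transition counts, row rates, stay-rate."""
    shared = baseline.index.intersection(followup.index)
    if len(shared) == 0:
        raise ValueError("no shared samples between visits")
    b = baseline.loc[shared]
    f = followup.loc[shared]
    labels = sorted(set(b.unique()) | set(f.unique()))
    counts = pd.crosstab(b, f).reindex(index=labels, columns=labels, fill_value=0)
    row_sums = counts.sum(axis=1)
    empty = [lab for lab in labels if row_sums[lab] == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = counts.div(row_sums, axis=0)
    stay = float(np.trace(counts.to_numpy()) / counts.to_numpy().sum())
    return TransitionMatrix(counts=counts, rates=rates, stay_rate=stay,
                            empty_rows=empty)


def adjusted_incidence_test(incident: pd.Series, membership: pd.Series,
                            covariates: pd.DataFrame) -> tuple[float, float]:
    """Logistic regression of incident disease on subset membership plus
    baseline covariates; returns (Wald p, coefficient) for membership.

    The caller restricts to individuals disease-free at baseline.
    """
    shared = incident.index.intersection(membership.index).intersection(covariates.index)
    y = incident.loc[shared].astype(float).to_numpy()
    if y.sum() == 0:
        raise ValueError("no incident cases")
    x = np.column_stack([
        np.ones(len(shared)),
        membership.loc[shared].astype(float).to_numpy(),
        covariates.loc[shared].to_numpy(dtype=float),
    ])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
    return float(fit.pvalues[1]), float(fit.params[1])


def cross_module_overlap(assignment_a: pd.Series, assignment_b: pd.Series,
                         subset_a, subset_b, n_permutations: int = 1000,
                         seed: int = 0) -> tuple[float, float, float]:
    """Membership overlap between a subset of one module's stratification
    and a subset of another's.

    Returns (overlap, reciprocal overlap, permutation p): overlap is
    |A_a intersect B_b| / |A_a|; the reciprocal uses |B_b| as denominator.
    The p-value permutes B's labels over the shared samples.
    """
    shared = assignment_a.index.intersection(assignment_b.index)
    a = assignment_a.loc[shared]
    b = assignment_b.loc[shared]
    in_a = (a == subset_a).to_numpy()
    in_b = (b == subset_b).to_numpy()
    if in_a.sum() == 0 or in_b.sum() == 0:
        raise ValueError("empty subset")
    overlap = float((in_a & in_b).sum() / in_a.sum())
    reciprocal = float((in_a & in_b).sum() / in_b.sum())
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(in_b)
        if (in_a & perm).sum() / in_a.sum() >= overlap - 1e-15:
            hits += 1
    p = (1 + hits) / (n_permutations + 1)
    return overlap, reciprocal, float(p)


def subset_disease_table(assignment: pd.Series, disease: pd.Series) -> pd.DataFrame:
    """K x 2 contingency table of subsets vs disease status."""
    shared = assignment.index.intersection(disease.index)
    return pd.crosstab(assignment.loc[shared], disease.loc[shared])
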