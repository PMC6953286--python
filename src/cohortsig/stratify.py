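"""Stratification of individuals by key-biomarker signatures.

Key-biomarker columns are z-scored (sample SD), missing values completed by
softImpute-style iterative soft-thresholded SVD, and individuals clustered
by complete-linkage agglomeration under the correlation distance
(1 - Pearson r between two individuals' biomarker profiles). The dendrogram
is cut at the lowest height at which every cluster holds at least
``min_size`` individuals. Each subset's representative signature is the
per-biomarker median over its members; validation individuals (standardized
with *training* statistics) are assigned to the signature at minimal
correlation distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import cross_val_score

DEFAULT_MIN_SIZE = 50


@dataclass
class ScalingStats:
    means: pd.Series
    sds: pd.Series


@dataclass
class SubsetAssignment:
    subset_of: pd.Series  # sample -> subset id (1..K)
    cut_height: float
    min_size: int
    K: int


@dataclass
class MembershipDiagnostics:
    median_distances: pd.DataFrame  # samples x subsets
    closest: pd.Series
    agreement_rate: float
    ties: list = field(default_factory=list)


def scale_features(values: pd.DataFrame,
                   stats: ScalingStats | None = None
                   ) -> tuple[pd.DataFrame, ScalingStats]:
    """Column z-scores (sample SD, ddof=1). Pass training ``stats`` to
    standardize a validation matrix in the training signature space."""
    if stats is None:
        means = values.mean(axis=0, skipna=True)
        sds = values.std(axis=0, ddof=1, skipna=True)
        zero = sds[sds == 0]
        if len(zero):
            raise ValueError(f"zero-variance features: {list(zero.index)[:5]}")
        stats = ScalingStats(means=means, sds=sds)
    out = (values - stats.means) / stats.sds
    return out, stats


def soft_impute(values: pd.DataFrame, rank_max: int | None = None,
                shrink: float | None = None, tol: float = 1e-6,
                max_iter: int = 500, holdout_seed: int = 0) -> pd.DataFrame:
    """Low-rank matrix completion by iterative soft-thresholded SVD.

    Missing entries start at 0; each sweep refits the low-rank estimate
    (singular values shrunk by ``shrink``, truncated to ``rank_max``) and
    refills the missing cells, until the relative change drops below
    ``tol``. Observed entries are returned unchanged. When ``shrink`` is
    None it is picked on a small grid by masked-entry holdout error.
    """
    x = values.to_numpy(dtype=float)
    missing = np.isnan(x)
    if not missing.any():
        return values.copy()
    if missing.mean() >= 0.5:
        raise ValueError("missing fraction must be below 0.5")
    if rank_max is None:
        rank_max = max(min(x.shape) - 1, 1)
    if shrink is None:
        shrink = _pick_shrink(x, missing, rank_max, tol, max_iter, holdout_seed)
    completed = _soft_impute_core(x, missing, rank_max, shrink, tol, max_iter)
    out = x.copy()
    out[missing] = completed[missing]
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def _soft_impute_core(x: np.ndarray, missing: np.ndarray, rank_max: int,
                      shrink: float, tol: float, max_iter: int) -> np.ndarray:
    z = np.where(missing, 0.0, x)
    m_old = np.zeros_like(z)
    for _ in range(max_iter):
        u, d, vt = np.linalg.svd(z, full_matrices=False)
        d_shrunk = np.maximum(d - shrink, 0.0)[:rank_max]
        m = (u[:, : len(d_shrunk)] * d_shrunk) @ vt[: len(d_shrunk)]
        denom = np.linalg.norm(m_old) + 1e-12
        delta = np.linalg.norm(m - m_old) / denom
        m_old = m
        z = np.where(missing, m, x)
        if delta < tol:
            return m
    raise RuntimeError(f"soft_impute did not converge in {max_iter} iterations")


def _pick_shrink(x, missing, rank_max, tol, max_iter, seed) -> float:
    rng = np.random.default_rng(seed)
    obs_idx = np.argwhere(~missing)
    n_mask = max(int(0.1 * len(obs_idx)), 1)
    chosen = obs_idx[rng.choice(len(obs_idx), size=n_mask, replace=False)]
    holdout = missing.copy()
    holdout[chosen[:, 0], chosen[:, 1]] = True
    truth = x[chosen[:, 0], chosen[:, 1]]
    top = np.linalg.svd(np.where(missing, 0.0, x), compute_uv=False)[0]
    best_shrink, best_err = 0.0, np.inf
    for frac in (0.0, 0.01, 0.05, 0.1, 0.2):
        try:
            m = _soft_impute_core(x, holdout, rank_max, frac * top, tol, max_iter)
        except RuntimeError:
            continue
        err = float(np.mean((m[chosen[:, 0], chosen[:, 1]] - truth) ** 2))
        if err < best_err:
            best_shrink, best_err = frac * top, err
    return best_shrink


def correlation_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - Pearson r between two profiles; range [0, 2]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    du = u - u.mean()
    dv = v - v.mean()
    nu, nv = np.linalg.norm(du), np.linalg.norm(dv)
    if nu == 0 or nv == 0:
        raise ValueError("correlation distance undefined for a constant profile")
    return float(1.0 - (du @ dv) / (nu * nv))


def hierarchical_cluster(profiles: pd.DataFrame) -> np.ndarray:
    """Complete-linkage merge tree under the correlation distance."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 individuals")
    x = profiles.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("profiles must be complete (impute first)")
    sds = x.std(axis=1)
    if np.any(sds == 0):
        raise ValueError("constant profile rows present")
    d = pdist(x, metric="correlation")
    return linkage(d, method="complete")


def cut_tree_min_size(z: np.ndarray, n_samples: int,
                      min_size: int = DEFAULT_MIN_SIZE,
                      sample_ids=None) -> SubsetAssignment:
    """Lowest dendrogram cut at which every cluster has >= min_size members.

    Candidate heights are the merge heights, scanned ascending; cuts that
    leave only one cluster do not qualify (the all-in-one root cut is the
    K=1 fallback, returned with a warning when no multi-cluster cut works).
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if sample_ids is None:
        sample_ids = list(range(n_samples))
    heights = np.unique(z[:, 2])
    candidates = np.concatenate([[0.0], heights])
    for h in candidates:
        labels = fcluster(z, t=h, criterion="distance")
        sizes = np.bincount(labels)[1:]
        if len(sizes) >= 2 and sizes.min() >= min_size:
            return SubsetAssignment(
                subset_of=pd.Series(labels, index=sample_ids, name="subset"),
                cut_height=float(h),
                min_size=min_size,
                K=int(len(sizes)),
            )
    warnings.warn("no multi-cluster cut satisfies the minimum size; returning K=1")
    return SubsetAssignment(
        subset_of=pd.Series(1, index=sample_ids, name="subset"),
        cut_height=float(heights.max()),
        min_size=min_size,
        K=1,
    )


def membership_diagnostics(profiles: pd.DataFrame,
                           assignment: SubsetAssignment) -> MembershipDiagnostics:
    """Per-individual median correlation distance to each subset.

    The individual is excluded from its own subset when computing its own
    median; the closest subset is the argmin with ties broken toward the
    lower subset id (tied individuals are flagged)."""
    labels = assignment.subset_of.loc[profiles.index]
    x = profiles.to_numpy(dtype=float)
    d = squareform(pdist(x, metric="correlation"))
    subsets = sorted(labels.unique())
    med = np.full((len(profiles), len(subsets)), np.nan)
    for sj, s in enumerate(subsets):
        members = np.flatnonzero((labels == s).to_numpy())
        for i in range(len(profiles)):
            others = members[members != i]
            if len(others) == 0:
                continue
            med[i, sj] = np.median(d[i, others])
    ties = []
    closest = []
    for i in range(len(profiles)):
        row = med[i]
        best = np.nanmin(row)
        hits = [subsets[j] for j in range(len(subsets))
                if not np.isnan(row[j]) and row[j] <= best + 1e-15]
        if len(hits) > 1:
            ties.append(profiles.index[i])
        closest.append(hits[0])
    closest = pd.Series(closest, index=profiles.index, name="closest_subset")
    agreement = float((closest.to_numpy() == labels.to_numpy()).mean())
    return MembershipDiagnostics(
        median_distances=pd.DataFrame(med, index=profiles.index, columns=subsets),
        closest=closest,
        agreement_rate=agreement,
        ties=ties,
    )


def compute_signatures(profiles: pd.DataFrame,
                       assignment: SubsetAssignment) -> pd.DataFrame:
    """Per-subset, per-biomarker median (midpoint convention for even sizes)."""
    labels = assignment.subset_of.loc[profiles.index]
    return profiles.groupby(labels).median()


def assign_by_signature(profiles: pd.DataFrame, signatures: pd.DataFrame
                        ) -> tuple[pd.Series, pd.DataFrame]:
    """Assign each profile to the representative signature at minimal
    correlation distance; the full distance vector is the sample
    similarity score. Constant profiles are unassignable (label <NA>)."""
    cols = list(signatures.columns)
    x = profiles[cols].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("profiles must be complete before assignment")
    dists = np.full((len(profiles), len(signatures)), np.nan)
    sig = signatures.to_numpy(dtype=float)
    labels = []
    for i in range(len(profiles)):
        if np.std(x[i]) == 0:
            labels.append(pd.NA)
            continue
        for j in range(len(signatures)):
            dists[i, j] = correlation_distance(x[i], sig[j])
        labels.append(signatures.index[int(np.nanargmin(dists[i]))])
    labels = pd.Series(labels, index=profiles.index, name="subset")
    dist_df = pd.DataFrame(dists, index=profiles.index, columns=signatures.index)
    return labels, dist_df


def l1_impute_missing_features(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    targets,
    cv: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Fill validation features absent from the registry by lasso regression.

    Per target: LassoCV fit on training rows where the target is observed,
    predictors being the shared features (mean-imputed with training
    means); the cross-validated R^2 at the selected penalty is reported.
    """
    targets = list(targets)
    completed = validation.copy()
    scores: dict = {}
    if not targets:
        return completed, scores
    predictors = [
        c for c in train.columns
        if c in validation.columns and c not in targets
        and not validation[c].isna().all()
    ]
    train_means = train[predictors].mean(axis=0, skipna=True)
    xt_all = train[predictors].fillna(train_means)
    xv = validation[predictors].fillna(train_means).to_numpy(dtype=float)
    for target in targets:
        y = train[target]
        rows = y.notna()
        if rows.sum() < 10:
            raise ValueError(f"target {target}: fewer than 10 complete training rows")
        xt = xt_all.loc[rows].to_numpy(dtype=float)
        yt = y[rows].to_numpy(dtype=float)
        model = LassoCV(cv=cv, random_state=seed, max_iter=50000)
        model.fit(xt, yt)
        refit = Lasso(alpha=model.alpha_, max_iter=50000)
        r2 = cross_val_score(refit, xt, yt, cv=cv, scoring="r2")
        scores[target] = float(np.mean(r2))
        completed[target] = model.predict(xv)
    return completed, scores
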