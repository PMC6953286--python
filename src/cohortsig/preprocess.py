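"""Feature normalization and covariate correction.

Pipeline order (fixed, to avoid re-introducing bias): rank-based inverse
normal transformation (INT) on features that need it, then per-feature
multiple linear regression on age, sex and four ancestry PCs, keeping the
covariates significant at ``alpha`` and replacing the feature by the
residuals of a refit on those covariates only. The fitted
:class:`PreprocessModel` stores which covariates were selected and their
coefficients so a validation cohort can be corrected with the *training*
coefficients, without refitting.

INT uses the Blom offset c = 3/8: x -> Phi^{-1}((r - 3/8) / (n + 1/4)),
with average ranks for ties. A feature is transformed when its modality is
a designated abundance modality (all microbiome abundances are non-Gaussian)
or when more than 40% of its non-missing values are identical (strict
inequality at the boundary).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import COVARIATE_COLUMNS, CovariateTable, FeatureMatrix

BLOM_OFFSET = 0.375
DEFAULT_ABUNDANCE_MODALITIES = frozenset({"microbiome"})


def rank_int(values: np.ndarray | pd.Series, c: float = BLOM_OFFSET) -> np.ndarray:
    """Rank-based inverse normal transformation with offset ``c``.

    Non-missing entries are mapped through Phi^{-1}((r - c)/(n - 2c + 1))
    using average ranks for ties; missing entries stay missing.

    Raises
    ------
    ValueError
        If fewer than 3 non-missing values, or all values identical.
    """
    arr = np.asarray(values, dtype=float)
    out = np.full(arr.shape, np.nan)
    obs = ~np.isnan(arr)
    n = int(obs.sum())
    if n < 3:
        raise ValueError("rank_int requires at least 3 non-missing values")
    x = arr[obs]
    if np.all(x == x[0]):
        raise ValueError("rank_int undefined for a constant vector")
    ranks = stats.rankdata(x, method="average")
    out[obs] = stats.norm.ppf((ranks - c) / (n - 2 * c + 1))
    return out


def needs_transformation(
    values: np.ndarray | pd.Series,
    modality: str,
    abundance_modalities: frozenset[str] = DEFAULT_ABUNDANCE_MODALITIES,
    max_tie_fraction: float = 0.40,
) -> bool:
    """Whether a feature gets the INT before covariate correction.

    True for every abundance-modality feature, and for any feature whose
    modal value occurs in strictly more than ``max_tie_fraction`` of the
    non-missing samples.
    """
    if modality in abundance_modalities:
        return True
    arr = np.asarray(values, dtype=float)
    x = arr[~np.isnan(arr)]
    if x.size == 0:
        raise ValueError("needs_transformation requires >= 1 non-missing value")
    _, counts = np.unique(x, return_counts=True)
    return bool(counts.max() / x.size > max_tie_fraction)


@dataclass
class FeatureModel:
    int_applied: bool
    selected_covariates: list[str]
    intercept: float
    coefficients: dict[str, float]
    skipped: bool = False

    def to_dict(self) -> dict:
        return {
            "int_applied": self.int_applied,
            "selected_covariates": list(self.selected_covariates),
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "skipped": self.skipped,
        }


@dataclass
class PreprocessModel:
    """Per-feature record of the fitted normalization + correction."""

    features: dict[str, FeatureModel] = field(default_factory=dict)
    alpha: float = 0.01

    def to_json(self) -> str:
        return json.dumps(
            {
                "alpha": self.alpha,
                "features": {f: m.to_dict() for f, m in self.features.items()},
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "PreprocessModel":
        raw = json.loads(text)
        feats = {
            f: FeatureModel(
                int_applied=d["int_applied"],
                selected_covariates=list(d["selected_covariates"]),
                intercept=d["intercept"],
                coefficients=dict(d["coefficients"]),
                skipped=d.get("skipped", False),
            )
            for f, d in raw["features"].items()
        }
        return cls(features=feats, alpha=raw["alpha"])


def _ols(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS fit with intercept; returns (coef incl. intercept, p-values)."""
    n, k = x.shape
    design = np.column_stack([np.ones(n), x])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design")
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    dof = n - design.shape[1]
    if dof <= 0:
        raise np.linalg.LinAlgError("not enough complete cases")
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(design.T @ design)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pvals = 2 * stats.t.sf(np.abs(tstat), dof)
    return beta, pvals


def fit_covariate_correction(
    matrix: FeatureMatrix,
    covariates: CovariateTable,
    alpha: float = 0.01,
    abundance_modalities: frozenset[str] = DEFAULT_ABUNDANCE_MODALITIES,
    on_degenerate: str = "raise",
) -> tuple[FeatureMatrix, PreprocessModel]:
    """Normalize and covariate-correct every feature; return the residual
    matrix and the fitted model for reuse on a validation cohort.

    Per feature: conditional INT; joint OLS on all six covariates over
    complete cases; covariates with coefficient p < ``alpha`` are selected;
    the feature is replaced by residuals of a refit on the selected
    covariates only. Features with no selected covariate pass through
    (post-INT) unchanged. Features with too few complete cases are skipped
    with a warning and recorded as such in the model. Exactly constant
    features are degenerate: an error by default, or skipped with a warning
    under ``on_degenerate="drop"``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if on_degenerate not in {"raise", "drop"}:
        raise ValueError("on_degenerate must be 'raise' or 'drop'")
    cov_df = covariates.aligned_to(matrix.sample_ids)
    covs = list(COVARIATE_COLUMNS)
    min_cases = len(covs) + 2
    out = matrix.values.copy()
    model = PreprocessModel(alpha=alpha)
    for fid in matrix.feature_ids:
        col = out[fid].to_numpy(dtype=float)
        modality = matrix.modality_of[fid]
        obs = ~np.isnan(col)
        if obs.sum() == 0:
            warnings.warn(f"feature {fid}: all values missing; skipped")
            model.features[fid] = FeatureModel(False, [], 0.0, {}, skipped=True)
            continue
        if np.all(col[obs] == col[obs][0]):
            if on_degenerate == "raise":
                raise ValueError(f"feature {fid} is degenerate (constant)")
            warnings.warn(f"feature {fid}: constant; skipped")
            model.features[fid] = FeatureModel(False, [], 0.0, {}, skipped=True)
            continue
        int_flag = needs_transformation(col, modality, abundance_modalities)
        if int_flag:
            try:
                col = rank_int(col)
            except ValueError as exc:
                warnings.warn(f"feature {fid}: {exc}; skipped")
                model.features[fid] = FeatureModel(True, [], 0.0, {}, skipped=True)
                continue
            out[fid] = col
        if obs.sum() < min_cases:
            warnings.warn(f"feature {fid}: fewer than {min_cases} complete cases; skipped")
            model.features[fid] = FeatureModel(int_flag, [], 0.0, {}, skipped=True)
            continue
        y = col[obs]
        x_full = cov_df.loc[obs, covs].to_numpy()
        if np.all(y == y[0]):
            raise ValueError(f"feature {fid} is degenerate (constant after INT)")
        try:
            _, pvals = _ols(y, x_full)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(f"feature {fid}: {exc}") from exc
        selected = [c for c, p in zip(covs, pvals[1:]) if p < alpha]
        if not selected:
            model.features[fid] = FeatureModel(int_flag, [], 0.0, {})
            continue
        x_sel = cov_df.loc[obs, selected].to_numpy()
        beta, _ = _ols(y, x_sel)
        fitted = beta[0] + x_sel @ beta[1:]
        col[obs] = y - fitted
        out[fid] = col
        model.features[fid] = FeatureModel(
            int_flag, selected, float(beta[0]),
            {c: float(b) for c, b in zip(selected, beta[1:])},
        )
    return FeatureMatrix(out, matrix.modality_of.copy()), model


def apply_covariate_correction(
    matrix: FeatureMatrix,
    covariates: CovariateTable,
    model: PreprocessModel,
) -> FeatureMatrix:
    """Correct a (validation) matrix with stored training coefficients.

    For each modelled feature: apply the INT (within the new cohort, as the
    transform is rank-based) when the model flags it, then subtract
    intercept + stored coefficients applied to the new covariates. No
    refitting. Features absent from the model pass through.
    """
    cov_df = covariates.aligned_to(matrix.sample_ids)
    out = matrix.values.copy()
    for fid, fm in model.features.items():
        if fid not in out.columns or fm.skipped:
            continue
        col = out[fid].to_numpy(dtype=float)
        if np.all(np.isnan(col)):
            continue
        if fm.int_applied:
            col = rank_int(col)
        if fm.selected_covariates:
            x = cov_df[fm.selected_covariates].to_numpy()
            beta = np.array([fm.coefficients[c] for c in fm.selected_covariates])
            col = col - (fm.intercept + x @ beta)
        out[fid] = col
    return FeatureMatrix(out, matrix.modality_of.copy())


def species_richness(abundances: np.ndarray | pd.Series, threshold: float = 1e-4) -> int:
    """Number of taxa present at relative abundance strictly above ``threshold``."""
    arr = np.asarray(abundances, dtype=float)
    arr = arr[~np.isnan(arr)]
    if np.any(arr < 0):
        raise ValueError("abundances must be non-negative")
    if arr.sum() > 1 + 1e-6:
        raise ValueError("abundances must sum to <= 1")
    return int(np.sum(arr > threshold))


def shannon_diversity(abundances: np.ndarray | pd.Series) -> float:
    """Shannon entropy (nats) of the abundance vector, renormalized to sum 1."""
    arr = np.asarray(abundances, dtype=float)
    arr = arr[~np.isnan(arr)]
    if np.any(arr < 0):
        raise ValueError("abundances must be non-negative")
    total = arr.sum()
    if total <= 0:
        raise ValueError("abundance vector must have positive sum")
    p = arr[arr > 0] / total
    return float(-(p * np.log(p)).sum())
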