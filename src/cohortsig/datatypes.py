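"""Core containers shared by every pipeline stage.

A :class:`FeatureMatrix` is a samples x features table with a per-feature
modality label (metabolome, microbiome, clinical_labs, ...); missing values
are ``NaN``. A :class:`CovariateTable` holds the adjustment covariates:
age, sex (0/1), and the first four ancestry principal components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COVARIATE_COLUMNS = ("age", "sex", "pc1", "pc2", "pc3", "pc4")


@dataclass
class FeatureMatrix:
    """Samples x features numeric table with modality labels.

    Parameters
    ----------
    values
        DataFrame indexed by sample id, one column per feature id. Missing
        entries are ``NaN``; infinities are rejected.
    modality_of
        Series mapping every feature id to its modality label.
    """

    values: pd.DataFrame
    modality_of: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("sample ids must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("feature ids must be unique")
        missing_labels = set(self.values.columns) - set(self.modality_of.index)
        if missing_labels:
            raise ValueError(
                f"modality_of does not cover features: {sorted(missing_labels)[:5]}"
            )
        self.modality_of = self.modality_of.reindex(self.values.columns)
        arr = self.values.to_numpy(dtype=float, copy=False)
        if np.isinf(arr).any():
            raise ValueError("feature matrix contains infinite values")

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list:
        return list(self.values.columns)

    @property
    def modalities(self) -> list:
        return sorted(self.modality_of.unique())

    def features_of_modality(self, modality: str) -> list:
        return list(self.modality_of.index[self.modality_of == modality])

    def subset_features(self, feature_ids) -> "FeatureMatrix":
        feature_ids = list(feature_ids)
        unknown = set(feature_ids) - set(self.values.columns)
        if unknown:
            raise KeyError(f"unknown feature ids: {sorted(unknown)[:5]}")
        return FeatureMatrix(
            values=self.values[feature_ids].copy(),
            modality_of=self.modality_of.loc[feature_ids].copy(),
        )

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.values.copy(), self.modality_of.copy())


@dataclass
class CovariateTable:
    """Adjustment covariates: age, sex and four ancestry PCs per sample."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(COVARIATE_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"covariate table lacks columns: {sorted(missing)}")
        if not self.table.index.is_unique:
            raise ValueError("covariate sample ids must be unique")
        self.table = self.table[list(COVARIATE_COLUMNS)].astype(float)
        if self.table.isna().any().any():
            raise ValueError("missing covariate values are not allowed")

    @property
    def sample_ids(self) -> list:
        return list(self.table.index)

    def aligned_to(self, sample_ids) -> pd.DataFrame:
        missing = set(sample_ids) - set(self.table.index)
        if missing:
            raise KeyError(f"covariates missing for samples: {sorted(missing)[:5]}")
        return self.table.loc[list(sample_ids)]


@dataclass
class SyntheticCohort:
    """A generated cohort with its planted ground truth.

    ``true_module_of_feature`` maps features belonging to a planted
    cross-modality module to the module id (features outside any planted
    module are absent from the map); ``true_subset_of_sample`` records the
    planted health-status subset of every individual.
    """

    features: FeatureMatrix
    covariates: CovariateTable
    true_module_of_feature: dict = field(default_factory=dict)
    true_subset_of_sample: pd.Series | None = None
    disease_labels: pd.DataFrame | None = None
    followup_features: FeatureMatrix | None = None
    followup_true_subset: pd.Series | None = None
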