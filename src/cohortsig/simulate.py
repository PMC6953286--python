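"""Seeded synthetic multimodal cohorts with planted structure.

The generator emulates the statistical structure the downstream analysis
assumes: several data modalities, latent-factor cross-modality correlation
modules, covariate (age/sex/ancestry) confounding, compositional microbiome
abundances (non-negative, per-sample sum <= 1, tie-rich after truncation),
missing-at-random entries plus whole-modality block missingness, planted
individual subsets realized as signed mean shifts of the first module's
features, disease labels with subset-specific prevalence, and follow-up
visits driven by a known subset transition matrix.

Every draw descends from a single integer seed, so a cohort is bit-identical
across runs with the same configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import COVARIATE_COLUMNS, CovariateTable, FeatureMatrix, SyntheticCohort

_DEFAULT_MODALITIES = {
    "metabolome": 40,
    "clinical_labs": 24,
    "microbiome": 30,
    "body_composition": 16,
    "vitals": 10,
}

# abundances below this floor are recorded as exact zeros, giving the
# tie-rich columns the conditional rank-INT rule is designed for
_ABUNDANCE_FLOOR = 1e-5


def _default_transition_matrix() -> np.ndarray:
    # mostly-stay dynamics, with subset 3 acting as a precursor state that
    # drains into subset 4 (the at-risk subset)
    t = np.full((4, 4), 0.1)
    np.fill_diagonal(t, 0.7)
    t[2] = [0.1, 0.1, 0.2, 0.6]
    return t / t.sum(axis=1, keepdims=True)


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic-cohort generator.

    Attributes
    ----------
    n_samples
        Individuals per generated visit.
    n_features_per_modality
        Modality label -> number of features.
    n_planted_modules
        Number of latent-factor cross-modality modules.
    module_loading
        Loading of module features on their latent factor, in [0, 1];
        scalar or one value per module.
    n_features_per_module
        Features drawn into each planted module (round-robin over
        modalities so every module spans >= 2 modalities).
    n_planted_subsets
        Number of planted individual subsets.
    subset_effect_size
        Standardized mean shift applied to each signature feature
        (the first planted module's features) per subset.
    covariate_effects
        Covariate name -> regression coefficient; each effect is applied to
        a seeded random half of the features.
    missing_rate
        Fraction of entries set missing at random (after signal build).
    modality_block_missing
        Modality -> fraction of samples with the whole modality missing.
    disease_enrichment
        Subset id (1-based) -> disease prevalence; subsets not listed use
        ``baseline_prevalence``.
    transition_matrix_true
        Row-stochastic subset x subset matrix driving follow-up visits.
    seed
        Master seed; all randomness descends from it.
    """

    n_samples: int = 600
    n_features_per_modality: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_MODALITIES)
    )
    n_planted_modules: int = 2
    module_loading: float | Sequence[float] = 0.7
    n_features_per_module: int = 24
    n_planted_subsets: int = 4
    subset_effect_size: float = 1.0
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"age": 0.3, "sex": 0.5, "pc1": 0.2}
    )
    missing_rate: float = 0.05
    modality_block_missing: Mapping[str, float] = field(
        default_factory=lambda: {"microbiome": 0.15}
    )
    disease_enrichment: Mapping[int, float] = field(default_factory=lambda: {4: 0.30})
    baseline_prevalence: float = 0.05
    transition_matrix_true: np.ndarray = field(
        default_factory=_default_transition_matrix
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if any(c <= 0 for c in self.n_features_per_modality.values()):
            raise ValueError("feature counts must be positive")
        if self.n_planted_modules < 0 or self.n_planted_subsets <= 0:
            raise ValueError("counts must be positive")
        loadings = self.loadings()
        if np.any((loadings < 0) | (loadings > 1)):
            raise ValueError("module_loading must lie in [0, 1]")
        for name, rate in [("missing_rate", self.missing_rate)] + [
            (f"modality_block_missing[{m}]", r)
            for m, r in self.modality_block_missing.items()
        ]:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for s, prev in self.disease_enrichment.items():
            if not 0.0 <= prev <= 1.0:
                raise ValueError(f"disease_enrichment[{s}] must lie in [0, 1]")
        unknown = set(self.covariate_effects) - set(COVARIATE_COLUMNS)
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")
        t = np.asarray(self.transition_matrix_true, dtype=float)
        if t.shape != (self.n_planted_subsets, self.n_planted_subsets):
            raise ValueError(
                "transition_matrix_true shape must match n_planted_subsets"
            )
        if np.any(t < 0) or np.any(np.abs(t.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition_matrix_true rows must sum to 1")
        self.transition_matrix_true = t

    def loadings(self) -> np.ndarray:
        if np.isscalar(self.module_loading):
            return np.full(self.n_planted_modules, float(self.module_loading))
        arr = np.asarray(self.module_loading, dtype=float)
        if arr.shape != (self.n_planted_modules,):
            raise ValueError("module_loading length must equal n_planted_modules")
        return arr

    @property
    def total_features(self) -> int:
        return int(sum(self.n_features_per_modality.values()))


def _feature_frame(config: GeneratorConfig) -> tuple[list[str], pd.Series]:
    """Feature ids and their modality labels, in a fixed deterministic order."""
    ids: list[str] = []
    modality: list[str] = []
    for mod in sorted(config.n_features_per_modality):
        for k in range(config.n_features_per_modality[mod]):
            ids.append(f"{mod}_{k:03d}")
            modality.append(mod)
    return ids, pd.Series(modality, index=ids, name="modality")


def _plant_modules(config: GeneratorConfig) -> dict[str, int]:
    """Assign features to planted modules, round-robin across modalities.

    Guarantees every module spans at least two modalities (requires at
    least two modalities in the config when modules are planted).
    """
    if config.n_planted_modules == 0:
        return {}
    mods = sorted(config.n_features_per_modality)
    if len(mods) < 2:
        raise ValueError("planted modules require >= 2 modalities")
    per_mod_cursor = {m: 0 for m in mods}
    assignment: dict[str, int] = {}
    for module_id in range(1, config.n_planted_modules + 1):
        taken = 0
        mi = 0
        while taken < config.n_features_per_module:
            mod = mods[mi % len(mods)]
            cursor = per_mod_cursor[mod]
            if cursor < config.n_features_per_modality[mod]:
                assignment[f"{mod}_{cursor:03d}"] = module_id
                per_mod_cursor[mod] = cursor + 1
                taken += 1
            elif all(
                per_mod_cursor[m] >= config.n_features_per_modality[m] for m in mods
            ):
                raise ValueError("not enough features to plant the requested modules")
            mi += 1
    return assignment


def _subset_sign_patterns(config: GeneratorConfig, rng: np.random.Generator,
                          signature_features: list[str]) -> np.ndarray:
    """Per-subset +/-1 pattern over signature features (rows: subsets).

    Patterns are mutually orthogonal, non-constant Hadamard rows (tiled to
    the signature length) so every pair of subsets is maximally separated
    under the correlation distance; which row each subset receives is
    randomized. Falls back to distinct random patterns when the signature
    is too short for an orthogonal construction.
    """
    from scipy.linalg import hadamard

    k, p = config.n_planted_subsets, len(signature_features)
    if p == 0:
        return np.zeros((k, 0))
    order = int(2 ** np.ceil(np.log2(k + 1)))
    if p >= order:
        h = hadamard(order).astype(float)
        rows = h[1:, :]  # drop the constant row: invisible to correlation
        chosen = rng.permutation(rows.shape[0])[:k]
        reps = int(np.ceil(p / order))
        return np.tile(rows[chosen], (1, reps))[:, :p]
    patterns = rng.choice([-1.0, 1.0], size=(k, p))
    for i in range(1, k):
        while any(np.array_equal(patterns[i], patterns[j]) for j in range(i)):
            patterns[i] = rng.choice([-1.0, 1.0], size=p)
    return patterns


def _covariate_targets(config: GeneratorConfig, rng: np.random.Generator,
                       feature_ids: list[str]) -> dict[str, np.ndarray]:
    """For each covariate with an effect, a boolean mask over features
    selecting the seeded random half that carries the effect."""
    targets = {}
    p = len(feature_ids)
    for cov in sorted(config.covariate_effects):
        mask = np.zeros(p, dtype=bool)
        mask[rng.choice(p, size=p // 2, replace=False)] = True
        targets[cov] = mask
    return targets


def _draw_covariates(config: GeneratorConfig, rng: np.random.Generator,
                     sample_ids: list[str]) -> CovariateTable:
    n = len(sample_ids)
    table = pd.DataFrame(
        {
            "age": rng.normal(0.0, 1.0, n),  # standardized age
            "sex": rng.integers(0, 2, n).astype(float),
            "pc1": rng.normal(0.0, 1.0, n),
            "pc2": rng.normal(0.0, 1.0, n),
            "pc3": rng.normal(0.0, 1.0, n),
            "pc4": rng.normal(0.0, 1.0, n),
        },
        index=sample_ids,
    )
    return CovariateTable(table)


def _build_feature_values(
    config: GeneratorConfig,
    rng: np.random.Generator,
    subsets: np.ndarray,
    covariates: CovariateTable,
    module_of: dict[str, int],
    patterns: np.ndarray,
    cov_targets: dict[str, np.ndarray],
    feature_ids: list[str],
    modality_of: pd.Series,
) -> pd.DataFrame:
    """Latent signal -> Gaussian features; microbiome mapped to compositions."""
    n, p = config.n_samples, len(feature_ids)
    loadings = config.loadings()
    factors = rng.normal(0.0, 1.0, size=(n, config.n_planted_modules))
    x = np.empty((n, p))
    signature_features = [f for f in feature_ids if module_of.get(f) == 1]
    sig_col = {f: j for j, f in enumerate(signature_features)}
    for j, fid in enumerate(feature_ids):
        module = module_of.get(fid)
        if module is not None:
            lam = loadings[module - 1]
            signal = lam * factors[:, module - 1]
            noise_sd = np.sqrt(max(1.0 - lam**2, 1e-12))
        else:
            signal = 0.0
            noise_sd = 1.0
        col = signal + rng.normal(0.0, noise_sd, n)
        if fid in sig_col:
            shift = patterns[subsets - 1, sig_col[fid]] * config.subset_effect_size
            col = col + shift
        x[:, j] = col
    cov_table = covariates.aligned_to(list(covariates.sample_ids))
    for cov in sorted(config.covariate_effects):
        beta = config.covariate_effects[cov]
        if beta == 0.0:
            continue
        mask = cov_targets[cov]
        x[:, mask] += beta * cov_table[cov].to_numpy()[:, None]
    values = pd.DataFrame(x, index=covariates.sample_ids, columns=feature_ids)
    micro_cols = [f for f in feature_ids if modality_of[f] == "microbiome"]
    if micro_cols:
        z = 2.0 * values[micro_cols].to_numpy()  # heavy-tailed latent scale
        expz = np.exp(z - z.max(axis=1, keepdims=True))
        # implicit "unclassified remainder" keeps per-sample sums < 1
        denom = expz.sum(axis=1, keepdims=True) + np.exp(-z.max(axis=1, keepdims=True))
        comp = expz / denom
        comp[comp < _ABUNDANCE_FLOOR] = 0.0
        values[micro_cols] = comp
    return values


def _apply_missingness(config: GeneratorConfig, rng: np.random.Generator,
                       values: pd.DataFrame, modality_of: pd.Series) -> pd.DataFrame:
    out = values.to_numpy(copy=True)
    if config.missing_rate > 0:
        mask = rng.random(out.shape) < config.missing_rate
        out[mask] = np.nan
    for mod in sorted(config.modality_block_missing):
        frac = config.modality_block_missing[mod]
        if frac <= 0:
            continue
        cols = np.asarray([modality_of[c] == mod for c in values.columns])
        n_block = int(round(frac * out.shape[0]))
        rows = rng.choice(out.shape[0], size=n_block, replace=False)
        out[np.ix_(rows, cols)] = np.nan
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def _draw_disease(config: GeneratorConfig, rng: np.random.Generator,
                  subsets: np.ndarray, sample_ids: list[str]) -> pd.DataFrame:
    prevalence = np.array(
        [
            config.disease_enrichment.get(s, config.baseline_prevalence)
            for s in subsets
        ]
    )
    labels = (rng.random(len(subsets)) < prevalence).astype(int)
    return pd.DataFrame({"disease": labels}, index=sample_ids)


def _generate_visit(
    config: GeneratorConfig,
    rng: np.random.Generator,
    sample_ids: list[str],
    subsets: np.ndarray,
    module_of: dict[str, int],
    patterns: np.ndarray,
    cov_targets: dict[str, np.ndarray],
    feature_ids: list[str],
    modality_of: pd.Series,
    covariates: CovariateTable | None = None,
) -> tuple[FeatureMatrix, CovariateTable]:
    if covariates is None:
        covariates = _draw_covariates(config, rng, sample_ids)
    values = _build_feature_values(
        config, rng, subsets, covariates, module_of, patterns, cov_targets,
        feature_ids, modality_of,
    )
    values = _apply_missingness(config, rng, values, modality_of)
    return FeatureMatrix(values, modality_of.copy()), covariates


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate the study cohort defined by ``config``.

    Returns a :class:`SyntheticCohort` carrying the feature matrix,
    covariates, disease labels and the planted ground truth (module of each
    module feature, subset of each individual).
    """
    rng = np.random.default_rng(config.seed)
    feature_ids, modality_of = _feature_frame(config)
    module_of = _plant_modules(config)
    signature_features = [f for f in feature_ids if module_of.get(f) == 1]
    patterns = _subset_sign_patterns(config, rng, signature_features)
    cov_targets = _covariate_targets(config, rng, feature_ids)
    sample_ids = [f"S{k:05d}" for k in range(config.n_samples)]
    subsets = rng.integers(1, config.n_planted_subsets + 1, config.n_samples)
    features, covariates = _generate_visit(
        config, rng, sample_ids, subsets, module_of, patterns, cov_targets,
        feature_ids, modality_of,
    )
    disease = _draw_disease(config, rng, subsets, sample_ids)
    return SyntheticCohort(
        features=features,
        covariates=covariates,
        true_module_of_feature=dict(module_of),
        true_subset_of_sample=pd.Series(subsets, index=sample_ids, name="subset"),
        disease_labels=disease,
    )


def generate_validation_cohort(
    cohort: SyntheticCohort,
    config: GeneratorConfig,
    drop_features: Sequence[str] = (),
) -> SyntheticCohort:
    """Generate an independent validation cohort plus a follow-up visit.

    New individuals are drawn from the same generative model (same planted
    module structure and subset signatures). Features in ``drop_features``
    are set entirely missing, emulating modalities a validation registry did
    not measure. The follow-up visit reuses each individual's covariates,
    with subsets resampled from ``config.transition_matrix_true``.
    """
    unknown = set(drop_features) - set(cohort.features.feature_ids)
    if unknown:
        raise KeyError(f"unknown feature ids in drop_features: {sorted(unknown)[:5]}")
    # reproduce the planted structure exactly as the study cohort drew it
    structure_rng = np.random.default_rng(config.seed)
    feature_ids, modality_of = _feature_frame(config)
    module_of = _plant_modules(config)
    signature_features = [f for f in feature_ids if module_of.get(f) == 1]
    patterns = _subset_sign_patterns(config, structure_rng, signature_features)
    cov_targets = _covariate_targets(config, structure_rng, feature_ids)

    rng = np.random.default_rng([config.seed, 2_000_003])
    sample_ids = [f"V{k:05d}" for k in range(config.n_samples)]
    subsets = rng.integers(1, config.n_planted_subsets + 1, config.n_samples)
    features, covariates = _generate_visit(
        config, rng, sample_ids, subsets, module_of, patterns, cov_targets,
        feature_ids, modality_of,
    )
    if drop_features:
        features.values.loc[:, list(drop_features)] = np.nan
    disease = _draw_disease(config, rng, subsets, sample_ids)

    t = config.transition_matrix_true
    followup_subsets = np.array(
        [rng.choice(config.n_planted_subsets, p=t[s - 1]) + 1 for s in subsets]
    )
    followup_features, _ = _generate_visit(
        config, rng, sample_ids, followup_subsets, module_of, patterns,
        cov_targets, feature_ids, modality_of, covariates=covariates,
    )
    if drop_features:
        followup_features.values.loc[:, list(drop_features)] = np.nan
    return SyntheticCohort(
        features=features,
        covariates=covariates,
        true_module_of_feature=dict(module_of),
        true_subset_of_sample=pd.Series(subsets, index=sample_ids, name="subset"),
        disease_labels=disease,
        followup_features=followup_features,
        followup_true_subset=pd.Series(
            followup_subsets, index=sample_ids, name="subset"
        ),
    )


def null_config(n_samples: int = 200, seed: int = 0,
                n_features_per_modality: Mapping[str, int] | None = None,
                ) -> GeneratorConfig:
    """A configuration with no planted signal of any kind.

    Used for false-discovery-rate and type-I-error checks: no modules, no
    subsets shifts, no covariate effects, no missingness (columns stay
    complete so every cross-modality pair is tested on the full cohort).
    """
    if n_features_per_modality is None:
        n_features_per_modality = {
            "metabolome": 30, "clinical_labs": 30,
            "body_composition": 30, "vitals": 30,
        }
    return GeneratorConfig(
        n_samples=n_samples,
        n_features_per_modality=dict(n_features_per_modality),
        n_planted_modules=0,
        module_loading=(),
        n_planted_subsets=1,
        subset_effect_size=0.0,
        covariate_effects={},
        missing_rate=0.0,
        modality_block_missing={},
        disease_enrichment={},
        transition_matrix_true=np.array([[1.0]]),
        seed=seed,
    )
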