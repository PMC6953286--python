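"""End-to-end orchestration of the multimodal stratification analysis.

``run_pipeline`` drives the full chain on a synthetic cohort: generation,
normalization and covariate correction, cross-modality association network,
consensus community modules, Markov-network key-biomarker selection for the
largest module, stratification of individuals, validation-cohort signature
assignment, and enrichment / longitudinal-transition statistics. All stages
are seeded through the generator configuration, so two runs with the same
configuration are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import enrich, markov, modules, network, preprocess, stratify
from .datatypes import SyntheticCohort
from .simulate import GeneratorConfig, generate_cohort, generate_validation_cohort


@dataclass
class PipelineResult:
    cohort: SyntheticCohort
    validation: SyntheticCohort
    corrected: "preprocess.FeatureMatrix"
    preprocess_model: preprocess.PreprocessModel
    association: network.AssociationResult
    graph: nx.Graph
    module_set: modules.ModuleSet
    module_id: int
    centrality: markov.CentralityRanking
    markov_net: markov.MarkovNetwork
    key_biomarkers: markov.KeyBiomarkerSet
    imputed_fraction: float
    assignment: stratify.SubsetAssignment
    diagnostics: stratify.MembershipDiagnostics
    signatures: pd.DataFrame
    scaling: stratify.ScalingStats
    validation_assignment: pd.Series
    validation_distances: pd.DataFrame
    followup_assignment: pd.Series
    transitions: enrich.TransitionMatrix
    enrichment: pd.DataFrame
    l1_imputation_r2: dict = field(default_factory=dict)


def _biomarker_profiles(fm, biomarkers, scaling=None):
    cols = [b for b in biomarkers if b in fm.values.columns]
    scaled, scaling = stratify.scale_features(fm.values[cols], stats=scaling)
    completed = stratify.soft_impute(scaled)
    return completed, scaling


def run_pipeline(
    config: GeneratorConfig,
    min_pairs: int = 30,
    fdr: float = 0.05,
    n_runs: int = modules.DEFAULT_N_RUNS,
    margin: int = modules.DEFAULT_MARGIN,
    k_central: int | None = None,
    min_size: int = stratify.DEFAULT_MIN_SIZE,
    drop_features: Sequence[str] = (),
    l1_targets: Sequence[str] = (),
    mc_replicates: int = 100_000,
) -> PipelineResult:
    """Run the full analysis on a synthetic study + validation cohort.

    ``drop_features`` are removed from the validation registry (entirely
    missing there); any of them listed in ``l1_targets`` are re-imputed by
    lasso regression from the shared features before assignment.
    """
    cohort = generate_cohort(config)
    validation = generate_validation_cohort(cohort, config, drop_features)

    corrected, model = preprocess.fit_covariate_correction(
        cohort.features, cohort.covariates, on_degenerate="drop"
    )
    kept = [f for f in corrected.feature_ids
            if not model.features.get(f, None) or not model.features[f].skipped]
    if len(kept) < len(corrected.feature_ids):
        corrected = corrected.subset_features(kept)
    graph, assoc = network.significant_association_network(
        corrected, min_pairs=min_pairs, q=fdr
    )
    module_set = modules.run_consensus(graph, n_runs=n_runs, margin=margin)
    module_id = module_set.modules_by_size()[0][0]
    module_nodes = module_set.module_nodes(module_id)

    detection = network.detection_graph(graph)
    subgraph = detection.subgraph(module_nodes)
    ranking = markov.eigenvector_centrality(subgraph, weighted=True)
    if k_central is None:
        k_central = 40
    k_central = max(min(k_central, len(module_nodes)), 2)
    central = markov.select_central_features(ranking, k_central)
    central_data, imputed_fraction = markov.impute_and_transform(
        corrected.values[central]
    )
    markov_net = markov.graphical_lasso(
        central_data, penalty="ebic",
        modality_of=corrected.modality_of.loc[central],
    )
    key_set = markov.select_key_biomarkers(
        markov_net, available_features=corrected.feature_ids
    )
    biomarkers = key_set.biomarkers
    if len(biomarkers) < 3:  # degenerate tiny fixture: fall back to central set
        biomarkers = central

    profiles, scaling = _biomarker_profiles(corrected, biomarkers)
    linkage_matrix = stratify.hierarchical_cluster(profiles)
    assignment = stratify.cut_tree_min_size(
        linkage_matrix, len(profiles), min_size=min_size,
        sample_ids=list(profiles.index),
    )
    diagnostics = stratify.membership_diagnostics(profiles, assignment)
    signatures = stratify.compute_signatures(profiles, assignment)

    val_corrected = preprocess.apply_covariate_correction(
        validation.features, validation.covariates, model
    )
    l1_r2: dict = {}
    val_values = val_corrected.values
    targets = [t for t in l1_targets if t in val_values.columns]
    if targets:
        val_values, l1_r2 = stratify.l1_impute_missing_features(
            corrected.values, val_values, targets, seed=config.seed
        )
    val_cols = [b for b in biomarkers if b in val_values.columns]
    val_scaled, _ = stratify.scale_features(val_values[val_cols], stats=scaling)
    val_profiles = stratify.soft_impute(val_scaled) if val_scaled.isna().any().any() else val_scaled
    val_labels, val_dists = stratify.assign_by_signature(val_profiles, signatures)

    fup_corrected = preprocess.apply_covariate_correction(
        validation.followup_features, validation.covariates, model
    )
    fup_values = fup_corrected.values
    if targets:
        fup_values, _ = stratify.l1_impute_missing_features(
            corrected.values, fup_values, targets, seed=config.seed
        )
    fup_scaled, _ = stratify.scale_features(fup_values[val_cols], stats=scaling)
    fup_profiles = stratify.soft_impute(fup_scaled) if fup_scaled.isna().any().any() else fup_scaled
    fup_labels, _ = stratify.assign_by_signature(fup_profiles, signatures)

    transitions = enrich.transition_analysis(val_labels.dropna(), fup_labels.dropna())

    disease = cohort.disease_labels["disease"]
    rows = []
    subsets = sorted(assignment.subset_of.unique())
    for s in subsets:
        in_s = (assignment.subset_of == s).astype(int)
        table = pd.crosstab(in_s, disease.loc[assignment.subset_of.index])
        if table.shape == (2, 2):
            p = enrich.fisher_exact_mc(
                table.to_numpy(), n_replicates=mc_replicates, seed=config.seed + s
            )
        else:
            p = np.nan
        rate = float(disease.loc[assignment.subset_of.index][in_s == 1].mean())
        rows.append({"subset": s, "trait": "disease", "rate": rate, "p": p})
    enrichment = pd.DataFrame(rows)
    flags, adj = enrich.bonferroni(enrichment["p"].to_numpy())
    enrichment["significant"] = flags
    enrichment["adjusted_alpha"] = adj

    return PipelineResult(
        cohort=cohort,
        validation=validation,
        corrected=corrected,
        preprocess_model=model,
        association=assoc,
        graph=graph,
        module_set=module_set,
        module_id=module_id,
        centrality=ranking,
        markov_net=markov_net,
        key_biomarkers=key_set,
        imputed_fraction=imputed_fraction,
        assignment=assignment,
        diagnostics=diagnostics,
        signatures=signatures,
        scaling=scaling,
        validation_assignment=val_labels,
        validation_distances=val_dists,
        followup_assignment=fup_labels,
        transitions=transitions,
        enrichment=enrichment,
        l1_imputation_r2=l1_r2,
    )
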