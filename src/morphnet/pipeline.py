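"""End-to-end orchestration: cohort -> networks -> metrics -> statistics.

The pipeline layer glues the building blocks together the way the study
design prescribes: per subject and feature a similarity network is built
and thresholded; clustering, path length (optionally normalized against
rewired nulls) and nodal efficiency are computed per sparsity level and
summarized as the range-normalized AUC across the grid; regional means,
global metrics and nodal efficiencies are then compared across groups
with permutation ANOVA, gated post-hoc t-tests and per-family BH-FDR;
finally clinical covariates are correlated (Spearman) with the measures
that showed significant group differences.

All randomness is derived from one master seed through named
``SeedSequence`` keys, so each stage is independently reproducible and
two runs with the same configuration produce identical result bundles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import graph as gm
from .cohort import cohort_regional_means
from .config import PipelineConfig
from .similarity import build_similarity, threshold_ensemble
from .stats import fdr_bh, gated_spearman, perm_anova_table, posthoc_pairwise, \
    shapiro_report

__all__ = [
    "subject_similarity",
    "subject_ensemble",
    "subject_nodal_efficiency_auc",
    "network_metrics",
    "regional_stats",
    "nodal_stats",
    "global_stats",
    "correlation_stats",
    "run_study",
]


def subject_similarity(record, feature: str, config: PipelineConfig | None = None):
    config = config or PipelineConfig()
    return build_similarity(
        record.feature_map(feature),
        grid_size=config.grid_size,
        bandwidth=config.bandwidth,
        variant=config.similarity_variant,
        grid_policy=config.grid_policy,
    )


def subject_ensemble(record, feature: str, config: PipelineConfig | None = None):
    config = config or PipelineConfig()
    S = subject_similarity(record, feature, config)
    return threshold_ensemble(S, config.sparsity_grid)


def subject_nodal_efficiency_auc(record, feature: str, config: PipelineConfig | None = None) -> dict:
    """Across-sparsity AUC of nodal efficiency per ROI for one subject."""
    config = config or PipelineConfig()
    ens = subject_ensemble(record, feature, config)
    E = np.stack([gm.nodal_efficiency(A) for A in ens.adjacencies])
    auc = np.array([gm.auc_over_sparsity(E[:, i], ens.sparsities)
                    for i in range(E.shape[1])])
    roi_ids = record.feature_map(feature).roi_ids
    return {int(r): float(a) for r, a in zip(roi_ids, auc)}


def network_metrics(
    records,
    features=None,
    config: PipelineConfig | None = None,
    small_world: bool = True,
):
    """Per-subject network topology for every feature.

    Returns ``(global_df, nodal)``: a tidy table of global metrics (one
    row per subject x feature x sparsity level x metric, plus ``"auc"``
    rows integrating each metric across the grid) and a dict mapping
    feature -> (n_roi x n_subjects) matrix of nodal-efficiency AUCs.
    ``small_world=False`` skips the zCp/zLp null normalization (the
    expensive part) for runs that only need raw topology.
    """
    config = config or PipelineConfig()
    if features is None:
        features = list(records[0].maps)
    grid = config.sparsity_grid
    rows = []
    nodal = {}
    for fi, feature in enumerate(features):
        n_roi = records[0].feature_map(feature).roi_ids.size
        nodal_mat = np.empty((n_roi, len(records)))
        for si, rec in enumerate(records):
            ens = subject_ensemble(rec, feature, config)
            cp = np.array([gm.clustering_coefficient(A) for A in ens.adjacencies])
            lp = np.array([gm.characteristic_path_length(A) for A in ens.adjacencies])
            E = np.stack([gm.nodal_efficiency(A) for A in ens.adjacencies])
            metrics = {"Cp": cp, "Lp": lp}
            if small_world and config.n_null > 0:
                zcp = np.empty(grid.size)
                zlp = np.empty(grid.size)
                for li, A in enumerate(ens.adjacencies):
                    zcp[li], zlp[li] = gm.normalize_small_world(
                        A, n_null=config.n_null,
                        seed=[config.seed, 7, fi, si, li],
                    )
                metrics["zCp"] = zcp
                metrics["zLp"] = zlp
            for name, vals in metrics.items():
                for s, v in zip(grid, vals):
                    rows.append({"subject_id": rec.subject_id, "group": rec.group,
                                 "feature": feature, "sparsity": float(s),
                                 "metric": name, "value": float(v)})
                rows.append({"subject_id": rec.subject_id, "group": rec.group,
                             "feature": feature, "sparsity": "auc",
                             "metric": name,
                             "value": gm.auc_over_sparsity(vals, grid)})
            nodal_mat[:, si] = [gm.auc_over_sparsity(E[:, i], grid)
                                for i in range(n_roi)]
        nodal[feature] = nodal_mat
    return pd.DataFrame(rows), nodal


def _group_order(records):
    order = []
    for r in records:
        if r.group not in order:
            order.append(r.group)
    return order


def _anova_with_posthoc(X, records, ids, id_col, feature, n_perm, seed, q):
    """Shared machinery for regional and nodal family tests."""
    labels = np.array([r.group for r in records])
    tests = perm_anova_table(X, labels, n_perm=n_perm, seed=seed)
    tests.insert(0, id_col, ids)
    tests.insert(0, "feature", feature)
    reject, qv = fdr_bh(tests["p"].to_numpy(), q=q)
    tests["q"] = qv
    tests["significant"] = reject
    tests["marginal"] = (~reject) & (tests["p"] < 0.1)
    order = _group_order(records)
    pairs = [(a, b) for i, a in enumerate(order) for b in order[i + 1:]]
    for a, b in pairs:
        tests[f"t_{a}_{b}"] = np.nan
        tests[f"p_{a}_{b}"] = np.nan
    groups_idx = {g: np.array([i for i, r in enumerate(records) if r.group == g])
                  for g in order}
    for ridx in np.flatnonzero((tests["p"] < 0.05).to_numpy()):
        values = {g: X[ridx, idx] for g, idx in groups_idx.items()}
        ph = posthoc_pairwise(values, float(tests.loc[ridx, "p"]), pairs=pairs)
        for _, row in ph.iterrows():
            tests.loc[ridx, f"t_{row.group_a}_{row.group_b}"] = row.t
            tests.loc[ridx, f"p_{row.group_a}_{row.group_b}"] = row.p
    return tests


def regional_stats(records, features=None, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Permutation ANOVA on regional means, per-feature BH-FDR families.

    One family per morphological feature across all ROIs, exactly the
    first FDR level of the statistical scheme; post-hoc pairwise t-tests
    are attached for main effects with p < 0.05.
    """
    config = config or PipelineConfig()
    if features is None:
        features = list(records[0].maps)
    out = []
    for fi, feature in enumerate(features):
        roi_ids = records[0].feature_map(feature).roi_ids
        X = cohort_regional_means(records, feature, roi_ids)
        out.append(_anova_with_posthoc(
            X, records, roi_ids, "roi_id", feature,
            config.n_perm, [config.seed, 11, fi], config.fdr_q))
    return pd.concat(out, ignore_index=True)


def nodal_stats(records, nodal, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Permutation ANOVA on nodal-efficiency AUC, per-network FDR families
    (the second FDR level: all nodes within each network type)."""
    config = config or PipelineConfig()
    out = []
    for fi, (feature, X) in enumerate(nodal.items()):
        roi_ids = records[0].feature_map(feature).roi_ids
        out.append(_anova_with_posthoc(
            X, records, roi_ids, "roi_id", feature,
            config.n_perm, [config.seed, 13, fi], config.fdr_q))
    return pd.concat(out, ignore_index=True)


def global_stats(records, global_df: pd.DataFrame, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Permutation ANOVA on AUC-summarized global metrics (Cp, Lp, zCp, zLp)
    per feature network; reported uncorrected with marginal labelling (few
    tests; the FDR families of the scheme cover regions and nodes)."""
    config = config or PipelineConfig()
    auc = global_df[global_df["sparsity"] == "auc"]
    sub_order = [r.subject_id for r in records]
    labels = np.array([r.group for r in records])
    rows = []
    for gi, ((feature, metric), chunk) in enumerate(auc.groupby(["feature", "metric"])):
        v = chunk.set_index("subject_id").loc[sub_order, "value"].to_numpy()
        tests = _anova_with_posthoc(
            v[None, :], records, [metric], "metric", feature,
            config.n_perm, [config.seed, 17, gi], config.fdr_q)
        rows.append(tests)
    return pd.concat(rows, ignore_index=True)


def _measure_name(feature, roi_id, kind):
    return f"{feature}_roi{int(roi_id)}_{kind}"


def correlation_stats(
    records,
    regional: pd.DataFrame | None = None,
    nodal_tests: pd.DataFrame | None = None,
    nodal: dict | None = None,
    config: PipelineConfig | None = None,
    groups=None,
) -> pd.DataFrame:
    """Shapiro-gated Spearman correlations between clinical variables and
    the measures with significant group differences (data-driven
    selection), FDR-corrected within each group x clinical variable."""
    config = config or PipelineConfig()
    if groups is None:
        groups = [g for g in _group_order(records) if g != "HC"]
    candidates = {}
    if regional is not None:
        for _, row in regional[regional["significant"] == True].iterrows():  # noqa: E712
            name = _measure_name(row["feature"], row["roi_id"], "mean")
            vals = cohort_regional_means(records, row["feature"], [int(row["roi_id"])])[0]
            candidates[name] = vals
    if nodal_tests is not None and nodal is not None:
        for _, row in nodal_tests[nodal_tests["significant"] == True].iterrows():  # noqa: E712
            feature = row["feature"]
            roi_ids = records[0].feature_map(feature).roi_ids
            i = int(np.flatnonzero(roi_ids == int(row["roi_id"]))[0])
            candidates[_measure_name(feature, row["roi_id"], "Ei")] = nodal[feature][i]
    if not candidates:
        return pd.DataFrame(columns=["group", "variable", "measure", "rho", "p",
                                     "n", "shapiro_p", "flag", "q",
                                     "significant", "marginal"])
    measures_all = pd.DataFrame(candidates, index=[r.subject_id for r in records])
    out = []
    for g in groups:
        idx = [r.subject_id for r in records if r.group == g]
        clin = pd.DataFrame([r.clinical for r in records if r.group == g], index=idx)
        out.append(gated_spearman(clin, measures_all.loc[idx], g, q=config.fdr_q))
    return pd.concat(out, ignore_index=True)


def run_study(
    records,
    config: PipelineConfig | None = None,
    features=None,
    small_world: bool = True,
) -> dict:
    """Full analysis bundle for a cohort of subject records.

    Returns a dict of tidy DataFrames (``regional``, ``global``,
    ``nodal``, ``correlations``, ``metrics``, ``shapiro``) plus a ``meta``
    block recording the configuration and seed for audit.
    """
    config = config or PipelineConfig()
    if features is None:
        features = list(records[0].maps)
    regional = regional_stats(records, features, config)
    metrics_df, nodal = network_metrics(records, features, config, small_world=small_world)
    nodal_tests = nodal_stats(records, nodal, config)
    glob = global_stats(records, metrics_df, config)
    correlations = correlation_stats(records, regional, nodal_tests, nodal, config)
    patient_clin = pd.DataFrame([r.clinical for r in records if r.group != "HC"])
    return {
        "meta": {
            "config": config.to_dict(),
            "n_subjects": len(records),
            "groups": {g: sum(1 for r in records if r.group == g)
                       for g in _group_order(records)},
            "features": list(features),
            "n_perm": config.n_perm,
            "summary_mode": config.summary_mode,
        },
        "regional": regional,
        "metrics": metrics_df,
        "nodal": nodal_tests,
        "global": glob,
        "correlations": correlations,
        "shapiro": shapiro_report(patient_clin) if len(patient_clin) else pd.DataFrame(),
    }
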