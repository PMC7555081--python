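"""End-to-end orchestration of the regional brain-age analysis.

The full workflow is: QC exclusions -> nuisance residualization ->
hemisphere averaging -> covariance clustering of regions -> per-cluster
cross-validated brain-age models -> exposure regressions with FDR and
pairwise correlated-estimates Z tests -> sub-clustering of the most
strongly associated cluster -> subcluster models, group contrast ->
single-region models for the focal subcluster -> leave-one-region-out
log-likelihood comparison.

``run_pipeline`` executes this from a config (either paths to cohort and
feature CSVs or a simulation config) and writes all result tables plus a
provenance record; identical configs give identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import brainage, clustering, preprocess, stats
from .brainage import BrainAgeResult, ModelParams
from .simulate import SimulationConfig, simulate_cohort


@dataclass
class RunConfig:
    seed: int = 0
    sim: SimulationConfig | None = None
    cohort_path: str | None = None
    features_path: str | None = None
    k_top: int = 5
    k_sub: int = 2
    linkage: str = "average"
    params: ModelParams = field(default_factory=ModelParams)
    fdr_q: float = 0.05
    outdir: str | None = None

    def validate(self) -> None:
        from_files = self.cohort_path is not None and self.features_path is not None
        from_sim = self.sim is not None
        if from_files == from_sim:
            raise ValueError(
                "provide exactly one input source: (cohort_path, features_path) or sim"
            )


@dataclass
class FeatureSetResult:
    result: BrainAgeResult
    metrics: brainage.PredictionMetrics
    association: stats.AssociationResult


@dataclass
class AnalysisReport:
    qc: preprocess.QCReport
    clusters: clustering.ClusterAssignment
    cluster_results: dict[int, FeatureSetResult]
    pairwise: pd.DataFrame                  # long-form pairwise Z tests
    focal_cluster: int
    subclusters: clustering.ClusterAssignment
    subcluster_results: dict[int, FeatureSetResult]
    subcluster_comparison: stats.ComparisonResult
    focal_subcluster: int
    contrast: stats.GroupDifference
    region_results: dict[str, FeatureSetResult]
    nested: pd.DataFrame
    n_analysis: int


def _associate(res: BrainAgeResult, cohort: pd.DataFrame, label: str) -> stats.AssociationResult:
    return stats.exposure_regression(
        res.delta, cohort["n_childbirths"],
        covariates=cohort[["age"]], feature_set=label,
    )


def analyze(
    cohort: pd.DataFrame,
    features: pd.DataFrame,
    params: ModelParams,
    k_top: int = 5,
    k_sub: int = 2,
    linkage: str = "average",
    fdr_q: float = 0.05,
) -> AnalysisReport:
    """Run the full analysis in memory on raw (per-hemisphere) tables."""
    cohort, features, qc = preprocess.exclude_participants(cohort, features)
    features = preprocess.residualize(features, preprocess.default_nuisance(cohort))
    averaged = preprocess.average_hemispheres(features)

    assignment = clustering.cluster_features(averaged, k_top, linkage=linkage)
    folds = brainage.assign_folds(averaged.index, params.n_folds, params.seed)
    age = cohort["age"]

    cluster_results: dict[int, FeatureSetResult] = {}
    for lab in range(1, assignment.n_clusters + 1):
        cols = assignment.members(lab)
        res = brainage.crossval_predict(
            averaged[cols], age, params, folds=folds, feature_set=f"cluster_{lab}"
        )
        cluster_results[lab] = FeatureSetResult(
            res, brainage.metrics(res, age, n_features=len(cols)),
            _associate(res, cohort, f"cluster_{lab}"),
        )
    labs = sorted(cluster_results)
    padj = stats.fdr_adjust([cluster_results[k].association.p for k in labs])
    for k, pa in zip(labs, padj):
        cluster_results[k].association.p_adj = float(pa)

    rows = []
    for i, a in enumerate(labs):
        for b in labs[i + 1:]:
            ra, rb = cluster_results[a], cluster_results[b]
            rho = stats.delta_correlation(ra.result.delta, rb.result.delta, age)
            cmp = stats.compare_associations(ra.association, rb.association, rho)
            rows.append({"a": a, "b": b, "z": cmp.z, "rho": cmp.rho, "p": cmp.p})
    pairwise = pd.DataFrame(rows)
    if len(pairwise):
        pairwise["p_adj"] = stats.fdr_adjust(pairwise["p"].to_numpy())

    focal = min(labs, key=lambda k: cluster_results[k].association.p)

    sub = clustering.subcluster(averaged, assignment, focal, k_sub, linkage=linkage)
    subcluster_results: dict[int, FeatureSetResult] = {}
    for lab in range(1, sub.n_clusters + 1):
        cols = sub.members(lab)
        res = brainage.crossval_predict(
            averaged[cols], age, params, folds=folds, feature_set=f"subcluster_{lab}"
        )
        subcluster_results[lab] = FeatureSetResult(
            res, brainage.metrics(res, age, n_features=len(cols)),
            _associate(res, cohort, f"subcluster_{lab}"),
        )
    slabs = sorted(subcluster_results)
    spadj = stats.fdr_adjust([subcluster_results[k].association.p for k in slabs])
    for k, pa in zip(slabs, spadj):
        subcluster_results[k].association.p_adj = float(pa)
    r1, r2 = subcluster_results[slabs[0]], subcluster_results[slabs[1]]
    sub_cmp = stats.compare_associations(
        r1.association, r2.association,
        stats.delta_correlation(r1.result.delta, r2.result.delta, age),
    )
    focal_sub = min(slabs, key=lambda k: subcluster_results[k].association.p)

    contrast = stats.group_contrast(
        subcluster_results[focal_sub].result.delta, cohort["parous"], age
    )

    region_results: dict[str, FeatureSetResult] = {}
    for col in sub.members(focal_sub):
        res = brainage.crossval_predict(
            averaged[[col]], age, params, folds=folds, feature_set=col
        )
        region_results[col] = FeatureSetResult(
            res, brainage.metrics(res, age, n_features=1),
            _associate(res, cohort, col),
        )
    regions = list(region_results)
    rpadj = stats.fdr_adjust([region_results[r].association.p for r in regions])
    for r, pa in zip(regions, rpadj):
        region_results[r].association.p_adj = float(pa)

    region_deltas = pd.DataFrame(
        {r: region_results[r].result.delta for r in regions}, index=averaged.index
    )
    nested = stats.nested_ll_comparison(region_deltas, cohort["n_childbirths"])

    return AnalysisReport(
        qc=qc, clusters=assignment, cluster_results=cluster_results,
        pairwise=pairwise, focal_cluster=focal,
        subclusters=sub, subcluster_results=subcluster_results,
        subcluster_comparison=sub_cmp, focal_subcluster=focal_sub,
        contrast=contrast, region_results=region_results, nested=nested,
        n_analysis=len(cohort),
    )


def _association_frame(results: dict) -> pd.DataFrame:
    rows = []
    for key, fs in results.items():
        a = fs.association
        rows.append(
            {"feature_set": a.feature_set, "n_feat": fs.metrics.n_features,
             "beta": a.beta, "se": a.se, "t": a.t, "p": a.p, "p_adj": a.p_adj,
             "r": fs.metrics.r, "r_ci_low": fs.metrics.r_ci[0],
             "r_ci_high": fs.metrics.r_ci[1], "R2": fs.metrics.r2,
             "RMSE": fs.metrics.rmse, "MAE": fs.metrics.mae}
        )
    return pd.DataFrame(rows).set_index("feature_set")


def _load_inputs(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    if config.sim is not None:
        return simulate_cohort(config.sim)
    for path in (config.cohort_path, config.features_path):
        if not Path(path).exists():
            raise FileNotFoundError(f"input file not found: {path}")
    cohort = pd.read_csv(config.cohort_path, index_col="participant_id")
    features = pd.read_csv(config.features_path, index_col="participant_id")
    return cohort, features


def run_pipeline(config: RunConfig) -> AnalysisReport:
    """Execute the full workflow; write result tables if outdir is set."""
    config.validate()
    cohort, features = _load_inputs(config)
    report = analyze(
        cohort, features, config.params,
        k_top=config.k_top, k_sub=config.k_sub,
        linkage=config.linkage, fdr_q=config.fdr_q,
    )
    if config.outdir is not None:
        write_report(report, config)
    return report


def write_report(report: AnalysisReport, config: RunConfig) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    report.qc.to_json(out / "qc_report.json")
    report.clusters.to_csv(out / "cluster_assignment.csv")
    report.subclusters.to_csv(out / "subcluster_assignment.csv")
    _association_frame(report.cluster_results).to_csv(
        out / "cluster_associations.csv", float_format=fmt)
    _association_frame(report.subcluster_results).to_csv(
        out / "subcluster_associations.csv", float_format=fmt)
    _association_frame(report.region_results).to_csv(
        out / "region_associations.csv", float_format=fmt)
    report.pairwise.to_csv(out / "pairwise_z.csv", index=False, float_format=fmt)
    report.nested.to_csv(out / "nested_comparison.csv", float_format=fmt)
    summary = {
        "n_analysis": report.n_analysis,
        "focal_cluster": report.focal_cluster,
        "focal_subcluster": report.focal_subcluster,
        "subcluster_comparison": asdict(report.subcluster_comparison),
        "group_contrast": asdict(report.contrast),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    cfg_dict = asdict(config)
    cfg_dict.pop("outdir", None)  # the record lives there; keep it location-free
    prov = {"seed": config.seed, "config": cfg_dict}
    (out / "provenance.json").write_text(json.dumps(prov, indent=2, default=str))


@dataclass
class ReplicationReport:
    metrics: brainage.PredictionMetrics
    association: stats.AssociationResult
    poly: stats.PolynomialFit
    group_counts: pd.Series
    n_train: int
    n_test: int


def replicate_split(
    config: RunConfig, train_ids: pd.Index, test_ids: pd.Index
) -> ReplicationReport:
    """Train a global brain-age model on one id set, evaluate associations
    on a disjoint held-out set (the replication design)."""
    config.validate()
    if len(pd.Index(train_ids).intersection(test_ids)) > 0:
        raise ValueError("train and test ids overlap")
    if len(test_ids) == 0:
        raise ValueError("empty test set")
    cohort, features = _load_inputs(config)
    cohort, features, _ = preprocess.exclude_participants(cohort, features)
    features = preprocess.residualize(features, preprocess.default_nuisance(cohort))
    averaged = preprocess.average_hemispheres(features)
    train_ids = pd.Index(train_ids).intersection(averaged.index)
    test_ids = pd.Index(test_ids).intersection(averaged.index)

    pred, _model = brainage.fit_then_predict(
        averaged.loc[train_ids], cohort.loc[train_ids, "age"],
        averaged.loc[test_ids], config.params,
    )
    delta = pred - cohort.loc[test_ids, "age"]
    table = pd.DataFrame(
        {"predicted_age": pred, "delta": delta,
         "fold": np.full(len(test_ids), -1)},
        index=test_ids,
    )
    res = BrainAgeResult(table=table, feature_set="global_test", params=config.params)
    mets = brainage.metrics(res, cohort.loc[test_ids, "age"], n_features=averaged.shape[1])
    assoc = _associate(res, cohort.loc[test_ids], "global_test")
    corrected = stats.age_bias_correct(delta, cohort.loc[test_ids, "age"])
    poly = stats.polynomial_group_fit(corrected, cohort.loc[test_ids, "n_childbirths"])
    counts = (
        cohort.loc[test_ids, "n_childbirths"].astype(int).value_counts().sort_index()
    )
    return ReplicationReport(
        metrics=mets, association=assoc, poly=poly, group_counts=counts,
        n_train=len(train_ids), n_test=len(test_ids),
    )
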