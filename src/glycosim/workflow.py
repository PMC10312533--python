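"""End-to-end analysis: standardize, filter, bootstrap, assess, compare, rank.

``run_analysis`` is the library entry point (matrices in, report object out);
``run_workflow`` wraps it with file IO, report serialization and plotting for
the command line. Exit-status semantics for pipelines:

* 0 — quality acceptable and the groups are differentiable
* 3 — quality acceptable but not differentiable
* 4 — data-quality failure (Internal Confidence or typicality)
* 1 — error in any stage
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import quality as q
from . import ranking as rk
from .bootstrap import make_null_collections, make_test_collections
from .data import AbundanceMatrix, load_abundance_matrix, load_tic, min_observation_filter, standardize
from .distributions import build_all_distributions, estimate_density, observed_similarity
from .similarity import SimilarityResult

logger = logging.getLogger(__name__)

EXIT_DIFFERENTIABLE = 0
EXIT_NOT_DIFFERENTIABLE = 3
EXIT_QUALITY_FAILURE = 4


@dataclass
class WorkflowConfig:
    """File-level configuration with every decision threshold overridable."""

    path_a: str
    path_b: str
    group_a: str = "File1"
    group_b: str = "File2"
    tic_path: str | None = None
    use_tic: bool = False
    site: str | None = None
    min_obs: int = 2
    strict_typicality: bool = False
    rescale_b: float = 1.0
    seed: int = 0
    output_dir: str = "glycosim_output"
    ic_threshold: float = q.IC_THRESHOLD
    alpha_threshold: float = rk.ALPHA_THRESHOLD
    beta_threshold: float = rk.BETA_THRESHOLD
    contribution_overlap_threshold: float = rk.CONTRIBUTION_OVERLAP_THRESHOLD
    outlier_z_threshold: float = q.OUTLIER_Z_THRESHOLD
    peak_mass_threshold: float = q.PEAK_MASS_THRESHOLD
    prominence_fraction: float = q.PEAK_PROMINENCE_FRACTION
    remove_outliers: bool = True
    make_plots: bool = True


@dataclass
class GroupQuality:
    assessment: q.InternalAssessment
    n_peaks: int
    verdicts: list[q.OutlierVerdict]


@dataclass
class AnalysisReport:
    matrix_a: AbundanceMatrix
    matrix_b: AbundanceMatrix
    distributions: dict
    observed: SimilarityResult
    quality_a: GroupQuality
    quality_b: GroupQuality
    typicality_z: float
    typical: bool
    general: rk.GeneralComparison
    ranking: list[rk.RankedIdentification]
    removed_replicates: list[tuple[str, str]] = field(default_factory=list)
    removed_ids: list = field(default_factory=list)
    null_below_test: bool = False

    @property
    def quality_ok(self) -> bool:
        return bool(self.quality_a.assessment.passes and self.quality_b.assessment.passes and self.typical)

    @property
    def status(self) -> str:
        if not self.quality_ok:
            return "quality_failure"
        return "differentiable" if self.general.differentiable else "not_differentiable"

    @property
    def exit_code(self) -> int:
        return {
            "differentiable": EXIT_DIFFERENTIABLE,
            "not_differentiable": EXIT_NOT_DIFFERENTIABLE,
            "quality_failure": EXIT_QUALITY_FAILURE,
        }[self.status]


def _bootstrap_and_build(a: AbundanceMatrix, b: AbundanceMatrix, seed: int):
    rng = np.random.default_rng(seed)
    test_a, test_b = make_test_collections(a, b, rng)
    null_1, null_2 = make_null_collections(a, b, rng)
    return build_all_distributions(a, b, test_a, test_b, null_1, null_2)


def _assess_group(dists, which: str, config_like) -> GroupQuality:
    dist = dists[f"internal_{which}"]
    density = estimate_density(dist)
    assignment = q.detect_peaks(density, dist, prominence_fraction=config_like.prominence_fraction)
    verdicts: list[q.OutlierVerdict] = []
    if assignment.multimodal:
        verdicts = q.assess_replicate_membership(
            assignment,
            dist,
            z_threshold=config_like.outlier_z_threshold,
            mass_threshold=config_like.peak_mass_threshold,
        )
    assessment = q.internal_confidence(dist, dists["test"], ic_threshold=config_like.ic_threshold)
    return GroupQuality(assessment=assessment, n_peaks=assignment.n_peaks, verdicts=verdicts)


@dataclass
class _Thresholds:
    ic_threshold: float = q.IC_THRESHOLD
    alpha_threshold: float = rk.ALPHA_THRESHOLD
    beta_threshold: float = rk.BETA_THRESHOLD
    contribution_overlap_threshold: float = rk.CONTRIBUTION_OVERLAP_THRESHOLD
    outlier_z_threshold: float = q.OUTLIER_Z_THRESHOLD
    peak_mass_threshold: float = q.PEAK_MASS_THRESHOLD
    prominence_fraction: float = q.PEAK_PROMINENCE_FRACTION


def run_analysis(
    raw_a: AbundanceMatrix,
    raw_b: AbundanceMatrix,
    seed: int = 0,
    min_obs: int = 2,
    use_tic: bool = False,
    strict_typicality: bool = False,
    rescale_b: float = 1.0,
    remove_outliers: bool = True,
    max_outlier_rounds: int = 2,
    thresholds: _Thresholds | WorkflowConfig | None = None,
) -> AnalysisReport:
    """Run the full contextual-similarity analysis on two raw matrices."""
    th = thresholds or _Thresholds()
    if rescale_b != 1.0:
        if rescale_b <= 0:
            raise ValueError("rescale_b must be positive")
        from dataclasses import replace as _replace

        raw_b = _replace(raw_b, values=raw_b.values * rescale_b)
    std_a = standardize(raw_a, use_tic=use_tic)
    std_b = standardize(raw_b, use_tic=use_tic)
    removed_replicates: list[tuple[str, str]] = []
    for round_no in range(max_outlier_rounds + 1):
        a, b, removed_ids = min_observation_filter(std_a, std_b, min_obs=min_obs)
        if a.n_ids == 0:
            raise ValueError("no identifications survive the minimum-observation filter")
        dists = _bootstrap_and_build(a, b, seed)
        qa = _assess_group(dists, "a", th)
        qb = _assess_group(dists, "b", th)
        if not remove_outliers or round_no == max_outlier_rounds:
            break
        removal_done = False
        for which, gq, std in (("A", qa, std_a), ("B", qb, std_b)):
            removable = [v for v in gq.verdicts if v.remove]
            if not removable:
                continue
            n_reps = (std_a if which == "A" else std_b).n_replicates
            if n_reps <= 3:
                logger.warning(
                    "group %s outlier flagged but only %d replicates remain: "
                    "not removing", which, n_reps,
                )
                continue
            worst = max(removable, key=lambda v: abs(v.z))
            logger.info("removing outlier replicate %s from group %s (z=%.2f)",
                        worst.replicate, which, worst.z)
            removed_replicates.append((which, worst.replicate))
            if which == "A":
                std_a = std_a.drop_replicate(worst.replicate)
            else:
                std_b = std_b.drop_replicate(worst.replicate)
            removal_done = True
        if not removal_done:
            break
    observed = observed_similarity(a, b)
    typ_z, typical = q.typicality_check(observed, dists["test"], strict=strict_typicality)
    general = rk.general_comparison(
        dists["test"], dists["null"],
        alpha_threshold=th.alpha_threshold, beta_threshold=th.beta_threshold,
    )
    ranking = rk.rank_identifications(
        dists["test"], dists["null"], dists["internal_a"], dists["internal_b"],
        a, b, overlap_threshold=th.contribution_overlap_threshold,
    )
    return AnalysisReport(
        matrix_a=a,
        matrix_b=b,
        distributions=dists,
        observed=observed,
        quality_a=qa,
        quality_b=qb,
        typicality_z=typ_z,
        typical=typical,
        general=general,
        ranking=ranking,
        removed_replicates=removed_replicates,
        removed_ids=removed_ids,
        null_below_test=q.null_below_test_warning(dists["null"], dists["test"]),
    )


def quality_report_dict(report: AnalysisReport) -> dict:
    def group_block(gq: GroupQuality) -> dict:
        return {
            "ic_score": gq.assessment.ic_score,
            "alpha": gq.assessment.alpha,
            "beta": gq.assessment.beta,
            "relation": gq.assessment.relation,
            "passes": gq.assessment.passes,
            "mu_internal": gq.assessment.mu_internal,
            "sd_internal": gq.assessment.sd_internal,
            "n_peaks": gq.n_peaks,
            "outlier_verdicts": [
                {
                    "replicate": v.replicate,
                    "peak": v.peak_index,
                    "z": v.z,
                    "direction": v.direction,
                    "remove": v.remove,
                    "note": v.note,
                }
                for v in gq.verdicts
            ],
        }

    return {
        "status": report.status,
        "observed_similarity": report.observed.total,
        "typicality_z": report.typicality_z,
        "typical": report.typical,
        "general": {
            "alpha": report.general.alpha,
            "beta": report.general.beta,
            "differentiable": report.general.differentiable,
        },
        "group_a": group_block(report.quality_a),
        "group_b": group_block(report.quality_b),
        "removed_replicates": [list(t) for t in report.removed_replicates],
        "removed_ids": [g.canonical for g in report.removed_ids],
        "null_below_test": report.null_below_test,
        "distribution_means": {k: d.mean for k, d in report.distributions.items()},
        "distribution_sds": {k: d.sd for k, d in report.distributions.items()},
    }


def distributions_frame(report: AnalysisReport) -> pd.DataFrame:
    rows = []
    for kind, dist in sorted(report.distributions.items()):
        for v in dist.values:
            rows.append((kind, v))
    return pd.DataFrame(rows, columns=["kind", "similarity"])


def run_workflow(config: WorkflowConfig) -> tuple[AnalysisReport, dict[str, str]]:
    """Load inputs per config, run the analysis, and write the report bundle."""
    tic = load_tic(config.tic_path) if config.tic_path else None
    raw_a = load_abundance_matrix(config.path_a, config.group_a, tic=tic)
    raw_b = load_abundance_matrix(config.path_b, config.group_b, tic=tic)
    if config.site:
        def subset(m: AbundanceMatrix) -> AbundanceMatrix:
            from dataclasses import replace as _replace

            keep = [i for i, gid in enumerate(m.ids) if gid.peptide == config.site]
            if not keep:
                raise ValueError(f"no identifications match site {config.site!r}")
            return _replace(m, ids=[m.ids[i] for i in keep], values=m.values[keep].copy())

        raw_a, raw_b = subset(raw_a), subset(raw_b)
    report = run_analysis(
        raw_a,
        raw_b,
        seed=config.seed,
        min_obs=config.min_obs,
        use_tic=config.use_tic,
        strict_typicality=config.strict_typicality,
        rescale_b=config.rescale_b,
        remove_outliers=config.remove_outliers,
        thresholds=config,
    )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    qpath = out / "quality_report.json"
    qpath.write_text(json.dumps(quality_report_dict(report), indent=2, sort_keys=True))
    paths["quality_report"] = str(qpath)

    rpath = out / "ranking.csv"
    rk.ranking_table(report.ranking).to_csv(rpath, index=False, float_format="%.6f")
    paths["ranking"] = str(rpath)

    dpath = out / "distributions.csv"
    distributions_frame(report).to_csv(dpath, index=False, float_format="%.10g")
    paths["distributions"] = str(dpath)

    if config.make_plots:
        from . import plots

        paths["internal_a_plot"] = plots.plot_internal(
            report.distributions["internal_a"], report.distributions["test"],
            report.quality_a.assessment, out / "internal_a.png",
        )
        paths["internal_b_plot"] = plots.plot_internal(
            report.distributions["internal_b"], report.distributions["test"],
            report.quality_b.assessment, out / "internal_b.png",
        )
        paths["general_plot"] = plots.plot_general(
            report.distributions["test"], report.distributions["null"],
            report.general, out / "general.png",
        )
        paths["abundance_plot"] = plots.plot_abundance_boxes(
            report.matrix_a, report.matrix_b, out / "abundances.png",
        )
    return report, paths
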