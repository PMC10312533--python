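"""General differentiability verdict and per-glycopeptide contribution ranking.

The general comparison reads the Test-vs-Null density overlap: the groups'
quantification patterns are called differentiable when alpha < 0.05 and
beta < 0.20.

Ranking uses *numerator-only* contributions (the per-id numerator term of the
weighted Tanimoto, never divided by the comparison denominator, since missing
values bias the denominator most in Null-type datasets). Each identification
gets the average z-score of its Test contributions in the context of the Null
contribution distribution: the lower the z, the higher the rank; sources of
differentiation ideally score below -2. Per-id quality is judged by how well
the id's Test contributions overlap its Internal contributions (histogram
densities; combined alpha + beta must reach 25%), and a failure cause is
reported: never observed in a group, or low per-group contribution quality.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import AbundanceMatrix
from .distributions import DensityEstimate, SimilarityDistribution, overlap
from .identifiers import GlycopeptideId

logger = logging.getLogger(__name__)

ALPHA_THRESHOLD = 0.05
BETA_THRESHOLD = 0.20
CONTRIBUTION_OVERLAP_THRESHOLD = 0.25
CONTRIBUTION_BINS = 32
RANK_Z_THRESHOLD = -2.0


class FailureCause(enum.Enum):
    PASSED = "Passed"
    UNSEEN_FILE1 = "UnseenIn_File1"
    UNSEEN_FILE2 = "UnseenIn_File2"
    LOW_QUALITY_FILE1 = "LowQuality_File1"
    LOW_QUALITY_FILE2 = "LowQuality_File2"
    LOW_QUALITY_BOTH = "LowQuality_Both"


@dataclass
class GeneralComparison:
    alpha: float
    beta: float
    differentiable: bool
    alpha_threshold: float = ALPHA_THRESHOLD
    beta_threshold: float = BETA_THRESHOLD


@dataclass
class RankedIdentification:
    id: GlycopeptideId
    z: float
    quality_pass: bool
    failure_cause: FailureCause
    rank: int
    degenerate_null: bool = False


def general_comparison(
    test: SimilarityDistribution,
    null: SimilarityDistribution,
    alpha_threshold: float = ALPHA_THRESHOLD,
    beta_threshold: float = BETA_THRESHOLD,
) -> GeneralComparison:
    """Test-vs-Null overlap verdict on the whole glycosite."""
    from .distributions import estimate_density

    ov = overlap(estimate_density(test), estimate_density(null))
    return GeneralComparison(
        alpha=ov.alpha,
        beta=ov.beta,
        differentiable=bool(ov.alpha < alpha_threshold and ov.beta < beta_threshold),
        alpha_threshold=alpha_threshold,
        beta_threshold=beta_threshold,
    )


def contribution_samples(dist: SimilarityDistribution, id_index: int) -> np.ndarray:
    """The numerator-only contribution of one id across all comparisons."""
    if not 0 <= id_index < dist.numerators.shape[1]:
        raise IndexError(f"unknown id index {id_index}")
    return dist.numerators[:, id_index]


def _histogram_density(x: np.ndarray, edges: np.ndarray) -> DensityEstimate:
    hist, _ = np.histogram(x, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    area = np.trapezoid(hist, centers)
    if area > 0:
        hist = hist / area
    return DensityEstimate(grid=centers, density=hist)


def contribution_overlap(
    test_samples: np.ndarray,
    internal_samples: np.ndarray,
    bins: int = CONTRIBUTION_BINS,
) -> float:
    """Combined alpha + beta overlap of two contribution samples.

    Histogram densities (not KDE) are used because contribution samples are
    heavily zero-inflated; the coarse bin count is the resolution limit that
    motivates combining alpha and beta into one threshold.
    """
    hi = float(max(test_samples.max(initial=0.0), internal_samples.max(initial=0.0)))
    if hi <= 0.0:
        return 1.0  # both identically zero: perfectly consistent
    edges = np.linspace(0.0, hi * (1 + 1e-9), bins + 1)
    ov = overlap(_histogram_density(test_samples, edges), _histogram_density(internal_samples, edges))
    return float(ov.alpha + ov.beta)


def rank_identifications(
    test: SimilarityDistribution,
    null: SimilarityDistribution,
    internal_a: SimilarityDistribution,
    internal_b: SimilarityDistribution,
    matrix_a: AbundanceMatrix,
    matrix_b: AbundanceMatrix,
    overlap_threshold: float = CONTRIBUTION_OVERLAP_THRESHOLD,
    bins: int = CONTRIBUTION_BINS,
) -> list[RankedIdentification]:
    """Rank every identification by its Test-vs-Null contribution z-score.

    z_i = mean over Test comparisons of (c - mu_null_i) / sd_null_i. A
    zero-variance Null contribution gets a signed infinite sentinel (negative
    when the id contributes in Test but the Null is constant zero) and is
    flagged rather than silently ranked. Quality is assessed per group, only
    in groups where the id was observed in the original matrix; an id unseen
    in a group's original data is reported as UnseenIn_File1/2 instead.
    """
    if matrix_a.id_labels != matrix_b.id_labels:
        raise ValueError("matrices must share an aligned id space")
    n = matrix_a.n_ids
    seen_a = (matrix_a.values > 0).any(axis=1)
    seen_b = (matrix_b.values > 0).any(axis=1)
    ranked: list[RankedIdentification] = []
    for i in range(n):
        c_test = test.numerators[:, i]
        c_null = null.numerators[:, i]
        mu, sd = float(c_null.mean()), float(c_null.std(ddof=1))
        degenerate = sd == 0.0
        if degenerate:
            if float(c_test.mean()) == mu:
                z = 0.0
            elif mu == 0.0 and (c_test > 0).all():
                z = float("-inf")
            else:
                z = float("inf")
            logger.warning(
                "id %s has a zero-variance Null contribution; z sentinel %s",
                matrix_a.ids[i].canonical, z,
            )
        else:
            z = float(((c_test - mu) / sd).mean())
        if not seen_a[i] and not seen_b[i]:
            cause = FailureCause.UNSEEN_FILE1
        elif not seen_a[i]:
            cause = FailureCause.UNSEEN_FILE1
        elif not seen_b[i]:
            cause = FailureCause.UNSEEN_FILE2
        else:
            fail_a = contribution_overlap(c_test, internal_a.numerators[:, i], bins) < overlap_threshold
            fail_b = contribution_overlap(c_test, internal_b.numerators[:, i], bins) < overlap_threshold
            if fail_a and fail_b:
                cause = FailureCause.LOW_QUALITY_BOTH
            elif fail_a:
                cause = FailureCause.LOW_QUALITY_FILE1
            elif fail_b:
                cause = FailureCause.LOW_QUALITY_FILE2
            else:
                cause = FailureCause.PASSED
        ranked.append(
            RankedIdentification(
                id=matrix_a.ids[i],
                z=z,
                quality_pass=cause is FailureCause.PASSED,
                failure_cause=cause,
                rank=0,
                degenerate_null=degenerate,
            )
        )
    ranked.sort(key=lambda r: (r.z, r.id.canonical))
    for pos, r in enumerate(ranked, start=1):
        r.rank = pos
    return ranked


def ranking_table(ranked: list[RankedIdentification]) -> pd.DataFrame:
    """The ranking report in the standard column layout."""
    return pd.DataFrame(
        {
            "Glycopeptide": [r.id.canonical for r in ranked],
            "ZScore": [r.z for r in ranked],
            "Quality": ["T" if r.quality_pass else "F" for r in ranked],
            "Likely Failure Cause": [r.failure_cause.value for r in ranked],
        }
    )
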