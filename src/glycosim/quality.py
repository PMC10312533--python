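"""Data-quality assessment from the Internal similarity distributions.

Three readouts:

* **Modality / peak membership** — a multimodal Internal distribution means
  some replicate combinations resemble each other much less than others. Each
  comparison is assigned to a density peak; a replicate whose representation
  in a peak deviates by |z| > 3 from the others (withheld z-score) is an
  outlier candidate, removable when the peak carries > 10% of comparisons and
  the replicate is under-represented in the primary peak or over-represented
  in a secondary one.

* **Internal Confidence** — IC = |mu_Test - mu_Internal| / sd_Internal *
  10^-(alpha+beta). IC >= 2 with the Internal mean above the Test mean marks
  the group's data as reliable enough to interpret the comparison.

* **Typicality** — the Observed Similarity must sit within 3 sd of the Test
  distribution mean (or, strictly, inside its central 50%) for the bootstrap
  to be trusted as a faithful simulation of the comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .distributions import (
    DensityEstimate,
    OverlapResult,
    SimilarityDistribution,
    estimate_density,
    overlap,
)
from .similarity import SimilarityResult

logger = logging.getLogger(__name__)

PEAK_PROMINENCE_FRACTION = 0.05
OUTLIER_Z_THRESHOLD = 3.0
PEAK_MASS_THRESHOLD = 0.10
IC_THRESHOLD = 2.0
TYPICALITY_Z_THRESHOLD = 3.0
EQUALITY_SD_FRACTION = 0.5


@dataclass
class Peak:
    location: float
    height: float
    comparison_indices: np.ndarray

    @property
    def n_comparisons(self) -> int:
        return int(self.comparison_indices.size)


@dataclass
class PeakAssignment:
    """Density peaks with every comparison assigned to exactly one of them."""

    peaks: list[Peak]
    boundaries: list[float]
    n_comparisons: int
    mass_threshold: float = PEAK_MASS_THRESHOLD

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def multimodal(self) -> bool:
        return self.n_peaks >= 2

    @property
    def masses(self) -> np.ndarray:
        return np.array([p.n_comparisons for p in self.peaks]) / max(self.n_comparisons, 1)

    @property
    def primary_index(self) -> int:
        """The coherent group's own mode: the highest-similarity peak among
        those holding a non-negligible share of comparisons.

        A strong outlier replicate can put the *majority* of resampled
        comparisons into low-similarity peaks, so the largest peak is not a
        safe definition of "primary"; the self-consistent behavior of a
        group always sits at the high end of its internal similarities.
        Peaks at or below the mass threshold are ignored so a spurious
        high-similarity density bump cannot claim primacy; if no peak
        qualifies, the largest one is used.
        """
        masses = self.masses
        eligible = [k for k in range(self.n_peaks) if masses[k] > self.mass_threshold]
        if not eligible:
            return int(np.argmax(masses))
        return max(eligible, key=lambda k: self.peaks[k].location)


@dataclass
class OutlierVerdict:
    """One replicate's representation in one peak."""

    replicate: str
    peak_index: int
    z: float
    direction: str  # "over" | "under"
    remove: bool
    note: str = ""


@dataclass
class InternalAssessment:
    """Internal Confidence verdict for one group against the Test distribution."""

    ic_score: float
    alpha: float
    beta: float
    relation: str  # internal_above_test | internal_equal_test | internal_below_test
    passes: bool
    mu_internal: float
    mu_test: float
    sd_internal: float


def detect_peaks(
    density: DensityEstimate,
    dist: SimilarityDistribution,
    prominence_fraction: float = PEAK_PROMINENCE_FRACTION,
) -> PeakAssignment:
    """Find density modes (prominence >= ``prominence_fraction`` of the max)
    and assign every comparison to a peak by the local-minimum boundaries
    between consecutive modes. A unimodal density yields a single peak
    holding everything; grid-edge maxima are detected via sentinel padding.
    """
    y = density.density
    padded = np.concatenate([[-np.inf], y, [-np.inf]])
    locs, _ = find_peaks(padded, prominence=prominence_fraction * float(y.max()))
    locs = locs - 1
    if locs.size == 0:
        locs = np.array([int(np.argmax(y))])
    boundaries = []
    for p, q in zip(locs[:-1], locs[1:]):
        boundaries.append(float(density.grid[p + int(np.argmin(y[p:q + 1]))]))
    edges = [-np.inf] + boundaries + [np.inf]
    peaks = []
    for k, loc in enumerate(locs):
        sel = np.flatnonzero((dist.values >= edges[k]) & (dist.values < edges[k + 1]))
        peaks.append(
            Peak(
                location=float(density.grid[loc]),
                height=float(y[loc]),
                comparison_indices=sel,
            )
        )
    return PeakAssignment(peaks=peaks, boundaries=boundaries, n_comparisons=len(dist))


def assess_replicate_membership(
    assignment: PeakAssignment,
    dist: SimilarityDistribution,
    z_threshold: float = OUTLIER_Z_THRESHOLD,
    mass_threshold: float = PEAK_MASS_THRESHOLD,
) -> list[OutlierVerdict]:
    """Withheld z-scores of per-replicate peak membership counts.

    For each (replicate, peak): the number of comparisons in the peak that
    involve the replicate is compared with the other replicates' counts
    (mean/sd computed with the replicate withheld). Removal is recommended
    only when |z| exceeds the threshold, the peak holds more than the mass
    threshold of all comparisons, and the deviation direction is
    under-representation in the primary peak or over-representation in a
    non-primary peak.
    """
    members = dist.pair_replicate_labels()
    replicates = sorted({lab for m in members for lab in m})
    verdicts: list[OutlierVerdict] = []
    if len(replicates) < 3:
        for rep in replicates:
            verdicts.append(
                OutlierVerdict(rep, -1, float("nan"), "over", False,
                               note="fewer than 3 replicates: no z-score computable")
            )
        return verdicts
    masses = assignment.masses
    primary = assignment.primary_index
    counts = np.zeros((len(replicates), assignment.n_peaks))
    for k, peak in enumerate(assignment.peaks):
        in_peak = [members[i] for i in peak.comparison_indices]
        for r, rep in enumerate(replicates):
            counts[r, k] = sum(rep in m for m in in_peak)
    for k in range(assignment.n_peaks):
        for r, rep in enumerate(replicates):
            others = np.delete(counts[:, k], r)
            sd = float(others.std(ddof=1))
            diff = float(counts[r, k] - others.mean())
            if sd == 0.0:
                z = 0.0 if diff == 0.0 else float(np.sign(diff)) * float("inf")
            else:
                z = diff / sd
            if abs(z) <= z_threshold:
                continue
            direction = "over" if z > 0 else "under"
            remove = bool(
                masses[k] > mass_threshold
                and ((direction == "under" and k == primary)
                     or (direction == "over" and k != primary))
            )
            note = "" if masses[k] > mass_threshold else (
                f"peak mass {masses[k]:.2f} <= {mass_threshold:.2f}: not removable"
            )
            verdicts.append(OutlierVerdict(rep, k, float(z), direction, remove, note))
    return verdicts


def internal_confidence(
    internal: SimilarityDistribution,
    test: SimilarityDistribution,
    ic_threshold: float = IC_THRESHOLD,
    overlap_result: OverlapResult | None = None,
) -> InternalAssessment:
    """Internal Confidence score of one group's Internal distribution.

    IC = |mu_Test - mu_Internal| / sd_Internal * 10^-(alpha + beta) where
    alpha/beta come from the Test-vs-Internal density overlap. The group
    passes when IC >= threshold and its Internal mean lies above the Test
    mean; an Internal mean statistically indistinguishable from the Test mean
    (within half the smaller sd) is flagged as a potential subset, and one
    below it marks the group as too variable to treat as a unified group.
    """
    mu_i, mu_t = internal.mean, test.mean
    sd_i, sd_t = internal.sd, test.sd
    ov = overlap_result or overlap(estimate_density(test), estimate_density(internal))
    if sd_i == 0.0:
        logger.warning("internal distribution %s is degenerate (sd = 0)", internal.kind)
        ic = float("inf") if mu_t != mu_i else 0.0
    else:
        ic = abs(mu_t - mu_i) / sd_i * 10.0 ** (-(ov.alpha + ov.beta))
    if abs(mu_i - mu_t) <= EQUALITY_SD_FRACTION * min(sd_i, sd_t):
        relation = "internal_equal_test"
        logger.warning(
            "%s mean is indistinguishable from the Test mean: the group may "
            "be a subset of the other", internal.kind,
        )
    elif mu_i > mu_t:
        relation = "internal_above_test"
    else:
        relation = "internal_below_test"
    return InternalAssessment(
        ic_score=float(ic),
        alpha=ov.alpha,
        beta=ov.beta,
        relation=relation,
        passes=bool(ic >= ic_threshold and relation == "internal_above_test"),
        mu_internal=mu_i,
        mu_test=mu_t,
        sd_internal=sd_i,
    )


def typicality_check(
    observed: SimilarityResult | float,
    test: SimilarityDistribution,
    strict: bool = False,
    z_threshold: float = TYPICALITY_Z_THRESHOLD,
) -> tuple[float, bool]:
    """Is the Observed Similarity a typical draw from the Test distribution?

    Returns ``(z, typical)``; strict mode additionally requires the observed
    value to lie inside the empirical interquartile range.
    """
    obs = observed.total if isinstance(observed, SimilarityResult) else float(observed)
    mu, sd = test.mean, test.sd
    if sd == 0.0:
        return (0.0 if obs == mu else float("inf")), bool(obs == mu)
    z = (obs - mu) / sd
    if strict:
        q1, q3 = np.quantile(test.values, [0.25, 0.75])
        return float(z), bool(q1 <= obs <= q3)
    return float(z), bool(abs(z) <= z_threshold)


def null_below_test_warning(null: SimilarityDistribution, test: SimilarityDistribution) -> bool:
    """Warn when the Null mean falls below the Test mean (very high internal
    variability with low missingness); informational only."""
    below = null.mean < test.mean
    if below:
        logger.warning(
            "Null distribution mean (%.4f) is below the Test mean (%.4f): "
            "very high internal variability; expect the Internal "
            "distributions to flag this", null.mean, test.mean,
        )
    return below
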