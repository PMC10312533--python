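"""Similarity distributions, kernel density estimates, and overlap statistics.

Four distributions are built from the bootstrap collections: Internal-A and
Internal-B (within-collection pairs: how much a group resembles itself), Test
(cross pairs between the two groups' test collections: how much the groups
resemble each other), and Null (cross pairs between the mixed-group null
collections: what "no difference" looks like for these data). The Observed
Similarity is the single un-resampled comparison of the two groups.

Overlap between two distributions is read off their densities: x is the
crossing point between the two density means where the Test density falls
below the reference density; alpha (false-positive proportion) is the
reference mass on the Test side of x and beta (false-negative proportion) the
Test mass on the reference side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy.stats import gaussian_kde

from .bootstrap import Collection, ResampledDataset, enumerate_comparisons
from .data import AbundanceMatrix, summarize_group
from .similarity import (
    EmptyComparisonError,
    SimilarityResult,
    modified_tanimoto,
    pairwise_modified_tanimoto,
)

logger = logging.getLogger(__name__)

GRID_SIZE = 512
SPIKE_BANDWIDTH = 1e-3


@dataclass
class SimilarityDistribution:
    """A labeled collection of pairwise similarity totals with provenance.

    ``values[p]`` is the total similarity of ``pairs[p]`` and
    ``numerators[p, i]`` identification i's numerator contribution to it.
    """

    kind: str  # internal_a, internal_b, test, null
    values: np.ndarray
    numerators: np.ndarray
    pairs: list[tuple[ResampledDataset, ResampledDataset]]
    n_dropped: int = 0

    def __len__(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1)) if self.values.size > 1 else 0.0

    def pair_replicate_labels(self) -> list[frozenset[str]]:
        """Replicate labels involved in each comparison (peak membership)."""
        return [d1.replicate_labels | d2.replicate_labels for d1, d2 in self.pairs]


@dataclass
class DensityEstimate:
    """A unit-integral density on a fixed grid over [0, 1]."""

    grid: np.ndarray
    density: np.ndarray
    source_kind: str = ""

    @cached_property
    def mean(self) -> float:
        return float(np.trapezoid(self.grid * self.density, self.grid))


@dataclass
class OverlapResult:
    """Crossing point and the two tail masses split at it."""

    crossing: float
    alpha: float
    beta: float


def _summaries_for(
    datasets: list[ResampledDataset],
    matrix_a: AbundanceMatrix,
    matrix_b: AbundanceMatrix,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-dataset (values, presence) rows for a list of datasets.

    Members tagged "A" index into ``matrix_a`` and "B" into ``matrix_b``;
    both matrices must be standardized and share an aligned id space.
    """
    if matrix_a.id_labels != matrix_b.id_labels:
        raise ValueError("matrices must share an aligned id space")
    cols = {("A", lab): matrix_a.values[:, r] for r, lab in enumerate(matrix_a.replicates)}
    cols.update({("B", lab): matrix_b.values[:, r] for r, lab in enumerate(matrix_b.replicates)})
    n = matrix_a.n_ids
    V = np.zeros((len(datasets), n))
    P = np.zeros((len(datasets), n))
    for k, ds in enumerate(datasets):
        sub = np.column_stack([cols[m] for m in ds.members])
        counts = (sub > 0).sum(axis=1)
        P[k] = counts / sub.shape[1]
        V[k] = np.where(counts > 0, sub.sum(axis=1) / np.maximum(counts, 1), 0.0)
    return V, P


def build_distribution(
    pairs: list[tuple[ResampledDataset, ResampledDataset]],
    matrix_a: AbundanceMatrix,
    matrix_b: AbundanceMatrix,
    kind: str,
) -> SimilarityDistribution:
    """Apply the weighted Tanimoto to every dataset pair of a comparison group.

    Pairs whose comparison is empty (zero denominator) are dropped with a
    logged count; if every pair fails, an error is raised.
    """
    if not pairs:
        raise ValueError("no comparison pairs supplied")
    unique: dict[tuple, int] = {}
    order: list[ResampledDataset] = []
    for d1, d2 in pairs:
        for d in (d1, d2):
            if d.signature not in unique:
                unique[d.signature] = len(order)
                order.append(d)
    V, P = _summaries_for(order, matrix_a, matrix_b)
    ia = np.array([unique[d1.signature] for d1, _ in pairs])
    ib = np.array([unique[d2.signature] for _, d2 in pairs])
    totals, nums = pairwise_modified_tanimoto(V[ia], P[ia], V[ib], P[ib])
    ok = ~np.isnan(totals)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("%s: dropped %d empty comparisons", kind, n_dropped)
    if not ok.any():
        raise EmptyComparisonError(f"every comparison pair in {kind!r} was empty")
    kept_pairs = [p for p, good in zip(pairs, ok) if good]
    return SimilarityDistribution(
        kind=kind,
        values=np.clip(totals[ok], 0.0, 1.0),
        numerators=nums[ok],
        pairs=kept_pairs,
        n_dropped=n_dropped,
    )


def build_all_distributions(
    matrix_a: AbundanceMatrix,
    matrix_b: AbundanceMatrix,
    test_a: Collection,
    test_b: Collection,
    null_1: Collection,
    null_2: Collection,
) -> dict[str, SimilarityDistribution]:
    """Convenience: the four bootstrap distributions keyed by kind."""
    return {
        "internal_a": build_distribution(enumerate_comparisons(test_a), matrix_a, matrix_b, "internal_a"),
        "internal_b": build_distribution(enumerate_comparisons(test_b), matrix_a, matrix_b, "internal_b"),
        "test": build_distribution(enumerate_comparisons(test_a, test_b), matrix_a, matrix_b, "test"),
        "null": build_distribution(enumerate_comparisons(null_1, null_2), matrix_a, matrix_b, "null"),
    }


def observed_similarity(matrix_a: AbundanceMatrix, matrix_b: AbundanceMatrix) -> SimilarityResult:
    """The single comparison of the two original, un-resampled groups."""
    if matrix_a.id_labels != matrix_b.id_labels:
        raise ValueError("matrices must share an aligned id space")
    sa = summarize_group(matrix_a, matrix_a.replicates)
    sb = summarize_group(matrix_b, matrix_b.replicates)
    return modified_tanimoto(
        sa,
        sb,
        members_a=tuple(("A", r) for r in matrix_a.replicates),
        members_b=tuple(("B", r) for r in matrix_b.replicates),
        kind_tag="observed",
    )


def estimate_density(
    dist: SimilarityDistribution | np.ndarray,
    grid_size: int = GRID_SIZE,
    bandwidth: str | float = "silverman",
    spike_bandwidth: float = SPIKE_BANDWIDTH,
) -> DensityEstimate:
    """Gaussian KDE of a similarity distribution on a fixed [0, 1] grid.

    All-identical values (or a singular KDE) degrade to a narrow Gaussian
    spike of width ``spike_bandwidth`` centered on the common value. The
    returned density is renormalized to unit trapezoid integral on the grid.
    """
    if isinstance(dist, SimilarityDistribution):
        values, kind = dist.values, dist.kind
    else:
        values, kind = np.asarray(dist, dtype=float), ""
    if values.size == 0:
        raise ValueError("cannot estimate a density from an empty distribution")
    grid = np.linspace(0.0, 1.0, grid_size)
    if values.size < 2 or float(values.std()) == 0.0:
        center = float(values.mean())
        density = np.exp(-0.5 * ((grid - center) / spike_bandwidth) ** 2)
    else:
        try:
            density = gaussian_kde(values, bw_method=bandwidth)(grid)
        except np.linalg.LinAlgError:
            center = float(values.mean())
            density = np.exp(-0.5 * ((grid - center) / spike_bandwidth) ** 2)
    area = np.trapezoid(density, grid)
    if area <= 0:
        raise ValueError("degenerate density (zero mass on the grid)")
    return DensityEstimate(grid=grid, density=density / area, source_kind=kind)


def _mass_below(grid: np.ndarray, density: np.ndarray, x: float) -> float:
    """Trapezoid mass of ``density`` on [grid[0], x], interpolating at x."""
    if x <= grid[0]:
        return 0.0
    if x >= grid[-1]:
        return float(np.trapezoid(density, grid))
    k = int(np.searchsorted(grid, x))
    gx = np.concatenate([grid[:k], [x]])
    dx = np.concatenate([density[:k], [np.interp(x, grid, density)]])
    return float(np.trapezoid(dx, gx))


def overlap(test_density: DensityEstimate, reference_density: DensityEstimate) -> OverlapResult:
    """Alpha/beta overlap between a Test density and a reference density.

    The crossing x is searched strictly between the two density means (KDE
    tails can produce spurious crossings elsewhere); with several crossings
    the one nearest the midpoint of the means wins, and with none (nearly
    coincident distributions) the midpoint itself is used, which yields
    alpha = beta = 0.5 for identical densities.
    """
    t, r = test_density, reference_density
    if t.grid.shape != r.grid.shape or not np.allclose(t.grid, r.grid):
        raise ValueError("densities must share a grid")
    grid = t.grid
    m_t, m_r = t.mean, r.mean
    if np.allclose(t.density, r.density):
        x = 0.5 * (m_t + m_r)
        return OverlapResult(crossing=x, alpha=0.5, beta=0.5)
    lo, hi = min(m_t, m_r), max(m_t, m_r)
    diff = t.density - r.density
    inside = (grid >= lo) & (grid <= hi)
    idx = np.flatnonzero(inside)
    crossings: list[float] = []
    if idx.size >= 2:
        d = diff[idx]
        sign_change = np.flatnonzero(np.diff(np.sign(d)) != 0)
        for j in sign_change:
            g0, g1 = grid[idx[j]], grid[idx[j + 1]]
            d0, d1 = d[j], d[j + 1]
            crossings.append(g0 if d0 == d1 else g0 + (g1 - g0) * (-d0) / (d1 - d0))
    mid = 0.5 * (m_t + m_r)
    x = min(crossings, key=lambda c: abs(c - mid)) if crossings else mid
    total_t = float(np.trapezoid(t.density, grid))
    total_r = float(np.trapezoid(r.density, grid))
    if m_t <= m_r:
        alpha = _mass_below(grid, r.density, x) / total_r
        beta = (total_t - _mass_below(grid, t.density, x)) / total_t
    else:
        alpha = (total_r - _mass_below(grid, r.density, x)) / total_r
        beta = _mass_below(grid, t.density, x) / total_t
    return OverlapResult(
        crossing=float(x),
        alpha=float(np.clip(alpha, 0.0, 1.0)),
        beta=float(np.clip(beta, 0.0, 1.0)),
    )
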