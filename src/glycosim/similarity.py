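"""Classic and presence/distance-weighted Tanimoto similarity.

The classic Tanimoto coefficient of two nonnegative vectors A, B is

    T = sum(A_i B_i) / (sum(A_i^2) + sum(B_i^2) - sum(A_i B_i)).

The weighted variant folds in per-identification presence rates P_iA, P_iB
(the fraction of replicates observing id i) and an abundance-distance damping
term: per id,

    K_i = 1 + (P_iA + P_iB) / 2          (1 <= K_i <= 2)
    d_i = |A_i - B_i|                     (Manhattan distance at id i)
    num_i = (A_i P_iA) (B_i P_iB) K_i^(-d_i)

    T = sum(num) / (sum((A P_A)^2) + sum((B P_B)^2) - sum(num)).

Absence annihilates a term (P = 0 => num = 0) and diverging abundances shrink
it smoothly, so the metric penalizes both missingness disagreement and
quantitative disagreement while staying in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import GroupSummary


class EmptyComparisonError(ValueError):
    """Both groups are empty on the shared id space; similarity is undefined."""


@dataclass
class ContributionTerm:
    """One identification's pieces of a weighted Tanimoto comparison."""

    id_index: int
    numerator: float
    k_scale: float
    distance: float
    denom_a: float
    denom_b: float


@dataclass
class SimilarityResult:
    """A single pairwise comparison: total similarity plus its decomposition."""

    total: float
    terms: list[ContributionTerm]
    members_a: tuple = ()
    members_b: tuple = ()
    kind_tag: str = "observed"

    @property
    def numerators(self) -> np.ndarray:
        return np.array([t.numerator for t in self.terms])


def _weighted_parts(
    va: np.ndarray, pa: np.ndarray, vb: np.ndarray, pb: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Elementwise numerator / K / d / squared-weight terms (broadcasting)."""
    xa = va * pa
    xb = vb * pb
    k = 1.0 + (pa + pb) / 2.0
    d = np.abs(va - vb)
    num = xa * xb * np.power(k, -d)
    return num, k, d, xa**2, xb**2


def classic_tanimoto(a: GroupSummary, b: GroupSummary, kind_tag: str = "observed") -> SimilarityResult:
    """Presence-blind Tanimoto on the aggregated abundance vectors."""
    va, vb = a.values, b.values
    if va.shape != vb.shape:
        raise ValueError("summaries must share an id space")
    num = va * vb
    denom = float((va**2).sum() + (vb**2).sum() - num.sum())
    if denom <= 0:
        raise EmptyComparisonError("both groups are empty; similarity undefined")
    terms = [
        ContributionTerm(i, float(num[i]), 1.0, 0.0, float(va[i] ** 2), float(vb[i] ** 2))
        for i in range(va.size)
    ]
    return SimilarityResult(total=float(num.sum() / denom), terms=terms, kind_tag=kind_tag)


def modified_tanimoto(
    a: GroupSummary,
    b: GroupSummary,
    members_a: Sequence = (),
    members_b: Sequence = (),
    kind_tag: str = "observed",
) -> SimilarityResult:
    """Presence- and distance-weighted Tanimoto between two group summaries.

    Raises :class:`EmptyComparisonError` when the denominator is zero (no id
    carries signal in either group): an empty-vs-empty comparison conveys no
    information and must not enter a distribution as similarity 1.
    """
    if a.values.shape != b.values.shape:
        raise ValueError("summaries must share an id space")
    num, k, d, da, db = _weighted_parts(a.values, a.presence, b.values, b.presence)
    denom = float(da.sum() + db.sum() - num.sum())
    if denom <= 0:
        raise EmptyComparisonError("both groups are empty; similarity undefined")
    terms = [
        ContributionTerm(i, float(num[i]), float(k[i]), float(d[i]), float(da[i]), float(db[i]))
        for i in range(num.size)
    ]
    return SimilarityResult(
        total=float(num.sum() / denom),
        terms=terms,
        members_a=tuple(members_a),
        members_b=tuple(members_b),
        kind_tag=kind_tag,
    )


def pairwise_modified_tanimoto(
    va: np.ndarray,
    pa: np.ndarray,
    vb: np.ndarray,
    pb: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized weighted Tanimoto over paired rows of dataset summaries.

    ``va, pa, vb, pb`` are (n_pairs, n_ids) arrays: row p holds the left and
    right summaries of pair p. Returns ``(totals, numerators)`` where totals
    has shape (n_pairs,) and numerators (n_pairs, n_ids). Pairs with a zero
    denominator get total = NaN (callers drop and count them).
    """
    num, _, _, da, db = _weighted_parts(va, pa, vb, pb)
    nsum = num.sum(axis=1)
    denom = da.sum(axis=1) + db.sum(axis=1) - nsum
    with np.errstate(invalid="ignore", divide="ignore"):
        totals = np.where(denom > 0, nsum / denom, np.nan)
    return totals, num
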