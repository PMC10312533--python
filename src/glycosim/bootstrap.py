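"""Bootstrap resampling of replicates into test and null dataset collections.

Test collections: per sample group, replicates are drawn with replacement into
datasets of size n-1 (one fewer than observed); 100 datasets are generated and
then deduplicated by their member multiset. Null collections: datasets of size
round((n_A + n_B)/2) draw half their members from each group (the odd member
alternates sides); two collections of 200 generated datasets each are built
and deduplicated within and across collections so they share no dataset.

Comparison enumeration is capped structurally by the collection sizes:
100 x 100 = 10,000 test comparisons, C(100, 2) = 4,950 internal comparisons
per group, and 200 x 200 = 40,000 null comparisons at most.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np

from .data import AbundanceMatrix

logger = logging.getLogger(__name__)

TEST_DRAWS = 100
NULL_DRAWS = 200
MAX_TEST_COMPARISONS = TEST_DRAWS * TEST_DRAWS
MAX_INTERNAL_COMPARISONS = TEST_DRAWS * (TEST_DRAWS - 1) // 2
MAX_NULL_COMPARISONS = NULL_DRAWS * NULL_DRAWS

Member = tuple[str, str]  # (group tag, replicate label)


@dataclass(frozen=True)
class ResampledDataset:
    """A with-replacement draw of replicates, identified by its multiset."""

    source_tag: str  # "A", "B" or "joint"
    members: tuple[Member, ...]

    @property
    def signature(self) -> tuple[Member, ...]:
        return tuple(sorted(self.members))

    def labels_for(self, group: str) -> list[str]:
        return [lab for g, lab in self.members if g == group]

    @property
    def replicate_labels(self) -> frozenset[str]:
        return frozenset(lab for _, lab in self.members)


@dataclass
class Collection:
    """A deduplicated set of resampled datasets of one kind."""

    kind: str  # test_A, test_B, null_1, null_2
    datasets: list[ResampledDataset]
    cap_generated: int

    def __post_init__(self) -> None:
        sigs = [d.signature for d in self.datasets]
        if len(set(sigs)) != len(sigs):
            raise ValueError(f"collection {self.kind} contains duplicate datasets")
        if len(self.datasets) > self.cap_generated:
            raise ValueError(f"collection {self.kind} exceeds its generation cap")

    def __len__(self) -> int:
        return len(self.datasets)

    @property
    def signatures(self) -> set[tuple[Member, ...]]:
        return {d.signature for d in self.datasets}


def _dedup(datasets: list[ResampledDataset], seen: set | None = None) -> list[ResampledDataset]:
    seen = set() if seen is None else set(seen)
    out = []
    for d in datasets:
        if d.signature not in seen:
            seen.add(d.signature)
            out.append(d)
    return out


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def make_test_collections(
    a: AbundanceMatrix,
    b: AbundanceMatrix,
    seed: int | np.random.Generator,
) -> tuple[Collection, Collection]:
    """Build both groups' test collections (size n-1 draws, 100 then dedup)."""
    rng = _as_rng(seed)
    out = []
    for tag, matrix in (("A", a), ("B", b)):
        n = matrix.n_replicates
        if n < 2:
            raise ValueError(f"group {matrix.group_name!r} needs >= 2 replicates")
        if n == 2:
            logger.warning(
                "group %r has only 2 replicates: test datasets are single "
                "replicates and internal comparisons are degenerate",
                matrix.group_name,
            )
        draws = [
            ResampledDataset(
                source_tag=tag,
                members=tuple((tag, lab) for lab in rng.choice(matrix.replicates, size=n - 1, replace=True)),
            )
            for _ in range(TEST_DRAWS)
        ]
        out.append(Collection(kind=f"test_{tag}", datasets=_dedup(draws), cap_generated=TEST_DRAWS))
    return out[0], out[1]


def null_dataset_size(n_a: int, n_b: int) -> int:
    """Average replicate count, rounded half up (documented tie-break)."""
    return int(math.floor((n_a + n_b) / 2 + 0.5))


def make_null_collections(
    a: AbundanceMatrix,
    b: AbundanceMatrix,
    seed: int | np.random.Generator,
) -> tuple[Collection, Collection]:
    """Build two cross-deduplicated null collections of mixed-group draws.

    Each dataset draws ceil(size/2) members from one group and floor(size/2)
    from the other, the extra member alternating sides across datasets so
    sampling stays at a roughly equal rate from both groups.
    """
    rng = _as_rng(seed)
    if a.n_replicates < 2 or b.n_replicates < 2:
        raise ValueError("both groups need >= 2 replicates for null sampling")
    size = null_dataset_size(a.n_replicates, b.n_replicates)
    half, odd = divmod(size, 2)

    def draw_batch(start_extra_a: bool) -> list[ResampledDataset]:
        batch = []
        extra_a = start_extra_a
        for _ in range(NULL_DRAWS):
            ka = half + (1 if odd and extra_a else 0)
            kb = size - ka
            members = tuple(
                [("A", lab) for lab in rng.choice(a.replicates, size=ka, replace=True)]
                + [("B", lab) for lab in rng.choice(b.replicates, size=kb, replace=True)]
            )
            batch.append(ResampledDataset(source_tag="joint", members=members))
            if odd:
                extra_a = not extra_a
        return batch

    start = bool(rng.integers(0, 2))
    first = _dedup(draw_batch(start))
    second = _dedup(draw_batch(not start))
    # signatures drawn by both batches are assigned alternately so neither
    # collection is starved when the distinct-multiset space is small
    common = {d.signature for d in first} & {d.signature for d in second}
    keep_first = True
    drop1: set = set()
    drop2: set = set()
    for d in first:
        if d.signature in common:
            (drop2 if keep_first else drop1).add(d.signature)
            keep_first = not keep_first
    c1 = Collection(
        kind="null_1",
        datasets=[d for d in first if d.signature not in drop1],
        cap_generated=NULL_DRAWS,
    )
    c2 = Collection(
        kind="null_2",
        datasets=[d for d in second if d.signature not in drop2],
        cap_generated=NULL_DRAWS,
    )
    if not c1.datasets or not c2.datasets:
        raise ValueError(
            "a null collection is empty after cross-collection deduplication "
            "(too few distinct replicate multisets)"
        )
    return c1, c2


def enumerate_comparisons(
    c1: Collection,
    c2: Collection | None = None,
) -> list[tuple[ResampledDataset, ResampledDataset]]:
    """Enumerate comparison pairs.

    Cross mode (two distinct collections): the full Cartesian product.
    Internal mode (``c2 is None`` or the same object): all unordered pairs
    within ``c1``.
    """
    if len(c1) == 0 or (c2 is not None and len(c2) == 0):
        raise ValueError("cannot enumerate comparisons over an empty collection")
    if c2 is None or c2 is c1:
        pairs = list(itertools.combinations(c1.datasets, 2))
        assert len(pairs) <= MAX_INTERNAL_COMPARISONS
        return pairs
    pairs = list(itertools.product(c1.datasets, c2.datasets))
    cap = MAX_NULL_COMPARISONS if c1.kind.startswith("null") else MAX_TEST_COMPARISONS
    assert len(pairs) <= cap
    return pairs
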