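"""Abundance matrices: ingestion, standardization, filtering and summarization.

A sample group is a glycopeptide x replicate matrix of nonnegative
quantifications where an exact 0 encodes "not observed" (the missing-value
convention of DDA glycoproteomics exports). Standardization converts raw
signal to *relative log abundance*: ``log10(x + 1)`` per cell followed by
per-replicate normalization to unit column sum, optionally rescaled by the
log-TIC ratio of each replicate against the strongest run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .identifiers import GlycopeptideId, parse_glycopeptide_id

logger = logging.getLogger(__name__)

_COLSUM_TOL = 1e-9


@dataclass
class AbundanceMatrix:
    """One sample group's glycopeptide x replicate quantifications.

    ``values[i, r]`` is the (raw or standardized) abundance of identification
    ``ids[i]`` in replicate ``replicates[r]``; 0 encodes not-observed.
    """

    group_name: str
    ids: list[GlycopeptideId]
    replicates: list[str]
    values: np.ndarray
    tic: np.ndarray | None = None
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.replicates)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.ids)} ids x {len(self.replicates)} replicates"
            )
        if np.isnan(self.values).any():
            raise ValueError("abundance values contain NaN after ingestion")
        if (self.values < 0).any():
            raise ValueError("abundance values must be nonnegative")
        if len(set(self.replicates)) != len(self.replicates):
            raise ValueError("replicate labels must be unique")
        labels = [gid.canonical for gid in self.ids]
        if len(set(labels)) != len(labels):
            raise ValueError("glycopeptide ids must be unique after canonicalization")
        if self.tic is not None:
            self.tic = np.asarray(self.tic, dtype=float)
            if self.tic.shape != (len(self.replicates),):
                raise ValueError("tic must provide one value per replicate")
            if (self.tic <= 0).any():
                raise ValueError("TIC values must be positive")

    @property
    def n_ids(self) -> int:
        return len(self.ids)

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    @property
    def id_labels(self) -> list[str]:
        return [gid.canonical for gid in self.ids]

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.replicates.index(label)]

    def drop_replicate(self, label: str) -> "AbundanceMatrix":
        """Return a copy without the named replicate column."""
        if label not in self.replicates:
            raise KeyError(f"unknown replicate {label!r} in group {self.group_name!r}")
        keep = [r for r, lab in enumerate(self.replicates) if lab != label]
        return replace(
            self,
            replicates=[self.replicates[r] for r in keep],
            values=self.values[:, keep].copy(),
            tic=None if self.tic is None else self.tic[keep].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.id_labels, columns=self.replicates)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().rename_axis("Glycopeptide").to_csv(path, float_format="%.10g")


@dataclass
class GroupSummary:
    """Per-identification aggregate for one (possibly resampled) dataset.

    ``values[i]`` is the mean standardized abundance of id ``i`` over the
    replicates where it was observed (0 if never observed) and ``presence[i]``
    the fraction of replicates observing it; both count multiplicity when the
    replicate multiset repeats labels.
    """

    values: np.ndarray
    presence: np.ndarray
    n_replicates: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.presence = np.asarray(self.presence, dtype=float)
        if self.values.shape != self.presence.shape:
            raise ValueError("values and presence must align")
        if ((self.presence < 0) | (self.presence > 1)).any():
            raise ValueError("presence must lie in [0, 1]")
        if ((self.presence == 0) != (self.values == 0)).any():
            raise ValueError("presence == 0 must coincide with value == 0")


def load_tic(path: str | Path) -> dict[str, float]:
    """Read a two-column (replicate, TIC) delimited file into a dict."""
    frame = pd.read_csv(path, sep=None, engine="python")
    if frame.shape[1] < 2:
        raise ValueError("TIC file must have replicate and TIC columns")
    return {str(k): float(v) for k, v in zip(frame.iloc[:, 0], frame.iloc[:, 1])}


def load_abundance_matrix(
    path: str | Path,
    group_name: str,
    tic: dict[str, float] | None = None,
) -> AbundanceMatrix:
    """Load a delimited abundance table (first column: id tokens; header:
    replicate labels). Blank/NA cells become 0; duplicate id rows are summed
    with a logged warning; negative values are an error.
    """
    frame = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if frame.shape[1] < 2:
        raise ValueError(
            f"{path}: need at least 2 replicate columns "
            "(similarity of a single-replicate group is undefined)"
        )
    frame = frame.apply(pd.to_numeric, errors="raise").fillna(0.0)
    if (frame.values < 0).any():
        raise ValueError(f"{path}: negative abundance values are not allowed")
    parsed = [parse_glycopeptide_id(str(tok)) for tok in frame.index]
    canon = [gid.canonical for gid in parsed]
    frame.index = pd.Index(canon)
    if frame.index.has_duplicates:
        dups = sorted(frame.index[frame.index.duplicated()].unique())
        logger.warning("%s: summing duplicate id rows: %s", path, ", ".join(dups))
        frame = frame.groupby(level=0, sort=False).sum()
        parsed = {gid.canonical: gid for gid in parsed}
        parsed = [parsed[c] for c in frame.index]
    replicates = [str(c) for c in frame.columns]
    tic_arr = None
    if tic is not None:
        missing = [r for r in replicates if r not in tic]
        if missing:
            raise ValueError(f"TIC values missing for replicates: {missing}")
        tic_arr = np.array([tic[r] for r in replicates], dtype=float)
    return AbundanceMatrix(
        group_name=group_name,
        ids=list(parsed),
        replicates=replicates,
        values=frame.values.astype(float),
        tic=tic_arr,
    )


def standardize(matrix: AbundanceMatrix, use_tic: bool = False) -> AbundanceMatrix:
    """Convert a raw matrix to relative log abundance.

    Per replicate column r: ``L = log10(raw + 1)`` then ``A = L / sum(L)``, so
    the nonzero entries of each column sum to 1. With ``use_tic``, column r is
    further multiplied by ``log10(TIC_r) / max_r log10(TIC_r)`` (ratios <= 1:
    weaker runs are shrunk toward zero, never inflated). Zeros stay zero.
    """
    if matrix.standardized:
        raise ValueError("matrix is already standardized")
    if use_tic and matrix.tic is None:
        raise ValueError("use_tic requested but no TIC values attached")
    log_vals = np.log10(matrix.values + 1.0)
    colsums = log_vals.sum(axis=0)
    dead = np.flatnonzero(colsums <= 0)
    if dead.size:
        names = [matrix.replicates[r] for r in dead]
        raise ValueError(f"all-zero replicate column(s): {names}")
    std = log_vals / colsums
    if use_tic:
        log_tic = np.log10(matrix.tic)
        std = std * (log_tic / log_tic.max())
    return replace(matrix, values=std, standardized=True)


def align_id_space(a: AbundanceMatrix, b: AbundanceMatrix) -> tuple[AbundanceMatrix, AbundanceMatrix]:
    """Put both matrices on the union of their canonical id spaces, filling
    absent ids with all-zero rows, in a deterministic shared order."""
    by_label_a = dict(zip(a.id_labels, a.ids))
    by_label_b = dict(zip(b.id_labels, b.ids))
    union = list(dict.fromkeys(a.id_labels + b.id_labels))

    def expand(m: AbundanceMatrix, lut: dict[str, GlycopeptideId], other: dict[str, GlycopeptideId]) -> AbundanceMatrix:
        rows = np.zeros((len(union), m.n_replicates))
        pos = {lab: i for i, lab in enumerate(m.id_labels)}
        ids = []
        for k, lab in enumerate(union):
            if lab in pos:
                rows[k] = m.values[pos[lab]]
                ids.append(lut[lab])
            else:
                ids.append(other[lab])
        return replace(m, ids=ids, values=rows)

    if a.id_labels == union and b.id_labels == union:
        return a, b
    return expand(a, by_label_a, by_label_b), expand(b, by_label_b, by_label_a)


def min_observation_filter(
    matrix_a: AbundanceMatrix,
    matrix_b: AbundanceMatrix,
    min_obs: int = 2,
) -> tuple[AbundanceMatrix, AbundanceMatrix, list[GlycopeptideId]]:
    """Drop ids observed fewer than ``min_obs`` times across both groups
    combined; ``min_obs=0`` disables. Matrices are id-space aligned first.
    """
    if min_obs < 0:
        raise ValueError("min_obs must be >= 0")
    a, b = align_id_space(matrix_a, matrix_b)
    counts = (a.values > 0).sum(axis=1) + (b.values > 0).sum(axis=1)
    keep = counts >= min_obs
    removed = [gid for gid, k in zip(a.ids, keep) if not k]
    if removed:
        logger.info(
            "min-observation filter (min_obs=%d) removed %d ids: %s",
            min_obs, len(removed), ", ".join(g.canonical for g in removed),
        )
    sel = np.flatnonzero(keep)
    a2 = replace(a, ids=[a.ids[i] for i in sel], values=a.values[sel].copy())
    b2 = replace(b, ids=[b.ids[i] for i in sel], values=b.values[sel].copy())
    return a2, b2, removed


def summarize_group(matrix: AbundanceMatrix, replicate_subset: Sequence[str]) -> GroupSummary:
    """Aggregate a (multi)set of replicate labels into a :class:`GroupSummary`.

    The subset may repeat labels (bootstrap resamples); presence and means
    count multiplicity. Values are averaged over observed members only.
    """
    if not matrix.standardized:
        raise ValueError("summarize_group requires a standardized matrix")
    if len(replicate_subset) == 0:
        raise ValueError("replicate subset must be non-empty")
    pos = {lab: i for i, lab in enumerate(matrix.replicates)}
    try:
        idx = [pos[lab] for lab in replicate_subset]
    except KeyError as exc:
        raise KeyError(
            f"unknown replicate label {exc.args[0]!r} in group {matrix.group_name!r}"
        ) from None
    sub = matrix.values[:, idx]
    observed = sub > 0
    counts = observed.sum(axis=1)
    presence = counts / len(idx)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sub.sum(axis=1) / np.maximum(counts, 1), 0.0)
    return GroupSummary(values=means, presence=presence, n_replicates=len(idx))
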