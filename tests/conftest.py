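"""Shared fixtures and the independent scalar similarity oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest

from glycosim import AbundanceMatrix, GlycopeptideId, GroupSummary


def modified_tanimoto_oracle(va, pa, vb, pb) -> float:
    """Loop-and-accumulate weighted Tanimoto, independent of the package's
    vectorized path: per id, K = 1 + mean presence, d = |A - B|,
    num = (A P_A)(B P_B) K^-d; T = sum(num) / (sum((A P_A)^2) +
    sum((B P_B)^2) - sum(num))."""
    num_sum = da_sum = db_sum = 0.0
    for a, p_a, b, p_b in zip(va, pa, vb, pb):
        k = 1.0 + (p_a + p_b) / 2.0
        d = abs(a - b)
        num_sum += (a * p_a) * (b * p_b) * k ** (-d)
        da_sum += (a * p_a) ** 2
        db_sum += (b * p_b) ** 2
    denom = da_sum + db_sum - num_sum
    if denom <= 0:
        raise ZeroDivisionError("empty comparison")
    return num_sum / denom


def make_summary(values, presence) -> GroupSummary:
    return GroupSummary(
        values=np.asarray(values, dtype=float),
        presence=np.asarray(presence, dtype=float),
        n_replicates=4,
    )


def make_matrix(values, group_name="A", standardized=True, replicates=None, peptide="YNTT"):
    """A small matrix with synthetic glycoform ids; values is (n_ids, n_reps)."""
    values = np.asarray(values, dtype=float)
    n, r = values.shape
    ids = [
        GlycopeptideId(peptide=peptide, composition=(5 + i, 4, i % 2, 1, 0))
        for i in range(n)
    ]
    reps = replicates or [f"{group_name}_r{j + 1}" for j in range(r)]
    return AbundanceMatrix(
        group_name=group_name,
        ids=ids,
        replicates=reps,
        values=values,
        standardized=standardized,
    )


@pytest.fixture
def derived_summaries():
    """The worked two-id example: A=(0.6@P=1, 0.4@P=0.5), B=(0.5@P=1, 0@P=0)."""
    a = make_summary([0.6, 0.4], [1.0, 0.5])
    b = make_summary([0.5, 0.0], [1.0, 0.0])
    return a, b


# hand-evaluated with modified_tanimoto_oracle:
# id1: K=2, d=0.1, num = 0.3 * 2**-0.1 = 0.27990983...
# denom = 0.36 + 0.04 + 0.25 - num = 0.37009017; T = 0.75632852
DERIVED_TOTAL = 0.2799098279 / (0.36 + 0.04 + 0.25 - 0.2799098279)
assert math.isclose(DERIVED_TOTAL, 0.7563285, abs_tol=5e-7)


@pytest.fixture
def derived_matrices():
    """Standardized matrices whose full-group summaries equal the worked
    two-id example (id2 observed in half of group A, never in group B)."""
    a = make_matrix([[0.6, 0.6], [0.4, 0.0]], group_name="A")
    b = make_matrix([[0.5, 0.5], [0.0, 0.0]], group_name="B", replicates=["B_r1", "B_r2"])
    return a, b
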