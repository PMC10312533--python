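"""The three standard figures: internal overlay, general comparison, boxplots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .data import AbundanceMatrix
from .distributions import SimilarityDistribution, estimate_density
from .quality import InternalAssessment
from .ranking import GeneralComparison

TEST_COLOR = "red"
INTERNAL_COLOR = "green"
NULL_COLOR = "blue"
FALSE_POSITIVE_COLOR = "black"
FALSE_NEGATIVE_COLOR = "grey"
GROUP_A_COLOR = "red"
GROUP_B_COLOR = "teal"


def plot_internal(
    internal: SimilarityDistribution,
    test: SimilarityDistribution,
    assessment: InternalAssessment,
    path: str | Path,
) -> str:
    """Internal (green) vs Test (red) density overlay with IC annotation."""
    di = estimate_density(internal)
    dt = estimate_density(test)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(dt.grid, dt.density, color=TEST_COLOR, label="Test")
    ax.plot(di.grid, di.density, color=INTERNAL_COLOR, label=f"Internal ({internal.kind})")
    ax.set_xlabel("similarity")
    ax.set_ylabel("density")
    ax.legend(loc="upper left")
    ax.set_title(
        f"IC={assessment.ic_score:.2f}  "
        f"FPR={assessment.alpha * 100:.1f}%  FNR={assessment.beta * 100:.1f}%"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)


def plot_general(
    test: SimilarityDistribution,
    null: SimilarityDistribution,
    general: GeneralComparison,
    path: str | Path,
) -> str:
    """Test (red) vs Null (blue) densities with false-positive region in
    black and false-negative region in grey, split at the crossing point."""
    dt = estimate_density(test)
    dn = estimate_density(null)
    from .distributions import overlap

    ov = overlap(dt, dn)
    x = ov.crossing
    fig, ax = plt.subplots(figsize=(6, 4))
    test_side_low = dt.mean <= dn.mean
    fp_mask = (dt.grid <= x) if test_side_low else (dt.grid >= x)
    ax.fill_between(dt.grid, 0, dn.density, where=fp_mask, color=FALSE_POSITIVE_COLOR, alpha=0.8)
    ax.fill_between(dt.grid, 0, dt.density, where=~fp_mask, color=FALSE_NEGATIVE_COLOR, alpha=0.8)
    ax.plot(dt.grid, dt.density, color=TEST_COLOR, label="Test")
    ax.plot(dn.grid, dn.density, color=NULL_COLOR, label="Null")
    ax.set_xlabel("similarity")
    ax.set_ylabel("density")
    ax.legend(loc="upper left")
    verdict = "differentiable" if general.differentiable else "not differentiable"
    ax.set_title(
        f"FPR={general.alpha * 100:.1f}%  FNR={general.beta * 100:.1f}%  ({verdict})"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)


def plot_abundance_boxes(
    a: AbundanceMatrix,
    b: AbundanceMatrix,
    path: str | Path,
    color_b: str = GROUP_B_COLOR,
) -> str:
    """Paired per-glycopeptide boxplots of standardized log abundances
    (group A red, group B teal by default; pass ``color_b='green'`` for the
    alternative palette)."""
    n = a.n_ids
    fig, ax = plt.subplots(figsize=(max(6, 0.5 * n), 4.5))
    positions_a = np.arange(n) * 3.0
    positions_b = positions_a + 1.0
    data_a = [row[row > 0] if (row > 0).any() else np.array([0.0]) for row in a.values]
    data_b = [row[row > 0] if (row > 0).any() else np.array([0.0]) for row in b.values]
    for data, pos, color in ((data_a, positions_a, GROUP_A_COLOR), (data_b, positions_b, color_b)):
        bp = ax.boxplot(data, positions=pos, widths=0.8, patch_artist=True)
        for box in bp["boxes"]:
            box.set_facecolor(color)
    ax.set_xticks(positions_a + 0.5)
    ax.set_xticklabels([g.canonical for g in a.ids], rotation=90, fontsize=7)
    ax.set_ylabel("standardized log abundance")
    ax.set_title(f"{a.group_name} ({GROUP_A_COLOR}) vs {b.group_name} ({color_b})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)
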