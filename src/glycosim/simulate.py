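"""Seeded synthetic abundance generator for testing and calibration.

The generator emulates a DDA glycoproteomics quantification table: a fixed
panel of glycopeptide glycoforms with characteristic log10 abundances,
lognormal replicate noise, and detection-limited missingness (the probability
of observing a glycoform follows a logistic curve in its log10 abundance, so
low-abundance glycoforms drop out first — the dominant missing-value
mechanism in DDA acquisition; the default curve is deliberately sharp,
approximating an instrument intensity cutoff, with the lognormal replicate
noise supplying the stochasticity around it). Group effects are multiplicative fold changes
applied to group B; a ten-fold suppression pushes a mid-abundance glycoform
below the detection limit, reproducing the absent-in-one-group regime that
drives real rankings. An outlier replicate is injected by scaling all of its
raw abundances, which both shifts its profile and knocks out its low end.

It does **not** simulate chromatography, charge states, spectra, or
glycoform interdependence; tests passing on these fixtures demonstrate the
statistical machinery, not robustness to every artifact of real LC-MS data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import AbundanceMatrix
from .identifiers import GlycopeptideId

DEFAULT_N_IDS = 20
DEFAULT_N_REPLICATES = (4, 4)
DEFAULT_LOG_RANGE = (4.7, 6.6)
DEFAULT_REPLICATE_SD = 0.15
DEFAULT_DETECTION_MIDPOINT = 4.3
DEFAULT_DETECTION_SLOPE = 25.0


@dataclass
class FixtureSpec:
    """Parameters of one synthetic two-group dataset.

    ``effect`` is the multiplicative fold change applied to ``effect_ids`` in
    group B (values < 1 suppress). ``base_log_abundance`` defaults to an
    evenly spaced log10 panel over ``DEFAULT_LOG_RANGE``; ``effect_ids``
    default (when an effect is requested) to the lowest-abundance panel
    members, the glycoforms DDA sampling loses first. ``missingness`` is an
    extra per-id probability of dropout on top of the detection model;
    ``outlier`` is ``(group, replicate_index, scale)``.
    """

    n_ids: int = DEFAULT_N_IDS
    n_replicates: tuple[int, int] = DEFAULT_N_REPLICATES
    base_log_abundance: np.ndarray | None = None
    replicate_sd: float = DEFAULT_REPLICATE_SD
    effect_ids: tuple[int, ...] | None = None
    n_effect_ids: int = 0
    effect: float = 1.0
    missingness: float | np.ndarray = 0.0
    abundance_dependent_missingness: bool = True
    detection_midpoint: float = DEFAULT_DETECTION_MIDPOINT
    detection_slope: float = DEFAULT_DETECTION_SLOPE
    outlier: tuple[str, int, float] | None = None
    seed: int = 0

    def resolved_base(self) -> np.ndarray:
        if self.base_log_abundance is not None:
            base = np.asarray(self.base_log_abundance, dtype=float)
            if base.shape != (self.n_ids,):
                raise ValueError("base_log_abundance must have one entry per id")
            return base
        return np.linspace(*DEFAULT_LOG_RANGE, self.n_ids)

    def resolved_effect_ids(self) -> tuple[int, ...]:
        if self.effect_ids is not None:
            return tuple(self.effect_ids)
        if self.n_effect_ids == 0 or self.effect == 1.0:
            return ()
        order = np.argsort(self.resolved_base())
        return tuple(int(i) for i in order[: self.n_effect_ids])


def _panel_ids(n_ids: int) -> list[GlycopeptideId]:
    """A deterministic panel of plausible glycoforms on one peptide tag."""
    ids = []
    for i in range(n_ids):
        comp = (3 + i % 6, 2 + (i // 2) % 6, i % 3, (i // 3) % 4, i % 2)
        ids.append(GlycopeptideId(peptide="YNTT", composition=comp, raw_label=""))
    # compositions above may repeat for very large panels; perturb Hex to keep
    # canonical labels unique
    seen: dict[str, int] = {}
    out = []
    for gid in ids:
        lab = gid.canonical
        if lab in seen:
            seen[lab] += 1
            comp = (gid.composition[0] + 6 * seen[lab],) + gid.composition[1:]
            gid = GlycopeptideId(peptide=gid.peptide, composition=comp)
        else:
            seen[lab] = 0
        out.append(gid)
    return out


def _detection_probability(log_abundance: np.ndarray, spec: FixtureSpec) -> np.ndarray:
    if not spec.abundance_dependent_missingness:
        return np.ones_like(log_abundance)
    from scipy.special import expit

    return expit(spec.detection_slope * (log_abundance - spec.detection_midpoint))


def _sample_group(
    spec: FixtureSpec,
    group: str,
    n_reps: int,
    base: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    log_x = base[:, None] + rng.normal(0.0, spec.replicate_sd, size=(spec.n_ids, n_reps))
    raw = 10.0 ** log_x
    if spec.outlier is not None and spec.outlier[0] == group:
        _, rep_idx, scale = spec.outlier
        raw[:, rep_idx] *= scale
    with np.errstate(divide="ignore"):
        log_raw = np.where(raw > 0, np.log10(np.maximum(raw, 1e-300)), -np.inf)
    detect_p = _detection_probability(log_raw, spec)
    extra = np.broadcast_to(np.asarray(spec.missingness, dtype=float), (spec.n_ids,))
    detect_p = detect_p * (1.0 - extra[:, None])
    observed = rng.random(size=raw.shape) < detect_p
    return np.where(observed, raw, 0.0)


def generate(spec: FixtureSpec) -> tuple[AbundanceMatrix, AbundanceMatrix, dict]:
    """Draw one two-group dataset; returns (matrix_A, matrix_B, truth).

    Infeasible draws (an id unobserved in both groups) are regenerated with a
    warning up to 10 times, then raise.
    """
    rng = np.random.default_rng(spec.seed)
    base = spec.resolved_base()
    effect_ids = spec.resolved_effect_ids()
    base_b = base.copy()
    if effect_ids:
        base_b[list(effect_ids)] += np.log10(spec.effect)
    n_a, n_b = spec.n_replicates
    ids = _panel_ids(spec.n_ids)
    for attempt in range(10):
        vals_a = _sample_group(spec, "A", n_a, base, rng)
        vals_b = _sample_group(spec, "B", n_b, base_b, rng)
        seen = (vals_a > 0).any(axis=1) | (vals_b > 0).any(axis=1)
        # ids fully suppressed by the injected effect are allowed to vanish
        # from group B; feasibility only requires each id somewhere overall
        # unless the effect itself removed it
        missing = np.flatnonzero(~seen)
        if all(i in effect_ids for i in missing):
            break
        import warnings

        warnings.warn(
            f"fixture draw {attempt} left ids unobserved in both groups; regenerating",
            stacklevel=2,
        )
    else:
        raise RuntimeError("could not draw a feasible fixture in 10 attempts")
    mk = lambda name, reps, vals: AbundanceMatrix(
        group_name=name,
        ids=list(ids),
        replicates=[f"{name}_r{j + 1}" for j in range(reps)],
        values=vals,
    )
    truth = {
        "effect_ids": list(effect_ids),
        "effect_labels": [ids[i].canonical for i in effect_ids],
        "effect": spec.effect,
        "outlier": None if spec.outlier is None else {
            "group": spec.outlier[0],
            "replicate": f"{spec.outlier[0]}_r{spec.outlier[1] + 1}",
            "scale": spec.outlier[2],
        },
        "seed": spec.seed,
    }
    return mk("A", n_a, vals_a), mk("B", n_b, vals_b), truth


def null_spec(seed: int, **overrides) -> FixtureSpec:
    """Both groups exchangeable draws from one generator (no effect)."""
    return FixtureSpec(seed=seed, **overrides)


def effect_spec(
    seed: int,
    n_effect_ids: int = 3,
    fold: float = 10.0,
    **overrides,
) -> FixtureSpec:
    """``n_effect_ids`` glycoforms suppressed ``fold``-fold in group B."""
    return FixtureSpec(seed=seed, n_effect_ids=n_effect_ids, effect=1.0 / fold, **overrides)


def outlier_spec(
    seed: int,
    group: str = "A",
    replicate_index: int = 0,
    scale: float = 0.1,
    n_replicates: tuple[int, int] = (5, 5),
    **overrides,
) -> FixtureSpec:
    """A null dataset with one globally rescaled (outlier) replicate."""
    return FixtureSpec(
        seed=seed,
        n_replicates=n_replicates,
        outlier=(group, replicate_index, scale),
        **overrides,
    )


def write_fixture_csvs(spec: FixtureSpec, directory) -> tuple[str, str, str]:
    """Write the two matrices and the truth record under ``directory``."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    a, b, truth = generate(spec)
    pa, pb, pt = directory / "group_a.csv", directory / "group_b.csv", directory / "truth.json"
    a.to_csv(pa)
    b.to_csv(pb)
    pt.write_text(json.dumps(truth, indent=2))
    return str(pa), str(pb), str(pt)
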