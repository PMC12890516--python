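"""Synthetic data generators with the statistical structure the analysis
assumes.

Three generators cover the package's inputs end to end:

* :func:`gen_decay_trace` / :func:`gen_cohort` - normalized Mant-ATP chase
  decays on the standard acquisition grid (a frame every 5 s for the first
  90 s, then every 10 s out to 300 s; 40 frames) with i.i.d. Gaussian noise,
  organized as subjects within groups with between- and within-subject
  parameter spread;
* :func:`gen_abundance_matrix` - log2 protein abundance matrices for a
  4-group genotype x treatment design with designated effect proteins, a
  configurable fraction of effects attenuated under treatment (restoration
  ground truth), and abundance-dependent (MNAR) missingness via a logistic
  left-censoring model;
* :func:`gen_annotation` - random term-to-protein annotations with one
  deliberately enriched term for enrichment-test calibration.

Every generator is deterministic given its spec and seed, and each returns
the ground truth alongside the data so recovery can be asserted exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import InvalidInputError
from .proteome import AbundanceMatrix
from .relax import DecayTrace, decay_model

_PARAM_NAMES = ("p1", "p2", "t1", "t2")


def paper_acquisition_grid() -> np.ndarray:
    """The standard 40-frame acquisition grid in seconds: every 5 s over
    0-90 s, then every 10 s over 100-300 s."""
    return np.concatenate(
        [np.arange(0.0, 91.0, 5.0), np.arange(100.0, 301.0, 10.0)]
    )


# ---------------------------------------------------------------------------
# Decay traces and cohorts
# ---------------------------------------------------------------------------

def gen_decay_trace(
    p1: float,
    p2: float,
    t1: float,
    t2: float,
    grid: np.ndarray | None = None,
    noise_sd: float = 0.01,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    fiber_id: str = "fiber",
    subject_id: str = "",
    group: str = "",
    treatment: str = "",
) -> DecayTrace:
    """Simulate one normalized decay trace (model + Gaussian noise).

    Amplitudes in percent, time constants in seconds.  The value at t=0 is
    forced to exactly 1, matching the normalization convention.
    """
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be non-negative")
    if t1 <= 0 or t2 <= 0 or p1 < 0 or p2 < 0:
        raise InvalidInputError("invalid decay parameters")
    grid = paper_acquisition_grid() if grid is None else np.asarray(grid, float)
    if grid[0] != 0 or np.any(np.diff(grid) <= 0):
        raise InvalidInputError("grid must start at 0 and strictly increase")
    if rng is None:
        rng = np.random.default_rng(seed)
    y = decay_model(grid, p1, p2, t1, t2)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=grid.size)
    y[0] = 1.0
    return DecayTrace(
        fiber_id=fiber_id,
        times=grid,
        intensities=y,
        background=0.0,
        subject_id=subject_id,
        group=group,
        treatment=treatment,
        state="normalized",
    )


@dataclass(frozen=True)
class GroupParams:
    """Group-level decay parameter means (p1/p2 percent, t1/t2 seconds)."""

    p1: float
    p2: float
    t1: float
    t2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p1, self.p2, self.t1, self.t2], float)


#: Default cohort conditions: a slow-twitch control cohort against a disease
#: cohort with more heads in the fast (DRX) phase and faster turnover.
DEFAULT_GROUP_MEANS: dict[str, GroupParams] = {
    "control": GroupParams(p1=20.0, p2=45.0, t1=25.0, t2=230.0),
    "disease": GroupParams(p1=28.0, p2=37.0, t1=20.0, t2=190.0),
}


@dataclass
class CohortSpec:
    """Hierarchical cohort design: subjects within groups, fibers within
    subjects.

    Subject-level parameter means are drawn around each group mean with
    ``between_subject_sd``; fiber-level parameters around the subject mean
    with ``within_subject_sd`` (both on the same units as the parameters).
    ``noise_sd`` is the Gaussian noise on the normalized fluorescence.
    """

    group_means: Mapping[str, GroupParams] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_MEANS)
    )
    n_subjects: int = 7
    fibers_per_subject: int = 10
    between_subject_sd: GroupParams = GroupParams(2.0, 2.0, 2.0, 15.0)
    within_subject_sd: GroupParams = GroupParams(3.0, 3.0, 2.0, 15.0)
    noise_sd: float = 0.01
    grid: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.fibers_per_subject < 1:
            raise InvalidInputError("subject and fiber counts must be positive")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be non-negative")
        for sd in (self.between_subject_sd, self.within_subject_sd):
            if np.any(sd.as_array() < 0):
                raise InvalidInputError("parameter sds must be non-negative")
        for name, gp in self.group_means.items():
            if gp.p1 + gp.p2 > 100:
                raise InvalidInputError(
                    f"group {name!r}: mean P1 + P2 exceeds 100%"
                )


def _clip_params(raw: np.ndarray) -> np.ndarray:
    """Project sampled parameters back into the physical region."""
    p1, p2, t1, t2 = raw
    p1, p2 = max(p1, 0.0), max(p2, 0.0)
    total = p1 + p2
    if total > 98.0:  # leave a plateau; amplitudes cannot exceed the signal
        p1, p2 = p1 * 98.0 / total, p2 * 98.0 / total
    t1 = max(t1, 2.0)
    t2 = max(t2, t1 * 2.0)
    return np.array([p1, p2, t1, t2])


def gen_cohort(spec: CohortSpec) -> tuple[list[DecayTrace], pd.DataFrame]:
    """Generate a hierarchical cohort of decay traces plus its ground truth.

    Returns (traces, truth) where ``truth`` has one row per fiber with the
    generating parameters (columns true_p1..true_t2) and labels.
    """
    rng = np.random.default_rng(spec.seed)
    traces: list[DecayTrace] = []
    rows = []
    for group in spec.group_means:
        mean = spec.group_means[group].as_array()
        for si in range(spec.n_subjects):
            subject_id = f"{group}_s{si + 1:02d}"
            subj_mean = rng.normal(mean, spec.between_subject_sd.as_array())
            for fi in range(spec.fibers_per_subject):
                fiber_id = f"{subject_id}_f{fi + 1:02d}"
                params = _clip_params(
                    rng.normal(subj_mean, spec.within_subject_sd.as_array())
                )
                trace = gen_decay_trace(
                    *params,
                    grid=spec.grid,
                    noise_sd=spec.noise_sd,
                    rng=rng,
                    fiber_id=fiber_id,
                    subject_id=subject_id,
                    group=group,
                )
                traces.append(trace)
                rows.append(
                    {
                        "fiber_id": fiber_id,
                        "subject_id": subject_id,
                        "group": group,
                        **{f"true_{n}": v for n, v in zip(_PARAM_NAMES, params)},
                    }
                )
    return traces, pd.DataFrame(rows)


def traces_to_frame(traces: Sequence[DecayTrace]) -> pd.DataFrame:
    """Long-format table of traces in the dialect :func:`~myofiber.relax.read_traces` reads."""
    frames = []
    for tr in traces:
        bg = (
            tr.background
            if not np.isscalar(tr.background)
            else np.full(tr.n_points, float(tr.background))
        )
        frames.append(
            pd.DataFrame(
                {
                    "fiber_id": tr.fiber_id,
                    "subject_id": tr.subject_id,
                    "group": tr.group,
                    "treatment": tr.treatment,
                    "time_s": tr.times,
                    "intensity": tr.intensities,
                    "background": bg,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Abundance matrices
# ---------------------------------------------------------------------------

@dataclass
class MatrixSpec:
    """Design of a synthetic log2 abundance matrix.

    The default emulates a 4-group genotype x treatment layout (wild-type /
    knockout, vehicle / drug, n=6 each).  ``n_effect`` proteins carry an
    additive ``effect_size`` log2 shift in the case (knockout) groups;
    ``restoration_fraction`` of them lose the effect in the treated case
    group (ground-truth "restored" proteins).  Missingness is MNAR: the
    probability of a dropout is ``expit(intercept - slope * x)`` in the true
    log2 abundance ``x``, i.e. low-abundance values censor more often.
    """

    n_proteins: int = 1000
    groups: Mapping[str, int] = field(
        default_factory=lambda: {
            "wt_vehicle": 6,
            "ko_vehicle": 6,
            "wt_treated": 6,
            "ko_treated": 6,
        }
    )
    case_groups: tuple[str, ...] = ("ko_vehicle", "ko_treated")
    treated_case_group: str | None = "ko_treated"
    baseline_mean: float = 25.0
    baseline_sd: float = 2.0
    within_sd: float = 0.3
    n_effect: int = 50
    effect_size: float = 2.0
    frac_up: float = 0.5
    restoration_fraction: float = 0.6
    mnar_slope: float = 1.0
    mnar_intercept: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_effect > self.n_proteins:
            raise InvalidInputError("n_effect exceeds n_proteins")
        if not 0 <= self.restoration_fraction <= 1:
            raise InvalidInputError("restoration_fraction must be in [0, 1]")
        if not 0 <= self.frac_up <= 1:
            raise InvalidInputError("frac_up must be in [0, 1]")
        if self.within_sd < 0 or self.baseline_sd < 0:
            raise InvalidInputError("sds must be non-negative")
        for g in self.case_groups:
            if g not in self.groups:
                raise InvalidInputError(f"case group {g!r} not in groups")
        if (
            self.treated_case_group is not None
            and self.treated_case_group not in self.groups
        ):
            raise InvalidInputError("treated_case_group not in groups")


def gen_abundance_matrix(
    spec: MatrixSpec,
) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Generate a log2 abundance matrix with MNAR missingness and truth labels.

    Returns (matrix, truth) where ``truth`` has one row per protein with
    ``is_effect``, ``direction`` (up/down in the case groups, '' otherwise)
    and ``is_restored`` (effect attenuated to zero in the treated case group).
    """
    rng = np.random.default_rng(spec.seed)
    protein_ids = [f"prot_{i:05d}" for i in range(spec.n_proteins)]
    sample_ids, group_labels = [], []
    for g, n in spec.groups.items():
        if n < 1:
            raise InvalidInputError(f"group {g!r} has non-positive n")
        for j in range(n):
            sample_ids.append(f"{g}_{j + 1:02d}")
            group_labels.append(g)
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, spec.n_proteins)

    effect_idx = rng.choice(spec.n_proteins, size=spec.n_effect, replace=False)
    effect_idx = np.sort(effect_idx)
    signs = np.where(
        rng.random(spec.n_effect) < spec.frac_up, 1.0, -1.0
    )
    n_restored = int(round(spec.restoration_fraction * spec.n_effect))
    restored_local = rng.choice(spec.n_effect, size=n_restored, replace=False)
    restored_mask_local = np.zeros(spec.n_effect, dtype=bool)
    restored_mask_local[restored_local] = True

    effect = np.zeros(spec.n_proteins)
    effect[effect_idx] = signs * spec.effect_size
    restored = np.zeros(spec.n_proteins, dtype=bool)
    restored[effect_idx] = restored_mask_local

    true_means = np.empty((spec.n_proteins, len(sample_ids)))
    for j, g in enumerate(group_labels):
        mean = baseline.copy()
        if g in spec.case_groups:
            eff = effect.copy()
            if g == spec.treated_case_group:
                eff[restored] = 0.0
            mean = mean + eff
        true_means[:, j] = mean
    values = true_means + rng.normal(
        0.0, spec.within_sd, size=true_means.shape
    )

    p_miss = expit(spec.mnar_intercept - spec.mnar_slope * values)
    if np.any(~np.isfinite(p_miss)):
        raise InvalidInputError("invalid missingness probabilities")
    mask = rng.random(values.shape) < p_miss
    data = np.where(mask, np.nan, values)

    matrix = AbundanceMatrix(
        values=pd.DataFrame(data, index=protein_ids, columns=sample_ids),
        groups=pd.Series(group_labels, index=sample_ids),
        scale="log2",
    )
    truth = pd.DataFrame(
        {
            "protein_id": protein_ids,
            "is_effect": effect != 0,
            "direction": np.where(
                effect > 0, "up", np.where(effect < 0, "down", "")
            ),
            "is_restored": restored,
        }
    ).set_index("protein_id")
    return matrix, truth


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def gen_annotation(
    background: Sequence[str],
    n_terms: int = 50,
    term_size_range: tuple[int, int] = (5, 50),
    enriched_hits: Sequence[str] | None = None,
    enriched_term_size: int = 20,
    enriched_hit_frac: float = 0.8,
    seed: int = 0,
) -> dict[str, frozenset]:
    """Random term annotations, optionally with one deliberately enriched term.

    Each of ``n_terms`` terms draws a uniform size from ``term_size_range``
    and samples members from the background without replacement.  When
    ``enriched_hits`` is given, an extra term ``term_enriched`` draws
    ``enriched_hit_frac`` of its members from the hit list.
    """
    background = list(background)
    if not background:
        raise InvalidInputError("background must be non-empty")
    lo, hi = term_size_range
    if lo < 1 or hi < lo or hi > len(background):
        raise InvalidInputError("invalid term size range for this background")
    rng = np.random.default_rng(seed)
    annotation: dict[str, frozenset] = {}
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(background), size=size, replace=False)
        annotation[f"term_{i:03d}"] = frozenset(background[j] for j in members)
    if enriched_hits is not None:
        hits = [h for h in enriched_hits if h in set(background)]
        if enriched_term_size > len(background):
            raise InvalidInputError("enriched term larger than background")
        n_from_hits = min(
            int(round(enriched_hit_frac * enriched_term_size)), len(hits)
        )
        chosen = list(
            rng.choice(hits, size=n_from_hits, replace=False)
        )
        rest_pool = [p for p in background if p not in set(chosen)]
        n_rest = enriched_term_size - n_from_hits
        chosen += list(rng.choice(rest_pool, size=n_rest, replace=False))
        annotation["term_enriched"] = frozenset(chosen)
    return annotation


def annotation_to_frame(annotation: Mapping[str, frozenset]) -> pd.DataFrame:
    """Two-column (term_id, protein_id) long format for an annotation map."""
    rows = [
        {"term_id": t, "protein_id": p}
        for t in sorted(annotation)
        for p in sorted(annotation[t])
    ]
    return pd.DataFrame(rows)


def read_annotation(path: str) -> dict[str, frozenset]:
    """Read a term annotation from two-column TSV/CSV or GMT format."""
    if str(path).endswith(".gmt"):
        annotation: dict[str, frozenset] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) >= 3:
                    annotation[parts[0]] = frozenset(p for p in parts[2:] if p)
        return annotation
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise InvalidInputError(f"annotation {path} needs term_id, protein_id")
    return {
        str(t): frozenset(sub.iloc[:, 1].astype(str))
        for t, sub in df.groupby(df.columns[0])
    }
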