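"""Myosin relaxed-state kinetics from Mant-ATP chase fluorescence decays.

In a Mant-ATP chase experiment a skinned myofiber is loaded with fluorescent
Mant-ATP which is then chased with unlabeled ATP; the fluorescence decay
reflects nucleotide turnover by myosin heads.  Two relaxed biochemical states
coexist: the disordered-relaxed state (DRX, heads "ON", fast ATP turnover) and
the super-relaxed state (SRX, heads folded "OFF", roughly ten-fold slower).
The normalized decay is modeled as a double exponential

    F(t) = 1 - P1*(1 - exp(-t/T1)) - P2*(1 - exp(-t/T2)),

where ``P1``/``P2`` are the DRX/SRX amplitudes (reported in percent) and
``T1``/``T2`` their turnover time constants in seconds, with ``T1 < T2`` by
convention (component 1 is always the fast phase).

This module provides trace preprocessing (background subtraction and T=0
normalization), the nonlinear least-squares fit of the two-state model, a
theoretical per-cell myosin ATP-consumption score built from the fitted
parameters assuming a 220 uM intrafiber myosin concentration, and the
relative-change transform used for paired pharmacology designs
(phosphatase / PKA vs. vehicle).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateTraceError,
    InvalidInputError,
    MissingBaselineError,
    NotFittedError,
)

logger = logging.getLogger(__name__)

#: Assumed concentration of myosin molecules within a myofiber, in uM.
MYOSIN_CONC_UM = 220.0

#: Seconds per minute; converts per-second turnover rates to per-minute.
SECONDS_PER_MINUTE = 60.0

#: Documented multistart grid for the time constants, in seconds.  The
#: amplitudes are profiled out exactly at every trial point (separable least
#: squares), so no amplitude starting values are needed.
DEFAULT_T1_STARTS: tuple[float, ...] = (10.0, 30.0, 60.0)
DEFAULT_T2_STARTS: tuple[float, ...] = (150.0, 250.0, 400.0)

#: Minimum number of time points accepted for a fit (must span both phases).
MIN_FIT_POINTS = 8

_TRACE_STATES = ("raw", "background_subtracted", "normalized")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class DecayTrace:
    """One fiber's fluorescence time series with cohort labels.

    ``times`` are seconds since washout (strictly increasing, starting at 0);
    ``intensities`` are arbitrary fluorescence units until normalized;
    ``background`` is a same-length series or a scalar.
    """

    fiber_id: str
    times: np.ndarray
    intensities: np.ndarray
    background: np.ndarray | float = 0.0
    subject_id: str = ""
    group: str = ""
    treatment: str = ""
    state: str = "raw"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.intensities.shape:
            raise InvalidInputError(
                f"fiber {self.fiber_id!r}: times and intensities must be "
                "1-D arrays of equal length"
            )
        if np.any(np.diff(self.times) <= 0):
            raise InvalidInputError(
                f"fiber {self.fiber_id!r}: times must be strictly increasing"
            )
        if not np.isscalar(self.background):
            self.background = np.asarray(self.background, dtype=float)
            if self.background.shape != self.times.shape:
                raise InvalidInputError(
                    f"fiber {self.fiber_id!r}: background series length "
                    "must match times"
                )
        if self.state not in _TRACE_STATES:
            raise InvalidInputError(f"unknown trace state {self.state!r}")
        if self.state == "normalized":
            if not np.all(np.isfinite(self.intensities)):
                raise InvalidInputError(
                    f"fiber {self.fiber_id!r}: normalized intensities must "
                    "be finite"
                )

    @property
    def n_points(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class RelaxFit:
    """Fitted two-state relaxed decay parameters for one fiber.

    Amplitudes are in percent; time constants in seconds; ``plateau`` is the
    non-decaying fraction ``1 - (P1 + P2)/100``.
    """

    p1: float
    p2: float
    t1: float
    t2: float
    rss: float
    converged: bool
    n_points: int

    @property
    def plateau(self) -> float:
        return 1.0 - (self.p1 + self.p2) / 100.0


@dataclass(frozen=True)
class AtpScore:
    """Theoretical myosin ATP consumption, in uM ATP per minute per cell."""

    value: float
    myosin_conc: float = MYOSIN_CONC_UM
    formula_variant: str = "corrected"


# ---------------------------------------------------------------------------
# Model and preprocessing
# ---------------------------------------------------------------------------

def decay_model(
    t: np.ndarray, p1: float, p2: float, t1: float, t2: float
) -> np.ndarray:
    """Normalized double-exponential decay; amplitudes ``p1``/``p2`` in percent."""
    t = np.asarray(t, dtype=float)
    return (
        1.0
        - p1 / 100.0 * (1.0 - np.exp(-t / t1))
        - p2 / 100.0 * (1.0 - np.exp(-t / t2))
    )


def preprocess_trace(raw: DecayTrace) -> DecayTrace:
    """Background-subtract and normalize a raw trace to its T=0 frame.

    The mean background is subtracted frame-wise, then every frame is divided
    by the background-subtracted intensity of the final pre-washout image
    (t = 0), so the normalized value at t = 0 is exactly 1.  No correction for
    the rapid washout of nonspecifically bound Mant-ATP is applied.
    """
    if raw.state != "raw":
        raise InvalidInputError(
            f"fiber {raw.fiber_id!r}: preprocess expects a raw trace, "
            f"got state {raw.state!r}"
        )
    if raw.times[0] != 0.0:
        raise InvalidInputError(
            f"fiber {raw.fiber_id!r}: trace must start at t=0 (washout)"
        )
    corrected = raw.intensities - raw.background
    denom = corrected[0]
    if not np.isfinite(denom) or denom <= 0:
        raise DegenerateTraceError(
            f"fiber {raw.fiber_id!r}: non-positive intensity at the "
            f"normalization frame ({denom!r})"
        )
    normalized = corrected / denom
    normalized[0] = 1.0
    return replace(raw, intensities=normalized, background=0.0, state="normalized")


# ---------------------------------------------------------------------------
# Fitting
#
# The amplitudes enter the model linearly, so for fixed time constants the
# best non-negative (P1, P2) solve in closed form (separable least squares).
# The remaining 2-parameter problem over (log T1, log T2) is minimized with a
# batched Levenberg-Marquardt iteration so that whole cohorts fit in a few
# vectorized passes; every trace is multistarted from the documented grid of
# time-constant pairs and the best residual sum of squares wins.
# ---------------------------------------------------------------------------

_LOG_TC_BOUNDS = (np.log(1e-2), np.log(1e7))
_TINY = 1e-300


def _nnls2_batch(basis: np.ndarray, depth: np.ndarray) -> np.ndarray:
    """Closed-form non-negative LS amplitudes for a batch of 2-column designs.

    ``basis``: (B, n, 2); ``depth``: (B, n).  Solves the 2x2 normal equations
    and falls back to the better single-component solution whenever the
    unconstrained optimum leaves the non-negative quadrant.
    """
    g11 = np.einsum("bn,bn->b", basis[..., 0], basis[..., 0])
    g12 = np.einsum("bn,bn->b", basis[..., 0], basis[..., 1])
    g22 = np.einsum("bn,bn->b", basis[..., 1], basis[..., 1])
    b1 = np.einsum("bn,bn->b", basis[..., 0], depth)
    b2 = np.einsum("bn,bn->b", basis[..., 1], depth)
    det = g11 * g22 - g12 * g12
    safe_det = np.where(det > _TINY, det, 1.0)
    a1 = (g22 * b1 - g12 * b2) / safe_det
    a2 = (g11 * b2 - g12 * b1) / safe_det
    bad = (det <= _TINY) | (a1 < 0) | (a2 < 0)
    if np.any(bad):
        c1 = np.where(g11 > _TINY, np.maximum(b1 / np.where(g11 > _TINY, g11, 1.0), 0.0), 0.0)
        c2 = np.where(g22 > _TINY, np.maximum(b2 / np.where(g22 > _TINY, g22, 1.0), 0.0), 0.0)
        # residual norms of the two single-component candidates
        rss1 = -2.0 * c1 * b1 + c1 * c1 * g11
        rss2 = -2.0 * c2 * b2 + c2 * c2 * g22
        use_first = rss1 <= rss2
        a1 = np.where(bad, np.where(use_first, c1, 0.0), a1)
        a2 = np.where(bad, np.where(use_first, 0.0, c2), a2)
    return np.stack([a1, a2], axis=-1)


def _profiled_residual(
    t: np.ndarray, depths: np.ndarray, log_tc: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Residuals, rss, and amplitudes with amplitudes profiled out.

    ``depths``: (B, n) decay depths (1 - normalized intensity);
    ``log_tc``: (B, 2) log time constants.
    """
    tc = np.exp(log_tc)
    basis = 1.0 - np.exp(-t[None, :, None] / tc[:, None, :])
    amps = _nnls2_batch(basis, depths)
    resid = np.einsum("bnk,bk->bn", basis, amps) - depths
    return resid, np.einsum("bn,bn->b", resid, resid), amps


def _lm_minimize(
    t: np.ndarray,
    depths: np.ndarray,
    log_tc0: np.ndarray,
    max_iter: int = 120,
    step_tol: float = 1e-11,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched Levenberg-Marquardt over (log T1, log T2).

    Returns (log_tc, rss, converged) for every problem in the batch.
    Numerical Jacobians; per-problem damping; bound-clipped steps.
    """
    lo, hi = _LOG_TC_BOUNDS
    theta = np.clip(log_tc0.astype(float).copy(), lo, hi)
    n_prob = theta.shape[0]
    if n_prob == 0:
        return theta, np.empty(0), np.empty(0, dtype=bool)
    resid, rss, _ = _profiled_residual(t, depths, theta)
    lam = np.full(n_prob, 1e-3)
    active = np.ones(n_prob, dtype=bool)
    h = 1e-6
    for _ in range(max_iter):
        if not active.any():
            break
        jac = np.empty((n_prob, depths.shape[1], 2))
        for j in range(2):
            shifted = theta.copy()
            shifted[:, j] += h
            resid_j, _, _ = _profiled_residual(t, depths, shifted)
            jac[:, :, j] = (resid_j - resid) / h
        grad = np.einsum("bnk,bn->bk", jac, resid)
        a11 = np.einsum("bn,bn->b", jac[:, :, 0], jac[:, :, 0])
        a12 = np.einsum("bn,bn->b", jac[:, :, 0], jac[:, :, 1])
        a22 = np.einsum("bn,bn->b", jac[:, :, 1], jac[:, :, 1])
        m11 = a11 + lam * np.maximum(a11, 1e-12)
        m22 = a22 + lam * np.maximum(a22, 1e-12)
        det = np.maximum(m11 * m22 - a12 * a12, _TINY)
        step1 = (m22 * grad[:, 0] - a12 * grad[:, 1]) / det
        step2 = (m11 * grad[:, 1] - a12 * grad[:, 0]) / det
        step = np.stack([step1, step2], axis=-1)
        trial = np.clip(theta - step, lo, hi)
        step_size = np.max(np.abs(trial - theta), axis=1)
        resid_t, rss_t, _ = _profiled_residual(t, depths, trial)
        improved = active & (rss_t < rss)
        theta[improved] = trial[improved]
        resid[improved] = resid_t[improved]
        rss[improved] = rss_t[improved]
        lam = np.where(improved, np.maximum(lam / 3.0, 1e-12), lam * 10.0)
        active &= ~(improved & (step_size < step_tol)) & (lam < 1e14)
    grad_norm = np.max(np.abs(grad), axis=1)
    converged = np.isfinite(rss) & (grad_norm <= 1e-6 * (1.0 + rss))
    return theta, rss, converged


def _fit_depth_batch(
    t: np.ndarray,
    depths: np.ndarray,
    t1_starts: Sequence[float],
    t2_starts: Sequence[float],
) -> list[RelaxFit]:
    """Multistart fit of a batch of traces sharing one time grid."""
    n_traces = depths.shape[0]
    starts = np.log(
        [[t1_0, t2_0] for t1_0 in t1_starts for t2_0 in t2_starts]
    )
    n_starts = starts.shape[0]
    theta0 = np.repeat(starts[None, :, :], n_traces, axis=0).reshape(-1, 2)
    depths_rep = np.repeat(depths, n_starts, axis=0)
    theta, rss, ok = _lm_minimize(t, depths_rep, theta0)
    theta = theta.reshape(n_traces, n_starts, 2)
    rss = rss.reshape(n_traces, n_starts)
    ok = ok.reshape(n_traces, n_starts)
    t_fast = np.exp(theta).min(axis=2)
    fits: list[RelaxFit] = []
    for i in range(n_traces):
        # best rss wins; ties go to the smaller fast time constant
        best_rss = rss[i].min()
        tol = 1e-9 * max(1.0, best_rss)
        near = rss[i] <= best_rss + tol
        best = np.flatnonzero(near)[np.argmin(t_fast[i, near])]
        resid, _, amps = _profiled_residual(
            t, depths[i : i + 1], theta[i, best][None, :]
        )
        tc = np.exp(theta[i, best])
        order = np.argsort(tc, kind="stable")  # fast phase first
        tc, a = tc[order], amps[0][order]
        fits.append(
            RelaxFit(
                p1=100.0 * float(a[0]),
                p2=100.0 * float(a[1]),
                t1=float(tc[0]),
                t2=float(tc[1]),
                rss=float(rss[i, best]),
                converged=bool(ok[i, best] and np.isfinite(rss[i, best])),
                n_points=t.size,
            )
        )
    return fits


def _check_fittable(trace: DecayTrace) -> None:
    if trace.state != "normalized":
        raise InvalidInputError(
            f"fiber {trace.fiber_id!r}: fit expects a normalized trace"
        )
    if trace.n_points < MIN_FIT_POINTS:
        raise InvalidInputError(
            f"fiber {trace.fiber_id!r}: need at least {MIN_FIT_POINTS} time "
            f"points, got {trace.n_points}"
        )


def fit_double_exponential(
    trace: DecayTrace,
    t1_starts: Sequence[float] = DEFAULT_T1_STARTS,
    t2_starts: Sequence[float] = DEFAULT_T2_STARTS,
) -> RelaxFit:
    """Fit the two-state relaxed decay model by nonlinear least squares.

    The amplitudes are profiled out exactly with a non-negative linear solve
    at every trial point, leaving a 2-parameter optimization over
    ``log(T1), log(T2)`` multistarted from the documented time-constant grid.
    The best residual sum of squares wins; ties go to the smaller fast time
    constant.  Components are relabeled after the fit so that ``T1 < T2``.
    Amplitudes are reported in percent.

    Non-convergence is reported via ``converged=False``, not an exception.
    Deterministic given the trace and start grids.
    """
    _check_fittable(trace)
    depth = (1.0 - trace.intensities)[None, :]
    return _fit_depth_batch(trace.times, depth, t1_starts, t2_starts)[0]


def fit_many(
    traces: Sequence[DecayTrace],
    t1_starts: Sequence[float] = DEFAULT_T1_STARTS,
    t2_starts: Sequence[float] = DEFAULT_T2_STARTS,
) -> list[RelaxFit]:
    """Fit many normalized traces, batching those that share a time grid.

    Equivalent to calling :func:`fit_double_exponential` per trace, but the
    Levenberg-Marquardt iterations run vectorized across traces.
    """
    for trace in traces:
        _check_fittable(trace)
    fits: list[RelaxFit | None] = [None] * len(traces)
    by_grid: dict[bytes, list[int]] = {}
    for i, trace in enumerate(traces):
        by_grid.setdefault(trace.times.tobytes(), []).append(i)
    for indices in by_grid.values():
        t = traces[indices[0]].times
        depths = np.stack([1.0 - traces[i].intensities for i in indices])
        for idx, fit in zip(
            indices, _fit_depth_batch(t, depths, t1_starts, t2_starts)
        ):
            fits[idx] = fit
    return fits  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Theoretical ATP consumption
# ---------------------------------------------------------------------------

def theoretical_atp_consumption(
    fit: RelaxFit,
    myosin_conc: float = MYOSIN_CONC_UM,
    variant: str = "corrected",
) -> AtpScore:
    """Score the theoretical myosin ATP consumption of one fiber.

    Each relaxed population contributes amplitude * concentration * turnover
    rate: ``P1/100 * C * 60/T1`` for DRX plus the SRX term.  The ``corrected``
    default divides the SRX term by its own time constant T2; ``verbatim``
    divides both terms by T1 (the formula as printed in the source protocol).
    Units: uM ATP per minute per cell.
    """
    if variant not in ("corrected", "verbatim"):
        raise InvalidInputError(f"unknown formula variant {variant!r}")
    if not fit.converged:
        raise NotFittedError("ATP score requires a converged fit")
    slow_tc = fit.t2 if variant == "corrected" else fit.t1
    drx = 0.0 if fit.p1 == 0 else fit.p1 / 100.0 * myosin_conc * SECONDS_PER_MINUTE / fit.t1
    srx = 0.0 if fit.p2 == 0 else fit.p2 / 100.0 * myosin_conc * SECONDS_PER_MINUTE / slow_tc
    return AtpScore(value=drx + srx, myosin_conc=myosin_conc, formula_variant=variant)


# ---------------------------------------------------------------------------
# Relative change (pharmacology designs)
# ---------------------------------------------------------------------------

def relative_change(
    fits: pd.DataFrame,
    baseline_label: str,
    value_cols: Sequence[str] = ("p1", "p2", "t1", "t2"),
    treatment_col: str = "treatment",
    stratum_col: str | None = None,
) -> pd.DataFrame:
    """Express per-fiber values as folds of the baseline-group mean.

    Within each stratum (e.g. genotype) the mean of every value column over
    the baseline (vehicle) rows is computed and every fiber's value is divided
    by it, so the baseline group mean maps to 1 by construction.
    """
    if treatment_col not in fits.columns:
        raise InvalidInputError(f"missing treatment column {treatment_col!r}")
    out = fits.copy()
    if stratum_col is None:
        strata = [(None, fits.index)]
    else:
        strata = [(k, idx) for k, idx in fits.groupby(stratum_col).groups.items()]
    for key, idx in strata:
        sub = fits.loc[idx]
        base = sub[sub[treatment_col] == baseline_label]
        if base.empty:
            raise MissingBaselineError(
                f"no {baseline_label!r} rows in stratum {key!r}"
            )
        means = base[list(value_cols)].mean()
        out.loc[idx, list(value_cols)] = sub[list(value_cols)] / means
    return out


# ---------------------------------------------------------------------------
# Table-level interface
# ---------------------------------------------------------------------------

_TRACE_COLUMNS = ("time_s", "intensity", "fiber_id")


def read_traces(path: str) -> list[DecayTrace]:
    """Read raw decay traces from a long-format TSV/CSV file.

    Required columns: ``time_s``, ``intensity``, ``fiber_id``; optional:
    ``background`` (default 0), ``subject_id``, ``group``, ``treatment``.
    One file may hold many fibers; rows are sorted by time within fiber.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"trace file {path}: missing columns {missing}")
    traces = []
    for fiber_id, sub in df.groupby("fiber_id", sort=True):
        sub = sub.sort_values("time_s")
        if sub["time_s"].duplicated().any():
            row = sub.index[sub["time_s"].duplicated()][0]
            raise InvalidInputError(
                f"trace file {path}: duplicated time for fiber {fiber_id!r} "
                f"(row {row})"
            )
        traces.append(
            DecayTrace(
                fiber_id=str(fiber_id),
                times=sub["time_s"].to_numpy(),
                intensities=sub["intensity"].to_numpy(),
                background=(
                    sub["background"].to_numpy()
                    if "background" in sub.columns
                    else 0.0
                ),
                subject_id=str(sub["subject_id"].iloc[0]) if "subject_id" in sub else "",
                group=str(sub["group"].iloc[0]) if "group" in sub else "",
                treatment=str(sub["treatment"].iloc[0]) if "treatment" in sub else "",
            )
        )
    return traces


def fit_traces(
    traces: Iterable[DecayTrace],
    myosin_conc: float = MYOSIN_CONC_UM,
    preprocess: bool = True,
) -> pd.DataFrame:
    """Preprocess and fit many traces; return the per-fiber fit table.

    Columns: fiber/subject/group/treatment labels, P1, P2 (percent), T1, T2
    (seconds), plateau, rss, converged, n_points, and the ATP score in both
    formula variants (NaN when the fit did not converge).
    """
    traces = list(traces)
    prepped = [
        preprocess_trace(tr) if preprocess and tr.state == "raw" else tr
        for tr in traces
    ]
    rows = []
    for trace, fit in zip(traces, fit_many(prepped)):
        if fit.converged:
            atp_c = theoretical_atp_consumption(fit, myosin_conc, "corrected").value
            atp_v = theoretical_atp_consumption(fit, myosin_conc, "verbatim").value
        else:
            logger.warning("fiber %s: fit did not converge", trace.fiber_id)
            atp_c = atp_v = np.nan
        rows.append(
            {
                "fiber_id": trace.fiber_id,
                "subject_id": trace.subject_id,
                "group": trace.group,
                "treatment": trace.treatment,
                "p1": fit.p1,
                "p2": fit.p2,
                "t1": fit.t1,
                "t2": fit.t2,
                "plateau": fit.plateau,
                "rss": fit.rss,
                "converged": fit.converged,
                "n_points": fit.n_points,
                "atp_corrected": atp_c,
                "atp_verbatim": atp_v,
            }
        )
    return pd.DataFrame(rows)
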