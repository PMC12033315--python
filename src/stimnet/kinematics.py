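"""Spiral-drawing kinematics: tangential velocity, its sample entropy, and
per-stimulation-level summaries.

The tangential velocity is the instantaneous radius around the spiral center
multiplied by the rate of change of the (unwrapped) angular displacement.
Sample entropy (template length m, tolerance r) quantifies the irregularity
of the resulting velocity series; the defaults m=2, r = 20% of the series SD
are the standard choice for movement time series.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .containers import SpiralTrace

logger = logging.getLogger(__name__)

try:  # pairwise template counting is the package's hot loop
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _njit = None


def _sampen_counts_numpy(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    nt = x.size - m
    cheb = np.abs(x[:nt, None] - x[None, :nt])
    for k in range(1, m):
        np.maximum(cheb, np.abs(x[k:k + nt, None] - x[None, k:k + nt]),
                   out=cheb)
    match_m = cheb <= r
    np.maximum(cheb, np.abs(x[m:m + nt, None] - x[None, m:m + nt]), out=cheb)
    match_m1 = cheb <= r
    # Full symmetric matrices: subtract the diagonal, halve.
    b = int((match_m.sum() - nt) // 2)
    a = int((match_m1.sum() - nt) // 2)
    return a, b


if _njit is not None:
    @_njit(cache=False)
    def _sampen_counts(x, m, r):  # pragma: no cover - exercised via wrapper
        nt = x.size - m
        a = 0
        b = 0
        for i in range(nt):
            for j in range(i + 1, nt):
                within = True
                for k in range(m):
                    if abs(x[i + k] - x[j + k]) > r:
                        within = False
                        break
                if within:
                    b += 1
                    if abs(x[i + m] - x[j + m]) <= r:
                        a += 1
        return a, b
else:  # pragma: no cover
    _sampen_counts = _sampen_counts_numpy

__all__ = [
    "KinematicSummary",
    "SlopeResult",
    "tangential_velocity",
    "position_derivatives",
    "sample_entropy",
    "summarize_level",
    "slope_across_levels",
]


@dataclass(frozen=True)
class KinematicSummary:
    """Per-condition kinematic parameters, averaged over repeated spirals."""

    mean_tangential_velocity: float  # cm/s
    peak_tangential_velocity: float  # cm/s
    velocity_sample_entropy: float  # dimensionless; NaN when undefined
    n_spirals_averaged: int

    def __post_init__(self) -> None:
        if self.peak_tangential_velocity < self.mean_tangential_velocity - 1e-9:
            raise ValueError("peak velocity cannot be below the mean")


@dataclass(frozen=True)
class SlopeResult:
    """OLS slope of a parameter against ordinal stimulation level 0..3."""

    slope: float
    intercept: float
    levels: tuple[int, ...]


def tangential_velocity(trace: SpiralTrace,
                        center: tuple[float, float] | None = None) -> np.ndarray:
    """Tangential velocity series v_t = r * |d(theta)/dt| in cm/s.

    The spiral center defaults to the first recorded sample (the instructed
    starting point). The angle is unwrapped through cumulative signed
    increments so traces spanning many turns are handled; the absolute value
    of the angular rate normalizes clockwise and counterclockwise drawings to
    non-negative velocity. Derivatives are second-order central differences
    on the (possibly non-uniform) time grid.
    """
    if center is None:
        center = (float(trace.x[0]), float(trace.y[0]))
    dx = trace.x - center[0]
    dy = trace.y - center[1]
    r = np.hypot(dx, dy)
    if np.all(r < 1e-12):
        raise ValueError("degenerate radius: all samples at the center point")
    raw_angle = np.arctan2(dy, dx)
    # Cumulative signed increments wrapped into (-pi, pi].
    inc = np.diff(raw_angle)
    inc = (inc + np.pi) % (2 * np.pi) - np.pi
    theta = np.concatenate(([raw_angle[0]], raw_angle[0] + np.cumsum(inc)))
    dtheta = np.gradient(theta, trace.t, edge_order=2)
    return r * np.abs(dtheta)


def position_derivatives(trace: SpiralTrace) -> dict[str, np.ndarray]:
    """First, second, and third time derivatives of x and y.

    Central differences on the interior, second-order one-sided at the
    boundaries (exact for quadratics); units cm/s, cm/s^2, cm/s^3. Uses the
    per-interval dt, so mildly non-uniform timestamps are handled without
    error (logged at debug level).
    """
    if trace.n_samples < 4:
        raise ValueError("need at least 4 samples for third derivatives")
    dts = np.diff(trace.t)
    if dts.max() / dts.min() > 1.01:
        logger.debug("non-uniform sampling (dt range %.3g..%.3g s); "
                     "using per-interval dt", dts.min(), dts.max())
    out: dict[str, np.ndarray] = {}
    for name, series in (("x", trace.x), ("y", trace.y)):
        d1 = np.gradient(series, trace.t, edge_order=2)
        d2 = np.gradient(d1, trace.t, edge_order=2)
        d3 = np.gradient(d2, trace.t, edge_order=2)
        out[f"d{name}"] = d1
        out[f"dd{name}"] = d2
        out[f"ddd{name}"] = d3
    return out


def sample_entropy(series: np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    """Sample entropy SampEn(m, r) of a 1-D series.

    SampEn = -ln(A / B) where B counts pairs of length-m templates within
    Chebyshev distance r = ``r_frac`` * SD(series) of each other, and A the
    same for length-(m+1) templates; self-matches are excluded and both
    counts run over the N - m template start points. Returns NaN (flagged
    undefined) when the SD is zero-with-tolerance-zero or when either count
    is zero, rather than an infinite value.

    Since r scales with the SD, the measure is invariant under affine
    transforms of the series.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    n = x.size
    if n <= m + 1:
        raise ValueError(f"series length {n} too short for m={m}")
    sd = x.std()
    r = r_frac * sd
    if sd == 0:
        # A constant series: every template matches every other exactly.
        return 0.0

    a, b = _sampen_counts(np.ascontiguousarray(x), m, r)
    if a == 0 or b == 0:
        warnings.warn("sample entropy undefined (no template matches); "
                      "returning NaN", stacklevel=2)
        return float("nan")
    return float(-np.log(a / b))


def summarize_level(traces: list[SpiralTrace], m: int = 2,
                    r_frac: float = 0.2) -> KinematicSummary:
    """Average the per-spiral kinematic parameters of one subject/task/level.

    Undefined sample entropies are excluded from the average with a warning;
    if every spiral's entropy is undefined the summary entropy is NaN.
    """
    if not traces:
        raise ValueError("cannot summarize an empty set of traces")
    key = (traces[0].subject, traces[0].task, traces[0].level)
    for tr in traces[1:]:
        if (tr.subject, tr.task, tr.level) != key:
            raise ValueError("traces mix subjects, tasks, or levels")
    means, peaks, ents = [], [], []
    for tr in traces:
        v = tangential_velocity(tr)
        means.append(v.mean())
        peaks.append(v.max())
        ents.append(sample_entropy(v, m=m, r_frac=r_frac))
    ents_arr = np.asarray(ents)
    n_def = int(np.sum(np.isfinite(ents_arr)))
    if n_def < len(ents):
        warnings.warn(f"{len(ents) - n_def} of {len(ents)} spirals had "
                      "undefined sample entropy; excluded from the average",
                      stacklevel=2)
    entropy = float(np.nanmean(ents_arr)) if n_def else float("nan")
    return KinematicSummary(
        mean_tangential_velocity=float(np.mean(means)),
        peak_tangential_velocity=float(np.mean(peaks)),
        velocity_sample_entropy=entropy,
        n_spirals_averaged=len(traces),
    )


def slope_across_levels(values: dict[int, float]) -> SlopeResult:
    """OLS slope of a parameter against the ordinal level index 0..3.

    Missing or NaN levels are dropped; at least two levels are required.
    """
    levels = sorted(lv for lv, v in values.items() if np.isfinite(v))
    if len(levels) < 2:
        raise ValueError("need values at >= 2 stimulation levels for a slope")
    x = np.asarray(levels, dtype=float)
    y = np.asarray([values[lv] for lv in levels])
    slope, intercept = np.polyfit(x, y, 1)
    return SlopeResult(slope=float(slope), intercept=float(intercept),
                       levels=tuple(levels))
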