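"""Piecewise (multiphasic) power-law release model with phase breakpoints.

Controlled-release curves from degradable polymer matrices are rarely
monophasic: a burst of surface-accessible drug (phase I) and a slow
diffusion period (phase II) are followed by a degradation-driven second
burst (phase III) and sometimes a terminal slow tail (phase IV). The
multiphasic model describes the cumulative release fraction with a separate
power law ``Q = kᵢ·t^nᵢ`` on each consecutive time interval:

    Q(t) = k₁·t^n₁  for 0 < t ≤ t₁   (phases I & II, modeled jointly)
           k₂·t^n₂  for t₁ < t ≤ t₂  (phase III)
           k₃·t^n₃  for t₂ < t ≤ t₃  (phase IV)

Each segment is fit independently on absolute time (no continuity
constraint), and each exponent is interpreted with the same cylinder
thresholds as the monophasic power law, so the per-phase exponents
separate diffusion-dominated from degradation-dominated periods.
Breakpoints may be user-supplied or found by exhaustive search over the
observed time points, scored by total piecewise SSE.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import DataError, DomainError, ParameterError, PartitionError
from .fitting import FitOptions
from .models import MechanismClass, ReleaseProfile, classify_mechanism

__all__ = [
    "PhaseSegment",
    "MultiphasicFit",
    "PHASE_LABELS",
    "eval_multiphasic",
    "fit_multiphasic",
    "detect_breakpoints",
    "phase_report",
]

#: Phase labels by segment count; phases I and II are never split.
PHASE_LABELS = {1: ("I_II",), 2: ("I_II", "III"), 3: ("I_II", "III", "IV")}


@dataclass
class PhaseSegment:
    """One fitted power-law segment ``Q = k·tⁿ`` on ``(t_start, t_end]``."""

    phase_label: str
    k: float
    n: float
    t_start: float  # days, exclusive
    t_end: float  # days, inclusive
    q_end: float  # observed cumulative fraction at the last observation <= t_end
    r_squared: float
    sse: float = 0.0
    n_obs: int = 0

    @property
    def mechanism(self) -> MechanismClass:
        return classify_mechanism(self.n)


@dataclass
class MultiphasicFit:
    """Ordered phase segments tiling ``(0, t_last]`` without overlap."""

    segments: list[PhaseSegment]
    breakpoints: list[float]  # interior phase boundaries, strictly increasing
    overall_sse: float
    breakpoint_mode: Literal["user_supplied", "auto"] = "user_supplied"

    def __post_init__(self) -> None:
        if not self.segments:
            raise DataError("a multiphasic fit needs at least one segment")
        for prev, cur in zip(self.segments, self.segments[1:]):
            if not np.isclose(prev.t_end, cur.t_start):
                raise DataError("segments must tile the time axis without gaps")
        if any(b2 <= b1 for b1, b2 in zip(self.breakpoints, self.breakpoints[1:])):
            raise DataError("breakpoints must be strictly increasing")

    @property
    def t_last(self) -> float:
        return self.segments[-1].t_end


# ---------------------------------------------------------------------------
# evaluation


def _eval_segments(
    segments: Sequence[tuple[float, float, float]],
    times: np.ndarray,
    extrapolate: bool,
) -> np.ndarray:
    """Evaluate piecewise ``k·tⁿ`` given (k, n, t_end) triples; t = 0 → 0."""
    t_ends = np.asarray([s[2] for s in segments], dtype=float)
    if np.any(np.diff(t_ends) <= 0):
        raise DataError("segment end times must be strictly increasing")
    if np.any(times < 0):
        raise DomainError("release times must be >= 0")
    if not extrapolate and np.any(times > t_ends[-1] * (1 + 1e-12)):
        raise DomainError(
            f"time beyond the last segment end ({t_ends[-1]} days); "
            "pass extrapolate=True to evaluate with the final segment"
        )
    out = np.zeros_like(times, dtype=float)
    # searchsorted with side='left' maps t in (t_end[i-1], t_end[i]] to i.
    idx = np.searchsorted(t_ends, times, side="left")
    idx = np.minimum(idx, len(segments) - 1)
    positive = times > 0
    for i, (k, n, _) in enumerate(segments):
        mask = positive & (idx == i)
        if mask.any():
            out[mask] = k * np.power(times[mask], n)
    return out


def eval_multiphasic(
    fit: MultiphasicFit,
    times: Sequence[float],
    extrapolate: bool = False,
) -> np.ndarray:
    """Evaluate a fitted multiphasic model; each t uses the segment whose
    half-open interval ``(t_start, t_end]`` contains it, and ``Q(0) = 0``."""
    t = np.asarray(times, dtype=float)
    triples = [(s.k, s.n, s.t_end) for s in fit.segments]
    return _eval_segments(triples, t, extrapolate)


# ---------------------------------------------------------------------------
# per-segment power-law fit


def _fit_power_segment(
    t: np.ndarray, q: np.ndarray, options: FitOptions
) -> tuple[float, float, float, float]:
    """Least squares of ``q = k·tⁿ`` on one segment.

    Returns (k, n, sse, r_squared); r_squared is NaN when the segment has no
    variance. Initialization is the log–log regression, refined on the
    untransformed fractions.
    """
    mask = q > 0
    if mask.sum() >= 2:
        slope, intercept = np.polyfit(np.log(t[mask]), np.log(q[mask]), 1)
        x0 = np.array([np.exp(intercept), slope])
    else:
        x0 = np.array([max(float(q.max()), 1e-9), 0.5])

    def residuals(p):
        with np.errstate(over="ignore", invalid="ignore"):
            r = p[0] * np.power(t, p[1]) - q
        return np.where(np.isfinite(r), r, 1e6)

    sol = least_squares(
        residuals,
        x0,
        xtol=options.convergence_tolerance,
        ftol=options.convergence_tolerance,
        gtol=options.convergence_tolerance,
        max_nfev=400,
    )
    k, n = float(sol.x[0]), float(sol.x[1])
    sse = float(2.0 * sol.cost)
    sst = float(np.sum((q - q.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    return k, n, sse, r2


def _partition_indices(
    t: np.ndarray, breakpoints: Sequence[float]
) -> list[np.ndarray]:
    """Index masks for segments (0, b1], (b1, b2], ..., (b_last, t_max]."""
    edges = [0.0, *breakpoints, np.inf]
    masks = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        masks.append((t > lo) & (t <= hi))
    return masks


# ---------------------------------------------------------------------------
# fitting and breakpoint search


def fit_multiphasic(
    profile: ReleaseProfile,
    breakpoints: Union[Sequence[float], Literal["auto"]] = "auto",
    n_phases: int = 2,
    options: Optional[FitOptions] = None,
    min_points: int = 3,
) -> MultiphasicFit:
    """Fit the piecewise power-law model with given or automatic breakpoints.

    Each segment is fit independently on absolute time; per-segment R² is
    computed within the segment, and ``q_end`` is the observed cumulative
    fraction at the last observation of the segment (not the fitted value).
    """
    if n_phases not in PHASE_LABELS:
        raise ParameterError(f"n_phases must be one of {sorted(PHASE_LABELS)}")
    options = options or FitOptions()
    t, q = profile.times, profile.q
    used = t > 0
    if used.sum() < n_phases * min_points:
        raise DataError(
            f"need at least {n_phases * min_points} observations with t > 0 "
            f"for {n_phases} phases, got {int(used.sum())}"
        )

    if isinstance(breakpoints, str):
        if breakpoints != "auto":
            raise ParameterError("breakpoints must be a list of days or 'auto'")
        bps = detect_breakpoints(profile, n_phases, min_points, options)
        mode = "auto"
    else:
        bps = [float(b) for b in breakpoints]
        if len(bps) != n_phases - 1:
            raise ParameterError(
                f"{n_phases} phases need {n_phases - 1} breakpoints, got {len(bps)}"
            )
        if any(b2 <= b1 for b1, b2 in zip(bps, bps[1:])):
            raise ParameterError("breakpoints must be strictly increasing")
        t_pos = t[used]
        if bps and not (t_pos.min() < bps[0] and bps[-1] < t_pos.max()):
            raise ParameterError(
                "breakpoints must lie strictly inside the observed time range"
            )
        mode = "user_supplied"

    labels = PHASE_LABELS[n_phases]
    masks = _partition_indices(t, bps)
    segments: list[PhaseSegment] = []
    total_sse = 0.0
    t_edges = [0.0, *bps, float(t.max())]
    for i, (label, mask) in enumerate(zip(labels, masks)):
        if mask.sum() < min_points:
            raise PartitionError(
                f"segment {label} ({t_edges[i]}, {t_edges[i + 1]}] contains "
                f"{int(mask.sum())} observations; at least {min_points} required"
            )
        k, n, sse, r2 = _fit_power_segment(t[mask], q[mask], options)
        total_sse += sse
        segments.append(
            PhaseSegment(
                phase_label=label,
                k=k,
                n=n,
                t_start=t_edges[i],
                t_end=t_edges[i + 1],
                q_end=float(q[mask][-1]),
                r_squared=r2,
                sse=sse,
                n_obs=int(mask.sum()),
            )
        )
    return MultiphasicFit(
        segments=segments,
        breakpoints=bps,
        overall_sse=total_sse,
        breakpoint_mode=mode,
    )


def detect_breakpoints(
    profile: ReleaseProfile,
    n_phases: int = 2,
    min_points: int = 3,
    options: Optional[FitOptions] = None,
) -> list[float]:
    """Exhaustive breakpoint search over the observed time points.

    Every combination of ``n_phases − 1`` observed times that leaves at least
    ``min_points`` observations in each segment is scored by the total
    piecewise power-law SSE; the argmin is returned, with ties broken toward
    earlier breakpoints.
    """
    if n_phases not in PHASE_LABELS:
        raise ParameterError(f"n_phases must be one of {sorted(PHASE_LABELS)}")
    if n_phases == 1:
        return []
    options = options or FitOptions()
    t, q = profile.times, profile.q
    pos = t > 0
    t_pos, q_pos = t[pos], q[pos]
    n = len(t_pos)
    if n < n_phases * min_points:
        raise PartitionError(
            f"need at least {n_phases * min_points} observations with t > 0, got {n}"
        )
    # Candidate breakpoints are observed times; a breakpoint at index i puts
    # observations [.. i] in the left segment (interval inclusive of t[i]).
    candidate_idx = range(min_points - 1, n - min_points)
    best_sse = np.inf
    best: Optional[tuple[int, ...]] = None
    for combo in itertools.combinations(candidate_idx, n_phases - 1):
        sizes = np.diff([-1, *combo, n - 1])
        if np.any(sizes < min_points):
            continue
        sse = 0.0
        lo = 0
        for idx in [*combo, n - 1]:
            seg_t, seg_q = t_pos[lo : idx + 1], q_pos[lo : idx + 1]
            _, _, seg_sse, _ = _fit_power_segment(seg_t, seg_q, options)
            sse += seg_sse
            lo = idx + 1
            if sse >= best_sse:
                break
        if sse < best_sse:
            best_sse = sse
            best = combo
    if best is None:
        raise PartitionError(
            "no admissible breakpoint placement satisfies the minimum "
            "points-per-segment constraint"
        )
    return [float(t_pos[i]) for i in best]


def phase_report(fit: MultiphasicFit) -> pd.DataFrame:
    """Per-phase summary table: k, n, R², phase end time and observed q_end."""
    return pd.DataFrame.from_records(
        [
            {
                "phase": s.phase_label,
                "k": s.k,
                "n": s.n,
                "r_squared": s.r_squared,
                "t_end_days": s.t_end,
                "q_end": s.q_end,
                "mechanism": s.mechanism.value,
            }
            for s in fit.segments
        ]
    )
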