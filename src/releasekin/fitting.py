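"""Least-squares estimation of monophasic release-model parameters.

Fits are performed on the untransformed cumulative release fraction
(objective Σ(q_obs − Q_model(t))²), because model comparison in this field
ranks models by R² on the cumulative-release curve. Power-law-type models
are initialized from a log–log linear regression on the positive
observations and refined by nonlinear least squares with a deterministic
multistart; the multistart perturbations come from a fixed pseudo-random
sequence so identical inputs always produce identical fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .exceptions import DataError, DegenerateDataError, ParameterError
from .models import (
    REQUIRED_PARAMS,
    MechanismClass,
    ModelId,
    ReleaseProfile,
    classify_mechanism,
    eval_model,
)

__all__ = [
    "FitOptions",
    "FitResult",
    "FailedFit",
    "fit_model",
    "compare_models",
    "free_parameter_count",
]

#: Seed of the deterministic multistart perturbation stream.
_MULTISTART_SEED = 20210617


@dataclass(frozen=True)
class FitOptions:
    """Options controlling the nonlinear fits.

    ``fix_m_peppas_sahlin`` keeps the Peppas–Sahlin exponent at the strictly
    Fickian cylinder value ``m = 0.45`` (the conventional choice when no
    per-sample m is reported); set it False to free m.
    """

    fix_m_peppas_sahlin: bool = True
    m_value: float = 0.45
    multistart_count: int = 8
    max_iterations: int = 200
    convergence_tolerance: float = 1e-12
    bounds: Optional[Mapping[str, tuple[float, float]]] = None

    def __post_init__(self) -> None:
        if self.multistart_count < 1:
            raise ParameterError("multistart_count must be >= 1")
        if self.convergence_tolerance <= 0:
            raise ParameterError("convergence_tolerance must be > 0")


@dataclass
class FitResult:
    """One fitted monophasic model."""

    model: ModelId
    params: dict[str, float]
    r_squared: float
    sse: float
    n_obs: int
    mechanism: Optional[MechanismClass] = None
    converged: bool = True

    def predict(self, times: Sequence[float]) -> np.ndarray:
        return eval_model(self.model, self.params, times)


@dataclass
class FailedFit:
    """Placeholder for a model that raised during :func:`compare_models`."""

    model: ModelId
    error: str


def free_parameter_count(model: ModelId, options: FitOptions) -> int:
    """Number of parameters actually estimated for ``model``."""
    model = ModelId.coerce(model)
    n = len(REQUIRED_PARAMS[model])
    if model is ModelId.PEPPAS_SAHLIN and options.fix_m_peppas_sahlin:
        n -= 1
    return n


# ---------------------------------------------------------------------------
# initializers


def _loglog_powerlaw_init(t: np.ndarray, q: np.ndarray) -> tuple[float, float]:
    """(k, n) from a log–log regression on points with t > 0, q > 0."""
    mask = (t > 0) & (q > 0)
    if mask.sum() >= 2:
        slope, intercept = np.polyfit(np.log(t[mask]), np.log(q[mask]), 1)
        return float(np.exp(intercept)), float(slope)
    return float(max(q.max(), 1e-6)), 0.5


def _first_order_init(t: np.ndarray, q: np.ndarray) -> float:
    mask = (t > 0) & (q > 0) & (q < 1)
    if mask.any():
        return float(np.mean(-np.log1p(-q[mask]) / t[mask]))
    return 0.1


# ---------------------------------------------------------------------------
# core fit


def _nls(
    model_fn,
    x0: np.ndarray,
    t: np.ndarray,
    q: np.ndarray,
    options: FitOptions,
    bounds=(-np.inf, np.inf),
) -> tuple[np.ndarray, float, bool]:
    """Multistart nonlinear least squares; returns (params, sse, converged)."""

    def residuals(p):
        with np.errstate(over="ignore", invalid="ignore"):
            r = model_fn(p, t) - q
        return np.where(np.isfinite(r), r, 1e6)

    rng = np.random.default_rng(_MULTISTART_SEED)
    starts = [x0]
    for _ in range(options.multistart_count - 1):
        starts.append(x0 * np.exp(rng.normal(0.0, 0.5, size=x0.shape)))
    best_p, best_sse, converged = x0, np.inf, False
    for start in starts:
        start = np.clip(start, bounds[0], bounds[1])
        try:
            sol = least_squares(
                residuals,
                start,
                bounds=bounds,
                xtol=options.convergence_tolerance,
                ftol=options.convergence_tolerance,
                gtol=options.convergence_tolerance,
                max_nfev=options.max_iterations * (len(x0) + 1),
            )
        except Exception:  # noqa: BLE001 - a diverging start is not fatal
            continue
        sse = float(2.0 * sol.cost)
        if sse < best_sse:
            best_p, best_sse, converged = sol.x, sse, bool(sol.success)
    if not np.isfinite(best_sse):
        best_sse = float(np.sum(residuals(x0) ** 2))
    return np.asarray(best_p, dtype=float), best_sse, converged


def _param_bounds(names: Iterable[str], options: FitOptions):
    if not options.bounds:
        return -np.inf, np.inf
    lo, hi = [], []
    for name in names:
        lo_i, hi_i = options.bounds.get(name, (-np.inf, np.inf))
        lo.append(lo_i)
        hi.append(hi_i)
    return np.asarray(lo), np.asarray(hi)


def fit_model(
    profile: ReleaseProfile,
    model: "ModelId | str",
    options: Optional[FitOptions] = None,
) -> FitResult:
    """Fit one monophasic model to a release profile by least squares.

    R² is computed as ``1 − SSE/SST`` with SST about the mean of the observed
    fractions; it may be negative for badly mismatched models and is reported
    as-is. For the Korsmeyer–Peppas model the result carries the transport
    mechanism implied by the fitted exponent.
    """
    model = ModelId.coerce(model)
    if model is ModelId.MULTIPHASIC:
        raise ParameterError(
            "the multiphasic model is piecewise; use releasekin.multiphasic"
        )
    options = options or FitOptions()
    t, q = profile.times, profile.q
    n_free = free_parameter_count(model, options)
    n_pos = int(np.sum(t > 0))
    if n_pos < n_free + 1:
        raise DataError(
            f"model {model.value!r} needs at least {n_free + 1} observations "
            f"with t > 0, got {n_pos}"
        )
    sst = float(np.sum((q - q.mean()) ** 2))
    if sst == 0.0:
        raise DegenerateDataError("all observed fractions are identical (SST = 0)")

    converged = True
    if model is ModelId.ZERO_ORDER:
        coef = np.polyfit(t, q, 1)
        params = {"k0": float(coef[0]), "q0": float(coef[1])}
    elif model is ModelId.HIGUCHI:
        root_t = np.sqrt(t)
        params = {"kH": float((root_t @ q) / (root_t @ root_t))}
    elif model is ModelId.FIRST_ORDER:
        x0 = np.array([_first_order_init(t, q)])
        p, _, converged = _nls(
            lambda p, tt: 1.0 - np.exp(-p[0] * tt), x0, t, q, options,
            _param_bounds(("k1",), options),
        )
        params = {"k1": float(p[0])}
    elif model is ModelId.FIRST_ORDER_LITERAL:
        mask = (q > 0)
        if mask.sum() >= 2:
            slope, intercept = np.polyfit(t[mask], np.log(q[mask]), 1)
            x0 = np.array([np.exp(intercept), slope])
        else:
            x0 = np.array([max(q.max(), 1e-6), 0.05])
        p, _, converged = _nls(
            lambda p, tt: p[0] * np.exp(p[1] * tt),
            np.array([x0[0], x0[1]]), t, q, options,
            _param_bounds(("q0", "k1"), options),
        )
        params = {"k1": float(p[1]), "q0": float(p[0])}
    elif model is ModelId.KORSMEYER_PEPPAS:
        k0, n0 = _loglog_powerlaw_init(t, q)
        p, _, converged = _nls(
            lambda p, tt: p[0] * np.power(tt, p[1]),
            np.array([k0, n0]), t[t > 0], q[t > 0], options,
            _param_bounds(("kKP", "n"), options),
        )
        params = {"kKP": float(p[0]), "n": float(p[1])}
    elif model is ModelId.PEPPAS_SAHLIN:
        if options.fix_m_peppas_sahlin:
            m = options.m_value
            tm = np.power(t, m)
            design = np.column_stack([tm, tm * tm])
            coef, *_ = np.linalg.lstsq(design, q, rcond=None)
            params = {"kd": float(coef[0]), "kr": float(coef[1]), "m": float(m)}
        else:
            k0, n0 = _loglog_powerlaw_init(t, q)
            x0 = np.array([k0, 0.0, max(n0, 0.1)])
            p, _, converged = _nls(
                lambda p, tt: p[0] * np.power(tt, p[2])
                + p[1] * np.power(tt, 2 * p[2]),
                x0, t[t > 0], q[t > 0], options,
                _param_bounds(("kd", "kr", "m"), options),
            )
            params = {"kd": float(p[0]), "kr": float(p[1]), "m": float(p[2])}
    else:  # pragma: no cover
        raise ParameterError(f"unhandled model {model!r}")

    pred = eval_model(model, params, t)
    sse = float(np.sum((q - pred) ** 2))
    mechanism = (
        classify_mechanism(params["n"]) if model is ModelId.KORSMEYER_PEPPAS else None
    )
    return FitResult(
        model=model,
        params=params,
        r_squared=1.0 - sse / sst,
        sse=sse,
        n_obs=profile.n_obs,
        mechanism=mechanism,
        converged=converged,
    )


#: Tie-break enumeration order for model comparison.
_MODEL_ORDER = {m: i for i, m in enumerate(ModelId)}


def compare_models(
    profile: ReleaseProfile,
    models: Iterable["ModelId | str"],
    options: Optional[FitOptions] = None,
) -> list["FitResult | FailedFit"]:
    """Fit several models and rank them by descending R².

    Ties break toward fewer free parameters, then model enumeration order.
    A model whose fit raises is reported at the end of the list as a
    :class:`FailedFit` rather than silently dropped.
    """
    model_list = [ModelId.coerce(m) for m in models]
    if not model_list:
        raise ParameterError("at least one model must be requested")
    options = options or FitOptions()
    results: list[FitResult] = []
    failures: list[FailedFit] = []
    for model in model_list:
        try:
            results.append(fit_model(profile, model, options))
        except Exception as exc:  # noqa: BLE001 - reported, not fatal
            failures.append(FailedFit(model=model, error=str(exc)))
    results.sort(
        key=lambda r: (
            -r.r_squared,
            free_parameter_count(r.model, options),
            _MODEL_ORDER[r.model],
        )
    )
    return [*results, *failures]
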