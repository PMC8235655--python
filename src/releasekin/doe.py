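"""Impregnation metrics and 3² factorial response-surface analysis.

The impregnation experiments vary CO₂ pressure (100/250/400 bar) and
temperature (35/55/75 °C) on a full 3² grid and measure three responses:
permanent swelling of the filament (%), total drug loading (%) and the
superficial fraction of the loaded drug (%). The analysis model is the
five-term quadratic response surface on coded factors

    y = β0 + βA·xA + βB·xB + βAA·(xA² − 2/3) + βAB·xA·xB + βBB·(xB² − 2/3) + ε

where xA, xB ∈ {−1, 0, +1}. Centering the quadratic predictors at their
design mean (2/3 on the balanced 3² grid) makes the five term columns
mutually orthogonal, so each term has a single-df sum of squares that is
simultaneously its sequential and partial SS, and the residual after the
model (df = n − 6, i.e. 3 on a 9-run design) is the ANOVA error term.

Standardized (Pareto) effects are the signed t-ratios coefficient/SE; for a
single-df term |t| = √F. Multi-response optimization uses a geometric-mean
desirability score on a dense deterministic grid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError, DegenerateDataError, DesignError, DomainError

__all__ = [
    "FactorialDesign",
    "AnovaRow",
    "AnovaTable",
    "EffectEstimate",
    "ResponseSurface",
    "OptimizationResult",
    "swelling_percent",
    "drug_loading_percent",
    "superficial_percent",
    "fit_response_surface",
    "anova",
    "finalize_anova",
    "standardized_effects",
    "optimize_responses",
    "TERM_NAMES",
]

TERM_NAMES = ("A_pressure", "B_temperature", "AA", "AB", "BB")

#: Design mean of x² over the three coded levels {−1, 0, +1}.
_QUAD_CENTER = 2.0 / 3.0


# ---------------------------------------------------------------------------
# scalar impregnation metrics


def swelling_percent(d: float, d0: float) -> float:
    """Permanent swelling ``100·(d − d0)/d0`` from diameters in mm.

    Negative values (shrinkage) are reported as-is, never clamped.
    """
    if d0 <= 0:
        raise DomainError(f"initial diameter must be > 0, got {d0}")
    if d < 0:
        raise DomainError(f"diameter must be >= 0, got {d}")
    return 100.0 * (d / d0 - 1.0)


def swelling_summary(diameters: Sequence[float], d0: float) -> tuple[float, float]:
    """Mean and standard deviation of per-measurement swelling percentages."""
    values = [swelling_percent(d, d0) for d in diameters]
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0


def drug_loading_percent(m_ket: float, m_pla: float) -> float:
    """Total drug loading ``100·m_ket/m_pla`` from masses in g."""
    if m_pla <= 0:
        raise DomainError(f"polymer mass must be > 0, got {m_pla}")
    if m_ket < 0:
        raise DomainError(f"drug mass must be >= 0, got {m_ket}")
    return 100.0 * m_ket / m_pla


def superficial_percent(m_sup: float, m_ket: float) -> float:
    """Superficial drug fraction ``100·m_sup/m_ket`` of the total load."""
    if m_ket <= 0:
        raise DomainError(f"total drug mass must be > 0, got {m_ket}")
    if m_sup < 0:
        raise DomainError(f"superficial drug mass must be >= 0, got {m_sup}")
    if m_sup > m_ket:
        raise DataError(
            f"superficial drug mass ({m_sup}) exceeds total drug mass ({m_ket})"
        )
    return 100.0 * m_sup / m_ket


# ---------------------------------------------------------------------------
# factorial design container


def _code(values: np.ndarray, levels: Sequence[float], name: str) -> np.ndarray:
    levels = np.asarray(sorted(levels), dtype=float)
    if len(levels) != 3:
        raise DesignError(f"{name} must have exactly 3 levels, got {levels.tolist()}")
    low, mid, high = levels
    half = (high - low) / 2.0
    if half <= 0 or abs(mid - (low + high) / 2.0) > 1e-9 * half:
        raise DesignError(
            f"{name} levels {levels.tolist()} are not equally spaced; "
            "affine coding to {-1, 0, +1} requires a centered middle level"
        )
    return (values - mid) / half


@dataclass
class FactorialDesign:
    """Runs of a 3² pressure × temperature factorial with one measured response."""

    pressure: np.ndarray  # bar
    temperature: np.ndarray  # °C
    response: np.ndarray  # response units (percent for all three study responses)
    response_name: str = "response"
    pressure_levels: tuple[float, float, float] = (100.0, 250.0, 400.0)
    temperature_levels: tuple[float, float, float] = (35.0, 55.0, 75.0)

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        n = len(self.pressure)
        if len(self.temperature) != n or len(self.response) != n:
            raise DesignError("pressure, temperature and response must be aligned")
        if not np.all(np.isfinite(self.response)):
            raise DesignError("responses must be finite")

    @property
    def n_runs(self) -> int:
        return len(self.response)

    @property
    def coded(self) -> tuple[np.ndarray, np.ndarray]:
        """Coded factor levels (xA for pressure, xB for temperature)."""
        xa = _code(self.pressure, self.pressure_levels, "pressure")
        xb = _code(self.temperature, self.temperature_levels, "temperature")
        return xa, xb

    def require_full(self) -> None:
        """Raise :class:`DesignError` unless all 9 factor cells are present."""
        cells = {
            (p, t)
            for p, t in zip(self.pressure.tolist(), self.temperature.tolist())
        }
        expected = set(itertools.product(self.pressure_levels, self.temperature_levels))
        missing = sorted(expected - cells)
        if missing:
            raise DesignError(f"design is missing factor cells: {missing}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pressure_bar": self.pressure,
                "temperature_C": self.temperature,
                "response": self.response,
            }
        )


def _model_columns(design: FactorialDesign) -> dict[str, np.ndarray]:
    """Centered, mutually orthogonal predictor columns of the quadratic model."""
    xa, xb = design.coded
    cols = {
        "A_pressure": xa,
        "B_temperature": xb,
        "AA": xa**2 - _QUAD_CENTER,
        "AB": xa * xb,
        "BB": xb**2 - _QUAD_CENTER,
    }
    # Re-center each column at its design mean so projections stay orthogonal
    # on balanced replicated designs.
    return {name: col - col.mean() for name, col in cols.items()}


# ---------------------------------------------------------------------------
# response surface


@dataclass
class ResponseSurface:
    """Fitted quadratic response surface in coded factor units."""

    coefficients: dict[str, float]  # keys: intercept + TERM_NAMES
    response_name: str = "response"
    pressure_levels: tuple[float, float, float] = (100.0, 250.0, 400.0)
    temperature_levels: tuple[float, float, float] = (35.0, 55.0, 75.0)

    def predict(self, pressure, temperature) -> np.ndarray:
        """Predicted response at physical (pressure bar, temperature °C)."""
        p = np.asarray(pressure, dtype=float)
        t = np.asarray(temperature, dtype=float)
        pl, tl = self.pressure_levels, self.temperature_levels
        xa = (p - pl[1]) / ((pl[2] - pl[0]) / 2.0)
        xb = (t - tl[1]) / ((tl[2] - tl[0]) / 2.0)
        c = self.coefficients
        return (
            c["intercept"]
            + c["A_pressure"] * xa
            + c["B_temperature"] * xb
            + c["AA"] * (xa**2 - _QUAD_CENTER)
            + c["AB"] * xa * xb
            + c["BB"] * (xb**2 - _QUAD_CENTER)
        )

    def physical_coefficients(self) -> dict[str, float]:
        """Expand the coded polynomial into raw pressure/temperature units.

        Returns coefficients of ``c0 + c1·P + c2·T + c3·P² + c4·P·T + c5·T²``.
        """
        pl, tl = self.pressure_levels, self.temperature_levels
        hp, ht = (pl[2] - pl[0]) / 2.0, (tl[2] - tl[0]) / 2.0
        mp, mt = pl[1], tl[1]
        c = self.coefficients
        c3 = c["AA"] / hp**2
        c5 = c["BB"] / ht**2
        c4 = c["AB"] / (hp * ht)
        c1 = c["A_pressure"] / hp - 2 * c3 * mp - c4 * mt
        c2 = c["B_temperature"] / ht - 2 * c5 * mt - c4 * mp
        c0 = (
            c["intercept"]
            - c["A_pressure"] * mp / hp
            - c["B_temperature"] * mt / ht
            + c3 * mp**2
            + c4 * mp * mt
            + c5 * mt**2
            - (c["AA"] + c["BB"]) * _QUAD_CENTER
        )
        return {"const": c0, "P": c1, "T": c2, "P2": c3, "PT": c4, "T2": c5}


def fit_response_surface(design: FactorialDesign) -> ResponseSurface:
    """Least-squares fit of the five-term quadratic model on coded factors."""
    design.require_full()
    cols = _model_columns(design)
    y = design.response
    x = np.column_stack([np.ones_like(y)] + [cols[name] for name in TERM_NAMES])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise DesignError("design matrix is rank deficient")  # pragma: no cover
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    coeffs = {name: float(b) for name, b in zip(TERM_NAMES, beta[1:])}
    # lstsq used columns re-centered at their design mean; shift the intercept
    # back to the canonical (x² − 2/3) parametrization. On a balanced design
    # the two bases coincide and the shift is zero.
    xa, xb = design.coded
    uncentered = {
        "A_pressure": xa,
        "B_temperature": xb,
        "AA": xa**2 - _QUAD_CENTER,
        "AB": xa * xb,
        "BB": xb**2 - _QUAD_CENTER,
    }
    shift = sum(
        coeffs[name] * float(uncentered[name].mean()) for name in TERM_NAMES
    )
    coeffs["intercept"] = float(beta[0]) - shift
    return ResponseSurface(
        coefficients=coeffs,
        response_name=design.response_name,
        pressure_levels=design.pressure_levels,
        temperature_levels=design.temperature_levels,
    )


# ---------------------------------------------------------------------------
# ANOVA


@dataclass(frozen=True)
class AnovaRow:
    term: str
    df: int
    ss: float
    ms: float
    f_value: float
    p_value: float


@dataclass
class AnovaTable:
    """Term decomposition of a factorial response with error and total rows."""

    rows: list[AnovaRow]
    error_df: int
    error_ss: float
    total_df: int
    total_ss: float
    r_squared: float  # percent

    @property
    def error_ms(self) -> float:
        return self.error_ss / self.error_df

    def to_frame(self) -> pd.DataFrame:
        records = [
            {
                "term": r.term,
                "Df": r.df,
                "Sum Sq": r.ss,
                "Mean Sq": r.ms,
                "F-Value": r.f_value,
                "p-Value": r.p_value,
            }
            for r in self.rows
        ]
        records.append(
            {
                "term": "Error",
                "Df": self.error_df,
                "Sum Sq": self.error_ss,
                "Mean Sq": self.error_ms,
                "F-Value": np.nan,
                "p-Value": np.nan,
            }
        )
        records.append(
            {
                "term": "Total",
                "Df": self.total_df,
                "Sum Sq": self.total_ss,
                "Mean Sq": np.nan,
                "F-Value": np.nan,
                "p-Value": np.nan,
            }
        )
        return pd.DataFrame.from_records(records)

    def to_dict(self) -> dict:
        return {
            "terms": {
                r.term: {
                    "Df": r.df,
                    "Sum Sq": r.ss,
                    "Mean Sq": r.ms,
                    "F-Value": r.f_value,
                    "p-Value": r.p_value,
                }
                for r in self.rows
            },
            "error": {"Df": self.error_df, "Sum Sq": self.error_ss,
                      "Mean Sq": self.error_ms},
            "total": {"Df": self.total_df, "Sum Sq": self.total_ss},
            "R-square": self.r_squared,
        }


def finalize_anova(
    terms: Mapping[str, tuple[float, int]] | Mapping[str, Mapping[str, float]],
    error_ss: float,
    error_df: int,
) -> AnovaTable:
    """Complete a sum-of-squares skeleton to a full ANOVA table.

    ``terms`` maps term name to ``(ss, df)`` (or mappings with ``ss``/``df``
    keys). Mean squares, F ratios, upper-tail F-distribution p-values, the
    total row and R² are filled in exactly as :func:`anova` computes them,
    which lets reported SS decompositions be completed without raw data.
    """
    if error_df < 1:
        raise DegenerateDataError(f"error df must be >= 1, got {error_df}")
    if error_ss <= 0:
        raise DegenerateDataError("error sum of squares must be > 0")
    error_ms = error_ss / error_df
    rows = []
    for name, entry in terms.items():
        if isinstance(entry, Mapping):
            ss, df = float(entry["ss"]), int(entry["df"])
        else:
            ss, df = float(entry[0]), int(entry[1])
        ms = ss / df
        f = ms / error_ms
        p = float(stats.f.sf(f, df, error_df))
        rows.append(AnovaRow(term=name, df=df, ss=ss, ms=ms, f_value=f, p_value=p))
    total_ss = sum(r.ss for r in rows) + error_ss
    total_df = sum(r.df for r in rows) + error_df
    r2 = 100.0 * (1.0 - error_ss / total_ss)
    return AnovaTable(
        rows=rows,
        error_df=error_df,
        error_ss=error_ss,
        total_df=total_df,
        total_ss=total_ss,
        r_squared=r2,
    )


def anova(design: FactorialDesign) -> AnovaTable:
    """Five-term quadratic ANOVA of a full 3² factorial response.

    Term sums of squares come from projections onto the orthogonal centered
    predictor columns; the error row is the residual after the quadratic
    model (lack of fit plus any replicate noise). Raises
    :class:`DegenerateDataError` when the residual SS vanishes (perfect fit,
    F undefined) while the response still varies. A constant response yields
    an all-zero table with undefined (NaN) F and p.
    """
    design.require_full()
    cols = _model_columns(design)
    y = design.response
    n = len(y)
    error_df = n - 6
    if error_df < 1:
        raise DesignError(f"need at least 7 runs for an error term, got {n}")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        rows = [
            AnovaRow(term=name, df=1, ss=0.0, ms=0.0, f_value=np.nan, p_value=np.nan)
            for name in TERM_NAMES
        ]
        return AnovaTable(rows=rows, error_df=error_df, error_ss=0.0,
                          total_df=n - 1, total_ss=0.0, r_squared=np.nan)
    term_ss = {}
    for name in TERM_NAMES:
        x = cols[name]
        xx = float(x @ x)
        term_ss[name] = float((x @ y) ** 2 / xx) if xx > 0 else 0.0
    error_ss = sst - sum(term_ss.values())
    if error_ss <= 1e-10 * sst:
        raise DegenerateDataError(
            "residual sum of squares is (numerically) zero: the quadratic model "
            "fits perfectly and F ratios are undefined"
        )
    return finalize_anova(
        {name: (term_ss[name], 1) for name in TERM_NAMES}, error_ss, error_df
    )


# ---------------------------------------------------------------------------
# standardized (Pareto) effects


@dataclass(frozen=True)
class EffectEstimate:
    """One term of the Pareto chart of standardized effects."""

    term: str
    coefficient: float  # response units per coded unit
    standardized_effect: float  # signed t-ratio
    p_value: float
    significant_at_95: bool


def pareto_critical_value(error_df: int, alpha: float = 0.05) -> float:
    """Two-sided t critical value drawn as the Pareto-chart reference line."""
    return float(stats.t.ppf(1.0 - alpha / 2.0, error_df))


def standardized_effects(design: FactorialDesign) -> list[EffectEstimate]:
    """Signed t-ratios of the quadratic-model terms, in Pareto (|t| desc) order.

    For every single-df term ``standardized_effect² == F`` of the matching
    ANOVA row, and significance at 95% is equivalent to ``p < 0.05``.
    """
    table = anova(design)
    cols = _model_columns(design)
    y = design.response
    mse = table.error_ms
    effects = []
    for row in table.rows:
        x = cols[row.term]
        xx = float(x @ x)
        coef = float(x @ y) / xx
        se = float(np.sqrt(mse / xx))
        t = coef / se
        effects.append(
            EffectEstimate(
                term=row.term,
                coefficient=coef,
                standardized_effect=t,
                p_value=row.p_value,
                significant_at_95=row.p_value < 0.05,
            )
        )
    effects.sort(key=lambda e: -abs(e.standardized_effect))
    return effects


# ---------------------------------------------------------------------------
# multi-response desirability optimization


@dataclass
class OptimizationResult:
    pressure: float  # bar
    temperature: float  # °C
    predicted: dict[str, float]
    desirability: float


#: Default optimization direction per response name.
DEFAULT_GOALS = {
    "loading": "maximize",
    "swelling": "minimize",
    "superficial": "minimize",
}


def optimize_responses(
    surfaces: Mapping[str, ResponseSurface],
    weights: Optional[Mapping[str, float]] = None,
    goals: Optional[Mapping[str, str]] = None,
    pressure_range: tuple[float, float] = (100.0, 400.0),
    temperature_range: tuple[float, float] = (35.0, 75.0),
    pressure_step: float = 1.0,
    temperature_step: float = 0.5,
) -> OptimizationResult:
    """Deterministic grid search of the geometric-mean desirability score.

    Each response is rescaled linearly between its worst and best predicted
    value over the search domain (direction per ``goals``, defaulting to
    larger-is-better for loading and smaller-is-better for swelling and
    superficial load); the overall score is ``D = (Π dᵢ^wᵢ)^(1/Σwᵢ)``.
    Ties resolve to the lowest pressure, then lowest temperature.
    """
    if not surfaces:
        raise DomainError("at least one fitted response surface is required")
    weights = dict(weights) if weights is not None else {k: 1.0 for k in surfaces}
    goals = {**DEFAULT_GOALS, **(goals or {})}
    active = {k: w for k, w in weights.items() if w > 0}
    if any(w < 0 for w in weights.values()) or not active:
        raise DomainError("weights must be >= 0 and not all zero")
    for name in active:
        if name not in surfaces:
            raise DomainError(f"no surface supplied for weighted response {name!r}")
        if name not in goals:
            raise DomainError(f"no optimization goal known for response {name!r}")

    p_lo, p_hi = pressure_range
    t_lo, t_hi = temperature_range
    if not (p_hi >= p_lo and t_hi >= t_lo):
        raise DomainError("empty search domain")
    p_grid = np.arange(p_lo, p_hi + 1e-9, pressure_step)
    t_grid = np.arange(t_lo, t_hi + 1e-9, temperature_step)
    pp, tt = np.meshgrid(p_grid, t_grid, indexing="ij")

    total_w = sum(active.values())
    log_d = np.zeros_like(pp)
    predictions = {}
    for name, w in active.items():
        pred = surfaces[name].predict(pp, tt)
        predictions[name] = pred
        lo, hi = float(pred.min()), float(pred.max())
        if hi - lo <= 0:
            d = np.ones_like(pred)
        elif goals[name] == "maximize":
            d = (pred - lo) / (hi - lo)
        elif goals[name] == "minimize":
            d = (hi - pred) / (hi - lo)
        else:
            raise DomainError(f"goal for {name!r} must be 'maximize' or 'minimize'")
        with np.errstate(divide="ignore"):
            log_d += (w / total_w) * np.log(np.maximum(d, 1e-300))
    desirability = np.exp(log_d)
    best = np.unravel_index(int(np.argmax(desirability)), desirability.shape)
    p_opt, t_opt = float(pp[best]), float(tt[best])
    predicted = {
        name: float(surfaces[name].predict(p_opt, t_opt)) for name in surfaces
    }
    return OptimizationResult(
        pressure=p_opt,
        temperature=t_opt,
        predicted=predicted,
        desirability=float(desirability[best]),
    )
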