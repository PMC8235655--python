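"""Closed-form drug-release kinetic models and transport-mechanism classification.

The models describe the cumulative fraction ``Q(t)`` of drug released from a
polymeric matrix into a dissolution medium as a function of time ``t`` (days):

* zero-order:          ``Q = q0 + k0·t``        (degradation-controlled, constant rate)
* first-order:         ``Q = 1 − exp(−k1·t)``   (conventional saturating release form)
* first-order literal: ``Q = q0·exp(k1·t)``     (textbook exponential-growth form,
  kept for fidelity; it diverges and cannot start from zero release)
* Higuchi:             ``Q = kH·√t``            (Fickian diffusion through the matrix)
* Korsmeyer–Peppas:    ``Q = kKP·tⁿ``           (power law; ``n`` diagnoses mechanism)
* Peppas–Sahlin:       ``Q = kd·tᵐ + kr·t²ᵐ``   (additive diffusion + relaxation terms)

For a cylindrical device the Ritger–Peppas thresholds on the power-law exponent
separate Fickian diffusion (n < 0.45), anomalous transport (0.45 ≤ n ≤ 0.89),
case-II / degradation-controlled transport (0.89 < n ≤ 1) and super-case-II
transport (n > 1).

``Q`` is always a dimensionless fraction of the total loaded mass; rate
constants carry units of day⁻ⁿ as appropriate for each model.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .exceptions import DataError, DomainError, ParameterError

__all__ = [
    "ModelId",
    "MechanismClass",
    "ReleaseProfile",
    "SinkCheck",
    "REQUIRED_PARAMS",
    "eval_model",
    "classify_mechanism",
    "release_ratio",
    "check_sink_conditions",
]


class ModelId(str, enum.Enum):
    """Closed enumeration of the supported release models."""

    ZERO_ORDER = "zero_order"
    FIRST_ORDER = "first_order"
    FIRST_ORDER_LITERAL = "first_order_literal"
    HIGUCHI = "higuchi"
    KORSMEYER_PEPPAS = "korsmeyer_peppas"
    PEPPAS_SAHLIN = "peppas_sahlin"
    MULTIPHASIC = "multiphasic"

    @classmethod
    def coerce(cls, value: "ModelId | str") -> "ModelId":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            raise ParameterError(
                f"unknown model {value!r}; valid models: "
                + ", ".join(m.value for m in cls)
            ) from None


class MechanismClass(str, enum.Enum):
    """Drug-transport mechanism implied by the power-law exponent (cylinder)."""

    FICKIAN_DIFFUSION = "fickian_diffusion"
    ANOMALOUS_TRANSPORT = "anomalous_transport"
    CASE_II_TRANSPORT = "case_II_transport"
    SUPER_CASE_II = "super_case_II"


#: Required parameter names per model, in canonical order.
REQUIRED_PARAMS: Mapping[ModelId, tuple[str, ...]] = {
    ModelId.ZERO_ORDER: ("k0", "q0"),
    ModelId.FIRST_ORDER: ("k1",),
    ModelId.FIRST_ORDER_LITERAL: ("k1", "q0"),
    ModelId.HIGUCHI: ("kH",),
    ModelId.KORSMEYER_PEPPAS: ("kKP", "n"),
    ModelId.PEPPAS_SAHLIN: ("kd", "kr", "m"),
}


@dataclass
class ReleaseProfile:
    """In-vitro release curve of one impregnated sample.

    Parameters
    ----------
    times : array-like
        Elapsed release time in days, strictly increasing, all >= 0.
    q : array-like
        Cumulative released fraction (dimensionless) aligned with ``times``.
    sample_label : str
        Free-text identifier of the sample.
    total_loaded_mass : float, optional
        Total loaded drug mass in mg (the denominator of the release ratio).
    fractional : bool
        If True (default), ``q`` is checked against ``1 + q_tolerance``.
    q_tolerance : float
        Allowed overshoot above 1 for noisy fractional data.
    """

    times: np.ndarray
    q: np.ndarray
    sample_label: str = ""
    total_loaded_mass: Optional[float] = None
    fractional: bool = True
    q_tolerance: float = 0.05

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.times.ndim != 1 or self.q.ndim != 1:
            raise DataError("times and q must be one-dimensional")
        if len(self.times) != len(self.q):
            raise DataError(
                f"times ({len(self.times)}) and q ({len(self.q)}) differ in length"
            )
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.q)):
            raise DataError("times and q must be finite")
        if np.any(self.times < 0):
            raise DomainError("release times must be >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise DataError("times must be strictly increasing")
        if np.any(self.q < 0):
            raise DataError("cumulative released fraction must be >= 0")
        if self.fractional and np.any(self.q > 1.0 + self.q_tolerance):
            raise DataError(
                "fractional profile exceeds 1 + tolerance "
                f"(max q = {self.q.max():.4g}, tolerance = {self.q_tolerance})"
            )

    @property
    def n_obs(self) -> int:
        return len(self.times)

    def to_frame(self):
        import pandas as pd

        frame = pd.DataFrame({"time_days": self.times, "q_fraction": self.q})
        if self.sample_label:
            frame["sample_label"] = self.sample_label
        return frame


@dataclass(frozen=True)
class SinkCheck:
    """Outcome of the sink-condition test for a release experiment."""

    ok: bool
    capacity_ratio: float  # (solubility * volume) / loaded mass
    factor: float


def _validate_params(model: ModelId, params: Mapping[str, float]) -> dict[str, float]:
    required = REQUIRED_PARAMS[model]
    out = {}
    for name in required:
        if name not in params:
            raise ParameterError(f"model {model.value!r} requires parameter {name!r}")
        value = float(params[name])
        if not math.isfinite(value):
            raise ParameterError(f"parameter {name!r} must be finite, got {value!r}")
        out[name] = value
    return out


def eval_model(
    model: "ModelId | str",
    params: Mapping[str, float],
    times: Sequence[float],
) -> np.ndarray:
    """Evaluate a monophasic release model ``Q(t)`` at the given times (days).

    Returns the cumulative released fraction, one value per input time.
    Raises :class:`ParameterError` for incomplete parameter sets and
    :class:`DomainError` for negative times or ``t = 0`` with a negative
    exponent.
    """
    model = ModelId.coerce(model)
    if model is ModelId.MULTIPHASIC:
        raise ParameterError(
            "the multiphasic model is piecewise; use releasekin.multiphasic"
        )
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise DomainError("release times must be >= 0")
    p = _validate_params(model, params)

    if model is ModelId.ZERO_ORDER:
        return p["q0"] + p["k0"] * t
    if model is ModelId.FIRST_ORDER:
        return 1.0 - np.exp(-p["k1"] * t)
    if model is ModelId.FIRST_ORDER_LITERAL:
        return p["q0"] * np.exp(p["k1"] * t)
    if model is ModelId.HIGUCHI:
        return p["kH"] * np.sqrt(t)
    if model is ModelId.KORSMEYER_PEPPAS:
        if p["n"] < 0 and np.any(t == 0):
            raise DomainError("t = 0 undefined for a negative power-law exponent")
        return p["kKP"] * np.power(t, p["n"])
    if model is ModelId.PEPPAS_SAHLIN:
        if p["m"] < 0 and np.any(t == 0):
            raise DomainError("t = 0 undefined for a negative exponent m")
        tm = np.power(t, p["m"])
        return p["kd"] * tm + p["kr"] * tm * tm
    raise ParameterError(f"unhandled model {model!r}")  # pragma: no cover


def classify_mechanism(n: float, geometry: str = "cylinder") -> MechanismClass:
    """Map a power-law exponent to a transport mechanism (cylindrical geometry).

    Boundaries are inclusive on the anomalous side: ``n = 0.45`` and
    ``n = 0.89`` both classify as anomalous transport.
    """
    if geometry != "cylinder":
        raise NotImplementedError(
            f"only cylindrical geometry is supported, got {geometry!r}"
        )
    n = float(n)
    if not math.isfinite(n):
        raise DomainError(f"exponent must be finite, got {n!r}")
    if n < 0.45:
        return MechanismClass.FICKIAN_DIFFUSION
    if n <= 0.89:
        return MechanismClass.ANOMALOUS_TRANSPORT
    if n <= 1.0:
        return MechanismClass.CASE_II_TRANSPORT
    return MechanismClass.SUPER_CASE_II


def release_ratio(mt: float, m_total: float) -> float:
    """Cumulative release ratio ``Qt = mt / m_total`` (masses in mg)."""
    if m_total <= 0:
        raise DomainError(f"total loaded mass must be > 0, got {m_total}")
    if mt < 0:
        raise DomainError(f"released mass must be >= 0, got {mt}")
    return mt / m_total


def check_sink_conditions(
    loaded_drug_mass: float,
    medium_volume: float,
    solubility: float,
    factor: float = 3.0,
) -> SinkCheck:
    """Check that the medium can dissolve ``factor`` times the administered dose.

    Parameters are the loaded drug mass (mg), the medium volume (mL), the drug
    solubility in the medium (mg/mL) and the required safety factor
    (conventionally 3). The boundary is inclusive.
    """
    for name, value in (
        ("loaded_drug_mass", loaded_drug_mass),
        ("medium_volume", medium_volume),
        ("solubility", solubility),
        ("factor", factor),
    ):
        if not value > 0:
            raise DomainError(f"{name} must be > 0, got {value}")
    capacity = solubility * medium_volume
    ratio = capacity / loaded_drug_mass
    return SinkCheck(ok=ratio >= factor, capacity_ratio=ratio, factor=factor)
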