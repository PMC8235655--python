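"""Seeded generators for synthetic release profiles and factorial datasets.

The generators emulate the statistical structure of the impregnation study:
cumulative release curves built from the piecewise power law (with phase
parameters on the scale of the reported multiphasic fits, additive Gaussian
measurement noise and an optional monotone increment-noise mode), and 3²
pressure × temperature factorial responses from a quadratic model on coded
factors plus Gaussian noise.

All randomness flows through ``numpy.random.default_rng(seed)``; identical
specs produce byte-identical data. The default measurement noise on release
fractions is σ = 0.01 (~1% of full release); the factorial fixture noise
uses the replicate standard deviations reported for the study's optimum
condition (≈0.4% for loading and swelling, ≈0.15% for superficial load).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import datasets
from .doe import FactorialDesign, ResponseSurface, TERM_NAMES
from .exceptions import DomainError, ParameterError
from .models import ReleaseProfile
from .multiphasic import _eval_segments

__all__ = [
    "ReleaseGeneratorSpec",
    "FactorialGeneratorSpec",
    "default_sampling_times",
    "generate_release_profile",
    "generate_factorial_dataset",
    "paper_like_fixtures",
]


def default_sampling_times(t_last: float) -> np.ndarray:
    """Sampling schedule denser early to resolve the burst phase.

    Days 0.5, 1, 2, 3, 4, 5, then every 2 days; the final observation always
    falls exactly at ``t_last``.
    """
    if t_last <= 0:
        raise ParameterError(f"t_last must be > 0, got {t_last}")
    early = [0.5, 1.0, 2.0, 3.0, 4.0, 5.0]
    times = [x for x in early if x < t_last]
    times.extend(np.arange(7.0, t_last, 2.0))
    times.append(float(t_last))
    return np.unique(np.asarray(times, dtype=float))


@dataclass(frozen=True)
class ReleaseGeneratorSpec:
    """Generating truth for one synthetic release profile.

    ``segments`` are (k, n, t_end) triples of the piecewise power law, with
    strictly increasing segment end times in days.
    """

    segments: tuple[tuple[float, float, float], ...]
    sampling_times: Optional[tuple[float, ...]] = None
    noise_sd: float = 0.01
    clamp_to_unit: bool = True
    monotone_noise: bool = False
    seed: int = 0
    sample_label: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.segments:
            raise ParameterError("at least one (k, n, t_end) segment is required")
        t_ends = [s[2] for s in self.segments]
        if any(b <= a for a, b in zip(t_ends, t_ends[1:])) or t_ends[0] <= 0:
            raise ParameterError("segment end times must be positive and increasing")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        for k, n, _ in self.segments:
            if not (np.isfinite(k) and np.isfinite(n)):
                raise ParameterError("segment parameters must be finite")


def generate_release_profile(spec: ReleaseGeneratorSpec) -> ReleaseProfile:
    """Sample a noisy cumulative release curve from a piecewise power law.

    At ``noise_sd = 0`` the output is exactly the piecewise evaluation, so
    the generator round-trips through the multiphasic evaluator.
    """
    if spec.sampling_times is not None:
        times = np.asarray(spec.sampling_times, dtype=float)
    else:
        times = default_sampling_times(spec.segments[-1][2])
    clean = _eval_segments(list(spec.segments), times, extrapolate=False)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd == 0.0:
        q = clean.copy()
    elif spec.monotone_noise:
        increments = np.diff(np.concatenate([[0.0], clean]))
        noisy_inc = np.maximum(
            increments + rng.normal(0.0, spec.noise_sd, size=increments.shape), 0.0
        )
        q = np.cumsum(noisy_inc)
    else:
        q = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape)
    q = np.maximum(q, 0.0)  # a cumulative fraction cannot be negative
    if spec.clamp_to_unit:
        q = np.minimum(q, 1.0)
    # Unclamped generating parameters may legitimately exceed 1 inside the
    # window; the profile is then declared non-fractional.
    return ReleaseProfile(
        times=times,
        q=q,
        sample_label=spec.sample_label,
        fractional=spec.clamp_to_unit,
    )


@dataclass(frozen=True)
class FactorialGeneratorSpec:
    """Generating truth for a synthetic 3² factorial dataset.

    ``beta`` maps {intercept, A_pressure, B_temperature, AA, AB, BB} to
    coefficients in response units per coded unit (quadratic terms in the
    centered x² − 2/3 basis).
    """

    beta: dict[str, float] = field(
        default_factory=lambda: {"intercept": 0.0, **{t: 0.0 for t in TERM_NAMES}}
    )
    sigma: float = 1.0
    replicates: int = 1
    seed: int = 0
    response_name: str = "response"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ParameterError("sigma must be >= 0")
        if self.replicates < 1:
            raise ParameterError("replicates must be >= 1")
        missing = {"intercept", *TERM_NAMES} - set(self.beta)
        if missing:
            raise ParameterError(f"beta is missing terms: {sorted(missing)}")


def generate_factorial_dataset(spec: FactorialGeneratorSpec) -> FactorialDesign:
    """Simulate the full 3² design: quadratic truth plus N(0, σ²) noise."""
    surface = ResponseSurface(
        coefficients={k: float(v) for k, v in spec.beta.items()},
        response_name=spec.response_name,
        pressure_levels=datasets.PRESSURE_LEVELS,
        temperature_levels=datasets.TEMPERATURE_LEVELS,
    )
    pressures, temperatures = [], []
    for p in datasets.PRESSURE_LEVELS:
        for t in datasets.TEMPERATURE_LEVELS:
            pressures.extend([p] * spec.replicates)
            temperatures.extend([t] * spec.replicates)
    pressures = np.asarray(pressures, dtype=float)
    temperatures = np.asarray(temperatures, dtype=float)
    truth = surface.predict(pressures, temperatures)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.sigma, size=truth.shape) if spec.sigma else 0.0
    return FactorialDesign(
        pressure=pressures,
        temperature=temperatures,
        response=truth + noise,
        response_name=spec.response_name,
    )


def _anchor_beta(name: str) -> dict[str, float]:
    """Quadratic-model coefficients of an anchor cell-mean table.

    The 3×3 anchor grid (pressure rows × temperature columns) is projected
    onto the orthogonal coded basis; the 9-cell table has 3 residual df, so
    the projection is the exact least-squares quadratic fit.
    """
    grid = np.asarray(datasets.FACTORIAL_ANCHORS[name], dtype=float)
    xa = np.repeat([-1.0, 0.0, 1.0], 3)
    xb = np.tile([-1.0, 0.0, 1.0], 3)
    y = grid.ravel()
    cols = {
        "A_pressure": xa,
        "B_temperature": xb,
        "AA": xa**2 - 2.0 / 3.0,
        "AB": xa * xb,
        "BB": xb**2 - 2.0 / 3.0,
    }
    beta = {"intercept": float(y.mean())}
    for term, x in cols.items():
        beta[term] = float((x @ y) / (x @ x))
    return beta


def paper_like_fixtures(seed: int = 7) -> dict[str, dict]:
    """Fixed-seed fixture bundle emulating the study's datasets.

    Returns ``{"profiles": {label: ReleaseProfile}, "designs": {name:
    FactorialDesign}}`` with four release profiles generated from the
    reported multiphasic phase parameters of the four analyzed impregnation
    conditions, and three factorial designs (loading, swelling, superficial)
    whose effect structure reproduces the reported trends: loading rising
    with temperature and pressure, swelling rising fastest with pressure at
    high temperature, superficial load falling with temperature.
    """
    profiles = {}
    for i, (label, segments) in enumerate(datasets.MULTIPHASIC_REFERENCE.items()):
        spec = ReleaseGeneratorSpec(
            segments=tuple((s["k"], s["n"], s["t_end"]) for s in segments),
            seed=seed + i,
            sample_label=label,
        )
        profiles[label] = generate_release_profile(spec)
    designs = {}
    for j, name in enumerate(("loading", "swelling", "superficial")):
        spec = FactorialGeneratorSpec(
            beta=_anchor_beta(name),
            sigma=datasets.FACTORIAL_NOISE_SD[name],
            replicates=1,
            seed=seed + 100 + j,
            response_name=name,
        )
        designs[name] = generate_factorial_dataset(spec)
    return {"profiles": profiles, "designs": designs}
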