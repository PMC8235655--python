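"""Readers, writers and the end-to-end analysis pipeline.

Tabular inputs are plain CSV with dot decimals and a required header
(release profiles: ``time_days``, ``q_fraction``; factorial designs:
``pressure_bar``, ``temperature_C``, ``response``). Structured output is
JSON. Reports carry a schema version and a provenance block (config hash,
seed, package version) and round-trip losslessly through JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import doe, fitting, multiphasic
from .exceptions import ParseError
from .fitting import FailedFit, FitOptions
from .models import ModelId, ReleaseProfile

__all__ = [
    "REPORT_SCHEMA_VERSION",
    "RunConfig",
    "AnalysisReport",
    "read_release_profile",
    "write_release_profile",
    "read_factorial_design",
    "write_factorial_design",
    "run_pipeline",
]

logger = logging.getLogger("releasekin")

REPORT_SCHEMA_VERSION = "1"

#: Monophasic models fitted by default in the pipeline.
DEFAULT_MODELS = (
    ModelId.ZERO_ORDER,
    ModelId.FIRST_ORDER,
    ModelId.HIGUCHI,
    ModelId.KORSMEYER_PEPPAS,
    ModelId.PEPPAS_SAHLIN,
)


# ---------------------------------------------------------------------------
# CSV readers / writers


def _read_csv(path: Union[str, Path], required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"input file not found: {path}")
    frame = pd.read_csv(path)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    for col in required:
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[values.isna() & frame[col].notna()]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric value in column {col!r} at row {bad[0] + 2}"
            )
        if values.isna().any():
            row = int(frame.index[values.isna()][0]) + 2
            raise ParseError(f"{path}: empty cell in column {col!r} at row {row}")
        frame[col] = values
    return frame


def read_release_profile(
    path: Union[str, Path], sample_label: Optional[str] = None
) -> ReleaseProfile:
    """Read a release profile CSV; rows are sorted by time, duplicates rejected."""
    frame = _read_csv(path, ("time_days", "q_fraction"))
    frame = frame.sort_values("time_days", kind="stable").reset_index(drop=True)
    dup = frame["time_days"].duplicated()
    if dup.any():
        t = frame.loc[dup.idxmax(), "time_days"]
        raise ParseError(f"{path}: duplicate time value {t}")
    if sample_label is None:
        if "sample_label" in frame.columns and len(frame):
            sample_label = str(frame["sample_label"].iloc[0])
        else:
            sample_label = Path(path).stem
    return ReleaseProfile(
        times=frame["time_days"].to_numpy(),
        q=frame["q_fraction"].to_numpy(),
        sample_label=sample_label,
    )


def write_release_profile(profile: ReleaseProfile, path: Union[str, Path]) -> None:
    profile.to_frame().to_csv(path, index=False)


def read_factorial_design(
    path: Union[str, Path], response_name: str = "response"
) -> doe.FactorialDesign:
    frame = _read_csv(path, ("pressure_bar", "temperature_C", "response"))
    return doe.FactorialDesign(
        pressure=frame["pressure_bar"].to_numpy(),
        temperature=frame["temperature_C"].to_numpy(),
        response=frame["response"].to_numpy(),
        response_name=response_name,
    )


def write_factorial_design(
    design: doe.FactorialDesign, path: Union[str, Path]
) -> None:
    design.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunConfig:
    """Configuration of one batch analysis run."""

    profile_paths: list[str] = field(default_factory=list)
    design_paths: dict[str, str] = field(default_factory=dict)  # response name -> path
    models: list[str] = field(default_factory=lambda: [m.value for m in DEFAULT_MODELS])
    fit_options: FitOptions = field(default_factory=FitOptions)
    breakpoint_mode: str = "auto"  # "auto" or comma-separated days, e.g. "5,14"
    n_phases: int = 2
    optimize_weights: dict[str, float] = field(
        default_factory=lambda: {"loading": 1.0, "swelling": 1.0, "superficial": 0.0}
    )
    output_dir: Optional[str] = None
    seed: int = 0
    verbosity: str = "info"

    def canonical_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["fit_options"]["bounds"] = (
            dict(payload["fit_options"]["bounds"] or {})
        )
        return json.dumps(payload, sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Batch analysis results: per-sample kinetics, ANOVA tables, optimizer."""

    samples: list[dict]
    designs: list[dict]
    optimization: Optional[dict]
    provenance: dict
    schema_version: str = REPORT_SCHEMA_VERSION

    def to_json_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_json_dict(cls, payload: dict) -> "AnalysisReport":
        return cls(
            samples=payload["samples"],
            designs=payload["designs"],
            optimization=payload.get("optimization"),
            provenance=payload["provenance"],
            schema_version=payload.get("schema_version", REPORT_SCHEMA_VERSION),
        )

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "AnalysisReport":
        return cls.from_json_dict(json.loads(Path(path).read_text()))


def _fit_result_dict(result) -> dict:
    if isinstance(result, FailedFit):
        return {"model": result.model.value, "error": result.error}
    return {
        "model": result.model.value,
        "params": {k: float(v) for k, v in result.params.items()},
        "r_squared": float(result.r_squared),
        "sse": float(result.sse),
        "mechanism": result.mechanism.value if result.mechanism else None,
        "converged": bool(result.converged),
        "negative_rate_warning": any(
            v < 0 for k, v in result.params.items() if k.startswith("k")
        ),
    }


def _analyze_profile(profile: ReleaseProfile, config: RunConfig) -> dict:
    ranking = fitting.compare_models(profile, config.models, config.fit_options)
    if config.breakpoint_mode == "auto":
        breakpoints = "auto"
    else:
        breakpoints = [float(x) for x in str(config.breakpoint_mode).split(",")]
    mfit = multiphasic.fit_multiphasic(
        profile, breakpoints, config.n_phases, config.fit_options
    )
    best = next((r for r in ranking if not isinstance(r, FailedFit)), None)
    return {
        "sample_label": profile.sample_label,
        "n_obs": profile.n_obs,
        "model_comparison": [_fit_result_dict(r) for r in ranking],
        "best_model": best.model.value if best else None,
        "multiphasic": {
            "breakpoints": [float(b) for b in mfit.breakpoints],
            "breakpoint_mode": mfit.breakpoint_mode,
            "overall_sse": float(mfit.overall_sse),
            "phases": multiphasic.phase_report(mfit).to_dict(orient="records"),
        },
    }


def run_pipeline(config: RunConfig) -> AnalysisReport:
    """Run the full analysis batch described by ``config``.

    Per-sample failures are recorded in the report instead of aborting the
    batch. The result is deterministic given the configuration.
    """
    logging.basicConfig(level=config.verbosity.upper())
    samples = []
    for path in config.profile_paths:
        logger.info("analyzing release profile %s", path)
        try:
            profile = read_release_profile(path)
            samples.append({"path": str(path), **_analyze_profile(profile, config)})
        except Exception as exc:  # noqa: BLE001 - error isolation per sample
            logger.warning("profile %s failed: %s", path, exc)
            samples.append({"path": str(path), "error": str(exc)})

    designs = []
    surfaces = {}
    for name, path in config.design_paths.items():
        logger.info("analyzing factorial design %s (%s)", path, name)
        try:
            design = read_factorial_design(path, response_name=name)
            table = doe.anova(design)
            effects = doe.standardized_effects(design)
            surfaces[name] = doe.fit_response_surface(design)
            designs.append(
                {
                    "path": str(path),
                    "response_name": name,
                    "anova": table.to_dict(),
                    "pareto": [dataclasses.asdict(e) for e in effects],
                    "pareto_critical_value": doe.pareto_critical_value(table.error_df),
                    "surface": surfaces[name].coefficients,
                }
            )
        except Exception as exc:  # noqa: BLE001
            logger.warning("design %s failed: %s", path, exc)
            designs.append({"path": str(path), "response_name": name, "error": str(exc)})

    optimization = None
    weighted = {
        k: w for k, w in config.optimize_weights.items() if w > 0 and k in surfaces
    }
    if weighted:
        logger.info("optimizing responses %s", sorted(weighted))
        result = doe.optimize_responses(
            {k: surfaces[k] for k in weighted}, weights=weighted
        )
        optimization = {
            "pressure_bar": result.pressure,
            "temperature_C": result.temperature,
            "predicted": result.predicted,
            "desirability": result.desirability,
            "weights": weighted,
        }

    from . import __version__

    report = AnalysisReport(
        samples=samples,
        designs=designs,
        optimization=optimization,
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "package_version": __version__,
        },
    )
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.save(out / "report.json")
    return report
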