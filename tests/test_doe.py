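"""Factorial metrics, quadratic response-surface ANOVA, Pareto effects,
and desirability optimization."""

import numpy as np
import pytest
from scipy import stats

from releasekin import (
    FactorialDesign,
    anova,
    drug_loading_percent,
    finalize_anova,
    fit_response_surface,
    optimize_responses,
    standardized_effects,
    superficial_percent,
    swelling_percent,
)
from releasekin.doe import TERM_NAMES, pareto_critical_value
from releasekin.exceptions import (
    DataError,
    DegenerateDataError,
    DesignError,
    DomainError,
)
from releasekin.synthetic import FactorialGeneratorSpec, generate_factorial_dataset


# ---------------------------------------------------------------------------
# impregnation metrics


@pytest.mark.parametrize(
    ("d", "d0", "expected"),
    [(1.75, 1.75, 0.0), (1.925, 1.75, 10.0), (1.575, 1.75, -10.0)],
)
def test_swelling_percent(d, d0, expected):
    assert swelling_percent(d, d0) == pytest.approx(expected)


@pytest.mark.parametrize(
    ("m_ket", "m_pla", "expected"),
    [(0.0, 0.3, 0.0), (0.027, 0.3, 9.0), (0.25, 0.25, 100.0)],
)
def test_drug_loading_percent(m_ket, m_pla, expected):
    assert drug_loading_percent(m_ket, m_pla) == pytest.approx(expected)


@pytest.mark.parametrize(
    ("m_sup", "m_ket", "expected"),
    [(0.0, 0.02, 0.0), (0.02, 0.02, 100.0), (0.0145 * 0.027, 0.027, 1.45)],
)
def test_superficial_percent(m_sup, m_ket, expected):
    assert superficial_percent(m_sup, m_ket) == pytest.approx(expected)


def test_metric_domain_errors():
    with pytest.raises(DomainError):
        swelling_percent(1.8, 0.0)
    with pytest.raises(DomainError):
        drug_loading_percent(0.01, 0.0)
    with pytest.raises(DomainError):
        superficial_percent(0.01, 0.0)
    with pytest.raises(DataError):
        superficial_percent(0.03, 0.02)  # superficial exceeds total


# ---------------------------------------------------------------------------
# designs and surfaces


def _full_design(response, replicates=1, name="response"):
    pressures, temperatures = [], []
    for p in (100.0, 250.0, 400.0):
        for t in (35.0, 55.0, 75.0):
            pressures.extend([p] * replicates)
            temperatures.extend([t] * replicates)
    return FactorialDesign(
        pressure=np.array(pressures),
        temperature=np.array(temperatures),
        response=np.asarray(response, dtype=float),
        response_name=name,
    )


def test_constant_response_surface():
    surface = fit_response_surface(_full_design([7.5] * 9))
    assert surface.coefficients["intercept"] == pytest.approx(7.5)
    for term in TERM_NAMES:
        assert surface.coefficients[term] == pytest.approx(0.0, abs=1e-12)


def test_pure_linear_term_recovered():
    xa = np.repeat([-1.0, 0.0, 1.0], 3)
    surface = fit_response_surface(_full_design(2.0 * xa))
    assert surface.coefficients["A_pressure"] == pytest.approx(2.0)
    for term in ("B_temperature", "AA", "AB", "BB"):
        assert surface.coefficients[term] == pytest.approx(0.0, abs=1e-12)


def test_known_beta_exact_recovery_and_prediction():
    beta = {"intercept": 5.0, "A_pressure": 1.2, "B_temperature": -0.7,
            "AA": 0.9, "AB": 0.4, "BB": -1.1}
    design = generate_factorial_dataset(FactorialGeneratorSpec(beta=beta, sigma=0.0))
    surface = fit_response_surface(design)
    for term, value in beta.items():
        assert surface.coefficients[term] == pytest.approx(value, abs=1e-10)
    # physical-unit expansion predicts identically
    phys = surface.physical_coefficients()
    p, t = 180.0, 62.0
    expanded = (phys["const"] + phys["P"] * p + phys["T"] * t
                + phys["P2"] * p**2 + phys["PT"] * p * t + phys["T2"] * t**2)
    assert expanded == pytest.approx(float(surface.predict(p, t)), rel=1e-10)


def test_missing_cells_listed():
    design = FactorialDesign(
        pressure=np.array([100.0, 250.0]),
        temperature=np.array([35.0, 55.0]),
        response=np.array([1.0, 2.0]),
    )
    with pytest.raises(DesignError, match="missing"):
        fit_response_surface(design)


# ---------------------------------------------------------------------------
# ANOVA


def test_anova_constant_response_all_zero_ss():
    table = anova(_full_design([3.0] * 9))
    assert all(row.ss == 0.0 for row in table.rows)
    assert np.isnan(table.rows[0].f_value)


def test_anova_perfect_fit_is_degenerate():
    beta = {"intercept": 10.0, "A_pressure": 2.0, "B_temperature": 3.0,
            "AA": 0.0, "AB": 1.0, "BB": 0.0}
    design = generate_factorial_dataset(FactorialGeneratorSpec(beta=beta, sigma=0.0))
    with pytest.raises(DegenerateDataError):
        anova(design)


def test_anova_flags_generating_terms():
    beta = {"intercept": 10.0, "A_pressure": 2.0, "B_temperature": 3.0,
            "AA": 0.0, "AB": 1.0, "BB": 0.0}
    design = generate_factorial_dataset(
        FactorialGeneratorSpec(beta=beta, sigma=1e-3, seed=0)
    )
    table = anova(design)
    flagged = {row.term for row in table.rows if row.p_value < 0.05}
    assert {"A_pressure", "B_temperature", "AB"} <= flagged


def test_anova_bookkeeping_on_replicated_design():
    rng = np.random.default_rng(5)
    design = generate_factorial_dataset(
        FactorialGeneratorSpec(
            beta={"intercept": 4.0, "A_pressure": 1.0, "B_temperature": 0.5,
                  "AA": -0.3, "AB": 0.2, "BB": 0.1},
            sigma=0.8, replicates=2, seed=17,
        )
    )
    table = anova(design)
    assert table.total_df == design.n_runs - 1
    assert table.error_df == design.n_runs - 6
    ss_sum = sum(r.ss for r in table.rows) + table.error_ss
    assert ss_sum == pytest.approx(table.total_ss, rel=1e-10)
    y = design.response
    assert table.total_ss == pytest.approx(float(np.sum((y - y.mean()) ** 2)))


@pytest.mark.parametrize(
    ("ss", "error_ms", "expected_f", "expected_p"),
    [
        (297.229, 3.21321, 92.50, 0.0024),
        (171.521, 8.68805, 19.74, 0.0212),
    ],
)
def test_finalize_anova_single_rows(ss, error_ms, expected_f, expected_p):
    table = finalize_anova({"B_temperature": (ss, 1)}, error_ms * 3, 3)
    row = table.rows[0]
    assert row.f_value == pytest.approx(expected_f, abs=0.01)
    assert row.p_value == pytest.approx(expected_p, abs=0.0002)


def test_finalize_anova_f_of_one():
    table = finalize_anova({"A_pressure": (6.0, 1)}, 18.0, 3)
    row = table.rows[0]
    assert row.f_value == pytest.approx(1.0)
    assert row.p_value == pytest.approx(float(stats.f.sf(1.0, 1, 3)))


def test_p_strictly_decreasing_in_f():
    ps = [
        finalize_anova({"A_pressure": (f * 3.0, 1)}, 9.0, 3).rows[0].p_value
        for f in (0.5, 1.0, 2.0, 5.0, 20.0)
    ]
    assert all(b < a for a, b in zip(ps, ps[1:]))


# ---------------------------------------------------------------------------
# standardized effects


def test_standardized_effect_squared_equals_f():
    design = generate_factorial_dataset(
        FactorialGeneratorSpec(
            beta={"intercept": 8.0, "A_pressure": 1.5, "B_temperature": -2.0,
                  "AA": 0.4, "AB": 0.8, "BB": -0.2},
            sigma=0.5, seed=23,
        )
    )
    table = anova(design)
    f_by_term = {row.term: row.f_value for row in table.rows}
    effects = standardized_effects(design)
    for effect in effects:
        assert effect.standardized_effect**2 == pytest.approx(
            f_by_term[effect.term], rel=1e-10
        )
        assert effect.significant_at_95 == (effect.p_value < 0.05)
    # Pareto order: |t| descending
    magnitudes = [abs(e.standardized_effect) for e in effects]
    assert magnitudes == sorted(magnitudes, reverse=True)
    assert pareto_critical_value(3) == pytest.approx(3.182, abs=0.001)


def test_zero_coefficient_gives_zero_effect():
    xa = np.repeat([-1.0, 0.0, 1.0], 3)
    rng = np.random.default_rng(2)
    design = _full_design(2.0 * xa + rng.normal(0, 0.3, 9))
    effects = {e.term: e for e in standardized_effects(design)}
    # construct a response orthogonal to BB up to noise: effect is small, and
    # the signed effect of the constructed A term dominates
    assert abs(effects["A_pressure"].standardized_effect) == max(
        abs(e.standardized_effect) for e in effects.values()
    )


# ---------------------------------------------------------------------------
# optimization


def _monotone_surface():
    beta = {"intercept": 5.0, "A_pressure": 1.0, "B_temperature": 2.0,
            "AA": 0.0, "AB": 0.0, "BB": 0.0}
    design = generate_factorial_dataset(FactorialGeneratorSpec(beta=beta, sigma=0.0))
    return fit_response_surface(design)


def test_loading_only_monotone_surface_maximized_at_corner():
    surface = _monotone_surface()
    result = optimize_responses({"loading": surface}, weights={"loading": 1.0})
    assert (result.pressure, result.temperature) == (400.0, 75.0)


def test_swelling_only_same_surface_opposite_corner():
    surface = _monotone_surface()
    result = optimize_responses({"swelling": surface}, weights={"swelling": 1.0})
    assert (result.pressure, result.temperature) == (100.0, 35.0)


def test_optimize_argument_errors():
    surface = _monotone_surface()
    with pytest.raises(DomainError):
        optimize_responses({}, weights={})
    with pytest.raises(DomainError):
        optimize_responses({"loading": surface}, weights={"loading": 0.0})
    with pytest.raises(DomainError):
        optimize_responses({"loading": surface}, weights={"loading": -1.0})
    with pytest.raises(DomainError):
        optimize_responses(
            {"loading": surface}, weights={"loading": 1.0},
            pressure_range=(400.0, 100.0),
        )
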