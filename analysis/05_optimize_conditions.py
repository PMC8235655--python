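"""Multi-response optimization of the impregnation conditions.

Fits quadratic response surfaces to the simulated loading/swelling/
superficial datasets and maximizes the geometric-mean desirability of high
loading with low swelling over 100–400 bar × 35–75 °C. Result goes to
results/optimization.json.
"""

import json

from _common import RESULTS, load_bundle

from releasekin import fit_response_surface, optimize_responses


def main() -> None:
    bundle = load_bundle()
    surfaces = {
        name: fit_response_surface(design)
        for name, design in bundle["designs"].items()
    }
    result = optimize_responses(
        surfaces, weights={"loading": 1.0, "swelling": 1.0, "superficial": 0.0}
    )
    print(
        f"desirability optimum at {result.pressure:g} bar, "
        f"{result.temperature:g} °C (D = {result.desirability:.3f})"
    )
    for name, value in result.predicted.items():
        print(f"  predicted {name}: {value:.2f} %")
    RESULTS.mkdir(parents=True, exist_ok=True)
    out = RESULTS / "optimization.json"
    out.write_text(json.dumps({
        "pressure_bar": result.pressure,
        "temperature_C": result.temperature,
        "desirability": result.desirability,
        "predicted": result.predicted,
        "weights": {"loading": 1.0, "swelling": 1.0, "superficial": 0.0},
    }, indent=2, sort_keys=True))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
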