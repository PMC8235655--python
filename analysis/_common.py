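"""Shared plumbing for the numbered analysis drivers."""

from pathlib import Path

from releasekin import (
    paper_like_fixtures,
    read_factorial_design,
    read_release_profile,
    write_factorial_design,
    write_release_profile,
)

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
DATASETS = RESULTS / "datasets"

FIXTURE_SEED = 7
PROFILE_LABELS = ("55C_400bar", "75C_250bar", "75C_200bar", "55C_250bar")
DESIGN_NAMES = ("loading", "swelling", "superficial")


def load_bundle():
    """Load the simulated datasets written by 01, generating them if absent."""
    profile_paths = {l: DATASETS / f"profile_{l}.csv" for l in PROFILE_LABELS}
    design_paths = {n: DATASETS / f"design_{n}.csv" for n in DESIGN_NAMES}
    if all(p.exists() for p in [*profile_paths.values(), *design_paths.values()]):
        return {
            "profiles": {l: read_release_profile(p) for l, p in profile_paths.items()},
            "designs": {
                n: read_factorial_design(p, response_name=n)
                for n, p in design_paths.items()
            },
        }
    return paper_like_fixtures(seed=FIXTURE_SEED)


def write_bundle(bundle):
    DATASETS.mkdir(parents=True, exist_ok=True)
    for label, profile in bundle["profiles"].items():
        write_release_profile(profile, DATASETS / f"profile_{label}.csv")
    for name, design in bundle["designs"].items():
        write_factorial_design(design, DATASETS / f"design_{name}.csv")
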