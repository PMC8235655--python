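"""Simulate the study-like datasets every later stage analyzes.

Generates four in-vitro release profiles (one per analyzed impregnation
condition, using the reported multiphasic phase parameters as generating
truth) and three 3² factorial response tables (loading, swelling,
superficial drug), then writes them as CSV under results/datasets/.
"""

from _common import FIXTURE_SEED, write_bundle

from releasekin import paper_like_fixtures


def main() -> None:
    bundle = paper_like_fixtures(seed=FIXTURE_SEED)
    write_bundle(bundle)
    print(f"seed {FIXTURE_SEED}:")
    for label, profile in bundle["profiles"].items():
        print(
            f"  profile {label}: {profile.n_obs} observations over "
            f"{profile.times.max():g} days, final fraction {profile.q[-1]:.3f}"
        )
    for name, design in bundle["designs"].items():
        print(
            f"  design {name}: {design.n_runs} runs, response range "
            f"{design.response.min():.2f}..{design.response.max():.2f} %"
        )
    print("wrote results/datasets/")


if __name__ == "__main__":
    main()
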