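"""Turn the screened compounds into a w/w mixture recipe with per-dose
masses, and diff the content-derived ratio against the published one.

The measured contents imply linalool : p-cymene : α-terpinene :
terpinen-4-ol : α-terpineol = 2 : 5 : 0.6 : 0.8 : 1, while the published
mixture used 0.8 : 5 : 0.6 : 2 : 1 — the linalool and terpinen-4-ol parts
are transposed. Both are computed and the diff written, neither silently
adopted.

Usage: python analysis/05_mixture_recipe.py [--out results] [--dose 12.5] [--body-mass 0.028]
"""

import argparse
from pathlib import Path

from netpharm.datasets import (
    CBEO_ACTIVE_COMPOUNDS,
    CBEO_REPORTED_RATIO,
    load_cbeo_contents,
    load_cbeo_topology,
)
from netpharm.mixture import component_masses, compute_ratio, diff_ratios, spec_from_ratio
from netpharm.network_topology import screen_compounds


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--dose", type=float, default=12.5, help="mg per kg body weight")
    parser.add_argument("--body-mass", type=float, default=0.028, help="kg")
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    contents = load_cbeo_contents()
    selected = screen_compounds(load_cbeo_topology()).selected
    assert set(selected) == set(CBEO_ACTIVE_COMPOUNDS)

    # α-terpineol as reference puts both vectors on the same ":1" tail
    derived = compute_ratio(list(CBEO_ACTIVE_COMPOUNDS), contents, reference="α-Terpineol")
    reported = spec_from_ratio(list(CBEO_ACTIVE_COMPOUNDS), list(CBEO_REPORTED_RATIO))

    recipe = derived.to_frame()
    masses = dict(component_masses(derived, args.dose, args.body_mass))
    recipe["mass_per_dose_mg"] = [masses[c] for c in recipe["compound"]]
    recipe.to_csv(args.out / "mixture_recipe.tsv", sep="\t", index=False)
    diff = diff_ratios(derived, reported)
    diff.to_csv(args.out / "mixture_ratio_diff.tsv", sep="\t", index=False)

    print(f"content-derived ratio ({', '.join(CBEO_ACTIVE_COMPOUNDS)}):")
    print(f"  {derived.ratio_string()}  (reference: {derived.reference_compound})")
    print(f"published ratio: {reported.ratio_string()}")
    print(f"per-dose masses at {args.dose} mg/kg x {args.body_mass} kg "
          f"(total {sum(masses.values()):.4g} mg):")
    for name, mg in masses.items():
        print(f"  {name}: {mg:.4f} mg")
    mismatches = diff[
        (diff["derived_mass_fraction"] - diff["override_mass_fraction"]).abs() > 1e-9
    ]["compound"].tolist()
    print(f"mass fractions differing from the published vector: {mismatches}")


if __name__ == "__main__":
    main()
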