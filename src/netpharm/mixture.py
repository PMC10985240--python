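"""w/w mixture formulation from GC–MS relative contents.

The screened active compounds are combined into a mixture whose mass
proportions mirror their relative contents in the source essential oil:
ratio parts are contents divided by a reference compound's content (by
default the lowest-content selected compound, so the reference part is 1
and the others are ≥ 1-comparable), and mass fractions are contents
normalized over the selected subset. Per-dose component masses follow from
dose (mg per kg body weight) times body mass times mass fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import CompoundTable


@dataclass(frozen=True)
class MixtureComponent:
    compound: str
    relative_content: float  # percent in the source oil
    ratio_part: float        # content / reference content
    mass_fraction: float     # content / sum of selected contents


@dataclass
class MixtureSpec:
    components: list[MixtureComponent]
    reference_compound: str

    def __post_init__(self) -> None:
        total = sum(c.mass_fraction for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mass fractions sum to {total}, not 1")

    def ratio_string(self, ndigits: int = 4) -> str:
        return ":".join(f"{round(c.ratio_part, ndigits):g}" for c in self.components)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound": [c.compound for c in self.components],
                "relative_content_pct": [c.relative_content for c in self.components],
                "ratio_part": [c.ratio_part for c in self.components],
                "mass_fraction": [c.mass_fraction for c in self.components],
            }
        )


def compute_ratio(
    selected: list[str], table: CompoundTable, reference: str | None = None
) -> MixtureSpec:
    """Derive the w/w ratio of the selected compounds from their contents.

    ``reference`` defaults to the lowest-content selected compound (its
    ratio part is 1). Component order follows ``selected``. The result is
    invariant under any positive rescaling of the contents.
    """
    if not selected:
        raise ValueError("no compounds selected")
    contents = {}
    for name in selected:
        value = table.content(name)  # KeyError if absent
        if value <= 0:
            raise ValueError(f"zero or negative content for {name!r}")
        contents[name] = value
    if reference is None:
        reference = min(selected, key=lambda n: (contents[n], n))
    if reference not in contents:
        raise ValueError(f"reference {reference!r} is not among the selected compounds")
    total = sum(contents.values())
    components = [
        MixtureComponent(
            compound=name,
            relative_content=contents[name],
            ratio_part=contents[name] / contents[reference],
            mass_fraction=contents[name] / total,
        )
        for name in selected
    ]
    return MixtureSpec(components, reference)


def spec_from_ratio(compounds: list[str], ratio_parts: list[float]) -> MixtureSpec:
    """Build a MixtureSpec directly from an explicit w/w ratio vector."""
    if len(compounds) != len(ratio_parts):
        raise ValueError("compounds and ratio parts differ in length")
    if any(part <= 0 for part in ratio_parts):
        raise ValueError("ratio parts must be positive")
    total = sum(ratio_parts)
    reference = compounds[min(range(len(ratio_parts)), key=lambda i: ratio_parts[i])]
    components = [
        MixtureComponent(name, float("nan"), part, part / total)
        for name, part in zip(compounds, ratio_parts)
    ]
    return MixtureSpec(components, reference)


def component_masses(
    spec: MixtureSpec, dose_mg_per_kg: float, body_mass_kg: float
) -> list[tuple[str, float]]:
    """Per-component masses (mg) for one administration.

    Masses sum to dose × body mass and scale linearly in both.
    """
    if dose_mg_per_kg <= 0 or body_mass_kg <= 0:
        raise ValueError("dose and body mass must be positive")
    total_mg = dose_mg_per_kg * body_mass_kg
    return [(c.compound, total_mg * c.mass_fraction) for c in spec.components]


def diff_ratios(derived: MixtureSpec, override: MixtureSpec) -> pd.DataFrame:
    """Side-by-side comparison of a content-derived and an override ratio.

    Both ratio vectors are renormalized to mass fractions so differently
    scaled ratios compare on the same footing.
    """
    d = {c.compound: c for c in derived.components}
    o = {c.compound: c for c in override.components}
    names = list(d) + [n for n in o if n not in d]
    return pd.DataFrame(
        {
            "compound": names,
            "derived_ratio_part": [d[n].ratio_part if n in d else float("nan") for n in names],
            "override_ratio_part": [o[n].ratio_part if n in o else float("nan") for n in names],
            "derived_mass_fraction": [d[n].mass_fraction if n in d else float("nan") for n in names],
            "override_mass_fraction": [o[n].mass_fraction if n in o else float("nan") for n in names],
        }
    )
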