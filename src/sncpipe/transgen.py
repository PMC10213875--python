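"""Inter- and transgenerational differential-expression overlap.

A feature is transgenerationally up-regulated in a lineage when it is in
the up set of the F1, F2 and F3 comparisons of that lineage; likewise for
down.  Mixed directions are excluded, so the up and down sets are disjoint
by construction.  The F1-and-F2 (intergenerational) overlap is reported as
well.  Features removed by the low-expression filter in any generation have
no DE call there and therefore can never be transgenerational.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

from .diffexpr import de_sets

GENERATIONS = ("F1", "F2", "F3")


@dataclass
class GenerationalCall:
    lineage: str
    up_sets: dict[str, set] = field(default_factory=dict)
    down_sets: dict[str, set] = field(default_factory=dict)
    transgenerational_up: set = field(default_factory=set)
    transgenerational_down: set = field(default_factory=set)
    intergenerational_up: set = field(default_factory=set)
    intergenerational_down: set = field(default_factory=set)
    log2fc: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def transgenerational(self) -> set:
        return self.transgenerational_up | self.transgenerational_down


def _check_keying(tables: Mapping[str, pd.DataFrame]) -> None:
    # Heuristic guard against mixed feature-identity schemes: three
    # non-empty DE tables whose feature universes are pairwise disjoint
    # cannot come from one consistent keying.
    ids = [set(t.index) for t in tables.values()]
    if all(ids) and not any(a & b for a in ids for b in ids if a is not b):
        raise ValueError(
            "DE tables share no feature ids across generations; "
            "feature keying is inconsistent"
        )


def transgenerational_overlap(
    de_f1: pd.DataFrame,
    de_f2: pd.DataFrame,
    de_f3: pd.DataFrame,
    lineage: str = "",
    require_direction: bool = True,
) -> GenerationalCall:
    """Directional intersection of the three generations' DE sets.

    ``require_direction=False`` switches to presence-only intersection of
    the union sets (sensitivity analysis); the default matches the
    sign-consistent definition.
    """
    tables = {"F1": de_f1, "F2": de_f2, "F3": de_f3}
    _check_keying(tables)
    up: dict[str, set] = {}
    down: dict[str, set] = {}
    for gen, tab in tables.items():
        up[gen], down[gen] = de_sets(tab)

    if require_direction:
        tg_up = up["F1"] & up["F2"] & up["F3"]
        tg_down = down["F1"] & down["F2"] & down["F3"]
        ig_up = up["F1"] & up["F2"]
        ig_down = down["F1"] & down["F2"]
    else:
        any_de = {g: up[g] | down[g] for g in GENERATIONS}
        both = any_de["F1"] & any_de["F2"] & any_de["F3"]
        tg_up = {f for f in both if f in up["F1"]}
        tg_down = both - tg_up
        ig_up = {f for f in any_de["F1"] & any_de["F2"] if f in up["F1"]}
        ig_down = (any_de["F1"] & any_de["F2"]) - ig_up

    features = sorted(tg_up | tg_down)
    lfc = pd.DataFrame(
        {gen: tables[gen]["log2fc"].reindex(features) for gen in GENERATIONS}
    )
    lfc.index.name = "feature_id"
    return GenerationalCall(
        lineage=lineage,
        up_sets=up,
        down_sets=down,
        transgenerational_up=tg_up,
        transgenerational_down=tg_down,
        intergenerational_up=ig_up,
        intergenerational_down=ig_down,
        log2fc=lfc,
    )


def export_fc_heatmap_table(
    call: GenerationalCall, feature_biotypes: Optional[Mapping[str, str]] = None
) -> pd.DataFrame:
    """Long-format table (feature, biotype, generation, log2fc, direction),
    one row per transgenerational feature x generation."""
    rows = []
    for feature in sorted(call.transgenerational):
        direction = "up" if feature in call.transgenerational_up else "down"
        for gen in GENERATIONS:
            rows.append(
                {
                    "feature_id": feature,
                    "biotype": feature_biotypes.get(feature, "")
                    if feature_biotypes
                    else "",
                    "generation": gen,
                    "log2fc": float(call.log2fc.loc[feature, gen]),
                    "direction": direction,
                }
            )
    return pd.DataFrame(
        rows, columns=["feature_id", "biotype", "generation", "log2fc", "direction"]
    )
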