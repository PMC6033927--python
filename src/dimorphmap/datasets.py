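"""Bundled reference data: canonical sexually dimorphic structure volumes.

Published mean volumes of four canonical structures of the C57BL/6J mouse
brain — bed nucleus of the stria terminalis (BNST), medial preoptic
nucleus (MPON), medial amygdala (MeA) and periaqueductal gray (PAG) —
across the nine-timepoint longitudinal MEMRI design (postnatal days 3-65),
for each sex, as absolute volume (mm^3) and relative volume (% of whole
brain).  These serve as worked-example inputs: sex percent differences and
the whole-brain volume implied by each (absolute, relative) pair are
recomputed from them at run time.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "load_canonical_structure_means",
    "percent_sex_difference",
    "implied_brain_volumes",
]


def load_canonical_structure_means() -> pd.DataFrame:
    """Long-format table: structure, age_days, sex, absolute_mm3, relative_pct_brain."""
    ref = resources.files("dimorphmap") / "data" / "canonical_structure_means.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def percent_sex_difference(table: pd.DataFrame, structure: str, age_days: float,
                           column: str = "absolute_mm3") -> float:
    """100 * (male - female) / female for one structure at one age."""
    sub = table[(table["structure"] == structure) & (table["age_days"] == age_days)]
    if sub.empty:
        raise ValueError(f"no rows for {structure} at age {age_days}")
    male = float(sub.loc[sub["sex"] == "M", column].iloc[0])
    female = float(sub.loc[sub["sex"] == "F", column].iloc[0])
    return 100.0 * (male - female) / female


def implied_brain_volumes(table: pd.DataFrame, age_days: float = 65) -> pd.DataFrame:
    """Whole-brain volume implied by each (absolute, relative) pair.

    relative = 100 * absolute / brain, so brain = 100 * absolute / relative.
    Internal consistency of a printed table requires the implied volumes to
    agree across structures for a given sex and age.
    """
    sub = table[table["age_days"] == age_days].copy()
    sub["implied_brain_mm3"] = 100.0 * sub["absolute_mm3"] / sub["relative_pct_brain"]
    out = sub[["structure", "sex", "implied_brain_mm3"]].reset_index(drop=True)
    spread = (
        out.groupby("sex")["implied_brain_mm3"]
        .agg(lambda v: (v.max() - v.min()) / v.mean())
        .rename("relative_spread")
    )
    out = out.merge(spread, on="sex")
    return out
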