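"""Private helpers shared by the normative and sequence-comparison modules."""

from __future__ import annotations

from functools import reduce
from operator import add

import pandas as pd

from .io import CohortTable
from .regions import RegionHierarchy, canonical_hierarchy, canonical_sequence, canonical_side


def scored_wide(
    cohort: CohortTable, sequence: str, side: str,
    hierarchy: RegionHierarchy | None = None,
) -> pd.DataFrame:
    """Subjects x 22-scored-regions volume matrix for one sequence and side.

    Combined labels are derived by summing member subregion columns in
    catalogue order (the whole hippocampus as head + body + tail), matching
    :func:`hippasym.regions.aggregate` bit for bit.
    """
    hierarchy = hierarchy or canonical_hierarchy()
    sequence = canonical_sequence(sequence)
    side = canonical_side(side)
    df = cohort.records
    df = df[(df["sequence"] == sequence) & (df["side"] == side)]
    if df.empty:
        raise ValueError(f"cohort has no records for {sequence} / {side}")
    wide = df.pivot(index="subject_id", columns="region", values="volume_mm3")
    missing = [r for r in hierarchy.subregions if r not in wide.columns]
    if missing:
        raise ValueError(f"cohort is missing subregions: {', '.join(missing)}")
    incomplete = wide[list(hierarchy.subregions)].isna().any(axis=1)
    if incomplete.any():
        subj = wide.index[incomplete][0]
        raise ValueError(f"subject {subj!r} is missing subregion volumes")
    for label, members in hierarchy.combined_labels.items():
        if label == "Whole_hippocampus":
            continue
        wide[label] = reduce(add, (wide[m] for m in members))
    wide["Whole_hippocampus"] = (
        wide["Whole_hippocampal_head"]
        + wide["Whole_hippocampal_body"]
        + wide["Hippocampal_tail"]
    )
    return wide[list(hierarchy.scored_regions)]
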