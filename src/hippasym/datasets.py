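"""Loaders for the small reference datasets shipped with the package.

Three resources are packaged as JSON under :mod:`hippasym.data`:

* ``normative_reference.json`` — per-region mean/SD of healthy right−left
  volume differences (20 controls, both sequence variants); the default
  reference for z-scoring.
* ``sequence_comparison_summary.json`` — per-region, per-side summary of the
  published paired comparison between the conventional T2 TSE sequence and
  its DRB-reconstructed variant (36 subjects); calibrates the synthetic
  cohort generator.
* ``worked_example_hs.json`` — right/left subfield volumes of a published
  right-sided hippocampal-sclerosis case, the package's worked example.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from typing import Any

import pandas as pd

from .regions import canonical_hierarchy, canonical_sequence

__all__ = [
    "load_sequence_comparison_summary",
    "load_worked_example",
    "worked_example_side_volumes",
]


@lru_cache(maxsize=8)
def _load_resource(name: str) -> dict[str, Any]:
    return json.loads(resources.files("hippasym.data").joinpath(name).read_text())


def load_sequence_comparison_summary() -> pd.DataFrame:
    """Published sequence-comparison summary as a tidy DataFrame.

    Columns: region, side, mean_tse, mean_drb, mean_diff, sd_diff,
    corrected_p. One row per (region, side); 22 regions x 2 sides.
    """
    raw = _load_resource("sequence_comparison_summary.json")
    records = []
    for region, sides in raw["rows"].items():
        for side, values in sides.items():
            records.append({"region": region, "side": side,
                            **dict(zip(raw["columns"], values))})
    return pd.DataFrame.from_records(records)


def load_worked_example() -> pd.DataFrame:
    """The worked hippocampal-sclerosis example as a DataFrame.

    Columns: region (22 rows, catalogue order), right, left, printed_diff
    (all mm^3). ``printed_diff`` is the right−left column as printed in the
    source table; it was computed from unrounded volumes, so in a few rows it
    differs by 0.1 mm^3 from ``right - left`` of the rounded volumes and is
    the more faithful input for reproducing the published z-scores.
    """
    raw = _load_resource("worked_example_hs.json")
    df = pd.DataFrame.from_dict(raw["rows"], orient="index",
                                columns=raw["columns"])
    df.index.name = "region"
    df = df.reset_index()
    df.attrs["sequence"] = canonical_sequence(raw["sequence"])
    return df


def worked_example_side_volumes() -> tuple["SideVolumes", "SideVolumes"]:
    """The worked example's 19 subregion volumes as (right, left) maps."""
    from .regions import SideVolumes  # local import avoids cycle at type time

    df = load_worked_example()
    hierarchy = canonical_hierarchy()
    sub = df[df["region"].isin(hierarchy.subregions)]
    right = SideVolumes("example-HS-right", "right", "T2_TSE_DRB",
                        dict(zip(sub["region"], sub["right"])))
    left = SideVolumes("example-HS-right", "left", "T2_TSE_DRB",
                       dict(zip(sub["region"], sub["left"])))
    return right, left
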