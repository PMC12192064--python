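"""Reading FreeSurfer subfield volume files and cohort tables; writing reports.

The per-hemisphere input is the plain-text two-column ``<region> <volume>``
format that FreeSurfer's hippocampal-subfield stream writes
(``[lr]h.hippoSfVolumes*.txt``). Cohorts are long-format CSV with one row per
(subject, group, sequence, side, region).

Volumes are mm^3 everywhere; no unit conversion is ever applied. Sequence
tags are mandatory and are never merged implicitly: joining volumes acquired
with different sequence variants requires an explicit override downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

from .regions import (
    SideVolumes,
    canonical_hierarchy,
    canonical_sequence,
    canonical_side,
)

__all__ = [
    "GROUPS",
    "COHORT_COLUMNS",
    "CohortTable",
    "read_subfield_volumes",
    "write_subfield_volumes",
    "read_cohort",
    "write_cohort",
    "write_report",
]

GROUPS = ("healthy", "HS", "FCD", "edema", "epilepsy_no_lesion")
COHORT_COLUMNS = ("subject_id", "group", "sequence", "side", "region", "volume_mm3")


def read_subfield_volumes(
    path: Union[str, Path], side: str, sequence: str, subject_id: str | None = None
) -> SideVolumes:
    """Parse a FreeSurfer hippoSfVolumes-style two-column text file.

    Each non-empty line is ``<region-name> <volume>``; region names are
    alias-resolved against the canonical catalogue. Unparseable lines and
    duplicate regions raise with the offending line number.
    """
    path = Path(path)
    hierarchy = canonical_hierarchy()
    volumes: dict[str, float] = {}
    problems: list[str] = []
    lines = path.read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 2:
            problems.append(f"line {lineno}: expected 'name value', got {line!r}")
            continue
        name, raw_value = parts
        try:
            canon = hierarchy.resolve(name)
        except KeyError:
            problems.append(f"line {lineno}: unknown region {name!r}")
            continue
        try:
            value = float(raw_value)
        except ValueError:
            problems.append(f"line {lineno}: non-numeric volume {raw_value!r}")
            continue
        if canon in volumes:
            problems.append(f"line {lineno}: duplicate region {canon!r}")
            continue
        volumes[canon] = value
    if problems:
        raise ValueError(f"errors parsing {path}:\n" + "\n".join(problems))
    if not volumes:
        raise ValueError(f"{path} contains no volume entries")
    return SideVolumes(
        subject_id=subject_id or path.stem,
        side=side,
        sequence=sequence,
        volumes=volumes,
    )


def write_subfield_volumes(volumes: SideVolumes, path: Union[str, Path]) -> Path:
    """Write a SideVolumes map back to the two-column text format.

    Full ``repr`` precision is used so a write/read round-trip is lossless.
    """
    path = Path(path)
    lines = [f"{region} {value!r}" for region, value in volumes.volumes.items()]
    path.write_text("\n".join(lines) + "\n")
    return path


@dataclass
class CohortTable:
    """Long-format per-subject, per-side, per-region volumes.

    ``records`` has columns subject_id, group, sequence, side, region,
    volume_mm3. (subject_id, sequence, side, region) is unique and every
    subject has both sides for each sequence it appears under.
    """

    records: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        df = self.records.copy()
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cohort table is missing columns: {missing}")
        hierarchy = canonical_hierarchy()
        df["subject_id"] = df["subject_id"].astype(str)
        df["region"] = df["region"].map(hierarchy.resolve)
        df["side"] = df["side"].map(canonical_side)
        df["sequence"] = df["sequence"].map(canonical_sequence)
        df["volume_mm3"] = df["volume_mm3"].astype(float)
        unknown_groups = set(df["group"]) - set(GROUPS)
        if unknown_groups:
            raise ValueError(
                f"unknown group labels {sorted(unknown_groups)}; expected {GROUPS}"
            )
        key = ["subject_id", "sequence", "side", "region"]
        dupes = df[df.duplicated(key, keep=False)]
        if len(dupes):
            first = dupes.iloc[0]
            raise ValueError(
                "duplicate cohort records, e.g. subject "
                f"{first['subject_id']!r} {first['sequence']} {first['side']} "
                f"{first['region']}"
            )
        sides_per = df.groupby(["subject_id", "sequence"])["side"].nunique()
        incomplete = sides_per[sides_per < 2]
        if len(incomplete):
            subj, seq = incomplete.index[0]
            raise ValueError(
                f"subject {subj!r} has only one side recorded for {seq}; "
                "both hemispheres are required"
            )
        self.records = df[list(COHORT_COLUMNS)].reset_index(drop=True)

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(self.records["subject_id"].unique())

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(self.records["sequence"].unique())

    def restrict(
        self, group: str | None = None, sequence: str | None = None
    ) -> "CohortTable":
        df = self.records
        if group is not None:
            df = df[df["group"] == group]
        if sequence is not None:
            df = df[df["sequence"] == canonical_sequence(sequence)]
        if df.empty:
            raise ValueError(
                f"no cohort records left after restricting to "
                f"group={group!r}, sequence={sequence!r}"
            )
        return CohortTable(df.copy(), provenance=self.provenance)

    def side_volumes(self, subject_id: str, side: str, sequence: str) -> SideVolumes:
        df = self.records
        mask = (
            (df["subject_id"] == str(subject_id))
            & (df["side"] == canonical_side(side))
            & (df["sequence"] == canonical_sequence(sequence))
        )
        sel = df[mask]
        if sel.empty:
            raise KeyError(
                f"no records for subject {subject_id!r}, side {side}, "
                f"sequence {sequence}"
            )
        return SideVolumes(
            subject_id=str(subject_id),
            side=side,
            sequence=sequence,
            volumes=dict(zip(sel["region"], sel["volume_mm3"])),
        )


def read_cohort(path: Union[str, Path]) -> CohortTable:
    """Read and validate a long-format cohort CSV."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    return CohortTable(df, provenance=str(path))


def write_cohort(cohort: CohortTable, path: Union[str, Path]) -> Path:
    path = Path(path)
    cohort.records.to_csv(path, index=False)
    return path


# columns rounded to 1 decimal in CSV output (volumes, differences, z);
# p-values get 4 decimals; JSON always keeps full precision
_ONE_DP = ("right_volume", "left_volume", "diff", "z", "mean_vol_a",
           "mean_vol_b", "mean_diff", "sd_diff", "mean_mm3", "sd_mm3")
_FOUR_DP = ("raw_p", "corrected_p", "p")


def write_report(report, path: Union[str, Path], format: str = "csv") -> Path:
    """Write an asymmetry report or comparison table to CSV or JSON.

    CSV mirrors the published tables' precision (volumes and z to 1 decimal,
    p-values to 4); JSON retains full precision plus the report's metadata.
    Any object exposing ``to_frame()`` and ``metadata`` is accepted.
    """
    path = Path(path)
    frame: pd.DataFrame = report.to_frame()
    metadata = getattr(report, "metadata", {})
    if format == "csv":
        out = frame.copy()
        for col in out.columns:
            if col in _ONE_DP:
                out[col] = out[col].astype(float).round(1)
            elif col in _FOUR_DP:
                out[col] = out[col].astype(float).round(4)
        out.to_csv(path, index=False)
    elif format == "json":
        payload = {"metadata": metadata, "rows": frame.to_dict(orient="records")}
        import json

        path.write_text(json.dumps(payload, indent=2, default=float) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}; use 'csv' or 'json'")
    return path
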