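"""Normative reference for right−left hippocampal subfield asymmetry.

The normative model is deliberately simple: in healthy controls, for each
scored region (19 subregions + 3 combined labels) the per-subject
right − left volume difference is treated as Gaussian, summarised by its
mean and sample SD. A patient's difference is then standardised against that
reference. Because the contrast is within-subject, global determinants of
hippocampal size — age, sex, total brain volume — cancel and need no
explicit adjustment; the price is that only unilateral pathology is
detectable.

A packaged reference estimated from 20 healthy controls is shipped for both
sequence variants; :func:`build_reference` produces the same object from any
healthy cohort. :func:`symmetry_screen` checks the model's premise — no
systematic left/right difference in the reference cohort — with paired
t-tests under Holm–Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._tables import scored_wide
from .datasets import _load_resource
from .io import CohortTable
from .regions import canonical_hierarchy, canonical_sequence

__all__ = [
    "NormativeReference",
    "SymmetryScreen",
    "packaged_reference",
    "build_reference",
    "symmetry_screen",
]


@dataclass
class NormativeReference:
    """Per-region mean/SD (mm^3) of healthy right−left volume differences."""

    sequence: str
    n_controls: int
    rows: pd.DataFrame  # index: region; columns: mean_mm3, sd_mm3
    source: str = "built"

    def __post_init__(self) -> None:
        self.sequence = canonical_sequence(self.sequence)
        hierarchy = canonical_hierarchy()
        expected = list(hierarchy.scored_regions)
        got = list(self.rows.index)
        if sorted(got) != sorted(expected):
            raise ValueError(
                "normative reference must cover exactly the 22 scored regions"
            )
        self.rows = self.rows.loc[expected]
        bad = self.rows.index[self.rows["sd_mm3"] <= 0]
        if len(bad):
            raise ValueError(
                f"non-positive normative SD for regions: {', '.join(bad)}"
            )

    def row(self, region: str) -> tuple[float, float]:
        region = canonical_hierarchy().resolve(region)
        r = self.rows.loc[region]
        return float(r["mean_mm3"]), float(r["sd_mm3"])

    @property
    def metadata(self) -> dict:
        return {
            "sequence": self.sequence,
            "n_controls": self.n_controls,
            "source": self.source,
        }

    def to_frame(self) -> pd.DataFrame:
        out = self.rows.reset_index().rename(columns={"index": "region"})
        out["sequence"] = self.sequence
        out["n_controls"] = self.n_controls
        return out


def packaged_reference(sequence: str) -> NormativeReference:
    """The shipped 20-control normative reference for one sequence variant."""
    sequence = canonical_sequence(sequence)
    raw = _load_resource("normative_reference.json")
    rows = pd.DataFrame.from_dict(
        {region: vals[sequence] for region, vals in raw["rows"].items()},
        orient="index",
        columns=["mean_mm3", "sd_mm3"],
    )
    rows.index.name = "region"
    return NormativeReference(
        sequence=sequence,
        n_controls=int(raw["n_controls"]),
        rows=rows,
        source="packaged",
    )


def _paired_sides(
    cohort: CohortTable, sequence: str, group: str | None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    if group is not None:
        cohort = cohort.restrict(group=group)
    right = scored_wide(cohort, sequence, "right")
    left = scored_wide(cohort, sequence, "left")
    common = right.index.intersection(left.index)
    if len(common) < 2:
        raise ValueError(
            f"need at least 2 subjects with both sides, got {len(common)}"
        )
    return right.loc[common], left.loc[common]


def build_reference(
    cohort: CohortTable, sequence: str, group: str | None = "healthy"
) -> NormativeReference:
    """Estimate the normative reference from a healthy cohort.

    Per scored region, the mean and sample SD (n−1 denominator) of the
    per-subject right − left differences. Regions with zero spread are
    rejected rather than silently passed, since they would make every
    patient's z infinite.
    """
    right, left = _paired_sides(cohort, sequence, group)
    diffs = right - left
    rows = pd.DataFrame(
        {"mean_mm3": diffs.mean(axis=0), "sd_mm3": diffs.std(axis=0, ddof=1)}
    )
    rows.index.name = "region"
    zero_sd = rows.index[rows["sd_mm3"] == 0]
    if len(zero_sd):
        raise ValueError(
            "zero variance of right-left differences for regions: "
            + ", ".join(zero_sd)
        )
    return NormativeReference(
        sequence=canonical_sequence(sequence),
        n_controls=len(diffs),
        rows=rows,
        source="built",
    )


@dataclass
class SymmetryScreen:
    """Region-wise paired test of right vs left volumes in a healthy cohort."""

    rows: pd.DataFrame  # columns: region, mean_diff, t, raw_p, corrected_p, cohens_d
    sequence: str
    n_subjects: int
    alpha: float

    @property
    def metadata(self) -> dict:
        return {
            "sequence": self.sequence,
            "n_subjects": self.n_subjects,
            "alpha": self.alpha,
        }

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()


def symmetry_screen(
    cohort: CohortTable,
    sequence: str,
    alpha: float = 0.05,
    group: str | None = "healthy",
) -> SymmetryScreen:
    """Verify the left/right symmetry assumption of the normative model.

    Per scored region a two-tailed paired t-test of right against left,
    Holm–Bonferroni corrected over the 22 regions of this sequence. Cohen's d
    (mean difference / SD of differences, the paired-contrast convention) is
    attached to rows that stay significant after correction.
    """
    from .stats import cohens_d_paired, holm_bonferroni, paired_ttest

    right, left = _paired_sides(cohort, sequence, group)
    records = []
    for region in right.columns:
        l = left[region].to_numpy()
        r = right[region].to_numpy()
        t, p = paired_ttest(l, r)  # differences are right - left
        records.append(
            {"region": region, "mean_diff": (r - l).mean(), "t": t, "raw_p": p,
             "_l": l, "_r": r}
        )
    rows = pd.DataFrame.from_records(records)
    rows["corrected_p"] = holm_bonferroni(rows["raw_p"].to_numpy())
    rows["cohens_d"] = [
        cohens_d_paired(row["_l"], row["_r"], mode="diff_sd")
        if row["corrected_p"] < alpha
        else np.nan
        for _, row in rows.iterrows()
    ]
    rows = rows.drop(columns=["_l", "_r"])
    return SymmetryScreen(
        rows=rows,
        sequence=canonical_sequence(sequence),
        n_subjects=len(right),
        alpha=alpha,
    )
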