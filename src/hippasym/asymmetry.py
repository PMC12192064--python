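"""Normative z-scoring of intra-individual hippocampal asymmetry.

For each scored region the statistic is

    z = ((right − left) − mean_healthy) / sd_healthy

with the reference mean/SD taken from a healthy-control
:class:`~hippasym.normative.NormativeReference` for the same sequence
variant. A region is flagged as pathological when z lies strictly outside
(−2, 2), the nominal 95% band of the normative Gaussian; the boundary values
±2 themselves are not flagged. Atrophy of the right hippocampus drives
differences (and z) negative.

Scoring a patient against a reference built from a different sequence
variant is refused unless explicitly overridden: systematic segmentation
offsets between variants would masquerade as asymmetry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .normative import NormativeReference, packaged_reference
from .regions import SideVolumes, aggregate, canonical_hierarchy

__all__ = [
    "AsymmetryResult",
    "AsymmetryReport",
    "z_from_difference",
    "zscore_asymmetry",
    "classify",
    "score_patient",
    "simulate_null_coverage",
]


@dataclass(frozen=True)
class AsymmetryResult:
    """One region's asymmetry: volumes, right−left difference, z, flag."""

    region: str
    right_volume: float
    left_volume: float
    diff: float
    z: float
    flagged: bool


@dataclass
class AsymmetryReport:
    """Per-patient asymmetry summary over the 22 scored regions."""

    subject_id: str
    sequence: str
    results: tuple[AsymmetryResult, ...]
    threshold: float
    n_subregions_flagged: int
    n_combined_flagged: int
    lateralization: str  # right_smaller | left_smaller | indeterminate

    @property
    def metadata(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "sequence": self.sequence,
            "threshold": self.threshold,
            "n_subregions_flagged": self.n_subregions_flagged,
            "n_combined_flagged": self.n_combined_flagged,
            "lateralization": self.lateralization,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "region": r.region,
                    "right_volume": r.right_volume,
                    "left_volume": r.left_volume,
                    "diff": r.diff,
                    "z": r.z,
                    "flagged": r.flagged,
                }
                for r in self.results
            ]
        )


def z_from_difference(
    diff: float, region: str, reference: NormativeReference
) -> float:
    """Standardise a right−left difference against the normative reference."""
    mean, sd = reference.row(region)
    return (float(diff) - mean) / sd


def zscore_asymmetry(
    right: SideVolumes,
    left: SideVolumes,
    reference: NormativeReference,
    threshold: float = 2.0,
    allow_sequence_mismatch: bool = False,
) -> list[AsymmetryResult]:
    """z-score all 22 regions of one patient against a normative reference.

    Both hemispheres must contain all 19 subregions; combined labels are
    aggregated before scoring. Flagging uses strict inequalities:
    ``flagged ⇔ |z| > threshold``.
    """
    if right.side != "right" or left.side != "left":
        raise ValueError("pass the right hemisphere first, then the left")
    if right.sequence != left.sequence:
        raise ValueError(
            f"hemisphere sequences differ: {right.sequence} vs {left.sequence}"
        )
    if right.sequence != reference.sequence and not allow_sequence_mismatch:
        raise ValueError(
            f"patient sequence {right.sequence} does not match reference "
            f"sequence {reference.sequence}; scoring across sequence variants "
            "is unreliable (pass allow_sequence_mismatch=True to override)"
        )
    hierarchy = canonical_hierarchy()
    r = aggregate(right, hierarchy).volumes
    l = aggregate(left, hierarchy).volumes
    results = []
    for region in hierarchy.scored_regions:
        diff = r[region] - l[region]
        z = z_from_difference(diff, region, reference)
        if not math.isfinite(z):
            raise ValueError(f"non-finite z for region {region!r}")
        results.append(
            AsymmetryResult(
                region=region,
                right_volume=r[region],
                left_volume=l[region],
                diff=diff,
                z=z,
                flagged=abs(z) > threshold,
            )
        )
    return results


def classify(
    results: Sequence[AsymmetryResult],
    threshold: float = 2.0,
    subject_id: str = "",
    sequence: str = "",
) -> AsymmetryReport:
    """Summarise per-region results into the per-patient report.

    Subregion and combined-label flags are counted separately (the merged
    HEAD/BODY/TAIL/FISSURE labels are not scored). Lateralization is
    ``right_smaller`` when every flagged region has a negative right−left
    difference, ``left_smaller`` when every one is positive, and
    ``indeterminate`` when flags are mixed or absent. It is a descriptive
    statement about volumes, not a seizure-origin call.
    """
    hierarchy = canonical_hierarchy()
    regions = [r.region for r in results]
    if len(set(regions)) != len(regions):
        raise ValueError("duplicate region rows in results")
    if set(regions) != set(hierarchy.scored_regions):
        raise ValueError("expected exactly the 22 scored regions")
    flagged = [r for r in results if abs(r.z) > threshold]
    n_sub = sum(1 for r in flagged if r.region in hierarchy.subregions)
    n_comb = len(flagged) - n_sub
    if flagged and all(r.diff < 0 for r in flagged):
        lateralization = "right_smaller"
    elif flagged and all(r.diff > 0 for r in flagged):
        lateralization = "left_smaller"
    else:
        lateralization = "indeterminate"
    # re-evaluate flags at this threshold so classify(threshold=t) is
    # self-consistent even if results were produced with another t
    results = tuple(
        AsymmetryResult(r.region, r.right_volume, r.left_volume, r.diff, r.z,
                        abs(r.z) > threshold)
        for r in results
    )
    return AsymmetryReport(
        subject_id=subject_id,
        sequence=sequence,
        results=results,
        threshold=threshold,
        n_subregions_flagged=n_sub,
        n_combined_flagged=n_comb,
        lateralization=lateralization,
    )


def score_patient(
    right: SideVolumes,
    left: SideVolumes,
    reference: NormativeReference | None = None,
    threshold: float = 2.0,
    allow_sequence_mismatch: bool = False,
) -> AsymmetryReport:
    """Convenience pipeline: z-score then classify one patient.

    With no explicit reference, the packaged 20-control reference matching
    the patient's sequence tag is used.
    """
    if reference is None:
        reference = packaged_reference(right.sequence)
    results = zscore_asymmetry(
        right, left, reference, threshold=threshold,
        allow_sequence_mismatch=allow_sequence_mismatch,
    )
    return classify(
        results, threshold=threshold, subject_id=right.subject_id,
        sequence=right.sequence,
    )


def simulate_null_coverage(
    reference: NormativeReference,
    n_subjects: int = 100_000,
    threshold: float = 2.0,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Empirical coverage of the |z| <= threshold band under the null.

    Draws per-region right−left differences from the reference's own
    Gaussian model — i.e. simulates healthy subjects — scores them against
    that same reference, and reports the fraction strictly inside
    (−threshold, threshold) per region plus a pooled row. The analytic value
    at threshold 2 is 2Φ(2) − 1 ≈ 95.45%.
    """
    rng = np.random.default_rng(rng)
    regions = list(reference.rows.index)
    means = reference.rows["mean_mm3"].to_numpy()
    sds = reference.rows["sd_mm3"].to_numpy()
    diffs = rng.normal(means, sds, size=(int(n_subjects), len(regions)))
    z = (diffs - means) / sds
    inside = (z > -threshold) & (z < threshold)
    frac = inside.mean(axis=0)
    out = pd.DataFrame({"region": regions, "fraction_inside": frac})
    pooled = pd.DataFrame(
        {"region": ["(pooled)"], "fraction_inside": [inside.mean()]}
    )
    return pd.concat([out, pooled], ignore_index=True)
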