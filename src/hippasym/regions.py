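"""Hippocampal subfield catalogue and label aggregation.

The FreeSurfer hippocampal-subfield pipeline reports 19 subregion volumes per
hemisphere. For reporting, those subregions are grouped into four merged
labels (HEAD, BODY, TAIL, FISSURE) and three combined labels obtained by
summing member subregions: the whole hippocampal head, the whole hippocampal
body, and the whole hippocampus (head + body + tail; the fissure is a CSF
space and is excluded from the whole-hippocampus sum).

Region names are messy in practice: FreeSurfer writes ``CA3-head`` where
published tables print ``CA2/3-Head``, capitalisation is inconsistent
(``CA1-Body`` but ``CA4-body``), and underscores and hyphens are used
interchangeably. A deterministic alias layer resolves all of these to one
canonical spelling so that volumes never silently fail to join.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "SIDES",
    "SEQUENCES",
    "UnknownRegionError",
    "MissingRegionError",
    "RegionHierarchy",
    "SideVolumes",
    "canonical_hierarchy",
    "canonical_sequence",
    "canonical_side",
    "aggregate",
]

SIDES = ("right", "left")
SEQUENCES = ("T2_TSE", "T2_TSE_DRB")

_SEQUENCE_ALIASES = {
    "t2_tse": "T2_TSE",
    "tse": "T2_TSE",
    "t2tse": "T2_TSE",
    "t2_tse_drb": "T2_TSE_DRB",
    "drb": "T2_TSE_DRB",
    "t2_tse_drb_": "T2_TSE_DRB",
    "t2tsedrb": "T2_TSE_DRB",
}

_SIDE_ALIASES = {"right": "right", "r": "right", "rh": "right",
                 "left": "left", "l": "left", "lh": "left"}


class UnknownRegionError(KeyError):
    """A region name that does not resolve to any canonical label."""


class MissingRegionError(KeyError):
    """A required subregion is absent from a volume map."""


def canonical_sequence(tag: str) -> str:
    """Resolve a sequence tag (``tse``, ``drb``, ``T2_TSE_DRB`` ...)."""
    key = str(tag).strip().lower().replace("-", "_").replace(" ", "_")
    try:
        return _SEQUENCE_ALIASES[key]
    except KeyError:
        raise ValueError(
            f"unknown sequence tag {tag!r}; expected one of {SEQUENCES}"
        ) from None


def canonical_side(tag: str) -> str:
    key = str(tag).strip().lower()
    try:
        return _SIDE_ALIASES[key]
    except KeyError:
        raise ValueError(f"unknown side {tag!r}; expected 'right' or 'left'") from None


def _normalize(name: str) -> str:
    """Case/separator-insensitive key used for alias resolution."""
    return name.strip().lower().replace("_", "-")


@dataclass(frozen=True)
class RegionHierarchy:
    """The fixed subregion catalogue and its aggregation structure.

    Attributes
    ----------
    subregions
        The 19 canonical subregion names, in catalogue (table) order.
    merged_labels
        HEAD/BODY/TAIL/FISSURE -> member subregions. The four merged labels
        partition the 19 subregions.
    combined_labels
        Combined label -> member subregions (already expanded, in catalogue
        order). The whole hippocampus has 18 members: everything except the
        fissure.
    aliases
        Normalised alternative spelling -> canonical name.
    """

    subregions: tuple[str, ...]
    merged_labels: Mapping[str, tuple[str, ...]]
    combined_labels: Mapping[str, tuple[str, ...]]
    aliases: Mapping[str, str] = field(default_factory=dict)

    @property
    def scored_regions(self) -> tuple[str, ...]:
        """The 22 regions that are z-scored: 19 subregions + 3 combined labels."""
        return self.subregions + tuple(self.combined_labels)

    @property
    def derived_labels(self) -> tuple[str, ...]:
        """All labels computed by aggregation (4 merged + 3 combined)."""
        return tuple(self.merged_labels) + tuple(self.combined_labels)

    def members(self, label: str) -> tuple[str, ...]:
        label = self.resolve(label)
        if label in self.merged_labels:
            return self.merged_labels[label]
        if label in self.combined_labels:
            return self.combined_labels[label]
        if label in self.subregions:
            return (label,)
        raise UnknownRegionError(label)

    def resolve(self, name: str) -> str:
        """Map any accepted spelling to the canonical region name."""
        key = _normalize(name)
        try:
            return self.aliases[key]
        except KeyError:
            raise UnknownRegionError(
                f"unknown region name {name!r} (no alias matches)"
            ) from None

    def __contains__(self, name: str) -> bool:
        try:
            self.resolve(name)
        except UnknownRegionError:
            return False
        return True


@dataclass
class SideVolumes:
    """Per-region volumes (mm^3) of one hemisphere of one subject/sequence."""

    subject_id: str
    side: str
    sequence: str
    volumes: dict[str, float]

    def __post_init__(self) -> None:
        self.side = canonical_side(self.side)
        self.sequence = canonical_sequence(self.sequence)
        hierarchy = canonical_hierarchy()
        resolved: dict[str, float] = {}
        for name, value in self.volumes.items():
            canon = hierarchy.resolve(name)
            if canon in resolved:
                raise ValueError(
                    f"duplicate region {canon!r} in volumes of subject "
                    f"{self.subject_id!r} ({name!r} after alias resolution)"
                )
            value = float(value)
            if not math.isfinite(value) or value < 0:
                raise ValueError(
                    f"volume for {canon!r} must be finite and non-negative, "
                    f"got {value!r}"
                )
            resolved[canon] = value
        self.volumes = resolved


@lru_cache(maxsize=1)
def canonical_hierarchy() -> RegionHierarchy:
    """The fixed 19-subregion hierarchy with merged and combined labels.

    Loaded from the packaged ``hierarchy.json`` resource so the membership
    lists can be audited without reading code.
    """
    raw = json.loads(
        resources.files("hippasym.data").joinpath("hierarchy.json").read_text()
    )
    subregions = tuple(raw["subregions"])
    merged = {k: tuple(v) for k, v in raw["merged_labels"].items()}

    # combined labels are declared in terms of merged labels; expand them
    # to subregion members, preserving catalogue order
    combined: dict[str, tuple[str, ...]] = {}
    for label, merged_refs in raw["combined_labels"].items():
        members: list[str] = []
        for ref in merged_refs:
            members.extend(merged[ref])
        combined[label] = tuple(sorted(members, key=subregions.index))

    aliases: dict[str, str] = {}
    for canon in (*subregions, *merged, *combined):
        aliases[_normalize(canon)] = canon
    for alt, canon in raw["aliases"].items():
        key = _normalize(alt)
        if key in aliases and aliases[key] != canon:
            raise ValueError(f"alias {alt!r} conflicts with {aliases[key]!r}")
        aliases[key] = canon

    return RegionHierarchy(
        subregions=subregions,
        merged_labels=merged,
        combined_labels=combined,
        aliases=aliases,
    )


def aggregate(
    volumes: SideVolumes, hierarchy: RegionHierarchy | None = None
) -> SideVolumes:
    """Add merged-label and combined-label sums to a subregion volume map.

    The input must contain all 19 subregions. Members are summed in catalogue
    order, which fixes floating-point associativity and makes
    ``Whole_hippocampus == Whole_hippocampal_head + Whole_hippocampal_body +
    Hippocampal_tail`` hold exactly. Input entries are never modified.
    """
    hierarchy = hierarchy or canonical_hierarchy()
    missing = [r for r in hierarchy.subregions if r not in volumes.volumes]
    if missing:
        raise MissingRegionError(
            f"subject {volumes.subject_id!r} ({volumes.side}) is missing "
            f"subregions: {', '.join(missing)}"
        )
    out = dict(volumes.volumes)
    for label in hierarchy.derived_labels:
        total = 0.0
        for member in hierarchy.members(label):
            total += out[member]
        out[label] = total
    # Whole_hippocampus must equal head + body + tail bit-for-bit; resumming
    # from the three parts (not the 18 members) guarantees it.
    out["Whole_hippocampus"] = (
        out["Whole_hippocampal_head"]
        + out["Whole_hippocampal_body"]
        + out["Hippocampal_tail"]
    )
    return replace(volumes, volumes=out)
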