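"""Synthetic morphometry cohorts with the structure the analysis assumes.

No imaging data accompany the published summaries, so every pipeline stage is
exercised on simulated cohorts built from the packaged per-region summary
statistics. The generative model per healthy subject and subregion:

* a latent bilateral volume ``B ~ Normal(base_mean, cv * base_mean)``;
* an anatomical asymmetry ``a ~ Normal(mu_region, sigma_region)`` split
  symmetrically around the latent mean: right = B + a/2, left = B − a/2
  (only the difference distribution is identified by the data; the split is
  a modelling convention);
* the second sequence variant re-measures the same anatomy with a
  per-subregion systematic shift plus extra measurement noise:
  ``v_drb = v_tse + shift + Normal(0, noise_sd)`` per hemisphere.

Patients additionally scale affected-side subregions by a pathology profile
interpolated by severity (severity 0 = healthy, 1 = the full profile). The
hippocampal-sclerosis profile is the right/left volume ratio of the packaged
worked example; the edema profile is a uniform 25% swelling. Combined labels
are never sampled — they are always derived downstream by aggregation.
Asymmetries are independent across regions, matching the per-region
univariate normative model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import load_sequence_comparison_summary
from .io import CohortTable
from .regions import canonical_hierarchy

__all__ = [
    "PathologyProfile",
    "CohortSpec",
    "hs_atrophy_profile",
    "edema_profile",
    "default_cohort_spec",
    "spec_from_yaml",
    "simulate_cohort",
]

PATHOLOGIES = ("HS_right", "HS_left", "edema_right", "edema_left", "none")

_PATHOLOGY_GROUP = {
    "HS_right": "HS",
    "HS_left": "HS",
    "edema_right": "edema",
    "edema_left": "edema",
    "none": "epilepsy_no_lesion",
}


@dataclass(frozen=True)
class PathologyProfile:
    """Per-subregion multiplicative volume factors on the affected side."""

    name: str
    factors: Mapping[str, float]

    def __post_init__(self) -> None:
        hierarchy = canonical_hierarchy()
        missing = set(hierarchy.subregions) - set(self.factors)
        if missing:
            raise ValueError(f"profile {self.name!r} missing factors: {missing}")
        bad = {r: f for r, f in self.factors.items() if not (0 < f <= 2)}
        if bad:
            raise ValueError(f"profile factors must lie in (0, 2]: {bad}")

    def at_severity(self, severity: float) -> np.ndarray:
        """Factors linearly interpolated between identity (0) and full (1)."""
        if not 0 <= severity <= 1:
            raise ValueError("severity must lie in [0, 1]")
        hierarchy = canonical_hierarchy()
        full = np.array([self.factors[r] for r in hierarchy.subregions])
        return 1.0 + severity * (full - 1.0)


def hs_atrophy_profile() -> PathologyProfile:
    """Hippocampal-sclerosis atrophy profile from the packaged worked example.

    Per subregion, the factor is the right/left volume ratio of the published
    right-sided HS case (e.g. CA4-body 40.6/103.4 ≈ 0.393), i.e. the
    relative shrinkage the lesion imposed on the affected side.
    """
    from .datasets import load_worked_example

    hierarchy = canonical_hierarchy()
    df = load_worked_example().set_index("region")
    factors = {
        region: float(df.loc[region, "right"] / df.loc[region, "left"])
        for region in hierarchy.subregions
    }
    return PathologyProfile(name="HS", factors=factors)


def edema_profile(swelling: float = 1.25) -> PathologyProfile:
    """Uniform swelling of all subregions on the affected side (default +25%)."""
    hierarchy = canonical_hierarchy()
    return PathologyProfile(
        name="edema", factors={r: swelling for r in hierarchy.subregions}
    )


@dataclass
class CohortSpec:
    """Complete specification of one synthetic cohort.

    ``base_means`` (mm^3), ``asymmetry_params`` (region -> (mu, sigma), mm^3)
    and ``sequence_effects`` (region -> (shift, extra-noise SD), mm^3) are
    per-subregion maps; ``between_subject_cv`` scales each region's
    cross-subject SD as a fraction of its base mean. ``patients`` is a list
    of (pathology, severity) pairs appended to the ``n_healthy`` controls.
    """

    n_healthy: int
    patients: tuple[tuple[str, float], ...] = ()
    base_means: Mapping[str, float] = field(default_factory=dict)
    between_subject_cv: float = 0.10
    asymmetry_params: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    sequence_effects: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        hierarchy = canonical_hierarchy()
        if self.n_healthy < 0 or self.n_healthy + len(self.patients) == 0:
            raise ValueError("cohort must contain at least one subject")
        if self.between_subject_cv <= 0:
            raise ValueError("between_subject_cv must be positive")
        for mapping, what in (
            (self.base_means, "base_means"),
            (self.asymmetry_params, "asymmetry_params"),
            (self.sequence_effects, "sequence_effects"),
        ):
            missing = set(hierarchy.subregions) - set(mapping)
            if missing:
                raise ValueError(f"{what} missing subregions: {sorted(missing)}")
        # sigma 0 is allowed so degenerate, exactly-symmetric cohorts can be
        # generated to exercise downstream zero-variance handling
        if any(sigma < 0 for _, sigma in self.asymmetry_params.values()):
            raise ValueError("asymmetry sigmas must be non-negative")
        if any(sd < 0 for _, sd in self.sequence_effects.values()):
            raise ValueError("sequence extra-noise SDs must be non-negative")
        for pathology, severity in self.patients:
            if pathology not in PATHOLOGIES:
                raise ValueError(f"unknown pathology {pathology!r}")
            if not 0 <= severity <= 1:
                raise ValueError("severity must lie in [0, 1]")


def default_cohort_spec(
    n_healthy: int = 20,
    patients: Sequence[tuple[str, float]] = (),
    seed: int = 0,
    **overrides,
) -> CohortSpec:
    """A spec calibrated to the packaged published summaries.

    Base means are each subregion's right/left average volume under the
    conventional sequence; asymmetry parameters are the packaged DRB
    normative mean/SD; sequence effects are the published right-hippocampus
    mean-difference and SD columns (so the generator reproduces the published
    detectable-shift regime, e.g. CA1-Body +2 mm^3 with SD 2.6). Keyword
    overrides replace whole fields.
    """
    from .normative import packaged_reference

    hierarchy = canonical_hierarchy()
    summary = load_sequence_comparison_summary()
    right = summary[summary["side"] == "right"].set_index("region")
    left = summary[summary["side"] == "left"].set_index("region")
    base_means = {
        r: float((right.loc[r, "mean_tse"] + left.loc[r, "mean_tse"]) / 2)
        for r in hierarchy.subregions
    }
    ref = packaged_reference("T2_TSE_DRB")
    asymmetry_params = {
        r: (float(ref.rows.loc[r, "mean_mm3"]), float(ref.rows.loc[r, "sd_mm3"]))
        for r in hierarchy.subregions
    }
    sequence_effects = {
        r: (float(right.loc[r, "mean_diff"]), float(right.loc[r, "sd_diff"]))
        for r in hierarchy.subregions
    }
    fields = dict(
        n_healthy=n_healthy,
        patients=tuple((p, float(s)) for p, s in patients),
        base_means=base_means,
        asymmetry_params=asymmetry_params,
        sequence_effects=sequence_effects,
        seed=seed,
    )
    fields.update(overrides)
    return CohortSpec(**fields)


def spec_from_yaml(path) -> CohortSpec:
    """Load a CohortSpec from YAML; omitted fields fall back to defaults."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    patients = tuple(
        (p["pathology"], float(p.get("severity", 1.0)))
        for p in raw.pop("patients", [])
    )
    kwargs = {}
    for key in ("base_means", "between_subject_cv", "seed"):
        if key in raw:
            kwargs[key] = raw.pop(key)
    for key in ("asymmetry_params", "sequence_effects"):
        if key in raw:
            kwargs[key] = {r: tuple(v) for r, v in raw.pop(key).items()}
    n_healthy = int(raw.pop("n_healthy", 20))
    if raw:
        raise ValueError(f"unknown keys in cohort spec: {sorted(raw)}")
    return default_cohort_spec(n_healthy=n_healthy, patients=patients, **kwargs)


def _profile_for(pathology: str) -> PathologyProfile | None:
    if pathology.startswith("HS"):
        return hs_atrophy_profile()
    if pathology.startswith("edema"):
        return edema_profile()
    return None


def simulate_cohort(spec: CohortSpec) -> CohortTable:
    """Draw one cohort from the spec; identical spec+seed is byte-identical.

    Returns a long-format :class:`CohortTable` with the 19 subregions under
    both sequence variants and both sides. Negative draws are clipped to 0
    with a warning (negligible at default parameters).
    """
    hierarchy = canonical_hierarchy()
    regions = list(hierarchy.subregions)
    k = len(regions)
    n = spec.n_healthy + len(spec.patients)
    rng = np.random.default_rng(spec.seed)

    base = np.array([spec.base_means[r] for r in regions])
    mu = np.array([spec.asymmetry_params[r][0] for r in regions])
    sigma = np.array([spec.asymmetry_params[r][1] for r in regions])
    shift = np.array([spec.sequence_effects[r][0] for r in regions])
    noise_sd = np.array([spec.sequence_effects[r][1] for r in regions])

    latent = rng.normal(base, spec.between_subject_cv * base, size=(n, k))
    asym = rng.normal(mu, sigma, size=(n, k))
    right_tse = latent + asym / 2.0
    left_tse = latent - asym / 2.0

    # pathology: multiplicative factors on the affected side, applied to the
    # anatomy (hence carried into both sequence variants)
    subject_ids = [f"H{i + 1:03d}" for i in range(spec.n_healthy)]
    groups = ["healthy"] * spec.n_healthy
    for j, (pathology, severity) in enumerate(spec.patients):
        i = spec.n_healthy + j
        subject_ids.append(f"P{j + 1:03d}")
        groups.append(_PATHOLOGY_GROUP[pathology])
        profile = _profile_for(pathology)
        if profile is not None:
            factors = profile.at_severity(severity)
            if pathology.endswith("right"):
                right_tse[i] *= factors
            else:
                left_tse[i] *= factors

    right_drb = right_tse + shift + rng.normal(0.0, 1.0, size=(n, k)) * noise_sd
    left_drb = left_tse + shift + rng.normal(0.0, 1.0, size=(n, k)) * noise_sd

    stacks = {
        ("T2_TSE", "right"): right_tse,
        ("T2_TSE", "left"): left_tse,
        ("T2_TSE_DRB", "right"): right_drb,
        ("T2_TSE_DRB", "left"): left_drb,
    }
    n_clipped = sum(int((m < 0).sum()) for m in stacks.values())
    if n_clipped:
        warnings.warn(
            f"clipped {n_clipped} negative simulated volumes to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    frames = []
    for (sequence, side), matrix in stacks.items():
        matrix = np.clip(matrix, 0.0, None)
        frame = pd.DataFrame(matrix, columns=regions)
        frame.insert(0, "subject_id", subject_ids)
        frame.insert(1, "group", groups)
        frame.insert(2, "sequence", sequence)
        frame.insert(3, "side", side)
        frames.append(
            frame.melt(
                id_vars=["subject_id", "group", "sequence", "side"],
                var_name="region",
                value_name="volume_mm3",
            )
        )
    records = pd.concat(frames, ignore_index=True)
    return CohortTable(
        records,
        provenance=f"simulated cohort (seed={spec.seed}, n={n})",
    )
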