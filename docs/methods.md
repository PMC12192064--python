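# Methods

## The normative asymmetry model

For each scored hippocampal region r the model treats the healthy
within-subject right−left volume difference d_r = V_right − V_left (mm³) as
Gaussian, d_r ~ N(μ_r, σ_r), with parameters estimated per region and per
MRI sequence variant from a healthy-control cohort (sample SD, n−1
denominator — conventional for small reference cohorts). A patient's
difference is standardised, z_r = (d_r − μ_r)/σ_r, and flagged when z_r
falls strictly outside (−2, 2), the 95.45% band of the standard normal;
the boundary values ±2 are deliberately not flagged (strict inequalities).

The 22 scored regions are the 19 FreeSurfer subregions plus three combined
labels derived by summation: whole hippocampal head (9 members), whole
hippocampal body (8), whole hippocampus (head + body + tail, 18 — the
hippocampal fissure is CSF and is excluded). Combined labels get their own
normative rows rather than being a function of member z-scores; member sums
are accumulated in catalogue order and the whole hippocampus is re-summed
from the head, body and tail totals, so the identity
whole = head + body + tail holds bit-for-bit. The merged HEAD/BODY/TAIL/
FISSURE labels are computed and reported but not scored, mirroring the
scored surface of the packaged reference.

Assumptions, and what they buy: the within-subject contrast cancels global
determinants of hippocampal size (age, sex, total intracranial volume), so
no covariate model is needed; each region is modelled univariately
(cross-region correlation of asymmetries is ignored); and pathology is
assumed unilateral — a symmetric bilateral process shifts both hemispheres
equally and leaves z unchanged. Per-side (bilateral-capable) normative
modelling would need a much larger control cohort and is out of scope.

Lateralization is reported descriptively from the signs of flagged
differences (`right_smaller` when every flagged region has d < 0,
`left_smaller` when every one has d > 0, `indeterminate` otherwise); no
seizure-origin claim is attached.

## Sequence handling

Volumes carry a mandatory sequence tag (`T2_TSE` or `T2_TSE_DRB`). Scoring
a patient against a reference from the other variant is a hard error with
an explicit `allow_sequence_mismatch` override, because systematic
segmentation offsets between variants (see below) would masquerade as
asymmetry. The packaged reference ships both variants' columns.

## The worked example and printed-precision arithmetic

The packaged worked example (a right-sided hippocampal sclerosis case,
DRB sequence) prints volumes, differences and z to one decimal. The printed
difference column was computed from unrounded volumes before printing, so
in four rows it differs by 0.1 mm³ from the difference of the two rounded
volumes; for one region (CA4-body, printed difference −62.7 vs
40.6 − 103.4 = −62.8) that single print unit moves the rounded z from −5.2
to −5.3. The worked-example reproduction therefore standardises the printed
per-region difference — the closest available estimate of the exact input —
while combined labels are aggregated from the printed subregion volumes
(either route reproduces their printed z). The general API takes volumes;
`z_from_difference` exposes the difference route. Aggregated combined
labels on 1-decimal inputs are allowed ±0.3 mm³ against printed combined
values (rounding of up to 18 addends).

A related note: the source narrative counts 15 flagged subregions for this
case under DRB, but recomputation from the printed tables gives 13
(matching the table's own bold marking); the package reports 13.

## Sequence-comparison protocol

Per scored region and side, a two-tailed paired t-test compares the
per-subject volumes under the two variants. Holm–Bonferroni is applied over
the whole family run in one invocation (44 = 22 regions × 2 sides by
default), corrected values capped at 1. Cohen's d is attached only to rows
significant after correction; the default denominator is the pooled SD
√((var_a + var_b)/2), which measures the shift on the raw volume scale —
the paired diff-SD convention is exposed as an option (it is the default
for the left/right symmetry screen, where the within-subject contrast is
the quantity of interest). Cross-sequence variability is screened by
pairing each region's cross-subject variance under the two variants in a
Wilcoxon signed-rank test; the construction of this variance comparison is
a package choice and the operation is separately named so it can be
bypassed.

Statistical cores are deliberately thin wrappers where a standard library
pins the convention (t and Shapiro–Wilk from scipy, Holm from statsmodels).
The Wilcoxon signed-rank test is implemented in-package so its conventions
are explicit: zero differences dropped before ranking, midranks for ties,
exact generating-function null for effective n ≤ 25 without tied ranks,
normal approximation with continuity and tie correction otherwise; the test
suite cross-checks it against exhaustive sign-flip enumeration and scipy.
Degenerate inputs are resolved explicitly: identical paired samples give
t = 0, p = 1; zero spread around a nonzero mean gives p → 0 with a warning;
an all-zero-difference Wilcoxon is an error, except in the whole-table
variance screen where identical variances are reported as (W = 0, p = 1).

## Synthetic cohorts

The generator exists so every stage is testable without scan data. Per
healthy subject and subregion: latent bilateral volume
B ~ N(base, cv·base); asymmetry a ~ N(μ_r, σ_r) split symmetrically
(right = B + a/2, left = B − a/2 — only the difference distribution is
identified, the split is a convention); the second variant re-measures with
v_drb = v_tse + shift_r + N(0, noise_r) per hemisphere. Patients scale
affected-side subregions by a severity-interpolated profile
(1 + s·(f_r − 1)); the HS profile's factors are the worked example's
right/left ratios (e.g. CA4-body ≈ 0.39), the edema profile a uniform 1.25
swelling. Combined labels are never sampled, always derived. Volumes are
clipped at 0 with a warning; at the defaults the truncation probability is
negligible.

Defaults are fixed once from the packaged summaries: base means are each
subregion's right/left average volume under the conventional sequence;
asymmetry (μ_r, σ_r) are the packaged DRB normative columns; sequence
effects are the published right-hippocampus mean-difference and SD columns
(so the default cohort sits in the published detectable-shift regime: the
CA1-Body +2 mm³ / SD 2.6 and CA4-body −3 mm³ / SD 3.3 shifts are
recovered as the significant rows at n in the 20–36 range).
Between-subject CV defaults to 0.10 — cross-subject volume SDs are not
published, so this is a free calibration knob, documented as such. σ_r = 0
is allowed so exactly-symmetric degenerate cohorts can exercise the
zero-variance error paths. Asymmetries are independent across regions,
matching the univariate normative model; real subfield asymmetries are
likely correlated within subject, so simulated whole-hippocampus power is
only an approximation of real-data behaviour. The generator also does not
model segmentation failure, motion artefacts, or non-Gaussian asymmetry
tails — passing tests certify the pipeline's arithmetic and its statistical
calibration under the stated model, not robustness to those effects.

## Problem sizes and numerical choices

Simulation-based tests use fixed seeds and the following sizes, chosen to
give comfortable Monte-Carlo margins: parameter recovery on 1,500–2,000
subject cohorts (mean within 4σ/√n, SD within 10%); null coverage of the
z band at 10⁵ subjects × 22 regions (pooled coverage within 0.5 percentage
points of the analytic 95.45%); family-wise error of the Holm-corrected
screens at 150–200 replicate cohorts against a binomial upper bound; power
of single-region shifts at 100–200 replicates, point claims of "≥ 90%"
checked either directly (where the margin is wide) or against a one-sided
95% Monte-Carlo binomial bound. Stochastic properties are asserted with
explicit sampling-error allowances rather than exact values.

## Known limitations

Only unilateral effects are detectable; the 19-region catalogue is fixed to
the FreeSurfer hippocampal-subfield stream (no amygdala, no alternative
atlases); reference and patient must share a sequence variant; printed
1-decimal inputs limit worked-example agreement to one print unit; and the
normative reference ships with n = 20 controls — sampling error in μ_r and
σ_r themselves is not propagated into z.
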