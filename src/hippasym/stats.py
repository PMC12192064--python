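"""Paired statistical protocol for comparing two MRI sequence variants.

Per scored region the pipeline runs a two-tailed paired t-test on the
per-subject volumes from the two sequences, applies the Holm–Bonferroni
step-down correction across the whole family of tests in the invocation
(capped at 1), and attaches a Cohen's d effect size to rows that remain
significant. Cross-sequence variability is additionally screened with a
Wilcoxon signed-rank test on per-region cross-subject variances, paired by
region; normality of any quantity can be checked with Shapiro–Wilk.

The scalar tests are thin, convention-pinned wrappers: t and Shapiro–Wilk
p-values come from scipy, Holm from statsmodels. The Wilcoxon signed-rank
test is implemented here directly — zeros dropped before ranking, midranks
for ties, generating-function exact null for n ≤ 25 when there are no tied
ranks, normal approximation with continuity and tie correction otherwise —
so the convention is explicit and stable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from ._tables import scored_wide
from .io import CohortTable
from .regions import canonical_hierarchy, canonical_sequence, canonical_side

__all__ = [
    "paired_ttest",
    "wilcoxon_signed_rank",
    "shapiro_wilk",
    "holm_bonferroni",
    "cohens_d_paired",
    "ComparisonTable",
    "compare_sequences",
]


def paired_ttest(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-tailed paired t-test of y against x.

    Returns ``(t, p)`` with ``t = mean(d) / (sd(d)/sqrt(n))`` for the
    per-subject differences ``d = y - x`` (sample SD, n-1 denominator) and a
    two-tailed p from Student's t with n-1 degrees of freedom.

    Degenerate differences are resolved explicitly: all differences zero
    gives ``(0, 1)``; zero spread around a nonzero mean gives ``(±inf, 0)``
    with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1-d and of equal length")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test requires n >= 2")
    d = y - x
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return 0.0, 1.0
        warnings.warn(
            "zero variance of paired differences with nonzero mean; p -> 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.copysign(math.inf, d.mean()), 0.0
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def _signed_rank_statistic(d: np.ndarray) -> tuple[float, np.ndarray]:
    """Sum of positive midranks of |d| and the rank vector."""
    ranks = sps.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    return float(w_plus), ranks


def _exact_signed_rank_sf_table(n: int) -> np.ndarray:
    """Null counts of W+ over all 2^n sign assignments (integer ranks 1..n).

    Classic generating-function recurrence: the number of sign subsets of
    {1..n} summing to w.
    """
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1, dtype=float)
    counts[0] = 1.0
    for rank in range(1, n + 1):
        counts[rank:] += counts[: max_w + 1 - rank].copy()
    return counts


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-tailed Wilcoxon signed-rank test of paired samples.

    Differences ``d = y - x``; zero differences are dropped before ranking
    (Wilcoxon's original treatment) and tied absolute differences receive
    midranks. Returns ``(W, p)`` where W is the sum of ranks of positive
    differences. The p-value uses the exact null distribution when the
    effective n is at most 25 and all ranks are distinct integers, and a
    normal approximation with continuity and tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1-d and of equal length")
    d = y - x
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero; test undefined")
    w_plus, ranks = _signed_rank_statistic(d)
    has_ties = np.unique(ranks).size != n
    if n <= 25 and not has_ties:
        counts = _exact_signed_rank_sf_table(n)
        total = counts.sum()  # 2^n
        w = int(round(w_plus))
        cdf = counts[: w + 1].sum() / total
        sf = counts[w:].sum() / total
        p = min(1.0, 2.0 * min(cdf, sf))
        return w_plus, float(p)
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        raise ValueError("degenerate rank variance (all differences tied)")
    # continuity correction toward the null mean
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return w_plus, float(min(1.0, p))


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk normality test (Royston's approximation via scipy)."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or not (3 <= values.size <= 5000):
        raise ValueError("Shapiro–Wilk requires a 1-d sample with 3 <= n <= 5000")
    if np.ptp(values) == 0.0:
        raise ValueError("Shapiro–Wilk is undefined for a constant sample")
    res = sps.shapiro(values)
    return float(res.statistic), float(res.pvalue)


def holm_bonferroni(raw_ps: Sequence[float]) -> np.ndarray:
    """Holm–Bonferroni step-down correction, capped at 1.

    For ascending p_(1) <= ... <= p_(m), the corrected value of p_(i) is
    ``max_{j<=i} (m-j+1) * p_(j)``, capped at 1; values are returned in the
    original order.
    """
    raw = np.asarray(raw_ps, dtype=float)
    if raw.ndim != 1 or raw.size == 0:
        raise ValueError("expected a non-empty 1-d array of p-values")
    if np.any((raw < 0) | (raw > 1)) or np.any(np.isnan(raw)):
        raise ValueError("p-values must lie in [0, 1]")
    _, corrected, _, _ = multipletests(raw, method="holm")
    return corrected


def cohens_d_paired(
    x: Sequence[float], y: Sequence[float], mode: str = "pooled_sd"
) -> float:
    """Paired Cohen's d of y against x.

    ``diff_sd`` standardises the mean difference by the SD of the paired
    differences; ``pooled_sd`` by ``sqrt((var(x) + var(y)) / 2)``, which
    measures the shift on the scale of the raw volumes and stays small for a
    systematic but consistent offset.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("paired samples must be 1-d, equal length, n >= 2")
    d = y - x
    if mode == "diff_sd":
        denom = d.std(ddof=1)
    elif mode == "pooled_sd":
        denom = math.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2.0)
    else:
        raise ValueError("mode must be 'diff_sd' or 'pooled_sd'")
    if denom == 0.0:
        raise ValueError(f"zero denominator for Cohen's d in mode {mode!r}")
    return float(d.mean() / denom)


@dataclass
class ComparisonTable:
    """Per-region paired-test results for one sequence-vs-sequence run.

    ``rows`` columns: side, region, mean_vol_a, mean_vol_b, mean_diff (mean of
    per-subject b - a), sd_diff, t, raw_p, corrected_p, cohens_d (NaN unless
    corrected_p < alpha). ``variance_test`` holds the per-side Wilcoxon
    signed-rank result on per-region cross-subject variances.
    """

    rows: pd.DataFrame
    n_subjects: int
    family_size: int
    alpha: float
    sequence_a: str
    sequence_b: str
    effect_size_mode: str
    variance_test: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def metadata(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "family_size": self.family_size,
            "alpha": self.alpha,
            "sequence_a": self.sequence_a,
            "sequence_b": self.sequence_b,
            "effect_size_mode": self.effect_size_mode,
            "variance_test": {
                side: {"W": w, "p": p} for side, (w, p) in self.variance_test.items()
            },
        }

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()


def compare_sequences(
    cohort: CohortTable,
    side: str = "both",
    sequence_a: str = "T2_TSE",
    sequence_b: str = "T2_TSE_DRB",
    alpha: float = 0.05,
    effect_size_mode: str = "pooled_sd",
) -> ComparisonTable:
    """Region-wise paired comparison of two sequence variants.

    Every subject must carry both sequences and both requested sides. Per
    scored region (19 subregions + 3 combined labels, aggregated first) a
    paired t-test of sequence_b against sequence_a is run; Holm–Bonferroni is
    applied jointly over all tests in this invocation (44 when
    ``side='both'``); Cohen's d is attached only where the corrected p falls
    below ``alpha``. The per-side variance comparison pairs each region's
    cross-subject variance under the two sequences in a Wilcoxon signed-rank
    test.
    """
    sequence_a = canonical_sequence(sequence_a)
    sequence_b = canonical_sequence(sequence_b)
    if sequence_a == sequence_b:
        raise ValueError("sequence_a and sequence_b must differ")
    sides = ("right", "left") if side == "both" else (canonical_side(side),)
    hierarchy = canonical_hierarchy()

    records = []
    variance_test: dict[str, tuple[float, float]] = {}
    n_subjects = None
    for s in sides:
        wide_a = scored_wide(cohort, sequence_a, s, hierarchy)
        wide_b = scored_wide(cohort, sequence_b, s, hierarchy)
        common = wide_a.index.intersection(wide_b.index)
        if len(common) < len(wide_a) or len(common) < len(wide_b):
            missing = wide_a.index.symmetric_difference(wide_b.index)
            raise ValueError(
                f"incomplete sequence pairing for subjects: {list(missing)}"
            )
        wide_a, wide_b = wide_a.loc[common], wide_b.loc[common]
        n_subjects = len(common)
        for region in hierarchy.scored_regions:
            a = wide_a[region].to_numpy()
            b = wide_b[region].to_numpy()
            t, p = paired_ttest(a, b)
            diffs = b - a
            records.append(
                {
                    "side": s,
                    "region": region,
                    "mean_vol_a": a.mean(),
                    "mean_vol_b": b.mean(),
                    "mean_diff": diffs.mean(),
                    "sd_diff": diffs.std(ddof=1),
                    "t": t,
                    "raw_p": p,
                    "_a": a,
                    "_b": b,
                }
            )
        var_a = wide_a.var(ddof=1).to_numpy()
        var_b = wide_b.var(ddof=1).to_numpy()
        if np.array_equal(var_a, var_b):
            # identical variances in every region: no evidence either way
            variance_test[s] = (0.0, 1.0)
        else:
            variance_test[s] = wilcoxon_signed_rank(var_a, var_b)

    rows = pd.DataFrame.from_records(records)
    rows["corrected_p"] = holm_bonferroni(rows["raw_p"].to_numpy())
    d_values = []
    for _, row in rows.iterrows():
        if row["corrected_p"] < alpha:
            d_values.append(cohens_d_paired(row["_a"], row["_b"], effect_size_mode))
        else:
            d_values.append(np.nan)
    rows["cohens_d"] = d_values
    rows = rows.drop(columns=["_a", "_b"])

    return ComparisonTable(
        rows=rows,
        n_subjects=int(n_subjects),
        family_size=len(rows),
        alpha=alpha,
        sequence_a=sequence_a,
        sequence_b=sequence_b,
        effect_size_mode=effect_size_mode,
        variance_test=variance_test,
    )
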