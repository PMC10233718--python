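"""Genotype group comparisons of per-section measurements.

Sections are the unit of analysis: each tissue section contributes one
value per measurement (e.g. spots-per-cell for one gene), and mutant
cohorts are compared against wild-type with

* a two-sided Mann-Whitney / Wilcoxon rank-sum test for location shifts
  (exact enumeration for small tie-free samples, normal approximation with
  tie correction otherwise), and
* a two-sided variance-ratio F test for changes in spread (the range of
  expression), flagged separately from location significance.

No multiple-testing correction is applied by default — results are reported
per gene — but Benjamini-Hochberg adjustment is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "rank_sum_test",
    "variance_ratio_test",
    "significance_stars",
    "annotate",
    "compare_groups",
]

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def rank_sum_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney rank-sum p-value.

    Exact null enumeration when the combined sample is small (n <= 20) and
    tie-free; otherwise the normal approximation with tie correction and
    continuity correction.  Deterministic.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    if np.ptp(combined) == 0:
        return 1.0  # identical constant samples: no evidence of a shift
    method = "exact" if (len(combined) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if not np.isfinite(p):
        return 1.0
    return min(p, 1.0)


def variance_ratio_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided F test on the ratio of sample variances.

    F is the larger variance over the smaller (so F >= 1) with matching
    degrees of freedom; the two-sided p doubles the upper tail.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = float(np.var(a, ddof=1)), float(np.var(b, ddof=1))
    if va == 0 and vb == 0:
        raise ValueError("both samples have zero variance; F undefined")
    if va >= vb:
        F, dfn, dfd = (va / vb if vb > 0 else np.inf), len(a) - 1, len(b) - 1
    else:
        F, dfn, dfd = vb / va, len(b) - 1, len(a) - 1
    p = 2.0 * float(stats.f.sf(F, dfn, dfd)) if np.isfinite(F) else 0.0
    return float(F), min(p, 1.0)


def significance_stars(p: float) -> str:
    """Star code for a p-value: ns / * / ** / *** / ****."""
    if not np.isfinite(p):
        return "ns"
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"


def annotate(comparisons: pd.DataFrame, bh_correction: bool = False) -> pd.DataFrame:
    """Attach star annotations to a table of computed p-values.

    Expects ``p_location`` and optionally ``p_variance`` columns; raw
    p-values are always retained alongside the annotations.  With
    ``bh_correction`` the location p-values are Benjamini-Hochberg adjusted
    first (off by default: per-gene reporting).
    """
    out = comparisons.copy()
    p = out["p_location"].astype(float)
    if bh_correction and len(p):
        out["p_location_adj"] = _benjamini_hochberg(p.to_numpy())
        p = out["p_location_adj"]
    out["stars"] = [significance_stars(v) for v in p]
    if "p_variance" in out.columns:
        out["variance_star"] = out["p_variance"].astype(float) < 0.05
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        val = min(prev, p[i] * m / (rank_idx + 1))
        adj[i] = val
        prev = val
    return adj


def compare_groups(values: pd.DataFrame, reference: str,
                   measurement_col: str = "measurement",
                   group_col: str = "genotype",
                   value_col: str = "value",
                   bh_correction: bool = False) -> pd.DataFrame:
    """Compare every non-reference group against the reference group.

    ``values`` is tidy: one row per section with measurement name, group
    label and value.  Returns one row per (measurement, group) with the
    rank-sum p-value, the F statistic and p-value, and star annotations.
    """
    rows = []
    for meas, sub in values.groupby(measurement_col):
        ref = sub.loc[sub[group_col] == reference, value_col].to_numpy(float)
        if len(ref) == 0:
            raise ValueError(f"no reference ({reference!r}) sections for {meas!r}")
        for grp, g in sub.groupby(group_col):
            if grp == reference:
                continue
            test = g[value_col].to_numpy(float)
            p_loc = rank_sum_test(test, ref)
            try:
                F, p_var = variance_ratio_test(test, ref)
            except ValueError:
                F, p_var = float("nan"), float("nan")
            rows.append(dict(measurement=meas, group=grp, reference=reference,
                             n_group=len(test), n_reference=len(ref),
                             p_location=p_loc, F=F, p_variance=p_var))
    return annotate(pd.DataFrame(rows), bh_correction=bh_correction)
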