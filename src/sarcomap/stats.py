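"""Small-cohort statistics relating imaging summaries to histology.

The layer mirrors a three-visit imaging study design: per-patient medians
of T1, ADC and iAUC60 (plus tumour volume) at up to three visits, joined to
per-patient histology (CD31, Ki67, HIF, hypoxia score, CAIX positivity).
Inference choices suit the small sample size:

* visit-to-visit changes — Wilcoxon signed-rank, exact null distribution
  for n <= 25 (tie-free), tie-corrected normal approximation otherwise;
* imaging-histology association — Pearson r with a two-sided p-value from
  t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom;
* CAIX stratification — Mann-Whitney U, exact for combined n <= 20;
* two-sided p-values throughout and no multiplicity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import get_logger

__all__ = [
    "CorrelationResult", "RankTestResult", "UndefinedTestError",
    "wilcoxon_signed_rank", "mann_whitney_u", "pearson_t", "pearson_p_from_r",
    "IMAGING_COLUMNS", "HISTOLOGY_COLUMNS", "validate_cohort",
    "build_table3", "compare_visits", "caix_stratification",
]

log = get_logger(__name__)

IMAGING_COLUMNS = ["t1_median", "iauc60_median", "adc_median", "volume_cm3"]
HISTOLOGY_COLUMNS = ["cd31_score", "ki67_score", "hif_score", "hypoxia_score"]

EXACT_N_WILCOXON = 25
EXACT_N_MWU = 20


class UndefinedTestError(ValueError):
    """The test statistic is undefined for the given data (e.g. all-zero
    paired differences, or zero variance for a correlation)."""


@dataclass
class RankTestResult:
    statistic: float
    p_value: float
    n: int
    method: str  # 'exact' or 'normal'


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int


def wilcoxon_signed_rank(paired_a, paired_b,
                         zero_method: str = "wilcox") -> RankTestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped by default (classic convention; their
    count is logged) or down-weighted with ``zero_method='pratt'``. The
    statistic reported is W+, the sum of ranks of positive differences.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = b - a
    n_zero = int(np.sum(d == 0))
    if n_zero and zero_method == "wilcox":
        log.info("wilcoxon: dropping %d zero differences", n_zero)
    d_nz = d[d != 0]
    if d_nz.size == 0:
        raise UndefinedTestError("all paired differences are zero")
    n = d_nz.size
    has_ties = len(np.unique(np.abs(d_nz))) < n
    if n <= EXACT_N_WILCOXON and not has_ties and zero_method == "wilcox":
        method, mode = "exact", "exact"
    else:
        method, mode = "normal", "approx"
    res = sps.wilcoxon(d, zero_method=zero_method, alternative="two-sided",
                       correction=(mode == "approx"), method=mode)
    ranks = sps.rankdata(np.abs(d_nz))
    w_plus = float(ranks[d_nz > 0].sum())
    return RankTestResult(statistic=w_plus, p_value=float(res.pvalue),
                          n=n, method=method)


def mann_whitney_u(group_a, group_b) -> RankTestResult:
    """Two-sided Mann-Whitney U test; exact null for combined n <= 20
    (tie-free), tie-corrected normal approximation otherwise. Statistic is
    U for group_a (midranks under ties)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    if a.size + b.size <= EXACT_N_MWU and not has_ties:
        method, mode = "exact", "exact"
    else:
        method, mode = "normal", "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=mode)
    # U from midranks so that identical groups give n_a*n_b/2 even with ties
    ranks = sps.rankdata(pooled)
    u_a = float(ranks[:a.size].sum() - a.size * (a.size + 1) / 2.0)
    return RankTestResult(statistic=u_a, p_value=float(res.pvalue),
                          n=int(a.size + b.size), method=method)


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a Pearson r via the t transform on n-2 df."""
    if n < 3:
        raise ValueError("need n >= 3 for a defined p-value")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def pearson_t(x, y) -> CorrelationResult:
    """Pearson correlation with its t-distribution p-value.

    Pairs with a missing value in either variable are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise UndefinedTestError(f"need >= 3 complete pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedTestError("constant input: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    return CorrelationResult(r=r, p_value=pearson_p_from_r(r, n), n=n)


# ---------------------------------------------------------------------------
# cohort-level reports

def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check the per-patient-per-visit cohort table schema and invariants."""
    required = {"patient", "visit"} | set(IMAGING_COLUMNS) | set(HISTOLOGY_COLUMNS) \
        | {"caix_positive"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if not cohort["visit"].isin([1, 2, 3]).all():
        raise ValueError("visits must be in {1, 2, 3}")
    hist = cohort.groupby("patient")[HISTOLOGY_COLUMNS + ["caix_positive"]].nunique(
        dropna=True)
    if (hist > 1).any().any():
        raise ValueError("histology must be constant across visits within a patient")
    return cohort


def build_table3(cohort: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Histology-vs-imaging Pearson correlation grid, one row per
    (visit, histology marker, imaging parameter) cell.

    Cells with fewer than ``min_pairs`` complete pairs are emitted with NaN
    r and p. No multiplicity correction is applied.
    """
    validate_cohort(cohort)
    rows = []
    for visit in (1, 2, 3):
        sub = cohort[cohort["visit"] == visit]
        for hcol in HISTOLOGY_COLUMNS:
            for icol in IMAGING_COLUMNS:
                x = sub[icol].to_numpy(float)
                y = sub[hcol].to_numpy(float)
                try:
                    res = pearson_t(x, y)
                    r, p, n = res.r, res.p_value, res.n
                except UndefinedTestError:
                    keep = np.isfinite(x) & np.isfinite(y)
                    r, p, n = np.nan, np.nan, int(keep.sum())
                if n < min_pairs:
                    r, p = np.nan, np.nan
                rows.append({"visit": visit, "histology": hcol, "imaging": icol,
                             "r": r, "p_value": p, "n": n})
    return pd.DataFrame(rows)


def compare_visits(cohort: pd.DataFrame, parameter: str,
                   visit_a: int, visit_b: int) -> dict:
    """Paired Wilcoxon signed-rank test of per-patient medians between two
    visits; patients missing either visit are excluded and counted."""
    if parameter not in IMAGING_COLUMNS:
        raise ValueError(f"unknown imaging parameter {parameter!r}")
    wide = cohort.pivot_table(index="patient", columns="visit", values=parameter,
                              aggfunc="first")
    have = wide.reindex(columns=[visit_a, visit_b]).dropna()
    n_excluded = wide.shape[0] - have.shape[0]
    if have.shape[0] < 1:
        raise ValueError("no usable pairs")
    a = have[visit_a].to_numpy(float)
    b = have[visit_b].to_numpy(float)
    out = {"parameter": parameter, "visit_a": visit_a, "visit_b": visit_b,
           "n_pairs": int(have.shape[0]), "n_excluded": int(n_excluded),
           "median_change": float(np.median(b - a))}
    try:
        res = wilcoxon_signed_rank(a, b)
        out.update(statistic=res.statistic, p_value=res.p_value, method=res.method)
    except UndefinedTestError:
        out.update(statistic=np.nan, p_value=np.nan, method="undefined")
    return out


def caix_stratification(cohort: pd.DataFrame) -> pd.DataFrame:
    """Mann-Whitney U comparison of each imaging parameter between
    CAIX-positive and CAIX-negative tumours, per visit."""
    validate_cohort(cohort)
    rows = []
    for visit in (1, 2, 3):
        sub = cohort[cohort["visit"] == visit]
        for icol in IMAGING_COLUMNS:
            pos = sub.loc[sub["caix_positive"].astype(bool), icol].dropna()
            neg = sub.loc[~sub["caix_positive"].astype(bool), icol].dropna()
            if len(pos) == 0 or len(neg) == 0:
                rows.append({"visit": visit, "imaging": icol, "n_pos": len(pos),
                             "n_neg": len(neg), "u_statistic": np.nan,
                             "p_value": np.nan, "method": "undefined"})
                continue
            res = mann_whitney_u(pos.to_numpy(float), neg.to_numpy(float))
            rows.append({"visit": visit, "imaging": icol, "n_pos": len(pos),
                         "n_neg": len(neg), "u_statistic": res.statistic,
                         "p_value": res.p_value, "method": res.method})
    return pd.DataFrame(rows)
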