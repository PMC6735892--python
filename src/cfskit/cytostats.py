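"""Statistics for scored metaphase-spread data.

Covers the group summaries (mean/SD/SEM) shown on break/gap plots, the
unpaired t-test used for group comparisons, the chi-square test of
fragile-locus breakage frequency across conditions, and pooled MiDAS
(mitotic DNA synthesis, EdU-positive break) proportions with Wilson
confidence intervals.
"""

from __future__ import annotations

import logging
import math
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)

BREAK_COLUMNS = ("spread_id", "group", "breaks_total", "breaks_edu_pos")


class TestResult(NamedTuple):
    statistic: float
    df: float
    p_value: float


def read_break_table(path) -> pd.DataFrame:
    """CSV with columns spread_id, group, breaks_total[, breaks_edu_pos]."""
    df = pd.read_csv(path)
    missing = {"spread_id", "group", "breaks_total"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "breaks_edu_pos" not in df.columns:
        df["breaks_edu_pos"] = np.nan
    present = df["breaks_edu_pos"].notna()
    if (df.loc[present, "breaks_edu_pos"] > df.loc[present, "breaks_total"]).any():
        raise ValueError(f"{path}: breaks_edu_pos exceeds breaks_total")
    return df


def read_locus_contingency(path) -> pd.DataFrame:
    """CSV with columns group, broken, intact -> indexed contingency."""
    df = pd.read_csv(path)
    missing = {"group", "broken", "intact"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = df.set_index("group")[["broken", "intact"]].astype(int)
    if ((out["broken"] + out["intact"]) <= 0).any():
        raise ValueError(f"{path}: each group needs a positive total")
    return out


def group_summary(
    table: pd.DataFrame,
    value_col: str = "breaks_total",
    group_col: str = "group",
) -> pd.DataFrame:
    """Per-group n, mean, SD (n-1) and SEM = SD/sqrt(n)."""
    rows = []
    for group, sub in table.groupby(group_col, sort=True):
        vals = sub[value_col].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            logger.info("group %r has no values; excluded from summary", group)
            continue
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        rows.append(
            {
                group_col: group,
                "n": int(vals.size),
                "mean": float(np.mean(vals)),
                "sd": sd,
                "sem": sd / math.sqrt(vals.size),
            }
        )
    return pd.DataFrame(rows)


def unpaired_t(
    group_a: Sequence[float], group_b: Sequence[float], welch: bool = True
) -> TestResult:
    """Two-sided unpaired t-test (Welch by default).

    Degenerate case: both groups with zero variance and equal means is
    reported as no evidence of a difference (t=0, p=1) rather than NaN.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            logger.info("both groups constant and equal; returning t=0, p=1")
            return TestResult(0.0, float(a.size + b.size - 2), 1.0)
        raise ValueError("both groups have zero variance but unequal means")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue))


def chisq_independence(
    table: pd.DataFrame | np.ndarray, correction: bool = False
) -> TestResult:
    """Pearson chi-square on a 2xk (groups x broken/intact) count table.

    No continuity correction by default; enable with ``correction`` for
    the Yates variant on 2x2 tables.  Expected counts below 1 trigger a
    warning recommending an exact test but the statistic is returned.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 2:
        raise ValueError("expected a k x 2 table of (broken, intact) counts")
    chi2, p, dof, expected = stats.chi2_contingency(obs, correction=correction)
    if (expected < 1).any():
        logger.warning(
            "chi-square expected count below 1; consider an exact test"
        )
    if np.allclose(chi2, 0.0):
        chi2, p = 0.0, 1.0
    return TestResult(float(chi2), float(dof), float(p))


def midas_proportions(table: pd.DataFrame) -> pd.DataFrame:
    """Pooled EdU-positive (MiDAS) break fraction per group, Wilson 95% CI.

    Spreads without EdU scoring are excluded; a group with zero scored
    breaks has an undefined fraction (reported as NaN).
    """
    rows = []
    for group, sub in table.groupby("group", sort=True):
        scored = sub[sub["breaks_edu_pos"].notna()]
        total = int(scored["breaks_total"].sum())
        pos = int(scored["breaks_edu_pos"].sum())
        if total == 0:
            logger.info("group %r has zero scored breaks; fraction undefined", group)
            frac = lo = hi = float("nan")
        else:
            frac = pos / total
            lo, hi = proportion_confint(pos, total, alpha=0.05, method="wilson")
        rows.append(
            {
                "group": group,
                "n_breaks": total,
                "n_edu_pos": pos if total else 0,
                "frac_edu_pos": frac,
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return pd.DataFrame(rows)
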