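"""Tissue-microarray immunohistochemistry scoring and group comparison.

Each stained core receives an additive score: staining intensity grade
(0-3) plus a percent-positive-cells category (0 = <1%, 1 = 1-10%,
2 = 10-25%, 3 = 25-75%, 4 = >75%), so a core scores 0-7. The published
bin edges overlap at 10, 25 and 75; this implementation fixes them as
right-closed: [0,1) -> 0, [1,10] -> 1, (10,25] -> 2, (25,75] -> 3,
(75,100] -> 4. Per-sample scores default to the sum over replicate cores
(group means above 7 imply multi-core summation); 'mean' is available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .differential import two_sample_t, TEST_VARIANTS
from .errors import ConfigurationError, DataError

AGGREGATIONS = ("sum", "mean")


def percent_category(pct: float) -> int:
    """Bin a raw percent-positive value (0-100) into category 0-4."""
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"percent positive {pct} outside [0, 100]")
    if pct < 1.0:
        return 0
    if pct <= 10.0:
        return 1
    if pct <= 25.0:
        return 2
    if pct <= 75.0:
        return 3
    return 4


def core_score(intensity: int, category: int) -> int:
    """Additive per-core score: intensity (0-3) + category (0-4)."""
    if intensity not in (0, 1, 2, 3):
        raise ValueError(f"intensity {intensity} outside 0-3")
    if category not in (0, 1, 2, 3, 4):
        raise ValueError(f"percent category {category} outside 0-4")
    return intensity + category


def score_cores(cores: pd.DataFrame) -> pd.DataFrame:
    """Add a per-core ``score`` column to an IHC core sheet.

    Uses the ``category`` column when present, otherwise bins
    ``percent_positive``.
    """
    df = cores.copy()
    if "category" in df.columns:
        cats = [int(c) for c in df["category"]]
    elif "percent_positive" in df.columns:
        cats = [percent_category(float(p)) for p in df["percent_positive"]]
    else:
        raise DataError("IHC sheet needs a percent_positive or category column")
    df["score"] = [core_score(int(i), c) for i, c in zip(df["intensity"], cats)]
    return df


def sample_scores(cores: pd.DataFrame, aggregation: str = "sum") -> pd.DataFrame:
    """Aggregate replicate core scores to one score per sample."""
    if aggregation not in AGGREGATIONS:
        raise ConfigurationError(f"aggregation must be one of {AGGREGATIONS}")
    scored = score_cores(cores) if "score" not in cores.columns else cores
    if scored.empty:
        raise DataError("no cores to aggregate")
    groups_per_sample = scored.groupby("sample_id")["group"].nunique()
    if (groups_per_sample > 1).any():
        bad = groups_per_sample[groups_per_sample > 1].index[0]
        raise DataError(f"sample {bad!r} carries more than one group label")
    agg = scored.groupby("sample_id").agg(group=("group", "first"), score=("score", aggregation))
    return agg.reset_index()


def group_summary(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-group n, mean and sample SD of the per-sample scores."""
    out = (
        scores.groupby("group")["score"]
        .agg(n="count", mean="mean", sd=lambda s: s.std(ddof=1))
        .reset_index()
    )
    return out


def summary_t_test(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    variant: str = "student_pooled",
) -> tuple[float, float, float]:
    """Two-sample t-test from summary statistics alone; returns (t, df, p)."""
    if variant not in TEST_VARIANTS:
        raise ConfigurationError(f"variant must be one of {TEST_VARIANTS}")
    if sd_a <= 0 or sd_b <= 0:
        raise DataError("standard deviations must be > 0")
    if n_a < 2 or n_b < 2:
        raise DataError("need n >= 2 per group")
    res = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=(variant == "student_pooled")
    )
    if variant == "student_pooled":
        df = float(n_a + n_b - 2)
    else:
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def compare_groups(
    scores: pd.DataFrame,
    group_a: str | None = None,
    group_b: str | None = None,
) -> dict:
    """Raw-score two-group comparison; both t-test variants reported."""
    groups = list(dict.fromkeys(scores["group"]))
    if len(groups) != 2:
        raise DataError(f"exactly 2 groups required, found {groups}")
    if group_a is None or group_b is None:
        group_a, group_b = groups
    a = scores.loc[scores["group"] == group_a, "score"].to_numpy(float)
    b = scores.loc[scores["group"] == group_b, "score"].to_numpy(float)
    out = {
        "group_a": group_a,
        "group_b": group_b,
        "n_a": len(a),
        "n_b": len(b),
        "mean_a": float(np.mean(a)),
        "mean_b": float(np.mean(b)),
        "sd_a": float(np.std(a, ddof=1)),
        "sd_b": float(np.std(b, ddof=1)),
    }
    for variant in TEST_VARIANTS:
        t, df, p = two_sample_t(a, b, variant)
        out[variant] = {"t_stat": t, "df": df, "p_value": p}
    return out
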