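"""Two-group statistics for beta values and event counts.

Per-unit differential methylation uses a plain two-sample t-test —
pooled-variance Student's t by default, Welch as an option — with
pairwise-complete observations (missing betas drop out per unit). The
default significance call is on the raw p at alpha (no adjustment),
with Benjamini-Hochberg q-values always reported alongside.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

TEST_VARIANTS = ("student_pooled", "welch")

DIRECTION_HYPO_IN_B = "hypo_in_b"
DIRECTION_HYPO_IN_A = "hypo_in_a"
DIRECTION_NONE = "none"


@dataclass
class AnalysisParams:
    """Shared testing parameters.

    alpha: two-sided significance level for the per-unit direction call.
    test_variant: 'student_pooled' (df = n_a + n_b - 2) or 'welch'
        (Welch-Satterthwaite df).
    adjust: 'none' keeps the raw-p significance call; 'bh' calls
        significance on the BH q-value instead. q is reported either way.
    group_a / group_b: optional explicit cohort labels; when omitted the
        order of first appearance in the sample sheet defines them.
    """

    alpha: float = 0.05
    test_variant: str = "student_pooled"
    adjust: str = "none"
    group_a: str | None = None
    group_b: str | None = None

    def validate(self) -> "AnalysisParams":
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha {self.alpha} outside (0, 1)")
        if self.test_variant not in TEST_VARIANTS:
            raise ConfigurationError(f"test_variant must be one of {TEST_VARIANTS}")
        if self.adjust not in ("none", "bh"):
            raise ConfigurationError("adjust must be 'none' or 'bh'")
        return self


def resolve_groups(sheet: pd.DataFrame, params: AnalysisParams) -> tuple[str, str]:
    """Return the (group_a, group_b) labels for a two-group sheet."""
    groups = list(dict.fromkeys(sheet["group"]))
    if len(groups) != 2:
        raise DataError(f"exactly 2 groups required, found {len(groups)}: {groups}")
    if params.group_a is not None or params.group_b is not None:
        if {params.group_a, params.group_b} != set(groups):
            raise ConfigurationError(
                f"configured groups ({params.group_a}, {params.group_b}) do not match sheet {groups}"
            )
        return params.group_a, params.group_b  # type: ignore[return-value]
    return groups[0], groups[1]


def two_sample_t(
    values_a, values_b, variant: str = "student_pooled"
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test; returns (t, df, p).

    Missing values are dropped. Zero variance in both groups with equal
    means yields p = 1 by convention (logged); zero pooled variance with
    unequal means yields an infinite statistic and p = 0 (logged).
    """
    if variant not in TEST_VARIANTS:
        raise ConfigurationError(f"variant must be one of {TEST_VARIANTS}")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise DataError(f"need >= 2 non-missing values per group, got {len(a)} and {len(b)}")
    na, nb = len(a), len(b)
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = ma - mb
    if variant == "student_pooled":
        df = na + nb - 2.0
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    else:
        se = np.sqrt(va / na + vb / nb)
        if va == 0.0 and vb == 0.0:
            df = na + nb - 2.0
        else:
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
    if se == 0.0:
        if diff == 0.0:
            logger.warning("zero variance in both groups with equal means; p = 1 by convention")
            return 0.0, float(df), 1.0
        logger.warning("zero variance with unequal means; degenerate p = 0")
        return float(np.sign(diff) * np.inf), float(df), 0.0
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def _direction(mean_a, mean_b, significant) -> np.ndarray:
    out = np.full(len(mean_a), DIRECTION_NONE, dtype=object)
    out[significant & (mean_b < mean_a)] = DIRECTION_HYPO_IN_B
    out[significant & (mean_a < mean_b)] = DIRECTION_HYPO_IN_A
    return out


def differential_units(
    values: pd.DataFrame,
    sheet: pd.DataFrame,
    params: AnalysisParams | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-unit two-group t-tests over a units x samples matrix.

    Returns (results, skipped_unit_ids). Units with fewer than 2
    non-missing observations in either group are skipped and enumerated.
    Results are sorted by p ascending, ties broken by unit_id, and carry
    columns: unit_id, mean_a, mean_b, t_stat, df, p_value, q_value,
    direction, n_a, n_b. The group label mapping is stored in
    ``results.attrs['group_a'/'group_b']``.
    """
    params = (params or AnalysisParams()).validate()
    group_a, group_b = resolve_groups(sheet, params)
    missing = set(sheet["sample_id"]) - set(values.columns)
    if missing:
        raise DataError(f"samples in sheet absent from matrix: {sorted(missing)}")
    samples_a = sheet.loc[sheet["group"] == group_a, "sample_id"].tolist()
    samples_b = sheet.loc[sheet["group"] == group_b, "sample_id"].tolist()
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise DataError("each group needs >= 2 samples")

    A = values[samples_a].to_numpy(dtype=float)
    B = values[samples_b].to_numpy(dtype=float)
    na = (~np.isnan(A)).sum(axis=1)
    nb = (~np.isnan(B)).sum(axis=1)
    ok = (na >= 2) & (nb >= 2)
    skipped = sorted(values.index[~ok].tolist())
    if skipped:
        logger.info("skipped %d unit(s) with < 2 non-missing values in a group", len(skipped))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows are masked by `ok`
        ma, mb = np.nanmean(A, axis=1), np.nanmean(B, axis=1)
        va, vb = np.nanvar(A, axis=1, ddof=1), np.nanvar(B, axis=1, ddof=1)

    ma, mb, va, vb, na_, nb_ = (x[ok] for x in (ma, mb, va, vb, na, nb))
    if params.test_variant == "student_pooled":
        df = (na_ + nb_ - 2).astype(float)
        sp2 = ((na_ - 1) * va + (nb_ - 1) * vb) / df
        se = np.sqrt(sp2 * (1.0 / na_ + 1.0 / nb_))
    else:
        se = np.sqrt(va / na_ + vb / nb_)
        with np.errstate(invalid="ignore", divide="ignore"):
            df = (va / na_ + vb / nb_) ** 2 / (
                (va / na_) ** 2 / (na_ - 1) + (vb / nb_) ** 2 / (nb_ - 1)
            )
        df = np.where(np.isfinite(df), df, (na_ + nb_ - 2).astype(float))

    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    # degenerate zero-variance units: equal means -> p=1; unequal -> p=0
    zero_se = se == 0.0
    t = np.where(zero_se, np.where(diff == 0.0, 0.0, np.sign(diff) * np.inf), t)
    p = np.where(zero_se & (diff == 0.0), 1.0, 2.0 * stats.t.sf(np.abs(t), df))
    p = np.minimum(p, 1.0)
    q = bh_adjust(p) if len(p) else np.array([])

    sig_p = q if params.adjust == "bh" else p
    results = pd.DataFrame(
        {
            "unit_id": values.index[ok],
            "mean_a": ma,
            "mean_b": mb,
            "t_stat": t,
            "df": df,
            "p_value": p,
            "q_value": q,
            "direction": _direction(ma, mb, sig_p < params.alpha),
            "n_a": na_,
            "n_b": nb_,
        }
    )
    results = results.sort_values(["p_value", "unit_id"], kind="mergesort").reset_index(drop=True)
    results.attrs["group_a"] = group_a
    results.attrs["group_b"] = group_b
    return results, skipped


def differential_probes(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    assignment,
    params: AnalysisParams | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Probe-level differential test restricted to probes inside >= 1 site."""
    assigned = [p for p in assignment.assigned_probes if p in beta.index]
    if not assigned:
        raise DataError("no probes overlap any binding site")
    return differential_units(beta.loc[assigned], sheet, params)


def global_burden_test(
    per_sample_counts: pd.Series,
    sheet: pd.DataFrame,
    params: AnalysisParams | None = None,
) -> dict:
    """Compare per-sample hypomethylated-site counts between the cohorts."""
    params = (params or AnalysisParams()).validate()
    group_a, group_b = resolve_groups(sheet, params)
    missing = set(sheet["sample_id"]) - set(per_sample_counts.index)
    if missing:
        raise DataError(f"counts missing for samples: {sorted(missing)}")
    ca = per_sample_counts[sheet.loc[sheet["group"] == group_a, "sample_id"]].to_numpy(float)
    cb = per_sample_counts[sheet.loc[sheet["group"] == group_b, "sample_id"]].to_numpy(float)
    t, df, p = two_sample_t(ca, cb, params.test_variant)
    return {
        "group_a": group_a,
        "group_b": group_b,
        "n_a": len(ca),
        "n_b": len(cb),
        "mean_a": float(ca.mean()),
        "mean_b": float(cb.mean()),
        "t_stat": t,
        "df": df,
        "p_value": p,
    }


def chi_square_2x2(table, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table (no continuity correction
    by default; ``yates=True`` enables it)."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise DataError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any() or not np.allclose(arr, np.rint(arr)):
        raise DataError("table entries must be non-negative integers")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DataError("zero marginal total; consider Fisher's exact test")
    res = stats.chi2_contingency(arr.astype(int), correction=yates)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise DataError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
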