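"""Volcano-plot statistics and clinical-table group comparisons."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def volcano(
    ratios: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.05,
    fc_bounds: tuple[float, float] = (2.0, 0.5),
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-feature fold change and t-test p-value, CTRL vs CRC.

    ``ratios`` are IS-normalised areas on the raw (pre-autoscale) scale;
    the fold change is mean(CTRL)/mean(CRC) on that scale, while the t-test
    (Welch by default, Student's with ``equal_var=True``) runs on
    log-transformed values. A feature is significant when p < alpha *and*
    the fold change is strictly outside ``fc_bounds`` (FC > 2 or FC < 0.5
    by default; a boundary value such as FC = 2 exactly is not significant).
    """
    hi, lo = fc_bounds
    labels = labels.loc[ratios.index]
    g_ctrl = ratios.loc[labels == "CTRL"]
    g_crc = ratios.loc[labels == "CRC"]
    if len(g_ctrl) == 0 or len(g_crc) == 0:
        raise ValueError("both CTRL and CRC groups must be non-empty")

    mean_ctrl = g_ctrl.mean(skipna=True)
    mean_crc = g_crc.mean(skipna=True)

    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_ctrl / mean_crc
        log2_fc = np.log2(fc)
    undefined = (mean_crc == 0) | (mean_ctrl == 0) | fc.isna()

    t_p = pd.Series(np.nan, index=ratios.columns)
    log_ctrl = np.log(g_ctrl)
    log_crc = np.log(g_crc)
    res = stats.ttest_ind(
        log_ctrl, log_crc, equal_var=equal_var, nan_policy="omit", axis=0
    )
    t_p[:] = res.pvalue

    significant = (t_p < alpha) & ((fc > hi) | (fc < lo)) & ~undefined
    direction = np.where(fc > 1, "higher_in_CTRL", "higher_in_CRC")
    direction = np.where(fc == 1, "equal", direction)

    return pd.DataFrame(
        {
            "feature_id": ratios.columns,
            "fc": fc.to_numpy(),
            "log2_fc": log2_fc.to_numpy(),
            "p": t_p.to_numpy(),
            "direction": direction,
            "significant": significant.to_numpy(),
            "undefined_fc": undefined.to_numpy(),
        }
    ).set_index("feature_id")


def shapiro_gate(values, alpha: float = 0.05) -> bool:
    """Shapiro–Wilk normality gate: True -> use a t-test, False -> rank-sum."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 3:
        raise ValueError(f"Shapiro–Wilk needs n >= 3, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("constant vector has no defined normality test")
    return bool(stats.shapiro(x).pvalue >= alpha)


def compare_groups_table(
    clinical: pd.DataFrame,
    groups: pd.Series,
    var_types: dict[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Clinical-table comparisons: Student's t for continuous variables,
    chi-square (without continuity correction) for proportions.

    ``var_types`` maps each column to 'continuous' or 'proportion'
    (proportion columns are 0/1 indicators).
    """
    uniq = [g for g in pd.unique(groups) if pd.notna(g)]
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {uniq}")
    rows = []
    for var, kind in var_types.items():
        a = clinical.loc[groups == uniq[0], var].dropna()
        b = clinical.loc[groups == uniq[1], var].dropna()
        if len(a) == 0 or len(b) == 0:
            raise ValueError(f"empty group for variable {var!r}")
        if kind == "continuous":
            stat, p = stats.ttest_ind(a, b, equal_var=True)
            test = "t"
        elif kind == "proportion":
            tbl = np.array(
                [[a.sum(), len(a) - a.sum()], [b.sum(), len(b) - b.sum()]],
                dtype=float,
            )
            if (tbl.sum(axis=0) == 0).any():
                stat, p = 0.0, 1.0
            else:
                stat, p, _, _ = stats.chi2_contingency(tbl, correction=False)
            test = "chi2"
        else:
            raise ValueError(f"unknown variable type {kind!r} for {var!r}")
        rows.append(
            {
                "variable": var,
                "test": test,
                "statistic": float(stat),
                "p": float(p),
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows).set_index("variable")
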