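"""Estimator performance metrics: rRMSE and REE.

Relative estimation error (signed percent; its median across replicates
measures bias, its spread precision):

    REE = 100 * (P_est - P_true) / P_true.

Relative root mean squared error (combined bias + precision; the
conventional definition, used for all method comparisons):

    rRMSE = sqrt( (1/n) * sum_r ((P_est,r - P_true) / P_true)^2 ).

A historical variant that divides the squared error by P_true (not
P_true^2) and by n^2 appears in some reports; it is dimensionally
inconsistent but is computed alongside as ``rrmse_printed`` for
transparency.  Quantiles use the linear-interpolation (type-7) rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["ree", "rrmse", "rrmse_printed", "summarize", "plot_rrmse", "plot_ree_box"]


def ree(p_est, p_true) -> float | np.ndarray:
    """Signed relative estimation error in percent."""
    p_true = np.asarray(p_true, dtype=float)
    if np.any(p_true == 0):
        raise ValueError("p_true must be non-zero")
    out = 100.0 * (np.asarray(p_est, dtype=float) - p_true) / p_true
    return float(out) if out.ndim == 0 else out


def rrmse(estimates, p_true) -> float:
    """Conventional relative RMSE of a vector of estimates of one truth."""
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("estimates must be non-empty")
    if not p_true > 0:
        raise ValueError("p_true must be positive")
    return float(np.sqrt(np.mean(((est - p_true) / p_true) ** 2)))


def rrmse_printed(estimates, p_true) -> float:
    """Variant form: sqrt( sum((P_est - P_true)^2 / P_true) / n^2 )."""
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("estimates must be non-empty")
    if not p_true > 0:
        raise ValueError("p_true must be positive")
    n = est.size
    return float(np.sqrt(np.sum((est - p_true) ** 2 / p_true) / n**2))


def summarize(table: pd.DataFrame, successful_only: bool = True) -> pd.DataFrame:
    """Per (parameter, method, IIV level) metric summaries of an SSE table.

    Uses only fits with ``minimization_success`` when ``successful_only``
    (the number actually used is reported as ``n_used``); a group with zero
    usable fits is still emitted, with NaN metrics, so nothing is silently
    dropped.  Row-order invariant.
    """
    if table.empty:
        raise ValueError("empty SSE table")
    rows = []
    for (param, method, level), grp in table.groupby(
        ["parameter", "method", "iiv_level"], sort=True
    ):
        used = grp[grp["minimization_success"]] if successful_only else grp
        used = used[np.isfinite(used["estimate"])]
        n_total = len(grp)
        if len(used) == 0:
            rows.append(
                {
                    "parameter": param,
                    "method": method,
                    "iiv_level": level,
                    "rrmse": np.nan,
                    "rrmse_printed": np.nan,
                    "median_ree": np.nan,
                    "ree_q1": np.nan,
                    "ree_q3": np.nan,
                    "n_used": 0,
                    "n_total": n_total,
                }
            )
            continue
        p_true = float(used["true_value"].iloc[0])
        est = used["estimate"].to_numpy(dtype=float)
        ree_vals = ree(est, p_true)
        q1, med, q3 = np.percentile(ree_vals, [25, 50, 75])  # type-7 linear
        rows.append(
            {
                "parameter": param,
                "method": method,
                "iiv_level": level,
                "rrmse": rrmse(est, p_true),
                "rrmse_printed": rrmse_printed(est, p_true),
                "median_ree": float(med),
                "ree_q1": float(q1),
                "ree_q3": float(q3),
                "n_used": len(used),
                "n_total": n_total,
            }
        )
    return pd.DataFrame(rows)


def ree_long(table: pd.DataFrame, successful_only: bool = True) -> pd.DataFrame:
    """Box-plot-ready long REE data (one row per estimate)."""
    df = table[table["minimization_success"]] if successful_only else table.copy()
    df = df[np.isfinite(df["estimate"])].copy()
    df["ree"] = 100.0 * (df["estimate"] - df["true_value"]) / df["true_value"]
    return df[["parameter", "method", "iiv_level", "replicate", "ree"]]


def plot_rrmse(metrics: pd.DataFrame, ax=None):
    """rRMSE vs IIV level, one panel-worth of lines per method, per call.

    Expects a single parameter's rows (filter beforehand for stratified
    panels); returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for method, grp in metrics.groupby("method"):
        grp = grp.sort_values("iiv_level")
        ax.plot(grp["iiv_level"], grp["rrmse"], marker="o", label=method)
    ax.set_xlabel("IIV level (CV%)")
    ax.set_ylabel("rRMSE")
    ax.legend()
    return ax


def plot_ree_box(long_ree: pd.DataFrame, ax=None):
    """REE box plot by method for one (parameter, IIV level) slice."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    methods = sorted(long_ree["method"].unique())
    data = [long_ree.loc[long_ree["method"] == m, "ree"] for m in methods]
    ax.boxplot(data, tick_labels=methods)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_ylabel("REE (%)")
    return ax
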