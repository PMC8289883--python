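"""Outcome variables of the Monte-Carlo linking study.

Per condition d with c replications and true parameter value tau:

    bias          = mean_k(tau_hat_k) - tau
    relative bias = (mean_k(tau_hat_k) - tau) / tau        (undefined at tau=0)
    RMSE          = sqrt( mean_k( (tau_hat_k - tau)^2 ) )

The RMSE divisor is c (no c-1 correction), matching the root-mean-of-squared-
deviations definition, so rmse^2 = bias^2 + population variance of the
estimates.  Relative bias is conventionally judged acceptable below 10%.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simulate import ConfigurationError


def _as_array(estimates: Sequence[float]) -> np.ndarray:
    arr = np.asarray(list(estimates), dtype=float)
    if arr.size == 0:
        raise ValueError("estimates must be non-empty")
    return arr


def bias(estimates: Sequence[float], truth: float) -> float:
    """Mean of the estimates minus the true value."""
    return float(_as_array(estimates).mean() - truth)


def relative_bias(estimates: Sequence[float], truth: float) -> float:
    """Bias as a proportion of the true value; undefined when truth == 0."""
    if truth == 0:
        raise ZeroDivisionError("relative bias is undefined for a true value of 0")
    return bias(estimates, truth) / truth


def rmse(estimates: Sequence[float], truth: float) -> float:
    """Root mean squared deviation of the estimates from the true value."""
    arr = _as_array(estimates)
    return float(np.sqrt(np.mean((arr - truth) ** 2)))


def convergence_rate(flags: Sequence[bool]) -> float:
    """Share of converged calibrations."""
    arr = np.asarray(list(flags), dtype=bool)
    if arr.size == 0:
        raise ValueError("flags must be non-empty")
    return float(arr.mean())


#: condition keys recognized by :func:`aggregate`
GROUPING_KEYS = ("method", "misfit", "anchor_count", "sample_size", "timepoint")


def aggregate(
    replications: pd.DataFrame,
    by: Iterable[str] = (),
    per_timepoint: bool = True,
    converged_only: bool = True,
    truth: str = "population",
) -> pd.DataFrame:
    """Outcome summaries of a tidy per-replication estimates table.

    ``replications`` has one row per replication x condition x method x
    time point with columns ``mu_hat``, ``sigma2_hat``, ``true_mean``,
    ``true_variance``, ``converged`` plus the condition keys.  Outcome
    statistics are computed on converged rows (non-converged calibrations are
    recorded in the convergence rate but excluded from parameter summaries,
    the convention for estimators with failure modes); the convergence rate
    itself uses all rows.

    Returns one row per group with bias / relative bias / RMSE of the latent
    mean and variance, their Monte-Carlo standard errors, replication counts
    and the convergence rate.  Relative bias is NA where the true value is 0.
    """
    by = list(by)
    unknown = [k for k in by if k not in GROUPING_KEYS]
    if unknown:
        raise ConfigurationError(f"unknown grouping keys: {unknown}")
    keys = by + (["timepoint"] if per_timepoint and "timepoint" not in by else [])
    if truth == "population":
        truth_cols = (("mu_hat", "true_mean", "mean"),
                      ("sigma2_hat", "true_variance", "variance"))
    elif truth == "sample":
        truth_cols = (("mu_hat", "sample_true_mean", "mean"),
                      ("sigma2_hat", "sample_true_variance", "variance"))
    else:
        raise ConfigurationError(f"unknown truth reference {truth!r}")
    missing = [c for _, c, _ in truth_cols if c not in replications.columns]
    if missing:
        raise ConfigurationError(f"replication table lacks columns {missing}")

    def summarize(group: pd.DataFrame) -> pd.Series:
        conv = group[group["converged"]] if converged_only else group
        out = {
            "n_replications": len(conv),
            "convergence_rate": float(group["converged"].mean()),
        }
        for est_col, true_col, tag in truth_cols:
            if len(conv) == 0:
                out.update({f"{s}_{tag}": np.nan
                            for s in ("bias", "relbias", "rmse", "mc_se_bias")})
                continue
            err = conv[est_col].to_numpy() - conv[true_col].to_numpy()
            b = float(err.mean())
            out[f"bias_{tag}"] = b
            tau_bar = float(conv[true_col].mean())
            # relative bias against the (mean) truth; undefined at tau = 0,
            # which is the reference time point's latent mean
            out[f"relbias_{tag}"] = b / tau_bar if abs(tau_bar) > 1e-9 else np.nan
            out[f"rmse_{tag}"] = float(np.sqrt(np.mean(err**2)))
            out[f"mc_se_bias_{tag}"] = float(err.std(ddof=1) / np.sqrt(len(err))) \
                if len(err) > 1 else np.nan
        return pd.Series(out)

    if not keys:
        return summarize(replications).to_frame().T.reset_index(drop=True)
    grouped = (
        replications.groupby(keys, sort=True, observed=True)
        .apply(summarize, include_groups=False)
        .reset_index()
    )
    return grouped
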