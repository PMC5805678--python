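"""Moderated linear-model differential methylation.

Per probe, a one-way group-means model is fitted on beta values.  Residual
variances are shrunk toward a common prior estimated from the whole array by
the closed-form moment/digamma method: with per-probe residual variance
``s2`` on ``d`` degrees of freedom, ``log(s2)`` follows a scaled
log-F distribution whose moments identify a prior ``(d0, s0^2)``; the
posterior variance is ``(d0*s0^2 + d*s2) / (d0 + d)`` and moderated t/F
statistics gain ``d0`` degrees of freedom.  ``d0 = 0`` degenerates exactly to
ordinary (pooled-variance) statistics.

Statistics are computed on beta values directly (the pipeline's effect-size
currency is delta-beta); callers wanting M-values can transform upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .types import BetaMatrix, SampleSheet


@dataclass
class ModerationParams:
    """Variance-shrinkage hyperparameters and per-probe inputs."""

    df_prior: float
    s2_prior: float
    df_resid: np.ndarray
    s2: np.ndarray
    s2_post: np.ndarray


@dataclass
class DifferentialResult:
    """Per-probe differential methylation table plus fit metadata."""

    table: pd.DataFrame
    comparison: tuple[str, ...]
    statistic: str
    alpha: float
    params: ModerationParams
    dropped_probes: list[str] = field(default_factory=list)

    @property
    def significant_probes(self) -> list[str]:
        return self.table.index[self.table["significant"]].tolist()


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Output order matches input order; values are monotone along the sorted
    p-values and capped at 1.  Inputs outside [0, 1] (or NaN) are an error.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-d vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def _bh_with_nan(p: np.ndarray) -> np.ndarray:
    out = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = bh_adjust(p[ok])
    return out


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration on 1/trigamma)."""
    if x <= 0:
        raise ValueError("trigamma_inverse requires a positive argument")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * abs(y):
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df_resid: np.ndarray) -> tuple[float, float]:
    """Estimate (df_prior, s2_prior) from the spread of log residual variances.

    Uses the method-of-moments on ``log s2`` with digamma/trigamma
    corrections.  Probes with non-positive s2 or df are excluded from the fit.
    Returns ``(inf, geometric-mean variance)`` when the observed spread is no
    larger than expected from sampling alone.
    """
    ok = np.isfinite(s2) & (s2 > 0) & (df_resid > 0)
    s2 = s2[ok]
    df = df_resid[ok].astype(float)
    if len(s2) < 2:
        return np.inf, float(np.mean(s2)) if len(s2) else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, df / 2.0)))
    if evar > 0:
        df_prior = 2.0 * trigamma_inverse(evar)
        s2_prior = float(
            np.exp(emean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0))
        )
    else:
        df_prior = np.inf
        s2_prior = float(np.exp(emean))
    return df_prior, s2_prior


def _resolve_groups(samples, beta: BetaMatrix) -> pd.Series:
    if isinstance(samples, SampleSheet):
        groups = samples.df["group"]
    elif isinstance(samples, pd.Series):
        groups = samples
    elif isinstance(samples, dict):
        groups = pd.Series(samples)
    else:
        raise TypeError("samples must be a SampleSheet, Series or dict")
    return groups[groups.index.isin(beta.sample_ids)]


def moderated_group_test(
    beta: BetaMatrix,
    samples,
    comparison: tuple[str, ...] | list[str] | None = None,
    *,
    statistic: str = "F",
    alpha: float = 0.05,
    df_prior: float | None = None,
) -> DifferentialResult:
    """Moderated differential methylation between sample groups.

    Parameters
    ----------
    beta
        Probes x samples beta matrix.
    samples
        SampleSheet or sample -> group-label mapping.
    comparison
        Ordered group labels; the first is the reference for delta-beta
        (delta = mean(last) - mean(first) for two groups).  Defaults to all
        labels present, in sorted order.
    statistic
        ``"F"`` (any number of groups; default) or ``"t"`` (two groups only).
        With two groups, F equals t squared.
    df_prior
        Override the estimated prior degrees of freedom.  ``0`` disables
        moderation (ordinary pooled-variance statistics); probes with zero
        residual variance are then reported indeterminate (NaN), never
        infinite.

    Returns a :class:`DifferentialResult` whose table holds per-group means,
    ``delta_beta``, the moderated statistic, raw and BH-adjusted p-values and
    a significance flag at ``alpha``.  Probes with all values missing are
    dropped and reported.
    """
    groups = _resolve_groups(samples, beta)
    if comparison is None:
        comparison = tuple(sorted(groups.unique()))
    comparison = tuple(comparison)
    if len(comparison) < 2:
        raise ValueError("comparison needs at least two group labels")
    if statistic not in ("t", "F"):
        raise ValueError("statistic must be 't' or 'F'")
    if statistic == "t" and len(comparison) != 2:
        raise ValueError("statistic 't' requires exactly two groups")

    sample_lists = []
    for g in comparison:
        ids = groups.index[groups == g].tolist()
        if len(ids) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        sample_lists.append(ids)

    used = [s for ids in sample_lists for s in ids]
    X = beta.df[used].to_numpy(dtype=float)
    obs = np.isfinite(X)
    all_missing = ~obs.any(axis=1)
    dropped = beta.probe_ids[all_missing].tolist()
    keep = ~all_missing
    X, obs = X[keep], obs[keep]
    probe_ids = beta.probe_ids[keep]
    n_probes = X.shape[0]

    g = len(comparison)
    bounds = np.cumsum([0] + [len(ids) for ids in sample_lists])
    counts = np.empty((n_probes, g))
    means = np.empty((n_probes, g))
    Xz = np.where(obs, X, 0.0)
    for k in range(g):
        sl = slice(bounds[k], bounds[k + 1])
        nk = obs[:, sl].sum(axis=1)
        counts[:, k] = nk
        with np.errstate(invalid="ignore", divide="ignore"):
            means[:, k] = np.where(nk > 0, Xz[:, sl].sum(axis=1) / nk, np.nan)

    n_total = counts.sum(axis=1)
    sum_sq = (Xz**2).sum(axis=1)
    group_term = np.nansum(counts * means**2, axis=1)
    ss_within = np.maximum(sum_sq - group_term, 0.0)
    df_resid = n_total - g
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = np.where(df_resid > 0, ss_within / np.maximum(df_resid, 1), np.nan)
        grand = np.nansum(counts * means, axis=1) / n_total
        ms_between = (
            np.nansum(counts * (means - grand[:, None]) ** 2, axis=1) / (g - 1)
        )

    if df_prior is None:
        d0, s02 = estimate_prior(s2, df_resid)
    else:
        d0 = float(df_prior)
        if d0 < 0:
            raise ValueError("df_prior must be >= 0")
        _, s02 = estimate_prior(s2, df_resid)
    with np.errstate(invalid="ignore"):
        if np.isinf(d0):
            s2_post = np.full_like(s2, s02)
        elif d0 == 0:
            s2_post = s2.copy()
        else:
            s2_post = (d0 * s02 + df_resid * np.nan_to_num(s2)) / (d0 + df_resid)
            s2_post = np.where(df_resid > 0, s2_post, np.nan)

    df_total = np.where(df_resid > 0, df_resid + (0 if np.isinf(d0) else d0), np.nan)
    if np.isinf(d0):
        df_total = np.full_like(df_resid, np.inf, dtype=float)
        df_total[df_resid <= 0] = np.nan

    computable = (df_resid > 0) & np.isfinite(s2_post) & (s2_post > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        inf_df = np.isinf(df_total)
        if statistic == "t":
            var_contrast = s2_post * (1.0 / counts[:, 0] + 1.0 / counts[:, -1])
            delta = means[:, -1] - means[:, 0]
            stat = np.where(computable, delta / np.sqrt(var_contrast), np.nan)
            p = np.where(
                np.isfinite(stat),
                2.0
                * np.where(
                    inf_df,
                    stats.norm.sf(np.abs(stat)),
                    stats.t.sf(np.abs(stat), np.where(inf_df, 1.0, df_total)),
                ),
                np.nan,
            )
        else:
            stat = np.where(computable, ms_between / s2_post, np.nan)
            # infinite denominator df: F(g-1, inf) is chi2(g-1) / (g-1)
            p = np.where(
                np.isfinite(stat),
                np.where(
                    inf_df,
                    stats.chi2.sf(stat * (g - 1), g - 1),
                    stats.f.sf(stat, g - 1, np.where(inf_df, 1.0, df_total)),
                ),
                np.nan,
            )

    adj = _bh_with_nan(p)
    table = pd.DataFrame(index=probe_ids)
    for k, label in enumerate(comparison):
        table[f"mean_{label}"] = means[:, k]
    table["delta_beta"] = (
        means[:, -1] - means[:, 0] if g == 2 else means[:, -1] - means[:, 0]
    )
    table["stat"] = stat
    table["df_total"] = df_total
    table["p_value"] = p
    table["adj_p_value"] = adj
    table["significant"] = np.where(np.isfinite(adj), adj < alpha, False).astype(bool)
    params = ModerationParams(
        df_prior=d0, s2_prior=s02, df_resid=df_resid, s2=s2, s2_post=s2_post
    )
    return DifferentialResult(
        table=table,
        comparison=comparison,
        statistic=statistic,
        alpha=alpha,
        params=params,
        dropped_probes=dropped,
    )
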