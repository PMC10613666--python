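"""Paired differential statistics shared by the taxon- and pathway-level
analyses: paired t, Benjamini–Hochberg, and the empirical-Bayes moderated
paired t.

The paired design compares a later timepoint against a baseline within each
subject (14D vs Pre in the study's terms): for feature *f* and subject *i*,
``d_i = value(i, t2) − value(i, t1)``, then a one-sample t on the d's.  The
moderated variant shrinks each feature's sample variance toward a prior
``s0²`` with ``d0`` prior degrees of freedom estimated from the spread of
all features' variances (the variance hierarchy of limma-style testing),
buying degrees of freedom when subjects are few.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tables import DIFFERENTIAL_COLUMNS, QuantMatrix, SampleDesign

logger = logging.getLogger(__name__)


def benjamini_hochberg(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Step-up FDR q-values: q_(i) = min_{j>=i} min(1, p_(j)·n/j).

    NaN p-values propagate as NaN and are excluded from n.  Ties keep input
    order (stable sort), which leaves the q-values of tied p's equal.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        pv = p[ok]
        if pv.min() < 0 or pv.max() > 1:
            raise ValueError("p-values must lie in [0, 1]")
        n = pv.size
        order = np.argsort(pv, kind="mergesort")
        adj = pv[order] * n / np.arange(1, n + 1)
        adj = np.minimum(1.0, np.minimum.accumulate(adj[::-1])[::-1])
        out = np.empty(n)
        out[order] = adj
        q[ok] = out
    return q


def paired_runs(
    design: SampleDesign, condition: str, t1: str = "Pre", t2: str = "14D"
) -> list[tuple[str, str, str]]:
    """(subject, run at t1, run at t2) for every subject of `condition`
    observed at both timepoints, sorted by subject.  Errors below 2 pairs."""
    sub = design.df[design.df["condition"] == condition]
    by_subject: dict[str, dict[str, str]] = {}
    for _, row in sub.iterrows():
        by_subject.setdefault(row["subject"], {})[row["timepoint"]] = row["run_id"]
    pairs = [
        (s, tp[t1], tp[t2])
        for s, tp in sorted(by_subject.items())
        if t1 in tp and t2 in tp
    ]
    if len(pairs) < 2:
        raise ValueError(
            f"condition {condition!r}: {len(pairs)} complete {t1}/{t2} pairs; need >= 2"
        )
    return pairs


def _log2_values(m: QuantMatrix) -> pd.DataFrame:
    return m.to_log2().data if m.scale == "linear" else m.data


_TINY_P = np.nextafter(0.0, 1.0)


def _finish(
    rows: list[dict], skipped: list[str], label: str
) -> pd.DataFrame:
    if skipped:
        logger.info("%s: skipped %d features with incomplete pairs", label, len(skipped))
    dt = pd.DataFrame(rows, columns=list(DIFFERENTIAL_COLUMNS))
    if len(dt):
        dt["q_value"] = benjamini_hochberg(dt["p_value"].to_numpy())
    return dt


def paired_ttest(
    m: QuantMatrix,
    design: SampleDesign,
    condition: str,
    t1: str = "Pre",
    t2: str = "14D",
) -> pd.DataFrame:
    """Ordinary paired t-test per feature with BH correction within the call.

    Linear matrices are log2-transformed internally.  Features with any
    missing value in a pair are skipped (complete-case, logged).  The
    degenerate sd(d)=0 case: p=1 when the mean difference is also 0, else
    the smallest positive float, flagged ``degenerate`` — this avoids NaNs
    entering BH while preserving ranking.
    """
    pairs = paired_runs(design, condition, t1, t2)
    vals = _log2_values(m)
    rows, skipped = [], []
    for feat in vals.index:
        v1 = vals.loc[feat, [r1 for _, r1, _ in pairs]].to_numpy(float)
        v2 = vals.loc[feat, [r2 for _, _, r2 in pairs]].to_numpy(float)
        if not (np.isfinite(v1).all() and np.isfinite(v2).all()):
            skipped.append(feat)
            continue
        d = v2 - v1
        n = d.size
        mean = d.mean()
        sd = d.std(ddof=1)
        degenerate = sd == 0.0
        if degenerate:
            t_stat = 0.0 if mean == 0 else np.sign(mean) * np.inf
            p = 1.0 if mean == 0 else _TINY_P
        else:
            t_stat = mean / (sd / np.sqrt(n))
            p = 2.0 * sps.t.sf(abs(t_stat), df=n - 1)
        rows.append(
            dict(
                feature_id=feat,
                condition=condition,
                mean_diff_log2=mean,
                t_stat=t_stat,
                df=float(n - 1),
                p_value=p,
                q_value=np.nan,
                n_pairs=n,
                degenerate=degenerate,
            )
        )
    return _finish(rows, skipped, "paired_ttest")


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F variance prior (d0, s0²).

    Under the hierarchy, sample variances are distributed as
    ``s0² · F(df, d0)``; matching the mean and squared coefficient of
    variation of the observed variances gives::

        CV² = 2 (df + d0 − 2) / (df (d0 − 4))
        d0  = (2 df − 4 + 4 CV² df) / (CV² df − 2)
        s0² = mean(s²) (d0 − 2) / d0

    When the observed spread is at or below the pure-sampling floor
    (CV²·df ≤ 2), the prior is effectively infinitely informative:
    d0 = inf and s0² = mean(s²) (complete shrinkage to the common
    variance).  If d0 ≤ 2 the mean relation is ill-posed; we fall back to
    s0² = mean(s²), a documented approximation for very heavy-tailed
    variance distributions.
    """
    s2 = np.asarray(s2, float)
    s2 = s2[np.isfinite(s2) & (s2 >= 0)]
    if s2.size < 2:
        return np.inf, float(s2.mean()) if s2.size else 0.0
    m = s2.mean()
    if m <= 0:
        return np.inf, 0.0
    cv2 = s2.var(ddof=1) / m**2
    denom = cv2 * df - 2.0
    if denom <= 0:
        return np.inf, m
    d0 = (2.0 * df - 4.0 + 4.0 * cv2 * df) / denom
    if d0 <= 0:
        return np.inf, m
    s02 = m * (d0 - 2.0) / d0 if d0 > 2 else m
    return float(d0), float(s02)


def moderated_paired_ttest(
    m: QuantMatrix,
    design: SampleDesign,
    condition: str,
    t1: str = "Pre",
    t2: str = "14D",
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated paired t-test with BH within the call.

    Posterior variance ``s̃² = (d0·s0² + d·s²)/(d0 + d)`` with residual
    df ``d = n−1``; the moderated t uses ``s̃`` and df ``d + d0``.
    ``prior_df``/``prior_var`` override the method-of-moments estimate
    (``prior_df=0`` recovers the ordinary test exactly).
    """
    pairs = paired_runs(design, condition, t1, t2)
    vals = _log2_values(m)
    feats, diffs, skipped = [], [], []
    for feat in vals.index:
        v1 = vals.loc[feat, [r1 for _, r1, _ in pairs]].to_numpy(float)
        v2 = vals.loc[feat, [r2 for _, _, r2 in pairs]].to_numpy(float)
        if not (np.isfinite(v1).all() and np.isfinite(v2).all()):
            skipped.append(feat)
            continue
        feats.append(feat)
        diffs.append(v2 - v1)
    if not feats:
        return _finish([], skipped, "moderated_paired_ttest")
    d_arr = np.vstack(diffs)
    n = d_arr.shape[1]
    df_resid = float(n - 1)
    means = d_arr.mean(axis=1)
    s2 = d_arr.var(axis=1, ddof=1)
    if prior_df is None:
        d0, s02 = fit_variance_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        s02 = float(prior_var) if prior_var is not None else float(np.mean(s2))
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = df_resid
    else:
        s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0
    df_t = min(df_total, 1e8)  # scipy's t is numerically normal well below this
    rows = []
    for feat, mean, s2p in zip(feats, means, s2_post):
        degenerate = s2p == 0.0
        if degenerate:
            t_stat = 0.0 if mean == 0 else np.sign(mean) * np.inf
            p = 1.0 if mean == 0 else _TINY_P
        else:
            t_stat = mean / np.sqrt(s2p / n)
            p = 2.0 * sps.t.sf(abs(t_stat), df=df_t)
        rows.append(
            dict(
                feature_id=feat,
                condition=condition,
                mean_diff_log2=mean,
                t_stat=t_stat,
                df=float(df_total if np.isfinite(df_total) else np.inf),
                p_value=p,
                q_value=np.nan,
                n_pairs=n,
                degenerate=degenerate,
            )
        )
    return _finish(rows, skipped, "moderated_paired_ttest")
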