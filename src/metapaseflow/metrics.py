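"""Replicate-quality metrics for comparing acquisition workflows:
data completeness, identification overlap, intra-group Pearson correlation
and coefficient-of-variation statistics (with the conventional CV < 0.2
quality threshold).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import ConfigError, QuantMatrix

logger = logging.getLogger(__name__)


@dataclass
class WorkflowMetrics:
    """Bundle of all replicate-quality metrics for one matrix."""

    completeness_per_feature: pd.Series
    completeness_histogram: pd.Series
    pairwise_overlap: pd.DataFrame
    pairwise_pearson: pd.DataFrame
    cv_per_feature: pd.Series
    frac_cv_below: float
    cv_threshold: float


def completeness(m: QuantMatrix) -> tuple[pd.Series, pd.Series]:
    """Per-feature fraction of runs quantified, plus a histogram of
    runs-quantified counts."""
    if len(m.runs) < 1:
        raise ConfigError("completeness needs at least one run")
    present = m.data.notna()
    frac = present.sum(axis=1) / len(m.runs)
    frac.name = "completeness"
    hist = present.sum(axis=1).value_counts().sort_index()
    hist.name = "n_features"
    return frac, hist


def pairwise_overlap(
    id_sets: dict[str, set[str]], metric: str = "jaccard"
) -> pd.DataFrame:
    """Identification overlap for all unordered run pairs.

    ``jaccard`` = |A∩B| / |A∪B|; ``min-denominator`` = |A∩B| / min(|A|,|B|).
    An empty set yields overlap 0 with a warning.
    """
    if metric not in ("jaccard", "min-denominator"):
        raise ConfigError(f"unknown overlap metric: {metric!r}")
    runs = sorted(id_sets)
    if len(runs) < 2:
        raise ConfigError("pairwise_overlap needs at least two runs")
    rows = []
    for a, b in itertools.combinations(runs, 2):
        sa, sb = id_sets[a], id_sets[b]
        if not sa or not sb:
            logger.warning("pairwise_overlap: empty identification set in (%s, %s)", a, b)
            val = 0.0
        else:
            inter = len(sa & sb)
            denom = len(sa | sb) if metric == "jaccard" else min(len(sa), len(sb))
            val = inter / denom
        rows.append(dict(run_a=a, run_b=b, overlap=val))
    return pd.DataFrame(rows, columns=["run_a", "run_b", "overlap"])


def intra_group_pearson(m: QuantMatrix, min_shared: int = 3) -> pd.DataFrame:
    """Pearson r on log2 intensities over mutually quantified features, for
    every unordered run pair; pairs with fewer than ``min_shared`` shared
    features are reported as NaN (logged)."""
    runs = m.runs
    if len(runs) < 2:
        raise ConfigError("intra_group_pearson needs at least two runs")
    log2 = m.to_log2().data if m.scale == "linear" else m.data
    rows = []
    for a, b in itertools.combinations(runs, 2):
        va, vb = log2[a].to_numpy(float), log2[b].to_numpy(float)
        both = np.isfinite(va) & np.isfinite(vb)
        if both.sum() < min_shared:
            logger.info("intra_group_pearson: <%d shared features for (%s, %s)", min_shared, a, b)
            r = np.nan
        else:
            r = float(np.corrcoef(va[both], vb[both])[0, 1])
        rows.append(dict(run_a=a, run_b=b, pearson_r=r))
    return pd.DataFrame(rows, columns=["run_a", "run_b", "pearson_r"])


def cv_stats(m: QuantMatrix, threshold: float = 0.2) -> tuple[pd.Series, float]:
    """Coefficient of variation per feature on the linear scale (sample sd,
    n−1) and the fraction of features with CV strictly below ``threshold``.
    Features with fewer than two quantified values are skipped (logged)."""
    if m.scale != "linear":
        raise ConfigError("cv_stats expects a linear-scale matrix")
    vals = m.data.to_numpy(float)
    n_obs = np.isfinite(vals).sum(axis=1)
    usable = n_obs >= 2
    if (~usable).any():
        logger.info("cv_stats: skipped %d features with <2 values", int((~usable).sum()))
    means = np.nanmean(np.where(np.isfinite(vals), vals, np.nan)[usable], axis=1)
    sds = np.nanstd(np.where(np.isfinite(vals), vals, np.nan)[usable], axis=1, ddof=1)
    cv = pd.Series(sds / means, index=m.data.index[usable], name="cv")
    frac = float((cv < threshold).sum() / len(cv)) if len(cv) else np.nan
    return cv, frac


def workflow_metrics(
    m: QuantMatrix, overlap_metric: str = "jaccard", cv_threshold: float = 0.2
) -> WorkflowMetrics:
    """Compute the full replicate-quality bundle for one matrix."""
    frac, hist = completeness(m)
    id_sets = {run: set(m.data.index[m.data[run].notna()]) for run in m.runs}
    overlap = pairwise_overlap(id_sets, metric=overlap_metric)
    pearson = intra_group_pearson(m)
    cv, frac_below = cv_stats(m, threshold=cv_threshold)
    return WorkflowMetrics(
        completeness_per_feature=frac,
        completeness_histogram=hist,
        pairwise_overlap=overlap,
        pairwise_pearson=pearson,
        cv_per_feature=cv,
        frac_cv_below=frac_below,
        cv_threshold=cv_threshold,
    )
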