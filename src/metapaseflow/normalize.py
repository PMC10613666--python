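"""Precursor-level filtering, normalization, batch correction and MaxLFQ.

The processing order follows the study pipeline: identification filtering at
q < 0.01 (strict) on both precursor and protein-group level, median
normalization, quantile batch correction, then MaxLFQ aggregation to peptide
and protein-group matrices.  All internal arithmetic is in log2; public
matrices are linear.

"Quantile batch correction" here is within-batch quantile normalization to a
global reference distribution (the mean of order statistics across all runs,
computed on complete features).  This exactly removes location–scale batch
artifacts; the reference-based variant keeps runs comparable across batches.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .tables import ConfigError, IntegrityError, PrecursorTable, QuantMatrix, SampleDesign

logger = logging.getLogger(__name__)


@dataclass
class NormalizationReport:
    """Bookkeeping emitted by each normalization step."""

    step: str
    run_medians_before: dict[str, float] = field(default_factory=dict)
    run_medians_after: dict[str, float] = field(default_factory=dict)
    target: float | None = None
    batches: dict[str, list[str]] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "step": self.step,
            "run_medians_before": self.run_medians_before,
            "run_medians_after": self.run_medians_after,
            "target": self.target,
            "batches": self.batches,
            "counts": self.counts,
        }


def filter_by_q(
    t: PrecursorTable, precursor_q_max: float = 0.01, protein_q_max: float = 0.01
) -> PrecursorTable:
    """Keep rows with precursor_q < precursor_q_max AND protein_group_q <
    protein_q_max (both strictly)."""
    for name, thr in (("precursor_q_max", precursor_q_max), ("protein_q_max", protein_q_max)):
        if not (0 < thr <= 1):
            raise ConfigError(f"{name} must lie in (0, 1]")
    keep = (t.df["precursor_q"] < precursor_q_max) & (
        t.df["protein_group_q"] < protein_q_max
    )
    n_in, n_out = len(t.df), int(keep.sum())
    logger.info("filter_by_q: %d of %d rows retained", n_out, n_in)
    if n_out == 0:
        logger.warning("filter_by_q: no rows pass the q-value thresholds")
    return PrecursorTable(t.df.loc[keep].reset_index(drop=True))


def median_normalize(m: QuantMatrix) -> tuple[QuantMatrix, NormalizationReport]:
    """Shift each run (in log2) so its median equals the mean of all runs'
    pre-normalization medians; returns a linear-scale matrix."""
    if m.scale != "linear":
        raise ConfigError("median_normalize expects a linear-scale matrix")
    log2 = np.log2(m.data)
    medians = log2.median(axis=0, skipna=True)
    dead = medians.index[medians.isna()]
    if len(dead):
        raise ValueError(f"run has no quantified values: {dead[0]!r}")
    target = float(medians.mean())
    shifted = log2 + (target - medians)
    report = NormalizationReport(
        step="median_normalize",
        run_medians_before={r: float(v) for r, v in medians.items()},
        run_medians_after={r: float(v) for r, v in shifted.median(axis=0).items()},
        target=target,
    )
    return QuantMatrix(2.0**shifted, scale="linear"), report


def quantile_batch_correct(
    m: QuantMatrix, design: SampleDesign
) -> tuple[QuantMatrix, NormalizationReport]:
    """Map each run's log2 values onto a global reference distribution by rank.

    The reference is the mean of order statistics across all runs, computed
    over complete features only.  A run with a different number of observed
    values is mapped by linear interpolation of the reference quantiles;
    tied values receive the average of their mapped values.  Missing entries
    stay missing; a batch with a single run is still mapped (no error).
    """
    if m.scale != "linear":
        raise ConfigError("quantile_batch_correct expects a linear-scale matrix")
    batch_of = design.batch_of()
    unassigned = [r for r in m.runs if r not in batch_of]
    if unassigned:
        raise ConfigError(f"runs without batch assignment: {unassigned[:3]}")
    log2 = np.log2(m.data)
    complete = log2.dropna(axis=0, how="any")
    if complete.empty:
        raise IntegrityError("no complete features to build the reference from")
    ref = np.sort(complete.to_numpy(float), axis=0).mean(axis=1)
    p = ref.size
    out = log2.copy()
    for run in log2.columns:
        col = log2[run].to_numpy(float)
        obs = np.isfinite(col)
        vals = col[obs]
        k = vals.size
        if k == 0:
            continue
        grid = np.linspace(0.0, 1.0, k) if k > 1 else np.array([0.5])
        mapped_sorted = np.interp(grid, np.linspace(0.0, 1.0, p), ref)
        order = np.argsort(vals, kind="mergesort")
        mapped = np.empty(k)
        mapped[order] = mapped_sorted
        # ties -> average of the reference values they were mapped to
        uniq, inv = np.unique(vals, return_inverse=True)
        if uniq.size < k:
            sums = np.bincount(inv, weights=mapped)
            cnts = np.bincount(inv)
            mapped = (sums / cnts)[inv]
        newcol = col.copy()
        newcol[obs] = mapped
        out[run] = newcol
    batches: dict[str, list[str]] = {}
    for run in m.runs:
        batches.setdefault(str(batch_of[run]), []).append(run)
    report = NormalizationReport(
        step="quantile_batch_correct",
        run_medians_before={r: float(v) for r, v in log2.median(axis=0).items()},
        run_medians_after={r: float(v) for r, v in out.median(axis=0).items()},
        batches=batches,
        counts={"reference_features": p},
    )
    return QuantMatrix(2.0**out, scale="linear"), report


# ---------------------------------------------------------------------------
# MaxLFQ
# ---------------------------------------------------------------------------


def _solve_profile(
    X: np.ndarray, linear: np.ndarray, min_ratio_count: int
) -> np.ndarray:
    """MaxLFQ run profile for one feature.

    X: (precursors × runs) log2 intensities with NaN; linear: same on linear
    scale.  Pairwise run-ratio = median of log2 ratios over precursors seen
    in both runs, kept when the shared count reaches ``min_ratio_count``;
    run abundances solve the least-squares system over the ratio graph per
    connected component; each component is anchored so the sum of its linear
    estimates equals the sum of its raw precursor intensities.
    """
    n_prec, n_runs = X.shape
    present = np.isfinite(X)
    quantified = present.any(axis=0)
    values = np.full(n_runs, np.nan)
    if n_prec == 1:
        values[quantified] = linear[0, quantified]
        return values
    shared = np.einsum("pj,pk->jk", present.astype(np.int64), present.astype(np.int64))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(X[:, None, :] - X[:, :, None], axis=0)  # med[j,k] = b_k - b_j
    adj = np.zeros((n_runs, n_runs), dtype=np.int8)
    edges: list[tuple[int, int, float]] = []
    for j in range(n_runs):
        if not quantified[j]:
            continue
        for k in range(j + 1, n_runs):
            if quantified[k] and shared[j, k] >= min_ratio_count and np.isfinite(med[j, k]):
                edges.append((j, k, med[j, k]))
                adj[j, k] = adj[k, j] = 1
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    for comp in range(n_comp):
        idx = np.where((labels == comp) & quantified)[0]
        if idx.size == 0:
            continue
        if idx.size == 1:
            b = np.zeros(1)
        else:
            pos = {run: i for i, run in enumerate(idx)}
            comp_edges = [(j, k, r) for j, k, r in edges if j in pos and k in pos]
            A = np.zeros((len(comp_edges), idx.size))
            rhs = np.zeros(len(comp_edges))
            for e, (j, k, r) in enumerate(comp_edges):
                A[e, pos[j]] = -1.0
                A[e, pos[k]] = 1.0
                rhs[e] = r
            b, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        raw_total = np.nansum(linear[:, idx])
        lin = 2.0**b
        values[idx] = lin * (raw_total / lin.sum())
    return values


def maxlfq(
    t: PrecursorTable, level: str = "protein_group", min_ratio_count: int = 1
) -> QuantMatrix:
    """MaxLFQ aggregation of precursors to peptide or protein-group profiles.

    ``level="peptide"`` groups precursors by stripped sequence,
    ``level="protein_group"`` by protein group.  Features with no quantified
    precursor in any run are omitted (logged).  Runs not connected to any
    quantified precursor of a feature are missing for that feature.
    """
    if level not in ("peptide", "protein_group"):
        raise ConfigError(f"unknown level: {level!r}")
    key = "stripped_sequence" if level == "peptide" else "protein_group"
    runs = sorted(t.df["run_id"].unique())
    out: dict[str, np.ndarray] = {}
    omitted = 0
    # fast path: features backed by a single precursor are their own profile
    n_prec = t.df.groupby(key)["precursor_id"].nunique()
    single = set(n_prec.index[n_prec == 1])
    if single:
        sub1 = t.df[t.df[key].isin(single)]
        piv = sub1.pivot(index=key, columns="run_id", values="intensity").reindex(
            columns=runs
        )
        vals = piv.to_numpy(float)
        quantified = np.isfinite(vals).any(axis=1)
        omitted += int((~quantified).sum())
        for feat, row in zip(piv.index[quantified], vals[quantified]):
            out[str(feat)] = row
    multi = t.df[~t.df[key].isin(single)]
    for feat, sub in multi.groupby(key, sort=True):
        mat = sub.pivot(index="precursor_id", columns="run_id", values="intensity")
        mat = mat.reindex(columns=runs)
        linear = mat.to_numpy(float)
        keep = np.isfinite(linear).any(axis=1)
        if not keep.any():
            omitted += 1
            continue
        linear = linear[keep]
        with np.errstate(invalid="ignore"):
            X = np.log2(linear)
        out[str(feat)] = _solve_profile(X, linear, min_ratio_count)
    if omitted:
        logger.info("maxlfq: omitted %d features with no quantified precursor", omitted)
    df = pd.DataFrame.from_dict(out, orient="index", columns=runs).sort_index()
    df.index.name = "feature_id"
    return QuantMatrix(df, scale="linear")
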