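"""Protein-level paired testing and KEGG-pathway-level quantification.

The functional quantification procedure:

1. proteins are tested 14D-vs-Pre within each condition (paired t, ordinary
   or limma-style moderated) and prefiltered at p < 0.005 (strict, raw p);
2. significant proteins without K-number annotation are dropped;
3. the linear intensities of significant proteins sharing a K number are
   summed into one K-level intensity per run;
4. each K number fans out to *all* of its pathways with duplicated
   intensities (a protein may serve several pathways);
5. per (pathway, run): summed intensity over the K numbers quantified in
   that run, divided by the number of such K numbers (a per-run mean over
   observed members), then log2-transformed for statistics.

Pathway-level differences are tested with the moderated paired t by default
and corrected with Benjamini–Hochberg within the call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import moderated_paired_ttest, paired_ttest
from .tables import ConfigError, FunctionMap, QuantMatrix, SampleDesign

logger = logging.getLogger(__name__)


@dataclass
class PathwayQuantResult:
    """Pathways × runs log2 matrix with membership bookkeeping.

    A pathway value is defined in a run iff at least one member K number is
    quantified there; ``k_counts`` holds the per-run member counts used as
    normalization denominators.
    """

    pathway_matrix: QuantMatrix  # scale="log2"
    k_counts: pd.DataFrame  # pathways × runs, int
    member_map: dict[str, set[str]]  # pathway -> K numbers used
    prefilter_log: dict[str, int] = field(default_factory=dict)


def protein_paired_test(
    protein_m: QuantMatrix,
    design: SampleDesign,
    condition: str,
    mode: str = "moderated",
    t1: str = "Pre",
    t2: str = "14D",
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Paired 14D-vs-Pre test per protein (log2 internally).

    ``mode="ordinary"`` is the plain paired t; ``mode="moderated"`` shrinks
    variances with the empirical-Bayes prior (``prior_df`` overrides the
    method-of-moments estimate; 0 recovers the ordinary test).
    """
    if mode == "ordinary":
        return paired_ttest(protein_m, design, condition, t1=t1, t2=t2)
    if mode == "moderated":
        return moderated_paired_ttest(
            protein_m, design, condition, t1=t1, t2=t2, prior_df=prior_df
        )
    raise ConfigError(f"unknown mode: {mode!r}")


def significant_proteins(dt: pd.DataFrame, p_max: float = 0.005) -> list[str]:
    """Prefilter: proteins with raw p strictly below ``p_max``."""
    if not (0 < p_max <= 1):
        raise ConfigError("p_max must lie in (0, 1]")
    return list(dt.loc[dt["p_value"] < p_max, "feature_id"])


def aggregate_pathways(
    sig_proteins: list[str] | set[str],
    protein_m: QuantMatrix,
    fmap: FunctionMap,
) -> PathwayQuantResult:
    """K-number and pathway aggregation of the significant protein set."""
    sig = [p for p in sorted(set(sig_proteins)) if p in set(protein_m.features)]
    data = protein_m.data if protein_m.scale == "linear" else protein_m.to_linear().data
    runs = list(data.columns)
    ks_of = fmap.ks_of_protein()
    pws_of = fmap.pathways_of_k()

    with_k = [p for p in sig if ks_of.get(p)]
    prefilter_log = {
        "proteins_in": len(set(sig_proteins)),
        "proteins_with_k": len(with_k),
    }
    # step 2: K-level intensity = sum over significant proteins mapping to K
    k_members: dict[str, list[str]] = {}
    for p in with_k:
        for k in sorted(ks_of[p]):
            k_members.setdefault(k, []).append(p)
    if not k_members:
        logger.warning("aggregate_pathways: no significant protein carries a K number")
        empty = pd.DataFrame(index=pd.Index([], name="pathway_id"), columns=runs, dtype=float)
        return PathwayQuantResult(
            QuantMatrix(empty, scale="log2"),
            empty.fillna(0).astype(int),
            {},
            prefilter_log,
        )
    k_int = pd.DataFrame(
        {
            k: data.loc[members].sum(axis=0, skipna=True, min_count=1)
            for k, members in sorted(k_members.items())
        }
    ).T  # K × runs; NaN where no member protein quantified

    # steps 3-5: fan out K numbers to all their pathways, mean over observed
    member_map: dict[str, set[str]] = {}
    for k in k_int.index:
        for pw in pws_of.get(k, ()):
            member_map.setdefault(pw, set()).add(k)
    pathways = sorted(member_map)
    values = pd.DataFrame(np.nan, index=pathways, columns=runs, dtype=float)
    counts = pd.DataFrame(0, index=pathways, columns=runs, dtype=int)
    for pw in pathways:
        sub = k_int.loc[sorted(member_map[pw])]
        n_obs = sub.notna().sum(axis=0)
        summed = sub.sum(axis=0, skipna=True, min_count=1)
        counts.loc[pw] = n_obs.astype(int)
        with np.errstate(invalid="ignore", divide="ignore"):
            values.loc[pw] = np.where(n_obs > 0, np.log2(summed / n_obs), np.nan)
    values.index.name = "pathway_id"
    counts.index.name = "pathway_id"
    return PathwayQuantResult(
        QuantMatrix(values, scale="log2"), counts, member_map, prefilter_log
    )


def pathway_paired_test(
    pr: PathwayQuantResult,
    design: SampleDesign,
    condition: str,
    mode: str = "moderated",
    t1: str = "Pre",
    t2: str = "14D",
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Paired test on log2 pathway values; BH within the call.

    Pathways missing in any run of a pair are skipped (logged by the
    underlying test).  Significance bands at q<0.05 and q<0.01 are
    attached as ``DataFrame.attrs["significance_bands"]``.
    """
    if mode == "ordinary":
        dt = paired_ttest(pr.pathway_matrix, design, condition, t1=t1, t2=t2)
    elif mode == "moderated":
        dt = moderated_paired_ttest(
            pr.pathway_matrix, design, condition, t1=t1, t2=t2, prior_df=prior_df
        )
    else:
        raise ConfigError(f"unknown mode: {mode!r}")
    dt.attrs["significance_bands"] = {
        "q<0.05": int((dt["q_value"] < 0.05).sum()),
        "q<0.01": int((dt["q_value"] < 0.01).sum()),
    }
    return dt
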