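"""Taxon-level quantification and paired differential analysis.

The taxonomic quantification procedure, per rank:

1. drop peptides without an annotation at the rank under analysis (the
   lineage table is an LCA result — a peptide blank at the rank is not
   specific to any taxon there);
2. group peptides by their taxon at that rank and retain taxa with at least
   ``min_unique_peptides`` distinct sequences (default 3);
3. drop peptides not quantified in all runs of the analysis scope
   (complete-case);
4. re-check the unique-peptide threshold after the complete-case filter, so
   no taxon is ever reported from fewer peptides than the threshold;
5. per run, the taxon value is the sum of log2-transformed intensities of
   its peptides.

Downstream, per-condition matrices of the later timepoint vs baseline are
compared with a paired t-test and Benjamini–Hochberg correction.  The
peptide-centric taxon × pathway crosstab applies the "at least 3 peptides
per taxon–pathway cell" threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .stats import benjamini_hochberg, moderated_paired_ttest, paired_ttest  # noqa: F401
from .tables import (
    RANKS,
    ConfigError,
    FunctionMap,
    QuantMatrix,
    SampleDesign,
    TaxonomyTable,
)

logger = logging.getLogger(__name__)


@dataclass
class TaxonQuantResult:
    """Taxa × runs summed-log2 matrix plus filter bookkeeping.

    Every retained taxon has at least the requested number of unique
    peptides; the matrix is complete by construction.
    """

    rank: str
    matrix: QuantMatrix  # scale="log2" (summed log2 intensities)
    peptides_per_taxon: dict[str, int]
    filter_log: dict[str, int] = field(default_factory=dict)


def aggregate_taxa(
    peptide_m: QuantMatrix,
    tax: TaxonomyTable,
    rank: str,
    min_unique_peptides: int = 3,
    complete_within: str = "all_runs",
    design: SampleDesign | None = None,
) -> TaxonQuantResult:
    """Aggregate a peptide matrix to taxon level at ``rank``.

    ``complete_within="all_runs"`` (default) requires peptides to be
    quantified in every column of the matrix.  ``"per_condition"``
    evaluates completeness within each condition's runs separately (needs
    ``design``): a peptide may contribute to some conditions only, and a
    taxon is retained only if it keeps the unique-peptide threshold in
    every condition present, so the matrix stays complete.
    """
    if rank not in RANKS:
        raise ConfigError(f"unknown rank: {rank!r}")
    if complete_within not in ("all_runs", "per_condition"):
        raise ConfigError(f"unknown complete_within: {complete_within!r}")
    if complete_within == "per_condition" and design is None:
        raise ConfigError("complete_within='per_condition' requires a design")

    data = peptide_m.to_log2().data if peptide_m.scale == "linear" else peptide_m.data
    runs = list(data.columns)
    lineage = tax.lineage_at(rank)
    flog: dict[str, int] = {"peptides_in": data.shape[0]}

    # step 1: rank-specific peptides only
    annotated = [p for p in data.index if lineage.get(p, "") != ""]
    flog["removed_unannotated_at_rank"] = data.shape[0] - len(annotated)

    # step 2: >= min unique peptides per taxon
    taxon_of = {p: lineage[p] for p in annotated}
    members: dict[str, list[str]] = {}
    for p in sorted(annotated):
        members.setdefault(taxon_of[p], []).append(p)
    retained = {t: ps for t, ps in members.items() if len(ps) >= min_unique_peptides}
    flog["taxa_annotated"] = len(members)
    flog["taxa_below_min_unique"] = len(members) - len(retained)

    if complete_within == "all_runs":
        scopes = {None: runs}
    else:
        scopes = {}
        for cond in design.df["condition"].unique():
            cond_runs = [r for r in runs if r in set(design.runs_for(cond))]
            if cond_runs:
                scopes[cond] = cond_runs

    # steps 3+4: complete-case within scope, then re-check the threshold
    kept_per_scope: dict[object, dict[str, list[str]]] = {}
    dropped_incomplete = 0
    for scope, scope_runs in scopes.items():
        kept: dict[str, list[str]] = {}
        for taxon, ps in retained.items():
            complete = [
                p for p in ps if np.isfinite(data.loc[p, scope_runs].to_numpy(float)).all()
            ]
            dropped_incomplete += len(ps) - len(complete)
            if len(complete) >= min_unique_peptides:
                kept[taxon] = complete
        kept_per_scope[scope] = kept
    flog["peptide_scope_drops_incomplete"] = dropped_incomplete

    final_taxa = sorted(set.intersection(*(set(k) for k in kept_per_scope.values()))) if kept_per_scope else []
    flog["taxa_dropped_after_complete_case"] = len(retained) - len(final_taxa)
    flog["taxa_retained"] = len(final_taxa)

    # step 5: summed log2 per taxon per run
    out = pd.DataFrame(np.nan, index=final_taxa, columns=runs, dtype=float)
    for scope, scope_runs in scopes.items():
        kept = kept_per_scope[scope]
        for taxon in final_taxa:
            out.loc[taxon, scope_runs] = (
                data.loc[kept[taxon], scope_runs].to_numpy(float).sum(axis=0)
            )
    out.index.name = "taxon"
    peptides_per_taxon = {
        t: min(len(kept_per_scope[s][t]) for s in kept_per_scope) for t in final_taxa
    }
    return TaxonQuantResult(
        rank=rank,
        matrix=QuantMatrix(out, scale="log2"),
        peptides_per_taxon=peptides_per_taxon,
        filter_log=flog,
    )


def taxon_function_crosstab(
    peptide_m: QuantMatrix,
    tax: TaxonomyTable,
    fmap: FunctionMap,
    peptide_to_pg: Mapping[str, str | Iterable[str]],
    rank: str,
    min_peptides: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Peptide-centric taxon × pathway crosstab.

    Each peptide inherits the K numbers (hence pathways) of its protein
    group(s); cell (taxon, pathway) counts distinct peptides annotated to
    the taxon at ``rank`` and to the pathway.  Cells below ``min_peptides``
    are blanked (NaN).  Returns ``(counts, intensity)`` where ``intensity``
    is long-format (taxon, pathway_id, run_id, intensity): per-run sums of
    linear intensities over the qualifying cells' peptides.
    """
    if rank not in RANKS:
        raise ConfigError(f"unknown rank: {rank!r}")
    data = peptide_m.data if peptide_m.scale == "linear" else peptide_m.to_linear().data
    lineage = tax.lineage_at(rank)
    ks = fmap.ks_of_protein()
    pws = fmap.pathways_of_k()

    cell_peptides: dict[tuple[str, str], set[str]] = {}
    for pep in data.index:
        taxon = lineage.get(pep, "")
        if taxon == "":
            continue
        pgs = peptide_to_pg.get(pep, ())
        if isinstance(pgs, str):
            pgs = (pgs,)
        pathways = {pw for pg in pgs for k in ks.get(pg, ()) for pw in pws.get(k, ())}
        for pw in pathways:
            cell_peptides.setdefault((taxon, pw), set()).add(pep)

    taxa = sorted({t for t, _ in cell_peptides})
    pathways_all = sorted({w for _, w in cell_peptides})
    counts = pd.DataFrame(np.nan, index=taxa, columns=pathways_all, dtype=float)
    rows = []
    for (taxon, pw), peps in sorted(cell_peptides.items()):
        n = len(peps)
        if n < min_peptides:
            continue
        counts.loc[taxon, pw] = float(n)
        per_run = data.loc[sorted(peps)].sum(axis=0, skipna=True)
        for run, v in per_run.items():
            rows.append(
                dict(taxon=taxon, pathway_id=pw, run_id=run, intensity=float(v))
            )
    counts.index.name = "taxon"
    intensity = pd.DataFrame(rows, columns=["taxon", "pathway_id", "run_id", "intensity"])
    return counts, intensity
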