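"""Monte-Carlo validation experiments for the pipeline.

These drivers run the full workflow on synthetic datasets and measure the
statistical properties the package is designed to guarantee: type-I error
calibration of the paired taxon- and pathway-level tests under a global
null, and recovery of planted log2 fold changes.  They are used by the test
suite and by the reproduction script.

Experiment design notes:

* The analysis pipeline is the study's: q-filter at 0.01, median
  normalization, quantile batch correction, MaxLFQ, per-condition
  aggregation and paired testing.  Complete-case filtering is applied
  within each condition's runs (the differential matrices are built per
  condition, so "quantified in all samples" refers to that condition's
  samples).
* Null calibration feeds the pathway test all proteins (prefilter p=1):
  under a global null the p<0.005 prefilter passes almost nothing, which
  would starve the test being calibrated rather than calibrate it.
* The recovery experiment uses an 80-species community so the planted
  species carries ~1% of total signal, as a single species does in real
  gut metaproteomes; at much smaller scale, run-level normalization
  consumes a measurable share of a planted fold change, which is an
  artifact of simulation size rather than a property of the method.
"""

from __future__ import annotations

import numpy as np

from . import functions as fn
from . import normalize as nz
from . import taxa as tx
from .simulate import SimBundle, SimConfig, simulate_dataset
from .tables import QuantMatrix

RECOVERY_TAXA = {
    "superkingdom": 1,
    "kingdom": 1,
    "phylum": 4,
    "class": 5,
    "order": 8,
    "family": 12,
    "genus": 20,
    "species": 80,
}


def normalized_matrices(bundle: SimBundle, batch_correct: bool = True):
    """q-filter + median normalize (+ quantile batch correct) + MaxLFQ at
    peptide and protein-group level."""
    filtered = nz.filter_by_q(bundle.precursors)
    pep = nz.maxlfq(filtered, level="peptide")
    pep, _ = nz.median_normalize(pep)
    prot = nz.maxlfq(filtered, level="protein_group")
    prot, _ = nz.median_normalize(prot)
    if batch_correct:
        pep, _ = nz.quantile_batch_correct(pep, bundle.design)
        prot, _ = nz.quantile_batch_correct(prot, bundle.design)
    return pep, prot


def microbial_peptides(pep: QuantMatrix, bundle: SimBundle) -> QuantMatrix:
    origin = bundle.precursors.origin_of_peptides()
    keep = [p for p in pep.features if origin.get(p) == "microbial"]
    return QuantMatrix(pep.data.loc[keep], scale=pep.scale)


def condition_matrix(m: QuantMatrix, bundle: SimBundle, condition: str) -> QuantMatrix:
    runs = [r for r in m.runs if r in set(bundle.design.runs_for(condition))]
    return QuantMatrix(m.data[runs], scale=m.scale)


def null_calibration(
    n_seeds: int = 50, base_seed: int = 2000, alpha: float = 0.05, rank: str = "species"
) -> dict:
    """Type-I error of the paired taxon and pathway tests on null data.

    Simulates ``n_seeds`` datasets with no planted effects under default
    conditions (4 subjects/condition, peptide CV 0.2), runs the full
    pipeline, and pools raw p-values over all conditions and seeds.
    """
    taxa_p: list[float] = []
    pw_p: list[float] = []
    for s in range(n_seeds):
        cfg = SimConfig(seed=base_seed + s)
        bundle = simulate_dataset(cfg)
        pep, prot = normalized_matrices(bundle)
        pepm = microbial_peptides(pep, bundle)
        for cond in cfg.conditions:
            sub = condition_matrix(pepm, bundle, cond)
            res = tx.aggregate_taxa(sub, bundle.taxonomy, rank=rank)
            dt = tx.paired_ttest(res.matrix, bundle.design, cond)
            taxa_p.extend(dt["p_value"].tolist())
            pdt = fn.protein_paired_test(prot, bundle.design, cond, mode="moderated")
            everything = fn.significant_proteins(pdt, p_max=1.0)
            pr = fn.aggregate_pathways(everything, prot, bundle.function_map)
            pwdt = fn.pathway_paired_test(pr, bundle.design, cond)
            pw_p.extend(pwdt["p_value"].tolist())
    taxa_arr = np.asarray(taxa_p)
    pw_arr = np.asarray(pw_p)
    both = np.concatenate([taxa_arr, pw_arr])
    return {
        "taxa_rate": float((taxa_arr < alpha).mean()),
        "taxa_n": int(taxa_arr.size),
        "pathway_rate": float((pw_arr < alpha).mean()),
        "pathway_n": int(pw_arr.size),
        "combined_rate": float((both < alpha).mean()),
        "combined_n": int(both.size),
        "alpha": alpha,
    }


def planted_taxon_recovery(
    n_seeds: int = 50,
    base_seed: int = 1000,
    taxon: str = "sp001",
    condition: str = "SNI",
    log2_fc: float = 1.0,
    q_threshold: float = 0.05,
) -> dict:
    """Recovery of a planted per-peptide log2 fold change on one species.

    Per seed: full pipeline, species-level aggregation within the planted
    condition, paired t with BH.  The per-peptide effect estimate is the
    taxon's summed-log2 mean difference divided by its peptide count; a
    seed counts as detected when the taxon's q-value clears ``q_threshold``
    (a seed where the taxon fails the filters counts as not detected).
    """
    estimates: list[float] = []
    detected = 0
    absent = 0
    for s in range(n_seeds):
        cfg = SimConfig(
            seed=base_seed + s,
            n_taxa_per_rank=dict(RECOVERY_TAXA),
            planted_taxa=((taxon, condition, log2_fc),),
        )
        bundle = simulate_dataset(cfg)
        pep, _ = normalized_matrices(bundle)
        pepm = microbial_peptides(pep, bundle)
        sub = condition_matrix(pepm, bundle, condition)
        res = tx.aggregate_taxa(sub, bundle.taxonomy, rank="species")
        dt = tx.paired_ttest(res.matrix, bundle.design, condition)
        sel = dt[dt["feature_id"] == taxon]
        if not len(sel):
            absent += 1
            continue
        row = sel.iloc[0]
        estimates.append(row["mean_diff_log2"] / res.peptides_per_taxon[taxon])
        if row["q_value"] < q_threshold:
            detected += 1
    return {
        "bias": float(np.mean(estimates) - log2_fc),
        "mean_estimate": float(np.mean(estimates)),
        "detection_rate": detected / n_seeds,
        "n_seeds": n_seeds,
        "n_measured": len(estimates),
        "absent": absent,
    }


def noise_free_pathway_recovery(
    seed: int = 7, pathway: str = "map00003", condition: str = "SNI", log2_fc: float = 1.0
) -> dict:
    """Exact recovery of a planted pathway fold change without noise.

    All noise sources off: the protein prefilter passes exactly the planted
    proteins and the pathway's mean-over-K normalization passes the uniform
    fold through log2 unchanged, so the mean difference equals the planted
    value to machine precision.
    """
    cfg = SimConfig(
        seed=seed,
        peptide_cv=0.0,
        batch_shift_sd_log2=0.0,
        sample_depth_sd_log2=0.0,
        subject_sd_log2=0.0,
        missingness="none",
        decoy_fraction=0.0,
        planted_pathways=((pathway, condition, log2_fc),),
    )
    bundle = simulate_dataset(cfg)
    filtered = nz.filter_by_q(bundle.precursors)
    prot = nz.maxlfq(filtered, level="protein_group")
    pdt = fn.protein_paired_test(prot, bundle.design, condition, mode="moderated")
    sig = fn.significant_proteins(pdt, p_max=0.005)
    pr = fn.aggregate_pathways(sig, prot, bundle.function_map)
    pwdt = fn.pathway_paired_test(pr, bundle.design, condition)
    row = pwdt[pwdt["feature_id"] == pathway].iloc[0]
    return {
        "mean_diff_log2": float(row["mean_diff_log2"]),
        "error": float(abs(row["mean_diff_log2"] - log2_fc)),
        "n_significant_proteins": len(sig),
    }
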