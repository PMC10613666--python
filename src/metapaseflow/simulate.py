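"""Synthetic metaproteomic dataset generator.

Emulates the study design the pipeline was built for: a paired two-timepoint
(Pre / 14D), three-condition (Naive / SHAM / SNI), four-subjects-per-
condition mouse gut metaproteome, acquired in batches, reported as a
precursor-level table with q-values plus the annotation tables the pipeline
consumes (peptide lineages, protein→K number, K number→pathway).

Intensities are generated in log2 space as

    taxon baseline + protein offset + peptide ionization offset
    + subject intercept + per-run depth shift + per-batch shift
    + planted effect + N(0, sigma)

and exponentiated, so planted log2 fold changes are exact in expectation and
match the pipeline's analysis scale.  Planted taxon effects shift every
peptide of the taxon in the chosen condition's 14D runs only; planted
pathway effects shift every protein annotated to any K number of the
pathway, so both the protein prefilter and pathway aggregation see the
signal.  Missingness is applied last: "dia-like" is a small uniform dropout
rate, "dda-like" is intensity-dependent (logistic in log2 intensity, more
dropout at low abundance).  q-values are Uniform(0, 0.009) for genuine
precursors with a decoy fraction at Uniform(0.01, 0.5) to exercise the
q < 0.01 filter.  Host proteins form a single Metazoa-only lineage branch
with origin="host".  Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import (
    RANKS,
    ConfigError,
    FunctionMap,
    PrecursorTable,
    SampleDesign,
    TaxonomyTable,
    write_design,
    write_function_map,
    write_precursor_report,
    write_taxonomy,
)

logger = logging.getLogger(__name__)

_RANK_PREFIX = {
    "superkingdom": "sk",
    "kingdom": "kng",
    "phylum": "phy",
    "class": "cls",
    "order": "ord",
    "family": "fam",
    "genus": "gen",
    "species": "sp",
}

_HOST_LINEAGE = (
    "Eukaryota",
    "Metazoa",
    "Chordata",
    "Mammalia",
    "Rodentia",
    "Muridae",
    "Mus",
    "Mus musculus",
)

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _default_taxa() -> dict[str, int]:
    return {
        "superkingdom": 1,
        "kingdom": 1,
        "phylum": 4,
        "class": 5,
        "order": 8,
        "family": 12,
        "genus": 20,
        "species": 40,
    }


def _default_rank_specific() -> dict[str, float]:
    # fraction of peptides whose lineage is blanked below the given rank
    # (LCA ambiguity); the remainder resolve to species
    return {"phylum": 0.05, "class": 0.05, "order": 0.05, "family": 0.10, "genus": 0.10}


@dataclass
class SimConfig:
    """Full specification of one synthetic dataset (seed mandatory)."""

    seed: int
    n_taxa_per_rank: Mapping[str, int] = field(default_factory=_default_taxa)
    n_proteins_per_species: int = 8
    n_peptides_per_protein: int = 6
    n_host_proteins: int = 10
    frac_rank_specific: Mapping[str, float] = field(default_factory=_default_rank_specific)
    n_k_numbers: int = 60
    n_pathways: int = 15
    k_per_protein: int = 1
    conditions: Sequence[str] = ("Naive", "SHAM", "SNI")
    n_subjects_per_condition: int = 4
    timepoints: Sequence[str] = ("Pre", "14D")
    n_batches: int = 2
    batch_shift_sd_log2: float = 0.3
    sample_depth_sd_log2: float = 0.2
    subject_sd_log2: float = 0.3
    peptide_cv: float = 0.2
    missingness: str = "dia-like"  # "dia-like" | "dda-like" | "none"
    dia_missing_rate: float = 0.02
    dda_midpoint_log2: float = 17.0
    dda_slope: float = 1.2
    decoy_fraction: float = 0.05
    baseline_mean_log2: float = 20.0
    baseline_sd_log2: float = 2.0
    protein_offset_sd_log2: float = 1.0
    peptide_offset_sd_log2: float = 1.5
    planted_taxa: Sequence[tuple[str, str, float]] = ()  # (taxon, condition, log2 fc at 14D)
    planted_pathways: Sequence[tuple[str, str, float]] = ()  # (pathway_id, condition, log2 fc)

    def validate(self) -> None:
        for rank in self.n_taxa_per_rank:
            if rank not in RANKS:
                raise ConfigError(f"unknown rank in n_taxa_per_rank: {rank!r}")
        for rank, frac in self.frac_rank_specific.items():
            if rank not in RANKS:
                raise ConfigError(f"unknown rank in frac_rank_specific: {rank!r}")
            if not (0 <= frac <= 1):
                raise ConfigError("frac_rank_specific values must lie in [0, 1]")
        if sum(self.frac_rank_specific.values()) > 1:
            raise ConfigError("frac_rank_specific fractions sum above 1")
        for p in (self.dia_missing_rate, self.decoy_fraction):
            if not (0 <= p <= 1):
                raise ConfigError("rates must lie in [0, 1]")
        for _, _, fc in list(self.planted_taxa) + list(self.planted_pathways):
            if not np.isfinite(fc):
                raise ConfigError("planted fold changes must be finite")
        if self.missingness not in ("dia-like", "dda-like", "none"):
            raise ConfigError(f"unknown missingness: {self.missingness!r}")
        if self.seed is None:
            raise ConfigError("seed is mandatory")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n_taxa_per_rank"] = dict(self.n_taxa_per_rank)
        d["frac_rank_specific"] = dict(self.frac_rank_specific)
        d["conditions"] = list(self.conditions)
        d["timepoints"] = list(self.timepoints)
        d["planted_taxa"] = [list(x) for x in self.planted_taxa]
        d["planted_pathways"] = [list(x) for x in self.planted_pathways]
        return d


@dataclass
class TruthSet:
    """Ground truth emitted alongside a simulated dataset."""

    taxon_effects: list[dict]
    pathway_effects: list[dict]
    baseline_taxon_abundance: dict[str, float]
    peptide_to_protein: dict[str, str]
    protein_to_taxon: dict[str, str]  # protein -> true species (or host species)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimBundle:
    precursors: PrecursorTable
    design: SampleDesign
    taxonomy: TaxonomyTable
    function_map: FunctionMap
    truth: TruthSet
    config: SimConfig


def _build_lineages(cfg: SimConfig) -> dict[str, tuple[str, ...]]:
    """Deterministic top-down taxonomy: species -> full 8-rank lineage.

    Children are attached to parents round-robin so every parent taxon is
    populated.
    """
    names: dict[str, list[str]] = {}
    parent_idx: dict[str, list[int]] = {}
    prev_n = None
    for rank in RANKS:
        n = int(cfg.n_taxa_per_rank.get(rank, 1))
        if n < 1:
            raise ConfigError(f"n_taxa_per_rank[{rank!r}] must be >= 1")
        names[rank] = [f"{_RANK_PREFIX[rank]}{i + 1:03d}" for i in range(n)]
        parent_idx[rank] = [i % prev_n for i in range(n)] if prev_n else [0] * n
        prev_n = n
    lineages: dict[str, tuple[str, ...]] = {}
    for si, sp in enumerate(names["species"]):
        lineage = [sp]
        idx = si
        for rank in reversed(RANKS[:-1]):
            idx = parent_idx[RANKS[RANKS.index(rank) + 1]][idx]
            lineage.append(names[rank][idx])
        lineages[sp] = tuple(reversed(lineage))
    return lineages


def _random_peptide(rng: np.random.Generator, taken: set[str]) -> str:
    while True:
        length = int(rng.integers(8, 16))
        seq = "".join(rng.choice(_AA, size=length))
        if seq not in taken:
            taken.add(seq)
            return seq


def simulate_dataset(cfg: SimConfig) -> SimBundle:
    """Generate one dataset; deterministic given ``cfg`` (seed included)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # --- taxonomy structure (deterministic, so planted refs can be checked
    # before any sampling) ---
    lineages = _build_lineages(cfg)
    species = list(lineages)
    all_taxa = {t for lin in lineages.values() for t in lin}

    # --- proteins, K numbers, pathways (K/pathway structure is needed to
    # validate planted pathways before sampling intensities) ---
    proteins: list[str] = []
    protein_species: dict[str, str] = {}
    for sp in species:
        for j in range(cfg.n_proteins_per_species):
            acc = f"MP_{sp}_{j + 1}"
            proteins.append(acc)
            protein_species[acc] = sp
    host_proteins = [f"HP_{j + 1:03d}" for j in range(cfg.n_host_proteins)]
    for acc in host_proteins:
        protein_species[acc] = _HOST_LINEAGE[-1]

    k_pool = [f"K{i + 1:05d}" for i in range(cfg.n_k_numbers)]
    pw_pool = [f"map{i + 1:05d}" for i in range(cfg.n_pathways)]
    p2k_rows = []
    for acc in proteins:  # host proteins carry no K numbers
        ks = rng.choice(cfg.n_k_numbers, size=min(cfg.k_per_protein, cfg.n_k_numbers), replace=False)
        for k in sorted(ks):
            p2k_rows.append((acc, k_pool[int(k)]))
    k2p_rows = []
    for i, k in enumerate(k_pool):
        n_pw = 1 + int(rng.random() < 0.3)  # ~30% of K numbers serve 2 pathways
        pws = rng.choice(cfg.n_pathways, size=min(n_pw, cfg.n_pathways), replace=False)
        for pw in sorted(pws):
            k2p_rows.append((k, pw_pool[int(pw)], f"Pathway {int(pw) + 1}"))

    # --- validate planted references before intensity sampling ---
    for taxon, cond, _ in cfg.planted_taxa:
        if taxon not in all_taxa:
            raise ConfigError(f"planted taxon not generated: {taxon!r}")
        if cond not in cfg.conditions:
            raise ConfigError(f"planted condition unknown: {cond!r}")
    pw_to_k = {}
    for k, pw, _ in k2p_rows:
        pw_to_k.setdefault(pw, set()).add(k)
    k_to_prot = {}
    for acc, k in p2k_rows:
        k_to_prot.setdefault(k, set()).add(acc)
    for pw, cond, _ in cfg.planted_pathways:
        members = {p for k in pw_to_k.get(pw, ()) for p in k_to_prot.get(k, ())}
        if not members:
            raise ConfigError(f"planted pathway has no annotated protein: {pw!r}")
        if cond not in cfg.conditions:
            raise ConfigError(f"planted condition unknown: {cond!r}")

    # --- peptides and their annotated (possibly blanked) lineages ---
    taken: set[str] = set()
    peptides: list[str] = []
    pep_protein: dict[str, str] = {}
    blank_ranks = list(cfg.frac_rank_specific)
    blank_probs = [cfg.frac_rank_specific[r] for r in blank_ranks]
    tax_rows = []
    for acc in proteins + host_proteins:
        is_host = acc in set(host_proteins)
        true_lineage = _HOST_LINEAGE if is_host else lineages[protein_species[acc]]
        for _ in range(cfg.n_peptides_per_protein):
            seq = _random_peptide(rng, taken)
            peptides.append(seq)
            pep_protein[seq] = acc
            u = rng.random()
            annotated = list(true_lineage)
            if not is_host:
                acc_p = 0.0
                for r, pr in zip(blank_ranks, blank_probs):
                    acc_p += pr
                    if u < acc_p:
                        cut = RANKS.index(r) + 1
                        annotated = list(true_lineage[:cut]) + [""] * (len(RANKS) - cut)
                        break
            tax_rows.append([seq, *annotated])

    # --- design ---
    design_rows = []
    subj_counter = 0
    for cond in cfg.conditions:
        for i in range(cfg.n_subjects_per_condition):
            subject = f"{cond}_m{i + 1}"
            batch = f"b{subj_counter % cfg.n_batches + 1}"
            subj_counter += 1
            for tp in cfg.timepoints:
                design_rows.append(
                    dict(
                        run_id=f"{cond}_m{i + 1}_{tp}",
                        subject=subject,
                        condition=cond,
                        timepoint=tp,
                        batch=batch,
                        replicate=1,
                    )
                )
    design = SampleDesign(pd.DataFrame(design_rows))
    runs = design.runs
    n_runs = len(runs)
    run_cond = dict(zip(design.df["run_id"], design.df["condition"]))
    run_tp = dict(zip(design.df["run_id"], design.df["timepoint"]))
    run_subj = dict(zip(design.df["run_id"], design.df["subject"]))
    run_batch = design.batch_of()
    t2 = cfg.timepoints[-1]

    # --- log2 intensity model ---
    base_sp = {sp: rng.normal(cfg.baseline_mean_log2, cfg.baseline_sd_log2) for sp in species}
    base_sp[_HOST_LINEAGE[-1]] = rng.normal(cfg.baseline_mean_log2, cfg.baseline_sd_log2)
    prot_off = {acc: rng.normal(0.0, cfg.protein_offset_sd_log2) for acc in proteins + host_proteins}
    pep_off = {p: rng.normal(0.0, cfg.peptide_offset_sd_log2) for p in peptides}
    subjects = sorted({r["subject"] for r in design_rows})
    subj_int = {s: rng.normal(0.0, cfg.subject_sd_log2) for s in subjects}
    depth = {r: rng.normal(0.0, cfg.sample_depth_sd_log2) for r in runs}
    batches = sorted(set(run_batch.values()))
    batch_shift = {b: rng.normal(0.0, cfg.batch_shift_sd_log2) for b in batches}

    # planted-effect lookup per peptide x run
    planted_prot: dict[str, dict[str, float]] = {}  # protein -> condition -> fc
    for pw, cond, fc in cfg.planted_pathways:
        for k in pw_to_k[pw]:
            for acc in k_to_prot.get(k, ()):
                planted_prot.setdefault(acc, {})[cond] = (
                    planted_prot.get(acc, {}).get(cond, 0.0) + fc
                )
    planted_tax: dict[str, dict[str, float]] = {}  # species -> condition -> fc
    for taxon, cond, fc in cfg.planted_taxa:
        for sp, lin in lineages.items():
            if taxon in lin:
                planted_tax.setdefault(sp, {})[cond] = (
                    planted_tax.get(sp, {}).get(cond, 0.0) + fc
                )

    sigma = np.sqrt(np.log1p(cfg.peptide_cv**2)) / np.log(2.0)
    P = len(peptides)
    base = np.array(
        [
            base_sp[protein_species[pep_protein[p]]]
            + prot_off[pep_protein[p]]
            + pep_off[p]
            for p in peptides
        ]
    )
    run_add = np.array(
        [subj_int[run_subj[r]] + depth[r] + batch_shift[run_batch[r]] for r in runs]
    )
    effect = np.zeros((P, n_runs))
    for pi, pep in enumerate(peptides):
        acc = pep_protein[pep]
        sp = protein_species[acc]
        per_cond: dict[str, float] = {}
        for cond, fc in planted_tax.get(sp, {}).items():
            per_cond[cond] = per_cond.get(cond, 0.0) + fc
        for cond, fc in planted_prot.get(acc, {}).items():
            per_cond[cond] = per_cond.get(cond, 0.0) + fc
        if per_cond:
            for ri, r in enumerate(runs):
                if run_tp[r] == t2 and run_cond[r] in per_cond:
                    effect[pi, ri] = per_cond[run_cond[r]]
    noise = rng.normal(0.0, sigma, size=(P, n_runs)) if sigma > 0 else np.zeros((P, n_runs))
    X = base[:, None] + run_add[None, :] + effect + noise

    # --- missingness (applied last) ---
    if cfg.missingness == "dia-like":
        miss = rng.random((P, n_runs)) < cfg.dia_missing_rate
    elif cfg.missingness == "dda-like":
        p_miss = 1.0 / (1.0 + np.exp(cfg.dda_slope * (X - cfg.dda_midpoint_log2)))
        miss = rng.random((P, n_runs)) < p_miss
    else:
        miss = np.zeros((P, n_runs), dtype=bool)

    # --- q-values ---
    decoy = rng.random(P) < cfg.decoy_fraction
    prec_q = rng.uniform(0.0, 0.009, size=(P, n_runs))
    prec_q[decoy] = rng.uniform(0.01, 0.5, size=(int(decoy.sum()), n_runs))
    prot_list = sorted({pep_protein[p] for p in peptides})
    pg_q_tab = {acc: rng.uniform(0.0, 0.009, size=n_runs) for acc in prot_list}

    intensity = np.where(miss, np.nan, 2.0**X)
    rows = {
        "precursor_id": np.repeat([f"{p}2" for p in peptides], n_runs),
        "stripped_sequence": np.repeat(peptides, n_runs),
        "protein_group": np.repeat([pep_protein[p] for p in peptides], n_runs),
        "run_id": np.tile(runs, P),
        "intensity": intensity.ravel(),
        "precursor_q": prec_q.ravel(),
        "protein_group_q": np.concatenate(
            [pg_q_tab[pep_protein[p]] for p in peptides]
        ),
        "origin": np.repeat(
            ["host" if pep_protein[p] in set(host_proteins) else "microbial" for p in peptides],
            n_runs,
        ),
    }
    precursors = PrecursorTable(pd.DataFrame(rows))

    taxonomy = TaxonomyTable(pd.DataFrame(tax_rows, columns=["peptide", *RANKS]))
    fmap = FunctionMap(
        pd.DataFrame(p2k_rows, columns=["protein_group", "k_number"]),
        pd.DataFrame(k2p_rows, columns=["k_number", "pathway_id", "pathway_name"]),
    )
    truth = TruthSet(
        taxon_effects=[
            dict(taxon=t, condition=c, log2_fc=fc) for t, c, fc in cfg.planted_taxa
        ],
        pathway_effects=[
            dict(pathway_id=p, condition=c, log2_fc=fc) for p, c, fc in cfg.planted_pathways
        ],
        baseline_taxon_abundance={sp: float(v) for sp, v in base_sp.items()},
        peptide_to_protein=dict(pep_protein),
        protein_to_taxon=dict(protein_species),
    )
    return SimBundle(precursors, design, taxonomy, fmap, truth, cfg)


def write_dataset(bundle: SimBundle, out_dir: str | Path) -> dict[str, dict]:
    """Write the five tables plus a truth JSON (which echoes the config);
    returns a manifest of paths and row counts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_precursor_report(bundle.precursors, out / "precursors.tsv")
    write_design(bundle.design, out / "design.tsv")
    write_taxonomy(bundle.taxonomy, out / "taxonomy.tsv")
    write_function_map(bundle.function_map, out / "protein_to_k.tsv", out / "k_to_pathway.tsv")
    truth = bundle.truth.to_dict()
    truth["config"] = bundle.config.to_dict()
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    manifest = {  # paths relative to out_dir so output trees are comparable
        "precursors.tsv": {"path": "precursors.tsv", "rows": len(bundle.precursors.df)},
        "design.tsv": {"path": "design.tsv", "rows": len(bundle.design.df)},
        "taxonomy.tsv": {"path": "taxonomy.tsv", "rows": len(bundle.taxonomy.df)},
        "protein_to_k.tsv": {
            "path": "protein_to_k.tsv",
            "rows": len(bundle.function_map.protein_to_k),
        },
        "k_to_pathway.tsv": {
            "path": "k_to_pathway.tsv",
            "rows": len(bundle.function_map.k_to_pathway),
        },
        "truth.json": {
            "path": "truth.json",
            "rows": len(truth["taxon_effects"]) + len(truth["pathway_effects"]),
        },
    }
    return manifest
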