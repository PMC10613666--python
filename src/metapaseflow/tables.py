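"""Typed tables and file I/O for the metaproteomic pipeline.

Every table the pipeline touches is carried as a thin dataclass around a
:class:`pandas.DataFrame` with validated invariants:

* :class:`PrecursorTable` — long-format per-run precursor intensities with
  identification q-values, the pipeline's raw input (the layout of a DIA
  search engine's main report table).
* :class:`SampleDesign` — run ↔ subject ↔ condition ↔ timepoint ↔ batch map
  defining the paired comparisons.
* :class:`TaxonomyTable` — peptide → ranked lineage (LCA-style, blanks below
  the deepest unambiguous rank).
* :class:`FunctionMap` — protein group → KEGG ortholog (K number) and
  K number → pathway relations; the K→pathway relation is one-to-many.
* :class:`QuantMatrix` — the shared feature × run carrier for every
  aggregation level, with an explicit ``linear``/``log2`` scale tag.

All files are TSV, UTF-8, "." decimal.  Intensity cells that are ``0`` or
empty decode to *missing*: the downstream complete-case filters treat
"unquantified" as "absent", so a zero carries no more information than a
blank.  Floats are written with Python's shortest round-trip ``repr`` so a
write→read cycle is bit-identical for non-missing values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fixed rank order of the lineage columns, shallowest to deepest.
RANKS = (
    "superkingdom",
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)


class FormatError(ValueError):
    """A file does not conform to its documented layout."""


class IntegrityError(ValueError):
    """A table violates one of its declared invariants."""


class ConfigError(ValueError):
    """An operation was configured inconsistently with its inputs."""


# ---------------------------------------------------------------------------
# Precursor report
# ---------------------------------------------------------------------------

PRECURSOR_FIELDS = (
    "precursor_id",
    "stripped_sequence",
    "protein_group",
    "run_id",
    "intensity",
    "precursor_q",
    "protein_group_q",
    "origin",
)

#: main-report header -> canonical field name ("diann-like" dialect)
_DIANN_HEADER = {
    "Precursor.Id": "precursor_id",
    "Stripped.Sequence": "stripped_sequence",
    "Protein.Group": "protein_group",
    "Run": "run_id",
    "Normalized.Intensity": "intensity",
    "Q.Value": "precursor_q",
    "PG.Q.Value": "protein_group_q",
    "Origin": "origin",
}


@dataclass
class PrecursorTable:
    """Long-format precursor quantification table.

    ``intensity`` is a positive linear-scale float or NaN (missing);
    ``(precursor_id, run_id)`` is a unique key; q-values lie in [0, 1];
    ``origin`` is ``"microbial"`` or ``"host"`` (free labels tolerated).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PRECURSOR_FIELDS if c not in self.df.columns]
        if missing:
            raise FormatError(f"precursor table lacks columns: {missing}")
        df = self.df
        dup = df.duplicated(subset=["precursor_id", "run_id"])
        if dup.any():
            key = df.loc[dup, ["precursor_id", "run_id"]].iloc[0].tolist()
            raise IntegrityError(f"duplicate (precursor_id, run_id): {key}")
        for col in ("precursor_q", "protein_group_q"):
            v = df[col].to_numpy(float)
            if v.size and (np.nanmin(v) < 0 or np.nanmax(v) > 1):
                raise IntegrityError(f"{col} outside [0, 1]")
        inten = df["intensity"].to_numpy(float)
        if np.any(inten[np.isfinite(inten)] <= 0):
            raise IntegrityError("non-missing intensities must be > 0")

    @property
    def runs(self) -> list[str]:
        return sorted(self.df["run_id"].unique())

    def peptide_to_protein_group(self) -> dict[str, set[str]]:
        """Map each stripped sequence to the protein group(s) carrying it."""
        out: dict[str, set[str]] = {}
        for seq, pg in zip(self.df["stripped_sequence"], self.df["protein_group"]):
            out.setdefault(seq, set()).add(pg)
        return out

    def origin_of_peptides(self) -> dict[str, str]:
        return dict(zip(self.df["stripped_sequence"], self.df["origin"]))


def _parse_floats(col: pd.Series) -> pd.Series:
    # str(float) -> float round-trips exactly; pandas' default csv float
    # parser does not, so numeric cells are parsed with Python's float()
    return col.map(lambda v: np.nan if v in ("", "nan") else float(v))


def read_precursor_report(path: str | Path, dialect: str = "diann-like") -> PrecursorTable:
    """Read a precursor report TSV in either supported dialect.

    ``diann-like`` is the long main-report layout; ``wide-matrix`` is a
    features × runs matrix (id columns ``precursor_id``,
    ``stripped_sequence``, ``protein_group`` followed by one column per run)
    accepted for interoperability with generic tools — q-values default to 0
    and origin to ``microbial`` there.  Zero or empty intensity cells become
    missing.
    """
    path = Path(path)
    if dialect == "diann-like":
        raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        for header, canonical in _DIANN_HEADER.items():
            if header not in raw.columns and canonical != "origin":
                raise FormatError(canonical)
        df = pd.DataFrame(
            {
                canonical: raw[header]
                for header, canonical in _DIANN_HEADER.items()
                if header in raw.columns
            }
        )
        if "origin" not in df.columns:
            df["origin"] = "microbial"
        for col in ("intensity", "precursor_q", "protein_group_q"):
            df[col] = _parse_floats(df[col])
        df.loc[df["intensity"] == 0, "intensity"] = np.nan
    elif dialect == "wide-matrix":
        raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        id_cols = ["precursor_id", "stripped_sequence", "protein_group"]
        for c in id_cols:
            if c not in raw.columns:
                raise FormatError(c)
        run_cols = [c for c in raw.columns if c not in id_cols]
        if not run_cols:
            raise FormatError("wide-matrix file has no run columns")
        df = raw.melt(
            id_vars=id_cols, value_vars=run_cols, var_name="run_id", value_name="intensity"
        )
        df["intensity"] = _parse_floats(df["intensity"])
        df.loc[df["intensity"] == 0, "intensity"] = np.nan
        df["precursor_q"] = 0.0
        df["protein_group_q"] = 0.0
        df["origin"] = "microbial"
    else:
        raise ConfigError(f"unknown dialect: {dialect!r}")
    return PrecursorTable(df[list(PRECURSOR_FIELDS)].reset_index(drop=True))


def write_precursor_report(
    t: PrecursorTable, path: str | Path, dialect: str = "diann-like"
) -> None:
    """Inverse of :func:`read_precursor_report`; missing intensities are
    written as empty cells."""
    path = Path(path)
    if dialect == "diann-like":
        inverse = {v: k for k, v in _DIANN_HEADER.items()}
        out = t.df.rename(columns=inverse)[list(_DIANN_HEADER)]
        out.to_csv(path, sep="\t", index=False)
    elif dialect == "wide-matrix":
        wide = t.df.pivot(index="precursor_id", columns="run_id", values="intensity")
        meta = (
            t.df.drop_duplicates("precursor_id")
            .set_index("precursor_id")[["stripped_sequence", "protein_group"]]
        )
        out = meta.join(wide).reset_index()
        out.to_csv(path, sep="\t", index=False)
    else:
        raise ConfigError(f"unknown dialect: {dialect!r}")


# ---------------------------------------------------------------------------
# Sample design
# ---------------------------------------------------------------------------

DESIGN_FIELDS = ("run_id", "subject", "condition", "timepoint", "batch", "replicate")


@dataclass
class SampleDesign:
    """Run-level experimental design.

    ``run_id`` is unique; within a condition, each (subject, timepoint)
    appears at most once.  Condition/timepoint values are free labels — the
    study's are Naive/SHAM/SNI and Pre/14D — so unknown labels are not an
    error.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_FIELDS if c not in self.df.columns]
        if missing:
            raise FormatError(f"design lacks columns: {missing}")
        if self.df["run_id"].duplicated().any():
            dup = self.df.loc[self.df["run_id"].duplicated(), "run_id"].iloc[0]
            raise IntegrityError(f"duplicate run_id: {dup!r}")
        counts = self.df.groupby(["condition", "subject", "timepoint"]).size()
        if (counts > 1).any():
            key = counts[counts > 1].index[0]
            raise IntegrityError(f"(subject, timepoint) duplicated in condition: {key}")

    @property
    def runs(self) -> list[str]:
        return list(self.df["run_id"])

    def runs_for(self, condition: str, timepoint: str | None = None) -> list[str]:
        sel = self.df["condition"] == condition
        if timepoint is not None:
            sel &= self.df["timepoint"] == timepoint
        return list(self.df.loc[sel, "run_id"])

    def batch_of(self) -> dict[str, str]:
        return dict(zip(self.df["run_id"], self.df["batch"].astype(str)))


def read_design(path: str | Path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "replicate" not in df.columns:
        df["replicate"] = "1"
    missing = [c for c in DESIGN_FIELDS if c not in df.columns]
    if missing:
        raise FormatError(f"design lacks columns: {missing}")
    df["replicate"] = df["replicate"].astype(int)
    return SampleDesign(df[list(DESIGN_FIELDS)])


def write_design(d: SampleDesign, path: str | Path) -> None:
    d.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------


@dataclass
class TaxonomyTable:
    """Peptide → ranked lineage with blanks ("" = unassigned).

    Lineages are LCA-consistent: once a rank is blank, all deeper ranks are
    blank.  Construction repairs violations by truncating below the first
    blank (with a logged warning) rather than rejecting the file, since
    third-party annotation exports are not always consistent.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        cols = ["peptide", *RANKS]
        missing = [c for c in cols if c not in self.df.columns]
        if missing:
            raise FormatError(f"taxonomy lacks columns: {missing}")
        if self.df["peptide"].duplicated().any():
            dup = self.df.loc[self.df["peptide"].duplicated(), "peptide"].iloc[0]
            raise IntegrityError(f"duplicate peptide: {dup!r}")
        vals = self.df[list(RANKS)].to_numpy(dtype=object)
        blank = vals == ""
        repaired = 0
        for i in range(vals.shape[0]):
            seen_blank = False
            for j in range(len(RANKS)):
                if seen_blank and not blank[i, j]:
                    vals[i, j] = ""
                    repaired += 1
                if blank[i, j]:
                    seen_blank = True
        if repaired:
            logger.warning(
                "taxonomy: truncated %d rank cells below a blank ancestor", repaired
            )
            self.df = self.df.copy()
            self.df[list(RANKS)] = vals

    def lineage_at(self, rank: str) -> pd.Series:
        if rank not in RANKS:
            raise ConfigError(f"unknown rank: {rank!r}")
        return self.df.set_index("peptide")[rank]


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return TaxonomyTable(df)


def write_taxonomy(t: TaxonomyTable, path: str | Path) -> None:
    t.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Function map
# ---------------------------------------------------------------------------


@dataclass
class FunctionMap:
    """protein group → K number and K number → pathway relations.

    Both relations may be empty or one-to-many; in particular a K number
    belonging to several pathways is essential to the pathway fan-out step.
    """

    protein_to_k: pd.DataFrame  # columns: protein_group, k_number
    k_to_pathway: pd.DataFrame  # columns: k_number, pathway_id, pathway_name

    def __post_init__(self) -> None:
        for c in ("protein_group", "k_number"):
            if c not in self.protein_to_k.columns:
                raise FormatError(f"protein_to_k lacks column: {c}")
        for c in ("k_number", "pathway_id", "pathway_name"):
            if c not in self.k_to_pathway.columns:
                raise FormatError(f"k_to_pathway lacks column: {c}")

    def ks_of_protein(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for pg, k in zip(self.protein_to_k["protein_group"], self.protein_to_k["k_number"]):
            out.setdefault(pg, set()).add(k)
        return out

    def pathways_of_k(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for k, pw in zip(self.k_to_pathway["k_number"], self.k_to_pathway["pathway_id"]):
            out.setdefault(k, set()).add(pw)
        return out

    def pathway_names(self) -> dict[str, str]:
        return dict(
            zip(self.k_to_pathway["pathway_id"], self.k_to_pathway["pathway_name"])
        )


def read_function_map(
    protein_to_k_path: str | Path, k_to_pathway_path: str | Path
) -> FunctionMap:
    p2k = pd.read_csv(protein_to_k_path, sep="\t", dtype=str, keep_default_na=False)
    k2p = pd.read_csv(k_to_pathway_path, sep="\t", dtype=str, keep_default_na=False)
    return FunctionMap(p2k, k2p)


def write_function_map(
    fm: FunctionMap, protein_to_k_path: str | Path, k_to_pathway_path: str | Path
) -> None:
    fm.protein_to_k.to_csv(protein_to_k_path, sep="\t", index=False)
    fm.k_to_pathway.to_csv(k_to_pathway_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Quantification matrix
# ---------------------------------------------------------------------------


@dataclass
class QuantMatrix:
    """Feature × run matrix with an explicit scale tag.

    ``scale="linear"`` forbids values ≤ 0 (missing is NaN); ``scale="log2"``
    allows any float.  Used for peptide, protein-group, taxon and pathway
    level matrices alike.
    """

    data: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ConfigError(f"unknown scale: {self.scale!r}")
        if self.scale == "linear":
            v = self.data.to_numpy(float)
            if np.any(v[np.isfinite(v)] <= 0):
                raise IntegrityError("linear-scale matrix contains values <= 0")

    @property
    def features(self) -> list[str]:
        return list(self.data.index)

    @property
    def runs(self) -> list[str]:
        return list(self.data.columns)

    def to_log2(self) -> "QuantMatrix":
        if self.scale == "log2":
            return self
        return QuantMatrix(np.log2(self.data), scale="log2")

    def to_linear(self) -> "QuantMatrix":
        if self.scale == "linear":
            return self
        return QuantMatrix(2.0 ** self.data, scale="linear")


def read_matrix(path: str | Path, scale: str) -> QuantMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return QuantMatrix(df.astype(float), scale=scale)


def write_matrix(m: QuantMatrix, path: str | Path) -> None:
    out = m.data.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Differential table
# ---------------------------------------------------------------------------

#: column contract for differential-analysis outputs (plain DataFrames)
DIFFERENTIAL_COLUMNS = (
    "feature_id",
    "condition",
    "mean_diff_log2",
    "t_stat",
    "df",
    "p_value",
    "q_value",
    "n_pairs",
    "degenerate",
)


# ---------------------------------------------------------------------------
# Reduced-FASTA utility
# ---------------------------------------------------------------------------


def reduce_fasta(
    fasta_path: str | Path, validated_ids: Iterable[str], out_path: str | Path
) -> int:
    """Subset a FASTA database to validated accessions.

    The accession is the first whitespace-delimited token of the header
    (">" stripped).  Matching records are written in input order with their
    full headers; duplicate accessions are preserved with a warning (their
    provenance is outside our control).  Returns the number of records
    written; zero matches is a warning, not an error.
    """
    from pyteomics import fasta as _fasta

    ids = set(validated_ids)
    if not ids:
        raise ValueError("validated_ids must be non-empty")
    fasta_path = Path(fasta_path)
    with open(fasta_path) as fh:
        head = fh.read(1024).lstrip()
    if not head.startswith(">"):
        raise FormatError(f"{fasta_path} does not look like FASTA")
    written = 0
    seen: set[str] = set()
    with open(out_path, "w") as out:
        for header, seq in _fasta.read(str(fasta_path)):
            accession = header.split()[0]
            if accession not in ids:
                continue
            if accession in seen:
                logger.warning("duplicate accession in FASTA: %s", accession)
            seen.add(accession)
            out.write(f">{header}\n")
            for i in range(0, len(seq), 60):
                out.write(seq[i : i + 60] + "\n")
            written += 1
    if written == 0:
        logger.warning("reduce_fasta: no accession matched validated_ids")
    return written
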