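"""Table parsing, invariant enforcement, round-trips, reduced FASTA."""

import logging

import numpy as np
import pandas as pd
import pytest

from metapaseflow import (
    FormatError,
    IntegrityError,
    QuantMatrix,
    read_design,
    read_precursor_report,
    read_taxonomy,
    reduce_fasta,
)
from metapaseflow.simulate import simulate_dataset, write_dataset
from metapaseflow.tables import (
    RANKS,
    TaxonomyTable,
    read_matrix,
    write_matrix,
    write_precursor_report,
)

from conftest import small_config

DIANN_HEADER = (
    "Precursor.Id\tStripped.Sequence\tProtein.Group\tRun\t"
    "Normalized.Intensity\tQ.Value\tPG.Q.Value\tOrigin\n"
)


def test_read_diann_report_parses_rows_and_zero_as_missing(tmp_path):
    text = DIANN_HEADER + (
        "PEPA2\tPEPA\tPG1\trun1\t1000.5\t0.001\t0.002\tmicrobial\n"
        "PEPB2\tPEPB\tPG1\trun1\t0\t0.001\t0.002\tmicrobial\n"
        "PEPC2\tPEPC\tPG2;PG3\trun1\t\t0.003\t0.004\thost\n"
    )
    f = tmp_path / "report.tsv"
    f.write_text(text)
    t = read_precursor_report(f)
    assert len(t.df) == 3
    assert t.runs == ["run1"]
    assert t.df.loc[0, "intensity"] == 1000.5
    assert np.isnan(t.df.loc[1, "intensity"])  # zero decodes to missing
    assert np.isnan(t.df.loc[2, "intensity"])  # empty decodes to missing
    assert t.df.loc[2, "protein_group"] == "PG2;PG3"


def test_missing_qvalue_column_names_canonical_field(tmp_path):
    text = (
        "Precursor.Id\tStripped.Sequence\tProtein.Group\tRun\t"
        "Normalized.Intensity\tPG.Q.Value\n"
        "PEPA2\tPEPA\tPG1\trun1\t10\t0.002\n"
    )
    f = tmp_path / "bad.tsv"
    f.write_text(text)
    with pytest.raises(FormatError, match="precursor_q"):
        read_precursor_report(f)


def test_duplicate_precursor_run_key_rejected(tmp_path):
    text = DIANN_HEADER + (
        "PEPA2\tPEPA\tPG1\trun1\t10\t0.001\t0.002\tmicrobial\n"
        "PEPA2\tPEPA\tPG1\trun1\t20\t0.001\t0.002\tmicrobial\n"
    )
    f = tmp_path / "dup.tsv"
    f.write_text(text)
    with pytest.raises(IntegrityError, match="duplicate"):
        read_precursor_report(f)


@pytest.mark.parametrize("dialect", ["diann-like", "wide-matrix"])
def test_precursor_report_roundtrip_bit_identical(tmp_path, dialect):
    bundle = simulate_dataset(small_config(seed=3))
    path = tmp_path / "report.tsv"
    write_precursor_report(bundle.precursors, path, dialect=dialect)
    back = read_precursor_report(path, dialect=dialect)
    a = bundle.precursors.df.sort_values(["precursor_id", "run_id"]).reset_index(drop=True)
    b = back.df.sort_values(["precursor_id", "run_id"]).reset_index(drop=True)
    # non-missing intensities survive the text round-trip exactly
    assert np.array_equal(
        a["intensity"].to_numpy(), b["intensity"].to_numpy(), equal_nan=True
    )
    if dialect == "diann-like":
        for col in ("precursor_q", "protein_group_q", "origin"):
            assert (a[col].to_numpy() == b[col].to_numpy()).all()


def test_design_of_study_shape_roundtrip(tmp_path):
    bundle = simulate_dataset(small_config(seed=5))
    path = tmp_path / "design.tsv"
    bundle.design.df.to_csv(path, sep="\t", index=False)
    d = read_design(path)
    # 4 mice x 3 conditions x 2 timepoints
    assert len(d.df) == 24
    assert d.df["subject"].nunique() == 12
    assert set(d.df["condition"]) == {"Naive", "SHAM", "SNI"}


def test_design_duplicate_run_rejected(tmp_path):
    rows = "run_id\tsubject\tcondition\ttimepoint\tbatch\treplicate\n" + (
        "r1\ts1\tSNI\tPre\tb1\t1\nr1\ts1\tSNI\t14D\tb1\t1\n"
    )
    f = tmp_path / "design.tsv"
    f.write_text(rows)
    with pytest.raises(IntegrityError, match="run_id"):
        read_design(f)


def test_taxonomy_blank_lineage_repair(tmp_path, caplog):
    header = "peptide\t" + "\t".join(RANKS) + "\n"
    # family blank but genus/species filled -> truncated below family
    row = "PEPA\tBacteria\tk1\tp1\tc1\to1\t\tg1\ts1\n"
    f = tmp_path / "tax.tsv"
    f.write_text(header + row)
    with caplog.at_level(logging.WARNING):
        t = read_taxonomy(f)
    assert t.df.loc[0, "genus"] == ""
    assert t.df.loc[0, "species"] == ""
    assert t.df.loc[0, "order"] == "o1"
    assert any("truncated" in r.message for r in caplog.records)


def test_empty_taxonomy_yields_zero_taxa(tmp_path):
    from metapaseflow import aggregate_taxa

    header = "peptide\t" + "\t".join(RANKS) + "\n"
    f = tmp_path / "tax.tsv"
    f.write_text(header)
    t = read_taxonomy(f)
    assert len(t.df) == 0
    m = QuantMatrix(
        pd.DataFrame([[1.0, 2.0]], index=["PEPA"], columns=["r1", "r2"]), scale="linear"
    )
    res = aggregate_taxa(m, t, rank="genus")
    assert res.matrix.data.empty


FASTA = (
    ">acc1 desc one\nMKTAYIAKQR\n"
    ">acc2 desc two\nGGLND\n"
    ">acc3\nPEPTIDE\n"
    ">acc2 duplicated copy\nWWWW\n"
    ">acc5 another\nAAAA\n"
)


def test_reduce_fasta_subsets_in_order(tmp_path):
    src = tmp_path / "db.fasta"
    src.write_text(FASTA)
    out = tmp_path / "reduced.fasta"
    n = reduce_fasta(src, {"acc3", "acc1"}, out)
    assert n == 2
    lines = out.read_text().splitlines()
    assert lines[0] == ">acc1 desc one"  # input order, full header preserved
    assert lines[2] == ">acc3"


def test_reduce_fasta_no_match_warns_empty(tmp_path, caplog):
    src = tmp_path / "db.fasta"
    src.write_text(FASTA)
    out = tmp_path / "reduced.fasta"
    with caplog.at_level(logging.WARNING):
        n = reduce_fasta(src, {"nope"}, out)
    assert n == 0
    assert out.read_text() == ""
    assert any("no accession matched" in r.message for r in caplog.records)


def test_reduce_fasta_duplicates_kept_with_warning(tmp_path, caplog):
    src = tmp_path / "db.fasta"
    src.write_text(FASTA)
    out = tmp_path / "reduced.fasta"
    with caplog.at_level(logging.WARNING):
        n = reduce_fasta(src, {"acc2"}, out)
    assert n == 2  # counted with multiplicity
    assert any("duplicate accession" in r.message for r in caplog.records)


def test_reduce_fasta_rejects_non_fasta(tmp_path):
    src = tmp_path / "junk.txt"
    src.write_text("this is not fasta\n")
    with pytest.raises(FormatError):
        reduce_fasta(src, {"x"}, tmp_path / "out.fasta")


def test_quantmatrix_rejects_nonpositive_linear():
    with pytest.raises(IntegrityError):
        QuantMatrix(pd.DataFrame([[1.0, -2.0]], columns=["a", "b"]), scale="linear")


def test_matrix_roundtrip(tmp_path):
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        rng.lognormal(10, 1, size=(5, 3)), index=[f"f{i}" for i in range(5)],
        columns=["r1", "r2", "r3"],
    )
    df.iloc[0, 1] = np.nan
    m = QuantMatrix(df, scale="linear")
    path = tmp_path / "m.tsv"
    write_matrix(m, path)
    back = read_matrix(path, scale="linear")
    assert np.array_equal(m.data.to_numpy(), back.data.to_numpy(), equal_nan=True)


def test_dataset_write_manifest_and_roundtrip(tmp_path):
    cfg = small_config(seed=9, planted_taxa=(("sp001", "SNI", 1.0),))
    bundle = simulate_dataset(cfg)
    manifest = write_dataset(bundle, tmp_path)
    assert len(manifest) == 6
    assert manifest["precursors.tsv"]["rows"] == len(bundle.precursors.df)
    back = read_precursor_report(tmp_path / "precursors.tsv")
    assert len(back.df) == len(bundle.precursors.df)
    tax = read_taxonomy(tmp_path / "taxonomy.tsv")
    pd.testing.assert_frame_equal(tax.df, bundle.taxonomy.df)
    import json

    truth = json.loads((tmp_path / "truth.json").read_text())
    assert truth["taxon_effects"] == [
        {"taxon": "sp001", "condition": "SNI", "log2_fc": 1.0}
    ]
    assert truth["config"]["seed"] == 9
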