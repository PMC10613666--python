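"""q-value filtering, median normalization, quantile batch correction and
MaxLFQ, each checked against hand computations or an independent
least-squares oracle."""

import logging

import numpy as np
import pandas as pd
import pytest

from metapaseflow import (
    QuantMatrix,
    SampleDesign,
    filter_by_q,
    maxlfq,
    median_normalize,
    quantile_batch_correct,
)
from metapaseflow.simulate import simulate_dataset

from conftest import make_precursors, small_config


def _lin(df):
    return QuantMatrix(2.0**df, scale="linear")


def _design_for(runs, batches=None):
    batches = batches or {r: "b1" for r in runs}
    rows = [
        dict(run_id=r, subject=f"s{i}", condition="SNI", timepoint="Pre",
             batch=batches[r], replicate=1)
        for i, r in enumerate(runs)
    ]
    return SampleDesign(pd.DataFrame(rows))


# ---------------------------------------------------------------- filter_by_q

def test_q_filter_is_strict():
    rows = [
        (f"p{i}2", f"P{i}", "G", "r1", 100.0, q, 0.001)
        for i, q in enumerate([0.001, 0.009, 0.010, 0.02])
    ]
    t = make_precursors(rows)
    kept = filter_by_q(t)
    assert len(kept.df) == 2  # strict "<" at 0.01
    assert set(kept.df["precursor_q"]) == {0.001, 0.009}


def test_q_filter_thresholds_one_is_identity():
    t = make_precursors([("p2", "P", "G", "r1", 10.0, 0.5, 0.7)])
    kept = filter_by_q(t, 1.0, 1.0)
    assert len(kept.df) == 1


def test_q_filter_all_fail_warns_empty(caplog):
    t = make_precursors([("p2", "P", "G", "r1", 10.0, 0.5, 0.5)])
    with caplog.at_level(logging.WARNING):
        kept = filter_by_q(t)
    assert len(kept.df) == 0
    assert any("no rows pass" in r.message for r in caplog.records)


# ----------------------------------------------------------- median_normalize

def test_median_normalize_hand_example():
    df = pd.DataFrame({"A": [10.0, 12.0, 14.0], "B": [11.0, 13.0, 15.0]},
                      index=["f1", "f2", "f3"])
    out, rep = median_normalize(_lin(df))
    log2 = np.log2(out.data)
    assert rep.target == pytest.approx(12.5)
    assert np.allclose(log2["A"], [10.5, 12.5, 14.5])
    assert np.allclose(log2["B"], [10.5, 12.5, 14.5])


def test_median_normalize_equal_medians_identity():
    df = pd.DataFrame({"A": [10.0, 12.0, 14.0], "B": [11.0, 12.0, 13.0]})
    out, _ = median_normalize(_lin(df))
    assert np.allclose(np.log2(out.data), df)


def test_median_normalize_single_run_identity():
    df = pd.DataFrame({"A": [10.0, 12.0, 14.0]})
    out, _ = median_normalize(_lin(df))
    assert np.allclose(np.log2(out.data), df)


def test_median_normalize_idempotent_and_medians_equal():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(rng.normal(20, 3, size=(50, 6)),
                      columns=[f"r{i}" for i in range(6)])
    df.iloc[rng.random((50, 6)) < 0.1] = np.nan
    once, _ = median_normalize(_lin(df))
    meds = np.log2(once.data).median(axis=0)
    assert np.ptp(meds.to_numpy()) < 1e-9
    twice, _ = median_normalize(once)
    assert np.allclose(once.data, twice.data, equal_nan=True)


def test_median_normalize_errors_on_empty_run():
    df = pd.DataFrame({"A": [10.0, 12.0], "B": [np.nan, np.nan]})
    with pytest.raises(ValueError, match="B"):
        median_normalize(_lin(df))


# ----------------------------------------------------- quantile_batch_correct

def test_quantile_hand_example_two_runs():
    df = pd.DataFrame({"A": [1.0, 3.0, 5.0], "B": [2.0, 4.0, 6.0]})
    out, _ = quantile_batch_correct(_lin(df), _design_for(["A", "B"]))
    log2 = np.log2(out.data)
    assert np.allclose(log2["A"], [1.5, 3.5, 5.5])
    assert np.allclose(log2["B"], [1.5, 3.5, 5.5])


def test_quantile_run_equal_to_reference_unchanged():
    df = pd.DataFrame({"A": [1.0, 3.0, 5.0], "B": [1.0, 3.0, 5.0]})
    out, _ = quantile_batch_correct(_lin(df), _design_for(["A", "B"]))
    assert np.allclose(np.log2(out.data), df)


def test_quantile_removes_planted_batch_shift():
    rng = np.random.default_rng(2)
    runs = [f"r{i}" for i in range(8)]
    base = rng.normal(20, 2, size=(200, 1))
    df = pd.DataFrame(np.repeat(base, 8, axis=1), columns=runs)
    shifted = df.copy()
    shifted[runs[4:]] += 1.0  # pure +1 log2 location shift on batch b2, no other noise
    batches = {r: ("b1" if i < 4 else "b2") for i, r in enumerate(runs)}
    out, _ = quantile_batch_correct(_lin(shifted), _design_for(runs, batches))
    log2 = np.log2(out.data)
    resid = log2[runs[:4]].mean(axis=1) - log2[runs[4:]].mean(axis=1)
    assert np.abs(resid).max() < 1e-9


def test_quantile_complete_data_sorted_vectors_identical():
    rng = np.random.default_rng(3)
    df = pd.DataFrame(rng.normal(20, 2, size=(40, 5)),
                      columns=[f"r{i}" for i in range(5)])
    out, _ = quantile_batch_correct(_lin(df), _design_for(list(df.columns)))
    log2 = np.log2(out.data).to_numpy()
    ref = np.sort(log2[:, 0])
    for j in range(1, 5):
        assert np.allclose(np.sort(log2[:, j]), ref)


def test_quantile_missing_stays_missing():
    df = pd.DataFrame({"A": [1.0, 3.0, 5.0], "B": [2.0, np.nan, 6.0]})
    out, _ = quantile_batch_correct(_lin(df), _design_for(["A", "B"]))
    assert np.isnan(out.data.loc[1, "B"])
    assert out.data.notna().sum().sum() == 5


# ----------------------------------------------------------------- maxlfq

def _oracle_profile(X, linear):
    """Independent normal-equations least-squares oracle (complete data)."""
    n_runs = X.shape[1]
    r = np.zeros((n_runs, n_runs))
    for j in range(n_runs):
        for k in range(n_runs):
            r[j, k] = np.median(X[:, k] - X[:, j])
    L = np.full((n_runs, n_runs), -1.0)
    np.fill_diagonal(L, n_runs - 1)
    rhs = r.sum(axis=0)
    b = np.linalg.pinv(L) @ rhs
    lin = 2.0**b
    return lin * (linear.sum() / lin.sum())


def _table_from_matrix(linear, pg="G"):
    rows = []
    for p in range(linear.shape[0]):
        for r in range(linear.shape[1]):
            if np.isfinite(linear[p, r]):
                rows.append((f"p{p}2", f"P{p}", pg, f"r{r:02d}", linear[p, r], 0.0, 0.0))
    return make_precursors(rows)


def test_maxlfq_single_precursor_identity():
    t = make_precursors(
        [("p2", "P", "G", r, v, 0.0, 0.0) for r, v in
         [("r1", 100.0), ("r2", 200.0), ("r3", 400.0)]]
    )
    m = maxlfq(t, level="protein_group")
    assert np.allclose(m.data.loc["G"], [100.0, 200.0, 400.0])


def test_maxlfq_median_of_pairwise_ratios():
    # three precursors with B/A linear ratios {2, 2, 8} -> median log2 ratio 1
    linear = np.array([[100.0, 200.0], [50.0, 100.0], [10.0, 80.0]])
    t = _table_from_matrix(linear)
    m = maxlfq(t, level="protein_group")
    a, b = m.data.loc["G"].to_numpy()
    assert b / a == pytest.approx(2.0, rel=1e-12)
    assert a + b == pytest.approx(linear.sum(), rel=1e-12)


def test_maxlfq_matches_least_squares_oracle_on_grid():
    rng = np.random.default_rng(17)
    for _ in range(200):
        n_r = int(rng.integers(2, 5))
        n_p = int(rng.integers(1, 6))
        X = rng.normal(20, 2, size=(n_p, n_r))
        linear = 2.0**X
        m = maxlfq(_table_from_matrix(linear), level="protein_group")
        got = m.data.loc["G"].to_numpy()
        exp = _oracle_profile(X, linear)
        assert np.max(np.abs(got - exp) / exp) < 1e-8
        assert abs(got.sum() - linear.sum()) <= 1e-9 * linear.sum()


def test_maxlfq_recovers_profile_up_to_constants():
    rng = np.random.default_rng(5)
    profile = np.array([1.0, 2.0, 0.5, 4.0])
    consts = np.array([[100.0], [3.0], [40000.0]])
    linear = consts * profile[None, :]
    m = maxlfq(_table_from_matrix(linear), level="protein_group")
    got = m.data.loc["G"].to_numpy()
    assert np.allclose(got / got[0], profile / profile[0], rtol=1e-10)


def test_maxlfq_invariant_to_scaling_one_precursor():
    rng = np.random.default_rng(6)
    linear = 2.0 ** rng.normal(20, 2, size=(4, 3))
    base = maxlfq(_table_from_matrix(linear), level="protein_group").data.loc["G"]
    scaled = linear.copy()
    scaled[2] *= 37.5  # complete-data ratios of other precursors dominate the median
    out = maxlfq(_table_from_matrix(scaled), level="protein_group").data.loc["G"]
    assert np.allclose(out / out.iloc[0], base / base.iloc[0], rtol=1e-9)


def test_maxlfq_disconnected_components_independent():
    # precursor p0 spans r0/r1 only, p1 spans r2/r3 only: two components
    linear = np.array(
        [[100.0, 200.0, np.nan, np.nan], [np.nan, np.nan, 50.0, 100.0]]
    )
    base = maxlfq(_table_from_matrix(linear), level="protein_group").data.loc["G"]
    changed = linear.copy()
    changed[1, 2:] *= 9.0
    out = maxlfq(_table_from_matrix(changed), level="protein_group").data.loc["G"]
    assert np.allclose(out.iloc[:2], base.iloc[:2])  # first component untouched
    assert np.allclose(out.iloc[2:], 9.0 * base.iloc[2:])


def test_maxlfq_feature_without_quantification_omitted(caplog):
    rows = [
        ("p02", "P0", "G1", "r1", 10.0, 0.0, 0.0),
        ("p12", "P1", "G2", "r1", np.nan, 0.0, 0.0),
    ]
    with caplog.at_level(logging.INFO):
        m = maxlfq(make_precursors(rows), level="protein_group")
    assert list(m.data.index) == ["G1"]


def test_pipeline_noise_free_null_reproduces_generating_profiles():
    """filter + maxlfq on the noise-free null gives each protein's true
    per-run profile up to one constant per protein."""
    cfg = small_config(
        seed=8,
        peptide_cv=0.0,
        batch_shift_sd_log2=0.0,
        sample_depth_sd_log2=0.0,
        missingness="none",
        decoy_fraction=0.0,
    )
    bundle = simulate_dataset(cfg)
    prot = maxlfq(bundle.precursors, level="protein_group")
    # any member peptide carries the true profile shape
    df = bundle.precursors.df
    for pg in list(prot.data.index)[:5]:
        pep = df[df["protein_group"] == pg].iloc[0]["stripped_sequence"]
        pep_prof = (
            df[df["stripped_sequence"] == pep]
            .set_index("run_id")["intensity"]
            .reindex(prot.data.columns)
            .to_numpy()
        )
        got = prot.data.loc[pg].to_numpy()
        ratio = got / pep_prof
        assert np.allclose(ratio, ratio[0], rtol=1e-9)
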