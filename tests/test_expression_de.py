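import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kiwitx import expression_de as ed


def make_matrix(data, stages=("s1", "s2", "s3"), reps=2, totals=None):
    cols = pd.MultiIndex.from_tuples(
        [(s, f"r{i+1}") for s in stages for i in range(reps)],
        names=["stage", "replicate"],
    )
    counts = pd.DataFrame(data, columns=cols)
    if totals is None:
        totals = pd.Series(1e6, index=cols)
    return ed.CountMatrix(counts=counts, totals=totals)


# ---------------------------------------------------------------------- FPKM

def test_fpkm_unit_example():
    cm = make_matrix([[10] * 6], stages=("s1", "s2", "s3"))
    cm.counts.index = ["g"]
    fpkm = ed.compute_fpkm(cm, {"g": 1000})
    assert fpkm.loc["g"].to_numpy() == pytest.approx(10.0)


def test_fpkm_zero_and_errors():
    cm = make_matrix([[0] * 6, [5] * 6])
    cm.counts.index = ["a", "b"]
    fpkm = ed.compute_fpkm(cm, {"a": 500, "b": 500})
    assert (fpkm.loc["a"] == 0).all()
    with pytest.raises(KeyError, match="b"):
        ed.compute_fpkm(cm, {"a": 500})
    bad = make_matrix([[0] * 6], totals=pd.Series(
        0.0, index=pd.MultiIndex.from_tuples(
            [(s, f"r{i+1}") for s in ("s1", "s2", "s3") for i in range(2)]
        )
    ))
    bad.counts.index = ["a"]
    with pytest.raises(ValueError, match="> 0"):
        ed.compute_fpkm(bad, {"a": 500})


def test_fpkm_scale_invariance(rng):
    counts = rng.integers(0, 500, size=(20, 6)).astype(float)
    cm1 = make_matrix(counts)
    cm2 = make_matrix(counts * 3, totals=pd.Series(3e6, index=cm1.counts.columns))
    lengths = {i: 200 + 10 * i for i in range(20)}
    pd.testing.assert_frame_equal(
        ed.compute_fpkm(cm1, lengths), ed.compute_fpkm(cm2, lengths)
    )


def test_count_matrix_validation():
    with pytest.raises(ValueError, match="MultiIndex"):
        ed.CountMatrix(pd.DataFrame({"a": [1]}), pd.Series({"a": 10}))
    cols = pd.MultiIndex.from_tuples([("s1", "r1")])
    with pytest.raises(ValueError, match="totals smaller"):
        ed.CountMatrix(pd.DataFrame([[100]], columns=cols),
                       pd.Series([50.0], index=cols))


# ---------------------------------------------------------------- stage means

def test_stage_means():
    cm = make_matrix([[2, 4, 10, 30, 0, 0]])
    cm.counts.index = ["g"]
    fpkm = ed.compute_fpkm(cm, {"g": 1000})
    means = ed.stage_means(fpkm)
    assert list(means.columns) == ["s1", "s2", "s3"]
    assert means.loc["g", "s1"] == pytest.approx(3.0)
    assert means.loc["g", "s2"] == pytest.approx(20.0)
    assert means.loc["g", "s3"] == 0.0


# --------------------------------------------------------------- replicate QC

def _qc_frame(columns, data):
    cols = pd.MultiIndex.from_tuples(columns, names=["stage", "replicate"])
    return pd.DataFrame(np.asarray(data, dtype=float).T, columns=cols)


def test_replicate_qc_excludes_outlier(rng):
    base = rng.gamma(2.0, 50.0, size=400)
    good1 = base * (1 + rng.normal(0, 0.02, 400))
    good2 = base * (1 + rng.normal(0, 0.02, 400))
    outlier = rng.permutation(base)
    fpkm = _qc_frame(
        [("s1", "r1"), ("s1", "r2"), ("s1", "r3"), ("s2", "r1"), ("s2", "r2")],
        [good1, good2, outlier, base, base],
    )
    qc = ed.replicate_qc(fpkm, threshold=0.85)
    assert qc.excluded == [("s1", "r3")]
    assert qc.correlations["s1"].loc["r1", "r2"] > 0.99


def test_replicate_qc_boundary_is_strict(rng):
    a = rng.gamma(2.0, 50.0, size=200)
    b = a * (1 + rng.normal(0, 0.5, 200)).clip(min=0)
    fpkm = _qc_frame([("s1", "r1"), ("s1", "r2")], [a, b])
    corr = ed.replicate_qc(fpkm, threshold=0.0).correlations["s1"].loc["r1", "r2"]
    # threshold equal to the observed correlation: strictly-below rule keeps it
    qc = ed.replicate_qc(fpkm, threshold=corr)
    assert qc.excluded == []
    qc2 = ed.replicate_qc(fpkm, threshold=np.nextafter(corr, 2.0))
    assert set(qc2.excluded) == {("s1", "r1"), ("s1", "r2")}


def test_replicate_qc_single_rep_skipped(caplog, rng):
    a = rng.gamma(2.0, 50.0, size=50)
    fpkm = _qc_frame([("s1", "r1"), ("s2", "r1"), ("s2", "r2")], [a, a, a])
    with caplog.at_level("WARNING"):
        qc = ed.replicate_qc(fpkm)
    assert qc.skipped_stages == ["s1"]
    assert "single replicate" in caplog.text


# --------------------------------------------------------------- trace filter

def test_filter_trace():
    means = pd.DataFrame(
        {"s1": [0.0, 0.005, 0.02], "s2": [0.0, 0.009, 0.0]},
        index=["dead", "trace", "alive"],
    )
    kept, dropped = ed.filter_trace(means, eps=0.01)
    assert kept == ["alive"] and dropped == ["dead", "trace"]


# ------------------------------------------------------------- max/min ratio

def test_maxmin_ratio():
    assert ed.maxmin_ratio([5.0, 5.0, 5.0]) == (pytest.approx(1.0), False)
    r, flag = ed.maxmin_ratio([4.0, 0.0, 2.0])
    assert r == pytest.approx(400.0) and flag
    r, flag = ed.maxmin_ratio([0.0, 0.0])
    assert np.isnan(r) and flag
    with pytest.raises(ValueError):
        ed.maxmin_ratio([1.0])


# -------------------------------------------------------------------- F test

def test_anova_f_degenerate():
    assert ed.anova_f([[1.0, 1.0], [1.0, 1.0]]) == (0.0, 1.0)
    f, p = ed.anova_f([[1.0, 1.0], [2.0, 2.0]])
    assert np.isinf(f) and p == 0.0
    with pytest.raises(ValueError):
        ed.anova_f([[1.0, 2.0]])


def test_anova_f_matches_scipy(rng):
    for _ in range(25):
        groups = [rng.normal(rng.uniform(0, 2), 1.0, size=int(rng.integers(2, 5)))
                  for _ in range(3)]
        f, p = ed.anova_f(groups)
        ref = stats.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


def test_f_table_per_gene_matches_anova(rng):
    x = rng.normal(0, 1, size=(30, 6))
    cols = pd.MultiIndex.from_tuples(
        [(s, f"r{i}") for s in ("s1", "s2", "s3") for i in range(2)]
    )
    df = pd.DataFrame(x, columns=cols)
    table = ed.f_test_table(df, variance="per_gene")
    for i in range(30):
        f, p = ed.anova_f([x[i, 0:2], x[i, 2:4], x[i, 4:6]])
        assert table["F"].iloc[i] == pytest.approx(f)
        assert table["raw_p"].iloc[i] == pytest.approx(p)
    with pytest.raises(ValueError, match="unknown variance"):
        ed.f_test_table(df, variance="bogus")


def test_f_table_pooled_monotone(rng):
    x = rng.normal(0, 1, size=(50, 6))
    cols = pd.MultiIndex.from_tuples(
        [(s, f"r{i}") for s in ("s1", "s2", "s3") for i in range(2)]
    )
    table = ed.f_test_table(pd.DataFrame(x, columns=cols), variance="pooled")
    order = table.sort_values("F")
    assert (np.diff(order["raw_p"].to_numpy()) <= 1e-12).all()


# ------------------------------------------------------------------------ BH

def bh_reference(p):
    """Quadratic-time textbook BH step-up."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def test_bh_examples():
    assert ed.bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
    assert ed.bh_adjust([]).size == 0
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        ed.bh_adjust([0.5, 1.2])


def test_bh_against_reference(rng):
    for _ in range(50):
        p = rng.uniform(0, 1, size=int(rng.integers(1, 40)))
        assert ed.bh_adjust(p) == pytest.approx(bh_reference(p))


# --------------------------------------------------------------------- gate

def test_call_de_boundaries():
    assert not ed.call_de(1.9, 0.001)
    assert not ed.call_de(2.5, 0.02)
    assert ed.call_de(2.0, 0.009)
    assert not ed.call_de(float("nan"), 0.001)


def test_run_de_external_p(rng):
    counts = rng.integers(50, 500, size=(8, 6)).astype(float)
    counts[0] *= [1, 1, 4, 4, 1, 1]  # 4-fold change in stage 2
    cm = make_matrix(counts)
    cm.counts.index = [f"g{i}" for i in range(8)]
    lengths = {f"g{i}": 1000 for i in range(8)}
    ext = {f"g{i}": (0.0001 if i == 0 else 0.9) for i in range(8)}
    res = ed.run_de(cm, lengths, external_p=ext, apply_qc=False)
    assert bool(res.table.loc["g0", "is_de"])
    assert not res.table.drop("g0")["is_de"].any()
    assert set(res.table.columns) >= {"maxmin_ratio", "raw_p", "adjusted_p", "is_de"}
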