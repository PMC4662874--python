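"""Moderated t, BH-FDR, group classification, interference correlation."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from chromexo import differential, expression
from conftest import box_probe_table
from oracles import bh_bruteforce

DATA = Path(__file__).parent / "data"


def _matrix(rows: dict[str, list[float]], columns) -> expression.ExpressionMatrix:
    vals = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    vals.index.name = "feature_id"
    return expression.ExpressionMatrix(
        values=vals, flags=pd.Series([""] * len(vals), index=vals.index))


# ----------------------------------------------------------------------
# BH adjustment
# ----------------------------------------------------------------------
@pytest.mark.parametrize("p,expected", [
    ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
    ([0.005, 0.1], [0.01, 0.1]),
    ([0.2, 0.2, 0.2], [0.2, 0.2, 0.2]),
    ([1.0], [1.0]),
])
def test_bh_examples(p, expected):
    np.testing.assert_allclose(differential.bh_adjust(p), expected)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        differential.bh_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        differential.bh_adjust([-0.1])


@settings(max_examples=200, derandomize=True, deadline=None)
@given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                min_size=1, max_size=40))
def test_bh_matches_stepup_oracle(p):
    np.testing.assert_array_equal(differential.bh_adjust(p),
                                  bh_bruteforce(p))


def test_bh_monotone_in_p(world, contrasts):
    tab = contrasts["rrp6_vs_WT"].table.sort_values("p")
    assert tab["padj"].is_monotonic_increasing
    assert (tab["padj"] >= tab["p"] - 1e-15).all()


# ----------------------------------------------------------------------
# moderated t
# ----------------------------------------------------------------------
HAND_FIXTURE = {
    # g1, g2 (3 + 3 replicates), forced d0 = 4, s02 = 0.04
    "t1": ([1.0, 1.2, 0.8], [2.0, 2.1, 2.2]),
    "t2": ([2.0, 2.5, 1.5], [2.0, 2.2, 1.8]),
    "t3": ([0.0, 0.1, -0.1], [1.0, 1.3, 0.7]),
    "t4": ([5.0, 5.0, 5.0], [4.0, 4.2, 4.4]),
}
# frozen step-by-step arithmetic of the stated formulas
HAND_EXPECTED = {
    "t1": dict(lfc=1.1, s2=0.025, s2_post=0.0325,
               t=7.473028425354332, p=7.107201159719021e-05),
    "t2": dict(lfc=0.0, s2=0.145, s2_post=0.0925, t=0.0, p=1.0),
    "t3": dict(lfc=1.0, s2=0.05, s2_post=0.045,
               t=5.773502691896256, p=0.0004176067926797178),
    "t4": dict(lfc=-0.8, s2=0.02, s2_post=0.03,
               t=-5.656854249492378, p=0.00047761405759400716),
}


def _hand_matrix():
    cols = ["g1_a", "g1_b", "g1_c", "g2_a", "g2_b", "g2_c"]
    rows = {k: v[0] + v[1] for k, v in HAND_FIXTURE.items()}
    return _matrix(rows, cols), cols[:3], cols[3:]


def test_moderated_t_matches_hand_computation():
    expr, g1, g2 = _hand_matrix()
    res = differential.fit_contrast(expr, g1, g2, d0=4.0, s02=0.04)
    for tid, exp in HAND_EXPECTED.items():
        row = res.table.loc[tid]
        for key, val in exp.items():
            assert row[key] == pytest.approx(val, abs=1e-10), (tid, key)


def test_zero_prior_df_recovers_ordinary_pooled_t():
    rng = np.random.default_rng(11)
    x = rng.normal(0, 1, size=(30, 6))
    cols = [f"s{i}" for i in range(6)]
    expr = _matrix({f"t{i}": list(x[i]) for i in range(30)}, cols)
    res = differential.fit_contrast(expr, cols[:3], cols[3:], d0=0.0,
                                    s02=1.0)
    ref = stats.ttest_ind(x[:, 3:], x[:, :3], axis=1, equal_var=True)
    np.testing.assert_allclose(res.table["t"], ref.statistic, atol=1e-12)
    np.testing.assert_allclose(res.table["p"], ref.pvalue, atol=1e-12)


def test_infinite_prior_df_gives_constant_posterior_variance():
    expr, g1, g2 = _hand_matrix()
    res = differential.fit_contrast(expr, g1, g2, d0=float("inf"), s02=0.04)
    np.testing.assert_allclose(res.table["s2_post"], 0.04)


def test_moderated_t_matches_limma_reference():
    """Frozen cross-validation against the Bioconductor limma eBayes fit of
    the same synthetic 20-transcript fixture."""
    x = pd.read_csv(DATA / "modt_fixture.tsv", sep="\t", index_col=0)
    ref = pd.read_csv(DATA / "modt_limma_reference.tsv", sep="\t",
                      index_col=0)
    expr = expression.ExpressionMatrix(
        values=x, flags=pd.Series([""] * len(x), index=x.index))
    g1 = [c for c in x.columns if c.startswith("g1")]
    g2 = [c for c in x.columns if c.startswith("g2")]
    res = differential.fit_contrast(expr, g1, g2)
    assert res.d0 == pytest.approx(1.725241943, abs=1e-8)
    assert res.s02 == pytest.approx(0.3425819536, abs=1e-9)
    for col in ("lfc", "t", "p", "padj", "s2_post"):
        np.testing.assert_allclose(res.table[col], ref[col], atol=1e-8)


def test_prior_moment_matching_recovers_known_prior():
    rng = np.random.default_rng(5)
    d0_true, s02_true, dg, n = 6.0, 0.3, 4, 5000
    sigma2 = d0_true * s02_true / rng.chisquare(d0_true, n)
    s2 = sigma2 * rng.chisquare(dg, n) / dg
    d0_hat, s02_hat = differential.estimate_prior(
        s2, np.full(n, float(dg)))
    assert d0_hat == pytest.approx(d0_true, rel=0.25)
    assert s02_hat == pytest.approx(s02_true, rel=0.1)


def test_underpowered_transcripts_flagged():
    cols = ["a1", "a2", "b1", "b2"]
    vals = pd.DataFrame([[1.0, np.nan, 2.0, 2.1]], index=["t0"],
                        columns=cols)
    vals.index.name = "feature_id"
    expr = expression.ExpressionMatrix(
        values=vals, flags=pd.Series([""], index=vals.index))
    res = differential.fit_contrast(expr, cols[:2], cols[2:], d0=0.0,
                                    s02=1.0)
    assert res.table.loc["t0", "flag"] == "too_few_replicates"
    assert np.isnan(res.table.loc["t0", "padj"])


# ----------------------------------------------------------------------
# group classification
# ----------------------------------------------------------------------
def _diff_from(values: dict[str, dict[str, tuple[float, float]]]):
    """Build DiffResults from {contrast: {id: (lfc, padj)}}."""
    out = {}
    ids = sorted({i for v in values.values() for i in v})
    for contrast, v in values.items():
        tab = pd.DataFrame(
            dict(lfc=[v[i][0] for i in ids], padj=[v[i][1] for i in ids]),
            index=pd.Index(ids, name="feature_id"))
        out[contrast] = differential.DiffResult(table=tab, d0=0, s02=1,
                                                n1=3, n2=3)
    return out


def test_classification_rule_examples():
    diff = _diff_from({
        "rrp6_vs_WT": {"orfA": (1.0, 0.05), "cutD": (2.1, 0.02),
                       "dull": (0.1, 0.5)},
        "rtt109_rrp6_vs_rrp6": {"orfA": (-0.8, 0.2), "cutD": (-0.7, 0.1),
                                "dull": (0.0, 0.9)},
        "swr1_rrp6_vs_rrp6": {"orfA": (0.0, 0.9), "cutD": (-0.7, 0.1),
                              "dull": (0.2, 0.5)},
    })
    bio = pd.Series({"orfA": "ORF", "cutD": "CUT", "dull": "ORF"})
    labels = differential.classify_groups(diff, bio)["label"]
    assert labels.loc["orfA"] == "A"
    assert labels.loc["cutD"] == "D"
    assert labels.loc["dull"] == "none"


def test_classification_strict_thresholds():
    # exactly at the printed cutoffs -> not significant (strict inequality)
    diff = _diff_from({
        "rrp6_vs_WT": {"x": (0.59, 0.05), "y": (1.0, 0.1)},
        "rtt109_rrp6_vs_rrp6": {"x": (-1.0, 0.01), "y": (-1.0, 0.01)},
        "swr1_rrp6_vs_rrp6": {"x": (0.0, 0.9), "y": (0.0, 0.9)},
    })
    bio = pd.Series({"x": "CUT", "y": "CUT"})
    labels = differential.classify_groups(diff, bio)["label"]
    assert (labels == "none").all()


def test_classification_requires_all_contrasts():
    diff = _diff_from({"rrp6_vs_WT": {"x": (1.0, 0.01)}})
    with pytest.raises(KeyError, match="rtt109_rrp6_vs_rrp6"):
        differential.classify_groups(diff, pd.Series({"x": "ORF"}))


def test_planted_groups_fully_recovered(world, contrasts):
    """With the default study conditions every planted label is recovered
    and no unchanged transcript is mislabeled."""
    bio = world["annotation"].set_index("feature_id")["biotype"]
    groups = differential.classify_groups(contrasts, bio)
    tl = world["truth"].features.set_index("feature_id")["true_label"]
    tl = tl.reindex(groups.index)
    assert (groups["label"] == tl).all()


# ----------------------------------------------------------------------
# interference correlation
# ----------------------------------------------------------------------
def _orf(fid, start, end, strand="+", chrom="chrX"):
    return dict(feature_id=fid, chrom=chrom, start=start, end=end,
                strand=strand, biotype="ORF")


def test_interference_perfect_copy_gives_rho_one():
    rng = np.random.default_rng(3)
    rows, orfs = [], []
    for k in range(30):
        tss = 1000 + k * 500
        level = rng.normal(0, 1)
        for p in range(tss - 100, tss + 100, 10):
            rows.append(("chrX", p, "+", "s1", level))
        orfs.append(_orf(f"o{k}", tss, tss + 200))
    pt = box_probe_table(["s1"], {"s1": 0.0})
    pt.data = pd.DataFrame(rows, columns=["chrom", "pos", "strand",
                                          "sample", "value"])
    rep = differential.interference_correlation(pt, pd.DataFrame(orfs),
                                                n_permutations=199)
    assert rep["rho"] == pytest.approx(1.0)
    assert rep["p_value"] < 0.05


def test_interference_independent_windows_uncorrelated():
    rng = np.random.default_rng(4)
    rows, orfs = [], []
    for k in range(200):
        tss = 1000 + k * 500
        up, down = rng.normal(0, 1, 2)
        for p in range(tss - 100, tss, 10):
            rows.append(("chrX", p, "+", "s1", up + rng.normal(0, 0.1)))
        for p in range(tss, tss + 100, 10):
            rows.append(("chrX", p, "+", "s1", down + rng.normal(0, 0.1)))
        orfs.append(_orf(f"o{k}", tss, tss + 200))
    pt = box_probe_table(["s1"], {"s1": 0.0})
    pt.data = pd.DataFrame(rows, columns=["chrom", "pos", "strand",
                                          "sample", "value"])
    rep = differential.interference_correlation(pt, pd.DataFrame(orfs),
                                                n_permutations=499, seed=1)
    assert abs(rep["rho"]) < 0.15
    assert rep["p_value"] > 0.05


def test_interference_minus_strand_upstream_at_larger_coordinates():
    """For a - strand ORF the upstream window is [end, end+100)."""
    rows = []
    end = 2000
    for p in range(end, end + 100, 10):          # upstream on - strand
        rows.append(("chrX", p, "-", "s1", 5.0))
    for p in range(end - 100, end, 10):          # downstream (gene body)
        rows.append(("chrX", p, "-", "s1", -3.0))
    orfs = pd.DataFrame([_orf("o_minus", 1000, end, strand="-"),
                         _orf("o2", 3000, 3500, strand="-"),
                         _orf("o3", 4000, 4500, strand="-")])
    extra = [("chrX", p, "-", "s1", 0.0)
             for s in (3400, 3500, 4400, 4500) for p in range(s, s + 100, 10)]
    pt = box_probe_table(["s1"], {"s1": 0.0})
    pt.data = pd.DataFrame(rows + extra,
                           columns=["chrom", "pos", "strand", "sample",
                                    "value"]).sort_values("pos")
    rep = differential.interference_correlation(pt, orfs, n_permutations=99)
    row = rep["table"].set_index("feature_id").loc["o_minus"]
    assert row["upstream"] == 5.0
    assert row["downstream"] == -3.0
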