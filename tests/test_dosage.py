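import numpy as np
import pandas as pd
import pytest

from zdosage import dosage
from zdosage.annot_io import GenomeAnnotation
from zdosage.dosage import (
    sex_bias_table,
    top_region,
    wilcoxon_rank_sum,
    window_scan,
    z_aa_test,
)
from zdosage.quantify import ExpressionMatrix

from helpers import brute_window_scan, exact_ranksum_enumeration, make_gene


# ---------------------------------------------------------------------------
# wilcoxon_rank_sum
# ---------------------------------------------------------------------------


def test_exact_definitional_case():
    _, p = wilcoxon_rank_sum([1, 2], [3, 4], mode="exact")
    assert p == pytest.approx(1 / 3)


def test_identical_multisets_p_one():
    with pytest.warns(UserWarning):
        _, p = wilcoxon_rank_sum([2, 2, 2], [2, 2], mode="exact")
    assert p == 1.0


def test_exact_matches_enumeration_with_ties(rng):
    for _ in range(200):
        nx, ny = rng.integers(2, 7, 2)
        vals = rng.integers(0, 6, int(nx + ny)).astype(float)
        x, y = vals[:nx], vals[nx:]
        if np.ptp(vals) == 0:
            continue
        _, p = wilcoxon_rank_sum(x, y, mode="exact")
        assert p == pytest.approx(exact_ranksum_enumeration(x, y), abs=1e-12)


def test_antisymmetry(rng):
    for _ in range(50):
        x = rng.normal(size=5)
        y = rng.normal(size=6)
        _, p_xy = wilcoxon_rank_sum(x, y, mode="exact")
        _, p_yx = wilcoxon_rank_sum(y, x, mode="exact")
        assert p_xy == pytest.approx(p_yx)


def test_auto_dispatches_exact_for_small_groups(rng):
    # 1-vs-many: auto must agree with exact, not the normal approximation
    x = [5.0]
    y = rng.normal(size=30).tolist()
    _, p_auto = wilcoxon_rank_sum(x, y, mode="auto")
    _, p_exact = wilcoxon_rank_sum(x, y, mode="exact")
    assert p_auto == pytest.approx(p_exact)


def test_normal_mode_reasonable_large_n(rng):
    x = rng.normal(size=60)
    y = rng.normal(loc=2.0, size=60)
    _, p = wilcoxon_rank_sum(x, y, mode="normal")
    assert p < 1e-6


def test_empty_group_rejected():
    with pytest.raises(ValueError):
        wilcoxon_rank_sum([], [1.0])


# ---------------------------------------------------------------------------
# sex_bias_table
# ---------------------------------------------------------------------------


def _bias_setup(simple_sheet, mean_m, mean_f):
    g = make_gene("G1", "1", "+", [[(100, 200)]])
    ann = GenomeAnnotation(chromosomes={"1": 1000}, genes=[g])
    cols = simple_sheet.sample_ids
    vals = [[mean_m] * 4 + [mean_f] * 4]
    expr = ExpressionMatrix(
        data=pd.DataFrame(np.array(vals, float), index=["G1"], columns=cols),
        unit="per_scale",
        level="gene",
    )
    return sex_bias_table(expr, simple_sheet, ann, "gonad")


def test_sex_bias_log2_and_amplitude(simple_sheet):
    tab = _bias_setup(simple_sheet, 4, 2)
    assert tab.loc[0, "log2_mf"] == pytest.approx(1.0)
    assert tab.loc[0, "amplitude"] == pytest.approx(1.0)
    assert not tab.loc[0, "outlier"]


def test_sex_bias_identity(simple_sheet):
    tab = _bias_setup(simple_sheet, 3, 3)
    assert tab.loc[0, "log2_mf"] == 0


def test_sex_bias_outlier_flag(simple_sheet):
    tab = _bias_setup(simple_sheet, 64, 1)
    assert tab.loc[0, "log2_mf"] == pytest.approx(6.0)
    assert bool(tab.loc[0, "outlier"])


def test_sex_bias_zero_mean_excluded(simple_sheet):
    tab = _bias_setup(simple_sheet, 4, 0)
    assert len(tab) == 0


def test_sex_bias_excluded_chromosomes(simple_sheet):
    gw = make_gene("GW", "W", "+", [[(10, 20)]])
    g1 = make_gene("G1", "1", "+", [[(10, 20)]])
    ann = GenomeAnnotation(chromosomes={"W": 100, "1": 100}, genes=[gw, g1])
    cols = simple_sheet.sample_ids
    expr = ExpressionMatrix(
        data=pd.DataFrame(np.ones((2, 8)), index=["GW", "G1"], columns=cols),
        unit="per_scale",
        level="gene",
    )
    tab = sex_bias_table(expr, simple_sheet, ann, "gonad")
    assert tab["feature_id"].tolist() == ["G1"]


def test_sex_bias_unknown_feature_errors(simple_sheet):
    g = make_gene("G1", "1", "+", [[(10, 20)]])
    ann = GenomeAnnotation(chromosomes={"1": 100}, genes=[g])
    expr = ExpressionMatrix(
        data=pd.DataFrame(
            np.ones((1, 8)), index=["GHOST"], columns=simple_sheet.sample_ids
        ),
        unit="per_scale",
        level="gene",
    )
    with pytest.raises(ValueError, match="GHOST"):
        sex_bias_table(expr, simple_sheet, ann, "gonad")


def test_sex_swap_antisymmetry(rng, simple_sheet):
    genes = [make_gene(f"G{i}", "1", "+", [[(i * 100 + 1, i * 100 + 50)]]) for i in range(10)]
    ann = GenomeAnnotation(chromosomes={"1": 10_000}, genes=genes)
    cols = simple_sheet.sample_ids
    vals = rng.random((10, 8)) + 0.1
    expr = ExpressionMatrix(
        data=pd.DataFrame(vals, index=[g.gene_id for g in genes], columns=cols),
        unit="per_scale",
        level="gene",
    )
    swapped_sheet = simple_sheet.table.copy()
    swapped_sheet["sex"] = swapped_sheet["sex"].map({"M": "F", "F": "M"})
    from zdosage.annot_io import SampleSheet

    t1 = sex_bias_table(expr, simple_sheet, ann, "gonad").set_index("feature_id")
    t2 = sex_bias_table(expr, SampleSheet(swapped_sheet), ann, "gonad").set_index("feature_id")
    assert np.allclose(t1["log2_mf"], -t2["log2_mf"])
    assert np.allclose(t1["amplitude"], t2["amplitude"])


# ---------------------------------------------------------------------------
# z_aa_test
# ---------------------------------------------------------------------------


def test_z_aa_empty_z_errors(simple_sheet):
    g = make_gene("G1", "1", "+", [[(10, 20)]])
    ann = GenomeAnnotation(chromosomes={"1": 100, "Z": 100}, genes=[g])
    expr = ExpressionMatrix(
        data=pd.DataFrame(np.ones((1, 8)), index=["G1"], columns=simple_sheet.sample_ids),
        unit="per_scale",
        level="gene",
    )
    with pytest.raises(ValueError):
        z_aa_test(expr, simple_sheet, ann, "gonad", "F")


def test_z_aa_single_z_feature_exact_mode(simple_sheet):
    genes = [make_gene("GZ", "Z", "+", [[(10, 20)]])] + [
        make_gene(f"G{i}", "1", "+", [[(i * 100 + 1, i * 100 + 50)]]) for i in range(12)
    ]
    ann = GenomeAnnotation(chromosomes={"1": 10_000, "Z": 100}, genes=genes)
    rng = np.random.default_rng(5)
    vals = rng.random((13, 8)) + 0.5
    expr = ExpressionMatrix(
        data=pd.DataFrame(vals, index=[g.gene_id for g in genes], columns=simple_sheet.sample_ids),
        unit="per_scale",
        level="gene",
    )
    res = z_aa_test(expr, simple_sheet, ann, "gonad", "F")
    assert res.n_z == 1 and res.n_aa == 12
    # auto must have dispatched to the exact distribution: p is a multiple of
    # the smallest achievable exact tail for 1-vs-12 (1/13)
    assert res.p_value * 13 / 2 == pytest.approx(round(res.p_value * 13 / 2))


# ---------------------------------------------------------------------------
# window_scan / top_region
# ---------------------------------------------------------------------------


def _records(rows):
    return pd.DataFrame(
        rows, columns=["feature_id", "chrom", "position", "mean_M", "mean_F", "log2_mf", "amplitude", "outlier"]
    )


def test_window_scan_trivial_means():
    rec = _records(
        [
            ("a", "Z", 500_001, 2, 1, 1.0, 1.0, False),
            ("b", "Z", 1_500_001, 8, 1, 3.0, 3.0, False),
        ]
    )
    scan = window_scan(rec, 4_000_000, window=3_000_000, shift=1_000_000)
    first = scan.iloc[0]
    assert first["n_genes"] == 2
    assert first["mean_log2_mf"] == pytest.approx(2.0)
    assert first["mean_amplitude"] == pytest.approx(2.0)


def test_window_scan_constancy(rng):
    rows = [
        (f"g{i}", "Z", int(p), 2, 1, 0.7, 0.7, False)
        for i, p in enumerate(rng.integers(1, 9_000_000, 40))
    ]
    scan = window_scan(_records(rows), 9_000_000)
    nonempty = scan[scan.n_genes > 0]
    assert np.allclose(nonempty["mean_log2_mf"], 0.7)


def test_window_scan_excludes_outliers():
    rec = _records(
        [
            ("a", "Z", 1_000, 2, 1, 1.0, 1.0, False),
            ("b", "Z", 2_000, 64, 1, 6.0, 6.0, True),
        ]
    )
    scan = window_scan(rec, 3_000_000)
    assert scan.iloc[0]["n_genes"] == 1
    assert scan.iloc[0]["mean_log2_mf"] == pytest.approx(1.0)


def test_window_scan_brute_force(rng):
    chrom_len = 10_000_000
    rows = []
    for i in range(120):
        pos = int(rng.integers(1, chrom_len + 1))
        l = float(rng.normal())
        rows.append((f"g{i}", "Z", pos, 1, 1, l, abs(l), bool(rng.random() < 0.1)))
    rec = _records(rows)
    for window, shift in ((3_000_000, 1_000_000), (2_000_000, 2_000_000), (2_500_000, 500_000)):
        scan = window_scan(rec, chrom_len, window=window, shift=shift)
        brute = brute_window_scan(
            [(r[2], r[5], r[6], r[7]) for r in rows], chrom_len, window, shift
        )
        assert len(scan) == len(brute)
        for got, want in zip(scan.itertuples(index=False), brute):
            assert (got.window_start, got.window_end, got.n_genes) == want[:3]
            if want[3] is None:
                assert np.isnan(got.mean_log2_mf)
            else:
                assert got.mean_log2_mf == pytest.approx(want[3])
                assert got.mean_amplitude == pytest.approx(want[4])


def test_window_scan_rejects_window_lt_shift():
    with pytest.raises(ValueError):
        window_scan(_records([]), 1_000, window=10, shift=20)


def test_top_region_merge_example():
    # best window 31-34 Mb, runner-up 32-35 Mb within 10% -> merged 31-35 Mb
    rows = []
    for start in range(0, 38_000_000, 1_000_000):
        val = 0.1
        if start == 31_000_000:
            val = 1.0
        elif start == 32_000_000:
            val = 0.95
        rows.append(("Z", start, start + 3_000_000, 3, val, abs(val)))
    scan = pd.DataFrame(
        rows,
        columns=["chrom", "window_start", "window_end", "n_genes", "mean_log2_mf", "mean_amplitude"],
    )
    region = top_region(scan)
    assert (region.start, region.end) == (31_000_000, 35_000_000)
    assert region.value == pytest.approx(1.0)


def test_top_region_unimodal_is_argmax():
    rows = [
        ("Z", s, s + 3_000_000, 2, v, abs(v))
        for s, v in ((0, 0.1), (1_000_000, 0.9), (2_000_000, 0.2))
    ]
    scan = pd.DataFrame(
        rows,
        columns=["chrom", "window_start", "window_end", "n_genes", "mean_log2_mf", "mean_amplitude"],
    )
    region = top_region(scan)
    assert (region.start, region.end) == (1_000_000, 4_000_000)


def test_top_region_all_empty_errors():
    scan = pd.DataFrame(
        [("Z", 0, 3_000_000, 0, np.nan, np.nan)],
        columns=["chrom", "window_start", "window_end", "n_genes", "mean_log2_mf", "mean_amplitude"],
    )
    with pytest.raises(ValueError):
        top_region(scan)
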