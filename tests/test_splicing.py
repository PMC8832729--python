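import numpy as np
import pandas as pd
import pytest

from zdosage import splicing
from zdosage.quantify import ExpressionMatrix
from zdosage.splicing import (
    ASEvent,
    classify_events,
    differential_splicing,
    psi,
    psi_table,
    unique_transcripts,
)

from helpers import (
    bh_stepup,
    brute_force_events,
    exact_ranksum_enumeration,
    make_gene,
    random_gene,
)


def _event_key(e: ASEvent):
    return (e.event_type, e.start, e.end, e.inclusion, e.exclusion)


# ---------------------------------------------------------------------------
# classify_events: definitional examples
# ---------------------------------------------------------------------------


def test_exon_skipping_definitional():
    g = make_gene(
        "G1", "1", "+",
        [
            [(1, 100), (201, 300), (401, 500)],  # A: includes middle exon
            [(1, 100), (401, 500)],  # B: skips it
        ],
    )
    events = classify_events(g)
    assert len(events) == 1
    e = events[0]
    assert e.event_type == "exon_skipping"
    assert (e.start, e.end) == (201, 300)
    assert e.inclusion == frozenset({"G1.1"})
    assert e.exclusion == frozenset({"G1.2"})


def test_intron_retention_definitional():
    g = make_gene(
        "G1", "1", "+",
        [
            [(1, 100), (201, 300)],  # A: spliced
            [(1, 300)],  # B: retains the intron
        ],
    )
    events = classify_events(g)
    assert len(events) == 1
    e = events[0]
    assert e.event_type == "intron_retention"
    assert (e.start, e.end) == (101, 200)
    assert e.inclusion == frozenset({"G1.2"})  # retainer carries the inclusion form
    assert e.exclusion == frozenset({"G1.1"})


def test_alt_5ss_and_strand_mirror():
    iso = [
        [(1, 100), (201, 300)],
        [(1, 80), (201, 300)],  # donor shifted left: intron (81,200) vs (101,200)
    ]
    plus = classify_events(make_gene("G1", "1", "+", iso))
    minus = classify_events(make_gene("G2", "1", "-", iso))
    assert len(plus) == len(minus) == 1
    assert plus[0].event_type == "alt_5ss"
    assert minus[0].event_type == "alt_3ss"
    # variable region is the exonic stretch present only in the long-exon form
    assert (plus[0].start, plus[0].end) == (81, 100)
    assert plus[0].inclusion == frozenset({"G1.1"})


def test_alt_3ss():
    iso = [
        [(1, 100), (201, 300)],
        [(1, 100), (231, 300)],  # acceptor shifted right: intron (101,230)
    ]
    ev = classify_events(make_gene("G1", "1", "+", iso))
    assert len(ev) == 1
    assert ev[0].event_type == "alt_3ss"
    assert (ev[0].start, ev[0].end) == (201, 230)
    assert ev[0].inclusion == frozenset({"G1.1"})


def test_mutually_exclusive_exons():
    g = make_gene(
        "G1", "1", "+",
        [
            [(1, 100), (201, 250), (401, 500)],
            [(1, 100), (301, 350), (401, 500)],
        ],
    )
    ev = classify_events(g)
    assert len(ev) == 1
    e = ev[0]
    assert e.event_type == "mutually_exclusive_exons"
    assert (e.start, e.end) == (201, 350)
    assert e.inclusion == frozenset({"G1.1"})  # leftmost-exon carrier
    assert e.exclusion == frozenset({"G1.2"})


def test_single_transcript_gene_empty():
    g = make_gene("G1", "1", "+", [[(1, 100), (201, 300)]])
    assert classify_events(g) == []


def test_order_invariance():
    iso = [
        [(1, 100), (201, 300), (401, 500)],
        [(1, 100), (401, 500)],
        [(1, 300), (401, 500)],
    ]
    g1 = make_gene("G1", "1", "+", iso)
    g2 = make_gene("G1", "1", "+", iso[::-1])
    # same gene content, transcripts constructed in reverse order; compare by
    # geometry only (ids differ by construction order)
    k1 = sorted((e.event_type, e.start, e.end) for e in classify_events(g1))
    k2 = sorted((e.event_type, e.start, e.end) for e in classify_events(g2))
    assert k1 == k2


def test_terminal_exon_differences_are_not_events():
    g = make_gene(
        "G1", "1", "+",
        [
            [(1, 100), (201, 300)],
            [(50, 100), (201, 400)],  # different terminal boundaries only
        ],
    )
    assert classify_events(g) == []


def test_brute_force_agreement(rng):
    mismatches = 0
    for i in range(400):
        g = random_gene(rng, gene_id=f"G{i}", max_exons=5)
        got = {_event_key(e) for e in classify_events(g)}
        want = brute_force_events(g)
        if got != want:
            mismatches += 1
            print(g.gene_id, got ^ want)
    assert mismatches == 0


def test_asevent_validation():
    with pytest.raises(ValueError):
        ASEvent("g", "exon_skipping", 1, 2, frozenset({"a"}), frozenset({"a"}))
    with pytest.raises(ValueError):
        ASEvent("g", "exon_skipping", 1, 2, frozenset(), frozenset({"a"}))


# ---------------------------------------------------------------------------
# PSI
# ---------------------------------------------------------------------------


def _expr(rows: dict, samples):
    return ExpressionMatrix(
        data=pd.DataFrame(rows, index=samples).T.astype(float),
        unit="per_scale",
        level="transcript",
    )


def test_psi_values(simple_sheet):
    cols = simple_sheet.sample_ids
    expr = _expr({"t_inc": [3.0] * 8, "t_exc": [1.0] * 8}, cols)
    ev = ASEvent("g", "exon_skipping", 1, 2, frozenset({"t_inc"}), frozenset({"t_exc"}))
    tab = psi(ev, expr)
    assert np.allclose(tab["psi"], 0.75)
    assert tab["defined"].all()


def test_psi_exclusion_zero(simple_sheet):
    cols = simple_sheet.sample_ids
    expr = _expr({"t_inc": [2.0] * 8, "t_exc": [0.0] * 8}, cols)
    ev = ASEvent("g", "exon_skipping", 1, 2, frozenset({"t_inc"}), frozenset({"t_exc"}))
    assert np.allclose(psi(ev, expr)["psi"], 1.0)


def test_psi_denominator_zero_undefined(simple_sheet):
    cols = simple_sheet.sample_ids
    expr = _expr({"t_inc": [0.0] * 8, "t_exc": [0.0] * 8}, cols)
    ev = ASEvent("g", "exon_skipping", 1, 2, frozenset({"t_inc"}), frozenset({"t_exc"}))
    tab = psi(ev, expr)
    assert not tab["defined"].any()


def test_psi_missing_transcript_errors(simple_sheet):
    expr = _expr({"t_inc": [1.0] * 8}, simple_sheet.sample_ids)
    ev = ASEvent("g", "exon_skipping", 1, 2, frozenset({"t_inc"}), frozenset({"gone"}))
    with pytest.raises(ValueError, match="gone"):
        psi(ev, expr)


def test_psi_bounds(rng, simple_sheet):
    cols = simple_sheet.sample_ids
    expr = _expr(
        {"a": rng.random(8) * 10, "b": rng.random(8) * 10}, cols
    )
    ev = ASEvent("g", "exon_skipping", 1, 2, frozenset({"a"}), frozenset({"b"}))
    vals = psi(ev, expr)["psi"]
    assert ((vals >= 0) & (vals <= 1)).all()


# ---------------------------------------------------------------------------
# differential splicing
# ---------------------------------------------------------------------------


def test_diff_splice_identical_distributions(simple_sheet):
    cols = simple_sheet.sample_ids
    expr = _expr({"a": [1, 2, 3, 4, 1, 2, 3, 4], "b": [4, 3, 2, 1, 4, 3, 2, 1]}, cols)
    ev = ASEvent("g", "exon_skipping", 1, 2, frozenset({"a"}), frozenset({"b"}))
    out = differential_splicing(psi_table([ev], expr), simple_sheet, "gonad")
    assert out.loc[0, "delta_psi"] == pytest.approx(0.0)
    assert not out.loc[0, "significant"]


def test_diff_splice_exact_p_2_over_70(simple_sheet):
    cols = simple_sheet.sample_ids
    # M PSIs all 0.9, F all 0.1 via expression 9:1 vs 1:9
    expr = _expr(
        {"a": [9, 9, 9, 9, 1, 1, 1, 1], "b": [1, 1, 1, 1, 9, 9, 9, 9]}, cols
    )
    ev = ASEvent("g", "exon_skipping", 1, 2, frozenset({"a"}), frozenset({"b"}))
    out = differential_splicing(psi_table([ev], expr), simple_sheet, "gonad")
    assert out.loc[0, "delta_psi"] == pytest.approx(0.8)
    assert out.loc[0, "p_value"] == pytest.approx(2 / 70)
    # single event: fdr == p; significant at the default thresholds
    assert bool(out.loc[0, "significant"])


def test_diff_splice_skips_underpowered_events(simple_sheet, caplog):
    cols = simple_sheet.sample_ids
    vals_a = [1, 0, 0, 0, 1, 1, 1, 1]
    vals_b = [1, 0, 0, 0, 1, 1, 1, 1]  # males have 3 undefined PSIs
    expr = _expr({"a": vals_a, "b": vals_b}, cols)
    ev = ASEvent("g", "exon_skipping", 1, 2, frozenset({"a"}), frozenset({"b"}))
    out = differential_splicing(psi_table([ev], expr), simple_sheet, "gonad")
    assert out.empty


def test_bh_matches_brute_force(rng):
    from statsmodels.stats.multitest import multipletests

    for _ in range(30):
        p = rng.random(int(rng.integers(1, 40)))
        ours = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, bh_stepup(p))


def test_diff_splice_power_and_null():
    from zdosage.synthetic_data import simulate_splicing_counts
    from zdosage.quantify import normalize

    # strong effect, low noise: all events recovered
    counts, sheet, events = simulate_splicing_counts(
        40, delta_psi=0.5, dispersion=0.005, seed=3
    )
    ptab = psi_table(events, normalize(counts))
    out = differential_splicing(ptab, sheet, "gonad")
    assert out["significant"].mean() >= 0.8

    # null: false-positive rate within calibration bounds
    counts0, sheet0, events0 = simulate_splicing_counts(
        200, delta_psi=0.0, dispersion=0.005, seed=4
    )
    out0 = differential_splicing(psi_table(events0, normalize(counts0)), sheet0, "gonad")
    assert out0["significant"].mean() <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 200)


# ---------------------------------------------------------------------------
# unique transcripts
# ---------------------------------------------------------------------------


def _two_tissue_sheet():
    from zdosage.annot_io import SampleSheet

    rows = [
        {"sample_id": f"{t}_{s}{r}", "sex": s, "tissue": t, "replicate": r}
        for t in ("gonad", "skin")
        for s in ("M", "F")
        for r in (1, 2)
    ]
    return SampleSheet(pd.DataFrame(rows))


def test_unique_transcripts_examples():
    sheet = _two_tissue_sheet()
    cols = sheet.sample_ids
    data = {
        "only_mg": [1, 1, 0, 0, 0, 0, 0, 0],  # gonad_M1, gonad_M2 first
        "everywhere": [1] * 8,
    }
    expr = ExpressionMatrix(
        data=pd.DataFrame(data, index=cols).T.astype(float),
        unit="per_scale",
        level="transcript",
    )
    uniques, member = unique_transcripts(expr, sheet)
    assert "only_mg" in uniques[("M", "gonad")]
    assert all("everywhere" not in s for s in uniques.values())
    assert member.loc["everywhere", "n_groups"] == 4


def test_unique_transcripts_brute_force(rng):
    sheet = _two_tissue_sheet()
    cols = sheet.sample_ids
    vals = (rng.random((60, 8)) < 0.4) * rng.random((60, 8))
    expr = ExpressionMatrix(
        data=pd.DataFrame(vals, index=[f"t{i}" for i in range(60)], columns=cols),
        unit="per_scale",
        level="transcript",
    )
    uniques, member = unique_transcripts(expr, sheet)
    meta = sheet.table
    for t in expr.feature_ids:
        expressed = set()
        for sex, tissue in {(r.sex, r.tissue) for r in meta.itertuples()}:
            cs = [r.sample_id for r in meta.itertuples() if r.sex == sex and r.tissue == tissue]
            if np.mean([expr.data.at[t, c] for c in cs]) > 0:
                expressed.add((sex, tissue))
        for grp, s in uniques.items():
            assert (t in s) == (expressed == {grp})
        assert member.loc[t, "n_groups"] == len(expressed)
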