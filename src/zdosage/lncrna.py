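"""lncRNA candidate filtering, positional classification, cis-target
assignment and sex-bias calls.

Classification is positional, relative to the protein-coding annotation, with
a fixed precedence: intergenic (lincRNA) → antisense (opposite-strand exonic
overlap) → sense (same-strand exonic overlap) → intronic (fully inside one
intron, same strand by default).  Targets are coding genes whose span lies
strictly within ``max_dist`` (gap distance; overlap = 0) of the lncRNA span.
Coding potential is not scored here: noncoding labels are an input (the
simulator's truth file, or any external boolean column).
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .annot_io import GenomeAnnotation, SampleSheet, TranscriptModel
from .quantify import ExpressionMatrix, group_mean

CLASSES = ("lincRNA", "antisense", "sense", "intronic")


def filter_candidates(
    transcripts: Iterable[TranscriptModel],
    noncoding_ids: Iterable[str],
    min_len: int = 200,
    min_exons: int = 2,
) -> list[TranscriptModel]:
    """Keep noncoding transcripts with spliced length > min_len (strict) and
    at least ``min_exons`` exons."""
    noncoding = set(noncoding_ids)
    return [
        t
        for t in transcripts
        if t.transcript_id in noncoding
        and t.length > min_len
        and t.n_exons >= min_exons
    ]


def _span_overlap(a_start, a_end, b_start, b_end) -> bool:
    return a_start <= b_end and b_start <= a_end


def classify(
    lnc: TranscriptModel,
    coding: GenomeAnnotation,
    intronic_same_strand: bool = True,
) -> str:
    """Positional class of one lncRNA against the coding annotation."""
    genes = [
        g
        for g in coding.coding_genes()
        if g.chrom == lnc.chrom and _span_overlap(lnc.start, lnc.end, g.start, g.end)
    ]
    if not genes:
        return "lincRNA"

    def exonic_overlap(g):
        return any(
            _span_overlap(le.start, le.end, ge.start, ge.end)
            for le in lnc.exons
            for t in g.transcripts
            for ge in t.exons
        )

    opposite = [g for g in genes if g.strand != lnc.strand and exonic_overlap(g)]
    if opposite:
        return "antisense"
    same = [g for g in genes if g.strand == lnc.strand and exonic_overlap(g)]
    if same:
        return "sense"
    for g in genes:
        if intronic_same_strand and g.strand != lnc.strand:
            continue
        for s, e in g.intron_union():
            if s <= lnc.start and lnc.end <= e:
                return "intronic"
    return "antisense"


def classify_all(
    lncs: Iterable[TranscriptModel],
    coding: GenomeAnnotation,
    intronic_same_strand: bool = True,
) -> pd.DataFrame:
    rows = [
        {
            "lncrna_id": t.transcript_id,
            "class": classify(t, coding, intronic_same_strand),
            "length": t.length,
            "n_exons": t.n_exons,
            "chrom": t.chrom,
            "start": t.start,
            "end": t.end,
            "strand": t.strand,
        }
        for t in lncs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "lncrna_id",
            "class",
            "length",
            "n_exons",
            "chrom",
            "start",
            "end",
            "strand",
        ],
    )


def assign_targets(
    lncs: Iterable[TranscriptModel],
    coding: GenomeAnnotation,
    max_dist: int = 100_000,
) -> pd.DataFrame:
    """Cis targets: coding genes with span-to-span gap strictly below max_dist.

    Distance is the number of bases between the spans (0 when overlapping);
    the sign and the up/downstream relation follow the lncRNA's strand.
    """
    by_chrom: dict[str, list] = {}
    for g in coding.coding_genes():
        by_chrom.setdefault(g.chrom, []).append(g)
    rows = []
    for lnc in lncs:
        for g in by_chrom.get(lnc.chrom, []):
            if _span_overlap(lnc.start, lnc.end, g.start, g.end):
                gap, relation, signed = 0, "overlapping", 0
            else:
                if g.start > lnc.end:
                    gap = g.start - lnc.end - 1
                    right_of_lnc = True
                else:
                    gap = lnc.start - g.end - 1
                    right_of_lnc = False
                downstream = right_of_lnc if lnc.strand == "+" else not right_of_lnc
                relation = "downstream" if downstream else "upstream"
                signed = gap if downstream else -gap
            if gap < max_dist:
                rows.append(
                    {
                        "lncrna_id": lnc.transcript_id,
                        "gene_id": g.gene_id,
                        "distance": signed,
                        "relation": relation,
                    }
                )
    return pd.DataFrame(rows, columns=["lncrna_id", "gene_id", "distance", "relation"])


def call_bias(
    lnc_expr: ExpressionMatrix,
    sheet: SampleSheet,
    tissue: str,
) -> pd.DataFrame:
    """Per-lncRNA log2 M:F and the male-bias flag (log2 M:F > 0, both sexes
    expressed)."""
    gm = group_mean(lnc_expr, sheet, tissue)
    both = (gm["mean_M"] > 0) & (gm["mean_F"] > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_mf = np.log2(gm["mean_M"] / gm["mean_F"])
    log2_mf = log2_mf.where(both, np.nan)
    return pd.DataFrame(
        {
            "lncrna_id": gm.index,
            "tissue": tissue,
            "mean_M": gm["mean_M"].to_numpy(),
            "mean_F": gm["mean_F"].to_numpy(),
            "log2_mf": log2_mf.to_numpy(),
            "male_biased": (both & (log2_mf > 0)).to_numpy(),
        }
    ).reset_index(drop=True)


def correlate_targets(
    lnc_expr: ExpressionMatrix,
    target_expr: ExpressionMatrix,
    pairs: pd.DataFrame,
) -> pd.DataFrame:
    """Rank (Spearman) and linear (Pearson) correlation between each lncRNA
    and each assigned target across all shared samples.

    Zero-variance vectors yield NaN correlations flagged ``defined=False``.
    Requires at least three shared samples.
    """
    shared = [s for s in lnc_expr.sample_ids if s in set(target_expr.sample_ids)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples for correlation")
    rows = []
    for row in pairs.itertuples(index=False):
        lid, gid = row.lncrna_id, row.gene_id
        if lid not in lnc_expr.data.index or gid not in target_expr.data.index:
            raise ValueError(f"pair ({lid}, {gid}) absent from matrices")
        x = lnc_expr.data.loc[lid, shared].to_numpy(dtype=float)
        y = target_expr.data.loc[gid, shared].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rho = r = np.nan
            defined = False
        else:
            rho = float(stats.spearmanr(x, y).statistic)
            r = float(stats.pearsonr(x, y).statistic)
            defined = True
        rows.append(
            {
                "lncrna_id": lid,
                "gene_id": gid,
                "spearman_rho": rho,
                "pearson_r": r,
                "n_samples": len(shared),
                "defined": defined,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["lncrna_id", "gene_id", "spearman_rho", "pearson_r", "n_samples", "defined"],
    )
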