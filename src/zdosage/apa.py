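"""Poly(A) site clustering and between-sex comparison of site counts.

Read 3'-end positions are clustered per gene (and per sample group) by
single linkage: sorted positions no more than ``merge_dist`` apart join one
cluster, and clusters supported by fewer than ``min_support`` reads are
discarded.  The per-gene number of surviving sites is summarized into the
categories {1, 2, 3, 4, >=5} and compared between the sexes with a
chi-square test of independence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .annot_io import PolyAEnd, SampleSheet

CATEGORIES = ("1", "2", "3", "4", ">=5")


@dataclass
class PolyASite:
    gene_id: str
    chrom: str
    position: int  # representative: most frequent member position (ties -> smallest)
    strand: str
    support: dict  # sample_id -> read count
    total_support: int


def _cluster_positions(positions: np.ndarray, merge_dist: int) -> list[np.ndarray]:
    """Single-linkage clusters of sorted positions (gap <= merge_dist joins)."""
    if len(positions) == 0:
        return []
    order = np.sort(positions)
    breaks = np.where(np.diff(order) > merge_dist)[0] + 1
    return np.split(order, breaks)


def cluster_sites(
    ends: Iterable[PolyAEnd],
    merge_dist: int = 24,
    min_support: int = 2,
) -> list[PolyASite]:
    """Cluster the read 3' ends of one gene (within one sample group)."""
    ends = list(ends)
    if not ends:
        return []
    genes = {e.gene_id for e in ends}
    chroms = {e.chrom for e in ends}
    strands = {e.strand for e in ends}
    if len(genes) > 1 or len(chroms) > 1 or len(strands) > 1:
        raise ValueError("cluster_sites expects ends of a single gene/chrom/strand")
    positions = np.array([e.position for e in ends])
    sites = []
    for cluster in _cluster_positions(positions, merge_dist):
        if len(cluster) < min_support:
            continue
        vals, counts = np.unique(cluster, return_counts=True)
        rep = int(vals[np.argmax(counts)])  # argmax -> first (smallest) on ties
        members = set(cluster.tolist())
        support: dict[str, int] = {}
        for e in ends:
            if e.position in members:
                support[e.sample_id] = support.get(e.sample_id, 0) + 1
        # positions may repeat across clusters only if clusters share values,
        # which single linkage forbids, so the membership test is exact
        sites.append(
            PolyASite(
                gene_id=ends[0].gene_id,
                chrom=ends[0].chrom,
                position=rep,
                strand=ends[0].strand,
                support=support,
                total_support=int(len(cluster)),
            )
        )
    return sites


def call_sites(
    ends: Iterable[PolyAEnd],
    sheet: SampleSheet,
    merge_dist: int = 24,
    min_support: int = 2,
    group_by: str = "sex_tissue",
) -> pd.DataFrame:
    """Cluster ends per gene per sample group.

    ``group_by='sex_tissue'`` pools replicates within each (sex, tissue)
    group; ``'sample'`` keeps samples separate.
    """
    meta = sheet.table.set_index("sample_id")
    if group_by == "sex_tissue":
        group_of = {s: f"{meta.at[s, 'sex']}|{meta.at[s, 'tissue']}" for s in meta.index}
    elif group_by == "sample":
        group_of = {s: s for s in meta.index}
    else:
        raise ValueError(f"unknown group_by {group_by!r}")

    buckets: dict[tuple, list[PolyAEnd]] = {}
    for e in ends:
        buckets.setdefault((e.gene_id, group_of[e.sample_id]), []).append(e)
    rows = []
    for (gene_id, group), bucket in sorted(buckets.items()):
        for site in cluster_sites(bucket, merge_dist=merge_dist, min_support=min_support):
            rows.append(
                {
                    "gene_id": gene_id,
                    "group": group,
                    "chrom": site.chrom,
                    "position": site.position,
                    "strand": site.strand,
                    "support": site.total_support,
                }
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "group", "chrom", "position", "strand", "support"]
    )


def _category(n: int) -> str:
    return str(n) if n < 5 else ">=5"


def sites_per_gene(sites: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per gene/group site counts plus the category distribution.

    Returns (summary, distribution): summary has one row per (gene, group)
    with ``n_sites`` and its category; the distribution counts genes per
    category per group and reports the fraction of genes with >= 2 sites.
    """
    if sites.empty:
        return (
            pd.DataFrame(columns=["gene_id", "group", "n_sites", "category"]),
            pd.DataFrame(columns=["group", *CATEGORIES, "n_genes", "frac_multi"]),
        )
    summary = (
        sites.groupby(["gene_id", "group"], sort=True)
        .size()
        .rename("n_sites")
        .reset_index()
    )
    summary["category"] = summary["n_sites"].map(_category)
    dist_rows = []
    for group, sub in summary.groupby("group", sort=True):
        counts = sub["category"].value_counts()
        row = {"group": group}
        for c in CATEGORIES:
            row[c] = int(counts.get(c, 0))
        row["n_genes"] = int(len(sub))
        row["frac_multi"] = float((sub["n_sites"] >= 2).mean())
        dist_rows.append(row)
    return summary, pd.DataFrame(dist_rows)


@dataclass
class SexComparison:
    tissue: str
    statistic: float
    df: int
    p_value: float
    table: pd.DataFrame  # pooled sex x category counts actually tested


def compare_sex_distributions(
    summary: pd.DataFrame, sheet: SampleSheet, tissue: str
) -> SexComparison:
    """Chi-square test of independence on the sex x site-count-category table
    for one tissue; categories with expected count < 1 are pooled into their
    neighbours."""
    counts = {}
    for sex in ("M", "F"):
        sub = summary.loc[summary["group"] == f"{sex}|{tissue}"]
        if sub.empty:
            raise ValueError(f"no genes with poly(A) sites for sex {sex} in {tissue}")
        vc = sub["category"].value_counts()
        counts[sex] = [int(vc.get(c, 0)) for c in CATEGORIES]
    table = np.array([counts["M"], counts["F"]], dtype=float)
    cols = list(CATEGORIES)

    # drop all-zero categories, then pool low-expectation categories
    keep = table.sum(axis=0) > 0
    table, cols = table[:, keep], [c for c, k in zip(cols, keep) if k]
    while table.shape[1] > 1:
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        col_min = expected.min(axis=0)
        j = int(np.argmin(col_min))
        if col_min[j] >= 1.0:
            break
        nb = j - 1 if j > 0 else j + 1
        table[:, nb] += table[:, j]
        cols[nb] = f"{cols[nb]}+{cols[j]}"
        table = np.delete(table, j, axis=1)
        del cols[j]

    if table.shape[1] == 1:
        stat, p, dof = 0.0, 1.0, 0
    else:
        stat, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return SexComparison(
        tissue=tissue,
        statistic=float(stat),
        df=int(dof),
        p_value=float(p),
        table=pd.DataFrame(table, index=["M", "F"], columns=cols),
    )
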