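"""Sex-bias expression statistics and the regional sliding-window scan.

The central statistic is the per-feature log2 male:female expression ratio
(log2 M:F) and its absolute value (the amplitude).  Chromosome-level dosage
patterns are assessed by comparing Z-linked to autosomal expression within
one sex via a Wilcoxon rank-sum test, and regional structure on the Z is
scanned with overlapping windows (3 Mb window, 1 Mb shift by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annot_io import GenomeAnnotation, SampleSheet
from .quantify import ExpressionMatrix, expressed_mask, group_mean

DEFAULT_EXCLUDE = frozenset({"W", "31", "33"})
OUTLIER_LOG2 = 5.0


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum test
# ---------------------------------------------------------------------------


def _exact_ranksum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact rank-sum p by dynamic programming over the permutation
    distribution of the (tie-aware, midrank) rank sum of the smaller group.

    Handles ties exactly; complexity O(N * n_small * S) where S is the rank-sum
    range, so it stays affordable even for 1-vs-many comparisons.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_x = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)  # Mann-Whitney U of x

    # work with the smaller group; the two-sided p is symmetric
    if n2 < n1:
        small_ranks = ranks[n1:]
        k = n2
    else:
        small_ranks = ranks[:n1]
        k = n1
    r2 = np.rint(ranks * 2).astype(np.int64)  # midranks doubled -> integers
    obs = int(np.rint(small_ranks.sum() * 2))

    order = np.sort(r2)
    max_sum = int(order[-k:].sum())
    ways = np.zeros((k + 1, max_sum + 1))
    ways[0, 0] = 1.0
    for r in r2:
        r = int(r)
        hi = min(k, len(r2))
        for kk in range(hi, 0, -1):
            ways[kk, r:] += ways[kk - 1, : max_sum + 1 - r]
    dist = ways[k]
    total = dist.sum()
    p_le = dist[: obs + 1].sum() / total
    p_ge = dist[obs:].sum() / total
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return u_x, p


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    ``normal``: midrank/tie-corrected normal approximation with continuity
    correction.  ``exact``: full enumeration of the permutation distribution
    (tie-aware).  ``auto`` uses the exact test when min(n) <= 8.

    Returns (U statistic of x, p-value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical across both groups; p = 1", stacklevel=2)
        return len(x) * len(y) / 2.0, 1.0
    if mode == "auto":
        mode = "exact" if min(len(x), len(y)) <= 8 else "normal"
    if mode == "exact":
        return _exact_ranksum(x, y)
    if mode == "normal":
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Per-feature sex bias
# ---------------------------------------------------------------------------


def sex_bias_table(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    annotation: GenomeAnnotation,
    tissue: str,
    exclude_chroms: Iterable[str] = DEFAULT_EXCLUDE,
    level: str = "gene",
    outlier_threshold: float = OUTLIER_LOG2,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Per-feature sex-bias records for one tissue.

    Features must be expressed in both sexes (mean > 0) and lie on a
    non-excluded chromosome.  ``log2_mf`` is computed without pseudocount by
    default (zero-expression features are already excluded); outliers
    (|log2 M:F| > 5) are flagged but retained.

    Columns: feature_id, chrom, position, mean_M, mean_F, log2_mf, amplitude,
    outlier.
    """
    exclude = set(exclude_chroms)
    if level == "gene":
        pos_of = {g.gene_id: (g.chrom, g.midpoint) for g in annotation.genes}
    elif level == "transcript":
        pos_of = {
            t.transcript_id: (t.chrom, (t.start + t.end) / 2.0)
            for g in annotation.genes
            for t in g.transcripts
        }
    else:
        raise ValueError(f"unknown level {level!r}")

    missing = [f for f in expr.feature_ids if f not in pos_of]
    if missing:
        raise ValueError(
            f"{len(missing)} features absent from annotation, e.g. {missing[:5]}"
        )

    gm = group_mean(expr, sheet, tissue)
    keep = expressed_mask(expr, sheet, tissue, threshold=0.0, rule="both_sexes")
    rows = []
    for fid in expr.feature_ids:
        chrom, pos = pos_of[fid]
        if chrom in exclude or not keep[fid]:
            continue
        m, f = gm.at[fid, "mean_M"], gm.at[fid, "mean_F"]
        log2_mf = float(np.log2((m + pseudocount) / (f + pseudocount)))
        amp = abs(log2_mf)
        rows.append((fid, chrom, pos, m, f, log2_mf, amp, amp > outlier_threshold))
    return pd.DataFrame(
        rows,
        columns=[
            "feature_id",
            "chrom",
            "position",
            "mean_M",
            "mean_F",
            "log2_mf",
            "amplitude",
            "outlier",
        ],
    )


@dataclass
class ZAAComparison:
    """Z-linked vs autosomal expression within one sex (one tissue)."""

    tissue: str
    sex: str
    statistic: float
    p_value: float
    n_z: int
    n_aa: int
    median_z: float
    median_aa: float
    median_ratio: float
    offset: float


def z_aa_test(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    annotation: GenomeAnnotation,
    tissue: str,
    sex: str,
    z_chrom: str = "Z",
    exclude_chroms: Iterable[str] = DEFAULT_EXCLUDE,
    offset: float = 1.0,
    mode: str = "auto",
    level: str = "gene",
) -> ZAAComparison:
    """Compare per-feature log2(mean + offset) expression of Z-linked features
    against autosomal features within one sex, Wilcoxon rank-sum.

    Features with zero mean in the chosen sex are dropped (expressed-only
    comparison); the offset admits low values on the log scale.
    """
    exclude = set(exclude_chroms)
    if level == "gene":
        chrom_of = {g.gene_id: g.chrom for g in annotation.genes}
    else:
        chrom_of = {
            t.transcript_id: g.chrom
            for g in annotation.genes
            for t in g.transcripts
        }
    cols = sheet.samples_for(tissue, sex)
    if not cols:
        raise ValueError(f"no {sex} samples in tissue {tissue!r}")
    means = expr.data[cols].mean(axis=1)

    z_vals, aa_vals = [], []
    for fid, v in means.items():
        chrom = chrom_of.get(fid)
        if chrom is None:
            raise ValueError(f"feature {fid} absent from annotation")
        if chrom in exclude or v <= 0:
            continue
        (z_vals if chrom == z_chrom else aa_vals).append(np.log2(v + offset))
    if not z_vals:
        raise ValueError(f"no expressed features on {z_chrom}")
    if not aa_vals:
        raise ValueError("no expressed autosomal features")
    stat, p = wilcoxon_rank_sum(z_vals, aa_vals, mode=mode)
    med_z, med_aa = float(np.median(z_vals)), float(np.median(aa_vals))
    return ZAAComparison(
        tissue=tissue,
        sex=sex,
        statistic=stat,
        p_value=p,
        n_z=len(z_vals),
        n_aa=len(aa_vals),
        median_z=med_z,
        median_aa=med_aa,
        median_ratio=med_z / med_aa if med_aa != 0 else float("nan"),
        offset=offset,
    )


# ---------------------------------------------------------------------------
# Sliding-window scan
# ---------------------------------------------------------------------------


def window_scan(
    records: pd.DataFrame,
    chrom_length: int,
    window: int = 3_000_000,
    shift: int = 1_000_000,
) -> pd.DataFrame:
    """Moving averages of log2 M:F and amplitude in overlapping windows.

    Windows are half-open ``[w, w + window)`` on the 0-based axis, starting at
    0 and advancing by ``shift``; a feature belongs to every window containing
    its midpoint.  Outlier-flagged records are excluded from window means
    (``n_genes`` counts the records contributing to the means).
    """
    if window < shift:
        raise ValueError("window must be >= shift")
    if records.empty:
        return pd.DataFrame(
            columns=[
                "chrom",
                "window_start",
                "window_end",
                "n_genes",
                "mean_log2_mf",
                "mean_amplitude",
            ]
        )
    chroms = records["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("window_scan expects records from a single chromosome")
    chrom = chroms[0]
    used = records.loc[~records["outlier"]]
    mid0 = used["position"].to_numpy() - 1.0  # 0-based midpoint
    lfc = used["log2_mf"].to_numpy()
    amp = used["amplitude"].to_numpy()

    rows = []
    start = 0
    while start < chrom_length:
        end = min(start + window, chrom_length)
        in_w = (mid0 >= start) & (mid0 < end)
        n = int(in_w.sum())
        rows.append(
            (
                chrom,
                start,
                end,
                n,
                float(lfc[in_w].mean()) if n else np.nan,
                float(amp[in_w].mean()) if n else np.nan,
            )
        )
        start += shift
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "window_start",
            "window_end",
            "n_genes",
            "mean_log2_mf",
            "mean_amplitude",
        ],
    )


@dataclass
class TopRegion:
    chrom: str
    start: int  # 0-based half-open, like the windows
    end: int
    statistic: str
    value: float  # statistic of the single best window
    n_windows: int  # windows merged into the region


def top_region(
    scan: pd.DataFrame,
    stat: str = "mean_log2_mf",
    merge_frac: float = 0.10,
) -> TopRegion:
    """The maximal-statistic window, merged with overlapping neighbours whose
    statistic is within ``merge_frac`` of the maximum; ties break leftmost.
    """
    if stat not in ("mean_log2_mf", "mean_amplitude"):
        raise ValueError(f"unknown statistic {stat!r}")
    nonempty = scan.loc[scan["n_genes"] > 0].reset_index(drop=True)
    if nonempty.empty:
        raise ValueError("all windows are empty")
    vals = nonempty[stat].to_numpy()
    best_i = int(np.argmax(vals))  # argmax returns the leftmost maximum
    best = vals[best_i]
    thresh = best - merge_frac * abs(best)
    qualifies = vals >= thresh

    # grow the region over chains of overlapping qualifying windows
    lo, hi = best_i, best_i
    start = int(nonempty.at[best_i, "window_start"])
    end = int(nonempty.at[best_i, "window_end"])
    changed = True
    while changed:
        changed = False
        for j in range(len(nonempty)):
            if lo <= j <= hi or not qualifies[j]:
                continue
            ws, we = int(nonempty.at[j, "window_start"]), int(nonempty.at[j, "window_end"])
            if ws < end and we > start:  # overlaps the growing region
                start, end = min(start, ws), max(end, we)
                lo, hi = min(lo, j), max(hi, j)
                changed = True
    return TopRegion(
        chrom=str(nonempty.at[best_i, "chrom"]),
        start=start,
        end=end,
        statistic=stat,
        value=float(best),
        n_windows=hi - lo + 1,
    )
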