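"""Expression normalization and group summaries.

Counts are normalized per sample to a fixed scale (counts per million by
default; ``scale=1e4`` reproduces a per-10k-mapped-reads convention).  Ratios
between samples are invariant to the choice of scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .annot_io import GenomeAnnotation, SampleSheet

RAW = "raw_counts"
PER_SCALE = "per_scale"


@dataclass
class ExpressionMatrix:
    """Features x samples, either raw counts or per-scale normalized values."""

    data: pd.DataFrame
    unit: str = RAW
    scale: Optional[float] = None
    level: Optional[str] = None  # "gene" | "transcript" | None

    def __post_init__(self):
        if self.unit not in (RAW, PER_SCALE):
            raise ValueError(f"unknown unit {self.unit!r}")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate feature ids")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


def normalize(counts: ExpressionMatrix, scale: float = 1e6) -> ExpressionMatrix:
    """Per-sample library-size normalization: value = count / column_sum * scale.

    An all-zero column stays all-zero.
    """
    if counts.unit != RAW:
        raise ValueError("normalize expects raw counts")
    if scale <= 0:
        raise ValueError("scale must be positive")
    totals = counts.data.sum(axis=0)
    safe = totals.replace(0, np.nan)
    out = counts.data.div(safe, axis=1).mul(scale).fillna(0.0)
    return ExpressionMatrix(data=out, unit=PER_SCALE, scale=scale, level=counts.level)


def group_mean(
    expr: ExpressionMatrix, sheet: SampleSheet, tissue: str
) -> pd.DataFrame:
    """Per-feature arithmetic means over replicates of each sex within a tissue.

    Returns a DataFrame indexed by feature with columns ``mean_M``/``mean_F``.
    """
    if tissue not in sheet.tissues:
        raise ValueError(f"tissue {tissue!r} not in sample sheet")
    out = {}
    for sex in ("M", "F"):
        cols = sheet.samples_for(tissue, sex)
        if not cols:
            raise ValueError(f"no {sex} samples for tissue {tissue!r}")
        out[f"mean_{sex}"] = expr.data[cols].mean(axis=1)
    return pd.DataFrame(out, index=expr.data.index)


def expressed_mask(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    tissue: str,
    threshold: float = 0.0,
    rule: str = "both_sexes",
) -> pd.Series:
    """Boolean per-feature expression filter within one tissue.

    ``both_sexes`` (default): mean_M > threshold AND mean_F > threshold.
    ``any``/``all``: per-sample values within the tissue.
    """
    if expr.unit != PER_SCALE:
        raise ValueError("expressed_mask expects normalized expression")
    if rule == "both_sexes":
        gm = group_mean(expr, sheet, tissue)
        return (gm["mean_M"] > threshold) & (gm["mean_F"] > threshold)
    cols = sheet.samples_for(tissue)
    sub = expr.data[cols]
    if rule == "any":
        return (sub > threshold).any(axis=1)
    if rule == "all":
        return (sub > threshold).all(axis=1)
    raise ValueError(f"unknown rule {rule!r}")


def sum_by_gene(
    expr: ExpressionMatrix, annotation: GenomeAnnotation
) -> ExpressionMatrix:
    """Aggregate a transcript-level matrix to gene level by summation."""
    tx2gene = annotation.gene_of_transcript()
    missing = [f for f in expr.feature_ids if f not in tx2gene]
    if missing:
        raise ValueError(
            f"{len(missing)} transcripts absent from annotation, e.g. {missing[:5]}"
        )
    gene_ids = [tx2gene[f] for f in expr.feature_ids]
    out = expr.data.groupby(pd.Index(gene_ids, name="gene_id"), sort=True).sum()
    return ExpressionMatrix(data=out, unit=expr.unit, scale=expr.scale, level="gene")
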