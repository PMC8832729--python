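"""Alternative-splicing event classification, inclusion levels and
differential splicing.

Events are defined by pairwise comparison of intron chains (the interval
structure between exons) within the shared terminal boundaries of two
isoforms, then merged across pairs by (type, coordinates).  Five canonical
modes are recognised — exon skipping, intron retention, alternative 5'/3'
splice site and mutually exclusive exons — and any other local difference is
reported as ``complex``.  Inclusion levels (PSI) are isoform-abundance
ratios, the natural definition for full-length long-read quantification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .annot_io import GeneModel, SampleSheet, TranscriptModel
from .dosage import wilcoxon_rank_sum
from .quantify import ExpressionMatrix

log = logging.getLogger(__name__)

FIVE_MODES = (
    "exon_skipping",
    "intron_retention",
    "alt_5ss",
    "alt_3ss",
    "mutually_exclusive_exons",
)


@dataclass(frozen=True)
class ASEvent:
    gene_id: str
    event_type: str
    start: int  # variable region, 1-based inclusive
    end: int
    inclusion: frozenset  # transcript ids carrying the inclusion form
    exclusion: frozenset

    def __post_init__(self):
        if self.inclusion & self.exclusion:
            raise ValueError("inclusion and exclusion sets overlap")
        if not self.inclusion or not self.exclusion:
            raise ValueError("inclusion and exclusion sets must be non-empty")

    @property
    def event_id(self) -> str:
        return f"{self.gene_id}:{self.event_type}:{self.start}-{self.end}"


def _components(d1: list, d2: list) -> list[tuple[list, list]]:
    """Connected components (by interval overlap) of the differing introns."""
    items = [(iv, 0) for iv in d1] + [(iv, 1) for iv in d2]
    items.sort(key=lambda x: x[0])
    comps = []
    cur: list = []
    cur_max = -1
    for iv, side in items:
        if cur and iv[0] > cur_max:
            comps.append(cur)
            cur = []
            cur_max = -1
        cur.append((iv, side))
        cur_max = max(cur_max, iv[1])
    if cur:
        comps.append(cur)
    return [
        ([iv for iv, s in comp if s == 0], [iv for iv, s in comp if s == 1])
        for comp in comps
    ]


def _exon_set(t: TranscriptModel) -> set[tuple[int, int]]:
    return {(e.start, e.end) for e in t.exons}


def _covered_by_one_exon(t: TranscriptModel, start: int, end: int) -> bool:
    return any(e.start <= start and end <= e.end for e in t.exons)


def _consecutive(introns: list, a: tuple, b: tuple) -> bool:
    """True when introns a < b are adjacent in the chain (one exon between)."""
    idx = sorted(introns)
    ia, ib = idx.index(a), idx.index(b)
    return ib == ia + 1


def _classify_component(
    a: list,
    b: list,
    ta: TranscriptModel,
    tb: TranscriptModel,
    strand: str,
    gene: GeneModel,
):
    """Map one differing-intron component onto a canonical mode.

    Returns (event_type, start, end, inclusion_tx, exclusion_tx) where the
    transcripts are those of this pair; returns a ``complex`` record when no
    mode matches.
    """
    ia, ib = sorted(a), sorted(b)

    def _complex():
        ivs = ia + ib
        return ("complex", min(s for s, _ in ivs), max(e for _, e in ivs), None, None)

    # exon skipping: one intron on one side, two on the other sharing its ends
    for one, two, t_one, t_two in ((ia, ib, ta, tb), (ib, ia, tb, ta)):
        if len(one) == 1 and len(two) == 2:
            (s, e), ((s1, e1), (s2, e2)) = one[0], sorted(two)
            if (
                s1 == s
                and e2 == e
                and e1 < s2
                and _consecutive(t_two.introns(), (s1, e1), (s2, e2))
            ):
                return ("exon_skipping", e1 + 1, s2 - 1, t_two, t_one)
            return _complex()

    # intron retention: intron on one side, nothing differing on the other,
    # and the other covers the intron (plus flanks) within one exon
    for one, other, t_one, t_other in ((ia, ib, ta, tb), (ib, ia, tb, ta)):
        if len(one) == 1 and len(other) == 0:
            s, e = one[0]
            if _covered_by_one_exon(t_other, s - 1, e + 1):
                return ("intron_retention", s, e, t_other, t_one)
            return _complex()

    # alternative 5'/3' splice sites: one intron each, one shared boundary
    if len(ia) == 1 and len(ib) == 1:
        (s1, e1), (s2, e2) = ia[0], ib[0]
        if not (s1 <= e2 and s2 <= e1):  # must overlap
            return _complex()
        if e1 == e2 and s1 != s2:
            region = (min(s1, s2), max(s1, s2) - 1)
            short_t = ta if s1 > s2 else tb  # shorter intron = more exon
            long_t = tb if short_t is ta else ta
            if not _covered_by_one_exon(short_t, region[0], region[1]):
                return _complex()
            etype = "alt_5ss" if strand == "+" else "alt_3ss"
            return (etype, region[0], region[1], short_t, long_t)
        if s1 == s2 and e1 != e2:
            region = (min(e1, e2) + 1, max(e1, e2))
            short_t = ta if e1 < e2 else tb
            long_t = tb if short_t is ta else ta
            if not _covered_by_one_exon(short_t, region[0], region[1]):
                return _complex()
            etype = "alt_3ss" if strand == "+" else "alt_5ss"
            return (etype, region[0], region[1], short_t, long_t)
        return _complex()

    # mutually exclusive exons: two introns each, shared outer boundaries,
    # one internal exon per side, non-overlapping, never co-occurring
    if len(ia) == 2 and len(ib) == 2:
        (a1, a2), (b1, b2) = ia, ib
        ok = (
            a1[0] == b1[0]
            and a2[1] == b2[1]
            and _consecutive(ta.introns(), a1, a2)
            and _consecutive(tb.introns(), b1, b2)
        )
        if ok:
            ex_a = (a1[1] + 1, a2[0] - 1)
            ex_b = (b1[1] + 1, b2[0] - 1)
            if ex_a[1] < ex_b[0] or ex_b[1] < ex_a[0]:  # non-overlapping
                cooccur = any(
                    ex_a in _exon_set(t) and ex_b in _exon_set(t)
                    for t in gene.transcripts
                )
                if not cooccur:
                    left_t, right_t = (ta, tb) if ex_a < ex_b else (tb, ta)
                    return (
                        "mutually_exclusive_exons",
                        min(ex_a[0], ex_b[0]),
                        max(ex_a[1], ex_b[1]),
                        left_t,
                        right_t,
                    )
        return _complex()

    return _complex()


def classify_events(gene: GeneModel, include_complex: bool = True) -> list[ASEvent]:
    """All AS events among a gene's isoforms, merged across transcript pairs.

    Single-transcript genes yield an empty list.  Unstranded input is
    rejected upstream by the annotation model.
    """
    if len(gene.transcripts) < 2:
        return []
    txs = sorted(gene.transcripts, key=lambda t: t.transcript_id)
    merged: dict[tuple, dict] = {}
    for ta, tb in combinations(txs, 2):
        lo = max(ta.start, tb.start)
        hi = min(ta.end, tb.end)
        i1 = [iv for iv in ta.introns() if iv[0] > lo and iv[1] < hi]
        i2 = [iv for iv in tb.introns() if iv[0] > lo and iv[1] < hi]
        shared = set(i1) & set(i2)
        d1 = [iv for iv in i1 if iv not in shared]
        d2 = [iv for iv in i2 if iv not in shared]
        if not d1 and not d2:
            continue
        for comp_a, comp_b in _components(d1, d2):
            etype, s, e, t_inc, t_exc = _classify_component(
                comp_a, comp_b, ta, tb, gene.strand, gene
            )
            key = (etype, s, e)
            rec = merged.setdefault(key, {"inc": set(), "exc": set()})
            if t_inc is not None:
                rec["inc"].add(t_inc.transcript_id)
                rec["exc"].add(t_exc.transcript_id)
            else:  # complex: keep the pair on both sides symmetrically
                rec["inc"].add(ta.transcript_id)
                rec["exc"].add(tb.transcript_id)

    events = []
    for (etype, s, e), rec in sorted(merged.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        if etype == "complex" and not include_complex:
            continue
        inc, exc = rec["inc"] - rec["exc"], rec["exc"] - rec["inc"]
        if not inc or not exc:
            # degenerate membership (only possible for complex regions where
            # sides are not geometrically determined): keep the record only
            # if a disjoint split exists
            continue
        events.append(
            ASEvent(
                gene_id=gene.gene_id,
                event_type=etype,
                start=s,
                end=e,
                inclusion=frozenset(inc),
                exclusion=frozenset(exc),
            )
        )
    return events


def classify_all(genes: Iterable[GeneModel], include_complex: bool = True) -> list[ASEvent]:
    out: list[ASEvent] = []
    for g in genes:
        out.extend(classify_events(g, include_complex=include_complex))
    return out


def event_table(events: Iterable[ASEvent]) -> pd.DataFrame:
    rows = [
        {
            "event_id": ev.event_id,
            "gene_id": ev.gene_id,
            "event_type": ev.event_type,
            "start": ev.start,
            "end": ev.end,
            "inclusion": ",".join(sorted(ev.inclusion)),
            "exclusion": ",".join(sorted(ev.exclusion)),
        }
        for ev in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "gene_id",
            "event_type",
            "start",
            "end",
            "inclusion",
            "exclusion",
        ],
    )


# ---------------------------------------------------------------------------
# PSI and differential splicing
# ---------------------------------------------------------------------------


def psi(event: ASEvent, expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-sample inclusion level of one event from transcript expression.

    psi = sum(inclusion isoforms) / sum(inclusion + exclusion isoforms);
    undefined (``defined=False``) where the denominator is zero.
    """
    if expr.level not in (None, "transcript"):
        raise ValueError("psi expects a transcript-level matrix")
    members = sorted(event.inclusion | event.exclusion)
    missing = [t for t in members if t not in expr.data.index]
    if missing:
        raise ValueError(f"transcripts absent from matrix: {missing}")
    inc = expr.data.loc[sorted(event.inclusion)].sum(axis=0)
    tot = expr.data.loc[members].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = inc / tot
    return pd.DataFrame(
        {
            "event_id": event.event_id,
            "sample_id": expr.sample_ids,
            "psi": vals.to_numpy(),
            "defined": (tot > 0).to_numpy(),
        }
    )


def psi_table(events: Iterable[ASEvent], expr: ExpressionMatrix) -> pd.DataFrame:
    frames = [psi(ev, expr) for ev in events]
    if not frames:
        return pd.DataFrame(columns=["event_id", "sample_id", "psi", "defined"])
    return pd.concat(frames, ignore_index=True)


def differential_splicing(
    psis: pd.DataFrame,
    sheet: SampleSheet,
    tissue: str,
    min_delta: float = 0.10,
    alpha: float = 0.05,
    mode: str = "auto",
) -> pd.DataFrame:
    """Male-vs-female test of inclusion levels per event, BH-corrected.

    An event is significant when |mean PSI(M) − mean PSI(F)| >= min_delta and
    its FDR is below alpha.  Events with fewer than two defined replicate
    PSIs in either sex are skipped (logged).
    """
    m_samples = set(sheet.samples_for(tissue, "M"))
    f_samples = set(sheet.samples_for(tissue, "F"))
    rows = []
    for event_id, sub in psis.groupby("event_id", sort=True):
        ok = sub.loc[sub["defined"]]
        mv = ok.loc[ok["sample_id"].isin(m_samples), "psi"].to_numpy()
        fv = ok.loc[ok["sample_id"].isin(f_samples), "psi"].to_numpy()
        if len(mv) < 2 or len(fv) < 2:
            log.info(
                "skipping event %s: <2 defined PSI replicates in a sex "
                "(M=%d, F=%d)", event_id, len(mv), len(fv)
            )
            continue
        _, p = wilcoxon_rank_sum(mv, fv, mode=mode)
        rows.append(
            {
                "event_id": event_id,
                "tissue": tissue,
                "delta_psi": float(mv.mean() - fv.mean()),
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows, columns=["event_id", "tissue", "delta_psi", "p_value"])
    if out.empty:
        out["fdr"] = []
        out["significant"] = []
        return out
    out["fdr"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = (out["delta_psi"].abs() >= min_delta) & (out["fdr"] < alpha)
    return out


# ---------------------------------------------------------------------------
# Group-unique transcripts
# ---------------------------------------------------------------------------


def unique_transcripts(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    groups: Optional[list[tuple[str, str]]] = None,
    threshold: float = 0.0,
) -> tuple[dict, pd.DataFrame]:
    """Transcripts expressed in exactly one (sex, tissue) group.

    A transcript is expressed in a group when its mean expression there
    exceeds ``threshold``.  Returns ({group: set of unique transcripts},
    membership table with per-group expression flags and the number of
    groups each transcript is expressed in).
    """
    if groups is None:
        groups = sorted(
            {(r.sex, r.tissue) for r in sheet.table.itertuples(index=False)}
        )
    flags = {}
    for sex, tissue in groups:
        cols = sheet.samples_for(tissue, sex)
        if not cols:
            raise ValueError(f"no samples for group ({sex}, {tissue})")
        flags[f"{sex}|{tissue}"] = expr.data[cols].mean(axis=1) > threshold
    member = pd.DataFrame(flags, index=expr.data.index)
    member["n_groups"] = member.sum(axis=1).astype(int)
    uniques = {}
    for sex, tissue in groups:
        key = f"{sex}|{tissue}"
        only = member.index[(member[key]) & (member["n_groups"] == 1)]
        uniques[(sex, tissue)] = set(only)
    return uniques, member
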