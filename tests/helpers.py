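"""Independent brute-force oracles used to validate the library.

Everything here is written as directly and naively as possible (transitive
closures by repeated passes, full enumerations, per-element loops) so that
agreement with the library is meaningful.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import rankdata

from zdosage.annot_io import Exon, GeneModel, TranscriptModel


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum: exact two-sided p by full enumeration of subsets
# ---------------------------------------------------------------------------


def exact_ranksum_enumeration(x, y) -> float:
    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    ranks = rankdata(pooled)
    nx = len(x)
    obs = ranks[:nx].sum()
    sums = np.array(
        [ranks[list(c)].sum() for c in itertools.combinations(range(len(pooled)), nx)]
    )
    le = np.mean(sums <= obs + 1e-9)
    ge = np.mean(sums >= obs - 1e-9)
    return float(min(1.0, 2.0 * min(le, ge)))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg step-up, written as the textbook procedure
# ---------------------------------------------------------------------------


def bh_stepup(pvals) -> np.ndarray:
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = p[i] * m / rank_from_top
        running_min = min(running_min, val)
        adj[i] = running_min
    return adj


# ---------------------------------------------------------------------------
# Single-linkage clustering by explicit transitive closure
# ---------------------------------------------------------------------------


def transitive_closure_clusters(positions, merge_dist) -> list[list[int]]:
    pts = sorted(positions)
    if not pts:
        return []
    # start with singletons, repeatedly merge any two clusters containing
    # points within merge_dist until no merge applies
    clusters = [[p] for p in pts]
    changed = True
    while changed:
        changed = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if any(
                    abs(a - b) <= merge_dist
                    for a in clusters[i]
                    for b in clusters[j]
                ):
                    clusters[i] = sorted(clusters[i] + clusters[j])
                    del clusters[j]
                    changed = True
                    break
            if changed:
                break
    return sorted(clusters)


# ---------------------------------------------------------------------------
# Sliding-window scan, brute-force double loop
# ---------------------------------------------------------------------------


def brute_window_scan(records, chrom_length, window, shift):
    """records: list of (position 1-based, log2_mf, amplitude, outlier)."""
    rows = []
    start = 0
    while start < chrom_length:
        end = min(start + window, chrom_length)
        vals = [
            (l, a)
            for pos, l, a, out in records
            if not out and start <= (pos - 1) < end
        ]
        n = len(vals)
        rows.append(
            (
                start,
                end,
                n,
                sum(v[0] for v in vals) / n if n else None,
                sum(v[1] for v in vals) / n if n else None,
            )
        )
        start += shift
    return rows


# ---------------------------------------------------------------------------
# Random gene builder for splicing fuzz tests
# ---------------------------------------------------------------------------


def random_gene(rng: np.random.Generator, gene_id="GX", max_exons=5) -> GeneModel:
    """A random multi-isoform gene whose isoforms are random exon subsets /
    boundary variants over a shared scaffold of at most ``max_exons`` exons."""
    n_exons = int(rng.integers(2, max_exons + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    # scaffold exon/intron layout
    bounds = []
    pos = int(rng.integers(1, 50))
    for _ in range(n_exons):
        length = int(rng.integers(20, 120))
        bounds.append((pos, pos + length - 1))
        pos += length + int(rng.integers(50, 200))
    n_tx = int(rng.integers(2, 4))
    transcripts = []
    for k in range(n_tx):
        exons = list(bounds)
        # random internal-exon dropout
        if len(exons) > 2 and rng.random() < 0.6:
            drop = int(rng.integers(1, len(exons) - 1))
            exons = exons[:drop] + exons[drop + 1 :]
        # random boundary shift of one internal splice site
        if rng.random() < 0.5 and len(exons) >= 2:
            i = int(rng.integers(0, len(exons) - 1))
            s, e = exons[i]
            delta = int(rng.integers(1, 15))
            if e - s - 1 > delta:
                exons[i] = (s, e - delta) if rng.random() < 0.5 else (s, e)
        transcripts.append(
            TranscriptModel(
                f"{gene_id}.{k + 1}",
                gene_id,
                [Exon("1", s, e, strand) for s, e in exons],
            )
        )
    return GeneModel.from_transcripts(gene_id, transcripts)


# ---------------------------------------------------------------------------
# Brute-force AS-event enumerator (independent re-derivation of the rules)
# ---------------------------------------------------------------------------


def _introns_of(t: TranscriptModel) -> list[tuple[int, int]]:
    exons = sorted((e.start, e.end) for e in t.exons)
    return [(exons[i][1] + 1, exons[i + 1][0] - 1) for i in range(len(exons) - 1)]


def _overlap(a, b) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _closure_components(intervals_with_side):
    comps = []
    pool = list(intervals_with_side)
    while pool:
        comp = [pool.pop()]
        changed = True
        while changed:
            changed = False
            for item in list(pool):
                if any(_overlap(item[0], c[0]) for c in comp):
                    comp.append(item)
                    pool.remove(item)
                    changed = True
        comps.append(comp)
    return comps


def _exon_covering(t, s, e) -> bool:
    return any(ex.start <= s and e <= ex.end for ex in t.exons)


def _adjacent_in_chain(t, i1, i2) -> bool:
    chain = sorted(_introns_of(t))
    return i2 in chain and i1 in chain and chain.index(i2) == chain.index(i1) + 1


def brute_force_events(gene: GeneModel):
    """Set of (event_type, start, end, inclusion frozenset, exclusion frozenset)
    for the five canonical modes plus 'complex' regions, enumerated naively."""
    merged = {}
    for ta, tb in itertools.combinations(
        sorted(gene.transcripts, key=lambda t: t.transcript_id), 2
    ):
        lo, hi = max(ta.start, tb.start), min(ta.end, tb.end)
        ca = [iv for iv in _introns_of(ta) if iv[0] > lo and iv[1] < hi]
        cb = [iv for iv in _introns_of(tb) if iv[0] > lo and iv[1] < hi]
        da = [iv for iv in ca if iv not in cb]
        db = [iv for iv in cb if iv not in ca]
        if not da and not db:
            continue
        items = [(iv, "a") for iv in da] + [(iv, "b") for iv in db]
        for comp in _closure_components(items):
            one = sorted(iv for iv, side in comp if side == "a")
            two = sorted(iv for iv, side in comp if side == "b")
            rec = _brute_classify(one, two, ta, tb, gene)
            key = rec[:3]
            slot = merged.setdefault(key, {"inc": set(), "exc": set()})
            if rec[3] is None:
                slot["inc"].add(ta.transcript_id)
                slot["exc"].add(tb.transcript_id)
            else:
                slot["inc"].add(rec[3])
                slot["exc"].add(rec[4])
    out = set()
    for (etype, s, e), slot in merged.items():
        inc = slot["inc"] - slot["exc"]
        exc = slot["exc"] - slot["inc"]
        if inc and exc:
            out.add((etype, s, e, frozenset(inc), frozenset(exc)))
    return out


def _brute_classify(one, two, ta, tb, gene):
    strand = gene.strand

    def cx():
        ivs = one + two
        return ("complex", min(s for s, _ in ivs), max(e for _, e in ivs), None, None)

    for xs, ys, tx, ty in ((one, two, ta, tb), (two, one, tb, ta)):
        # intron retention: ty keeps the intron, tx spans it with one exon
        if len(ys) == 1 and len(xs) == 0:
            s, e = ys[0]
            if _exon_covering(tx, s - 1, e + 1):
                return ("intron_retention", s, e, tx.transcript_id, ty.transcript_id)
            return cx()
        # exon skipping: tx has two adjacent introns around an exon, ty one
        if len(xs) == 2 and len(ys) == 1:
            (s1, e1), (s2, e2) = xs
            (s, e) = ys[0]
            if (
                s1 == s
                and e2 == e
                and e1 + 1 <= s2 - 1
                and _adjacent_in_chain(tx, (s1, e1), (s2, e2))
            ):
                return (
                    "exon_skipping",
                    e1 + 1,
                    s2 - 1,
                    tx.transcript_id,
                    ty.transcript_id,
                )
            return cx()
    if len(one) == 1 and len(two) == 1:
        (s1, e1), (s2, e2) = one[0], two[0]
        if not _overlap(one[0], two[0]):
            return cx()
        if e1 == e2 and s1 != s2:
            lo, hi = min(s1, s2), max(s1, s2) - 1
            short, lng = (ta, tb) if s1 > s2 else (tb, ta)
            if _exon_covering(short, lo, hi):
                etype = "alt_5ss" if strand == "+" else "alt_3ss"
                return (etype, lo, hi, short.transcript_id, lng.transcript_id)
            return cx()
        if s1 == s2 and e1 != e2:
            lo, hi = min(e1, e2) + 1, max(e1, e2)
            short, lng = (ta, tb) if e1 < e2 else (tb, ta)
            if _exon_covering(short, lo, hi):
                etype = "alt_3ss" if strand == "+" else "alt_5ss"
                return (etype, lo, hi, short.transcript_id, lng.transcript_id)
            return cx()
        return cx()
    if len(one) == 2 and len(two) == 2:
        (a1, a2), (b1, b2) = one, two
        if (
            a1[0] == b1[0]
            and a2[1] == b2[1]
            and _adjacent_in_chain(ta, a1, a2)
            and _adjacent_in_chain(tb, b1, b2)
        ):
            ex_a = (a1[1] + 1, a2[0] - 1)
            ex_b = (b1[1] + 1, b2[0] - 1)
            if not _overlap(ex_a, ex_b):
                def has_both(t):
                    es = {(e.start, e.end) for e in t.exons}
                    return ex_a in es and ex_b in es

                if not any(has_both(t) for t in gene.transcripts):
                    left, right = (ta, tb) if ex_a < ex_b else (tb, ta)
                    return (
                        "mutually_exclusive_exons",
                        min(ex_a[0], ex_b[0]),
                        max(ex_a[1], ex_b[1]),
                        left.transcript_id,
                        right.transcript_id,
                    )
        return cx()
    return cx()


# ---------------------------------------------------------------------------
# Small annotation builders
# ---------------------------------------------------------------------------


def make_transcript(tid, gid, chrom, strand, exon_pairs):
    return TranscriptModel(
        tid, gid, [Exon(chrom, s, e, strand) for s, e in exon_pairs]
    )


def make_gene(gid, chrom, strand, isoform_exons, biotype="coding"):
    txs = [
        make_transcript(f"{gid}.{i + 1}", gid, chrom, strand, pairs)
        for i, pairs in enumerate(isoform_exons)
    ]
    return GeneModel.from_transcripts(gid, txs, biotype=biotype)
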