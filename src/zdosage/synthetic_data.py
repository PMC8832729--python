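"""Ground-truth simulator for a toy diploid genome with a Z chromosome.

The generator emulates the statistical structure a Z-dosage analysis assumes:

* autosomes plus one Z chromosome, non-overlapping coding gene loci;
* incomplete dosage compensation — on the Z, females express at
  ``1/z_male_fold`` of the autosomal baseline while males stay at baseline,
  so the expected male:female ratio is ``z_male_fold`` and male Z:AA is ~1
  while female Z:AA is depressed;
* an optional regional hotspot multiplying the male:female fold further;
* multi-isoform genes whose isoforms differ by exactly one alternative
  splicing event of a known mode, recorded as ground truth;
* positionally constructed lncRNAs realizing a requested class
  (lincRNA / antisense / sense / intronic) exactly;
* per-gene poly(A) cleavage sites with jittered read 3' ends.

Counts are negative-binomial; all output is a pure function of the
configuration (including its seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .annot_io import (
    CODING,
    NONCODING,
    Exon,
    GeneModel,
    GenomeAnnotation,
    PolyAEnd,
    SampleSheet,
    TranscriptModel,
    write_chrom_sizes,
    write_counts,
    write_gtf,
    write_polya_ends,
    write_sample_sheet,
)
from .quantify import ExpressionMatrix

AS_MODES = (
    "exon_skipping",
    "intron_retention",
    "alt_5ss",
    "alt_3ss",
    "mutually_exclusive_exons",
)

# Mode mix of injected events; exon skipping dominates as in long-read surveys
# of vertebrate transcriptomes (~55% of alternative transcripts).
DEFAULT_AS_MODE_PROBS = {
    "exon_skipping": 0.5538,
    "intron_retention": 0.17,
    "alt_3ss": 0.12,
    "alt_5ss": 0.10,
    "mutually_exclusive_exons": 0.0562,
}

DEFAULT_LNC_PROPORTIONS = {
    "lincRNA": 0.7616,
    "antisense": 0.1192,
    "sense": 0.0066,
    "intronic": 0.1126,
}


class SimulationError(ValueError):
    pass


@dataclass
class ChromSpec:
    name: str
    length: int
    is_z: bool = False
    n_genes: int = 0


@dataclass
class Hotspot:
    chrom: str
    start: int  # 1-based inclusive interval on the chromosome
    end: int
    extra_fold: float = 1.5


@dataclass
class LncRNASpec:
    count: int = 40
    proportions: dict = field(default_factory=lambda: dict(DEFAULT_LNC_PROPORTIONS))


@dataclass
class SimulationConfig:
    seed: int = 0
    chromosomes: list = field(
        default_factory=lambda: [
            ChromSpec("1", 40_000_000, False, 120),
            ChromSpec("2", 30_000_000, False, 90),
            ChromSpec("Z", 80_000_000, True, 160),
        ]
    )
    isoform_count_distribution: dict = field(
        default_factory=lambda: {1: 0.51, 2: 0.22, 3: 0.14, 4: 0.08, 5: 0.05}
    )
    as_mode_probs: dict = field(default_factory=lambda: dict(DEFAULT_AS_MODE_PROBS))
    baseline_log_mean: float = float(np.log(100.0))  # log-normal mu of per-gene mean count
    baseline_log_sd: float = 1.0
    nb_dispersion: float = 0.1
    z_male_fold: float = 1.75
    per_gene_fold_sd: float = 0.0  # optional log-normal jitter of the Z fold
    hotspot: Optional[Hotspot] = field(
        default_factory=lambda: Hotspot("Z", 31_000_000, 36_000_000, 1.5)
    )
    lncrna_spec: LncRNASpec = field(default_factory=LncRNASpec)
    polya_sites_per_gene_distribution: dict = field(
        default_factory=lambda: {1: 0.30, 2: 0.30, 3: 0.20, 4: 0.12, 5: 0.08}
    )
    polya_reads_per_site: float = 8.0
    library_size_sd: float = 0.1  # log-normal sigma of per-sample depth factor
    tissues: list = field(default_factory=lambda: ["gonad", "head_skin"])
    n_replicates: int = 4

    def __post_init__(self):
        for dist, name in (
            (self.isoform_count_distribution, "isoform_count_distribution"),
            (self.as_mode_probs, "as_mode_probs"),
            (self.polya_sites_per_gene_distribution, "polya_sites_per_gene_distribution"),
            (self.lncrna_spec.proportions, "lncrna_spec.proportions"),
        ):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise SimulationError(f"{name} probabilities sum to {total}, not 1")
            if any(p < 0 for p in dist.values()):
                raise SimulationError(f"{name} has negative probabilities")
        if self.z_male_fold <= 0:
            raise SimulationError("z_male_fold must be positive")
        if self.hotspot is not None and self.hotspot.extra_fold <= 0:
            raise SimulationError("hotspot extra_fold must be positive")
        if self.nb_dispersion < 0:
            raise SimulationError("nb_dispersion must be >= 0")

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["chromosomes"] = [ChromSpec(**c) for c in d.get("chromosomes", [])]
        if d.get("hotspot") is not None:
            d["hotspot"] = Hotspot(**d["hotspot"])
        if "lncrna_spec" in d and d["lncrna_spec"] is not None:
            d["lncrna_spec"] = LncRNASpec(**d["lncrna_spec"])
        for key in ("isoform_count_distribution", "polya_sites_per_gene_distribution"):
            if key in d:
                d[key] = {int(k): float(v) for k, v in d[key].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class TruthEvent:
    gene_id: str
    event_type: str
    start: int
    end: int
    inclusion: list
    exclusion: list


@dataclass
class GroundTruth:
    gene_fold: dict = field(default_factory=dict)  # gene_id -> expected M:F fold
    noncoding: list = field(default_factory=list)  # lncRNA transcript ids
    lncrna_class: dict = field(default_factory=dict)  # transcript_id -> class
    lncrna_gene: dict = field(default_factory=dict)  # transcript_id -> gene_id
    lncrna_targets: dict = field(default_factory=dict)  # transcript_id -> [gene ids]
    polya_sites: dict = field(default_factory=dict)  # gene_id -> [positions]
    as_events: list = field(default_factory=list)  # list[TruthEvent]
    hotspot: Optional[list] = None  # [chrom, start, end]
    isoform_weights: dict = field(default_factory=dict)  # transcript_id -> weight

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["as_events"] = [TruthEvent(**e) for e in d.get("as_events", [])]
        return cls(**d)


# ---------------------------------------------------------------------------
# Gene/isoform construction
# ---------------------------------------------------------------------------


def _draw_from_dist(rng: np.random.Generator, dist: dict):
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[rng.choice(len(keys), p=probs)]


def _build_gene_structure(rng: np.random.Generator, n_isoforms: int, mode_probs: dict):
    """Relative (0-offset) exon layout for one gene plus its injected events.

    Each extra isoform differs from the primary isoform by exactly one AS
    event; event loci are spaced three exon slots apart so that pairwise
    comparisons between any two isoforms reproduce exactly the injected
    events and nothing else.
    """
    n_events = n_isoforms - 1
    n_exons = int(rng.integers(3, 7)) if n_events == 0 else 4 + 3 * n_events

    modes = [
        _draw_from_dist(rng, mode_probs) for _ in range(n_events)
    ]
    slots = [2 + 3 * e for e in range(n_events)]  # internal exon indices

    exon_len = rng.integers(120, 400, size=n_exons)
    intron_len = rng.integers(300, 1500, size=max(n_exons - 1, 0))
    # MXE needs room for the alternative exon inside the slot intron
    mxe_alt_len: dict[int, int] = {}
    for mode, s in zip(modes, slots):
        if mode == "mutually_exclusive_exons":
            alt = int(rng.integers(120, 300))
            mxe_alt_len[s] = alt
            intron_len[s] = alt + 2 * int(rng.integers(250, 500))

    starts = np.zeros(n_exons, dtype=int)
    pos = 0
    base_exons = []
    for i in range(n_exons):
        starts[i] = pos
        base_exons.append((pos, pos + int(exon_len[i]) - 1))
        pos += int(exon_len[i])
        if i < n_exons - 1:
            pos += int(intron_len[i])
    span = pos  # total genomic footprint of the base isoform

    isoforms = [list(base_exons)]  # isoform 0 = primary
    events = []
    for e, (mode, s) in enumerate(zip(modes, slots)):
        exons = list(base_exons)
        es, ee = exons[s]
        next_s, next_e = exons[s + 1]
        # every isoform except the alternative one carries the base form at
        # this slot, so the base side of the event is all other isoforms
        alt = e + 1
        base_side = [i for i in range(n_isoforms) if i != alt]
        if mode == "exon_skipping":
            del exons[s]
            coords = (es, ee)
            inclusion, exclusion = base_side, [alt]
        elif mode == "intron_retention":
            exons[s] = (es, next_e)
            del exons[s + 1]
            coords = (ee + 1, next_s - 1)
            inclusion, exclusion = [alt], base_side  # retainer = inclusion
        elif mode in ("alt_5ss", "alt_3ss"):
            gap = next_s - ee - 1
            delta = int(rng.integers(25, min(90, gap - 50)))
            # choose the genomic boundary so that the detected, strand-aware
            # label matches the requested mode; the caller fixes the strand
            # afterwards by relabeling (see _strand_adjust_events)
            if mode == "alt_5ss":
                exons[s] = (es, ee + delta)  # donor shift on '+'
                coords = (ee + 1, ee + delta)
            else:
                exons[s + 1] = (next_s - delta, next_e)  # acceptor shift on '+'
                coords = (next_s - delta, next_s - 1)
            inclusion, exclusion = [alt], base_side
        else:  # mutually exclusive exons
            alt_len = mxe_alt_len[s]
            gap_start = ee + 1
            gap_end = next_s - 1
            alt_start = gap_start + (gap_end - gap_start + 1 - alt_len) // 2
            exons[s] = (alt_start, alt_start + alt_len - 1)
            coords = (es, alt_start + alt_len - 1)
            inclusion, exclusion = base_side, [alt]  # leftmost exon = inclusion side
        exons.sort()
        isoforms.append(exons)
        events.append({"mode": mode, "coords": coords,
                       "inclusion": inclusion, "exclusion": exclusion})
    return isoforms, events, span


def _strand_adjust_events(events, strand: str):
    """On the minus strand the genomic left boundary is the acceptor, so the
    alt-5'/alt-3' labels swap relative to the plus-strand construction."""
    if strand == "+":
        return events
    swapped = []
    for ev in events:
        ev = dict(ev)
        if ev["mode"] == "alt_5ss":
            ev["mode"] = "alt_3ss"
        elif ev["mode"] == "alt_3ss":
            ev["mode"] = "alt_5ss"
        swapped.append(ev)
    return swapped


def generate_annotation(
    config: SimulationConfig,
) -> tuple[GenomeAnnotation, GroundTruth]:
    """Build the annotated toy genome and its ground truth."""
    rng = np.random.default_rng([config.seed, 11])
    truth = GroundTruth()
    if config.hotspot is not None:
        truth.hotspot = [config.hotspot.chrom, config.hotspot.start, config.hotspot.end]

    genes: list[GeneModel] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    gene_counter = 0
    min_gap = 2000

    for chrom in config.chromosomes:
        structures = []
        for _ in range(chrom.n_genes):
            k = _draw_from_dist(rng, config.isoform_count_distribution)
            structures.append(_build_gene_structure(rng, k, config.as_mode_probs))
        # near-uniform placement: one gene per equal-width slot, jittered
        # within the slot, so every genomic window carries comparable gene
        # density (a regional fold signal is then visible wherever injected)
        slot = chrom.length // chrom.n_genes
        max_span = max(s[2] for s in structures)
        if slot < max_span + 2 * min_gap:
            raise SimulationError(
                f"chromosome {chrom.name} too short for {chrom.n_genes} genes; "
                f"needs at least {(max_span + 2 * min_gap) * chrom.n_genes}"
            )
        occupied[chrom.name] = []
        for i, (isoforms, events, span) in enumerate(structures):
            slack = slot - span - 2 * min_gap
            pos = i * slot + min_gap + int(rng.integers(0, slack + 1))
            offset = pos + 1  # 1-based start
            strand = "+" if rng.random() < 0.5 else "-"
            gene_counter += 1
            gid = f"G{gene_counter:05d}"
            events = _strand_adjust_events(events, strand)
            transcripts = []
            for i, exon_list in enumerate(isoforms):
                tid = f"{gid}.{i + 1}"
                exons = [
                    Exon(chrom.name, offset + s, offset + e, strand)
                    for s, e in exon_list
                ]
                transcripts.append(TranscriptModel(tid, gid, exons))
            gene = GeneModel.from_transcripts(gid, transcripts, biotype=CODING)
            genes.append(gene)
            occupied[chrom.name].append((gene.start, gene.end))
            for ev in events:
                truth.as_events.append(
                    TruthEvent(
                        gene_id=gid,
                        event_type=ev["mode"],
                        start=offset + ev["coords"][0],
                        end=offset + ev["coords"][1],
                        inclusion=[f"{gid}.{i + 1}" for i in ev["inclusion"]],
                        exclusion=[f"{gid}.{i + 1}" for i in ev["exclusion"]],
                    )
                )

    sizes = {c.name: c.length for c in config.chromosomes}
    ann = GenomeAnnotation(chromosomes=sizes, genes=genes)

    _place_lncrnas(rng, config, ann, truth, occupied)
    _assign_folds(rng, config, ann, truth)
    _assign_polya_truth(rng, config, ann, truth)
    # refresh annotation: lncRNA genes were appended in _place_lncrnas
    ann = GenomeAnnotation(chromosomes=sizes, genes=ann.genes)
    return ann, truth


def _place_lncrnas(rng, config, ann, truth, occupied):
    """Place lncRNA loci so each realizes its assigned positional class exactly.

    Every lncRNA is >200 nt spliced and has >= 2 exons.  Placements avoid
    exons of other isoforms (intronic class) and other lncRNAs.
    """
    spec = config.lncrna_spec
    if spec.count == 0:
        return
    classes = [_draw_from_dist(rng, spec.proportions) for _ in range(spec.count)]
    coding = [g for g in ann.genes if g.biotype == CODING]
    if not coding and spec.count > 0:
        raise SimulationError("cannot place lncRNAs without coding genes")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in coding:
        by_chrom.setdefault(g.chrom, []).append(g)
    for gs in by_chrom.values():
        gs.sort(key=lambda g: g.start)

    lnc_n = 0
    new_genes = []
    for cls in classes:
        placed = None
        for _attempt in range(200):
            chrom = rng.choice(sorted(by_chrom))
            genes_c = by_chrom[chrom]
            gi = int(rng.integers(0, len(genes_c)))
            host = genes_c[gi]
            if cls == "lincRNA":
                # between host and the next gene, >= 300 bp clearance each side
                nxt = genes_c[gi + 1].start if gi + 1 < len(genes_c) else (
                    ann.chromosomes[chrom] + 1
                )
                lo, hi = host.end + 300, nxt - 300
                need = 600  # two exons + internal gap
                if hi - lo + 1 < need:
                    continue
                s = int(rng.integers(lo, hi - need + 1))
                exon_ivs = [(s, s + 180), (s + 300, s + 480)]
                strand = "+" if rng.random() < 0.5 else "-"
            elif cls in ("antisense", "sense"):
                anchor = host.transcripts[0].exons[0]
                # first lnc exon straddles the anchor exon start
                s = anchor.start - 150
                if s < 1:
                    continue
                exon_ivs = [(s, anchor.start + 60), (anchor.start + 160, anchor.start + 320)]
                if exon_ivs[1][1] > ann.chromosomes[chrom]:
                    continue
                # must not reach the previous gene
                prev_end = genes_c[gi - 1].end if gi > 0 else 0
                if s <= prev_end:
                    continue
                strand = (
                    ("-" if host.strand == "+" else "+")
                    if cls == "antisense"
                    else host.strand
                )
            else:  # intronic: fully inside one exon-free gap of the host gene
                gaps = [
                    iv for iv in host.intron_union() if iv[1] - iv[0] + 1 >= 700
                ]
                if not gaps:
                    continue
                gs, ge = gaps[int(rng.integers(0, len(gaps)))]
                s = gs + 80
                exon_ivs = [(s, s + 140), (s + 260, s + 420)]
                if exon_ivs[1][1] > ge - 80:
                    continue
                strand = host.strand
            span = (exon_ivs[0][0], exon_ivs[-1][1])
            # avoid collision with previously placed lncRNAs
            prior = [(g.start, g.end) for g in new_genes if g.chrom == chrom]
            clash = any(not (span[1] < a or span[0] > b) for a, b in prior)
            if clash:
                continue
            placed = (chrom, strand, exon_ivs, host)
            break
        if placed is None:
            raise SimulationError(
                f"could not place a {cls} lncRNA; increase chromosome lengths "
                "or reduce lncRNA count"
            )
        chrom, strand, exon_ivs, host = placed
        lnc_n += 1
        gid = f"LNC{lnc_n:04d}"
        tid = f"{gid}.1"
        exons = [Exon(chrom, s, e, strand) for s, e in exon_ivs]
        t = TranscriptModel(tid, gid, exons)
        g = GeneModel.from_transcripts(gid, [t], biotype=NONCODING)
        new_genes.append(g)
        truth.noncoding.append(tid)
        truth.lncrna_class[tid] = cls
        truth.lncrna_gene[tid] = gid
        # positional targets: every coding gene within 100 kb (gap distance)
        targets = [
            cg.gene_id
            for cg in by_chrom.get(chrom, [])
            if _gap(g.start, g.end, cg.start, cg.end) < 100_000
        ]
        truth.lncrna_targets[tid] = targets
    ann.genes.extend(new_genes)


def _gap(a_start, a_end, b_start, b_end) -> int:
    if a_start <= b_end and b_start <= a_end:
        return 0
    return b_start - a_end - 1 if b_start > a_end else a_start - b_end - 1


def _assign_folds(rng, config, ann, truth):
    hs = config.hotspot
    for g in ann.genes:
        chrom_spec = next(c for c in config.chromosomes if c.name == g.chrom)
        fold = 1.0
        if chrom_spec.is_z:
            fold = config.z_male_fold
            if config.per_gene_fold_sd > 0:
                fold *= float(
                    np.exp(rng.normal(0.0, config.per_gene_fold_sd))
                )
            if (
                hs is not None
                and g.chrom == hs.chrom
                and hs.start <= g.midpoint <= hs.end
            ):
                fold *= hs.extra_fold
        truth.gene_fold[g.gene_id] = fold


def _assign_polya_truth(rng, config, ann, truth):
    for g in ann.genes:
        if g.biotype != CODING:
            continue
        k = _draw_from_dist(rng, config.polya_sites_per_gene_distribution)
        # sites near the 3' end, 400 bp apart, walking into the gene body
        if g.strand == "+":
            sites = [g.end - 400 * j for j in range(k)]
        else:
            sites = [g.start + 400 * j for j in range(k)]
        sites = [int(s) for s in sites if 1 <= s <= ann.chromosomes[g.chrom]]
        truth.polya_sites[g.gene_id] = sorted(sites)


# ---------------------------------------------------------------------------
# Expression and poly(A) simulation
# ---------------------------------------------------------------------------


def make_sample_sheet(config: SimulationConfig) -> SampleSheet:
    rows = [
        {
            "sample_id": f"{tissue}_{sex}{rep}",
            "sex": sex,
            "tissue": tissue,
            "replicate": rep,
        }
        for tissue in config.tissues
        for sex in ("M", "F")
        for rep in range(1, config.n_replicates + 1)
    ]
    return SampleSheet(pd.DataFrame(rows))


def _nb_draw(rng, mean, dispersion):
    """Negative-binomial with Var = mu + dispersion * mu^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_expression(
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleSheet]:
    """Transcript-level negative-binomial counts for every sample.

    mean = per-gene baseline x isoform weight x sex factor x library factor.
    On the Z the male factor is 1 and the female factor 1/fold (females below
    the autosomal baseline, males at it — incomplete dosage compensation).
    """
    rng = np.random.default_rng([config.seed, 23])
    sheet = make_sample_sheet(config)
    samples = sheet.table

    tx_ids, gene_of, weights = [], [], []
    for g in annotation.genes:
        b = float(np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd)))
        w = rng.dirichlet(np.full(len(g.transcripts), 5.0)) if len(g.transcripts) > 1 else np.array([1.0])
        for t, wi in zip(g.transcripts, w):
            tx_ids.append(t.transcript_id)
            gene_of.append(g.gene_id)
            weights.append(b * float(wi))
            truth.isoform_weights[t.transcript_id] = float(wi)
    base = np.array(weights)

    fold = np.array([truth.gene_fold[gid] for gid in gene_of])
    lib = np.exp(rng.normal(0.0, config.library_size_sd, size=len(samples)))

    data = {}
    for j, row in enumerate(samples.itertuples(index=False)):
        sex_factor = 1.0 if row.sex == "M" else 1.0 / fold
        mu = base * sex_factor * lib[j]
        data[row.sample_id] = _nb_draw(rng, mu, config.nb_dispersion)
    df = pd.DataFrame(data, index=pd.Index(tx_ids, name="feature_id"))
    return ExpressionMatrix(data=df, unit="raw_counts", level="transcript"), sheet


def simulate_polya_ends(
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    config: SimulationConfig,
    jitter: int = 5,
) -> list[PolyAEnd]:
    """Poisson read 3' ends per true site per sample, jittered within ±jitter bp."""
    rng = np.random.default_rng([config.seed, 37])
    sheet = make_sample_sheet(config)
    genes = {g.gene_id: g for g in annotation.genes}
    records: list[PolyAEnd] = []
    read_n = 0
    if config.polya_reads_per_site <= 0:
        return records
    for gid in sorted(truth.polya_sites):
        g = genes[gid]
        length = annotation.chromosomes[g.chrom]
        for sid in sheet.sample_ids:
            for site in truth.polya_sites[gid]:
                n = int(rng.poisson(config.polya_reads_per_site))
                if n == 0:
                    continue
                offs = rng.integers(-jitter, jitter + 1, size=n)
                for o in offs:
                    pos = int(np.clip(site + o, 1, length))
                    read_n += 1
                    records.append(
                        PolyAEnd(gid, sid, g.chrom, pos, g.strand, f"read{read_n:07d}")
                    )
    return records


def simulate_splicing_counts(
    n_events: int,
    delta_psi: float,
    n_replicates: int = 4,
    base_psi: float = 0.5,
    depth: float = 500.0,
    dispersion: float = 0.01,
    seed: int = 0,
    tissue: str = "gonad",
) -> tuple[ExpressionMatrix, SampleSheet, list]:
    """Two-isoform genes with a sex-dependent inclusion level, for splicing
    power/calibration studies.

    Males use PSI = base + delta/2, females base - delta/2; counts for the
    inclusion/exclusion isoforms are negative-binomial around depth * psi and
    depth * (1 - psi).  Returns (counts, sheet, events) where events pair the
    isoforms per gene.
    """
    from .splicing import ASEvent  # deferred: splicing imports nothing from here

    rng = np.random.default_rng([seed, 41])
    rows = [
        {"sample_id": f"{tissue}_{sex}{r}", "sex": sex, "tissue": tissue, "replicate": r}
        for sex in ("M", "F")
        for r in range(1, n_replicates + 1)
    ]
    sheet = SampleSheet(pd.DataFrame(rows))
    psi_by_sex = {
        "M": np.clip(base_psi + delta_psi / 2.0, 0.0, 1.0),
        "F": np.clip(base_psi - delta_psi / 2.0, 0.0, 1.0),
    }
    ids, data = [], {s["sample_id"]: [] for s in rows}
    events = []
    for i in range(n_events):
        gid = f"EV{i:04d}"
        inc, exc = f"{gid}.inc", f"{gid}.exc"
        ids.extend([inc, exc])
        for s in rows:
            psi = psi_by_sex[s["sex"]]
            vals = _nb_draw(
                rng, np.array([depth * psi, depth * (1.0 - psi)]), dispersion
            )
            data[s["sample_id"]].extend(vals.tolist())
        events.append(
            ASEvent(
                gene_id=gid,
                event_type="exon_skipping",
                start=1,
                end=2,
                inclusion=frozenset({inc}),
                exclusion=frozenset({exc}),
            )
        )
    df = pd.DataFrame(data, index=pd.Index(ids, name="feature_id"))
    expr = ExpressionMatrix(data=df, unit="raw_counts", level="transcript")
    return expr, sheet, events


# ---------------------------------------------------------------------------
# One-call dataset writer
# ---------------------------------------------------------------------------


def simulate_dataset(config: SimulationConfig, outdir: str | Path) -> dict:
    """Generate annotation, counts, sample sheet, poly(A) ends and truth, and
    write them as plain-text files under *outdir*.  Returns the file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann, truth = generate_annotation(config)
    counts, sheet = simulate_expression(ann, truth, config)
    ends = simulate_polya_ends(ann, truth, config)

    paths = {
        "gtf": outdir / "genome.gtf",
        "chrom_sizes": outdir / "chrom.sizes",
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "polya_ends": outdir / "polya_ends.tsv",
        "truth": outdir / "truth.json",
        "config": outdir / "sim_config.yaml",
    }
    write_gtf(ann, paths["gtf"])
    write_chrom_sizes(ann.chromosomes, paths["chrom_sizes"])
    write_counts(counts, paths["counts"])
    write_sample_sheet(sheet, paths["samples"])
    write_polya_ends(ends, paths["polya_ends"])
    truth.to_json(paths["truth"])
    config.to_yaml(paths["config"])
    return {k: str(v) for k, v in paths.items()}
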