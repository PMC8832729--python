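"""Readers and writers for the formats the pipeline touches.

Coordinate conventions follow the source formats: GTF is 1-based inclusive,
BED-like files are 0-based half-open and are converted to 1-based positions
on load.  All annotation objects are validated on construction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional

import pandas as pd

VALID_STRANDS = ("+", "-")
CODING = "coding"
NONCODING = "noncoding_candidate"


class GtfParseError(ValueError):
    """Raised for malformed GTF input; carries the offending line number."""


class AnnotationError(ValueError):
    """Raised when annotation objects violate their structural invariants."""


@dataclass(frozen=True)
class Exon:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str

    def __post_init__(self):
        if self.strand not in VALID_STRANDS:
            raise AnnotationError(f"invalid strand {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise AnnotationError(
                f"invalid exon coordinates {self.start}-{self.end} (1-based inclusive)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    exons: list[Exon]

    def __post_init__(self):
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise AnnotationError(
                f"transcript {self.transcript_id} mixes chromosomes or strands"
            )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise AnnotationError(
                    f"transcript {self.transcript_id} has overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def length(self) -> int:
        """Spliced (mature) length in nt."""
        return sum(e.length for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def introns(self) -> list[tuple[int, int]]:
        """1-based inclusive intron intervals between consecutive exons."""
        return [
            (a.end + 1, b.start - 1) for a, b in zip(self.exons, self.exons[1:])
        ]


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str
    transcripts: list[TranscriptModel]

    def __post_init__(self):
        if not self.transcripts:
            raise AnnotationError(f"gene {self.gene_id} has no transcripts")
        if self.biotype not in (CODING, NONCODING):
            raise AnnotationError(f"gene {self.gene_id}: unknown biotype {self.biotype!r}")
        for t in self.transcripts:
            if t.chrom != self.chrom or t.strand != self.strand:
                raise AnnotationError(
                    f"gene {self.gene_id}: transcript {t.transcript_id} disagrees "
                    "on chrom/strand"
                )
            if not (self.start <= t.start and t.end <= self.end):
                raise AnnotationError(
                    f"gene {self.gene_id} span does not cover transcript "
                    f"{t.transcript_id}"
                )

    @classmethod
    def from_transcripts(
        cls, gene_id: str, transcripts: list[TranscriptModel], biotype: str = CODING
    ) -> "GeneModel":
        ts = sorted(transcripts, key=lambda t: (t.start, t.transcript_id))
        return cls(
            gene_id=gene_id,
            chrom=ts[0].chrom,
            strand=ts[0].strand,
            start=min(t.start for t in ts),
            end=max(t.end for t in ts),
            biotype=biotype,
            transcripts=ts,
        )

    @property
    def midpoint(self) -> float:
        """Representative position: midpoint of the gene span (1-based)."""
        return (self.start + self.end) / 2.0

    def exon_union(self) -> list[tuple[int, int]]:
        """Merged exonic intervals over all transcripts (1-based inclusive)."""
        ivs = sorted((e.start, e.end) for t in self.transcripts for e in t.exons)
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [(s, e) for s, e in merged]

    def intron_union(self) -> list[tuple[int, int]]:
        """Gaps between merged exon intervals, within the gene span."""
        ex = self.exon_union()
        return [(a[1] + 1, b[0] - 1) for a, b in zip(ex, ex[1:])]


@dataclass
class GenomeAnnotation:
    chromosomes: dict[str, int]
    genes: list[GeneModel]

    def __post_init__(self):
        gene_ids: set[str] = set()
        tx_ids: set[str] = set()
        for g in self.genes:
            if g.gene_id in gene_ids:
                raise AnnotationError(f"duplicate gene_id {g.gene_id}")
            gene_ids.add(g.gene_id)
            for t in g.transcripts:
                if t.transcript_id in tx_ids:
                    raise AnnotationError(f"duplicate transcript_id {t.transcript_id}")
                tx_ids.add(t.transcript_id)
            if g.chrom not in self.chromosomes:
                raise AnnotationError(
                    f"gene {g.gene_id} on unknown chromosome {g.chrom}"
                )
            if g.end > self.chromosomes[g.chrom]:
                raise AnnotationError(
                    f"gene {g.gene_id} extends past the end of {g.chrom} "
                    f"({g.end} > {self.chromosomes[g.chrom]})"
                )

    def genes_by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    def transcripts_by_id(self) -> dict[str, TranscriptModel]:
        return {t.transcript_id: t for g in self.genes for t in g.transcripts}

    def gene_of_transcript(self) -> dict[str, str]:
        return {t.transcript_id: g.gene_id for g in self.genes for t in g.transcripts}

    def coding_genes(self) -> list[GeneModel]:
        return [g for g in self.genes if g.biotype == CODING]

    def noncoding_genes(self) -> list[GeneModel]:
        return [g for g in self.genes if g.biotype == NONCODING]

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return [g for g in self.genes if g.chrom == chrom]


@dataclass
class SampleSheet:
    """Sample metadata: sample_id, sex in {M, F}, tissue label, replicate >= 1."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "sex", "tissue", "replicate")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise AnnotationError(f"sample sheet missing columns: {missing}")
        t = self.table.reset_index(drop=True).copy()
        t["replicate"] = t["replicate"].astype(int)
        if t["sample_id"].duplicated().any():
            dups = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise AnnotationError(f"duplicate sample_ids: {dups}")
        bad_sex = set(t["sex"]) - {"M", "F"}
        if bad_sex:
            raise AnnotationError(f"sex must be M or F, got {sorted(bad_sex)}")
        if (t["replicate"] < 1).any():
            raise AnnotationError("replicate numbers must be >= 1")
        self.table = t

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def tissues(self) -> list[str]:
        return sorted(self.table["tissue"].unique())

    def samples_for(self, tissue: str, sex: Optional[str] = None) -> list[str]:
        m = self.table["tissue"] == tissue
        if sex is not None:
            m &= self.table["sex"] == sex
        return self.table.loc[m, "sample_id"].tolist()


class PolyAEnd(NamedTuple):
    """A single read 3'-end observation (position is 1-based)."""

    gene_id: str
    sample_id: str
    chrom: str
    position: int
    strand: str
    read_id: str


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(
    path: str | Path,
    chrom_sizes: Optional[dict[str, int] | str | Path] = None,
) -> GenomeAnnotation:
    """Parse a GTF file into a validated :class:`GenomeAnnotation`.

    Only ``gene_id``/``transcript_id`` (and optionally ``gene_biotype``)
    attributes are interpreted.  Chromosome lengths come from *chrom_sizes*
    (a mapping or a two-column sizes file); when absent they are inferred as
    the maximum annotated end per chromosome.
    """
    path = Path(path)
    exons: dict[str, list[Exon]] = {}
    tx_gene: dict[str, str] = {}
    gene_biotype: dict[str, str] = {}
    seen_exon_lines: set[tuple] = set()

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path.name}:{lineno}: expected 9 tab-delimited fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(
                    f"{path.name}:{lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from None
            if strand not in VALID_STRANDS:
                raise GtfParseError(f"{path.name}:{lineno}: invalid strand {strand!r}")
            a = _parse_attributes(attrs)
            if feature == "gene":
                if "gene_id" not in a:
                    raise GtfParseError(f"{path.name}:{lineno}: gene without gene_id")
                bt = a.get("gene_biotype", CODING)
                gene_biotype[a["gene_id"]] = bt if bt == NONCODING else CODING
            elif feature == "exon":
                if "transcript_id" not in a:
                    raise GtfParseError(
                        f"{path.name}:{lineno}: exon without transcript_id"
                    )
                if "gene_id" not in a:
                    raise GtfParseError(f"{path.name}:{lineno}: exon without gene_id")
                key = (chrom, start, end, strand, a["transcript_id"], a["gene_id"])
                if key in seen_exon_lines:  # benign identical duplicate
                    continue
                seen_exon_lines.add(key)
                tid = a["transcript_id"]
                prior_gene = tx_gene.setdefault(tid, a["gene_id"])
                if prior_gene != a["gene_id"]:
                    raise GtfParseError(
                        f"{path.name}:{lineno}: transcript {tid} assigned to "
                        f"conflicting genes {prior_gene!r} and {a['gene_id']!r}"
                    )
                exons.setdefault(tid, []).append(Exon(chrom, start, end, strand))
            elif feature == "transcript":
                if "transcript_id" not in a or "gene_id" not in a:
                    raise GtfParseError(
                        f"{path.name}:{lineno}: transcript without "
                        "transcript_id/gene_id"
                    )
                prior_gene = tx_gene.setdefault(a["transcript_id"], a["gene_id"])
                if prior_gene != a["gene_id"]:
                    raise GtfParseError(
                        f"{path.name}:{lineno}: transcript {a['transcript_id']} "
                        f"assigned to conflicting genes"
                    )
            # other feature types (CDS, UTR, ...) are ignored

    transcripts = [
        TranscriptModel(tid, tx_gene[tid], exs) for tid, exs in exons.items()
    ]
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    genes = [
        GeneModel.from_transcripts(gid, ts, biotype=gene_biotype.get(gid, CODING))
        for gid, ts in by_gene.items()
    ]
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))

    if chrom_sizes is None:
        sizes: dict[str, int] = {}
        for g in genes:
            sizes[g.chrom] = max(sizes.get(g.chrom, 0), g.end)
    elif isinstance(chrom_sizes, (str, Path)):
        sizes = read_chrom_sizes(chrom_sizes)
    else:
        sizes = dict(chrom_sizes)
    return GenomeAnnotation(chromosomes=sizes, genes=genes)


def write_gtf(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write gene/transcript/exon records, 1-based inclusive, deterministic order."""
    with open(path, "w") as fh:
        for g in sorted(annotation.genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            gattr = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(
                f"{g.chrom}\tzdosage\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{gattr}\n"
            )
            for t in g.transcripts:
                tattr = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{g.chrom}\tzdosage\ttranscript\t{t.start}\t{t.end}\t.\t"
                    f"{g.strand}\t.\t{tattr}\n"
                )
                for e in t.exons:
                    fh.write(
                        f"{g.chrom}\tzdosage\texon\t{e.start}\t{e.end}\t.\t"
                        f"{g.strand}\t.\t{tattr}\n"
                    )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 2:
                raise GtfParseError(
                    f"{Path(path).name}:{lineno}: expected 'name<TAB>length'"
                )
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# Count matrix / sample sheet
# ---------------------------------------------------------------------------


def read_counts(path: str | Path, samples: SampleSheet):
    """Read a feature x sample TSV into an ExpressionMatrix of raw counts.

    The header must match the sample sheet exactly (no missing, no unknown
    columns); values must be non-negative.
    """
    from .quantify import ExpressionMatrix  # local import avoids a module cycle

    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    want = set(samples.sample_ids)
    have = set(df.columns)
    missing = sorted(want - have)
    if missing:
        raise ValueError(f"count matrix missing sample columns: {missing}")
    extra = sorted(have - want)
    if extra:
        raise ValueError(f"count matrix has unknown columns: {extra}")
    df = df[samples.sample_ids]
    if (df.to_numpy() < 0).any():
        raise ValueError("count matrix contains negative values")
    return ExpressionMatrix(data=df, unit="raw_counts")


def write_counts(expr, path: str | Path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="feature_id")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, sep="\t", comment="#"))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Poly(A) read ends (BED6-like + gene_id, sample_id)
# ---------------------------------------------------------------------------

_POLYA_COLS = ["chrom", "start", "end", "read_id", "score", "strand", "gene_id", "sample_id"]


def read_polya_ends(
    path: str | Path, annotation: Optional[GenomeAnnotation] = None
) -> list[PolyAEnd]:
    """Load read 3'-end records; BED starts (0-based) become 1-based positions."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=_POLYA_COLS,
            comment="#",
            dtype={"chrom": str, "read_id": str, "gene_id": str, "sample_id": str},
        )
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    records = []
    for row in df.itertuples(index=False):
        pos = int(row.start) + 1  # 0-based half-open -> 1-based
        if annotation is not None:
            length = annotation.chromosomes.get(str(row.chrom))
            if length is not None and not (1 <= pos <= length):
                raise ValueError(
                    f"poly(A) end at {row.chrom}:{pos} outside chromosome "
                    f"length {length}"
                )
        records.append(
            PolyAEnd(
                gene_id=str(row.gene_id),
                sample_id=str(row.sample_id),
                chrom=str(row.chrom),
                position=pos,
                strand=str(row.strand),
                read_id=str(row.read_id),
            )
        )
    return records


def write_polya_ends(records: Iterable[PolyAEnd], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            start0 = r.position - 1
            fh.write(
                f"{r.chrom}\t{start0}\t{start0 + 1}\t{r.read_id}\t0\t{r.strand}\t"
                f"{r.gene_id}\t{r.sample_id}\n"
            )
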