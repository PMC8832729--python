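"""End-to-end orchestration: simulate → quantify → dosage → splicing →
lncRNA → APA, with deterministic on-disk artifacts and a machine-readable
run summary recomputed purely from the written tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import annot_io, apa, dosage, lncrna, quantify, splicing
from .annot_io import GenomeAnnotation, SampleSheet
from .synthetic_data import GroundTruth, SimulationConfig, simulate_dataset

log = logging.getLogger(__name__)

TABLES = [
    "cpm_gene.tsv",
    "cpm_transcript.tsv",
    "sex_bias.tsv",
    "zaa_tests.tsv",
    "window_scan.tsv",
    "top_region.bed",
    "as_events.tsv",
    "psi.tsv",
    "diff_splice.tsv",
    "unique_transcripts.tsv",
    "lnc_classes.tsv",
    "lnc_targets.tsv",
    "lnc_bias.tsv",
    "lnc_target_corr.tsv",
    "apa_sites.tsv",
    "apa_per_gene.tsv",
    "apa_sex_test.tsv",
]

STAGE_TABLES = {
    "quantify": ["cpm_gene.tsv", "cpm_transcript.tsv"],
    "dosage": ["sex_bias.tsv", "zaa_tests.tsv", "window_scan.tsv", "top_region.bed"],
    "splicing": ["as_events.tsv", "psi.tsv", "diff_splice.tsv", "unique_transcripts.tsv"],
    "lncrna": ["lnc_classes.tsv", "lnc_targets.tsv", "lnc_bias.tsv", "lnc_target_corr.tsv"],
    "apa": ["apa_sites.tsv", "apa_per_gene.tsv", "apa_sex_test.tsv"],
}


@dataclass
class RunConfig:
    """One structured configuration for a full pipeline run.

    Exactly one of ``simulation`` or the explicit input paths
    (gtf/chrom_sizes/counts/samples) must be provided.
    """

    outdir: str = "zdosage_run"
    simulation: Optional[SimulationConfig] = None
    gtf: Optional[str] = None
    chrom_sizes: Optional[str] = None
    counts: Optional[str] = None
    samples: Optional[str] = None
    polya_ends: Optional[str] = None
    noncoding_labels: Optional[str] = None  # TSV transcript_id<TAB>noncoding
    stages: dict = field(
        default_factory=lambda: {
            "dosage": True,
            "splicing": True,
            "lncrna": True,
            "apa": True,
        }
    )
    scale: float = 1e6
    z_chrom: str = "Z"
    exclude_chroms: list = field(default_factory=lambda: ["W", "31", "33"])
    window: int = 3_000_000
    shift: int = 1_000_000
    merge_frac: float = 0.10
    min_delta_psi: float = 0.10
    fdr_alpha: float = 0.05
    min_lnc_len: int = 200
    min_lnc_exons: int = 2
    max_target_dist: int = 100_000
    merge_dist: int = 24
    min_support: int = 2
    seed: Optional[int] = None

    def __post_init__(self):
        has_paths = self.gtf is not None and self.counts is not None and self.samples is not None
        if (self.simulation is None) == (not has_paths):
            raise ValueError(
                "provide exactly one of a simulation config or input paths "
                "(gtf + counts + samples)"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        # outdir is where results land, not what was computed; exclude it
        d = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def _write_table(df: pd.DataFrame, path: Path, params: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# zdosage {__version__} {params}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def run_pipeline(config: RunConfig) -> "RunSummary":
    """Execute all enabled stages and return the summary recomputed from disk."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # ---------------- inputs -------------------------------------------
        truth: Optional[GroundTruth] = None
        if config.simulation is not None:
            stage = "simulate"
            sim = config.simulation
            if config.seed is not None:
                sim = SimulationConfig.from_dict({**sim.to_dict(), "seed": config.seed})
                config.simulation = sim
            paths = simulate_dataset(sim, outdir / "inputs")
            truth = GroundTruth.from_json(paths["truth"])
            gtf, sizes = paths["gtf"], paths["chrom_sizes"]
            counts_path, samples_path = paths["counts"], paths["samples"]
            polya_path = paths["polya_ends"]
        else:
            gtf, sizes = config.gtf, config.chrom_sizes
            counts_path, samples_path = config.counts, config.samples
            polya_path = config.polya_ends

        stage = "load"
        ann = annot_io.read_gtf(gtf, chrom_sizes=sizes)
        sheet = annot_io.read_sample_sheet(samples_path)
        counts = annot_io.read_counts(counts_path, sheet)
        counts.level = "transcript"
        log.info("loaded %d genes, %d transcripts, %d samples",
                 len(ann.genes), len(ann.transcripts_by_id()), len(sheet.sample_ids))

        # ---------------- quantify -----------------------------------------
        stage = "quantify"
        cpm_tx = quantify.normalize(counts, scale=config.scale)
        counts_gene = quantify.sum_by_gene(counts, ann)
        cpm_gene = quantify.normalize(counts_gene, scale=config.scale)
        _write_table(
            cpm_gene.data.rename_axis("feature_id").reset_index(),
            outdir / "cpm_gene.tsv",
            f"quantify scale={config.scale:g} level=gene",
        )
        _write_table(
            cpm_tx.data.rename_axis("feature_id").reset_index(),
            outdir / "cpm_transcript.tsv",
            f"quantify scale={config.scale:g} level=transcript",
        )

        # ---------------- dosage -------------------------------------------
        if config.stages.get("dosage", True):
            stage = "dosage"
            bias_frames, zaa_rows, scan_frames, region_rows = [], [], [], []
            for tissue in sheet.tissues:
                tab = dosage.sex_bias_table(
                    cpm_gene, sheet, ann, tissue,
                    exclude_chroms=config.exclude_chroms,
                )
                tab.insert(0, "tissue", tissue)
                bias_frames.append(tab)
                log.info("sex_bias %s: %d/%d features retained",
                         tissue, len(tab), len(cpm_gene.feature_ids))
                for sex in ("M", "F"):
                    z = dosage.z_aa_test(
                        cpm_gene, sheet, ann, tissue, sex,
                        z_chrom=config.z_chrom, exclude_chroms=config.exclude_chroms,
                    )
                    zaa_rows.append(
                        {
                            "tissue": tissue,
                            "sex": sex,
                            "statistic": z.statistic,
                            "p_value": z.p_value,
                            "n_z": z.n_z,
                            "n_aa": z.n_aa,
                            "median_z": z.median_z,
                            "median_aa": z.median_aa,
                            "median_ratio": z.median_ratio,
                        }
                    )
                zrec = tab.loc[tab["chrom"] == config.z_chrom]
                scan = dosage.window_scan(
                    zrec, ann.chromosomes[config.z_chrom],
                    window=config.window, shift=config.shift,
                )
                scan.insert(0, "tissue", tissue)
                scan_frames.append(scan)
                region = dosage.top_region(scan, merge_frac=config.merge_frac)
                region_rows.append(
                    f"{region.chrom}\t{region.start}\t{region.end}\t"
                    f"{tissue}:{region.statistic}={region.value:.4f}"
                )
            _write_table(
                pd.concat(bias_frames, ignore_index=True), outdir / "sex_bias.tsv",
                f"dosage exclude={','.join(config.exclude_chroms)}",
            )
            _write_table(
                pd.DataFrame(zaa_rows), outdir / "zaa_tests.tsv",
                f"dosage z_chrom={config.z_chrom} offset=1",
            )
            _write_table(
                pd.concat(scan_frames, ignore_index=True), outdir / "window_scan.tsv",
                f"dosage window={config.window} shift={config.shift}",
            )
            (outdir / "top_region.bed").write_text("\n".join(region_rows) + "\n")

        # ---------------- splicing -----------------------------------------
        if config.stages.get("splicing", True):
            stage = "splicing"
            events = splicing.classify_all(ann.coding_genes())
            five = [e for e in events if e.event_type in splicing.FIVE_MODES]
            _write_table(
                splicing.event_table(events), outdir / "as_events.tsv", "splicing"
            )
            ptab = splicing.psi_table(five, cpm_tx)
            _write_table(ptab, outdir / "psi.tsv", "splicing psi")
            ds = [
                splicing.differential_splicing(
                    ptab, sheet, tissue,
                    min_delta=config.min_delta_psi, alpha=config.fdr_alpha,
                )
                for tissue in sheet.tissues
            ]
            _write_table(
                pd.concat(ds, ignore_index=True), outdir / "diff_splice.tsv",
                f"splicing min_delta={config.min_delta_psi} alpha={config.fdr_alpha}",
            )
            _, member = splicing.unique_transcripts(cpm_tx, sheet)
            _write_table(
                member.rename_axis("feature_id").reset_index(),
                outdir / "unique_transcripts.tsv",
                "splicing unique threshold=0",
            )

        # ---------------- lncRNA -------------------------------------------
        if config.stages.get("lncrna", True):
            stage = "lncrna"
            noncoding: set[str] = set()
            if truth is not None:
                noncoding = set(truth.noncoding)
            elif config.noncoding_labels:
                lab = pd.read_csv(config.noncoding_labels, sep="\t", comment="#")
                noncoding = set(
                    lab.loc[lab.iloc[:, 1].astype(bool), lab.columns[0]].astype(str)
                )
            all_tx = list(ann.transcripts_by_id().values())
            cands = lncrna.filter_candidates(
                all_tx, noncoding,
                min_len=config.min_lnc_len, min_exons=config.min_lnc_exons,
            )
            log.info("lncRNA candidates: %d of %d noncoding labels", len(cands), len(noncoding))
            classes = lncrna.classify_all(cands, ann)
            _write_table(classes, outdir / "lnc_classes.tsv",
                         f"lncrna min_len={config.min_lnc_len} min_exons={config.min_lnc_exons}")
            targets = lncrna.assign_targets(cands, ann, max_dist=config.max_target_dist)
            _write_table(targets, outdir / "lnc_targets.tsv",
                         f"lncrna max_dist={config.max_target_dist}")
            cand_ids = [t.transcript_id for t in cands if t.transcript_id in cpm_tx.data.index]
            lnc_expr = quantify.ExpressionMatrix(
                data=cpm_tx.data.loc[cand_ids], unit=cpm_tx.unit,
                scale=cpm_tx.scale, level="transcript",
            )
            bias = pd.concat(
                [lncrna.call_bias(lnc_expr, sheet, t) for t in sheet.tissues],
                ignore_index=True,
            )
            _write_table(bias, outdir / "lnc_bias.tsv", "lncrna bias")
            if len(targets):
                corr = lncrna.correlate_targets(lnc_expr, cpm_gene, targets)
            else:
                corr = pd.DataFrame(
                    columns=["lncrna_id", "gene_id", "spearman_rho",
                             "pearson_r", "n_samples", "defined"]
                )
            _write_table(corr, outdir / "lnc_target_corr.tsv", "lncrna corr")

        # ---------------- APA ----------------------------------------------
        if config.stages.get("apa", True) and polya_path:
            stage = "apa"
            ends = annot_io.read_polya_ends(polya_path, ann)
            sites = apa.call_sites(
                ends, sheet,
                merge_dist=config.merge_dist, min_support=config.min_support,
            )
            _write_table(sites, outdir / "apa_sites.tsv",
                         f"apa merge_dist={config.merge_dist} min_support={config.min_support}")
            summary, dist = apa.sites_per_gene(sites)
            _write_table(summary, outdir / "apa_per_gene.tsv", "apa per-gene")
            test_rows = []
            for tissue in sheet.tissues:
                cmp_ = apa.compare_sex_distributions(summary, sheet, tissue)
                test_rows.append(
                    {
                        "tissue": tissue,
                        "statistic": cmp_.statistic,
                        "df": cmp_.df,
                        "p_value": cmp_.p_value,
                    }
                )
            _write_table(pd.DataFrame(test_rows), outdir / "apa_sex_test.tsv", "apa chi2")

        stage = "summarize"
        (outdir / "run_config.json").write_text(
            json.dumps(config.to_dict(), sort_keys=True, indent=1)
        )
        summary = summarize(outdir)
        (outdir / "summary.json").write_text(summary.to_json())
        return summary
    except Exception:
        (outdir / "FAILED").write_text(f"stage: {stage}\n")
        log.exception("pipeline failed in stage %r", stage)
        raise RuntimeError(f"pipeline failed in stage {stage!r}") from None


@dataclass
class RunSummary:
    version: str
    config_hash: str
    tables_hash: str
    table_rows: dict
    stats: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)


def _hash_tables(outdir: Path) -> str:
    h = hashlib.sha256()
    for name in TABLES:
        p = outdir / name
        if p.exists():
            h.update(name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def summarize(outdir: str | Path) -> RunSummary:
    """Recompute the run summary purely from the written tables."""
    outdir = Path(outdir)
    cfg_path = outdir / "run_config.json"
    if not cfg_path.exists():
        raise FileNotFoundError(f"missing table: {cfg_path.name}")
    cfg = json.loads(cfg_path.read_text())
    z_chrom = cfg.get("z_chrom", "Z")
    config_hash = hashlib.sha256(
        json.dumps(
            {k: v for k, v in cfg.items() if k != "outdir"}, sort_keys=True
        ).encode()
    ).hexdigest()

    rows: dict[str, int] = {}
    stats: dict = {}

    def need(name: str) -> Path:
        p = outdir / name
        if not p.exists():
            raise FileNotFoundError(f"missing table: {name}")
        return p

    for name in TABLES:
        p = outdir / name
        if not p.exists():
            continue
        if name.endswith(".bed"):
            rows[name] = sum(1 for _ in open(p))
        else:
            rows[name] = len(_read_table(p))

    if (outdir / "sex_bias.tsv").exists():
        bias = _read_table(need("sex_bias.tsv"))
        for tissue, sub in bias.groupby("tissue"):
            ok = sub.loc[~sub["outlier"]]
            z = ok.loc[ok["chrom"].astype(str) == z_chrom]
            aa = ok.loc[ok["chrom"].astype(str) != z_chrom]
            stats[f"z_mean_log2_mf|{tissue}"] = float(z["log2_mf"].mean())
            stats[f"z_median_log2_mf|{tissue}"] = float(z["log2_mf"].median())
            stats[f"z_aggregate_log2_mf|{tissue}"] = float(
                np.log2(z["mean_M"].sum() / z["mean_F"].sum())
            )
            stats[f"autosome_mean_log2_mf|{tissue}"] = float(aa["log2_mf"].mean())
        zaa = _read_table(need("zaa_tests.tsv"))
        for r in zaa.itertuples(index=False):
            stats[f"zaa_p|{r.tissue}|{r.sex}"] = float(r.p_value)
        for line in need("top_region.bed").read_text().splitlines():
            chrom, start, end, name = line.split("\t")
            tissue = name.split(":")[0]
            stats[f"top_region|{tissue}"] = [chrom, int(start), int(end)]

    if (outdir / "as_events.tsv").exists():
        ev = _read_table(need("as_events.tsv"))
        tallies = ev["event_type"].value_counts().to_dict() if len(ev) else {}
        stats["as_event_tallies"] = {k: int(v) for k, v in sorted(tallies.items())}
        ds = _read_table(need("diff_splice.tsv"))
        stats["n_significant_splice"] = int(ds["significant"].sum()) if len(ds) else 0

    if (outdir / "lnc_classes.tsv").exists():
        lc = _read_table(need("lnc_classes.tsv"))
        props = (
            (lc["class"].value_counts(normalize=True)).round(6).to_dict()
            if len(lc)
            else {}
        )
        stats["lnc_class_proportions"] = {k: float(v) for k, v in sorted(props.items())}
        lb = _read_table(need("lnc_bias.tsv"))
        for tissue, sub in lb.groupby("tissue"):
            stats[f"n_male_biased_lnc|{tissue}"] = int(sub["male_biased"].sum())

    if (outdir / "apa_per_gene.tsv").exists():
        ap = _read_table(need("apa_per_gene.tsv"))
        for group, sub in ap.groupby("group"):
            stats[f"apa_frac_multi|{group}"] = float((sub["n_sites"] >= 2).mean())
        at = _read_table(need("apa_sex_test.tsv"))
        for r in at.itertuples(index=False):
            stats[f"apa_sex_p|{r.tissue}"] = float(r.p_value)

    return RunSummary(
        version=__version__,
        config_hash=config_hash,
        tables_hash=_hash_tables(outdir),
        table_rows=rows,
        stats=stats,
    )
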