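"""End-to-end orchestration: merge → align → classify → statistics.

The pipeline is driven by one YAML experiment configuration declaring
the amplicon regions, the sample files with their replicate layout, and
the merge/alignment parameters.  Every stage writes its intermediate
table (TSV) so each CLI subcommand can also be run standalone on the
previous stage's output, and reruns on identical inputs are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .align import ScoringParams, align_read, load_alignments, IngestStats
from .alleles import (AlleleCountTable, AlleleKey, Kind, Replicate,
                      count_alleles)
from .merge import MergeParams, MergeStats, merge_fastq, write_merge_stats
from .motif import (build_profile, compare_to_pfm, logo_heights,
                    motif_proportions, importance_scores, read_pfm,
                    render_text_logo)
from .region import AmpliconRegion, region_from_dict
from .stats import effect_size, summarize_experiment

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


class ConfigError(ValueError):
    """Invalid experiment configuration (exit code 1 in the CLI)."""


@dataclass
class Sample:
    file: Path
    replicate_id: str
    readout: str
    region: str
    file2: Optional[Path] = None  # mate file => needs merging
    premerged: bool = False

    @property
    def is_alignment(self) -> bool:
        return self.file.suffix in (".sam", ".bam")


@dataclass
class ExperimentConfig:
    regions: list[AmpliconRegion]
    samples: list[Sample]
    merge: MergeParams = field(default_factory=MergeParams)
    scoring: ScoringParams = field(default_factory=ScoringParams)
    output_dir: Path = Path("atacedit_out")
    seed: int = 0
    motif_config: dict[str, dict] = field(default_factory=dict)

    def region(self, name: str) -> AmpliconRegion:
        for r in self.regions:
            if r.name == name:
                return r
        raise ConfigError(f"sample references unknown region {name!r}")

    def validate(self) -> None:
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate region names")
        seen = set()
        for s in self.samples:
            self.region(s.region)
            if s.readout not in ("ATAC", "gDNA", "RNA"):
                raise ConfigError(f"sample {s.replicate_id!r}: unknown readout "
                                  f"{s.readout!r}")
            key = (s.region, s.readout, s.replicate_id)
            if key in seen:
                raise ConfigError(f"duplicate replicate id {s.replicate_id!r} "
                                  f"for region {s.region!r} readout {s.readout!r}")
            seen.add(key)
            for p in filter(None, (s.file, s.file2)):
                if not Path(p).exists():
                    raise ConfigError(f"sample {s.replicate_id!r}: missing file {p}")


def load_config(path) -> ExperimentConfig:
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    base = path.parent

    def _resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    regions = []
    motif_cfg = {}
    for rd in doc.get("regions", []):
        regions.append(region_from_dict(rd))
        if "motif" in rd:
            motif_cfg[rd["name"]] = rd["motif"]
    samples = [Sample(file=_resolve(sd["file"]),
                      file2=_resolve(sd["file2"]) if sd.get("file2") else None,
                      replicate_id=str(sd["replicate_id"]),
                      readout=str(sd["readout"]),
                      region=str(sd["region"]),
                      premerged=bool(sd.get("premerged", False)))
               for sd in doc.get("samples", [])]
    merge = MergeParams(**doc.get("merge", {}))
    scoring = ScoringParams(**doc.get("scoring", {}))
    out = doc.get("output_dir", "atacedit_out")
    return ExperimentConfig(regions=regions, samples=samples, merge=merge,
                            scoring=scoring, output_dir=_resolve(out),
                            seed=int(doc.get("seed", 0)), motif_config=motif_cfg)


def _iter_fastq(path):
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fastq"):
        yield (rec.id, str(rec.seq),
               tuple(rec.letter_annotations["phred_quality"]))


def quantify_region(cfg: ExperimentConfig, region: AmpliconRegion,
                    merged_dir: Path) -> AlleleCountTable:
    """Align and classify every sample of one region into a count table."""
    samples = [s for s in cfg.samples if s.region == region.name]
    layout = [Replicate(s.replicate_id, s.readout) for s in samples]

    def stream():
        for s in samples:
            if s.is_alignment:
                stats = IngestStats()
                for aln in load_alignments(s.file, region, stats):
                    yield s.replicate_id, aln
                logger.info("%s: ingested %d/%d alignments", s.replicate_id,
                            stats.used, stats.total)
            else:
                path = (merged_dir / f"{s.replicate_id}.fastq"
                        if s.file2 is not None else s.file)
                n = 0
                for read in _iter_fastq(path):
                    n += 1
                    yield s.replicate_id, align_read(read, region, cfg.scoring)
                logger.info("%s: aligned %d reads", s.replicate_id, n)

    return count_alleles(stream(), region, layout)


def run_pipeline(cfg: ExperimentConfig) -> pd.DataFrame:
    """Execute all stages; returns the summary table and writes artifacts.

    Regions with fewer than two replicates in either the ATAC or the
    gDNA readout are skipped with a warning.  Identical configuration
    and inputs produce byte-identical outputs.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    merged_dir = out / "merged"

    # stage 1: merge paired samples
    merge_stats: dict[str, MergeStats] = {}
    for s in cfg.samples:
        if s.file2 is not None and not s.is_alignment:
            merged_dir.mkdir(exist_ok=True)
            merge_stats[s.replicate_id] = merge_fastq(
                s.file, s.file2, merged_dir / f"{s.replicate_id}.fastq", cfg.merge)
            logger.info("merged %s: %d/%d reads", s.replicate_id,
                        merge_stats[s.replicate_id].merged,
                        merge_stats[s.replicate_id].total)
    if merge_stats:
        write_merge_stats(merge_stats, out / "merge_stats.tsv")

    # stages 2+3: align and classify per region
    tables: list[AlleleCountTable] = []
    for region in sorted(cfg.regions, key=lambda r: r.name):
        reps = [(s.readout) for s in cfg.samples if s.region == region.name]
        if reps.count("ATAC") < 2 or reps.count("gDNA") < 2:
            logger.warning("region %s skipped: needs >= 2 replicates per readout",
                           region.name)
            continue
        tables.append(quantify_region(cfg, region, merged_dir))

    counts_frames = [t.to_frame() for t in tables]
    if counts_frames:
        pd.concat(counts_frames).to_csv(out / "counts.tsv", sep="\t", index=False)
    qc = []
    for t in tables:
        q = t.dropped.copy()
        q.insert(0, "classified", t.counts.sum(axis=1))
        q.insert(0, "readout", t.readouts)
        q.insert(0, "region", t.region.name)
        qc.append(q.reset_index())
    qc_frame = (pd.concat(qc, ignore_index=True) if qc
                else pd.DataFrame(columns=["region", "replicate"]))
    qc_frame.to_csv(out / "qc.tsv", sep="\t", index=False, float_format=FLOAT_FMT)

    # stage 4: statistics
    summary = summarize_experiment(tables)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False,
                   float_format=FLOAT_FMT)
    summary.to_json(out / "summary.json", orient="records", indent=1)

    # stage 5 (optional): saturation-mutagenesis motif profiling
    motif_sections = {}
    for t in tables:
        mc = cfg.motif_config.get(t.region.name)
        if mc is None:
            continue
        motif_sections[t.region.name] = run_motif_stage(t, mc, out)

    _write_manifest(cfg, out)
    report = write_report(summary, qc_frame, motif_sections)
    (out / "report.md").write_text(report)
    return summary


def run_motif_stage(table: AlleleCountTable, mc: dict, out: Path) -> dict:
    """Build the saturation profile for one region and write its tables.

    Every HDR allele consisting of a single substitution contributes the
    cell (offset, alternate base); cells listed under ``masked`` (e.g.
    the PAM base) are carried as unmeasurable.
    """
    region = table.region
    results = {}
    for spec in region.hdr_alleles:
        if len(spec.edits) == 1 and spec.edits[0].is_substitution \
                and len(spec.edits[0].ref_bases) == 1:
            e = spec.edits[0]
            key = AlleleKey(Kind.HDR, hdr_name=spec.name)
            if key in table.counts.columns:
                results[(e.ref_offset, e.alt_bases)] = effect_size(table, key)
    masked = {(int(p), str(b).upper()) for p, b in mc.get("masked", [])}
    profile = build_profile(results, region, masked=masked)
    heights = logo_heights(profile)
    props = motif_proportions(profile)
    imp = importance_scores(profile)
    prefix = out / f"motif_{region.name}"
    heights.to_csv(f"{prefix}_heights.tsv", sep="\t",
                   index_label="position", float_format=FLOAT_FMT)
    props.to_csv(f"{prefix}_proportions.tsv", sep="\t",
                 index_label="position", float_format=FLOAT_FMT)
    imp.to_csv(f"{prefix}_importance.tsv", sep="\t",
               index_label="position", float_format=FLOAT_FMT)
    section = {"heights": heights, "proportions": props,
               "logo": render_text_logo(heights)}
    if mc.get("pfm"):
        pfm = read_pfm(mc["pfm"])
        r, cells = compare_to_pfm(props, pfm, offset=int(mc.get("offset", 0)),
                                  strand=str(mc.get("strand", "+")))
        cells.to_csv(f"{prefix}_pfm_cells.tsv", sep="\t", index=False,
                     float_format=FLOAT_FMT)
        section["pearson_r"] = r
    return section


def _write_manifest(cfg: ExperimentConfig, out: Path) -> None:
    manifest = {
        "tool": "atacedit",
        "version": __version__,
        "seed": cfg.seed,
        "merge": vars(cfg.merge) | {},
        "scoring": vars(cfg.scoring) | {},
        "regions": [r.name for r in cfg.regions],
        "samples": [{"file": str(s.file), "file2": str(s.file2) if s.file2 else None,
                     "replicate_id": s.replicate_id, "readout": s.readout,
                     "region": s.region} for s in cfg.samples],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))


def write_report(summary: pd.DataFrame, qc: pd.DataFrame,
                 motif_sections: Optional[dict] = None) -> str:
    """Human-readable markdown report.

    Per region: the allele effect table (HDR effect, pooled
    deletion-window effect, top deletions), editing rates, and the
    replicate QC tallies; saturation regions get an extra motif section.
    """
    lines = ["# atacedit report", ""]
    if summary.empty:
        lines.append("No regions analysed.")
        return "\n".join(lines) + "\n"
    for region in summary["region"].unique():
        sub = summary[summary["region"] == region]
        lines.append(f"## Region {region}")
        lines.append("")
        lines.append("### Allele effects")
        lines.append("")
        cols = ["allele", "kind", "effect_size", "ci_low", "ci_high", "p", "q"]
        lines.append(_md_table(sub[cols]))
        hdr_rate = sub["hdr_rate"].iloc[0]
        indel_rate = sub["indel_rate"].iloc[0]
        lines.append("")
        lines.append(f"### Editing rates")
        lines.append("")
        lines.append(f"- HDR: {hdr_rate:.2%}")
        lines.append(f"- indels: {indel_rate:.2%}")
        lines.append("")
        qsub = qc[qc["region"] == region] if "region" in qc.columns else qc.iloc[0:0]
        if not qsub.empty:
            lines.append("### Replicate QC")
            lines.append("")
            lines.append(_md_table(qsub.drop(columns=["region"])))
            lines.append("")
        if motif_sections and region in motif_sections:
            sec = motif_sections[region]
            lines.append("### Saturation-mutagenesis motif")
            lines.append("")
            lines.append("Logo heights (squared effect size, WT = 1):")
            lines.append("")
            lines.append("```")
            lines.append(sec["logo"])
            lines.append("```")
            if "pearson_r" in sec:
                lines.append("")
                lines.append(f"Pearson r vs reference PFM: {sec['pearson_r']:.3f}")
            lines.append("")
    return "\n".join(lines) + "\n"


def _md_table(df: pd.DataFrame) -> str:
    def fmt(v):
        if isinstance(v, float):
            return FLOAT_FMT % v
        return str(v)

    header = "| " + " | ".join(df.columns) + " |"
    sep = "|" + "|".join("---" for _ in df.columns) + "|"
    rows = ["| " + " | ".join(fmt(v) for v in row) + " |"
            for row in df.itertuples(index=False)]
    return "\n".join([header, sep] + rows)
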