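"""End-to-end pipeline: tags in, annotated scored transcripts out.

Stages run in assembly order: load tags, per-sample merge, cross-sample
merge, density-aware stitch (with in-gene gap boost when a reference is
supplied and segmentation is not naive), noise filter, optional boundary
segmentation, scoring, annotation association, classification, reports.
Every output file carries a hash of the configuration so runs are
auditable; identical inputs and config give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import pandas as pd

from . import annotate, io_formats, refseq, scoring
from .assembly import AssemblyParams, assemble
from .model import AnnotationRecord, Tag, Transcript
from .refseq import SegmentationPolicy


@dataclass
class RunConfig:
    """Declarative pipeline configuration; defaults are the published defaults."""

    samples: List[Dict[str, str]] = field(default_factory=list)  # {id, path, format}
    out_dir: str = "grostitch_out"
    max_edge: float = 500.0
    density_multiplier: float = 10_000.0
    min_one_tag_per_sample: bool = True
    segmentation_mode: str = "respect_boundaries"
    gap_boost_factor: float = 10.0
    score_scheme: str = "custom"
    score_threshold: float = 1.0
    tss_window: int = 1000
    proximal_window: int = 1000
    near_peak_window: int = 2000
    refseq_path: Optional[str] = None
    refseq_format: Optional[str] = None
    ncrna_path: Optional[str] = None
    peaks_path: Optional[str] = None
    genome_sizes_path: Optional[str] = None
    seed: int = 0

    def validate(self) -> None:
        if self.max_edge <= 0:
            raise ValueError("max_edge must be > 0")
        if self.density_multiplier <= 0:
            raise ValueError("density_multiplier must be > 0")
        if self.segmentation_mode not in ("naive", "respect_boundaries"):
            raise ValueError(f"unknown segmentation mode {self.segmentation_mode!r}")
        if self.score_scheme not in ("rpkm", "custom"):
            raise ValueError(f"unknown score scheme {self.score_scheme!r}")
        if not self.samples:
            raise ValueError("no samples configured")
        seen = set()
        for s in self.samples:
            if "id" not in s or "path" not in s:
                raise ValueError("each sample needs 'id' and 'path'")
            if s["id"] in seen:
                raise ValueError(f"duplicate sample id {s['id']!r}")
            seen.add(s["id"])

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: Dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: RunConfig,
                 tags_by_sample: Optional[Dict[str, List[Tag]]] = None) -> Dict:
    """Run all stages and write the output bundle into ``config.out_dir``.

    ``tags_by_sample`` may be supplied directly (e.g. from the simulator)
    to bypass file loading.  Returns a summary dict with stage counts.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    cfg_hash = config.hash()
    log: List[str] = [f"config_hash={cfg_hash}"]

    if tags_by_sample is None:
        tags_by_sample = {}
        for s in config.samples:
            tags_by_sample[s["id"]] = list(io_formats.read_tags(
                s["path"], s.get("format"), sample_id=s["id"]))
    for sid in sorted(tags_by_sample):
        log.append(f"tags_read[{sid}]={len(tags_by_sample[sid])}")

    refseq_records: List[AnnotationRecord] = []
    if config.refseq_path:
        refseq_records = io_formats.read_annotations(
            config.refseq_path, config.refseq_format, source="refseq")
    ncrna_records = (io_formats.read_annotations(config.ncrna_path, None, "ncrna")
                     if config.ncrna_path else [])
    peak_records = (io_formats.read_annotations(config.peaks_path, "bed", "peak")
                    if config.peaks_path else [])

    params = AssemblyParams(max_edge=config.max_edge,
                            density_multiplier=config.density_multiplier,
                            min_one_tag_per_sample=config.min_one_tag_per_sample,
                            gap_boost_factor=config.gap_boost_factor)
    policy = SegmentationPolicy(mode=config.segmentation_mode,
                                gap_boost_factor=config.gap_boost_factor)
    boost = (refseq.gene_body_gap_regions(refseq_records)
             if refseq_records and policy.mode != "naive" else None)

    transcripts, library_sizes = assemble(tags_by_sample, params, boost)
    log.append(f"transcripts_assembled={len(transcripts)}")

    all_tags = [t for sid in sorted(tags_by_sample) for t in tags_by_sample[sid]]
    if policy.mode == "respect_boundaries" and refseq_records:
        transcripts = refseq.segment_at_boundaries(transcripts, refseq_records,
                                                   policy, tags=all_tags)
        log.append(f"transcripts_after_segmentation={len(transcripts)}")

    scoring.score_all(transcripts, library_sizes, scheme=config.score_scheme)

    associations = annotate.associate(
        transcripts, refseq_records + ncrna_records + peak_records)
    log.append(f"associations={len(associations)}")

    if refseq_records:
        annotate.classify(transcripts, refseq_records, ncrna_records, peak_records,
                          score_threshold=config.score_threshold,
                          tss_window=config.tss_window,
                          proximal_window=config.proximal_window,
                          near_peak_window=config.near_peak_window,
                          scheme=config.score_scheme)

    _write_outputs(config, cfg_hash, transcripts, associations, refseq_records, log)
    return {"config_hash": cfg_hash, "n_transcripts": len(transcripts),
            "library_sizes": library_sizes, "transcripts": transcripts,
            "log": log}


def _write_outputs(config: RunConfig, cfg_hash: str,
                   transcripts: List[Transcript], associations,
                   refseq_records, log: List[str]) -> None:
    out = config.out_dir
    header = f"config_hash={cfg_hash}"
    io_formats.write_transcripts(transcripts, os.path.join(out, "transcripts.bed"),
                                 "bed", config.score_scheme, header=header)
    io_formats.write_transcripts(transcripts, os.path.join(out, "transcripts.gtf"),
                                 "gtf", config.score_scheme, header=header)

    score_rows = [{"transcript_id": t.id, "chrom": t.chrom, "strand": t.strand,
                   "start": t.start, "end": t.end, "length": t.length,
                   "total_tags": t.total_tags,
                   "rpkm_mean": t.scores.rpkm_mean,
                   "custom_mean": t.scores.custom_mean,
                   "label": t.label or ""}
                  for t in sorted(transcripts, key=lambda x: (x.chrom, x.start, x.end))]
    _tsv(pd.DataFrame(score_rows), os.path.join(out, "scores.tsv"), header)

    assoc_rows = [{"transcript_id": a.transcript_id, "source": a.source,
                   "annotation_id": a.annotation_id, "overlap_bp": a.overlap_bp,
                   "fraction_of_annotation": a.fraction_of_annotation,
                   "fraction_of_transcript": a.fraction_of_transcript,
                   "relative_strand": a.relative_strand} for a in associations]
    _tsv(pd.DataFrame(assoc_rows, columns=["transcript_id", "source", "annotation_id",
                                           "overlap_bp", "fraction_of_annotation",
                                           "fraction_of_transcript", "relative_strand"]),
         os.path.join(out, "associations.tsv"), header)

    if refseq_records and any(t.label for t in transcripts):
        _tsv(annotate.category_report(transcripts),
             os.path.join(out, "categories.tsv"), header)
        _tsv(refseq.post_gene_table(transcripts, refseq_records, config.score_scheme),
             os.path.join(out, "post_gene.tsv"), header)

    with open(os.path.join(out, "run.log"), "w") as fh:
        fh.write("\n".join(log) + "\n")


def _tsv(df: pd.DataFrame, path: str, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"#{header}\n")
        df.to_csv(fh, sep="\t", index=False)
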