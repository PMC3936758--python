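"""Readers and writers for the standard formats the pipeline touches.

Mapped reads come in as SAM/BAM (via pysam) or 6-column BED; gene models as
refFlat or GTF; peaks and custom intervals as BED.  Assembled transcripts go
out as BED6+ or GTF.  Every coordinate crossing this module is converted to
the package-internal 0-based half-open convention.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, Iterator, List, Optional, Sequence

import pysam

from .model import AnnotationRecord, ScoreSet, Tag, Transcript


class FormatError(ValueError):
    """A record that does not parse in the named format."""


def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    return {
        ".sam": "sam", ".bam": "bam", ".bed": "bed",
        ".gtf": "gtf", ".gff": "gtf", ".refflat": "refflat", ".txt": "refflat",
    }.get(ext, "")


# ---------------------------------------------------------------------------
# mapped reads


def read_tags(path: str, format: Optional[str] = None, sample_id: str = "sample") -> Iterator[Tag]:
    """Stream mapped reads as :class:`Tag` objects.

    SAM/BAM records that are unmapped, secondary or supplementary are
    skipped (only primary alignments of uniquely-placed reads are evidence
    of nascent transcription).  Spliced alignments are collapsed to the
    span from leftmost to rightmost mapped base.  BED input must carry a
    strand column.
    """
    fmt = format or _infer_format(path)
    if fmt in ("sam", "bam"):
        yield from _read_tags_alignment(path, fmt, sample_id)
    elif fmt == "bed":
        yield from _read_tags_bed(path, sample_id)
    else:
        raise FormatError(f"unknown tag format {fmt!r} for {path}")


def _read_tags_alignment(path: str, fmt: str, sample_id: str) -> Iterator[Tag]:
    mode = "rb" if fmt == "bam" else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for i, rec in enumerate(fh):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            start = rec.reference_start
            end = rec.reference_end
            if start is None or end is None or end <= start:
                raise FormatError(f"{path}: record {i + 1} ({rec.query_name}) lacks coordinates")
            strand = "-" if rec.is_reverse else "+"
            yield Tag(rec.reference_name, strand, start, end, sample_id)


def _read_tags_bed(path: str, sample_id: str) -> Iterator[Tag]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: tag BED needs 6 columns (strand required)")
            strand = fields[5]
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: unstranded tag record rejected")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed coordinates") from exc
            yield Tag(fields[0], strand, start, end, sample_id)


# ---------------------------------------------------------------------------
# annotations


def read_annotations(path: str, format: Optional[str] = None,
                     source: str = "refseq") -> List[AnnotationRecord]:
    """Read stranded annotation intervals spanning transcription start->end.

    For GTF, transcript-level records are used and exon structure is
    ignored — nascent reads cover introns, so the relevant unit is the
    full primary-transcript span.  Duplicate ids (isoforms) are kept.
    """
    fmt = format or _infer_format(path)
    if fmt == "refflat":
        return list(_read_refflat(path, source))
    if fmt == "gtf":
        return list(_read_gtf(path, source))
    if fmt == "bed":
        return list(_read_annotation_bed(path, source))
    raise FormatError(f"unknown annotation format {fmt!r} for {path}")


def _read_refflat(path: str, source: str) -> Iterator[AnnotationRecord]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FormatError(f"{path}:{lineno}: refFlat needs >=6 columns")
            gene_name, name, chrom, strand = f[0], f[1], f[2], f[3]
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: refFlat record missing strand")
            yield AnnotationRecord(source, name or gene_name, chrom, strand,
                                   int(f[4]), int(f[5]), kind="mRNA")


def _read_gtf(path: str, source: str) -> Iterator[AnnotationRecord]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise FormatError(f"{path}:{lineno}: GTF needs 9 columns")
            if f[2] != "transcript":
                continue
            attrs = _parse_gtf_attributes(f[8])
            name = attrs.get("transcript_id") or attrs.get("gene_id") or f"{path}:{lineno}"
            strand = f[6]
            if source in ("refseq", "ncrna") and strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: {source} record missing strand")
            # GTF is 1-based inclusive on both ends
            yield AnnotationRecord(source, name, f[0], strand, int(f[3]) - 1, int(f[4]),
                                   kind=attrs.get("transcript_biotype", ""))


def _read_annotation_bed(path: str, source: str) -> Iterator[AnnotationRecord]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >=3 columns")
            name = f[3] if len(f) > 3 and f[3] else f"{source}_{lineno}"
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
            if source in ("refseq", "ncrna") and strand == ".":
                raise FormatError(f"{path}:{lineno}: {source} BED record must be stranded")
            yield AnnotationRecord(source, name, f[0], strand, int(f[1]), int(f[2]))


def _parse_gtf_attributes(text: str) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


# ---------------------------------------------------------------------------
# transcript output


def write_transcripts(transcripts: Sequence[Transcript], path: str,
                      format: str = "bed", scheme: str = "custom",
                      header: Optional[str] = None) -> None:
    """Write finalized transcripts sorted by (chrom, start).

    BED6+ carries the aggregate score (clamped to the 0-1000 BED range)
    in column 5 and the full-precision value in column 7; GTF carries
    per-sample tag counts, scores, classification label and post-gene
    linkage as attributes.
    """
    ordered = sorted(transcripts, key=lambda t: (t.chrom, t.start, t.end, t.strand))
    with open(path, "w") as out:
        if header:
            for line in header.splitlines():
                out.write(f"#{line}\n")
        if format == "bed":
            for t in ordered:
                score = t.scores.aggregate(scheme) if t.scores is not None else 0.0
                clamped = int(round(min(max(score, 0.0), 1000.0)))
                out.write("\t".join([t.chrom, str(t.start), str(t.end), t.id,
                                     str(clamped), t.strand, repr(score)]) + "\n")
        elif format == "gtf":
            for t in ordered:
                out.write(_gtf_line(t))
        else:
            raise FormatError(f"unknown transcript output format {format!r}")


def _gtf_line(t: Transcript) -> str:
    attrs = [f'transcript_id "{t.id}"', f'gap_count "{t.gap_count}"']
    for sid in sorted(t.tag_counts):
        attrs.append(f'tags_{sid} "{t.tag_counts[sid]}"')
    if t.scores is not None:
        for sid in sorted(t.scores.rpkm):
            attrs.append(f'rpkm_{sid} "{t.scores.rpkm[sid]!r}"')
            attrs.append(f'custom_{sid} "{t.scores.custom[sid]!r}"')
        attrs.append(f'rpkm_mean "{t.scores.rpkm_mean!r}"')
        attrs.append(f'custom_mean "{t.scores.custom_mean!r}"')
    if t.label is not None:
        attrs.append(f'label "{t.label}"')
    if t.post_gene_link is not None:
        attrs.append(f'post_gene_link "{t.post_gene_link}"')
    if t.is_post_gene:
        attrs.append('post_gene "1"')
    return "\t".join([t.chrom, "grostitch", "transcript", str(t.start + 1), str(t.end),
                      ".", t.strand, ".", "; ".join(attrs) + ";"]) + "\n"


def read_transcripts_gtf(path: str) -> List[Transcript]:
    """Reload transcripts written by :func:`write_transcripts` (GTF flavour).

    Used by the CLI so that assemble / score / classify stages can chain
    through files without losing per-sample counts or labels.
    """
    out: List[Transcript] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9 or f[2] != "transcript":
                continue
            attrs = _parse_gtf_attributes(f[8])
            tag_counts = {k[len("tags_"):]: int(v) for k, v in attrs.items()
                          if k.startswith("tags_")}
            rpkm = {k[len("rpkm_"):]: float(v) for k, v in attrs.items()
                    if k.startswith("rpkm_") and k != "rpkm_mean"}
            custom = {k[len("custom_"):]: float(v) for k, v in attrs.items()
                      if k.startswith("custom_") and k != "custom_mean"}
            scores = None
            if rpkm:
                scores = ScoreSet(rpkm, custom,
                                  float(attrs["rpkm_mean"]), float(attrs["custom_mean"]))
            out.append(Transcript(
                id=attrs.get("transcript_id", f"T{len(out):06d}"),
                chrom=f[0], strand=f[6], start=int(f[3]) - 1, end=int(f[4]),
                tag_counts=tag_counts, gap_count=int(attrs.get("gap_count", 0)),
                scores=scores, label=attrs.get("label"),
                post_gene_link=attrs.get("post_gene_link"),
                is_post_gene=attrs.get("post_gene") == "1"))
    return out


def read_genome_sizes(path: str) -> Dict[str, int]:
    """Read a UCSC chrom.sizes-style two-column table."""
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 2:
                raise FormatError(f"{path}:{lineno}: chrom.sizes needs two columns")
            sizes[f[0]] = int(f[1])
    return sizes


def write_tags_bed(tags: Iterable[Tag], path: str) -> None:
    """Write tags as 6-column BED, sorted for reproducible output."""
    rows = sorted(tags, key=lambda t: (t.chrom, t.start, t.end, t.strand))
    with open(path, "w") as out:
        for i, t in enumerate(rows):
            out.write(f"{t.chrom}\t{t.start}\t{t.end}\ttag{i}\t0\t{t.strand}\n")
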