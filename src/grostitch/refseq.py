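"""Reference-gene heuristics applied around assembly.

Two allowances are made for annotated genes.  First, the merge distance
traversed during stitching can be boosted inside gene bodies, where
coverage gaps are more likely to belong to one long transcript.  Second,
assembly can be forced to respect annotated 3' gene ends: a transcript
that runs through a termination site is cut there, and the downstream
("post-gene") piece is linked back to its gene-side piece so that
readthrough transcription can be quantified against the gene it follows.
"""

from __future__ import annotations

from bisect import bisect_left
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .assembly import Regions
from .model import AnnotationRecord, Tag, Transcript

Key = Tuple[str, str]


@dataclass(frozen=True)
class SegmentationPolicy:
    """How annotations steer assembly.

    ``naive`` ignores annotations entirely; ``respect_boundaries``
    additionally cuts transcripts at annotated same-strand 3' ends.
    ``gap_boost_factor`` multiplies max_edge for proto pairs inside the
    same gene body (>= 1; 10 bridges 5 kb in-gene gaps at the default
    max_edge of 500).
    """

    mode: str = "respect_boundaries"
    gap_boost_factor: float = 10.0
    boundary_set: str = "three_prime"  # which annotation edges force cuts

    def __post_init__(self) -> None:
        if self.mode not in ("naive", "respect_boundaries"):
            raise ValueError(f"unknown segmentation mode {self.mode!r}")
        if self.gap_boost_factor < 1:
            raise ValueError("gap_boost_factor must be >= 1")
        if self.boundary_set != "three_prime":
            raise ValueError("only 3' boundary cuts are supported")


def _merged_intervals(records: Iterable[AnnotationRecord]) -> Dict[Key, List[Tuple[int, int]]]:
    """Strand-specific union of annotation intervals (overlap/abut merged)."""
    by_key: Dict[Key, List[Tuple[int, int]]] = defaultdict(list)
    for r in records:
        by_key[(r.chrom, r.strand)].append((r.start, r.end))
    out: Dict[Key, List[Tuple[int, int]]] = {}
    for key, ivs in by_key.items():
        ivs.sort()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[key] = [(s, e) for s, e in merged]
    return out


def gene_body_gap_regions(annotations: Iterable[AnnotationRecord]) -> Regions:
    """Strand-specific union of gene bodies, fed to stitch as boost regions."""
    return _merged_intervals(a for a in annotations if a.source == "refseq")


def _cut_points(annotations: Iterable[AnnotationRecord]) -> Dict[Key, List[int]]:
    """One forced cut per merged same-strand gene locus, at its outermost 3' end.

    Overlapping isoforms collapse to a single locus so that alternative 3'
    ends internal to a longer isoform never segment the transcript.
    """
    loci = _merged_intervals(a for a in annotations if a.source == "refseq")
    cuts: Dict[Key, List[int]] = {}
    for (chrom, strand), ivs in loci.items():
        cuts[(chrom, strand)] = sorted(e if strand == "+" else s for s, e in ivs)
    return cuts


def segment_at_boundaries(transcripts: Sequence[Transcript],
                          annotations: Iterable[AnnotationRecord],
                          policy: SegmentationPolicy,
                          tags: Optional[Iterable[Tag]] = None) -> List[Transcript]:
    """Cut transcripts at annotated same-strand 3' gene ends.

    Tag counts are apportioned by re-counting tags per piece, each tag
    assigned to the piece containing its 5' end; if no tags are supplied,
    counts are apportioned by length with largest-remainder rounding so
    per-sample totals are still conserved exactly.  The downstream piece
    of each cut carries ``post_gene_link`` to its upstream neighbour and
    the ``is_post_gene`` flag.
    """
    if policy.mode == "naive":
        return list(transcripts)
    cuts = _cut_points(annotations)

    # per (chrom, strand, sample): sorted 5'-end positions for fast recounts
    fp_index: Optional[Dict[Tuple[str, str, str], List[int]]] = None
    if tags is not None:
        fp_index = defaultdict(list)
        for t in tags:
            fp_index[(t.chrom, t.strand, t.sample_id)].append(t.five_prime)
        for positions in fp_index.values():
            positions.sort()

    out: List[Transcript] = []
    for t in transcripts:
        inner = [c for c in cuts.get((t.chrom, t.strand), []) if t.start < c < t.end]
        if not inner:
            out.append(t)
            continue
        bounds = [t.start] + sorted(inner) + [t.end]
        pieces = list(zip(bounds[:-1], bounds[1:]))
        counts = _apportion(t, pieces, fp_index)
        order = range(len(pieces)) if t.strand == "+" else range(len(pieces) - 1, -1, -1)
        prev_id: Optional[str] = None
        for rank, gi in enumerate(order, start=1):
            s, e = pieces[gi]
            pid = f"{t.id}.{rank}"
            out.append(Transcript(
                id=pid, chrom=t.chrom, strand=t.strand, start=s, end=e,
                tag_counts=counts[gi],
                gap_count=t.gap_count if rank == 1 else 0,
                post_gene_link=prev_id, is_post_gene=prev_id is not None))
            prev_id = pid
    out.sort(key=lambda x: (x.chrom, x.start, x.end, x.strand))
    return out


def _apportion(t: Transcript, pieces: List[Tuple[int, int]],
               fp_index) -> List[Dict[str, int]]:
    counts: List[Dict[str, int]] = [dict() for _ in pieces]
    for sid, total in t.tag_counts.items():
        if fp_index is not None:
            positions = fp_index.get((t.chrom, t.strand, sid), [])
            for i, (s, e) in enumerate(pieces):
                counts[i][sid] = bisect_left(positions, e) - bisect_left(positions, s)
        else:
            length = t.length
            shares = [(e - s) * total / length for s, e in pieces]
            floors = [int(x) for x in shares]
            rem = total - sum(floors)
            order = sorted(range(len(pieces)), key=lambda i: shares[i] - floors[i],
                           reverse=True)
            for i in order[:rem]:
                floors[i] += 1
            for i, n in enumerate(floors):
                counts[i][sid] = n
    return counts


def post_gene_table(transcripts: Sequence[Transcript],
                    annotations: Optional[Iterable[AnnotationRecord]] = None,
                    scheme: str = "custom") -> pd.DataFrame:
    """Readthrough summary: one row per gene / post-gene transcript pair.

    Pairs come from post-gene links created by segmentation.  When the
    reference annotation is supplied, expressed gene loci whose transcript
    has no downstream partner are reported with a null partner and a
    ``truncated`` flag marking transcripts that stop short of the
    annotated 3' end.
    """
    by_id = {t.id: t for t in transcripts}
    downstream_of: Dict[str, Transcript] = {}
    for t in transcripts:
        if t.post_gene_link is not None and t.post_gene_link in by_id:
            downstream_of[t.post_gene_link] = t

    def _score(t: Transcript) -> float:
        return t.scores.aggregate(scheme) if t.scores is not None else float("nan")

    rows = []
    paired_ids = set()
    for gene_t, post_t in sorted(downstream_of.items()):
        g = by_id[gene_t]
        if g.is_post_gene:
            continue  # chains report only the gene-side head against its first tail
        rows.append({"gene_id": g.id, "post_gene_id": post_t.id,
                     "gene_score": _score(g), "post_gene_score": _score(post_t),
                     "post_gene_length": post_t.length, "truncated": False})
        paired_ids.add(g.id)

    if annotations is not None:
        loci = _merged_intervals(a for a in annotations if a.source == "refseq")
        for (chrom, strand), ivs in sorted(loci.items()):
            cands = [t for t in transcripts
                     if t.chrom == chrom and t.strand == strand and not t.is_post_gene]
            for s, e in ivs:
                over = [(min(t.end, e) - max(t.start, s), t) for t in cands]
                over = [(o, t) for o, t in over if o > 0]
                if not over:
                    continue  # silent locus
                best = max(over, key=lambda x: (x[0], x[1].id))[1]
                if best.id in paired_ids:
                    continue
                three_prime = e if strand == "+" else s
                truncated = (best.end < three_prime) if strand == "+" else (best.start > three_prime)
                rows.append({"gene_id": best.id, "post_gene_id": None,
                             "gene_score": _score(best), "post_gene_score": float("nan"),
                             "post_gene_length": 0, "truncated": truncated})
                paired_ids.add(best.id)

    return pd.DataFrame(rows, columns=["gene_id", "post_gene_id", "gene_score",
                                       "post_gene_score", "post_gene_length", "truncated"])
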