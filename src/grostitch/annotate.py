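"""Annotation association and RNA-species classification.

Transcripts are linked to annotation intervals by strand-aware genomic
overlap, then assigned exactly one taxonomy label by a fixed-priority
cascade: same-strand gene overlap (major/minor by fraction of the gene
covered), known ncRNA, promoter-associated antisense RNA near active
TSSs, antisense of transcribed gene bodies, gene-proximal remainder,
then the distal classes — enhancer RNA (overlapping an enhancer mark
peak), near-enhancer, and unlabeled distal.  Post-gene status from
boundary segmentation is an orthogonal flag, not a cascade slot.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .model import Association, AnnotationRecord, CLASS_LABELS, Transcript


def _trees_by_chrom(records: Sequence[AnnotationRecord]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
    for r in records:
        trees[r.chrom].addi(r.start, r.end, r)
    return trees


def associate(transcripts: Sequence[Transcript],
              annotations: Sequence[AnnotationRecord],
              min_overlap: int = 1) -> List[Association]:
    """All (transcript, annotation) overlap pairs of at least ``min_overlap`` bp.

    Stranded sources associate in both orientations with the orientation
    recorded; strandless records (peaks) yield ``strandless`` links.
    """
    trees = _trees_by_chrom(annotations)
    out: List[Association] = []
    for t in transcripts:
        tree = trees.get(t.chrom)
        if tree is None:
            continue
        hits = sorted(tree.overlap(t.start, t.end),
                      key=lambda iv: (iv.begin, iv.end, iv.data.id))
        for iv in hits:
            a: AnnotationRecord = iv.data
            overlap = min(t.end, a.end) - max(t.start, a.start)
            if overlap < min_overlap:
                continue
            if a.strand == ".":
                rel = "strandless"
            else:
                rel = "sense" if a.strand == t.strand else "antisense"
            out.append(Association(t.id, a.source, a.id, overlap,
                                   overlap / a.length, overlap / t.length, rel))
    return out


def _min_gap(t: Transcript, a: AnnotationRecord) -> int:
    """Minimum genomic gap between intervals, 0 when overlapping."""
    if t.chrom != a.chrom:
        raise ValueError("gap undefined across chromosomes")
    return max(0, max(t.start, a.start) - min(t.end, a.end))


def classify(transcripts: Sequence[Transcript],
             refseq: Sequence[AnnotationRecord],
             ncrna: Optional[Sequence[AnnotationRecord]] = None,
             peaks: Optional[Sequence[AnnotationRecord]] = None,
             score_threshold: float = 1.0,
             tss_window: int = 1000,
             proximal_window: int = 1000,
             near_peak_window: int = 2000,
             scheme: str = "custom") -> Sequence[Transcript]:
    """Assign one cascade label per transcript (in place) and return them.

    A gene is "active" when some same-strand transcript overlapping it
    passes the score threshold; only active TSSs anchor the paRNA label
    and only active bodies the antisense-body label.  Without a peak set
    the two enhancer rules are skipped and distal transcripts fall
    through to ``distal_unlabeled``.
    """
    ncrna = ncrna or []
    peaks = peaks or []
    refseq_trees = _trees_by_chrom(refseq)
    ncrna_trees = _trees_by_chrom(ncrna)
    peak_trees = _trees_by_chrom(peaks)

    # which refseq records are actively transcribed (sense, scored)
    active: Dict[int, bool] = {}
    for t in transcripts:
        if t.scores is None:
            raise ValueError(f"transcript {t.id} must be scored before classification")
        if t.score(scheme) < score_threshold:
            continue
        tree = refseq_trees.get(t.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(t.start, t.end):
            if iv.data.strand == t.strand:
                active[id(iv.data)] = True

    for t in transcripts:
        t.label = _classify_one(t, refseq_trees, ncrna_trees, peak_trees, active,
                                tss_window, proximal_window, near_peak_window)
    return transcripts


def _classify_one(t: Transcript, refseq_trees, ncrna_trees, peak_trees,
                  active, tss_window, proximal_window, near_peak_window) -> str:
    rtree = refseq_trees.get(t.chrom)
    r_hits = [iv.data for iv in rtree.overlap(t.start, t.end)] if rtree is not None else []
    sense = [a for a in r_hits if a.strand == t.strand]
    antisense = [a for a in r_hits if a.strand != t.strand]

    # (1)/(2): same-strand gene overlap, split at half the gene covered
    if sense:
        best_frac = max((min(t.end, a.end) - max(t.start, a.start)) / a.length
                        for a in sense)
        return "refseq_major" if best_frac >= 0.5 else "refseq_minor"

    # (3): known non-coding RNA overlap (either orientation)
    ntree = ncrna_trees.get(t.chrom)
    if ntree is not None and ntree.overlap(t.start, t.end):
        return "ncrna"

    # (4): promoter-associated RNA — 5' end within the TSS window of an
    # active gene, antisense to it
    if rtree is not None:
        fp = t.five_prime
        for iv in rtree.overlap(fp - tss_window, fp + tss_window + 1):
            a = iv.data
            if a.strand != t.strand and active.get(id(a)) and abs(fp - a.tss) <= tss_window:
                return "paRNA"

    # (5): antisense of a transcribed gene body
    if any(active.get(id(a)) for a in antisense):
        return "antisense_body"

    # (6): proximal to any gene (either strand) but none of the above
    if rtree is not None:
        for iv in rtree.overlap(t.start - proximal_window, t.end + proximal_window):
            if _min_gap(t, iv.data) <= proximal_window:
                return "proximal_other"

    # distal classes
    ptree = peak_trees.get(t.chrom)
    if ptree is not None:
        if ptree.overlap(t.start, t.end):
            return "eRNA"
        for iv in ptree.overlap(t.start - near_peak_window, t.end + near_peak_window):
            if _min_gap(t, iv.data) <= near_peak_window:
                return "near_enhancer"
    return "distal_unlabeled"


def coverage_fraction(transcripts: Sequence[Transcript],
                      genome_sizes: Dict[str, int],
                      per_strand: bool = True):
    """Fraction of the genome covered by transcripts, per strand or overall.

    Transcripts on one (chromosome, strand) are non-overlapping by
    construction, so lengths sum without double counting.
    """
    total = sum(genome_sizes.values())
    if total <= 0:
        raise ValueError("empty genome")
    covered: Dict[str, int] = {"+": 0, "-": 0}
    for t in transcripts:
        if t.chrom not in genome_sizes:
            raise ValueError(f"transcript {t.id} on unknown chromosome {t.chrom}")
        covered[t.strand] += t.length
    if per_strand:
        return {s: covered[s] / total for s in ("+", "-")}
    return (covered["+"] + covered["-"]) / (2 * total)


_PARENT = {"refseq_major": "annotated", "refseq_minor": "annotated",
           "ncrna": "annotated"}


def category_report(transcripts: Sequence[Transcript]) -> pd.DataFrame:
    """Counts and fractions per class label (and per parent panel).

    The parent panels mirror the annotated / unannotated split: fractions
    of the parent are computed within each panel.
    """
    counts = {label: 0 for label in CLASS_LABELS}
    for t in transcripts:
        if t.label is None:
            raise ValueError(f"transcript {t.id} is unclassified")
        counts[t.label] += 1
    total = max(sum(counts.values()), 1)
    parent_totals: Dict[str, int] = defaultdict(int)
    for label, n in counts.items():
        parent_totals[_PARENT.get(label, "unannotated")] += n
    rows = []
    for label in CLASS_LABELS:
        parent = _PARENT.get(label, "unannotated")
        ptot = max(parent_totals[parent], 1)
        rows.append({"label": label, "count": counts[label],
                     "fraction": counts[label] / total,
                     "parent": parent,
                     "fraction_of_parent": counts[label] / ptot})
    return pd.DataFrame(rows)
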