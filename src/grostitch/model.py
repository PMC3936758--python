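"""Core domain types shared by all stages of the pipeline.

All genomic coordinates in this package are 0-based, half-open
([start, end)), so interval length is simply ``end - start`` and abutting
intervals share no base.  Strand is ``'+'`` or ``'-'``; annotation records
from strandless sources (e.g. ChIP-seq peaks) may carry ``'.'``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

STRANDS = ("+", "-")
STRANDLESS = "."

#: annotation sources that must carry a strand
_STRANDED_SOURCES = ("refseq", "ncrna")


@dataclass(frozen=True)
class Tag:
    """One mapped read reduced to its genomic coordinates plus sample identity."""

    chrom: str
    strand: str
    start: int
    end: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"tag strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"tag requires start < end, got [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Position of the read's 5' base (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class AnnotationRecord:
    """A named stranded interval from RefSeq / ncRNA / peak / custom sources."""

    source: str  # {refseq, ncrna, peak, custom}
    id: str
    chrom: str
    strand: str
    start: int
    end: int
    kind: str = ""  # free-form subtype, e.g. mRNA or rRNA

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"annotation {self.id}: requires start < end, got [{self.start}, {self.end})"
            )
        if self.source in _STRANDED_SOURCES and self.strand not in STRANDS:
            raise ValueError(f"{self.source} annotation {self.id} must be stranded")
        if self.strand not in STRANDS + (STRANDLESS,):
            raise ValueError(f"annotation {self.id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start site (5' edge, strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        """Coordinate of the 3' boundary (the cut point for segmentation)."""
        return self.end if self.strand == "+" else self.start


@dataclass
class ProtoTranscript:
    """A merged run of tags: the node of the 2D merge graph.

    ``tag_counts`` maps sample id to the number of tags absorbed into this
    run; ``gap_count`` counts zero-coverage gaps bridged during stitching
    (kept for diagnostics, never consumed by any formula).
    """

    chrom: str
    strand: str
    start: int
    end: int
    tag_counts: Dict[str, int]
    gap_count: int = 0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"proto-transcript requires start < end: [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def total_tags(self) -> int:
        return sum(self.tag_counts.values())


@dataclass(frozen=True)
class MergePlanePoint:
    """The (basepair, scaled-density) embedding of a proto-transcript.

    ``y`` is (total tags / length in bp) x DENSITY_MULTIPLIER, recomputable
    from the owning proto-transcript at any time.
    """

    chrom: str
    strand: str
    x_start: int
    x_end: int
    y: float


@dataclass
class ScoreSet:
    """Per-sample RPKM and length-compensated custom score, plus means."""

    rpkm: Dict[str, float]
    custom: Dict[str, float]
    rpkm_mean: float
    custom_mean: float

    def aggregate(self, scheme: str = "custom") -> float:
        if scheme == "custom":
            return self.custom_mean
        if scheme == "rpkm":
            return self.rpkm_mean
        raise ValueError(f"unknown scoring scheme {scheme!r}")


@dataclass
class Association:
    """A strand-aware overlap link between a transcript and an annotation."""

    transcript_id: str
    source: str
    annotation_id: str
    overlap_bp: int
    fraction_of_annotation: float
    fraction_of_transcript: float
    relative_strand: str  # {sense, antisense, strandless}


@dataclass
class Transcript:
    """A final stitched transcription unit."""

    id: str
    chrom: str
    strand: str
    start: int
    end: int
    tag_counts: Dict[str, int]
    gap_count: int = 0
    scores: Optional[ScoreSet] = None
    annotations: List[Association] = field(default_factory=list)
    label: Optional[str] = None
    post_gene_link: Optional[str] = None
    is_post_gene: bool = False

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError(f"transcript {self.id}: requires end - start >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def total_tags(self) -> int:
        return sum(self.tag_counts.values())

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def score(self, scheme: str = "custom") -> float:
        if self.scores is None:
            raise ValueError(f"transcript {self.id} has not been scored")
        return self.scores.aggregate(scheme)


#: the classification taxonomy, in cascade priority order
CLASS_LABELS = (
    "refseq_major",
    "refseq_minor",
    "ncrna",
    "paRNA",
    "antisense_body",
    "proximal_other",
    "eRNA",
    "near_enhancer",
    "distal_unlabeled",
)
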