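"""Transcript expression scores.

Two schemes: standard RPKM, and a length-compensated custom score that
multiplies RPKM by log base 100 of the transcript length.  The log factor
levels out long low-coverage transcripts so a single score threshold can
retain them without also admitting short noisy stitches; transcripts
shorter than 200 bp score exactly 0 under the custom scheme, suppressing
artifacts from a few overlapping reads.
"""

from __future__ import annotations

import math
from typing import Dict, Sequence

from .model import ScoreSet, Transcript

#: custom scores are zeroed below this transcript length (bp)
MIN_SCORED_LENGTH = 200

#: base of the length logarithm; base 100 keeps the factor nearly flat
#: across the enormous range of transcript lengths
LOG_BASE = 100.0


def rpkm(tag_count: int, length: int, library_size: int) -> float:
    """Reads per kilobase of transcript per million mapped tags."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if library_size < 1:
        raise ValueError("library_size must be >= 1 (no mapped tags?)")
    if tag_count < 0:
        raise ValueError("tag_count must be >= 0")
    return tag_count / (length / 1_000.0) / (library_size / 1_000_000.0)


def custom_score(tag_count: int, length: int, library_size: int) -> float:
    """RPKM scaled by log100(length); 0 for transcripts shorter than 200 bp."""
    if length < MIN_SCORED_LENGTH:
        # still validate the denominator contract
        if library_size < 1:
            raise ValueError("library_size must be >= 1 (no mapped tags?)")
        return 0.0
    return rpkm(tag_count, length, library_size) * (math.log(length) / math.log(LOG_BASE))


def score_all(transcripts: Sequence[Transcript], library_sizes: Dict[str, int],
              scheme: str = "custom") -> Sequence[Transcript]:
    """Populate each transcript's :class:`ScoreSet` in place.

    Both schemes are always computed; ``scheme`` only checks validity of
    the caller's later choice of aggregate.  The cross-sample aggregate is
    the unweighted mean over all samples with a known library size.
    """
    if scheme not in ("rpkm", "custom"):
        raise ValueError(f"unknown scoring scheme {scheme!r}")
    samples = sorted(library_sizes)
    if not samples:
        raise ValueError("no library sizes supplied")
    for t in transcripts:
        missing = set(t.tag_counts) - set(samples)
        if missing:
            raise ValueError(f"transcript {t.id}: no library size for {sorted(missing)}")
        r: Dict[str, float] = {}
        c: Dict[str, float] = {}
        for sid in samples:
            n = t.tag_counts.get(sid, 0)
            r[sid] = rpkm(n, t.length, library_sizes[sid])
            c[sid] = custom_score(n, t.length, library_sizes[sid])
        t.scores = ScoreSet(r, c,
                            sum(r.values()) / len(samples),
                            sum(c.values()) / len(samples))
    return transcripts
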