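"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: adjacency is built as a
dense all-pairs matrix and components come from scipy's csgraph, whereas
the implementation uses a sorted sweep with its own union-find.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


def brute_force_stitch(protos, max_edge: float, density_multiplier: float,
                       gap_boost_regions: Optional[dict] = None,
                       gap_boost_factor: float = 1.0,
                       ) -> List[Tuple[str, str, int, int, int]]:
    """O(n^2) edge construction + csgraph components + interval collapse.

    Returns sorted (chrom, strand, start, end, total_tags) tuples.
    """
    by_key: Dict[Tuple[str, str], list] = {}
    for p in protos:
        by_key.setdefault((p.chrom, p.strand), []).append(p)

    out: List[Tuple[str, str, int, int, int]] = []
    for (chrom, strand), group in sorted(by_key.items()):
        group = sorted(group, key=lambda p: (p.start, p.end))
        n = len(group)
        starts = np.array([p.start for p in group], dtype=float)
        ends = np.array([p.end for p in group], dtype=float)
        ys = np.array([p.total_tags / p.length * density_multiplier for p in group])

        gap = np.maximum(starts[None, :] - ends[:, None],
                         starts[:, None] - ends[None, :])
        gap = np.maximum(gap, 0.0)
        dist = np.hypot(gap, ys[:, None] - ys[None, :])

        thresholds = np.full((n, n), float(max_edge))
        regions = sorted((gap_boost_regions or {}).get((chrom, strand), []))
        if regions:
            region_of = np.full(n, -1)
            for i, p in enumerate(group):
                for r, (rs, re) in enumerate(regions):
                    if rs <= p.start and p.end <= re:
                        region_of[i] = r
                        break
            same = (region_of[:, None] == region_of[None, :]) & (region_of[:, None] >= 0)
            thresholds[same] = max_edge * gap_boost_factor

        adj = dist <= thresholds
        np.fill_diagonal(adj, False)
        _, labels = connected_components(csr_matrix(adj), directed=False)

        spans = []
        for c in range(labels.max() + 1):
            idx = np.nonzero(labels == c)[0]
            spans.append((int(starts[idx].min()), int(ends[idx].max()),
                          int(sum(group[i].total_tags for i in idx))))
        spans.sort()
        merged = []
        for s, e, t in spans:
            if merged and s < merged[-1][1]:
                ps, pe, pt = merged[-1]
                merged[-1] = (ps, max(pe, e), pt + t)
            else:
                merged.append((s, e, t))
        out.extend((chrom, strand, s, e, t) for s, e, t in merged)
    return sorted(out)


def brute_force_associations(transcripts, annotations, min_overlap: int = 1):
    """All-pairs overlap scan; returns sorted (tid, aid, overlap, rel) tuples."""
    out = []
    for t in transcripts:
        for a in annotations:
            if t.chrom != a.chrom:
                continue
            ov = min(t.end, a.end) - max(t.start, a.start)
            if ov < min_overlap:
                continue
            rel = ("strandless" if a.strand == "." else
                   "sense" if a.strand == t.strand else "antisense")
            out.append((t.id, a.id, ov, rel))
    return sorted(out)


def brute_force_summed_error(called, reference, min_overlap: int = 1,
                             expressed_only: bool = True) -> Tuple[float, float]:
    """Double-loop overlap counting for the segmentation error."""
    def _iv(r):
        return r if isinstance(r, tuple) else (r.chrom, r.strand, r.start, r.end)

    refs = [_iv(r) for r in reference]
    ref_hits = [0] * len(refs)
    merging = 0
    for t in called:
        partners = 0
        for i, (chrom, strand, s, e) in enumerate(refs):
            if (t.chrom, t.strand) != (chrom, strand):
                continue
            if min(t.end, e) - max(t.start, s) >= min_overlap:
                ref_hits[i] += 1
                partners += 1
        if partners >= 2:
            merging += 1
    denom = sum(1 for h in ref_hits if h >= 1) if expressed_only else len(refs)
    broken = sum(1 for h in ref_hits if h >= 2)
    return (broken / denom if denom else 0.0,
            merging / len(called) if called else 0.0)


def random_disjoint_protos(rng: np.random.Generator, n: int,
                           chrom: str = "chr1", strand: str = "+",
                           samples=("A", "B")) -> list:
    """Random non-overlapping proto-transcripts for oracle comparisons."""
    from grostitch.model import ProtoTranscript

    gaps = rng.integers(1, 2000, n)
    lengths = rng.integers(30, 3000, n)
    starts = np.cumsum(gaps + lengths) - lengths
    protos = []
    for i in range(n):
        counts = {s: int(c) for s, c in zip(samples, rng.integers(0, 40, len(samples)))}
        if sum(counts.values()) == 0:
            counts[samples[0]] = 1
        protos.append(ProtoTranscript(chrom, strand, int(starts[i]),
                                      int(starts[i] + lengths[i]), counts))
    return protos
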