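"""Density-aware assembly of tags into transcription units.

The pipeline stages implemented here:

1. per-sample merge of overlapping/abutting tags into proto-transcripts
   (no density reasoning yet);
2. cross-sample merge, summing per-sample tag counts;
3. embedding of each proto-transcript into the 2D merge plane, where x is
   genomic position and y is read density scaled by DENSITY_MULTIPLIER;
4. stitching: connect two proto-transcripts iff their Euclidean distance
   in that plane is <= MAX_EDGE, take connected components, collapse each
   to its spanning interval, and merge any overlapping results;
5. a noise filter dropping units averaging fewer than one tag per sample.

The stitch is a sorted sweep: because proto-transcripts on one
(chromosome, strand) are disjoint, only neighbours within the maximum
reachable x-gap can ever be connected, so the pass is effectively linear
in the number of proto-transcripts.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .model import MergePlanePoint, ProtoTranscript, Tag, Transcript

Key = Tuple[str, str]  # (chrom, strand)
Regions = Dict[Key, List[Tuple[int, int]]]


@dataclass(frozen=True)
class AssemblyParams:
    """Tunable parameters of the merge plane.

    ``max_edge`` is the maximum Euclidean distance (in bp-equivalents) for
    two proto-transcripts to be joined; ``density_multiplier`` converts
    tags-per-bp density to the bp-equivalent y axis, so a difference of
    one tag per ``density_multiplier`` bp weighs like a one-bp gap.
    Defaults are the published tuning optimum (500, 10 000).
    """

    max_edge: float = 500.0
    density_multiplier: float = 10_000.0
    min_one_tag_per_sample: bool = True
    gap_boost_factor: float = 10.0  # effective max_edge multiplier inside gene bodies
    per_sample_mean_density: bool = False  # y = total/(len*n_samples) instead of total/len
    n_samples: int = 1  # used only when per_sample_mean_density is on
    recursive_reembed: bool = False  # re-embed merged components and stitch again

    def __post_init__(self) -> None:
        if self.max_edge <= 0:
            raise ValueError("max_edge must be > 0")
        if self.density_multiplier <= 0:
            raise ValueError("density_multiplier must be > 0")
        if self.gap_boost_factor < 1:
            raise ValueError("gap_boost_factor must be >= 1")


# ---------------------------------------------------------------------------
# stages 2-3: interval-union merging


def merge_sample_tags(tags: Iterable[Tag]) -> List[ProtoTranscript]:
    """Merge one sample's tags into maximal runs of overlapping/abutting reads."""
    by_key: Dict[Key, List[Tag]] = defaultdict(list)
    sample_ids = set()
    for t in tags:
        by_key[(t.chrom, t.strand)].append(t)
        sample_ids.add(t.sample_id)
    if len(sample_ids) > 1:
        raise ValueError(f"merge_sample_tags expects one sample, got {sorted(sample_ids)}")
    out: List[ProtoTranscript] = []
    for (chrom, strand), group in sorted(by_key.items()):
        group.sort(key=lambda t: (t.start, t.end))
        cur_start, cur_end, cur_n = group[0].start, group[0].end, 1
        sid = group[0].sample_id
        for t in group[1:]:
            if t.start <= cur_end:  # overlap or abutment (half-open)
                cur_end = max(cur_end, t.end)
                cur_n += 1
            else:
                out.append(ProtoTranscript(chrom, strand, cur_start, cur_end, {sid: cur_n}))
                cur_start, cur_end, cur_n = t.start, t.end, 1
        out.append(ProtoTranscript(chrom, strand, cur_start, cur_end, {sid: cur_n}))
    return out


def merge_across_samples(per_sample: Sequence[Sequence[ProtoTranscript]]) -> List[ProtoTranscript]:
    """Union proto-transcripts from all samples, summing tag counts key-wise."""
    by_key: Dict[Key, List[ProtoTranscript]] = defaultdict(list)
    for protos in per_sample:
        for p in protos:
            by_key[(p.chrom, p.strand)].append(p)
    out: List[ProtoTranscript] = []
    for (chrom, strand), group in sorted(by_key.items()):
        group.sort(key=lambda p: (p.start, p.end))
        cur = ProtoTranscript(chrom, strand, group[0].start, group[0].end,
                              dict(group[0].tag_counts), group[0].gap_count)
        for p in group[1:]:
            if p.start <= cur.end:
                cur.end = max(cur.end, p.end)
                for sid, n in p.tag_counts.items():
                    cur.tag_counts[sid] = cur.tag_counts.get(sid, 0) + n
                cur.gap_count += p.gap_count
            else:
                out.append(cur)
                cur = ProtoTranscript(chrom, strand, p.start, p.end,
                                      dict(p.tag_counts), p.gap_count)
        out.append(cur)
    return out


# ---------------------------------------------------------------------------
# stage 4: the merge plane


def embed(proto: ProtoTranscript, params: AssemblyParams) -> MergePlanePoint:
    """Map a proto-transcript to its horizontal segment in the merge plane."""
    if proto.total_tags < 1:
        raise ValueError("cannot embed a proto-transcript with no tags")
    density = proto.total_tags / proto.length
    if params.per_sample_mean_density:
        density /= max(params.n_samples, 1)
    return MergePlanePoint(proto.chrom, proto.strand, proto.start, proto.end,
                           density * params.density_multiplier)


def plane_distance(a: MergePlanePoint, b: MergePlanePoint) -> float:
    """Euclidean distance between two horizontal segments in the merge plane.

    The x component is the genomic gap between ``a``'s right edge and
    ``b``'s left edge, clamped at zero for overlapping segments; the y
    component is the scaled-density difference.
    """
    if (a.chrom, a.strand) != (b.chrom, b.strand):
        raise ValueError("plane_distance requires the same chromosome and strand")
    if a.x_start > b.x_start:
        a, b = b, a
    dx = max(0, b.x_start - a.x_end)
    dy = abs(a.y - b.y)
    return math.hypot(dx, dy)


# ---------------------------------------------------------------------------
# stage 5: stitching


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        p = self.parent
        while p[i] != i:
            p[i] = p[p[i]]
            i = p[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _region_index(regions: List[Tuple[int, int]], start: int, end: int) -> int:
    """Index of the merged region fully containing [start, end), else -1."""
    i = bisect_right(regions, (start, float("inf"))) - 1
    if i >= 0 and regions[i][0] <= start and end <= regions[i][1]:
        return i
    return -1


def stitch(protos: Sequence[ProtoTranscript], params: AssemblyParams,
           gap_boost_regions: Optional[Regions] = None) -> List[Transcript]:
    """Connected-component stitching over the merge plane.

    An edge joins two proto-transcripts iff their plane distance is
    <= ``max_edge`` (inclusive).  When both lie inside the same merged
    gene-body region of ``gap_boost_regions``, the threshold for that pair
    is ``max_edge * gap_boost_factor``.  Components collapse to spanning
    intervals; overlapping intervals are re-merged; tag counts are summed.
    """
    by_key: Dict[Key, List[ProtoTranscript]] = defaultdict(list)
    for p in protos:
        by_key[(p.chrom, p.strand)].append(p)

    results: List[Transcript] = []
    for (chrom, strand), group in sorted(by_key.items()):
        group = sorted(group, key=lambda p: (p.start, p.end))
        regions = sorted((gap_boost_regions or {}).get((chrom, strand), []))
        intervals = _stitch_key(group, params, regions)
        if params.recursive_reembed:
            intervals = _reembed_fixpoint(chrom, strand, intervals, params, regions)
        for start, end, counts, gaps in intervals:
            results.append(Transcript("", chrom, strand, start, end, counts, gaps))

    results.sort(key=lambda t: (t.chrom, t.start, t.end, t.strand))
    for i, t in enumerate(results):
        t.id = f"T{i:06d}"
    return results


def _stitch_key(group: List[ProtoTranscript], params: AssemblyParams,
                regions: List[Tuple[int, int]],
                ) -> List[Tuple[int, int, Dict[str, int], int]]:
    n = len(group)
    if n == 0:
        return []
    ys = [embed(p, params).y for p in group]
    boost = params.gap_boost_factor if regions else 1.0
    max_reach = params.max_edge * boost
    uf = _UnionFind(n)
    for j in range(1, n):
        pj = group[j]
        for i in range(j - 1, -1, -1):
            pi = group[i]
            dx = pj.start - pi.end
            if dx > max_reach:
                break  # disjoint sorted intervals: ends are increasing
            eff = params.max_edge
            if regions:
                ri = _region_index(regions, pi.start, pi.end)
                if ri >= 0 and ri == _region_index(regions, pj.start, pj.end):
                    eff = params.max_edge * params.gap_boost_factor
            if math.hypot(max(dx, 0), ys[j] - ys[i]) <= eff:
                uf.union(i, j)

    members: Dict[int, List[int]] = defaultdict(list)
    for i in range(n):
        members[uf.find(i)].append(i)

    intervals: List[Tuple[int, int, Dict[str, int], int]] = []
    for idxs in members.values():
        idxs.sort()
        start = min(group[i].start for i in idxs)
        end = max(group[i].end for i in idxs)
        counts: Dict[str, int] = {}
        gaps = 0
        prev_end = None
        for i in idxs:
            p = group[i]
            for sid, c in p.tag_counts.items():
                counts[sid] = counts.get(sid, 0) + c
            gaps += p.gap_count
            if prev_end is not None and p.start > prev_end:
                gaps += 1
            prev_end = max(prev_end, p.end) if prev_end is not None else p.end
        intervals.append((start, end, counts, gaps))

    # components can interleave on the x axis: re-merge overlapping spans
    intervals.sort(key=lambda iv: (iv[0], iv[1]))
    merged: List[Tuple[int, int, Dict[str, int], int]] = []
    for iv in intervals:
        if merged and iv[0] < merged[-1][1]:
            s, e, c, g = merged[-1]
            for sid, n_ in iv[2].items():
                c[sid] = c.get(sid, 0) + n_
            merged[-1] = (s, max(e, iv[1]), c, g + iv[3])
        else:
            merged.append((iv[0], iv[1], dict(iv[2]), iv[3]))
    return merged


def _reembed_fixpoint(chrom: str, strand: str,
                      intervals: List[Tuple[int, int, Dict[str, int], int]],
                      params: AssemblyParams, regions: List[Tuple[int, int]],
                      ) -> List[Tuple[int, int, Dict[str, int], int]]:
    """Optional recursive mode: re-embed merged units and stitch again."""
    while True:
        protos = [ProtoTranscript(chrom, strand, s, e, dict(c), g)
                  for s, e, c, g in intervals]
        nxt = _stitch_key(protos, params, regions)
        if len(nxt) == len(intervals):
            return nxt
        intervals = nxt


def filter_noise(units: Sequence, n_samples: int,
                 params: Optional[AssemblyParams] = None) -> List:
    """Drop units with fewer than one tag per sample on average.

    Works on proto-transcripts or transcripts (anything with
    ``total_tags``); order is preserved.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if params is not None and not params.min_one_tag_per_sample:
        return list(units)
    return [u for u in units if u.total_tags >= n_samples]


# ---------------------------------------------------------------------------
# convenience driver


def assemble(tags_by_sample: Dict[str, Iterable[Tag]],
             params: Optional[AssemblyParams] = None,
             gap_boost_regions: Optional[Regions] = None,
             ) -> Tuple[List[Transcript], Dict[str, int]]:
    """Run stages 2-5 end to end; returns (transcripts, library sizes)."""
    params = params or AssemblyParams()
    per_sample: List[List[ProtoTranscript]] = []
    library_sizes: Dict[str, int] = {}
    for sid in sorted(tags_by_sample):
        tags = list(tags_by_sample[sid])
        library_sizes[sid] = len(tags)
        if tags:
            per_sample.append(merge_sample_tags(tags))
    merged = merge_across_samples(per_sample)
    transcripts = stitch(merged, params, gap_boost_regions)
    transcripts = filter_noise(transcripts, max(len(library_sizes), 1), params)
    for i, t in enumerate(transcripts):
        t.id = f"T{i:06d}"
    return transcripts, library_sizes
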