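"""Embedded persistence for incremental sample addition.

Per-sample merging (stage 2) depends only on that sample's tags, so a
store that keeps each sample's tags and stage-2 proto-transcripts can
absorb a new sample and rebuild from the cross-sample merge onward,
producing output identical to batch processing of the full sample set.
The optional on-disk form is a single SQLite file whose tables mirror the
in-memory model: samples, tags, proto_transcripts, transcripts.
"""

from __future__ import annotations

import sqlite3
from typing import Dict, Iterable, List, Optional

from .assembly import (AssemblyParams, Regions, filter_noise,
                       merge_across_samples, merge_sample_tags)
from .assembly import stitch as _stitch
from .model import ProtoTranscript, Tag, Transcript

_SCHEMA = """
CREATE TABLE IF NOT EXISTS samples (sample_id TEXT PRIMARY KEY, library_size INTEGER);
CREATE TABLE IF NOT EXISTS tags (
  sample_id TEXT, chrom TEXT, strand TEXT, start INTEGER, end INTEGER);
CREATE TABLE IF NOT EXISTS proto_transcripts (
  sample_id TEXT, chrom TEXT, strand TEXT, start INTEGER, end INTEGER,
  tag_count INTEGER, gap_count INTEGER);
"""


class TranscriptStore:
    """Holds per-sample tags and stage-2 protos; rebuilds transcripts on demand."""

    def __init__(self, params: Optional[AssemblyParams] = None) -> None:
        self.params = params or AssemblyParams()
        self.tags: Dict[str, List[Tag]] = {}
        self.protos: Dict[str, List[ProtoTranscript]] = {}

    @property
    def sample_ids(self) -> List[str]:
        return sorted(self.tags)

    @property
    def library_sizes(self) -> Dict[str, int]:
        return {sid: len(ts) for sid, ts in sorted(self.tags.items())}

    def add_sample(self, sample_id: str, tags: Iterable[Tag]) -> None:
        if sample_id in self.tags:
            raise ValueError(f"sample {sample_id!r} already in store")
        tag_list = list(tags)
        self.tags[sample_id] = tag_list
        self.protos[sample_id] = merge_sample_tags(tag_list) if tag_list else []

    def build(self, gap_boost_regions: Optional[Regions] = None) -> List[Transcript]:
        """Cross-sample merge, stitch and noise-filter the current samples."""
        merged = merge_across_samples([self.protos[sid] for sid in self.sample_ids])
        transcripts = _stitch(merged, self.params, gap_boost_regions)
        transcripts = filter_noise(transcripts, max(len(self.tags), 1), self.params)
        for i, t in enumerate(transcripts):
            t.id = f"T{i:06d}"
        return transcripts

    def all_tags(self) -> List[Tag]:
        out: List[Tag] = []
        for sid in self.sample_ids:
            out.extend(self.tags[sid])
        return out

    # -- persistence ---------------------------------------------------

    def save(self, path: str) -> None:
        con = sqlite3.connect(path)
        try:
            con.executescript(_SCHEMA)
            con.execute("DELETE FROM samples")
            con.execute("DELETE FROM tags")
            con.execute("DELETE FROM proto_transcripts")
            for sid in self.sample_ids:
                con.execute("INSERT INTO samples VALUES (?, ?)", (sid, len(self.tags[sid])))
                con.executemany(
                    "INSERT INTO tags VALUES (?, ?, ?, ?, ?)",
                    [(sid, t.chrom, t.strand, t.start, t.end) for t in self.tags[sid]])
                con.executemany(
                    "INSERT INTO proto_transcripts VALUES (?, ?, ?, ?, ?, ?, ?)",
                    [(sid, p.chrom, p.strand, p.start, p.end,
                      p.tag_counts.get(sid, 0), p.gap_count) for p in self.protos[sid]])
            con.commit()
        finally:
            con.close()

    @classmethod
    def load(cls, path: str, params: Optional[AssemblyParams] = None) -> "TranscriptStore":
        store = cls(params)
        con = sqlite3.connect(path)
        try:
            for (sid,) in con.execute("SELECT sample_id FROM samples ORDER BY sample_id"):
                tags = [Tag(c, s, a, b, sid) for c, s, a, b in con.execute(
                    "SELECT chrom, strand, start, end FROM tags WHERE sample_id = ?"
                    " ORDER BY chrom, strand, start, end", (sid,))]
                store.tags[sid] = tags
                store.protos[sid] = [
                    ProtoTranscript(c, s, a, b, {sid: n}, g) for c, s, a, b, n, g
                    in con.execute(
                        "SELECT chrom, strand, start, end, tag_count, gap_count"
                        " FROM proto_transcripts WHERE sample_id = ?"
                        " ORDER BY chrom, strand, start", (sid,))]
        finally:
            con.close()
        return store
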