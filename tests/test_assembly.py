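"""Merging, the 2D embedding, the stitch and its invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import grostitch as gs
from grostitch.assembly import AssemblyParams
from conftest import make_proto
from _oracles import brute_force_stitch, random_disjoint_protos


def tag(start, end, strand="+", sample="A", chrom="chr1"):
    return gs.Tag(chrom, strand, start, end, sample)


# ---------------------------------------------------------------------------
# stage 2-3 merging


@pytest.mark.parametrize("tags,expected", [
    # overlapping reads merge into one run
    ([tag(100, 136), tag(120, 156)], [(100, 156, 2)]),
    # disjoint reads stay separate
    ([tag(100, 136), tag(200, 236)], [(100, 136, 1), (200, 236, 1)]),
    # abutting half-open intervals share no base but form a gap-free run
    ([tag(100, 136), tag(136, 172)], [(100, 172, 2)]),
])
def test_merge_sample_tags(tags, expected):
    protos = gs.merge_sample_tags(tags)
    assert [(p.start, p.end, p.total_tags) for p in protos] == expected
    assert all(p.gap_count == 0 for p in protos)


def test_merge_sample_tags_handles_unsorted_input_and_strand_separation():
    tags = [tag(300, 336), tag(100, 136, strand="-"), tag(100, 136), tag(90, 126)]
    protos = gs.merge_sample_tags(tags)
    by_strand = {(p.strand, p.start, p.end): p.total_tags for p in protos}
    assert by_strand == {("+", 90, 136): 2, ("+", 300, 336): 1, ("-", 100, 136): 1}


def test_merge_sample_tags_union_of_bases_is_preserved():
    rng = np.random.default_rng(7)
    tags = [tag(int(s), int(s) + 36) for s in rng.integers(0, 5000, 200)]
    protos = gs.merge_sample_tags(tags)
    base_union = set()
    for t in tags:
        base_union.update(range(t.start, t.end))
    proto_union = set()
    for p in protos:
        proto_union.update(range(p.start, p.end))
    assert proto_union == base_union


def test_merge_sample_tags_rejects_mixed_samples():
    with pytest.raises(ValueError, match="one sample"):
        gs.merge_sample_tags([tag(0, 36, sample="A"), tag(50, 86, sample="B")])


def test_merge_across_samples_sums_counts_keywise():
    a = [make_proto(100, 200, 5, sample="A")]
    b = [make_proto(150, 250, 3, sample="B")]
    (merged,) = gs.merge_across_samples([a, b])
    assert (merged.start, merged.end) == (100, 250)
    assert merged.tag_counts == {"A": 5, "B": 3}


def test_merge_across_samples_single_sample_is_identity():
    a = [make_proto(100, 200, 5), make_proto(400, 500, 2)]
    merged = gs.merge_across_samples([a])
    assert [(p.start, p.end, p.tag_counts) for p in merged] == \
        [(p.start, p.end, p.tag_counts) for p in a]


def test_merge_across_samples_chain_overlap_collapses():
    lists = [[make_proto(0, 10, 1, sample="A")],
             [make_proto(8, 20, 1, sample="B")],
             [make_proto(18, 30, 1, sample="C")]]
    (merged,) = gs.merge_across_samples(lists)
    assert (merged.start, merged.end) == (0, 30)
    assert merged.total_tags == 3


# ---------------------------------------------------------------------------
# embedding and distance


def test_embed_density_multiplier_gloss():
    # one tag per density_multiplier bp scales to y = 1: a one-tag density
    # difference over that span weighs like a one-bp gap
    p = make_proto(0, 10_000, 1)
    assert gs.embed(p, AssemblyParams()).y == pytest.approx(1.0)


@pytest.mark.parametrize("length,tags_,dm,expected_y", [
    (100, 10, 10_000, 1000.0),
    (100, 10, 1, 0.1),
])
def test_embed_arithmetic(length, tags_, dm, expected_y):
    p = make_proto(0, length, tags_)
    params = AssemblyParams(density_multiplier=dm)
    assert gs.embed(p, params).y == pytest.approx(expected_y)


def test_plane_distance_cases():
    def point(xs, xe, y):
        return gs.MergePlanePoint("chr1", "+", xs, xe, y)

    # pure genomic gap
    assert gs.plane_distance(point(0, 100, 5.0), point(200, 300, 5.0)) == 100
    # x-overlap clamps dx to zero, leaving the density difference
    assert gs.plane_distance(point(0, 100, 3.0), point(50, 150, 7.0)) == 4
    # gap 100 with a density difference of 0.01 tags/bp at multiplier 10^4
    assert gs.plane_distance(point(0, 100, 100.0), point(200, 300, 200.0)) == \
        pytest.approx(math.sqrt(2) * 100)
    # symmetric after orientation
    assert gs.plane_distance(point(200, 300, 5.0), point(0, 100, 5.0)) == 100
    with pytest.raises(ValueError):
        gs.plane_distance(point(0, 100, 1.0),
                          gs.MergePlanePoint("chr1", "-", 0, 100, 1.0))


# ---------------------------------------------------------------------------
# stitching


def test_stitch_max_edge_boundary_is_inclusive():
    params = AssemblyParams(max_edge=500, density_multiplier=10_000)
    # equal densities so the plane distance is exactly the genomic gap
    near = [make_proto(0, 100, 1), make_proto(599, 699, 1)]       # distance 499
    far = [make_proto(0, 100, 1), make_proto(601, 701, 1)]        # distance 501
    exact = [make_proto(0, 100, 1), make_proto(600, 700, 1)]      # distance 500
    assert len(gs.stitch(near, params)) == 1
    assert len(gs.stitch(far, params)) == 2
    assert len(gs.stitch(exact, params)) == 1  # "less than or equal"


def test_stitch_chain_transitivity():
    params = AssemblyParams(max_edge=500)
    protos = [make_proto(0, 100, 1), make_proto(500, 600, 1),
              make_proto(1000, 1100, 1)]
    (t,) = gs.stitch(protos, params)  # a-b and b-c close, a-c far
    assert (t.start, t.end, t.total_tags) == (0, 1100, 3)


def test_stitch_density_separation_both_sides_of_boundary():
    # two dense blocks flanking a sparse gap: merged iff
    # sqrt(gap^2 + dy^2) <= max_edge
    params = AssemblyParams(max_edge=500, density_multiplier=10_000)

    def blocks(gap, c1, c2):
        return [make_proto(0, 1000, c1), make_proto(1000 + gap, 2000 + gap, c2)]

    # equal densities, gap exactly at threshold vs just beyond
    assert len(gs.stitch(blocks(500, 100, 100), params)) == 1
    assert len(gs.stitch(blocks(501, 100, 100), params)) == 2
    # gap 300 with dy = 300 -> distance 424 merges; dy = 500 -> 583 splits
    assert len(gs.stitch(blocks(300, 100, 70), params)) == 1
    assert len(gs.stitch(blocks(300, 100, 50), params)) == 2


def test_stitch_conserves_tags_and_covered_bases():
    rng = np.random.default_rng(11)
    protos = random_disjoint_protos(rng, 300)
    for me, dm in [(100, 1000), (500, 10_000), (5000, 100_000)]:
        out = gs.stitch(protos, AssemblyParams(max_edge=me, density_multiplier=dm))
        assert sum(t.total_tags for t in out) == sum(p.total_tags for p in protos)
        for p in protos:  # every proto base is inside exactly one transcript
            containing = [t for t in out if t.start <= p.start and p.end <= t.end]
            assert len(containing) == 1


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.integers(2, 60),
       st.sampled_from([50.0, 200.0, 500.0, 2000.0]),
       st.sampled_from([1_000.0, 10_000.0, 100_000.0]))
def test_stitch_matches_brute_force_oracle(seed, n, max_edge, dm):
    rng = np.random.default_rng(seed)
    protos = random_disjoint_protos(rng, n)
    params = AssemblyParams(max_edge=max_edge, density_multiplier=dm)
    ours = sorted((t.chrom, t.strand, t.start, t.end, t.total_tags)
                  for t in gs.stitch(protos, params))
    assert ours == brute_force_stitch(protos, max_edge, dm)


def test_stitch_monotone_coarsening_in_max_edge():
    rng = np.random.default_rng(5)
    protos = random_disjoint_protos(rng, 200)
    prev = None
    for me in (100, 250, 500, 1000, 2500, 5000):
        out = gs.stitch(protos, AssemblyParams(max_edge=me))
        if prev is not None:
            assert len(out) <= len(prev)
            # every finer transcript is contained in exactly one coarser one
            for t in prev:
                assert sum(1 for u in out
                           if u.start <= t.start and t.end <= u.end) == 1
        prev = out


def test_restitching_scenario_output_only_coarsens(default_scenario):
    # single-pass stitching is not an exact fixpoint (a merged component's
    # averaged density can newly reach a neighbour), but re-stitching the
    # output may only coarsen it, never split a called unit
    _, tags, _ = default_scenario
    transcripts, _ = gs.assemble(tags)
    params = AssemblyParams()
    reembedded = [gs.ProtoTranscript(t.chrom, t.strand, t.start, t.end,
                                     dict(t.tag_counts)) for t in transcripts]
    again = gs.stitch(reembedded, params)
    assert len(again) <= len(transcripts)
    for t in transcripts:
        assert sum(1 for u in again
                   if (u.chrom, u.strand) == (t.chrom, t.strand)
                   and u.start <= t.start and t.end <= u.end) == 1


def test_recursive_reembed_reaches_fixpoint():
    params = AssemblyParams(max_edge=100, density_multiplier=1.0,
                            recursive_reembed=True)
    rng = np.random.default_rng(3)
    protos = random_disjoint_protos(rng, 100)
    once = gs.stitch(protos, params)
    re_protos = [gs.ProtoTranscript(t.chrom, t.strand, t.start, t.end,
                                    dict(t.tag_counts)) for t in once]
    twice = gs.stitch(re_protos, params)
    assert [(t.start, t.end) for t in once] == [(t.start, t.end) for t in twice]


# ---------------------------------------------------------------------------
# noise filter


@pytest.mark.parametrize("total,n_samples,kept", [
    (2, 5, False),   # fewer than one tag per sample on average
    (5, 5, True),    # boundary: "fewer than" is strict
    (1, 1, True),    # with one sample nothing can be dropped
])
def test_filter_noise_threshold(total, n_samples, kept):
    p = make_proto(0, 100, total)
    out = gs.filter_noise([p], n_samples)
    assert (p in out) is kept


def test_filter_noise_respects_disable_switch():
    params = AssemblyParams(min_one_tag_per_sample=False)
    p = make_proto(0, 100, 1)
    assert gs.filter_noise([p], 5, params) == [p]


def test_params_validation():
    with pytest.raises(ValueError):
        AssemblyParams(max_edge=0)
    with pytest.raises(ValueError):
        AssemblyParams(density_multiplier=-1)
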