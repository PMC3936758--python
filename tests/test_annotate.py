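"""Overlap association, the classification cascade, coverage and reports."""

import numpy as np
import pytest

import grostitch as gs
from _oracles import brute_force_associations


def ann(start, end, strand="+", source="refseq", aid="NM_1", chrom="chr1"):
    return gs.AnnotationRecord(source, aid, chrom, strand, start, end)


def scored(tid, start, end, strand="+", count=1000, chrom="chr1", lib=100_000):
    t = gs.Transcript(tid, chrom, strand, start, end, {"S": count})
    gs.score_all([t], {"S": lib})
    return t


def test_associate_overlap_arithmetic_and_orientation():
    t = scored("T0", 100, 500)
    (sense,) = gs.associate([t], [ann(300, 900)])
    assert (sense.overlap_bp, sense.relative_strand) == (200, "sense")
    assert sense.fraction_of_annotation == pytest.approx(200 / 600)
    assert sense.fraction_of_transcript == pytest.approx(200 / 400)
    (anti,) = gs.associate([t], [ann(300, 900, strand="-")])
    assert (anti.overlap_bp, anti.relative_strand) == (200, "antisense")
    (less,) = gs.associate([t], [ann(300, 900, strand=".", source="peak")])
    assert less.relative_strand == "strandless"


def test_associate_min_overlap_threshold_and_disjoint():
    t = scored("T0", 100, 500)
    assert gs.associate([t], [ann(500, 900)]) == []  # abutting: zero overlap
    assert gs.associate([t], [ann(499, 900)], min_overlap=2) == []
    assert len(gs.associate([t], [ann(499, 900)], min_overlap=1)) == 1


def test_associate_matches_all_pairs_oracle():
    rng = np.random.default_rng(23)
    transcripts = []
    for i, s in enumerate(rng.integers(0, 500_000, 400)):
        transcripts.append(scored(f"T{i}", int(s), int(s) + int(rng.integers(50, 5000)),
                                  strand="+" if i % 2 else "-"))
    annotations = []
    for i, s in enumerate(rng.integers(0, 500_000, 400)):
        src = ("refseq", "ncrna", "peak")[i % 3]
        strand = ("+", "-", ".")[i % 3] if src == "peak" else ("+", "-")[i % 2]
        annotations.append(ann(int(s), int(s) + int(rng.integers(50, 5000)),
                               strand=strand, source=src, aid=f"A{i}"))
    ours = sorted((a.transcript_id, a.annotation_id, a.overlap_bp, a.relative_strand)
                  for a in gs.associate(transcripts, annotations))
    assert ours == brute_force_associations(transcripts, annotations)


# ---------------------------------------------------------------------------
# classification cascade


@pytest.fixture
def cascade_world():
    """One annotation landscape exercising every label in the taxonomy."""
    refseq = [ann(10_000, 20_000, aid="geneA"),               # active + gene
              ann(50_000, 60_000, strand="-", aid="geneB")]   # active - gene
    ncrna = [ann(30_000, 31_000, strand="+", source="ncrna", aid="nc1")]
    peaks = [gs.AnnotationRecord("peak", "p1", "chr1", ".", 100_000, 101_000)]
    return refseq, ncrna, peaks


def classify_one(t, refseq, ncrna, peaks, activators=()):
    ts = [t, *activators]
    gs.classify(ts, refseq, ncrna, peaks)
    return t.label


def test_cascade_labels(cascade_world):
    refseq, ncrna, peaks = cascade_world
    # activators: high-score sense transcripts making both genes "active"
    act_a = scored("actA", 10_000, 20_000, count=5000)
    act_b = scored("actB", 50_000, 60_000, strand="-", count=5000)
    acts = (act_a, act_b)

    # sense overlap covering >= half the gene
    assert classify_one(scored("t", 9_000, 16_000), *cascade_world, acts) == "refseq_major"
    # sense overlap covering < half
    assert classify_one(scored("t", 9_000, 12_000), *cascade_world, acts) == "refseq_minor"
    # ncRNA overlap
    assert classify_one(scored("t", 30_500, 32_000), *cascade_world, acts) == "ncrna"
    # antisense 5' end within 1 kb of the active TSS of geneA
    assert classify_one(scored("t", 8_500, 9_700, strand="-"), *cascade_world,
                        acts) == "paRNA"
    # antisense overlap with an active gene body, 5' end far from the TSS
    assert classify_one(scored("t", 14_000, 16_000, strand="-"), *cascade_world,
                        acts) == "antisense_body"
    # near a gene (sense, within 1 kb) without overlapping
    assert classify_one(scored("t", 20_300, 20_900), *cascade_world, acts) == \
        "proximal_other"
    # distal and overlapping the enhancer peak
    assert classify_one(scored("t", 100_200, 100_800), *cascade_world, acts) == "eRNA"
    # distal, 1.5 kb from the peak
    assert classify_one(scored("t", 102_500, 103_000), *cascade_world, acts) == \
        "near_enhancer"
    # distal, 3 kb from everything
    assert classify_one(scored("t", 110_000, 111_000), *cascade_world, acts) == \
        "distal_unlabeled"


def test_paRNA_requires_active_tss(cascade_world):
    refseq, ncrna, peaks = cascade_world
    # with no expressed sense transcript, the gene is inactive: the
    # would-be paRNA falls through to the proximal class
    t = scored("t", 8_500, 9_700, strand="-")
    gs.classify([t], refseq, ncrna, peaks)
    assert t.label == "proximal_other"


def test_sense_refseq_beats_ncrna_beats_antisense(cascade_world):
    refseq, _, peaks = cascade_world
    act = scored("act", 10_000, 20_000, count=5000)
    ncrna_on_gene = [ann(12_000, 13_000, strand="+", source="ncrna", aid="nc")]
    t = scored("t", 11_000, 19_000)
    gs.classify([t, act], refseq, ncrna_on_gene, peaks)
    assert t.label == "refseq_major"  # sense gene overlap wins over ncRNA
    anti = scored("t2", 12_100, 12_500, strand="-")
    gs.classify([anti, act], refseq, ncrna_on_gene, peaks)
    assert anti.label == "ncrna"  # ncRNA wins over antisense-body


def test_missing_peak_set_skips_enhancer_rules(cascade_world):
    refseq, ncrna, _ = cascade_world
    t = scored("t", 100_200, 100_800)
    gs.classify([t], refseq, ncrna, None)
    assert t.label == "distal_unlabeled"


def test_labels_stable_under_reordering_and_irrelevant_annotations(cascade_world):
    refseq, ncrna, peaks = cascade_world
    ts = [scored("a", 9_000, 16_000), scored("b", 100_200, 100_800),
          scored("c", 110_000, 111_000)]
    gs.classify(ts, refseq, ncrna, peaks)
    want = {t.id: t.label for t in ts}
    ts2 = [scored("c", 110_000, 111_000), scored("a", 9_000, 16_000),
           scored("b", 100_200, 100_800)]
    extra = refseq + [ann(5_000, 9_000, aid="other", chrom="chr9")]
    gs.classify(ts2, extra, ncrna, peaks)
    assert {t.id: t.label for t in ts2} == want


def test_classification_is_total_on_scenario(deep_scenario):
    _, tags, truth = deep_scenario
    trans, libs = gs.assemble(tags)
    gs.score_all(trans, libs)
    gs.classify(trans, truth.refflat, [], truth.enhancer_peaks)
    assert all(t.label in gs.model.CLASS_LABELS for t in trans)


def test_classify_requires_scores():
    t = gs.Transcript("T0", "chr1", "+", 0, 1000, {"S": 1})
    with pytest.raises(ValueError, match="scored"):
        gs.classify([t], [ann(0, 1000)])


# ---------------------------------------------------------------------------
# coverage and report


def test_coverage_fraction_simple_and_empty():
    t = scored("t", 10, 20)
    cov = gs.coverage_fraction([t], {"chr1": 100})
    assert cov == {"+": 0.10, "-": 0.0}
    assert gs.coverage_fraction([], {"chr1": 100}) == {"+": 0.0, "-": 0.0}


def test_coverage_fraction_unknown_chrom_errors():
    t = scored("t", 10, 20, chrom="chr1")
    with pytest.raises(ValueError, match="unknown"):
        gs.coverage_fraction([t], {"chr2": 100})


def test_coverage_recovers_planted_fraction():
    # plant known coverage and call it back perfectly
    genome = {"c": 100_000}
    ts = [scored(f"t{i}", s, s + 5_000, chrom="c")
          for i, s in enumerate(range(0, 50_000, 10_000))]
    cov = gs.coverage_fraction(ts, genome)
    assert cov["+"] == pytest.approx(0.25)


def test_category_report_partitions_to_one(deep_scenario):
    _, tags, truth = deep_scenario
    trans, libs = gs.assemble(tags)
    gs.score_all(trans, libs)
    gs.classify(trans, truth.refflat, [], truth.enhancer_peaks)
    report = gs.category_report(trans)
    assert report["count"].sum() == len(trans)
    assert report["fraction"].sum() == pytest.approx(1.0)
    for parent, grp in report.groupby("parent"):
        if grp["count"].sum():
            assert grp["fraction_of_parent"].sum() == pytest.approx(1.0)


def test_planted_features_land_in_expected_categories(deep_scenario):
    # 20 genes, 10 eRNA pairs (2 strands each), 5 paRNAs at high depth
    _, tags, truth = deep_scenario
    trans, libs = gs.assemble(tags)
    gs.score_all(trans, libs)
    gs.classify(trans, truth.refflat, [], truth.enhancer_peaks)
    counts = gs.category_report(trans).set_index("label")["count"]
    strong = [t for t in trans if t.score() >= 1]
    strong_counts = {}
    for t in strong:
        strong_counts[t.label] = strong_counts.get(t.label, 0) + 1
    assert strong_counts.get("refseq_major", 0) == 20
    assert strong_counts.get("eRNA", 0) == 20
    assert strong_counts.get("paRNA", 0) == 5
    assert counts["refseq_major"] >= 20
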