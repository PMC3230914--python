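"""Transcript caller: association, prediction rules, overlap resolution,
classification, categorization, annotation comparison and TFBS scanning."""

from __future__ import annotations

import pytest

from ncscribe.io import GeneAnnotation, Genome, NcRNALocus
from ncscribe.sidd import SiddSite
from ncscribe.terminators import TAIL_LENGTH, Terminator
from ncscribe.transcripts import (AnnotatedRNA, CallerParameters,
                                  TranscriptPrediction, associate_features,
                                  categorize_transcript, classify_loci,
                                  compare_to_annotation, join_same_strand,
                                  predict_from_site, resolve_antistrand,
                                  scan_tfbs)


def term(strand: str, tail_end: int, conf: int) -> Terminator:
    if strand == "+":
        extent = (tail_end - TAIL_LENGTH - 23, tail_end - TAIL_LENGTH)
    else:
        extent = (tail_end + TAIL_LENGTH, tail_end + TAIL_LENGTH + 23)
    return Terminator(strand=strand, confidence=conf, source="parsed",
                      tail_end=tail_end, _extent=extent)


def tx(tid, start, end, strand, site=None, terminator=None, locus="L"):
    return TranscriptPrediction(
        id=tid, start=start, end=end, strand=strand, source_locus=locus,
        sidd_site=site or SiddSite(start=start if strand == "+" else end - 40,
                                   end=start + 40 if strand == "+" else end,
                                   min_energy=3.0),
        terminator=terminator)


# ---------------------------------------------------------------------------
# association


def test_sidd_site_association_uses_flank_overlap():
    locus = NcRNALocus(id="L", start=100, end=300)
    inside = SiddSite(start=90, end=120, min_energy=3.0)
    outside = SiddSite(start=420, end=460, min_energy=3.0)
    associate_features([locus], [inside, outside], [], flank=0)
    assert locus.sidd_sites == [inside]
    associate_features([locus], [outside], [], flank=150)
    assert locus.sidd_sites == [outside]


def test_terminator_association_extends_downstream_only():
    locus = NcRNALocus(id="L", start=100, end=300)
    near_plus = term("+", 365, 80)     # stem 327..350: within +100 downstream
    far_plus = term("+", 815, 80)      # stem 777..800: 500 nt past the locus
    upstream_minus = term("-", 35, 80)  # stem 50..73: upstream flank, - strand
    associate_features([locus], [], [near_plus, far_plus, upstream_minus],
                       flank=100)
    assert locus.terminators == [near_plus, upstream_minus]


def test_empty_features_classify_everything_non_transcript():
    loci = [NcRNALocus(id="L1", start=100, end=300)]
    associate_features(loci, [], [], flank=100)
    cls = classify_loci(loci, [])
    assert cls[0].verdict == "non_transcript"


# ---------------------------------------------------------------------------
# per-site prediction branches (plus strand variants live in the conflict
# suite; here the minus strand and scan-cap behaviour are exercised)


def test_minus_strand_prediction_runs_downhill():
    locus = NcRNALocus(id="L", start=100, end=700)
    site = SiddSite(start=600, end=640, min_energy=3.0)
    t = predict_from_site(locus, site, "-",
                          [term("-", 250, 80), term("-", 420, 90)], [])
    # downstream on '-' means decreasing coordinates; 420 is reached first
    assert (t.start, t.end, t.strand) == (420, 640, "-")
    assert t.term_confidence == 90


def test_fallback_scan_reaches_beyond_flank_up_to_cap():
    locus = NcRNALocus(id="L", start=100, end=400)
    site = SiddSite(start=120, end=160, min_energy=3.0)
    beyond_flank = term("+", 900, 60)   # past locus+flank, inside the 1 kb cap
    t = predict_from_site(locus, site, "+", [beyond_flank], [])
    assert (t.start, t.end) == (120, 900)
    past_cap = term("+", 1450, 60)
    t2 = predict_from_site(locus, site, "+", [past_cap], [])
    assert t2 is not None and t2.end == locus.end  # cap excluded it: fallback


def test_tie_between_equal_confidences_takes_the_nearest():
    locus = NcRNALocus(id="L", start=100, end=700)
    site = SiddSite(start=100, end=140, min_energy=3.0)
    t = predict_from_site(locus, site, "+",
                          [term("+", 400, 70), term("+", 600, 70)], [])
    assert t.end == 400


# ---------------------------------------------------------------------------
# joining and antistrand resolution basics (rule branches: conflict suite)


def test_join_leaves_different_strands_and_disjoint_intervals_alone():
    a = tx("a", 100, 400, "+", terminator=term("+", 400, 80))
    b = tx("b", 100, 400, "-", terminator=term("-", 100, 70))
    c = tx("c", 500, 600, "+", terminator=term("+", 600, 60))
    out = join_same_strand([a, b, c])
    assert sorted((t.start, t.end, t.strand) for t in out) == [
        (100, 400, "+"), (100, 400, "-"), (500, 600, "+")]


def test_join_merges_overlaps_keeping_best_terminator_and_upstream_site():
    s1 = SiddSite(start=100, end=140, min_energy=3.0)
    s2 = SiddSite(start=350, end=380, min_energy=2.0)
    a = tx("a", 100, 400, "+", site=s1, terminator=term("+", 400, 60))
    b = tx("b", 350, 600, "+", site=s2, terminator=term("+", 600, 90))
    (merged,) = join_same_strand([a, b])
    assert (merged.start, merged.end) == (100, 600)
    assert merged.term_confidence == 90
    assert merged.sidd_site is s1


def test_resolution_without_opposite_overlaps_is_identity():
    a = tx("a", 100, 400, "+", terminator=term("+", 400, 80))
    b = tx("b", 500, 700, "-", terminator=term("-", 500, 70))
    out = resolve_antistrand([a, b], [])
    assert {(t.start, t.end) for t in out} == {(100, 400), (500, 700)}


# ---------------------------------------------------------------------------
# categorization


GENES = [GeneAnnotation(start=200, end=500, strand="+", synonym="gp"),
         GeneAnnotation(start=800, end=1100, strand="-", synonym="gm")]


@pytest.mark.parametrize("start,end,strand,expected", [
    (1300, 1500, "+", "intergenic"),
    (700, 900, "+", "antisense"),       # overlaps gm on the opposite strand
    (400, 600, "+", "sense_overlap"),   # partial same-strand overlap
    (100, 900, "+", "sense_overlap"),   # both strands: sense takes precedence
    (450, 900, "-", "sense_overlap"),
])
def test_transcript_categories(start, end, strand, expected):
    assert categorize_transcript(tx("t", start, end, strand), GENES) == expected


def test_every_transcript_gets_exactly_one_category(pipeline_run):
    _, result = pipeline_run
    cats = [t.category for t in result.transcripts]
    assert all(c in ("antisense", "sense_overlap", "intergenic") for c in cats)
    total = sum(sum(1 for c in cats if c == k)
                for k in ("antisense", "sense_overlap", "intergenic"))
    assert total == len(result.transcripts)


# ---------------------------------------------------------------------------
# comparison to annotation


def test_compare_to_annotation_statuses():
    known = [AnnotatedRNA(id="k_same", start=100, end=200, strand="+"),
             AnnotatedRNA(id="k_wrong", start=500, end=600, strand="+"),
             AnnotatedRNA(id="k_miss", start=900, end=980, strand="+")]
    preds = [tx("t1", 100, 200, "+"),
             tx("t2", 480, 620, "-"),
             tx("t3", 2000, 2100, "+")]
    report = compare_to_annotation(preds, known, min_cov=0.5)
    status = dict(zip(report.known["id"], report.known["status"]))
    assert status == {"k_same": "matched_same_strand",
                      "k_wrong": "matched_wrong_strand",
                      "k_miss": "unmatched"}
    assert report.novel_transcripts == ["t3"]


def test_compare_to_annotation_coverage_threshold():
    known = [AnnotatedRNA(id="k", start=100, end=299, strand="+")]
    barely = [tx("t", 200, 400, "+")]   # covers exactly half
    short = [tx("t", 251, 400, "+")]    # covers under half
    assert compare_to_annotation(barely, known).counts[
        "matched_same_strand"] == 1
    assert compare_to_annotation(short, known).counts["unmatched"] == 1


# ---------------------------------------------------------------------------
# TFBS scanning


def test_tfbs_forward_hit_coordinates():
    g = Genome(id="x", seq="CCCCTTGACACCCC")
    (hit,) = scan_tfbs(g, ["TTGACA"])
    assert (hit.start, hit.end, hit.strand, hit.match) == (5, 10, "+", "TTGACA")


def test_tfbs_reverse_complement_hit_mapped_back():
    # TTGACA only as reverse complement: forward carries TGTCAA
    g = Genome(id="x", seq="GGGGTGTCAAGGGG")
    (hit,) = scan_tfbs(g, {"sig70": "TTGACA"})
    assert (hit.start, hit.end, hit.strand) == (5, 10, "-")
    assert hit.match == "TTGACA"


def test_tfbs_empty_pattern_list_and_bad_pattern():
    g = Genome(id="x", seq="ACGTACGT")
    assert scan_tfbs(g, []) == []
    with pytest.raises(ValueError, match="bad"):
        scan_tfbs(g, {"bad": "("})
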