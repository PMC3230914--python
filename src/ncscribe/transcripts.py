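"""Integration of SIDD sites and terminators into transcript predictions.

A candidate ncRNA locus (e.g. from a comparative structural screen) has no
strand and only approximate boundaries.  The caller anchors a transcript 5'
end in each SIDD site associated with the locus — SIDD sites are strandless,
so both strands are attempted — and extends downstream to a terminator:

1. the first *high-confidence* terminator (confidence >= 76) encountered
   downstream stops the transcript immediately;
2. failing that, the highest-confidence downstream terminator is used
   (ties resolved towards the nearest);
3. with no terminator at all, the transcript runs to the locus boundary,
   but only when the SIDD site cannot be attributed to a protein-coding
   gene's promoter region.

Same-strand overlapping predictions are then joined; opposite-strand
overlaps are resolved in favour of the better terminator, the weaker
prediction being trimmed to a nearer terminator or discarded.  Finally each
locus is classified transcribed / not transcribed and each transcript
categorized as antisense, sense-overlap or intergenic relative to the
protein-coding annotation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

from .io import GeneAnnotation, Genome, NcRNALocus
from .sidd import SiddSite
from .terminators import HIGH_CONFIDENCE, Terminator

__all__ = [
    "CallerParameters",
    "TranscriptPrediction",
    "LocusClassification",
    "TfbsHit",
    "AnnotatedRNA",
    "MatchReport",
    "associate_features",
    "predict_from_site",
    "predict_transcripts",
    "join_same_strand",
    "resolve_antistrand",
    "call_transcripts",
    "classify_loci",
    "categorize_transcript",
    "compare_to_annotation",
    "scan_tfbs",
]


@dataclass(frozen=True)
class CallerParameters:
    """Tunables of the transcript decision procedure (all in nt except
    confidences)."""

    high_confidence: int = HIGH_CONFIDENCE   # immediate-stop threshold
    flank: int = 100                         # locus extension for association
    downstream_cap: int = 1000               # genome-wide fallback scan reach
    gene_upstream_margin: int = 150          # SIDD-site gene attribution (U)


@dataclass
class TranscriptPrediction:
    """A strand-specific predicted ncRNA transcript.

    The 5' extremity lies inside the anchoring SIDD site; the 3' extremity
    equals the terminator's tail end, or the locus boundary when no
    terminator exists (``terminator is None``).
    """

    id: str
    start: int
    end: int
    strand: str
    source_locus: str
    sidd_site: SiddSite
    terminator: Optional[Terminator] = None
    category: Optional[str] = None
    merged_from: tuple = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"transcript {self.id}: start > end")

    @property
    def term_confidence(self) -> Optional[int]:
        return self.terminator.confidence if self.terminator else None

    @property
    def source_loci(self) -> tuple:
        return (self.source_locus,) + self.merged_from

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class LocusClassification:
    locus_id: str
    verdict: str                      # "transcript" | "non_transcript"
    transcripts: tuple = ()

    def __post_init__(self) -> None:
        if (self.verdict == "transcript") != bool(self.transcripts):
            raise ValueError("verdict inconsistent with transcript list")


@dataclass(frozen=True)
class TfbsHit:
    pattern_id: str
    start: int
    end: int
    strand: str
    match: str


@dataclass(frozen=True)
class AnnotatedRNA:
    """A known ncRNA annotation used for benchmarking predictions."""

    id: str
    start: int
    end: int
    strand: str


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


# ---------------------------------------------------------------------------
# feature association


def associate_features(loci: Sequence[NcRNALocus], sidd_sites: Sequence[SiddSite],
                       terminators: Sequence[Terminator],
                       flank: int = 100) -> Sequence[NcRNALocus]:
    """Attach SIDD sites and terminators to the loci they may serve.

    A (strandless) SIDD site is associated when it overlaps the locus
    extended by ``flank`` nt on both ends; a terminator when its stem-loop
    overlaps the locus extended by ``flank`` nt downstream on the
    terminator's strand only.
    """
    for locus in loci:
        locus.sidd_sites = [
            s for s in sidd_sites
            if _overlap(s.start, s.end, locus.start - flank, locus.end + flank)
        ]
        locus.terminators = []
        for t in terminators:
            lo = locus.start if t.strand == "+" else locus.start - flank
            hi = locus.end + flank if t.strand == "+" else locus.end
            if _overlap(t.start, t.end, lo, hi):
                locus.terminators.append(t)
    return loci


# ---------------------------------------------------------------------------
# per-site prediction


def _downstream_candidates(site: SiddSite, strand: str,
                           terminators: Iterable[Terminator],
                           lo: int, hi: int) -> list[Terminator]:
    """Terminators on ``strand`` strictly downstream of ``site`` whose tail
    ends inside [lo, hi], ordered by increasing downstream distance."""
    out = []
    for t in terminators:
        if t.strand != strand:
            continue
        if strand == "+":
            if t.start >= site.start and t.tail_end > site.end and lo <= t.tail_end <= hi:
                out.append(t)
        else:
            if t.end <= site.end and t.tail_end < site.start and lo <= t.tail_end <= hi:
                out.append(t)
    out.sort(key=lambda t: t.tail_end if strand == "+" else -t.tail_end)
    return out


def _select_terminator(cands: list[Terminator],
                       high_confidence: int) -> Optional[Terminator]:
    for t in cands:  # downstream order: first high-confidence wins
        if t.confidence >= high_confidence:
            return t
    if not cands:
        return None
    # fallback: best confidence, ties towards the nearest (list order)
    return max(cands, key=lambda t: t.confidence)


def _site_attributable_to_gene(site: SiddSite, strand: str,
                               genes: Iterable[GeneAnnotation],
                               margin: int) -> bool:
    """Could this SIDD site be the promoter region of a coding gene?

    True when any part of the site lies within ``margin`` nt upstream of a
    same-strand gene start.
    """
    for g in genes:
        if g.strand != strand:
            continue
        if strand == "+":
            lo, hi = g.start - margin, g.start - 1
        else:
            lo, hi = g.end + 1, g.end + margin
        if _overlap(site.start, site.end, lo, hi):
            return True
    return False


def predict_from_site(locus: NcRNALocus, site: SiddSite, strand: str,
                      terminators: Sequence[Terminator],
                      genes: Sequence[GeneAnnotation],
                      params: CallerParameters | None = None,
                      transcript_id: str = "") -> Optional[TranscriptPrediction]:
    """Predict one transcript anchored at ``site`` on ``strand``.

    Terminators are first sought with their tail inside the locus extended
    downstream by the association flank; when that window holds none, the
    scan widens to ``downstream_cap`` nt past the locus.  Without any
    terminator the transcript runs to the locus boundary, unless the SIDD
    site is attributable to a protein-coding gene on the tested strand.
    """
    params = params or CallerParameters()
    if strand == "+":
        near_lo, near_hi = site.end + 1, locus.end + params.flank
        far_lo, far_hi = site.end + 1, locus.end + params.downstream_cap
    else:
        near_lo, near_hi = locus.start - params.flank, site.start - 1
        far_lo, far_hi = locus.start - params.downstream_cap, site.start - 1
    cands = _downstream_candidates(site, strand, terminators, near_lo, near_hi)
    if not cands:
        cands = _downstream_candidates(site, strand, terminators, far_lo, far_hi)
    chosen = _select_terminator(cands, params.high_confidence)

    if chosen is not None:
        if strand == "+":
            start, end = site.start, chosen.tail_end
        else:
            start, end = chosen.tail_end, site.end
    else:
        if _site_attributable_to_gene(site, strand, genes,
                                      params.gene_upstream_margin):
            return None
        if strand == "+":
            start, end = site.start, locus.end
        else:
            start, end = locus.start, site.end
    if start > end:
        return None
    return TranscriptPrediction(id=transcript_id or f"{locus.id}_t",
                                start=start, end=end, strand=strand,
                                source_locus=locus.id, sidd_site=site,
                                terminator=chosen)


def predict_transcripts(loci: Sequence[NcRNALocus],
                        terminators: Sequence[Terminator],
                        genes: Sequence[GeneAnnotation],
                        params: CallerParameters | None = None
                        ) -> list[TranscriptPrediction]:
    """Raw per-(locus, site, strand) predictions, before overlap resolution."""
    params = params or CallerParameters()
    out = []
    for locus in loci:
        k = 0
        for site in locus.sidd_sites:
            for strand in "+-":
                t = predict_from_site(locus, site, strand, terminators, genes,
                                      params,
                                      transcript_id=f"{locus.id}_t{k + 1}")
                if t is not None:
                    k += 1
                    t.id = f"{locus.id}_t{k}"
                    out.append(t)
    return out


# ---------------------------------------------------------------------------
# overlap resolution


def _conf(t: TranscriptPrediction) -> int:
    return t.term_confidence if t.term_confidence is not None else -1


def join_same_strand(transcripts: Sequence[TranscriptPrediction]
                     ) -> list[TranscriptPrediction]:
    """Merge overlapping same-strand predictions.

    The merged record keeps the higher-confidence terminator and the more
    upstream SIDD site, and its boundaries are re-derived from those
    anchors: the 5' end is the most upstream 5' extremity, the 3' end the
    kept terminator's tail end (or the union boundary when no prediction
    has a terminator).  This keeps the boundary-anchoring invariant intact
    when a weaker prediction reaches past the best terminator.  Merged-in
    locus ids are retained for locus classification.
    """
    out: list[TranscriptPrediction] = []
    for strand in "+-":
        group = sorted((t for t in transcripts if t.strand == strand),
                       key=lambda t: (t.start, t.end, t.id))
        current: Optional[TranscriptPrediction] = None
        for t in group:
            if current is None:
                current = t
                continue
            if t.start <= current.end:  # overlap: merge
                upstream = current if strand == "+" else \
                    max((current, t), key=lambda u: u.end)
                best_term = max((current, t), key=_conf)
                site = (min((current.sidd_site, t.sidd_site),
                            key=lambda s: s.start) if strand == "+" else
                        max((current.sidd_site, t.sidd_site),
                            key=lambda s: s.end))
                if strand == "+":
                    start = min(current.start, t.start)
                    end = (best_term.terminator.tail_end
                           if best_term.terminator
                           else max(current.end, t.end))
                else:
                    end = max(current.end, t.end)
                    start = (best_term.terminator.tail_end
                             if best_term.terminator
                             else min(current.start, t.start))
                merged_from = tuple(dict.fromkeys(
                    current.source_loci + t.source_loci))
                primary = upstream.source_locus
                current = TranscriptPrediction(
                    id=upstream.id, start=start, end=end, strand=strand,
                    source_locus=primary, sidd_site=site,
                    terminator=best_term.terminator,
                    merged_from=tuple(l for l in merged_from if l != primary))
            else:
                out.append(current)
                current = t
        if current is not None:
            out.append(current)
    out.sort(key=lambda t: (t.start, t.end, t.strand))
    return out


def _alternative_terminator(t: TranscriptPrediction, keeper: TranscriptPrediction,
                            terminators: Sequence[Terminator]) -> Optional[Terminator]:
    """Nearest same-strand terminator downstream of t's SIDD site whose tail
    removes the overlap with ``keeper``."""
    site = t.sidd_site
    best: Optional[Terminator] = None
    for term in terminators:
        if term.strand != t.strand:
            continue
        if t.strand == "+":
            ok = (term.start >= site.start and term.tail_end > site.end
                  and term.tail_end < keeper.start)
            nearer = best is None or term.tail_end < best.tail_end
        else:
            ok = (term.end <= site.end and term.tail_end < site.start
                  and term.tail_end > keeper.end)
            nearer = best is None or term.tail_end > best.tail_end
        if ok and nearer:
            best = term
    return best


def resolve_antistrand(transcripts: Sequence[TranscriptPrediction],
                       terminators: Sequence[Terminator]
                       ) -> list[TranscriptPrediction]:
    """Remove opposite-strand overlaps, keeping the better terminator.

    For each overlapping +/- pair the prediction with the higher terminator
    confidence survives unchanged (ties: the longer transcript, then the
    plus strand).  The other is re-anchored to the nearest terminator that
    clears the overlap, or discarded when none exists.
    """
    pool = sorted(transcripts, key=lambda t: (t.start, t.end, t.strand))
    while True:
        clash = None
        for i, a in enumerate(pool):
            for b in pool[i + 1:]:
                if b.start > a.end:
                    break
                if a.strand != b.strand and _overlap(a.start, a.end,
                                                     b.start, b.end):
                    clash = (a, b)
                    break
            if clash:
                break
        if clash is None:
            return pool
        a, b = clash
        keep, lose = sorted(
            (a, b), key=lambda t: (_conf(t), len(t), t.strand == "+"),
            reverse=True)
        alt = _alternative_terminator(lose, keep, terminators)
        pool.remove(lose)
        if alt is not None:
            if lose.strand == "+":
                trimmed = replace(lose, end=alt.tail_end, terminator=alt)
            else:
                trimmed = replace(lose, start=alt.tail_end, terminator=alt)
            pool.append(trimmed)
            pool.sort(key=lambda t: (t.start, t.end, t.strand))


def call_transcripts(loci: Sequence[NcRNALocus],
                     sidd_sites: Sequence[SiddSite],
                     terminators: Sequence[Terminator],
                     genes: Sequence[GeneAnnotation],
                     params: CallerParameters | None = None
                     ) -> tuple[list[TranscriptPrediction], list[LocusClassification]]:
    """Full decision procedure: associate, predict, join, resolve, classify,
    categorize."""
    params = params or CallerParameters()
    associate_features(loci, sidd_sites, terminators, flank=params.flank)
    raw = predict_transcripts(loci, terminators, genes, params)
    joined = join_same_strand(raw)
    final = resolve_antistrand(joined, terminators)
    for t in final:
        t.category = categorize_transcript(t, genes)
    return final, classify_loci(loci, final)


# ---------------------------------------------------------------------------
# classification / categorization


def classify_loci(loci: Sequence[NcRNALocus],
                  transcripts: Sequence[TranscriptPrediction]
                  ) -> list[LocusClassification]:
    """A locus is a transcript iff >= 1 surviving prediction originated
    from it (including predictions merged across loci)."""
    by_locus: dict[str, list[TranscriptPrediction]] = {}
    for t in transcripts:
        for lid in t.source_loci:
            by_locus.setdefault(lid, []).append(t)
    out = []
    for locus in loci:
        ts = tuple(by_locus.get(locus.id, ()))
        out.append(LocusClassification(
            locus_id=locus.id,
            verdict="transcript" if ts else "non_transcript",
            transcripts=ts))
    return out


def categorize_transcript(t: TranscriptPrediction,
                          genes: Sequence[GeneAnnotation]) -> str:
    """antisense / sense_overlap / intergenic relative to coding genes.

    Sense overlap takes precedence when a transcript overlaps genes on both
    strands.
    """
    sense = antisense = False
    for g in genes:
        if _overlap(t.start, t.end, g.start, g.end):
            if g.strand == t.strand:
                sense = True
            else:
                antisense = True
    if sense:
        return "sense_overlap"
    if antisense:
        return "antisense"
    return "intergenic"


# ---------------------------------------------------------------------------
# benchmarking against known annotation


@dataclass
class MatchReport:
    """Per-annotation match status plus unexplained predictions."""

    known: pd.DataFrame           # id, start, end, strand, status
    novel_transcripts: list[str]  # ids of putative-novel predictions

    @property
    def counts(self) -> dict:
        c = self.known["status"].value_counts().to_dict()
        c.setdefault("matched_same_strand", 0)
        c.setdefault("matched_wrong_strand", 0)
        c.setdefault("unmatched", 0)
        c["putative_novel"] = len(self.novel_transcripts)
        return c


def compare_to_annotation(transcripts: Sequence[TranscriptPrediction],
                          known: Sequence[AnnotatedRNA],
                          min_cov: float = 0.5) -> MatchReport:
    """Match predictions to annotated ncRNAs with wrong-strand accounting.

    A known feature is matched on the same strand when a same-strand
    transcript covers at least ``min_cov`` of it; matched on the wrong
    strand when only an opposite-strand transcript does; unmatched
    otherwise.  Transcripts explaining no known feature are putative novel.
    """
    rows = []
    explained: set[str] = set()
    for k in known:
        klen = k.end - k.start + 1
        same = wrong = False
        for t in transcripts:
            cov = _overlap(t.start, t.end, k.start, k.end) / klen
            if cov >= min_cov:
                if t.strand == k.strand:
                    same = True
                else:
                    wrong = True
                explained.add(t.id)
        status = ("matched_same_strand" if same
                  else "matched_wrong_strand" if wrong else "unmatched")
        rows.append((k.id, k.start, k.end, k.strand, status))
    df = pd.DataFrame(rows, columns=["id", "start", "end", "strand", "status"])
    novel = [t.id for t in transcripts if t.id not in explained]
    return MatchReport(known=df, novel_transcripts=novel)


# ---------------------------------------------------------------------------
# TFBS pattern scan


def scan_tfbs(genome: Genome, patterns) -> list[TfbsHit]:
    """Scan both strands for regular-expression TFBS patterns.

    ``patterns`` may be a mapping ``{id: regex}`` or an iterable of regex
    strings (auto-named ``pattern_<k>``).  Matches are the non-overlapping
    leftmost ones on each strand; minus-strand hits are found on the
    reverse complement and mapped back to forward coordinates.
    """
    if isinstance(patterns, dict):
        items = list(patterns.items())
    else:
        items = [(f"pattern_{i}", p) for i, p in enumerate(patterns, start=1)]
    hits: list[TfbsHit] = []
    n = len(genome)
    rc = genome.revcomp()
    for pid, pat in items:
        try:
            cre = re.compile(pat)
        except re.error as exc:
            raise ValueError(f"invalid TFBS pattern {pid!r}: {exc}") from None
        for m in cre.finditer(genome.seq):
            if m.end() > m.start():
                hits.append(TfbsHit(pattern_id=pid, start=m.start() + 1,
                                    end=m.end(), strand="+", match=m.group()))
        for m in cre.finditer(rc):
            if m.end() > m.start():
                hits.append(TfbsHit(pattern_id=pid, start=n - m.end() + 1,
                                    end=n - m.start(), strand="-",
                                    match=m.group()))
    hits.sort(key=lambda h: (h.start, h.end, h.strand, h.pattern_id))
    return hits
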