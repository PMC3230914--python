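"""Rho-independent (intrinsic) terminator detection and scoring.

Intrinsic bacterial terminators are RNA stem-loops followed by a U-rich
tail; the weak rU:dA hybrid under the paused polymerase promotes transcript
release.  This module provides

* an internal detector/scorer: inverted repeats (4-20 bp stems, G:C / A:T /
  G:U-wobble pairs, at most one internal mismatch, 3-13 nt loops) are
  enumerated on both strands and scored for stem strength, loop geometry
  and tail U-richness; the three part scores are combined into a 0-100
  confidence through a logistic map.  The scorer is a transparent surrogate
  with documented coefficients, not a numerical clone of any external tool.
* a parser for externally produced terminator prediction files (TransTermHP
  style ``TERM`` lines), so users who prefer that program's exact scores
  can feed them straight into the transcript caller.

Confidence conventions used downstream: predictions with confidence >= 76
count as *high confidence* (they stop transcript extension immediately);
the default reporting threshold is 50.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .io import FormatError, Genome

__all__ = [
    "HairpinConstraints",
    "ScoringCoefficients",
    "Hairpin",
    "Terminator",
    "HIGH_CONFIDENCE",
    "DEFAULT_CONFIDENCE_THRESHOLD",
    "find_hairpins",
    "score_terminator",
    "find_terminators",
    "read_transterm_output",
    "confidence_from_scores",
]

HIGH_CONFIDENCE = 76
DEFAULT_CONFIDENCE_THRESHOLD = 50

TAIL_LENGTH = 15

# pair weights used for stem scoring
_PAIR_WEIGHT = {("G", "C"): 3, ("C", "G"): 3,
                ("A", "T"): 2, ("T", "A"): 2,
                ("G", "T"): 1, ("T", "G"): 1}
MISMATCH_PENALTY = -3


@dataclass(frozen=True)
class HairpinConstraints:
    stem_min: int = 4
    stem_max: int = 20
    loop_min: int = 3
    loop_max: int = 13
    max_internal_mismatches: int = 1


@dataclass(frozen=True)
class ScoringCoefficients:
    """Logistic-map coefficients: conf = 100 sigma(c0 + c1 s + c2 l + c3 t).

    Calibrated once on planted-fixture versus background score
    distributions (see scripts/calibrate_terminators.py): a perfect >= 8 bp
    G:C stem with a U8 tail always clears the high-confidence mark of 76,
    while typical background hairpins in G+C-rich sequence fall below 50.
    """

    c0: float = -4.0
    c1: float = 0.13   # stem
    c2: float = 0.10   # loop
    c3: float = 0.45   # tail


def confidence_from_scores(stem_score: float, loop_score: float,
                           tail_score: float,
                           coeffs: ScoringCoefficients | None = None) -> int:
    coeffs = coeffs or ScoringCoefficients()
    z = (coeffs.c0 + coeffs.c1 * stem_score + coeffs.c2 * loop_score
         + coeffs.c3 * tail_score)
    conf = round(100.0 / (1.0 + math.exp(-z)))
    return int(min(100, max(0, conf)))


@dataclass(frozen=True)
class Hairpin:
    """A stem-loop candidate in strand-local coordinates.

    ``loop_start`` is the 0-based offset of the loop's first base in the
    strand-local sequence (the forward sequence for ``+``, its reverse
    complement for ``-``); helper properties expose 1-based forward-axis
    coordinates.
    """

    strand: str
    loop_start: int          # 0-based, strand-local
    loop_len: int
    stem_len: int
    mismatches: int
    stem_score: float
    genome_length: int
    local_seq: str = field(repr=False, compare=False)

    def _fwd(self, local0: int) -> int:
        """Map a 0-based strand-local offset to a 1-based forward coordinate."""
        if self.strand == "+":
            return local0 + 1
        return self.genome_length - local0

    @property
    def local_span(self) -> tuple[int, int]:
        """0-based [start, end) of the full hairpin in local coordinates."""
        s = self.loop_start - self.stem_len
        e = self.loop_start + self.loop_len + self.stem_len
        return s, e

    @property
    def start(self) -> int:
        s, e = self.local_span
        return min(self._fwd(s), self._fwd(e - 1))

    @property
    def end(self) -> int:
        s, e = self.local_span
        return max(self._fwd(s), self._fwd(e - 1))


@dataclass
class Terminator:
    """A scored intrinsic-terminator prediction on the forward genome axis.

    For internally detected terminators all part coordinates are populated
    and the confidence is reproducible from the part scores through
    :func:`confidence_from_scores`.  Parsed (external) terminators carry
    only their overall extent and confidence.

    ``tail_end`` is the 3' extremity of the 15 nt tail *on the terminator's
    strand*; transcript predictions end exactly there, since an intrinsic
    terminator is considered part of the transcript it terminates.
    """

    strand: str
    confidence: int
    source: str                          # "internal" | "parsed"
    stem5_start: Optional[int] = None    # forward-axis, 1-based inclusive
    stem5_end: Optional[int] = None
    loop_start: Optional[int] = None
    loop_end: Optional[int] = None
    stem3_start: Optional[int] = None
    stem3_end: Optional[int] = None
    tail_end: int = 0
    stem_score: float = 0.0
    loop_score: float = 0.0
    tail_score: float = 0.0
    _extent: Optional[tuple[int, int]] = None  # parsed-source hairpin extent

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not (0 <= self.confidence <= 100):
            raise FormatError(
                f"terminator confidence {self.confidence} outside [0, 100]")
        if self.source == "internal":
            arm5 = self.stem5_end - self.stem5_start
            arm3 = self.stem3_end - self.stem3_start
            if arm5 != arm3:
                raise ValueError("stem arms differ in length")
            if not (3 <= self.loop_end - self.loop_start + 1 <= 13):
                raise ValueError("loop length outside [3, 13]")

    @property
    def start(self) -> int:
        """Leftmost forward coordinate of the stem-loop."""
        if self._extent:
            return self._extent[0]
        return min(self.stem5_start, self.stem3_start)

    @property
    def end(self) -> int:
        if self._extent:
            return self._extent[1]
        return max(self.stem5_end, self.stem3_end)

    @property
    def is_high_confidence(self) -> bool:
        return self.confidence >= HIGH_CONFIDENCE


# ---------------------------------------------------------------------------
# detection

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

# match matrix over encoded bases: WC plus G:T wobble
_MATCH = np.zeros((5, 5), dtype=bool)
_WEIGHT = np.zeros((5, 5))
for (b1, b2), w in _PAIR_WEIGHT.items():
    _MATCH[_ENC[b1], _ENC[b2]] = True
    _WEIGHT[_ENC[b1], _ENC[b2]] = w


def _find_hairpins_local(seq: str, constraints: HairpinConstraints):
    """Vectorized stem-loop search on one strand-local sequence.

    For every loop placement the stem is grown outwards from the innermost
    pair; a single internal mismatch may be bridged if at least one further
    pair closes outside it.  Returns per-candidate arrays
    (loop_start, loop_len, stem_len, mismatches, stem_score).
    """
    n = len(seq)
    code = np.array([_ENC.get(c, 4) for c in seq], dtype=np.int64)
    smax = constraints.stem_max
    out = []
    for l in range(constraints.loop_min, constraints.loop_max + 1):
        xs = np.arange(n)
        # suffix run lengths / weights over stem depth, computed backwards
        run = np.zeros(n, dtype=np.int64)
        wrun = np.zeros(n)
        runs_by_depth = np.zeros((smax + 2, n), dtype=np.int64)
        wruns_by_depth = np.zeros((smax + 2, n))
        for d in range(smax, 0, -1):
            left = xs - d
            right = xs + l - 1 + d
            valid = (left >= 0) & (right < n)
            m = np.zeros(n, dtype=bool)
            w = np.zeros(n)
            lv, rv = left[valid], right[valid]
            m[valid] = _MATCH[code[lv], code[rv]]
            w[valid] = _WEIGHT[code[lv], code[rv]]
            run = np.where(m, run + 1, 0)
            wrun = np.where(m, wrun + w, 0.0)
            runs_by_depth[d] = run
            wruns_by_depth[d] = wrun
        inner = runs_by_depth[1]
        winner = wruns_by_depth[1]
        depth2 = np.minimum(inner + 2, smax + 1)
        bridged = runs_by_depth[depth2, xs]
        wbridged = wruns_by_depth[depth2, xs]
        if constraints.max_internal_mismatches < 1:
            bridged = np.zeros_like(bridged)
            wbridged = np.zeros_like(wbridged)
        use_mm = (inner >= 1) & (bridged >= 1) & (inner + 1 + bridged <= smax)
        stem = np.where(use_mm, inner + 1 + bridged, np.minimum(inner, smax))
        score = np.where(use_mm, winner + MISMATCH_PENALTY + wbridged, winner)
        mism = use_mm.astype(np.int64)
        ok = stem >= constraints.stem_min
        # full tail must fit on the strand
        ok &= (xs + l + stem + TAIL_LENGTH) <= n
        ok &= (xs - stem) >= 0
        idx = np.nonzero(ok)[0]
        if idx.size:
            out.append((idx, np.full(idx.size, l), stem[idx], mism[idx],
                        score[idx]))
    if not out:
        z = np.zeros(0, dtype=np.int64)
        return z, z, z, z, np.zeros(0)
    cols = [np.concatenate([o[i] for o in out]) for i in range(5)]
    return tuple(cols)


def find_hairpins(genome: Genome, strand: str,
                  constraints: HairpinConstraints | None = None) -> list[Hairpin]:
    """All maximal stem-loop candidates terminating transcription on ``strand``."""
    constraints = constraints or HairpinConstraints()
    if strand not in "+-":
        raise ValueError("strand must be + or -")
    local = genome.seq if strand == "+" else genome.revcomp()
    ls, ll, st, mm, sc = _find_hairpins_local(local, constraints)
    n = len(genome)
    return [Hairpin(strand=strand, loop_start=int(x), loop_len=int(l),
                    stem_len=int(s), mismatches=int(m), stem_score=float(w),
                    genome_length=n, local_seq=local)
            for x, l, s, m, w in zip(ls, ll, st, mm, sc)]


def score_terminator(hairpin: Hairpin, genome: Genome | None = None,
                     coeffs: ScoringCoefficients | None = None) -> Terminator:
    """Score one hairpin candidate and emit a Terminator.

    stem: sum of pair weights (G:C +3, A:T +2, G:U +1, mismatch -3);
    loop: ``-0.5 |len - 8|`` (8 nt is treated as the ideal loop);
    tail: U-count over the 15 nt downstream of the stem, each position
    weighted ``(16 - i) / 15`` so stem-proximal U's dominate.
    """
    h = hairpin
    seq = h.local_seq
    x, l, d = h.loop_start, h.loop_len, h.stem_len
    loop_score = -0.5 * abs(l - 8)
    tail0 = x + l + d
    tail = seq[tail0:tail0 + TAIL_LENGTH]
    tail_score = sum((16 - i) / 15.0
                     for i, ch in enumerate(tail, start=1) if ch == "T")
    conf = confidence_from_scores(h.stem_score, loop_score, tail_score, coeffs)

    def fwd(p0: int) -> int:
        return p0 + 1 if h.strand == "+" else h.genome_length - p0

    # strand-local intervals, mapped (and re-ordered) onto the forward axis
    def interval(a0: int, b0: int) -> tuple[int, int]:
        p, q = fwd(a0), fwd(b0)
        return (p, q) if p <= q else (q, p)

    s5 = interval(x - d, x - 1)
    lp = interval(x, x + l - 1)
    s3 = interval(x + l, x + l + d - 1)
    tail_end = fwd(tail0 + TAIL_LENGTH - 1)
    return Terminator(strand=h.strand, confidence=conf, source="internal",
                      stem5_start=s5[0], stem5_end=s5[1],
                      loop_start=lp[0], loop_end=lp[1],
                      stem3_start=s3[0], stem3_end=s3[1],
                      tail_end=tail_end,
                      stem_score=h.stem_score, loop_score=loop_score,
                      tail_score=tail_score)


def find_terminators(genome: Genome,
                     min_confidence: int = DEFAULT_CONFIDENCE_THRESHOLD,
                     constraints: HairpinConstraints | None = None,
                     coeffs: ScoringCoefficients | None = None) -> list[Terminator]:
    """Detect and score intrinsic terminators on both strands.

    Returns terminators with confidence >= ``min_confidence`` sorted by
    forward start coordinate.
    """
    terms = []
    for strand in "+-":
        for h in find_hairpins(genome, strand, constraints):
            t = score_terminator(h, genome, coeffs)
            if t.confidence >= min_confidence:
                terms.append(t)
    terms.sort(key=lambda t: (t.start, t.end, t.strand))
    return terms


# ---------------------------------------------------------------------------
# external predictions (TransTermHP-style text)

_TERM_RE = re.compile(
    r"^\s*TERM\s+\S+\s+(\d+)\s*(?:-|\.\.)\s*(\d+)\s+([+-])\s+(.*)$")


def read_transterm_output(path: str | Path) -> list[Terminator]:
    """Parse TransTermHP-style ``TERM`` prediction lines.

    Expected shape: ``TERM <n> <start> - <end> <strand> [codes] <conf> ...``
    where the confidence is the first integer token after the strand field.
    Minus-strand records listed with descending coordinates are reordered.
    The tail is taken as the 15 nt 3' of the reported hairpin extent.
    """
    path = Path(path)
    terms: list[Terminator] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if "TERM" not in line:
                continue
            m = _TERM_RE.match(line)
            if not m:
                raise FormatError(f"{path}:{lineno}: malformed TERM line")
            start, end = int(m.group(1)), int(m.group(2))
            strand = m.group(3)
            if start > end:
                start, end = end, start
            conf = None
            for tok in m.group(4).split():
                try:
                    conf = int(tok)
                    break
                except ValueError:
                    continue
            if conf is None:
                raise FormatError(f"{path}:{lineno}: no confidence value found")
            if not (0 <= conf <= 100):
                raise FormatError(
                    f"{path}:{lineno}: confidence {conf} outside [0, 100]")
            tail_end = end + TAIL_LENGTH if strand == "+" else start - TAIL_LENGTH
            terms.append(Terminator(strand=strand, confidence=conf,
                                    source="parsed", tail_end=tail_end,
                                    _extent=(start, end)))
    return terms
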