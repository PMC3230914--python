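"""Deterministic synthetic replicons with planted transcriptional features.

Generates Streptomyces-like (G+C-rich) background sequence carrying planted
transcript templates, each consisting of

* an AT-rich island (the duplex-destabilization promoter signal: in a
  G+C-rich background such islands dominate the SIDD profile),
* a spacer,
* a strong intrinsic terminator (pure G:C stem, U-rich tail) whose exact
  tail end is the expected transcript 3' coordinate.

Protein-coding genes are placed to realize each transcript category
(antisense / sense-overlap / intergenic), candidate loci cover each planted
element, and a truth table records the expected transcript coordinates so
every pipeline stage can be validated without external data.  All output is
reproducible from the seed.

The generator screens each planted region against the internal terminator
scorer and redraws the local background when a spurious near-high-confidence
hairpin lands close to a locus, so planted terminators are always the
signals the caller should select.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io import (GeneAnnotation, Genome, NcRNALocus, write_fasta,
                 write_loci_gff, write_ptt)
from .sidd import SiddSite
from .terminators import (TAIL_LENGTH, Terminator, find_terminators)

__all__ = [
    "FixtureSpec",
    "TruthRow",
    "Fixture",
    "make_fixture",
    "ConflictScenario",
    "make_conflict_suite",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def _rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic replicon with planted transcripts."""

    genome_length: int = 100_000
    gc_background: float = 0.72        # Streptomyces-like background
    n_planted: int = 20
    seed: int = 0
    at_len: tuple[int, int] = (40, 80)   # promoter island length range
    at_fraction: float = 0.85            # min A/T fraction inside the island
    spacer: tuple[int, int] = (60, 160)  # island-to-terminator distance
    stem_len: int = 10                   # planted terminator stem (all G:C)
    loop_seq: str = "TTCG"
    tail_t: int = 8                      # leading U's (T's) in the tail
    locus_pad_upstream: int = 20
    locus_pad_downstream: int = 10
    spurious_confidence: int = 70        # redraw background above this

    def __post_init__(self) -> None:
        if self.n_planted < 1 or self.genome_length < 1:
            raise ValueError("need a positive genome length and plant count")
        if self.genome_length // self.n_planted < 1200:
            raise ValueError(
                "cannot place planted elements without interference: "
                "need >= 1200 nt of genome per planted transcript")
        if self.stem_len < 8 or self.tail_t < 8:
            raise ValueError("planted terminators must have >= 8 bp stems "
                             "and >= 8 nt U-tails to be strong by design")


@dataclass(frozen=True)
class TruthRow:
    """Expected outcome for one planted transcript."""

    locus_id: str
    start_lo: int     # acceptable 5'-boundary window (includes site fringe)
    start_hi: int
    end: int          # exact expected 3' coordinate (terminator tail end)
    strand: str
    category: str


@dataclass
class Fixture:
    """A generated replicon plus its ground truth and planted features."""

    spec: FixtureSpec
    genome: Genome
    genes: list[GeneAnnotation]
    loci: list[NcRNALocus]
    terminators: list[Terminator]   # the planted ones, internally scored
    truth: list[TruthRow]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.truth])

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA / PTT / loci GFF / terminator text / truth TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fna",
            "ptt": outdir / "genes.ptt",
            "loci": outdir / "loci.gff",
            "transterm": outdir / "terminators.txt",
            "truth": outdir / "truth.tsv",
        }
        write_fasta(self.genome, paths["fasta"])
        write_ptt(self.genes, paths["ptt"], title=self.genome.id)
        write_loci_gff(self.loci, paths["loci"], seqid=self.genome.id)
        with paths["transterm"].open("w") as fh:
            for i, t in enumerate(self.terminators, start=1):
                # minus-strand records use descending coordinates, as the
                # external terminator predictor prints them
                a, b = (t.start, t.end) if t.strand == "+" else (t.end, t.start)
                fh.write(f"  TERM {i} {a} - {b} {t.strand} F "
                         f"{t.confidence} -11.0 -4.0 | planted\n")
        self.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _background(rng: np.random.Generator, n: int, gc: float) -> str:
    p_s, p_w = gc / 2.0, (1.0 - gc) / 2.0
    return "".join(rng.choice(list("ACGT"), size=n, p=[p_w, p_s, p_s, p_w]))


def _at_island(rng: np.random.Generator, spec: FixtureSpec) -> str:
    n = int(rng.integers(spec.at_len[0], spec.at_len[1] + 1))
    while True:
        mask = rng.random(n) < max(spec.at_fraction, 0.8)
        if mask.mean() >= 0.8:
            break
    weak = rng.choice(list("AT"), size=n)
    strong = rng.choice(list("GC"), size=n)
    return "".join(w if m else s for w, s, m in zip(weak, strong, mask))


_CATEGORIES = ("antisense", "sense_overlap", "intergenic")


def make_fixture(spec: FixtureSpec | None = None) -> Fixture:
    """Generate a replicon with ``spec.n_planted`` planted transcripts.

    Planted elements are laid out one per equal-width slot; strands
    alternate and categories cycle antisense / sense-overlap / intergenic.
    Raises when the requested layout leaves no room to place elements
    cleanly.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    slot = spec.genome_length // spec.n_planted

    chunks: list[str] = []
    genes: list[GeneAnnotation] = []
    loci: list[NcRNALocus] = []
    planted_terms: list[Terminator] = []
    truth: list[TruthRow] = []

    for i in range(spec.n_planted):
        slot_start = i * slot  # 0-based
        strand = "+" if i % 2 == 0 else "-"
        category = _CATEGORIES[i % 3]
        for attempt in range(60):
            piece = _plant_slot(rng, spec, slot, slot_start, i, strand,
                                category)
            if piece is not None:
                break
        else:
            raise RuntimeError(
                f"could not place planted transcript {i} without spurious "
                "terminator signals; enlarge the genome or slots")
        seq, gene_list, locus, term, row = piece
        chunks.append(seq)
        genes.extend(gene_list)
        loci.append(locus)
        planted_terms.append(term)
        truth.append(row)
    rest = spec.genome_length - slot * spec.n_planted
    if rest:
        chunks.append(_background(rng, rest, spec.gc_background))
    genome = Genome(id=f"synthetic_replicon_seed{spec.seed}",
                    seq="".join(chunks))
    genes.sort(key=lambda g: g.start)
    return Fixture(spec=spec, genome=genome, genes=genes, loci=loci,
                   terminators=planted_terms, truth=truth)


def _plant_slot(rng, spec: FixtureSpec, slot: int, slot_start: int,
                index: int, strand: str, category: str):
    """One attempt at building a slot; None when a spurious strong hairpin
    contaminates the locus neighbourhood."""
    island = _at_island(rng, spec)
    sp_len = int(rng.integers(spec.spacer[0], spec.spacer[1] + 1))
    spacer = _background(rng, sp_len, spec.gc_background)
    stem5 = "".join(rng.choice(list("GC"), size=spec.stem_len))
    # "CC" guards cannot pair with the U-tail, so the detected stem extent
    # (and hence the tail end) is exactly the planted one
    core = ("CC" + stem5 + spec.loop_seq + _rc(stem5)
            + "T" * spec.tail_t
            + _background(rng, TAIL_LENGTH - spec.tail_t, spec.gc_background))
    construct = island + spacer + core
    insert = construct if strand == "+" else _rc(construct)

    offset = 400 + int(rng.integers(0, 120))  # within-slot placement jitter
    if offset + len(insert) + 700 > slot:
        return None
    pre = _background(rng, offset, spec.gc_background)
    post = _background(rng, slot - offset - len(insert), spec.gc_background)
    slot_seq = pre + insert + post

    # 1-based forward coordinates of the planted parts
    ins0 = slot_start + offset  # 0-based genome offset of the insert
    L = len(construct)

    def fwd(local0: int) -> int:
        """construct-local 0-based offset -> 1-based genome coordinate."""
        if strand == "+":
            return ins0 + local0 + 1
        return ins0 + (L - 1 - local0) + 1

    isl_a, isl_b = sorted((fwd(0), fwd(len(island) - 1)))
    stem5_0 = len(island) + sp_len + 2
    stem3_end_0 = stem5_0 + 2 * spec.stem_len + len(spec.loop_seq) - 1
    tail_end_0 = stem3_end_0 + TAIL_LENGTH
    hp_a, hp_b = sorted((fwd(stem5_0), fwd(stem3_end_0)))
    tail_end = fwd(tail_end_0)
    locus_lo = min(isl_a, hp_a) - (spec.locus_pad_upstream if strand == "+"
                                   else spec.locus_pad_downstream)
    locus_hi = max(isl_b, hp_b) + (spec.locus_pad_downstream if strand == "+"
                                   else spec.locus_pad_upstream)

    # screen the slot for spurious hairpins that could compete with the
    # planted terminator: anything near-strong in the locus core, and any
    # high-confidence signal within the caller's genome-wide scan reach
    slot_genome = Genome(id="slot", seq=slot_seq)
    planted_tail_local = tail_end - slot_start
    core_lo, core_hi = locus_lo - slot_start - 150, locus_hi - slot_start + 150
    far_lo, far_hi = core_lo - 1000, core_hi + 1000
    planted = None
    for t in find_terminators(slot_genome, min_confidence=spec.spurious_confidence):
        if t.strand == strand and t.tail_end == planted_tail_local:
            if planted is None or t.confidence > planted.confidence:
                planted = t
            continue
        if t.end >= core_lo and t.start <= core_hi:
            return None  # spurious near-strong signal too close: redraw
        if t.confidence >= 76 and t.end >= far_lo and t.start <= far_hi:
            return None  # spurious high-confidence signal in scan reach
    if planted is None or planted.confidence < 76:
        return None

    # shift the detected planted terminator onto genome coordinates
    shift = slot_start
    term = Terminator(
        strand=planted.strand, confidence=planted.confidence,
        source="internal",
        stem5_start=planted.stem5_start + shift,
        stem5_end=planted.stem5_end + shift,
        loop_start=planted.loop_start + shift,
        loop_end=planted.loop_end + shift,
        stem3_start=planted.stem3_start + shift,
        stem3_end=planted.stem3_end + shift,
        tail_end=planted.tail_end + shift,
        stem_score=planted.stem_score, loop_score=planted.loop_score,
        tail_score=planted.tail_score)

    genes = _genes_for_category(rng, index, strand, category,
                                isl_a, isl_b, tail_end, slot_start, slot)
    locus = NcRNALocus(id=f"locus_{index + 1:03d}", start=locus_lo,
                       end=locus_hi,
                       pvalue=round(float(rng.uniform(0.5, 1.0)), 3))
    row = TruthRow(locus_id=locus.id, start_lo=isl_a - 15, start_hi=isl_b + 15,
                   end=tail_end, strand=strand, category=category)
    return slot_seq, genes, locus, term, row


def _genes_for_category(rng, index: int, strand: str, category: str,
                        isl_a: int, isl_b: int, tail_end: int,
                        slot_start: int, slot: int) -> list[GeneAnnotation]:
    """Coding genes realizing the requested transcript category."""
    genes: list[GeneAnnotation] = []
    other = "-" if strand == "+" else "+"
    t_lo, t_hi = sorted((isl_a, tail_end))
    mid = (t_lo + t_hi) // 2
    if category == "antisense":
        genes.append(GeneAnnotation(start=max(1, mid - 150), end=mid + 150,
                                    strand=other,
                                    synonym=f"SYN{index + 1:04d}",
                                    product="hypothetical protein"))
    elif category == "sense_overlap":
        # partial same-strand overlap extending past the transcript 3' end
        if strand == "+":
            g = GeneAnnotation(start=t_hi - 40, end=t_hi + 260, strand=strand,
                               synonym=f"SYN{index + 1:04d}",
                               product="hypothetical protein")
        else:
            g = GeneAnnotation(start=max(1, t_lo - 260), end=t_lo + 40,
                               strand=strand,
                               synonym=f"SYN{index + 1:04d}",
                               product="hypothetical protein")
        genes.append(g)
    # a distant decoy gene keeps the PTT realistic without touching the locus
    decoy_start = slot_start + slot - 900
    genes.append(GeneAnnotation(start=decoy_start, end=decoy_start + 450,
                                strand="+" if index % 2 else "-",
                                synonym=f"DEC{index + 1:04d}",
                                product="decoy protein"))
    return genes


# ---------------------------------------------------------------------------
# decision-branch scenarios


@dataclass(frozen=True)
class ConflictScenario:
    """One hand-checkable configuration of the transcript decision rules.

    Branch scenarios carry pre-built loci/sites/terminators/genes and the
    frozen expected outcome; see tests for their evaluation.  ``strand`` is
    the strand the prediction is attempted on for single-branch cases.
    """

    name: str
    locus: NcRNALocus
    site: SiddSite
    strand: str
    terminators: tuple
    genes: tuple = ()
    # single-prediction branches:
    expected_interval: Optional[tuple[int, int]] = None
    expected_conf: Optional[int] = None
    expect_none: bool = False
    # pipeline branches (join/trim/discard): extra prediction inputs
    extra: tuple = ()     # (site, strand) pairs predicted alongside
    expected_final: tuple = ()  # ((start, end, strand), ...) after resolution


def _term(strand: str, tail_end: int, conf: int) -> Terminator:
    """Minimal parsed-style terminator for scenario construction."""
    if strand == "+":
        extent = (tail_end - TAIL_LENGTH - 23, tail_end - TAIL_LENGTH)
    else:
        extent = (tail_end + TAIL_LENGTH, tail_end + TAIL_LENGTH + 23)
    return Terminator(strand=strand, confidence=conf, source="parsed",
                      tail_end=tail_end, _extent=extent)


def make_conflict_suite() -> list[ConflictScenario]:
    """The seven decision branches of the transcript caller.

    Expected outcomes were derived once by hand from the stated rules and
    frozen here.
    """
    locus = NcRNALocus(id="L", start=80, end=700)
    site = SiddSite(start=100, end=140, min_energy=3.0)
    scenarios = [
        ConflictScenario(
            name="high_confidence_stop",
            locus=locus, site=site, strand="+",
            terminators=(_term("+", 400, 80), _term("+", 600, 95)),
            expected_interval=(100, 400), expected_conf=80),
        ConflictScenario(
            name="best_confidence_fallback",
            locus=locus, site=site, strand="+",
            terminators=(_term("+", 400, 60), _term("+", 600, 70)),
            expected_interval=(100, 600), expected_conf=70),
        ConflictScenario(
            name="locus_end_fallback",
            locus=locus, site=site, strand="+",
            terminators=(),
            expected_interval=(100, 700), expected_conf=None),
        ConflictScenario(
            name="gene_attribution_suppression",
            locus=locus, site=site, strand="+",
            terminators=(),
            genes=(GeneAnnotation(start=180, end=600, strand="+",
                                  synonym="G1"),),
            expect_none=True),
        ConflictScenario(
            name="same_strand_join",
            locus=NcRNALocus(id="L", start=80, end=700),
            site=SiddSite(start=100, end=140, min_energy=3.0),
            strand="+",
            terminators=(_term("+", 400, 80), _term("+", 600, 90)),
            extra=((SiddSite(start=365, end=390, min_energy=3.5), "+"),),
            expected_final=((100, 600, "+"),)),
        ConflictScenario(
            name="antistrand_trim",
            locus=NcRNALocus(id="L", start=80, end=900),
            site=SiddSite(start=100, end=140, min_energy=3.0),
            strand="+",
            terminators=(_term("+", 500, 90), _term("-", 300, 70),
                         _term("-", 540, 65)),
            extra=((SiddSite(start=600, end=640, min_energy=3.2), "-"),),
            expected_final=((100, 500, "+"), (540, 640, "-"))),
        ConflictScenario(
            name="antistrand_discard",
            locus=NcRNALocus(id="L", start=80, end=900),
            site=SiddSite(start=100, end=140, min_energy=3.0),
            strand="+",
            terminators=(_term("+", 500, 90), _term("-", 300, 70)),
            extra=((SiddSite(start=600, end=640, min_energy=3.2), "-"),),
            expected_final=((100, 500, "+"),)),
    ]
    return scenarios
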