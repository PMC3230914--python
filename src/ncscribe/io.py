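"""Readers and writers for the external formats the pipeline touches.

All coordinates are 1-based inclusive throughout the package, matching the
conventions of PTT and GFF.  Parsers validate ``start <= end`` and report
the offending line number; the results writer emits GFF3 with a fully
deterministic ordering so repeated runs are byte-identical.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

__all__ = [
    "Genome",
    "GeneAnnotation",
    "NcRNALocus",
    "FormatError",
    "read_fasta",
    "read_ptt",
    "read_loci",
    "write_loci_gff",
    "write_results_gff",
]


class FormatError(ValueError):
    """Malformed input file (carries file context in the message)."""


_VALID_BASES = set("ACGTN")


@dataclass
class Genome:
    """A named DNA sequence plus its topology (the coordinate frame)."""

    id: str
    seq: str
    topology: str = "linear"  # or "circular"

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError(f"genome record {self.id!r} has an empty sequence")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")
        seq = self.seq.upper()
        if not set(seq) <= _VALID_BASES:
            seq = re.sub("[^ACGT]", "N", seq)
        self.seq = seq

    def __len__(self) -> int:
        return len(self.seq)

    _COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

    def revcomp(self) -> str:
        return self.seq.translate(self._COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneAnnotation:
    """Protein-coding gene interval from a PTT table."""

    start: int
    end: int
    strand: str
    synonym: str = ""
    product: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise FormatError(
                f"gene {self.synonym or '?'}: invalid interval "
                f"{self.start}..{self.end}")
        if self.strand not in "+-":
            raise FormatError(f"gene strand must be + or -, got {self.strand!r}")


@dataclass
class NcRNALocus:
    """Candidate functional-RNA interval awaiting transcript assessment."""

    id: str
    start: int
    end: int
    pvalue: Optional[float] = None
    sidd_sites: list = field(default_factory=list)
    terminators: list = field(default_factory=list)
    tfbs_hits: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"locus {self.id}: start {self.start} > end {self.end}")
        if self.pvalue is not None and not (0.0 <= self.pvalue <= 1.0):
            raise FormatError(
                f"locus {self.id}: P-value {self.pvalue} outside [0, 1]")

    def __len__(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[Genome]:
    """Load all FASTA records as Genomes, preserving file order."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    genomes = []
    for rec in records:
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        genomes.append(Genome(id=rec.id, seq=str(rec.seq)))
    return genomes


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with Path(path).open("w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, len(genome.seq), width):
            fh.write(genome.seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# PTT (NCBI protein table)

_LOCATION_RE = re.compile(r"^(\d+)\.\.(\d+)$")


def read_ptt(path: str | Path) -> list[GeneAnnotation]:
    """Parse a PTT protein table into gene annotations sorted by start.

    Header lines (2 or 3 of them depending on provenance) are skipped by
    pattern: records begin at the first line whose leading field matches
    ``start..end``.
    """
    path = Path(path)
    genes = []
    in_body = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            m = _LOCATION_RE.match(fields[0].strip())
            if not m:
                if in_body:
                    raise FormatError(
                        f"{path}:{lineno}: malformed location field {fields[0]!r}")
                continue  # header
            in_body = True
            start, end = int(m.group(1)), int(m.group(2))
            if start > end:
                raise FormatError(
                    f"{path}:{lineno}: location start {start} > end {end}")
            if len(fields) < 2 or fields[1] not in "+-":
                raise FormatError(f"{path}:{lineno}: missing or bad strand field")
            synonym = fields[5] if len(fields) > 5 else ""
            product = fields[8] if len(fields) > 8 else ""
            genes.append(GeneAnnotation(start=start, end=end, strand=fields[1],
                                        synonym=synonym, product=product))
    genes.sort(key=lambda g: (g.start, g.end, g.strand))
    return genes


def write_ptt(genes: Iterable[GeneAnnotation], path: str | Path,
              title: str = "synthetic replicon") -> None:
    genes = list(genes)
    with Path(path).open("w") as fh:
        fh.write(f"{title} - 1..-\n")
        fh.write(f"{len(genes)} proteins\n")
        fh.write("Location\tStrand\tLength\tPID\tGene\tSynonym\tCode\tCOG\tProduct\n")
        for i, g in enumerate(genes, start=1):
            aa = max((g.end - g.start + 1) // 3 - 1, 1)
            fh.write(f"{g.start}..{g.end}\t{g.strand}\t{aa}\t{i}\t-\t"
                     f"{g.synonym or f'gene_{i}'}\t-\t-\t{g.product or '-'}\n")


# ---------------------------------------------------------------------------
# ncRNA loci (GFF3 or simple tabular)

_PVALUE_KEYS = ("pvalue", "p_value", "p-value", "pval")


def _parse_gff_attributes(text: str) -> dict:
    attrs = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
        elif " " in part:  # tolerate GFF2-style "key value"
            k, v = part.split(None, 1)
            v = v.strip('"')
        else:
            k, v = part, ""
        attrs[k.strip()] = v.strip()
    return attrs


def read_loci(path: str | Path, format: str | None = None) -> list[NcRNALocus]:
    """Read candidate ncRNA loci from GFF or a simple tabular file.

    Tabular lines are ``id<TAB>start<TAB>end[<TAB>pvalue]``.  When the
    format is not given it is inferred: 9-column lines starting with a
    seqid are treated as GFF.  Missing GFF IDs are auto-numbered
    ``locus_<k>``; duplicate ids are rejected.
    """
    path = Path(path)
    if format is None:
        fmt = "gff"
        with path.open() as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                fmt = "gff" if len(line.rstrip("\n").split("\t")) >= 8 else "tabular"
                break
    else:
        fmt = format
    if fmt not in ("gff", "tabular"):
        raise ValueError(f"unknown loci format {fmt!r}")

    loci: list[NcRNALocus] = []
    seen: set[str] = set()
    counter = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "gff":
                    if len(fields) < 8:
                        raise FormatError("expected >= 8 GFF columns")
                    start, end = int(fields[3]), int(fields[4])
                    attrs = _parse_gff_attributes(fields[8]) if len(fields) > 8 else {}
                    lid = attrs.get("ID") or attrs.get("Name")
                    pval = None
                    for key in _PVALUE_KEYS:
                        for k, v in attrs.items():
                            if k.lower() == key:
                                pval = float(v)
                else:
                    if len(fields) < 3:
                        raise FormatError("expected id<TAB>start<TAB>end")
                    lid = fields[0]
                    start, end = int(fields[1]), int(fields[2])
                    pval = float(fields[3]) if len(fields) > 3 and fields[3] else None
                if not lid:
                    counter += 1
                    lid = f"locus_{counter}"
                if lid in seen:
                    raise FormatError(f"duplicate locus id {lid!r}")
                seen.add(lid)
                loci.append(NcRNALocus(id=lid, start=start, end=end, pvalue=pval))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return loci


def write_loci_gff(loci: Iterable[NcRNALocus], path: str | Path,
                   seqid: str = "genome") -> None:
    """Write loci as GFF3 ``ncRNA_region`` features (round-trip safe)."""
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for loc in loci:
            attrs = f"ID={loc.id}"
            if loc.pvalue is not None:
                attrs += f";pvalue={loc.pvalue:g}"
            fh.write(f"{seqid}\tncscribe\tncRNA_region\t{loc.start}\t{loc.end}"
                     f"\t.\t.\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# combined results GFF3

_TYPE_ORDER = {"ncRNA_region": 0, "SIDD_site": 1, "terminator": 2,
               "ncRNA_transcript": 3, "TFBS_hit": 4}


def write_results_gff(path: str | Path, seqid: str, loci=(), sidd_sites=(),
                      terminators=(), transcripts=(), tfbs_hits=()) -> None:
    """Condense every predicted feature into one deterministic GFF3 file.

    Rows are ordered by (start, feature type, strand, end, ID) so the output
    is byte-identical across runs and worker counts.
    """
    rows = []
    for loc in loci:
        attrs = f"ID={loc.id}"
        if loc.pvalue is not None:
            attrs += f";pvalue={loc.pvalue:g}"
        rows.append((loc.start, loc.end, "ncRNA_region", ".", ".", attrs))
    for i, s in enumerate(sidd_sites, start=1):
        attrs = f"ID=sidd_{i};min_energy={s.min_energy:.3f};strong={'yes' if s.strong else 'no'}"
        rows.append((s.start, s.end, "SIDD_site", ".", f"{s.min_energy:.3f}", attrs))
    for i, t in enumerate(terminators, start=1):
        attrs = f"ID=term_{i};confidence={t.confidence};source={t.source}"
        rows.append((t.start, t.end, "terminator", t.strand,
                     f"{t.confidence}", attrs))
    for t in transcripts:
        attrs = (f"ID={t.id};Parent={t.source_locus};category={t.category}")
        if t.term_confidence is not None:
            attrs += f";term_confidence={t.term_confidence}"
        rows.append((t.start, t.end, "ncRNA_transcript", t.strand, ".", attrs))
    for i, h in enumerate(tfbs_hits, start=1):
        attrs = f"ID=tfbs_{i};pattern={h.pattern_id};match={h.match}"
        rows.append((h.start, h.end, "TFBS_hit", h.strand, ".", attrs))

    rows.sort(key=lambda r: (r[0], _TYPE_ORDER[r[2]], r[3], r[1], r[5]))
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for start, end, ftype, strand, score, attrs in rows:
            fh.write(f"{seqid}\tncscribe\t{ftype}\t{start}\t{end}\t{score}"
                     f"\t{strand}\t.\t{attrs}\n")
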