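"""Single-command orchestration: SIDD -> terminators -> transcripts -> GFF.

The pipeline reads a genome (FASTA), coding genes (PTT) and candidate ncRNA
loci (GFF or tabular), computes or loads a cached SIDD profile, detects or
parses terminators, runs the transcript decision procedure and condenses
all results into one GFF3 file plus a plain-text summary.

The SIDD profile cache is keyed by a digest of the genome sequence and all
SIDD parameters, so a stale profile is never silently reused: a mismatch is
logged and the profile recomputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import hashlib

from . import io as io_formats
from .io import FormatError, Genome
from .sidd import (SiddParameters, SiddProfile, call_sidd_sites, load_profile,
                   profile_windowed, save_profile)
from .terminators import (DEFAULT_CONFIDENCE_THRESHOLD, HIGH_CONFIDENCE,
                          find_terminators, read_transterm_output)
from .transcripts import (CallerParameters, call_transcripts, scan_tfbs)

logger = logging.getLogger("ncscribe")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "read_config"]


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run (flat key=value file + CLI overrides)."""

    genome: str = ""
    genes: str = ""
    loci: str = ""
    terminator_file: Optional[str] = None   # parsed route when provided
    tfbs_file: Optional[str] = None
    output_dir: str = "ncscribe_out"
    circular: bool = False

    sidd_window: int = 10000
    sidd_step: int = 1000
    sidd_threshold: float = 5.0             # site-calling cutoff, kcal/mol
    sidd_min_len: int = 10
    sidd_max_run_length: int = 150

    terminator_threshold: int = DEFAULT_CONFIDENCE_THRESHOLD
    high_confidence: int = HIGH_CONFIDENCE
    flank: int = 100
    downstream_cap: int = 1000
    gene_upstream_margin: int = 150

    workers: int = 1
    sigma: float = -0.055

    def __post_init__(self) -> None:
        if self.sidd_window % self.sidd_step:
            raise ValueError("sidd_window must be divisible by sidd_step")
        if not (0 <= self.terminator_threshold <= 100):
            raise ValueError("terminator_threshold outside [0, 100]")
        if not (0 <= self.high_confidence <= 100):
            raise ValueError("high_confidence outside [0, 100]")

    def sidd_parameters(self) -> SiddParameters:
        return SiddParameters(sigma=self.sigma)

    def caller_parameters(self) -> CallerParameters:
        return CallerParameters(high_confidence=self.high_confidence,
                                flank=self.flank,
                                downstream_cap=self.downstream_cap,
                                gene_upstream_margin=self.gene_upstream_margin)


_BOOL_KEYS = {"circular"}
_INT_KEYS = {"sidd_window", "sidd_step", "sidd_min_len", "sidd_max_run_length",
             "terminator_threshold", "high_confidence", "flank",
             "downstream_cap", "gene_upstream_margin", "workers"}
_FLOAT_KEYS = {"sidd_threshold", "sigma"}


def read_config(path: str | Path, **overrides) -> PipelineConfig:
    """Flat ``key = value`` configuration file; overrides win."""
    values: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected key = value")
        k, v = (s.strip() for s in line.split("=", 1))
        if k in _BOOL_KEYS:
            values[k] = v.lower() in ("1", "true", "yes")
        elif k in _INT_KEYS:
            values[k] = int(v)
        elif k in _FLOAT_KEYS:
            values[k] = float(v)
        else:
            values[k] = v
    values.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**values)


@dataclass
class PipelineResult:
    genome: Genome
    profile: SiddProfile
    sidd_sites: list
    terminators: list
    transcripts: list
    classifications: list
    tfbs_hits: list
    gff_path: Path
    summary: str
    cache_hit: bool


def _load_or_compute_profile(genome: Genome, config: PipelineConfig,
                             outdir: Path) -> tuple[SiddProfile, bool]:
    params = config.sidd_parameters()
    cache = outdir / "sidd_profile.tsv"
    want_digest = hashlib.sha256(genome.seq.encode()).hexdigest()
    if cache.exists() and cache.with_suffix(".tsv.json").exists():
        try:
            prof, meta = load_profile(cache)
        except Exception:
            logger.warning("unreadable SIDD cache at %s; recomputing", cache)
        else:
            if (meta.get("genome_sha256") == want_digest
                    and meta["window"] == min(config.sidd_window, len(genome))
                    and prof.params == params):
                logger.info("SIDD cache hit: %s", cache)
                return prof, True
            logger.warning("SIDD cache at %s does not match the current "
                           "genome/parameters; recomputing", cache)
    prof = profile_windowed(genome, params, window=config.sidd_window,
                            step=config.sidd_step, workers=config.workers,
                            max_run_length=config.sidd_max_run_length)
    save_profile(prof, cache, genome=genome)
    return prof, False


def _read_tfbs_patterns(path: str | Path) -> dict[str, str]:
    patterns: dict[str, str] = {}
    k = 0
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        k += 1
        if "\t" in line:
            pid, pat = line.split("\t", 1)
        else:
            pid, pat = f"pattern_{k}", line
        patterns[pid] = pat
    return patterns


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow and write results under ``output_dir``."""
    for key in ("genome", "genes", "loci"):
        value = getattr(config, key)
        if not value or not Path(value).exists():
            raise FormatError(f"mandatory input {key!r} missing: {value!r}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    genomes = io_formats.read_fasta(config.genome)
    if len(genomes) > 1:
        logger.warning("FASTA holds %d records; processing the first "
                       "(one replicon per run)", len(genomes))
    genome = genomes[0]
    if config.circular:
        genome.topology = "circular"
    genes = io_formats.read_ptt(config.genes)
    loci = io_formats.read_loci(config.loci)

    profile, cache_hit = _load_or_compute_profile(genome, config, outdir)
    sites = call_sidd_sites(profile, threshold=config.sidd_threshold,
                            min_len=config.sidd_min_len)

    if config.terminator_file:
        terminators = [t for t in read_transterm_output(config.terminator_file)
                       if t.confidence >= config.terminator_threshold]
        term_source = f"parsed from {config.terminator_file}"
    else:
        terminators = find_terminators(
            genome, min_confidence=config.terminator_threshold)
        term_source = "internal hairpin scorer"

    transcripts, classifications = call_transcripts(
        loci, sites, terminators, genes, config.caller_parameters())

    tfbs_hits = []
    if config.tfbs_file:
        tfbs_hits = scan_tfbs(genome, _read_tfbs_patterns(config.tfbs_file))
        for locus in loci:
            locus.tfbs_hits = [
                h for h in tfbs_hits
                if h.end >= locus.start - config.flank
                and h.start <= locus.end + config.flank]

    gff_path = outdir / "results.gff3"
    io_formats.write_results_gff(gff_path, genome.id, loci=loci,
                                 sidd_sites=sites, terminators=terminators,
                                 transcripts=transcripts, tfbs_hits=tfbs_hits)
    _write_intermediates(outdir, sites, terminators)

    n_cat = {c: sum(1 for t in transcripts if t.category == c)
             for c in ("antisense", "sense_overlap", "intergenic")}
    n_with_site = sum(1 for l in loci if l.sidd_sites)
    n_with_term = sum(1 for l in loci if l.terminators)
    n_transcribed = sum(1 for c in classifications if c.verdict == "transcript")
    summary = "\n".join([
        f"genome: {genome.id} ({len(genome)} nt, {genome.topology})",
        f"ncRNA loci provided as input: {len(loci)}",
        f"loci annotated with a SIDD site: {n_with_site}",
        f"loci annotated with a terminator: {n_with_term}",
        f"SIDD sites called: {len(sites)} "
        f"(threshold {config.sidd_threshold} kcal/mol, "
        f"min length {config.sidd_min_len} nt)",
        f"terminators ({term_source}): {len(terminators)} "
        f"(reporting threshold {config.terminator_threshold}, "
        f"high confidence {config.high_confidence})",
        f"predicted ncRNA transcripts: {len(transcripts)}",
        f"  antisense: {n_cat['antisense']}",
        f"  sense overlap: {n_cat['sense_overlap']}",
        f"  intergenic: {n_cat['intergenic']}",
        f"loci classified as transcribed: {n_transcribed} / {len(loci)}",
        f"TFBS hits: {len(tfbs_hits)}",
    ]) + "\n"
    (outdir / "summary.txt").write_text(summary)
    return PipelineResult(genome=genome, profile=profile, sidd_sites=sites,
                          terminators=terminators, transcripts=transcripts,
                          classifications=classifications,
                          tfbs_hits=tfbs_hits, gff_path=gff_path,
                          summary=summary, cache_hit=cache_hit)


def _write_intermediates(outdir: Path, sites, terminators) -> None:
    with (outdir / "sidd_sites.tsv").open("w") as fh:
        fh.write("start\tend\tmin_energy\tstrong\n")
        for s in sites:
            fh.write(f"{s.start}\t{s.end}\t{s.min_energy:.3f}"
                     f"\t{int(s.strong)}\n")
    with (outdir / "terminators.tsv").open("w") as fh:
        fh.write("start\tend\tstrand\tconfidence\ttail_end\tsource\n")
        for t in terminators:
            fh.write(f"{t.start}\t{t.end}\t{t.strand}\t{t.confidence}"
                     f"\t{t.tail_end}\t{t.source}\n")
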