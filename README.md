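# ncscribe

Strand-specific prediction of bacterial non-coding RNA (ncRNA) transcripts
from transcriptional features.

Comparative and structural genome screens (RNAz-style) yield *loci* that
probably contain a functional RNA — but with fuzzy boundaries, no strand,
and no indication of whether the element is actually transcribed or is an
untranscribed cis-regulatory motif. `ncscribe` closes that gap for bacteria
in which Rho-independent termination dominates: it detects the
transcriptional features that bracket a real transcript and integrates them
with the candidate loci to produce strand-specific transcript models.

Two physical signals drive the prediction:

* **Promoter proxy — SIDD.** Under negative superhelical stress, duplex DNA
  preferentially opens at susceptible sites (stress-induced duplex
  destabilization). For a superhelical domain the model assigns each
  separation state the free energy

  `G(state) = a·r + Σᵢ∈open b(i) + Q(n_open)`

  with nucleation energy `a` per separated run, copolymeric base-pair
  separation energies `b_AT < b_GC`, and a residual-superhelicity term
  `Q(n) = x²/2 · 4π²CK / (Kn + 4π²C)` (with `x = α + n/A`) obtained by
  minimizing analytically over the inter-strand twist of open regions. The
  per-position profile `G(x) = ⟨G | x open⟩ − ⟨G⟩` (Boltzmann-averaged) is
  computed in sliding windows over the genome; maximal runs of strongly
  destabilized positions are called as strandless **SIDD sites** and serve
  as promoter-region proxies for transcript 5′ ends.

* **3′ signal — intrinsic terminators.** Stem-loop hairpins followed by
  U-rich tails are detected on both strands and scored for stem strength,
  loop geometry and tail composition; the part scores combine into a 0–100
  confidence. Predictions from TransTermHP-style output files can be used
  instead of the internal scorer.

The transcript caller anchors a transcript in each SIDD site associated
with a locus (both strands — SIDD sites are strandless) and extends
downstream to the first *high-confidence* terminator (confidence ≥ 76), or
to the best downstream terminator, or to the locus boundary when no
terminator exists and the site cannot belong to a protein-coding gene.
Same-strand overlaps are joined; opposite-strand overlaps are resolved in
favour of the better terminator (the weaker prediction is trimmed to a
nearer terminator or discarded). Each locus is classified transcribed / not
transcribed, and each transcript categorized **antisense**,
**sense-overlap** or **intergenic** relative to the coding annotation.

## Worked example

`ncscribe` ships a generator of synthetic G+C-rich replicons with planted
promoters, terminators, genes and loci (plus a truth table), so the whole
workflow can be exercised without downloads:

```sh
ncscribe simulate -o fixture --length 20000 --n-planted 4 --seed 7
ncscribe run -g fixture/genome.fna -p fixture/genes.ptt -l fixture/loci.gff \
             -o out --window 2000 --step 1000
```

which prints

```
genome: synthetic_replicon_seed7 (20000 nt, linear)
ncRNA loci provided as input: 4
loci annotated with a SIDD site: 4
loci annotated with a terminator: 4
SIDD sites called: 4 (threshold 5.0 kcal/mol, min length 10 nt)
terminators (internal hairpin scorer): 97 (reporting threshold 50, high confidence 76)
predicted ncRNA transcripts: 4
  antisense: 2
  sense overlap: 1
  intergenic: 1
loci classified as transcribed: 4 / 4
TFBS hits: 0
results written to out/results.gff3
```

All four planted transcripts are recovered. The GFF3 output contains, e.g.

```
synthetic_replicon_seed7  ncscribe  ncRNA_transcript  454  607  .  +  .  ID=locus_001_t1;Parent=locus_001;category=antisense;term_confidence=93
```

a plus-strand antisense transcript whose 5′ end (454) lies inside the
planted destabilized promoter island (truth window 447–516) and whose 3′
end (607) is exactly the planted terminator's tail end. The companion
`truth.tsv` lists the expected coordinates for comparison. Genuine inputs
work the same way: a genome FASTA, an NCBI PTT protein table, and loci from
any screen in GFF or `id<TAB>start<TAB>end[<TAB>pvalue]` form. Regular
expression TFBS patterns (`--tfbs-file`) are scanned on both strands and
attached to the loci; a TransTermHP output file (`-t`) replaces the
internal terminator scorer. Repeated runs reuse the cached SIDD profile
(the slow step) whenever genome and parameters are unchanged.

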