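# Methods

## Scope and model overview

`ncscribe` predicts strand-specific bacterial ncRNA transcripts by
combining two transcriptional features inside candidate functional-RNA
loci: stress-induced duplex destabilization (SIDD) sites as promoter-region
proxies for transcript 5′ starts, and Rho-independent (intrinsic)
terminators for 3′ ends. The method presumes organisms in which intrinsic
termination is the dominant termination mechanism; Rho-dependent
terminators are invisible to it.

## The SIDD model

A window of DNA under superhelical stress is treated as one topological
domain. A *separation state* is a set of open (denatured) base pairs,
grouped into `r` maximal runs. Its free energy is

```
G(state) = a·r + Σ_{i∈open} b(i) + Q(n_open)
```

* `a` — nucleation (junction) energy per run, default **10.84 kcal/mol**;
* `b(i)` — copolymeric separation energy per opened pair: **0.255**
  (A·T) and **1.301 kcal/mol** (G·C) at 310.15 K; `N` bases use the mean;
* `Q(n)` — the energy of residual superhelicity. The imposed linking
  difference `α = σN/A` (superhelical density `σ = −0.055`, helical repeat
  `A = 10.4` bp/turn) is partially absorbed by opening (`n/A` turns) and by
  inter-strand twist of the open regions (torsional stiffness `C = 3.6`
  kcal/(mol·rad²) per base). Minimizing over that twist analytically gives

  ```
  Q(n) = x²/2 · (4π²·C·K) / (K·n + 4π²·C),   x = α + n/A
  ```

  with quadratic superhelical stiffness `K = 2200·RT/N` for a domain of
  `N` bp; `Q(0) = K·α²/2` is the closed-state energy.

These constants are the standard values of the superhelical strand
separation literature for bacterial DNA at 37 °C and ~0.01 M ionic
strength. They are configuration values (`SiddParameters`); every property
the package asserts (ensemble-oracle agreement, AT-vs-GC ordering,
monotonicity in stress) holds for any physically sensible setting.

### Per-position profile

The destabilization profile is the Boltzmann conditional-mean increment

```
G(x) = ⟨G | x open⟩ − ⟨G⟩
```

at `T = 310.15 K`. Positions that never open in the evaluated ensemble get
a sentinel ceiling value (default 25 kcal/mol), which also caps computed
values so profiles live on one finite scale. Values are floored at zero.

### Restricted ensemble

Full enumeration of all `2^n` states is feasible only for tiny windows and
serves as the test oracle. Production windows use a restricted ensemble:
all states with at most `r_max = 2` separated runs, run lengths up to a cap
(default 150 nt), and energy within `θ = 12 kcal/mol` of the minimum-energy
state, plus the closed state. At `RT ≈ 0.616 kcal/mol` a state at the
cutoff carries a relative weight of `e^(−θ/RT) ≈ 3·10⁻⁹`, so the truncation
is far below numerical relevance; the test suite verifies agreement with
the full ensemble to 10⁻⁶ kcal/mol. Enumeration is branch-and-bound over
single runs and run pairs with pruning bounds that are exact with respect
to `θ` (using the closed form of `Q`), so no qualifying state is missed.
The run-length cap is a computational limit, not part of the model:
sequences whose minimum-energy opening exceeds it (e.g. AT stretches much
longer than 150 nt) would need a larger cap.

### Genome-wide profiles

The genome is scanned with overlapping windows (defaults: 10,000 nt window,
1,000 nt step, so interior positions are covered by exactly 10 windows).
Each window is an independent domain; per-position values are combined by a
weighted average using a triangular kernel peaking at the window centre,
renormalized per position over the windows actually covering it (so
genome ends, flush final windows and circular wrap-around are handled
uniformly, and a constant input aggregates to itself). The kernel choice is
a design decision; any centre-peaked kernel gives near-identical site
calls. Circular genomes wrap windows across the origin. Window profiles may
be computed in worker processes; aggregation order is fixed, so results are
bit-identical for any worker count.

For the synthetic-fixture studies in the test suite and the acceptance
script we use 2,000 nt windows with a 1,000 nt step: at ~100 kb the planted
AT islands dominate any window containing them, and the smaller domain
keeps the whole suite fast while exercising the same code paths as the
genome-scale defaults.

### SIDD sites

Sites are maximal runs of positions with `G(x) ≤ 5.0 kcal/mol` of length
≥ 10 nt, carrying `min_energy = min G(x)`. Sites with `min_energy <
4.0 kcal/mol` are flagged *strong*. The 4.0 threshold is the strict
promoter-strength criterion; the 5.0/10 nt calling defaults are this
package's choice — destabilized flanks of an opening run typically add a
few positions at 1–3 kcal/mol around the AT core, so sites are slightly
wider than the underlying islands.

## Terminator detection and scoring

The internal detector enumerates stem-loop candidates on both strands:
stems of 4–20 pairs (Watson–Crick plus G·U wobble, at most one internal
mismatch, grown maximally outwards from the innermost pair), loops of
3–13 nt, and a 15 nt tail 3′ of the stem. Scores:

* stem: sum of pair weights (G·C +3, A·T +2, G·U +1, mismatch −3);
* loop: `−0.5·|len − 8|`;
* tail: `Σ_{i=1..15} [tailᵢ = U]·(16−i)/15` (stem-proximal U's dominate).

Confidence is `round(100·σ(c₀ + c₁·stem + c₂·loop + c₃·tail))` with
defaults `c₀ = −4.0, c₁ = 0.13, c₂ = 0.10, c₃ = 0.45`, clipped to [0,100]
and strictly increasing in stem and tail scores. The coefficients were
calibrated once on planted-versus-background distributions
(`scripts/calibrate_terminators.py`): planted strong terminators (perfect
≥ 8 bp G:C stem, U8 tail) score ≥ 76 — the *high confidence* mark — while
background hairpins in G+C-rich sequence have median confidence ~6 and
only ~0.1 % reach the default reporting threshold of 50. The scorer is a
transparent surrogate with documented behaviour, not a numerical clone of
TransTermHP; users wanting that tool's exact confidences can supply its
output file, which is parsed into the same `Terminator` stream
(minus-strand records with descending coordinates are normalized; the tail
is taken as the 15 nt 3′ of the reported extent).

A terminator's *position* for transcript calling is its `tail_end` — the 3′
extremity of the tail on its strand — because an intrinsic terminator is
considered part of the transcript it terminates.

## Transcript decision procedure

1. **Association** (flank 100 nt): a strandless SIDD site is attached to a
   locus if it overlaps the locus extended by the flank on both ends; a
   terminator if its stem-loop overlaps the locus extended by the flank
   downstream on the terminator's strand.
2. **Per-site prediction**, for each associated site on each strand:
   terminators strictly downstream of the site are scanned with tails
   inside the locus + flank; if that window holds none, the scan widens
   genome-wide to 1 kb past the locus (a cap that keeps predictions inside
   a plausible local context). The first terminator with confidence ≥ 76
   stops extension immediately; otherwise the highest-confidence candidate
   is used (ties go to the nearest). With no terminator at all the
   transcript runs to the locus boundary — but only when no part of the
   site lies within 150 nt upstream of a same-strand coding gene start
   (otherwise the site is attributable to that gene's promoter and the
   prediction is suppressed). The 5′ end is always the site's upstream
   boundary; the whole site is included because a precise transcription
   start cannot be read off a destabilized region.
3. **Same-strand joining**: overlapping same-strand predictions merge. The
   merged transcript keeps the higher-confidence terminator and the most
   upstream SIDD site, and its boundaries are re-derived from those
   anchors (5′ = most upstream 5′ extremity, 3′ = kept terminator's tail
   end). Re-deriving instead of taking the raw interval union preserves
   the anchoring invariant when a weaker prediction reaches past the best
   terminator — which happens systematically, because a terminator's
   U-rich tail is itself mildly destabilized and can seed a secondary SIDD
   site just 3′ of the stem.
4. **Opposite-strand resolution**: for every overlapping +/− pair the
   prediction with the higher terminator confidence survives
   (terminator-less predictions rank lowest; ties: the longer transcript,
   then the plus strand). The other is re-anchored to the nearest
   same-strand terminator downstream of its site that clears the overlap,
   or discarded. The loop runs to a fixed point, so no opposite-strand
   overlaps survive.
5. **Classification and categorization**: a locus is *transcript* iff at
   least one surviving prediction originated from it (including merges). A
   transcript overlapping a same-strand gene by ≥ 1 nt is *sense_overlap*
   (this takes precedence when both strands are overlapped), else
   opposite-strand overlap makes it *antisense*, else *intergenic*.
6. **Annotation comparison** (benchmarking): a known ncRNA is matched on
   the same strand when a same-strand transcript covers ≥ 50 % of it,
   matched on the wrong strand when only an opposite-strand transcript
   does, else unmatched; transcripts explaining nothing are putative
   novel.

Tie-break rules, the 150 nt gene-attribution margin, the 100 nt flank and
the 1 kb scan cap are design choices of this package, documented here
because no principled value exists; all are configurable.

## Synthetic fixtures

The generator emulates a G+C-rich (72 %) bacterial replicon — the regime
where SIDD signals are most informative, since AT islands dominate the
profile. Each planted transcript is an AT-rich island (40–80 nt, ≥ 80 %
A/T), a spacer, and a strong terminator (pure G:C stem, U8 tail) whose
guard bases are chosen so the detected stem cannot extend into the tail,
making the expected 3′ coordinate exact. Genes are placed to realize each
category; loci cover island-to-terminator; strands alternate. The
generator redraws a slot's background when a spurious hairpin scores ≥ 70
near the locus or ≥ 76 within the caller's scan reach, so planted
terminators are always the signals the caller should select.

What the fixtures do **not** emulate: real promoter architecture (SIDD
sites in vivo are neither perfectly AT-contiguous nor always present),
Rho-dependent termination, overlapping/polycistronic transcription units,
long ncRNAs spanning several loci, and sequencing-derived locus noise.
Passing the planted-truth tests therefore demonstrates that the decision
machinery implements its rules exactly — not that real-genome accuracy
reaches any particular level.

## Numerical and degenerate-input choices

* Energies in kcal/mol throughout; `R = 1.987·10⁻³ kcal/(mol·K)`.
* Boltzmann weights are computed relative to the ensemble minimum, so no
  overflow occurs; never-open positions are detected by an exactly zero
  conditional weight.
* Genomes shorter than the window fall back to a single whole-genome
  window; a step that does not divide the (possibly clipped) window
  collapses to one window rather than producing uneven coverage.
* Unknown bases map to `N` (mean separation energy, no hairpin pairing).
* The profile cache is keyed by a SHA-256 digest of the genome sequence
  plus all SIDD parameters; mismatches are logged and recomputed, never
  silently reused.
* All output orderings (GFF rows, site/terminator lists) are total, so
  repeated runs are byte-identical for any worker count.

## Known limitations

* Only Rho-independent termination is modelled; transcripts terminated
  Rho-dependently will be truncated at the locus boundary or missed.
* Long ncRNAs fragmented across several input loci are not stitched.
* The SIDD run-length cap (150 nt) bounds the size of a single opening;
  extreme AT stretches need a larger cap at quadratic cost.
* The internal terminator confidence is calibrated, not thermodynamic; it
  will not numerically match TransTermHP.
* tRNA/operon-specific transcription (polycistronic units) is outside the
  model.
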