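#!/usr/bin/env python
"""Report terminator-confidence score distributions for calibration.

Evaluates the logistic scoring coefficients by printing confidence
statistics for (a) planted strong terminators (perfect >= 8 bp G:C stems,
U8 tails) and (b) background hairpins in G+C-rich random sequence.  The
shipped defaults were chosen so planted terminators clear the
high-confidence mark (76) while typical background stays below the
reporting threshold (50).

Usage:  python scripts/calibrate_terminators.py [--seed 0]
"""

from __future__ import annotations

import argparse
import statistics

import numpy as np

from ncscribe.io import Genome
from ncscribe.terminators import (HIGH_CONFIDENCE, ScoringCoefficients,
                                  find_hairpins, score_terminator)

_COMP = str.maketrans("ACGT", "TGCA")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-planted", type=int, default=50)
    args = ap.parse_args()
    rng = np.random.default_rng(args.seed)
    bg = lambda n: "".join(rng.choice(list("ACGT"), n,
                                      p=[0.14, 0.36, 0.36, 0.14]))
    coeffs = ScoringCoefficients()
    print(f"coefficients: {coeffs}")

    planted_confs = []
    for _ in range(args.n_planted):
        stem_len = int(rng.integers(8, 13))
        stem = "".join(rng.choice(list("GC"), stem_len))
        loop = "".join(rng.choice(list("ACGT"), int(rng.integers(3, 9))))
        plant = "CC" + stem + loop + stem.translate(_COMP)[::-1] + "T" * 8 + bg(7)
        seq = bg(200) + plant + bg(200)
        g = Genome(id="p", seq=seq)
        s5 = 203
        s3e = 202 + 2 * stem_len + len(loop)
        cands = [score_terminator(h) for h in find_hairpins(g, "+")
                 if h.start == s5 and h.end == s3e]
        if cands:
            planted_confs.append(max(t.confidence for t in cands))
    print(f"planted strong terminators (n={len(planted_confs)}): "
          f"min={min(planted_confs)} median={statistics.median(planted_confs)} "
          f"max={max(planted_confs)}")
    print(f"  all >= {HIGH_CONFIDENCE}: "
          f"{all(c >= HIGH_CONFIDENCE for c in planted_confs)}")

    g = Genome(id="b", seq=bg(50_000))
    background = [score_terminator(h).confidence
                  for strand in "+-" for h in find_hairpins(g, strand)]
    background.sort()
    q = lambda p: background[int(p * (len(background) - 1))]
    print(f"background hairpins (n={len(background)}): "
          f"median={q(0.5)} p90={q(0.9)} p99={q(0.99)} max={background[-1]}")
    print(f"  fraction above reporting threshold 50: "
          f"{sum(c >= 50 for c in background) / len(background):.4f}")


if __name__ == "__main__":
    main()
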