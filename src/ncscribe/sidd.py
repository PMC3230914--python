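"""Stress-induced duplex destabilization (SIDD) profiles and site calling.

Negatively supercoiled DNA preferentially denatures at susceptible (AT-rich)
positions because local strand separation relaxes part of the imposed
superhelical stress.  The SIDD model assigns every separation state of a
superhelical domain a free energy composed of

* a nucleation (junction) penalty ``a`` per contiguous separated run,
* a copolymeric base-pair separation energy ``b(i)`` per opened position
  (``b_AT < b_GC``), and
* a residual-superhelicity term ``Q(n)`` that penalizes the supercoiling not
  absorbed by opening ``n`` base pairs, after analytic minimization over the
  inter-strand twist of the open regions.

The per-position destabilization profile ``G(x)`` is the Boltzmann-expected
extra free energy required to have position ``x`` open::

    G(x) = <G | x open> - <G>

evaluated over either the complete ``2^n`` state ensemble (small windows,
used as the test oracle) or a restricted ensemble of biologically plausible
states (few separated runs, energies close to the ensemble minimum).
Contiguous low-``G(x)`` stretches are reported as strandless SIDD sites and
serve as promoter-region proxies for the 5' ends of predicted transcripts.
"""

from __future__ import annotations

import hashlib
import json
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import Genome

__all__ = [
    "SiddParameters",
    "SeparationState",
    "SiddProfile",
    "SiddSite",
    "state_energy",
    "residual_energy",
    "profile_exact",
    "profile_windowed",
    "aggregate_windows",
    "window_starts",
    "call_sidd_sites",
    "save_profile",
    "load_profile",
]

#: energy assigned to positions that never open in the evaluated ensemble;
#: also caps computed values so profiles stay on one finite scale
_DEFAULT_CEILING = 25.0

_MAX_EXACT_N = 18


@dataclass(frozen=True)
class SiddParameters:
    """Physical parameters of the superhelical strand-separation model.

    Defaults are the standard values used for bacterial DNA at 37 degC
    (0.01 M ionic conditions): separation energies ``b_AT`` = 0.255 and
    ``b_GC`` = 1.301 kcal/mol, nucleation energy ``a`` = 10.84 kcal/mol,
    torsional stiffness of denatured regions ``C`` = 3.6 kcal/(mol rad^2)
    per base, and a quadratic superhelical stiffness ``K = 2200 RT / N``
    where ``N`` is the domain (window) length.
    """

    temperature: float = 310.15            # K
    gas_constant: float = 1.987e-3         # kcal/(mol K)
    sigma: float = -0.055                  # superhelical density (negative)
    helical_repeat: float = 10.4           # bp/turn (A)
    nucleation_energy: float = 10.84       # kcal/mol per separated run (a)
    b_at: float = 0.255                    # kcal/mol per opened A:T pair
    b_gc: float = 1.301                    # kcal/mol per opened G:C pair
    torsional_stiffness: float = 3.6       # C, kcal/(mol rad^2) per open base
    stiffness_coefficient: float = 2200.0  # K = coeff * R * T / N
    max_runs: int = 2                      # r_max for the restricted ensemble
    energy_cutoff: float = 12.0            # theta, kcal/mol above G_min
    ceiling: float = _DEFAULT_CEILING      # cap / sentinel for G(x)

    def __post_init__(self) -> None:
        if self.sigma >= 0:
            raise ValueError("superhelical density sigma must be negative")
        if self.max_runs < 1:
            raise ValueError("max_runs must be >= 1")
        if self.energy_cutoff <= 0:
            raise ValueError("energy_cutoff must be positive")

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature

    def separation_energies(self, seq: str) -> np.ndarray:
        """Per-position opening energies; N counts as the A/T-G/C mean."""
        b = np.empty(len(seq))
        lut = {
            "A": self.b_at, "T": self.b_at,
            "G": self.b_gc, "C": self.b_gc,
            "N": 0.5 * (self.b_at + self.b_gc),
        }
        for i, ch in enumerate(seq):
            try:
                b[i] = lut[ch]
            except KeyError:
                raise ValueError(f"unexpected base {ch!r} in sequence")
        return b

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass(frozen=True)
class SeparationState:
    """A strand-separation state: the set of open positions in a window.

    Positions are 0-based offsets into the window sequence.  The fully
    closed state has zero runs.
    """

    open_positions: frozenset

    @property
    def runs(self) -> int:
        pos = sorted(self.open_positions)
        if not pos:
            return 0
        return 1 + sum(1 for a, b in zip(pos, pos[1:]) if b - a > 1)

    @property
    def n_open(self) -> int:
        return len(self.open_positions)


def residual_energy(n_open: float, domain_length: int, params: SiddParameters):
    """Free energy of residual superhelicity with ``n_open`` separated bp.

    The imposed linking difference ``alpha = sigma * N / A`` is partially
    relaxed by opening (``n/A`` turns) and by twisting the open strands
    about each other; minimizing analytically over that twist leaves a
    quadratic in the unabsorbed linking difference ``x = alpha + n/A``::

        Q(n) = x^2 / 2 * (4 pi^2 C K) / (K n + 4 pi^2 C)

    which reduces to ``K alpha^2 / 2`` for the closed state.  Accepts
    scalars or arrays for ``n_open``.
    """
    n = np.asarray(n_open, dtype=float)
    A = params.helical_repeat
    alpha = params.sigma * domain_length / A
    K = params.stiffness_coefficient * params.rt / domain_length
    fp2c = 4.0 * np.pi ** 2 * params.torsional_stiffness
    x = alpha + n / A
    q = 0.5 * x ** 2 * (fp2c * K) / (K * n + fp2c)
    return q if q.ndim else float(q)


def state_energy(state: SeparationState, window_seq: str,
                 params: SiddParameters) -> float:
    """Free energy of one separation state (reference implementation).

    ``G = a r + sum_i b(i) + Q(n_open)``.  Total on all valid states; the
    vectorized enumerators must agree with this function exactly.
    """
    n = len(window_seq)
    if state.open_positions and (min(state.open_positions) < 0
                                 or max(state.open_positions) >= n):
        raise ValueError("open positions outside the window")
    b = params.separation_energies(window_seq)
    bsum = float(b[sorted(state.open_positions)].sum()) if state.open_positions else 0.0
    return (params.nucleation_energy * state.runs
            + bsum
            + residual_energy(state.n_open, n, params))


# ---------------------------------------------------------------------------
# ensemble enumeration


def _profile_from_states(n: int, weights: np.ndarray, energies: np.ndarray,
                         starts: Sequence[np.ndarray], ends: Sequence[np.ndarray],
                         which: Sequence[np.ndarray], params: SiddParameters):
    """Turn an enumerated state set into the per-position G(x) profile.

    ``starts``/``ends`` list interval arrays (0-based, end exclusive) and
    ``which`` maps each interval to its state index.
    """
    total_w = float(weights.sum())
    total_wg = float((weights * energies).sum())
    dw = np.zeros(n + 1)
    dwg = np.zeros(n + 1)
    for s, e, k in zip(starts, ends, which):
        w = weights[k]
        wg = w * energies[k]
        np.add.at(dw, s, w)
        np.add.at(dw, e, -w)
        np.add.at(dwg, s, wg)
        np.add.at(dwg, e, -wg)
    open_w = np.cumsum(dw)[:n]
    open_wg = np.cumsum(dwg)[:n]
    prof = np.full(n, params.ceiling)
    seen = open_w > 0.0
    prof[seen] = open_wg[seen] / open_w[seen] - total_wg / total_w
    return np.clip(prof, 0.0, params.ceiling)


def _enumerate_full(seq: str, params: SiddParameters):
    """All 2^n separation states; only feasible for short windows."""
    n = len(seq)
    if n > _MAX_EXACT_N:
        raise ValueError(
            f"unrestricted enumeration needs 2^n states; n={n} exceeds the "
            f"supported maximum of {_MAX_EXACT_N}")
    b = params.separation_energies(seq)
    codes = np.arange(1 << n, dtype=np.uint32)
    bits = ((codes[:, None] >> np.arange(n, dtype=np.uint32)) & 1).astype(bool)
    n_open = bits.sum(axis=1)
    # a run starts wherever an open position has no open left neighbour
    starts_mask = bits & ~np.pad(bits, ((0, 0), (1, 0)))[:, :n]
    runs = starts_mask.sum(axis=1)
    energies = (params.nucleation_energy * runs
                + bits @ b
                + residual_energy(n_open, n, params))
    return bits, energies


def _restricted_states(seq: str, params: SiddParameters,
                       max_run_length: int | None = None):
    """Enumerate low-energy states with at most ``max_runs`` separated runs.

    Exact with respect to the ``energy_cutoff`` (theta) filter: every state
    with ``r <= max_runs``, run lengths within the cap, and
    ``G <= G_min + theta`` is produced.  The branch-and-bound prune uses the
    closed-form Q, so no qualifying two-run state is missed.
    """
    n = len(seq)
    b = params.separation_energies(seq)
    lmax = n if max_run_length is None else min(max_run_length, n)
    a = params.nucleation_energy
    theta = params.energy_cutoff
    prefix = np.concatenate(([0.0], np.cumsum(b)))
    q = residual_energy(np.arange(2 * lmax + 1), n, params)
    g_closed = float(q[0])

    # single-run states, grouped by run length
    bs_by_len = {}      # l -> bsum array over starts 0..n-l
    g1_min = np.inf
    for l in range(1, lmax + 1):
        bs = prefix[l:] - prefix[:-l]
        bs_by_len[l] = bs
        m = float(bs.min()) + a + q[l]
        g1_min = min(g1_min, m)
    gmin_est = min(g_closed, g1_min)

    r1_starts, r1_lens, r1_g = [], [], []
    for l in range(1, lmax + 1):
        g = a + bs_by_len[l] + q[l]
        keep = np.nonzero(g <= gmin_est + theta)[0]
        if keep.size:
            r1_starts.append(keep)
            r1_lens.append(np.full(keep.size, l))
            r1_g.append(g[keep])

    # two-run states: for every ordered pair of run lengths, select the
    # run pairs whose combined opening energy can stay within theta of the
    # current minimum; the bound is exact, so nothing qualifying is missed
    pair_s1 = []
    pair_l1 = []
    pair_s2 = []
    pair_l2 = []
    pair_g = []
    if params.max_runs >= 2 and lmax >= 1:
        qlist = [float(v) for v in q]
        order = {l: np.argsort(bs_by_len[l], kind="stable") for l in bs_by_len}
        sorted_bs = {l: bs_by_len[l][order[l]] for l in bs_by_len}
        min_bs = [0.0] + [float(sorted_bs[l][0]) for l in range(1, lmax + 1)]
        budget = gmin_est + theta - 2.0 * a
        n_pairs = 0
        for l1 in range(1, lmax + 1):
            mb1 = min_bs[l1]
            for l2 in range(l1, lmax + 1):
                t = budget - qlist[l1 + l2]
                if mb1 + min_bs[l2] > t:
                    continue
                bs1_all, ord1 = sorted_bs[l1], order[l1]
                bs2_all, ord2 = sorted_bs[l2], order[l2]
                n1 = int(np.searchsorted(bs1_all, t - min_bs[l2], "right"))
                bs1 = bs1_all[:n1]
                counts = np.searchsorted(bs2_all, t - bs1, "right")
                total = int(counts.sum())
                if not total:
                    continue
                n_pairs += total
                if n_pairs > 5_000_000:
                    raise RuntimeError(
                        "restricted ensemble exploded; tighten energy_cutoff "
                        "or the run-length cap")
                i1 = np.repeat(np.arange(n1), counts)
                i2 = np.arange(total) - np.repeat(
                    np.cumsum(counts) - counts, counts)
                s1 = ord1[i1]
                s2 = ord2[i2]
                # runs must be disjoint with a closed gap between them
                # (adjacent runs are one run, already enumerated as r=1)
                ok = (s2 > s1 + l1) | (s2 + l2 < s1)
                if l1 == l2:
                    ok &= s2 > s1  # count unordered same-length pairs once
                if not ok.any():
                    continue
                s1, s2 = s1[ok], s2[ok]
                g = 2.0 * a + bs1[i1[ok]] + bs2_all[i2[ok]] + qlist[l1 + l2]
                lo_is_1 = s1 <= s2
                pair_s1.append(np.where(lo_is_1, s1, s2))
                pair_l1.append(np.where(lo_is_1, l1, l2))
                pair_s2.append(np.where(lo_is_1, s2, s1))
                pair_l2.append(np.where(lo_is_1, l2, l1))
                pair_g.append(g)

    if pair_g:
        pair_s1 = np.concatenate(pair_s1)
        pair_l1 = np.concatenate(pair_l1)
        pair_s2 = np.concatenate(pair_s2)
        pair_l2 = np.concatenate(pair_l2)
        pair_g = np.concatenate(pair_g)
        gmin = min(gmin_est, float(pair_g.min()))
    else:
        pair_g = np.empty(0)
        gmin = gmin_est
    cut = gmin + theta

    out_starts, out_ends, out_which = [], [], []
    energies = [g_closed]  # closed state always retained
    k = 1
    for st, ln, g in zip(r1_starts, r1_lens, r1_g):
        keep = g <= cut
        st, ln, g = st[keep], ln[keep], g[keep]
        if st.size:
            idx = np.arange(k, k + st.size)
            out_starts.append(st)
            out_ends.append(st + ln)
            out_which.append(idx)
            energies.append(g)
            k += st.size
    if pair_g.size:
        keep = pair_g <= cut
        if keep.any():
            s1, l1 = pair_s1[keep], pair_l1[keep]
            s2, l2 = pair_s2[keep], pair_l2[keep]
            g = pair_g[keep]
            idx = np.arange(k, k + g.size)
            out_starts.extend([s1, s2])
            out_ends.extend([s1 + l1, s2 + l2])
            out_which.extend([idx, idx])
            energies.append(g)
            k += g.size
    energies = np.concatenate([np.atleast_1d(e) for e in energies])
    return energies, out_starts, out_ends, out_which


def profile_exact(window_seq: str, params: SiddParameters | None = None,
                  restrict: bool = True,
                  max_run_length: int | None = None) -> np.ndarray:
    """Per-position destabilization energies ``G(x)`` for one window.

    With ``restrict=False`` every one of the ``2^n`` separation states is
    enumerated (test oracle; n is limited).  With ``restrict=True`` only
    states with at most ``params.max_runs`` runs and energies within
    ``params.energy_cutoff`` of the minimum are used, plus the closed state.
    """
    params = params or SiddParameters()
    seq = window_seq.upper()
    n = len(seq)
    if n == 0:
        return np.empty(0)
    if not restrict:
        bits, energies = _enumerate_full(seq, params)
        gmin = float(energies.min())
        w = np.exp(-(energies - gmin) / params.rt)
        total_w = float(w.sum())
        total_wg = float((w * energies).sum())
        open_w = bits.T @ w
        open_wg = bits.T @ (w * energies)
        prof = np.full(n, params.ceiling)
        seen = open_w > 0.0
        prof[seen] = open_wg[seen] / open_w[seen] - total_wg / total_w
        return np.clip(prof, 0.0, params.ceiling)
    energies, starts, ends, which = _restricted_states(seq, params, max_run_length)
    gmin = float(energies.min())
    w = np.exp(-(energies - gmin) / params.rt)
    return _profile_from_states(n, w, energies, starts, ends, which, params)


# ---------------------------------------------------------------------------
# sliding-window genome profiles


@dataclass
class SiddProfile:
    """Genome-wide SIDD profile (one value per position, kcal/mol)."""

    values: np.ndarray
    window: int
    step: int
    params: SiddParameters

    def __post_init__(self) -> None:
        if self.window % self.step:
            raise ValueError("window must be divisible by step")


def window_starts(length: int, window: int, step: int, circular: bool):
    """0-based start offsets of the sliding windows covering a genome."""
    if circular:
        return list(range(0, length, step))
    if length <= window:
        return [0]
    last = length - window
    starts = list(range(0, last + 1, step))
    if starts[-1] != last:
        starts.append(last)  # flush final window so every position is covered
    return starts


def _window_weights(window: int) -> np.ndarray:
    """Triangular kernel peaking at the window center (unnormalized)."""
    x = np.arange(window, dtype=float)
    c = (window - 1) / 2.0
    return (window / 2.0) - np.abs(x - c)


def _window_profile(args) -> np.ndarray:
    seq, params, max_run_length = args
    return profile_exact(seq, params, restrict=True,
                         max_run_length=max_run_length)


def aggregate_windows(starts: Sequence[int], profiles: Sequence[np.ndarray],
                      length: int, window: int,
                      circular: bool = False) -> np.ndarray:
    """Per-position weighted average of overlapping window profiles.

    Window weights follow a triangular kernel peaking at the window center
    and are renormalized per position over the windows actually covering
    it, so a constant set of window profiles aggregates to that constant.
    """
    kernel = _window_weights(window)
    acc = np.zeros(length)
    wsum = np.zeros(length)
    for s, prof in zip(starts, profiles):
        idx = np.arange(s, s + window) % length if circular \
            else np.arange(s, s + window)
        acc[idx] += kernel * prof
        wsum[idx] += kernel
    return acc / wsum


def profile_windowed(genome: Genome, params: SiddParameters | None = None,
                     window: int = 10000, step: int = 1000,
                     workers: int = 1,
                     max_run_length: int | None = 150) -> SiddProfile:
    """Sliding-window SIDD profile of a whole replicon.

    Each window is treated as an independent superhelical domain and its
    restricted-ensemble profile computed; overlapping window values are
    combined per position by a weighted average whose (triangular) weights
    favour windows in which the position lies near the center, normalized to
    sum to one.  Interior positions receive exactly ``window // step``
    contributions.  The result is independent of ``workers``: windows are
    aggregated in a fixed order whatever the executor schedule.
    """
    params = params or SiddParameters()
    if window % step:
        raise ValueError("window must be divisible by step")
    seq = genome.seq
    n = len(seq)
    circular = genome.topology == "circular"
    win = min(window, n)
    stp = min(step, win)
    if win % stp:
        stp = win  # degenerate tiny genome: single-window fallback
    starts = window_starts(n, win, stp, circular)
    seqs = []
    for s in starts:
        if s + win <= n:
            seqs.append(seq[s:s + win])
        else:  # circular wrap
            seqs.append(seq[s:] + seq[:s + win - n])
    jobs = [(ws, params, max_run_length) for ws in seqs]
    if workers > 1:
        with ProcessPoolExecutor(max_workers=workers) as ex:
            profiles = list(ex.map(_window_profile, jobs, chunksize=1))
    else:
        profiles = [_window_profile(j) for j in jobs]

    values = aggregate_windows(starts, profiles, n, win, circular)
    return SiddProfile(values=values, window=win, step=stp, params=params)


# ---------------------------------------------------------------------------
# site calling


@dataclass(frozen=True)
class SiddSite:
    """Maximal strandless run of destabilized positions (1-based inclusive)."""

    start: int
    end: int
    min_energy: float

    STRONG_THRESHOLD = 4.0  # kcal/mol, strict promoter-strength criterion

    @property
    def strong(self) -> bool:
        return self.min_energy < self.STRONG_THRESHOLD

    def __len__(self) -> int:
        return self.end - self.start + 1


def call_sidd_sites(profile: SiddProfile | np.ndarray, threshold: float = 5.0,
                    min_len: int = 10) -> list[SiddSite]:
    """Maximal runs with ``G(x) <= threshold`` of length >= ``min_len``."""
    values = profile.values if isinstance(profile, SiddProfile) else np.asarray(profile)
    below = values <= threshold
    sites: list[SiddSite] = []
    if not below.any():
        return sites
    padded = np.concatenate(([False], below, [False]))
    d = np.diff(padded.astype(np.int8))
    run_starts = np.nonzero(d == 1)[0]
    run_ends = np.nonzero(d == -1)[0]  # exclusive
    for s, e in zip(run_starts, run_ends):
        if e - s >= min_len:
            sites.append(SiddSite(start=int(s) + 1, end=int(e),
                                  min_energy=float(values[s:e].min())))
    return sites


# ---------------------------------------------------------------------------
# persistence (text profile + parameter sidecar, used by the pipeline cache)


def save_profile(profile: SiddProfile, path: str | Path,
                 genome: Genome | None = None) -> None:
    """Write a profile as two columns (position, energy) plus a sidecar."""
    path = Path(path)
    with path.open("w") as fh:
        for i, v in enumerate(profile.values, start=1):
            fh.write(f"{i}\t{v:.6f}\n")
    meta = {
        "window": profile.window,
        "step": profile.step,
        "params": asdict(profile.params),
    }
    if genome is not None:
        meta["genome_sha256"] = hashlib.sha256(genome.seq.encode()).hexdigest()
        meta["genome_id"] = genome.id
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n")


def load_profile(path: str | Path) -> tuple[SiddProfile, dict]:
    """Read a saved profile; returns the profile and its sidecar metadata."""
    path = Path(path)
    data = np.loadtxt(path, ndmin=2)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    params = SiddParameters(**meta["params"])
    prof = SiddProfile(values=data[:, 1], window=meta["window"],
                       step=meta["step"], params=params)
    return prof, meta
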