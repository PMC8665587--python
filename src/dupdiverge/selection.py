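"""Pairwise dN/dS by the Nei–Gojobori (1986) counting method with the
Jukes–Cantor multiple-hit correction, plus sliding-window selection scans.

Synonymous/nonsynonymous *sites* are counted per codon as the fraction of
single-base alternatives that preserve the amino acid; mutations that would
create a stop codon are excluded from the denominator (renormalisation), so
``s_sites + n_sites == 3`` always holds for sense codons.  *Differences*
between two codons are averaged over all orderings of the differing positions,
excluding pathways that pass through stop codons (with a flagged fallback to
all pathways when every ordering hits a stop).

Selection classes follow the threshold heuristic used for sliding windows:
dN/dS > 1.5 → POSITIVE, < 0.67 → PURIFYING, else INTERMEDIATE; windows where
dS = 0 have no defined ratio and are UNDEFINED.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)

OMEGA_POSITIVE = 1.5
OMEGA_PURIFYING = 0.67

POSITIVE = "POSITIVE"
PURIFYING = "PURIFYING"
INTERMEDIATE = "INTERMEDIATE"
UNDEFINED = "UNDEFINED"

_sites_cache: dict[str, tuple[float, float]] = {}


def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous sites, nonsynonymous sites) for one sense codon.

    Per position, the synonymous fraction over the three alternative bases;
    alternatives creating stops are dropped from the denominator.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon}")
    if codon not in CODON_TABLE:
        raise ValueError(f"ambiguous or invalid codon {codon!r}")
    cached = _sites_cache.get(codon)
    if cached is not None:
        return cached
    aa = CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        counted = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if mut in STOP_CODONS:
                continue
            counted += 1
            if CODON_TABLE[mut] == aa:
                syn += 1
        if counted:
            s += syn / counted
    result = (s, 3.0 - s)
    _sites_cache[codon] = result
    return result


def codon_differences(codonA: str, codonB: str) -> tuple[float, float, bool]:
    """(synonymous diffs, nonsynonymous diffs, stop_fallback_flag).

    Averages step classifications over all orderings of the differing
    positions; orderings passing through a stop codon are excluded and the
    remainder renormalised.  If every ordering hits a stop, all orderings are
    used and the flag is set.
    """
    a, b = codonA.upper(), codonB.upper()
    for c in (a, b):
        if c in STOP_CODONS or c not in CODON_TABLE:
            raise ValueError(f"invalid or stop codon {c!r}")
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0, False

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        cur = a
        sd = nd = 0
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                return None
            if CODON_TABLE[cur] == CODON_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    paths = [walk(o) for o in permutations(diff_pos)]
    valid = [p for p in paths if p is not None]
    fallback = not valid
    if fallback:
        # every ordering passes through a stop: count steps ignoring stops
        def walk_any(order):
            cur = a
            sd = nd = 0
            for pos in order:
                nxt = cur[:pos] + b[pos] + cur[pos + 1:]
                same = (cur not in STOP_CODONS and nxt not in STOP_CODONS
                        and CODON_TABLE[cur] == CODON_TABLE[nxt])
                if same:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            return sd, nd

        valid = [walk_any(o) for o in permutations(diff_pos)]
    sd = sum(p[0] for p in valid) / len(valid)
    nd = sum(p[1] for p in valid) / len(valid)
    return sd, nd, fallback


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction d = −(3/4)·ln(1 − 4p/3); domain 0 ≤ p < 3/4."""
    if not 0.0 <= p < 0.75:
        raise ValueError(f"proportion {p} outside [0, 0.75): saturated")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class DnDsResult:
    """NG86 site/difference counts and JC-corrected rates for one pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    n_codons: int
    n_dropped_codons: int = 0
    n_stop_fallbacks: int = 0
    saturated: bool = False

    @property
    def pS(self) -> float:
        return self.Sd / self.S if self.S > 0 else 0.0

    @property
    def pN(self) -> float:
        return self.Nd / self.N if self.N > 0 else 0.0

    @property
    def dS(self) -> float | None:
        try:
            return jukes_cantor(self.pS)
        except ValueError:
            return None

    @property
    def dN(self) -> float | None:
        try:
            return jukes_cantor(self.pN)
        except ValueError:
            return None

    @property
    def omega(self) -> float | None:
        """dN/dS; None (UNDEFINED) when dS is 0 or either rate is saturated."""
        ds, dn = self.dS, self.dN
        if ds is None or dn is None or ds == 0.0:
            return None
        return dn / ds

    def as_dict(self) -> dict:
        return {
            "S": self.S, "N": self.N, "Sd": self.Sd, "Nd": self.Nd,
            "pS": self.pS, "pN": self.pN, "dS": self.dS, "dN": self.dN,
            "omega": self.omega, "n_codons": self.n_codons,
        }


def _codons(seq: str) -> list[str]:
    return [seq[i: i + 3] for i in range(0, len(seq), 3)]


def pairwise_dnds(cdsA: str, cdsB: str) -> DnDsResult:
    """NG86 + JC on an in-frame pairwise codon alignment.

    Codons containing gaps, Ns or stops in either sequence are dropped pairwise.
    S and N are the averages of the two sequences' site counts.
    """
    cdsA, cdsB = cdsA.upper(), cdsB.upper()
    if len(cdsA) != len(cdsB):
        raise ValueError("sequences must be aligned to equal length")
    if len(cdsA) % 3:
        raise ValueError(f"alignment length {len(cdsA)} not divisible by 3")
    S = N = Sd = Nd = 0.0
    n_used = n_dropped = n_fallback = 0
    for ca, cb in zip(_codons(cdsA), _codons(cdsB)):
        ok = all(c in CODON_TABLE for c in (ca, cb))
        if not ok:
            n_dropped += 1
            continue
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd, fb = codon_differences(ca, cb)
        Sd += sd
        Nd += nd
        n_fallback += fb
        n_used += 1
    if n_used == 0:
        raise ValueError("no comparable codons after pairwise deletion")
    res = DnDsResult(S=S, N=N, Sd=Sd, Nd=Nd, n_codons=n_used,
                     n_dropped_codons=n_dropped, n_stop_fallbacks=n_fallback)
    res.saturated = res.dS is None or res.dN is None
    return res


def classify_selection(omega: float | None) -> str:
    """Threshold calls: > 1.5 POSITIVE, < 0.67 PURIFYING, else INTERMEDIATE."""
    if omega is None:
        return UNDEFINED
    if omega < 0:
        raise ValueError("negative dN/dS is impossible")
    if omega > OMEGA_POSITIVE:
        return POSITIVE
    if omega < OMEGA_PURIFYING:
        return PURIFYING
    return INTERMEDIATE


@dataclass
class Window:
    start_codon: int  # 0-based codon index of window start
    result: DnDsResult
    selection_class: str


@dataclass
class WindowTrack:
    """Sliding-window dN/dS track (window/step in codons)."""

    window_size: int
    step: int
    windows: list[Window] = field(default_factory=list)
    whole_sequence_fallback: bool = False

    def classes(self) -> list[str]:
        return [w.selection_class for w in self.windows]

    def to_frame(self):
        import pandas as pd

        rows = []
        for w in self.windows:
            d = w.result.as_dict()
            d["start_codon"] = w.start_codon + 1  # report 1-based
            d["selection_class"] = w.selection_class
            rows.append(d)
        return pd.DataFrame(rows)


def sliding_window(cdsA: str, cdsB: str, window: int = 45, step: int = 9) -> WindowTrack:
    """Windowed NG86 scan; window count is floor((L − window)/step) + 1 codons.

    Alignments shorter than one window fall back to a single whole-sequence
    window (flagged).
    """
    if len(cdsA) != len(cdsB) or len(cdsA) % 3:
        raise ValueError("need an equal-length, in-frame alignment")
    L = len(cdsA) // 3
    track = WindowTrack(window_size=window, step=step)
    if L < window:
        res = pairwise_dnds(cdsA, cdsB)
        track.windows.append(Window(0, res, classify_selection(res.omega)))
        track.whole_sequence_fallback = True
        return track
    for start in range(0, L - window + 1, step):
        a = cdsA[3 * start: 3 * (start + window)]
        b = cdsB[3 * start: 3 * (start + window)]
        res = pairwise_dnds(a, b)
        track.windows.append(Window(start, res, classify_selection(res.omega)))
    return track


def nterm_cterm_summary(track: WindowTrack, nterm_codons: int = 50) -> dict:
    """Max dN/dS in windows starting inside the first ``nterm_codons`` codons vs
    the rest, plus whether any C-terminal window is POSITIVE."""
    if not track.windows:
        raise ValueError("empty window track")
    nterm = [w for w in track.windows if w.start_codon < nterm_codons]
    cterm = [w for w in track.windows if w.start_codon + track.window_size > nterm_codons]
    if len(track.windows) == 1:
        nterm = cterm = track.windows

    def max_omega(ws):
        vals = [w.result.omega for w in ws if w.result.omega is not None]
        return max(vals) if vals else None

    return {
        "nterm_max_omega": max_omega(nterm),
        "cterm_max_omega": max_omega(cterm),
        "cterm_positive": any(w.selection_class == POSITIVE for w in cterm),
        "n_nterm_windows": len(nterm),
        "n_cterm_windows": len(cterm),
    }
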