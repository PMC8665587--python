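"""Self-comparison dot matrix and tandem-repeat calling.

The matrix compares every pair of forward-strand windows (stride 1, default
window 30) and keeps pairs agreeing at ≥ ceil(window × min_identity)
positions (18 at the defaults) — the classic dot-plot stringency.  Direct
tandem repeats appear as off-diagonal runs at offsets that are multiples of
the repeat unit; ``call_repeats`` chains collinear matches into runs and
groups runs into repeat regions with a unit-length estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections import Counter

import numpy as np

from .io_models import GeneModel


@dataclass
class DotMatrix:
    seq_id: str
    length: int
    window: int
    min_identity: float
    matches: list[tuple[int, int]] = field(default_factory=list)  # i < j window starts

    @property
    def min_matching(self) -> int:
        return math.ceil(self.window * self.min_identity)


@dataclass
class RepeatCall:
    region: tuple[int, int]     # 0-based half-open sequence span
    unit_length: int
    n_offdiag_runs: int
    mean_offset: float


def self_dot_matrix(seq: str, window: int = 30, min_identity: float = 0.6,
                    seq_id: str = "seq") -> DotMatrix:
    """All off-diagonal window-start pairs (i, j), i < j, whose windows agree
    at ≥ ceil(window × min_identity) positions; forward strand only."""
    L = len(seq)
    if L < window:
        raise ValueError(f"sequence length {L} < window {window}")
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    thr = math.ceil(window * min_identity)
    n_win = L - window + 1
    matches: list[tuple[int, int]] = []
    for d in range(1, n_win):
        eq = (arr[:-d] == arr[d:]).astype(np.int32)
        if eq.size < window:
            break
        c = np.concatenate(([0], np.cumsum(eq)))
        wins = c[window:] - c[:-window]          # wins[i] = agreement of (i, i+d)
        hits = np.nonzero(wins >= thr)[0]
        for i in hits:
            j = int(i) + d
            if j < n_win:
                matches.append((int(i), j))
    matches.sort()
    return DotMatrix(seq_id=seq_id, length=L, window=window,
                     min_identity=min_identity, matches=matches)


def _runs(matrix: DotMatrix, offset_tol: int = 2, min_windows: int = 2) -> list[dict]:
    """Chain matches into collinear runs: same offset ± tol, adjacent starts."""
    by_key = sorted(matrix.matches, key=lambda m: (m[1] - m[0], m[0]))
    runs: list[dict] = []
    cur: list[tuple[int, int]] = []
    for m in by_key:
        d = m[1] - m[0]
        if cur:
            d0 = cur[-1][1] - cur[-1][0]
            if abs(d - d0) <= offset_tol and m[0] - cur[-1][0] <= offset_tol + 1:
                cur.append(m)
                continue
        if len(cur) >= min_windows:
            runs.append(_run_record(cur, matrix.window))
        cur = [m]
    if len(cur) >= min_windows:
        runs.append(_run_record(cur, matrix.window))
    return runs


def _run_record(ms: list[tuple[int, int]], window: int) -> dict:
    offsets = [j - i for i, j in ms]
    start = min(i for i, _ in ms)
    end = max(j for _, j in ms) + window
    i_end = max(i for i, _ in ms) + window
    return {"start": start, "end": end, "i_end": i_end,
            "offset": sum(offsets) / len(offsets), "n_windows": len(ms)}


def call_repeats(matrix: DotMatrix, offset_tol: int = 2,
                 min_windows: int = 2, min_unit: int = 10) -> list[RepeatCall]:
    """Call tandem-repeat regions from periodic off-diagonal runs.

    A tandem array of unit u produces off-diagonal runs at offsets u, 2u, 3u…
    whose matched segments lie *inside the array itself*: the run's query span
    reaches past its own offset (offset ≤ i-span + window).  Runs failing that
    periodicity test connect two distant look-alike segments (dispersed
    similarity, or chance at the dot-plot stringency) and are ignored.
    Periodic runs with overlapping regions are pooled; a pool is called when a
    common unit ≥ ``min_unit`` explains at least two runs including both the
    adjacent-copy offset (k = 1) and the two-copy offset (k = 2), all within
    ± ``offset_tol``.  The unit maximising the number of explained runs wins
    (ties go to the larger unit, since a divisor explains the same runs).
    """
    runs = _runs(matrix, offset_tol=offset_tol, min_windows=min_windows)
    periodic = [r for r in runs
                if r["offset"] >= min_unit
                and r["offset"] <= (r["i_end"] - r["start"])]
    if not periodic:
        return []
    periodic.sort(key=lambda r: r["start"])
    pools: list[list[dict]] = []
    for r in periodic:
        if pools and r["start"] <= max(x["end"] for x in pools[-1]):
            pools[-1].append(r)
        else:
            pools.append([r])
    calls: list[RepeatCall] = []
    for pool in pools:
        call = _call_from_pool(pool, offset_tol, min_unit)
        if call is not None:
            calls.append(call)
    return calls


def _call_from_pool(pool: list[dict], offset_tol: int,
                    min_unit: int) -> RepeatCall | None:
    """Fit a common unit to a pool of periodic runs; None when no signature."""
    offsets = sorted({int(round(r["offset"])) for r in pool})
    gaps = [b - a for a, b in zip(offsets, offsets[1:])]
    candidates = sorted({g for g in gaps if g >= min_unit}
                        | {o for o in offsets if o >= min_unit})
    best: tuple[int, int, list[dict]] | None = None  # (n_fit, unit, kept)
    for u in candidates:
        kept = []
        ks: set[int] = set()
        base_windows = 0
        for r in pool:
            k = max(1, round(r["offset"] / u))
            if abs(r["offset"] - k * u) <= offset_tol:
                kept.append(r)
                ks.add(k)
                if k == 1:
                    base_windows = max(base_windows, r["n_windows"])
        if not {1, 2} <= ks or len(kept) < 2:
            continue
        # the adjacent-copy diagonal is the longest, least-diverged run of a
        # true array; a "unit" whose base run is weaker than its multiples is
        # a harmonic of something else
        if base_windows < max(r["n_windows"] for r in kept):
            continue
        if best is None or (len(kept), u) > (best[0], best[1]):
            best = (len(kept), u, kept)
    if best is None:
        return None
    _, unit, kept = best
    start = min(r["start"] for r in kept)
    end = max(r["end"] for r in kept)
    if end - start < 2 * unit:
        return None
    return RepeatCall(
        region=(start, end),
        unit_length=unit,
        n_offdiag_runs=len(kept),
        mean_offset=sum(r["offset"] for r in kept) / len(kept),
    )


def annotate_introns(gene: GeneModel, calls: list[RepeatCall]):
    """Per-intron overlap with repeat regions (bp and fraction of the intron).

    Repeat-call coordinates are taken in the gene's local (span-relative)
    frame, matching a dot-plot of the gene's own genomic sequence.
    """
    import pandas as pd

    rows = []
    for idx, (s, e) in enumerate(gene.local_introns()):
        ov = 0
        for call in calls:
            cs, ce = call.region
            ov += max(0, min(e, ce) - max(s, cs))
        ov = min(ov, e - s)
        rows.append({"intron_index": idx, "intron_start": s, "intron_end": e,
                     "intron_len": e - s, "repeat_overlap_bp": ov,
                     "repeat_overlap_frac": ov / (e - s) if e > s else 0.0})
    return pd.DataFrame(rows)
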