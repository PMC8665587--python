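"""Tandem-duplication clustering of a gene family from gene order.

Two family members are tandem-linked when they lie on the same chromosome with
no more than ``max_gap`` (default 20) intervening genes in the full gene order;
clusters are the transitive closure (connected components) of that relation,
so chains longer than two can form.  Size-1 components are singletons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_models import GeneCatalog

DEFAULT_MAX_GAP = 20


@dataclass
class TandemCluster:
    chrom: str
    members: list[str]          # ordered by rank
    span: tuple[int, int]       # min start .. max end, genomic bp


@dataclass
class TandemClusterSet:
    clusters: list[TandemCluster]
    singletons: set[str]
    max_gap: int = DEFAULT_MAX_GAP

    @property
    def n_tandem(self) -> int:
        return sum(len(c.members) for c in self.clusters)

    @property
    def n_single(self) -> int:
        return len(self.singletons)

    def membership(self) -> dict[str, int]:
        """gene → cluster index, −1 for singletons."""
        out = {g: -1 for g in self.singletons}
        for i, c in enumerate(self.clusters):
            for g in c.members:
                out[g] = i
        return out


def cluster_tandem(
    catalog: GeneCatalog,
    family: Iterable[str],
    max_gap: int = DEFAULT_MAX_GAP,
    chain: bool = True,
) -> TandemClusterSet:
    """Partition family genes into tandem clusters and singletons.

    A pair is linked iff same chromosome and rank difference ≤ max_gap + 1
    (≤ max_gap intervening genes, family members counted like any other gene).
    With ``chain=False`` only mutually-linked runs form clusters (no transitive
    chaining); the default transitive closure is what allows clusters > 2.
    """
    family = sorted(set(family))
    located: dict[str, list[tuple[int, str]]] = {}
    for gid in family:
        chrom, r = catalog.rank(gid)  # raises KeyError naming unknown ids
        located.setdefault(chrom, []).append((r, gid))

    clusters: list[TandemCluster] = []
    singletons: set[str] = set()
    for chrom in sorted(located):
        ranked = sorted(located[chrom])
        comp: list[tuple[int, str]] = []
        comps: list[list[tuple[int, str]]] = []
        for r, gid in ranked:
            if chain:
                linked = bool(comp) and r - comp[-1][0] <= max_gap + 1
            else:
                # no chaining: every pair in a cluster must satisfy the window,
                # i.e. the component is a clique (max rank − min rank ≤ gap+1)
                linked = bool(comp) and r - comp[0][0] <= max_gap + 1
            if linked:
                comp.append((r, gid))
            else:
                if comp:
                    comps.append(comp)
                comp = [(r, gid)]
        if comp:
            comps.append(comp)
        for comp in comps:
            if len(comp) == 1:
                singletons.add(comp[0][1])
            else:
                members = [gid for _, gid in comp]
                starts, ends = [], []
                for gid in members:
                    _, s, e, _ = catalog.coords(gid)
                    starts.append(s)
                    ends.append(e)
                clusters.append(TandemCluster(chrom=chrom, members=members,
                                              span=(min(starts), max(ends))))
    clusters.sort(key=lambda c: (c.chrom, c.span[0]))
    return TandemClusterSet(clusters=clusters, singletons=singletons, max_gap=max_gap)


def summarize_tandem(tcs: TandemClusterSet, family_size: int) -> dict:
    """Counts and percent-tandem (nearest integer percent) for one family."""
    n_tandem = tcs.n_tandem
    n_single = tcs.n_single
    if n_tandem + n_single != family_size:
        raise ValueError(
            f"family_size {family_size} != {n_single} singletons + {n_tandem} tandem"
        )
    pct = round(100.0 * n_tandem / family_size) if family_size else 0
    return {"n_single": n_single, "n_tandem": n_tandem, "percent_tandem": pct}


def big_clusters(tcs: TandemClusterSet, min_size: int = 5) -> list[TandemCluster]:
    """Clusters with ≥ min_size members, ordered by chromosome then coordinate."""
    return sorted((c for c in tcs.clusters if len(c.members) >= min_size),
                  key=lambda c: (c.chrom, c.span[0]))


@dataclass
class DensityTrack:
    chrom: str
    window_bp: int
    counts: list[int] = field(default_factory=list)


def density_track(
    catalog: GeneCatalog,
    family: Iterable[str],
    window_bp: int = 1_000_000,
) -> list[DensityTrack]:
    """Family-gene counts per fixed genomic window (gene counted at its start).

    The last partial window is included; every chromosome with a known length
    gets a track, so empty chromosomes yield all-zero tracks.
    """
    family = set(family)
    lengths = dict(catalog.chrom_lengths)
    for chrom in catalog.genes:
        if chrom not in lengths:
            lengths[chrom] = max((e for _, _, e, _ in catalog.genes[chrom]), default=0)
    tracks = []
    for chrom in sorted(lengths):
        n_win = max(1, -(-lengths[chrom] // window_bp))
        counts = [0] * n_win
        for gid, s, e, _ in catalog.genes.get(chrom, []):
            if gid in family:
                if s >= lengths[chrom]:
                    raise ValueError(f"gene {gid} start {s} beyond chromosome length")
                counts[s // window_bp] += 1
        tracks.append(DensityTrack(chrom=chrom, window_bp=window_bp, counts=counts))
    return tracks
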