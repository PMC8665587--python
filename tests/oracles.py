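"""Independent brute-force oracles used only by the tests.

Each oracle re-derives the quantity a library routine computes, by the most
direct method available (exhaustive enumeration, naive double loops, textbook
DP), sharing no code path with the implementation under test.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

from Bio.Seq import Seq

BASES = "ACGT"


_trans_cache: dict[str, str] = {}


def _translate(codon: str) -> str:
    aa = _trans_cache.get(codon)
    if aa is None:
        aa = _trans_cache[codon] = str(Seq(codon).translate())
    return aa


def _is_stop(codon: str) -> bool:
    return _translate(codon) == "*"


# ---------------------------------------------------------------------------
# NG86 + Jukes-Cantor


def ng86_sites(codon: str) -> tuple[Fraction, Fraction]:
    """Synonymous/nonsynonymous site counts by direct mutant enumeration."""
    aa = _translate(codon)
    s = Fraction(0)
    for pos in range(3):
        syn, counted = 0, 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if _is_stop(mut):
                continue
            counted += 1
            syn += _translate(mut) == aa
        if counted:
            s += Fraction(syn, counted)
    return s, 3 - s


def ng86_diffs(a: str, b: str) -> tuple[Fraction, Fraction]:
    """Pathway-averaged synonymous/nonsynonymous difference counts."""
    pos = [i for i in range(3) if a[i] != b[i]]
    if not pos:
        return Fraction(0), Fraction(0)
    paths = []
    for order in itertools.permutations(pos):
        cur, sd, nd, ok = a, 0, 0, True
        for p in order:
            nxt = cur[:p] + b[p] + cur[p + 1:]
            if _is_stop(nxt):
                ok = False
                break
            if _translate(cur) == _translate(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:  # stop-exclusion fallback: count every ordering, stops nonsyn
        for order in itertools.permutations(pos):
            cur, sd, nd = a, 0, 0
            for p in order:
                nxt = cur[:p] + b[p] + cur[p + 1:]
                if (not _is_stop(cur) and not _is_stop(nxt)
                        and _translate(cur) == _translate(nxt)):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((sd, nd))
    n = len(paths)
    return (Fraction(sum(p[0] for p in paths), n),
            Fraction(sum(p[1] for p in paths), n))


def ng86_pair(cdsA: str, cdsB: str) -> dict:
    """Whole-pair NG86 + JC from the per-codon oracles."""
    S = N = Fraction(0)
    Sd = Nd = Fraction(0)
    for i in range(0, len(cdsA), 3):
        ca, cb = cdsA[i:i + 3], cdsB[i:i + 3]
        if _is_stop(ca) or _is_stop(cb) or set(ca + cb) - set(BASES):
            continue
        for c in (ca, cb):
            s, n = ng86_sites(c)
            S += s / 2
            N += n / 2
        sd, nd = ng86_diffs(ca, cb)
        Sd += sd
        Nd += nd
    pS, pN = float(Sd / S), float(Nd / N)

    def jc(p):
        return None if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    return {"S": float(S), "N": float(N), "Sd": float(Sd), "Nd": float(Nd),
            "pS": pS, "pN": pN, "dS": jc(pS), "dN": jc(pN)}


# ---------------------------------------------------------------------------
# Smith-Waterman local alignment score (full affine-gap DP)


def sw_score(target: str, query: str, match=2, mismatch=-3,
             gap_open=-5, gap_extend=-2) -> float:
    """Best local alignment score; gap_open is the cost of a gap's first base."""
    n, m = len(target), len(query)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (target consumed)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in target
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] + gap_open, E[i - 1][j] + gap_extend)
            F[i][j] = max(H[i][j - 1] + gap_open, F[i][j - 1] + gap_extend)
            sub = match if target[i - 1] == query[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


# ---------------------------------------------------------------------------
# tandem clustering by explicit pairwise linkage + connected components


def tandem_components(ranks_by_chrom: dict[str, dict[str, int]],
                      max_gap: int) -> list[set[str]]:
    """Connected components of the ≤ max_gap intervening-genes relation,
    computed from ALL pairs (O(n²)) with union-find."""
    parent: dict[str, str] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for chrom, ranks in ranks_by_chrom.items():
        ids = list(ranks)
        for g in ids:
            parent.setdefault(g, g)
        for a, b in itertools.combinations(ids, 2):
            if abs(ranks[a] - ranks[b]) <= max_gap + 1:
                union(a, b)
    comps: dict[str, set[str]] = {}
    for g in parent:
        comps.setdefault(find(g), set()).add(g)
    return list(comps.values())


# ---------------------------------------------------------------------------
# duplication-loss reconciliation by exhaustive mapping search


class SpeciesTreeTiny:
    """Minimal species tree for brute-force reconciliation (nested tuples)."""

    def __init__(self, topo):
        self.parent: dict = {}
        self.children: dict = {}
        self.nodes: list = []

        def build(t, par):
            self.nodes.append(t)
            self.parent[t] = par
            if isinstance(t, tuple):
                self.children[t] = list(t)
                for c in t:
                    build(c, t)
            else:
                self.children[t] = []

        build(topo, None)
        self.root = topo

    def ancestors(self, x):
        out = [x]
        while self.parent[out[-1]] is not None:
            out.append(self.parent[out[-1]])
        return out

    def is_ancestor(self, a, d):
        return a in self.ancestors(d)

    def lca(self, a, b):
        anc = set(self.ancestors(a))
        for x in self.ancestors(b):
            if x in anc:
                return x
        raise ValueError

    def dist(self, anc, desc):
        d = 0
        while desc != anc:
            desc = self.parent[desc]
            d += 1
        return d


def brute_force_dl_cost(gene_topo, stree: SpeciesTreeTiny) -> int:
    """Minimum duplications + losses over all valid gene→species mappings.

    ``gene_topo`` is a nested tuple whose leaves are species names.  Every
    internal gene node ranges over the species-tree ancestors of the LCA of
    its children's mappings (any other mapping is invalid or dominated); the
    cost of each full mapping is evaluated directly.
    """

    class Leaf:
        __slots__ = ("sp",)

        def __init__(self, sp):
            self.sp = sp

    def uniquify(t):
        if isinstance(t, tuple):
            return tuple(uniquify(c) for c in t)
        return Leaf(t)

    root = uniquify(gene_topo)
    mapping: dict[int, object] = {}
    internals: list = []

    def collect(t):  # postorder: children before parents
        if isinstance(t, tuple):
            for c in t:
                collect(c)
            internals.append(t)
        else:
            mapping[id(t)] = t.sp

    collect(root)
    best = [math.inf]

    def cost_of() -> int:
        cost = 0
        for g in internals:
            c1, c2 = g
            m, m1, m2 = mapping[id(g)], mapping[id(c1)], mapping[id(c2)]
            dup = not (m == stree.lca(m1, m2) and _separated(stree, m, m1, m2))
            cost += dup
            for mc in (m1, m2):
                l = stree.dist(m, mc)
                cost += l if dup else l - 1
        return cost

    def assign(idx):
        if idx == len(internals):
            best[0] = min(best[0], cost_of())
            return
        g = internals[idx]
        c1, c2 = g
        lca = stree.lca(mapping[id(c1)], mapping[id(c2)])
        for cand in stree.ancestors(lca):
            mapping[id(g)] = cand
            assign(idx + 1)
        del mapping[id(g)]

    assign(0)
    return int(best[0])


def _separated(stree, m, m1, m2) -> bool:
    """True when m1 and m2 descend through different children of m."""
    kids = stree.children[m]
    if len(kids) != 2:
        return False
    a, b = kids
    return ((stree.is_ancestor(a, m1) and stree.is_ancestor(b, m2))
            or (stree.is_ancestor(b, m1) and stree.is_ancestor(a, m2)))


def enumerate_gene_topologies(n_leaves: int, species: tuple[str, ...]):
    """All rooted binary species-labeled tree shapes with ``n_leaves`` leaves,
    up to isomorphism (unordered children)."""
    memo: dict[int, set] = {1: set(species)}

    def trees(n: int):
        if n in memo:
            return memo[n]
        out = set()
        for i in range(1, n // 2 + 1):
            for x in trees(i):
                for y in trees(n - i):
                    out.add(tuple(sorted((x, y), key=repr)))
        memo[n] = out
        return out

    return sorted(trees(n_leaves), key=repr)


def topo_to_newick(topo) -> str:
    """Species-labeled nested tuple → Newick with unique gene leaf ids."""
    counter = [0]

    def walk(t):
        if isinstance(t, tuple):
            return "(" + ",".join(walk(c) for c in t) + ")"
        counter[0] += 1
        return f"{t}|g{counter[0]}"

    return walk(topo) + ";"


# ---------------------------------------------------------------------------
# naive dot matrix


def naive_dot_matches(seq: str, window: int, min_identity: float):
    """O(L²·w) double-loop window comparison."""
    thr = math.ceil(window * min_identity)
    L = len(seq)
    out = []
    for i in range(L - window + 1):
        for j in range(i + 1, L - window + 1):
            agree = sum(seq[i + k] == seq[j + k] for k in range(window))
            if agree >= thr:
                out.append((i, j))
    return out
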