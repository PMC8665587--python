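"""Synthetic-data generators with planted ground truth for every pipeline stage.

Every generator is a pure, deterministic function of its parameters and a seed:
ordered gene catalogs with planted tandem clusters, paralog gene-model pairs
carrying exactly one planted structural-divergence mechanism, codon sequence
pairs evolved at a specified dN/dS by acceptance–rejection, birth–death gene
trees on a species tree with recorded duplication/loss events per branch,
tandem-repeat-bearing DNA, and stage-profiled expression matrices with planted
archetype clusters and concordant/divergent paralog pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .io_models import GeneCatalog, GeneModel, LabeledTree, read_newick
from .selection import CODON_TABLE, STOP_CODONS, codon_sites

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# mechanism labels for paralog-pair simulation and classification
EXON_INTRON_GAIN_LOSS = "EXON_INTRON_GAIN_LOSS"
INTRON_ELONGATION = "INTRON_ELONGATION"
EXONIZATION = "EXONIZATION_PSEUDOEXONIZATION"
BOUNDARY_SHIFT = "BOUNDARY_ALTERATION"
EXON_SPLIT = "EXON_SPLIT"
NONE = "NONE"
MECHANISMS = (EXON_INTRON_GAIN_LOSS, INTRON_ELONGATION, EXONIZATION,
              BOUNDARY_SHIFT, EXON_SPLIT, NONE)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode()


def mutate_dna(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Independent per-site substitutions at ``rate`` (uniform alternative base)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        alts = BASES[BASES != arr[i]]
        arr[i] = rng.choice(alts)
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# gene catalogs with planted tandem clusters


@dataclass
class CatalogTruth:
    clusters: list[list[str]]
    singletons: list[str]

    def as_dict(self) -> dict:
        return {"clusters": self.clusters, "singletons": self.singletons}


def sim_catalog_with_family(
    n_chroms: int = 1,
    genes_per_chrom: int = 200,
    planted_clusters: Sequence[tuple[int, int, int, int]] = ((0, 10, 5, 3),),
    n_singletons: int = 2,
    seed: int = 0,
    mean_gene_len: int = 2000,
    mean_gap_len: int = 3000,
) -> tuple[GeneCatalog, set[str], CatalogTruth]:
    """Ordered gene catalog with a family planted as tandem clusters + singletons.

    ``planted_clusters`` entries are (chrom_index, start_rank, size,
    max_internal_gap in genes): members are placed from ``start_rank`` with
    0..max_internal_gap intervening non-family genes between neighbours.
    Singletons are placed > 21 gene ranks from every other family member, so
    that the planted partition is exactly the truth under the 20-gene rule.
    Infeasible placements raise before anything is produced.
    """
    rng = np.random.default_rng(seed)
    family_ranks: dict[int, list[tuple[int, str]]] = {c: [] for c in range(n_chroms)}
    clusters: list[list[str]] = []
    gid_counter = 0

    def new_fid() -> str:
        nonlocal gid_counter
        gid_counter += 1
        return f"FAM{gid_counter:04d}"

    for chrom_i, start_rank, size, max_internal_gap in planted_clusters:
        if chrom_i >= n_chroms:
            raise ValueError(f"cluster on chromosome {chrom_i} but only {n_chroms} exist")
        if max_internal_gap > 20:
            raise ValueError("internal gap > 20 would break the planted cluster apart")
        members: list[tuple[int, str]] = []
        rank = start_rank
        for k in range(size):
            if rank >= genes_per_chrom:
                raise ValueError("planted cluster does not fit on its chromosome")
            members.append((rank, new_fid()))
            if k < size - 1:
                rank += 1 + int(rng.integers(0, max_internal_gap + 1))
        for r, _ in family_ranks[chrom_i]:
            for rm, _ in members:
                if abs(rm - r) <= 21:
                    raise ValueError("planted clusters too close (≤ 20 intervening genes)")
        family_ranks[chrom_i].extend(members)
        clusters.append([fid for _, fid in members])

    singles: list[str] = []
    for _ in range(n_singletons):
        for _attempt in range(1000):
            c = int(rng.integers(0, n_chroms))
            r = int(rng.integers(0, genes_per_chrom))
            if all(abs(r - r2) > 21 for r2, _ in family_ranks[c]):
                fid = new_fid()
                family_ranks[c].append((r, fid))
                singles.append(fid)
                break
        else:
            raise ValueError("could not place singleton > 21 genes from all family members")

    genes: dict[str, list[tuple[str, int, int, str]]] = {}
    chrom_lengths: dict[str, int] = {}
    bg_counter = 0
    for c in range(n_chroms):
        chrom = f"chr{c + 1}"
        fam_at = dict(family_ranks[c])
        pos = 1000
        lst = []
        for rank in range(genes_per_chrom):
            glen = int(rng.integers(mean_gene_len // 2, mean_gene_len * 2))
            if rank in fam_at:
                gid = fam_at[rank]
            else:
                bg_counter += 1
                gid = f"BG{bg_counter:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            lst.append((gid, pos, pos + glen, strand))
            pos += glen + int(rng.integers(mean_gap_len // 2, mean_gap_len * 2))
        genes[chrom] = lst
        chrom_lengths[chrom] = pos + 1000
    catalog = GeneCatalog(genes=genes, chrom_lengths=chrom_lengths)
    family = set(singles) | {g for cl in clusters for g in cl}
    return catalog, family, CatalogTruth(clusters=clusters, singletons=singles)


# ---------------------------------------------------------------------------
# paralog pairs with one planted structural mechanism


@dataclass
class PairTruth:
    mechanism: str
    detail: dict = field(default_factory=dict)


def _base_gene(rng: np.random.Generator, gene_id: str, n_exons: int,
               exon_len_range=(90, 300), intron_len_range=(50, 200)) -> GeneModel:
    parts = []
    pos = 0
    exons = []
    for i in range(n_exons):
        el = int(rng.integers(*exon_len_range))
        exons.append((pos, pos + el))
        parts.append(random_dna(rng, el))
        pos += el
        if i < n_exons - 1:
            il = int(rng.integers(*intron_len_range))
            parts.append(random_dna(rng, il))
            pos += il
    return GeneModel(gene_id=gene_id, chrom="sim", strand="+", exons=exons,
                     genomic_seq="".join(parts))


def sim_paralog_pair(
    mechanism: str,
    seed: int = 0,
    n_exons: int = 4,
    point_mut_rate: float = 0.05,
    elongation_factor: float = 5.0,
    repeat_unit_len: int = 50,
    boundary_offset: int = 9,
    intron_index: int | None = None,
) -> tuple[GeneModel, GeneModel, PairTruth]:
    """Sibling pair: B derives from A by point mutations plus one planted event.

    Events mirror the five divergence mechanisms: exon deletion (gain/loss),
    intron elongation by inserted ~50 bp tandem repeats (length ratio
    ``elongation_factor`` > 2), exon→intron re-annotation (exonization/
    pseudoexonization), splice-boundary shift by ``boundary_offset`` bp, and
    exon split by a novel intron.  The truth records the event coordinates.
    """
    if mechanism not in MECHANISMS:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    if mechanism == INTRON_ELONGATION and elongation_factor <= 2:
        raise ValueError("elongation_factor must exceed 2 to plant a detectable event")
    rng = np.random.default_rng(seed)
    A = _base_gene(rng, "geneA", n_exons)
    seqB = mutate_dna(rng, A.genomic_seq, point_mut_rate)
    exonsB = list(A.exons)
    detail: dict = {}

    if mechanism == NONE:
        pass

    elif mechanism == EXON_INTRON_GAIN_LOSS:
        # delete one internal exon's sequence from B; flanking introns merge
        i = int(rng.integers(1, n_exons - 1))
        s, e = A.exons[i]
        seqB = seqB[:s] + seqB[e:]
        d = e - s
        exonsB = A.exons[:i] + [(xs - d, xe - d) for xs, xe in A.exons[i + 1:]]
        detail = {"lost_exon_index": i, "lost_exon_len": d}

    elif mechanism == INTRON_ELONGATION:
        i = intron_index if intron_index is not None else int(rng.integers(0, n_exons - 1))
        s, e = A.introns[i]
        old_len = e - s
        target = int(round(old_len * elongation_factor))
        unit = random_dna(rng, repeat_unit_len)
        n_copies = max(2, -(-(target - old_len) // repeat_unit_len))
        insert = "".join(mutate_dna(rng, unit, 0.02) for _ in range(n_copies))
        seqB = seqB[:e] + insert + seqB[e:]
        d = len(insert)
        exonsB = A.exons[:i + 1] + [(xs + d, xe + d) for xs, xe in A.exons[i + 1:]]
        detail = {"intron_index": i, "old_len": old_len, "new_len": old_len + d,
                  "unit_len": repeat_unit_len, "n_copies": n_copies}

    elif mechanism == EXONIZATION:
        # an internal exon keeps its sequence but loses exon status in B:
        # flanking introns and the exon merge into one long intron
        i = int(rng.integers(1, n_exons - 1))
        exonsB = A.exons[:i] + A.exons[i + 1:]
        detail = {"intronised_exon_index": i, "exon_len": A.exons[i][1] - A.exons[i][0]}

    elif mechanism == BOUNDARY_SHIFT:
        # extend one exon's 3' boundary into the downstream intron
        i = int(rng.integers(0, n_exons - 1))
        s, e = A.exons[i]
        ilen = A.introns[i][1] - A.introns[i][0]
        off = min(boundary_offset, max(3, ilen // 3))  # keep flanking intron ratio ≤ 2
        exonsB = list(A.exons)
        exonsB[i] = (s, e + off)
        detail = {"exon_index": i, "offset": off}

    elif mechanism == EXON_SPLIT:
        # insert a novel intron inside one exon of B
        candidates = [i for i, (s, e) in enumerate(A.exons) if e - s >= 90]
        if not candidates:
            raise ValueError("no exon long enough to split (need ≥ 90 bp)")
        i = int(rng.choice(candidates))
        s, e = A.exons[i]
        cut = s + int(rng.integers(40, e - s - 40))
        novel = random_dna(rng, int(rng.integers(60, 90)))
        seqB = seqB[:cut] + novel + seqB[cut:]
        d = len(novel)
        exonsB = (A.exons[:i] + [(s, cut), (cut + d, e + d)]
                  + [(xs + d, xe + d) for xs, xe in A.exons[i + 1:]])
        detail = {"exon_index": i, "cut_offset": cut - s, "novel_intron_len": d}

    B = GeneModel(gene_id="geneB", chrom="sim", strand="+", exons=exonsB,
                  genomic_seq=seqB)
    return A, B, PairTruth(mechanism=mechanism, detail=detail)


# ---------------------------------------------------------------------------
# codon pair evolution at a target dN/dS (acceptance–rejection)


@dataclass
class CodonPairTruth:
    n_syn: int
    n_nonsyn: int
    omega_nominal: float


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    sense = sorted(CODON_TABLE)
    return "".join(sense[i] for i in rng.integers(0, len(sense), size=n_codons))


def sim_codon_pair(
    n_codons: int, omega: float, n_attempts: int, seed: int = 0,
    min_codons: int = 15,
) -> tuple[str, str, CodonPairTruth]:
    """Evolve B from a random stop-free CDS A by single-base proposals.

    Each of ``n_attempts`` proposals picks a uniform site and a uniform
    alternative base; proposals creating stops are rejected; nonsynonymous
    changes are accepted with probability min(1, ω) and synonymous changes
    with probability min(1, 1/ω) — i.e. always, for ω ≤ 1; the reciprocal rule
    extends the scheme so that diversifying regimes (ω > 1) are realizable
    too.  The truth records the realized synonymous/nonsynonymous counts.
    """
    if omega < 0:
        raise ValueError("omega must be ≥ 0")
    if n_codons < min_codons:
        raise ValueError(f"n_codons must be ≥ {min_codons}")
    rng = np.random.default_rng(seed)
    A = random_cds(rng, n_codons)
    b = list(A)
    n_syn = n_nonsyn = 0
    L = 3 * n_codons
    for _ in range(n_attempts):
        site = int(rng.integers(0, L))
        old = b[site]
        alts = [x for x in "ACGT" if x != old]
        new = alts[int(rng.integers(0, 3))]
        ci = site // 3
        cur = "".join(b[3 * ci: 3 * ci + 3])
        nxt = cur[: site % 3] + new + cur[site % 3 + 1:]
        if nxt in STOP_CODONS:
            continue
        if CODON_TABLE[cur] == CODON_TABLE[nxt]:
            if omega <= 1.0 or rng.random() < 1.0 / omega:
                b[site] = new
                n_syn += 1
        elif rng.random() < min(1.0, omega):
            b[site] = new
            n_nonsyn += 1
    return A, "".join(b), CodonPairTruth(n_syn=n_syn, n_nonsyn=n_nonsyn,
                                         omega_nominal=omega)


def realized_omega(cdsA: str, truth: CodonPairTruth) -> float | None:
    """The simulation's realized dN/dS: true substitution counts over the NG86
    site counts of the start sequence, JC-corrected; None when no synonymous
    substitution was realized (ratio undefined)."""
    from .selection import jukes_cantor

    S = N = 0.0
    for i in range(0, len(cdsA), 3):
        s, n = codon_sites(cdsA[i: i + 3])
        S += s
        N += n
    if truth.n_syn == 0:
        return None
    ds = jukes_cantor(truth.n_syn / S)
    dn = jukes_cantor(truth.n_nonsyn / N)
    return dn / ds if ds > 0 else None


# ---------------------------------------------------------------------------
# birth–death gene families along a species tree


@dataclass
class ForestTruth:
    dup_per_branch: dict[str, int]    # branch label (child clade) → planted dups
    loss_per_branch: dict[str, int]
    n_discarded: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


def species_branch_label(node) -> str:
    """Stable label for the species branch entering ``node``: its leaf clade."""
    if node.is_leaf():
        return node.taxon.label
    return "+".join(sorted(lf.taxon.label for lf in node.leaf_iter()))


def sim_gene_trees_dl(
    species_tree: LabeledTree,
    dup_rate: float,
    loss_rate: float,
    n_families: int,
    seed: int = 0,
) -> tuple[list[LabeledTree], ForestTruth]:
    """Simulate gene families top-down along the species tree.

    One gene lineage enters the species root and speciates there.  On each
    species branch every entering lineage duplicates k ~ Poisson(dup_rate)
    times (copies joined by a caterpillar of duplication nodes, recorded per
    branch) and each resulting copy is independently lost with probability
    1 − exp(−loss_rate) (recorded).  Surviving lineages at species leaves
    become gene-tree leaves labelled ``SPECIES|famF_gN``.  Families with fewer
    than two surviving genes are discarded and counted; all families extinct
    is an error suggesting a lower loss rate.
    """
    if dup_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be ≥ 0")
    stree = species_tree.tree
    root = stree.seed_node
    if any(len(n.child_nodes()) not in (0, 2) for n in stree.preorder_node_iter()):
        raise ValueError("species tree must be binary")
    rng = np.random.default_rng(seed)
    p_loss = 1.0 - float(np.exp(-loss_rate))
    dup_truth: dict[str, int] = {}
    loss_truth: dict[str, int] = {}
    trees: list[LabeledTree] = []
    n_discarded = 0

    for fam in range(n_families):
        counter = [0]
        fam_dups: dict[str, int] = {}
        fam_losses: dict[str, int] = {}

        def at_node(snode) -> str | None:
            """Newick of the subtree of one lineage present at species node."""
            if snode.is_leaf():
                counter[0] += 1
                return f"{snode.taxon.label}|fam{fam}_g{counter[0]}"
            left, right = snode.child_nodes()
            ln = into_branch(left)
            rn = into_branch(right)
            if ln and rn:
                return f"({ln},{rn})"
            return ln or rn

        def into_branch(snode) -> str | None:
            lab = species_branch_label(snode)
            k = int(rng.poisson(dup_rate))
            if k:
                fam_dups[lab] = fam_dups.get(lab, 0) + k
            survivors: list[str] = []
            for _copy in range(k + 1):
                if p_loss > 0 and rng.random() < p_loss:
                    fam_losses[lab] = fam_losses.get(lab, 0) + 1
                    continue
                sub = at_node(snode)
                if sub is not None:
                    survivors.append(sub)
            if not survivors:
                return None
            out = survivors[0]
            for s in survivors[1:]:  # caterpillar of duplication nodes
                out = f"({out},{s})"
            return out

        nwk = at_node(root)
        n_leaves = counter[0]
        if nwk is None or n_leaves < 2:
            # discarded families contribute no gene tree, so their planted
            # events are not part of the recoverable truth either
            n_discarded += 1
            continue
        for lab, k in fam_dups.items():
            dup_truth[lab] = dup_truth.get(lab, 0) + k
        for lab, k in fam_losses.items():
            loss_truth[lab] = loss_truth.get(lab, 0) + k
        trees.append(read_newick(data=nwk + ";"))
    if not trees:
        raise ValueError("all simulated families went extinct; lower loss_rate")
    return trees, ForestTruth(dup_per_branch=dup_truth, loss_per_branch=loss_truth,
                              n_discarded=n_discarded)


# ---------------------------------------------------------------------------
# stage-specific expression matrices


STAGES_7 = ("EE", "LE", "L1", "L2", "L3", "L4", "YA")
STAGES_4 = ("EE", "L2", "L4", "YA")


@dataclass
class ExpressionTruth:
    archetype: dict[str, int]          # gene → archetype index (k-1 = flat-low)
    peak_stage: dict[str, str | None]  # gene → planted peak stage (None = flat)
    pair_flags: dict[tuple[str, str], bool]  # (a, b) → planted "divergent"

    def as_dict(self) -> dict:
        return {
            "archetype": self.archetype,
            "peak_stage": self.peak_stage,
            "pair_flags": {f"{a}::{b}": v for (a, b), v in self.pair_flags.items()},
        }


def sim_expression(
    stages: Sequence[str] = STAGES_7,
    n_genes: int = 400,
    k: int = 8,
    noise_sd: float = 0.2,
    pair_plan: Sequence[str] = (),
    seed: int = 0,
    base_log: float = 2.0,
    peak_delta: float = 6.0,
    flat_log: float = -1.0,
) -> tuple[pd.DataFrame, ExpressionTruth]:
    """Genes × stages FPKM-like matrix from one-peak-per-stage archetypes.

    Archetypes 0..n_stages−1 peak at the corresponding stage; archetype
    n_stages is flat-low, so ``k`` can be at most n_stages + 1.  Profiles are
    built on a log2 scale (base ``base_log``, peak ``base_log + peak_delta``)
    with Gaussian noise, then back-transformed (2^x − 1, floored at 0).  The
    flat-low archetype sits below the detection floor (``flat_log`` < 0), so
    its FPKM values clip to exactly zero — silent genes, as in real FPKM
    tables, have no reads rather than Gaussian jitter around a tiny mean.
    ``pair_plan`` entries "concordant"/"divergent" append gene pairs drawn
    from the same / different peaked archetypes; truth records all assignments
    and flags.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be ≥ 0")
    stages = tuple(stages)
    n_arch = len(stages) + 1  # peaks + flat-low
    if k > n_arch:
        raise ValueError(f"k={k} exceeds the {n_arch} constructible archetypes")
    rng = np.random.default_rng(seed)

    def profile(arch: int) -> np.ndarray:
        log = np.full(len(stages), base_log)
        if arch < len(stages):
            log[arch] += peak_delta
        else:
            log[:] = flat_log  # flat-low: below the FPKM detection floor
        return log

    names: list[str] = []
    rows: list[np.ndarray] = []
    arch_truth: dict[str, int] = {}
    peak_truth: dict[str, str | None] = {}

    def add_gene(name: str, arch: int) -> None:
        log = profile(arch) + rng.normal(0.0, noise_sd, len(stages))
        rows.append(np.maximum(np.exp2(log) - 1.0, 0.0))
        names.append(name)
        arch_truth[name] = arch
        peak_truth[name] = stages[arch] if arch < len(stages) else None

    archetypes_used = list(range(k - 1)) + [len(stages)] if k == n_arch else list(range(k))
    for i in range(n_genes):
        add_gene(f"G{i:04d}", archetypes_used[i % len(archetypes_used)])

    pair_flags: dict[tuple[str, str], bool] = {}
    peaked = [a for a in archetypes_used if a < len(stages)]
    for j, plan in enumerate(pair_plan):
        if plan not in ("concordant", "divergent"):
            raise ValueError(f"pair plan entries must be concordant/divergent, got {plan!r}")
        a_name, b_name = f"P{j:04d}a", f"P{j:04d}b"
        arch_a = int(peaked[int(rng.integers(0, len(peaked)))])
        if plan == "concordant":
            arch_b = arch_a
        else:
            others = [a for a in peaked if a != arch_a]
            arch_b = int(others[int(rng.integers(0, len(others)))])
        add_gene(a_name, arch_a)
        add_gene(b_name, arch_b)
        pair_flags[(a_name, b_name)] = plan == "divergent"

    matrix = pd.DataFrame(np.vstack(rows) if rows else np.empty((0, len(stages))),
                          index=names, columns=list(stages))
    return matrix, ExpressionTruth(archetype=arch_truth, peak_stage=peak_truth,
                                   pair_flags=pair_flags)


# ---------------------------------------------------------------------------
# tandem-repeat-bearing DNA


@dataclass
class RepeatTruth:
    unit_len: int
    span: tuple[int, int]  # 0-based half-open repeat region
    n_copies: int


def sim_repeat_sequence(
    unit_len: int = 50,
    n_copies: int = 6,
    flank_len: int = 500,
    mutation_rate: float = 0.02,
    seed: int = 0,
    max_mutation_rate: float = 0.3,
) -> tuple[str, RepeatTruth]:
    """Random flank + n tandem copies of a random unit (each independently
    mutated) + random flank; truth records the unit length and repeat span."""
    if unit_len < 10:
        raise ValueError("unit_len must be ≥ 10")
    if n_copies < 2:
        raise ValueError("n_copies must be ≥ 2")
    if not 0 <= mutation_rate <= max_mutation_rate:
        raise ValueError(f"mutation_rate must be in [0, {max_mutation_rate}]")
    rng = np.random.default_rng(seed)
    unit = random_dna(rng, unit_len)
    copies = [mutate_dna(rng, unit, mutation_rate) for _ in range(n_copies)]
    left = random_dna(rng, flank_len)
    right = random_dna(rng, flank_len)
    seq = left + "".join(copies) + right
    span = (flank_len, flank_len + unit_len * n_copies)
    return seq, RepeatTruth(unit_len=unit_len, span=span, n_copies=n_copies)


# ---------------------------------------------------------------------------
# ground-truth sidecar serialisation


def write_ground_truth(truth, path) -> None:
    """Serialise any *Truth dataclass to a JSON sidecar."""
    obj = truth.as_dict() if hasattr(truth, "as_dict") else asdict(truth)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=str)
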