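"""Classification of exon/intron structural divergence between paralog siblings.

Each exon of one gene is locally aligned (Smith–Waterman, affine gaps) against
the full genomic span of the other; alignments shorter than ``min_length`` or
below ``min_identity`` count as "no counterpart".  From the two directional
exon-correspondence maps, five mechanisms are called, in priority order:

1. EXON_SPLIT — two adjacent exons of one gene map inside a single exon of the
   other, with the intervening intron lacking a counterpart (a novel intron).
2. EXONIZATION_PSEUDOEXONIZATION — an exon's counterpart lies inside an intron
   of the sibling (the sequence survives but exon status differs).
3. EXON_INTRON_GAIN_LOSS — an exon with no counterpart anywhere in the sibling.
4. BOUNDARY_ALTERATION — a matched exon pair whose lengths differ by at least
   ``min_offset`` bp while the flanking intron length ratio stays ≤ 2.
5. INTRON_ELONGATION — a homologous intron pair (both flanking exon pairs
   matched) with length ratio > ``elongation_factor`` (default 2).

Without an outgroup the polarity of every event (gain vs loss, exonization vs
pseudoexonization, elongation vs shortening) is UNKNOWN; ratios are reported
direction-symmetrically as max/min.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .io_models import GeneModel
from .synthetic_data import (BOUNDARY_SHIFT, EXON_INTRON_GAIN_LOSS, EXON_SPLIT,
                             EXONIZATION, INTRON_ELONGATION, NONE)

PRIORITY = (EXON_SPLIT, EXONIZATION, EXON_INTRON_GAIN_LOSS, BOUNDARY_SHIFT,
            INTRON_ELONGATION)

DEFAULT_SCORES = {"match": 2, "mismatch": -3, "open": -5, "extend": -2}


@dataclass
class ExonHit:
    """Best local alignment of one exon against the sibling's genomic span."""

    exon_index: int
    target_start: int      # coordinates in the sibling's local frame
    target_end: int
    identity: float
    aligned_length: int
    score: float
    accepted: bool


@dataclass
class DivergenceEvent:
    mechanism: str
    feature_a: int | None            # exon/intron index in A (transcript order)
    feature_b: int | None
    numbers: dict = field(default_factory=dict)
    polarity: str = "UNKNOWN"


def _aligner(scores=None) -> Align.PairwiseAligner:
    s = dict(DEFAULT_SCORES, **(scores or {}))
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = s["match"]
    al.mismatch_score = s["mismatch"]
    al.open_gap_score = s["open"]
    al.extend_gap_score = s["extend"]
    return al


def align_exon_to_gene(
    exon_seq: str,
    gene_seq: str,
    min_identity: float = 0.6,
    min_length: int = 30,
    scores: dict | None = None,
    exon_index: int = 0,
) -> ExonHit:
    """Highest-scoring Smith–Waterman local alignment of an exon in a gene span.

    Ties are broken deterministically: lowest start in the gene, then in the
    exon.  The hit is accepted as a counterpart only when the aligned length
    and identity clear the thresholds.
    """
    for s in (exon_seq, gene_seq):
        if not s or set(s.upper()) - set("ACGTN"):
            raise ValueError("sequences must be non-empty DNA over ACGTN")
    al = _aligner(scores)
    res = al.align(gene_seq.upper(), exon_seq.upper())
    if res.score <= 0:
        return ExonHit(exon_index, 0, 0, 0.0, 0, 0.0, False)
    best = None
    # res is sorted by score; scan the top-scoring alignments for the tie-break
    try:
        n_scan = min(len(res), 16)
    except OverflowError:  # degenerate low-complexity inputs
        n_scan = 16
    for k in range(n_scan):
        aln = res[k]
        if aln.score < res.score:
            break
        t0 = int(aln.aligned[0][0][0])
        q0 = int(aln.aligned[1][0][0])
        if best is None or (t0, q0) < best[0]:
            best = ((t0, q0), aln)
    aln = best[1]
    t_start = int(aln.aligned[0][0][0])
    t_end = int(aln.aligned[0][-1][1])
    matches = 0
    length = 0
    for (ts, te), (qs, qe) in zip(aln.aligned[0], aln.aligned[1]):
        seg_t = gene_seq[ts:te].upper()
        seg_q = exon_seq[qs:qe].upper()
        matches += sum(a == b for a, b in zip(seg_t, seg_q))
        length += te - ts
    identity = matches / length if length else 0.0
    accepted = length >= min_length and identity >= min_identity
    return ExonHit(exon_index, t_start, t_end, identity, length, float(aln.score),
                   accepted)


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


@dataclass
class ExonCorrespondence:
    """Directional exon assignments between two gene models.

    ``a_hits[i]`` is exon i of A aligned into B's span; ``a_to_exons[i]`` lists
    B-exon indices overlapping the hit (reciprocal overlap ≥ 50% of the
    shorter); ``a_to_intron[i]`` is the B-intron containing the hit (± 10 bp),
    or None.  Symmetric fields for B against A.
    """

    a_hits: list[ExonHit]
    b_hits: list[ExonHit]
    a_to_exons: list[list[int]]
    b_to_exons: list[list[int]]
    a_to_intron: list[int | None]
    b_to_intron: list[int | None]


def _assign(hits: list[ExonHit], target: GeneModel,
            intron_slop: int = 10) -> tuple[list[list[int]], list[int | None]]:
    exon_iv = target.local_exons()
    intron_iv = target.local_introns()
    to_exons: list[list[int]] = []
    to_intron: list[int | None] = []
    for h in hits:
        ex_idx: list[int] = []
        in_idx: int | None = None
        if h.accepted:
            region = (h.target_start, h.target_end)
            rlen = region[1] - region[0]
            for j, iv in enumerate(exon_iv):
                ov = _overlap(region, iv)
                if ov >= 0.5 * min(rlen, iv[1] - iv[0]):
                    ex_idx.append(j)
            if not ex_idx:
                for j, iv in enumerate(intron_iv):
                    if region[0] >= iv[0] - intron_slop and region[1] <= iv[1] + intron_slop:
                        in_idx = j
                        break
        to_exons.append(ex_idx)
        to_intron.append(in_idx)
    return to_exons, to_intron


def build_correspondence(
    geneA: GeneModel,
    geneB: GeneModel,
    min_identity: float = 0.6,
    min_length: int = 30,
    scores: dict | None = None,
) -> ExonCorrespondence:
    """Align every exon of each gene against the sibling's genomic span and
    assign it to an overlapping exon, a containing intron, or nothing."""
    if geneA.genomic_seq is None or geneB.genomic_seq is None:
        raise ValueError("both genes need attached genomic sequence")
    seqs_a = geneA.exon_seqs()
    seqs_b = geneB.exon_seqs()
    a_hits = [align_exon_to_gene(s, geneB.genomic_seq, min_identity, min_length,
                                 scores, exon_index=i) for i, s in enumerate(seqs_a)]
    b_hits = [align_exon_to_gene(s, geneA.genomic_seq, min_identity, min_length,
                                 scores, exon_index=i) for i, s in enumerate(seqs_b)]
    a_to_exons, a_to_intron = _assign(a_hits, geneB)
    b_to_exons, b_to_intron = _assign(b_hits, geneA)
    return ExonCorrespondence(a_hits, b_hits, a_to_exons, b_to_exons,
                              a_to_intron, b_to_intron)


def _matched_pairs(corr: ExonCorrespondence) -> list[tuple[int, int]]:
    """Reciprocal exon↔exon matches (i in A, j in B)."""
    pairs = []
    for i, ex in enumerate(corr.a_to_exons):
        for j in ex:
            if i in corr.b_to_exons[j]:
                pairs.append((i, j))
    return pairs


def classify_pair(
    corr: ExonCorrespondence,
    geneA: GeneModel,
    geneB: GeneModel,
    min_offset: int = 3,
    elongation_factor: float = 2.0,
    boundary_intron_ratio: float = 2.0,
) -> tuple[list[DivergenceEvent], str]:
    """All divergence events between two siblings plus the primary mechanism
    (the highest-priority event; NONE when no rule fires)."""
    events: list[DivergenceEvent] = []
    lens_a = geneA.exon_lengths()
    lens_b = geneB.exon_lengths()
    ilens_a = geneA.intron_lengths()
    ilens_b = geneB.intron_lengths()
    pairs = _matched_pairs(corr)
    matched_a = {i for i, _ in pairs}
    matched_b = {j for _, j in pairs}

    # EXON_SPLIT: two adjacent B-exons land in one A-exon (or vice versa)
    split_a: set[int] = set()
    split_b: set[int] = set()
    for j in range(len(lens_b) - 1):
        t1, t2 = corr.b_to_exons[j], corr.b_to_exons[j + 1]
        common = set(t1) & set(t2)
        for i in common:
            events.append(DivergenceEvent(
                EXON_SPLIT, feature_a=i, feature_b=j,
                numbers={"part_lengths_b": (lens_b[j], lens_b[j + 1]),
                         "novel_intron_len_b": ilens_b[j],
                         "exon_len_a": lens_a[i]}))
            split_a.add(i)
            split_b.update({j, j + 1})
    for i in range(len(lens_a) - 1):
        t1, t2 = corr.a_to_exons[i], corr.a_to_exons[i + 1]
        common = (set(t1) & set(t2)) - split_a  # avoid double-reporting
        for j in common:
            events.append(DivergenceEvent(
                EXON_SPLIT, feature_a=i, feature_b=j,
                numbers={"part_lengths_a": (lens_a[i], lens_a[i + 1]),
                         "novel_intron_len_a": ilens_a[i],
                         "exon_len_b": lens_b[j]}))
            split_a.update({i, i + 1})
            split_b.add(j)

    # EXONIZATION / PSEUDOEXONIZATION: exon ↔ intron
    for i, intr in enumerate(corr.a_to_intron):
        if intr is not None and not corr.a_to_exons[i]:
            events.append(DivergenceEvent(
                EXONIZATION, feature_a=i, feature_b=intr,
                numbers={"exon_len_a": lens_a[i],
                         "identity": corr.a_hits[i].identity}))
    for j, intr in enumerate(corr.b_to_intron):
        if intr is not None and not corr.b_to_exons[j]:
            events.append(DivergenceEvent(
                EXONIZATION, feature_a=intr, feature_b=j,
                numbers={"exon_len_b": lens_b[j],
                         "identity": corr.b_hits[j].identity}))

    # EXON/INTRON GAIN/LOSS: exon with no feature-localised counterpart — a
    # weak alignment that overlaps no exon and sits in no intron is noise, not
    # a counterpart (short spurious local hits are expected at this scoring)
    for i in range(len(lens_a)):
        if (i not in matched_a and i not in split_a and not corr.a_to_exons[i]
                and corr.a_to_intron[i] is None):
            events.append(DivergenceEvent(
                EXON_INTRON_GAIN_LOSS, feature_a=i, feature_b=None,
                numbers={"exon_len_a": lens_a[i]}))
    for j in range(len(lens_b)):
        if (j not in matched_b and j not in split_b and not corr.b_to_exons[j]
                and corr.b_to_intron[j] is None):
            events.append(DivergenceEvent(
                EXON_INTRON_GAIN_LOSS, feature_a=None, feature_b=j,
                numbers={"exon_len_b": lens_b[j]}))

    # BOUNDARY_ALTERATION and INTRON_ELONGATION need 1:1 matched exon pairs
    unique_pairs = [(i, j) for i, j in pairs
                    if i not in split_a and j not in split_b
                    and sum(1 for p in pairs if p[0] == i) == 1
                    and sum(1 for p in pairs if p[1] == j) == 1]
    for i, j in unique_pairs:
        off = abs(lens_a[i] - lens_b[j])
        if off >= min_offset:
            ratios = []
            for ia, ib in ((i - 1, j - 1), (i, j)):  # flanking introns
                if 0 <= ia < len(ilens_a) and 0 <= ib < len(ilens_b):
                    ratios.append(max(ilens_a[ia], ilens_b[ib])
                                  / max(1, min(ilens_a[ia], ilens_b[ib])))
            if all(r <= boundary_intron_ratio for r in ratios) or not ratios:
                events.append(DivergenceEvent(
                    BOUNDARY_SHIFT, feature_a=i, feature_b=j,
                    numbers={"offset_bp": off, "len_a": lens_a[i],
                             "len_b": lens_b[j]}))
    pair_map = dict(unique_pairs)
    for i, j in unique_pairs:
        # intron after exon i homologous to intron after exon j when the next
        # exons also pair up
        if pair_map.get(i + 1) == j + 1 and i < len(ilens_a) and j < len(ilens_b):
            la, lb = ilens_a[i], ilens_b[j]
            ratio = max(la, lb) / max(1, min(la, lb))
            if ratio > elongation_factor:
                events.append(DivergenceEvent(
                    INTRON_ELONGATION, feature_a=i, feature_b=j,
                    numbers={"len_a": la, "len_b": lb, "ratio": ratio}))

    primary = NONE
    for mech in PRIORITY:
        if any(e.mechanism == mech for e in events):
            primary = mech
            break
    return events, primary


def pair_report(events: list[DivergenceEvent], geneA: GeneModel,
                geneB: GeneModel) -> dict:
    """Serializable per-pair comparison record: feature lengths, per-mechanism
    tally, and the event list (drives the structure diagram / TSV outputs)."""
    tally = {m: 0 for m in PRIORITY}
    for e in events:
        tally[e.mechanism] += 1
    return {
        "gene_a": geneA.gene_id,
        "gene_b": geneB.gene_id,
        "exon_lengths_a": geneA.exon_lengths(),
        "exon_lengths_b": geneB.exon_lengths(),
        "intron_lengths_a": geneA.intron_lengths(),
        "intron_lengths_b": geneB.intron_lengths(),
        "mechanism_tally": tally,
        "events": [
            {"mechanism": e.mechanism, "feature_a": e.feature_a,
             "feature_b": e.feature_b, "polarity": e.polarity, **e.numbers}
            for e in events
        ],
    }
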