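"""Core domain types and readers/writers for GFF3, FASTA and Newick.

Coordinate conventions: files on disk follow the GFF3 standard (1-based,
inclusive); every in-memory interval in this package is 0-based half-open.
Conversion happens exactly once, at read/write time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """One gene: chromosome, strand, ordered exon intervals, optional sequences.

    ``exons`` are stored in genomic order (ascending start), 0-based half-open,
    sorted and non-overlapping.  ``genomic_seq``, when present, is the plus-strand
    sequence of the gene span ``[span_start, span_end)`` so that exon/intron
    coordinates index into it after subtracting ``span_start``.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_phase_offset: int = 0
    genomic_seq: str | None = None
    cds_seq: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if e1 >= s2:  # adjacent exons would yield a zero-length intron
                raise ValueError(f"{self.gene_id}: overlapping/abutting exons {(s1, e1)} / {(s2, e2)}")
        for s, e in ex:
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty/inverted exon {(s, e)}")
        self.exons = ex

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def span_length(self) -> int:
        s, e = self.span
        return e - s

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Intervals between consecutive exons, genomic order, 0-based half-open."""
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    def exon_lengths(self) -> list[int]:
        return [e - s for s, e in self.exons]

    def intron_lengths(self) -> list[int]:
        return [e - s for s, e in self.introns]

    def local_exons(self) -> list[tuple[int, int]]:
        """Exon intervals relative to the gene span start."""
        off = self.span[0]
        return [(s - off, e - off) for s, e in self.exons]

    def local_introns(self) -> list[tuple[int, int]]:
        off = self.span[0]
        return [(s - off, e - off) for s, e in self.introns]

    def exon_seqs(self) -> list[str]:
        if self.genomic_seq is None:
            raise ValueError(f"{self.gene_id}: no genomic sequence attached")
        return [self.genomic_seq[s:e] for s, e in self.local_exons()]

    def spliced_seq(self) -> str:
        """Exon sequence concatenated in transcript orientation."""
        s = "".join(self.exon_seqs())
        return revcomp(s) if self.strand == "-" else s


@dataclass
class GeneCatalog:
    """Per-chromosome ordered gene lists; the substrate for tandem clustering.

    ``genes[chrom]`` is a list of (gene_id, start, end, strand) sorted by start;
    ranks are consecutive 0..n-1 per chromosome.
    """

    genes: dict[str, list[tuple[str, int, int, str]]]
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._rank: dict[str, tuple[str, int]] = {}
        for chrom in self.genes:
            self.genes[chrom] = sorted(self.genes[chrom], key=lambda g: (g[1], g[0]))
            for i, (gid, _s, _e, _st) in enumerate(self.genes[chrom]):
                if gid in self._rank:
                    raise ValueError(f"duplicate gene id {gid!r} in catalog")
                self._rank[gid] = (chrom, i)

    def rank(self, gene_id: str) -> tuple[str, int]:
        """(chromosome, ordinal position in gene order); KeyError naming the id."""
        try:
            return self._rank[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in catalog") from None

    def coords(self, gene_id: str) -> tuple[str, int, int, str]:
        chrom, i = self.rank(gene_id)
        gid, s, e, st = self.genes[chrom][i]
        return chrom, s, e, st

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._rank

    @property
    def n_genes(self) -> int:
        return len(self._rank)

    def to_frame(self):
        import pandas as pd

        rows = [
            (chrom, i, gid, s, e, st)
            for chrom, lst in sorted(self.genes.items())
            for i, (gid, s, e, st) in enumerate(lst)
        ]
        return pd.DataFrame(rows, columns=["chrom", "rank", "gene_id", "start", "end", "strand"])


@dataclass
class HomologyGroups:
    """Within-species paragroups, cross-species orthogroups, closest-paralog pairs."""

    paragroups: list[set[str]] = field(default_factory=list)
    orthogroups: list[set[str]] = field(default_factory=list)
    sibling_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for grp in self.paragroups:
            dup = seen & grp
            if dup:
                raise ValueError(f"gene(s) in more than one paragroup: {sorted(dup)}")
            seen |= grp
        pairs = {frozenset(p) for p in self.sibling_pairs}
        if len(pairs) != len(self.sibling_pairs):
            raise ValueError("sibling pairs must be unique (unordered)")


@dataclass
class LabeledTree:
    """A rooted binary tree plus, for gene trees, a leaf gene→species mapping.

    Wraps a :class:`dendropy.Tree`; polytomies found on input are resolved to a
    left-to-right caterpillar with zero-length edges and the fact is recorded in
    ``resolved_polytomies``.
    """

    tree: dendropy.Tree
    species_map: dict[str, str] = field(default_factory=dict)
    resolved_polytomies: int = 0

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def is_binary(self) -> bool:
        return all(
            len(n.child_nodes()) in (0, 2) for n in self.tree.preorder_node_iter()
        )


def _resolve_polytomies(tree: dendropy.Tree) -> int:
    """Caterpillar-resolve every polytomy, left to right; returns count resolved."""
    n_resolved = 0
    for node in list(tree.preorder_node_iter()):
        children = node.child_nodes()
        while len(children) > 2:
            n_resolved += 1
            left, second = children[0], children[1]
            new = dendropy.Node()
            new.edge.length = 0.0
            node.remove_child(left)
            node.remove_child(second)
            new.add_child(left)
            new.add_child(second)
            node.insert_child(0, new)
            children = node.child_nodes()
    return n_resolved


def read_newick(
    path: str | Path | None = None,
    species_map: Mapping[str, str] | None = None,
    *,
    data: str | None = None,
    species_leaves: bool = False,
) -> LabeledTree:
    """Read one Newick tree into a :class:`LabeledTree`.

    Gene-tree leaf labels of the form ``"SPECIES|gene"`` are mapped automatically;
    otherwise ``species_map`` must resolve each leaf.  With ``species_leaves=True``
    the tree is taken as a species tree and no mapping is built.  Polytomies are
    resolved deterministically (caterpillar, recorded).
    """
    if (path is None) == (data is None):
        raise ValueError("provide exactly one of path= or data=")
    src = {"path": str(path)} if path is not None else {"data": data}
    try:
        tree = dendropy.Tree.get(
            schema="newick", preserve_underscores=True, suppress_internal_node_taxa=True, **src
        )
    except Exception as exc:  # dendropy raises schema-specific errors with positions
        raise ValueError(f"Newick parse error: {exc}") from exc
    n_res = _resolve_polytomies(tree)
    if n_res:
        log.info("resolved %d polytomies (caterpillar, zero-length edges)", n_res)

    smap: dict[str, str] = {}
    if not species_leaves:
        for lf in tree.leaf_node_iter():
            label = lf.taxon.label
            if "|" in label:
                sp, gene = label.split("|", 1)
                lf.taxon.label = label  # keep full label; map by gene id too
                smap[label] = sp
                smap.setdefault(gene, sp)
            elif species_map is not None and label in species_map:
                smap[label] = species_map[label]
            else:
                raise ValueError(f"leaf {label!r} cannot be mapped to a species")
    else:
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("species tree leaf labels must be unique")
    return LabeledTree(tree=tree, species_map=smap, resolved_polytomies=n_res)


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA → {id: uppercased sequence}; duplicate ids are an error."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper().replace(" ", "")
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_gff3(
    path: str | Path, fasta: Mapping[str, str] | None = None
) -> tuple[list[GeneModel], GeneCatalog]:
    """Parse gene/mRNA/exon/CDS features into GeneModels plus a GeneCatalog.

    When a gene carries several mRNAs the isoform with the longest summed CDS is
    retained (ties: lexicographically smallest transcript id).  Records whose
    exons overlap within one mRNA are rejected with a logged warning.  All genes,
    of any biotype, enter the catalog ordering.
    """
    path = Path(path)
    if path.stat().st_size == 0 or not path.read_text().strip():
        return [], GeneCatalog(genes={})
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    catalog: dict[str, list[tuple[str, int, int, str]]] = {}
    for gene in db.features_of_type("gene", order_by="start"):
        gid = gene.id
        catalog.setdefault(gene.seqid, []).append(
            (gid, gene.start - 1, gene.end, gene.strand)
        )
        mrnas = list(db.children(gene, featuretype="mRNA"))
        best = None
        if mrnas:
            def cds_len(m):
                return sum(c.end - c.start + 1 for c in db.children(m, featuretype="CDS"))

            best = min(mrnas, key=lambda m: (-cds_len(m), m.id))
            exon_feats = list(db.children(best, featuretype="exon", order_by="start"))
            cds_feats = list(db.children(best, featuretype="CDS", order_by="start"))
        else:
            exon_feats = list(db.children(gene, featuretype="exon", order_by="start"))
            cds_feats = list(db.children(gene, featuretype="CDS", order_by="start"))
        if not exon_feats:
            if cds_feats:
                exon_feats = cds_feats
            else:
                exon_feats = [gene]
        exons = [(f.start - 1, f.end) for f in exon_feats]
        exons.sort()
        if any(e1 > s2 for (_, e1), (s2, _) in zip(exons, exons[1:])):
            log.warning("gene %s: overlapping exons within one mRNA; record rejected", gid)
            continue
        genomic = None
        cds_seq = None
        if fasta is not None and gene.seqid in fasta:
            chrom_seq = fasta[gene.seqid]
            genomic = chrom_seq[exons[0][0]: exons[-1][1]]
            if cds_feats:
                parts = [chrom_seq[f.start - 1: f.end] for f in sorted(cds_feats, key=lambda f: f.start)]
                cds_seq = "".join(parts)
                if gene.strand == "-":
                    cds_seq = revcomp(cds_seq)
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=gene.seqid,
                strand=gene.strand,
                exons=exons,
                genomic_seq=genomic,
                cds_seq=cds_seq,
            )
        )
    return models, GeneCatalog(genes=catalog)


def write_gff3(
    models: Iterable[GeneModel],
    path: str | Path,
    chrom_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write GeneModels as gene/mRNA/exon features (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if chrom_lengths:
            for chrom, ln in sorted(chrom_lengths.items()):
                fh.write(f"##sequence-region {chrom} 1 {ln}\n")
        for gm in sorted(models, key=lambda g: (g.chrom, g.span[0])):
            s, e = gm.span
            base = f"{gm.chrom}\tdupdiverge\t"
            fh.write(base + f"gene\t{s + 1}\t{e}\t.\t{gm.strand}\t.\tID={gm.gene_id}\n")
            tid = f"{gm.gene_id}.t1"
            fh.write(base + f"mRNA\t{s + 1}\t{e}\t.\t{gm.strand}\t.\tID={tid};Parent={gm.gene_id}\n")
            for i, (xs, xe) in enumerate(gm.exons, 1):
                fh.write(
                    base
                    + f"exon\t{xs + 1}\t{xe}\t.\t{gm.strand}\t.\tID={tid}.e{i};Parent={tid}\n"
                )


def write_catalog_tsv(catalog: GeneCatalog, path: str | Path) -> None:
    catalog.to_frame().to_csv(path, sep="\t", index=False)


def read_catalog_tsv(path: str | Path) -> GeneCatalog:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    genes: dict[str, list[tuple[str, int, int, str]]] = {}
    for row in df.itertuples(index=False):
        genes.setdefault(str(row.chrom), []).append(
            (str(row.gene_id), int(row.start), int(row.end), str(row.strand))
        )
    return GeneCatalog(genes=genes)
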