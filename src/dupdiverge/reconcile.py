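"""Duplication–loss maximum-parsimony reconciliation of gene trees against a
species tree, aggregated into per-branch gains/losses and ancestral counts.

The LCA (last-common-ancestor) mapping sends every gene-tree node to the
species-tree LCA of its leaves' species; under unit duplication and loss costs
this mapping attains the minimum total cost.  A gene node is a DUPLICATION iff
it maps to the same species node as one of its children, otherwise a
SPECIATION.  Losses are charged to the species branches skipped on the path
between a node's mapping and its child's mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy

from .io_models import LabeledTree
from .synthetic_data import species_branch_label

SPECIATION = "SPECIATION"
DUPLICATION = "DUPLICATION"


class _SpeciesIndex:
    """Parent pointers, depths and clade labels for fast LCA on the species tree."""

    def __init__(self, stree: dendropy.Tree) -> None:
        self.tree = stree
        self.parent: dict[int, dendropy.Node | None] = {}
        self.depth: dict[int, int] = {}
        self.by_leaf: dict[str, dendropy.Node] = {}
        self.label: dict[int, str] = {}
        for node in stree.preorder_node_iter():
            p = node.parent_node
            self.parent[id(node)] = p
            self.depth[id(node)] = 0 if p is None else self.depth[id(p)] + 1
            self.label[id(node)] = species_branch_label(node)
            if node.is_leaf():
                self.by_leaf[node.taxon.label] = node

    def lca(self, a: dendropy.Node, b: dendropy.Node) -> dendropy.Node:
        while a is not b:
            if self.depth[id(a)] >= self.depth[id(b)]:
                a = self.parent[id(a)]
            else:
                b = self.parent[id(b)]
        return a

    def dist(self, anc: dendropy.Node, desc: dendropy.Node) -> int:
        """Edges on the path from ancestor ``anc`` down to ``desc``."""
        d = self.depth[id(desc)] - self.depth[id(anc)]
        if d < 0:
            raise ValueError("dist() called with non-ancestor")
        return d

    def path_down(self, anc: dendropy.Node, desc: dendropy.Node) -> list[dendropy.Node]:
        """Nodes strictly between anc and desc plus both endpoints, top-down."""
        path = [desc]
        n = desc
        while n is not anc:
            n = self.parent[id(n)]
            path.append(n)
        return path[::-1]


@dataclass
class Reconciliation:
    """LCA mapping, event labels, per-branch losses and the DL cost of one tree."""

    lca_map: dict[int, dendropy.Node]
    events: dict[int, str]                  # internal gene node id → event
    losses: list[tuple[str, int]]           # (species branch label, count)
    cost: int
    root_species: dendropy.Node
    duplications_per_branch: dict[str, int] = field(default_factory=dict)
    leaf_species_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_duplications(self) -> int:
        return sum(1 for e in self.events.values() if e == DUPLICATION)

    @property
    def n_losses(self) -> int:
        return sum(c for _, c in self.losses)


def lca_reconcile(gene_tree: LabeledTree, species_tree: LabeledTree) -> Reconciliation:
    """Minimum duplication+loss reconciliation via the LCA mapping."""
    gtree = gene_tree.tree
    sidx = _SpeciesIndex(species_tree.tree)
    if not gene_tree.is_binary() or any(
        len(n.child_nodes()) not in (0, 2) for n in species_tree.tree.preorder_node_iter()
    ):
        raise ValueError("both trees must be rooted and binary")

    lca_map: dict[int, dendropy.Node] = {}
    events: dict[int, str] = {}
    leaf_counts: dict[str, int] = {}
    for g in gtree.postorder_node_iter():
        if g.is_leaf():
            label = g.taxon.label
            sp = gene_tree.species_map.get(label)
            if sp is None and "|" in label:
                sp = label.split("|", 1)[0]
            if sp is None or sp not in sidx.by_leaf:
                raise ValueError(f"gene leaf {label!r} maps to unknown species {sp!r}")
            lca_map[id(g)] = sidx.by_leaf[sp]
            leaf_counts[sp] = leaf_counts.get(sp, 0) + 1
        else:
            c1, c2 = g.child_nodes()
            m = sidx.lca(lca_map[id(c1)], lca_map[id(c2)])
            lca_map[id(g)] = m
            if m is lca_map[id(c1)] or m is lca_map[id(c2)]:
                events[id(g)] = DUPLICATION
            else:
                events[id(g)] = SPECIATION

    loss_counts: dict[str, int] = {}
    dup_per_branch: dict[str, int] = {}
    for g in gtree.preorder_node_iter():
        if not g.is_leaf():
            if events[id(g)] == DUPLICATION:
                lab = sidx.label[id(lca_map[id(g)])]
                dup_per_branch[lab] = dup_per_branch.get(lab, 0) + 1
        for c in g.child_nodes():
            mu, mv = lca_map[id(g)], lca_map[id(c)]
            path = sidx.path_down(mu, mv)  # mu .. mv inclusive
            # a copy passes through the intermediate species nodes; at each,
            # the off-path child branch loses a copy.  For a duplication that
            # stays above mv, the copy is also present at mu itself.
            start = 0 if events[id(g)] == DUPLICATION and mu is not mv else 1
            for node, nxt in zip(path[start:], path[start + 1:]) if len(path) > 1 else []:
                for ch in node.child_nodes():
                    if ch is not nxt:
                        lab = sidx.label[id(ch)]
                        loss_counts[lab] = loss_counts.get(lab, 0) + 1

    losses = sorted(loss_counts.items())
    cost = sum(1 for e in events.values() if e == DUPLICATION) + sum(loss_counts.values())
    return Reconciliation(
        lca_map=lca_map,
        events=events,
        losses=losses,
        cost=cost,
        root_species=lca_map[id(gtree.seed_node)],
        duplications_per_branch=dup_per_branch,
        leaf_species_counts=leaf_counts,
    )


@dataclass
class FamilyHistory:
    """Per-branch gains/losses and ancestral copy numbers over a forest."""

    gains: dict[str, int]
    losses: dict[str, int]
    ancestral_counts: dict[str, int]   # species node label → inferred count
    observed_counts: dict[str, int]
    n_families: int

    @property
    def total_gains(self) -> int:
        return sum(self.gains.values())

    @property
    def total_losses(self) -> int:
        return sum(self.losses.values())

    def to_frame(self):
        import pandas as pd

        branches = sorted(set(self.gains) | set(self.losses) | set(self.ancestral_counts))
        return pd.DataFrame(
            {
                "branch": branches,
                "gains": [self.gains.get(b, 0) for b in branches],
                "losses": [self.losses.get(b, 0) for b in branches],
                "count": [self.ancestral_counts.get(b, 0) for b in branches],
            }
        )


def aggregate_histories(
    reconciliations: Iterable[Reconciliation],
    species_tree: LabeledTree,
    observed_counts: Mapping[str, int] | None = None,
) -> FamilyHistory:
    """Sum per-branch events over a forest and infer ancestral family sizes.

    Each family contributes its duplications (as gains on the branch entering
    the species node they map to), its losses, and one "origin" gain of 1 on
    the branch entering the species LCA of its observed members — so a family
    absent from a clade creates no phantom losses above its root.  Ancestral
    counts then satisfy count(child) = count(parent) + gains − losses on every
    branch.
    """
    sidx = _SpeciesIndex(species_tree.tree)
    recs = list(reconciliations)
    gains: dict[str, int] = {}
    losses: dict[str, int] = {}
    observed: dict[str, int] = {}
    for rec in recs:
        for lab, k in rec.duplications_per_branch.items():
            gains[lab] = gains.get(lab, 0) + k
        for lab, k in rec.losses:
            losses[lab] = losses.get(lab, 0) + k
        origin_lab = sidx.label[id(rec.root_species)]
        gains[origin_lab] = gains.get(origin_lab, 0) + 1
        for sp, k in rec.leaf_species_counts.items():
            observed[sp] = observed.get(sp, 0) + k

    if observed_counts is not None:
        if dict(observed_counts) != observed:
            raise ValueError(
                f"observed counts {dict(observed_counts)} inconsistent with "
                f"forest leaves {observed}"
            )

    # ancestral counts from the bookkeeping identity, top-down from zero above
    # every family's origin: count(child) = count(parent) + gains − losses
    counts: dict[str, int] = {}
    for node in species_tree.tree.preorder_node_iter():
        lab = sidx.label[id(node)]
        parent = node.parent_node
        above = counts[sidx.label[id(parent)]] if parent is not None else 0
        counts[lab] = above + gains.get(lab, 0) - losses.get(lab, 0)
    for sp, k in observed.items():
        if counts.get(sp, 0) != k:
            raise ValueError(
                f"internal inconsistency: inferred count {counts.get(sp, 0)} at "
                f"{sp} != observed {k}"
            )
    return FamilyHistory(
        gains=gains,
        losses=losses,
        ancestral_counts=counts,
        observed_counts=observed,
        n_families=len(recs),
    )
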