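"""Gene-family gain/loss/duplication reconstruction on a species tree.

The model is Dollo parsimony: each family arises exactly once, on the
branch subtending the most recent common ancestor of the species that
retain it, and is subsequently lost independently on whole branches.
Duplications are inferred from the family's gene-tree topology by LCA
mapping (reconciliation): a gene-tree node is a duplication when it maps
to the same species-tree node as one of its children. Each duplication is
assumed to contribute one extra gene copy to every descendant species
that retains the family, which is what lets predicted terminal gene
counts be read off the event set.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import pandas as pd

from .trees import SpeciesTree, tip_species

GAIN = "gain"
LOSS = "loss"
DUPLICATION = "duplication"


@dataclass(frozen=True)
class Event:
    """A single reconstructed event placed on a named species-tree branch."""

    family: str
    kind: str
    branch: str


@dataclass
class MonophylyReport:
    family: str
    monophyletic: bool
    intruders: tuple[str, ...] = ()


@dataclass
class EventSummary:
    """Totals over an event set plus per-branch and per-species breakdowns."""

    n_families: int
    n_stem_gains: int
    n_losses: int
    n_duplications: int
    losses_per_branch: dict = field(default_factory=dict)
    dups_per_branch: dict = field(default_factory=dict)
    terminal_counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_families": self.n_families,
            "n_stem_gains": self.n_stem_gains,
            "n_losses": self.n_losses,
            "n_duplications": self.n_duplications,
            "losses_per_branch": dict(self.losses_per_branch),
            "dups_per_branch": dict(self.dups_per_branch),
            "terminal_counts": dict(self.terminal_counts),
        }


# ---------------------------------------------------------------------------
# isoform removal


def dedup_isoforms(
    tree: dendropy.Tree,
    focal_species: Iterable[str],
    tolerance: float = 1e-9,
    sidecar: Mapping[str, str] | None = None,
) -> dendropy.Tree:
    """Collapse zero-length same-species cherries down to one tip.

    Transcript assemblies often carry several isoforms of one gene; on a
    tree these appear as cherries of tips from the same (focal) species
    joined by zero-length terminal branches. For every such cherry the
    lexicographically smallest tip label is kept; the scan repeats until
    no removable cherry remains, so the operation is idempotent.
    """
    focal = set(focal_species)
    out = tree.clone(depth=1)
    for leaf in out.leaf_node_iter():
        if leaf.edge.length is None:
            raise ValueError(
                f"tip {leaf.taxon.label!r} is missing a branch length"
            )
    changed = True
    while changed:
        changed = False
        for node in list(out.preorder_internal_node_iter()):
            leaves = [c for c in node.child_nodes() if c.is_leaf()]
            by_species: dict[str, list] = {}
            for lf in leaves:
                sp = tip_species(lf.taxon.label, sidecar)
                if sp in focal and (lf.edge.length or 0.0) <= tolerance:
                    by_species.setdefault(sp, []).append(lf)
            for group in by_species.values():
                if len(group) >= 2:
                    group.sort(key=lambda lf: lf.taxon.label)
                    for extra in group[1:]:
                        node.remove_child(extra)
                    changed = True
            if changed:
                break
        if changed:
            out.suppress_unifurcations()
    out.purge_taxon_namespace()
    return out


# ---------------------------------------------------------------------------
# presence matrix


def build_presence_matrix(
    tree: dendropy.Tree,
    fam: Mapping[str, str],
    sp: SpeciesTree,
    sidecar: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Tabulate per-(family, species) gene-copy counts from gene-tree tips.

    Returns the family x species count matrix and the list of tips whose
    gene id is not covered by the assignment. A gene assigned to a family
    but absent from the tree is an error.
    """
    tip_by_gene: dict[str, list[str]] = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        gene = label.split("_", 1)[1] if "_" in label else label
        tip_by_gene.setdefault(gene, []).append(label)
        if label != gene:  # allow assignment keyed by full tip label
            tip_by_gene.setdefault(label, []).append(label)
    missing = [g for g in fam if g not in tip_by_gene]
    if missing:
        raise ValueError(
            f"genes assigned to families but absent from the tree: {sorted(missing)}"
        )
    ambiguous = [g for g in fam if len(tip_by_gene[g]) > 1]
    if ambiguous:
        raise ValueError(
            f"gene ids match multiple tips: {sorted(ambiguous)}"
        )
    families = sorted(set(fam.values()))
    counts = pd.DataFrame(0, index=families, columns=list(sp.species), dtype=int)
    assigned_tips = {tip_by_gene[g][0]: f for g, f in fam.items()}
    unassigned: list[str] = []
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        species = tip_species(label, sidecar)
        if label in assigned_tips:
            counts.loc[assigned_tips[label], species] += 1
        else:
            unassigned.append(label)
    return counts, sorted(unassigned)


# ---------------------------------------------------------------------------
# reconciliation


def lca_map(
    subtree: dendropy.Tree,
    sp: SpeciesTree,
    sidecar: Mapping[str, str] | None = None,
) -> dict:
    """Map each gene-tree node to its species-tree LCA image.

    Tips map to their species leaf; an internal node maps to the MRCA of
    its children's images.
    """
    mapping: dict = {}
    for node in subtree.postorder_node_iter():
        if node.is_leaf():
            code = tip_species(node.taxon.label, sidecar)
            if code not in sp.species:
                raise ValueError(f"unknown species code {code!r} on tip "
                                 f"{node.taxon.label!r}")
            mapping[node] = sp.leaf(code)
        else:
            mapping[node] = sp.mrca_node(mapping[c] for c in node.child_nodes())
    return mapping


def infer_duplications(
    family_subtree: dendropy.Tree,
    sp: SpeciesTree,
    family: str = "",
    sidecar: Mapping[str, str] | None = None,
) -> list[Event]:
    """Call duplication nodes on one family's gene subtree by LCA mapping.

    A node is a duplication when its species-tree image equals the image
    of at least one of its children; the event is placed on the branch
    leading to that image.
    """
    n_tips = sum(1 for _ in family_subtree.leaf_node_iter())
    if n_tips < 2:
        return []
    mapping = lca_map(family_subtree, sp, sidecar)
    events = []
    for node in family_subtree.preorder_internal_node_iter():
        if any(mapping[c] is mapping[node] for c in node.child_nodes()):
            events.append(
                Event(family, DUPLICATION, sp.branch_label(mapping[node]))
            )
    return events


# ---------------------------------------------------------------------------
# Dollo gain/loss


def dollo_events(
    presence: Iterable[str], sp: SpeciesTree, family: str = ""
) -> tuple[Event, list[Event]]:
    """Single-gain (Dollo) reconstruction for one family's presence set.

    The gain is placed on the branch subtending the MRCA of the species
    retaining the family; one loss is emitted on each maximal branch
    below it whose whole descendant clade lacks the family. This loss
    placement is the unique minimum under a single gain.
    """
    present = set(presence)
    if not present:
        raise ValueError("presence set is empty: no Dollo reconstruction")
    gain_node = sp.mrca(present)
    gain = Event(family, GAIN, sp.branch_label(gain_node))
    losses: list[Event] = []

    def descend(node):
        for child in node.child_nodes():
            if sp.leaves_below(child) & present:
                descend(child)
            else:
                losses.append(Event(family, LOSS, sp.branch_label(child)))

    descend(gain_node)
    return gain, losses


# ---------------------------------------------------------------------------
# whole-set summary


def _family_subtree(tree: dendropy.Tree, tips: list[str]) -> dendropy.Tree:
    sub = tree.extract_tree_with_taxa_labels(labels=tips)
    sub.is_rooted = True
    return sub


def summarize_events(
    matrix: pd.DataFrame,
    tree: dendropy.Tree,
    fam: Mapping[str, str],
    sp: SpeciesTree,
    sidecar: Mapping[str, str] | None = None,
) -> tuple[list[Event], EventSummary]:
    """Run Dollo gain/loss plus LCA-mapping duplications for every family.

    Predicted terminal gene counts replay the events: each species
    retaining a family contributes one copy plus one more per duplication
    on a branch whose clade contains that species.
    """
    zero = matrix.index[(matrix.sum(axis=1) == 0)]
    if len(zero):
        raise ValueError(f"families with zero copies everywhere: {list(zero)}")
    tips_by_family: dict[str, list[str]] = {f: [] for f in matrix.index}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        gene = label.split("_", 1)[1] if "_" in label else label
        family = fam.get(label, fam.get(gene))
        if family is not None:
            tips_by_family.setdefault(family, []).append(label)

    events: list[Event] = []
    for family in matrix.index:
        presence = set(matrix.columns[matrix.loc[family] > 0])
        gain, losses = dollo_events(presence, sp, family)
        events.append(gain)
        events.extend(losses)
        tips = tips_by_family.get(family, [])
        if len(tips) >= 2:
            events.extend(
                infer_duplications(_family_subtree(tree, tips), sp, family,
                                   sidecar)
            )

    loss_counter = Counter(e.branch for e in events if e.kind == LOSS)
    dup_counter = Counter(e.branch for e in events if e.kind == DUPLICATION)
    terminal = {}
    for species in sp.species:
        n = int((matrix[species] > 0).sum())
        for e in events:
            if e.kind == DUPLICATION and species in sp.clade(e.branch) \
                    and matrix.loc[e.family, species] > 0:
                n += 1
        terminal[species] = n
    summary = EventSummary(
        n_families=int(matrix.shape[0]),
        n_stem_gains=sum(
            1 for e in events if e.kind == GAIN and e.branch == "stem"
        ),
        n_losses=sum(1 for e in events if e.kind == LOSS),
        n_duplications=sum(1 for e in events if e.kind == DUPLICATION),
        losses_per_branch=dict(loss_counter),
        dups_per_branch=dict(dup_counter),
        terminal_counts=terminal,
    )
    return events, summary


def validate_family_monophyly(
    tree: dendropy.Tree,
    fam: Mapping[str, str],
    sidecar: Mapping[str, str] | None = None,
) -> list[MonophylyReport]:
    """Check that each family's genes form a clade (other families excluded).

    Unassigned tips inside a family's span do not break monophyly; only
    tips assigned to a different family count as intruders.
    """
    tips_by_family: dict[str, list] = {}
    assigned: dict = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        gene = label.split("_", 1)[1] if "_" in label else label
        family = fam.get(label, fam.get(gene))
        if family is not None:
            tips_by_family.setdefault(family, []).append(leaf)
            assigned[leaf] = family
    reports = []
    for family in sorted(tips_by_family):
        tips = tips_by_family[family]
        mrca = tree.mrca(taxa=[t.taxon for t in tips])
        intruders = tuple(
            sorted(
                lf.taxon.label
                for lf in mrca.leaf_iter()
                if lf in assigned and assigned[lf] != family
            )
        )
        reports.append(MonophylyReport(family, not intruders, intruders))
    return reports


def events_to_frame(events: list[Event]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.family, e.kind, e.branch) for e in events],
        columns=["family", "kind", "branch"],
    )
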