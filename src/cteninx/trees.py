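"""Rooted-tree utilities shared by the event-reconstruction code.

Species trees are small rooted binary trees whose terminal branches are
named by two-letter species codes (Bo = *Beroe ovata*, Ml = *Mnemiopsis
leidyi*, Pb = *Pleurobrachia bachei*, Hc = *Hormiphora californensis*) and
whose internal branches are named by clade (``BoMl-ancestor``,
``PbHc-ancestor``) with the branch subtending the root called ``stem``.
Gene trees carry tips labelled ``<SpeciesCode>_<geneid>``; an optional
sidecar mapping can override that convention.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import dendropy

#: Default four-ctenophore topology implied by the stated family origins
#: (INXP in the Bo+Ml ancestor, INXE in the Pb+Hc ancestor).
DEFAULT_SPECIES_NEWICK = (
    "((Bo:1.0,Ml:1.0)BoMl-ancestor:1.0,(Pb:1.0,Hc:1.0)PbHc-ancestor:1.0)stem;"
)

STEM_BRANCH = "stem"


def read_newick(source: str) -> dendropy.Tree:
    """Parse a Newick string (or ``@path``) into a rooted dendropy tree."""
    if source.startswith("@"):
        tree = dendropy.Tree.get(
            path=source[1:], schema="newick", preserve_underscores=True
        )
    else:
        tree = dendropy.Tree.get(
            data=source, schema="newick", preserve_underscores=True
        )
    tree.is_rooted = True
    return tree


def tip_species(label: str, sidecar: Mapping[str, str] | None = None) -> str:
    """Species code of a gene-tree tip: sidecar lookup, else prefix before '_'."""
    if sidecar is not None and label in sidecar:
        return sidecar[label]
    if "_" not in label:
        raise ValueError(
            f"tip {label!r} has no '_' species prefix and no sidecar entry"
        )
    return label.split("_", 1)[0]


def tip_gene(label: str, sidecar: Mapping[str, str] | None = None) -> str:
    """Gene id of a gene-tree tip: sidecar lookup, else suffix after '_'."""
    if sidecar is not None and label in sidecar:
        return sidecar[label]
    if "_" not in label:
        return label
    return label.split("_", 1)[1]


class SpeciesTree:
    """A rooted species tree with named branches.

    Each branch is identified by the node it subtends: species code for
    terminal branches, the Newick internal-node label where present
    (otherwise the preorder concatenation of descendant codes plus
    ``-ancestor``), and ``stem`` for the root.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._tree.is_rooted = True
        self._leaves_below: dict = {}
        self._parent: dict = {}
        self._label: dict = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                if node.taxon is None or not node.taxon.label:
                    raise ValueError("species tree has an unlabelled leaf")
                self._leaves_below[node] = frozenset({node.taxon.label})
            else:
                below = frozenset().union(
                    *(self._leaves_below[c] for c in node.child_nodes())
                )
                self._leaves_below[node] = below
            for child in node.child_nodes():
                self._parent[child] = node
        codes = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(codes) != len(set(codes)):
            raise ValueError("species codes are not unique")
        self.species = tuple(codes)
        for node in tree.preorder_node_iter():
            self._label[node] = self._make_label(node)
        self._by_label = {v: k for k, v in self._label.items()}

    @classmethod
    def from_newick(cls, source: str = DEFAULT_SPECIES_NEWICK) -> "SpeciesTree":
        return cls(read_newick(source))

    @classmethod
    def default(cls) -> "SpeciesTree":
        """The four-species ctenophore tree ((Bo,Ml),(Pb,Hc))."""
        return cls.from_newick(DEFAULT_SPECIES_NEWICK)

    # -- structure ---------------------------------------------------------

    @property
    def root(self):
        return self._tree.seed_node

    def _make_label(self, node) -> str:
        if node is self._tree.seed_node:
            return STEM_BRANCH
        if node.is_leaf():
            return node.taxon.label
        if node.label:
            return node.label
        order = [
            lf.taxon.label
            for lf in node.preorder_iter()
            if lf.is_leaf()
        ]
        return "".join(order) + "-ancestor"

    def branch_label(self, node) -> str:
        return self._label[node]

    def node_for_branch(self, label: str):
        try:
            return self._by_label[label]
        except KeyError:
            raise KeyError(f"no species-tree branch named {label!r}") from None

    def leaves_below(self, node) -> frozenset:
        return self._leaves_below[node]

    def clade(self, branch: str) -> frozenset:
        """Species codes in the clade subtended by a named branch."""
        return self._leaves_below[self.node_for_branch(branch)]

    def leaf(self, code: str):
        node = self._by_label.get(code)
        if node is None or not node.is_leaf():
            raise KeyError(f"unknown species code {code!r}")
        return node

    def parent(self, node):
        return self._parent.get(node)

    def preorder_nodes(self):
        return self._tree.preorder_node_iter()

    def leaf_nodes(self):
        return self._tree.leaf_node_iter()

    def ancestors(self, node) -> list:
        """Path from node to the root, inclusive of both ends."""
        path = [node]
        while node in self._parent:
            node = self._parent[node]
            path.append(node)
        return path

    def mrca(self, codes: Iterable[str]):
        """Most recent common ancestor node of a set of species codes."""
        codes = set(codes)
        unknown = codes - set(self.species)
        if unknown:
            raise ValueError(f"unknown species code(s): {sorted(unknown)}")
        if not codes:
            raise ValueError("empty species set has no MRCA")
        paths = [self.ancestors(self.leaf(c)) for c in codes]
        common = set(paths[0]).intersection(*map(set, paths[1:]))
        # deepest common ancestor = first common node on any root-ward path
        for node in paths[0]:
            if node in common:
                return node
        raise AssertionError("rooted tree must have a common ancestor")

    def mrca_node(self, nodes) -> object:
        """MRCA of species-tree nodes (used by gene-tree LCA mapping)."""
        nodes = list(nodes)
        paths = [self.ancestors(n) for n in nodes]
        common = set(paths[0]).intersection(*map(set, paths[1:]))
        for node in paths[0]:
            if node in common:
                return node
        raise AssertionError("rooted tree must have a common ancestor")
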