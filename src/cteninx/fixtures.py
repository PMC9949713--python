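"""Packaged fixture encoding the published ctenophore innexin membership.

Seventeen families (INXA--INXR, INXI unused) over the four species
Bo, Ml, Pb, Hc on the tree ((Bo,Ml),(Pb,Hc)):

* fourteen families present in the stem ancestor: A-D, G, H, J-O, Q, R;
* INXP arose in the Bo+Ml ancestor, INXE in the Pb+Hc ancestor, INXF in Hc;
* losses: Ml lost K, N, Q, R; Bo lost A, J; Pb lost A, G, H, K, O, Q, R;
* duplications: INXG in Ml, INXJ in Hc, INXF in Hc, and one in the Pb+Hc
  ancestor, here carried by INXE (which family holds that duplication is
  not determined by the published counts; INXE is a documented choice).

The gene tree realizes each family as a species-concordant clade with the
paralog topology needed for LCA-mapping to recover the duplications.
"""

from __future__ import annotations

import dendropy

from .trees import SpeciesTree, read_newick

#: family -> per-species copy counts after all events
PAPER_FAMILY_COPIES: dict[str, dict[str, int]] = {
    "INXA": {"Ml": 1, "Hc": 1},
    "INXB": {"Bo": 1, "Ml": 1, "Pb": 1, "Hc": 1},
    "INXC": {"Bo": 1, "Ml": 1, "Pb": 1, "Hc": 1},
    "INXD": {"Bo": 1, "Ml": 1, "Pb": 1, "Hc": 1},
    "INXE": {"Pb": 2, "Hc": 2},
    "INXF": {"Hc": 2},
    "INXG": {"Bo": 1, "Ml": 2, "Hc": 1},
    "INXH": {"Bo": 1, "Ml": 1, "Hc": 1},
    "INXJ": {"Ml": 1, "Pb": 1, "Hc": 2},
    "INXK": {"Bo": 1, "Hc": 1},
    "INXL": {"Bo": 1, "Ml": 1, "Pb": 1, "Hc": 1},
    "INXM": {"Bo": 1, "Ml": 1, "Pb": 1, "Hc": 1},
    "INXN": {"Bo": 1, "Pb": 1, "Hc": 1},
    "INXO": {"Bo": 1, "Ml": 1, "Hc": 1},
    "INXP": {"Bo": 1, "Ml": 1},
    "INXQ": {"Bo": 1, "Hc": 1},
    "INXR": {"Bo": 1, "Hc": 1},
}

_SPECIES_ORDER = ("Bo", "Ml", "Pb", "Hc")
_BLEN = 0.1


def _tip(species: str, family: str, copy: int, multi: bool) -> str:
    # gene ids carry the species code so they are globally unique
    suffix = f".{copy}" if multi else ""
    return f"{species}_{species.lower()}-{family.lower()}{suffix}"


def _family_clade(family: str, copies: dict[str, int]) -> str:
    """Species-concordant Newick for one family, with paralog cherries.

    A duplication in a terminal lineage becomes a same-species cherry;
    the INXE ancestor duplication becomes two parallel (Pb,Hc) cherries.
    """
    if family == "INXE":
        return (
            f"((Pb_pb-inxe.1:{_BLEN},Hc_hc-inxe.1:{_BLEN}):{_BLEN},"
            f"(Pb_pb-inxe.2:{_BLEN},Hc_hc-inxe.2:{_BLEN}):{_BLEN})"
        )

    def leaf_group(species: str) -> str:
        n = copies[species]
        multi = n > 1
        tips = [
            f"{_tip(species, family, k + 1, multi)}:{_BLEN}" for k in range(n)
        ]
        if n == 1:
            return tips[0]
        return "(" + ",".join(tips) + f"):{_BLEN}"

    groups = {sp: leaf_group(sp) for sp in copies}
    # assemble following ((Bo,Ml),(Pb,Hc)), dropping absent species
    left = [groups[sp] for sp in ("Bo", "Ml") if sp in groups]
    right = [groups[sp] for sp in ("Pb", "Hc") if sp in groups]

    def join(parts: list[str]) -> str | None:
        if not parts:
            return None
        if len(parts) == 1:
            return parts[0]
        return "(" + ",".join(parts) + f"):{_BLEN}"

    sides = [s for s in (join(left), join(right)) if s is not None]
    if len(sides) == 1:
        inner = sides[0]
        return inner if inner.startswith("(") else f"({inner})"
    return "(" + ",".join(sides) + ")"


def paper_family_map() -> dict[str, str]:
    """gene id -> family name for every tip of the fixture gene tree."""
    mapping: dict[str, str] = {}
    for family, copies in PAPER_FAMILY_COPIES.items():
        for species, n in copies.items():
            multi = n > 1
            for k in range(n):
                label = _tip(species, family, k + 1, multi)
                mapping[label.split("_", 1)[1]] = family
    return mapping


def paper_gene_tree() -> dendropy.Tree:
    """Fixture gene tree: a ladder of the 17 family clades."""
    clades = [
        _family_clade(f, c) for f, c in sorted(PAPER_FAMILY_COPIES.items())
    ]
    newick = clades[0]
    for clade in clades[1:]:
        newick = f"({newick}:{_BLEN},{clade}:{_BLEN})"
    return read_newick(newick + ";")


def paper_species_tree() -> SpeciesTree:
    return SpeciesTree.default()


def paper_fixture() -> tuple[dendropy.Tree, dict[str, str], SpeciesTree]:
    """(gene tree, gene->family map, species tree) for the published data."""
    return paper_gene_tree(), paper_family_map(), paper_species_tree()
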