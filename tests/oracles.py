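"""Independent brute-force oracles used to check the analysis modules.

These deliberately use naive enumeration rather than the package's own
algorithms, so agreement is informative.
"""

from __future__ import annotations

import random

import numpy as np


def dollo_min_losses(sp, presence: set[str]) -> int:
    """Exhaustive minimum loss count under a single gain.

    Tries every candidate gain node whose clade covers the presence set;
    given a gain, the forced losses are the maximal subtrees containing
    no present species.
    """
    best = None
    for node in sp.preorder_nodes():
        below = sp.leaves_below(node)
        if not presence <= below:
            continue
        losses = 0
        stack = [node]
        while stack:
            n = stack.pop()
            for child in n.child_nodes():
                if sp.leaves_below(child) & presence:
                    stack.append(child)
                else:
                    losses += 1
        best = losses if best is None else min(best, losses)
    return best


def random_species_newick(codes: list[str], rng: random.Random) -> str:
    """Random rooted binary topology over the given species codes."""
    parts = [f"{c}:1.0" for c in codes]
    while len(parts) > 1:
        i, j = rng.sample(range(len(parts)), 2)
        a, b = parts[i], parts[j]
        parts = [p for k, p in enumerate(parts) if k not in (i, j)]
        parts.append(f"({a},{b}):1.0")
    return parts[0] + ";"


def chain_clusters(loci, targets: set[str], max_gap: int) -> list[frozenset]:
    """Union-find over sorted target loci; components are the clusters."""
    out = []
    for seqid, group in loci.groupby("seqid"):
        members = (
            group[group["family"].isin(targets)]
            .sort_values(["start", "end"])
            .reset_index(drop=True)
        )
        comp: list[list[str]] = []
        for k in range(len(members)):
            if (
                k > 0
                and members.loc[k, "start"] - members.loc[k - 1, "end"]
                <= max_gap
            ):
                comp[-1].append(members.loc[k, "gene"])
            else:
                comp.append([members.loc[k, "gene"]])
        out.extend(frozenset(c) for c in comp)
    return out


def all_interval_blocks(
    genome_a, genome_b, orthologs, min_len: int
) -> set[frozenset]:
    """All maximal valid interval pairs by O(n^2) enumeration."""

    def ranked(df):
        df = df.sort_values(["seqid", "start", "end"]).reset_index(drop=True)
        df["rank"] = df.groupby("seqid").cumcount()
        return df

    a = ranked(genome_a)
    b = ranked(genome_b)
    cols = list(orthologs.columns[:2])
    a2b = dict(zip(orthologs[cols[0]], orthologs[cols[1]]))
    bpos = {r.gene: (r.seqid, r.rank) for r in b.itertuples(index=False)}
    valid = []
    for seqid, group in a.groupby("seqid"):
        genes = group.sort_values("rank")["gene"].tolist()
        n = len(genes)
        for i in range(n):
            for j in range(i + max(min_len, 2) - 1, n):
                window = genes[i : j + 1]
                images = [a2b.get(g) for g in window]
                if any(im is None or im not in bpos for im in images):
                    continue
                seqs = {bpos[im][0] for im in images}
                if len(seqs) != 1:
                    continue
                ranks = sorted(bpos[im][1] for im in images)
                if ranks == list(range(ranks[0], ranks[0] + len(ranks))):
                    valid.append((seqid, i, j, frozenset(zip(window, images))))
    maximal = set()
    for seqid, i, j, pairs in valid:
        if not any(
            s == seqid and ii <= i and jj >= j and (ii, jj) != (i, j)
            for s, ii, jj, _ in valid
        ):
            maximal.add(pairs)
    return maximal


def pair_percent(mask_df, a: str, b: str) -> float | None:
    """Set-arithmetic coexpression percentage."""
    cells_a = set(mask_df.columns[mask_df.loc[a]])
    cells_b = set(mask_df.columns[mask_df.loc[b]])
    denom = min(len(cells_a), len(cells_b))
    if denom == 0:
        return None
    return 100.0 * len(cells_a & cells_b) / denom


def histogram_fractions(mask_df, targets) -> tuple[float, float, float, float]:
    per_cell = np.asarray(mask_df.loc[list(targets)].sum(axis=0))
    n = per_cell.size
    return (
        float((per_cell == 0).sum()) / n,
        float((per_cell == 1).sum()) / n,
        float((per_cell == 2).sum()) / n,
        float((per_cell >= 3).sum()) / n,
    )
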