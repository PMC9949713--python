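"""Tandem family clusters and cross-genome microsynteny blocks.

Clustering chains target-family loci along a scaffold when the distance
from one gene's end to the next gene's start is at most ``max_gap``
(40 kb by default, the working threshold for the innexin cluster).
Microsynteny blocks are maximal sets of one-to-one orthologs occupying
consecutive gene ranks in both genomes, irrespective of gene order and
strand within the block.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
import pyranges as pr

LOCUS_COLUMNS = ["gene", "seqid", "start", "end", "strand", "family"]


@dataclass
class FamilyCluster:
    """A maximal chain of target-family loci on one scaffold."""

    seqid: str
    genes: tuple[str, ...]
    families: tuple[str, ...]
    span: int                       # bp, min start to max end
    gap_intervening: tuple[int, ...]  # non-target genes per inter-member gap

    @property
    def n_members(self) -> int:
        return len(self.genes)

    @property
    def total_intervening(self) -> int:
        return sum(self.gap_intervening)


@dataclass
class MicrosyntenyBlock:
    """Ortholog pairs contiguous (by gene rank) in both genomes."""

    pairs: tuple[tuple[str, str], ...]
    seqid_a: str
    seqid_b: str

    @property
    def length(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# input


def read_loci_gff3(path: str, family_attribute: str = "family") -> pd.DataFrame:
    """Load gene features from GFF3 into the internal locus table.

    Coordinates come back 0-based half-open. The family label is read
    from the named attribute when present, else "other".
    """
    df = pr.read_gff3(path).df
    df = df[df["Feature"] == "gene"].copy()
    fam = (
        df[family_attribute]
        if family_attribute in df.columns
        else pd.Series("other", index=df.index)
    )
    out = pd.DataFrame(
        {
            "gene": df["ID"].astype(str),
            "seqid": df["Chromosome"].astype(str),
            "start": df["Start"].astype(int),
            "end": df["End"].astype(int),
            "strand": df.get("Strand", pd.Series(".", index=df.index)),
            "family": fam.fillna("other").astype(str),
        }
    )
    return out.reset_index(drop=True)


def read_loci_bed(path: str) -> pd.DataFrame:
    """Load BED6 (name column = gene id; family defaults to 'other')."""
    df = pr.read_bed(path).df
    out = pd.DataFrame(
        {
            "gene": df["Name"].astype(str),
            "seqid": df["Chromosome"].astype(str),
            "start": df["Start"].astype(int),
            "end": df["End"].astype(int),
            "strand": df.get("Strand", pd.Series(".", index=df.index)),
            "family": "other",
        }
    )
    return out.reset_index(drop=True)


def _check_loci(loci: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in LOCUS_COLUMNS if c not in loci.columns]
    if missing:
        raise ValueError(f"locus table lacks columns: {missing}")
    if (loci["start"] >= loci["end"]).any():
        bad = loci.loc[loci["start"] >= loci["end"], "gene"].tolist()
        raise ValueError(f"loci with start >= end: {bad}")
    return loci


# ---------------------------------------------------------------------------
# tandem clusters


def find_family_clusters(
    loci: pd.DataFrame,
    target_families: Iterable[str],
    max_gap: int = 40_000,
) -> list[FamilyCluster]:
    """Chain target-family loci whose boundary-to-boundary gap <= max_gap.

    Every target locus lands in exactly one (possibly singleton) cluster.
    Intervening counts are the non-target genes lying wholly inside each
    inter-member gap.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    loci = _check_loci(loci)
    targets = set(target_families)
    clusters: list[FamilyCluster] = []
    for seqid, group in loci.groupby("seqid", sort=True):
        group = group.sort_values(["start", "end"]).reset_index(drop=True)
        members = group[group["family"].isin(targets)]
        others = group[~group["family"].isin(targets)]
        chain: list[pd.Series] = []

        def flush(chain: list[pd.Series]):
            if not chain:
                return
            gaps = []
            for prev, nxt in zip(chain, chain[1:]):
                inside = others[
                    (others["start"] >= prev["end"])
                    & (others["end"] <= nxt["start"])
                ]
                gaps.append(int(len(inside)))
            clusters.append(
                FamilyCluster(
                    seqid=str(seqid),
                    genes=tuple(m["gene"] for m in chain),
                    families=tuple(m["family"] for m in chain),
                    span=int(
                        max(m["end"] for m in chain)
                        - min(m["start"] for m in chain)
                    ),
                    gap_intervening=tuple(gaps),
                )
            )

        for _, row in members.iterrows():
            if chain and row["start"] - chain[-1]["end"] > max_gap:
                flush(chain)
                chain = []
            chain.append(row)
        flush(chain)
    return clusters


# ---------------------------------------------------------------------------
# microsynteny


def _ranks(loci: pd.DataFrame) -> pd.DataFrame:
    loci = _check_loci(loci).sort_values(["seqid", "start", "end"])
    loci = loci.reset_index(drop=True)
    loci["rank"] = loci.groupby("seqid").cumcount()
    return loci


def microsynteny_blocks(
    genome_a: pd.DataFrame,
    genome_b: pd.DataFrame,
    orthologs: pd.DataFrame,
    min_len: int = 2,
) -> list[MicrosyntenyBlock]:
    """Maximal order-free contiguous ortholog runs shared by two genomes.

    An interval of consecutive genes in A forms a block when every gene in
    it has an ortholog, all orthologs sit on one B scaffold, and their B
    ranks form a contiguous interval of the same size. Blocks shorter
    than ``min_len`` are dropped; non-maximal intervals are absorbed.
    """
    cols = list(orthologs.columns[:2])
    pairs = orthologs.rename(columns={cols[0]: "gene_a", cols[1]: "gene_b"})
    dup_a = pairs["gene_a"][pairs["gene_a"].duplicated()].unique()
    dup_b = pairs["gene_b"][pairs["gene_b"].duplicated()].unique()
    if len(dup_a) or len(dup_b):
        raise ValueError(
            "ortholog map is not one-to-one; offending genes: "
            f"{sorted(dup_a.tolist() + dup_b.tolist())}"
        )
    a = _ranks(genome_a)
    b = _ranks(genome_b)
    b_pos = {
        row.gene: (row.seqid, row.rank)
        for row in b.itertuples(index=False)
    }
    a_to_b = dict(zip(pairs["gene_a"], pairs["gene_b"]))

    candidates: list[tuple[str, int, int, list[tuple[str, str]], str]] = []
    for seqid, group in a.groupby("seqid", sort=True):
        genes = group.sort_values("rank")["gene"].tolist()
        n = len(genes)
        for i in range(n):
            gb = a_to_b.get(genes[i])
            if gb is None or gb not in b_pos:
                continue
            b_seq, r = b_pos[gb]
            lo = hi = r
            block = [(genes[i], gb)]
            for j in range(i + 1, n):
                gb = a_to_b.get(genes[j])
                if gb is None or gb not in b_pos or b_pos[gb][0] != b_seq:
                    break
                r = b_pos[gb][1]
                lo, hi = min(lo, r), max(hi, r)
                block = block + [(genes[j], gb)]
                if hi - lo == len(block) - 1:
                    candidates.append((seqid, i, j, list(block), b_seq))
    # keep maximal intervals only
    valid = {(c[0], c[1], c[2]) for c in candidates}
    blocks = []
    for seqid, i, j, block, b_seq in candidates:
        if len(block) < max(min_len, 2):
            continue
        if (seqid, i - 1, j) in valid or (seqid, i, j + 1) in valid:
            continue
        contained = any(
            (s, ii, jj) in valid
            for (s, ii, jj) in valid
            if s == seqid and ii <= i and jj >= j and (ii, jj) != (i, j)
        )
        if contained:
            continue
        blocks.append(
            MicrosyntenyBlock(pairs=tuple(block), seqid_a=seqid, seqid_b=b_seq)
        )
    return blocks


# ---------------------------------------------------------------------------
# tabular output


def clusters_to_frame(clusters: Sequence[FamilyCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "seqid": c.seqid,
                "n_members": c.n_members,
                "genes": ",".join(c.genes),
                "families": ",".join(c.families),
                "span_bp": c.span,
                "intervening_per_gap": ",".join(map(str, c.gap_intervening)),
                "total_intervening": c.total_intervening,
            }
            for c in clusters
        ]
    )


def blocks_to_frame(blocks: Sequence[MicrosyntenyBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "seqid_a": blk.seqid_a,
                "seqid_b": blk.seqid_b,
                "length": blk.length,
                "pairs": ";".join(f"{a}|{b}" for a, b in blk.pairs),
            }
            for blk in blocks
        ]
    )
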