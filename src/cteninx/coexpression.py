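"""Single-cell UMI coexpression statistics and bulk expression ratios.

A gene is "expressed" in a cell when its raw UMI count reaches a
threshold (1 by default; no normalization is applied). On the binarized
matrix the module computes per-cell target-gene histograms, metacell
marker calls (a gene expressed in at least half of a metacell's cells),
and pairwise coexpression percentages, where a pair's percentage is the
number of doubly-positive cells divided by the smaller of the two
single-gene positive-cell counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation


@dataclass
class ExpressionMask:
    """Boolean genes x cells matrix plus the UMI threshold that made it."""

    mask: pd.DataFrame
    min_umi: int


@dataclass
class CellInnexinHistogram:
    """Fractions of cells expressing 0 / 1 / 2 / >=3 target genes."""

    fractions: tuple[float, float, float, float]
    max_per_cell: int
    bucket_labels: tuple[str, str, str, str]


@dataclass
class CoexpressionMatrix:
    n_expressing: pd.Series          # gene -> number of positive cells
    n_both: pd.DataFrame             # gene x gene doubly-positive counts
    percent: pd.DataFrame            # 100 * n_both / min(n_A, n_B); NaN if min 0


def binarize(umi: pd.DataFrame, min_umi: int = 1) -> ExpressionMask:
    """Threshold raw UMI counts into an expressed/not-expressed mask."""
    if min_umi < 1:
        raise ValueError("min_umi must be >= 1")
    values = umi.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.allclose(values, np.round(values)):
            raise ValueError("UMI matrix must contain integer counts")
        values = np.round(values).astype(np.int64)
    if (values < 0).any():
        raise ValueError("UMI matrix must be non-negative")
    mask = pd.DataFrame(values >= min_umi, index=umi.index, columns=umi.columns)
    return ExpressionMask(mask=mask, min_umi=min_umi)


def innexin_count_histogram(
    mask: ExpressionMask,
    targets: Iterable[str],
    top_bucket: str = "ge3",
) -> CellInnexinHistogram:
    """Bucket cells by how many target genes they express.

    ``top_bucket='ge3'`` (default) buckets per-cell counts as
    0 / 1 / 2 / >=3; ``'gt3'`` as 0 / 1 / 2-3 / >3. Either way the four
    fractions sum to one.
    """
    targets = list(targets)
    if not targets:
        raise ValueError("target gene set is empty")
    missing = set(targets) - set(mask.mask.index)
    if missing:
        raise ValueError(f"target genes absent from matrix: {sorted(missing)}")
    per_cell = mask.mask.loc[targets].sum(axis=0).to_numpy()
    n = per_cell.size
    if top_bucket == "ge3":
        edges = [
            (per_cell == 0),
            (per_cell == 1),
            (per_cell == 2),
            (per_cell >= 3),
        ]
        labels = ("0", "1", "2", ">=3")
    elif top_bucket == "gt3":
        edges = [
            (per_cell == 0),
            (per_cell == 1),
            (per_cell == 2) | (per_cell == 3),
            (per_cell > 3),
        ]
        labels = ("0", "1", "2-3", ">3")
    else:
        raise ValueError("top_bucket must be 'ge3' or 'gt3'")
    fracs = tuple(float(e.sum()) / n for e in edges)
    return CellInnexinHistogram(
        fractions=fracs,
        max_per_cell=int(per_cell.max(initial=0)),
        bucket_labels=labels,
    )


def metacell_markers(
    mask: ExpressionMask,
    metacells: Mapping[str, str],
    min_fraction: float = 0.5,
) -> pd.DataFrame:
    """Call marker genes per metacell by expressing-cell fraction.

    A gene is a marker when it is expressed in at least ``min_fraction``
    of the metacell's cells (boundary inclusive). Returns a long table
    (gene, metacell, n_cells, n_expressing, fraction, is_marker).
    """
    unknown = set(metacells) - set(mask.mask.columns)
    if unknown:
        raise ValueError(f"metacell map names unknown cells: {sorted(unknown)}")
    groups: dict[str, list[str]] = {}
    for cell, mc in metacells.items():
        groups.setdefault(str(mc), []).append(cell)
    rows = []
    for mc in sorted(groups):
        cells = groups[mc]
        if not cells:
            warnings.warn(f"metacell {mc} has no cells; skipped")
            continue
        sub = mask.mask[cells]
        n_expr = sub.sum(axis=1)
        frac = n_expr / len(cells)
        for gene in mask.mask.index:
            rows.append(
                {
                    "gene": gene,
                    "metacell": mc,
                    "n_cells": len(cells),
                    "n_expressing": int(n_expr[gene]),
                    "fraction": float(frac[gene]),
                    "is_marker": bool(frac[gene] >= min_fraction),
                }
            )
    return pd.DataFrame(rows)


def pairwise_coexpression(
    mask: ExpressionMask, targets: Iterable[str]
) -> CoexpressionMatrix:
    """Doubly-positive cell counts and min-denominator percentages.

    percent[A, B] = 100 * |cells(A) & cells(B)| / min(|cells(A)|, |cells(B)|),
    undefined (NaN) when either gene is expressed in no cell.
    """
    targets = list(targets)
    if not targets:
        raise ValueError("target gene set is empty")
    m = mask.mask.loc[targets].to_numpy().astype(np.int64)
    both = m @ m.T
    n = np.diag(both).copy()
    denom = np.minimum.outer(n, n).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(denom > 0, 100.0 * both / denom, np.nan)
    idx = pd.Index(targets, name="gene")
    return CoexpressionMatrix(
        n_expressing=pd.Series(n, index=idx),
        n_both=pd.DataFrame(both, index=idx, columns=idx),
        percent=pd.DataFrame(pct, index=idx, columns=idx),
    )


def coexpression_pairs(
    cm: CoexpressionMatrix, threshold: float = 50.0
) -> pd.DataFrame:
    """Unordered gene pairs whose coexpression percentage reaches threshold."""
    rows = []
    genes = list(cm.percent.index)
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            pct = cm.percent.loc[a, b]
            if np.isfinite(pct) and pct >= threshold:
                rows.append(
                    {
                        "gene_a": a,
                        "gene_b": b,
                        "n_a": int(cm.n_expressing[a]),
                        "n_b": int(cm.n_expressing[b]),
                        "n_both": int(cm.n_both.loc[a, b]),
                        "percent": round(float(pct), 1),
                    }
                )
    return pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "n_a", "n_b", "n_both", "percent"]
    )


def expression_ratio(
    tpm: pd.DataFrame, gene_a: str, gene_b: str
) -> tuple[pd.Series, float, float]:
    """Per-sample expression ratio A/B with median and MAD summary.

    Samples where B is zero are dropped; B all-zero is an error. Used for
    the characteristic ~2:1 INXB:INXD bulk-expression ratio.
    """
    for g in (gene_a, gene_b):
        if g not in tpm.index:
            raise KeyError(f"gene {g!r} absent from expression table")
    b = tpm.loc[gene_b]
    if (b <= 0).all():
        raise ValueError(f"gene {gene_b!r} is zero in every sample")
    keep = b > 0
    ratios = tpm.loc[gene_a][keep] / b[keep]
    med = float(np.median(ratios))
    mad = float(median_abs_deviation(ratios))
    return ratios, med, mad
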