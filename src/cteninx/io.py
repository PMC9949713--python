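"""Readers and writers for the plain-text interchange formats.

Trees travel as Newick, tabular data as TSV, UMI matrices as MTX
triplets (matrix.mtx + genes.tsv + barcodes.tsv) or dense TSV, sweep
traces as two-column text with a JSON sidecar per sweep.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from .simulate import Sweep, SweepSet


# ---------------------------------------------------------------------------
# phylogenetics tables


def read_family_map_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene", "family"} <= set(df.columns):
        raise ValueError("family map needs columns: gene, family")
    return dict(zip(df["gene"], df["family"]))


def write_family_map_tsv(fam: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(fam.items()), columns=["gene", "family"]
    ).to_csv(path, sep="\t", index=False)


def read_tip_sidecar_tsv(path: str | Path) -> dict[str, str]:
    """tip -> species map from a (tip, species, gene) table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"tip", "species"} <= set(df.columns):
        raise ValueError("sidecar needs columns: tip, species[, gene]")
    return dict(zip(df["tip"], df["species"]))


# ---------------------------------------------------------------------------
# loci / orthologs


def write_loci_gff3(loci: pd.DataFrame, path: str | Path) -> None:
    """Write the internal 0-based locus table as 1-based GFF3 gene rows."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in loci.itertuples(index=False):
            attrs = f"ID={row.gene};family={row.family}"
            fh.write(
                f"{row.seqid}\tcteninx\tgene\t{row.start + 1}\t{row.end}\t."
                f"\t{row.strand}\t.\t{attrs}\n"
            )


def read_orthologs_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("ortholog map needs two gene columns")
    return df


# ---------------------------------------------------------------------------
# UMI matrices


def read_umi(path: str | Path) -> pd.DataFrame:
    """Genes x cells integer counts from MTX triplet dir or dense TSV."""
    path = Path(path)
    if path.is_dir():
        mat = scipy_io.mmread(path / "matrix.mtx")
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0]
        cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0]
        return pd.DataFrame(
            np.asarray(mat.todense(), dtype=np.int64),
            index=genes.astype(str),
            columns=cells.astype(str),
        )
    return pd.read_csv(path, sep="\t", index_col=0).astype(np.int64)


def write_umi_mtx(umi: pd.DataFrame, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy_io.mmwrite(
        outdir / "matrix.mtx", sparse.coo_matrix(umi.to_numpy())
    )
    pd.Series(umi.index).to_csv(
        outdir / "genes.tsv", sep="\t", index=False, header=False
    )
    pd.Series(umi.columns).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )


def read_metacells_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"cell", "metacell"} <= set(df.columns):
        raise ValueError("metacell map needs columns: cell, metacell")
    return dict(zip(df["cell"], df["metacell"]))


def write_metacells_tsv(metacells: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(metacells.items()), columns=["cell", "metacell"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sweep traces


def write_sweeps(sweeps: SweepSet, outdir: str | Path) -> None:
    """One two-column text file (time ms, current pA) + JSON sidecar each."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for k, sw in enumerate(sweeps.sweeps):
        stem = outdir / f"sweep_{k:03d}"
        t = np.arange(sw.current_pa.size) / sw.sampling_khz
        np.savetxt(
            f"{stem}.txt",
            np.column_stack([t, sw.current_pa]),
            fmt="%.6f",
            header="time_ms\tcurrent_pa",
        )
        with open(f"{stem}.json", "w") as fh:
            json.dump(
                {
                    "voltage_mv": sw.voltage_mv,
                    "sampling_khz": sw.sampling_khz,
                    "filter_khz": sw.filter_khz,
                },
                fh,
            )
    with open(outdir / "metadata.json", "w") as fh:
        json.dump(sweeps.metadata, fh)


def read_sweeps(indir: str | Path) -> SweepSet:
    indir = Path(indir)
    sweeps = []
    for txt in sorted(indir.glob("sweep_*.txt")):
        sidecar = txt.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"missing sidecar for {txt.name}")
        with open(sidecar) as fh:
            meta = json.load(fh)
        data = np.loadtxt(txt)
        sweeps.append(
            Sweep(
                voltage_mv=float(meta["voltage_mv"]),
                current_pa=data[:, 1],
                sampling_khz=float(meta["sampling_khz"]),
                filter_khz=float(meta["filter_khz"]),
                n_open=np.array([], dtype=np.int16),
                dwells=[],
            )
        )
    metadata = {}
    meta_path = indir / "metadata.json"
    if meta_path.exists():
        with open(meta_path) as fh:
            metadata = json.load(fh)
    return SweepSet(sweeps=sweeps, metadata=metadata)
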