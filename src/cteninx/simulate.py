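"""Reproducible synthetic inputs for every analysis stage.

Each generator is a pure function of its parameter bundle (which carries
the seed) and returns machine-readable ground truth alongside the data,
so the corresponding analysis module can be scored without re-deriving
anything. A single global seed fans out to four independent streams
(families=1, genomes=2, umi=3, traces=4) via ``numpy`` seed sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .ephys import VoltageProtocol
from .phylo_events import DUPLICATION, GAIN, LOSS, Event
from .trees import SpeciesTree, read_newick

STREAMS = {"families": 1, "genomes": 2, "umi": 3, "traces": 4}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for one named stream of a global seed."""
    return np.random.default_rng(np.random.SeedSequence((seed, STREAMS[stream])))


# ===========================================================================
# family evolution


@dataclass
class FamilySimParams:
    n_families: int = 200
    p_loss: float = 0.15
    p_dup: float = 0.10
    seed: int = 0
    species_newick: str | None = None   # None -> default four-species tree

    def __post_init__(self):
        if not (0 <= self.p_loss <= 1 and 0 <= self.p_dup <= 1):
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SimulatedFamilies:
    gene_tree: object               # dendropy.Tree
    family_map: dict[str, str]      # gene id -> family
    species_tree: SpeciesTree
    events: list[Event]             # Dollo-canonical ground-truth log
    raw_events: list[Event]         # per-branch draws before canonicalization
    n_regenerated: int = 0


class _Clade:
    """Lightweight nested structure used to assemble family gene trees."""

    __slots__ = ("children", "species")

    def __init__(self, species=None, children=None):
        self.species = species
        self.children = children or []

    def copy(self):
        if self.species is not None:
            return _Clade(species=self.species)
        return _Clade(children=[c.copy() for c in self.children])

    def tips(self):
        if self.species is not None:
            yield self
        else:
            for c in self.children:
                yield from c.tips()


def _clade_newick(clade: _Clade, labeller) -> str:
    if clade.species is not None:
        return f"{labeller(clade.species)}:0.1"
    inner = ",".join(_clade_newick(c, labeller) for c in clade.children)
    return f"({inner}):0.1"


def simulate_family_evolution(p: FamilySimParams) -> SimulatedFamilies:
    """Gain-at-root histories with per-branch loss and duplication draws.

    Every family is gained on the stem; on each branch below it the
    family is lost with ``p_loss`` (pruning the whole clade, so regain is
    impossible) or duplicated with ``p_dup``. Families lost everywhere
    are redrawn (counted in ``n_regenerated``). The returned event log is
    Dollo-canonical: the gain is re-placed at the MRCA of surviving
    species, losses are reported as the maximal extinct clades below it,
    and each duplication is re-placed at the MRCA of its surviving
    descendant species (dropped when none survive), since only this form
    is identifiable from the tip data.
    """
    sp = (
        SpeciesTree.from_newick(p.species_newick)
        if p.species_newick
        else SpeciesTree.default()
    )
    rng = stream_rng(p.seed, "families")
    events: list[Event] = []
    raw_events: list[Event] = []
    family_map: dict[str, str] = {}
    clades: list[_Clade] = []
    n_regen = 0

    fam_idx = 0
    while fam_idx < p.n_families:
        family = f"FAM{fam_idx:04d}"
        alive: dict = {sp.root: True}
        dup_branches = []
        raw: list[Event] = [Event(family, GAIN, "stem")]
        for node in sp.preorder_nodes():
            if node is sp.root:
                continue
            parent = sp.parent(node)
            if not alive[parent]:
                alive[node] = False
                continue
            if rng.random() < p.p_loss:
                alive[node] = False
                raw.append(Event(family, LOSS, sp.branch_label(node)))
                continue
            alive[node] = True
            if rng.random() < p.p_dup:
                dup_branches.append(node)
                raw.append(Event(family, DUPLICATION, sp.branch_label(node)))

        surviving = {
            lf.taxon.label for lf in sp.leaf_nodes() if alive[lf]
        }
        if not surviving:
            n_regen += 1
            continue
        raw_events.extend(raw)

        # canonical gain + losses from the alive flags
        gain_node = sp.mrca(surviving)
        events.append(Event(family, GAIN, sp.branch_label(gain_node)))

        def dead_below(node):
            return not (sp.leaves_below(node) & surviving)

        stack = [gain_node]
        while stack:
            node = stack.pop()
            for child in node.child_nodes():
                if dead_below(child):
                    events.append(
                        Event(family, LOSS, sp.branch_label(child))
                    )
                else:
                    stack.append(child)

        # canonical duplications
        surviving_dups = []
        for b in dup_branches:
            below = sp.leaves_below(b) & surviving
            if below:
                events.append(
                    Event(family, DUPLICATION, sp.branch_label(sp.mrca(below)))
                )
                surviving_dups.append(b)

        # build the family clade mirroring the surviving topology + dups;
        # the copy created by a duplication is a plain single-copy lineage
        def plain(node) -> _Clade | None:
            if not alive[node] or dead_below(node):
                return None
            if node.is_leaf():
                return _Clade(species=node.taxon.label)
            kids = [plain(c) for c in node.child_nodes()]
            kids = [k for k in kids if k is not None]
            return kids[0] if len(kids) == 1 else _Clade(children=kids)

        def build(node) -> _Clade | None:
            if not alive[node] or dead_below(node):
                return None
            if node.is_leaf():
                sub = _Clade(species=node.taxon.label)
            else:
                kids = [build(c) for c in node.child_nodes()]
                kids = [k for k in kids if k is not None]
                sub = kids[0] if len(kids) == 1 else _Clade(children=kids)
            if node in surviving_dups:
                sub = _Clade(children=[sub, plain(node)])
            return sub

        clade = build(gain_node)
        # duplications on branches above the surviving MRCA double the
        # whole surviving clade
        ancestors = set(sp.ancestors(gain_node)) - {gain_node}
        for b in surviving_dups:
            if b in ancestors:
                clade = _Clade(children=[clade, plain(gain_node)])
        counter: dict[str, int] = {}

        def labeller(species: str, family=family, counter=counter) -> str:
            counter[species] = counter.get(species, 0) + 1
            gene = f"{species.lower()}-{family.lower()}.{counter[species]}"
            family_map[gene] = family
            return f"{species}_{gene}"

        clades.append(_clade_newick(clade, labeller))
        fam_idx += 1

    parts = clades
    newick = parts[0]
    for part in parts[1:]:
        newick = f"({newick}:0.1,{part}:0.1)"
    if len(parts) == 1 and not newick.startswith("("):
        newick = f"({newick})"
    gene_tree = read_newick(newick + ";")
    return SimulatedFamilies(
        gene_tree=gene_tree,
        family_map=family_map,
        species_tree=sp,
        events=events,
        raw_events=raw_events,
        n_regenerated=n_regen,
    )


# ===========================================================================
# genome order


@dataclass
class ClusterSpec:
    families: tuple[str, ...]
    intra_gap_bp: int = 5_000
    intervening: tuple[int, ...] = ()   # per inter-member gap; default zeros

    def gaps(self) -> tuple[int, ...]:
        n = len(self.families) - 1
        if self.intervening and len(self.intervening) != n:
            raise ValueError("need one intervening count per gap")
        return self.intervening or (0,) * n


@dataclass
class ClusterSimParams:
    clusters: tuple[ClusterSpec, ...] = (
        ClusterSpec(families=("INXA", "INXB", "INXC", "INXD"),
                    intervening=(3, 0, 0)),
    )
    n_background: int = 30
    background_spacing_bp: tuple[int, int] = (60_000, 120_000)
    gene_length_bp: tuple[int, int] = (1_000, 3_000)
    recoverable: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.recoverable:
            for c in self.clusters:
                if c.intra_gap_bp >= self.background_spacing_bp[0]:
                    raise ValueError(
                        "infeasible spacing: intra-cluster gap must be below "
                        "the minimum background spacing for recoverable layouts"
                    )


@dataclass
class SimulatedGenomes:
    genome_a: pd.DataFrame
    genome_b: pd.DataFrame
    orthologs: pd.DataFrame
    true_clusters: list[dict]
    true_blocks: list[list[tuple[str, str]]]


def simulate_genome_order(p: ClusterSimParams) -> SimulatedGenomes:
    """Plant tandem clusters in genome A and conserved blocks in genome B.

    Genome A lays background genes far apart (beyond any clustering
    threshold) and inserts each planted cluster as a run of family genes
    with small internal gaps, optionally with "other" genes inside the
    gaps. Genome B contains a renamed ortholog of every A gene; planted
    cluster genes stay contiguous while every other gene is separated by
    private B-only genes, so the planted blocks are the only
    microsynteny present.
    """
    rng = stream_rng(p.seed, "genomes")
    rows_a = []
    pos = 10_000
    gid = 0

    def glen():
        return int(rng.integers(*p.gene_length_bp))

    # background genes, with cluster insertion points among them
    insert_at = sorted(
        rng.choice(max(p.n_background, 1), size=len(p.clusters), replace=False)
    )
    true_clusters = []
    cluster_iter = iter(zip(insert_at, p.clusters))
    next_ins = next(cluster_iter, None)
    for k in range(p.n_background):
        if next_ins is not None and k == next_ins[0]:
            spec = next_ins[1]
            members = []
            run = []                 # every gene in the contiguous run
            for idx, famname in enumerate(spec.families):
                length = glen()
                gene = f"gA{gid:04d}"
                gid += 1
                rows_a.append((gene, "scafA1", pos, pos + length, "+", famname))
                members.append(gene)
                run.append(gene)
                pos += length
                if idx < len(spec.families) - 1:
                    n_mid = spec.gaps()[idx]
                    gap = spec.intra_gap_bp
                    if n_mid:
                        slot = gap // (n_mid + 1)
                        cursor = pos
                        for _ in range(n_mid):
                            cursor += max(slot // 4, 50)
                            mid_len = min(max(slot // 2, 100), slot - 100)
                            gene_m = f"gA{gid:04d}"
                            gid += 1
                            rows_a.append(
                                (gene_m, "scafA1", cursor,
                                 cursor + mid_len, "+", "other")
                            )
                            run.append(gene_m)
                            cursor += mid_len
                    pos += gap
            true_clusters.append(
                {"genes": tuple(members), "families": spec.families,
                 "block_genes": tuple(run)}
            )
            pos += int(rng.integers(*p.background_spacing_bp))
            next_ins = next(cluster_iter, None)
        length = glen()
        gene = f"gA{gid:04d}"
        gid += 1
        rows_a.append((gene, "scafA1", pos, pos + length, "+", "other"))
        pos += length + int(rng.integers(*p.background_spacing_bp))

    genome_a = pd.DataFrame(
        rows_a, columns=["gene", "seqid", "start", "end", "strand", "family"]
    )

    # genome B: units = planted blocks (contiguous) + all remaining genes,
    # shuffled, with private spacer genes between units
    block_sets = [set(c["block_genes"]) for c in true_clusters]
    in_block = set().union(*block_sets) if block_sets else set()
    units: list[list[str]] = [list(c["block_genes"]) for c in true_clusters]
    units += [[g] for g in genome_a["gene"] if g not in in_block]
    order = rng.permutation(len(units))
    rows_b = []
    ortho = []
    posb = 5_000
    spacer = 0
    for ui in order:
        for gene_a in units[ui]:
            gene_b = gene_a.replace("gA", "gB")
            length = glen()
            rows_b.append((gene_b, "scafB1", posb, posb + length, "+",
                           genome_a.loc[genome_a["gene"] == gene_a,
                                        "family"].iloc[0]))
            ortho.append((gene_a, gene_b))
            posb += length + 8_000
        gene_s = f"gBspacer{spacer:04d}"
        spacer += 1
        length = glen()
        rows_b.append((gene_s, "scafB1", posb, posb + length, "+", "other"))
        posb += length + 8_000
    genome_b = pd.DataFrame(
        rows_b, columns=["gene", "seqid", "start", "end", "strand", "family"]
    )
    orthologs = pd.DataFrame(ortho, columns=["gene_a", "gene_b"])
    true_blocks = [
        [(g, g.replace("gA", "gB")) for g in c["block_genes"]]
        for c in true_clusters
    ]
    return SimulatedGenomes(
        genome_a=genome_a,
        genome_b=genome_b,
        orthologs=orthologs,
        true_clusters=true_clusters,
        true_blocks=true_blocks,
    )


# ===========================================================================
# UMI matrices


@dataclass
class PlantedPair:
    gene_a: str
    gene_b: str
    fraction: float = 0.3           # shared-program on fraction of cells

    def __post_init__(self):
        if not 0 <= self.fraction <= 1:
            raise ValueError("program fraction must lie in [0, 1]")


@dataclass
class UMISimParams:
    n_genes: int = 20
    metacell_sizes: tuple[int, ...] = (200, 200, 200, 200, 200)
    base_expr_prob: float = 0.15
    program_expr_prob: float = 0.8  # per-metacell program genes
    n_program_genes: int = 4
    mean_depth: float = 3.0
    dispersion: float = 1.5         # NB size parameter; lower = noisier
    planted_pairs: tuple[PlantedPair, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.mean_depth <= 0:
            raise ValueError("mean depth must be positive")
        if not 0 <= self.base_expr_prob <= 1:
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SimulatedUMI:
    umi: pd.DataFrame               # genes x cells integer counts
    metacells: dict[str, str]       # cell -> metacell label
    truth: dict                     # analytic expectations per planted pair


def nb_zero_prob(mean: float, dispersion: float) -> float:
    """P(count = 0) for a negative binomial with given mean and size."""
    return float((dispersion / (dispersion + mean)) ** dispersion)


def expected_pair_percent(p: UMISimParams) -> float:
    """Analytic coexpression percentage for a planted pair.

    Both genes are on in the program fraction of cells and silent
    elsewhere; dropout is the NB zero probability. With identical depth
    for both genes the min-denominator percentage tends to
    100 * (1 - p0) as cells grow.
    """
    p0 = nb_zero_prob(p.mean_depth, p.dispersion)
    detect = 1.0 - p0
    return 100.0 * detect * detect / detect


def simulate_umi(p: UMISimParams) -> SimulatedUMI:
    """Negative-binomial UMI counts with metacell structure + planted pairs.

    Each metacell gets a random set of program genes expressed with high
    probability; other genes use the base probability. Planted pair genes
    ignore metacell structure and fire together on a shared latent on/off
    program in the stated fraction of cells.
    """
    rng = stream_rng(p.seed, "umi")
    genes = [f"G{i:03d}" for i in range(p.n_genes)]
    planted_genes = {g for pair in p.planted_pairs
                     for g in (pair.gene_a, pair.gene_b)}
    missing = planted_genes - set(genes)
    if missing:
        genes = genes + sorted(missing)
    n_cells = int(sum(p.metacell_sizes))
    cells = [f"c{i:05d}" for i in range(n_cells)]
    metacells = {}
    start = 0
    mc_of_cell = np.empty(n_cells, dtype=int)
    for mi, size in enumerate(p.metacell_sizes):
        for ci in range(start, start + size):
            metacells[cells[ci]] = f"C{mi + 1}"
            mc_of_cell[ci] = mi
        start += size

    on = np.zeros((len(genes), n_cells), dtype=bool)
    gene_idx = {g: i for i, g in enumerate(genes)}
    free_genes = [g for g in genes if g not in planted_genes]
    for mi in range(len(p.metacell_sizes)):
        program = rng.choice(
            len(free_genes),
            size=min(p.n_program_genes, len(free_genes)),
            replace=False,
        )
        program = {free_genes[k] for k in program}
        cols = mc_of_cell == mi
        for g in free_genes:
            prob = p.program_expr_prob if g in program else p.base_expr_prob
            on[gene_idx[g], cols] = rng.random(cols.sum()) < prob
    for pair in p.planted_pairs:
        z = rng.random(n_cells) < pair.fraction
        on[gene_idx[pair.gene_a]] = z
        on[gene_idx[pair.gene_b]] = z

    nb_p = p.dispersion / (p.dispersion + p.mean_depth)
    counts = np.zeros(on.shape, dtype=np.int64)
    n_on = int(on.sum())
    counts[on] = rng.negative_binomial(p.dispersion, nb_p, size=n_on)
    umi = pd.DataFrame(counts, index=genes, columns=cells)
    truth = {
        "nb_zero_prob": nb_zero_prob(p.mean_depth, p.dispersion),
        "pairs": {
            (pair.gene_a, pair.gene_b): {
                "fraction": pair.fraction,
                "expected_percent": expected_pair_percent(p),
            }
            for pair in p.planted_pairs
        },
    }
    return SimulatedUMI(umi=umi, metacells=metacells, truth=truth)


# ===========================================================================
# patch-clamp traces


@dataclass
class ChannelSimParams:
    n_channels: int = 1
    conductance_ps: float = 340.0
    v_rev_mv: float = 0.0
    k_open: float = 30.0            # s^-1, closed -> open
    k_close: float = 70.0           # s^-1, open -> closed
    calcium: str = "high"           # "high" | "zero"
    noise_sd_pa: float = 2.0
    sampling_khz: float = 10.0
    filter_khz: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.k_open < 0 or self.k_close < 0:
            raise ValueError("rates must be non-negative")
        if self.calcium not in ("high", "zero"):
            raise ValueError("calcium condition must be 'high' or 'zero'")
        if self.sampling_khz < 2 * self.filter_khz:
            raise ValueError("sampling rate must be at least twice the "
                             "filter cutoff")

    @property
    def effective_k_open(self) -> float:
        return 0.0 if self.calcium == "zero" else self.k_open

    @property
    def stationary_open(self) -> float:
        ko = self.effective_k_open
        if ko + self.k_close == 0:
            return 0.0
        return ko / (ko + self.k_close)


@dataclass
class Sweep:
    voltage_mv: float
    current_pa: np.ndarray
    sampling_khz: float
    filter_khz: float
    n_open: np.ndarray              # ground-truth open-channel count
    dwells: list[tuple[int, float]]  # ground-truth (level, ms) sequence


@dataclass
class SweepSet:
    sweeps: list[Sweep]
    metadata: dict = field(default_factory=dict)


def _gate_channel(
    rng: np.random.Generator, k_open: float, k_close: float,
    duration_ms: float, dt_ms: float,
) -> np.ndarray:
    """Sampled open/closed state of one two-state channel (exact dwells)."""
    n = int(round(duration_ms / dt_ms))
    state = np.zeros(n, dtype=np.int8)
    p_open = k_open / (k_open + k_close) if (k_open + k_close) > 0 else 0.0
    open_now = bool(rng.random() < p_open)
    t = 0.0
    idx = 0
    while idx < n:
        rate = k_close if open_now else k_open
        if rate == 0:
            dwell = duration_ms - t
        else:
            dwell = rng.exponential(1000.0 / rate)  # rates s^-1, time ms
        end = min(t + dwell, duration_ms)
        j = min(int(round(end / dt_ms)), n)
        state[idx:j] = 1 if open_now else 0
        idx = j
        t = end
        open_now = not open_now
    return state


def simulate_patch_traces(
    p: ChannelSimParams,
    protocol: VoltageProtocol | None = None,
    sweeps_per_voltage: int = 1,
) -> SweepSet:
    """Two-state gating currents under a voltage-step protocol.

    Channels gate independently; the summed open count times the unitary
    driving force g (V - V_rev) gives the clean current (pA), to which
    Gaussian noise is added before zero-phase low-pass filtering at the
    stated cutoff. Per-sweep dwell logs are the simulation ground truth.
    """
    protocol = protocol or VoltageProtocol()
    rng = stream_rng(p.seed, "traces")
    dt = 1.0 / p.sampling_khz
    sos = signal.butter(
        4, p.filter_khz / (p.sampling_khz / 2.0), btype="low", output="sos"
    )
    sweeps = []
    for voltage in protocol.steps:
        for _ in range(sweeps_per_voltage):
            counts = np.zeros(int(round(protocol.duration_ms / dt)),
                              dtype=np.int16)
            for _ch in range(p.n_channels):
                counts += _gate_channel(
                    rng, p.effective_k_open, p.k_close,
                    protocol.duration_ms, dt,
                )
            unitary = p.conductance_ps * (voltage - p.v_rev_mv) * 1e-3  # pA
            clean = counts.astype(float) * unitary
            noisy = clean + rng.normal(0.0, p.noise_sd_pa, size=clean.size)
            filtered = signal.sosfiltfilt(sos, noisy)
            change = np.flatnonzero(np.diff(counts)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [counts.size]))
            dwells = [
                (int(counts[s]), float((e - s) * dt))
                for s, e in zip(starts, ends)
            ]
            sweeps.append(
                Sweep(
                    voltage_mv=float(voltage),
                    current_pa=filtered,
                    sampling_khz=p.sampling_khz,
                    filter_khz=p.filter_khz,
                    n_open=counts,
                    dwells=dwells,
                )
            )
    return SweepSet(
        sweeps=sweeps,
        metadata={
            "calcium": p.calcium,
            "n_channels": p.n_channels,
            "conductance_ps": p.conductance_ps,
            "v_rev_mv": p.v_rev_mv,
        },
    )
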