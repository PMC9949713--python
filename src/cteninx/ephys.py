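"""Single-channel voltage-clamp analysis for putative innexon activity.

The workflow mirrors standard patch-clamp practice: keep only cells with
adequate seal and input resistance; estimate the unitary current at each
holding potential from the all-points amplitude histogram (a Gaussian
mixture whose component count is chosen by BIC); idealize traces by
half-amplitude threshold crossing to get dwell sequences and the number
of simultaneously open channels; fit the unitary current-voltage points
with a line whose slope is the channel conductance and whose x-intercept
is the reversal potential; and predict ideal-selectivity reversal
potentials with the Nernst equation from the recording solutions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

R_GAS = 8.314        # J / (mol K)
FARADAY = 96485.0    # C / mol
DEFAULT_TEMPERATURE_K = 295.15

#: Recording solutions (mM). Chloride totals sum the contributions of every
#: chloride salt in the recipe (NaCl + 2*CaCl2 + 2*MgCl2 outside; KCl plus a
#: trace of CaCl2 inside).
SOLUTIONS: dict[str, dict[str, float]] = {
    "extracellular": {
        "Na": 486.0,
        "K": 5.0,
        "Ca": 13.6,
        "Mg": 9.8,
        "Cl": 486.0 + 2 * 13.6 + 2 * 9.8,
    },
    "intracellular_low_ca": {"K": 210.0, "Cl": 210.0},
    "intracellular_high_ca": {"K": 210.0, "Cl": 210.0 + 2 * 0.001,
                              "Ca": 0.001},
}


@dataclass
class VoltageProtocol:
    """Step protocol: hyperpolarizing pre-step then fixed-duration steps."""

    holding_mv: float = -60.0
    prestep_mv: float = -50.0       # offset applied before the step series
    increment_mv: float = 10.0
    duration_ms: float = 200.0
    steps: tuple[float, ...] = tuple(float(v) for v in range(-120, -30, 10))

    def __post_init__(self):
        if self.duration_ms <= 0:
            raise ValueError("step duration must be positive")
        diffs = np.diff(self.steps)
        if len(self.steps) > 1 and not np.allclose(diffs, self.increment_mv):
            raise ValueError("step list inconsistent with increment")


@dataclass
class UnitaryAmplitudeEstimate:
    """Unitary current estimate at one voltage from an all-points histogram."""

    voltage: float                  # mV
    amplitude: float | None         # pA, signed; None when no activity
    n_levels: int
    level_means: tuple[float, ...]
    baseline: float | None = None   # most populated level mean
    sublevels_flagged: bool = False

    @property
    def no_activity(self) -> bool:
        return self.amplitude is None


@dataclass
class IVFit:
    """Least-squares line through unitary (V, i) points."""

    voltages: tuple[float, ...]
    currents: tuple[float, ...]
    conductance_ps: float           # slope, pS
    reversal_mv: float              # -intercept / slope
    residuals: tuple[float, ...] = ()


@dataclass
class OpenProbabilityRecord:
    integral_current: float         # pA
    n_channels: int
    unitary_amplitude: float        # pA
    p_open: float                   # clamped to [0, 1]
    p_open_raw: float


# ---------------------------------------------------------------------------
# QC


def qc_filter(
    cells: pd.DataFrame,
    r_in_min: float = 300.0,
    r_seal_min: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition cells by input resistance (MOhm) and seal (GOhm) thresholds.

    Both bounds are inclusive. Cells with missing metadata are discarded
    with reason "missing". Expects columns ``r_in_mohm``, ``r_seal_gohm``.
    """
    for col in ("r_in_mohm", "r_seal_gohm"):
        if col not in cells.columns:
            raise ValueError(f"cell table lacks column {col!r}")
    missing = cells["r_in_mohm"].isna() | cells["r_seal_gohm"].isna()
    ok = (
        (cells["r_in_mohm"] >= r_in_min)
        & (cells["r_seal_gohm"] >= r_seal_min)
        & ~missing
    )
    kept = cells[ok].copy()
    discarded = cells[~ok].copy()
    discarded["reason"] = np.where(
        missing[~ok], "missing", "below_threshold"
    )
    return kept, discarded


# ---------------------------------------------------------------------------
# Nernst


def nernst_potential(
    c_out: float,
    c_in: float,
    z: int,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
) -> float:
    """Equilibrium potential in mV: (1000 RT / zF) ln(c_out / c_in)."""
    if c_out <= 0 or c_in <= 0:
        raise ValueError("ion concentrations must be positive")
    if z == 0:
        raise ValueError("valence must be nonzero")
    return 1000.0 * R_GAS * temperature_k / (z * FARADAY) * np.log(c_out / c_in)


def predicted_reversals(
    temperature_k: float = DEFAULT_TEMPERATURE_K,
    intracellular: str = "intracellular_low_ca",
) -> dict[str, float]:
    """Ideal-selectivity reversal potentials for the recording solutions.

    K+ uses the K gradient, Cl- the summed chloride gradient, and X+
    (nonselective monovalent cation) pools Na + K on each side.
    """
    out = SOLUTIONS["extracellular"]
    inn = SOLUTIONS[intracellular]
    cation_out = out.get("Na", 0.0) + out.get("K", 0.0)
    cation_in = inn.get("Na", 0.0) + inn.get("K", 0.0)
    return {
        "K+": nernst_potential(out["K"], inn["K"], 1, temperature_k),
        "Cl-": nernst_potential(out["Cl"], inn["Cl"], -1, temperature_k),
        "X+": nernst_potential(cation_out, cation_in, 1, temperature_k),
    }


# ---------------------------------------------------------------------------
# unitary amplitude


def estimate_unitary_amplitude(
    current: np.ndarray,
    sampling_khz: float,
    voltage: float,
    max_components: int = 4,
    min_weight: float = 0.05,
    random_state: int = 0,
) -> UnitaryAmplitudeEstimate:
    """Unitary current from the all-points histogram of one trace segment.

    Fits Gaussian mixtures with 1..max_components components, picks the
    count by BIC, and takes the unitary amplitude as the median spacing
    between adjacent level means, signed away from the baseline (the
    most populated level). Components with weight below ``min_weight``
    (filter-transition bridges in the all-points histogram) are dropped,
    and components closer than twice their pooled standard deviation are
    merged, since such levels are not resolvable above the noise. One
    remaining component means no channel activity. Segments shorter than
    50 ms are rejected.
    """
    current = np.asarray(current, dtype=float)
    if current.size / sampling_khz < 50.0:
        raise ValueError("segment shorter than 50 ms")
    x = current.reshape(-1, 1)
    if x.shape[0] > 20000:           # histogram shape is what matters
        step = x.shape[0] // 20000 + 1
        x = x[::step]
    best = None
    best_bic = np.inf
    for k in range(1, max_components + 1):
        gm = GaussianMixture(
            n_components=k, n_init=2, random_state=random_state,
            reg_covar=1e-3,
        ).fit(x)
        bic = gm.bic(x)
        if bic < best_bic:
            best_bic = bic
            best = gm
    order = np.argsort(best.means_.ravel())
    means = best.means_.ravel()[order]
    weights = best.weights_[order]
    sigmas = np.sqrt(best.covariances_.reshape(-1)[order])
    keep = weights >= min_weight
    means, weights, sigmas = means[keep], weights[keep], sigmas[keep]
    # merge adjacent levels separated by less than the resolution limit
    merged = [(means[0], weights[0], sigmas[0])]
    for m, w, s in zip(means[1:], weights[1:], sigmas[1:]):
        pm, pw, ps = merged[-1]
        pooled = np.sqrt((ps**2 + s**2) / 2.0)
        if m - pm < 2.0 * pooled:
            tot = pw + w
            merged[-1] = ((pm * pw + m * w) / tot, tot,
                          np.sqrt((ps**2 * pw + s**2 * w) / tot))
        else:
            merged.append((m, w, s))
    means = np.array([m for m, _, _ in merged])
    weights = np.array([w for _, w, _ in merged])
    if means.size == 1:
        return UnitaryAmplitudeEstimate(
            voltage=voltage, amplitude=None, n_levels=1,
            level_means=(float(means[0]),), baseline=float(means[0]),
        )
    baseline = float(means[np.argmax(weights)])
    spacings = np.diff(means)
    i_abs = float(np.median(spacings))
    direction = np.sign(np.sum((means - baseline) * weights)) or \
        np.sign(means[-1] - baseline)
    amplitude = i_abs * float(direction if direction != 0 else 1.0)
    sublevels = bool(np.any(np.abs(spacings - i_abs) > 0.3 * i_abs))
    return UnitaryAmplitudeEstimate(
        voltage=voltage,
        amplitude=amplitude,
        n_levels=int(means.size),
        level_means=tuple(float(m) for m in means),
        baseline=baseline,
        sublevels_flagged=sublevels,
    )


# ---------------------------------------------------------------------------
# idealization


def filter_rise_time_ms(filter_khz: float) -> float:
    """10-90% rise time of a Gaussian-response low-pass filter (ms)."""
    return 0.3321 / filter_khz


def idealize(
    current: np.ndarray,
    i: float,
    baseline: float,
    sampling_khz: float,
    filter_khz: float | None = None,
) -> tuple[list[tuple[int, float]], int]:
    """Half-amplitude idealization into (level, dwell-ms) runs.

    Each sample is assigned to level k when it lies within
    [k-0.5, k+0.5) * i of baseline (levels clamped at 0). Dwells shorter
    than twice the filter rise time are merged into the preceding level,
    since the filter cannot faithfully report them. Returns the dwell
    sequence and N, the maximum simultaneous open-channel count.
    """
    if i == 0:
        raise ValueError("unitary amplitude must be nonzero")
    current = np.asarray(current, dtype=float)
    levels = np.floor((current - baseline) / i + 0.5).astype(int)
    levels = np.clip(levels, 0, None)
    # run-length encode
    change = np.flatnonzero(np.diff(levels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [levels.size]))
    dt = 1.0 / sampling_khz
    dwells = [
        (int(levels[s]), float((e - s) * dt)) for s, e in zip(starts, ends)
    ]
    if filter_khz is not None:
        min_dwell = 2.0 * filter_rise_time_ms(filter_khz)
        merged: list[tuple[int, float]] = []
        for level, dur in dwells:
            if merged and (dur < min_dwell or level == merged[-1][0]):
                merged[-1] = (merged[-1][0], merged[-1][1] + dur)
            elif not merged and dur < min_dwell:
                merged.append((level, dur))  # leading stub: keep, may absorb
            else:
                merged.append((level, dur))
        # collapse adjacent equal levels produced by merging
        dwells = []
        for level, dur in merged:
            if dwells and dwells[-1][0] == level:
                dwells[-1] = (level, dwells[-1][1] + dur)
            else:
                dwells.append((level, dur))
    n_max = max((lvl for lvl, _ in dwells), default=0)
    return dwells, n_max


def open_fraction(dwells: Sequence[tuple[int, float]]) -> float:
    """Fraction of time spent with at least one channel open."""
    total = sum(d for _, d in dwells)
    if total == 0:
        return 0.0
    return sum(d for lvl, d in dwells if lvl > 0) / total


# ---------------------------------------------------------------------------
# I-V fit and open probability


def fit_iv(points: Sequence[tuple[float, float]]) -> IVFit:
    """Ordinary least squares line i = g (V - V_rev) through unitary points.

    Slope in pA/mV is nS; reported in pS. V_rev is the x-intercept.
    """
    pts = [(float(v), float(i)) for v, i in points]
    voltages = np.array([p[0] for p in pts])
    currents = np.array([p[1] for p in pts])
    if np.unique(voltages).size < 2:
        raise ValueError("need at least two distinct voltages for an I-V fit")
    slope, intercept = np.polyfit(voltages, currents, 1)
    fitted = slope * voltages + intercept
    return IVFit(
        voltages=tuple(voltages),
        currents=tuple(currents),
        conductance_ps=float(slope * 1000.0),
        reversal_mv=float(-intercept / slope),
        residuals=tuple(currents - fitted),
    )


def analyze_sweeps(
    sweeps, max_components: int = 4
) -> tuple[pd.DataFrame, pd.DataFrame, IVFit | None]:
    """Per-voltage unitary analysis over a collection of sweeps.

    Sweeps sharing a command voltage are pooled into one all-points
    histogram (each needs ``voltage_mv``, ``current_pa``, ``sampling_khz``
    and ``filter_khz`` attributes). Returns the per-voltage amplitude
    table, the per-voltage open-probability table (P_o = I/Ni using the
    baseline-subtracted mean current and the idealized channel count),
    and the I-V fit over active voltages (None when fewer than two).
    """
    by_v: dict[float, list] = {}
    for sw in sweeps:
        by_v.setdefault(float(sw.voltage_mv), []).append(sw)
    amp_rows, po_rows, points = [], [], []
    for voltage in sorted(by_v):
        group = by_v[voltage]
        seg = np.concatenate([np.asarray(s.current_pa, float) for s in group])
        est = estimate_unitary_amplitude(
            seg, group[0].sampling_khz, voltage, max_components
        )
        amp_rows.append(
            {
                "voltage_mv": voltage,
                "amplitude_pa": est.amplitude,
                "n_levels": est.n_levels,
                "no_activity": est.no_activity,
                "sublevels_flagged": est.sublevels_flagged,
            }
        )
        if est.no_activity:
            continue
        points.append((voltage, est.amplitude))
        dwells, n_max = idealize(
            seg, est.amplitude, est.baseline,
            group[0].sampling_khz, group[0].filter_khz,
        )
        if n_max >= 1:
            rec = open_probability(
                float(np.mean(seg)) - est.baseline, n_max, est.amplitude
            )
            po_rows.append(
                {
                    "voltage_mv": voltage,
                    "n_channels": n_max,
                    "open_fraction": open_fraction(dwells),
                    "p_open": rec.p_open,
                }
            )
    fit = fit_iv(points) if len(points) >= 2 else None
    return pd.DataFrame(amp_rows), pd.DataFrame(po_rows), fit


def open_probability(
    integral_current: float, n_channels: int, unitary_amplitude: float
) -> OpenProbabilityRecord:
    """P_o = I / (N i), clamped to [0, 1] with the raw value retained."""
    if n_channels < 1:
        raise ValueError("channel count must be >= 1")
    if unitary_amplitude == 0:
        raise ValueError("unitary amplitude must be nonzero")
    raw = integral_current / (n_channels * unitary_amplitude)
    return OpenProbabilityRecord(
        integral_current=integral_current,
        n_channels=n_channels,
        unitary_amplitude=unitary_amplitude,
        p_open=float(min(1.0, max(0.0, raw))),
        p_open_raw=float(raw),
    )
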