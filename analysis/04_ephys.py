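"""Single-channel analysis of simulated innexon voltage-clamp sweeps.

Simulates the step protocol (200 ms steps, 10 mV increments, -120 to
-40 mV) for a 340 pS, nonselective (V_rev = 0) two-state channel in the
high-calcium condition and for silent zero-calcium controls, then runs
the unitary-amplitude / idealization / I-V pipeline and prints the
recovered conductance, reversal potential and open probabilities next
to the Nernst predictions for the recording solutions. Outputs under
results/04_ephys/.
"""

import json
from pathlib import Path

from cteninx.ephys import (
    VoltageProtocol,
    analyze_sweeps,
    predicted_reversals,
)
from cteninx.simulate import ChannelSimParams, simulate_patch_traces

OUT = Path(__file__).resolve().parent.parent / "results" / "04_ephys"
SEED = 303


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    proto = VoltageProtocol()
    high = ChannelSimParams(seed=SEED, calcium="high")
    sweeps = simulate_patch_traces(high, proto, sweeps_per_voltage=5)
    amp, po, fit = analyze_sweeps(sweeps.sweeps)
    amp.to_csv(OUT / "amplitudes.tsv", sep="\t", index=False)
    po.to_csv(OUT / "open_probability.tsv", sep="\t", index=False)

    print(f"high calcium: slope conductance {fit.conductance_ps:.0f} pS, "
          f"reversal {fit.reversal_mv:+.1f} mV "
          f"(simulated truth 340 pS, 0 mV)")
    print("open probability by voltage:",
          {f"{v:.0f}": round(p, 2)
           for v, p in zip(po['voltage_mv'], po['p_open'])})

    zero = ChannelSimParams(seed=SEED + 1, calcium="zero")
    zsweeps = simulate_patch_traces(zero, proto, sweeps_per_voltage=1)
    zamp, _, zfit = analyze_sweeps(zsweeps.sweeps)
    n_silent = int(zamp["no_activity"].sum())
    print(f"zero calcium: {n_silent}/{len(zamp)} voltages silent "
          f"(no unitary activity), I-V fit "
          f"{'absent' if zfit is None else 'present'}")

    reversals = predicted_reversals()
    (OUT / "iv_and_nernst.json").write_text(
        json.dumps(
            {
                "conductance_ps": fit.conductance_ps,
                "reversal_mv": fit.reversal_mv,
                "nernst_mv": reversals,
                "zero_calcium_silent_voltages": n_silent,
            },
            indent=2,
        )
    )
    print("Nernst predictions (mV):",
          {k: round(float(v), 1) for k, v in reversals.items()})
    print("fitted reversal sits far from the K+ and Cl- predictions, "
          "consistent with a nonselective pore")


if __name__ == "__main__":
    main()
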