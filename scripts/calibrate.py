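"""Calibration harness for the tripartite-synapse constants.

Evaluates the current defaults (or overrides passed as key=value arguments)
against the healthy-band target and the directional effects of the four
pathological regimes, using short paired-seed probes.  This is the tool the
shipped default constants were chosen with; see docs/methods.md for the
resulting operating point and its known residual trade-offs.

Usage:
    python scripts/calibrate.py                 # evaluate the defaults
    python scripts/calibrate.py kappa_p=64 u_release=0.038
"""

import sys
from dataclasses import replace
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from gliasim.features import response_record
from gliasim.network_builder import (
    ConnectivityParams,
    connect_network,
    place_cells,
    remove_cells,
)
from gliasim.simulate import SimulationParams, run_simulation

N_SEEDS = 3
DURATION = 300.0


def feats(topo, params):
    rows = []
    for s in range(N_SEEDS):
        trace = run_simulation(topo, replace(params, duration_s=DURATION,
                                             seed=9000 + s))
        rows.append(response_record(trace))
    return {k: np.array([r[k] for r in rows])
            for k in ("Z_spike", "Z_burst", "Z_astro")}


def main():
    overrides = {}
    for arg in sys.argv[1:]:
        key, val = arg.split("=", 1)
        overrides[key] = float(val)
    base = replace(SimulationParams(), **overrides)

    npos, apos = place_cells(250, 107, seed=1)
    topo = connect_network(npos, apos, ConnectivityParams(), seed=2)
    probes = {
        "astro_removed": (remove_cells(topo, "astrocyte", 0.25, 7), base),
        "neuron_removed": (remove_cells(topo, "neuron", 0.25, 7), base),
        "wf_quarter": (topo, replace(base, w_f=0.25)),
        "wg_quarter": (topo, replace(base, w_g=0.25)),
        "y_astro_high": (topo, replace(base, y_astro=0.1)),
        "y_exc_high": (topo, replace(base, y_max_exc=0.9)),
    }

    h = feats(topo, base)
    print(f"healthy: spike={h['Z_spike'].mean():7.1f}/min "
          f"burst={h['Z_burst'].mean():5.1f}/min "
          f"astro={h['Z_astro'].mean():5.1f} activations")
    band_ok = 30 <= h["Z_spike"].mean() <= 200
    print(f"30-200 spikes/min band: {'OK' if band_ok else 'MISS'}")
    for name, (t_, p_) in probes.items():
        v = feats(t_, p_)
        deltas = "  ".join(
            f"{k[2:]}:{100 * (v[k].mean() - h[k].mean()) / max(h[k].mean(), 1e-9):+6.1f}%"
            for k in ("Z_spike", "Z_burst", "Z_astro"))
        print(f"{name:15s} {deltas}")


if __name__ == "__main__":
    main()
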