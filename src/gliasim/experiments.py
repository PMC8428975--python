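"""Experiment driver: the four pathological-parameter studies.

A *suite* is nine networks: three spatial placements (topologies A, B, C),
each connected three times independently (connectivity configurations
1, 2, 3).  Every hypothesis experiment simulates all nine networks over a
parameter grid with ``n_reps`` repetitions and collects the three response
variables per simulation into a tidy table:

* H1 -- cell-density reduction: three removal copies per network and cell
  type (25 % of astrocytes or neurons removed at random);
* H2 -- astrocytic ATP depression: y_Astro in {0.01, 0.025, 0.05, 0.075, 0.1};
* H3 -- glutamate dynamics: (w_f, w_g) in {1, 1/2, 1/4}^2;
* H4 -- synaptic weight bounds: Ymax+ in {0.7, 0.8, 0.9} x
  Ymax- in {0.1, 0.5, 0.6, 0.7}.

Seeds are derived deterministically from (base seed, hypothesis, network,
parameter point, repetition), so any row of a table can be re-simulated in
isolation.
"""

from __future__ import annotations

import itertools
import logging
import time
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import CmaParams, response_record
from .network_builder import (
    DEFAULT_MIN_DIST,
    DEFAULT_N_ASTRO,
    DEFAULT_N_NEURONS,
    DEFAULT_VOLUME,
    ConnectivityParams,
    NetworkTopology,
    connect_network,
    place_cells,
    remove_cells,
    topology_metrics,
)
from .simulate import SimulationParams, run_simulation

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentPlan",
    "build_network_suite",
    "suite_metrics_table",
    "run_h1_removal",
    "run_h2_atp",
    "run_h3_glutamate",
    "run_h4_weights",
]

H2_GRID = (0.01, 0.025, 0.05, 0.075, 0.1)
H3_GRID = tuple(itertools.product((1.0, 0.5, 0.25), (1.0, 0.5, 0.25)))
H4_GRID = tuple(itertools.product((0.1, 0.5, 0.6, 0.7), (0.7, 0.8, 0.9)))  # (y_in, y_ex)
REMOVAL_FRACTION = 0.25
N_REMOVAL_COPIES = 3


@dataclass(frozen=True)
class ExperimentPlan:
    """Design constants of the simulation study."""

    base_seed: int = 0
    n_reps: int = 10
    duration_s: float = 300.0
    n_neurons: int = DEFAULT_N_NEURONS
    n_astro: int = DEFAULT_N_ASTRO
    sim: SimulationParams = field(default_factory=SimulationParams)
    conn: ConnectivityParams = field(default_factory=ConnectivityParams)
    cma: CmaParams = field(default_factory=CmaParams)

    def derive_seed(self, *key) -> int:
        """Deterministic 31-bit seed from (base_seed, *key)."""
        parts = [self.base_seed] + [
            zlib.crc32(str(k).encode()) & 0x7FFFFFFF for k in key
        ]
        return int(np.random.SeedSequence(parts).generate_state(1)[0] % (2**31))


def build_network_suite(plan: ExperimentPlan) -> dict[str, NetworkTopology]:
    """Nine labelled topologies: placements A, B, C x connection seeds 1-3."""
    suite: dict[str, NetworkTopology] = {}
    for i, topo_id in enumerate("ABC"):
        pos = place_cells(
            plan.n_neurons,
            plan.n_astro,
            DEFAULT_VOLUME,
            DEFAULT_MIN_DIST,
            seed=plan.derive_seed("placement", topo_id),
        )
        for cc in (1, 2, 3):
            label = f"{topo_id}{cc}"
            suite[label] = connect_network(
                pos[0],
                pos[1],
                plan.conn,
                seed=plan.derive_seed("connect", topo_id, cc),
                label=label,
                topology_id=topo_id,
                cc_id=str(cc),
            )
    return suite


def suite_metrics_table(suite: dict[str, NetworkTopology]) -> pd.DataFrame:
    rows = []
    for label, topo in suite.items():
        m = topology_metrics(topo)
        rows.append(
            {
                "network": label,
                "connectivity_pct": m.connectivity_pct,
                "avg_gap_junctions": m.avg_gap_junctions,
                "exc_without_astro_pct": m.exc_without_astro_pct,
            }
        )
    return pd.DataFrame(rows)


def _simulate_row(topo, params, plan, **meta):
    t0 = time.time()
    trace = run_simulation(topo, params)
    rec = response_record(trace, plan.cma, **meta)
    logger.info(
        "sim %s: %.1fs  Z_spike=%.1f Z_burst=%.2f Z_astro=%.2f",
        meta, time.time() - t0, rec["Z_spike"], rec["Z_burst"], rec["Z_astro"],
    )
    return rec, trace


def run_h1_removal(
    suite: dict[str, NetworkTopology],
    plan: ExperimentPlan,
    collect_glutamate: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Cell-density experiment: default vs 25 % astrocyte / neuron removal.

    Per network: the intact graph plus ``N_REMOVAL_COPIES`` independent
    removal draws per cell type ("identical copies" that differ only in the
    removal randomness), each simulated ``n_reps`` times.  Returns the
    response table and, optionally, per-condition mean astrocytic glutamate
    time courses (averaged over repetitions of network B1).
    """
    rows = []
    glu_rows = []
    for label, topo in suite.items():
        variants: list[tuple[str, int, NetworkTopology]] = [("default", 0, topo)]
        for cell_type, tag in (("astrocyte", "astro_removed"), ("neuron", "neuron_removed")):
            for copy in range(1, N_REMOVAL_COPIES + 1):
                reduced = remove_cells(
                    topo, cell_type, REMOVAL_FRACTION,
                    seed=plan.derive_seed("remove", label, cell_type, copy),
                )
                variants.append((tag, copy, reduced))
        for tag, copy, variant in variants:
            for rep in range(plan.n_reps):
                params = replace(
                    plan.sim,
                    duration_s=plan.duration_s,
                    seed=plan.derive_seed("h1", label, tag, copy, rep),
                )
                rec, trace = _simulate_row(
                    variant, params, plan,
                    hypothesis="H1", network=label, condition=tag,
                    copy=copy, rep=rep, seed=params.seed,
                    instance=f"{label}:{tag}:{copy}",
                )
                rows.append(rec)
                if collect_glutamate and label == "B1":
                    glu_rows.append(
                        pd.DataFrame(
                            {
                                "time_s": np.arange(trace.n_steps) * trace.dt,
                                "mean_glutamate": trace.mean_glu,
                                "condition": tag,
                                "copy": copy,
                                "rep": rep,
                            }
                        )
                    )
    table = pd.DataFrame(rows)
    glu = pd.concat(glu_rows, ignore_index=True) if glu_rows else None
    return table, glu


def _run_grid(suite, plan, hypothesis, grid, param_setter):
    rows = []
    for label, topo in suite.items():
        for point_idx, point in enumerate(grid):
            for rep in range(plan.n_reps):
                params = param_setter(
                    replace(
                        plan.sim,
                        duration_s=plan.duration_s,
                        seed=plan.derive_seed(hypothesis, label, point_idx, rep),
                    ),
                    point,
                )
                meta = {
                    "hypothesis": hypothesis, "network": label,
                    "rep": rep, "seed": params.seed, "instance": label,
                }
                meta.update(_point_meta(hypothesis, point))
                rec, _ = _simulate_row(topo, params, plan, **meta)
                rows.append(rec)
    return pd.DataFrame(rows)


def _point_meta(hypothesis, point):
    if hypothesis == "H2":
        return {"y_astro": point, "is_default": point == 0.01}
    if hypothesis == "H3":
        wf, wg = point
        return {"w_f": wf, "w_g": wg, "is_default": point == (1.0, 1.0)}
    wi, we = point
    return {"y_in": wi, "y_ex": we, "is_default": point == (0.7, 0.7)}


def run_h2_atp(suite, plan: ExperimentPlan) -> pd.DataFrame:
    """Astrocytic ATP experiment: sweep the depression magnitude y_Astro."""
    return _run_grid(
        suite, plan, "H2", H2_GRID,
        lambda p, ya: replace(p, y_astro=ya),
    )


def run_h3_glutamate(suite, plan: ExperimentPlan) -> pd.DataFrame:
    """Glutamate-dynamics experiment: scale release (w_f) and uptake (w_g)."""
    return _run_grid(
        suite, plan, "H3", H3_GRID,
        lambda p, point: replace(p, w_f=point[0], w_g=point[1]),
    )


def run_h4_weights(suite, plan: ExperimentPlan) -> pd.DataFrame:
    """Synaptic-weight experiment: sweep the weight bounds (Ymax-, Ymax+)."""
    return _run_grid(
        suite, plan, "H4", H4_GRID,
        lambda p, point: replace(p, y_max_inh=point[0], y_max_exc=point[1]),
    )
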