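"""Spatial neuron-astrocyte network construction.

Cells are scattered uniformly at random in a thin slab (mimicking the
electrode field of an in-vitro multielectrode array), with a minimum
inter-cell distance enforced by resampling.  Connectivity follows three
rules:

* astrocyte-astrocyte gap junctions join every pair closer than a fixed
  distance (deterministic rule);
* neuron->neuron synapses are drawn with a distance-dependent truncated
  Gaussian probability p(d) = exp(-d^2 / (2 sigma^2)) for d <= d_cut;
* astrocyte-neuron links use the same kernel family with its own scale.

Each excitatory synapse may be enclosed by at most one astrocyte (the
tripartite-synapse arrangement): among the astrocytes linked to the
postsynaptic neuron, the one nearest to the synapse midpoint encloses it.
Inhibitory synapses are never enclosed, reflecting the lack of data on
GABAergic-astrocyte signalling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ConnectivityParams",
    "NetworkTopology",
    "TopologyMetrics",
    "place_cells",
    "connect_network",
    "remove_cells",
    "topology_metrics",
    "save_topology",
    "load_topology",
]

#: default slab extent in micrometres
DEFAULT_VOLUME = (750.0, 750.0, 10.0)
DEFAULT_MIN_DIST = 30.0
DEFAULT_N_NEURONS = 250
DEFAULT_N_ASTRO = 107


@dataclass(frozen=True)
class ConnectivityParams:
    """Parameters of the connection step.

    The kernel scales were calibrated once so that, with the default cell
    counts and volume, network connectivity lands in the 27-29 % band, the
    mean astrocyte gap-junction degree in 4.5-4.9, and a few percent of
    excitatory synapses end up without an enclosing astrocyte.
    """

    gap_junction_dist: float = 100.0  # um, deterministic threshold
    sigma_nn: float = 200.0           # um, neuron-neuron kernel scale
    d_cut_nn: float = 750.0           # um, neuron-neuron truncation
    sigma_an: float = 50.0            # um, astrocyte-neuron kernel scale
    d_cut_an: float = 100.0           # um, astrocyte-neuron truncation
    exc_fraction: float = 0.45        # fraction of excitatory neurons
    y_max_exc: float = 0.7            # upper bound for excitatory base weights
    y_max_inh: float = 0.7            # magnitude bound for inhibitory base weights


@dataclass
class NetworkTopology:
    """Immutable-ish container for one built network.

    Synaptic base weights are signed: positive for excitatory presynaptic
    neurons, negative for inhibitory ones, drawn uniformly within the bound
    recorded in ``build_y_max_exc`` / ``build_y_max_inh``.  Simulations may
    rescale them to other bounds.
    """

    neuron_pos: np.ndarray          # (N, 3) um
    astro_pos: np.ndarray           # (M, 3) um
    neuron_sign: np.ndarray         # (N,) int8, +1 excitatory / -1 inhibitory
    syn_pre: np.ndarray             # (S,) int32 presynaptic neuron
    syn_post: np.ndarray            # (S,) int32 postsynaptic neuron
    syn_weight: np.ndarray          # (S,) float64 signed base weight
    syn_astro: np.ndarray           # (S,) int32 enclosing astrocyte or -1
    gap_a: np.ndarray               # (E,) int32
    gap_b: np.ndarray               # (E,) int32
    build_y_max_exc: float = 0.7
    build_y_max_inh: float = 0.7
    label: str = ""
    topology_id: str = ""
    cc_id: str = ""

    @property
    def n_neurons(self) -> int:
        return self.neuron_pos.shape[0]

    @property
    def n_astro(self) -> int:
        return self.astro_pos.shape[0]

    @property
    def n_synapses(self) -> int:
        return self.syn_pre.shape[0]

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on violation."""
        s = self.neuron_sign[self.syn_pre]
        exc = s > 0
        if np.any(self.syn_weight[exc] < 0) or np.any(
            self.syn_weight[exc] > self.build_y_max_exc + 1e-12
        ):
            raise ValueError("excitatory base weights outside [0, y_max_exc]")
        if np.any(self.syn_weight[~exc] > 0) or np.any(
            self.syn_weight[~exc] < -self.build_y_max_inh - 1e-12
        ):
            raise ValueError("inhibitory base weights outside [-y_max_inh, 0]")
        if np.any(self.syn_astro[~exc] >= 0):
            raise ValueError("an inhibitory synapse is enclosed by an astrocyte")
        if np.any(self.gap_a == self.gap_b):
            raise ValueError("gap junction self-edge")
        if self.syn_pre.size and np.any(self.syn_pre == self.syn_post):
            raise ValueError("autapse present")


@dataclass(frozen=True)
class TopologyMetrics:
    connectivity_pct: float       # % of ordered neuron pairs connected
    avg_gap_junctions: float      # mean astrocyte gap-junction degree
    exc_without_astro_pct: float  # % excitatory synapses lacking an astrocyte


def place_cells(
    n_neurons: int,
    n_astro: int,
    volume: tuple[float, float, float] = DEFAULT_VOLUME,
    min_dist: float = DEFAULT_MIN_DIST,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Place cells uniformly at random with a minimum pairwise distance.

    Cells are inserted sequentially; a cell whose position violates the
    minimum distance against already-placed cells is resampled, up to
    ``max_attempts`` times, after which a RuntimeError names the cap.
    Deterministic for a fixed seed.

    Returns (neuron_positions, astro_positions), each (n, 3) in um.
    """
    if n_neurons < 0 or n_astro < 0:
        raise ValueError("cell counts must be non-negative")
    if min_dist < 0:
        raise ValueError("min_dist must be non-negative")
    ext = np.asarray(volume, dtype=float)
    if np.any(ext <= 0):
        raise ValueError("volume extents must be positive")

    rng = np.random.default_rng(seed)
    total = n_neurons + n_astro
    pos = np.empty((total, 3))
    d2min = min_dist * min_dist
    for i in range(total):
        for attempt in range(max_attempts):
            cand = rng.random(3) * ext
            if i == 0:
                break
            d2 = np.sum((pos[:i] - cand) ** 2, axis=1)
            if d2.min() >= d2min:
                break
        else:
            raise RuntimeError(
                f"could not place cell {i} within {max_attempts} attempts; "
                "packing is too dense for the requested min_dist"
            )
        pos[i] = cand
    return pos[:n_neurons].copy(), pos[n_neurons:].copy()


def _kernel_prob(d: np.ndarray, sigma: float, d_cut: float) -> np.ndarray:
    p = np.exp(-(d * d) / (2.0 * sigma * sigma))
    p[d > d_cut] = 0.0
    return p


def connect_network(
    neuron_pos: np.ndarray,
    astro_pos: np.ndarray,
    params: ConnectivityParams = ConnectivityParams(),
    seed: int = 0,
    label: str = "",
    topology_id: str = "",
    cc_id: str = "",
) -> NetworkTopology:
    """Sample connectivity on a fixed placement.

    Draws neuron signs (a fixed excitatory fraction, shuffled), directed
    neuron->neuron synapses, astrocyte-neuron links, gap junctions, base
    weights and the synapse->astrocyte enclosure map.
    """
    rng = np.random.default_rng(seed)
    n = neuron_pos.shape[0]
    m = astro_pos.shape[0]

    # neuron signs: exact excitatory count, random assignment
    n_exc = int(round(params.exc_fraction * n))
    sign = np.full(n, -1, dtype=np.int8)
    sign[:n_exc] = 1
    rng.shuffle(sign)

    # gap junctions: deterministic distance rule
    if m > 1:
        diff = astro_pos[:, None, :] - astro_pos[None, :, :]
        da = np.sqrt(np.sum(diff * diff, axis=2))
        iu, ju = np.triu_indices(m, k=1)
        keep = da[iu, ju] < params.gap_junction_dist
        gap_a = iu[keep].astype(np.int32)
        gap_b = ju[keep].astype(np.int32)
    else:
        gap_a = np.zeros(0, dtype=np.int32)
        gap_b = np.zeros(0, dtype=np.int32)

    # neuron -> neuron synapses, truncated Gaussian kernel on distance
    if n > 1:
        diff = neuron_pos[:, None, :] - neuron_pos[None, :, :]
        dn = np.sqrt(np.sum(diff * diff, axis=2))
        p = _kernel_prob(dn, params.sigma_nn, params.d_cut_nn)
        np.fill_diagonal(p, 0.0)
        draw = rng.random((n, n))
        pre, post = np.nonzero(draw < p)  # ordered pairs (pre -> post)
        pre = pre.astype(np.int32)
        post = post.astype(np.int32)
    else:
        pre = np.zeros(0, dtype=np.int32)
        post = np.zeros(0, dtype=np.int32)

    # base weights within the sign's bounds
    w = rng.random(pre.size)
    exc_syn = sign[pre] > 0
    weight = np.where(exc_syn, w * params.y_max_exc, -w * params.y_max_inh)

    # astrocyte-neuron links: same kernel family, own scale
    if m > 0 and n > 0:
        diff = astro_pos[:, None, :] - neuron_pos[None, :, :]
        dan = np.sqrt(np.sum(diff * diff, axis=2))
        pan = _kernel_prob(dan, params.sigma_an, params.d_cut_an)
        linked = rng.random((m, n)) < pan  # (astro, neuron)
    else:
        linked = np.zeros((m, n), dtype=bool)

    # enclosure: nearest astro (to the synapse midpoint) among those linked
    # to the postsynaptic neuron; none linked -> astrocyte-free synapse
    astro_of = np.full(pre.size, -1, dtype=np.int32)
    if m > 0 and pre.size:
        mid = 0.5 * (neuron_pos[pre] + neuron_pos[post])
        for k in np.nonzero(exc_syn)[0]:
            cand = np.nonzero(linked[:, post[k]])[0]
            if cand.size == 0:
                continue
            d2 = np.sum((astro_pos[cand] - mid[k]) ** 2, axis=1)
            astro_of[k] = cand[np.argmin(d2)]

    topo = NetworkTopology(
        neuron_pos=neuron_pos.copy(),
        astro_pos=astro_pos.copy(),
        neuron_sign=sign,
        syn_pre=pre,
        syn_post=post,
        syn_weight=weight,
        syn_astro=astro_of,
        gap_a=gap_a,
        gap_b=gap_b,
        build_y_max_exc=params.y_max_exc,
        build_y_max_inh=params.y_max_inh,
        label=label,
        topology_id=topology_id,
        cc_id=cc_id,
    )
    topo.validate()
    return topo


def remove_cells(
    topology: NetworkTopology,
    cell_type: str,
    fraction: float,
    seed: int = 0,
) -> NetworkTopology:
    """Remove ``floor(fraction * n)`` cells of one type, uniformly at random.

    All synapses, gap junctions and enclosure entries incident to a removed
    cell disappear; the remaining structure (including weights) is unchanged.
    Cell indices are compacted, preserving the original order.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if cell_type not in ("astrocyte", "neuron"):
        raise ValueError(f"unknown cell_type: {cell_type!r}")

    rng = np.random.default_rng(seed)
    if cell_type == "astrocyte":
        m = topology.n_astro
        n_remove = int(np.floor(fraction * m))
        removed = rng.choice(m, size=n_remove, replace=False)
        keep = np.ones(m, dtype=bool)
        keep[removed] = False
        new_index = np.cumsum(keep) - 1  # old -> new id
        syn_astro = topology.syn_astro.copy()
        enclosed = syn_astro >= 0
        gone = enclosed & ~np.isin(topology.syn_astro, np.nonzero(keep)[0])
        syn_astro[gone] = -1
        syn_astro[syn_astro >= 0] = new_index[syn_astro[syn_astro >= 0]]
        gkeep = keep[topology.gap_a] & keep[topology.gap_b]
        return replace(
            topology,
            astro_pos=topology.astro_pos[keep],
            syn_astro=syn_astro.astype(np.int32),
            gap_a=new_index[topology.gap_a[gkeep]].astype(np.int32),
            gap_b=new_index[topology.gap_b[gkeep]].astype(np.int32),
        )

    n = topology.n_neurons
    n_remove = int(np.floor(fraction * n))
    removed = rng.choice(n, size=n_remove, replace=False)
    keep = np.ones(n, dtype=bool)
    keep[removed] = False
    new_index = np.cumsum(keep) - 1
    skeep = keep[topology.syn_pre] & keep[topology.syn_post]
    return replace(
        topology,
        neuron_pos=topology.neuron_pos[keep],
        neuron_sign=topology.neuron_sign[keep],
        syn_pre=new_index[topology.syn_pre[skeep]].astype(np.int32),
        syn_post=new_index[topology.syn_post[skeep]].astype(np.int32),
        syn_weight=topology.syn_weight[skeep],
        syn_astro=topology.syn_astro[skeep],
    )


def topology_metrics(topology: NetworkTopology) -> TopologyMetrics:
    """Connectivity percentage, mean gap-junction degree, unenclosed share."""
    n = topology.n_neurons
    m = topology.n_astro
    if n < 2:
        if n == 0:
            warnings.warn("empty network: metrics defined as 0")
        conn = 0.0
    else:
        conn = 100.0 * topology.n_synapses / (n * (n - 1))
    avg_gj = 2.0 * topology.gap_a.size / m if m > 0 else 0.0
    exc = topology.neuron_sign[topology.syn_pre] > 0 if topology.n_synapses else np.zeros(0, bool)
    n_exc = int(exc.sum())
    if n_exc == 0:
        woa = 0.0
    else:
        woa = 100.0 * float(np.sum(topology.syn_astro[exc] < 0)) / n_exc
    return TopologyMetrics(conn, avg_gj, woa)


# ---------------------------------------------------------------------------
# serialization: a plain-CSV bundle (cells.csv / synapses.csv / gap_junctions.csv)

def save_topology(topology: NetworkTopology, out_dir) -> None:
    import pandas as pd
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n, m = topology.n_neurons, topology.n_astro
    cells = pd.DataFrame(
        {
            "id": np.concatenate([np.arange(n), np.arange(m)]),
            "type": ["neuron"] * n + ["astrocyte"] * m,
            "sign": np.concatenate([topology.neuron_sign, np.zeros(m, dtype=np.int8)]),
            "x": np.concatenate([topology.neuron_pos[:, 0], topology.astro_pos[:, 0]]),
            "y": np.concatenate([topology.neuron_pos[:, 1], topology.astro_pos[:, 1]]),
            "z": np.concatenate([topology.neuron_pos[:, 2], topology.astro_pos[:, 2]]),
        }
    )
    cells.to_csv(out / "cells.csv", index=False)
    pd.DataFrame(
        {
            "pre": topology.syn_pre,
            "post": topology.syn_post,
            "base_weight": topology.syn_weight,
            "astro_id": topology.syn_astro,
        }
    ).to_csv(out / "synapses.csv", index=False)
    pd.DataFrame({"a": topology.gap_a, "b": topology.gap_b}).to_csv(
        out / "gap_junctions.csv", index=False
    )
    meta = pd.DataFrame(
        {
            "key": ["label", "topology_id", "cc_id", "build_y_max_exc", "build_y_max_inh"],
            "value": [
                topology.label,
                topology.topology_id,
                topology.cc_id,
                topology.build_y_max_exc,
                topology.build_y_max_inh,
            ],
        }
    )
    meta.to_csv(out / "meta.csv", index=False)


def load_topology(in_dir) -> NetworkTopology:
    import pandas as pd
    from pathlib import Path

    src = Path(in_dir)
    cells = pd.read_csv(src / "cells.csv")
    syn = pd.read_csv(src / "synapses.csv")
    gj = pd.read_csv(src / "gap_junctions.csv")
    meta = dict(
        zip(pd.read_csv(src / "meta.csv")["key"], pd.read_csv(src / "meta.csv")["value"])
    )
    neu = cells[cells["type"] == "neuron"]
    ast = cells[cells["type"] == "astrocyte"]
    return NetworkTopology(
        neuron_pos=neu[["x", "y", "z"]].to_numpy(),
        astro_pos=ast[["x", "y", "z"]].to_numpy(),
        neuron_sign=neu["sign"].to_numpy(np.int8),
        syn_pre=syn["pre"].to_numpy(np.int32),
        syn_post=syn["post"].to_numpy(np.int32),
        syn_weight=syn["base_weight"].to_numpy(float),
        syn_astro=syn["astro_id"].to_numpy(np.int32),
        gap_a=gj["a"].to_numpy(np.int32),
        gap_b=gj["b"].to_numpy(np.int32),
        build_y_max_exc=float(meta.get("build_y_max_exc", 0.7)),
        build_y_max_inh=float(meta.get("build_y_max_inh", 0.7)),
        label=str(meta.get("label", "")),
        topology_id=str(meta.get("topology_id", "")),
        cc_id=str(meta.get("cc_id", "")),
    )
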