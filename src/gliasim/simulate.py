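"""Coupled neuron-astrocyte network dynamics.

The model is a discrete-time (5 ms step) stochastic rate network with a
tripartite-synapse layer:

* Neurons fire as inhomogeneous Bernoulli processes.  The firing rate of
  neuron i at step k is

      lambda_i = max(0, c_i + sum_j y_ij s_j(k-1) - sum_j y_Astro A_ija(k-1))

  where c_i is basal noise, y_ij the (time-varying) synaptic weight, s_j the
  spike indicator, and A_ija flags synapses enclosed by a currently active
  astrocyte, which exerts a per-synapse depression y_Astro (modelling
  ATP/P2X-receptor downregulation of postsynaptic NMDA receptors).

* Each excitatory synapse carries a ready-releasable glutamate pool
  x in [0, 1] that recovers at rate alpha_rec, leaks continuously at rate
  w_f * Omega_f into the cleft, and releases a fraction U on each
  presynaptic spike.  All glutamate leaving the pool is taken up by the
  enclosing astrocyte (or lost if the synapse has none).  The effective
  weight scales with the pool and with astrocyte-sourced potentiation p:

      y_ij = clamp(yhat_ij * (1 + p) * x / x_ss0, 0, Ymax+)

  with x_ss0 = alpha_rec / (alpha_rec + Omega_f) the quiescent pool under
  *default* rates.  The normaliser is deliberately a fixed calibration
  constant: lowering the release rate (w_f < 1) then enlarges the ready
  pool and strengthens transmission, the mechanism proposed for the
  pathological regime.  Inhibitory synapses are static (y_ij = yhat_ij).

* Astrocytes sense cleft glutamate through mGluR occupancy Gamma in [0,1]
  (recovery rate w_g * Omega_g), produce IP3, and accumulate calcium per
  synapse:

      Ca(k) = Ca(k-1) + Omega_acc * (IP3(k) - Ca(k-1)).

  Astrocyte-level calcium (the mean over enclosed synapses) diffuses
  between gap-junction-coupled neighbours.  When it crosses theta_Ca the
  astrocyte *activates* for a fixed window t_active: it releases a fraction
  of its stored glutamate (raising p on its enclosed synapses) and
  depresses them via the A_ija term.  At the end of the window the
  synapse-level Ca and IP3 reset (ER depletion), so sustained glutamate
  input produces repeated activation cycles whose rate grows with mGluR
  occupancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .network_builder import NetworkTopology

__all__ = [
    "SimulationParams",
    "SimTrace",
    "firing_rate",
    "draw_spikes",
    "synapse_step",
    "astrocyte_step",
    "run_simulation",
]


@dataclass(frozen=True)
class SimulationParams:
    """All rates and bounds of one simulation.

    Times are in seconds, rates in 1/s unless noted.  ``omega_acc`` and
    ``d_gj`` are dimensionless per-step factors.  Defaults are the healthy
    baseline; the pathological regimes modify ``y_astro``, ``w_f``, ``w_g``,
    ``y_max_exc`` and ``y_max_inh`` only.
    """

    dt: float = 0.005               # step, s
    duration_s: float = 300.0       # simulated time (5 min default)
    noise: float = 0.02             # basal rate c_i per step
    y_max_exc: float = 0.7          # bound on |y| for excitatory synapses
    y_max_inh: float = 0.7          # bound on |y| for inhibitory synapses
    omega_f: float = 0.0020         # presynaptic glutamate release rate, 1/s
    omega_g: float = 0.0770         # mGluR recovery rate, 1/s
    w_f: float = 1.0                # scaling of omega_f (pathology dial)
    w_g: float = 1.0                # scaling of omega_g (pathology dial)
    y_astro: float = 0.01           # per-synapse astrocytic depression
    omega_acc: float = 0.005        # Ca relaxation factor per step
    # --- tripartite-synapse constants (calibrated once, see docs/methods.md)
    u_release: float = 0.042        # pool fraction released per spike
    alpha_rec: float = 0.001        # pool recovery rate, 1/s
    kappa_gamma: float = 0.06       # mGluR occupancy jump per (saturating) release bolus
    gamma_half: float = 2e-4        # half-saturation of the mGluR bolus response
    k_ip3: float = 0.26             # IP3 production gain, 1/s per unit Gamma
    omega_ip3: float = 0.2          # IP3 decay rate, 1/s
    theta_ca: float = 0.45          # astrocyte activation threshold
    t_active: float = 5.0           # activation window, s
    g_release: float = 0.8          # stored-glutamate fraction released
    p_half: float = 0.5             # half-saturation of the release->potentiation transfer
    kappa_p: float = 56.0           # potentiation gain per released glutamate
    omega_p: float = 0.2            # potentiation decay rate, 1/s
    p_tonic: float = 0.5            # tonic potentiation of enclosed synapses
    d_gj: float = 0.01              # gap-junction Ca coupling per step
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for name in ("noise", "omega_f", "omega_g", "w_f", "w_g", "y_astro",
                     "alpha_rec", "k_ip3", "omega_ip3", "kappa_gamma",
                     "kappa_p", "omega_p", "y_max_exc", "y_max_inh", "d_gj"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.omega_acc <= 1.0:
            raise ValueError("omega_acc must be in [0, 1]")
        for name in ("u_release", "g_release"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_s / self.dt))

    @property
    def x_ss0(self) -> float:
        """Quiescent ready-pool level at default (w_f = 1) rates."""
        return self.alpha_rec / (self.alpha_rec + self.omega_f)

    @property
    def active_steps(self) -> int:
        return max(1, int(round(self.t_active / self.dt)))


@dataclass
class SimTrace:
    """Recorded series of one simulation."""

    raster: np.ndarray       # (steps, N) uint8 spike indicators
    active: np.ndarray       # (steps, M) uint8 astrocyte active flags
    mean_ca: np.ndarray      # (steps,) mean astrocyte-level calcium
    mean_glu: np.ndarray     # (steps,) mean stored glutamate per astrocyte
    mean_x: np.ndarray       # (steps,) mean ready-pool level over exc synapses
    mean_gamma: np.ndarray   # (steps,) mean mGluR occupancy over exc synapses
    mean_p: np.ndarray       # (steps,) mean astrocytic potentiation
    dt: float
    params: SimulationParams | None = None

    @property
    def n_neurons(self) -> int:
        return self.raster.shape[1]

    @property
    def n_astro(self) -> int:
        return self.active.shape[1]

    @property
    def n_steps(self) -> int:
        return self.raster.shape[0]

    @property
    def duration_min(self) -> float:
        return self.n_steps * self.dt / 60.0

    def spike_times(self, neuron: int) -> np.ndarray:
        """Spike times of one neuron in seconds."""
        return np.nonzero(self.raster[:, neuron])[0] * self.dt


# ---------------------------------------------------------------------------
# unit-level operations (single-step semantics; the fused kernel below applies
# exactly these updates)

def firing_rate(noise, spikes_prev, weights, astro_flags_prev, y_astro):
    """Clamped linear firing rate of one postsynaptic neuron.

    ``spikes_prev`` and ``weights`` are aligned arrays over incoming
    synapses; ``astro_flags_prev`` flags synapses enclosed by an astrocyte
    that was active at the previous step.
    """
    drive = float(np.dot(np.asarray(weights, float), np.asarray(spikes_prev, float)))
    depress = y_astro * float(np.sum(astro_flags_prev))
    return max(0.0, noise + drive - depress)


def draw_spikes(lam, rng):
    """Bernoulli(1 - exp(-lambda)) spike indicators (Poisson thinning)."""
    lam = np.asarray(lam, float)
    if np.any(lam < 0):
        raise ValueError("negative rate")
    u = rng.random(lam.shape) if lam.ndim else rng.random()
    return (u < -np.expm1(-lam)).astype(np.uint8)


def synapse_step(x, gamma, p, spike, params: SimulationParams):
    """One step of the presynaptic pool / mGluR occupancy of one synapse.

    Returns (x, gamma, released) where ``released`` is the total glutamate
    leaving the pool this step (continuous leak plus spike-triggered
    release), which is what the enclosing astrocyte takes up.
    """
    dt = params.dt
    a = dt * params.alpha_rec
    leak = dt * params.w_f * params.omega_f
    out = leak * x
    x = x + a * (1.0 - x) - out
    rho = 0.0
    if spike:
        rho = params.u_release * min(1.0, 1.0 + p) * x
        x -= rho
        out += rho
    if rho > 0.0:
        gamma = gamma + params.kappa_gamma * rho / (rho + params.gamma_half) * (1.0 - gamma)
    gamma = gamma - dt * params.w_g * params.omega_g * gamma
    return x, gamma, out


def effective_weight(base_w, x, p, params: SimulationParams):
    """clamp(yhat (1+p) x / x_ss0, 0, Ymax+); inhibitory weights are static."""
    if base_w <= 0:
        return base_w
    y = base_w * (1.0 + p) * x / params.x_ss0
    return min(y, params.y_max_exc)


def astrocyte_step(ca, ip3, gamma, params: SimulationParams, gj_drive=0.0):
    """One step of per-synapse IP3/Ca dynamics of one astrocyte.

    ``ca``/``ip3``/``gamma`` are aligned arrays over the enclosed synapses.
    Returns (ca, ip3, ca_astro) where ca_astro is the astrocyte-level
    calcium (mean over synapses plus the gap-junction term ``gj_drive``,
    folded back uniformly into the per-synapse values).
    """
    ca = np.asarray(ca, float).copy()
    ip3 = np.asarray(ip3, float).copy()
    gamma = np.asarray(gamma, float)
    if ca.size == 0:
        return ca, ip3, 0.0
    dt = params.dt
    ip3 += dt * params.k_ip3 * gamma - dt * params.omega_ip3 * ip3
    ca += params.omega_acc * (ip3 - ca)
    ca += gj_drive
    return ca, ip3, float(np.mean(ca))


# ---------------------------------------------------------------------------
# fused simulation kernel


@njit(cache=True, fastmath=True)
def _sim_kernel(
    n_steps, n_neurons, n_astro, seed,
    noise,
    e_pre, e_post, e_w, e_astro,            # excitatory synapses
    e_indptr, e_syn,                        # CSR presyn -> exc synapse index
    i_indptr, i_post, i_w,                  # CSR presyn -> inhibitory edges
    enc_indptr,                             # astro -> slice of enclosed prefix
    gj_indptr, gj_idx,                      # CSR astro -> astro neighbours
    a_rec, leak, u_rel, kap_g, gamma_half, dec_g,
    k_ip3_dt, dec_ip3, om_acc, d_gj_dt,
    x_ss0, y_max_exc, y_astro,
    theta, act_steps, g_rel_frac, p_half, kap_p, dec_p, p_tonic,
):
    np.random.seed(seed)
    n_exc = e_pre.shape[0]
    n_enc = enc_indptr[n_astro]  # enclosed synapses occupy indices [0, n_enc)

    # pools start at the steady state of noise-driven firing, so recordings
    # begin near the network's operating point rather than fully rested
    r_noise = -math.expm1(-noise)
    x0 = a_rec / (a_rec + leak + u_rel * r_noise)
    x = np.full(n_exc, x0)
    gam = np.zeros(n_exc)
    flux = np.zeros(n_exc)
    ip3 = np.zeros(n_exc)
    ca = np.zeros(n_exc)
    G = np.zeros(n_astro)
    p = np.zeros(n_astro)
    timer = np.zeros(n_astro, dtype=np.int64)
    acc = np.zeros(n_neurons)       # synaptic input accumulated for next step
    dep = np.zeros(n_neurons)       # astrocytic depression for next step
    ca_mean = np.zeros(n_astro)
    ca_post = np.zeros(n_astro)
    spiking = np.zeros(n_neurons, dtype=np.int64)

    raster = np.zeros((n_steps, n_neurons), dtype=np.uint8)
    active_rec = np.zeros((n_steps, n_astro), dtype=np.uint8)
    mean_ca = np.zeros(n_steps)
    mean_glu = np.zeros(n_steps)
    mean_x = np.zeros(n_steps)
    mean_gamma = np.zeros(n_steps)
    mean_p = np.zeros(n_steps)
    one_m_decg = 1.0 - dec_g

    for k in range(n_steps):
        # --- neurons: rate from step k-1 quantities, then Bernoulli draw
        n_spk = 0
        for i in range(n_neurons):
            lam = noise + acc[i] - dep[i]
            if lam < 0.0:
                lam = 0.0
            u = np.random.random()
            if u < -math.expm1(-lam):
                raster[k, i] = 1
                spiking[n_spk] = i
                n_spk += 1
            acc[i] = 0.0

        # --- dense pool/receptor relaxation (branch-free, vectorizable);
        #     the continuous leak is transporter uptake into the astrocyte
        #     store, recorded in `flux`
        for m in range(n_exc):
            xm = x[m]
            flux[m] = leak * xm
            x[m] = xm + a_rec * (1.0 - xm) - flux[m]
            gam[m] = gam[m] * one_m_decg

        # --- sparse spike-triggered release; mGluR occupancy responds to the
        #     phasic bolus with a saturating dose-response
        for s in range(n_spk):
            i = spiking[s]
            for e in range(e_indptr[i], e_indptr[i + 1]):
                m = e_syn[e]
                rho = u_rel * x[m]
                x[m] -= rho
                g0 = gam[m] / one_m_decg
                gam[m] = (g0 + kap_g * rho / (rho + gamma_half) * (1.0 - g0)) \
                    * one_m_decg
                if m < n_enc:
                    flux[m] += rho

        # --- enclosed synapses: IP3 production and Ca relaxation (dense)
        for m in range(n_enc):
            im = ip3[m] + k_ip3_dt * gam[m] - dec_ip3 * ip3[m]
            ip3[m] = im
            ca[m] = ca[m] + om_acc * (im - ca[m])

        # --- astrocyte level: uptake, mean Ca, gap-junction diffusion
        for a in range(n_astro):
            s_ca = 0.0
            s_fx = 0.0
            for m in range(enc_indptr[a], enc_indptr[a + 1]):
                s_ca += ca[m]
                s_fx += flux[m]
            G[a] += s_fx
            ne = enc_indptr[a + 1] - enc_indptr[a]
            ca_mean[a] = s_ca / ne if ne > 0 else 0.0
        tot_ca = 0.0
        for a in range(n_astro):
            s_gj = 0.0
            for e in range(gj_indptr[a], gj_indptr[a + 1]):
                s_gj += ca_mean[gj_idx[e]] - ca_mean[a]
            delta = d_gj_dt * s_gj
            if delta != 0.0:
                for m in range(enc_indptr[a], enc_indptr[a + 1]):
                    ca[m] += delta
            ca_post[a] = ca_mean[a] + delta
            tot_ca += ca_post[a]

        # --- activation windows
        for a in range(n_astro):
            ne = enc_indptr[a + 1] - enc_indptr[a]
            if timer[a] > 0:
                timer[a] -= 1
                if timer[a] == 0:
                    # window end: ER depletion, reset synapse-level Ca/IP3
                    for m in range(enc_indptr[a], enc_indptr[a + 1]):
                        ca[m] = 0.0
                        ip3[m] = 0.0
                        dep[e_post[m]] -= y_astro
            elif ne > 0 and ca_post[a] >= theta:
                # rising edge: release stored glutamate, potentiate, depress
                timer[a] = act_steps
                rel = g_rel_frac * G[a]
                G[a] -= rel
                # saturating transfer: presynaptic receptors saturate for
                # large gliotransmitter boluses
                p[a] += kap_p * rel / (rel + p_half)
                for m in range(enc_indptr[a], enc_indptr[a + 1]):
                    dep[e_post[m]] += y_astro
            if timer[a] > 0:
                active_rec[k, a] = 1
            p[a] *= 1.0 - dec_p

        if n_astro > 0:
            mean_ca[k] = tot_ca / n_astro
            s_g = 0.0
            s_p = 0.0
            for a in range(n_astro):
                s_g += G[a]
                s_p += p[a]
            mean_glu[k] = s_g / n_astro
            mean_p[k] = s_p / n_astro
        if n_exc > 0:
            s_x = 0.0
            s_gm = 0.0
            for m in range(n_exc):
                s_x += x[m]
                s_gm += gam[m]
            mean_x[k] = s_x / n_exc
            mean_gamma[k] = s_gm / n_exc

        # --- effective weights of spiking neurons feed the next step
        for s in range(n_spk):
            i = spiking[s]
            for e in range(e_indptr[i], e_indptr[i + 1]):
                msyn = e_syn[e]
                aa = e_astro[msyn]
                # tonic gliotransmission: astrocyte contact strengthens
                # its enclosed synapse even between activation events
                pa = p_tonic + p[aa] if aa >= 0 else 0.0
                y = e_w[msyn] * (1.0 + pa) * x[msyn] / x_ss0
                if y > y_max_exc:
                    y = y_max_exc
                acc[e_post[msyn]] += y
            for e in range(i_indptr[i], i_indptr[i + 1]):
                acc[i_post[e]] += i_w[e]

        if k % 400 == 0:
            chk = tot_ca
            for i in range(n_neurons):
                chk += acc[i]
            if not math.isfinite(chk):
                return raster, active_rec, mean_ca, mean_glu, mean_x, mean_gamma, mean_p, k

    return raster, active_rec, mean_ca, mean_glu, mean_x, mean_gamma, mean_p, -1


def _csr(groups: np.ndarray, n_groups: int, order_values: np.ndarray):
    """Build (indptr, indices) sorting ``order_values`` by ``groups``."""
    order = np.argsort(groups, kind="stable")
    counts = np.bincount(groups, minlength=n_groups)
    indptr = np.zeros(n_groups + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    return indptr, order_values[order].astype(np.int64)


def _pack(topology: NetworkTopology, params: SimulationParams):
    """Split the topology into kernel arrays, rescaling base weights to the
    simulation's weight bounds.

    Excitatory synapses are reordered so that enclosed synapses come first,
    grouped contiguously by their enclosing astrocyte; the kernel's
    per-astrocyte passes then run over contiguous slices.
    """
    sign = topology.neuron_sign[topology.syn_pre]
    exc = sign > 0
    scale_e = params.y_max_exc / topology.build_y_max_exc
    scale_i = params.y_max_inh / topology.build_y_max_inh

    e_pre = topology.syn_pre[exc].astype(np.int64)
    e_post = topology.syn_post[exc].astype(np.int64)
    e_w = topology.syn_weight[exc] * scale_e
    e_astro = topology.syn_astro[exc].astype(np.int64)

    # enclosed-first ordering, grouped by astrocyte (stable within groups)
    sort_key = np.where(e_astro >= 0, e_astro, topology.n_astro)
    order = np.argsort(sort_key, kind="stable")
    e_pre, e_post, e_w, e_astro = (
        e_pre[order], e_post[order], e_w[order], e_astro[order]
    )

    i_pre = topology.syn_pre[~exc].astype(np.int64)
    i_post_all = topology.syn_post[~exc].astype(np.int64)
    i_w_all = topology.syn_weight[~exc] * scale_i

    n = topology.n_neurons
    m = topology.n_astro
    n_exc = e_pre.size

    e_indptr, e_syn = _csr(e_pre, n, np.arange(n_exc))
    order = np.argsort(i_pre, kind="stable")
    i_counts = np.bincount(i_pre, minlength=n) if i_pre.size else np.zeros(n, np.int64)
    i_indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(i_counts, out=i_indptr[1:])
    i_post = i_post_all[order]
    i_w = i_w_all[order]

    # enclosed synapses are the contiguous prefix, grouped by astrocyte
    enc_counts = np.bincount(e_astro[e_astro >= 0], minlength=m) \
        if (e_astro >= 0).any() else np.zeros(m, dtype=np.int64)
    enc_indptr = np.zeros(m + 1, dtype=np.int64)
    np.cumsum(enc_counts, out=enc_indptr[1:])

    deg = np.concatenate([topology.gap_a, topology.gap_b])
    nbr = np.concatenate([topology.gap_b, topology.gap_a])
    if deg.size:
        gj_indptr, gj_idx = _csr(deg.astype(np.int64), m, nbr.astype(np.int64))
    else:
        gj_indptr = np.zeros(m + 1, dtype=np.int64)
        gj_idx = np.zeros(0, dtype=np.int64)

    return (e_pre, e_post, e_w, e_astro, e_indptr, e_syn,
            i_indptr, i_post, i_w, enc_indptr, gj_indptr, gj_idx)


def run_simulation(
    topology: NetworkTopology,
    params: SimulationParams,
    engine: str = "numba",
) -> SimTrace:
    """Run the full network simulation; reproducible from (topology, params).

    ``engine`` selects the fused compiled kernel (default) or a slow NumPy
    reference implementation that performs the identical update sequence
    and consumes the identical random stream (used for validation).
    """
    (e_pre, e_post, e_w, e_astro, e_indptr, e_syn,
     i_indptr, i_post, i_w, enc_indptr, gj_indptr, gj_idx) = _pack(
        topology, params
    )
    dt = params.dt
    args = (
        params.n_steps, topology.n_neurons, topology.n_astro, params.seed,
        params.noise,
        e_pre, e_post, e_w, e_astro, e_indptr, e_syn,
        i_indptr, i_post, i_w, enc_indptr, gj_indptr, gj_idx,
        dt * params.alpha_rec, dt * params.w_f * params.omega_f,
        params.u_release, params.kappa_gamma, params.gamma_half,
        dt * params.w_g * params.omega_g,
        dt * params.k_ip3, dt * params.omega_ip3, params.omega_acc,
        dt * params.d_gj,
        params.x_ss0, params.y_max_exc, params.y_astro,
        params.theta_ca, params.active_steps, params.g_release,
        params.p_half, params.kappa_p, dt * params.omega_p, params.p_tonic,
    )
    if engine == "numba":
        out = _sim_kernel(*args)
    elif engine == "reference":
        out = _sim_kernel.py_func(*args)
    else:
        raise ValueError(f"unknown engine: {engine!r}")
    raster, active, mean_ca, mean_glu, mean_x, mean_gamma, mean_p, bad = out
    if bad >= 0:
        raise RuntimeError(f"non-finite network state at step {bad}")
    return SimTrace(raster, active, mean_ca, mean_glu, mean_x, mean_gamma, mean_p,
                    dt, params)
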