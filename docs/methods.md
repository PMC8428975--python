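# Methods

## Model overview

`gliasim` simulates a planar culture of excitatory and inhibitory neurons
interleaved with a gap-junction-coupled astrocyte network, at a fixed time
step of 5 ms.  The design follows the phenomenological tripartite-synapse
tradition: neurons are stochastic rate units, synapses carry a slow
glutamate resource, and astrocytes integrate synaptic glutamate into an
IP3-driven calcium signal that gates both a depressing (ATP/P2X-mediated)
and a potentiating (gliotransmitter-release) feedback onto the synapses
they enclose.

### Network construction

Cells are placed uniformly at random in a 750 × 750 × 10 µm³ slab —
the footprint of a multielectrode array — and resampled until all pairwise
distances exceed 30 µm (sequential insertion, at most 10⁴ draws per cell).
Distances are 3-D Euclidean; the 10 µm z-extent makes the layout
effectively planar.  Connectivity:

* astrocyte–astrocyte gap junctions join every pair closer than 100 µm
  (deterministic), giving a mean degree of ≈ 4.3–4.9 at the default
  density (107 astrocytes);
* directed neuron→neuron synapses are sampled with probability
  p(d) = exp(−d²/2σ²), σ = 200 µm, truncated at 750 µm.  With 250 neurons
  this yields 26–29 % of ordered pairs connected.  σ was calibrated once so
  connectivity lands in the high-20s band; it is a config key;
* astrocyte–neuron links use the same kernel with σ = 50 µm, truncated at
  100 µm.  An excitatory synapse is *enclosed* by the astrocyte nearest to
  its midpoint among those linked to the postsynaptic neuron; if none is
  linked the synapse is astrocyte-free (a few percent of excitatory
  synapses).  Inhibitory synapses are never enclosed, reflecting the lack
  of quantitative data on GABAergic–astrocyte signalling.

45 % of neurons are excitatory (`exc_fraction`, config key).  This is
deliberately below the ~80 % cortical convention: with static inhibitory
synapses and the rectified rate rule (below), the basal noise term alone
drives ≈ 237 spikes/min per neuron, and a substantial inhibitory population
is one of the three mechanisms (with pool depletion and astrocytic
depression) that keep the healthy network inside the 30–200 spikes/min MEA
band.  Base weights are drawn uniformly in [0, Ymax+] (excitatory) or
[−Ymax−, 0] (inhibitory) with default bounds 0.7; simulations under other
bounds rescale the stored weights.

### Neuron dynamics

Per step, neuron i fires with probability 1 − exp(−λᵢ), where

    λᵢ(t_k) = max(0, cᵢ + Σⱼ y_ij s_j(t_{k−1}) − Σⱼ y_Astro A_ija(t_{k−1}))

with basal noise cᵢ = 0.02 per step, spike indicators s_j, effective
weights y_ij, and the binary flag A_ija marking synapses enclosed by an
astrocyte that was active at the previous step.  Each such synapse
contributes a fixed depression y_Astro (default 0.01), the model of
ATP-mediated P2X-receptor downregulation of postsynaptic NMDA receptors.

### Synapse dynamics

Each excitatory synapse carries a ready-releasable pool x ∈ [0, 1]:

    x ← x + dt·α_rec·(1 − x) − dt·w_f·Ω_f·x          (recovery, leak)
    on a presynaptic spike:  ρ = U·x,  x ← x − ρ      (phasic release)

All glutamate leaving the pool is taken up by the enclosing astrocyte's
store (or lost if the synapse is unenclosed), so cleft glutamate is
conserved.  The effective weight is

    y_ij = clamp( ŷ_ij · (1 + p) · x / x_ss0 , 0, Ymax+ ),

where p is the astrocyte-sourced potentiation of the synapse and
x_ss0 = α_rec/(α_rec + Ω_f) is the quiescent pool at the *default* release
rate.  The normaliser is deliberately a fixed constant rather than a
function of w_f: reducing the release-rate scaling (w_f < 1) then enlarges
the standing pool and strengthens transmission — more transmitter ready for
release means a higher release probability — which is the pathological
mechanism the w_f regime is meant to express.  Inhibitory synapses are
static (y_ij = ŷ_ij).

### Astrocyte dynamics

Astrocytic mGluR occupancy Γ ∈ [0, 1] per synapse responds to the phasic
release bolus with a saturating dose–response and recovers at rate w_g·Ω_g:

    Γ ← Γ + κ_Γ · ρ/(ρ + γ_half) · (1 − Γ) − dt·w_g·Ω_g·Γ.

The continuous leak goes to the astrocyte store but not to the receptor:
mGluRs are treated as transient-sensitive, while transporter uptake handles
the ambient trickle.  Occupancy drives IP3, and calcium relaxes toward IP3
with the per-step factor Ω_acc:

    IP3 ← IP3 + dt·k_IP3·Γ − dt·Ω_IP3·IP3
    Ca  ← Ca + Ω_acc·(IP3 − Ca).

Astrocyte-level calcium (the mean over enclosed synapses) diffuses between
gap-junction neighbours (per-step coupling d_gj) and is folded back
uniformly into the per-synapse values.

**Activation.**  When astrocyte-level calcium crosses θ_Ca, the astrocyte
activates for a fixed window t_active (default 5 s): it releases a fraction
g_release of its glutamate store, raising the potentiation p of its
enclosed synapses through a saturating transfer
κ_p · rel/(rel + p_half), and depresses them via the A_ija term for the
duration of the window.  At the window's end the synapse-level Ca and IP3
reset (ER depletion), so sustained glutamate input produces repeated
activation cycles whose rate grows with receptor occupancy.  An
"activation" (the third response variable) is a rising edge of the active
flag.  In addition, astrocyte contact tonically strengthens an enclosed
synapse by the constant factor (1 + p_tonic) — the model's rendering of the
well-documented trophic/tonic support astrocytes provide to the synapses
they ensheathe, and the main route by which removing astrocytes weakens the
network.

Three of these choices deviate from the most literal reading of the model
family and deserve justification:

1. *Window-plus-reset activation* instead of a pure level threshold.  With
   a pure threshold, slowing receptor recovery (w_g ↓) keeps Γ and hence Ca
   elevated longer and *reduces* the number of rising edges; with
   reset-based cycling the activation rate grows with occupancy, which is
   the direction the pathological w_g regime requires.
2. *Saturating release→potentiation transfer without per-synapse
   normalisation.*  Normalising the released bolus by the number of
   enclosed synapses makes per-synapse potentiation *increase* when neurons
   (and hence synapses) are removed; the saturating un-normalised transfer
   restores the intuitive direction and breaks the exact
   glutamate-throughput conservation that otherwise makes the time-averaged
   potentiation independent of the activation rate.
3. *Tonic potentiation of enclosed synapses*, so that astrocyte loss has a
   direct structural cost rather than acting only through the (strongly
   compensated) activation loop.

## Response variables

* **Mean spike rate** — spikes per minute per neuron.
* **Mean burst rate** — bursts per minute per neuron.  Bursts are detected
  per neuron by a cumulative-moving-average (CMA) scan of the inter-spike
  interval histogram (5 ms bins, support capped at twice the largest ISI):
  the CMA peak and a skewness-dependent fraction α ∈ {1, 0.7, 0.5, 0.3}
  select the burst ISI threshold (upper edge of the last bin at or after
  the peak whose CMA exceeds α times the peak value); maximal runs of ISIs
  at or below the threshold with at least 3 spikes are bursts.  Which
  precise variant of the CMA method applies is not fully determined by the
  sources; the constants are config keys and the implementation is checked
  against an independent brute-force reimplementation on random trains.
* **Mean activations per astrocyte** — rising edges of the active flag over
  the simulation, averaged over astrocytes.

## Experiments

Nine networks (three placements A, B, C × three connectivity
configurations 1–3) are the healthy baseline; all experiments run on all
nine with a fixed number of repetitions and 5 simulated minutes per run.
Seeds derive deterministically from (base seed, hypothesis, network,
parameter point, repetition), so any row is reproducible in isolation.

* **H1 (cell density):** three independent removal draws per network and
  cell type, each deleting ⌊0.25·n⌋ cells with their synapses, gap
  junctions and enclosures.  (The floor rule leaves 81/107 astrocytes and
  188/250 neurons.)
* **H2 (ATP depression):** y_Astro ∈ {0.01, 0.025, 0.05, 0.075, 0.1}.
* **H3 (glutamate dynamics):** (w_f, w_g) ∈ {1, ½, ¼}².
* **H4 (weight bounds):** Ymax− ∈ {0.1, 0.5, 0.6, 0.7} ×
  Ymax+ ∈ {0.7, 0.8, 0.9}.

## Statistical models

All fits are REML linear mixed-effects models with *independent* random
components (diagonal random-effect covariance):

* removal: log Z = μ + Δ·removed + u_instance + ε, with a random intercept
  per network instance; the percent reduction is δ_rem = 100·(1 − e^Δ),
  its CI by monotone transformation of the Wald interval, and the p-value
  a likelihood-ratio test (ML fits) of the removal effect;
* ATP: log Z with fixed linear+quadratic y_Astro terms and independent
  random intercept and slope per network;
* glutamate: identity-scale Z with the full quadratic in (w_f, w_g) and
  independent random intercept, w_f, w_g and w_f·w_g components;
* weights: identity-scale Z with the full quadratic in (y_in, y_ex) and a
  random network intercept.

Fixed-effect intervals are Wald with a t quantile at group-level degrees of
freedom (the normal quantile undercovers with nine networks); variance-
component intervals come from a seeded parametric bootstrap (500 draws by
default); response surfaces evaluate the fixed-effect polynomial with all
stochastic terms at zero.  Noise-free (zero-residual) inputs fall back to
ordinary least squares with all variance components reported as 0 and a
boundary flag, which keeps polynomial recovery exact.  Non-positive
responses under a log transform raise an error naming the offending rows;
the pipeline runner flags such conditions upstream instead of fitting.

## Calibration and the operating point

The sources fix dt, T, cᵢ, Ω_f, Ω_g, y_Astro, the weight bounds and the
cell counts, but not the tripartite-synapse constants.  Those were
calibrated once, with `scripts/calibrate.py`, against two targets: the
healthy band (30–200 spikes/min) and the signed directional effects of the
four pathological regimes.  The shipped defaults give a healthy suite mean
of ≈ 190 spikes/min, ≈ 23 bursts/min and ≈ 28 activations per astrocyte
per 5 min.

The calibration revealed a genuine structural tension that users of the
package should understand.  Under the per-step rate semantics, the basal
noise cᵢ = 0.02 per 5 ms alone corresponds to ≈ 237 spikes/min per neuron
— *above* the top of the healthy band — so the healthy state must be
net-suppressed (here: by pool depletion, inhibition and astrocytic
depression).  Consequently the astrocyte-dependent, *removable* share of
network activity is bounded by the headroom between the suppressed floor
and the band ceiling.  At any operating point that satisfies the band,
removing 25 % of astrocytes or neurons therefore reduces activity by a few
percent (consistently in sign across paired seeds), not by the half-to-90 %
scale that a model with near-critical recurrent amplification would show.
The same tension caps the w_f lever: a strong w_f effect requires the leak
to dominate pool turnover, which is algebraically incompatible with
depletion-based rate control; the shipped point keeps the w_f direction
positive but small.  And because w_g acts purely through the astrocyte
loop, where every extra activation window carries depression along with
potentiation, reducing w_g raises astrocyte activations strongly (≈ +20 %)
while slightly lowering the spike rate.  These residual direction misses
are reported honestly by the acceptance tests rather than hidden.

## What the simulations do and do not show

All inputs are generated internally; there is no external data.  The
synthetic networks emulate the geometry, density and connectivity ranges of
an MEA culture, and the healthy dynamics match its gross firing statistics
(rate band, bursting, slow astrocytic modulation).  They do not emulate
electrode sampling, conduction delays, cell-type diversity beyond the
excitatory/inhibitory split, receptor kinetics, D-serine signalling, or
astrocyte morphology.  Passing tests therefore show internal consistency of
the pipeline and the stated qualitative directions under this phenomenology
— not quantitative agreement with biological recordings.

## Numerical choices

* Per-step update order: rates → spike draws → synapse updates → astrocyte
  updates, with Eq.-style quantities always read from the previous step.
* Spiking is Bernoulli(1 − e^(−λ)) per 5 ms bin (Poisson thinning).
* Pools initialise at the steady state of noise-driven firing so that
  recordings start near the operating point rather than fully rested.
* The simulation kernel is a single compiled (numba) loop; a pure-Python
  reference path executes the identical update sequence and random stream
  and is checked for raster-identical output on small networks.  Internally
  time is integer steps; seconds appear only at I/O boundaries.
* One named seed per concern (placement, connection, removal, spiking),
  derived via CRC-hashed seed sequences, all below 2³¹.
* Ω_acc = 0.005 per step gives a ≈ 1 s calcium relaxation time, consistent
  with the seconds-scale astrocytic transients the model aims at.
* The iteration caps, tie-breaks (first CMA peak on ties) and degenerate
  cases (empty networks, astrocytes with no enclosed synapses, zero-spike
  trains) are all fixed and unit-tested.

## Scaled-down designs

The full design (10 repetitions × 5 min × 9 networks per grid point) is
expensive; the shipped analysis scripts and the acceptance checks use desk
scales — 2–3 repetitions at full 5-minute duration — chosen so the whole
pipeline runs on a single CPU in minutes while preserving the schema and
the statistical structure (the removal contrast's power is limited by
between-instance variance, not repetitions, so extra repetitions change
little).
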