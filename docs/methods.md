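# Methods

## Model

The simulator is a discrete-time, rate-based bilateral network of six units:
left/right sensory (`S_L`, `S_R`), central (`C_L`, `C_R`) and motor
(`M_L`, `M_R`) nodes.  All nodes update synchronously,

    x_i(t+1) = tanh( g · net_i(t) ),
    net_i(t) = Σ_j w_ij · x_j(t − d_ij) + I_i(t) + ε_i(t),

so every activity is bounded in (−1, 1), integration is memoryless apart
from the explicit delay lines, and the only state is the recent activity
history (a ring buffer whose depth exceeds the largest delay).  External
task input `I_i` reaches the sensory nodes only.  Noise `ε_i(t)` is
independent zero-mean Gaussian with standard deviation `sigma`, drawn for
**all six nodes** each step; the description of additive node noise does not
restrict it to a subset of nodes, and applying it uniformly avoids a free
choice per node class.

Eight candidate architectures arise from three binary factors:

* **sensory routing** — `S_L→C_L, S_R→C_R` (ipsilateral) or crossed
  (`S_L→C_R, S_R→C_L`);
* **commissural excitation** — reciprocal `C_L↔C_R` excitation present or
  absent; this is the only pathway carrying the long delay `d_long`;
* **local feedback** — a bidirectional within-side `S↔C` loop present or
  absent.

Motor routing is fixed ipsilateral (`C→M` on each side), so laterality
enters only through sensory routing and central interactions.  Reciprocal
inhibition between the central nodes (`w_inh = −I_inhib·w_inhib_scale`,
short delay) is instantiated whenever `I_inhib > 0`, in every architecture:
the grid value 0.0 encodes its absence, so inhibition is a continuous
environmental condition rather than a fourth architectural factor.

### Parameters

| name | default | role |
|---|---|---|
| `w_sc` | 1.0 | sensory→central weight |
| `w_cs` | 0.4 | local feedback weight (both directions) |
| `w_cm` | 1.0 | central→motor weight |
| `w_cc` | 0.7 | excitatory commissural weight |
| `g` | 1.0 | tanh gain |
| `d_short` | 1 step | delay of every non-commissural link |
| `d_long` | 1–20 steps (grid axis) | excitatory commissural delay |
| `sigma` | grid axis | node-noise std |
| `I_inhib` | grid axis | central inhibition strength |
| `kappa` | 1.6 | noise multiplier of the elevated-noise rerun |

All weights are fixed; nothing is learned.  Initial activities and the full
delay history start at zero — a neutral choice whose transient is discarded
by the warmup window.

## Task

The network controls a body position along the lateral (x) axis.  The target
sits at `±1` and flips sign with probability `p_switch = 0.08` per step; its
initial sign is drawn uniformly per trial, which avoids a systematic
left/right bias across repetitions.  The signed tracking error
`e_x = x_target − x_body` drives the sensors through half-wave rectification
blended by the twist `θ`:

    u_L = (1−θ)·max(−e_x,0) + θ·max(+e_x,0),   u_R symmetric,

so `u_L + u_R = |e_x|` identically and θ continuously rotates the error's
lateral code from direct (θ=0) to inverted (θ=1).  The body integrates the
opposed motors, `x_body ← x_body + k_move·(m_R − m_L) + η_x`
(`k_move = 0.55`, process noise std 0.02), and is **not clipped**: under
mis-routed control the error grows without bound at the saturated motor
speed, which is exactly the failure mode the objective must see.

In two-dimensional mode a second (y) axis with its own switching target is
controlled by fixed proportional feedback (`y_body ← y_body + 0.55·e_y + η_y`),
independent of the network.  It adds architecture-independent tracking cost
and makes the task genuinely two-dimensional while keeping lateralized
selection confined to the x axis.

Within a step the order is: target switch → error computation → sensory
drive → synchronous network update → body update using the just-computed
motor activities.  This matches the indexing of the update rules (the body
at `t+1` moves under motors at `t`) and makes `e_x(t) = x_target(t) −
x_body(t)` hold exactly at every recorded row.

### One-dimensional drive

The one-dimensional *selection* scans use a laterality-neutral drive: both
sensors receive the common signed signal `u_L = u_R = e_x/2`.  Under the
rectified directional drive, crossed routing in one dimension is sign-
unstable — the loop feeds the error back with the wrong sign and diverges —
so any objective that sees the dynamics at all would reject contralateral
wiring outright, which contradicts the near-neutral one-dimensional
selection this configuration is meant to exhibit (contralateral solutions
dynamically viable, winning about half the time, with matched-pair objective
values agreeing to a few parts in ten thousand).  With the common drive the
pure routing contrast is exactly exchangeable (swapping the two sensory
noise streams maps one routing onto the other), so neutrality is a symmetry
property rather than a numerical accident.  The directional rectified drive
remains available as the `oned_tracking` configuration, where tracking
performance dominates selection and contralateral routing is suppressed
essentially to zero.

## Objective

Each architecture is scored over the post-warmup window (steps 20–219 of
220) by

    J = λ_track·J_track + λ_effort·J_effort + λ_asym·J_asym
        + λ_delay·J_delay + λ_noise·J_noise

* `J_track` — mean squared tracking error (x, plus y in 2-D);
* `J_effort` — mean `m_L² + m_R²`;
* `J_asym` — mean `(m_L − m_R)²`;
* `J_delay` — `Σ_connections d·|w|·mean_t|x_source|`, penalizing reliance on
  delayed, strong, active pathways;
* `J_noise` — the *increase* in tracking cost when node noise is rescaled to
  `κ·σ` (κ = 1.6) in a paired rerun.  It may be negative.

Baseline weights: `λ_track = 1.0, λ_effort = 0.08, λ_asym = 0.05,
λ_delay = 1.0, λ_noise = 1.0`.  The elevated-noise rerun shares the target
and process-noise streams with the baseline trial and redraws only the node
noise (from an independent substream, scaled to κσ): pairing isolates noise
sensitivity from the task realization and sharply reduces the variance of
`J_noise`.  Only node noise is scaled; process noise is part of the task.

A second preset, `dynamical` (`λ_track = λ_noise = 0`), scores architectures
on delay, effort and asymmetry alone.  It is the preset of the
one-dimensional selection scans, where the laterality-neutral drive makes
tracking performance uninformative about routing (see above); the mean
winning objective it produces (~2) matches the scale those analyses report.

## Scan protocol

A grid cell is `(d_long, sigma, I_inhib, theta)`.  Within a cell all eight
architectures are evaluated on the **same** repetition seeds — the
repetition seed is `SeedSequence((base_seed, d_long, ⌊σ·10⁶⌉, ⌊I·10⁶⌉,
⌊θ·10⁶⌉, rep))`, split into six fixed substreams (x/y target switching,
baseline node noise, elevated node noise, x/y process noise) — so candidates
face identical conditions and scans are reproducible cell-by-cell,
byte-for-byte.  Per architecture J is averaged over repetitions; the winner
is the argmin, with exact ties broken by the fixed enumeration order
(ipsilateral variants first — conservative against the contralateral
headline).  The per-cell `cross` indicator is 1 iff the winner routes
contralaterally; curves report the mean indicator per θ.  A per-repetition
winner fraction is recorded alongside.

Named grids: `oned_exhaustive` (20 delays × 13 noise levels, inhibition
fixed at the mid-grid 0.5 since the 260-cell count leaves no inhibition
axis; 12 reps), `oned_inhibitory` and `oned_tracking` (20×14×6 = 1,680
cells, 10 reps), `twod_baseline` (θ=0), `twod_discrete_twist`
(θ ∈ {0, 1/3, 2/3, 1}) and `twod_dense_twist` (13 θ values ×1,680 = 21,840
cells).  The pairwise comparison contrasts the minimal pure-routing pair
(no commissural excitation, no feedback) per cell and realization on
single-run objectives; ties do not count as contralateral-better.  The
all-four-matched-pairs policy is available as an option but is not the
default because the local-feedback pairs are genuinely asymmetric under a
symmetric drive (crossed routing turns the local loop into a stabilizing
cross-excitation), which would contaminate a comparison meant to isolate
routing.

## Transition point, bootstrap, sensitivity, mechanism

`theta_c` is the 0.5-crossing of the mean cross-frequency curve, located at
the **first** consecutive sample pair lying on opposite sides of 0.5 and
linearly interpolated; a sampled frequency of exactly 0.5 counts as a
crossing at that sample, and a flat 0.5–0.5 pair is reported as degenerate
rather than silently resolved.

The percentile bootstrap resamples the full cell set with replacement
(B = 2000), recomputing the curve and `theta_c` per replicate, globally and
separately per `d_long`; each replicate also yields an ordinary-least-squares
slope of `theta_c(d_long)` over the full delay range (OLS is the default
reading of "a linear slope").  The 95% interval is the 2.5/97.5 percentile
band.  Replicates in which some curve fails to cross 0.5 are excluded from
the quantiles and their count is reported — on the full grids none occur.

The one-factor-at-a-time sensitivity rescales each objective weight to
0.5×/1×/1.5× and re-selects winners **from the stored per-architecture
component means without re-simulation** — valid because J is linear in its
components; at scale 1.0 the re-selection reproduces the original winners
exactly, which the tests assert.

Mechanism metrics compare the required correction `e_x` with the produced
command `u_x = m_R − m_L` over the post-warmup window: temporal mismatch
`mean|e_x − u_x|`, sign alignment (fraction of steps with the same strict
nonzero sign — steps where either quantity is exactly zero count as not
aligned; zeros have measure zero under noise, so the rule only matters for
deterministic traces), and total squared tracking error (a post-warmup sum,
not a mean, so it scales with trace length).  The canonical comparison pair
is the fully-coupled architecture (commissural + feedback) in both routings
at `d_long = 5, σ = 0.05, I_inhib = 0.5`, 5 repetitions with shared seeds.
The published description does not pin down this cell, so mechanism *levels*
are cell-specific; the analyses here rely only on the sign structure (which
routing has lower mismatch/higher alignment on each side of the transition),
which is robust to the cell choice.

## What the generator emulates — and what it does not

All data are produced by the simulator itself under the study conditions:
fixed weights, the printed grids, T = 220 steps with a 20-step warmup, and
10–12 repetitions per cell at full scale.  The synthetic task captures the
features the architecture question needs — delayed feedback, bounded
nonlinear units, stochastic set-point changes, bilateral competition, and a
parameterized sensorimotor inversion — and nothing else.  It does not
emulate spiking dynamics, conduction-delay heterogeneity, plasticity,
partial decussation, spatial embedding, or any empirical neural recording;
conclusions from passing tests are claims about this abstract control
system, not about anatomy.

## Numerical choices and problem sizes

* All simulation flows through a numba kernel vectorized over trials;
  batched cells share pre-generated input arrays, so the closed loop is a
  deterministic function of the seed and rerunning a scan reproduces its
  CSVs byte-for-byte.
* Ring-buffer depth is `max(d_long) + 2`; unwritten history reads as zero,
  matching the zero initial condition.
* CSV floats are written with 9 significant digits, `.` decimal, no locale
  dependence.
* The reproduction tests and the acceptance script run the two-dimensional
  grids at 4 repetitions per cell (the package's desk-scale protocol; the
  full 10-repetition scans change the transition estimate by less than the
  bootstrap CI width) and the one-dimensional analyses at their full printed
  protocols.  The complete pipeline takes ~2 minutes on one core.
* The sigmoid drawn over cross-frequency curves in figures is cosmetic;
  every inference uses the interpolation rule above.

## Known limitations

* The architecture space is tiny and discrete; graded (partial) decussation
  and learned weights are out of scope.
* The objective is one operationalization of "good control"; the weight
  sensitivity analysis probes moderate rescalings only.
* The one-dimensional selection configuration (common drive + dynamical
  weights) is this package's resolution of an under-specified analysis; the
  directional alternative is provided (`oned_tracking`) and behaves
  qualitatively differently by construction.
* Mechanism metric levels depend on the (unpinned) evaluation cell; only
  their sign structure is treated as a result.
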