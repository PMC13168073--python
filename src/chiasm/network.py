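"""Six-node bilateral network: candidate architectures and delayed dynamics.

The model is a discrete-time nonlinear rate network with six units — left and
right sensory (``S_L``, ``S_R``), central integrative (``C_L``, ``C_R``) and
motor (``M_L``, ``M_R``) nodes.  Candidate architectures differ in three binary
factors: whether sensory input is routed to the same-side or the opposite-side
central node, whether the two central nodes are coupled by an excitatory
commissural connection (the only link carrying the long delay ``d_long``), and
whether a local bidirectional sensory-central loop exists within each side.
Motor routing is always ipsilateral (``C_L -> M_L``, ``C_R -> M_R``), and the
two central nodes compete through reciprocal inhibition whenever the
inhibition strength is nonzero.

Each node updates synchronously as ``x_i(t+1) = tanh(g * net_i(t))`` where
``net_i`` sums delayed synaptic input, external task input (sensory nodes
only) and additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

__all__ = [
    "N_NODES",
    "NODE_NAMES",
    "S_L",
    "S_R",
    "C_L",
    "C_R",
    "M_L",
    "M_R",
    "ArchitectureSpec",
    "ModelParams",
    "Connection",
    "NetworkState",
    "enumerate_architectures",
    "build_connection_table",
    "split_weight_matrices",
    "delay_cost_coefficients",
    "step_states",
]

# Node indices, fixed everywhere (arrays, traces, CSV columns).
S_L, S_R, C_L, C_R, M_L, M_R = range(6)
N_NODES = 6
NODE_NAMES = ("S_L", "S_R", "C_L", "C_R", "M_L", "M_R")

IPSILATERAL = "ipsilateral"
CONTRALATERAL = "contralateral"


@dataclass(frozen=True)
class ArchitectureSpec:
    """One of the eight candidate routing/coupling configurations.

    Parameters
    ----------
    sensory_routing
        ``"ipsilateral"`` (S_L->C_L, S_R->C_R) or ``"contralateral"``
        (S_L->C_R, S_R->C_L).
    commissural_excitation
        Whether the excitatory C_L<->C_R coupling (weight ``w_cc``, delay
        ``d_long``) is present.
    local_feedback
        Whether the bidirectional within-side S<->C loop (weight ``w_cs``)
        is present.

    Motor routing is not a factor: it is always ipsilateral.
    """

    sensory_routing: str
    commissural_excitation: bool
    local_feedback: bool

    def __post_init__(self) -> None:
        if self.sensory_routing not in (IPSILATERAL, CONTRALATERAL):
            raise ValueError(
                f"sensory_routing must be '{IPSILATERAL}' or '{CONTRALATERAL}', "
                f"got {self.sensory_routing!r}"
            )

    @property
    def is_contralateral(self) -> bool:
        return self.sensory_routing == CONTRALATERAL

    @property
    def code(self) -> str:
        """Three-character code used in CSV outputs, e.g. ``"iC-"``.

        First char: ``i``/``c`` sensory routing; second: ``C`` if commissural
        excitation else ``-``; third: ``L`` if local feedback else ``-``.
        """
        return (
            ("c" if self.is_contralateral else "i")
            + ("C" if self.commissural_excitation else "-")
            + ("L" if self.local_feedback else "-")
        )


def enumerate_architectures() -> list[ArchitectureSpec]:
    """All 8 candidate architectures in the canonical tie-break order.

    Ipsilateral variants come first; within each routing, architectures are
    ordered by (commissural_excitation, local_feedback) with absent before
    present.  Index 0 is therefore the bare ipsilateral feed-forward chain.
    This enumeration order is the deterministic tie-break used when two
    architectures attain exactly the same objective value.
    """
    archs = []
    for routing in (IPSILATERAL, CONTRALATERAL):
        for commissural in (False, True):
            for feedback in (False, True):
                archs.append(ArchitectureSpec(routing, commissural, feedback))
    return archs


@dataclass(frozen=True)
class ModelParams:
    """Connection weights, delays, gain and noise constants.

    Defaults are the fixed values used throughout all scans; only ``d_long``,
    ``sigma`` and ``i_inhib`` are varied on scan grids.

    Attributes
    ----------
    w_sc : sensory-to-central projection weight.
    w_cs : local within-side sensory-central feedback weight.
    w_cm : central-to-motor projection weight.
    w_cc : excitatory commissural weight.
    g : gain of the tanh activation.
    d_short : delay (steps) of every connection except excitatory commissural.
    d_long : delay (steps) of the excitatory commissural coupling, 1..20.
    sigma : std of the per-node additive Gaussian noise.
    i_inhib : interhemispheric inhibition strength (>= 0); 0 means absent.
    w_inhib_scale : scale factor of the inhibitory weight.
    kappa : noise multiplier for the elevated-noise rerun (noise-sensitivity
        cost).
    """

    w_sc: float = 1.0
    w_cs: float = 0.4
    w_cm: float = 1.0
    w_cc: float = 0.7
    g: float = 1.0
    d_short: int = 1
    d_long: int = 5
    sigma: float = 0.05
    i_inhib: float = 0.5
    w_inhib_scale: float = 1.0
    kappa: float = 1.6

    def __post_init__(self) -> None:
        if int(self.d_short) != self.d_short or self.d_short < 1:
            raise ValueError(f"d_short must be an integer >= 1, got {self.d_short}")
        if int(self.d_long) != self.d_long or self.d_long < 1:
            raise ValueError(f"d_long must be an integer >= 1, got {self.d_long}")
        if self.i_inhib < 0:
            raise ValueError(f"i_inhib must be >= 0, got {self.i_inhib}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")

    @property
    def w_inh(self) -> float:
        """Effective inhibitory commissural weight (<= 0)."""
        return -self.i_inhib * self.w_inhib_scale

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Connection:
    """A directed delayed connection ``source -> target``."""

    source: int
    target: int
    weight: float
    delay: int

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("self-connections are not allowed")
        if self.delay < 1:
            raise ValueError(f"delay must be >= 1, got {self.delay}")


def build_connection_table(
    arch: ArchitectureSpec, params: ModelParams
) -> list[Connection]:
    """Instantiate the connection list for one architecture.

    The table contains: two sensory->central links (crossed iff contralateral),
    four local feedback links iff ``local_feedback``, two excitatory
    commissural links (the only ones with delay ``d_long``) iff
    ``commissural_excitation``, two inhibitory commissural links iff
    ``i_inhib > 0``, and two always-ipsilateral central->motor links.
    """
    p = params
    ds, dl = int(p.d_short), int(p.d_long)
    table: list[Connection] = []
    if arch.is_contralateral:
        table.append(Connection(S_L, C_R, p.w_sc, ds))
        table.append(Connection(S_R, C_L, p.w_sc, ds))
    else:
        table.append(Connection(S_L, C_L, p.w_sc, ds))
        table.append(Connection(S_R, C_R, p.w_sc, ds))
    if arch.local_feedback:
        # bidirectional within-side loop on each side
        table.append(Connection(S_L, C_L, p.w_cs, ds))
        table.append(Connection(C_L, S_L, p.w_cs, ds))
        table.append(Connection(S_R, C_R, p.w_cs, ds))
        table.append(Connection(C_R, S_R, p.w_cs, ds))
    if arch.commissural_excitation:
        table.append(Connection(C_L, C_R, p.w_cc, dl))
        table.append(Connection(C_R, C_L, p.w_cc, dl))
    if p.i_inhib > 0:
        table.append(Connection(C_L, C_R, p.w_inh, ds))
        table.append(Connection(C_R, C_L, p.w_inh, ds))
    table.append(Connection(C_L, M_L, p.w_cm, ds))
    table.append(Connection(C_R, M_R, p.w_cm, ds))
    return table


def split_weight_matrices(
    table: Iterable[Connection], d_short: int, d_long: int
) -> tuple[np.ndarray, np.ndarray]:
    """Split a connection table into short-delay and long-delay weight matrices.

    Returns ``(w_short, w_long)``, each ``(6, 6)`` with ``W[target, source]``
    summed over parallel links.  Every connection must carry either ``d_short``
    or ``d_long``; this is the form consumed by the vectorized simulator.
    """
    w_short = np.zeros((N_NODES, N_NODES))
    w_long = np.zeros((N_NODES, N_NODES))
    for c in table:
        if c.delay == d_short:
            w_short[c.target, c.source] += c.weight
        elif c.delay == d_long:
            w_long[c.target, c.source] += c.weight
        else:
            raise ValueError(
                f"connection delay {c.delay} is neither d_short={d_short} "
                f"nor d_long={d_long}"
            )
    return w_short, w_long


def delay_cost_coefficients(table: Iterable[Connection]) -> np.ndarray:
    """Per-source-node coefficients ``c_j = sum over links from j of d*|w|``.

    The delay cost is ``sum_j c_j * mean_t |x_j(t)|``; precomputing ``c``
    lets scans evaluate it from accumulated mean absolute activities.
    """
    c = np.zeros(N_NODES)
    for conn in table:
        c[conn.source] += conn.delay * abs(conn.weight)
    return c


@dataclass
class NetworkState:
    """Activity ring buffer for explicit single-step updates.

    ``history`` has shape ``(depth, 6)``; ``history[(t - d) % depth]`` holds
    the activity ``d`` steps in the past.  Depth must exceed the maximum
    delay in the connection table.  All history starts at zero (the neutral
    initial condition; the warmup window discards its transient).
    """

    depth: int
    t: int = 0
    history: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("history depth must be >= 2")
        self.history = np.zeros((self.depth, N_NODES))

    def delayed(self, d: int) -> np.ndarray:
        """Activities ``d`` steps before the next update (d >= 1)."""
        if d >= self.depth:
            raise ValueError(f"delay {d} exceeds history depth {self.depth}")
        return self.history[(self.t - d) % self.depth]

    @property
    def current(self) -> np.ndarray:
        """Most recently written activities (zeros before the first step)."""
        return self.history[(self.t - 1) % self.depth]


def step_states(
    state: NetworkState,
    table: Iterable[Connection],
    external_input: np.ndarray,
    noise_draws: np.ndarray,
    g: float = 1.0,
) -> NetworkState:
    """Advance the network one step (synchronous update), in place.

    ``net_i = sum_j w_ij x_j(t - d_ij) + I_i + eps_i`` followed by
    ``x_i <- tanh(g * net_i)``.  External input may only target the sensory
    nodes; all ``net_i`` are computed from the pre-update history.
    """
    external_input = np.asarray(external_input, dtype=float)
    noise_draws = np.asarray(noise_draws, dtype=float)
    if external_input.shape != (N_NODES,) or noise_draws.shape != (N_NODES,):
        raise ValueError("external_input and noise_draws must have shape (6,)")
    if np.any(external_input[C_L:] != 0.0):
        raise ValueError("external input may only target sensory nodes S_L, S_R")
    net = external_input + noise_draws
    for c in table:
        net[c.target] += c.weight * state.delayed(c.delay)[c.source]
    state.history[state.t % state.depth] = np.tanh(g * net)
    state.t += 1
    return state
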