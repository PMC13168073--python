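"""Stochastic tracking task, twist-parameterized sensory mapping, body dynamics.

The network controls a body position along the lateral (x) axis, tracking a
target whose sign flips stochastically between ``+amp`` and ``-amp``.  The
signed tracking error ``e_x = x_target - x_body`` is split by half-wave
rectification into nonnegative left/right sensory drives; the twist parameter
``theta`` blends the direct assignment (``theta = 0``: the right sensor sees
rightward error) with the fully inverted one (``theta = 1``).  For every
``theta`` the drives conserve ``u_L + u_R = |e_x|``.

In two-dimensional mode a second, orthogonal (y) axis is tracked by a fixed
proportional controller that is independent of the network; it contributes
tracking cost but no lateralized control, so architecture selection acts
through the x axis only.

Each trial's randomness is split into six independent substreams (x/y target
switching, baseline node noise, elevated node noise, x/y process noise) so
that the elevated-noise rerun used by the noise-sensitivity cost shares its
task realization with the baseline run.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import _engine
from .network import (
    M_L,
    M_R,
    N_NODES,
    NODE_NAMES,
    ArchitectureSpec,
    ModelParams,
    build_connection_table,
    split_weight_matrices,
)

__all__ = [
    "ONE_D",
    "TWO_D",
    "TaskParams",
    "TrialInputs",
    "SimulationTrace",
    "update_target",
    "twist_inputs",
    "update_body_x",
    "update_body_y",
    "simulate",
    "run_trial",
]

ONE_D = "one_d"
TWO_D = "two_d"

DRIVE_TWIST_NAME = "twist"
DRIVE_COMMON_NAME = "common"
_DRIVE_CODES = {DRIVE_TWIST_NAME: _engine.DRIVE_TWIST,
                DRIVE_COMMON_NAME: _engine.DRIVE_COMMON}

SeedLike = Union[int, np.random.SeedSequence]

# Fixed order of the per-trial random substreams.
STREAM_TARGET_X, STREAM_TARGET_Y, STREAM_NODE_NOISE, STREAM_NODE_NOISE_HIGH, \
    STREAM_PROC_X, STREAM_PROC_Y = range(6)
N_STREAMS = 6


@dataclass(frozen=True)
class TaskParams:
    """Task constants for the tracking environment.

    Attributes
    ----------
    x_target_amp, y_target_amp : target magnitudes (the target is ``+-amp``).
    p_switch, p_switch_y : per-step sign-flip probabilities.
    k_move : gain converting net motor drive ``m_R - m_L`` into body motion.
    k_y : proportional feedback gain of the y-axis controller.
    proc_noise_x, proc_noise_y : std of additive body process noise.
    theta : twist in [0, 1] blending direct and inverted sensory mapping.
    dims : ``"one_d"`` or ``"two_d"``.
    drive : sensory encoding of the error.  ``"twist"`` (default) is the
        rectified left/right split blended by ``theta``; ``"common"`` is the
        laterality-neutral broadcast ``u_L = u_R = e_x / 2`` used by the
        one-dimensional selection scans, under which the drive carries no
        lateral information and routing competes on dynamical cost alone.
    T : total simulated steps per trial.
    warmup : initial steps excluded from every summary statistic.
    """

    x_target_amp: float = 1.0
    y_target_amp: float = 1.0
    p_switch: float = 0.08
    p_switch_y: float = 0.08
    k_move: float = 0.55
    k_y: float = 0.55
    proc_noise_x: float = 0.02
    proc_noise_y: float = 0.02
    theta: float = 0.0
    dims: str = TWO_D
    drive: str = DRIVE_TWIST_NAME
    T: int = 220
    warmup: int = 20

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError(f"theta must lie in [0, 1], got {self.theta}")
        for name in ("p_switch", "p_switch_y"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.dims not in (ONE_D, TWO_D):
            raise ValueError(f"dims must be '{ONE_D}' or '{TWO_D}', got {self.dims!r}")
        if self.drive not in (DRIVE_TWIST_NAME, DRIVE_COMMON_NAME):
            raise ValueError(
                f"drive must be '{DRIVE_TWIST_NAME}' or '{DRIVE_COMMON_NAME}', "
                f"got {self.drive!r}"
            )
        if not 0 <= self.warmup < self.T:
            raise ValueError(f"need 0 <= warmup < T, got warmup={self.warmup}, T={self.T}")

    @property
    def two_d(self) -> bool:
        return self.dims == TWO_D

    def with_(self, **kwargs) -> "TaskParams":
        return replace(self, **kwargs)


def update_target(
    current: float, p: float, rng: np.random.Generator
) -> float:
    """One step of the stochastic target: flip sign with probability ``p``."""
    if rng.random() < p:
        return -current
    return current


def twist_inputs(e_x, theta):
    """Split a signed error into nonnegative (u_L, u_R) drives at twist theta.

    ``u_L = (1-theta)*max(-e_x, 0) + theta*max(+e_x, 0)`` and symmetrically
    for ``u_R``; the pair always satisfies ``u_L + u_R = |e_x|``.
    Accepts scalars or arrays.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0.0) or np.any(theta > 1.0):
        raise ValueError("theta must lie in [0, 1]")
    e_x = np.asarray(e_x, dtype=float)
    ipsi_l = np.maximum(-e_x, 0.0)
    ipsi_r = np.maximum(e_x, 0.0)
    u_l = (1.0 - theta) * ipsi_l + theta * ipsi_r
    u_r = (1.0 - theta) * ipsi_r + theta * ipsi_l
    if u_l.ndim == 0:
        return float(u_l), float(u_r)
    return u_l, u_r


def update_body_x(x_body, m_l, m_r, k_move, eta_x=0.0):
    """Body motion from opposed motors: ``x + k_move*(m_R - m_L) + eta``."""
    return x_body + k_move * (m_r - m_l) + eta_x


def update_body_y(y_body, e_y, k_y, eta_y=0.0, *, dims: str = TWO_D):
    """Proportional y-axis controller: ``y + k_y*e_y + eta`` (two_d only)."""
    if dims != TWO_D:
        raise ValueError("the y-axis controller only exists in two_d mode")
    return y_body + k_y * e_y + eta_y


def _target_series(
    gen: np.random.Generator, amp: float, p: float, T: int
) -> np.ndarray:
    """Pre-generate a target series: random initial sign, then Markov flips."""
    u = gen.random(T)
    steps = np.ones(T)
    steps[0] = 1.0 if u[0] < 0.5 else -1.0
    steps[1:][u[1:] < p] = -1.0
    return amp * np.cumprod(steps)


@dataclass(frozen=True)
class TrialInputs:
    """All pre-generated stochastic inputs of one closed-loop trial.

    The closed loop is a deterministic function of these arrays, which is what
    makes candidate fairness (identical task realization across architectures)
    and the paired elevated-noise rerun exact by construction.
    """

    target_x: np.ndarray          # (T,)
    target_y: Optional[np.ndarray]  # (T,) or None in one_d mode
    node_noise: np.ndarray        # (T, 6), already scaled by its std
    proc_x: np.ndarray            # (T,)
    proc_y: Optional[np.ndarray]  # (T,) or None

    @classmethod
    def draw(
        cls, mp: ModelParams, tp: TaskParams, seed: SeedLike,
        *, high_noise: bool = False,
    ) -> "TrialInputs":
        """Draw inputs from the trial's six fixed substreams.

        With ``high_noise=True`` the node-noise substream is replaced by the
        independent elevated stream scaled to ``kappa * sigma``; the target
        and process-noise substreams are identical to the baseline draw.
        """
        base, high = cls.draw_pair(mp, tp, seed)
        return high if high_noise else base

    @classmethod
    def draw_pair(
        cls, mp: ModelParams, tp: TaskParams, seed: SeedLike
    ) -> tuple["TrialInputs", "TrialInputs"]:
        """Draw the (baseline, elevated-noise) input pair for one trial."""
        if isinstance(seed, np.random.SeedSequence):
            # rebuild so repeated draws from the same object are identical
            # (SeedSequence.spawn advances the parent's spawn counter)
            ss = np.random.SeedSequence(entropy=seed.entropy,
                                        spawn_key=seed.spawn_key)
        else:
            ss = np.random.SeedSequence(seed)
        children = ss.spawn(N_STREAMS)
        gens = [np.random.default_rng(c) for c in children]
        T = tp.T
        tx = _target_series(gens[STREAM_TARGET_X], tp.x_target_amp, tp.p_switch, T)
        nn = gens[STREAM_NODE_NOISE].standard_normal((T, N_NODES)) * mp.sigma
        nn_high = gens[STREAM_NODE_NOISE_HIGH].standard_normal((T, N_NODES)) * (
            mp.kappa * mp.sigma
        )
        px = gens[STREAM_PROC_X].standard_normal(T) * tp.proc_noise_x
        if tp.two_d:
            ty = _target_series(gens[STREAM_TARGET_Y], tp.y_target_amp, tp.p_switch_y, T)
            py = gens[STREAM_PROC_Y].standard_normal(T) * tp.proc_noise_y
        else:
            ty = None
            py = None
        base = cls(tx, ty, nn, px, py)
        high = cls(tx, ty, nn_high, px, py)
        return base, high

    def mirrored(self) -> "TrialInputs":
        """The left/right mirror image: x axis negated, L/R noise swapped."""
        swap = [1, 0, 3, 2, 5, 4]
        return TrialInputs(
            target_x=-self.target_x,
            target_y=self.target_y,
            node_noise=self.node_noise[:, swap],
            proc_x=-self.proc_x,
            proc_y=self.proc_y,
        )


@dataclass(frozen=True)
class SimulationTrace:
    """Full per-step record of one closed-loop trial.

    ``x_body``/``y_body`` are the positions the step's error was computed
    from, so ``e_x(t) = x_target(t) - x_body(t)`` holds exactly at every row;
    the body moves after the step's motor update.  ``nodes[t]`` holds the six
    activities in :data:`chiasm.network.NODE_NAMES` order.
    """

    arch: ArchitectureSpec
    theta: float
    warmup: int
    x_target: np.ndarray
    x_body: np.ndarray
    u_l: np.ndarray
    u_r: np.ndarray
    nodes: np.ndarray
    y_target: Optional[np.ndarray] = None
    y_body: Optional[np.ndarray] = None

    @property
    def T(self) -> int:
        return len(self.x_target)

    @property
    def e_x(self) -> np.ndarray:
        return self.x_target - self.x_body

    @property
    def e_y(self) -> Optional[np.ndarray]:
        if self.y_target is None:
            return None
        return self.y_target - self.y_body

    @property
    def m_l(self) -> np.ndarray:
        return self.nodes[:, M_L]

    @property
    def m_r(self) -> np.ndarray:
        return self.nodes[:, M_R]

    @property
    def u_x(self) -> np.ndarray:
        """Produced lateral motor command ``m_R - m_L``."""
        return self.m_r - self.m_l

    @property
    def two_d(self) -> bool:
        return self.y_target is not None

    def post(self, series: np.ndarray) -> np.ndarray:
        """Post-warmup view of a per-step series."""
        return series[self.warmup:]

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-step DataFrame (the trace CSV format)."""
        data = {
            "t": np.arange(self.T),
            "x_target": self.x_target,
            "x_body": self.x_body,
            "e_x": self.e_x,
        }
        if self.two_d:
            data["y_target"] = self.y_target
            data["y_body"] = self.y_body
            data["e_y"] = self.e_y
        data["u_L"] = self.u_l
        data["u_R"] = self.u_r
        for i, name in enumerate(NODE_NAMES):
            data[name] = self.nodes[:, i]
        data["u_x"] = self.u_x
        return pd.DataFrame(data)


def _zeros_if_none(arr: Optional[np.ndarray], T: int) -> np.ndarray:
    return np.zeros(T) if arr is None else np.asarray(arr, dtype=float)


def simulate(
    arch: ArchitectureSpec,
    mp: ModelParams,
    tp: TaskParams,
    inputs: TrialInputs,
) -> SimulationTrace:
    """Run one closed-loop trial on explicit pre-generated inputs."""
    table = build_connection_table(arch, mp)
    w_short, w_long = split_weight_matrices(table, mp.d_short, mp.d_long)
    T = tp.T
    tx = np.asarray(inputs.target_x, dtype=float)[None, :]
    if tx.shape[1] != T:
        raise ValueError(f"inputs cover {tx.shape[1]} steps, task expects T={T}")
    ty = _zeros_if_none(inputs.target_y, T)[None, :]
    nn = np.asarray(inputs.node_noise, dtype=float)[None, :, :]
    px = np.asarray(inputs.proc_x, dtype=float)[None, :]
    py = _zeros_if_none(inputs.proc_y, T)[None, :]
    nodes, body_x, body_y, u_lr = _engine.batch_traces(
        w_short[None, :, :],
        w_long[None, :, :],
        np.array([mp.d_long], dtype=np.int64),
        np.array([tp.theta], dtype=float),
        tx, ty, nn, px, py,
        mp.g, tp.k_move, tp.k_y, tp.two_d, _DRIVE_CODES[tp.drive],
    )
    return SimulationTrace(
        arch=arch,
        theta=tp.theta,
        warmup=tp.warmup,
        x_target=tx[0],
        x_body=body_x[0],
        u_l=u_lr[0, :, 0],
        u_r=u_lr[0, :, 1],
        nodes=nodes[0],
        y_target=ty[0] if tp.two_d else None,
        y_body=body_y[0] if tp.two_d else None,
    )


def run_trial(
    arch: ArchitectureSpec,
    mp: ModelParams,
    tp: TaskParams,
    seed: SeedLike,
    *,
    high_noise: bool = False,
) -> SimulationTrace:
    """Run one seeded closed-loop trial and return its full trace.

    Deterministic: the same seed yields a bit-identical trace.  With
    ``high_noise=True`` the node noise is the independent elevated stream at
    ``kappa * sigma`` while the task realization (targets, process noise) is
    shared with the baseline trial of the same seed.
    """
    inputs = TrialInputs.draw(mp, tp, seed, high_noise=high_noise)
    return simulate(arch, mp, tp, inputs)
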