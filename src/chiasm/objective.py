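"""Five-component objective for scoring a candidate architecture.

``J = lambda_track*J_track + lambda_effort*J_effort + lambda_asym*J_asym
+ lambda_delay*J_delay + lambda_noise*J_noise`` where, over the post-warmup
window,

* ``J_track``  — mean squared tracking error (``e_x^2``, plus ``e_y^2`` in 2-D),
* ``J_effort`` — mean summed squared motor activity ``m_L^2 + m_R^2``,
* ``J_asym``   — mean squared left/right motor difference,
* ``J_delay``  — sum over connections of ``d_ij * |w_ij| * mean_t |x_j|``,
  penalizing reliance on delayed communication,
* ``J_noise``  — extra tracking cost when node noise is raised to
  ``kappa * sigma`` (may be negative).

The noise-sensitivity term requires a paired rerun of the trial at elevated
noise; the pair shares the target and process-noise streams so that the term
isolates noise sensitivity from the task realization.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Iterable

import numpy as np

from .network import ArchitectureSpec, Connection, ModelParams, build_connection_table
from .task import SeedLike, SimulationTrace, TaskParams, TrialInputs, simulate

__all__ = [
    "ObjectiveWeights",
    "ObjectiveBreakdown",
    "tracking_cost",
    "effort_cost",
    "asym_cost",
    "delay_cost",
    "noise_cost",
    "combine",
    "evaluate_architecture",
]


@dataclass(frozen=True)
class ObjectiveWeights:
    """Weighting coefficients of the combined objective (baseline defaults)."""

    lambda_track: float = 1.0
    lambda_effort: float = 0.08
    lambda_asym: float = 0.05
    lambda_delay: float = 1.0
    lambda_noise: float = 1.0

    # Order must match ObjectiveBreakdown.components / scan component columns.
    names = ("lambda_track", "lambda_effort", "lambda_asym", "lambda_delay",
             "lambda_noise")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.names])

    def scaled(self, name: str, scale: float) -> "ObjectiveWeights":
        """A copy with one coefficient multiplied by ``scale`` (OFAT helper)."""
        if name not in self.names:
            raise ValueError(f"unknown objective weight {name!r}")
        return replace(self, **{name: getattr(self, name) * scale})

    @classmethod
    def baseline(cls) -> "ObjectiveWeights":
        return cls()

    @classmethod
    def preset(cls, name: str) -> "ObjectiveWeights":
        """Named weight presets used by the scan configurations.

        ``"baseline"`` (synonym ``"tracking"``) carries the standard
        coefficients, under which the tracking terms dominate selection
        whenever the sensory drive is directional.  ``"dynamical"`` zeroes
        the tracking and noise-sensitivity weights, scoring architectures on
        delay, effort and asymmetry alone; it is the preset of the
        one-dimensional selection scans, whose laterality-neutral drive makes
        tracking performance uninformative about routing.
        """
        if name in ("baseline", "tracking"):
            return cls.baseline()
        if name == "dynamical":
            return cls(lambda_track=0.0, lambda_noise=0.0)
        raise ValueError(f"unknown objective preset {name!r}")


@dataclass(frozen=True)
class ObjectiveBreakdown:
    """The five cost components, the elevated-noise tracking cost, and J."""

    j_track: float
    j_effort: float
    j_asym: float
    j_delay: float
    j_noise: float
    j_track_high_noise: float
    j: float

    def components(self) -> np.ndarray:
        """Component vector in ObjectiveWeights order."""
        return np.array(
            [self.j_track, self.j_effort, self.j_asym, self.j_delay, self.j_noise]
        )


def _post_len(trace: SimulationTrace) -> int:
    n = trace.T - trace.warmup
    if n <= 0:
        raise ValueError("trace has an empty post-warmup window")
    return n


def tracking_cost(trace: SimulationTrace) -> float:
    """Mean post-warmup squared tracking error (x plus y in two_d mode)."""
    _post_len(trace)
    cost = float(np.mean(trace.post(trace.e_x) ** 2))
    if trace.two_d:
        cost += float(np.mean(trace.post(trace.e_y) ** 2))
    return cost


def effort_cost(trace: SimulationTrace) -> float:
    """Mean post-warmup summed squared motor activity."""
    _post_len(trace)
    return float(np.mean(trace.post(trace.m_l) ** 2 + trace.post(trace.m_r) ** 2))


def asym_cost(trace: SimulationTrace) -> float:
    """Mean post-warmup squared left-right motor difference."""
    _post_len(trace)
    return float(np.mean((trace.post(trace.m_l) - trace.post(trace.m_r)) ** 2))


def delay_cost(table: Iterable[Connection], trace: SimulationTrace) -> float:
    """Sum over connections of ``delay * |weight| * mean_t |x_source|``."""
    _post_len(trace)
    mean_abs = np.mean(np.abs(trace.post(trace.nodes)), axis=0)
    return float(sum(c.delay * abs(c.weight) * mean_abs[c.source] for c in table))


def noise_cost(j_track_baseline: float, j_track_high_noise: float) -> float:
    """Tracking-cost increase under elevated node noise (may be negative)."""
    return j_track_high_noise - j_track_baseline


def combine(weights: ObjectiveWeights, parts: "ObjectiveBreakdown | np.ndarray") -> float:
    """Weighted sum of the five components (the recombination identity)."""
    comps = parts.components() if isinstance(parts, ObjectiveBreakdown) else np.asarray(parts)
    lam = weights.as_array()
    return float(lam @ comps)


def evaluate_architecture(
    arch: ArchitectureSpec,
    mp: ModelParams,
    tp: TaskParams,
    weights: ObjectiveWeights,
    seed: SeedLike,
) -> ObjectiveBreakdown:
    """Score one architecture: a baseline trial plus a paired elevated-noise
    trial (node noise at ``kappa * sigma``, same task realization), then all
    five components and the combined J.
    """
    base_inputs, high_inputs = TrialInputs.draw_pair(mp, tp, seed)
    base = simulate(arch, mp, tp, base_inputs)
    high = simulate(arch, mp, tp, high_inputs)
    table = build_connection_table(arch, mp)
    j_track = tracking_cost(base)
    j_track_high = tracking_cost(high)
    parts = ObjectiveBreakdown(
        j_track=j_track,
        j_effort=effort_cost(base),
        j_asym=asym_cost(base),
        j_delay=delay_cost(table, base),
        j_noise=noise_cost(j_track, j_track_high),
        j_track_high_noise=j_track_high,
        j=np.nan,
    )
    return replace(parts, j=combine(weights, parts))
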