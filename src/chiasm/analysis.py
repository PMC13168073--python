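"""Transition-point estimation, bootstrap, weight sensitivity, mechanism metrics.

The ipsilateral-to-contralateral transition point ``theta_c`` is the twist
value at which the mean contralateral frequency crosses 0.5, located by
linear interpolation between the two sampled theta values straddling 0.5.
Its sampling stability is assessed by a percentile bootstrap over grid cells
(resampling cells with replacement, recomputing the cross-frequency curve and
``theta_c`` per replicate), globally and separately per commissural delay
``d_long``; a per-replicate ordinary-least-squares slope of
``theta_c(d_long)`` quantifies the delay dependence.

Two further analyses probe robustness and mechanism: a one-factor-at-a-time
(OFAT) rescaling of each objective weight, which re-selects winners from the
stored per-architecture component breakdowns without re-simulation (J is
linear in its components), and per-trace mismatch/alignment metrics comparing
the required lateral correction ``e_x`` with the produced motor command
``u_x = m_R - m_L``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .network import ArchitectureSpec, CONTRALATERAL, IPSILATERAL, ModelParams
from .objective import ObjectiveWeights
from .scan import ScanResult, cell_seed_sequence, mean_cross_curve
from .task import SimulationTrace, TaskParams, run_trial

__all__ = [
    "NoCrossingError",
    "TransitionEstimate",
    "BootstrapSummary",
    "estimate_transition",
    "bootstrap_transition",
    "ofat_sensitivity",
    "mechanism_metrics",
    "mechanism_scan",
    "MECHANISM_ARCHS",
]


class NoCrossingError(ValueError):
    """Raised when a cross-frequency curve never straddles 0.5."""


@dataclass(frozen=True)
class TransitionEstimate:
    """Interpolated transition point with its bracketing samples."""

    theta_c: float
    bracket: tuple[float, float]
    bracket_freqs: tuple[float, float]


def estimate_transition(
    curve: "pd.DataFrame | Sequence[tuple[float, float]]"
) -> TransitionEstimate:
    """Locate the 0.5 crossing of a (theta, cross_freq) curve.

    Scans for the *first* consecutive pair whose frequencies lie on opposite
    sides of 0.5 (a frequency exactly equal to 0.5 counts as a crossing at
    that sample) and linearly interpolates:
    ``theta_c = theta_k + (0.5 - f_k) / (f_{k+1} - f_k) * (theta_{k+1} - theta_k)``.

    Raises :class:`NoCrossingError` if no pair straddles 0.5, and
    ``ValueError`` on a degenerate flat pair ``f_k == f_{k+1} == 0.5``.
    """
    if isinstance(curve, pd.DataFrame):
        thetas = curve["theta"].to_numpy(dtype=float)
        freqs = curve["cross_freq"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(curve), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("curve must be (theta, frequency) pairs")
        thetas, freqs = arr[:, 0], arr[:, 1]
    if len(thetas) < 2:
        raise ValueError("curve needs at least two points")
    if np.any(np.diff(thetas) <= 0):
        raise ValueError("theta values must be strictly increasing")
    for k in range(len(thetas) - 1):
        lo, hi = freqs[k] - 0.5, freqs[k + 1] - 0.5
        if lo == 0.0 and hi == 0.0:
            raise ValueError(
                f"degenerate flat crossing at theta in "
                f"[{thetas[k]}, {thetas[k + 1]}]"
            )
        if lo == 0.0 or hi == 0.0 or (lo < 0.0) != (hi < 0.0):
            theta_c = thetas[k] + (0.5 - freqs[k]) / (freqs[k + 1] - freqs[k]) * (
                thetas[k + 1] - thetas[k]
            )
            return TransitionEstimate(
                theta_c=float(theta_c),
                bracket=(float(thetas[k]), float(thetas[k + 1])),
                bracket_freqs=(float(freqs[k]), float(freqs[k + 1])),
            )
    raise NoCrossingError("no crossing: curve never straddles cross_freq = 0.5")


@dataclass(frozen=True)
class BootstrapSummary:
    """Percentile-bootstrap summary of the transition and its delay slope."""

    B: int
    theta_c_point: float
    theta_c_median: float
    theta_c_ci: tuple[float, float]
    per_dlong_theta_c: dict[int, float]   # point estimates per d_long
    slope_point: float
    slope_median: float
    slope_ci: tuple[float, float]
    n_failed_global: int   # replicates whose global curve had no crossing
    n_failed_slope: int    # replicates lacking a crossing at some d_long
    replicates_theta: Optional[np.ndarray] = None  # kept only on request

    def to_dict(self) -> dict:
        return {
            "B": self.B,
            "theta_c_point": self.theta_c_point,
            "theta_c_median": self.theta_c_median,
            "theta_c_ci_low": self.theta_c_ci[0],
            "theta_c_ci_high": self.theta_c_ci[1],
            "per_dlong_theta_c": {str(k): v for k, v in
                                  self.per_dlong_theta_c.items()},
            "slope_point": self.slope_point,
            "slope_median": self.slope_median,
            "slope_ci_low": self.slope_ci[0],
            "slope_ci_high": self.slope_ci[1],
            "n_failed_global": self.n_failed_global,
            "n_failed_slope": self.n_failed_slope,
        }


def _curve_theta_c(thetas: np.ndarray, freqs: np.ndarray) -> float:
    """theta_c of a dense curve given as parallel arrays (raises on failure)."""
    est = estimate_transition(list(zip(thetas, freqs)))
    return est.theta_c


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xm = x - x.mean()
    return float(xm @ (y - y.mean()) / (xm @ xm))


def bootstrap_transition(
    results: ScanResult, B: int = 2000, seed: int = 0,
    ci: tuple[float, float] = (2.5, 97.5), keep_replicates: bool = False,
) -> BootstrapSummary:
    """Bootstrap the transition point by resampling scan cells.

    Each of the ``B`` replicates resamples the full cell set with replacement
    (preserving sample size), recomputes the mean cross-frequency curve and
    re-interpolates ``theta_c``; the same is repeated per ``d_long`` to get
    delay-specific transition points, from which an OLS slope of
    ``theta_c`` against ``d_long`` is computed per replicate.  Replicates
    without a 0.5 crossing are excluded from the quantiles and counted.
    """
    coords = results.coords
    thetas = np.sort(coords["theta"].unique())
    dlongs = np.sort(coords["d_long"].unique())
    if len(thetas) < 2:
        raise ValueError("bootstrap needs a multi-theta scan")
    theta_idx = np.searchsorted(thetas, coords["theta"].to_numpy())
    dlong_idx = np.searchsorted(dlongs, coords["d_long"].to_numpy())
    cross = results.cross.astype(float)
    n = len(cross)
    n_theta, n_dlong = len(thetas), len(dlongs)
    combo = dlong_idx * n_theta + theta_idx

    # point estimates
    point_curve = mean_cross_curve(results)
    theta_c_point = _curve_theta_c(
        point_curve["theta"].to_numpy(), point_curve["cross_freq"].to_numpy()
    )
    per_dlong_point: dict[int, float] = {}
    for di, dl in enumerate(dlongs):
        sel = dlong_idx == di
        freqs = np.bincount(theta_idx[sel], weights=cross[sel],
                            minlength=n_theta)
        counts = np.bincount(theta_idx[sel], minlength=n_theta)
        per_dlong_point[int(dl)] = _curve_theta_c(thetas, freqs / counts)
    slope_point = _ols_slope(
        dlongs.astype(float), np.array([per_dlong_point[int(d)] for d in dlongs])
    )

    rng = np.random.default_rng(seed)
    reps_theta = np.full(B, np.nan)
    reps_slope = np.full(B, np.nan)
    n_failed_global = 0
    n_failed_slope = 0
    for b in range(B):
        idx = rng.integers(0, n, n)
        c = cross[idx]
        # global curve
        f = np.bincount(theta_idx[idx], weights=c, minlength=n_theta)
        m = np.bincount(theta_idx[idx], minlength=n_theta)
        try:
            with np.errstate(invalid="ignore"):
                reps_theta[b] = _curve_theta_c(thetas, f / m)
        except (NoCrossingError, ValueError):
            n_failed_global += 1
        # per-d_long curves and slope
        fc = np.bincount(combo[idx], weights=c, minlength=n_theta * n_dlong)
        mc = np.bincount(combo[idx], minlength=n_theta * n_dlong)
        with np.errstate(invalid="ignore", divide="ignore"):
            curves = (fc / mc).reshape(n_dlong, n_theta)
        try:
            tc = np.array([_curve_theta_c(thetas, curves[di])
                           for di in range(n_dlong)])
            reps_slope[b] = _ols_slope(dlongs.astype(float), tc)
        except (NoCrossingError, ValueError):
            n_failed_slope += 1

    ok_t = reps_theta[np.isfinite(reps_theta)]
    ok_s = reps_slope[np.isfinite(reps_slope)]
    if ok_t.size == 0 or ok_s.size == 0:
        raise NoCrossingError("every bootstrap replicate lacked a crossing")
    lo, hi = ci
    return BootstrapSummary(
        B=B,
        theta_c_point=theta_c_point,
        theta_c_median=float(np.median(ok_t)),
        theta_c_ci=(float(np.percentile(ok_t, lo)), float(np.percentile(ok_t, hi))),
        per_dlong_theta_c=per_dlong_point,
        slope_point=slope_point,
        slope_median=float(np.median(ok_s)),
        slope_ci=(float(np.percentile(ok_s, lo)), float(np.percentile(ok_s, hi))),
        n_failed_global=n_failed_global,
        n_failed_slope=n_failed_slope,
        replicates_theta=reps_theta if keep_replicates else None,
    )


# ---------------------------------------------------------------------------
# Objective-weight sensitivity (OFAT)
# ---------------------------------------------------------------------------

def reselect_cross(
    results: ScanResult, weights: ObjectiveWeights
) -> np.ndarray:
    """Per-cell cross indicators after re-scoring stored components.

    Because J is a linear recombination of the stored per-architecture mean
    components, winners under any weight vector can be recomputed exactly
    without re-simulation.
    """
    j = results.components @ weights.as_array()
    best = np.argmin(j, axis=1)
    return results.is_contra[best].astype(int)


def ofat_sensitivity(
    results: ScanResult,
    base_weights: Optional[ObjectiveWeights] = None,
    scales: Sequence[float] = (0.5, 1.0, 1.5),
    high_twist_threshold: float = 0.70,
    probe_theta: float = 0.85,
) -> pd.DataFrame:
    """One-factor-at-a-time weight sensitivity on a dense twist scan.

    For each objective weight and scale, re-selects the per-cell winner from
    the stored component breakdowns, recomputes the cross-frequency curve and
    ``theta_c``, and summarizes high-twist contralateral dominance (mean
    cross_freq over ``theta >= high_twist_threshold`` and at ``probe_theta``).
    """
    if base_weights is None:
        base_weights = results.grid.weights
    theta = results.coords["theta"].to_numpy()
    rows = []
    for name in ObjectiveWeights.names:
        for scale in scales:
            w = base_weights.scaled(name, scale)
            cross = reselect_cross(results, w)
            curve = (
                pd.DataFrame({"theta": theta, "cross": cross})
                .groupby("theta", sort=True)["cross"].mean().reset_index()
                .rename(columns={"cross": "cross_freq"})
            )
            try:
                theta_c = _curve_theta_c(
                    curve["theta"].to_numpy(), curve["cross_freq"].to_numpy()
                )
            except (NoCrossingError, ValueError):
                theta_c = np.nan
            high = cross[theta >= high_twist_threshold - 1e-12]
            at_probe = cross[np.isclose(theta, probe_theta)]
            rows.append(
                {
                    "weight": name,
                    "scale": scale,
                    "theta_c": theta_c,
                    "cross_freq_high_twist": float(np.mean(high)),
                    "cross_freq_at_probe": (
                        float(np.mean(at_probe)) if at_probe.size else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mechanism metrics: temporal mismatch and sign alignment
# ---------------------------------------------------------------------------

# Canonical architectures for the mechanism comparison: full coupling
# (commissural excitation + local feedback), differing only in routing.
MECHANISM_ARCHS = {
    "ipsilateral": ArchitectureSpec(IPSILATERAL, True, True),
    "contralateral": ArchitectureSpec(CONTRALATERAL, True, True),
}


def mechanism_metrics(trace: SimulationTrace) -> tuple[float, float, float]:
    """(mean mismatch, sign alignment, total squared tracking error).

    Over the post-warmup window: mismatch is ``mean |e_x - u_x|`` with
    ``u_x = m_R - m_L``; alignment is the fraction of steps where ``e_x`` and
    ``u_x`` have the same strict nonzero sign (steps with either quantity
    exactly zero count as not aligned); the total tracking error is the
    post-warmup *sum* of ``e_x^2``.
    """
    e = trace.post(trace.e_x)
    if e.size == 0:
        raise ValueError("trace has an empty post-warmup window")
    u = trace.post(trace.u_x)
    mismatch = float(np.mean(np.abs(e - u)))
    aligned = ((e > 0) & (u > 0)) | ((e < 0) & (u < 0))
    alignment = float(np.mean(aligned))
    total_err = float(np.sum(e ** 2))
    return mismatch, alignment, total_err


def mechanism_scan(
    theta_values: Sequence[float],
    mp: Optional[ModelParams] = None,
    tp: Optional[TaskParams] = None,
    repetitions: int = 5,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Mismatch/alignment comparison of the canonical architecture pair.

    Runs ``repetitions`` paired trials (shared seeds across the two
    architectures) per twist value at the canonical mechanism cell
    (``d_long = 5``, ``sigma = 0.05``, ``I_inhib = 0.5`` unless overridden)
    and averages the per-trace metrics.  Returns a tidy frame with one row
    per (theta, architecture class) plus ipsilateral-minus-contralateral
    difference rows (``arch_class = "difference"``).
    """
    mp = mp if mp is not None else ModelParams(d_long=5, sigma=0.05, i_inhib=0.5)
    tp = tp if tp is not None else TaskParams(dims="two_d")
    rows = []
    for theta in theta_values:
        tp_theta = tp.with_(theta=float(theta))
        per_class: dict[str, np.ndarray] = {}
        for label, arch in MECHANISM_ARCHS.items():
            vals = np.empty((repetitions, 3))
            for r in range(repetitions):
                ss = cell_seed_sequence(base_seed, mp.d_long, mp.sigma,
                                        mp.i_inhib, theta, r)
                trace = run_trial(arch, mp, tp_theta, ss)
                vals[r] = mechanism_metrics(trace)
            per_class[label] = vals.mean(axis=0)
            rows.append(
                {
                    "theta": float(theta), "arch_class": label,
                    "mismatch": per_class[label][0],
                    "alignment": per_class[label][1],
                    "total_sq_error": per_class[label][2],
                }
            )
        diff = per_class["ipsilateral"] - per_class["contralateral"]
        rows.append(
            {
                "theta": float(theta), "arch_class": "difference",
                "mismatch": diff[0], "alignment": diff[1],
                "total_sq_error": diff[2],
            }
        )
    return pd.DataFrame(rows)
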