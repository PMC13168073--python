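"""Figure rendering for scan and analysis outputs (matplotlib, Agg backend).

All plots are display-only summaries of quantities computed elsewhere; the
fitted sigmoid on the cross-frequency curve is cosmetic and is never used
for inference (the transition point always comes from linear interpolation).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "plot_cross_curve",
    "plot_phase_map",
    "plot_objective_landscape",
    "plot_bootstrap_histogram",
    "plot_mechanism_curves",
]


def _sigmoid(x, x0, k):
    return 1.0 / (1.0 + np.exp(-k * (x - x0)))


def plot_cross_curve(
    curve: pd.DataFrame, theta_c: Optional[float] = None, path=None
):
    """Cross-frequency versus twist, with a cosmetic sigmoid overlay."""
    theta = curve["theta"].to_numpy()
    freq = curve["cross_freq"].to_numpy()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(theta, freq, "o", color="C0", label="mean cross_freq")
    try:
        popt, _ = curve_fit(_sigmoid, theta, freq, p0=[0.5, 20.0], maxfev=5000)
        xs = np.linspace(theta.min(), theta.max(), 300)
        ax.plot(xs, _sigmoid(xs, *popt), "--", color="C0", alpha=0.6,
                label="sigmoid fit (display only)")
    except RuntimeError:
        pass
    if theta_c is not None:
        ax.axvline(theta_c, color="C3", lw=1,
                   label=rf"$\theta_c$ = {theta_c:.4f}")
    ax.axhline(0.5, color="gray", lw=0.5, ls=":")
    ax.set_xlabel(r"twist $\theta$")
    ax.set_ylabel("contralateral frequency")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return _finish(fig, path)


def plot_phase_map(scan_df: pd.DataFrame, path=None):
    """Mean cross-frequency over the (theta, d_long) plane."""
    pivot = scan_df.pivot_table(index="d_long", columns="theta",
                                values="cross", aggfunc="mean")
    fig, ax = plt.subplots(figsize=(5.5, 3.5))
    im = ax.imshow(
        pivot.to_numpy(), aspect="auto", origin="lower", cmap="coolwarm",
        vmin=0, vmax=1,
        extent=[pivot.columns.min(), pivot.columns.max(),
                pivot.index.min(), pivot.index.max()],
    )
    fig.colorbar(im, ax=ax, label="cross_freq")
    ax.set_xlabel(r"twist $\theta$")
    ax.set_ylabel(r"commissural delay $d_{long}$")
    fig.tight_layout()
    return _finish(fig, path)


def plot_objective_landscape(scan_df: pd.DataFrame, path=None):
    """Mean winning objective value versus twist."""
    curve = scan_df.groupby("theta")["J"].mean()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve.index, curve.to_numpy(), "o-", color="C2")
    ax.set_xlabel(r"twist $\theta$")
    ax.set_ylabel("mean best J")
    fig.tight_layout()
    return _finish(fig, path)


def plot_bootstrap_histogram(replicates: np.ndarray, theta_c: float,
                             ci: tuple[float, float], path=None):
    """Bootstrap distribution of the transition point."""
    replicates = np.asarray(replicates)
    replicates = replicates[np.isfinite(replicates)]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(replicates, bins=40, color="C0", alpha=0.8)
    ax.axvline(theta_c, color="C3", lw=1.5, label=rf"$\theta_c$ median")
    for v in ci:
        ax.axvline(v, color="gray", lw=1, ls="--")
    ax.set_xlabel(r"$\theta_c$ (bootstrap replicates)")
    ax.set_ylabel("count")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return _finish(fig, path)


def plot_mechanism_curves(mech_df: pd.DataFrame, path=None):
    """Temporal mismatch and sign alignment per architecture class."""
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.2))
    for label, style in (("ipsilateral", "o-"), ("contralateral", "s-")):
        sub = mech_df[mech_df["arch_class"] == label]
        axes[0].semilogy(sub["theta"], sub["mismatch"], style, label=label)
        axes[1].plot(sub["theta"], sub["alignment"], style, label=label)
    axes[0].set_ylabel("temporal mismatch (log)")
    axes[1].set_ylabel("sign alignment")
    for ax in axes:
        ax.set_xlabel(r"twist $\theta$")
        ax.legend(fontsize=8)
    fig.tight_layout()
    return _finish(fig, path)


def _finish(fig, path):
    if path is not None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return path
    return fig
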