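"""End-to-end reproduction workflow: scans, analyses, summary, figures.

``reproduce_all`` runs the full study pipeline — the two-dimensional dense
and discrete twist scans, the one-dimensional selection and tracking scans,
the pairwise routing comparison, transition interpolation, bootstrap,
objective-weight sensitivity and the mechanism analysis — writing each
stage's CSV/JSON artifacts plus a combined ``summary.json``.  A ``scale``
below 1 subsamples the non-twist grid axes and the repetition counts for
desk-scale smoke runs; the twist axis is always kept whole so the transition
remains estimable.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from .analysis import (
    NoCrossingError,
    bootstrap_transition,
    estimate_transition,
    mechanism_scan,
    ofat_sensitivity,
)
from .config import write_provenance
from .scan import (
    ScanResult,
    THETA_DENSE,
    grid_preset,
    mean_cross_curve,
    pairwise_comparison,
    run_scan,
    shrink_grid,
)

__all__ = ["reproduce_all"]


def _log(quiet: bool, msg: str) -> None:
    if not quiet:
        import sys

        print(msg, file=sys.stderr)


def reproduce_all(
    out_dir,
    base_seed: int = 0,
    scale: float = 1.0,
    repetitions: Optional[dict] = None,
    make_figures: bool = True,
    quiet: bool = False,
    progress: bool = False,
) -> dict:
    """Run the whole analysis pipeline; return (and write) the summary dict.

    ``repetitions`` may map preset names to explicit repetition counts,
    overriding both the preset defaults and ``scale``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    repetitions = repetitions or {}

    def make_grid(name: str):
        g = grid_preset(name, base_seed=base_seed)
        g = shrink_grid(g, scale)
        if name in repetitions:
            g = replace(g, repetitions=int(repetitions[name]))
        return g

    summary: dict = {"base_seed": base_seed, "scale": scale}

    # -- scans -----------------------------------------------------------
    results: dict[str, ScanResult] = {}
    for name in ("twod_dense_twist", "twod_discrete_twist",
                 "oned_exhaustive", "oned_inhibitory", "oned_tracking"):
        grid = make_grid(name)
        _log(quiet, f"[chiasm] scan {name}: {grid.n_cells} cells x "
                    f"{grid.repetitions} reps")
        res = run_scan(grid, progress=progress)
        res.save(out / name)
        write_provenance(out / name, {"stage": "scan", "preset": name,
                                      "grid": grid.to_dict()})
        results[name] = res

    dense = results["twod_dense_twist"]
    discrete = results["twod_discrete_twist"]
    disc_curve = mean_cross_curve(discrete)
    disc_by_theta = dict(zip(disc_curve["theta"], disc_curve["cross_freq"]))
    summary["discrete_cross_freq"] = {f"{t:g}": float(f)
                                      for t, f in disc_by_theta.items()}
    disc_df = discrete.to_frame()
    best_by_theta = disc_df.groupby("theta")["J"].mean()
    summary["discrete_mean_best_j"] = {f"{t:g}": float(v)
                                       for t, v in best_by_theta.items()}

    # -- transition ------------------------------------------------------
    curve = mean_cross_curve(dense)
    curve.to_csv(out / "cross_curve.csv", index=False, float_format="%.9g")
    est = estimate_transition(curve)
    summary["theta_c"] = est.theta_c
    summary["theta_c_bracket"] = list(est.bracket)
    summary["dense_cross_freq"] = {
        f"{t:g}": float(f)
        for t, f in zip(curve["theta"], curve["cross_freq"])
    }
    dense_df = dense.to_frame()
    dense_best = dense_df.groupby("theta")["J"].mean()
    summary["dense_mean_best_j"] = {f"{t:g}": float(v)
                                    for t, v in dense_best.items()}
    with open(out / "transition.json", "w") as fh:
        json.dump({"theta_c": est.theta_c, "bracket": list(est.bracket),
                   "bracket_freqs": list(est.bracket_freqs)}, fh, indent=2)

    # -- bootstrap -------------------------------------------------------
    B = max(200, int(round(2000 * scale)))
    _log(quiet, f"[chiasm] bootstrap: B={B}")
    boot = bootstrap_transition(dense, B=B, seed=base_seed + 1,
                                keep_replicates=make_figures)
    summary["bootstrap"] = boot.to_dict()
    with open(out / "bootstrap.json", "w") as fh:
        json.dump(boot.to_dict(), fh, indent=2)

    # -- weight sensitivity ---------------------------------------------
    _log(quiet, "[chiasm] OFAT weight sensitivity")
    ofat = ofat_sensitivity(dense)
    ofat.to_csv(out / "ofat_sensitivity.csv", index=False, float_format="%.9g")
    summary["ofat"] = {
        "theta_c_min": float(np.nanmin(ofat["theta_c"])),
        "theta_c_max": float(np.nanmax(ofat["theta_c"])),
        "cross_freq_high_twist_min": float(ofat["cross_freq_high_twist"].min()),
        "cross_freq_at_085_min": float(ofat["cross_freq_at_probe"].min()),
    }

    # -- one-dimensional analyses ---------------------------------------
    ex_df = results["oned_exhaustive"].to_frame()
    summary["oned_exhaustive"] = {
        "mean_cross_freq": float(ex_df["cross"].mean()),
        "mean_cross_rep_fraction": float(ex_df["cross_rep_fraction"].mean()),
        "mean_best_j": float(ex_df["J"].mean()),
    }
    inh_df = results["oned_inhibitory"].to_frame()
    summary["oned_inhibitory"] = {
        "mean_cross_freq": float(inh_df["cross"].mean()),
        "mean_cross_rep_fraction": float(inh_df["cross_rep_fraction"].mean()),
    }
    trk_df = results["oned_tracking"].to_frame()
    summary["oned_tracking"] = {
        "mean_cross_freq": float(trk_df["cross"].mean()),
        "mean_cross_rep_fraction": float(trk_df["cross_rep_fraction"].mean()),
    }

    pw_grid = make_grid("oned_exhaustive")
    reals = max(2, round(5 * scale)) if scale < 1.0 else 5
    _log(quiet, f"[chiasm] pairwise comparison: {pw_grid.n_cells} cells x "
                f"{reals} realizations")
    pw = pairwise_comparison(pw_grid, realizations=reals, progress=progress)
    summary["pairwise"] = {
        "proportion_contra_better": pw.proportion_contra_better,
        "mean_j_difference": pw.mean_j_difference,
        "mean_j_contra": pw.mean_j_contra,
        "mean_j_ipsi": pw.mean_j_ipsi,
        "n_comparisons": pw.n_comparisons,
    }

    # -- mechanism -------------------------------------------------------
    _log(quiet, "[chiasm] mechanism analysis")
    mech_reps = max(2, round(5 * scale)) if scale < 1.0 else 5
    mech = mechanism_scan(THETA_DENSE, repetitions=mech_reps,
                          base_seed=base_seed)
    mech.to_csv(out / "mechanism.csv", index=False, float_format="%.9g")
    mdiff = mech[mech["arch_class"] == "difference"].set_index("theta")
    mclasses = mech[mech["arch_class"] != "difference"]
    summary["mechanism"] = {
        "mismatch_diff_theta_025": float(mdiff.loc[0.25, "mismatch"]),
        "mismatch_diff_theta_050": float(mdiff.loc[0.50, "mismatch"]),
        "mismatch_diff_theta_085": float(mdiff.loc[0.85, "mismatch"]),
        "alignment_ipsi_theta_085": float(
            mclasses.query("arch_class == 'ipsilateral' and theta == 0.85")
            ["alignment"].iloc[0]),
        "alignment_contra_theta_085": float(
            mclasses.query("arch_class == 'contralateral' and theta == 0.85")
            ["alignment"].iloc[0]),
        "total_sq_error_diff_theta_085": float(
            mdiff.loc[0.85, "total_sq_error"]),
    }

    # -- figures ---------------------------------------------------------
    if make_figures:
        _log(quiet, "[chiasm] rendering figures")
        from . import figures

        fig_dir = out / "figures"
        figures.plot_cross_curve(curve, est.theta_c,
                                 fig_dir / "cross_curve.png")
        figures.plot_phase_map(dense_df, fig_dir / "phase_map.png")
        figures.plot_objective_landscape(dense_df,
                                         fig_dir / "objective_landscape.png")
        figures.plot_bootstrap_histogram(
            boot.replicates_theta, boot.theta_c_median, boot.theta_c_ci,
            fig_dir / "bootstrap_theta_c.png")
        figures.plot_mechanism_curves(mech, fig_dir / "mechanism.png")

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    write_provenance(out, {"stage": "reproduce_all", "base_seed": base_seed,
                           "scale": scale})
    return summary
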