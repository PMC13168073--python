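"""Parameter-grid scans: evaluate all candidate architectures per grid cell.

A grid cell is a combination of ``(d_long, sigma, i_inhib, theta)``.  Within
a cell every one of the eight candidate architectures is evaluated on the
*same* repetition seeds — identical target trajectories, node-noise and
process-noise realizations — so that selection reflects architecture, not
luck.  Per architecture the objective is averaged over repetitions; the cell
winner is the architecture with the lowest mean J, ties broken by the fixed
enumeration order (ipsilateral variants first, which is conservative against
contralateral dominance).  The per-cell ``cross`` indicator is 1 iff the
winner routes sensation contralaterally; averaging indicators over cells
gives the contralateral frequency ``cross_freq``.

Seeding policy: the repetition seed is ``SeedSequence((base_seed, d_long,
round(sigma*1e6), round(i_inhib*1e6), round(theta*1e6), rep))`` — a pure
function of the cell coordinates, so scans are reproducible cell-by-cell and
architectures share repetition streams by construction.

Cells are simulated in vectorized batches through the numba kernel; a full
dense twist scan (21,840 cells) runs in minutes on one core.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import _engine
from .network import (
    ArchitectureSpec,
    ModelParams,
    build_connection_table,
    delay_cost_coefficients,
    enumerate_architectures,
    split_weight_matrices,
)
from .objective import ObjectiveWeights
from .task import (
    _DRIVE_CODES,
    DRIVE_COMMON_NAME,
    ONE_D,
    TWO_D,
    TaskParams,
    TrialInputs,
)

__all__ = [
    "GridSpec",
    "ScanCellResult",
    "ScanResult",
    "PairwiseResult",
    "cell_seed_sequence",
    "summarize_cell",
    "evaluate_cell",
    "run_scan",
    "mean_cross_curve",
    "pairwise_comparison",
    "grid_preset",
    "shrink_grid",
    "PRESET_NAMES",
    "COMPONENT_NAMES",
]

COMPONENT_NAMES = ("J_track", "J_effort", "J_asym", "J_delay", "J_noise")

# Canonical parameter sets of the study conditions.
D_LONG_FULL = tuple(range(1, 21))
SIGMA_MAIN = (0.01, 0.02, 0.03, 0.04, 0.05, 0.055, 0.06, 0.065,
              0.07, 0.08, 0.09, 0.10, 0.11, 0.12)
SIGMA_ONED = (0.01, 0.02, 0.03, 0.04, 0.045, 0.05, 0.055, 0.06,
              0.065, 0.07, 0.08, 0.10, 0.12)
I_INHIB_FULL = (0.0, 0.2, 0.5, 0.8, 1.2, 1.8)
THETA_DISCRETE = (0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0)
THETA_DENSE = (0.25, 0.30, 0.35, 0.40, 0.45, 0.50, 0.55,
               0.60, 0.65, 0.70, 0.75, 0.80, 0.85)

PRESET_NAMES = (
    "oned_exhaustive",
    "oned_inhibitory",
    "oned_tracking",
    "twod_baseline",
    "twod_discrete_twist",
    "twod_dense_twist",
)


@dataclass(frozen=True)
class GridSpec:
    """A parameter grid plus everything needed to evaluate it.

    The cell list is the Cartesian product ``d_long x sigma x i_inhib x
    theta`` with theta varying fastest.  ``model`` and ``task`` carry the
    non-gridded constants; per cell the gridded fields are substituted.
    """

    d_long_values: tuple
    sigma_values: tuple
    i_inhib_values: tuple
    theta_values: tuple
    dims: str = TWO_D
    repetitions: int = 10
    weights: ObjectiveWeights = field(default_factory=ObjectiveWeights)
    base_seed: int = 0
    name: str = "custom"
    model: ModelParams = field(default_factory=ModelParams)
    task: TaskParams = field(default_factory=TaskParams)

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.base_seed < 0:
            raise ValueError("base_seed must be a nonnegative integer")
        for axis in ("d_long_values", "sigma_values", "i_inhib_values",
                     "theta_values"):
            if len(getattr(self, axis)) == 0:
                raise ValueError(f"{axis} must not be empty")

    @property
    def n_cells(self) -> int:
        return (len(self.d_long_values) * len(self.sigma_values)
                * len(self.i_inhib_values) * len(self.theta_values))

    def cells(self) -> Iterable[tuple]:
        """Cell coordinates in scan order (theta fastest)."""
        return itertools.product(
            self.d_long_values, self.sigma_values,
            self.i_inhib_values, self.theta_values,
        )

    def cell_params(self, d_long, sigma, i_inhib, theta):
        mp = self.model.with_(d_long=int(d_long), sigma=float(sigma),
                              i_inhib=float(i_inhib))
        tp = self.task.with_(theta=float(theta), dims=self.dims)
        return mp, tp

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def cell_seed_sequence(
    base_seed: int, d_long: int, sigma: float, i_inhib: float,
    theta: float, rep: int,
) -> np.random.SeedSequence:
    """The repetition seed of one grid cell (shared by all architectures)."""
    return np.random.SeedSequence(
        (int(base_seed), int(d_long), int(round(sigma * 1e6)),
         int(round(i_inhib * 1e6)), int(round(theta * 1e6)), int(rep))
    )


@dataclass(frozen=True)
class ScanCellResult:
    """Per-cell outcome: per-architecture means, the winner, cross indicator."""

    d_long: int
    sigma: float
    i_inhib: float
    theta: float
    mean_j: np.ndarray            # (8,) per-architecture mean J over reps
    mean_components: np.ndarray   # (8, 5) per-architecture mean components
    best_index: int
    best_code: str
    cross: int
    cross_rep_fraction: float


def summarize_cell(
    j_rep_arch: np.ndarray, is_contra: np.ndarray
) -> tuple[np.ndarray, int, int, float]:
    """Select the cell winner from a ``(reps, 8)`` objective array.

    Returns ``(mean_j, best_index, cross, cross_rep_fraction)``.  The winner
    is the argmin of the repetition-mean J; ``np.argmin`` returns the first
    minimum, which implements the enumeration-order tie-break.  The
    per-repetition cross fraction applies the same argmin rule within each
    repetition separately.
    """
    j_rep_arch = np.asarray(j_rep_arch, dtype=float)
    if not np.all(np.isfinite(j_rep_arch)):
        raise FloatingPointError("non-finite objective value in cell")
    mean_j = j_rep_arch.mean(axis=0)
    best = int(np.argmin(mean_j))
    cross = int(is_contra[best])
    rep_winners = np.argmin(j_rep_arch, axis=1)
    frac = float(np.mean(is_contra[rep_winners]))
    return mean_j, best, cross, frac


class ScanResult:
    """All cells of one scan, with tidy export and analysis accessors."""

    def __init__(self, grid: GridSpec, cells: list[ScanCellResult],
                 archs: Optional[list[ArchitectureSpec]] = None):
        self.grid = grid
        self.cells = cells
        self.archs = archs if archs is not None else enumerate_architectures()
        self.arch_codes = [a.code for a in self.archs]
        self.is_contra = np.array([a.is_contralateral for a in self.archs])

    def __len__(self) -> int:
        return len(self.cells)

    # -- array accessors -------------------------------------------------
    @property
    def coords(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "d_long": [c.d_long for c in self.cells],
                "sigma": [c.sigma for c in self.cells],
                "I_inhib": [c.i_inhib for c in self.cells],
                "theta": [c.theta for c in self.cells],
            }
        )

    @property
    def cross(self) -> np.ndarray:
        return np.array([c.cross for c in self.cells])

    @property
    def mean_j(self) -> np.ndarray:
        """(n_cells, 8) per-architecture mean objective values."""
        return np.stack([c.mean_j for c in self.cells])

    @property
    def components(self) -> np.ndarray:
        """(n_cells, 8, 5) per-architecture mean component breakdowns."""
        return np.stack([c.mean_components for c in self.cells])

    @property
    def best_j(self) -> np.ndarray:
        return np.array([c.mean_j[c.best_index] for c in self.cells])

    # -- export ----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """One row per cell: coordinates, per-arch mean J, winner breakdown."""
        df = self.coords.copy()
        mj = self.mean_j
        for a, code in enumerate(self.arch_codes):
            df[f"J_mean_{code}"] = mj[:, a]
        df["best_arch"] = [c.best_code for c in self.cells]
        df["cross"] = self.cross
        df["cross_rep_fraction"] = [c.cross_rep_fraction for c in self.cells]
        comps = self.components
        best = np.array([c.best_index for c in self.cells])
        rows = np.arange(len(self.cells))
        for k, name in enumerate(COMPONENT_NAMES):
            df[name] = comps[rows, best, k]
        df["J"] = self.best_j
        return df

    def components_frame(self) -> pd.DataFrame:
        """Long-format per-architecture component table (for re-weighting)."""
        n = len(self.cells)
        coords = self.coords
        frames = []
        comps = self.components
        mj = self.mean_j
        for a, code in enumerate(self.arch_codes):
            df = coords.copy()
            df["arch"] = code
            for k, name in enumerate(COMPONENT_NAMES):
                df[name] = comps[:, a, k]
            df["J"] = mj[:, a]
            frames.append(df)
        out = pd.concat(frames, ignore_index=True)
        out.insert(0, "cell", np.tile(np.arange(n), len(self.arch_codes)))
        return out.sort_values(["cell", "arch"], kind="stable").reset_index(drop=True)

    def save(self, directory) -> None:
        """Write ``scan.csv``, ``components.csv`` and ``grid.json``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / "scan.csv", index=False,
                               float_format="%.9g")
        self.components_frame().to_csv(directory / "components.csv",
                                       index=False, float_format="%.9g")
        with open(directory / "grid.json", "w") as fh:
            json.dump(self.grid.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, directory) -> "ScanResult":
        """Rebuild a ScanResult from a saved scan directory."""
        directory = Path(directory)
        with open(directory / "grid.json") as fh:
            gd = json.load(fh)
        grid = GridSpec(
            d_long_values=tuple(gd["d_long_values"]),
            sigma_values=tuple(gd["sigma_values"]),
            i_inhib_values=tuple(gd["i_inhib_values"]),
            theta_values=tuple(gd["theta_values"]),
            dims=gd["dims"],
            repetitions=gd["repetitions"],
            weights=ObjectiveWeights(**gd["weights"]),
            base_seed=gd["base_seed"],
            name=gd["name"],
            model=ModelParams(**gd["model"]),
            task=TaskParams(**gd["task"]),
        )
        scan_df = pd.read_csv(directory / "scan.csv")
        comp_df = pd.read_csv(directory / "components.csv")
        archs = enumerate_architectures()
        codes = [a.code for a in archs]
        n = len(scan_df)
        comps = np.empty((n, len(codes), len(COMPONENT_NAMES)))
        mj = np.empty((n, len(codes)))
        for a, code in enumerate(codes):
            sub = comp_df[comp_df["arch"] == code].sort_values("cell")
            comps[:, a, :] = sub[list(COMPONENT_NAMES)].to_numpy()
            mj[:, a] = sub["J"].to_numpy()
        cells = []
        for i, row in scan_df.iterrows():
            cells.append(
                ScanCellResult(
                    d_long=int(row["d_long"]), sigma=float(row["sigma"]),
                    i_inhib=float(row["I_inhib"]), theta=float(row["theta"]),
                    mean_j=mj[i], mean_components=comps[i],
                    best_index=codes.index(row["best_arch"]),
                    best_code=row["best_arch"], cross=int(row["cross"]),
                    cross_rep_fraction=float(row["cross_rep_fraction"]),
                )
            )
        return cls(grid, cells, archs)


# ---------------------------------------------------------------------------
# Batched evaluation
# ---------------------------------------------------------------------------

_TARGET_BATCH = 16384  # trials per kernel call; keeps transient arrays small


def _evaluate_cell_block(
    grid: GridSpec, cell_coords: list[tuple], reps: int
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate a block of cells; return per-(cell, rep, arch) components and J.

    Returns ``(comps, j)`` with shapes ``(nc, reps, 8, 5)`` and
    ``(nc, reps, 8)``.  Trial layout within the kernel batch is cell-major,
    then repetition, then noise level (baseline, elevated), then architecture
    — so all 16 trials of a (cell, repetition) share one task realization.
    """
    archs = enumerate_architectures()
    n_arch = len(archs)
    nc = len(cell_coords)
    T = grid.task.T
    warmup = grid.task.warmup
    two_d = grid.dims == TWO_D
    ncr = nc * reps

    w_short = np.empty((nc, n_arch, 6, 6))
    w_long = np.empty((nc, n_arch, 6, 6))
    coeffs = np.empty((nc, n_arch, 6))
    tx = np.empty((ncr, T))
    ty = np.zeros((ncr, T))
    px = np.empty((ncr, T))
    py = np.zeros((ncr, T))
    nn = np.empty((ncr, 2, T, 6))

    for ci, (dl, sig, inh, th) in enumerate(cell_coords):
        mp, tp = grid.cell_params(dl, sig, inh, th)
        for a, arch in enumerate(archs):
            table = build_connection_table(arch, mp)
            ws, wl = split_weight_matrices(table, mp.d_short, mp.d_long)
            w_short[ci, a] = ws
            w_long[ci, a] = wl
            coeffs[ci, a] = delay_cost_coefficients(table)
        for r in range(reps):
            ss = cell_seed_sequence(grid.base_seed, dl, sig, inh, th, r)
            base, high = TrialInputs.draw_pair(mp, tp, ss)
            k = ci * reps + r
            tx[k] = base.target_x
            px[k] = base.proc_x
            nn[k, 0] = base.node_noise
            nn[k, 1] = high.node_noise
            if two_d:
                ty[k] = base.target_y
                py[k] = base.proc_y

    # expand to the full trial batch: (cell, rep, level, arch)
    rep16 = 2 * n_arch
    tx_f = np.repeat(tx, rep16, axis=0)
    ty_f = np.repeat(ty, rep16, axis=0)
    px_f = np.repeat(px, rep16, axis=0)
    py_f = np.repeat(py, rep16, axis=0)
    nn_f = np.repeat(nn.reshape(ncr * 2, T, 6), n_arch, axis=0)
    w_short_f = np.ascontiguousarray(
        np.broadcast_to(w_short[:, None, None], (nc, reps, 2, n_arch, 6, 6))
    ).reshape(-1, 6, 6)
    w_long_f = np.ascontiguousarray(
        np.broadcast_to(w_long[:, None, None], (nc, reps, 2, n_arch, 6, 6))
    ).reshape(-1, 6, 6)
    dls = np.array([c[0] for c in cell_coords], dtype=np.int64)
    ths = np.array([c[3] for c in cell_coords], dtype=float)
    dl_f = np.repeat(dls, reps * rep16)
    th_f = np.repeat(ths, reps * rep16)

    mp0 = grid.model
    tp0 = grid.task
    acc, absx = _engine.batch_summaries(
        w_short_f, w_long_f, dl_f, th_f, tx_f, ty_f, nn_f, px_f, py_f,
        mp0.g, tp0.k_move, tp0.k_y, warmup, two_d,
        _DRIVE_CODES[tp0.drive],
    )
    count = T - warmup
    acc = acc.reshape(nc, reps, 2, n_arch, _engine.N_ACC)
    absx = absx.reshape(nc, reps, 2, n_arch, 6)

    track = (acc[..., _engine.ACC_E2X] + acc[..., _engine.ACC_E2Y]) / count
    track_base = track[:, :, 0, :]
    track_high = track[:, :, 1, :]
    effort = acc[:, :, 0, :, _engine.ACC_M2] / count
    asym = acc[:, :, 0, :, _engine.ACC_ASYM] / count
    mean_absx = absx[:, :, 0, :, :] / count
    delay = np.einsum("caj,craj->cra", coeffs, mean_absx)
    noise = track_high - track_base

    comps = np.stack([track_base, effort, asym, delay, noise], axis=-1)
    j = comps @ grid.weights.as_array()
    return comps, j


def _block_to_cells(
    grid: GridSpec, cell_coords: list[tuple],
    comps: np.ndarray, j: np.ndarray, is_contra: np.ndarray,
    arch_codes: list[str],
) -> list[ScanCellResult]:
    out = []
    for ci, (dl, sig, inh, th) in enumerate(cell_coords):
        try:
            mean_j, best, cross, frac = summarize_cell(j[ci], is_contra)
        except FloatingPointError as err:
            raise FloatingPointError(
                f"non-finite objective at cell (d_long={dl}, sigma={sig}, "
                f"I_inhib={inh}, theta={th})"
            ) from err
        out.append(
            ScanCellResult(
                d_long=int(dl), sigma=float(sig), i_inhib=float(inh),
                theta=float(th), mean_j=mean_j,
                mean_components=comps[ci].mean(axis=0),
                best_index=best, best_code=arch_codes[best],
                cross=cross, cross_rep_fraction=frac,
            )
        )
    return out


def evaluate_cell(
    grid: GridSpec, d_long: int, sigma: float, i_inhib: float, theta: float,
    repetitions: Optional[int] = None,
) -> ScanCellResult:
    """Evaluate all eight architectures in one grid cell."""
    reps = repetitions if repetitions is not None else grid.repetitions
    archs = enumerate_architectures()
    comps, j = _evaluate_cell_block(grid, [(d_long, sigma, i_inhib, theta)], reps)
    is_contra = np.array([a.is_contralateral for a in archs])
    codes = [a.code for a in archs]
    return _block_to_cells(grid, [(d_long, sigma, i_inhib, theta)],
                           comps, j, is_contra, codes)[0]


def run_scan(grid: GridSpec, progress: bool = False) -> ScanResult:
    """Evaluate every cell of the grid (deterministic given ``base_seed``)."""
    archs = enumerate_architectures()
    is_contra = np.array([a.is_contralateral for a in archs])
    codes = [a.code for a in archs]
    all_coords = list(grid.cells())
    reps = grid.repetitions
    per_cell = reps * 2 * len(archs)
    block = max(1, _TARGET_BATCH // per_cell)
    blocks = [all_coords[i:i + block] for i in range(0, len(all_coords), block)]
    if progress:
        from tqdm import tqdm
        blocks = tqdm(blocks, desc=f"scan {grid.name}", unit="block")
    cells: list[ScanCellResult] = []
    for chunk in blocks:
        comps, j = _evaluate_cell_block(grid, chunk, reps)
        cells.extend(_block_to_cells(grid, chunk, comps, j, is_contra, codes))
    return ScanResult(grid, cells, archs)


# ---------------------------------------------------------------------------
# Analyses on scan output
# ---------------------------------------------------------------------------

def mean_cross_curve(
    results: "ScanResult | pd.DataFrame", d_long: Optional[int] = None
) -> pd.DataFrame:
    """Mean per-cell cross indicator per theta, ordered by theta ascending."""
    df = results.to_frame() if isinstance(results, ScanResult) else results
    if len(df) == 0:
        raise ValueError("no cells to average")
    if d_long is not None:
        df = df[df["d_long"] == d_long]
    curve = (
        df.groupby("theta", sort=True)["cross"].mean().reset_index()
        .rename(columns={"cross": "cross_freq"})
    )
    return curve


@dataclass(frozen=True)
class PairwiseResult:
    """Matched-pair contralateral-versus-ipsilateral comparison summary."""

    proportion_contra_better: float
    mean_j_difference: float        # mean of (J_contra - J_ipsi)
    mean_j_contra: float
    mean_j_ipsi: float
    n_comparisons: int


def pairwise_comparison(
    grid: GridSpec, realizations: int = 5, pairs: str = "minimal",
    progress: bool = False,
) -> PairwiseResult:
    """Compare contralateral versus ipsilateral routing on identical seeds.

    With ``pairs="minimal"`` (default) the comparison isolates the pure
    routing contrast: the two architectures without commissural excitation
    or local feedback, which differ in nothing but the side their sensory
    projection targets.  With ``pairs="matched"`` all four pairs matched on
    (commissural_excitation, local_feedback) are compared and pooled.
    Comparisons are per cell and per realization on single-run objective
    values; a tie (exactly equal J) does not count as contralateral-better.
    """
    archs = enumerate_architectures()
    is_contra = np.array([a.is_contralateral for a in archs])
    # match pairs by the non-routing factors
    key = {(a.commissural_excitation, a.local_feedback): i
           for i, a in enumerate(archs) if not a.is_contralateral}
    pair_list = [(key[(a.commissural_excitation, a.local_feedback)], i)
                 for i, a in enumerate(archs) if a.is_contralateral]
    if pairs == "minimal":
        pair_list = [
            (i, c) for i, c in pair_list
            if not archs[i].commissural_excitation and not archs[i].local_feedback
        ]
    elif pairs != "matched":
        raise ValueError("pairs must be 'minimal' or 'matched'")

    all_coords = list(grid.cells())
    per_cell = realizations * 2 * len(archs)
    block = max(1, _TARGET_BATCH // per_cell)
    diffs = []
    contra_vals = []
    ipsi_vals = []
    blocks = [all_coords[i:i + block] for i in range(0, len(all_coords), block)]
    if progress:
        from tqdm import tqdm
        blocks = tqdm(blocks, desc="pairwise", unit="block")
    for chunk in blocks:
        _, j = _evaluate_cell_block(grid, chunk, realizations)
        if not np.all(np.isfinite(j)):
            raise FloatingPointError("non-finite objective in pairwise block")
        for ipsi_idx, contra_idx in pair_list:
            ipsi_vals.append(j[:, :, ipsi_idx].ravel())
            contra_vals.append(j[:, :, contra_idx].ravel())
            diffs.append((j[:, :, contra_idx] - j[:, :, ipsi_idx]).ravel())
    diff = np.concatenate(diffs)
    contra = np.concatenate(contra_vals)
    ipsi = np.concatenate(ipsi_vals)
    return PairwiseResult(
        proportion_contra_better=float(np.mean(diff < 0.0)),
        mean_j_difference=float(np.mean(diff)),
        mean_j_contra=float(np.mean(contra)),
        mean_j_ipsi=float(np.mean(ipsi)),
        n_comparisons=int(diff.size),
    )


# ---------------------------------------------------------------------------
# Named grid presets
# ---------------------------------------------------------------------------

def grid_preset(
    name: str, base_seed: int = 0, repetitions: Optional[int] = None
) -> GridSpec:
    """One of the six named study grids.

    ``oned_exhaustive`` (260 cells, 12 reps), ``oned_inhibitory`` and
    ``oned_tracking`` (1,680 cells, 10 reps), ``twod_baseline`` (1,680 cells,
    theta = 0), ``twod_discrete_twist`` (4 theta values) and
    ``twod_dense_twist`` (13 theta values, 21,840 cells), all 10 reps.

    The one-dimensional exhaustive/inhibitory selection scans use the
    laterality-neutral common drive (both sensors receive ``e_x / 2``) and
    the ``"dynamical"`` objective preset, under which the drive carries no
    lateral information and routing competes on the dynamical cost terms
    alone; ``oned_tracking`` instead uses the directional rectified drive
    (twist 0) with baseline weights, which makes tracking performance
    dominate selection.  See the methods note for the rationale.
    """
    kw: dict = {"name": name, "base_seed": base_seed}
    common_1d = TaskParams(dims=ONE_D, drive=DRIVE_COMMON_NAME)
    dyn = ObjectiveWeights.preset("dynamical")
    if name == "oned_exhaustive":
        grid = GridSpec(D_LONG_FULL, SIGMA_ONED, (0.5,), (0.0,), dims=ONE_D,
                        repetitions=12, task=common_1d, weights=dyn, **kw)
    elif name == "oned_inhibitory":
        grid = GridSpec(D_LONG_FULL, SIGMA_MAIN, I_INHIB_FULL, (0.0,),
                        dims=ONE_D, repetitions=10, task=common_1d,
                        weights=dyn, **kw)
    elif name == "oned_tracking":
        grid = GridSpec(D_LONG_FULL, SIGMA_MAIN, I_INHIB_FULL, (0.0,),
                        dims=ONE_D, repetitions=10, **kw)
    elif name == "twod_baseline":
        grid = GridSpec(D_LONG_FULL, SIGMA_MAIN, I_INHIB_FULL, (0.0,),
                        dims=TWO_D, repetitions=10, **kw)
    elif name == "twod_discrete_twist":
        grid = GridSpec(D_LONG_FULL, SIGMA_MAIN, I_INHIB_FULL, THETA_DISCRETE,
                        dims=TWO_D, repetitions=10, **kw)
    elif name == "twod_dense_twist":
        grid = GridSpec(D_LONG_FULL, SIGMA_MAIN, I_INHIB_FULL, THETA_DENSE,
                        dims=TWO_D, repetitions=10, **kw)
    else:
        raise ValueError(f"unknown grid preset {name!r}; "
                         f"choose one of {PRESET_NAMES}")
    if repetitions is not None:
        grid = replace(grid, repetitions=repetitions)
    return grid


def _subsample(values: Sequence, scale: float) -> tuple:
    n = max(1, math.ceil(len(values) * scale))
    idx = np.unique(np.round(np.linspace(0, len(values) - 1, n)).astype(int))
    return tuple(values[i] for i in idx)


def shrink_grid(grid: GridSpec, scale: float) -> GridSpec:
    """Desk-scale version of a grid: subsample the d_long/sigma/inhibition
    axes and scale repetitions, keeping the full theta axis (the transition
    estimate needs the whole twist range)."""
    if not 0 < scale <= 1:
        raise ValueError("scale must lie in (0, 1]")
    if scale == 1.0:
        return grid
    return replace(
        grid,
        d_long_values=_subsample(grid.d_long_values, scale),
        sigma_values=_subsample(grid.sigma_values, scale),
        i_inhib_values=_subsample(grid.i_inhib_values, scale),
        repetitions=max(1, round(grid.repetitions * scale)),
    )
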