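"""Parameter sweeps and least-squares analysis of Monte Carlo error surfaces.

These routines tabulate the per-cell Monte Carlo error summaries over grids
of section height z, tilt angle beta, and noise half-width epsilon, and fit
the error-versus-noise scaling.  Each grid cell is simulated with its own
deterministic substream of the master seed, so a sweep row is bit-identical
to an independent `simulate_cell` call at the same parameters.

Tables are pandas DataFrames with columns
``localizer, z_mm, beta_deg, epsilon_mm, n, seed, rms_mm, max_mm``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .localizers import NLocalizerSpec, SectionPose, SturmPastyrSpec
from .montecarlo import ErrorSummary, Localizer, MCConfig, NoiseModel, simulate_cell

__all__ = [
    "SweepGrid",
    "FitResult",
    "TABLE_COLUMNS",
    "sweep_cells",
    "sweep_error_vs_z",
    "sweep_error_vs_beta",
    "sweep_error_vs_epsilon",
    "linear_fit",
    "find_beta_of_max_rms",
]

logger = logging.getLogger(__name__)

TABLE_COLUMNS = ["localizer", "z_mm", "beta_deg", "epsilon_mm", "n", "seed", "rms_mm", "max_mm"]

#: Noise half-widths (mm) of the error-vs-noise study, covering sub-pixel to
#: several-pixel fiducial displacement at typical stereotactic pixel sizes.
DEFAULT_EPSILONS = (0.25, 0.5, 1.0, 2.0, 3.0)


@dataclass(frozen=True)
class SweepGrid:
    """Cartesian grid of cell parameters for a sweep."""

    z_values: tuple[float, ...]
    beta_values: tuple[float, ...] = (0.0,)
    epsilon_values: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        for name, vals in (
            ("z_values", self.z_values),
            ("beta_values", self.beta_values),
            ("epsilon_values", self.epsilon_values),
        ):
            if len(vals) == 0:
                raise ValueError(f"{name} must be nonempty")


@dataclass(frozen=True)
class FitResult:
    """Ordinary least-squares line fit with Pearson correlation."""

    slope: float
    intercept: float
    pearson_r: float


def _summary_row(s: ErrorSummary) -> dict:
    return {
        "localizer": s.localizer.value,
        "z_mm": s.z,
        "beta_deg": s.beta,
        "epsilon_mm": s.epsilon,
        "n": s.n,
        "seed": s.seed,
        "rms_mm": s.rms_error,
        "max_mm": s.max_error,
    }


def sweep_cells(
    localizer: "str | Localizer",
    cells: Iterable[tuple[float, float, float]],
    config: MCConfig,
    n_spec: NLocalizerSpec | None = None,
    sp_spec: SturmPastyrSpec | None = None,
) -> pd.DataFrame:
    """Simulate a sequence of (z, beta, epsilon) cells into a table.

    Cells whose pose is outside the localizer's valid domain are skipped
    with a logged warning rather than aborting the sweep.
    """
    loc = Localizer.parse(localizer)
    rows = []
    for z, beta, eps in cells:
        try:
            pose = SectionPose(z=z, beta=beta)
            summary = simulate_cell(loc, pose, NoiseModel(eps), config, n_spec, sp_spec)
        except ValueError as exc:
            logger.warning(
                "skipping invalid cell (localizer=%s, z=%g, beta=%g, eps=%g): %s",
                loc.value, z, beta, eps, exc,
            )
            continue
        rows.append(_summary_row(summary))
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def _grid_cells(grid: SweepGrid) -> list[tuple[float, float, float]]:
    return [
        (z, b, e)
        for e in grid.epsilon_values
        for b in grid.beta_values
        for z in grid.z_values
    ]


def sweep_error_vs_z(
    localizer: "str | Localizer",
    grid: SweepGrid,
    config: MCConfig,
    **specs,
) -> pd.DataFrame:
    """RMS/max error tabulated along z for each (beta, epsilon) in the grid."""
    return sweep_cells(localizer, _grid_cells(grid), config, **specs)


def sweep_error_vs_beta(
    localizer: "str | Localizer",
    grid: SweepGrid,
    config: MCConfig,
    **specs,
) -> pd.DataFrame:
    """RMS/max error tabulated along beta for each (z, epsilon) in the grid."""
    cells = [
        (z, b, e)
        for e in grid.epsilon_values
        for z in grid.z_values
        for b in grid.beta_values
    ]
    return sweep_cells(localizer, cells, config, **specs)


def sweep_error_vs_epsilon(
    pose: SectionPose,
    epsilon_values: Sequence[float] = DEFAULT_EPSILONS,
    config: MCConfig = MCConfig(),
    localizers: Sequence["str | Localizer"] = (Localizer.N, Localizer.STURM_PASTYR),
    **specs,
) -> pd.DataFrame:
    """Error-versus-noise sweep at a fixed pose, for both localizers by default."""
    eps = [float(e) for e in epsilon_values]
    if any(e < 0 for e in eps):
        raise ValueError("epsilon values must be nonnegative")
    if sorted(eps) != eps:
        raise ValueError("epsilon values must be sorted ascending")
    frames = [
        sweep_cells(loc, [(pose.z, pose.beta, e) for e in eps], config, **specs)
        for loc in localizers
    ]
    return pd.concat(frames, ignore_index=True)


def linear_fit(x: Sequence[float], y: Sequence[float]) -> FitResult:
    """Ordinary least-squares line y = slope*x + intercept, with Pearson r.

    Degenerate inputs (fewer than two points, constant x, or constant y,
    for which the correlation is undefined) raise ``ValueError``.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if np.unique(xa).size < 2:
        raise ValueError("degenerate fit: need at least two distinct x values")
    if np.unique(ya).size < 2:
        raise ValueError("degenerate fit: y is constant, correlation undefined")
    res = stats.linregress(xa, ya)
    return FitResult(slope=float(res.slope), intercept=float(res.intercept),
                     pearson_r=float(res.rvalue))


def find_beta_of_max_rms(
    localizer: "str | Localizer",
    z: float,
    beta_grid: Sequence[float],
    noise: NoiseModel,
    config: MCConfig,
    **specs,
) -> float:
    """Grid tilt angle (deg) at which the Monte Carlo RMS error peaks.

    Ties are broken toward the smaller beta.  A flat all-zero error surface
    (epsilon = 0) has no meaningful maximum and raises ``ValueError``.
    """
    betas = sorted(beta_grid)
    if not betas:
        raise ValueError("beta_grid must be nonempty")
    table = sweep_cells(localizer, [(z, b, noise.epsilon) for b in betas], config, **specs)
    if table.empty:
        raise ValueError("no valid cells in beta_grid")
    if (table["rms_mm"] == 0.0).all():
        raise ValueError("error surface is identically zero; no maximum")
    best = table.loc[table["rms_mm"].idxmax()]
    # idxmax returns the first occurrence; rows are in ascending-beta order
    return float(best["beta_deg"])
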