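"""Roost inference: the rho error surface, point estimates and search effort.

For every cell centre ``z`` of a landscape grid the model-expected call
proportions ``F~(z)`` are compared with the observed proportions ``C`` by the
squared-distance metric

    rho(z) = sum_i (F~_i(z) - C_i)^2 / max_z' sum_i (F~_i(z') - C_i)^2,

so rho is in [0, 1] with its maximum exactly 1 somewhere on the grid.  Low
rho flags plausible roost locations.  Two point estimates are extracted:

* ``z_p``  — the cell centre minimising rho (the model-based prediction);
* ``CC``   — the centre of calls, sum_i C_i X_i, the detector positions
  weighted by their share of calls.  CC always lies inside the convex hull
  of the detectors, which makes it useless when the roost is outside the
  array; the rho surface has no such restriction.

Search effort is summarised by the area (and percentage of the mapped area)
below rho thresholds: searching cells in order of increasing rho finds the
roost after covering the area below ``rho_c``, the rho value at the true
roost.

Note the normalisation is over the evaluated grid only, so rho values (and
rho_c) depend on the grid extent.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .diffusion import DiffusionParams, expected_calls_matrix
from .survey_io import SurveySet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridSpec:
    """A rectangular evaluation grid of n_x x n_y square-ish cells.

    Cell CENTRES are the evaluation points; row 0 is the northernmost row
    and column 0 the westernmost column, so the rho matrix reads like a map.
    ``padding`` expands the extent on all four sides.
    """

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    n_x: int = 500
    n_y: int = 500
    padding: float = 0.0

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("grid extent must have positive width and height")
        if self.n_x < 2 or self.n_y < 2:
            raise ValueError("grid needs at least 2 cells per axis")
        if self.padding < 0:
            raise ValueError("padding must be non-negative")

    @classmethod
    def from_positions(
        cls, positions: np.ndarray, n_x: int = 500, n_y: int = 500, padding: float = 0.0
    ) -> "GridSpec":
        """Grid extent from the min/max of detector coordinates (the map
        extent used for survey rho maps), optionally padded outward.

        A degenerate axis (all detectors collinear) is widened to half the
        other axis' span, or 100 m if both collapse.
        """
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        lo = positions.min(axis=0)
        hi = positions.max(axis=0)
        span = hi - lo
        for ax in (0, 1):
            if span[ax] == 0.0:
                half = max(span[1 - ax] / 2.0, 100.0) / 2.0
                lo[ax] -= half
                hi[ax] += half
        return cls(
            x_min=float(lo[0]),
            x_max=float(hi[0]),
            y_min=float(lo[1]),
            y_max=float(hi[1]),
            n_x=n_x,
            n_y=n_y,
            padding=padding,
        )

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(x_min, x_max, y_min, y_max) after padding."""
        return (
            self.x_min - self.padding,
            self.x_max + self.padding,
            self.y_min - self.padding,
            self.y_max + self.padding,
        )

    @property
    def cell_size(self) -> tuple[float, float]:
        x0, x1, y0, y1 = self.bounds
        return (x1 - x0) / self.n_x, (y1 - y0) / self.n_y

    @property
    def cell_area_km2(self) -> float:
        dx, dy = self.cell_size
        return dx * dy / 1e6

    def x_centres(self) -> np.ndarray:
        x0, x1, _, _ = self.bounds
        dx = (x1 - x0) / self.n_x
        return x0 + dx * (np.arange(self.n_x) + 0.5)

    def y_centres(self) -> np.ndarray:
        """North to south, matching row order of the rho matrix."""
        _, _, y0, y1 = self.bounds
        dy = (y1 - y0) / self.n_y
        return y1 - dy * (np.arange(self.n_y) + 0.5)

    def cell_centres(self) -> np.ndarray:
        """(n_y * n_x, 2) cell centres in row-major (map) order."""
        xs = self.x_centres()
        ys = self.y_centres()
        XX, YY = np.meshgrid(xs, ys)
        return np.stack([XX.ravel(), YY.ravel()], axis=1)

    def cell_of(self, point) -> tuple[int, int] | None:
        """(row, col) of the cell containing ``point``, or None if outside."""
        x, y = float(point[0]), float(point[1])
        x0, x1, y0, y1 = self.bounds
        if not (x0 <= x <= x1 and y0 <= y <= y1):
            return None
        dx, dy = self.cell_size
        col = min(int((x - x0) / dx), self.n_x - 1)
        row = min(int((y1 - y) / dy), self.n_y - 1)
        return row, col


@dataclass
class RhoSurface:
    """The normalised error surface over a grid, with its argmin."""

    grid: GridSpec
    rho: np.ndarray  # (n_y, n_x), row 0 = north
    raw_sse: np.ndarray
    max_sse: float
    argmin_cell: tuple[int, int]

    @property
    def zp(self) -> tuple[float, float]:
        """Best point prediction: centre of the argmin cell."""
        row, col = self.argmin_cell
        return (float(self.grid.x_centres()[col]), float(self.grid.y_centres()[row]))

    def rho_at(self, point) -> float:
        """rho of the cell containing ``point`` (no interpolation)."""
        cell = self.grid.cell_of(point)
        if cell is None:
            raise ValueError(f"point {point} lies outside the evaluated grid")
        return float(self.rho[cell])

    def to_csv(self, path) -> None:
        np.savetxt(path, self.rho, delimiter=",", fmt="%.10g")

    def to_esri_ascii(self, path) -> None:
        """Write the surface as an ESRI ASCII grid (square cells required)."""
        dx, dy = self.grid.cell_size
        if abs(dx - dy) > 1e-9 * max(dx, dy):
            raise ValueError("ESRI ASCII export requires square cells (dx == dy)")
        x0, _, y0, _ = self.grid.bounds
        header = (
            f"ncols {self.grid.n_x}\nnrows {self.grid.n_y}\n"
            f"xllcorner {x0}\nyllcorner {y0}\ncellsize {dx}\n"
            f"NODATA_value -9999\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.rho, fmt="%.10g")


@dataclass
class RoostEstimate:
    """Point estimates and search-effort summaries for one survey."""

    zp: tuple[float, float]
    cc: tuple[float, float]
    dist_zp_cc: float
    confidence: str = "unknown"
    rho_c: float | None = None
    dist_zp_roost: float | None = None
    dist_cc_roost: float | None = None
    area_below: dict[float, float] = field(default_factory=dict)  # threshold -> km^2
    percent_below: dict[float, float] = field(default_factory=dict)
    area_below_rho_c: float | None = None
    percent_below_rho_c: float | None = None
    total_area_km2: float | None = None

    def to_dict(self) -> dict:
        return {
            "zp": list(self.zp),
            "cc": list(self.cc),
            "confidence": self.confidence,
            "rho_c": self.rho_c,
            "distances_km": {
                "zp_cc": self.dist_zp_cc / 1e3,
                "zp_roost": None
                if self.dist_zp_roost is None
                else self.dist_zp_roost / 1e3,
                "cc_roost": None
                if self.dist_cc_roost is None
                else self.dist_cc_roost / 1e3,
            },
            "total_area_km2": self.total_area_km2,
            "area_below_km2": {str(k): v for k, v in self.area_below.items()},
            "percent_below": {str(k): v for k, v in self.percent_below.items()},
            "area_below_rho_c_km2": self.area_below_rho_c,
            "percent_below_rho_c": self.percent_below_rho_c,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def rho_metric(C, F, exponent: float = 2.0) -> float:
    """Unnormalised mismatch sum_i |F_i - C_i|^exponent between observed and
    expected call proportions.  Zero iff the vectors coincide."""
    C = np.asarray(C, dtype=float)
    F = np.asarray(F, dtype=float)
    if C.shape != F.shape:
        raise ValueError(f"length mismatch: C has {C.shape}, F has {F.shape}")
    return float(np.sum(np.abs(F - C) ** exponent))


def build_rho_surface(
    survey: SurveySet,
    grid: GridSpec,
    params: DiffusionParams | None = None,
    mode: str = "approx",
    exponent: float = 2.0,
    time_steps: int | None = None,
) -> RhoSurface:
    """Evaluate rho at every cell centre of ``grid``.

    Each cell is independent (the scan is embarrassingly parallel and any
    evaluation order gives the identical surface); the normalising maximum
    is taken over all evaluated cells so max(rho) == 1 exactly.
    """
    params = params or DiffusionParams()
    C = survey.proportions
    centres = grid.cell_centres()
    E = expected_calls_matrix(
        centres, survey.positions, params, mode=mode, time_steps=time_steps
    )
    totals = E.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = E / totals[:, None]
    raw = np.sum(np.abs(F - C[None, :]) ** exponent, axis=1)
    raw[totals <= 0] = np.nan
    n_bad = int(np.sum(~np.isfinite(raw)))
    if n_bad:
        frac = n_bad / raw.size
        warnings.warn(
            f"{n_bad} grid cell(s) ({100 * frac:.2f}%) could not be evaluated "
            "(no numerical support); set to NaN"
        )
        if frac > 0.01:
            raise ValueError(
                f"{100 * frac:.1f}% of grid cells failed to evaluate; "
                "the grid extends far beyond the kernel support"
            )
    raw = raw.reshape(grid.n_y, grid.n_x)
    max_sse = float(np.nanmax(raw))
    if max_sse <= 0:
        raise ValueError("rho surface is identically zero; degenerate survey")
    rho = raw / max_sse
    flat_argmin = int(np.nanargmin(rho))
    ties = int(np.sum(rho == rho.flat[flat_argmin]))
    if ties > 1:
        logger.info("rho argmin tied across %d cells; keeping first row-major", ties)
    argmin_cell = np.unravel_index(flat_argmin, rho.shape)
    return RhoSurface(
        grid=grid,
        rho=rho,
        raw_sse=raw,
        max_sse=max_sse,
        argmin_cell=(int(argmin_cell[0]), int(argmin_cell[1])),
    )


def centre_of_calls(survey: SurveySet) -> tuple[float, float]:
    """CC = sum_i C_i X_i: detector positions weighted by call share.

    A convex combination of detector positions, so CC always lies within
    their convex hull.
    """
    cc = survey.proportions @ survey.positions
    return (float(cc[0]), float(cc[1]))


def confidence_heuristic(
    estimate: "RoostEstimate | float",
    high: float = 500.0,
    moderate: float = 1000.0,
) -> str:
    """Qualitative confidence from the separation of the two point estimates.

    When z_p and CC agree to within a few hundred metres the roost tends to
    be within a few hundred metres of both; a separation of a kilometre or
    more signals a poor point prediction (though the rho surface can still
    shrink the search area).
    """
    d = estimate.dist_zp_cc if isinstance(estimate, RoostEstimate) else float(estimate)
    if d < high:
        return "high"
    if d < moderate:
        return "moderate"
    return "low"


def search_statistics(
    surface: RhoSurface,
    survey: SurveySet | None = None,
    roost: tuple[float, float] | None = None,
    thresholds: tuple[float, ...] = (0.1, 0.2, 0.3),
    cc: tuple[float, float] | None = None,
) -> RoostEstimate:
    """Assemble point estimates, distances and search-area summaries.

    ``area_below(tau)`` is the mapped area with rho <= tau (cell-count times
    cell area); ``percent_below`` is the same as a percentage of the mapped
    area.  If the true roost is known, ``rho_c`` is the rho of the cell
    containing it and the area below rho_c is the search effort needed to
    find the roost by expanding the search outward from min(rho).
    """
    if cc is None:
        if survey is None:
            raise ValueError("need either a survey or a precomputed centre of calls")
        cc = centre_of_calls(survey)
    if roost is None and survey is not None:
        roost = survey.roost_known
    zp = surface.zp
    n_cells = surface.rho.size
    cell_km2 = surface.grid.cell_area_km2
    finite = surface.rho[np.isfinite(surface.rho)]

    def _below(tau: float) -> int:
        return int(np.sum(finite <= tau))

    area_below = {float(t): _below(t) * cell_km2 for t in thresholds}
    percent_below = {float(t): 100.0 * _below(t) / n_cells for t in thresholds}
    est = RoostEstimate(
        zp=zp,
        cc=cc,
        dist_zp_cc=float(np.hypot(zp[0] - cc[0], zp[1] - cc[1])),
        area_below=area_below,
        percent_below=percent_below,
        total_area_km2=n_cells * cell_km2,
    )
    est.confidence = confidence_heuristic(est)
    if roost is not None:
        est.dist_zp_roost = float(np.hypot(zp[0] - roost[0], zp[1] - roost[1]))
        est.dist_cc_roost = float(np.hypot(cc[0] - roost[0], cc[1] - roost[1]))
        cell = surface.grid.cell_of(roost)
        if cell is None:
            warnings.warn(
                "known roost lies outside the evaluated grid; rho_c undefined"
            )
        else:
            est.rho_c = float(surface.rho[cell])
            est.area_below_rho_c = _below(est.rho_c) * cell_km2
            est.percent_below_rho_c = 100.0 * _below(est.rho_c) / n_cells
    return est
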