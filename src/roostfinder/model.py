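"""Model/Results front end for roost estimation.

``RoostModel`` binds a survey to the diffusion forward model and a landscape
grid; ``fit()`` performs the grid scan and returns a ``RoostResults`` object
carrying the rho surface, the point estimates (z_p and the centre of calls),
search-effort summaries and a text summary() in the style of the survey
tables ecologists report (distances in km, percentages of mapped area).

Typical use::

    model = RoostModel.from_csv("survey.csv", roost=(281500, 67300))
    res = model.fit()
    print(res.summary())
    res.plot()            # rho heatmap with contours
    res.save("outdir/")   # rho CSV + summary JSON
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .diffusion import DiffusionParams
from .inference import (
    GridSpec,
    RhoSurface,
    RoostEstimate,
    build_rho_surface,
    search_statistics,
)
from .survey_io import Detector, SurveySet, load_survey


class RoostModel:
    """Diffusion-based roost location estimator for one acoustic survey.

    Parameters
    ----------
    survey : SurveySet
        Validated detector table with call proportions.
    params : DiffusionParams, optional
        Dispersal/detection parameters (default D=80 m^2/s, T=90 min, r=15 m).
    grid : GridSpec, optional
        Evaluation grid; defaults to a 500 x 500 grid spanning the detector
        extent (optionally padded via ``padding``).
    padding : float
        Metres added on every side when the grid is derived from the
        detectors (use ~3000 when the roost may lie outside the array).
    """

    def __init__(
        self,
        survey: SurveySet,
        params: DiffusionParams | None = None,
        grid: GridSpec | None = None,
        n_x: int = 500,
        n_y: int = 500,
        padding: float = 0.0,
    ):
        self.survey = survey
        self.params = params or DiffusionParams()
        self.grid = grid or GridSpec.from_positions(
            survey.positions, n_x=n_x, n_y=n_y, padding=padding
        )

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        roost: tuple[float, float] | None = None,
        **kwargs,
    ) -> "RoostModel":
        return cls(load_survey(path, roost=roost), **kwargs)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        roost: tuple[float, float] | None = None,
        **kwargs,
    ) -> "RoostModel":
        detectors = [
            Detector(
                id=str(r["id"]),
                easting=float(r["easting"]),
                northing=float(r["northing"]),
                nights_active=int(r["nights_active"]),
                total_calls=int(r["total_calls"]),
            )
            for _, r in df.iterrows()
        ]
        return cls(SurveySet(detectors=detectors, roost_known=roost), **kwargs)

    def fit(
        self,
        mode: str = "approx",
        exponent: float = 2.0,
        thresholds: tuple[float, ...] = (0.1, 0.2, 0.3),
        time_steps: int | None = None,
    ) -> "RoostResults":
        """Scan the grid, normalise the error surface and extract estimates."""
        surface = build_rho_surface(
            self.survey,
            self.grid,
            self.params,
            mode=mode,
            exponent=exponent,
            time_steps=time_steps,
        )
        estimate = search_statistics(
            surface, survey=self.survey, thresholds=thresholds
        )
        return RoostResults(self, surface, estimate)


class RoostResults:
    """Fitted rho surface plus point estimates and search-effort statistics."""

    def __init__(
        self, model: RoostModel, surface: RhoSurface, estimate: RoostEstimate
    ):
        self.model = model
        self.surface = surface
        self.estimate = estimate

    # -- convenience accessors -------------------------------------------
    @property
    def zp(self) -> tuple[float, float]:
        """Best point prediction (argmin of rho)."""
        return self.estimate.zp

    @property
    def cc(self) -> tuple[float, float]:
        """Centre of calls."""
        return self.estimate.cc

    @property
    def rho_c(self) -> float | None:
        """rho at the known roost, if one was supplied."""
        return self.estimate.rho_c

    @property
    def confidence(self) -> str:
        return self.estimate.confidence

    def summary(self) -> str:
        e = self.estimate
        lines = [
            "Roost location estimate (diffusion grid scan)",
            "=" * 53,
            f"detectors: {self.model.survey.n_detectors}   "
            f"grid: {self.surface.grid.n_x} x {self.surface.grid.n_y}   "
            f"mapped area: {e.total_area_km2:.2f} km^2",
            f"D = {self.model.params.D:g} m^2/s   T = {self.model.params.T:g} s   "
            f"r = {self.model.params.detector_radius:g} m",
            "-" * 53,
            f"z_p (argmin rho)     : ({e.zp[0]:.1f}, {e.zp[1]:.1f})",
            f"centre of calls (CC) : ({e.cc[0]:.1f}, {e.cc[1]:.1f})",
            f"|z_p - CC|           : {e.dist_zp_cc / 1e3:.2f} km "
            f"(confidence: {e.confidence})",
        ]
        if e.dist_zp_roost is not None:
            lines += [
                f"|z_R - z_p|          : {e.dist_zp_roost / 1e3:.2f} km",
                f"|z_R - CC|           : {e.dist_cc_roost / 1e3:.2f} km",
            ]
        if e.rho_c is not None:
            lines += [
                f"rho_c (rho at roost) : {e.rho_c:.2f}",
                f"area with rho <= rho_c: {e.area_below_rho_c:.2f} km^2 "
                f"({e.percent_below_rho_c:.2f}% of mapped area)",
            ]
        lines.append("-" * 53)
        lines.append("percentage of mapped area below rho thresholds:")
        for tau, pct in sorted(e.percent_below.items()):
            lines.append(
                f"  rho <= {tau:<4g}: {pct:6.2f}%  ({e.area_below[tau]:.2f} km^2)"
            )
        return "\n".join(lines)

    def plot(self, ax=None, contours: int = 8, show_detectors: bool = True):
        """Heatmap of rho with contours; detectors as crosses, z_p a diamond,
        CC a square, and the known roost (if any) a circle."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 6))
        x0, x1, y0, y1 = self.surface.grid.bounds
        im = ax.imshow(
            self.surface.rho,
            extent=(x0, x1, y0, y1),
            origin="upper",
            cmap="viridis_r",
            vmin=0.0,
            vmax=1.0,
        )
        xs = self.surface.grid.x_centres()
        ys = self.surface.grid.y_centres()
        ax.contour(xs, ys, self.surface.rho, levels=contours, colors="white",
                   linewidths=0.6)
        if show_detectors:
            pos = self.model.survey.positions
            ax.plot(pos[:, 0], pos[:, 1], "k+", ms=7, label="detectors")
        ax.plot(*self.zp, "wD", mec="k", ms=9, label="$z_p$ (argmin rho)")
        ax.plot(*self.cc, "ws", mec="k", ms=9, label="centre of calls")
        if self.model.survey.roost_known is not None:
            ax.plot(*self.model.survey.roost_known, "wo", mec="k", ms=9,
                    label="known roost")
        ax.set_xlabel("easting (m)")
        ax.set_ylabel("northing (m)")
        ax.legend(loc="upper right", fontsize=8)
        ax.figure.colorbar(im, ax=ax, label=r"$\rho$")
        return ax

    def save(self, outdir: str | Path, stem: str = "roost") -> dict[str, Path]:
        """Write the rho surface (CSV matrix) and the summary JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "rho_csv": outdir / f"{stem}_rho.csv",
            "summary_json": outdir / f"{stem}_summary.json",
        }
        self.surface.to_csv(paths["rho_csv"])
        self.estimate.to_json(paths["summary_json"])
        return paths

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        zp = self.zp
        return f"<RoostResults z_p=({zp[0]:.0f}, {zp[1]:.0f}) confidence={self.confidence}>"
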