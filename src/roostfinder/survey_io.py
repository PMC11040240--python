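"""Reading, writing and validation of static-detector survey tables.

A survey is a table of acoustic detectors, each with a planar position
(eastings/northings in metres), the number of nights it was active and the
total number of bat passes it recorded in the analysis window (the first
90 minutes after sunset).  Because detectors fail on different nights, call
counts are first averaged per detector over its own active nights, and the
nightly rates are then normalised into proportions

    C_i = c_i / sum_j c_j,      c_i = total_calls_i / nights_active_i.

Coordinates are treated as a metric Cartesian system (UK Ordnance Survey
eastings/northings or any planar equivalent); no geographic projection is
performed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CSV_COLUMNS = ["id", "easting", "northing", "nights_active", "total_calls"]


@dataclass(frozen=True)
class Detector:
    """One static acoustic detector and its aggregated survey record."""

    id: str
    easting: float
    northing: float
    nights_active: int
    total_calls: int

    def __post_init__(self) -> None:
        if not (np.isfinite(self.easting) and np.isfinite(self.northing)):
            raise ValueError(f"detector {self.id!r}: non-finite coordinates")
        if self.nights_active < 0:
            raise ValueError(f"detector {self.id!r}: nights_active must be >= 0")
        if self.total_calls < 0:
            raise ValueError(f"detector {self.id!r}: total_calls must be >= 0")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.easting, self.northing], dtype=float)


@dataclass
class SurveySet:
    """A validated survey: detectors plus derived nightly rates and proportions.

    Only detectors with ``nights_active > 0`` are retained (a detector that
    never ran carries no information); detectors that ran but recorded zero
    calls are kept, since silence constrains the roost location too.
    """

    detectors: list[Detector]
    roost_known: tuple[float, float] | None = None
    daily_rates: np.ndarray = field(init=False)
    proportions: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        dropped = [d for d in self.detectors if d.nights_active == 0]
        if dropped:
            logger.warning(
                "excluding %d detector(s) with zero active nights: %s",
                len(dropped),
                ", ".join(d.id for d in dropped),
            )
        self.detectors = [d for d in self.detectors if d.nights_active > 0]
        if not self.detectors:
            raise ValueError("survey contains no detectors with active nights")
        ids = [d.id for d in self.detectors]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate detector ids: {dupes}")
        self.daily_rates = np.array(
            [d.total_calls / d.nights_active for d in self.detectors], dtype=float
        )
        self.proportions = normalize_calls(self.daily_rates)
        if self.roost_known is not None:
            self.roost_known = (float(self.roost_known[0]), float(self.roost_known[1]))

    @property
    def n_detectors(self) -> int:
        return len(self.detectors)

    @property
    def positions(self) -> np.ndarray:
        """(N, 2) array of detector (easting, northing)."""
        return np.array([[d.easting, d.northing] for d in self.detectors])

    @property
    def ids(self) -> list[str]:
        return [d.id for d in self.detectors]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": self.ids,
                "easting": [d.easting for d in self.detectors],
                "northing": [d.northing for d in self.detectors],
                "nights_active": [d.nights_active for d in self.detectors],
                "total_calls": [d.total_calls for d in self.detectors],
            }
        )
        return df


def normalize_calls(daily_rates: np.ndarray) -> np.ndarray:
    """Turn per-detector nightly call rates into proportions of the total.

    Parameters
    ----------
    daily_rates : array-like
        Non-negative calls-per-night values, at least one positive.

    Returns
    -------
    ndarray summing to 1, in the input order.
    """
    rates = np.asarray(daily_rates, dtype=float)
    if rates.ndim != 1 or rates.size == 0:
        raise ValueError("daily_rates must be a non-empty 1-D vector")
    if np.any(rates < 0) or not np.all(np.isfinite(rates)):
        raise ValueError("daily_rates must be finite and non-negative")
    total = rates.sum()
    if total <= 0:
        raise ValueError("no calls recorded: cannot normalise an all-zero survey")
    return rates / total


def load_survey(
    path: str | Path, roost: tuple[float, float] | None = None
) -> SurveySet:
    """Read a detector CSV (columns id, easting, northing, nights_active,
    total_calls) into a validated :class:`SurveySet`.

    Detectors with zero active nights are dropped with a logged warning.
    Malformed rows raise ``ValueError`` naming the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    detectors = []
    for idx, row in df.iterrows():
        try:
            nights = int(row["nights_active"])
            calls = int(row["total_calls"])
            if nights != row["nights_active"] or calls != row["total_calls"]:
                raise ValueError("counts must be integers")
            detectors.append(
                Detector(
                    id=str(row["id"]),
                    easting=float(row["easting"]),
                    northing=float(row["northing"]),
                    nights_active=nights,
                    total_calls=calls,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row {idx} (id={row['id']!r}): {exc}") from exc
    return SurveySet(detectors=detectors, roost_known=roost)


def save_survey(survey: SurveySet, path: str | Path) -> None:
    """Write a survey back to the standard CSV schema (full float precision)."""
    df = survey.to_dataframe()
    df.to_csv(path, index=False, float_format="%.17g")
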