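"""Tabular I/O for dissolution experiments and topography metrics.

Covers the three on-disk shapes of a flow-channel dissolution study:

* measurement tables (substance, temperature, Re, sample diameter,
  replicate, IDR) as CSV;
* closed-loop concentration--time series, from which the IDR follows as
  (V/A) times the OLS slope over an evaluation window;
* profilometer line profiles along the flow direction, compared between
  states (dry, start of evaluation t1, end of test t2) to quantify
  protrusion, erosion and swelling.

IDR is stored internally in SI (kg m^-2 s^-1); the pharma convention
mg min^-1 cm^-2 is accepted on disk and converted on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConcentrationSeries",
    "DissolutionMeasurement",
    "TopographyMetrics",
    "TopographyProfile",
    "idr_from_series",
    "read_measurements",
    "read_series",
    "read_topography",
    "topography_metrics",
    "write_measurements",
]

#: 1 mg min^-1 cm^-2 in kg m^-2 s^-1
MG_MIN_CM2_TO_SI = 1e-6 / (60.0 * 1e-4)

_IDR_UNIT_FACTORS = {
    "kg_m2_s": 1.0,
    "mg_min_cm2": MG_MIN_CM2_TO_SI,
}

MEASUREMENT_COLUMNS = [
    "substance", "temperature_C", "reynolds", "sample_diameter_mm",
    "replicate", "idr", "idr_unit",
]

DEFAULT_DIAMETERS_MM = (8.0, 13.0)


@dataclass(frozen=True)
class DissolutionMeasurement:
    """One intrinsic-dissolution experiment at a fixed operating point."""

    substance: str
    temperature_C: float
    reynolds: float
    sample_diameter_mm: float
    replicate: int
    idr: float  # kg m^-2 s^-1 (SI)

    def __post_init__(self) -> None:
        if self.idr <= 0:
            raise ValueError("idr must be positive")
        if self.reynolds <= 0:
            raise ValueError("reynolds must be positive")


@dataclass
class ConcentrationSeries:
    """Closed-loop concentration--time series (SI internally)."""

    time_s: np.ndarray
    concentration_kg_m3: np.ndarray
    medium_volume_ml: float = 900.0
    tablet_area_m2: float = np.pi * (4e-3) ** 2  # 8 mm disc
    window: tuple[float, float] | None = None  # [t_start, t_end], s

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.concentration_kg_m3 = np.asarray(self.concentration_kg_m3, dtype=float)
        if self.time_s.shape != self.concentration_kg_m3.shape:
            raise ValueError("time and concentration must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.concentration_kg_m3 < 0):
            raise ValueError("concentrations must be non-negative")
        if self.window is not None:
            t0, t1 = self.window
            if not (self.time_s[0] <= t0 < t1 <= self.time_s[-1]):
                raise ValueError("window must lie within the series span")


def idr_from_series(series: ConcentrationSeries) -> float:
    """IDR (kg m^-2 s^-1) from a closed-loop concentration series.

    IDR = (V/A) * slope, where the slope comes from an OLS line fitted on
    the evaluation window (default: skip the first 60 s of equilibration).
    """
    t, c = series.time_s, series.concentration_kg_m3
    if series.window is None:
        window = (min(t[0] + 60.0, t[-1] - 1e-9), t[-1])
    else:
        window = series.window
    mask = (t >= window[0]) & (t <= window[1])
    if mask.sum() < 3:
        raise ValueError(
            f"evaluation window {window} contains {int(mask.sum())} points; "
            "need at least 3"
        )
    slope, _ = np.polyfit(t[mask], c[mask], 1)
    if slope < 0:
        raise ValueError(
            f"negative concentration slope ({slope:.3g} kg m^-3 s^-1): "
            "data-quality problem in the evaluation window"
        )
    volume_m3 = series.medium_volume_ml * 1e-6
    return volume_m3 * float(slope) / series.tablet_area_m2


def read_measurements(
    path: str | Path,
    allowed_diameters_mm=DEFAULT_DIAMETERS_MM,
) -> list[DissolutionMeasurement]:
    """Read a measurement CSV (schema-validated; unknown columns ignored)."""
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement CSV {path}: missing columns {missing}")
    out: list[DissolutionMeasurement] = []
    for idx, row in df.iterrows():
        try:
            unit = str(row["idr_unit"])
            if unit not in _IDR_UNIT_FACTORS:
                raise ValueError(
                    f"unknown idr_unit {unit!r}; "
                    f"supported: {sorted(_IDR_UNIT_FACTORS)}"
                )
            diameter = float(row["sample_diameter_mm"])
            if not any(abs(diameter - d) < 1e-9 for d in allowed_diameters_mm):
                raise ValueError(
                    f"sample diameter {diameter} mm not in the declared set "
                    f"{tuple(allowed_diameters_mm)}"
                )
            out.append(DissolutionMeasurement(
                substance=str(row["substance"]),
                temperature_C=float(row["temperature_C"]),
                reynolds=float(row["reynolds"]),
                sample_diameter_mm=diameter,
                replicate=int(row["replicate"]),
                idr=float(row["idr"]) * _IDR_UNIT_FACTORS[unit],
            ))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"measurement CSV {path}, row {idx}: {exc}") from exc
    return out


def write_measurements(
    measurements, path: str | Path, idr_unit: str = "kg_m2_s"
) -> None:
    """Write measurements to CSV in the requested IDR unit."""
    if idr_unit not in _IDR_UNIT_FACTORS:
        raise ValueError(f"unknown idr_unit {idr_unit!r}")
    factor = _IDR_UNIT_FACTORS[idr_unit]
    df = pd.DataFrame([
        {
            "substance": m.substance,
            "temperature_C": m.temperature_C,
            "reynolds": m.reynolds,
            "sample_diameter_mm": m.sample_diameter_mm,
            "replicate": m.replicate,
            "idr": m.idr / factor,
            "idr_unit": idr_unit,
        }
        for m in measurements
    ], columns=MEASUREMENT_COLUMNS)
    df.to_csv(path, index=False)


def read_series(path: str | Path) -> ConcentrationSeries:
    """Read a series CSV (time_s, concentration_kg_m3) with an optional
    ``# key: value`` metadata header block (volume_ml, diameter_mm,
    window_start_s, window_end_s)."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    data_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line.lstrip("#").partition(":")
            meta[key.strip()] = float(value)
            data_start = i + 1
        else:
            break
    import io

    df = pd.read_csv(io.StringIO("".join(lines[data_start:])))
    for col in ("time_s", "concentration_kg_m3"):
        if col not in df.columns:
            raise ValueError(f"series CSV {path}: missing column {col!r}")
    diameter_mm = meta.get("diameter_mm", 8.0)
    window = None
    if "window_start_s" in meta and "window_end_s" in meta:
        window = (meta["window_start_s"], meta["window_end_s"])
    return ConcentrationSeries(
        time_s=df["time_s"].to_numpy(),
        concentration_kg_m3=df["concentration_kg_m3"].to_numpy(),
        medium_volume_ml=meta.get("volume_ml", 900.0),
        tablet_area_m2=np.pi * (diameter_mm * 1e-3 / 2.0) ** 2,
        window=window,
    )


@dataclass
class TopographyProfile:
    """Line profile of the tablet surface along the flow direction.

    ``position_mm`` runs along the ~10 mm evaluation line through the
    tablet center; ``tablet_start_mm`` marks where the tablet's leading
    edge sits on that line.
    """

    position_mm: np.ndarray
    height_um: np.ndarray
    state: str  # dry | t1 | t2
    temperature_C: float = 37.0
    reynolds: float = 600.0
    tablet_start_mm: float = 1.0

    def __post_init__(self) -> None:
        self.position_mm = np.asarray(self.position_mm, dtype=float)
        self.height_um = np.asarray(self.height_um, dtype=float)
        if self.position_mm.shape != self.height_um.shape:
            raise ValueError("position and height must have equal length")
        if np.any(np.diff(self.position_mm) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.state not in ("dry", "t1", "t2"):
            raise ValueError("state must be one of dry, t1, t2")


@dataclass(frozen=True)
class TopographyMetrics:
    """Surface-change metrics between measurement states (um).

    Sign convention for changes: negative = erosion (mass removal),
    positive = swelling / protrusion growth.
    """

    max_protrusion_um: dict[str, float]
    leading_edge_change_um: float  # t2 - t1 over the first 0.5 mm of tablet
    mean_change_um: float  # t2 - t1 averaged over the full common grid
    leading_edge_window_mm: float = 0.5


def topography_metrics(
    profiles: dict[str, TopographyProfile],
    leading_edge_window_mm: float = 0.5,
) -> TopographyMetrics:
    """Compare profiles between states on a common position grid.

    Requires at least the ``t1`` and ``t2`` states; profiles are resampled
    by linear interpolation onto the grid of ``t1`` restricted to the
    overlap of all profiles.  The leading-edge change averages t2 - t1 over
    the first ``leading_edge_window_mm`` of the tablet.
    """
    if "t1" not in profiles or "t2" not in profiles:
        raise ValueError("need at least states t1 and t2 to compute changes")
    lo = max(p.position_mm[0] for p in profiles.values())
    hi = min(p.position_mm[-1] for p in profiles.values())
    if hi <= lo:
        raise ValueError("profiles have no overlapping position range")
    base = profiles["t1"]
    grid = base.position_mm[(base.position_mm >= lo) & (base.position_mm <= hi)]
    resampled = {
        state: np.interp(grid, p.position_mm, p.height_um)
        for state, p in profiles.items()
    }
    diff = resampled["t2"] - resampled["t1"]
    edge_start = base.tablet_start_mm
    edge_mask = (grid >= edge_start) & (grid <= edge_start + leading_edge_window_mm)
    if not edge_mask.any():
        raise ValueError(
            "no profile points in the leading-edge window "
            f"[{edge_start}, {edge_start + leading_edge_window_mm}] mm"
        )
    return TopographyMetrics(
        max_protrusion_um={s: float(h.max()) for s, h in resampled.items()},
        leading_edge_change_um=float(diff[edge_mask].mean()),
        mean_change_um=float(diff.mean()),
        leading_edge_window_mm=leading_edge_window_mm,
    )


def read_topography(path: str | Path) -> dict[str, TopographyProfile]:
    """Read a topography CSV (position_mm, height_um, state, temperature_C,
    reynolds) into per-state profiles."""
    df = pd.read_csv(path)
    required = ["position_mm", "height_um", "state"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"topography CSV {path}: missing columns {missing}")
    profiles: dict[str, TopographyProfile] = {}
    for state, group in df.groupby("state"):
        group = group.sort_values("position_mm")
        profiles[str(state)] = TopographyProfile(
            position_mm=group["position_mm"].to_numpy(),
            height_um=group["height_um"].to_numpy(),
            state=str(state),
            temperature_C=float(group["temperature_C"].iloc[0])
            if "temperature_C" in group else 37.0,
            reynolds=float(group["reynolds"].iloc[0])
            if "reynolds" in group else 600.0,
        )
    return profiles
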