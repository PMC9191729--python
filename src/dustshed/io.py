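"""Plot-table and grid I/O, distance classes, imputation, map projection.

The canonical interchange format is CSV.  A *plot table* is a pandas
DataFrame with one row per vegetation plot and the required columns

    plot_id, x, y, dist_road, side, habitat, richness

plus ``log_dist`` (derived, = log10(dist_road)) and any number of extra
numeric columns, which are treated as covariates (element concentrations
in moss tissue, % blackening, cover values, ...).  Coordinates are metres
in a projected system; ``dist_road`` is distance to the road centreline.

A *grid table* holds prediction points:

    point_id, x, y, dist_road, side, habitat, area_weight_km2, in_easement
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("dustshed")

REQUIRED_PLOT_COLUMNS = ("plot_id", "x", "y", "dist_road", "side", "habitat", "richness")
REQUIRED_GRID_COLUMNS = (
    "point_id", "x", "y", "dist_road", "side", "habitat", "area_weight_km2", "in_easement",
)

#: Distance-to-road strata (m).  Half-open [lo, hi); the closing edge is
#: inclusive so a plot at exactly 4000 m falls in the last stratum.
DEFAULT_CLASS_EDGES = (0.0, 50.0, 100.0, 300.0, 1000.0, 2000.0, 3000.0, 4000.0)

#: The nominal sampling distances of the transect design (m).
DESIGN_DISTANCES = (10.0, 50.0, 100.0, 300.0, 1000.0, 2000.0, 4000.0)

FLOAT_FORMAT = "%.17g"


class FormatError(ValueError):
    """A file does not match the expected layout (e.g. a missing column)."""


class ValidationError(ValueError):
    """A file parses but carries invalid values."""


# ---------------------------------------------------------------------------
# distance classes
# ---------------------------------------------------------------------------

def distance_class(dist: np.ndarray | float, edges: Sequence[float] = DEFAULT_CLASS_EDGES) -> np.ndarray:
    """Assign distances to half-open strata [lo, hi); the last edge is inclusive.

    Returns integer class indices 0 .. len(edges)-2.  Distances outside
    [edges[0], edges[-1]] raise ValidationError.
    """
    edges = np.asarray(edges, dtype=float)
    if not np.all(np.diff(edges) > 0):
        raise ValidationError("class edges must be strictly increasing")
    d = np.atleast_1d(np.asarray(dist, dtype=float))
    if np.any(d < edges[0]) or np.any(d > edges[-1]):
        bad = d[(d < edges[0]) | (d > edges[-1])]
        raise ValidationError(f"distances outside [{edges[0]}, {edges[-1]}]: {bad[:5]}")
    idx = np.digitize(d, edges, right=False) - 1
    idx[d == edges[-1]] = len(edges) - 2
    return idx if np.ndim(dist) else int(idx[0])


def class_labels(edges: Sequence[float] = DEFAULT_CLASS_EDGES) -> list[str]:
    e = [int(v) if float(v).is_integer() else v for v in edges]
    return [f"{lo}-{hi}" for lo, hi in zip(e[:-1], e[1:])]


# ---------------------------------------------------------------------------
# plot tables
# ---------------------------------------------------------------------------

def validate_plot_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate invariants of a plot table and derive ``log_dist``.

    Returns the (possibly augmented) table; raises FormatError /
    ValidationError on violations.
    """
    for col in REQUIRED_PLOT_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"missing required column: {col!r}")
    t = table.copy()
    if t["plot_id"].duplicated().any():
        dup = t.loc[t["plot_id"].duplicated(), "plot_id"].tolist()
        raise ValidationError(f"duplicate plot_id values: {dup}")
    rich = pd.to_numeric(t["richness"], errors="coerce")
    bad = rich.isna() | (rich < 0) | (rich != np.floor(rich))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"richness must be a non-negative integer; bad value at row {row}: "
            f"{t['richness'].iloc[row]!r}"
        )
    t["richness"] = rich.astype(int)
    d = pd.to_numeric(t["dist_road"], errors="coerce")
    if d.isna().any() or (d <= 0).any():
        row = int(np.flatnonzero((d.isna() | (d <= 0)).to_numpy())[0])
        raise ValidationError(f"dist_road must be > 0 (log10 undefined); bad row {row}")
    t["dist_road"] = d.astype(float)
    t["log_dist"] = np.log10(t["dist_road"].to_numpy())
    return t


def read_plot_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a plot CSV; unknown columns are kept as covariates."""
    table = pd.read_csv(path)
    return validate_plot_table(table)


def write_plot_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def covariate_columns(table: pd.DataFrame) -> list[str]:
    known = set(REQUIRED_PLOT_COLUMNS) | {"log_dist", "lon", "lat", "transect"}
    return [c for c in table.columns if c not in known]


def read_grid_table(path: str | Path) -> pd.DataFrame:
    grid = pd.read_csv(path)
    for col in REQUIRED_GRID_COLUMNS:
        if col not in grid.columns:
            raise FormatError(f"missing required column: {col!r}")
    if (grid["area_weight_km2"] < 0).any():
        raise ValidationError("area_weight_km2 must be >= 0")
    if (grid["dist_road"] < 0).any():
        raise ValidationError("dist_road must be >= 0")
    grid["in_easement"] = grid["in_easement"].astype(bool)
    return grid


def write_grid_table(grid: pd.DataFrame, path: str | Path) -> None:
    grid.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_community_matrix(path: str | Path) -> pd.DataFrame:
    """Community CSV: first column plot_id, remaining columns taxa (% cover)."""
    m = pd.read_csv(path, index_col=0)
    if (m.to_numpy(dtype=float) < 0).any():
        raise ValidationError("negative abundances in community matrix")
    return m


def write_community_matrix(m: pd.DataFrame, path: str | Path) -> None:
    m.to_csv(path, index=True, index_label="plot_id", float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# missing-covariate imputation
# ---------------------------------------------------------------------------

def impute_missing_covariate(
    table: pd.DataFrame,
    covariate: str,
    edges: Sequence[float] = DEFAULT_CLASS_EDGES,
) -> pd.DataFrame:
    """Fill missing covariate values from same-side, same-distance-class plots.

    Each missing entry is replaced by the mean of the other plots from the
    same side of the road in the same distance-to-road stratum (the rule
    used for the two moss-tissue samples that could not be collected in
    the field).  Raises ValidationError when a missing entry has no
    non-missing neighbours in its (side, stratum) cell.
    """
    if covariate not in table.columns:
        raise FormatError(f"no such covariate column: {covariate!r}")
    t = table.copy()
    cls = distance_class(t["dist_road"].to_numpy(), edges)
    values = pd.to_numeric(t[covariate], errors="coerce")
    missing = values.isna()
    if not missing.any():
        return t
    n_imputed = 0
    for idx in np.flatnonzero(missing.to_numpy()):
        side = t["side"].iloc[idx]
        cell = (t["side"] == side).to_numpy() & (cls == cls[idx])
        donors = values[cell & ~missing.to_numpy()]
        if donors.empty:
            raise ValidationError(
                f"cannot impute {covariate!r} for plot "
                f"{t['plot_id'].iloc[idx]!r}: no non-missing values on side "
                f"{side!r} in its distance class"
            )
        values.iloc[idx] = donors.mean()
        n_imputed += 1
    t[covariate] = values
    log.info("imputed %d missing value(s) of %r", n_imputed, covariate)
    return t


# ---------------------------------------------------------------------------
# Transverse Mercator projection (WGS84, Snyder series)
# ---------------------------------------------------------------------------

_WGS84_A = 6378137.0
_WGS84_F = 1.0 / 298.257223563


def project_coordinates(
    lon: Iterable[float],
    lat: Iterable[float],
    central_meridian: float | None = None,
    false_easting: float = 500_000.0,
    k0: float = 0.9996,
) -> tuple[np.ndarray, np.ndarray]:
    """Project geographic coordinates to Transverse Mercator metres.

    The central meridian defaults to the mean of the input longitudes, so
    a local study area sits near the distortion-free line of the
    projection.  Uses the ellipsoidal series expansion (WGS84); accuracy
    is millimetres within a few degrees of the meridian.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    if lon.shape != lat.shape:
        raise ValidationError("lon and lat must have the same shape")
    if np.any((lat < -90.0) | (lat > 90.0)):
        raise ValidationError("latitude outside [-90, 90]")
    if central_meridian is None:
        central_meridian = float(lon.mean())

    a, f = _WGS84_A, _WGS84_F
    e2 = f * (2.0 - f)
    ep2 = e2 / (1.0 - e2)
    phi = np.radians(lat)
    dlam = np.radians(lon - central_meridian)

    sin_phi, cos_phi, tan_phi = np.sin(phi), np.cos(phi), np.tan(phi)
    N = a / np.sqrt(1.0 - e2 * sin_phi**2)
    T = tan_phi**2
    C = ep2 * cos_phi**2
    A = dlam * cos_phi

    M = a * (
        (1 - e2 / 4 - 3 * e2**2 / 64 - 5 * e2**3 / 256) * phi
        - (3 * e2 / 8 + 3 * e2**2 / 32 + 45 * e2**3 / 1024) * np.sin(2 * phi)
        + (15 * e2**2 / 256 + 45 * e2**3 / 1024) * np.sin(4 * phi)
        - (35 * e2**3 / 3072) * np.sin(6 * phi)
    )

    x = false_easting + k0 * N * (
        A
        + (1 - T + C) * A**3 / 6
        + (5 - 18 * T + T**2 + 72 * C - 58 * ep2) * A**5 / 120
    )
    y = k0 * (
        M
        + N * tan_phi * (
            A**2 / 2
            + (5 - T + 9 * C + 4 * C**2) * A**4 / 24
            + (61 - 58 * T + T**2 + 600 * C - 330 * ep2) * A**6 / 720
        )
    )
    return x, y


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    config: dict,
    seed: int | None,
    inputs: Sequence[str | Path] = (),
) -> Path:
    """Write a machine-readable run manifest (config + seed + input hashes)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "seed": seed,
        "config": config,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return path
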