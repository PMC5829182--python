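"""Point-cloud I/O and projection rendering for dual-wavelength TLS scans.

In-memory container convention
------------------------------
Point clouds are :class:`pandas.DataFrame` objects with a fixed column schema.
Monospectral clouds (one per laser band) carry::

    x, y, z, range, shot_number, band, intensity, rho_app

and classified bispectral clouds additionally carry ``class`` and ``prob``.
``intensity`` (raw digital number, counts) and ``rho_app`` (apparent
reflectance, unitless) are mutually exclusive per file: exactly one of the two
is populated, the other is NaN. ``azimuth`` and ``zenith`` (radians) are
derived columns, recomputed from the Cartesian coordinates on read.

Coordinate convention (used everywhere in the package): scanner-centric,
z-up, right-handed; zenith is measured from +z and azimuth clockwise from the
north-equivalent +y axis, so a unit direction is
``(sin z * sin a, sin z * cos a, cos z)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NIR = "NIR_1064"
SWIR = "SWIR_1548"
BANDS = (NIR, SWIR)

#: wavelengths (nm) of the two laser bands
BAND_WAVELENGTHS = {NIR: 1064.0, SWIR: 1548.0}

#: class labels of a classified cloud
CLASS_LABELS = ("ground", "leaf", "wood")

#: native CSV column order (fixed package convention)
CSV_COLUMNS = ["x", "y", "z", "range", "shot_number", "band",
               "intensity", "rho_app", "class", "prob"]

MONO_COLUMNS = ["x", "y", "z", "range", "shot_number", "band",
                "intensity", "rho_app"]

#: coordinate / range agreement tolerance (m)
RANGE_TOL_M = 1e-6

#: no-data value of projection label images
NO_DATA = -1


class FormatError(ValueError):
    """A file does not conform to the expected point-cloud format."""


class ValidationError(ValueError):
    """Point records violate a structural invariant."""


@dataclass(frozen=True)
class ScanConfig:
    """Angular geometry of one hemispherical scan.

    Defaults follow the DWEL operating mode used throughout this package:
    2 mrad angular sampling with 2.5 mrad beam divergence, zenith coverage
    0-117 degrees and full azimuth coverage.

    Parameters
    ----------
    angular_resolution : float
        Angular step between successive shots, mrad.
    beam_divergence : float
        Full divergence (footprint diameter in angle space), mrad. Must be
        at least the angular resolution for gapless coverage.
    zenith_range, azimuth_range : tuple of float
        (min, max) in degrees.
    """

    angular_resolution: float = 2.0
    beam_divergence: float = 2.5
    zenith_range: tuple[float, float] = (0.0, 117.0)
    azimuth_range: tuple[float, float] = (0.0, 360.0)
    band_wavelengths: tuple[float, float] = (1064.0, 1548.0)

    def __post_init__(self) -> None:
        if not self.angular_resolution > 0:
            raise ValueError("angular_resolution must be > 0")
        if self.beam_divergence < self.angular_resolution:
            raise ValueError("beam_divergence must be >= angular_resolution")
        z0, z1 = self.zenith_range
        a0, a1 = self.azimuth_range
        if not (0.0 <= z0 < z1 <= 180.0):
            raise ValueError("zenith_range must be ordered within [0, 180] deg")
        if not (0.0 <= a0 < a1 <= 360.0):
            raise ValueError("azimuth_range must be ordered within [0, 360] deg")
        if tuple(self.band_wavelengths) != (1064.0, 1548.0):
            raise ValueError("band_wavelengths are fixed at (1064, 1548) nm")


def direction_from_angles(azimuth: np.ndarray, zenith: np.ndarray) -> np.ndarray:
    """Unit direction vectors (n, 3) from azimuth/zenith in radians."""
    az = np.asarray(azimuth, dtype=float)
    zn = np.asarray(zenith, dtype=float)
    sz = np.sin(zn)
    return np.stack([sz * np.sin(az), sz * np.cos(az), np.cos(zn)], axis=-1)


def angles_from_xyz(x: np.ndarray, y: np.ndarray, z: np.ndarray,
                    r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(azimuth, zenith) in radians from Cartesian coordinates; azimuth in [0, 2pi)."""
    az = np.mod(np.arctan2(x, y), 2.0 * math.pi)
    with np.errstate(invalid="ignore"):
        zn = np.arccos(np.clip(np.asarray(z, dtype=float) / np.asarray(r, dtype=float),
                               -1.0, 1.0))
    return az, zn


def _attach_angles(df: pd.DataFrame) -> pd.DataFrame:
    az, zn = angles_from_xyz(df["x"].to_numpy(), df["y"].to_numpy(),
                             df["z"].to_numpy(), df["range"].to_numpy())
    df = df.copy()
    df["azimuth"] = az
    df["zenith"] = zn
    return df


def validate_mono(df: pd.DataFrame) -> None:
    """Check the MonoReturn invariants; raise :class:`ValidationError` on failure."""
    r = df["range"].to_numpy(dtype=float)
    if not np.all(r > 0):
        raise ValidationError("all ranges must be > 0")
    rr = np.sqrt(df["x"].to_numpy(dtype=float) ** 2
                 + df["y"].to_numpy(dtype=float) ** 2
                 + df["z"].to_numpy(dtype=float) ** 2)
    bad = np.abs(rr - r) > RANGE_TOL_M
    if bad.any():
        i = int(np.argmax(bad))
        raise ValidationError(
            f"record {i}: range {r[i]:.6f} disagrees with |xyz| {rr[i]:.6f} "
            f"by more than {RANGE_TOL_M} m")
    unknown = set(df["band"].unique()) - set(BANDS)
    if unknown:
        raise ValidationError(f"unknown band value(s): {sorted(unknown)}")
    if (df["shot_number"].to_numpy() < 0).any():
        raise ValidationError("shot_number must be non-negative")
    rho = df["rho_app"].to_numpy(dtype=float)
    if np.any(rho[~np.isnan(rho)] < 0):
        raise ValidationError("rho_app must be >= 0 where populated")


def is_calibrated(df: pd.DataFrame) -> bool:
    """True when apparent reflectance (not raw DN) is the populated intensity field."""
    return bool(df["rho_app"].notna().all()) and len(df) > 0


def read_point_cloud(path, format: str = "ascii_csv") -> pd.DataFrame:
    """Read a point cloud in the package-native ASCII CSV format.

    Returns a DataFrame with the mono/classified schema plus derived
    ``azimuth`` and ``zenith`` columns. Record order is preserved. Shot
    numbers need not be monotonic.
    """
    if format == "las":
        raise FormatError(
            "LAS I/O requires the optional 'laspy' dependency, which is not "
            "installed; use format='ascii_csv'")
    if format != "ascii_csv":
        raise FormatError(f"unknown format {format!r}")
    df = pd.read_csv(path)
    required = ["x", "y", "z", "range", "shot_number", "band"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column: {col!r}")
    if "intensity" not in df.columns and "rho_app" not in df.columns:
        raise FormatError("missing required column: 'intensity' or 'rho_app'")
    for col in CSV_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df["shot_number"] = df["shot_number"].astype(np.int64)
    if df["intensity"].isna().all() and df["rho_app"].isna().all():
        raise FormatError("neither 'intensity' nor 'rho_app' is populated")
    validate_mono(df)
    return _attach_angles(df)


def write_point_cloud(df: pd.DataFrame, path, format: str = "ascii_csv") -> None:
    """Write a (mono or classified) cloud to the native CSV format.

    Numeric fields are written with 10 significant digits so round trips are
    lossless well past the 6-significant-digit contract.
    """
    if format == "las":
        raise FormatError(
            "LAS I/O requires the optional 'laspy' dependency, which is not "
            "installed; use format='ascii_csv'")
    if format != "ascii_csv":
        raise FormatError(f"unknown format {format!r}")
    out = df.copy()
    for col in CSV_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    # extra columns (e.g. simulator truth labels) ride after the fixed schema
    extras = [c for c in out.columns
              if c not in CSV_COLUMNS and c not in ("azimuth", "zenith")]
    out[CSV_COLUMNS + extras].to_csv(path, index=False, float_format="%.10g")


def write_classified_cloud(df: pd.DataFrame, path, format: str = "ascii_csv") -> None:
    """Write a classified bispectral cloud; refuses empty inputs."""
    if len(df) == 0:
        raise ValueError("refusing to write an empty classified cloud")
    if "class" not in df.columns:
        raise ValidationError("classified cloud must carry a 'class' column")
    labels = set(df["class"].dropna().unique())
    if not labels <= set(CLASS_LABELS):
        raise ValidationError(f"unknown class label(s): {sorted(labels - set(CLASS_LABELS))}")
    if "prob" in df.columns:
        p = df["prob"].to_numpy(dtype=float)
        p = p[~np.isnan(p)]
        if p.size and (np.any(p < 0) or np.any(p > 1)):
            raise ValidationError("class probabilities must lie in [0, 1]")
    write_point_cloud(df, path, format=format)


def read_classified_cloud(path, format: str = "ascii_csv") -> pd.DataFrame:
    """Read a classified cloud written by :func:`write_classified_cloud`."""
    if format != "ascii_csv":
        raise FormatError(f"unknown format {format!r}")
    df = pd.read_csv(path)
    for col in ("class", "prob"):
        if col not in df.columns:
            raise FormatError(f"missing required column: {col!r}")
    for col in CSV_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df["shot_number"] = df["shot_number"].astype(np.int64)
    return _attach_angles(df)


# ---------------------------------------------------------------------------
# Equal-angle projection
# ---------------------------------------------------------------------------

#: integer codes of class labels in projection images
CLASS_CODES = {label: i for i, label in enumerate(CLASS_LABELS)}


@dataclass
class ProjectionImage:
    """Equal-angle projection of a classified cloud.

    ``labels`` holds per-pixel class codes (:data:`CLASS_CODES`) with
    :data:`NO_DATA` marking gaps without returns; ``counts`` tallies the
    points that fell into each pixel. X is azimuth, Y is zenith.
    """

    labels: np.ndarray
    counts: np.ndarray
    pixel_size_mrad: float
    azimuth_range: tuple[float, float] = field(default=(0.0, 360.0))
    zenith_range: tuple[float, float] = field(default=(0.0, 117.0))

    @property
    def gap_fraction(self) -> float:
        return float(np.mean(self.counts == 0))


def render_equal_angle(points: pd.DataFrame, config: ScanConfig,
                       pixel_size: float) -> ProjectionImage:
    """Project a classified cloud onto the (azimuth, zenith) grid.

    Parameters
    ----------
    points : DataFrame
        Classified cloud with ``class`` and ``range`` columns (azimuth /
        zenith are derived from x, y, z if absent).
    config : ScanConfig
        Supplies the angular extents of the image.
    pixel_size : float
        Pixel size in mrad; must be >= the scan's angular resolution.

    When several points fall in one pixel the class of the nearest-range
    (front-most) point wins, which is what a viewer of the projected scan
    perceives.
    """
    if pixel_size < config.angular_resolution:
        raise ValueError("pixel_size must be >= the scan angular resolution")
    if "azimuth" not in points.columns or "zenith" not in points.columns:
        points = _attach_angles(points)
    px = pixel_size * 1e-3  # rad
    a0, a1 = np.deg2rad(config.azimuth_range)
    z0, z1 = np.deg2rad(config.zenith_range)
    ncol = int(math.ceil((a1 - a0) / px))
    nrow = int(math.ceil((z1 - z0) / px))
    labels = np.full((nrow, ncol), NO_DATA, dtype=np.int16)
    counts = np.zeros((nrow, ncol), dtype=np.int64)
    if len(points) == 0:
        return ProjectionImage(labels, counts, pixel_size,
                               config.azimuth_range, config.zenith_range)

    col = np.clip(((points["azimuth"].to_numpy() - a0) / px).astype(np.int64), 0, ncol - 1)
    row = np.clip(((points["zenith"].to_numpy() - z0) / px).astype(np.int64), 0, nrow - 1)
    np.add.at(counts, (row, col), 1)

    codes = points["class"].map(CLASS_CODES).to_numpy(dtype=np.int16)
    rng = points["range"].to_numpy(dtype=float)
    # nearest range wins: process far-to-near so the last write is the nearest
    order = np.argsort(-rng, kind="stable")
    labels[row[order], col[order]] = codes[order]
    return ProjectionImage(labels, counts, pixel_size,
                           config.azimuth_range, config.zenith_range)
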