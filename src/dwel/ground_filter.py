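"""Ground/vegetation separation by a minimum-surface morphological filter.

The pipeline needs ground returns removed before leaf/wood classification.
The filter here is a deliberately simple, pluggable stand-in: the cloud is
binned on a horizontal grid, the lowest return of each cell anchors a
piecewise-linear local-minimum surface, and a point is ground when it lies
within ``height_tol`` of that surface and the local surface slope does not
exceed ``slope_tol``. The slope test keeps steep structures (trunk bases,
fallen stems) out of the ground class while tolerating naturally tilted
terrain.

The grid origin is taken from the cloud's own horizontal extent, so the mask
is invariant to horizontal translation of the whole cloud.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import griddata
from scipy.spatial import QhullError


@dataclass(frozen=True)
class GroundFilterConfig:
    """Parameters of the minimum-surface filter.

    cell_size : horizontal grid cell edge, m.
    height_tol : maximum height above the local-minimum surface, m.
    slope_tol : maximum local surface gradient (rise/run, unitless).
    """

    cell_size: float = 0.5
    height_tol: float = 0.1
    slope_tol: float = 0.6

    def __post_init__(self) -> None:
        if min(self.cell_size, self.height_tol, self.slope_tol) <= 0:
            raise ValueError("all ground-filter parameters must be positive")


def filter_ground(cloud: pd.DataFrame,
                  config: GroundFilterConfig | None = None) -> np.ndarray:
    """Boolean mask, True where a point is classified as ground."""
    if len(cloud) == 0:
        raise ValueError("cloud must be non-empty")
    if config is None:
        config = GroundFilterConfig()
    x = cloud["x"].to_numpy(dtype=float)
    y = cloud["y"].to_numpy(dtype=float)
    z = cloud["z"].to_numpy(dtype=float)

    cs = config.cell_size
    ix = np.floor((x - x.min()) / cs).astype(np.int64)
    iy = np.floor((y - y.min()) / cs).astype(np.int64)
    cells = ix * (iy.max() + 1) + iy
    order = np.argsort(cells, kind="stable")
    uniq, first = np.unique(cells[order], return_index=True)
    if len(uniq) < 3:
        warnings.warn("fewer than 3 occupied ground-filter cells; "
                      "returning an all-vegetation mask", stacklevel=2)
        return np.zeros(len(cloud), dtype=bool)

    # lowest return per occupied cell anchors the minimum surface
    zs = z[order]
    min_idx = np.array([order[s:e][np.argmin(zs[s:e])]
                        for s, e in zip(first, np.append(first[1:], len(order)))])
    mx, my, mz = x[min_idx], y[min_idx], z[min_idx]

    nearest = griddata((mx, my), mz, (x, y), method="nearest")
    try:
        surf = griddata((mx, my), mz, (x, y), method="linear")
    except QhullError:  # near-collinear cell minima
        surf = np.full(len(x), np.nan)
    surf = np.where(np.isnan(surf), nearest, surf)

    # per-cell slope from the cell-minimum grid (nearest fill for empty cells)
    nx_, ny_ = ix.max() + 1, iy.max() + 1
    zgrid = np.full((nx_, ny_), np.nan)
    zgrid[ix[min_idx], iy[min_idx]] = mz
    if np.isnan(zgrid).any():
        gi, gj = np.meshgrid(np.arange(nx_), np.arange(ny_), indexing="ij")
        filled = griddata((ix[min_idx], iy[min_idx]), mz, (gi, gj),
                          method="nearest")
        zgrid = np.where(np.isnan(zgrid), filled, zgrid)
    if nx_ >= 2 and ny_ >= 2:
        dzdx, dzdy = np.gradient(zgrid, cs, cs)
        slope = np.hypot(dzdx, dzdy)
    else:
        slope = np.zeros_like(zgrid)

    point_slope = slope[ix, iy]
    height = z - surf
    return (height <= config.height_tol) & (point_slope <= config.slope_tol)
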