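"""Per-point classification attributes: spectral and multiscale spatial.

Spectral attributes are the two apparent reflectances and the NDI carried by
each bispectral point. Spatial attributes describe the local 3D organisation
("dimensionality") of the cloud around a point: within a sphere of a given
diameter (the *scale*), the covariance of the mean-recentred neighbour
coordinates is eigendecomposed and each eigenvalue expressed as a proportion
of their sum. A line-like cluster (trunk, branch) gives proportions near
(1, 0, 0), a surface near (0.5, 0.5, 0) and a volume-filling cluster (leaves)
near (1/3, 1/3, 1/3). Because the dimensionality of vegetation changes with
the scale of observation, the proportions are computed at 16 scales from
1 m (s01) down to 0.05 m (s16), geometrically spaced.

Scale-selection guidance: the smallest scale should exceed the minimum point
spacing implied by the angular sampling at the ranges of interest, and the
largest should approach the typical spacing between stems; the defaults
follow that rationale for forest scans at 2 mrad resolution. This guidance
is documentation, not automation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

#: number of scales and their default span (sphere diameters, m)
N_SCALES = 16
SCALE_MAX = 1.0
SCALE_MIN = 0.05

#: minimum neighbour count (centre included) for a valid local PCA
MIN_NEIGHBOURS = 3

#: imputation value for invalid scales: the volumetric prior, treating a
#: cluster without evidence as shapeless rather than line-like
VOLUMETRIC_PRIOR = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)

SPECTRAL_COLUMNS = ["rho_nir", "rho_swir", "ndi"]


def default_scales(n: int = N_SCALES, largest: float = SCALE_MAX,
                   smallest: float = SCALE_MIN) -> np.ndarray:
    """Geometrically spaced sphere diameters, largest first."""
    return np.geomspace(largest, smallest, n)


def scale_names(scales) -> list[str]:
    return [f"s{i + 1:02d}" for i in range(len(scales))]


def spatial_columns(scales=None, include_pc3: bool = False) -> list[str]:
    """Feature-column names pc1_s01 ... pc2_s16 (pc3 behind the flag)."""
    if scales is None:
        scales = default_scales()
    comps = ["pc1", "pc2"] + (["pc3"] if include_pc3 else [])
    return [f"{c}_{s}" for c in comps for s in scale_names(scales)]


def feature_columns(attribute_set: str, scales=None,
                    include_pc3: bool = False) -> list[str]:
    """Column names of one of the three attribute sets."""
    if attribute_set == "spectral":
        return list(SPECTRAL_COLUMNS)
    if attribute_set == "spatial":
        return spatial_columns(scales, include_pc3)
    if attribute_set == "spectral_spatial":
        return list(SPECTRAL_COLUMNS) + spatial_columns(scales, include_pc3)
    raise ValueError(f"unknown attribute set {attribute_set!r}")


def local_dimensionality(neighbours: np.ndarray,
                         centre=None) -> tuple[float, float, float]:
    """Eigenvalue proportions of one local neighbourhood.

    ``neighbours`` is an (n, 3) array of the coordinates inside the sphere
    (the centre point itself included). Returns the descending-sorted
    eigenvalues of the covariance of the mean-recentred coordinates, each
    divided by their sum. With fewer than three neighbours, or a degenerate
    all-coincident cluster, returns (nan, nan, nan).
    """
    pts = np.asarray(neighbours, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < MIN_NEIGHBOURS:
        return (np.nan, np.nan, np.nan)
    rec = pts - pts.mean(axis=0)
    cov = rec.T @ rec / pts.shape[0]
    ev = np.linalg.eigvalsh(cov)[::-1]
    ev = np.clip(ev, 0.0, None)
    tot = ev.sum()
    if tot <= 0:
        return (np.nan, np.nan, np.nan)
    p = ev / tot
    return (float(p[0]), float(p[1]), float(p[2]))


def spectral_features(point) -> tuple[float, float, float]:
    """(rho_nir, rho_swir, ndi) of one bispectral point (pass-through).

    An undefined-NDI sentinel (NaN) propagates unchanged.
    """
    return (float(point["rho_nir"]), float(point["rho_swir"]), float(point["ndi"]))


def _chunk_dimensionality(coords: np.ndarray, centre_idx: np.ndarray,
                          neigh_lists: list, radii: np.ndarray,
                          min_neighbours: int):
    """Eigen-proportions for a chunk of centres at all scales.

    For each centre, neighbours found at the largest radius are sorted by
    distance once; cumulative coordinate and second-moment sums then give the
    covariance at every smaller radius in O(1) each, and all (centre, scale)
    3x3 problems are eigendecomposed in a single batched call.
    """
    n_c, n_s = len(centre_idx), len(radii)
    props = np.full((n_c, n_s, 3), np.nan)
    counts = np.zeros((n_c, n_s), dtype=np.int64)
    mats, where = [], []
    for ci, (idx_list, c) in enumerate(zip(neigh_lists, centre_idx)):
        idx = np.asarray(idx_list, dtype=np.intp)
        pts = coords[idx]
        d = np.linalg.norm(pts - coords[c], axis=1)
        order = np.argsort(d, kind="stable")
        d = d[order]
        pts = pts[order]
        s1 = np.cumsum(pts, axis=0)
        outer = np.einsum("ni,nj->nij", pts, pts)
        s2 = np.cumsum(outer, axis=0)
        ms = np.searchsorted(d, radii, side="right")
        for si, m in enumerate(ms):
            counts[ci, si] = m
            if m < min_neighbours:
                continue
            mean = s1[m - 1] / m
            cov = s2[m - 1] / m - np.outer(mean, mean)
            mats.append(cov)
            where.append((ci, si))
    if mats:
        ev = np.linalg.eigvalsh(np.stack(mats))[:, ::-1]
        ev = np.clip(ev, 0.0, None)
        tot = ev.sum(axis=1)
        ok = tot > 0
        prop = np.full_like(ev, np.nan)
        prop[ok] = ev[ok] / tot[ok, None]
        wi = np.asarray(where, dtype=np.intp)
        props[wi[:, 0], wi[:, 1]] = prop
    return props, counts


def multiscale_features(cloud: pd.DataFrame, scales=None,
                        min_neighbours: int = MIN_NEIGHBOURS,
                        include_pc3: bool = False,
                        chunk_size: int = 2000) -> pd.DataFrame:
    """Feature table (one row per point) of spectral + multiscale attributes.

    Parameters
    ----------
    cloud : DataFrame
        Bispectral cloud with x, y, z and the spectral columns.
    scales : sequence of float, optional
        Sphere *diameters* in metres, strictly decreasing; neighbours are
        gathered within radius = scale / 2. Defaults to 16 geometric scales
        from 1 m to 0.05 m.
    min_neighbours : int
        Minimum points (centre included) for a scale to be valid.
    include_pc3 : bool
        Also emit the third eigenvalue proportion per scale.

    Scales with too few neighbours (or degenerate geometry) are masked
    invalid (``valid_sXX`` columns) and their proportions imputed with the
    volumetric prior (1/3, 1/3[, 1/3]).
    """
    if len(cloud) == 0:
        raise ValueError("cloud must be non-empty")
    if scales is None:
        scales = default_scales()
    scales = np.asarray(scales, dtype=float)
    if np.any(np.diff(scales) >= 0) or np.any(scales <= 0):
        raise ValueError("scales must be strictly decreasing and positive")
    radii = scales / 2.0
    names = scale_names(scales)

    coords = np.ascontiguousarray(cloud[["x", "y", "z"]].to_numpy(dtype=float))
    tree = cKDTree(coords)
    n = len(coords)
    all_props = np.full((n, len(scales), 3), np.nan)
    all_counts = np.zeros((n, len(scales)), dtype=np.int64)
    for start in range(0, n, chunk_size):
        sel = np.arange(start, min(start + chunk_size, n))
        neigh = tree.query_ball_point(coords[sel], r=radii[0])
        props, counts = _chunk_dimensionality(coords, sel, neigh, radii,
                                              min_neighbours)
        all_props[sel] = props
        all_counts[sel] = counts

    valid = ~np.isnan(all_props[:, :, 0])
    imputed = all_props.copy()
    for k in range(3):
        imputed[:, :, k][~valid] = VOLUMETRIC_PRIOR[k]

    out = {c: cloud[c].to_numpy(dtype=float) if c in cloud.columns
           else np.full(n, np.nan) for c in SPECTRAL_COLUMNS}
    comps = [0, 1] + ([2] if include_pc3 else [])
    for k in comps:
        for si, sname in enumerate(names):
            out[f"pc{k + 1}_{sname}"] = imputed[:, si, k]
    for si, sname in enumerate(names):
        out[f"valid_{sname}"] = valid[:, si]
        out[f"nn_{sname}"] = all_counts[:, si]
    return pd.DataFrame(out, index=cloud.index)
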