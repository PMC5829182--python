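"""Merge two monospectral point clouds into one bispectral cloud.

Two merge strategies are provided:

* **intersection** — keep only returns matched across bands by laser-shot
  sequence number and range (same shot, range difference below a tolerance);
* **union** — additionally rescue single-band returns (caused by the other
  band falling below the detection threshold) by synthesizing the missing
  band's apparent reflectance from a shot-level normalized difference index
  (NDI), taken from the shot's own matched pairs or interpolated from
  neighbouring shots on the scan grid.

The NDI of a reflectance pair is ``(rho_nir - rho_swir) / (rho_nir +
rho_swir)``; it is high for water-rich leaves and near zero for dry wood. A
zero denominator yields the undefined-NDI sentinel (NaN), never an exception.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .pointcloud_io import NIR, SWIR, is_calibrated

logger = logging.getLogger(__name__)

#: sentinel for an undefined NDI (zero-sum reflectance pair, or a shot with
#: no matched pairs and no interpolatable neighbours)
NDI_UNDEFINED = np.nan

#: default shot-matching range tolerance, m (~2x the coarser single-target
#: range resolution of 4.752 cm)
DEFAULT_RANGE_TOL = 0.10

#: default neighbour-interpolation window, in angular steps on the scan grid
DEFAULT_NEIGHBOUR_WINDOW = 2


class MergeStateError(RuntimeError):
    """Inputs are not in the state the merge requires (e.g. uncalibrated)."""


def compute_ndi(rho_nir, rho_swir):
    """Normalized difference index of one or more reflectance pairs.

    Antisymmetric under band swap and invariant under joint positive
    scaling. Pairs summing to zero return :data:`NDI_UNDEFINED`.
    """
    a = np.asarray(rho_nir, dtype=float)
    b = np.asarray(rho_swir, dtype=float)
    if np.any(a[~np.isnan(a)] < 0) or np.any(b[~np.isnan(b)] < 0):
        raise ValueError("apparent reflectances must be >= 0")
    denom = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (a - b) / np.where(denom > 0, denom, 1.0),
                       NDI_UNDEFINED)
    if out.ndim == 0:
        return float(out)
    return out


def synthesize_missing_band(rho_known, known_band: str, ndi):
    """Reflectance of the missing band from the known band and a shot NDI.

    Inverts the NDI definition: with the NIR value known,
    ``rho_swir = rho_nir (1 - ndi) / (1 + ndi)``; with the SWIR value known,
    ``rho_nir = rho_swir (1 + ndi) / (1 - ndi)``. Returns NaN where the
    required division is undefined (|ndi| = 1 on the dividing side, or ndi
    itself undefined).
    """
    rho = np.asarray(rho_known, dtype=float)
    nd = np.asarray(ndi, dtype=float)
    if np.any(rho[~np.isnan(rho)] < 0):
        raise ValueError("rho_known must be >= 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        if known_band == NIR:
            denom = 1.0 + nd
            out = np.where(denom > 0, rho * (1.0 - nd) / np.where(denom != 0, denom, 1.0),
                           np.nan)
        elif known_band == SWIR:
            denom = 1.0 - nd
            out = np.where(denom > 0, rho * (1.0 + nd) / np.where(denom != 0, denom, 1.0),
                           np.nan)
        else:
            raise ValueError(f"unknown band {known_band!r}")
    out = np.where(np.abs(nd) >= 1.0, np.nan, out)
    if out.ndim == 0:
        return float(out)
    return out


def _greedy_pairs(nir_ranges: np.ndarray, swir_ranges: np.ndarray,
                  tol: float) -> list[tuple[int, int]]:
    """Greedy in-shot matching by smallest range difference.

    Indices refer to the (range-sorted) within-shot arrays. Candidates are
    taken in order of |delta range|, ties broken by (nir range, swir range)
    so the result does not depend on input record order.
    """
    cands = []
    for i, rn in enumerate(nir_ranges):
        for j, rs in enumerate(swir_ranges):
            d = abs(rn - rs)
            if d <= tol:
                cands.append((d, rn, rs, i, j))
    cands.sort()
    used_n: set[int] = set()
    used_s: set[int] = set()
    pairs = []
    for _, _, _, i, j in cands:
        if i not in used_n and j not in used_s:
            used_n.add(i)
            used_s.add(j)
            pairs.append((i, j))
    return pairs


def match_intersection(nir: pd.DataFrame, swir: pd.DataFrame,
                       range_tol: float = DEFAULT_RANGE_TOL
                       ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Match returns across bands by shot number and range.

    Returns ``(pairs, nir_only, swir_only)``. ``pairs`` is a bispectral
    frame (geometry taken from the NIR return) with ``rho_nir``,
    ``rho_swir``, ``ndi`` and ``source='matched'``; the leftovers keep their
    monospectral schema. Each return appears in at most one pair. Within a
    shot, candidate pairings are resolved greedily by smallest range
    difference; records are canonicalised by range first so the result is
    invariant to input record order.
    """
    if range_tol <= 0:
        raise ValueError("range_tol must be > 0")
    for df, name in ((nir, "NIR"), (swir, "SWIR")):
        if len(df) and not is_calibrated(df):
            raise MergeStateError(
                f"{name} cloud is not calibrated (rho_app not populated); "
                "run calibration first")

    ni = nir.sort_values(["shot_number", "range"], kind="stable").reset_index(drop=True)
    si = swir.sort_values(["shot_number", "range"], kind="stable").reset_index(drop=True)

    n_groups = {s: g for s, g in ni.groupby("shot_number").indices.items()}
    s_groups = {s: g for s, g in si.groupby("shot_number").indices.items()}

    n_matched_idx: list[int] = []
    s_matched_idx: list[int] = []
    for shot in sorted(set(n_groups) & set(s_groups)):
        gi = n_groups[shot]
        gj = s_groups[shot]
        pairs = _greedy_pairs(ni["range"].to_numpy()[gi],
                              si["range"].to_numpy()[gj], range_tol)
        for i, j in pairs:
            n_matched_idx.append(gi[i])
            s_matched_idx.append(gj[j])

    n_mask = np.zeros(len(ni), dtype=bool)
    s_mask = np.zeros(len(si), dtype=bool)
    n_mask[n_matched_idx] = True
    s_mask[s_matched_idx] = True

    np_ = ni.iloc[n_matched_idx].reset_index(drop=True)
    sp_ = si.iloc[s_matched_idx].reset_index(drop=True)
    pairs_df = pd.DataFrame({
        "x": np_["x"], "y": np_["y"], "z": np_["z"],
        "range": np_["range"], "shot_number": np_["shot_number"],
        "azimuth": np_.get("azimuth", np.nan), "zenith": np_.get("zenith", np.nan),
        "rho_nir": np_["rho_app"].to_numpy(dtype=float),
        "rho_swir": sp_["rho_app"].to_numpy(dtype=float),
    })
    pairs_df["ndi"] = compute_ndi(pairs_df["rho_nir"].to_numpy(),
                                  pairs_df["rho_swir"].to_numpy()) \
        if len(pairs_df) else np.array([], dtype=float)
    pairs_df["source"] = "matched"
    if "truth" in np_.columns:  # simulator ground-truth labels, if present
        pairs_df["truth"] = np_["truth"].to_numpy()
    return pairs_df, ni[~n_mask].reset_index(drop=True), si[~s_mask].reset_index(drop=True)


def merge_intersection(nir: pd.DataFrame, swir: pd.DataFrame,
                       range_tol: float = DEFAULT_RANGE_TOL) -> pd.DataFrame:
    """Intersection merge: matched pairs only."""
    pairs, _, _ = match_intersection(nir, swir, range_tol)
    return pairs


def shot_ndi(pair_rho_nir=None, pair_rho_swir=None,
             neighbour_ndis=None, neighbour_distances=None) -> float:
    """NDI estimate for one laser shot.

    If the shot has matched pairs, the NDI of the per-band mean apparent
    reflectances of those pairs is returned. Otherwise an inverse-distance
    weighted mean of neighbouring shots' NDIs (distances in angle space) is
    used. With neither, the undefined sentinel is returned.
    """
    if pair_rho_nir is not None and len(np.atleast_1d(pair_rho_nir)) > 0:
        return compute_ndi(float(np.mean(pair_rho_nir)), float(np.mean(pair_rho_swir)))
    if neighbour_ndis is not None and len(np.atleast_1d(neighbour_ndis)) > 0:
        ndis = np.asarray(neighbour_ndis, dtype=float)
        d = np.asarray(neighbour_distances, dtype=float)
        ok = ~np.isnan(ndis)
        ndis, d = ndis[ok], d[ok]
        if ndis.size == 0:
            return NDI_UNDEFINED
        if np.any(d == 0):
            return float(np.mean(ndis[d == 0]))
        w = 1.0 / d
        return float(np.sum(w * ndis) / np.sum(w))
    return NDI_UNDEFINED


def _shot_angles(frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-shot mean azimuth/zenith over all returns of all frames."""
    parts = [f[["shot_number", "azimuth", "zenith"]] for f in frames if len(f)]
    allpts = pd.concat(parts, ignore_index=True)
    return allpts.groupby("shot_number", as_index=True).mean()


def _interpolate_shot_ndi(undefined_shots: np.ndarray, shot_table: pd.DataFrame,
                          angles: pd.DataFrame, window: int,
                          step_rad: float) -> pd.Series:
    """Fill NDIs of shots without pairs from neighbours on the scan grid.

    A square window of +/- ``window`` angular steps in azimuth and zenith is
    searched; contributions are weighted by inverse angular distance.
    """
    defined = shot_table.dropna()
    out = pd.Series(NDI_UNDEFINED, index=undefined_shots, dtype=float)
    if len(defined) == 0 or len(undefined_shots) == 0:
        return out
    def_ang = angles.loc[defined.index]
    tree = cKDTree(def_ang[["azimuth", "zenith"]].to_numpy())
    und_ang = angles.loc[undefined_shots]
    half = window * step_rad
    # circumscribe the square window, then filter to it
    cand = tree.query_ball_point(und_ang[["azimuth", "zenith"]].to_numpy(),
                                 r=half * math.sqrt(2.0) * (1 + 1e-9))
    def_xy = def_ang[["azimuth", "zenith"]].to_numpy()
    def_ndi = defined.to_numpy()
    und_xy = und_ang[["azimuth", "zenith"]].to_numpy()
    tol = 1e-9
    for k, shot in enumerate(undefined_shots):
        idx = np.asarray(cand[k], dtype=int)
        if idx.size == 0:
            continue
        delta = np.abs(def_xy[idx] - und_xy[k])
        inside = (delta[:, 0] <= half + tol) & (delta[:, 1] <= half + tol)
        idx = idx[inside]
        if idx.size == 0:
            continue
        d = np.hypot(*(def_xy[idx] - und_xy[k]).T)
        out.loc[shot] = shot_ndi(neighbour_ndis=def_ndi[idx], neighbour_distances=d)
    return out


def merge_union(nir: pd.DataFrame, swir: pd.DataFrame,
                range_tol: float = DEFAULT_RANGE_TOL,
                neighbour_window: int = DEFAULT_NEIGHBOUR_WINDOW,
                angular_step_mrad: float = 2.0) -> pd.DataFrame:
    """Union merge: matched pairs plus synthesized single-band leftovers.

    Leftover returns (present in one band only) get the missing band's
    apparent reflectance synthesized from the shot-level NDI (own pairs, or
    interpolated from neighbouring shots within ``neighbour_window`` grid
    steps). Leftovers whose shot NDI cannot be determined, or whose
    synthesis is undefined (|NDI| = 1 on the dividing side), are dropped
    with a logged count. The union result is a superset of the intersection
    result.
    """
    pairs, nir_only, swir_only = match_intersection(nir, swir, range_tol)

    # per-shot NDI from matched pairs
    if len(pairs):
        g = pairs.groupby("shot_number")
        shot_table = compute_ndi(g["rho_nir"].mean().to_numpy(),
                                 g["rho_swir"].mean().to_numpy())
        shot_table = pd.Series(np.atleast_1d(shot_table), index=g.size().index, dtype=float)
    else:
        shot_table = pd.Series(dtype=float)

    leftover_shots = np.unique(np.concatenate([
        nir_only["shot_number"].to_numpy(), swir_only["shot_number"].to_numpy()
    ])) if (len(nir_only) or len(swir_only)) else np.array([], dtype=np.int64)
    undefined = np.setdiff1d(leftover_shots, shot_table.dropna().index.to_numpy())
    if undefined.size:
        angles = _shot_angles([nir, swir])
        interp = _interpolate_shot_ndi(undefined, shot_table, angles,
                                       neighbour_window, angular_step_mrad * 1e-3)
        shot_table = pd.concat([shot_table, interp])

    parts = [pairs]
    n_dropped = 0
    for leftovers, known_band, source in ((nir_only, NIR, "swir_synthesized"),
                                          (swir_only, SWIR, "nir_synthesized")):
        if not len(leftovers):
            continue
        ndi = shot_table.reindex(leftovers["shot_number"].to_numpy()).to_numpy()
        rho_known = leftovers["rho_app"].to_numpy(dtype=float)
        rho_other = synthesize_missing_band(rho_known, known_band, ndi)
        ok = ~np.isnan(np.atleast_1d(rho_other))
        n_dropped += int((~ok).sum())
        lf = leftovers[ok].reset_index(drop=True)
        bi = pd.DataFrame({
            "x": lf["x"], "y": lf["y"], "z": lf["z"],
            "range": lf["range"], "shot_number": lf["shot_number"],
            "azimuth": lf.get("azimuth", np.nan), "zenith": lf.get("zenith", np.nan),
            "rho_nir": rho_known[ok] if known_band == NIR else np.atleast_1d(rho_other)[ok],
            "rho_swir": np.atleast_1d(rho_other)[ok] if known_band == NIR else rho_known[ok],
        })
        bi["ndi"] = ndi[ok]
        bi["source"] = source
        if "truth" in lf.columns:
            bi["truth"] = lf["truth"].to_numpy()
        parts.append(bi)

    if n_dropped:
        logger.info("union merge dropped %d single-band point(s) with "
                    "undefined shot NDI", n_dropped)
    out = pd.concat(parts, ignore_index=True)
    return out
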