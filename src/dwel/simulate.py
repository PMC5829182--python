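"""Synthetic dual-wavelength TLS scans with known leaf/wood/ground truth.

The simulator emulates the scanning geometry and artefacts of a coaxial
dual-laser instrument:

* a hemispherical shot grid (default 2 mrad angular step, zenith 0-117 deg)
  with shot sequence numbers shared across the two bands;
* scene primitives — trunk and branch cylinders, volumetric leaf clusters
  and a ground plane — each carrying band-specific reflectances (leaf-like
  pairs centred on 0.431 @ 1064 nm / 0.239 @ 1548 nm, wood-like pairs
  near-equal at both bands);
* coaxial beam misalignment: the SWIR beam is cast at a fixed angular offset
  (default 0.79 mrad) from the NIR beam, so at silhouettes the two bands
  illuminate partially different footprints and the apparent NDI is
  distorted;
* beam-footprint mixing: each beam is sampled by a fixed equal-area fan of
  sub-rays; a partial hit mixes the reflectances of the intercepted
  primitives by intercepted-area fraction and dims the return by the missed
  fraction;
* range-dependent SNR: additive Gaussian noise on digital numbers, with the
  per-band noise floor set so a leaf-like target at the reference range
  (70 m) has the reference SNR (10);
* per-band detection dropouts: returns whose measured SNR falls below the
  band's detection threshold are discarded, creating single-band points
  that exercise the union merge.

Leaf clusters are realised at scene-building time as a seeded set of small
"leaflet" spheres filling the cluster ellipsoid, so ray interception is a
deterministic function of geometry: with zero misalignment and no noise the
two bands see identical ranges shot for shot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import CalibrationModel, default_models, instrument_response
from .bispectral_merge import compute_ndi
from .pointcloud_io import CLASS_LABELS, NIR, SWIR, ScanConfig

#: leaf-like reference reflectance pair (1064 nm, 1548 nm) used for the
#: noise-floor normalisation and the misalignment worked example
LEAF_RHO_REF = {NIR: 0.431, SWIR: 0.239}

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))

_CLASS_CODE = {label: i for i, label in enumerate(CLASS_LABELS)}


# ---------------------------------------------------------------------------
# Misalignment artefact model (closed forms)
# ---------------------------------------------------------------------------

def beam_overlap_fraction(divergence: float, offset: float) -> float:
    """Fractional overlap area of the two beam footprints.

    Both beams are discs of diameter ``divergence`` (mrad) whose centres are
    ``offset`` (mrad) apart; the returned fraction is the lens-shaped
    intersection area divided by one disc's area. 1 at zero offset, 0 once
    the offset reaches the divergence, strictly decreasing in between.
    """
    if divergence <= 0:
        raise ValueError("divergence must be > 0")
    if offset < 0:
        raise ValueError("offset must be >= 0")
    r = divergence / 2.0
    d = offset
    if d >= 2.0 * r:
        return 0.0
    if d == 0.0:
        return 1.0
    lens = (2.0 * r * r * math.acos(d / (2.0 * r))
            - 0.5 * d * math.sqrt(4.0 * r * r - d * d))
    return lens / (math.pi * r * r)


def ndi_distortion(rho_leaf: tuple[float, float], rho_wood: tuple[float, float],
                   overlap: float) -> tuple[float, float]:
    """(true, distorted) NDI for the misaligned-footprint worst case.

    The NIR beam falls entirely on a leaf target with reflectances
    ``rho_leaf`` = (nir, swir); the SWIR beam overlaps the leaf over the
    ``overlap`` fraction of its footprint and intercepts wood (``rho_wood``)
    over the rest. The distorted NDI uses the resulting mixed SWIR
    reflectance against the pure-leaf NIR value.
    """
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must lie in [0, 1]")
    ln, ls = rho_leaf
    _, ws = rho_wood
    if min(ln, ls, ws) < 0:
        raise ValueError("reflectances must be >= 0")
    true = compute_ndi(ln, ls)
    mixed_swir = overlap * ls + (1.0 - overlap) * ws
    distorted = compute_ndi(ln, mixed_swir)
    return true, distorted


# ---------------------------------------------------------------------------
# Scene primitives
# ---------------------------------------------------------------------------

@dataclass
class GroundPlane:
    kind = "ground_plane"
    label = "ground"
    z0: float = -1.7
    rho_nir: float = 0.40
    rho_swir: float = 0.40

    def intersect(self, dirs: np.ndarray) -> np.ndarray:
        dz = dirs[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(dz < 0, self.z0 / np.where(dz < 0, dz, -1.0), np.inf)
        return t


@dataclass
class Cylinder:
    """Finite cylinder between axis endpoints p0 and p1 (no end caps)."""

    p0: np.ndarray
    p1: np.ndarray
    radius: float
    rho_nir: float
    rho_swir: float
    kind: str = "trunk_cylinder"
    label: str = "wood"

    def intersect(self, dirs: np.ndarray) -> np.ndarray:
        p0 = np.asarray(self.p0, dtype=float)
        axis = np.asarray(self.p1, dtype=float) - p0
        length = np.linalg.norm(axis)
        a = axis / length
        w = -p0  # origin - p0, scanner at origin
        da = dirs @ a
        wa = w @ a
        d_perp = dirs - np.outer(da, a)
        w_perp = w - wa * a
        A = np.einsum("ij,ij->i", d_perp, d_perp)
        B = 2.0 * d_perp @ w_perp
        C = w_perp @ w_perp - self.radius ** 2
        disc = B * B - 4.0 * A * C
        ok = (disc >= 0) & (A > 0)
        t = np.full(len(dirs), np.inf)
        sq = np.sqrt(np.where(ok, disc, 0.0))
        t_hit = np.where(ok, (-B - sq) / np.where(A > 0, 2.0 * A, 1.0), np.inf)
        s = wa + t_hit * da  # axial coordinate of the hit point
        valid = ok & (t_hit > 1e-9) & (s >= 0.0) & (s <= length)
        t[valid] = t_hit[valid]
        return t


@dataclass
class LeafCluster:
    """Ellipsoidal leaf cluster realised as discrete leaflet spheres."""

    centre: np.ndarray
    semi_axes: np.ndarray
    leaflets: np.ndarray  # (n, 3) leaflet sphere centres
    leaflet_radius: float
    rho_nir: float
    rho_swir: float
    kind: str = "leaf_cluster"
    label: str = "leaf"

    def intersect(self, dirs: np.ndarray) -> np.ndarray:
        t = np.full(len(dirs), np.inf)
        if len(self.leaflets) == 0:
            return t
        c = np.asarray(self.centre, dtype=float)
        bound = float(np.max(self.semi_axes)) + self.leaflet_radius
        b = dirs @ c
        miss = (c @ c) - b * b  # squared distance of closest approach
        near = (b > 0) & (miss <= bound * bound)
        idx = np.flatnonzero(near)
        if idx.size == 0:
            return t
        L = self.leaflets
        l2 = np.einsum("ij,ij->i", L, L)
        r2 = self.leaflet_radius ** 2
        max_block = max(1, int(4e6 // max(1, len(L))))
        for start in range(0, idx.size, max_block):
            sel = idx[start:start + max_block]
            bb = dirs[sel] @ L.T                      # (s, k)
            disc = bb * bb - (l2 - r2)[None, :]
            ok = disc >= 0
            th = np.where(ok, bb - np.sqrt(np.where(ok, disc, 0.0)), np.inf)
            th = np.where(th > 1e-9, th, np.inf)
            t[sel] = th.min(axis=1)
        return t


# ---------------------------------------------------------------------------
# Scene construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneSpec:
    """Counts and size/reflectance distributions of a synthetic stand.

    Leaf reflectance pairs are drawn around the reference leaf-like pair
    (0.431, 0.239); wood pairs share a near-equal value at both bands. A
    ``photosynthetic_bark_fraction`` of the woody primitives receives
    leaf-like spectra, emulating trunks and branches with atypically high
    water content.
    """

    n_trunks: int = 3
    n_branches: int = 4
    n_leaf_clusters: int = 6
    trunk_distance: tuple[float, float] = (4.0, 25.0)
    trunk_radius: tuple[float, float] = (0.12, 0.30)
    trunk_height: tuple[float, float] = (4.0, 12.0)
    branch_radius: tuple[float, float] = (0.02, 0.07)
    branch_length: tuple[float, float] = (0.5, 2.5)
    cluster_distance: tuple[float, float] = (4.0, 20.0)
    cluster_semi_axes: tuple[float, float] = (0.3, 0.9)
    cluster_height: tuple[float, float] = (2.0, 8.0)
    leaflet_radius: float = 0.04
    leaf_density: float = 150.0  # leaflets per m^3 of cluster volume
    leaf_rho: tuple[float, float] = (0.431, 0.239)
    leaf_rho_sd: float = 0.03
    wood_rho_mean: float = 0.45
    wood_rho_sd: float = 0.05
    wood_band_jitter: float = 0.02
    photosynthetic_bark_fraction: float = 0.0
    ground_rho: tuple[float, float] = (0.40, 0.40)
    ground_z: float = -1.7
    placement_azimuth: tuple[float, float] = (0.0, 360.0)  # deg

    def __post_init__(self) -> None:
        if min(self.n_trunks, self.n_branches, self.n_leaf_clusters) < 0:
            raise ValueError("primitive counts must be >= 0")
        if self.leaf_density <= 0 or self.leaflet_radius <= 0:
            raise ValueError("leaf density and leaflet radius must be positive")


def _draw_leaf_rho(rng, spec: SceneSpec) -> tuple[float, float]:
    n = max(0.01, rng.normal(spec.leaf_rho[0], spec.leaf_rho_sd))
    s = max(0.01, rng.normal(spec.leaf_rho[1], spec.leaf_rho_sd))
    return float(n), float(s)


def _draw_wood_rho(rng, spec: SceneSpec) -> tuple[float, float]:
    if rng.uniform() < spec.photosynthetic_bark_fraction:
        return _draw_leaf_rho(rng, spec)
    base = max(0.05, rng.normal(spec.wood_rho_mean, spec.wood_rho_sd))
    n = max(0.01, base + rng.normal(0.0, spec.wood_band_jitter))
    s = max(0.01, base + rng.normal(0.0, spec.wood_band_jitter))
    return float(n), float(s)


def build_scene(spec: SceneSpec | None = None, seed: int = 0) -> list:
    """Instantiate the scene primitives (plus the ground plane), seeded.

    The same seed always yields the identical scene; every primitive
    carries its truth class label.
    """
    if spec is None:
        spec = SceneSpec()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    a0, a1 = np.deg2rad(spec.placement_azimuth)
    prims: list = [GroundPlane(z0=spec.ground_z, rho_nir=spec.ground_rho[0],
                               rho_swir=spec.ground_rho[1])]

    trunks = []
    for _ in range(spec.n_trunks):
        dist = rng.uniform(*spec.trunk_distance)
        az = rng.uniform(a0, a1)
        base = np.array([dist * math.sin(az), dist * math.cos(az), spec.ground_z])
        h = rng.uniform(*spec.trunk_height)
        rn, rs = _draw_wood_rho(rng, spec)
        cyl = Cylinder(base, base + np.array([0.0, 0.0, h]),
                       rng.uniform(*spec.trunk_radius), rn, rs,
                       kind="trunk_cylinder")
        trunks.append(cyl)
        prims.append(cyl)

    for _ in range(spec.n_branches):
        if trunks:
            host = trunks[rng.integers(len(trunks))]
            hlen = np.linalg.norm(host.p1 - host.p0)
            s = rng.uniform(0.3, 0.9) * hlen
            start = host.p0 + np.array([0.0, 0.0, s])
        else:
            dist = rng.uniform(*spec.trunk_distance)
            az = rng.uniform(a0, a1)
            start = np.array([dist * math.sin(az), dist * math.cos(az),
                              spec.ground_z + rng.uniform(*spec.cluster_height)])
        theta = rng.uniform(0.0, 2.0 * math.pi)
        tilt = rng.uniform(math.radians(30), math.radians(80))
        direction = np.array([math.sin(tilt) * math.cos(theta),
                              math.sin(tilt) * math.sin(theta), math.cos(tilt)])
        length = rng.uniform(*spec.branch_length)
        rn, rs = _draw_wood_rho(rng, spec)
        prims.append(Cylinder(start, start + length * direction,
                              rng.uniform(*spec.branch_radius), rn, rs,
                              kind="branch_cylinder"))

    for _ in range(spec.n_leaf_clusters):
        dist = rng.uniform(*spec.cluster_distance)
        az = rng.uniform(a0, a1)
        centre = np.array([dist * math.sin(az), dist * math.cos(az),
                           spec.ground_z + rng.uniform(*spec.cluster_height)])
        semi = rng.uniform(*spec.cluster_semi_axes, size=3)
        volume = 4.0 / 3.0 * math.pi * float(np.prod(semi))
        n_leaf = max(1, int(round(spec.leaf_density * volume)))
        u = rng.normal(size=(n_leaf, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        radii = rng.uniform(size=n_leaf) ** (1.0 / 3.0)
        leaflets = centre + u * radii[:, None] * semi[None, :]
        rn, rs = _draw_leaf_rho(rng, spec)
        prims.append(LeafCluster(centre, semi, leaflets, spec.leaflet_radius,
                                 rn, rs))
    return prims


# ---------------------------------------------------------------------------
# Scan simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Instrument and acquisition parameters of one simulated scan.

    ``alignment_offset`` is the coaxial misalignment between the two laser
    beams in mrad; ``snr_reference`` anchors the per-band noise floor (a
    leaf-like target at ``reference_range`` metres returns this SNR);
    ``detection_threshold`` is the minimum measured SNR for a return to be
    detected (scalar, or a per-band ``{band: value}`` mapping).
    """

    scan: ScanConfig = field(default_factory=ScanConfig)
    alignment_offset: float = 0.79
    snr_reference: float = 10.0
    reference_range: float = 70.0
    detection_threshold: float | dict = 3.0
    max_range: float = 100.0  # m; beyond this no return is recorded
    seed: int = 0
    n_subrays: int = 61
    noise: bool = True
    return_gate: float = 0.5  # m; sub-ray hits within this of the first
    # return are mixed into it
    multi_return: bool = False
    max_returns: int = 3
    calibration: dict = field(default_factory=default_models)

    def __post_init__(self) -> None:
        if self.alignment_offset < 0:
            raise ValueError("alignment_offset must be >= 0")
        if self.n_subrays < 1:
            raise ValueError("need at least one sub-ray")

    def threshold(self, band: str) -> float:
        if isinstance(self.detection_threshold, dict):
            return float(self.detection_threshold.get(band, 0.0))
        return float(self.detection_threshold)

    def noise_sigma(self, band: str) -> float:
        """Per-band noise floor in counts (leaf SNR = snr_reference at the
        reference range)."""
        resp = instrument_response(self.reference_range, self.calibration[band])
        return LEAF_RHO_REF[band] * resp / self.snr_reference


@dataclass
class SimulatedScan:
    """Simulator output: one monospectral cloud per band (raw DN, with a
    per-return ``truth`` class label) plus the shot-grid bookkeeping."""

    nir: pd.DataFrame
    swir: pd.DataFrame
    n_shots: int
    grid_shape: tuple[int, int]  # (zenith lines, azimuth shots)
    config: SimulationConfig
    scene: list


def _subray_pattern(n: int, beam_radius_rad: float) -> tuple[np.ndarray, np.ndarray]:
    """Equal-area sunflower layout of sub-ray angular offsets on the beam disc."""
    i = np.arange(n)
    rho = beam_radius_rad * np.sqrt((i + 0.5) / n)
    theta = i * _GOLDEN_ANGLE
    return rho * np.cos(theta), rho * np.sin(theta)


def _grid(scan: ScanConfig) -> tuple[np.ndarray, np.ndarray]:
    step = scan.angular_resolution * 1e-3
    a0, a1 = np.deg2rad(scan.azimuth_range)
    z0, z1 = np.deg2rad(scan.zenith_range)
    n_az = max(1, int(math.floor((a1 - a0) / step)))
    n_zen = max(1, int(math.floor((z1 - z0) / step)))
    az = a0 + (np.arange(n_az) + 0.5) * step
    zen = z0 + (np.arange(n_zen) + 0.5) * step
    return az, zen


def _frames(az: np.ndarray, zen: np.ndarray):
    """Central directions and tangent bases of every shot (row-major grid)."""
    A, Z = np.meshgrid(az, zen)  # (n_zen, n_az)
    A, Z = A.ravel(), Z.ravel()
    sa, ca = np.sin(A), np.cos(A)
    sz, cz = np.sin(Z), np.cos(Z)
    d = np.stack([sz * sa, sz * ca, cz], axis=1)
    e_zen = np.stack([cz * sa, cz * ca, -sz], axis=1)
    e_az = np.stack([ca, -sa, np.zeros_like(sa)], axis=1)
    return d, e_az, e_zen, A, Z


def _cast_band(dirs_central: np.ndarray, e_az: np.ndarray, e_zen: np.ndarray,
               subray_xy: tuple[np.ndarray, np.ndarray], prims: list,
               rho_per_prim: np.ndarray, code_per_prim: np.ndarray,
               gate: float, n_sub: int):
    """First-return aggregation of all sub-rays of one band.

    Returns per-shot arrays: hit flag, range, effective reflectance (area
    fraction weighted, missed fraction contributing zero) and majority truth
    code among the contributing sub-rays.
    """
    n_shots = len(dirs_central)
    sx, sy = subray_xy
    # (n_shots, n_sub, 3) sub-ray directions; small-angle rotation on the cone
    cosr = np.cos(np.hypot(sx, sy))
    dirs = (dirs_central[:, None, :] * cosr[None, :, None]
            + e_az[:, None, :] * np.sin(sx)[None, :, None]
            + e_zen[:, None, :] * np.sin(sy)[None, :, None])
    dirs = dirs.reshape(-1, 3)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    t = np.full(len(dirs), np.inf)
    pid = np.full(len(dirs), -1, dtype=np.int32)
    for k, prim in enumerate(prims):
        tp = prim.intersect(dirs)
        closer = tp < t
        t[closer] = tp[closer]
        pid[closer] = k

    T = t.reshape(n_shots, n_sub)
    P = pid.reshape(n_shots, n_sub)
    hit = np.isfinite(T)
    any_hit = hit.any(axis=1)
    rmin = np.where(any_hit, np.min(np.where(hit, T, np.inf), axis=1), np.nan)
    contrib = hit & (T <= rmin[:, None] + gate)
    n_contrib = contrib.sum(axis=1)
    Psafe = np.where(P >= 0, P, 0)
    rho_eff = np.where(contrib, rho_per_prim[Psafe], 0.0).sum(axis=1) / n_sub
    with np.errstate(invalid="ignore"):
        r_ret = np.where(contrib, T, 0.0).sum(axis=1) / np.where(
            n_contrib > 0, n_contrib, 1)
    codes = code_per_prim[Psafe]
    counts = np.stack([((codes == c) & contrib).sum(axis=1)
                       for c in range(len(CLASS_LABELS))], axis=1)
    majority = counts.argmax(axis=1)
    return any_hit, r_ret, rho_eff, majority, T, P, contrib


def _emit_returns(shots, dirs, A, Z, any_hit, r_ret, rho_eff, majority,
                  band, config, rng):
    """Apply the radiometric forward model, noise and detection."""
    model = config.calibration[band]
    sigma = config.noise_sigma(band)
    keep0 = any_hit & (r_ret > 0) & (rho_eff > 0) & (r_ret <= config.max_range)
    idx = np.flatnonzero(keep0)
    dn = rho_eff[idx] * instrument_response(r_ret[idx], model)
    if config.noise and sigma > 0:
        dn = dn + rng.normal(0.0, sigma, size=len(idx))
    dn = np.clip(dn, 0.0, None)
    thr = config.threshold(band)
    if sigma > 0:
        detected = dn / sigma >= thr
    else:
        detected = dn > 0.0
    idx = idx[detected]
    dn = dn[detected]
    r = r_ret[idx]
    xyz = dirs[idx] * r[:, None]
    return pd.DataFrame({
        "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
        "range": r, "shot_number": shots[idx], "band": band,
        "intensity": dn, "rho_app": np.nan,
        "azimuth": np.mod(np.arctan2(xyz[:, 0], xyz[:, 1]), 2 * math.pi),
        "zenith": np.arccos(np.clip(xyz[:, 2] / r, -1, 1)),
        "truth": np.asarray(CLASS_LABELS, dtype=object)[majority[idx]],
    })


def simulate_scan(scene: list, config: SimulationConfig | None = None
                  ) -> SimulatedScan:
    """Cast both bands' beams over the scan grid and detect returns.

    The NIR beam follows the grid direction of each shot; the SWIR beam is
    offset by ``alignment_offset`` mrad along the zenith tangent. Each beam
    is sampled with ``n_subrays`` equal-area sub-rays; the first-return
    range gate mixes silhouette hits by intercepted-area fraction. Digital
    numbers follow the calibration forward model plus seeded Gaussian
    noise; returns below the band's detection threshold are dropped.
    """
    if config is None:
        config = SimulationConfig()
    az, zen = _grid(config.scan)
    d, e_az, e_zen, A, Z = _frames(az, zen)
    n_shots = len(d)
    shots = np.arange(n_shots, dtype=np.int64)

    if not scene:
        empty = pd.DataFrame({c: [] for c in
                              ["x", "y", "z", "range", "shot_number", "band",
                               "intensity", "rho_app", "azimuth", "zenith",
                               "truth"]})
        return SimulatedScan(empty.copy(), empty.copy(), n_shots,
                             (len(zen), len(az)), config, scene)

    rho_nir = np.array([p.rho_nir for p in scene])
    rho_swir = np.array([p.rho_swir for p in scene])
    codes = np.array([_CLASS_CODE[p.label] for p in scene], dtype=np.int64)
    beam_radius = config.scan.beam_divergence * 1e-3 / 2.0
    pattern = _subray_pattern(config.n_subrays, beam_radius)

    ss = np.random.SeedSequence(config.seed)
    rng_nir, rng_swir = (np.random.default_rng(c) for c in ss.spawn(2))

    out = {}
    for band, rho, rng in ((NIR, rho_nir, rng_nir), (SWIR, rho_swir, rng_swir)):
        if band == SWIR and config.alignment_offset > 0:
            delta = config.alignment_offset * 1e-3
            dc = d * math.cos(delta) + e_zen * math.sin(delta)
        else:
            dc = d
        any_hit, r_ret, rho_eff, majority, T, P, contrib = _cast_band(
            dc, e_az, e_zen, pattern, scene, rho, codes,
            config.return_gate, config.n_subrays)
        if config.multi_return:
            frames = _emit_multi(shots, dc, any_hit, T, P, contrib, rho,
                                 codes, band, config, rng)
        else:
            frames = _emit_returns(shots, dc, A, Z, any_hit, r_ret, rho_eff,
                                   majority, band, config, rng)
        out[band] = frames.reset_index(drop=True)
    return SimulatedScan(out[NIR], out[SWIR], n_shots, (len(zen), len(az)),
                         config, scene)


def _emit_multi(shots, dirs, any_hit, T, P, contrib, rho_per_prim, codes,
                band, config, rng):
    """Multi-return mode: up to ``max_returns`` per shot, >= 0.5 m apart."""
    n_sub = T.shape[1]
    rows = []
    for si in np.flatnonzero(any_hit):
        ts = T[si]
        ok = np.isfinite(ts)
        order = np.argsort(ts[ok])
        tv = ts[ok][order]
        pv = P[si][ok][order]
        groups = []
        start = 0
        for i in range(1, len(tv) + 1):
            if i == len(tv) or tv[i] - tv[start] > config.return_gate:
                groups.append((start, i))
                start = i
            if len(groups) >= config.max_returns:
                break
        for g0, g1 in groups[:config.max_returns]:
            r = float(tv[g0:g1].mean())
            rho_eff = float(rho_per_prim[pv[g0:g1]].sum() / n_sub)
            cls = int(np.bincount(codes[pv[g0:g1]],
                                  minlength=len(CLASS_LABELS)).argmax())
            rows.append((si, r, rho_eff, cls))
    if not rows:
        return pd.DataFrame({c: [] for c in
                             ["x", "y", "z", "range", "shot_number", "band",
                              "intensity", "rho_app", "azimuth", "zenith",
                              "truth"]})
    arr = np.array(rows, dtype=float)
    si = arr[:, 0].astype(np.int64)
    r = arr[:, 1]
    rho_eff = arr[:, 2]
    majority = arr[:, 3].astype(np.int64)
    model = config.calibration[band]
    sigma = config.noise_sigma(band)
    dn = rho_eff * instrument_response(r, model)
    if config.noise and sigma > 0:
        dn = dn + rng.normal(0.0, sigma, size=len(dn))
    dn = np.clip(dn, 0.0, None)
    thr = config.threshold(band)
    keep = ((dn / sigma >= thr) if sigma > 0 else (dn > 0)) & (r <= config.max_range)
    si, r, dn, majority = si[keep], r[keep], dn[keep], majority[keep]
    xyz = dirs[si] * r[:, None]
    return pd.DataFrame({
        "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
        "range": r, "shot_number": shots[si], "band": band,
        "intensity": dn, "rho_app": np.nan,
        "azimuth": np.mod(np.arctan2(xyz[:, 0], xyz[:, 1]), 2 * math.pi),
        "zenith": np.arccos(np.clip(xyz[:, 2] / r, -1, 1)),
        "truth": np.asarray(CLASS_LABELS, dtype=object)[majority],
    })
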