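"""End-to-end orchestration: simulate/load -> calibrate -> merge -> features
-> ground filter -> train -> classify.

These helpers wire the stage modules together in the order the method runs
and are what the smoke tests, the command-line interface and the synthetic
benchmark suites drive. Each stage remains usable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bispectral_merge import merge_union
from .calibration import calibrate_cloud
from .classify import (AccuracyReport, ForestModel, ForestSettings,
                       accuracy_metrics, confusion_matrix, cross_validate,
                       predict, train)
from .features import default_scales, multiscale_features
from .ground_filter import GroundFilterConfig, filter_ground
from .pointcloud_io import ScanConfig
from .simulate import SceneSpec, SimulationConfig, build_scene, simulate_scan

#: a compact scan window used by the demonstration / benchmark scenes: a
#: 2 mrad grid over a modest azimuth sector covering ground, trunks and
#: canopy (the full hemisphere at 2 mrad is ~3M shots, far more than a
#: demonstration needs)
def demo_scan(azimuth_deg: tuple[float, float] = (0.0, 30.0),
              zenith_deg: tuple[float, float] = (40.0, 110.0),
              angular_resolution: float = 2.0) -> ScanConfig:
    return ScanConfig(angular_resolution=angular_resolution,
                      beam_divergence=max(2.5, angular_resolution * 1.25),
                      zenith_range=zenith_deg, azimuth_range=azimuth_deg)


def demo_scene_spec(azimuth_deg: tuple[float, float] = (2.0, 28.0),
                    **overrides) -> SceneSpec:
    """A stand that fits inside the demo scan window."""
    kwargs = dict(placement_azimuth=azimuth_deg,
                  trunk_distance=(4.0, 15.0), cluster_distance=(4.0, 12.0))
    kwargs.update(overrides)
    return SceneSpec(**kwargs)


@dataclass
class PipelineResult:
    """Everything the end-to-end run produces."""

    merged: pd.DataFrame          # bispectral cloud (union merge)
    ground_mask: np.ndarray       # True = ground (over merged rows)
    features: pd.DataFrame        # feature table of the vegetation points
    model: ForestModel
    classified: pd.DataFrame      # merged + class / prob columns
    report: AccuracyReport        # predictions vs simulator truth


def simulate_merged_cloud(spec: SceneSpec, config: SimulationConfig,
                          scene_seed: int = 0) -> pd.DataFrame:
    """simulate -> calibrate -> union merge, keeping truth labels."""
    scene = build_scene(spec, seed=scene_seed)
    sim = simulate_scan(scene, config)
    nir = calibrate_cloud(sim.nir, config.calibration)
    swir = calibrate_cloud(sim.swir, config.calibration)
    return merge_union(nir, swir,
                       angular_step_mrad=config.scan.angular_resolution)


def scan_training_table(spec: SceneSpec, config: SimulationConfig,
                        scene_seed: int = 0, scales=None,
                        max_per_class: int | None = None,
                        sample_seed: int = 0
                        ) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature table + truth labels of one scan's leaf/wood points.

    Ground returns are removed by the ground filter; points whose truth is
    'ground' but that escaped the filter are excluded from the labelled
    table (they are classified, never trained on).
    """
    merged = simulate_merged_cloud(spec, config, scene_seed)
    mask = filter_ground(merged)
    veg = merged[~mask].reset_index(drop=True)
    feats = multiscale_features(veg, scales=scales)
    labels = veg["truth"].to_numpy()
    keep = np.isin(labels, ("leaf", "wood")) & ~np.isnan(
        feats["rho_nir"].to_numpy())
    feats, labels = feats[keep].reset_index(drop=True), labels[keep]
    if max_per_class is not None:
        rng = np.random.default_rng(sample_seed)
        sel = []
        for c in ("leaf", "wood"):
            idx = np.flatnonzero(labels == c)
            if len(idx) > max_per_class:
                idx = rng.choice(idx, size=max_per_class, replace=False)
            sel.append(idx)
        sel = np.sort(np.concatenate(sel))
        feats, labels = feats.iloc[sel].reset_index(drop=True), labels[sel]
    return feats, labels


def run_pipeline(spec: SceneSpec | None = None,
                 config: SimulationConfig | None = None,
                 scene_seed: int = 0, seed: int = 0,
                 attribute_set: str = "spectral_spatial", scales=None,
                 settings: ForestSettings | None = None,
                 ground_config: GroundFilterConfig | None = None,
                 max_train_per_class: int = 2000) -> PipelineResult:
    """Full seeded pipeline on one synthetic scan.

    Trains on a per-class subsample of the truth-labelled vegetation
    points, classifies every vegetation point and scores the predictions
    against the simulator truth. Bit-repeatable for fixed seeds.
    """
    if spec is None:
        spec = demo_scene_spec()
    if config is None:
        config = SimulationConfig(scan=demo_scan(), seed=seed)
    if scales is None:
        scales = default_scales()

    merged = simulate_merged_cloud(spec, config, scene_seed)
    mask = filter_ground(merged, ground_config)
    veg = merged[~mask].reset_index(drop=True)
    feats = multiscale_features(veg, scales=scales)
    truth = veg["truth"].to_numpy()

    trainable = np.isin(truth, ("leaf", "wood"))
    rng = np.random.default_rng(seed)
    sel = []
    for c in ("leaf", "wood"):
        idx = np.flatnonzero(trainable & (truth == c))
        if len(idx) > max_train_per_class:
            idx = rng.choice(idx, size=max_train_per_class, replace=False)
        sel.append(idx)
    sel = np.sort(np.concatenate(sel))

    model = train(feats.iloc[sel], truth[sel], attribute_set,
                  settings=settings, seed=seed, scales=scales)
    labels, probs = predict(model, feats)

    classified = merged.copy()
    classified["class"] = "ground"
    classified["prob"] = 1.0
    vi = merged.index[~mask]
    classified.loc[vi, "class"] = labels
    classified.loc[vi, "prob"] = probs

    scorable = trainable
    report = accuracy_metrics(confusion_matrix(truth[scorable], labels[scorable]))
    report.n_train, report.n_test = len(sel), int(scorable.sum())
    return PipelineResult(merged, mask, feats, model, classified, report)


def crossval_suite(n_scans: int, attribute_sets: tuple[str, ...] =
                   ("spectral", "spatial", "spectral_spatial"),
                   seed: int = 0, scales=None,
                   settings: ForestSettings | None = None,
                   max_per_class: int = 300,
                   scan=None, spec_overrides: dict | None = None
                   ) -> pd.DataFrame:
    """Stratified 75/25 cross-validation over a suite of varied scans.

    Each scan gets its own seeded scene (geometry varies: trunk/branch/
    cluster counts and placements change with the scene seed) and its own
    75/25 stratified hold-out per attribute set. Returns one row per
    (scan, attribute_set) with the overall accuracy.
    """
    if scan is None:
        scan = demo_scan()
    a0, a1 = scan.azimuth_range
    inset = min(2.0, 0.1 * (a1 - a0))
    rows = []
    rng = np.random.default_rng(seed)
    for s in range(n_scans):
        scene_seed = int(rng.integers(2 ** 31 - 1))
        overrides = dict(
            n_trunks=int(rng.integers(1, 4)),
            n_branches=int(rng.integers(2, 6)),
            n_leaf_clusters=int(rng.integers(3, 8)),
            placement_azimuth=(a0 + inset, a1 - inset),
        )
        if spec_overrides:
            overrides.update(spec_overrides)
        spec = demo_scene_spec(**overrides)
        config = SimulationConfig(scan=scan, seed=scene_seed + 1)
        feats, labels = scan_training_table(
            spec, config, scene_seed=scene_seed, scales=scales,
            max_per_class=max_per_class, sample_seed=scene_seed + 2)
        for aset in attribute_sets:
            rep = cross_validate(feats, labels, aset, settings=settings,
                                 seed=scene_seed + 3, scales=scales)
            rows.append({"scan": s, "attribute_set": aset,
                         "overall": rep.overall,
                         "n_train": rep.n_train, "n_test": rep.n_test})
    return pd.DataFrame(rows)
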