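# dwel — dual-wavelength TLS leaf/wood point classification

`dwel` processes scans from coaxial dual-wavelength terrestrial laser
scanners (two simultaneous lasers at 1064 nm and 1548 nm) and classifies
every 3D point of a forest or crop scan as **leaf**, **wood** or **ground**.
It is aimed at vegetation-lidar researchers who need the woody and
photosynthetic components of a canopy separated in 3D — for leaf-area
estimation, biomass partitioning, or radiative-transfer modelling — and at
instrument developers studying the artefacts of dual-laser coalignment.

## The method

Each scan yields one monospectral point cloud per band. The package:

1. **Calibrates** raw return intensities to apparent reflectance
   `ρ_app = DN / response(r)`, where the instrument response
   `response(r) = C · S(r) · e^(−k r) / r^b` combines a generalized
   logistic `S(r) = 1/(1 + e^(−g(r − r0)))` for near-range telescopic
   defocus with a negative-exponential and power-law range fall-off.
2. **Merges** the two clouds into one bispectral cloud. The *intersection*
   keeps returns matched by laser-shot number and range; the *union*
   additionally rescues single-band returns (the other band fell below its
   detection threshold) by synthesizing the missing reflectance from a
   shot-level normalized difference index,

       NDI = (ρ_nir − ρ_swir) / (ρ_nir + ρ_swir),

   which is high for water-rich leaves and near zero for dry wood.
3. **Derives attributes** per point: spectral (ρ_nir, ρ_swir, NDI) and
   spatial — the proportions pc1 ≥ pc2 ≥ pc3 of the eigenvalues of the
   local covariance within spheres of 16 diameters from 1 m (s01) to
   0.05 m (s16). Lines (trunks, branches) give pc1 ≈ 1, surfaces
   pc1 ≈ pc2 ≈ 0.5, volume-filling leaf clusters pc1 ≈ pc2 ≈ pc3 ≈ ⅓.
4. **Filters ground** with a minimum-surface morphological filter, then
   **classifies** the vegetation points with a random forest (500 trees)
   trained on labelled clusters, using spectral, spatial or joint
   attributes; stratified 75/25 cross-validation and feature-importance
   summaries compare the three attribute sets.

A **simulator** generates dual-wavelength scans of synthetic stands
(trunk/branch cylinders, volumetric leaf clusters, ground plane) with known
truth, including the coaxial-misalignment artefact: when the two beams are
offset (0.79 mrad at 2.5 mrad divergence ⇒ ≈60% footprint overlap), the
bands illuminate partially different targets at silhouettes and the NDI is
distorted.

## Worked example

The misalignment artefact in closed form — a leaf target with reflectances
0.431 (1064 nm) and 0.239 (1548 nm), with 40% of the SWIR footprint
spilling onto a branch reflecting 0.431 at both bands:

```python
>>> from dwel import compute_ndi, beam_overlap_fraction, ndi_distortion
>>> compute_ndi(0.431, 0.239)          # true leaf NDI
0.2865671641791045
>>> beam_overlap_fraction(2.5, 0.79)   # footprint overlap at 0.79 mrad offset
0.604456433416492
>>> ndi_distortion((0.431, 0.239), (0.431, 0.431), overlap=0.6)
(0.2865671641791045, 0.15425816818425286)
```

The distorted NDI (0.154) is roughly half the true value (0.287) — the
reason spectral attributes misclassify trunk edges.

A full seeded pipeline on a synthetic scan:

```python
from dwel import SimulationConfig, run_pipeline
from dwel.pipeline import demo_scan, demo_scene_spec

spec = demo_scene_spec((1.0, 11.0), n_trunks=2, n_branches=3, n_leaf_clusters=4)
scan = demo_scan((0.0, 12.0), (55.0, 105.0), angular_resolution=4.0)
res = run_pipeline(spec, SimulationConfig(scan=scan, seed=42),
                   scene_seed=42, seed=42, max_train_per_class=500)
print(res.report)
```

prints

```
overall accuracy: 0.9921 (train n=1000, test n=4789)
  leaf   producer's 1.0000  user's 0.9651
  wood   producer's 0.9898  user's 1.0000
```

i.e. on this scan 99.2% of truth-labelled vegetation points are classified
correctly; producer's accuracy is per-class recall (1 − omission error) and
user's accuracy per-class precision (1 − commission error). The trained
forest's importances put ρ_swir first, then NDI, then ρ_nir and the
coarse-scale pc1 features.

The same stages are available from the shell:

```bash
dwel simulate demo --config scene.toml --seed 7
dwel calibrate demo_nir.csv cal_nir.csv
dwel merge cal_nir.csv cal_swir.csv merged.csv --mode union
dwel features merged.csv feats.csv
dwel train labelled.csv model.joblib
dwel classify model.joblib feats.csv merged.csv classified.csv
dwel io project classified.csv overview.png --pixel-mrad 4
```

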