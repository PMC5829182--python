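# Methods

This note records the models implemented by `dwel`, the parameter choices
that matter, what the synthetic scan generator does and does not emulate,
and the numerical decisions taken where the design was genuinely open.

## Coordinate and scan conventions

Coordinates are scanner-centric, z-up, right-handed. Zenith is measured
from +z, azimuth clockwise from the north-equivalent +y axis; a unit
direction is `(sin z sin a, sin z cos a, cos z)`. A *shot* is one outgoing
pulse at a grid position; both bands share shot sequence numbers, laid out
row-major over (zenith line, azimuth column). The default instrument mode
is 2 mrad angular sampling with 2.5 mrad beam divergence, zenith coverage
0–117°; the coarser 4 mrad / 5 mrad mode is used for the multi-scan
benchmark suites, where many small scans matter more than angular density.

## Radiometric calibration

Apparent reflectance is obtained by inverting

    response(r) = C · S(r) · exp(−k r) / r^b,   S(r) = 1/(1 + e^(−g(r−r0)))

with per-band parameters supplied by configuration. `b` defaults to 2
(inverse-square spreading) but is left free so that calibrations fitted
with either a fixed or a free fall-off exponent can be expressed.
Parameters are never fitted here — estimating them against reference
panels is a separate instrument-characterisation exercise. The demo
constants (`C = 1×10⁵` NIR / `1.5×10⁵` SWIR counts, `k = 0.01 m⁻¹`,
`r0 = 2 m`, `g = 2 m⁻¹`) are chosen so that, with the simulator's noise
floor, a leaf-like target at 70 m has SNR ≈ 10 in each band — the
reference operating point used throughout.

## Bispectral merging

Matching uses shot number plus a range tolerance, default **0.10 m** —
about twice the coarser band's single-target range resolution (4.752 cm) —
so that both bands' range noise is covered. Within a shot, candidate
pairings are resolved greedily by smallest range difference. Records are
canonicalised (sorted by range) per shot before matching, so tie-breaking
is by range order and the result is invariant to input record order; on
simulated scans, where successive returns are separated by at least the
0.5 m return gate (≫ tolerance), the greedy count provably equals the
optimal-assignment count, which the tests verify against an exhaustive
oracle.

For the union merge, a shot without matched pairs takes its NDI from
neighbouring shots within a square window of ±2 grid steps in azimuth and
zenith, weighted by inverse angular distance. The window, the weighting and
the range tolerance are all exposed in configuration; none has a canonical
published value. Undefined NDI (zero-sum reflectance pair, or no usable
neighbours) is the sentinel NaN — never an exception. Sentinel-NDI points
are excluded from training; at prediction time the forest's native
missing-value routing classifies them by their remaining attributes.
Single-band leftovers whose shot NDI cannot be determined are dropped with
a logged count.

## Multiscale dimensionality features

For each point and each scale (sphere *diameter*), the neighbours within
radius = scale/2 (centre included, minimum 3) are mean-recentred; the
eigenvalues of their covariance, sorted descending and normalised to unit
sum, give (pc1, pc2, pc3). The 16 scales span 1 m (s01) to 0.05 m (s16)
and are **geometrically** spaced: shape transitions with scale are
multiplicative, and geometric spacing gives equal resolution per octave.
pc1/pc2 are the default feature set; pc3 is redundant given the unit-sum
constraint and sits behind a flag. Scales with too few neighbours or
degenerate geometry are masked invalid and imputed with the volumetric
prior (⅓, ⅓): absent evidence, a neighbourhood is treated as shapeless
rather than line-like, which avoids spurious wood calls on sparse
far-range returns. The validity mask is exposed alongside the features.

Scale selection guidance (not automated): the smallest scale should exceed
the point spacing implied by the angular step at the ranges of interest;
the largest should approach typical stem spacing.

Implementation: one KD-tree ball query at the largest radius per point,
then cumulative first/second moments over the distance-sorted neighbours
give the covariance at every smaller scale in O(1) each; all (point,
scale) 3×3 eigenproblems are solved in a single batched call.

## Ground filtering

The pipeline stage contract is simply "separate ground from vegetation
before classification", and the stage is pluggable. The stand-in
implemented here bins the cloud on a horizontal grid (0.5 m cells), anchors
a piecewise-linear surface on each cell's lowest return, and calls a point
ground when it is within 0.1 m of that surface and the local surface
gradient is below 0.6. The grid origin derives from the cloud extent, so
the mask is invariant to horizontal translation. Linear interpolation falls
back to nearest-neighbour where the cell minima are degenerate (e.g. near
collinear). Cells that contain no true ground return anchor the surface on
whatever their lowest return is; dense ground coverage is assumed, as is
typical for below-canopy TLS.

## Classification

Random forest, 500 trees, per-split feature subsampling at √(number of
features), unlimited depth, seeded. Feature importance is the forest's
native mean impurity decrease; permutation importance is available through
scikit-learn on the wrapped estimator. Cross-validation takes a stratified
75% of the labelled samples for training and scores the held-out 25%;
accuracy reports follow remote-sensing convention (reference on rows;
producer's = recall, user's = precision). Importance-score summaries
across scans use the population standard deviation for the coefficient of
variation. Training labels are restricted to {leaf, wood}; ground is
removed by the filter, not learned.

## The scan simulator

The generator emulates: the angular grid with shared shot numbers;
band-specific reflectances (leaf pairs drawn around 0.431/0.239 with 0.03
spread; wood pairs near-equal at both bands around 0.45, with an optional
"photosynthetic bark" fraction receiving leaf-like spectra); coaxial
misalignment (the SWIR beam cast 0.79 mrad off the NIR beam along the
zenith tangent); beam-footprint mixing (61 equal-area sunflower sub-rays
per beam; a partial hit mixes intercepted reflectances by area fraction and
dims the return by the missed fraction); additive Gaussian noise on digital
numbers with σ per band set so leaf SNR at 70 m equals 10 (SNR = mean
signal / σ); per-band SNR detection thresholds (default 3) that create
single-band dropouts; and a 100 m range gate.

Leaf clusters are realised at build time as seeded discrete "leaflet"
spheres (default 150 m⁻³, radius 4 cm) filling an ellipsoid. This makes
interception a deterministic function of geometry — with zero offset and
no noise the two bands see bitwise-identical ranges — while producing the
partial hits and band-dependent dropouts that motivate the union merge.
All randomness flows from one seed through named per-component generators
(scene vs per-band noise), so components can be varied independently.

Not emulated: full-waveform shapes and pulse-width information, multiple
scattering, leaf angle distributions, wind motion, and real instruments'
residual calibration error. Multi-return detection (up to 3 returns ≥0.5 m
apart) exists behind a flag; the default is first-return-only. Passing
tests on these scenes therefore demonstrate the correctness of the
algorithms and the qualitative artefact behaviour, not field-scan accuracy
figures: real scans add occlusion complexity, mislabelled training
clusters and calibration residuals that the generator idealises away.

## Benchmark problem sizes

The end-to-end smoke scene is a 2 mrad grid over a 20° × 60° window
(~91k shots, ~56k merged points). The 20-scan cross-validation suite uses
the 4 mrad instrument mode over a 12° × 50° window with 1–3 trunks, 2–5
branches and 3–7 leaf clusters per scene and up to 300 labelled samples
per class per scan — enough to exercise geometry variation across scans
while each scan remains a minute-scale computation. On these suites the
joint spectral–spatial classification shows both the lowest accuracy
variance across scans and per-scan accuracy within 0.05 of the better
single-domain classifier, and spectral importances are more stable across
scans than spatial ones when geometry varies — the behaviour the method
predicts.

## Known limitations

- LAS I/O requires the optional `laspy` dependency; without it the
  ASCII CSV native format is the interchange format.
- The ground filter is a deliberately simple morphological stand-in; dense
  canopies with no ground returns under them will anchor the minimum
  surface on canopy bottoms (mitigated, not eliminated, by the slope
  test).
- The greedy shot matcher is optimal only when within-shot returns are
  separated by more than the range tolerance — true for this simulator and
  for typical multi-return spacing, but not guaranteed for arbitrary
  inputs.
- Apparent reflectance of partial hits is intrinsically dimmed (the missed
  beam fraction returns nothing); the simulator and the merge treat this
  as signal, as a real instrument would, so silhouette points carry lower
  ρ_app than their material's reflectance.
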