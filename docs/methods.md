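# Methods

## Model and procedure

`lnatlas` builds a population-level metastasis-density atlas of the 16 JGCA
gastric lymph-node stations (19 labels, since station 16 splits into
16a1/16a2/16b1/16b2; "14" denotes 14v) on one reference CT. The pipeline:

1. **Vessel-guided placement.** A node center observed in a patient CT is
   transferred to the reference frame so that its relative position to the
   named landmarks (16 reference vessels + gastric wall) is preserved. The
   clinical act is manual; we codify it as inverse-distance-weighted (IDW)
   offset transfer with power 2: each correspondence proposes
   `r_i + (q − p_i)` and proposals are blended with weights `∝ d_i^(−2)`.
   The map interpolates the landmarks exactly (a node on a landmark snaps to
   it), reduces to pure offset transfer with one landmark, and is equivariant
   under a common rigid translation of both frames. This is a stated,
   deterministic stand-in for the manual procedure, not a claim about how any
   individual physician combined distances.
2. **Confluent-node merging.** Nodes closer than a merge radius (default
   5 mm, one disc diameter — no numeric criterion is published) form
   single-linkage clusters replaced by their centroid; distinguishable nodes
   are kept individually.
3. **Disc rasterization.** Each node center becomes a 5-mm-diameter disc on
   the single axial atlas slice containing it (atlas slices are 5-mm bins,
   cranial→caudal). A pixel belongs to the disc iff its *center* is within
   the radius — the standard convergent convention (area error < 5% already
   at 0.5-mm pixels). Border discs are clipped, never dropped; a disc too
   small to cover any pixel center degenerates to its containing pixel so a
   mask is never empty.
4. **Density and contours.** Per-station, per-slice overlap counts form the
   density map. Contours: union mask → morphological closing (disc
   structuring element, radius 2 px at 1 mm — bridges discs ≤ 4 mm apart) →
   Roberts-cross edge. The Roberts output is thresholded at "any nonzero
   gradient", i.e. any mixed 2×2 window; on a binary mask no other threshold
   is meaningful. Closing is computed on an input padded by the SE radius,
   so the result equals the infinite-domain Minkowski closing restricted to
   the window (extensive and idempotent, including near borders). We contour
   the *closed* mask (the published account does not say whether the union
   or closed mask was contoured; the closed one matches the purpose of the
   closing step).
5. **Shading and compositing.** `gray = count / max_count` per station;
   `alpha = alpha_max · gray` (default `alpha_max` 0.8). Opacity grows with
   density; the opposite reading ("denser = more transparent") is available
   via `invert_alpha`, which maps support pixels to `alpha_max · (1 − gray)`.
   Slices composite back-to-front over the soft-tissue-windowed CT
   (center 40 HU, width 400 HU) in ascending station order, 16a1→16b2 last.
   The 19 station colors are fixed constants of this package: the scheme's
   published form names colors ("Rose red", "Claybank", …) without RGB
   values, so we assign documented triples, pairwise distinct.
6. **Statistics.** Counts and percentages of the two evidence classes —
   PRLN (pathological + radiological positive) vs RLN (radiological only) —
   per station and overall, rounded half-away-from-zero to one decimal to
   match the printed style (62.2 / 37.8).
7. **CTV margins.** The per-station elective-CTV recommendations are a
   lookup table: station 3 10–20 mm, station 7 5–15 mm, stations
   1,2,4,5,6,8–12,14,15 5–10 mm, 16a2/16b1 20 mm, 16a1/16b2 10 mm around
   the aorta. Station 13 has no published margin and carries the generic
   5–10 mm, flagged `provisional`. `expand_vessel_ctv` turns a centerline
   plus margin into a 3-D isotropic tube mask (voxel-center inclusion, with
   the vertex-containing voxels always present).

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| disc diameter | 5 | mm | fixed size replacing each node center |
| atlas slice thickness | 5 | mm | axial atlas bin size |
| in-plane spacing | 1 | mm | the reference acquisition is 1-mm pitch; the atlas's in-plane resolution is otherwise unstated — 1 mm is this package's choice, configurable in the grid block |
| closing SE radius | 2 | px | bridges discs ≤ 4 mm apart at 1 mm spacing; the closing element itself is not published |
| alpha_max | 0.8 | – | keeps CT anatomy visible under saturated overlay |
| merge radius | 5 | mm | one disc diameter; "confluent" is not quantified |
| high-risk fraction | 0.75 | – | operationalizes "high-risk region" as ≥ 75% of peak count |
| IDW power | 2 | – | standard inverse-square weighting |

Grid conventions: right-handed world frame in mm, z increasing caudally,
0-based half-open bins with the grid origin at the corner of voxel (0,0,0)
(the binning formula `floor((p − origin)/spacing)` defines the contract).

## The synthetic phantom

The generator emulates the study conditions so the pipeline is testable
offline: a 220×220 px × 40-slice soft-tissue volume (background 40 HU with
10 HU Gaussian noise, water-density stomach ellipsoid, 200 HU vessel tubes
of 3 mm radius), 16 schematic vessel centerlines respecting branch topology
(celiac trunk → LGA/SA/CHA, etc.), and the gastric wall as the stomach's
equatorial ring. Station-wise node counts are uniform in [31, 599]; each
node is a uniform arc-length point on its station's anchor segment plus
isotropic 3-D Gaussian scatter (σ = 6 mm), PRLN with probability 0.622.
Everything is deterministic given the seed.

Design choices that were genuinely open:

- **Anchor mapping.** Each station anchors on a short (~10–25 mm) segment of
  its anatomically guiding vessel (station 7 → LGA trunk, 11 → proximal SA,
  …). The vessel vocabulary has no aorta, so the four para-aortic
  substations anchor on the midline root segments of PISA, CA, SMA and IMA,
  which the phantom places on a common vertical axis standing in for the
  aorta. Anchor segments are kept short so the along-curve spread stays
  comparable to the 6-mm scatter; station point clouds are then genuinely
  localized, as station definitions intend.
- **Scatter σ = 6 mm** is a free simulation parameter (true per-station
  spread is unknowable from published material); 6 mm makes neighbouring
  discs overlap enough to form contiguous contours.
- **PRLN probability** is the overall 62.2% applied uniformly to all
  stations; per-station values are not published as numbers.

What the phantom does *not* emulate: realistic CT texture, organ deformation,
patient-to-patient anatomical variation, station-specific cloud shapes, or
imbalanced per-station evidence mixes. Passing recovery tests therefore shows
the *pipeline* is unbiased and mass-conserving under the stated sampling
model — not that the atlas reproduces clinical anatomy.

## Verification

Every geometric/morphological operation is tested against an independent
brute-force oracle (pixel-center enumeration for discs, all-pairs union-find
for merging, set-arithmetic Minkowski closing, double-loop Roberts,
per-pixel sequential compositing), plus property tests: disc-area
convergence to πr², translation covariance, bin partition of the z-extent,
closing extensivity/idempotence, mass conservation, order preservation of
count→gray→alpha, tube monotonicity and reversal invariance.

End-to-end recovery runs the default conditions (19 stations,
n ~ U[31, 599], σ = 6 mm, p = 0.622, seed 0): each station's
density-weighted centroid must land within 4σ/√n of its anchor-curve
centroid and the recovered PRLN fraction within 3 binomial standard errors
of 0.622. The centroid band is tight — it budgets only the Gaussian scatter,
while the sample centroid also varies along the anchor curve — so across
seeds a single station exceeds it in roughly one run in ten from sampling
noise alone (the rasterization itself contributes < 0.1 mm bias). The
packaged test asserts at the canonical default seed; `scripts/acceptance.py`
reports the measured error-to-band ratio at any seed.

Problem sizes in the shipped tests and acceptance script (desk scale: a full
simulated cohort of ~6000 nodes on the 220×220×40 grid, brute-force oracles
on ≤ 40×40 grids and 32×32 masks) run the whole suite in well under a
minute.

## Known limitations

- The IDW placement is this package's codification; the published transfer
  was manual and expert-driven. With very asymmetric landmark sets the IDW
  blend can bow toward landmark-dense regions.
- Density maps merge PRLN and RLN nodes (the atlas itself does not separate
  them); evidence classes survive only in the statistics.
- A disc contributes to exactly one atlas slice; nodes near slice boundaries
  are not split across slices.
- Per-station clinical counts exist only as figure graphics, so per-station
  tallies are reported but not validated against published numbers.
- No DICOM-RTSTRUCT export, no dose/DVH computation, no deformable
  registration, no automatic vessel segmentation.
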