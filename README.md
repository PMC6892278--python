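# blastoseg

Digital reconstruction of pre-implantation (cleavage-stage to blastocyst)
embryos from 3D fluorescence volumes — light-sheet or spinning-disk stacks
with a membrane channel, optionally nuclear and polarity-marker channels.
For developmental biologists and bioimage analysts who need per-blastomere
geometry, division-orientation statistics, and polarity-inheritance
quantification without hand-segmenting volumes.

## What it does

* **Segmentation** by a narrow-band (sparse-field) level set evolving the
  generalized subjective-surface flow with a ballooning term,

      φ_t = w_a ∇g·∇φ + w_d g |∇φ| div(∇φ/|∇φ|) − δ g |∇φ|,

  solved semi-implicitly (red-black SOR for the curvature term) on a
  ±3-voxel band around the front: the embryo outer surface (inward flow
  from a thresholded hull), the individual cells (outward flows from
  nucleus-centroid seeds on a membrane-probability map, with Dilate-3D
  growth onto the membrane and minimum-distance resolution of contested
  voxels — an exact partition of the embryo), and the blastocoel cavity
  (blur/invert/threshold at 1 μm with crest-accurate volume measurement).
* **Shape metrics** from the unit-density inertia tensor: volume, principal
  moments I1 ≤ I2 ≤ I3 and axes, equivalent ellipsoid radii
  r_i = √(5/2·(I_j+I_k−I_i)/V), and the aspect ratio r1/r3 — per cell and
  for the whole embryo.
* **Division orientation**: θ = 90° − arccos|e1·e2| between the mother's
  shortest axis (50 min before division) and the daughter-daughter axis,
  tested against the isotropic null F(θ) = sin θ (exact KS for n ≤ 100)
  and histogrammed in equal-null-probability (arcsine) bins; plus the
  apico-basal angle variant.
* **Polarity quantification**: Pard6b inheritance ratios from membrane
  shells (b1–b2) with Gaussian-mixture background separation, Ezrin
  apical-domain ratios, the strict asymmetric/symmetric call at
  ratio < 0.33, and Sox2/Cdx2 nuclear classification.
* **Drift compensation**: Kabsch and trimmed ICP on nucleus centroid
  clouds, with exact inverse-transform recovery of original coordinates.
* **Synthetic embryos** with exact ground truth (Voronoi blastomeres,
  membrane/nuclear/polarity channels, optional compression and cavities)
  so the whole pipeline is verifiable without proprietary imaging data.

`docs/methods.md` describes the model, the numerics, and the generator's
scope in detail.

## Worked example

Simulate a 16-cell embryo, segment it, and measure cell shapes:

```bash
blastoseg --output-dir run --seed 1 simulate --n-cells 16
blastoseg --output-dir run segment-surface run/membrane.tif --spacing 0.5 0.5 0.5
blastoseg --output-dir run segment-cells run/membrane.tif run/centroids.csv \
    run/embryo_mask.tif --spacing 0.5 0.5 0.5
blastoseg --output-dir run measure run/labels.tif --spacing 0.5 0.5 0.5
```

which prints

```
simulate: wrote 16-cell embryo to run
segment-surface: 631380 voxels, converged=True
segment-cells: 16 cells, 16 converged fronts
measure: 16 cells -> run/shape_metrics.csv
```

`shape_metrics.csv` then holds one row per cell. For the first cell of
this run:

```
cell_id,frame,volume_um3,...,r1_um,r2_um,r3_um,aspect_ratio,...
1,0,5225.62,...,14.4759,11.239,8.32274,1.73932,...
```

volume in μm³, the three equivalent ellipsoid radii in μm, and the aspect
ratio r1/r3 — this cell is a moderately elongated blastomere (aspect 1.74),
typical for a Voronoi region of a 16-cell embryo. Each stage also writes a
`*.provenance.json` with resolved parameters and input hashes; rerunning
with the same seed and inputs reproduces every output byte for byte.

The same operations are importable (`blastoseg.segment_cells`,
`blastoseg.shape_record`, `blastoseg.division_angle`, …) for scripted use;
see the test suite for end-to-end examples.

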