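# Methods

`blastoseg` reconstructs pre-implantation embryos from 3D fluorescence
volumes: it segments the embryo surface, the individual blastomeres and the
blastocoel cavity with a narrow-band subjective-surface level set, measures
per-cell geometry through the inertia tensor, scores division orientations
against the isotropic (sine) null, and quantifies polarity-marker
inheritance between daughter cells. A synthetic embryo generator with exact
ground truth closes the loop: every stage is verified against volumes whose
boundaries, moments, angles and intensity ratios are known by construction.

## The subjective-surface flow

The segmenting boundary is the zero set of a signed implicit function φ
(negative inside, positive outside, voxel units) evolving under the
generalized subjective-surface equation with an added ballooning term:

    φ_t = w_a ∇g·∇φ + w_d g |∇φ| div(∇φ/|∇φ|) − δ g |∇φ|

* **Edge field** g = 1/(1 + K |∇(G_σ * I_n)|²), with I_n the input rescaled
  to [0, 1]. g ≈ 1 in flat regions and → 0 at membranes; every term carries
  a factor of g or ∇g, so the front freezes on edges.
* **Advection** (w_a): transports the front downhill in g, i.e. toward edge
  minima, from both sides.
* **Curvature** (w_d): geodesic smoothing; closes gaps where the membrane
  signal is locally weak.
* **Ballooning** (δ): constant normal speed δ·g. Positive δ inflates the
  enclosed region (seeded cell fronts), negative δ deflates it (the embryo
  surface found from outside). The sign convention is ours; the flow needs
  both directions.

With a gradient-based edge detector on a bright membrane *ridge*, g has
two walls — one on each flank of the ridge. A front growing from inside a
cell therefore converges at the **inner flank**, the border between
cytoplasm and membrane (b1); a front shrinking from outside stops one or
two voxels **outside** the signal. The segmentation procedures account for
this: cell regions are subsequently dilated onto the membrane, and the
embryo surface is eroded (default 2 steps) onto it. This is behaviour of
the method, not an artifact of this implementation.

### Numerics

* **Narrow band.** Only a band of ±3 voxels around the sign-change set is
  updated (layers L0, L±1, L±2 are exposed on `LevelSetField`); all work
  happens on a bounding box around the band, tracked incrementally since
  the front moves under one voxel per step. φ is clamped to ±3 outside the
  band. A voxel entering the band carries the clamp value, which *is* its
  distance at the band edge — so no redistancing is required for band
  maintenance. Optional redistancing sweeps (`reinit_sweeps`, default 0)
  act only on the outermost band layer; measured on sphere test flows,
  per-step redistancing through the front stencil biases the front speed
  by several percent, while the no-redistancing scheme tracks the
  closed-form curvature and ballooning laws to ~1–2%.
* **Time stepping.** Advection is upwinded per component on the
  characteristic speed; ballooning uses the Godunov gradient. The stiff
  curvature term is handled semi-implicitly: the 7-point face-weighted
  system (1 + cΣw)φ − cΣw_f φ_nb = φ*, c = τ·w_d·g·|∇φⁿ|,
  w_f = 1/(h²|∇φ|_face), is relaxed by red-black SOR (ω = 1.5 default)
  until the residual falls below `sor_tol` (1e-4). Because the
  face-weighted operator alone is only first-order accurate in κh and
  overdrives the shrinkage of small features, the difference to the
  second-order central mean-curvature formula is added explicitly
  (a deferred correction); the implicit part keeps stability, the explicit
  part restores accuracy.
* **CFL.** The explicit terms are checked before iterating:
  τ·(|w_a|·max Σ|∂g|/h + |δ|·max g·Σ1/h) ≤ 1, otherwise a parameter error.
  Stage wrappers pick the largest stable τ up to the configured cap via
  `stable_tau`.
* **Convergence.** The front counts as stationary in a step when at most a
  `convergence_tol` fraction (default 1%) of L0 voxels changed; the run is
  converged after `convergence_window` consecutive stationary steps. An
  exact L0 freeze almost never occurs on noisy data — the front keeps
  creeping along membrane junctions at ≲0.5% of L0 per step long after the
  segmentation is geometrically stable — so the flag operationalizes
  "converged into the membrane" as quasi-stationarity.
* φ is regularized as sqrt(|∇φ|² + eps²), eps = 1e-6. NaN in φ raises a
  numerical-failure error naming the iteration. The solver is fully
  deterministic.

### Stage defaults

| stage | w_a | w_d | δ | τ (cap) | K | window |
|---|---|---|---|---|---|---|
| embryo surface (inward) | 1.0 | 0.3 | −0.8 | 0.2 | 2500 | 20 |
| cell fronts (outward)   | 1.0 | 0.3 | +0.8 | 0.2 | 2500 | 20 |

`edge_detector` itself defaults to K = 100 (configuration, not a claim);
the segmentation stages use K = 2500 because with I_n ∈ [0, 1] the edge
floor at K = 100 (g ≈ 0.15 on a strong membrane) lets a ballooning front
tunnel through. σ = 1 μm smoothing throughout. All parameters are exposed
in the CLI config.

## Segmentation procedures

* **Embryo surface** — Otsu (or fixed) threshold, morphological closing,
  hole filling, largest component, small dilation → an approximative
  surface strictly containing the embryo; inward flow to the cell–medium
  interface; erosion (default 2, 6-connected) onto the membrane signal.
  Percolating binarizations (noise images) raise a threshold error; an
  embryo touching the volume border raises a boundary-contact error.
* **Cells** — one front per nucleus centroid (seed balls of 2 μm),
  grown outward on the edge field of the membrane-probability map
  (floored at 0.2 to keep noise ridges from pinning fronts). Each
  converged region is dilated (6-connected, ≤ 5 steps) until its boundary
  overlaps membrane-classified voxels (p ≥ 0.5) by ≥ 50%. Voxels claimed
  by several cells — or, after the dilation cap, by none — go to the cell
  whose converged front is nearest (one Euclidean distance transform per
  cell). The result is an exact partition of the embryo mask, independent
  of seed order; the outer surface is kept exactly as segmented above.
* **Membrane shells** — b1 = a cell's boundary voxels; b2 = the boundary
  after `dilate_steps` (default 2) dilations; the shell spans b1…b2.
  Shells of adjacent cells overlap on shared membrane by design: signal
  there counts for both cells.
* **Cavity** — membrane image resampled to 1 μm isotropic, Gaussian blur
  (σ = 2 μm), inversion, Otsu within the embryo mask, 6-connected
  components fully inside the mask with core volume ≥ `min_volume`
  (default 8000 μm³). Each kept component is then grown voxel-wise uphill
  to the membrane-signal crest — any fixed intensity threshold stops on
  the rising flank of the ridge, ~2 voxels short of the cell–cavity
  interface — and boundary voxels straddling the crest are counted half.
  Measured error on planted 25–32 μm cavities: under ±1% (vs −25% without
  the crest correction). Limitation: a cavity whose thresholded core is
  smaller than `min_volume` (comparable to a cell interior) cannot be
  distinguished from cytoplasm by this recipe.

## Shape metrics

Unit density (mass = volume, per the radii formulas below). The inertia
tensor about the region centroid, in μm, is I = Σ(|d|²𝟙 − ddᵀ)·v_vox.
Principal moments ascending I1 ≤ I2 ≤ I3; the long/mid/short axes belong to
the smallest/middle/largest moment. Axis signs are fixed (first nonzero
component non-negative) so downstream angles are reproducible; relative
eigenvalue gaps < 1e-6 set a degeneracy flag. Equivalent radii

    r1 = √(5/2·(I2+I3−I1)/V),  r2 = √(5/2·(I3+I1−I2)/V),  r3 = √(5/2·(I1+I2−I3)/V)

are exact for a uniform ellipsoid (a ball of radius R gives r1=r2=r3=R);
the aspect ratio is r1/r3 ≥ 1. Rasterized ellipsoids with the shortest
semi-axis ≥ 8 voxels recover their generating radii within 3%. Cells with
fewer than 4 voxels, coplanar support, or a negative radicand raise a
degeneracy error; cells touching the volume border are flagged and
excluded from the measurement table by default. The same machinery applied
to the whole embryo mask gives the embryo aspect ratio used in the
compression analyses.

## Division orientation

e1 = the mother's shortest axis at the frame nearest to t_div − 50 min
(ties round toward the earlier frame); e2 = the unit vector between the
daughter centroids just after division (the first frame with two labels).
θ = 90° − arccos|e1·e2| ∈ [0°, 90°]: θ = 90° means division along the
shortest axis. If e2 is isotropic, θ has CDF F(θ) = sin θ (the folded
polar angle has density ∝ sin α on [0°, 90°]); observed samples are tested
with a one-sample KS test (exact p for n ≤ 100) and histogrammed in
arcsine-spaced bins θ_k = arcsin(k/n)·180/π so each bin carries equal null
mass. The apico-basal variant takes the longest axis 60 min before
division against the embryo-center→cell-center axis. θ (not α = 90°−θ) is
the stored statistic.

## Polarity quantification

* **Pard6b (membrane-bound)** — per daughter, intensities in the b1–b2
  shell 10 min after cytokinesis. A two-component Gaussian mixture
  (scikit-learn EM, best of 10 seeded initializations, components ordered
  by mean) separates background from marker signal. The reported signal
  is Σ(I − bg) over the whole shell with the background level measured
  outside all labels (a global camera/ambient offset), guarded by a
  3σ-exceedance presence test; summing only the high mixture component
  biases a dim daughter's ratio by up to ±0.06 because the posterior cut
  sits at a different relative height of the cap profile per daughter
  (the raw high-component sum remains available via
  `subtract_background=False`). Ratio = dimmer/brighter ∈ [0, 1]; two
  signal-free daughters score 1 (indistinguishable = symmetric).
* **Ezrin (apical domain)** — total GFP inside (apical mask ∩ daughter
  label), 1 h after cytokinesis to let cleavage-furrow signal clear; the
  apical mask is imported or derived by Otsu on a 4 μm band under the
  embryo surface.
* **Classification** — asymmetric iff ratio < 0.33 (strict, so 0.33 itself
  is symmetric). Ratios are invariant to positive intensity scaling; a
  nonzero camera offset matters only in the non-subtracting mode.
* **Sox2/Cdx2** — per-nucleus Sox2/Cdx2 mean-intensity ratios, mitotic
  nuclei excluded, two-component mixture on log-ratios (ratios are
  scale-skewed; the raw-ratio mode is available via `use_log=False`);
  the higher component is Sox2-positive.

## Registration

Frame-to-frame drift/rotation of nucleus centroid clouds: Kabsch (SVD,
reflections excluded) with correspondences, trimmed ICP (keep the best 80%
nearest-neighbour matches, robust to nuclei appearing at divisions)
without. Original coordinates are recovered exactly by the inverse
transform Rᵀ(q − t). Transforms serialize to JSON; frame-to-frame chaining
composes transforms rather than registering everything to one reference.

## Synthetic embryos

Blastomeres are Voronoi regions of repulsion-relaxed seeds in a sphere —
crude biology, but the pipeline's requirements are geometric: known
boundaries, volumes, moments, angles, intensities. Channels: a
Gaussian-profile membrane ridge (σ = 1 μm) at 10:1 peak:background over
every boundary; Gaussian nuclear blobs; apical caps (half-angle 50°)
painted on contact-free surface patches of outer cells and scaled by
per-cell inheritance fractions. Optional volume-preserving z-compression
(z × f^(−2/3), xy × f^(1/3)) plants an embryo aspect ratio of exactly f.
Gaussian noise σ = 5% of the membrane peak (Poisson optional) is added
last; identical seeds give bit-identical volumes. Division fixtures plant
a triaxial mother (shortest axis in a seeded random direction) and two
daughter spheres separated along an axis at the requested θ, with caps
split at the requested intensity ratio. Blastocyst fixtures carve one or
more signal-free cavities.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: optical PSF anisotropy and depth attenuation,
membrane-intensity variation along cell contacts, cell shapes with
non-planar interfaces (Voronoi faces are planar), nucleus tracking errors,
mitotic rounding, and furrow transients. Default sizes (16 cells, 25 μm
radius, 1 μm isotropic voxels for the test fixtures; the generator's
native default is 0.5 μm) keep every full-pipeline check within minutes
on one core while leaving ≥ 8 voxels across the smallest cell axis, the
regime where the 3% shape-accuracy statement holds.

## Known limitations

* The solver's convergence flag is quasi-stationarity, not an exact L0
  freeze; pathological inputs (no edges anywhere) run to `max_iters`.
* Two seeds inside one true cell cannot be detected; the cell is split.
* The cavity recipe cannot separate cavities of cell-interior size from
  cytoplasm (see above).
* Fiji's 8-bit conversion depends on an unrecorded display range; the
  percentile-window substitute (0.1/99.9 defaults) is close but not
  identical.
* Anisotropy is honoured through physical-unit gradients and distance
  transforms, but the solver's accuracy statements were measured on
  isotropic working grids (the pipeline resamples to isotropic first, as
  the processing conventions assume).
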