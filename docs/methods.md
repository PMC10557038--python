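# Methods

This note documents the models implemented in `headmc`, the defaults
they ship with, the numerical choices behind them, and what the
synthetic phantoms do and do not capture about real MRI-derived head
models.

## Synthetic head phantoms

Real head models for photon-transport studies are segmented from
T1-weighted MRI into five tissues (scalp, skull, cerebrospinal fluid,
gray matter, white matter) and meshed. Such models cannot be bundled
here, so `headmc` generates a geometric stand-in: nested ellipsoidal
shells. The reference phantom uses outer semiaxes 80 × 95 × 70 mm
(lateral × anterior-posterior × superior-inferior, a typical adult
head) with shell thicknesses scalp 6 mm, skull 7 mm, CSF 2 mm — all
within the adult ranges reported across the NIRS literature — and a
gray-matter ribbon of 4 mm (cortical thickness plus partial-volume
margin) over a white-matter core. Each inner boundary is the outer
ellipsoid with every semiaxis reduced by the cumulative thickness, so
shell thickness is exact for spherical phantoms and approximately
uniform for head-like aspect ratios. An optional sinusoidal modulation
of the gray/white boundary radius (`gyri_amplitude_mm`,
`gyri_frequency`) provides a crude gyral texture.

What the phantom does **not** emulate: true anatomical thickness maps
(frontal-thin/occipital-thick skull), sulci filled with CSF, the neck
truncation of real scans, and segmentation noise. Tests passing on the
phantom therefore validate the *pipeline geometry* (surface topology,
arc-length bookkeeping, label handling), not anatomical fidelity.

## Volume → tetrahedral mesh

The labeled grid is pooled to the requested element size by per-block
label mode (ties resolved toward the deeper tissue so thin inner
layers are not eroded preferentially), and every occupied voxel is
split into six tetrahedra by the Freudenthal/Kuhn subdivision around
the cube's main diagonal. That subdivision is face-to-face across a
uniform grid, so the boundary triangles of the tet set form the scalp
surface directly. Two properties are enforced rather than assumed:

- **Well-composedness.** Voxelized ellipsoids can contain voxel pairs
  meeting only along an edge or a corner, which pinches the extracted
  surface. A repair pass fills such configurations (the filled voxel
  inherits the modal label of its face neighbors) and iterates until
  the occupancy mask is clean; meshing fails loudly if it cannot
  converge.
- **Manifoldness.** After extraction, every surface edge must be
  shared by exactly two triangles; violations raise with a diagnostic
  rather than producing a silently broken surface.

All tets are positively oriented by construction, per-tissue mesh
volume equals the pooled voxel count exactly (within a few percent of
the unpooled volume at 2:1 pooling), and the scalp surface of the
reference phantom has Euler characteristic 2 (closed, genus 0). The
trade-off of voxel meshing is a staircase surface: normals are
axis-aligned at the face level and arc lengths along the raw surface
exceed those of the smooth underlying ellipsoid. The placement stage
(below) resamples and smooths its working curve, which is where
sub-voxel geometry matters.

## Scalp surface locations

Candidate probe locations are Poisson-disk samples of the scalp
triangulation: candidates drawn uniformly by area with a seeded
generator (about one candidate per mm², independent of spacing so the
accepted count varies predictably with the spacing), accepted greedily
with a hard minimum separation. Face and ear regions are excluded with
spherical zones (the analogue of the de-identified face and removed
ears of published head models): one 45 mm sphere at the anterior pole,
two 20 mm spheres at the ear fiducials. Ear fiducials are the scalp
vertices best aligned with the lateral (±x) axis, pushed 5 mm
inferior and snapped back to the surface — a reproducible, anatomically
plausible stand-in for "a point near each ear".

The shipped default configuration (spacing 8.042188 mm, seed 1305) was
calibrated once so the reference phantom yields exactly 805 locations
— matching the density of published full-head location sets — and then
frozen; it is part of the product, not a tunable. Guarantees: every
point is on the scalp (within 0.5 mm), minimum pairwise distance ≥ the
spacing, and every non-excluded scalp triangle centroid lies within
2× spacing of a sample (full-head coverage).

## Optode placement

Given a POI and the two ear fiducials:

1. **Cutting plane** through the three points; the normal is the unit
   cross product of the two in-plane directions, signed superior.
   Collinear inputs raise.
2. **Mesh–plane intersection**: each scalp triangle crossed by the
   plane contributes one segment between its two edge crossings.
   Crossing points are computed in canonical (sorted) node order so
   shared edges give bit-identical points in both adjacent triangles;
   vertices exactly on the plane are perturbed infinitesimally
   (simulation of simplicity), so every crossed triangle has exactly
   two crossed edges. Segments chain into closed loops via shared
   edges; a closed manifold surface guarantees each crossing edge
   belongs to exactly two crossed triangles, and violations raise with
   the triangle ids. When several loops exist, placement uses the loop
   nearest the POI.
3. **Segment extraction**: an open sub-curve of arc length
   `dmax + 40 mm` centered (by arc length) on the loop vertex nearest
   the POI (`dmax` = farthest requested distance; the 20 mm margin per
   side guarantees room for the centering rule; equidistant-vertex
   ties go to the lower index).
4. **Resampling and smoothing**: uniform 0.1 mm arc-length resampling
   by linear interpolation, then a centered moving average of 5 mm
   extent whose window shrinks symmetrically at the ends — endpoints
   are preserved and straight segments are fixed points. Smoothing
   suppresses the voxel staircase so placement resolution is set by the
   0.1 mm resampling, not the 2 mm mesh. Note that length is preserved
   (within 2%) only for curves whose features are larger than the
   window; sub-window jitter is deliberately removed, length included.
5. **Arc placement**: source at arc coordinate `s(POI) − dmax/2`,
   detector *i* at `d_i` beyond the source, so the POI is centered
   between source and farthest detector. Achieved separations are
   re-measured along the dense curve; they land within 0.1 mm of the
   request (in practice, at interpolation precision). Optodes are
   snapped to the nearest scalp point (KD-tree prefilter + exact
   point-triangle projection, since smoothing can pull the curve
   off-surface) and carry inward unit-normal directions, i.e. the
   launch directions a transport engine expects.

Arc distances always exceed the Euclidean chord on a curved head; this
matches how flat probe strips behave when wrapped. Geodesic
(surface-shortest-path) metrics are out of scope by design.

## Simulation input files

The session writer emits a JSON document with Session / Forward / Mesh
/ Optode / Media blocks in the key style of mesh-based Monte Carlo
engines, and the properties writer a whitespace table `index mua mus g
n` (one line per tissue, fixed six-decimal formatting). Both writers
are byte-deterministic (sorted keys, fixed formats) and validated by
round-trip and frozen golden files rather than by invoking an external
engine, whose schema evolves independently. The `.mch` history dialect
is read-only in spirit (a writer exists for fixtures): little-endian,
`MCXH` magic, a 64-byte header carrying media count, column count and
the pathlength unit, then float32 records. Only the column layouts
`[det_id, ppath×5, mom×5]` and the same plus a trailing weight are
accepted; anything else is rejected loudly, because per-tissue
momentum transfer is what the DCS chain requires. Absent weights are
reconstructed as `exp(−Σ μa L)` from supplied optics. Detector ids are
1-based.

## Forward Monte Carlo

The in-repo engine is a planar layered half-space random walk, not a
mesh transport code: the DCS chain consumes only per-photon tallies,
which are geometry-agnostic, and a layered medium exercises every
record field. Choices, in order of consequence:

- **Isotropic similarity walk** (g = 0, step rate μs′). For DCS this
  has the convenient exact property E[1 − cos θ] = 1 per event, so the
  per-layer scattering-event count *is* the momentum-transfer tally;
  the residual difference against accumulating 1 − cos θ per event is
  O(c²/6) per event in the g₁ exponent (c the per-event decay
  argument), far below the stochastic noise over the default τ window.
- **Continuous absorption**: survival weight `exp(−Σ_l μa_l L_l)`,
  accumulated from per-layer pathlengths; layer interfaces split
  segments exactly, and crossing a boundary resamples a fresh
  exponential step in the new layer (exact by memorylessness).
- **Boundaries**: unpolarized Fresnel reflection at the top surface
  with total internal reflection beyond the critical angle; internal
  interfaces are index-matched (head tissues share n ≈ 1.37 in
  practice; the engine stores per-layer n but only the surface step
  uses it).
- **Russian roulette** below weight 1e-4 with survival factor 10,
  folded into the stored weight — unbiased, bounded runtime. The
  `weight == exp(−Σ μa L)` identity therefore holds exactly for every
  photon that never triggered roulette (all weights ≥ 1e-3) and the
  invariant is tested on that subset.
- **Detection**: escape position within `|r − ρ| ≤` half-width of a
  ring records the photon (first matching ring, ids 1-based).

The kernel is a numba-compiled scalar loop seeded per run
(`np.random.seed` inside the kernel), bit-reproducible for a fixed
seed. Validation is against an independent closed-form oracle: total
detected weight in the 15 mm annulus of the standard homogeneous
condition (μa 0.01/mm, μs′ 1.0/mm, n 1.37) agrees with
extrapolated-boundary diffusion theory to ~0.1% at 10⁶ photons (the
test tolerance is 15%).

## DCS estimators and fitting

`compute_g1` implements the momentum-transfer estimator; it returns 1
at τ = 0 exactly and is non-increasing for Brownian dynamics. The
semi-infinite model uses z₀ = 1/μs′, the extrapolated-boundary offset
z_b = (2/3μs′)(1+R_eff)/(1−R_eff), and R_eff from the standard cubic
polynomial in the relative index (R_eff ≈ 0.493 at n = 1.37). The
default τ grid is 50 log-spaced lags in [10⁻⁷, 10⁻²] s and the default
fit window [10⁻⁷, 10⁻³] s, covering scalp/brain decays at 785 nm for
αD_b between ~10⁻⁷ and ~10⁻⁵ mm²/s.

`fit_dcs` minimizes bounded least squares in log₁₀ αD_b with three
starts (10⁻⁷, 10⁻⁶, 10⁻⁵ mm²/s; best residual wins), optionally
jointly with β against g₂ = 1 + β g₁²; β is otherwise fixed at 0.5, a
typical single-mode-fiber value. Non-convergence returns
`converged=False` with the best residual instead of raising. On
model-generated curves the fit recovers αD_b to better than 0.1% and β
to well under 5%; closing the loop through the Monte Carlo engine at
the homogeneous condition recovers αD_b within a few percent (tested
at 15%) — the numerical analogue of the simulate → autocorrelate → fit
workflow the package prepares for mesh-based engines.

A numerical caveat: inverting the Siegert relation loses precision
once g₁ ≲ 10⁻³, because g₂ − 1 cancels catastrophically; the algebraic
identity is exact, the float encoding is not.

## Problem sizes and determinism

Default working sizes, chosen as the package's own demonstration
scale: reference phantom ≈ 4.7 M voxels at 1 mm, meshed at 2 mm into
≈ 1.7 M tets with ≈ 63 k scalp triangles; placement runs in well under
a second; Monte Carlo validation uses 10⁶ photons (≈ 20 s compiled)
and 2 × 10⁴–10⁵ photons for distributional checks. Every stochastic
component (surface sampler, Monte Carlo) is seeded; the placement
chain is deterministic. The pipeline runner hashes its config, embeds
seed and hash in every artifact, and skips completed stages on re-run.

## Known limitations

- Ellipsoidal phantoms cannot probe anatomy-specific effects
  (thickness heterogeneity, sulci, superficial vessels).
- Voxel meshing yields staircase surfaces; curvature-adaptive meshing
  is delegated to external tools when real models are available.
- The forward engine is planar-layered, CW (no time gating), isotropic
  scattering only, and CPU-bound; it is a validation instrument, not a
  replacement for mesh-based transport engines.
- The semi-infinite fit applied to layered media returns an effective
  αD_b weighted toward superficial layers at short separations —
  inherent to the homogeneous model, not a defect of the optimizer;
  multi-layer and Monte Carlo-based inverses are out of scope.
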