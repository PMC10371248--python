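# Methods

## Scope and model chain

`canophot` simulates the daily photosynthesis of a maize canopy from
explicit 3D geometry and dissects variety differences into per-trait
contributions. The chain is:

1. plant geometry (parametric generator, or extraction from labeled point
   clouds) → leaf **vector models**;
2. lofted triangle meshes → replicated field **canopy** with a central
   scoring region;
3. clear-sky solar boundary conditions → **Monte-Carlo light transport**
   → absorbed PPFD per leaf facet;
4. **non-rectangular hyperbola** leaf response per facet → hourly canopy
   rate *A_c* → daily integral *A_c,d*;
5. **factorial dissection** and one-at-a-time sensitivity sweeps.

All geometry is in centimeters (Z up, ground at z = 0); areas convert to
m² only at the LAI/photosynthesis reporting boundary. Fluxes are
μmol photons m⁻² s⁻¹ (PPFD) and μmol CO₂ m⁻² s⁻¹; daily totals are
mol CO₂ m⁻² ground day⁻¹ (hourly sum × 3600 / 10⁶ — plain rectangle rule,
one trace per hour).

## Leaf vector models and meshing

A leaf is an ordered midrib axis of `stations` points (default 31) with a
pair of midrib-to-edge vectors per station. Meshing lofts two triangle
strips (left/right of the midrib) between consecutive stations — 4
triangles per station interval — and a closed 8-sided tube for the stem.
Facets with area < 10⁻⁴ cm² or severely degenerate shape are dropped.
Lofting is exact for this data structure, so mesh area converges to the
smooth-surface area as stations increase (doubling 31 → 62 changes a
curved leaf's area by < 0.5%).

Trait edits operate on the vectors:

- **LL / LW** (multiplicative): scale axis about the leaf base / scale the
  half-width vectors.
- **LA** (additive, degrees): rigid rotation of the whole leaf about the
  horizontal axis through its base that lies in the leaf's vertical plane.
  Sign convention: **positive = more erect** (toward vertical).
- **LC** (additive, degrees): progressive bending — each station interval
  turns by delta/(S−1) about the same horizontal axis, accumulating to the
  full delta at the tip. Sign convention: **positive = more droop**. Arc
  length is preserved exactly.
- **LN** (additive count): positive deltas clone leaves cycling from the
  top of the plant, rotate them 180° in azimuth about the stem, and stack
  them above the current top leaf at the plant's mean internode spacing
  (this preserves the canopy-top structure that dominates light capture);
  negative deltas remove leaves from the bottom up.

The identity adjustment is a geometric no-op (bit-identical mesh).

## Synthetic plants

The generator emulates maize-like architectures: 8–16 leaves inserted
along the stem with alternating (or spiral) phyllotaxis, blade length
40–90 cm and width 4–10 cm with mid-canopy leaves the longest, an
insertion angle measured from vertical, and progressive droop along the
blade. The blade outline follows sin(π·s^0.7)^0.8 (widest about a third of
the way from the base, pointed tip). Presets:

- `erect`: 12 leaves, 60 × 8 cm, insertion 18°, droop 25° — a compact
  upright ideotype;
- `spread`: 10 leaves, 75 × 8.5 cm, insertion 50°, droop 60° — a
  planophile ideotype;
- `toy-flat`: 4 rectangular horizontal leaves, used for analytic checks.

Preset parameter values are synthetic magnitudes chosen to reproduce the
qualitative erect-vs-spread contrast between real breeding lines; they are
not measurements. Per-leaf jitter (10% length, 8% width, 5° angle) is
drawn from a seeded generator, so a (params, seed) pair is reproducible.

What the generator does *not* emulate: leaf sheaths, tassels, ears, blade
twisting and waviness, senescence, and time-dependent growth. Tests passing
on these plants therefore validate the machinery (geometry, transport,
integration, dissection algebra), not agronomic parameter values for any
real cultivar.

`sample_point_cloud` turns a plant into a labeled cloud by area-uniform
sampling of the lofted mesh plus optional Gaussian noise — a stand-in for
a segmented multi-view-stereo scan with ideal labels and homogeneous
density (real scans have occlusion holes and density gradients).

## Point-cloud preprocessing

- **Ground plane**: RANSAC (200 three-point hypotheses, seeded) keeps the
  plane with most inliers within 5 cm, refits by SVD, and removes its
  inliers. The dominant plane must be the soil: a sparse ground under a
  dense, nearly planar plant can lose this contest — callers should crop
  to the pot/soil region first, as any scan pipeline does.
- **Clustering**: points connected within 0.5 cm form components; only the
  largest survives.
- **Statistical outlier removal**: a point is dropped when its mean
  distance to its 50 nearest neighbors exceeds the global mean of that
  statistic by more than 0.3 global standard deviations. On any bounded
  surface this rule also shaves the outermost "edge band" (edge points
  have intrinsically elevated kNN distances), and re-running it nibbles a
  fresh ring; the tests therefore assert that noise is removed and the
  blade *interior* is untouched, rather than literal idempotence.

## Vector-model extraction

Per leaf: a kNN graph (k = 10) over the leaf's points; the base point is
the point nearest the stem (ties broken toward low z); Dijkstra distances
from the base give the main path to the graph-farthest point (tip); the
path is resampled and smoothed (endpoint-pinned moving average), then cut
at each station by a plane perpendicular to the local tangent, taking the
extreme signed lateral offsets within a slab (±0.75 station spacings) as
the edge vectors. Two refinements stabilize the cut:

- **midrib re-centering** (two passes): each station moves to the midpoint
  of its cross-section, because the shortest path drifts toward blade
  edges (e.g., the corner of a truncate tip);
- **tip extrapolation**: the outermost two stations are rebuilt along the
  interior tangent direction, projecting the graph tip onto it, since the
  graph endpoint lies on the blade edge.

On scan-density clouds (≈25 points/cm², 0.5 mm noise) the round trip
generator → cloud → extraction recovers leaf length and base height within
~2% and width within ~3% (width is intrinsically the noisiest trait — the
cut plane tilts with any residual midrib wiggle).

Leaf layer (up/bottom) is assigned by base height relative to half the
plant's maximum height. Centroid height is an alternative the data
structure supports; base height was chosen because insertion height, not
blade posture, is the stable botanical property.

## Canopy and incident light

Default layout: 4 rows × 13 plants, 55 / 15 cm spacings, plants cycled
over the grid, optional 0/90/180/270° azimuth randomization (on by
default, to avoid artificial alignment of cloned plants; seeded). The
scoring region is the central 110 × 75 cm (2 rows × 5 plants); a plant is
scored wholly by its base position. Rows run north–south.

Solar position uses the Cooper declination and a 15°/hour angle in local
solar time (≤ ~1° error — negligible against canopy-scale radiation
uncertainty). Clear-sky PPFD on a horizontal plane:

- beam normal = I₀ · τ^m, with I₀ = 1367 W m⁻² × 0.45 (PAR fraction)
  × 4.57 μmol J⁻¹ ≈ 2811 μmol m⁻² s⁻¹, air mass m = 1/cos(zenith),
  τ = 0.7 by default;
- direct (horizontal) = beam normal × cos(zenith);
- diffuse = 0.5 · (1 − τ^m) · I₀ · cos(zenith) — half of the scattered
  flux reaches the ground, the classic clear-sky partition used in canopy
  modeling.

This formulation is a documented stand-in for whichever climate model a
user prefers; it is isolated behind `incident_ppfd` and all constants are
module-level.

Leaf optics come from either (a) solar-spectrum-weighted means of measured
reflectance/transmittance spectra over 400–700 nm (plain sums on the given
grid, matching the Σ definition of broadband PAR optics), or (b) SPAD
regressions calibrated for the lines W64A and A619 (shared quadratic for
transmittance; quadratic/linear reflectance per line; percent converted to
fractions, clamped to [0, 1] with a warning). Absorptance under these
regressions rises monotonically with SPAD up to the transmittance
quadratic's vertex near SPAD 65 and flattens beyond it.

## Monte-Carlo light transport

A single numba kernel traces both components:

- **direct**: stratified jittered grid on the top plane, all rays along
  the solar direction, each carrying direct_ppfd × domain area / N;
- **diffuse**: uniform positions, cosine-weighted downward directions
  (uniform-overcast sky), weight analogous.

Acceleration is a uniform voxel grid (~8 triangles per cell target,
≤192³ cells) traversed by 3D DDA with Möller–Trumbore intersection.
Lateral boundaries are periodic (a ray exiting one side re-enters the
opposite side), emulating an extended field; the guard rows of the default
layout are kept anyway, and scoring already excludes them. The ground
absorbs; rays crossing the domain top escape.

At a facet hit with reflectance R and transmittance T, a single uniform
deviate decides: reflect (probability R), transmit (probability T), or
terminate and deposit the full ray weight on the facet (probability
1 − R − T). This Russian-roulette scheme is unbiased (expected deposit =
w·(1−R−T)) and conserves energy *exactly* per ray — every ray's weight
lands in exactly one of {facet, ground, escaped}, so the reported balance
error is at floating-point level regardless of ray count. Scattered rays
redistribute cosine-weighted about the facet normal on the incident side
(reflection) or its inverse (transmission); facets are scored on both
sides and absorbed flux is normalized by one-sided facet area. Paths are
capped at `max_bounces` (default 5); a ray still alive at the cap deposits
its weight at the last hit — a ≲0.1% bias toward absorption for typical
leaf optics (R+T ≈ 0.1), chosen over losing the energy because the
balance identity is used as a correctness invariant.

Randomness is counter-based: splitmix64 hashes of (seed, ray, bounce,
dimension), so results are bitwise reproducible and independent of
evaluation order; each hour of a diurnal series derives its own stream
from the base seed.

## Leaf and canopy photosynthesis

`leaf_A` returns the lower root of θA′² − (ϕI+P_max)A′ + ϕI·P_max = 0
minus R_d, with the rectangular-hyperbola limit at θ → 0. It is monotone
nondecreasing and concave in I over θ ∈ (0, 1].

Fitting uses bounded trust-region least squares with gas-exchange
initialization (R_d from the dark point, ϕ from the ≤250 μmol slope,
P_max from the plateau, θ = 0.7) over bounds P_max ∈ (0, 200],
ϕ ∈ (0, 0.125), θ ∈ [0, 1], R_d ∈ [0, 20]. Non-convergence and degenerate
(flat) data are flagged in the diagnostics, not raised.

Identifiability on the standard 12-level measurement grid (2000 … 50, 0)
is limited at realistic noise: at σ = 0.5 μmol m⁻² s⁻¹ per observation the
Cramér–Rao bound puts the relative standard error of R_d near 25% and of
θ near 10%, so individual noisy curves recover P_max and ϕ well (median
error ~2–6%) but *cannot* pin down all four parameters within 10% at a 95%
rate — averaging replicate curves (the usual n = 5 practice) or fixing
R_d from separate dark measurements is required for tight θ/R_d estimates.
The acceptance suite states this check at its nominal rate and documents
the shortfall rather than weakening it.

Canopy assimilation sums leaf_A(absorbed PPFD) × facet area over scored
leaf facets, divided by the scoring-region area; parameters are per layer
(up/bottom) with no within-layer gradient. The facet response is driven by
**absorbed** PPFD (the tracer already applied 1 − R − T); driving it with
incident flux instead would double-count leaf optics, but the quantity fed
to the response is a caller decision — pass a different field to
`canopy_A` to reproduce the incident-basis convention. Nighttime
respiration is excluded from A_c,d by default (`include_night` adds
−R_d × LAI for listed night hours).

## Factorial dissection and sweeps

`run_dissection` builds the 8 scenario canopies (O, S, P, C, SP, SC, PC,
SPC) from a base and a donor bundle and computes

    c(X)   = A(X) − A(O)                      X ∈ {S, P, C}
    c(XY)  = A(XY) − A(X) − A(Y) + A(O)
    c(SPC) = A(SPC) − ΣA(pairs) + ΣA(singles) − A(O)

plus relative values as % of A(O). All 8 scenarios within a replicate
share one RNG seed (placement and ray streams), so Monte-Carlo noise
differences out and the inclusion–exclusion identity holds exactly;
replicates vary the seed to quantify spread. Geometry and traced light
fields are cached per (architecture, optics, seed) — a P-swap reuses the
cached absorption, because leaf photosynthetic parameters do not affect
light transport.

Sweeps scale one NRH parameter (0.6–1.4, θ clipped at 1 with a warning;
light fields reused) or one architectural trait (LW/LL 0.6–2.0, LN −4…+8,
LC ±180°, LA −20…40°; full re-mesh and re-trace per value, with LAI
reported alongside A_c,d and the arg-max flagged as the optimum). Failed
adjustments (e.g., LN below the leaf count) are recorded per point and the
sweep continues.

Simulated behavior on the synthetic presets matches canopy-physiology
expectations: A_c,d responds linearly to P_max/ϕ scaling and negatively to
R_d; curvature and leaf-angle sweeps are non-monotone with interior optima
(extreme droop clumps leaves, extreme erectness under-intercepts); and
swapping in the higher-capacity light responses of the spread bundle
raises A_c,d by ~20% while optics swaps contribute ~1%.

## Problem sizes and tolerances

The test suite and acceptance script run reduced-size configurations
chosen to keep Monte-Carlo noise well below every asserted tolerance: a
2 × 5-plant canopy (scoring 55 × 45 cm) for dissection and sweeps, 2–6
daylight hours where the full 16 are not needed, 2×10³–6×10⁵ rays/m²
depending on the check, 4000-facet turbid scenes for the interception law,
and 25 points/cm² clouds for the geometry round trip. Analytic oracles are
held to 10⁻⁹ (NRH roots) or exact equality (identity adjustments,
determinism); Monte-Carlo comparisons use 2–5% bands consistent with their
measured standard errors.

## Known limitations

- Organ segmentation is out of scope: point clouds must arrive labeled.
- Broadband PAR transport only — no spectral tracing, no specular
  component, no penumbra.
- No biochemical (C4) model, stomatal conductance, temperature response,
  or canopy nitrogen gradient; layer-specific NRH parameters are the only
  vertical differentiation.
- The clear-sky partition is a fixed stand-in; overcast fractions or
  measured radiation series must be supplied by the caller.
- Scoring is whole-plant by base position; facet-level clipping at the
  region boundary is not implemented.
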