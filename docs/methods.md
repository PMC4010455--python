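# Methods

This note records the model underlying `windpath`, the choices made where
the design was genuinely open, and what the synthetic tests do and do not
demonstrate.

## Wind-field interpolation

Wind is a vector; interpolating speed and direction separately fails at
direction wrap-around. Each observation (s, d) is therefore decomposed
into Cartesian components — with the meteorological *from* convention,
u = −s·sin(d), v = −s·cos(d) — and each component surface is fitted with
plain multiquadric radial basis functions, φ(r) = √(r² + c²), by a dense
direct solve of Φλ = z. Station networks here are tiny (tens of points),
so no approximation or preconditioning is needed; the solver refuses
systems whose condition estimate exceeds 1e12 and reports it.

Choices and their consequences:

- **No appended polynomial term.** The classical component-wise scheme
  uses the bare multiquadric basis. A consequence worth knowing: constants
  are *not* in the span, so a uniform wind sampled at stations is
  reproduced exactly at the stations but its *magnitude* can deviate by
  O(10 %) between them. The *direction* of a uniform field is still exact
  everywhere, because both component surfaces are the same scalar
  interpolant scaled by u₀ and v₀ — and direction is all the cost graph
  consumes (speed weighting is off by default).
- **Shape parameter c** defaults to the mean nearest-neighbour station
  spacing (metres): scale-aware, and reduces to the grid cell size when
  only one station exists. No published value exists for this constant;
  it is exposed as `shape_c` everywhere.
- **Calm observations** (speed 0) are legal inputs fitted as u = v = 0.
- Grid cells are 500 m — the customary resolution for urban air-quality
  work; internal arrays put row 0 at the south edge, and the ASCII-grid
  writer flips to north-up at the file boundary.

## The movement-cost graph

The gridded field becomes a directed graph: cells are vertices, each cell
connects to its 8 neighbours, and a directed edge (A → B) of geometric
length L (cell or √2·cell) costs

    cost = L · (1 + γ · (θ̄/180)^β)

with θ̄ the mean of the angular deviations between the edge azimuth and
the flow azimuth at A and at B. Defaults γ = 4, β = 2.

Rationale and fine print:

- The Gaussian plume model says ground-level concentration decays with
  azimuth off the wind axis and scales with 1/u; the penalty's ingredients
  (edge length, wind direction at both endpoints, movement direction) and
  monotonicities mirror that. The exact published algebra of the
  simplified cost used by the original SWPD study is not recoverable, so
  the law above is this package's declared reconstruction; it is a
  pluggable callable (`cost_law=`) so alternatives can be swapped in
  without touching the graph machinery.
- **Both endpoints** enter the deviation because transport between two
  cells is conditioned by the wind at each; a cell below the calm
  threshold (0.1 m/s) has no meaningful direction and contributes zero
  deviation — with both endpoints calm the edge is isotropic, cost = L.
- **Wind speed does not enter the default cost**; an optional 1/ū factor
  (`speed_weighting`) exists because dispersion dilutes with speed, but it
  changes absolute rather than relative costs under near-uniform speeds.
- Costs satisfy L ≤ cost ≤ L·(1 + γ), are asymmetric (A → B ≠ B → A), and
  rotating a uniform wind by 90° permutes a cell's 8 edge costs exactly.

## Shortest paths and the SWPD

Paths are minimised on accumulated **cost** (classic Dijkstra, binary
heap); the distance reported — the SWPD — is the geometric **length** of
that minimum-cost path. These are different numbers and both are kept.
Ties are broken deterministically: the heap orders by (cost, row, col) and
neighbours expand in the fixed N, NE, E, SE, S, SW, W, NW order, so
identical inputs give bit-identical paths.

Structural facts that shape everything downstream:

- With γ = 0 (or calm wind) the SWPD degenerates to the octile metric of
  the 8-lattice, which overestimates Euclidean distance by at most 8.24 %.
- Moving dead upwind under the default law zig-zags at 45°, inflating the
  geometric path length by exactly √2; crosswind movement stays straight.
  Hence **the SWPD/Euclidean ratio is bounded by √2 on this lattice**, no
  matter how large γ is — the anisotropy the metric can express is
  intrinsically capped.
- Query points between cell centres snap to the nearest centre; the snap
  offset is *not* added to the SWPD.

## IDW on either metric

The estimate at x₀ is the λ-weighted mean of all station values with
λᵢ ∝ dᵢ^(−p), p = 2 by default, weights normalised to sum to one. No
search radius is applied and a zero distance returns that station's value
exactly (first match in input order). Estimates are convex combinations of
the observations and invariant to rescaling all distances.

The SWPD is asymmetric, so a direction had to be chosen: by default the
distance is measured **from the station to the prediction point** —
pollution travels from where it was measured toward where it is being
estimated, so a station whose air can reach x₀ cheaply (x₀ downwind of it)
gets full weight, while a station downwind of x₀ is discounted. The
opposite convention is available (`direction="point_to_station"`); in the
synthetic experiments the two perform indistinguishably.

For gridded surfaces the cell containing a station is assigned distance
zero to it under both metrics, so station cells reproduce their
measurements exactly; point-wise prediction uses raw coordinates.

## Evaluation statistics

Leave-one-out cross-validation: each station is removed, predicted from
the rest, and summarised by plain means over the n hold-outs —
MSE = mean squared error, MAE = mean absolute error, and MRE = the
**signed** mean of (estimate − measured)/measured in percent. The sign is
deliberate (over- and under-prediction cancel), matching published tables
in which MRE is negative on some dates. Improvement ratios come in two
denominators because published comparisons mix them: MSE improvements are
quoted against the Euclidean baseline, MAE improvements against the SWPD
value; the summary emits the customary pair and warns about the mixture.

The station-to-station distance matrix is computed once (one Dijkstra
sweep per station) and reused across hold-out folds; this is exactly
equivalent to re-running the predictor per fold and is tested against an
independently scripted hold-out loop.

## Synthetic scenarios

The generator emulates the study conditions of a dense urban monitoring
setting: a 30×30 km domain at 500 m (60×60 cells), 13 concentration
stations, 16 wind stations, and daily-mean wind speeds drawn from the
1.5–2.5 m/s band in which horizontal transport dominates and direction
measurements are reliable; direction is uniform on the circle.

- **Wind kinds**: `uniform`, solid-body `rotational`, linearly `sheared`
  (±45° across the domain), and `two_regime` (two directions 60° apart
  blended over a 3-cell seam) — archetypes of the small-scale structure
  urban fields exhibit.
- **Truth surfaces** are Gaussian-plume ribbons: for each source the
  domain is rotated into downwind/crosswind coordinates of the local flow
  and the ground-level plume kernel is evaluated (zero strictly upwind),
  summed over sources on a uniform background. The default single source
  sits in the central third with σ_y = 8 km, σ_z = 50 m, H = 0 and an
  emission rate giving an 80 µg/m³ centreline enhancement over a
  30 µg/m³ background. The 8 km crosswind spread represents a *daily
  averaged* plume — direction meander over the averaging day broadens the
  instantaneous width several-fold. Note the kernel has no downwind decay
  (σ's are fixed inputs, deposition is not modelled), so ribbons run to
  the domain edge; real urban footprints also decay along the transport
  axis.
- **Stations**: concentration stations are placed by best-candidate
  (Mitchell) sampling — monitoring networks are sited to cover their area,
  not scattered by chance — with optional additive Gaussian noise clipped
  at zero; wind stations sample the true field at random distinct cells.
  Every generator is a pure function of (parameters, seed).

What passing synthetic tests show — and what they do not: they verify the
pipeline's mechanics (exact interpolation, cost monotonicities, shortest
-path optimality, downwind dominance of estimates) on fields whose
anisotropy is generated by the very plume geometry the cost law is
motivated by. They do not show that the SWPD captures real urban fields,
which have multi-scale sources, chemistry, deposition and terrain effects
absent here.

## Observed behaviour of the method on synthetic data

Across seeded single-plume scenarios the SWPD variant beats the Euclidean
baseline on leave-one-out MSE in roughly 60–70 % of draws, with a median
MSE improvement under 1 % (the acceptance script reports the exact numbers
for its seed). The effect is real but small, and the cap explains why: on
an 8-neighbour lattice the SWPD can exceed the Euclidean distance by at
most √2, so IDW weights shift by at most a factor of 2 at p = 2 — a
modest re-weighting that competes with the octile lattice artefact
(≤8.24 %, direction-dependent) and with the fold-to-fold variance of a
13-station cross-validation. Published results on real data show larger
and more consistent gains; reproducing those would require either the
original (undeposited) observations or a finer-than-8-neighbour lattice
that lifts the √2 cap.

## Numerical conventions

- Directions: degrees clockwise from north; meteorological *from* on
  input, flow (*toward*) vectors internally; calm recomposes to (0, 0°).
- Angular deviation wraps at 360° into [0, 180].
- Rasters: ESRI ASCII grid, nodata −9999, north-up on disk.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); nothing reads global RNG state.
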