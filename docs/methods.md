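# Methods

This note documents the models implemented in `mint32`, the parameter
choices that matter, and what the tests do and do not demonstrate.

## The representation

A MINT32 coordinate is a signed 32-bit integer per axis. The mapping
`X_α = round(x_α S_α)` with `S_α = 2³²/L_α` is the unique scaling for
which one periodic box length equals one integer cycle; any other fixed
scale would need explicit wrapping logic and would forfeit the central
property that two's-complement overflow *is* the periodic boundary. Key
consequences, all exercised by tests:

* **Uniform resolution.** The grid spacing is `1/S_α = L_α/2³²`
  everywhere (≈9.3×10⁻⁹ Å in a 40 Å box), independent of position —
  unlike FP32, whose spacing grows by binade with coordinate magnitude.
* **Every bit pattern is a valid position.** There is no out-of-range
  state; encoding is a total function and out-of-box inputs wrap silently.
* **Exact minimum image.** `ΔX = X_i − X_j` reduced modulo 2³² into
  `[−2³¹, 2³¹−1]` equals the nearest-image displacement exactly, with no
  cancellation. We implement the reduction as arithmetic modulo 2³²
  rather than relying on hardware overflow (undefined behaviour in some
  languages); the result is bit-identical and portable.
* **Rounding.** Round-half-to-even everywhere a real is taken to the
  grid. The round-trip error is uniform on `±1/(2S)` with variance
  `1/(12S²)`, which the Monte Carlo statistics reproduce within 5%.
* **Box rescaling.** A volume change only replaces `S`; integer
  coordinates are untouched, so fractional positions are exactly
  invariant and repeated rescales are bit-reversible. (No barostat
  dynamics are implemented; the rescale operation is tested statically.)

Degenerate case: a separation of exactly half the box has two equally
valid images. The modular reduction yields −2³¹ deterministically; the
negation of −2³¹ is itself, which is the one documented exception to
antisymmetry of the integer delta.

### Conversion policies

Converting `ΔX` to a Cartesian float admits two paths: promotion to FP64
before scaling (`PROMOTE_FP64`, the numerically optimal route, default
here) and direct narrowing to FP32 with FP32 scaling (`DIRECT_FP32`,
the cheap route used by GPU production kernels). The direct path
re-quantizes large integer differences to the 24-bit significand (the
"staircase effect"); the gap between the two paths is bounded by 1.5 ulp
of the 32-bit result (three rounding stages at half an ulp each), and a
stratified sweep verifies it. This desk-scale package is not
arithmetic-cost-bound, so it defaults to the optimal path everywhere and
leaves the direct path selectable per backend for studying the staircase.

### Triclinic cells

For a general cell matrix `H` (lattice vectors in columns) the same
machinery runs on fractional coordinates `u = H⁻¹r ∈ [−1/2, 1/2)` with
`U = round(u·2³²)`; self-wrapping then acts along lattice directions.
The truncated octahedron (all lattice angles arccos(−1/3) ≈ 109.47°,
condition number exactly 2) is the worked nonorthorhombic case. The
per-component reconstruction-error bound

```
|err(Δr_i)| ≤ γ₂ Σ_j |H_ij||Δu_j| + Σ_j |H_ij| (η_j/2³² + |Δu_j|·u)
```

uses `u = 2⁻²⁴` (FP32 unit roundoff), `γ₂ = 2u` (the exact accumulation
constant is `2u/(1−2u)`; at this magnitude the difference is far below
the bound's slack, and `2u` is the documented choice), and `η_j` = the
worst-case INT32→FP32 conversion error, i.e. half the FP32 spacing at the
integer magnitude `|Δu_j|·2³²`. The worst-case `|Δu_j|` for a separation
at the nonbonded cutoff takes every component simultaneously at
`cutoff / w_j`, `w_j` the perpendicular width of the cell — deliberately
conservative so the bound remains an upper bound. For `a = 56.5` Å at an
8 Å cutoff the bound evaluates to 3.6×10⁻⁶ Å per component, and 10⁵
Monte Carlo pairs pushed through the actual FP32 evaluation path never
exceed it.

## Precision models

Two FP32 error conventions coexist on purpose, each tied to the analysis
it belongs to:

* the **spacing** (full ulp) at the box edge measures worst-case grid
  resolution and feeds the resolution table (edge at `x = L` for an
  uncentered box, `x = L/2` for a centered one);
* the **rounding error** (half ulp at the centered-box edge) is the
  worst-case representation error of a stored coordinate and feeds the
  PME alignment analysis.

For PME, a coordinate error `δx` becomes a fractional grid-position error
`δg = δx·K/L` and a fourth-order B-spline weight error `δW ≤ (2/3)δg`,
2/3 being the maximum derivative of the cardinal B-spline M₄ (located by
grid search plus golden-section refinement in the tests, not asserted).
For MINT32, `δx = L/2³³` gives `δg = K/2³³` — independent of the box.

## The NVE engine

Units: Å, fs, kcal/mol, amu, elementary charge;
k_B = 0.0019872041 kcal/(mol·K); Coulomb constant 332.0637 kcal·Å/(mol·e²).

The engine exists to measure one thing: how the coordinate representation
alone changes the total-energy drift of microcanonical dynamics. Design
choices follow from that goal.

* **Backends.** All pair displacements, position updates and constraint
  geometry go through a `CoordinateBackend`. `fp64` is the reference.
  `fp32_emulated` mirrors a single-precision-coordinate engine at the
  stages that matter for coordinate noise: positions are quantized to the
  FP32 grid after every integration step, and nonbonded displacements are
  formed in FP32 arithmetic with its cancellation behaviour; integration
  and bonded/constraint geometry use FP64 arithmetic on the (FP32-valued)
  master state, as mixed-precision engines do. The per-step storage
  narrowing is essential: it is the irreversible quantization that makes
  FP32 coordinates *inject* energy, whereas narrowing only a transient
  working copy leaves the force error a deterministic function of the
  FP64 state, whose apparent drift merely wanders without trend. `mint32`
  stores int32 and performs the drift as the integer update
  `X(t+δt) = X(t) + round(v·δt·S)`, whose modular wrap is the periodic
  boundary (this rounding is also irreversible, but on a grid roughly two
  orders of magnitude finer than the FP32 spacing at the benchmark box,
  hence ~10⁴× less injected power).
* **Velocities are 64-bit in every backend.** Velocity precision is not
  the variable under study; keeping it fixed isolates coordinate effects.
* **Forces.** O(N²) pair loop behind a Verlet candidate list
  (cutoff + 1 Å skin, re-selected when the exact accumulated per-step
  displacement bound reaches half the skin). Lennard-Jones is switched
  smoothly to zero over the last 1 Å before the cutoff and electrostatics
  use shifted-force Coulomb, because truncation discontinuities would
  inject drift orders of magnitude above the quantization signal being
  measured. Force accumulation is FP64 by default; an optional fixed-point
  accumulator (2²⁴ counts per kcal/mol/Å) makes summation exactly
  associative, hence bit-identical under pair reordering.
* **Constraint coupling.** After SHAKE, the constraint displacement is
  folded back into the half-step velocities; that difference is taken
  minimum-image, since a correction that pushes an atom across the
  periodic boundary is a tiny move, not a box-length one.
* **Drift metric.** Energies are recorded every 20 steps; the first 10%
  of the series is discarded as transient and an ordinary least-squares
  slope is converted to k_BT/ns per degree of freedom at 300 K, with
  DOF = 3N − n_constraints − 3 (center-of-mass momentum removed once at
  the start). The stability ratio of a run is |drift_ref|/|drift| against
  the FP64 reference (capped when the measured drift is zero).

### The drift benchmark

The backend comparison uses 125 rigid three-site waters in a 40 Å cubic
box at 300 K, δt = 1 fs, an 8 Å cutoff, 2 ps of discarded FP64
equilibration, and a 40 ps measurement window, with three seeds and
matched initial states (every backend starts from the identical
equilibrated configuration). The 40 Å box places coordinates where FP32
spacing is ≈2×10⁻⁶ Å — more than two decades above the MINT32 grid — so
the representations separate cleanly. The measurement window is set by
the estimator: over windows much shorter than ~40 ps the slowly varying
shadow-energy offset of the Verlet integrator produces apparent slopes of
a few 10⁻³ k_BT/ns/DOF that mask any drift below that level; at 40 ps the
FP64 and MINT32 drifts resolve to ~10⁻⁴ while the FP32 analogue sits near
10⁻².

What the benchmark shows is the *ordering and separation* of the three
representations under identical conditions. The absolute drift values are
not comparable to production-scale GPU numbers: those come from
10⁴–10⁵-atom PME systems integrated for 50–100 ns, while this is a
375-atom cutoff-electrostatics system measured for 40 ps.

## Constraints

SHAKE iterates Gauss–Seidel sweeps in ascending constraint order:
reference vectors from the previous step's positions, current distances
by the backend's exact minimum-image difference promoted to FP64,
Lagrange corrections in FP64, and each correction rounded back into the
coordinate representation (`ΔX_corr = rint(Δx_corr·S)` for MINT32) every
iteration. Convergence means `|r − d₀| ≤ tol` in Å for every constraint
(not the relative-squared convention some engines use); the sweep
terminates when no implied correction exceeds the tolerance and a direct
residual check confirms it. RATTLE projects relative velocities along
bond directions with tolerance `tol/δt`, dimensionally consistent with
the position tolerance.

Two numerically identical execution paths exist: a vectorised sweep over
greedily-coloured atom-disjoint constraint groups (pure numpy), and a
compiled sequential sweep (numba) used when available — constraints that
share no atom commute, so the two orderings converge to the same
tolerance. Rigid water is three coupled distance constraints (two O–H,
one H–H from the law of cosines); an analytic rigid-water solver is
deliberately out of scope.

The achievable tolerance is bounded below by the representation grid; a
tolerance under twice the grid spacing (e.g. 10⁻⁷ Å in a box larger than
~215 Å) triggers a configuration warning. At the benchmark box sizes the
grid is ~10⁻⁸ Å and the tightened 10⁻⁷ Å tolerance converges every step
of a 10⁴-step run with no failures.

## Synthetic systems

All inputs are generated, seeded and bit-reproducible.

* **Rigid water** uses a TIP3P-like parameter set (`tip3p-like-1`:
  q_O = −0.834 e, q_H = +0.417 e, O: ε = 0.1521 kcal/mol, σ = 3.1507 Å,
  O–H 0.9572 Å, H–O–H 104.52°); molecules are placed on a lattice with
  uniform random orientations, relaxed by a short constrained steepest
  descent, and given Maxwell–Boltzmann velocities that are
  RATTLE-projected, COM-cleaned and rescaled to the target temperature.
* **LJ fluid** is an argon-like lattice with ≤0.1 Å jitter.
* **Harmonic chain** is a bonded/angled chain placed at a configurable
  offset from the box center; at offset ≈ L/2 it probes bonded-term
  cancellation where FP32 coordinates are coarsest.

What the generators do *not* emulate: long-range (reciprocal-space)
electrostatics, real biomolecular topologies and force-field diversity,
liquid-state equilibration at production length, or system sizes beyond a
few hundred atoms. Passing the drift ordering here demonstrates the
coordinate-representation mechanism under controlled desk-scale
conditions; it does not by itself predict drift magnitudes for production
systems.

## Storage layout

In-memory positions are plain `(N, 3)` int32 arrays, and the binary
container stores three little-endian int32 words per atom after a header
recording the box lengths and the centered flag (bit-exact round trip).
GPU engines typically pad each position to a fourth word for 128-bit
aligned loads; that word has no numerical content and is omitted here.

## Known limitations

* Orthorhombic boxes only in the engine; triclinic support covers the
  representation and its error analysis, not dynamics.
* No reciprocal-space PME solver — only the charge-assignment error
  analysis; engine electrostatics are shifted-force with a cutoff.
* No thermostats or barostats (the box rescale is static), no
  hydrogen-mass repartitioning, no trajectory unwrapping bookkeeping.
* The drift estimator needs tens of picoseconds to resolve drifts below
  10⁻³ k_BT/ns/DOF; comparisons at shorter windows are noise-dominated.
* 64-bit coordinate modes are out of scope by design: for boxes under
  ~200 Å the 32-bit grid already resolves ≤5×10⁻⁸ Å.
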