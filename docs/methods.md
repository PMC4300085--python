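# Methods

This note documents the model, the numerical scheme, the simulated
protocol, the analysis conventions and the design decisions behind
`calwave`, in the package's own terms.  Nothing here states a result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Model

**Field.**  The cytosolic calcium concentration on a periodic 1-D
domain, nondimensionalized by the volume-average concentration
`[Ca²⁺]_ave` (so `C = [Ca²⁺]/[Ca²⁺]_ave`), obeys

    ∂C/∂t = D ∇²C + (1 + v_r)(γ₁ N_open + γ₀)(1 − C) − p C²/(C² + q²).

Luminal (ER) calcium is not a dynamical variable: eliminating it
through the fixed volume average produces the `(1 − C)` driving factor
on both the channel flux and the leak.  The SERCA pump is a Hill
function with coefficient 2, capacity `p = p̂/[Ca²⁺]_ave` and
threshold `q = q̂/[Ca²⁺]_ave`.  Exchange with the extracellular medium
is neglected.

**Gating.**  One IP₃R subunit carries three regulatory sites filled
strictly in order — IP₃, activating Ca²⁺, inhibitory Ca²⁺ — giving the
linear chain `X000 ⇌ X100 ⇌ X110 ⇌ X111` with mass-action rates
(`k₁[IP₃]`, `k₂[Ca²⁺]`, `k₃[Ca²⁺]` forward; `k₋₁`, `k₋₂`, `k₋₃`
backward).  Only `X110` is active.  A channel is four independent
subunits and conducts when at least three are active; a cluster is
`N = 64` channels sharing the calcium concentration of one grid cell.
The stationary subunit law is the detailed-balance solution of the
chain, and the stationary channel open probability
`P_a⁴ + 4 P_a³(1 − P_a)` is bell-shaped in calcium: activation
(`k₂ = 30 (µM s)⁻¹`) dominates at low concentration, inhibition
(`k₃ = 3.6 (µM s)⁻¹`, unbinding `k₋₃ = 0.064 s⁻¹`) at high.  The
concentration maximizing it — the *ignition point*, ≈ 0.04 µM for the
default constants — is where a release site is most excitable, and the
slow inhibitory unbinding (≈ 16 s) is the longest timescale in the
model; both control the protocol choices below.

### Parameters

| name | meaning | default | units |
| --- | --- | --- | --- |
| `D` | calcium diffusion constant | 25 | µm²/s |
| `v_r` | ER/cytosol volume ratio | 0.185 | – |
| `γ₀` | basal ER leak | 0.02 | s⁻¹ |
| `γ₁` | flux per open channel | 9.0 | s⁻¹ |
| `p̂` | pump capacity (swept) | 1.6, range [1.2, 3.0] | µM/s |
| `q̂` | pump threshold | 0.01 | µM |
| `[Ca²⁺]_ave` | average concentration | 1.6 | µM |
| `[IP₃]` | IP₃ concentration | 0.5 | µM |
| `k₁, k₋₁` | IP₃ on/off | 24.0, 32.0 | (µM s)⁻¹, s⁻¹ |
| `k₂, k₋₂` | activating Ca on/off | 30.0, 0.82 | (µM s)⁻¹, s⁻¹ |
| `k₃, k₋₃` | inhibitory Ca on/off | 3.6, 0.064 | (µM s)⁻¹, s⁻¹ |
| `d` | intercluster distance (swept) | 2.5, range [1.6, 3.7] | µm |

With these values the closed-channel resting state is
C\* ≈ 9.7 × 10⁻⁴ (≈ 1.6 nM free calcium): the pump's low threshold
clamps the quiescent cytosol far below the event-detection level.

## Numerics

* **Field update**: forward Euler with the 3-point periodic Laplacian,
  Δx = 0.18 µm, Δt = 0.5 ms, 640 cells (domain 115.2 µm).  The
  diffusive stability number `D Δt/Δx² = 0.386 < 1/2` is asserted at
  construction.  Negative or non-finite concentrations abort the run —
  no silent clamping, because clamping would mask an unstable scheme.
* **Gating update**: per subunit and step, transition probabilities are
  linearized as `rate · Δt` (error O((rate Δt)²); the largest total
  rate over the physiological range gives total exit probability
  < 0.05) and resolved by a single categorical draw, which avoids
  ordering bias between the two exits of `X100` and `X110`.  A total
  exit probability ≥ 1 raises an error telling the user to reduce Δt.
* **Coupling order** per step: read `C` at cluster cells → advance all
  subunits → count open channels per cluster → advance the field with
  the channel flux deposited into each cluster's single cell.  A
  cluster occupies one cell: cluster spacing (≥ 1.6 µm) is an order of
  magnitude above Δx, and depositing the flux over a wider footprint
  changes front speeds by < 5% (diffusion equilibrates the footprint
  within milliseconds).
* **Determinism**: one seeded `numpy` generator per run; subunit draws
  are consumed in a fixed (cluster, channel, subunit) order, so runs
  are bit-reproducible given the seed.  Equal seeds give bit-identical
  kymographs.
* **Fixed points**: the basal state C\* is obtained by bracketed root
  finding (Brent) of the closed-channel balance on (0, 1).

## Protocol

A standard run lasts 5 s (10 000 steps).  Every 75 steps a row of the
8-bit kymograph is written (0.0375 s/row — chosen so that the
pixel-calibration constants of the velocity formula are exact), with
intensity 255 mapped to `record_max = 2·[Ca²⁺]_ave = 3.2 µM; the
0.3 µM analysis threshold then falls at intensity 24 with a
quantization bin of ≈ 0.0126 µM.

**Trigger.**  The run is seeded with a focal stimulus at the domain
center: the field is clamped at 0.5 µM over ± 0.5 µm for 0.25 s.  The
hold is essential: the receptor responds to a *sustained* rise (IP₃
binding then Ca²⁺ activation take ~0.1 s at 0.5 µM), whereas an
instantaneous bump of that size diffuses away within ~10 ms and ignites
nothing.  0.25 s sits between the activation timescale
(`1/(k₂ · 0.5 µM) ≈ 0.07 s`) and the inhibition timescale
(`1/(k₃ · 0.5 µM) ≈ 0.6 s`).  Multiple triggers can be configured
(e.g. two, to observe fronts annihilating on collision).

**Initial receptor states.**  The default (`init="primed"`) emulates
desynchronized release sites: each cluster independently starts either
*primed* — subunits drawn from the stationary law at the ignition point
(probability 0.5) — or *resting* (stationary law at basal).  Primed
clusters fire a puff within the first couple of seconds as their
activated subunits play out; resting clusters relay waves.  This
choice, rather than an equilibrium start, is what produces the observed
phenomenology of linescan records: discrete puffs on a dark background,
abortive and propagating waves coexisting, event merging at small
`d`/weak pump, and only sparse isolated events at the far
(large-d, strong-pump) corner.  Alternatives are available in the
configuration: `x000` (all subunits empty — a quiescent run in which
only the triggered wave appears), `stationary` (equilibrium at basal —
nearly identical to `x000` in practice) and `active` (every cluster at
the ignition point — a synchronized burst that floods the first second
of the record).  The quiescent state is *not* spontaneously active on
5-s timescales: at 1.6 nM the stationary open probability is ~10⁻⁵ per
channel, and the self-sustained flickering regime decays within ~10 s
everywhere except the smallest-d/weakest-pump corner, so a 5-s record
is a transient of its initial condition by construction.

**Layout.**  `floor(L/d)` clusters at a uniform spacing of
`round(d/Δx)` cells, centered on the domain; the realized spacing
(within Δx/2 of the request) is recorded with every run.  The nominal
domain of 113 µm at 640 pixels is internally inconsistent
(640 × 0.18 µm = 115.2 µm); the grid takes 640 cells and L = 115.2 µm.

## Analysis

* **Segmentation**: threshold the calibrated image at 0.3 µM; label
  space–time connected components with 8-connectivity (a front that
  advances one column over several rows stays one event); merge
  components across the periodic seam before measuring (extent of a
  wrapped event is its circular span).  Events touching the first or
  last row are flagged censored — their durations are lower bounds —
  and events touching row 0 began before the record.
* **Measures**: duration = row span × 0.0375 s; extent = column span ×
  0.18 µm; Ca_T = mean 8-bit intensity × pixel area, in arbitrary
  units, matching image-analysis practice (a calibrated µM·px variant
  is exported alongside).
* **Classification**: spatial — puff < 5 µm, abortive 5–25 µm
  (boundaries inclusive), propagating > 25 µm; Ca_T — puff < 200 a.u.,
  abortive 200–1800 a.u. (inclusive), propagating > 1800 a.u.
* **Phase metrics**: `d_max` is the distance with the highest total
  wave count (abortive + propagating) at fixed pump strength, ties
  toward smaller d; the propagating/abortive *frontier* is the linear
  interpolation zero of `n_w − n_aw` against d at each pump strength,
  with multiple crossings flagged and the smallest reported.

## Wave velocities

The front angle replaces the manual protractor step of linescan
analysis with a reproducible fit.  For a propagating event the
*first-passage profile* — the earliest above-threshold row in each
column — is walked outward from the initiation point (centroid of the
event's first row).  The running maximum of the profile traces the
advancing front and steps across pockets that fired before the front
arrived; the walk ends when the front stalls for 40 columns or at a
sub-threshold gap wider than 5 columns.  The quarter of columns nearest
the apex (where the profile is flat) is trimmed, each side is fit by
least squares, and the per-side angles `α = arctan |Δrow/Δcol|` are
averaged.  Velocity is `v_w = Δx_pixel/(tan α · Δt_row)` with both
constants taken from the kymograph calibration, never hard-coded.
Quality control: events must span ≥ 5 rows and yield a segment of
≥ 8 columns; a mean side-fit R² below 0.9 excludes the event from
velocity averages.  On planted synthetic fronts of known slope the
estimator recovers the speed to well within 5%.

Velocities are computed for propagating-class events only.  Conditions
enter the Luther fit through the mean over their pooled event estimates
(across seeds), with at least 3 usable estimates required per condition
(a configuration knob).  The Luther analysis fits
`v_w²(d, p) = β₀ + β_d d + β_p p` by ordinary least squares — one point
per condition — and converts to the apparent first-order autocatalytic
rate constant `k(d, p) = v_w²/(a² D)` with `a = 1`.  The fit requires
≥ 4 conditions spanning ≥ 2 distinct values of each of d and p and
rejects rank-deficient designs.

Fronts in this model propagate saltatorily (cluster-to-cluster
ignition) at steady speeds of roughly 7–17 µm/s over the studied
region, fastest at small intercluster distance and weak pump and
decreasing in both parameters — the Spearman correlation with pump
strength is significantly negative on the default sweep, while the
distance trend, monotone within every pump stratum, is confounded in
pooled ranks because waves only propagate in a triangular region of the
(d, p) plane.

## Problem sizes

The package's standard sweeps are sized for single-CPU work: the
acceptance script and the sweep-level tests use a 4 × 4 (d, p̂) grid
with 5 seeds and 5-s runs (80 simulations, a few minutes), and the
phase-structure tests a 4 × 3 grid with 3 seeds.  Denser grids
(e.g. 8 × 10) reproduce the same analyses unchanged.

## Known limitations

* One-dimensional geometry only; no 2-D/3-D wave curvature effects.
* Luminal calcium is fixed: pump strength does not feed back on ER
  load, so phenomena driven by store refilling are out of scope.
* No cytosolic buffers and no IP₃ dynamics; IP₃ is a constant
  parameter.
* Within a cluster all channels share one grid cell; there is no
  intra-cluster spatial structure and no inter-subunit cooperativity.
* The 5-s records are transients of the configured initial condition
  (see Protocol); statistics such as event counts per condition depend
  on the primed fraction, which is a declared protocol parameter, not
  a fitted one.
* Puffs outnumber waves by roughly 3–8× on the default sweep; because
  multi-cluster chains are classified as abortive waves, puff and wave
  counts rise together and the ratio is insensitive to the priming
  fraction.
* The synthetic fixtures (rectangles and constant-slope fronts) give
  exact ground truth for the segmentation and velocity estimators, but
  they do not emulate photon noise, optical blur or drifting baselines
  of real linescan data — passing those tests validates the estimator
  mathematics, not robustness to microscope artifacts.
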