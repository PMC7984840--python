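# Methods

`segclock` simulates the zebrafish segmentation clock as a population of
noisy phase oscillators carried by mechanically interacting cells in a
three-dimensional, U-shaped presomitic mesoderm (PSM) and tailbud, and
provides the measurement machinery used to score the resulting segment
boundaries.  This note records the model, its assumptions, the default
parameters and why they take the values they do, what the synthetic-data
generators emulate, and the numerical choices that matter.

## Tissue geometry

The PSM is two straight tubes of radius `r0` (default 25 μm, half the
~50 μm PSM diameter) whose axes run along the anterior–posterior (x) axis,
joined posteriorly by a half torus (the tailbud) of core radius `R`
(default 50 μm, so the left–right axis separation is 2R).  The posterior
tip is fixed at `x = Lx` (the tailbud frame: all motion is expressed
relative to the tailbud, so axis elongation appears as anterior-directed
advection of cells).  The anterior PSM end `xa(t)` starts at 0 and, in
shortening protocols, moves posteriorly at speed `ua`; the PSM length is
`L(t) = Lx − xa(t)`, default `L0 = 400 μm`, at the upper end of lengths
reported for early-somitogenesis zebrafish (see *Calibration* below for
why this default, rather than a mid-range value, is used).  The tissue
occupies `y ∈ [0, 2R + 2 r0]`, `z ∈ [0, 2 r0]`; the left tube axis is at
`(y, z) = (r0, r0)` and the right at `(2R + r0, r0)`.

Cells are confined by frictionless exponential wall forces: each
transverse component has magnitude `μb · exp(−δ/rb)` with `μb = 20 μm/min`
and decay length `rb = 1 μm`, where δ is the projected distance to the
wall (δ = |cos q| (r − ρ) and analogues; this is the half-toroid form
applied consistently to the tubes, which keeps the force positive-definite
on both sides of the axis).  The force on a cell at the wall is exactly
`μb`; twenty decay lengths inside it is numerically zero.

## Cell mechanics

Each cell i obeys the overdamped equation of motion

    dx_i/dt = v_d(x_i) + v0(x_i) n_i + Σ_j F(x_i, x_j) + F_b(x_i).

**Advection** `v_d = (−v(χ), 0, 0)`, `χ = (x − xa)/L`, is piecewise linear
with a knot at `χ = xq`: `v(0) = va` at the anterior end and `v(1) = 0` at
the tailbud tip.  The segment length is `S = va · Ta` (one segment of
advected pattern per anterior period), so `va = 55/30 μm/min` makes
`S = 55 μm = 5` cell diameters.  The strain rate `|∂v/∂x|` is uniform
within each of the two subdomains.

**Intrinsic motility** follows the posterior-high mobility gradient
`v0 = vs / (1 + ((1 − x̄/L)/Xv)^h)` with defaults `vs = 2 μm/min`,
`Xv = 0.4`, `h = 3`: near-zero anteriorly, saturating at `vs` in the
tailbud, reproducing the observed cell-mixing gradient qualitatively.

**Polarity** n_i performs an isotropic random walk on the unit sphere with
intensity `Dφ = 0.1 /min`, integrated by a Gaussian kick of size
`sqrt(2 Dφ dt)` in the tangent plane followed by renormalization.  The
equivalent Itô angle equations carry a `Dφ cot φ` drift; integrating those
angles directly with Euler–Maruyama at dt = 0.01 min is unstable near the
coordinate poles and measurably biases the stationary distribution, while
the tangent-plane scheme keeps it uniform on the sphere (verified by a
Kolmogorov–Smirnov test on cos φ).

**Contact repulsion** is linear elastic with cutoff `dc = 11 μm` (the cell
diameter) and coefficient `μ = 8.71 μm/min`; exactly coincident cells
(possible at insertion) are separated along a fixed, seeded unit vector.

## Phase dynamics

Each cell carries a phase θ_i:

    dθ_i/dt = ω(x_i) + (κ(t)/n_i) Σ_{|x_j−x_i| ≤ dc} sin(θ_j − θ_i)
              + sqrt(2 Dθ) ξ_i(t).

The frequency profile is `ω = ω0 [σ + (1 − σ)(1 − e^{−kχ})/(1 − e^{−k})]`
with `ω0 = 0.2094 rad/min` (30-min posterior period), `σ = 0.7`, `k = 3`
(profile-shape defaults chosen to give the documented concave,
posterior-high profile; the exact published values are not available).
Because cells advect anteriorly while the tailbud acts as the pacemaker,
the tissue frequency-locks at ω0 everywhere and kinematic waves travel
posterior→anterior; the pattern arrested at `x < xa` (phases frozen,
cells advected out at `va`) has stripe spacing `va · Ta`.

Coupling is zero before the washout time and `κs t + κ0` afterwards
(`κ0 = 0.07 /min`; the ramp slope in the combined-development preset,
`κs = κ0/450 min⁻²`, doubles the coupling by ~15 somite stages).  Phase
noise `Dθ = 0.0013 /min` makes the local order of an uncoupled,
synchronized population decay as `e^{−Dθ t}`, crossing the boundary
threshold `Zc = 0.85` between the fourth and fifth segment windows — the
anterior limit of defects of ~5 observed under saturated Notch inhibition.

## Tissue programs

* **Shortening**: `xa = ua t`, with `va + ua = c` so the segment length
  `S = c · Ta` is invariant across shortening speeds.  Because waves then
  travel toward an approaching boundary, the anterior readout period is
  Doppler-shortened; `engine.calibrate_omega0` retunes ω0 by a secant
  iteration on short deterministic probe runs until the measured anterior
  period is `Ta = 30 min` (1% tolerance).
* **Radius change**: `r(t) = r0 − sr t`, floored at `2 dc`; cells stranded
  outside a narrowing wall are pulled back to `ρ = r − 2 rb`.
* **Cell flux**: every cell that crosses `xa` is a removal event.  The
  engine then measures the density of left tube, right tube and tailbud
  (active-cell count over the analytic region volume — no binning noise)
  and, if any region is below the target `ϱ0 = 0.0015 cells/μm³` (998
  cells per 110×110×55 μm³), inserts one cell uniformly at random into the
  most-depleted region — ties broken left → right → tailbud — with random
  phase, random polarity, and never within `ζ = 100 μm` of the anterior
  end.  Arrested cells are retained for 150 min (the visible stripe
  pattern) and then dropped.

## Calibration of the advection defaults

Three printed observations pin down the advection pattern and PSM length
used as defaults, none of which are published as numbers:

1. the density stays ≈ ϱ0 throughout the tissue (no large density
   fluctuations from the velocity-field gradient);
2. with phase noise off, cell addition alone leaves the first five
   arrested stripes intact before the pattern degrades;
3. ALD ≈ 5 corresponds to `Dθ = 0.0013` through the `e^{−Dθ t}` decay.

An anterior-dominated strain profile violates all three: it depletes the
anterior tube by ~40%, routes density-triggered insertions into the
mid-tube (their random phases reach the anterior scoring slab within
~50 min, destroying stripes 2–3), and makes cell-addition noise dominate
the ALD.  Placing the knot at the tube–tailbud junction
(`xq = Xc/Lx = 0.8125`) with `vp = va/(1 − xq)` instead makes the tubes a
uniform conveyor at `va`: measured density stays within 0.94–1.06 ϱ0,
~90% of insertions land in the tailbud, and the random-phase material must
transit the full PSM (~180 min at `L0 = 400 μm`) before reaching the
anterior — leaving exactly five intact stripes in noise-free
desynchronization runs.  The advection-switch protocols use
`vp_early = 0.3 va` (anterior-dominated strain before `tg = 270 min`,
i.e. 9 somite stages) and the junction value afterwards.

## Boundary scoring

Local phase order is measured in thin axial slices of width `Δx = dc`
(the mean resultant length `Z_m` and mean phase `Ψ_m` of the slice
phasors; phasor averaging, because arithmetic phase means are ill-defined
across the 0/2π cut), then averaged over `M = 5` consecutive slices —
high even across a wave gradient, low in disorder.  Boundary-setting
times τ_i are upward crossings of the temporally unwrapped anterior mean
phase `Ψ1(t, xa)` through `ϑ = 3π/2` (linearly interpolated; crossings
closer than Ta/2 are merged to suppress noise doubles).  A boundary is
*normal* iff `Z(t, xa) ≥ Zc = 0.85` at every sample in the window
`[τ − Ta/2, τ − Ta/2 + η]`, `η = 4 min`.  Normal boundaries are numbered
by chaining (previous normal j → j+1) or by `round(τ/Ta)` with an early
tolerance `Δ = 0.3`; every unclaimed index is defective.  From the labeled
record: ALD (first defective index), FRS (`jf − 1`, `jf` the first normal
index; an experimental-convention variant takes the first normal after
boundary 9), PLD (last defective index), defect-run lengths within
(FRS, PLD], and left–right single/double defect counts `(Ns, Nt, Fs)`
over loci posterior to segment 9.  Under left–right independence with
per-side defect probability p, `Fs = 2(1−p)/(2−p)`.

## Phase vorticity

Vortices are detected on four 20-μm slice projections per side (two z
slabs → x–y planes, two y slabs → x–z planes) on a grid of spacing
`Δx = 5 μm` axially and 2 μm transversely.  Around each grid point a ring
`5.5 ≤ d < 19.5 μm` is cut into six 60° sectors; the sector phasor means,
cyclically permuted to start at the smallest (ascending for one
handedness, descending for the other), are Pearson-correlated against
i = 0..5 (index mean 5/2, variance 35/12).  If the correlation exceeds α
and the winding `(θ̂5 − θ̂0)/2π` is at least `ψ_min`, the winding is the
vorticity; otherwise 0, and any empty sector gives 0.  The published α and
minimum-winding values are not recoverable, so both are calibration
constants: `α = 0.98`, `ψ_min = 0.75` detect every planted ideal vortex
core while triggering on < 0.2% of ring evaluations in fully random fields
(and never on uniform or pure-gradient fields).  A linear gradient with
the segment wavelength spans only ~2.4 rad across the ring, well under
`2π ψ_min` — the guard exists precisely for this case.

## Integration and reproducibility

Euler–Maruyama with `dt = 0.01 min`.  Production runs use a numba kernel
that mirrors the numpy reference implementations term by term (an
integration test holds the two within 1e-9 over a block of steps); the
kernel keeps a Verlet neighbor list with a 0.2 dc skin rebuilt every five
steps from a counting-sorted cell grid — the exact `d ≤ dc` cutoff is
applied every step, so the list is an optimization, not an approximation.
Arrest of cells crossing `xa` happens inside the step it occurs; removal
and insertion events are processed at 0.5-min block boundaries (≤ 6
deferred events at default flux; density stays well within the 5%
invariant).  Within each step all increments are evaluated from the state
at time t and applied simultaneously.

One `SeedSequence` per run spawns fixed substreams (initialization, phase
noise, polarity noise, insertion), so disabling one noise channel never
shifts another's draws; identical seed and configuration give bit-identical
trajectories on a given platform.  Initialization places
`round(ϱ0 × volume)` cells uniformly (region chosen by volume), relaxes
contact stresses for 10 min without advection and with a temporary wall at
`x = xa`, then assigns phases (3π/2 everywhere, or i.i.d. uniform) and
polarity angles.

## Synthetic data and desk-scale ensembles

The fixtures module plants phase fields (uniform, axial gradient, random,
ideal ±1 vortices about y or z) on uniform point clouds at tissue density,
and generates paired Bernoulli segment records.  These are oracles for the
observables: planted winding numbers are recovered exactly by a
brute-force loop integral, and the toy records reproduce the closed-form
single-defect fraction.  They emulate the *patterns* the simulator
produces, not its dynamics — passing detector tests on planted fields
shows the measurement machinery is correct, not that the tissue model
generates such patterns.

Ensemble experiments (resynchronization statistics and their dependence on
tissue parameters) run at a reduced desk scale chosen so that one
condition costs minutes, not hours: `r0 = 22 μm`, `L0 = 260 μm`,
junction-aligned advection, 5 seeds × 2 independently scored sides per
condition (left and right sides are scored separately, as in embryos).
The radius cannot be reduced much further: the vortex ring detector spans
39 μm and persistent tailbud vortices — the mechanism behind several
parameter dependences — need the tube to accommodate them.  Deterministic
anchors (posterior period, stripe spacing) run at the full default
geometry.

The mixing default `vs = 2 μm/min` is itself an anchor-driven choice: at
`vs = 1` the insertion-fed tailbud pool occasionally nucleates a
persistent phase defect that survives transit and produces a defective
boundary even in untreated controls, which the modeled system never
shows; doubling the tailbud mixing — the model's own vortex-suppression
mechanism — makes 400-min controls defect-free without affecting the
period, segment length, or desynchronization anchors.

At desk scale the PLD-vs-PSM-length dependence is non-monotonic: near
the baseline, a longer PSM raises PLD (vortices need longer to reach the
anterior), but beyond L ≈ 370 μm the extra re-entrainment time for
insertion-derived disorder wins and PLD falls again.  The length
comparison in the acceptance suite therefore uses a moderate shift
(260 → 330 μm) on the rising branch, matching the single-parameter
shifts it emulates.

## Known limitations

* Coupling delays are omitted (as in the modeled system description).
* The strict all-samples-≥-Zc classifier makes desynchronization ALD
  sensitive to single inserted cells transiting the anterior slab; visual
  stripe recognizability is more tolerant.  See the ALD discussion above.
* At desk scale, slowing the posterior advection reroutes insertions from
  the tailbud into the tubes (the segment-length constraint fixes `va`, so
  slower posterior transport necessarily adds tube strain); the extra
  protection of the tailbud pool then outweighs the longer vortex
  residence, and the posterior limit of defects *decreases* where the
  full-scale model is reported to show an increase.
* Segment length is constant; dorsal tissue flows and convergent extension
  are abstracted into the advection field; there is no explicit gene
  network, cell division, or adhesion.
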