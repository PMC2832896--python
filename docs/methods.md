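# Methods

## The model

`nlhvdm` implements nonlinear hidden-variable dynamic modelling (HVDM) of
transcription: a transcription factor's activity p(t) is treated as an
unobserved time course and inferred jointly with kinetic parameters from the
expression time series of its target genes.  Each target gene i follows the
delay ODE

    dx_i/dt = c_i + k_i * f_i( p(t − τ_i) ) − d_i * x_i(t)

with basal transcription rate c_i (expression-units/h), maximal TF-driven
rate k_i, degradation rate d_i (1/h) and regulatory delay τ_i (h).  The
cis-regulatory function composes a per-site Hill occupancy with a direction
switch:

    g(p) = [ p^n / (K_i^n + p^n) ]^m
    f_i  = δ_i g + (1 − δ_i)(1 − g),       δ_i ∈ {0, 1}

so an activator (δ=1) transmits the occupancy and an inhibitor (δ=0) its
complement, and f(g,1) + f(g,0) = 1.  At m = n = 1 the occupancy reduces to
the Michaelis–Menten form; n > 1 models cooperative binding (default n = 4,
appropriate for a tetramer-binding factor such as p53; m is the number of
binding sites, default 1).  Multi-site composition uses [g_site]^m (per-site
saturation) rather than a single Hill with exponent n·m; both reduce to the
same limits.

Activity is represented by values at the measurement times joined by a
natural cubic spline (zero second derivative at the end knots), clipped into
the unit box [0, 1] and clamped to the boundary knots outside the measured
range.  The delayed activity obeys the convention p(t − τ) = 0 for t ≤ τ:
before the stimulus has had time to propagate, the gene sees no TF.

## Inference

**Hidden-activity fit.**  For N training genes measured at M time points the
unknowns are the N×4 kinetic rates plus the M−1 post-stimulus activity knots
(activity at t = 0 is pinned at the pre-stimulus baseline, 0 by default):
4N + (M−1) free parameters, 26 for the canonical N = 5, M = 7 design.
Training fits take τ = 0.  The objective is the summed per-gene relative
squared error over the post-initial measurement times,

    ε_i = Σ_j (u_ij − x_ij)² / Σ_j x_ij²,       E = Σ_i ε_i,

with u the simulated and x the measured levels; normalising by the measured
signal keeps genes of different magnitude comparable.  Search boxes are
[0, 5] for c, k, K (K floored at 10⁻³ to stay positive), [0, 2] for d, and
[0, 1] for each activity knot.

**Optimiser.**  A real-coded genetic algorithm: population 100, 200
generations, tournament selection (size 3), BLX-α blend crossover (α = 0.5,
probability 0.9), per-coordinate Gaussian mutation (σ = 5 % of the box width,
rate 0.1), single-individual elitism, clamp-to-bounds repair.  Each restart's
best individual is then polished with bounded trust-region least squares on
the residual vector (whose sum of squares equals the objective).  The polish
matters: kinetic fits live in long, shallow "sloppy" valleys where a
finite-difference quasi-Newton step stalls on gradient noise, while the
Gauss–Newton geometry of a least-squares solver follows the valley floor —
on noise-free data it routinely improves the objective from ~10⁻⁵ to ~10⁻¹²
and tightens kinetic estimates from ~30 % to ~3 %.  Ten independent restarts
(sub-seed = master seed + run index) guard against distant local optima; the
smallest-objective run is reported and the 2.5/97.5 percentile band across
runs (optionally across replicates) quantifies run-to-run spread.

**Identifiability gauge.**  The Hill term depends on activity only through
p/K, so the joint fit determines (p(t), K_i) only up to a common positive
scale within the unit activity box.  Estimates are canonicalised to unit peak
activity — knots divided by their maximum, every K_i divided by the same
factor — which leaves the objective exactly unchanged.  All reported
activities and half-saturations are in this gauge; the synthetic generator's
activity shapes peak at 1 so that recovery is measured in the same gauge.

**Per-gene screening.**  With the activity profile fixed, each candidate gene
is fitted over (c, k, K, d, η[, τ]); the continuous surrogate η ∈ [−1, 1]
selects the regulation direction (η > 0 → δ = 1), keeping a single real-coded
genome.  Each restart runs twice — τ locked at 0, and τ free in [0, 2.5] h —
and the overall smallest error wins; `used_delay` records a strict
improvement by the delayed variant.  Fits use the spline-expanded grid
(3 equidistant insertions per interval, 7 → 25 points) to stabilise the delay
estimate, with a smaller GA budget (population 40, 60 generations) since the
problem has only 5–6 dimensions and the polish does the final refinement.

A numerically consequential detail: the expanded-grid objective compares
model and data **through the same observation operator** — both are sampled
at the 7 measurement times and lifted onto the 25-point grid with the same
natural spline.  Comparing the raw ODE trajectory to the interpolated data
instead lets the spline's non-causal anticipation of a delayed rise bias the
delay estimate low by about half a grid spacing (0.5 h); with the symmetric
operator, noise-free delays are recovered essentially exactly.

Screening utilities mirror standard practice: Pearson-correlation sign
calling between expression and activity on the measurement grid (zero below
a configurable |r| threshold), two-way consensus counts (model vs
correlation), collapsing multi-probe genes to the smallest-error probe
(lexicographic tie-break), a small-k filter (default k_min = 0.05, 1 % of the
k box — genes the TF barely drives carry no direction information), an
optional no-motif filter, and top-fraction selection by error rank.

## Simulation and sensitivity

Trajectories are integrated with classic fixed-step 4th-order Runge–Kutta,
default step 0.05 h (240 steps over 12 h) — the discretisation error is far
below measurement noise and halves ~16× per step halving.  Because the ODE
right-hand side is affine in the state, the population-wide objective
evaluations precompute the forcing A(t) = c + k·f on the RK4 node grid and
collapse the step recursion x_{j+1} = βx_j + γ_j into a cumulative sum; a
plain stepping fallback covers the stiff/underflow regime.  The scalar
reference integrator (`simulate_gene`) keeps the classic four-stage loop and
the two paths are cross-checked in the tests.

Two sensitivity views are provided.  The perturbation **error ratio**
re-simulates with one rate scaled by a factor (±10 % by convention) and
reports |x̃(T) − data(T)| / |x(T) − data(T)| at a horizon T.  The **adjacent
model** integrates dE_p/dt = −d·E_p + ∂F/∂p with E_p(0) = 0 jointly with the
base trajectory (analytic partials: ∂F/∂c = 1, ∂F/∂k = f,
∂F/∂K = k(2δ−1)∂g^m/∂K, ∂F/∂d = −x), giving the first-order drift of the
solution per unit parameter perturbation; it is validated against central
finite differences to 10⁻³ relative.

## Motif scanning

The consensus scanner counts stride-1 (overlapping) perfect matches of a
degenerate IUPAC pattern, by default the 10-bp p53 consensus RRRCWWGYYY, on
upstream windows.  Sequences run 5'→3' and end at the TSS (last base =
TSS−1, half-open window), so the 5 kb window is the TSS-proximal half of a
10 kb sequence.  Scanning is forward-strand only: this pattern equals its own
reverse complement as a degenerate motif, so forward counting already equals
both-strand site counting (property-tested).  N never matches.  Counts are
binned 0 / 1 / 2 / >2 per window, with per-category fractions tabulated.
Under a uniform base model the per-position match probability is
(1/2)³·(1/4)·(1/2)²·(1/4)·(1/2)³ = 1/4096, ≈ 2.44 expected sites per 10 kb —
used as a sanity band in the tests.

## Preprocessing

Each array (time × replicate column) is median-centred; probes are
transformed to z-scores (population SD) across all arrays, dropping
zero-variance probes; responsiveness is scored by a pairwise Fisher linear
discriminant against the pre-stimulus baseline, max over post-baseline time
points of (mean_t − mean_0)²/(var_t + var_0) with sample variances across
replicates (an all-pairs variant is available behind a flag); the top
ceil(fraction·n) probes (fraction 0.15 by default) are kept, ties broken by
probe id.  Raw chip-level quality filtering is out of scope; inputs are
assumed pre-filtered.

## Synthetic data

The generator emulates the targeted experimental design: 7 time points
(0–12 h, 2 h spacing), 3 replicates, additive i.i.d. Gaussian noise
(default σ = 0.1 in the expression units of the panel).  Activity shapes —
pulse (single induction bump), ramp, biphasic — start at 0 (pre-stimulus)
and peak at 1, with optional seeded jitter at interior knots.  Kinetics are
drawn uniformly inside the search boxes: c ∈ [0, 5], k ∈ [0, 5],
K ∈ [0.1, 5], d ∈ [0.05, 2] (degradation below ~0.05/h is indistinguishable
from none over 12 h and makes the pre-stimulus steady state diverge);
delays come from {0, 1, 2} h and the inhibited fraction is allocated
exactly.  The initial level is the pre-stimulus steady state
(c + k(1−δ))/d.

For parameter-recovery experiments a **well-conditioned** sub-box is
documented separately: k ≥ 0.5 (the TF must matter), d ≥ 0.2 (turnover
visible within the course) and K ≤ 1 (half-saturation within the observed
activity range).  With n = 4 and unit-peak activity, a gene with K well
above the peak never leaves the occupancy floor ((p/K)⁴ < 0.06 for K ≥ 2):
its kinetics — and its regulation sign — are structurally unidentifiable, so
recovery benchmarks on full-box draws measure the draw distribution, not the
estimator.  On full-box panels the regulation-sign accuracy drops to ~75 %,
with essentially every miss at K ≳ 2.4; this is a limitation of what the
data can carry, mirrored in real screens by responsiveness filtering and the
small-k exclusion.

What the generator does **not** emulate: probe-level cross-hybridisation,
array spatial artefacts, heteroscedastic or correlated noise, missing
values, and mRNA-vs-protein discrepancies beyond the hidden-activity
abstraction itself.  Passing recovery tests therefore demonstrates the
estimator's correctness and conditioning under the stated design, not
performance on any particular laboratory dataset.

## Numerical choices and defaults

| parameter | default | meaning / rationale |
|---|---|---|
| n (Hill) | 4 | tetrameric TF binding |
| m (sites) | 1 | single effective site unless known otherwise |
| W_MAX (c,k,K,d) | (5,5,5,2) | search-box widths in expression units/h, 1/h |
| τ_max | 2.5 h | experimentally motivated delay cap |
| RK4 step | 0.05 h | error ≪ noise; configurable |
| grid insertions | 3 | 7 → 25 points; delay resolution 0.5 h |
| restarts | 10 | best-of-restarts, percentile band across runs |
| top fraction | 0.15 | responsiveness screen |
| k_min | 0.05 | small-k exclusion (1 % of the k box) |
| GA (joint fit) | pop 100 × 200 gen | 26-dimensional search |
| GA (per gene) | pop 40 × 60 gen | 5–6 dimensional search |

Tie-breaks are deterministic (lexicographic probe id).  Degenerate inputs
warn rather than fail where a value is still defined (constant probes,
single-run confidence bands) and raise typed errors where it is not
(all-zero reference in a relative error, exact fit at the error-ratio
horizon, K ≤ 0).

Recovery experiments in the tests and the acceptance script use 5-gene
training panels, 20-gene screening panels and 5 replicate seeds; these sizes
exercise the canonical design while keeping a complete run in minutes on a
single CPU.

## Known limitations

- Single-TF regulation only; the data model leaves hooks for multi-regulator
  cis functions but combinatorial regulation is not implemented.
- Activity is identified up to the unit-peak gauge; absolute activity scale
  (and hence absolute K) requires external calibration.
- The delay is a single lumped constant per gene; distributed or
  state-dependent delays are not modelled.
- Deterministic ODE only; no intrinsic-noise (SDE) variant.
- The correlation sign is computed against the inferred activity on the
  measurement grid; with strongly delayed genes the correlation and model
  signs can legitimately disagree.
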