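# Methods

## Model

The animal is reduced to a planar rigid trunk with four massless,
telescoping (prismatic) legs. Hindlimbs act at the hips, forelimbs at the
shoulders; each leg pushes along the line from its fixed ground contact to
its attachment point, with no upper bound on force but no pulling
(`F_i >= 0`) and infinite friction at the foot. A limb can produce force
only while its length does not exceed its maximum length (the
strut-complementarity condition `F_i (l_max,i - l_i) >= 0`): contact timing
and footfall locations are decision quantities, not inputs
(contact-invariant formulation).

Two trunk variants are supported:

* **distributed mass** — the trunk carries a pitch moment of inertia
  parameterized by the Murphy number `Mu = 4 I / (m GAD^2)` (GAD =
  glenoacetabular, hip-to-shoulder distance). Forces applied at hip or
  shoulder generate pitch moments about the COM.
* **point mass** — rotational dynamics are omitted. Attachment points stay
  at the hip/shoulder offsets of a permanently level trunk, so limb-length
  geometry is preserved while forces generate no moments. This is the
  design choice for the otherwise under-determined "no rotation" variant;
  it keeps the two variants' limb constraint geometry identical.

Internal units set trunk mass, gravitational acceleration and the maximum
hindlimb length to one, so all works are natively in `m g l_H` and speeds
are Froude-type numbers `U' = U / sqrt(g l_H)`. The shipped horse preset
(adult Warmblood: `l_H = 1.38 m`, COM at 0.57 GAD from the hips,
`Mu = 0.82`, walking at `U' = 0.43` with stride `D' = 1.34`) uses equal
forelimb length and GAD (`= l_H`) in the main configuration and measured
values (1.14 m, 1.63 m) in the `horse_anatomical` alternative.

## Objectives

Four positive mechanical work measures per stride:

* `NCW = int |F_net . V_com|+ dt` — net COM work, equal to the positive
  fluctuations of COM kinetic plus gravitational potential energy;
* `ILCW = int sum_i |F_i . V_com|+ dt` — per-limb COM work (does not let
  simultaneous positive and negative work cancel);
* `LEW = int sum_i |F_i l_i_dot|+ dt` — axial limb (extension) work, the
  actuator work of the strut legs;
* `NSW` — positive fluctuations of total mechanical energy including
  rotational kinetic energy.

Percent (pendular) recovery uses the standard Cavagna convention on COM
energies only, `100 (W+_Ek + W+_Ep - W+_{Ek+Ep}) / (W+_Ek + W+_Ep)`; no
rotational term is included (the rotational bookkeeping is what `NSW` is
for). Positive-part integrals of sampled signals are evaluated exactly for
the piecewise-linear interpolant (sign-crossing segments are split
analytically); energy-series fluctuations are sums of positive increments,
which is the same quadrature applied to the energy rate.

A force-rate regularization `c1 sum_i int (dF_i/dt')^2 dt'` (forces in body
weights, time normalized to the stride period, default `c1 = 3e-5`)
penalizes non-smooth force profiles; it is orders of magnitude smaller than
the work terms and acts mainly as a tie-breaker among work-equivalent
solutions.

## Transcription

Gaits are assumed periodic and left-right symmetric, so only the half
cycle `t' in [0, 0.5]` is discretized. States are trunk kinematics, the
five footfall-channel forces (left hind; right hind; left fore through a
trailing and a leading footfall one stride apart; right fore) and the
running integral of the leading left-fore force; force rates are controls;
the left-limb footfall positions are static parameters (right-limb
footfalls are the left ones translated by half a stride). Boundary
conditions tie kinematics at the half-cycle ends (horizontal position
advances by `D/2`) and hand forces across the left/right swap; the left
hind is the reference limb (zero force at `t' = 0`).

Complementarity conditions — strut length (`F (l_max - l) >= 0`), the
exclusion of the trailing fore footfall once the leading one has been
loaded (`F_LFt int F_LFl = 0`), and optionally `F_LFt dF_LFl/dt = 0` for
the net-COM-work objective (whose degenerate flat solutions otherwise
admit brief five-contact artifacts between nodes) — are relaxed by
nonnegative relaxation parameters `eps` bounding the residuals, penalized
in the objective with a weight that grows tenfold per solve round. In the
final rounds the relaxation parameters are additionally clamped to the
complementarity tolerance (1e-4 in body-weight-length product units), so
accepted solutions satisfy the conditions at every node by construction of
the bounds, and are re-verified post hoc.

The positive-part objectives are transcribed with one nonnegative epigraph
slack per power term per node (`s >= T p`, `s >= 0`, objective integrates
`s`): minimization drives each slack onto the positive part exactly, so no
complementarity pair or smoothing parameter is needed for the objective
itself. Collocation uses trapezoidal defects on a uniform normalized-time
grid (a Hermite–Simpson rule is also implemented and selectable); the
objective uses trapezoidal quadrature weights on the same grid. All
constraint Jacobians and the objective gradient are analytic (dense),
verified in the test suite against central finite differences.

## Solver protocol

Each restart starts from a random guess: trunk height sampled near
standing, linear horizontal progression, small random pitch, nonnegative
random spline force profiles windowed to meet the reference-limb endpoint
zeros and scaled so mean total vertical force is about one body weight, and
footfall positions sampled within half a stride of the mean attachment
positions. Guesses are deterministic in the seed.

The staged protocol then runs SLSQP rounds at 12 coarse nodes with
relaxation penalties `w0 * 10^round` (`w0 = 1`, iteration caps 300/150/150,
last two rounds with clamped relaxation parameters), followed by midpoint
mesh refinement to 23 nodes and a final solve (cap 80). A restart is
**accepted** when (i) the final solve is feasible to 1e-5 and terminated
cleanly (SLSQP status 0, or status 8 — a line-search stall that this dense
SQP routinely reports at numerically converged points), (ii) exact
complementarity residuals at all nodes are at most 1e-4, and (iii) the
optimized work metric changes by less than 5e-3 m g l_H under the mesh
refinement. The accepted solution with the smallest total objective (work
plus force-rate and relaxation penalties) is the pseudoglobal optimum.

Problem sizes (12 -> 23 nodes, 10 restarts) are the package's desk-scale
defaults; they solve one campaign in a few minutes on one CPU. Larger node
counts and restart numbers are plain parameters. Independent forward
integration (`solve_ivp` on the solved force profiles) reproduces the
collocation states to about 5e-4 at these sizes, and dense-path
re-evaluation changes the work integrals only in the fourth decimal, so
the 23-node quadrature is adequate for the reported precision.

## Gait metrics

Stance is `GRF > 0.02` body weights (linear interpolation of the crossing,
sub-grid gaps merged); duty factor is the stance fraction of the stride,
and limb phases are touchdown times relative to the left hind. Force humps
are local maxima of the 3-point-smoothed stance profile with prominence at
least 10% of the limb's peak force, merged unless separated by a trough at
least 5% below the lower peak; the prominence condition exists because
near-constant compliant-gait profiles otherwise count small load-shifting
wobbles as humps. Classification: `compliant_high_duty` (all duty factors
above 0.8, single-hump), `single_stance_vaulting` (some period with
exactly one supporting limb), `four_beat_singlefoot` (four staggered
touchdowns, support alternating between two and three limbs, duty factors
in [0.45, 0.75]), else `other` with the measured feature vector attached.

## Validation oracles

Conservative one-degree-of-freedom toys with closed-form recovery anchor
the energy bookkeeping: point pendulum and bead on a frictionless wire
(100%); physical pendulum and rolling sphere (recovery `2f/(1+f)` where
`f` is the translational share of kinetic energy: 6/7 for a rod-like
pendulum, 5/6 for a rolling uniform sphere with `f = 5/7`); and a passive
4-bar quadruped that vaults with 100% recovery in the parallelogram
(trot-like) configuration but less when the feet are staggered and the
trunk pitches. All conserve total energy to integrator tolerance, giving
zero net system work while still exhibiting nonzero positive COM work
whenever rotational energy fluctuates.

## Numerical choices and known limitations

* Works reported to ~1e-3 m g l_H; duty factors and phases to ~0.02 of a
  stride at the default grids.
* The symmetry/feasibility tolerance of accepted solutions is 1e-5
  (constraint scale: forces about one body weight); the mirroring step
  refuses half cycles whose boundary residuals exceed it.
* The work-objective landscapes are rugged, and for the extension-work
  objective nearly flat across limb-phase offsets: restarts converge to
  four-beat walks whose phase lag between hind and fore touchdowns spans
  roughly 0.05-0.35 of a stride at nearly equal cost. Consequently the
  pseudoglobal solution's secondary metrics (especially percent recovery,
  observed anywhere between about 60 and 90% across seeds) are less
  reproducible than its own objective value. Reported work minima at desk
  scale should be read with the +/-15% band used in the tests.
* Left and right limbs are interchangeable in a planar model: lateral- vs
  diagonal-sequence walks are energetically identical here and the
  classifier is label-agnostic. Lateral dynamics, limb mass and swing
  cost, compliant ground, slipping, and muscle-level costs beyond the
  force-rate penalty are out of scope.
* The stride length and speed are inputs, not predictions; with massless
  legs there is no cost limiting stride frequency, so the model cannot
  select its own stride.
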