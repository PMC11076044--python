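# Methods

`gravistoch` implements a stochastic world model on gravity: an internal
simulator of block-stack collapse whose gravity direction is not fixed
straight down but drawn from a Gaussian around vertical.  This note records
the models, the numerical choices, and what the synthetic experiments do and
do not establish.

## Scene model and stack generation

Blocks are rigid 3:1:1 cuboids, 1.2 x 0.4 x 0.4 length units, 0.2 kg each,
with the long axis chosen uniformly among x, y, z per block.  Stacks are
grown in three steps: (1) designate a placement area with half-ranges
`area_x`, `area_y` (each drawn from U(0.2, 2.0) unless fixed); (2) drop
blocks at uniform random horizontal positions, each resting on the ground or
on the topmost block whose footprint overlaps its own (block heights are
multiples of 0.4, so equal tops are common; ties go to the earliest-placed
block); (3) re-position each supported block horizontally so
that its overlap with its designated support equals a draw from U(0.2, 0.8).

Overlap is measured per axis as the shared footprint length divided by the
*smaller* of the two footprints along that axis, and the pair's overlap is
the minimum over x and y.  Measuring against the smaller footprint makes the
whole (0, 1] range reachable for every block-type combination — against the
upper block's own length, a long block on a short one could never exceed 1/3,
leaving the U(0.2, 0.8) target unreachable.  The adjustment moves the block
along its least-overlap axis first and raises the other axis only if it
falls below the target.  When the exact target would push a block's center
outside the designated area, the move is clamped to the area boundary, which
can only increase the realized overlap; overlaps therefore never fall below
0.2, and they are uniform on [0.2, 0.8] whenever the area leaves room (the
test suite checks both).

Stability labels come from one natural-gravity simulation: a stack is stable
iff no block's center ever moves more than the displacement
just-noticeable-difference eps = 0.01 units.  The graded stability score is
the fraction of blocks whose final-stage displacement stays below eps.  Note
the two criteria quantify differently (all stages vs final stage), so a
transient excursion can make a stack "unstable" while its score is still 1;
both are kept as defined.  Labeled-set generation rejection-samples stacks
and uses an early-exit run (stop at the first eps crossing, or when the scene
goes fully static) that returns exactly the same verdict as scanning a full
recorded trajectory.  Stable 10-block stacks are rare (about 1-10% depending
on area size, U-shaped: tiny areas force well-aligned towers, mid-size areas
produce sprawling precarious ones), so the attempt budget (default 10,000
per category) matters.

## Rigid-body backend

The simulator is implemented in-repo (numba-compiled kernels) and treats the
scene as boxes plus a ground plane at z = 0 under uniform gravity

    G = g (sin t cos p, sin t sin p, -cos t),   g = 9.8,

so tilt t = 0 is straight down and t = 180 straight up.  (The sign of the
z component is chosen so that the zero-tilt vector is (0, 0, -9.8).)
Friction is 1 and restitution 0 for all contacts, block-ground included.

The scheme is *equilibrium-preserving*.  Every body starts asleep.  A
sleeping island (a connected component of resting bodies) is woken only when

* a static-equilibrium test proves no admissible contact forces can hold it:
  existence of contact forces — non-negative normals plus a 4-direction
  friction pyramid — balancing gravity on every body is checked as a linear
  program (HiGHS via scipy); a cheap aggregate screen (no ground support,
  upward gravity, or tangential gravity beyond the friction cone) skips the
  LP for clear cases; or
* a moving body hits it with a normal impulse above 0.01 N s.

Sleeping bodies do not move at all, so a stable stack yields a bit-for-bit
constant trajectory — important because the eps = 0.01 stability criterion
leaves no room for resting jitter.  Awake bodies are integrated by
semi-implicit Euler at dt = 1/240 s (one step per recorded stage; 500 stages
~ 2.1 s) with a sequential-impulse velocity solver (12 iterations, friction
box clamp) and split-impulse position correction.  Contacts come from the
separating-axis test with reference-face clipping manifolds for face
features and closest-point contacts for edge-edge features.  A settling pile
re-sleeps as a whole island once every member stays below the velocity
thresholds; if the equilibrium test rejects a pose that dynamics has brought
to rest (the LP's linearized manifold can be blind to a contact the solver
uses), the dynamic verdict wins and the island stays asleep until its
contact topology changes.

The 4-direction friction pyramid under-grips diagonal directions by up to
1/sqrt(2); since the horizontal gravity orientation phi is uniformly random
in every experiment, the anisotropy averages out.  The solver's integration
step and iteration counts are configurable; the prior-learning loop uses a
coarser setting (6 velocity iterations, 1 position iteration, earlier
sleeping) because its match statistic only distinguishes moved from unmoved
blocks at the 0.01 threshold.

Within a trajectory, stage 0 is the initial configuration and each later
stage follows one integration step; per-block centers and the 8 box vertices
are recorded (vertices lazily, from stored quaternions).

## Natural and mental gravity simulators

NGS: one simulation with gravity straight down; defines ground truth.
MGS: the stability estimate is the mean score over `n_mgs_samples` (default
100) simulations whose tilt t is drawn from a half-Gaussian truncated to
[0, 45] degrees and whose phi is uniform.  The default width sigma = 18.6
degrees is the mean of the psychophysically measured tuning widths in the
upright (19.9) and inverted (17.2) worlds; 45 degrees is the design limit of
that measurement.  The truncation ignores spherical solid-angle weighting,
matching the grid treatment of (theta, phi) throughout.

Inference bias IB = MGS - NGS.  For an NGS-stable stack the bias can only be
negative or zero (tilting cannot stabilize), and it grows in magnitude with
stack height because taller stacks topple at smaller tilts.  The
height-illusion experiment generates equal numbers of stable and unstable
10-block stacks in square areas of several side lengths ("side" here is the
placement half-range, the same parameter the area draws use), scores each
with both simulators, bins stacks by height deciles, and reports per-bin
mean IB with a one-sided t test plus the Spearman correlation of height with
IB across stacks.

## Psychophysics model and synthetic observers

The tuning-curve analysis takes trial-level binary "normal trajectory"
judgments on the design grid theta in {0, 3, ..., 45} x phi in
{0, 24, ..., 336} (15 distinct orientations; 0 and 360 coincide), forms
acceptance ratios n/N per sampled pair, fills unsampled pairs with the mean
ratio over phi at the same theta, marginalizes over phi, and fits

    Ratio(theta) = A exp(-theta^2 / (2 sigma^2))

by bounded nonlinear least squares (A in (0, 1.5], sigma in (0, 90],
initialized at the peak ratio and sigma = 20).  Synthetic observers replace
human participants: Bernoulli responses with p = 0.91 exp(-theta^2 / (2
sigma_true^2)) (0.91 is the canonical peak acceptance), a balanced run
design (each theta six times per 96-trial run, phi shuffled against theta),
four runs per session, no lapse or guess floor.  Parameter recovery is
within +-3 degrees of sigma_true across the 10-40 degree range at this
design size; an inverted-world observer shares the same tuning model, so
upright and inverted fitted widths agree up to sampling noise.  Passing
these tests shows the estimation pipeline is consistent for data that follow
the assumed response model; it says nothing about lapses, learning, or
criterion shifts real observers might show.

## Learning the gravity prior

Sampling weights W(theta, phi) live on a 61 x 60 grid (61 tilts on [0, 180];
61 orientations on [0, 360] deduplicated to 60) initialized at 0.5.  Per
generated stack (block count uniform on 2-15), three distinct cells are
drawn with probability proportional to W; for each, the stack is simulated
under that direction and compared with its natural-gravity outcome through
the match fraction Q = (1/M) sum_m 1[|P_m(dir) - P_m(NGS)| < eps], and the
cell is updated by W <- W + gamma (Q - W) with gamma = 0.15.  Directions
that keep predicting reality (small tilts) gain weight; a cell's weight
converges to its expected Q under the stack distribution.

E[Q](theta) is 1 at theta = 0 by construction, drops to ~0.5 immediately
(for collapsing stacks, a tilted replay never reproduces the exact final
pose), then decays smoothly to 0 around 60-70 degrees; the decay width is
what the Gaussian fit picks up.  The grid fit rescales the theta-marginal to
peak 1 and includes a non-negative baseline term: cells a finite training
pass has rarely touched still sit near the 0.5 initialization, flooring the
marginal; the baseline absorbs that floor and tends to zero as training
lengthens, leaving the pure Gaussian model in the long-training limit.
Training with single-block-count worlds narrows the fitted width
monotonically as blocks increase — stacks with more blocks are easier to
knock over, so mismatches punish tilted directions at smaller angles.

## Speed-accuracy-efficiency analysis

For each block count, equal numbers of stable and unstable stacks (labels
always from NGS) are simulated by one simulator — NGS, or MGS with a single
sampled direction per stack, modeling one mental simulation pass — and one
logistic-regression classifier per stage (scikit-learn, C = 1, lbfgs) is
trained on the flattened vertex displacements relative to stage 0 (24
features per block) and scored on a held-out set.  Stages whose features
have stopped changing reuse the previous fit.  From the accuracy-by-stage
curve: plateau accuracy = max over stages; response time = (first 1-based
stage attaining the max) / T; efficiency = plateau / time, so efficiency x
time = plateau exactly.  The tilted simulator collapses stacks sooner and
more violently, so its classifier peaks early at a lower plateau: lower
accuracy, much shorter time, higher efficiency.

## Problem sizes

The desk-scale runs used by the test suite and `scripts/acceptance.py`:
speed-accuracy with blocks {3, 5, 7} and 50+50 train and test stacks per
count (the reproduction script keeps the full 500-stage horizon because the
response time is a *fraction* of that horizon — a truncated horizon cuts
into the settling phase and inflates t_hat/T; the test suite also exercises
the 300-stage variant); prior learning with 5,000 stacks at 150 stages;
height illusion
with 5 area sizes spanning [0.2, 2.0], 20+20 stacks each, 30 MGS samples,
200 stages with the coarse solver setting (the displacement verdicts that
feed the scores are decided early in a collapse).  Full-scale counterparts (blocks 2-10 with 100+100 stacks,
100,000 training configurations, 19 area sizes, 100 MGS samples, 500 stages)
run through the same code paths via the configuration objects and the CLI.

## Known limitations

* The rigid-body backend is this package's own; contact-level trajectories
  will not match any other engine step for step, and quantities that depend
  on collapse microdynamics (exact response-time fractions, efficiency
  ratios) inherit that engine dependence.  The deterministic simulator's
  response time is the most sensitive: because settled scenes here are
  exactly static, the accuracy curve stops fluctuating once collapses finish
  and the first-argmax lands earlier than it would under an engine with
  resting jitter; the pooled time also shifts with the block-number mix,
  since larger stacks collapse (and reveal themselves) later.
* The equilibrium LP decides stability sharply; marginally balanced poses
  that a noisy engine would topple remain standing here.
* Fine-tuning overlaps can interpenetrate non-support neighbors slightly;
  resting interpenetration is tolerated by the statics test and resolved
  smoothly by position correction if the island ever wakes.
* Synthetic observers are the statistical stand-in for the deposited human
  data: identical trial structure and response model, but no human will
  match the Bernoulli-with-Gaussian-tuning model exactly.
* The height-illusion trend is reported over generated stacks; with small
  per-bin counts the per-bin t tests are underpowered even when the sign is
  consistent.
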