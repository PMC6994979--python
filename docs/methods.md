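# Methods

This note documents the models, parameter choices and known limitations
of `voxevo`. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Genotype and development

A genome is a pair of deterministic scalar fields over the normalized
body cube [0, 1]³ — one for voxel presence, one for tissue type — plus
a phase-offset grid and lineage bookkeeping (clade id, age). Each field
is a bias plus a weighted sum of 2–6 primitive nodes drawn from
{linear, sine, absolute value, Gaussian bump of radial distance}, each
applied to a random affine combination of the coordinates. Development
at resolution (nx, ny, nz) evaluates both fields at every voxel center:
a voxel is present iff the presence field is strictly positive (ties
break to empty), contractile iff the tissue field is strictly positive
(ties break to passive). All but the largest face-connected component
are pruned to empty rather than rejected, which keeps the search
productive while guaranteeing single-component phenotypes. Because the
fields are functions of continuous coordinates, the encoding is
scale-free: the same genome develops at any resolution with preserved
geometry. The linear coefficients are sampled N(0, 3); this keeps the
phenotype boundary to a few percent of the grid so that development at
doubled resolution agrees with majority-downsampled occupancy on ≥95%
of voxels (verified over 50 random genomes in the test suite).

Phase offsets live on a fixed *workspace* grid (default 8×8×7, also the
default working resolution) and are sampled uniformly over the valid
[−π/2, π/2] range when a clade is founded; the founding distribution is
not otherwise constrained, and uniform is the maximum-entropy choice.
Development at any resolution reads the phase of the workspace cell
containing each voxel center.

Mutation always perturbs body structure — one field-graph node or
coefficient in the default generative encoding, or one workspace-voxel
tissue switch in the optional `direct` encoding (both encodings are
supported because either granularity is consistent with a
"developmental process whose mutations switch voxels"; generative is
the default). A mutation must change the developed phenotype in at
least one voxel; it is resampled up to 50 times, after which a
mutation-failure signal tells the caller to draw a new parent. In
`second_pass` mode the clade's phase grid is copied bit-for-bit down
every lineage; in `first_pass` mode phases may additionally receive
Gaussian perturbations (SD 0.1π, probability 0.5 per mutation), clipped
to ±π/2.

## Soft-body physics

Bodies are simulated as mass-spring lattices: point masses at voxel
corners (voxel mass 1, split over its 8 corners), springs along the 12
edges and 12 face diagonals of every voxel, all with stiffness 5·10³
and per-spring damping 2ζ√(kμ) from the endpoint reduced mass μ, with
damping ratio ζ = 0.3. Contractile voxels modulate the rest lengths of
their springs by 1 + A·sin(2πft + φ) during the evaluation window
(A = 0.1, f = 2 Hz); springs shared between voxels average the
multipliers of their owners, passive owners contributing 1. Integration
is semi-implicit Euler at Δt = 10⁻³ s, which makes every simulation a
pure function of its inputs: identical (design, configs, seed) give
bit-identical trajectories. Units are voxel edge = 1 length unit, voxel
mass = 1 mass unit, seconds for time; reference gravity is 9.81
length-units/s².

The ground plane at z = 0 exerts a penalty normal force
(stiffness 10⁴, normal damping 10) on penetrating nodes plus
regularized Coulomb friction (μ = 0.8): the tangential force is
μN·**v**ₜ/(‖**v**ₜ‖ + 10⁻³), capped at the force that would bring the
node to rest within one timestep. The cap matters: an uncapped
regularization acts as a tangential viscosity far above the explicit
stability limit for near-resting nodes, which injects noise-like
lateral jitter; with the cap, a mirror-symmetric design's lateral drift
stays at machine precision over 10 s. A design is "in contact" when any
corner node is within 10⁻³ voxel lengths of the plane; a velocity
condition was deliberately omitted because penalty-contact nodes at
rest oscillate around zero normal velocity, which would make the
contact signal chatter.

Each evaluation starts from rest with the lowest nodes touching the
plane, settles for 1 s without actuation, then actuates for the 10-s
evaluation window; the trajectory (100 Hz output) and net displacement
are measured from the post-settling position. Net displacement is
horizontal-plane distance (organisms locomote on a dish surface).
Trajectories are computed in the body frame and translated afterwards,
so placement translation is exact. Randomized phase modulation — the
noise under which locomotion fitness is scored — draws one clipped
Gaussian perturbation of the phase field per evaluation (SD 0.4π, the
same scale as the robustness filter, keeping a single noise scale in
the model).

### Environments

*Terrestrial*: full gravity, no drag. *Aquatic*: the body is submerged;
buoyancy scales gravity by 0.5 and every exposed voxel face feels a
linear drag force −c·A·(**v**·**n̂**)**n̂** on its normal velocity, with
c = 40 per unit face area. These two constants are the package's own
calibration of the submerged regime (no reference values exist for
them): together they make hopping ineffective under water — kick
energy is dissipated by drag and bodies sink back quickly — so
negatively buoyant designs keep their ventral surfaces in ground
contact, while the same bodies on land can and do leave the ground.
With a much smaller gravity scale or weaker drag the model behaves
unphysically for a submerged dense body: hops become cheap and the body
floats between them. Setting `drag_coefficient = 0` and
`gravity_scale = 1` in aquatic mode reproduces terrestrial trajectories
bit-exactly (the drag term contributes exactly zero force), which the
test suite asserts.

First-order drag acts on face-normal velocity only: no lift, no added
mass, no lubrication film between body and plane.

## Evolutionary search

Selection is age–fitness Pareto with per-clade truncation: an
individual is dominated if another has both no-worse fitness and
no-older clade age (with one strict). Survivors (half the population)
are taken in Pareto order with at most 3 per clade; freed slots are
refilled with mutants of survivors; exactly one brand-new random genome
(new clade, age 0) is injected per generation; all pre-existing clade
ages increment each generation. This realizes competition within and
between lineages while guaranteeing a steady influx of new clades. Each
individual is evaluated once, when it is created (no averaging);
robustness to the stochastic fitness is assessed post hoc by the
robustness filter. The champion of a trial is the best-ever evaluated
individual (elitist tracking), so best-ever fitness is non-decreasing.
Empty phenotypes and numerically unstable simulations score −∞ and are
logged.

All randomness derives from a single master seed: trial seeds are drawn
from it, and each trial's generator supplies genome seeds, mutation
draws and per-evaluation phase-noise seeds in a fixed order, so a full
pipeline run is reproducible file-for-file. (Evaluation seeds are drawn
from the per-trial stream rather than hashed from
(trial, generation, individual) tuples; the two schemes are equally
reproducible and the stream is simpler.)

Defaults at full scale are population 50, 100 generations, 100
independent trials; the shipped tests and the acceptance script use a
micro budget (3 trials, population 10, 15 generations, 8×8×7 grid,
~500 locomotion simulations per mode) chosen so both evolutionary modes
run in minutes on one CPU. At this budget the champion contact
statistics carry sampling error of several percentage points — the
tests therefore check them within ±10 percentage points and check the
aquatic-vs-terrestrial ordering strictly.

## Filters

*Robustness*: each candidate is simulated `n_noise_samples` (default
25) times under independent clipped-Gaussian phase perturbations
(SD 0.4π — 40% of the π-wide valid range; clipping rather than
resampling, so large SDs pile mass at the bounds). Sample j of every
design shares the same noise seed, making comparisons paired. Ranking
is by mean net displacement, ties by lower SD, then input order.
Unstable samples score 0 rather than aborting the ranking.

*Build*: muscle fraction is the contractile share of non-empty voxels;
designs above 0.5 fail (exactly 0.5 passes). Concavity analysis closes
the occupancy volume with cube structuring elements of growing
half-width until no further growth changes the result, labels the
face-connected components of (closed − body), and measures each
region's width as the smallest extent of its bounding box; the minimum
over regions, divided by the largest body extent, must reach 0.12
(100 µm at build scale). Cubes rather than discretized spheres: on a
voxel lattice the cube is the natural isotropic element, and it closes
a rectangular gap of width w exactly when its half-width reaches w/2 —
discretized spheres suffer corner-rounding that leaves the top layer of
a gap open and misreports its width. The whole computation is checked
against a brute-force dual-form oracle (explicit point-pair distances,
no morphology routines) on enumerated single-notch bodies.

Whether the muscle rule counts voxels or deformed volume is ambiguous;
voxel count is used. Robustness averages displacement (consistent with
the fitness), not velocity.

## Behavior analysis

Trajectory smoothing is a normalized 1D Gaussian kernel per coordinate
(reflect boundary; σ default 5 samples, configurable; σ = 0 is the
identity). Inversion rotates a design 180° about the horizontal
mid-plane of its grid ("transverse plane"), implemented as a z-flip of
grid and phases — the accompanying yaw is a rigid motion with no
locomotor consequence. The upright-vs-inverted protocol evaluates a
design n times (default 25) under independent phase-modulation draws
and compares displacement distributions with a one-sided permutation
test on the difference of means: exact enumeration when C(n₁+n₂, n₁) ≤
10⁶, otherwise seeded Monte-Carlo with add-one smoothing. The
permutation test is a distribution-free stand-in for the original
analysis protocol, and reports flag it as such. The gait-cycle airborne
fraction is averaged over whole 0.5-s actuation cycles only, so partial
cycles cannot bias it.

## Numerical and degenerate-input choices

- Field-threshold ties (exactly 0) develop to empty / passive.
- Divergence (any non-finite coordinate) raises an error naming the
  design and timestep; fitness evaluation converts it to −∞.
- Contact tolerance 10⁻³ voxel lengths; friction regularization
  velocity 10⁻³ lengths/s.
- Designs are validated on load: labels outside {0, 1, 2}, phases
  outside ±π/2, wrong value counts and unknown versions are parse
  errors naming the offending line.

## What the synthetic setup does and does not show

The fixture designs (solid block, notched blocks, walker, symmetric
brick, muscle-heavy block) are constructed, not evolved; the walker is
deliberately ventral-driven so the inversion comparison has a known
direction. Everything the tests establish concerns this simulated
physics: a mass-spring lattice with penalty contact and first-order
drag, not wet-lab tissue. In particular the build filter's 100-µm rule
enters only as the dimensionless 12%-of-body-length threshold, and the
aquatic environment is a two-parameter caricature of submersion.
Agreement of the scaled-down contact statistics with their full-scale
reference values shows that the generator-and-filter architecture
reproduces the qualitative regime shift between the two passes — not
that the physics is quantitatively predictive of living tissue.

## Known limitations

- No voxel–voxel collision between separate bodies, no particulate
  debris, no fluid momentum (Navier–Stokes), no GPU path.
- The evolutionary budget at desk scale is ~100× smaller than the
  reference setting of 100 trials; champion statistics are
  correspondingly noisy.
- The mass-spring material model has no volumetric (pressure) term;
  very soft or very elongated bodies can be floppier than a
  finite-element model would predict.
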