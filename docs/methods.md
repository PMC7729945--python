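# Methods

`opmarray` answers a design question for wearable (on-scalp, OPM-based) MEG
systems: *given a desired spatial discrimination, a source depth/SNR regime
and a calibration-error level, how densely must a scalp array sample the
field?* It frames discrimination statistically — the Euclidean distance at
which two competing source models can be distinguished at 20:1 evidence —
and complements it with a worst-case analysis of the noise that spatial
undersampling aliases into the measurement.

## Synthetic head geometry

Real studies of this kind start from a template (MNI) cortical mesh with
~3 mm vertex spacing, an anatomical atlas, and a subject scalp surface.
This package generates stand-ins with the same structural properties, which
keeps the whole pipeline reproducible and makes the forward model exact:

* **Scalp** — an exact sphere (default radius 90 mm, adult scale),
  triangulated from a golden-spiral lattice (any vertex count, default
  2562). A spherical scalp makes the Sarvas closed-form conductor model
  exact rather than approximate.
* **Cortex** — a star-shaped surface strictly inside the scalp. Its radius
  field combines a band-limited random oscillation (order ~10, RMS
  12 mm — the cm-scale folding that spreads vertex depths over
  ~8–45 mm) passed through a tanh soft saturation (no flat clipping
  plateaus), with an optional flat inferior truncation at
  z = −(R − max_depth) emulating the skull base, so the brain occupies the
  upper head and sensor packing gets a head-like inferior limit.
* **Dipole orientations** — the normals of the *fully folded* surface,
  including a fine fold field (order ~40, i.e. ~10 mm angular wavelength,
  RMS 3 mm — gyral-wall scale) evaluated analytically at the mesh
  vertices. This matters in a spherical conductor, where purely radial
  dipoles are magnetically silent: a smooth star-shaped surface would give
  its depth-extreme vertices (exactly the ones the depth-ranked source
  selection picks) radial normals and hence zero signal, a degeneracy real
  folded cortex does not have. The fine folds restore realistic
  orientation statistics (median tangential fraction ~0.8) at the expense
  of *shorter* orientation coherence than real cortex — consequences are
  noted below.
* **Depth** is the exact Euclidean distance from a cortex vertex to the
  triangulated scalp surface (vectorized point-to-triangle distance).
  "Deep" and "superficial" sources are the depth extremes, greedily
  selected one per parcel; parcels are nearest-seed regions grown from
  farthest-point-sampled seeds (an atlas stand-in, default 90 regions).
* Band-limited fields on the sphere are generated as sums of 24 random
  oriented cosine waves, which concentrates the angular spectrum near the
  requested order and gives analytic gradients for the orientation tilt.

What the generator does **not** emulate: skull/CSF conductivity structure,
white/pial separation, hemispheric asymmetry, and — importantly — the long
orientation coherence of gyral walls. Results that depend on neighbouring
sources *mimicking* each other (discrimination radii, gain-error
sensitivity) are therefore systematically more optimistic here than on a
real cortex, and results that depend on patch-coherent summation
(source-space smoothing) cancel more than they would in reality. Tests
passing on this geometry validate the machinery and the qualitative
structure, not millimetre-exact clinical numbers.

## Forward model

Point magnetometers in a homogeneous spherical conductor, via the exact
Sarvas closed form; the measurement is the projection of **B** onto the
sensor orientation (radial, the standard single-axis OPM assumption).
Positions are mm (converted to m internally), moments nAm, fields fT.
The implementation is cross-checked in the tests against two independent
oracles: the radial-field identity (the radial component outside the
conductor equals that of the primary dipole current alone) and the Sarvas
kernel of MNE-Python. For user-supplied meshes the conductor centre/radius
are fitted to the scalp by least squares. The widely used single-shell
correction reduces to this closed form for spherical geometry, which is
why the scalp is spherical by design; the `build_leadfield` surface is the
hook where an alternative conductor model would plug in.

## Array design

Sensors are packed on scalp vertices by a five-step point-packing scheme:
bounding-box grid projection for initialisation, stochastic 1-ring moves
accepted when they reduce the summed |nearest-sensor distance − target|,
a coverage step that adds a sensor wherever a scalp vertex is farther than
the target spacing from every sensor, iterated (default 10,000 proposals,
early stop after 1,000 consecutive rejections; coverage re-enforced every
1,000 iterations and at termination, so the coverage property holds
exactly on return). Sensors are restricted to Z at or above the inferior
edge of the brain. Standoffs: 6.5 mm = wearable on-scalp, 20 mm =
cryogenic helmet.

## Simulation and SNR

One epoch of a 10 Hz sinusoid, 1000 ms at 200 Hz (Nyquist-consistent round
number for a 100 Hz bandwidth), single dipole, i.i.d. Gaussian sensor
noise of SD 100 fT (10 fT/√Hz over 100 Hz). Gain errors — OPM
calibration errors from nonlinearity, movement through field gradients or
crosstalk — are drawn once per channel from Gaussian(1, gain_sd) and
multiply the channel's recording; the inversion always uses the *nominal*
lead field, so gain error is a controlled model mismatch. SNR is defined
as 10·log10(mean-over-channels clean variance / noise variance); with this
definition the 1/10/100 nAm amplitude ladder is exactly 20 dB per decade.
On the default geometry the superficial class means ~18 dB at 100 nAm and
the deep class ~12 dB lower — the superficial–deep gap matches the ladder
structure reported for full-scale template-anatomy simulations, while the absolute level sits a few dB
lower because a spherical conductor suppresses the near-radial component
that real (non-spherical) head models preserve.

## Inversion and model comparison

Empirical Bayesian beamformer: the per-source prior variances are
q_i = (l̂ᵢᵀC⁻¹l̂ᵢ)⁻¹ (unit-norm columns, regularised data covariance),
rescaled so the implied sensor covariance matches the data trace. ReML
fits the two log-hyperparameters of Σ = e^{λ₀}I + e^{λ₁}·L diag(q) Lᵀ by
Fisher scoring with step halving (monotone objective), hyperpriors
λ ~ N(−4, 256) on standardised data (unit mean channel variance, unit
mean lead-field column norm; standardisation is common to all models
fitted to one recording and cancels in comparisons), convergence |ΔF| <
1e-3 twice, max 128 iterations, covariance regularisation ε =
1e-6·tr(C)/N. The reported free energy adds the Laplace complexity term
for the hyperparameters; only *differences* between models on the same
data are interpreted (ΔF = 3 ⇔ evidence ratio e³ ≈ 20).

Discrimination: the base model is the true source plus all sources within
20 mm; void (target) models exclude a growing ring (3…20 mm in 1 mm
steps) around the source; the smallest void radius with ΔF ≤ −3 is the
array's discrimination for that source. Sweeps that never cross are
censored at 20 mm and averaged at that value (conservative), flags
propagated. On this geometry the short orientation coherence makes
neighbours poor mimics of an excluded source, so high-SNR sweeps often
cross at the 3 mm floor — better than real-cortex curves; bound-type
claims (≤ 1 cm with < 100 channels) are meaningful, exact radii are not.
For the same reason the gain-error degradation seen on real geometry
(deep sources, high SNR) is masked at the floor here.

## Aliasing

A dense reference array (~700 potential positions; 11.5 mm packing on
this scalp) defines the fully sampled lead field. A channel subset
reconstructs it by nearest-neighbour interpolation; per-source VE is the
squared Pearson correlation across dense sensors, 1−VE the worst-case
aliased variance fraction, and 10·log10(VE/(1−VE)) the implied effective
SNR. Subsets are improved by stochastic hill climbing over the k = 6
nearest free positions (convergence: a full sweep with no accepted move,
max 50 sweeps), with the mean VE maintained incrementally (running
per-source sums over only the reassigned rows), making a trial move
O(changed rows × sources). A zero-variance reconstruction of a varying
column scores VE 0; a zero-variance true column is excluded with a
warning.

Numbers to expect on the default geometry: rank-95/99 of the dense
covariance at 51/~96 components; a greedy 100-channel subset explains
~91% of per-source variance (aliased ~9%, median ~7%). That is roughly twice the
4–5% reported for full-scale template-anatomy simulations: the synthetic head has proportionally
more very-superficial cortex (sharp topographies) and no skull standoff
beyond the 8 mm minimum depth. Source-space smoothing (Gaussian in
Euclidean distance, weights normalised) reduces aliasing marginally for
10–20 mm patches when patch orientations cohere; at 50 mm FWHM the signed
fields of hemisphere-scale patches cancel and the residual is dominated
by the sharpest superficial detail, so aliased variance *rises* — the
monotone-through-50 mm behaviour reported on real geometry is not
reproduced by amplitude-coherent Gaussian patches on a folded closed
surface.

## Problem sizes and determinism

Desk-scale defaults: 2562-vertex scalp, ~6,500-vertex cortex (3 mm
spacing), 5 spacings × 3 amplitudes × 2 offsets × 10 sources for the
grid, ~680 × 6,500 dense lead field for aliasing — the full bundle runs
in minutes on one CPU. The full-scale 50-spacing × 40-source × 30-repeat
grids are available behind `ExperimentConfig.full()` and an explicit
force flag. Every stochastic step takes a seed; a fixed config reproduces
every table bitwise.
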