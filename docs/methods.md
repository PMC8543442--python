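# Methods

This note documents the models and estimators the package implements, the
defaults that matter, the numerical choices, and what the synthetic
generators do and do not emulate.

## Geometry conventions

All coordinates are in Å, times in ps, energies in mJ/m² (surfaces) or
kJ/mol per molecule (adsorption).  Slabs lie in the *xy* plane with *z* the
surface normal; the box is rectangular and laterally periodic
(minimum-image convention in *x*, *y*), with *z* aperiodic for slabs.
Monoclinic cells (e.g. a γ = 96.5° molecular crystal) must be
pre-orthogonalized by the caller; an axis-permutation option on the readers
re-orients samples whose surface normal is not *z*.  Van der Waals radii
come from a pinned Bondi-style table shipped as package data (H 1.20,
C 1.70, N 1.55, O 1.52, Cl 1.75 Å, …); users can override it with a
two-column file, and the table is treated as immutable once a height map is
built so that contact detection is reproducible bit for bit.

## Virtual AFM and Monte-Carlo volumetry

A spherical tip of radius *R* (default 2 Å — much sharper than a real AFM
tip; larger values lower the map resolution) descends along *z* at a
lateral point until its center is within *R* + *r*ᵥdW of some atom.  Two
probe evaluations are provided and are required to agree within one step:

- *analytic* (default): *z*₊ = max over atoms with lateral minimum-image
  distance *d* ≤ *R* + *r* of [*z*ₐ + √((*R*+*r*)² − *d*²)]; mirrored for
  the lower surface.
- *stepped*: a literal descent in steps δ*z* (default 0.001 Å) from a
  starting height above the highest possible contact (margin default 1 Å),
  evaluated in vectorized blocks of steps.

The recorded height is the tip **center** at contact, which makes the
thickness inflation symmetric (≈ 2*R* + 2*r* for a dense slab); a tip-apex
convention is available (`contact="apex"`).  Volumes are Monte-Carlo
estimates over *N*ₚ uniform random lateral points (random, not gridded, to
avoid bias toward commensurate overlayers): *V* = *A*⟨Δ*z*⟩ with
SE = *A*·sd(Δ*z*)/√*n*.  Columns with no contact (possible for sparse
samples) are excluded and their fraction reported.  Adlayer volumes probe
the full sample and the substrate-only sample with the same seed (hence the
same points), so the point-sampling noise largely cancels in the
subtraction.  The probe inflation means absolute volumes are overestimates;
differences and trends are the meaningful outputs.

## Height–height correlation and roughness

*h*(*r*) is the mean squared height difference between points separated by
lateral minimum-image distance *r*, pooled over the upper and lower maps
(the two surfaces of a slab are averaged when requested; pair-count
weights).  Direction averaging is automatic with random points; an
axis-restricted mode (*r* = |Δ*x*|) exists because 1D-corrugated fixtures
then obey the closed form *h*(*r*) = *h*₀²(1 − cos 2π*r*/λ).  Default bins:
40 logarithmic bins from the mean nearest-neighbour point spacing to half
the smallest lateral box length; empty bins are flagged, never
interpolated.

The classifier fits a constant and *c*₁ + *c*₂ log *r* for *r* > *r*\_min
and calls a surface **rough** only when the log model is preferred by more
than ΔAIC = 2 *and* *c*₂ is positive with *t* ≥ 3; **smooth** when the
constant model suffices; **undetermined** otherwise.  The asymmetry is
deliberate: saturation over an accessible window never proves smoothness,
so borderline evidence lands in `undetermined` rather than `rough`.
Roughness exponents are out of scope.

## Surface thermodynamics

The surface energy table *u*ₛ(*T*) (typically 0–400 K spaced by 20 K) is
fitted with the constrained [2/1] Padé form

u(T) = (b + cT + dT²)/(e + fT),  e ≡ 1,  c = b·f  ⇔  u(T) = u₀ + αT²/(1 + fT)

The constraint enforces *u*′(0) = 0: a harmonic solid has equal kinetic
contributions in slab and bulk, so the surface excess is quadratic at low
*T*; the rational form is the minimal one that adds a linear high-*T*
asymptote.  Fitting uses bounded least squares (denominator kept positive
on the grid; a fitted root inside [0, *T*\_max] rejects the fit with a
diagnostic), weighted by per-point uncertainties when given.  Derived
curves: *c*ₛ = d*u*/d*T* analytically; *s*ₛ(*T*) = ∫₀ᵀ *c*ₛ/*T*′ d*T*′ by
adaptive quadrature with the finite limit *c*ₛ/*T* → 2α applied at the
origin (the low-*T* part of this integral is the error amplifier, hence the
analytic limit rather than naive division); γ = *u* − *T*·*s*ₛ with
*s*ₛ(0) = 0.  *s*ₛ is a difference of entropies and may legitimately be
negative.  The identity dγ/d*T* = −*s*ₛ holds to 10⁻⁶ relative and is
tested.

Adsorption energies use the two-surface balance
*U*\_A = [*E*\_slab + *n·E*\_mol − *E*\_composite]/*n* (positive =
attraction; *n* counts all adsorbed molecules, e.g. *n* = 2 for one
molecule on each face of a slab).  *U*\_A(*T*) tables are pushed through
the same Padé machinery to give *S*\_A(*T*) and −*T S*\_A(*T*).

## Hydrogen bonds

An O–H···O triplet is bonded when the O–O distance is **strictly** below
3.3 Å and the angle at the hydrogen is ≥ 140°.  Hydrogens are assigned to
their donor oxygen by a covalent cutoff of 1.2 Å (no topology is read).
The angle vertex is configurable (`angle_at="H"` or `"donor"`) because both
conventions circulate; at-H is the default.  An oxygen may donate and
accept simultaneously; bonds are directional, so a mutual pair counts twice
only if both directions pass.  Bonds are intra-chain when donor and
acceptor share a `chain_id`.  Counts are monotone in the thresholds and the
implementation is checked against an independent all-triplet brute-force
oracle.

## Adlayer dynamics

- **MSD / diffusion**: tracks are unwrapped across periodic images before
  analysis (frame-to-frame minimum-image steps), and intra-molecular images
  are reassembled before computing centers of mass.  The MSD uses all time
  origins (FFT evaluation) up to a maximum lag of 10 % of the trajectory
  (long lags are origin-starved); *D* = slope/(2*d*) with *d* the number of
  axes, fitted over 10–50 % of the maximum lag.  The reported *D* is the
  mean of 10 block estimates and its SE the block scatter — one long-lag
  fit is both less efficient and blind to its own variance.
- **Arrhenius**: *E*\_a = *R* ln(*D*₂/*D*₁)/(1/*T*₁ − 1/*T*₂) from exactly
  two temperatures is always labelled a two-point estimate and never given
  a confidence interval; two points cannot establish Arrhenius behaviour.
- **Jumps**: single-frame displacements above a threshold (default 5 Å)
  are flagged; the event list and the fraction of total path length carried
  by jumps are reported.  No heavy-tail exponent is fitted.
- **Rotation**: *C*(*t*) = ⟨**u**(*t*₀+*t*)·**u**(*t*₀)⟩ by FFT; τ from a
  log-linear fit over the initial run with *C* > 0.05.  A non-decaying
  *C* yields a lower-bound flag; decorrelation within one frame an
  upper-bound flag.
- **Orientation**: the in-plane angle φ is measured from the first lateral
  axis, counterclockwise, in [0°, 360°); peaks are contiguous bin runs
  above 1.5× the uniform density.
- **Pair structure**: the 2D *g*(*r*) is normalized with the exact
  perimeter of the annulus inside the rectangular minimum-image cell (not
  2π*r*), so the density-weighted integral of *g* over the cell recovers
  *N* − 1 exactly for ideal gases — without this the corners beyond *L*/2
  bias the tail.
- **Layer occupancy / growth mode**: molecules are binned by
  ⌊(*z*\_com − *z*\_top)/thickness⌋ (supply a *z*\_top below the
  first-layer centers, e.g. half a layer spacing above the substrate
  surface).  With per-layer coverage = count × molecule footprint / area:
  *layer_by_layer* when every layer below the topmost populated one is
  ≥ 90 % covered; *stranski_krastanov* when upper layers populate over a
  first layer that is 30–90 % covered; *islands_3d* otherwise.  Both
  thresholds are configurable; the verdict is invariant under rigid *z*
  translation.
- **Dipole density**: μ\_z = Σᵢ qᵢzᵢ in e·Å, converted at 1 e·Å = 4.8032 D
  and divided by the lateral area in nm².  Exactly origin-independent for
  net-neutral regions; non-neutral selections are flagged as
  origin-dependent rather than silently reported.

## Synthetic generators — what they emulate, and what they do not

All generators are pure functions of (spec, seed).  They reproduce the
*statistical and geometric structure* each estimator assumes, not the
chemistry:

- Slabs are square-lattice planes with a sinusoidal corrugation of the
  outer planes — not a real molecular crystal surface cell.
- Admolecules are rigid flat disks (ring + center atom).  The analyses
  under test depend only on footprint, height, center of mass and
  orientation, which disks control exactly; nothing about real
  porphyrin conformations (peripheral-ring tilt, macrocycle bending) is
  represented.  Stacked mode fills complete grid layers with a per-layer
  lateral offset (leaning columns); cluster3d puts a partial compact first
  layer under a 3D mound.
- Walkers are Gaussian increments of per-axis variance 2*D*·d*t* plus a
  Bernoulli fixed-length jump admixture.  Observed long-jump behaviour on
  real surfaces has no agreed jump-length law, so length and probability
  are free parameters, defaults *D* = 0.088 Å²/ps (= 0.88×10⁻⁵ cm²/s, a
  realistic value for a small flat molecule on a smooth molecular surface)
  and 5 Å threshold-scale jumps.
- Rotors perform angle diffusion with per-step variance 2 d*t*/τ; for a 2D
  unit vector ⟨cos Δθ⟩ = exp(−σ²/2) gives exactly ⟨**u**(*t*)·**u**(0)⟩ =
  e^(−t/τ).  Default τ = 37 ps.
- *u*ₛ(*T*) tables use the same constrained rational form the fitter
  assumes, plus i.i.d. Gaussian noise (default scale 2 mJ/m², the
  uncertainty typical of slab-minus-bulk energy differences).  Recovery
  tests therefore check the estimator, not model misspecification.
- Water boxes are rigid 3-site molecules (0.9572 Å, 104.52°, SPC/E
  charges) placed without O–O overlap in a cube sized so mass/volume
  equals the requested density; 1000 molecules at 1 g/cm³ occupy
  *N·M*/(ρ*N*\_A) ≈ 2.99×10⁴ Å³.

Consequently, passing tests demonstrate that the estimators recover known
inputs under the stated statistical models at desk scale; they do not
validate force fields, sampling quality, or any property of real
cellulose–porphyrin interfaces.

## Problem sizes and defaults in the reproduction script

`scripts/acceptance.py` uses 1000-molecule water boxes; 500 random probe
fixtures for stepped-vs-analytic agreement; 24 seeds × (32…2048) points for
the Monte-Carlo convergence exponent (expected −0.5); 50 noisy tables for
Padé recovery; 4 × 50 000-step walkers for *D*; 300 000-frame rotors for τ;
10⁴ steps at jump probability 0.01 for jump counts.  These sizes put each
stochastic quantity within a few percent of its target while keeping the
full script under a minute on one CPU.

## Known limitations

- Rectangular cells only; no triclinic lateral periodicity.
- Spherical tips only; no tip compliance, no force curves, no real-AFM
  image simulation.
- The growth-mode verdict is a geometric classification of a single
  configuration; it does not track deposition kinetics.
- Two-point Arrhenius barriers inherit the full uncertainty of their two
  inputs; treat them as order-of-magnitude estimates.
- Binary trajectory formats (XTC/TRR/DCD) are not read; convert to
  multi-frame GRO/XYZ first.
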