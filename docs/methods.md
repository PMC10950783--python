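# Methods

`nanoturbine` models and analyses the rotation of a fluorophore-labelled
DNA bundle driven by a chiral DNA origami turbine docked in a solid-state
nanopore. This note records the models, the defaults and why they are
what they are, what the synthetic data do and do not emulate, and the
numerical choices that matter.

## Rotor motion model and synthetic localizations

The labelled bundle tip is treated as a point on a circle of radius
*R* (default 150 nm, half the 300 nm crossbar) about the pore axis. Its
angle follows driven rotational Brownian motion,

    dθ = ω_d dt + √(2 D_r) dW,

integrated by Euler–Maruyama at the camera frame interval
Δt = 1/frame_rate. Defaults are the standard acquisition: 200 frames/s,
8,000 frames (≈40 s), drift speeds |ω_d|/2π in the experimentally
observed 0.5–10 rev/s range and D_r in [0, 1] rad²/s. Each retained
frame yields one localization at

    center + R (cos θ, sin θ) + ε,   ε ~ N(0, σ²I),

with σ = 15 nm by default (sub-diffraction localization precision) and
independent per-frame detection with probability `detection_prob`. The
*reported* uncertainty of each record is drawn from a truncated Gaussian
(mean 15 nm, sd 5 nm, floor 1 nm) independently of the realized error,
as in real localization software.

Non-rotating negative controls are 2D Brownian walks with translational
coefficient D_t through the same noise/detection model. Two reference
settings are used in the studies: an *extent-matched* slow walker,
D_t = (300 nm)²/(4·40 s) ≈ 562 nm²/s, whose RMS excursion over the
acquisition equals the rotor footprint; and a *free* diffuser at
1 µm²/s, the realistic mobility of an undocked assembly.

Deliberately not modelled: point-spread-function rendering and spot
fitting (the generator emulates the output of upstream localization
software, not raw images), blinking/bleaching kinetics beyond the
Bernoulli detection, stage drift, multi-fluorophore tip substructure,
and intra-frame motion blur. At ≤10 rev/s the arc traversed within one
5 ms exposure is ≤18°, which in real data mildly inflates the effective
localization noise; tests passing on this generator therefore exercise
the analysis logic, not the robustness to these instrument effects.

Angle sign convention: positive angles are anticlockwise in the y-up
mathematical frame, which the package identifies with the view from the
cis side of the membrane. Camera-frame (y-down) tables can be flagged at
the CLI (`--y-down`), which mirrors the data and flips the reported
handedness; |ω| is unchanged.

## Rotation-analysis pipeline

1. **Quality filter** — keep records with reported uncertainty strictly
   below 50 nm.
2. **Density filter** — keep records with ≥ 15 *other* records within
   50 nm, pooled over all frames. This is what removes free-diffusing
   particles: a 1 µm²/s walker leaves its own 50 nm neighbourhood within
   a frame and never accumulates 15 revisits.
3. **Clustering** — DBSCAN with eps = 50 nm, min_samples = 15 (standard
   DBSCAN semantics, self included), clusters returned largest first.
4. **Circle fit** — algebraic Kåsa least squares on mean-centred
   coordinates: closed-form, deterministic, exact on noiseless circles,
   with radius bias ~σ²/R (≈1.5 nm here), negligible at this SNR. A
   geometric refinement pass was considered and rejected as unnecessary.
5. **Annulus validity test** — compare the point density in the ring
   R ± 1 nm (area 4πR·w) against the equal-area central disk of radius
   2√(R·w); valid iff the ring density is strictly higher (ties are
   invalid). Limitation, measured on synthetic ensembles: the test
   accepts essentially all driven rotors and rejects centrally peaked
   clouds, but an extent-matched *slow* walker realizes an arc-like
   cloud in roughly half of instances — the fitted circle then passes
   through the data while the centre disk is empty, and the test
   accepts it. Slow non-rotating contaminants are therefore not reliably
   removed by this rule alone (free diffusers are, by the density
   filter upstream).
6. **Cumulative angle** — atan2 about the fitted centre, consecutive
   differences wrapped to (−π, π] (assumes < half a turn between
   observations, also across short gaps), cumulative sum from zero.
   Gaps > 50 frames split the trajectory and the longest segment is
   kept. If contamination places two records in one frame, the record
   radially closest to the fitted circle wins.
7. **MSD estimate** — overlapping-pair mean of squared cumulative-angle
   differences at integer frame lags up to 25% of the trajectory
   duration (missing frames contribute no pairs).
8. **MSD fit** — least squares of MSD(t) = a t² + b t (+ c), a, b ≥ 0,
   giving ω_d = ±√a (sign from the net cumulative displacement — the
   MSD is blind to direction) and D_r = b/2.

Two estimator choices here are the package's own, both configurable:

- **Inverse-variance weighting** (on by default). The single-trajectory
  MSD variance grows with lag, var[MSD(τ_k)] ≈ MSD(τ_k)²·2k/n_k; an
  unweighted fit lets the noisy long-lag points dominate and the fitted
  D_r becomes statistically meaningless (measured rank correlation with
  truth ≈ 0.3 over synthetic ensembles, vs 0.98 weighted).
- **Constant offset term** (on by default). Localization noise adds a
  static floor 2(σ/R)² ≈ 0.02 rad² to the angular MSD at every lag;
  without a free constant this floor is misattributed to D_r. The
  two-parameter model (no offset) is available via
  `include_offset=False`.

  On data lying exactly in the model span the fit is exact to machine
  precision: the unweighted normal equations are solved first and kept
  whenever they reproduce the curve to 1e-12, and the non-negativity
  constraints are handled by exact active-set enumeration rather than an
  iterative bounded solver.

9. **Torque** — Γ = wall_correction · ξ_r · ω_d with the
   Tirado–García de la Torre rotational drag of a rod about its
   perpendicular mid-axis,

       ξ_r = π η L³ / [3 (ln p − 0.662 + 0.917/p − 0.050/p²)],  p = L/d,

   defaults η = 1 mPa·s, L = 300 nm, d = 7 nm. This bulk formula gives
   ≈ 0.57 pN·nm at 10 rev/s. The experimental torque scale (tens of
   pN·nm) implies a large near-wall drag enhancement for a crossbar
   rotating nanometres above a membrane; that enhancement is not
   modelled and must be supplied explicitly through `wall_correction`.
   The package makes no claim of reproducing the experimental torque
   magnitude.

## Continuum direction model

A turbine blade is idealized as a rigid cylindrical rod tilted by θ from
the pore axis in an axial field E_z, with anisotropic hydrodynamic
(h = M_h,⊥/M_h,∥) and electrophoretic (e = M_el,⊥/M_el,∥) mobility
ratios. Holding the rod at fixed height (axial constraint force, free in
x) gives the in-plane velocity

    v_x = [½ M_el,∥ E_z sin 2θ / (cos²θ + h sin²θ)] (h − e),

so sign(v_x) = sign(sin 2θ)·sign(h − e): the blade tilt sign (chirality)
and the sign of h − e jointly set the rotation direction, and since e
rises with ionic strength (0.38 at 4 mM → ≈1 at 2.6 M NaCl) while h
stays at ½ for a slender rod, raising the salt reverses the direction at
the e = h crossover. The same quantity is computed independently by a
3×3 tensor force balance (`oracle_velocity`), used in tests; agreement
is asserted at 1e-12 relative to the driving scale M_el,∥·|E_z|
(v_x itself crosses zero inside the domain, where a ratio of the two
evaluations is numerically ill-posed).

The blade-tilt sign is *identified* with the rod-model θ sign and the
direction labels with the cis view; this is a modelling identification
consistent with the synthetic generator's convention, not an observed
mapping.

`slender_rod_mobility_ratio(p)` evaluates h from the translational drag
coefficients with Tirado–García de la Torre end corrections,
h = (ln p + ν_⊥)/(2(ln p + ν_∥)). It decreases monotonically from ≈1
near p = 1 toward the slender-rod limit ½, but the convergence is
logarithmic (deviation ≈ 0.52/ln p): h is 0.546 at p = 10⁵ and within 1%
of ½ only for astronomically long rods. The constant ½ quoted for
slender rods is the asymptote, not a value attained at practical aspect
ratios.

`interp_e_ratio` interpolates e monotonically (PCHIP) in log ionic
strength through an anchor table, clamped outside the anchor range. The
default table holds only the two measured anchors (4 mM, 0.38) and
(2.6 M, 1.0); with those two points the implied e = h crossover falls at
≈14 mM, far below the experimentally observed ~0.5–1 M reversal window —
two anchors cannot pin the shape of e(I), so the package does not treat
the predicted crossover salt as quantitative. Richer user-supplied
anchor tables move `predict_reversal_salt` accordingly.

Blade angle from twist: one base pair advances the helix by 0.34 nm
axially while the blade edge at radius r moves r·twist azimuthally, so
angle = atan(r·twist[rad/bp]/rise). With the default r = 12.5 nm the
measured twist densities −1.1°/bp and +0.69°/bp give −35.2° and +23.9°
(printed values −36° and +24°). Neither the outer-edge radius (13.5 nm →
−37.3°) nor an edge-minus-helix-radius convention reproduces both
printed angles exactly; the radius entering the published calculation is
not stated, so r is configurable and the default follows the value that
matches both angles to within 2°.

## Voxel flux/force maps

Particle trajectories (flat id/frame/x/y/z/species/charge tables;
conversion from MD formats is upstream) are binned on a regular grid,
default 0.1 nm (≈1 Å) spacing, per-axis periodic flags off by default.

- **Concentration**: occupancy count / (voxel volume × number of
  distinct frames). Out-of-grid particles on non-periodic axes go to an
  overflow tally so that voxel-sum × volume + overflow/frames equals the
  mean particle count per frame exactly.
- **Flux**: centred finite differences v_k = (r_{k+1} − r_{k−1})/(2Δt)
  on contiguous frame triplets, assigned to the voxel containing the
  central position; voxel flux = velocity sum / (volume × central-frame
  count), i.e. mean velocity × local density. Track endpoints carry no
  centred difference and are skipped. Normalization is per frame (not
  per time-in-voxel); positions must be unwrapped — periodic grids wrap
  at binning time only, so wrap jumps never corrupt the differences.
- **Charge density**: voxelwise c_Na − c_Cl on congruent grids
  (elementary charges per volume).
- **Force map**: charge × field × voxel volume per voxel; optionally
  divided by the uniform water-oxygen density convention (33 nm⁻³ ×
  voxel volume) to give the force per water molecule.

## Study sizes and determinism

Every stochastic routine takes an explicit seed (numpy `default_rng` /
`SeedSequence` spawning, all derived seeds < 2³¹) and identical inputs
give bit-identical outputs. The standard ensembles are 100 rotors for
parameter recovery and 100 instances per class for validity
discrimination, each at the full 8,000-frame acquisition — large enough
that the measured rates (0.3% median speed error, 100% direction
accuracy, 0.99 D_r rank correlation, 100%/≈50%/100% for
rotor/slow-walker/free-diffuser decisions) are stable to a few percent
between seeds; the `analysis/` drivers run 30-instance versions of the
same studies.
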