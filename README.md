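# nanoturbine

Analysis tools for nanopore-driven DNA origami turbines: single-molecule
rotation tracking, synthetic localization data with ground truth, a
continuum model of the rotation direction and its salt-dependent
reversal, and voxel-binned solvent flux/force maps.

A chiral three-bladed DNA origami turbine docked into a solid-state
nanopore converts a transmembrane potential (applied voltage or salt
gradient) into sustained rotation of a 300 nm DNA crossbar, monitored by
localizing a fluorophore-labelled tip at 200 frames/s. This package
implements the computational side of such experiments for four
audiences: generating realistic synthetic localization tables with known
ground truth, recovering rotor kinematics from localization tables,
predicting the rotation direction from mobility anisotropies, and
post-processing particle trajectories into voxel maps.

## The core quantities

**Tracking.** Localizations are filtered (uncertainty < 50 nm; ≥ 15
neighbours within 50 nm), clustered per rotor (DBSCAN), fitted with a
circle (Kåsa), validated by comparing the point density in a ±1 nm
annulus around the fitted circle against an equal-area central disk, and
unwrapped into a cumulative angle θ(t). The mean-square angular
displacement is fitted to

    MSD(t) = ω_d² t² + 2 D_r t        (+ optional constant offset)

giving the signed drift speed ω_d (direction from the net displacement)
and the rotational diffusion coefficient D_r, and the torque follows
from slender-rod rotational drag, Γ = ξ_r ω_d.

**Direction model.** A blade is a rod tilted by θ from the pore axis;
with hydrodynamic and electrophoretic anisotropy ratios
h = M_h,⊥/M_h,∥ and e = M_el,⊥/M_el,∥ the in-plane blade velocity is

    v_x = [½ M_el,∥ E_z sin 2θ / (cos²θ + h sin²θ)] (h − e)

so the rotation direction is sign(sin 2θ)·sign(h − e): chirality sets
the sign of θ, and because e grows with ionic strength (≈0.38 at 4 mM to
≈1 at 2.6 M NaCl) while h stays at ½, the direction reverses at the
e = h crossover.

**Flux maps.** Trajectory tables are binned into ~1 Å voxels:
concentration, centred-finite-difference flux, net charge c_Na − c_Cl,
and solvent force = charge × field.

## Worked example

```bash
nanoturbine simulate --seed 5 --omega-rev 6.0 --d-r 0.3 --out /tmp/sim
nanoturbine analyze /tmp/sim.csv --out /tmp/ana
```

prints

```
wrote 8000 localizations from 1 emitters to /tmp/sim.csv
1 clusters analyzed, 1 valid rotors
```

and `/tmp/ana_results.csv` contains the recovered rotor:

```
id,center_x,center_y,radius_nm,valid,omega_rev_s,D_r,torque_pNnm,n_localizations,note
0,-0.2607...,-0.2230...,151.526...,True,6.01465...,0.28388...,0.34277...,8000,
```

i.e. the 6.0 rev/s anticlockwise drift is recovered to 0.2%, the 150 nm
rotation radius to 1%, D_r = 0.28 vs the true 0.3 rad²/s, and the bulk
rotational drag converts the speed into Γ ≈ 0.34 pN·nm. The continuum
model similarly:

```bash
nanoturbine model --theta 35 --ionic-strength 0.004 --blade-sign right
```

```
theta_deg = 35.0000
h = 0.5000
e = 0.3800
v_x = 0.067482  (units of M_el_par * E_z)
crossover_e = 0.5000
direction (right-handed, cis view) = clockwise
```

— a right-handed turbine at low salt (e = 0.38 < h = 0.5) rotates
clockwise viewed from the cis side; rerunning with `--ionic-strength
2.6` gives e = 1.0 and the reversed direction.

The numbered scripts under `analysis/` run the same machinery as a
narrative: `01_simulate_rotors.py` builds a three-rotor field of view
with non-rotating controls, `02_analyze_rotations.py` recovers the
manifest truth, `03_recovery_and_validity.py` runs ensemble
recovery/discrimination studies, `04_direction_model.py` tabulates the
continuum model and `05_flux_maps.py` produces voxel maps from a
synthetic ion-drift trajectory set; tables land in `results/`.

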