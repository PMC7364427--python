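# stereoloc

Geometry and noise analysis of stereotactic fiducial localizers.

Image-guided stereotactic neurosurgery (deep-brain stimulation, functional
lesioning, radiosurgery) relies on a localizer attached to the stereotactic
frame to map points from the 2-D (u, v) coordinate system of a CT/MRI slice
into the 3-D (x, y, z) frame coordinate system. `stereoloc` models the two
classical designs and quantifies how image noise in the measured fiducial
centres propagates into error in the reconstructed section height z:

* **N-localizer** — two vertical rods A, C and one diagonal rod B. With
  d_BC and d_AC the inter-fiducial distances in the image,

  z = z_C + (d_BC / d_AC) (z_A − z_C)

  The distance ratio is dimensionless, so no pixel-size calibration enters.

* **Sturm-Pastyr localizer** — a V of two diagonal rods meeting a vertical
  rod, each diagonal at υ = arctan(1/2) from the vertical. With d_AB and
  d_BC in millimetres,

  z = 4 d_AB d_BC / √((d_BC + d_AB)² + 4 (d_BC − d_AB)²)

  which reduces to z = 2 d_AB = 2 d_BC for a section parallel to the frame
  base. The result carries the units of the distances, so the image pixel
  size must be known and correct.

The Monte Carlo engine places the unperturbed fiducials for a section pose
(height z, tilt β), perturbs all six centre coordinates with i.i.d. uniform
noise on [−ε, +ε] mm, recomputes the distances, reconstructs ẑ, and
accumulates the RMS error √((1/n) Σ (z − ẑᵢ)²) and the maximum |z − ẑᵢ| per
cell. Sweep utilities tabulate these errors over z, β and ε grids and fit
the error-versus-noise scaling by ordinary least squares.

## Worked example

Reconstruct z from measured Sturm-Pastyr distances (mm):

```
$ stereoloc zcalc --localizer sp --dab 8.944 --dbc 14.907
19.999392
```

These are the exact forward distances of a section at z = 20 mm tilted by
β = υ = 26.565°, rounded to 3 decimals, so the reconstruction returns
20 mm to the rounding error.

Compare the two localizers at the pose typical of basal-ganglia targets
(a section 20 mm above the frame base, tilted 5°) under ±1 mm noise:

```
$ stereoloc simulate --localizer sp --z 20 --beta 5 --epsilon 1 --n 1048576 --seed 1
localizer,z_mm,beta_deg,epsilon_mm,n,seed,rms_mm,max_mm
sp,20,5,1,1048576,1,0.977464103,3.11493787
$ stereoloc simulate --localizer n --z 20 --beta 5 --epsilon 1 --n 1048576 --seed 1
localizer,z_mm,beta_deg,epsilon_mm,n,seed,rms_mm,max_mm
n,20,5,1,1048576,1,0.762549603,2.02144369
```

The Sturm-Pastyr localizer turns ±1 mm fiducial noise into 0.98 mm RMS
(worst case 3.1 mm) of z error, versus 0.76 mm RMS (worst case 2.0 mm) for
the N-localizer — the V-shaped geometry amplifies noise, and increasingly
so near its apex (small z) and at large tilt. Identical seed and arguments
reproduce these rows byte for byte.

Other subcommands: `forward` (unperturbed fiducial coordinates for a pose),
`sweep-z`, `sweep-beta`, `sweep-epsilon` (error tables over parameter
grids, CSV) and `fit` (OLS slope/intercept/Pearson-r of error vs noise).

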