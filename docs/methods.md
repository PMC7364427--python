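# Methods

## Geometric model

Both localizers are reduced to their cylindrical rod axes, and the
tomographic section is idealized as its infinitely thin central plane, so
every rod-section intersection is a point. Finite slice thickness, rod
diameter, and the fiducial-detection step that produces centre coordinates
from pixel data are outside the model; the inputs to every analysis are the
ideal centre points plus additive noise.

A section pose is (z, β): the height in mm at which the plane crosses the
axis of rod B, and the tilt in degrees of the plane relative to the frame
base. All public interfaces use degrees and millimetres; radians appear
only internally.

**N-localizer forward model.** With the two vertical rods a distance
`rod_spacing` apart and spanning heights `z_bottom`..`z_top` (defaults
0, 140, 140 mm — a common frame geometry, all three configurable), a
section at (z, β) meets the rods at in-plane distances stretched by
1/cos β. Placing fiducial C at the image origin and the triplet on the
u-axis gives C = (0, 0), B = (z/cos β, 0), A = (spacing/cos β, 0). Any
other rigid placement yields the same inter-fiducial distances, which are
all the inverse model uses.

**Sturm-Pastyr forward model.** With υ the manufactured angle between each
diagonal rod and the vertical rod (default arctan(1/2) = 26.565051°), the
law of sines in the two rod-plane triangles gives

    d_AB = z sin υ / sin(π/2 + β − υ)
    d_BC = z sin υ / sin(π/2 − β − υ)

and fiducials A = (−d_AB, 0), B = (0, 0), C = (d_BC, 0). d_BC diverges as
β → 90° − υ = 63.435°.

**Inverse models.** The N-localizer reconstruction is the linear
interpolation z = z_C + (d_BC/d_AC)(z_A − z_C); the cos β stretch cancels
in the ratio, so reconstruction is exact at any tilt and needs no pixel
size. The Sturm-Pastyr reconstruction is the closed-form
z = 4 d_AB d_BC / √((d_BC + d_AB)² + 4(d_BC − d_AB)²), an algebraic inverse
of the forward distances for υ = arctan(1/2); its output carries the units
of its inputs, so pixel-to-mm conversion is a documented caller
responsibility. Both forward→inverse round trips are exact to 1e-9
relative across the valid domain (property-tested).

**Domain limits.** Tilt is capped at 85° for the N-localizer (1/cos β
blow-up guard) and 60° for the Sturm-Pastyr localizer, strictly below the
63.435° singularity; out-of-domain poses raise errors rather than return
extrapolated values. `sturm_pastyr_z(0, 0)` returns 0: the apex of the V
is at z = 0 and the 0/0 limit along any approach ray is 0.

## Noise model and Monte Carlo engine

Measured fiducial centres are modelled as the ideal centres plus i.i.d.
uniform noise on [−ε, +ε] mm in each of the six coordinates (u and v of A,
B, C). Uniform rather than Gaussian noise reflects a bounded displacement
of the detected centre — at typical stereotactic fields of view
(250–360 mm over 512² pixels, i.e. 0.5–0.7 mm pixels), ε = 1 mm is a
conservative two-pixel bound, and ε ∈ {0.25, 0.5, 1, 2, 3} mm spans
sub-pixel to several-pixel displacement. The v coordinates are perturbed
even though the unperturbed fiducials lie on the u-axis: distances are
recomputed from full 2-D coordinates, and the transverse component is what
produces the mild super-linearity of the Sturm-Pastyr error at small z.

Each (localizer, z, β, ε) cell generates n perturbed triplets, recomputes
the distances by the Pythagorean formula, reconstructs ẑᵢ, and reports

    rms_error = √((1/n) Σ (z − ẑᵢ)²),   max_error = max |z − ẑᵢ|.

The reference cell size is n = 2²⁵ draws. Tests and the acceptance script
use n = 2²² for the error-versus-noise fits and n = 2²⁰ per grid cell for
the tilt-angle sweep: at these sizes the RMS estimates are stable to well
under 1%, while the maximum-error statistic — an extreme-value quantity —
sits a few percent below its 2²⁵-draw value, which is reflected in the
wider tolerance used for the max-error slope.

**Reproducibility.** Every cell draws from its own PCG64 substream keyed by
(master seed, localizer, z, β, ε quantized to 1e-6), so sweeps reproduce
bit-identically regardless of evaluation order or parallelization, and a
sweep row equals a standalone cell simulation. Iterations are streamed in
blocks (default 2²⁰) to bound memory; uniform variates are consumed
sequentially, so summaries are invariant to the block size. Per-block sums
of squares are combined with exact (fsum) summation to keep the RMS stable
at n = 2²⁵. A zero-noise cell short-circuits to exactly zero error — the
forward/inverse pair is an algebraic identity, and running the arithmetic
would report only ~1e-15 floating round-off.

## Error-surface analyses

Sweep utilities tabulate per-cell summaries over z, β and ε grids
(default study grids: z in 5 mm steps to 140 mm at β ∈ {0, 5, 10, 15, 20}°;
β in 1° steps to 60° at z ∈ {5, 10, 15, 20} mm; ε ∈ {0.25, 0.5, 1, 2, 3} mm
at z = 20 mm, β = 5°). Invalid cells are skipped with a logged warning so a
grid that brushes a domain limit does not abort. Error-versus-noise scaling
is fit by ordinary least squares *with* intercept (scipy.stats.linregress),
reporting slope, intercept and Pearson r; with-intercept is the
conventional reading of a "linear least-squares fit", and on the
N-localizer data dropping the intercept moves the slope by under 2%. Fits
on degenerate data (constant x or y) raise rather than return an undefined
correlation. The tilt of maximal RMS error is located on the evaluation
grid directly, ties broken toward the smaller angle.

The first-order cross-check used by the tests linearizes ẑ in the six
coordinates by central finite differences; each coordinate contributes
variance ε²/3, so rms ≈ ‖∇ẑ‖ ε/√3. For the N-localizer at z = 20 mm,
β = 5° this predicts an RMS-vs-ε slope of ≈ 0.762, matching the simulated
fit. The linearization is accurate to 3% only while the fiducial spacing
dominates the noise; for the Sturm-Pastyr localizer at z = 10 mm the
spacing is ~5 mm and the second-order transverse term already contributes
~3.5% at ε = 0.25 mm, so first-order checks are confined to cells with
z ≥ 20 mm for that localizer.

## Known limitations

* The noise model is additive, independent and identically uniform per
  coordinate; correlated noise, pixel-grid quantization, and
  intensity-dependent centroid error are not modelled.
* Real images add pixel-size miscalibration, which biases the Sturm-Pastyr
  reconstruction multiplicatively and the N-localizer not at all; this
  systematic channel is documented but not simulated.
* (x, y) reconstruction is omitted: both designs fix the in-plane rod
  positions, making that step trivial and noise-insensitive by comparison.
* Monte Carlo point estimates are reported without uncertainty bands; at
  the default n they are stable to the digits shown, but max_error remains
  an extreme-value statistic with slow convergence in n.
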