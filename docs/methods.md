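# Methods

`monomech` quantifies the mechanics of directed collective cell migration
from timelapse microscopy: cell kinematics by particle image velocimetry
(PIV), cell–substrate forces by Fourier-transform traction cytometry
(FTTC) on a finite-thickness gel, intercellular stresses by monolayer
stress microscopy (MSM), strain-energy efficiency metrics, and the
spatiotemporal post-processing readouts (kymographs, centre/edge zones,
directionality distributions). This note documents the models, the
numerical choices, and what the synthetic test bed does and does not
establish about real data.

## Coordinate and unit conventions

Arrays are image-convention `(row, col) = (y, x)`, origin at the top
left, y increasing downward. The migration axis is x. Distances are in
µm, tractions in Pa, velocities in µm/h, energies in J. Angles reported
to the user are measured from the +x axis with y pointing *up*
(mathematical convention), in `(-180°, 180°]` for vectors and
`[0°, 180°)` for principal orientations.

## Image registration and stitching

Timelapse frames are aligned to the cell-free reference bead image by the
integer translation maximizing the global normalized cross-correlation;
frames whose correlation peak falls below a threshold (default 0.1) are
flagged rather than silently passed. All frames and the reference are
then cropped to the common overlap. Only rigid translation is modelled —
the stage is fixed, and sub-pixel motion is the business of PIV.
Neighbouring tiles of a tiled acquisition are merged by searching the
nominal overlap band (10% by default) for the overlap width with the
highest correlation, then linearly blending intensities across the seam;
seam geometry is fixed from the first frame so the merged image geometry
is constant in time.

## PIV

Displacements are estimated per interrogation window (64 px for
phase-contrast cell velocity on consecutive frames, 32 px for bead
displacement of each frame against the reference, both at 0.5 overlap)
from the FFT cross-correlation peak of zero-mean windows, refined by a
three-point Gaussian fit (parabolic fallback when a neighbour is
non-positive).

Two details matter for accuracy:

* **Unbiased correlation normalization.** Window content is not
  periodic, so the circular correlation is damped by the autocorrelation
  of the window weighting. Left uncorrected, this tilts the log-domain
  peak fit and biases every estimate toward zero by roughly
  `sigma_c^2 / N` per pixel of displacement (`sigma_c` = correlation peak
  width, `N` = window size) — a 15–20% multiplicative underestimation at
  typical settings. Each window is tapered with a Tukey (alpha = 0.5)
  profile and the correlation divided by the taper's autocorrelation
  (floored at 0.05 of its peak); the taper also suppresses
  edge-discontinuity noise that otherwise wobbles the subpixel fit.
* **Multipass with window deformation.** `PIVConfig(passes=n)` repeats
  the interrogation after warping the second image by the previous
  pass's interpolated displacement field. The residual correlation peak
  then sits near zero lag, where the estimator is most accurate, and
  in-window displacement gradients — the dominant noise source in
  strongly sheared regions — are largely removed. The default is a
  single pass; bead displacement fields with multi-pixel amplitude
  benefit from `passes=2..3`.

Outliers are detected by a normalized-median test: a vector deviating
from its 8-neighbourhood median by more than `k * (MAD + 0.1 px)`
(k = 2 default) is flagged invalid and replaced by the local median. The
field is edge-repeat padded for this test; a one-sided neighbourhood
median is biased by the field's slope and falsely flags correct border
vectors. Flat (zero-variance) windows are flagged invalid, never NaN.

Measured on rendered bead images (see below): integer shifts are
recovered to ≤ 0.1 px, smooth subpixel fields (amplitude ≤ 4 px,
wavelength ≥ 8 windows) to ≤ 0.2 px RMS, at both standard window
settings.

## Elasticity of the gel: forward model and traction inversion

The gel is a laterally infinite linear elastic layer of thickness `h`
bonded to a rigid base (Young's modulus `E`, Poisson ratio `nu`;
`h = inf` selects the classical Boussinesq half-space). For a tangential
surface traction with zero normal surface stress, the in-plane surface
displacement in Fourier space is `u(k) = G(k) T(k)` with `G` diagonal in
the longitudinal/transverse basis of each wavevector:

    G_l(k) = 2(1-nu^2)/(E k) * 2[2s + c sinh 2s] / [4s^2 + c^2 + 1 + 2c cosh 2s]
    G_t(k) = 2(1+nu)/(E k)   * tanh(s),          s = k h,  c = 3 - 4 nu

Both were derived in closed form from the plane-strain (longitudinal)
and antiplane (transverse) boundary-value problems of the bonded layer
and reduce to the standard half-space FTTC factors `2(1-nu^2)/(Ek)` and
`2(1+nu)/(Ek)` as `h -> inf`; the expressions are finite at `nu = 1/2`,
so the incompressible gel needs no special casing. On the Nyquist
rows/columns of an even grid the sign of k is ambiguous, so the odd
cross term of the tensor is set to zero there; this keeps the operator
exactly real-to-real and exactly invertible.

**Forward solve** (`elastic.forward_displacement`): multiply the
traction transform by `G`, zero-padding the field 2x (configurable) to
suppress periodic wrap-around.

**Inversion** (`traction.fttc_invert`): per wavevector, apply
`g / (g^2 + lambda^2)` to each eigenvalue of `G` — plain inversion at
`lambda = 0`, Tikhonov damping otherwise. Invalid displacement vectors
are filled by linear/nearest interpolation first; the zero-wavevector
traction is set to zero (no-net-force convention). With `pad=1` on both
operations the inverse is the exact algebraic partner of the forward
operator (round trip < 1e-8 relative); with the default `pad=2` the
mean is subtracted and the field zero-padded before the FFT.

**Noise control** (`traction.denoise_displacement`): PIV noise is close
to white while the elastic displacement field of a collective is
spectrally concentrated at low wavenumber, and the inversion amplifies
noise in proportion to `k`. An optional Wiener-style shrinkage
multiplies each displacement mode by `max(0, 1 - N sigma^2/|u(k)|^2)`,
with the noise floor `sigma` estimated from the local detrended
residual of the measured field. On the synthetic benchmark below this
step lowers the masked relative RMS traction error from ~15–22% to ~7%;
it is off by default and purely a pre-filter — the inversion itself is
untouched.

## Monolayer stress microscopy

The monolayer is modelled as a thin elastic plate of height `h_m`
(default 5 µm) in equilibrium with the substrate reaction: with `T` the
cell-on-gel traction, the in-plane stress tensor satisfies
`h_m * d(sigma_ij)/dx_j = T_i` inside the collective mask with
stress-free boundary (`sigma . n = 0`) at the mask margin. Positive
recovered normal stress means intercellular tension — an inward-pulling
(contractile) collective is in tension, as the 1D oracle below makes
explicit. The balance is closed by linear-elastic compatibility with
Poisson ratio `poisson_m` (default 0.5, the standard MSM choice); the
sheet modulus cancels exactly, and the recovered stresses depend only
weakly on `poisson_m` (the 1D plateau not at all — it is statically
determinate). Because the paper never states its monolayer height, `h_m`
is a required, recorded parameter; `sigma * h_m` is the height-free line
tension.

Discretisation: bilinear Q4 plane-stress finite elements on the traction
grid, one element per grid cell whose four corners lie in the mask;
lumped nodal loads `-T a^2/4`; net force and torque are projected out of
the load (error if the imbalance exceeds 5% of the total load and
projection is disabled); rigid-body modes are removed by pinning three
well-separated degrees of freedom, which with a balanced load leaves the
stress field unaffected. Disconnected mask islands are solved
independently. Element stresses (mean of the 2x2 Gauss values) are
averaged to nodes. The reported equilibrium residual is the nodal force
imbalance of the solved system relative to the peak load — machine-level
for a successful solve.

Oracle: a strip loaded by uniform inward edge bands of width `w` has the
closed-form profile `sigma_xx(x) = (1/h_m) \int Tx dx` — linear ramps in
the bands and an interior plateau `T0 w / h_m`. The discrete solution
reproduces the profile of the trapezoid-interpolated load exactly; with
a 20-cell band the plateau agrees with the sharp-band formula within
2.5% (the half-cell taper of the lumped load is the entire difference).

Derived quantities follow the standard closed forms: principal stresses
`(sxx+syy)/2 ± sqrt(((sxx-syy)/2)^2 + sxy^2)` (validated against a
brute-force eigensolver), average normal stress ANS = (smax+smin)/2,
maximum shear stress MSS = (smax-smin)/2 — a `difference` mode
(smax-smin, the literal phrasing) is selectable and labelled. Stress
anisotropy defaults to the ellipse eccentricity
`e = sqrt(1 - smin^2/smax^2)` (0 = isotropic circle, 1 = degenerate
line, matching the verbal contract); the literal printed ratio form
`sqrt(smin^2/smax^2)` — which is 1, not 0, for an isotropic state — is
selectable for audit. Isotropic nodes have no defined orientation and
are flagged rather than given an arbitrary angle.

## Strain energy and migration efficiency

The work done by the collective on the gel is
`U = 1/2 sum_mask (T . u) dA` (J, with Pa, µm and µm^2 converted to SI),
its perfect-alignment bound `U* = 1/2 sum_mask |T||u| dA`, and the total
efficiency `eta = U/U*`: 1 for a perfectly aligned collective, 0 for
orthogonal fields. Although perfectly antagonistic fields give
`eta = -1`, and the metric is often quoted as lying in [0, 1], negative
values are physically meaningful (net antagonistic traction) and are
reported with a warning, never clamped. The local alignment
`cos(theta) = T.u/(|T||u|)` is the per-node analogue; nodes whose
traction or displacement magnitude falls below a noise floor (default:
the 5th percentile of the background outside the mask) carry no
meaningful direction and are masked from cos(theta) maps.

## Post-processing geometry

* **Temporal summary**: per timepoint, the median of the quantity inside
  the mask per position, then mean ± SEM across positions (SEM = 0 for a
  single position). Positions with an empty mask at a timepoint are
  excluded there and logged.
* **Zonal split**: the mask is eroded one pixel per iteration from the
  two x-margins (a 1x3 structuring element; isotropic erosion available
  for confined geometries) until the remaining central zone holds fewer
  than half of the original pixels; centre = remainder, edge =
  complement. The stopping rule guarantees the centre share lies within
  one erosion step below 50%; the step is `2 * n_rows` pixels, so the
  achievable closeness to an even split is a granularity property of the
  mask shape, not of the algorithm. On a solid 73-row, 8322-px rectangle
  the centre lands at 49.1%; on a 38-row rectangle of the same area, at
  49.8%.
* **Kymograph**: per timepoint and side, 1-px-wide vertical lines are
  peeled from the current mask edge toward the centre (a pixel belongs
  to the side whose edge is nearer); the cell value is the median of the
  quantity over the line's in-mask pixels, NaN where a line is empty.
  The distance axis is kept in absolute px from the current edge (not
  normalised per frame), and rows are stacked in time. `left`, `right`
  or the two-side average are selectable.
* **Directionality**: per-pixel angles of a vector field (sampled at
  pixel resolution inside the mask by linear interpolation) or of the
  maximum-principal-stress orientation, binned at 10° (fractions sum
  to 1). Vector angles span (-180°, 180°] and may be folded to
  [0°, 180°] by flipping negative angles; principal orientations are
  natively [0°, 180°). Zero-magnitude pixels are excluded and counted.
* **Early/late split**: 4 h by default, applied to zonal summaries and
  regression slopes. Relative spreading slopes are unweighted OLS fits
  of one condition's normalised area against the other's, fitted
  separately before and after the split.

## Synthetic test bed

`synthetic.make_contractile_strip_scene` builds the ground truth every
stage is tested against: a rectangular monolayer strip (default width
300 µm) pulling the gel inward along x, antisymmetric about the strip
midline so the net force is exactly zero, with the pull either confined
to raised-cosine edge bands (default, width 100 µm — the traction
penetration scale reported for expanding monolayers) or uniform across
each half-strip. The strip is capped in y with a smooth taper (the
laboratory strip is centimetres long; the cap keeps the scene compact so
periodic wrap-around cannot contaminate the finite field of view). The
displacement truth is the forward elastic solution of the traction
truth; bead images render Poisson-count Gaussian spots (pixel-integrated,
continuous subpixel centres, default sigma 0.8 px and 0.15 beads/µm²)
displaced by the truth interpolated at each bead, plus Gaussian photon
noise. Everything is seed-deterministic and bit-reproducible.

The accuracy benchmark scene uses a 0.5 µm pixel (within the reach of a
20x objective with optional zoom), a 12 kPa, 50-µm gel, 600 Pa peak
traction (≈ 5 px peak bead displacement) and 0.3 beads/µm² — i.e. a
well-prepared TFM experiment. Under those conditions the full chain
(render → PIV 32/0.5, 3 deformation passes → Wiener pre-filter → FTTC
at lambda = 0) recovers the traction truth to ~7% relative RMS inside
the mask, stable across seeds. What this does **not** establish:
performance on real phase-contrast texture (the generator makes no
attempt at cell appearance), on drifting or defocused acquisitions, on
gels with depth-dependent stiffness, or for traction features sharper
than ~3 interrogation windows, where the window transfer function, not
noise, limits recovery (with a 60 µm band the same chain measures
~12–15%).

The expanding-mask generator grows a strip mask linearly in width to a
target areal fold (e.g. 2.7x over 15 h) with optional seeded edge
roughness, monotone by construction — it emulates the *geometry* of
collective spreading for testing the kinematics readouts, not the
dynamics of real expansion.

## Problem sizes

Tests run the full chain on scenes of 160x256–512x1024 px with 1–2
frames; the complete suite takes ~15 s on one core, and the acceptance
script a few seconds. Fields scale as `O(n log n)` (FFT stages) and the
MSM solve as a sparse 2D factorization (~1 s per 20k-element mask).

## Known limitations

* Registration models integer translation only (no rotation, scale or
  illumination drift).
* Single-channel, 2D: no z-resolved (2.5D/3D) traction, no out-of-plane
  stress components.
* MSM assumes a uniform effective monolayer height and an elastic
  compatibility closure; recovered stresses are reported in Pa but scale
  as 1/h_m.
* The FTTC grid is the PIV grid; tractions are never computed at pixel
  resolution (fields are upsampled only for mask statistics).
* The Wiener pre-filter assumes spatially white PIV noise; strongly
  non-uniform noise (e.g. bead-free patches) violates that assumption.
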