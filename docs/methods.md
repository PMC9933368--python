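# Methods

## Input model

The analysis consumes an already-tracked representation of the left
ventricle: per cardiac frame, endocardial and epicardial control points
at 12 fixed rotational positions (30° apart) on each of 4 short-axis
slices — 48 control points per boundary per frame — plus the tracked
apex and base positions along the long axis. Pixel-level feature
tracking and interactive correction are out of scope; the package starts
where a tracker ends. Times are normalized cycle fractions with frame 0
defined as end-diastole; coordinates are millimetres.

`apex_z`/`base_z` are stored as projections of the apex/base onto the
longitudinal-axis direction. This makes them well defined for unaligned
data and exactly transportable under rigid transforms (they shift by the
translation component along the transformed axis).

## Geometry pipeline

**Alignment.** The axis is estimated as the line through the
end-diastolic endocardial centroids of the most apical and most basal
slices; a rigid transform takes it to +z with the end-diastolic apex at
z = 0. The in-plane rotation is fixed by minimizing the circular-mean
offset between each control point's azimuth and its angle label, which
anchors θ = 0 at the anterior reference and makes the whole downstream
analysis invariant to any global rigid motion of the input (verified to
< 1e−6 strain-% numerically). Coincident slice centroids are rejected as
non-orientable.

**Canonical slices.** Each frame is resampled to planes at 25/50/75/100 %
of that frame's apex-to-base distance (through-plane compensation:
the planes follow the moving base). Point coordinates are interpolated
in z — cubic through ≥ 4 slices, linear otherwise; slices sharing a z
position are averaged first. Planes may fall outside the tracked stack
by at most 2 % of the LV length (configurable): the 100 % plane sits at
the valve level, which trackers often cover only marginally.

**Dynamic mesh.** Interpolation is separable: a periodic cubic spline
around each contour (through the 12 control angles), a not-a-knot cubic
spline across the 4 slice levels, and a periodic cubic spline over the
cycle through the tracked frames. Both surfaces are sampled on a uniform
(T × Θ × Z) grid, 60×60×60 by default; the z grid spans the tracked
slice-fraction range (0.25–1.00), apex → base. The mesh object retains
its control data, so the spline surface can be evaluated exactly at the
control locations — the interpolation property (deviation ≈ 1e−14 mm) is
tested rather than assumed. Self-intersecting control polygons are
rejected up front (shapely simplicity test).

## Strain measures

All strains are percent, referenced to end-diastole, and exactly zero at
t = 0 by construction (the reference is computed by the same code path).

- **Ecc** uses the Green–Lagrange form on the slice circumference; the
  circumference is the arc length of the closed θ-spline, measured by
  dense resampling (12 points per spline interval; relative error
  ~1e−6, and the error cancels in the C/C_D ratio for affine
  deformations).
- **Ell** uses the engineering form on the apex-to-base meridian arc
  length at fixed θ, same dense-sampling approach in z.
- **Err** is the engineering strain of the *in-plane* (short-axis
  projected) endo→epi distance at matching (z, θ) grid indices — the
  measure is defined per short-axis slice, so the projection is
  deliberate. End-diastolic thickness below 0.5 mm is treated as a
  tracking fault.
- **Ea** is the relative area change of the endocardial quad patch
  between adjacent slices and rotations (θ wraps), each quad split into
  two triangles along a fixed diagonal. Patches are indexed by their
  lower slice index; the Ea grid therefore has Z−1 rows, and per-node
  region assignment uses that lower index.

Ecc and Ell default to the endocardium (Ea is endocardial by definition;
using one boundary keeps the four measures mutually consistent); the
epicardium is selectable via `boundary="epi"`.

## Curves, metrics, regions

Region curves are unweighted means over the selected nodes at each time
point. Ecc/Err/Ea localize by slice level (equal thirds of the z grid:
apical/mid/basal), Ell by 60° wall sector (anterior at θ = 0, then
anterior septum, posterior septum, posterior, posterior free wall,
anterior free wall counterclockwise). AHA-17: basal 1–6 and mid 7–12
follow the sector order, the apical level splits into four 90° segments
13–16 anchored at θ = 0, and the apical cap (most apical 5 % of the z
grid, configurable) is segment 17. The partition property (every node in
exactly one segment, all 17 nonempty at the default grid) is tested by
enumeration.

Metric extraction per curve:

- **peak strain** — signed extremum of largest magnitude (first frame on
  ties; a flat curve reports peak 0 with zero rates);
- **systolic strain rate** — least-squares slope from frame 0 to the
  peak frame;
- **early-diastolic strain rate** — steepest slope of opposite sign to
  the peak over a 5-frame moving window after the peak and within the
  first three quarters of the cycle;
- **late-diastolic strain rate** — least-squares slope over the final
  quarter.

Rates are % per frame with one frame defined as 1/60 cycle regardless of
the curve's sampling; the unit is recorded in output metadata. No
smoothing is applied before slope fitting — the temporal spline
resampling of the mesh is the only filter. The diastolic windows are
package definitions (no community standard exists for slope windows on
normalized cycles); they are deterministic and documented rather than
tuned. Global metrics average the regional metrics (region-mean); for
the nodal fields a node-mean-at-peak variant averages all nodes at the
time the all-node mean curve peaks (the convention used for global Ea).

Note a property of least-squares slopes worth knowing when comparing
rates across tools: for a smooth S-shaped ramp the fitted slope is ≈1.2×
the endpoint mean derivative. The package's rate is the fitted slope;
tests validate it against an independently fitted slope of the
closed-form trajectory, and the window rules themselves against
constructed piecewise-linear curves where the answer is exact.

## Phantom

The validation phantom is a truncated-ellipsoid LV:

| parameter | default | meaning |
|---|---|---|
| endo base radius | 25 mm | endocardial radius at the base |
| wall thickness | 8 mm | uniform at end-diastole |
| LV length | 80 mm | apex to base |
| pole extension | 0.25 | ellipsoid pole sits 25 % of the length below the tracked apex |
| λc at ES | 0.85 | circumferential stretch at end-systole |
| λl at ES | 0.95 | longitudinal stretch at end-systole |
| t_ES | 0.35 | end-systolic cycle fraction |
| relaxation end | 0.75 | strain returns to 0; diastasis after |
| frames | 20 | tracked frames per cycle (clinical cine: 20–25) |

The temporal profile is a pair of cosine ramps (C¹, periodic, analytic
derivative). Kinematics: endocardial radii scale by the local
circumferential stretch; longitudinal positions scale affinely by λl
about the apex; the epicardial radius solves per-column wall-volume
conservation, `r_epi² = r_endo² + (r_epi,ED² − r_endo,ED²)/λl`, giving
closed-form radial thickening. Hypokinesia multiplies the contraction
amplitude: λ̃c = 1 − d(level, sector)·(1 − λc), with the default disease
map d = 0.5 in the basal free-wall sectors. Jitter is isotropic Gaussian
on the control points only, seeded (`numpy` Generator); identical
config + seed reproduces byte-identical output.

Closed forms: Ecc = 50(λ̃c² − 1) is exact; Ell = (λl − 1)·100 and
Ea = (λ̃c·λl − 1)·100 are exact on a cylindrical wall and hold to ≲0.1
strain-% on the default taper (the affine z-scaling does not exactly
scale meridian arc length where the wall slopes; the pole-extension
default keeps the tracked span mild). The measured global peaks at the
default grid are −13.875 / −5.09 / −19.33 % against targets −13.875 /
−5 / −19.25 %. Err closed forms are checked against an independent
brentq root-finding of the conservation equation.

What the phantom does *not* emulate: MR contrast and noise physics,
trabeculation, realistic fiber-driven torsion (no twist), breathing
artifacts, or inter-slice misregistration. Passing phantom tests
demonstrates the geometry/strain/statistics machinery is correct, not
that any tracker's output on real images is accurate.

### Synthetic cohorts

`simulate_cohort` draws per-subject geometry and kinematics
(radius ~ N(25, 2) mm, length ~ N(80, 5) mm, thickness ~ N(8, 0.7) mm,
λc,ES ~ N(0.85, 0.02), λl,ES ~ N(0.95, 0.015)), applies 0.5 mm jitter,
and runs the full pipeline per subject. Diseased subjects carry the
basal free-wall deficit (d = 0.5) and a delayed end-systole
(t_ES ~ N(0.42, 0.02) vs N(0.35, 0.02)) emulating slowed contraction
kinetics; the kinetic component is what lets strain *rate* carry
information beyond peak strain, matching the physiology the method
targets. At 25 vs 25 subjects the basal Ea strain-rate AUC lands around
0.94–0.99 and apical AUCs near 0.5.

## Statistics

- Normality gate: Anderson–Darling with estimated parameters; the
  p-value uses the Stephens small-sample correction
  A*² = A²(1 + 0.75/n + 2.25/n²) and the D'Agostino piecewise
  approximation (the test agrees with scipy's 5 % critical value by
  construction). Applied per group; n < 8 or either group non-normal
  routes to Mann–Whitney, otherwise Welch's t (no equal-variance
  assumption).
- AUC is the Mann–Whitney U statistic / (n₁n₂), ties counted 0.5 —
  exactly concordant-pair counting (property-tested). Metrics whose
  healthy sign is positive (Err) are negated first so a larger score
  always means more diseased; negative-signed metrics pass through, so
  reported AUCs are not forced above 0.5.
- AUC CI: Wilson score interval with effective sample size
  n_eff = A(1−A)/Var_HM from the Hanley–McNeil variance (fallback n₁n₂
  when the variance is 0 at perfect separation). This is a
  binomial-style interval in the spirit of the Wilson/Brown hybrid used
  by common GraphPad workflows, whose exact formula is not published;
  the choice is documented here and in the code.
- Spearman's rho with average ranks, large-sample p, Bonferroni
  `min(1, m·p)` over the full metric × covariate family; incomplete
  pairs dropped pairwise.
- Multi-group: one-way ANOVA + Tukey HSD (scipy); at k = 2 the adjusted
  p equals the ANOVA p (tested to 1e−9).

## Numerical choices and limitations

- Arc lengths by dense polyline sampling of cubic splines (12× the grid
  density): refinement changes circumference/meridian length by < 0.1 %
  on smooth shapes, tested.
- Grid-size defaults (60×60×60, 20 tracked frames, 10-phantom noise
  averages, 25+25 cohorts, 1000 AUC trials) are the package's standard
  problem sizes; they keep a full validation run in tens of seconds
  while leaving all tolerances comfortably met.
- Ties: peak on first extremal frame; duplicate z slices averaged;
  θ normalized mod 360°.
- Degenerate inputs raise typed errors (`ContourError`, `GeometryError`,
  `StrainError`, `StatsError`) rather than propagating NaNs.
- The basal (100 %) plane sits at the valve level where real contours
  are least reliable; the phantom does not model this, and the 2 %
  extrapolation tolerance is the only guard.
- Strain-rate magnitudes depend on the % -per-1/60-cycle-frame unit
  convention; compare across tools only after unit conversion.
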