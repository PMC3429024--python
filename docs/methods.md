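# Methods

## The release cascade model

The intracellular model tracks four species as dimensionless fractions of
conserved pools: activated G-protein (GPa), cAMP, activated PKA (PKAa) and
activated CFTR (CFTRa). Hemoglobin desaturation enters phenomenologically:
the G-protein activation rate is proportional to tHb^α with tHb = 1 − sO₂.
How desaturation mechanically activates Gi is not modeled, nor is the
pannexin-1 gating step beyond proportionality of ATP flux to CFTRa; shear-
induced and receptor-mediated release pathways are out of scope.

PKAa feeds back on cAMP twice: it divides the adenylyl-cyclase production
term, 1/(1 + k_cAMPi·PKAa), and it multiplies the Michaelis–Menten PDE3
degradation term, v₀·PDE3_rel·PKAa·cAMP/(K_PDE3 + cAMP). Both feedbacks are
required: with the production-side feedback removed, the cAMP peak shifts
from ~50 ms to ~61 ms and the calibrated dose–response moves away from the
measured values, so the two-feedback form is used.

All rate constants are per-second. This is forced by the cascade's measured
~100 ms time scale: with the shipped constants the model produces a cAMP peak
at 50.3 ms and an ATP-flux peak at 156.9 ms after a 40 ms desaturation step
to 15.7% sO₂, and the flux falls below 1% of its peak 0.94 s after the
stimulus ends. AC_base = 0 encodes the assumption that fully saturated
erythrocytes release no ATP through this pathway.

### Numerical integration

`solve_ivp` with LSODA (stiffness-switching; the CFTR equation with β = 6.3
is sharply nonlinear), rtol 1e-8, atol 1e-12, restarted at every stimulus
discontinuity so step edges are not smoothed. The integrator carries two
quadrature states — cumulative ATP release and cumulative cAMP — so that
integrated quantities inherit the ODE tolerance rather than a sampling-grid
error. Output is sampled at 0.1 ms and peaks are refined by a local quadratic
fit (well under 1 ms precision). Halving or relaxing tolerances (rtol 5e-9 to
1e-6) moves total release by far less than 0.1%.

The integration window for "total release" runs from the stimulus onset until
the flux has effectively stopped (first fall below 10⁻⁶ of its peak, after
the peak), or the trajectory end. The trajectory sampler clips pool overshoot
at integrator-tolerance level back into [0, pool].

### Calibration and scenarios

The model computes relative activations of an average pathway copy, so its
integrated flux is in arbitrary units. A single anchor fixes the scale:
11.8 nmol ATP per 4×10⁸ erythrocytes for a 40 ms pulse to 15.7% sO₂. All
dose–response values are reported on that scale. A monotone model anchored at
11.8 cannot also pass exactly through the measured 13.1 at 21.6% sO₂; the
model yields 10.7 there (within the measurement spread). At the insulin
condition (PDE3_rel = 1.87, 20.9% sO₂) the model yields 3.36 against a
measured 2.77; the value is insensitive to the integration window and
tolerances.

Scenario conventions: a Gi deficit scales GP_total (type 2 diabetes: ×0.6,
predicting a 59% release decrease at 15.7% sO₂); the PDE3 rescue is a
bracketed Brent search over PDE3_rel for the activity restoring baseline
release (≈0.60 for the 40% deficit); the insulin scan reports calibrated
release and time-integrated cAMP versus PDE3_rel, both strictly decreasing.

## Network transport

The transport model needs only S(z) per segment, so the full 3D blood–tissue
diffusion problem is replaced by a 1D convective O₂ balance: total tissue
consumption (rate × bounding volume) is apportioned to segments by lateral
surface area, making S piecewise linear along each segment — consistent with
the nearly linear saturation decline seen in resting muscle capillaries.
Erythrocyte-flux-weighted mixing at converging nodes conserves O₂ exactly
(verified to machine precision on generated networks). Prescribed profiles
(per-segment tables, or linear in the arterio-venous coordinate) can be used
instead. A segment whose erythrocyte flux cannot carry its consumption share
raises an infeasibility error naming the segment.

The plasma ATP equation is marched in time from [ATP] = 0 by a first-order
explicit upwind finite-volume scheme, with concentrations at converging
junctions mixed by plasma flow. The march is genuinely time-dependent;
steady state (largest local d[ATP]/dt below 10⁻⁶ of the characteristic
release or inflow rate) is the default stopping condition. The scheme is
positivity-preserving under the enforced CFL bound
dt ≤ 0.9·min(Δz(1−H_T)/(|u|(1−H_D))) and its discrete mass balance
telescopes exactly: at steady state the per-segment and whole-network budgets
(plasma inflow + release − degradation − outflow) close to solver tolerance,
far inside the 0.5% requirement. Counter-current segments need no special
handling — each segment's grid is oriented along its own flow.

Grid convention: unknowns sit at the downstream face of each cell,
arclength (j+1)Δz from the flow inlet, which is where upwind finite volumes
are pointwise accurate. Against the closed-form single-capillary solution
[ATP](z) = (R·H_T·C₀(1−C₁S)/2k_d)·(1 − e^(−2k_d z / (R u (1−H_D)))) the
solver is within 0.26% at Δz = 2 µm, converging at first order. Segment
means use the trapezoid rule with the upstream end value linearly
extrapolated (second-order, exact for linear profiles). The network mean is
volume-weighted by default; a plain grid-point mean is provided for
comparison.

Units: C₀ (mol s⁻¹ cm⁻³) and k_d (cm/s) are kept in cgs as conventionally
given; lengths in µm and velocities in mm/s are converted internally;
concentrations are reported in µM (1 µM = 10⁻⁹ mol/cm³). With the default
(1 − C₁·S) release factor no clamping is needed for S ≤ 1 (C₁ = 0.891); a
parameter set that makes it negative triggers a warning and the solver floors
concentrations at zero (uptake stops when ATP is exhausted).

σ_dilation sums segment-mean [ATP] in mol/cm³ attenuated by exp(−(L−zᵢ)/λ),
with zᵢ the segment midpoint projected on the arterio-venous axis and L the
network span. With λ = 1 cm ≫ L ≈ 350 µm the attenuation is under 4%, so the
midpoint convention is numerically immaterial; it is nonetheless fixed and
recorded in the `DilationSignal.convention` tag. Because the steady equation
is linear, halving C₀ with zero inlet ATP halves mean [ATP] and σ_dilation
exactly, on any geometry — this is the geometry-independent insulin
prediction. With a 0.25 µM inlet concentration the decrease lies strictly
between 0 and 50% (superposition of the inlet-driven and release-driven
solutions), and near the inlet [ATP] first falls while wall degradation
exceeds local release. σ_dilation is reported only; arterioles are not
modeled, so it never feeds back on diameters, and velocities and hematocrits
are inputs (no two-phase flow computation).

## Synthetic networks

The generator emulates the stated statistics of a reconstructed rat extensor
digitorum longus (EDL) capillary network — 208 cylindrical segments in an
84 × 169 × 342 µm domain, 63% mean entrance saturation, 1.5×10⁻⁴ ml O₂/ml/s
consumption, at least one counter-current segment — whose measured data are
not redistributable. The 208 segments are read as short discretization
cylinders along 13 roughly parallel flow paths (~23 µm per cylinder), since
a reconstructed network of that extent contains far fewer than 208 distinct
capillaries.

Topology is a layered directed acyclic mesh from the inlet face (z = 0) to
the outlet face (z = L): 13 paths × 15 columns plus 13 diagonal cross-links
that create diverging/converging junctions; counter-current flow is produced
by swapping the axial order of two interior nodes on one path. Velocities
(0.30 ± 0.10 mm/s), radii (2.5 ± 0.3 µm) and discharge hematocrits
(0.15 ± 0.04) are drawn from truncated normals — literature-typical resting
rat-EDL values standing in for the unpublished measured distributions — and
then corrected to exact junction conservation by alternating projection
between the conservation subspace and a velocity-floor box (0.05 mm/s). A
plain least-squares projection is not enough: cross-link flows carry the
difference of independent path draws (mean zero) and are systematically
driven negative. Blood and erythrocyte flows are conserved independently, so
plasma flow is conserved too; tube hematocrit follows from discharge
hematocrit through the Pries et al. Fahraeus relation. Each draw is accepted
only if the resulting network can carry the default O₂ consumption; draws
are retried (bounded) otherwise. Identical spec + seed reproduce identical
networks byte-for-byte.

What passing tests on these networks do show: conservation, linearity,
positivity, junction mixing, scaling and signal-summary behaviour of the
transport solver, on geometry with realistic statistics. What they do not
show: agreement with the absolute published mean [ATP] (0.076 µM), which
depends on the specific reconstructed geometry, hemodynamics and 3D-computed
saturation field; the synthetic default yields ~0.04 µM with a prescribed
63→17% linear profile. All geometry-independent results (the exact 50%
scaling, peak times, dose–response) are unaffected.

## Problem sizes and defaults

Pathway runs integrate 2 s of dynamics at 0.1 ms output resolution (~0.1 s
wall time each). Network solves default to Δz = 2 µm (≈2700 unknowns on the
208-segment fixture) and converge in well under a second; the full test
suite runs in seconds. Tunable parameters worth knowing: `pde3_rel`
(relative PDE3 activity, 1 at baseline, 1.87 under ~1 nM insulin),
`gp_total` (Gi pool, 0.6 in type 2 diabetes), `release_scale` (multiplies
C₀; 0.5 under insulin), `atp_in` (inlet plasma ATP, 0 or 0.25 µM), λ
(conduction attenuation length, 1 cm, experimentally 0.15–1.6 cm).

## Known limitations

The cascade constants are mostly not directly measured; they encode the
measured time scale and dose–response, so predictions far from those
conditions are extrapolations. The lumen is treated as well mixed radially;
if near-wall ATP matters more than the mean, endothelial activation would
differ. The 1D O₂ balance ignores diffusive interaction between capillaries,
which in dense networks redistributes consumption away from low-flow
segments. Arteriolar/venular compartments, diameter regulation, myoglobin,
and intravascular resistance are out of scope.
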