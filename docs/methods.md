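# Methods

## Scope and model

`pahemo` reproduces, at desk scale, a patient-specific PA hemodynamics
analysis for repaired tetralogy of Fallot: geometry metrics on vessel
centerlines, pulsatile inlet/outlet boundary conditions, wall-shear
fields, the taWSS/OSI family of focal metrics, and the downstream
association of those metrics with RV remodeling and PVR-free survival.
The 3D finite-element Navier–Stokes solve of the clinical workflow is
out of scope; in its place sits an analytic, locally-cylindrical engine
(below) that is exactly verifiable against closed forms, plus an import
path for externally computed WSS fields so real CFD output can be
post-processed through the identical metric code.

## Geometry and centerlines

Tubes are built around parametric centerlines with parallel-transport
(twist-minimizing) frames; every surface vertex lies exactly at the
prescribed local radius from its centerline station, which gives the
test suite a machine-precision construction identity. A tube whose
radius exceeds the local curvature radius (κ·r ≥ 1) would self-intersect
and is rejected. The default bifurcation places a straight MPA trunk
(radius 1.5 cm, length 4 cm) and two circular-arc branches that meet it
at a junction point: an LPA that is narrower (0.8 cm) and more tightly
curved (0.9 cm⁻¹) than the RPA (1.0 cm, 0.6 cm⁻¹). These defaults encode
the cohort-typical post-repair anatomy — LPA curvature and WSS above RPA
above MPA — and are the fixed study conditions for the ordering tests.
The three tube meshes are concatenated; the junction is shared by
construction but not re-meshed into a watertight union, which is
adequate for labeling and the per-point shear model and is the main
geometric simplification of the package.

Curvature is κ = |c′×c″|/|c′|³ with derivatives taken analytically from
a per-coordinate cubic spline fitted against arclength after resampling
at 0.1 cm. The spline's smoothing parameter defaults to 0 (an
interpolating spline, the limiting member of the smoothing-spline
family): the synthetic centerlines are noise-free, and any nonzero
smoothing biases the curvature of tightly curved arcs; for noisy
centerlines the parameter is exposed. The reported mean excludes the two
endpoints, where spline derivatives are unreliable. Verified accuracy:
circle and helix curvature within 1% at the 0.1 cm step for radii
≥ 1 cm. Tortuosity Χ = L/D − 1 uses the polyline arclength and the
endpoint chord; closed loops (D → 0) are an error rather than an
infinity. Branch metrics are computed on inlet→branch-outlet paths
(MPA + branch concatenated).

Branch splitting assigns each wall point by centerline proximity. When
per-branch lumen radii are available (they accompany any centerline
extraction, and the synthetic generator knows them exactly) the
assignment minimizes |dist(point, centerline) − radius| — the
closest-tube-surface criterion, which resolves the junction region
correctly and recovers the construction labels exactly on the default
geometry. Without radii the fallback is plain nearest-centerline
distance after trimming the branch centerlines back to where they
separate by more than one junction radius. Ties break deterministically
in MPA < LPA < RPA order. Flow extensions extrude each open boundary
loop along its outward best-fit normal for 5× the local diameter;
extension points are labeled and always trimmed before any segment
metric.

## Boundary conditions

All internal units are CGS (cm, s, g, dynes); mL and beats/min convert
at the interface. The steady inflow is stroke volume × heart rate, with
stroke volume defined as the NET forward volume (forward minus
regurgitant) — the quantity RV stroke-volume indexing measures; the
generator exposes forward and net volumes separately so the alternative
convention is one argument away. The periodic inlet waveform is
represented by its first 10 Fourier harmonics (a least-squares
truncation computed by FFT); reconstruction takes the real part of the
one-sided series, so mode 0 is the mean flow. Outlets are parallel
resistances in indexed Wood units (iWU = WU × BSA, so the absolute
resistance is iWU/BSA; 1 WU = 1333.22/16.667 ≈ 80 dyn·s/cm⁵); the flow
fraction to each outlet is its share of total conductance. Defaults are
2 iWU per branch outlet (1 iWU total) and blood with ρ = 1.06 g/cm³,
μ = 0.04 g/(cm·s). Systole and diastole are located as the argmax/argmin
of inflow on the 20 discrete output timepoints, not on the continuous
waveform, because that is where the shear fields are saved; ties go to
the earliest index.

The synthetic waveform is a pair of raised-cosine lobes: a systolic
forward lobe (0.35 of the cycle) integrating to the forward volume and a
diastolic reverse lobe (0.45 of the cycle) integrating to RF × forward
volume, followed by diastasis. The shape is C¹, band-limited enough for
the 10-mode truncation, and hits a requested regurgitant fraction to
better than 1e-3 under trapezoidal quadrature at the default 200 samples.
The default RF of 0.40 is the severe-regurgitation regime typical of
this population.

## Wall-shear engine

Each wall point sees fully developed pipe flow in a tube whose radius is
the point's distance to the nearest sample of its branch centerline, and
whose flow is the inlet flow scaled by the branch's resistance-split
fraction (the trunk carries everything). The steady component is
Poiseuille, τ = 4μQ/(πR³). Each inlet harmonic Qₙe^{inωt} adds the
flow-forced Womersley solution; writing Λ = i^{3/2}αₙ with Womersley
number αₙ = R√(nωρ/μ), the complex wall shear per unit flow is

    τₙ/Qₙ = −(μ/πR²)(Λ/R)·J₁(Λ)/J₀(Λ) / (1 − 2J₁(Λ)/(ΛJ₀(Λ))).

As α → 0 this reduces to the quasi-static Poiseuille shear of the
instantaneous flow (verified to <1%), and by linearity the cycle mean of
the pulsatile shear equals the Poiseuille shear of the mean flow
(verified to 1e-6). Above α = 100 the Bessel ratio J₁/J₀ is replaced by
its large-argument limit i to avoid overflow. Shear vectors point along
the local centerline tangent with the sign of the instantaneous flow —
the axisymmetric surrogate has no secondary flow, which is why junction
vortices, curvature-driven skewing and any 3D effects are outside this
model; the import path exists precisely so solver output can replace the
surrogate without touching the metric code. The engine emits the
periodic steady state directly at 20 uniform timepoints per cycle; the
transient 5-cycle/1e-4 s solver protocol (25,000 steady steps) is
retained as manifest metadata only.

## Metrics

For vector shear WSS(x, t) over a cycle of length T, sampled at the 20
uniform output timepoints with periodic trapezoidal quadrature (which on
uniform periodic samples reduces to mean × T and is spectrally accurate
for band-limited integrands):

- taWSS(x) = (1/T)∫|WSS| dt — the time average of the magnitude, the
  standard convention; the alternative |time-average of the vector| is
  exactly the information OSI's numerator carries, so nothing is lost.
- OSI(x) = ½(1 − |∫WSS dt| / ∫|WSS| dt), clipped to [0, 0.5]; a point
  with identically zero shear reports OSI 0 with a warning.
- systolic/diastolic WSS: |WSS| at the argmax/argmin-inflow timepoints.

Segment summaries report the area-weighted mean (per-vertex areas are
one third of incident triangle areas, so mesh refinement does not shift
the weighting) and the pointwise maximum; a percentile alternative to
the max is exposed to probe outlier sensitivity. Peaks are computed
after extension trimming. Empty regions are reported as missing, never
as zero.

## Synthetic cohorts and statistics

The cohort generator draws sex (59% female), age at first scan
(≈12 ± 5 y), inter-scan gap (≈3.5 ± 1 y), RV metrics around
cohort-typical anchors (RVEDVi 145, RVESVi 64.6, RVSVi 70.8 mL/m²,
RVEF 56.6%), pulmonary RF around 0.40, and hemodynamic predictors as
independent normals on their physiological scales. The linear outcome is
its anchor plus centered predictor effects plus Gaussian noise; event
times are exponential with hazard λ₀·exp(Σ log-hazard × centered
predictor), λ₀ set by a 1500-day baseline median; censoring is an
independent exponential calibrated so the expected censored fraction
matches the requested rate. A single integer seed drives everything
through `numpy.random.default_rng`, and generated artifacts carry a JSON
sidecar with the spec and generator identity. What this emulates is the
effect *structure* of a registry cohort, not its correlation structure:
predictors are independent by default, outcomes are Gaussian, hazards
are exactly proportional — so estimator-recovery tests validate the
fitting code, not the clinical robustness of any finding.

The primary stage is OLS of a follow-up RV metric on one baseline
predictor plus sex and both scan ages; patients with PVR between scans
are excluded with an audit entry. BH adjustment is applied per outcome
table by default (a global family is a config choice), implemented as
the textbook step-up and cross-checked against statsmodels in the tests.
The secondary stage is a Cox model of time to PVR on the predictor plus
sex and age at the baseline scan (lifelines), with optional per-SD
normalization of the predictor (a pure reparameterization: the
coefficient scales by the sample SD) and a rank-transformed Schoenfeld
residual test at α = 0.05 whose result is reported, never acted on.
ROC analysis labels subjects by event status at the median event time;
subjects censored before that median have unknown status and are
excluded rather than called event-free (configurable). The Youden cutoff
maximizes sensitivity + specificity over midpoints between adjacent
unique scores, in both orientations, ties resolving to the smallest
cutoff; it is cross-checked against exhaustive search. Kaplan–Meier
curves come from lifelines and are verified against a hand product-limit
computation.

## Problem sizes and numerical choices

Default meshes use 60 axial × 24 circumferential samples per tube
(≈4,300 wall points for a bifurcation); segment-averaged WSS moves by
less than 1% when both sampling rates are doubled, the desk-scale
analogue of a mesh-independence check. Cohort studies default to tens of
cases and the estimator-recovery tests use n = 500 patients with 100–200
replicates where distributional claims are made. Quadrature is
trapezoidal everywhere a waveform is integrated, with the periodic
closure sample appended. Degenerate inputs fail loudly: zero forward
flow, closed-loop centerlines, constant predictors, zero-event cohorts
and out-of-range timepoints all raise rather than return silent
defaults.

## Known limitations

The analytic engine has no junction mixing, secondary flow, or
non-Newtonian rheology, and the walls are rigid; absolute OSI levels are
therefore higher than a 3D solve would give for the same waveform
(regurgitant flow reverses everywhere at once in a 1D-in-radius model).
The concatenated junction is not watertight. The cohort generator's
independence assumptions understate real-world collinearity between
hemodynamic predictors. These are deliberate trade-offs for exact
verifiability; conclusions about real patients require the import path
plus real solver output.
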