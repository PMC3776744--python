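# Methods

`hypoperf` quantifies the MRI and histology read-outs used to
characterise chronic cerebral hypoperfusion after bilateral common
carotid artery occlusion (BCCAo) in rats: arteriogenesis of the
vertebrobasilar tree from time-of-flight (TOF) angiograms, ischemic
lesion volumes from T2 relaxometry, relative perfusion from dynamic
susceptibility contrast (DSC) bolus tracking, white/grey-matter
microstructure from voxel-based analysis (VBA) of diffusion tensor
indexes, vessel-wall remodeling from ring morphometry, and the
mixed-design statistics tying the longitudinal arms together.  Because
no animal data ship with the package, every pathway is validated on
synthetic phantoms whose ground truth comes from independent numerical
oracles (adaptive quadrature, root finding, closed forms, enumeration)
rather than from the analysis code itself.

## Phantoms and their ground truth

**Vessel volumes.** Tubes of constant radius are rasterised around
parametric centrelines (line, planar arc, helix, piecewise-linear); a
voxel is vessel if its centre lies within the tube radius of a 3x
supersampled polyline of the curve.  Arc length is computed by adaptive
quadrature of |dgamma/dt| and chord length as the Euclidean endpoint
distance; both are emitted as a sidecar table, never re-derived from
the image.  Metric-grade phantoms are rasterised isotropically at
0.137 mm, the in-plane resolution of the TOF protocol; the 0.39 mm
slice direction of the acquisition is too coarse to support
skeleton-metric validation of strongly out-of-plane curves and is used
only for registration/masking fixtures.

**Longitudinal cohorts.** Subject trajectories follow the study design:
seven timepoints (pre-occlusion, 2 h, 24 h, 10 d, 3, 7, 12 weeks),
occluded n = 6 vs sham n = 4.  Occluded vessel length and tortuosity
ramp from the 10-day timepoint to +20% / +25% at 12 weeks while sham
stays flat; each subject carries a lognormal scale (sd 5% of the base
value, between-subject anatomy) and each measurement a multiplicative
residual (sd 3%, scan-to-scan variability).  These levels were chosen
once as representative of longitudinal MR morphometry.  Each
subject-timepoint pair is rendered as a single-turn helix whose
parameters are solved exactly from the target (length, tortuosity):
pitch = L/(N*tau), coil radius = pitch*sqrt(tau^2-1)/(2*pi).  A single
turn keeps the coil radius well above the tube radius so the rendered
vessel never touches itself; multi-turn helices at short lengths
self-intersect and the skeleton shortcuts through the contact.

**Multi-echo series.** S(TE) = S0 exp(-TE/T2) on the 16-echo ladder
11-176 ms, with Gaussian or Rician noise (Rician = magnitude of the
complex signal with iid per-channel noise, the correct model for
magnitude MRI; it is the default for MR phantoms, Gaussian for optical
micrographs).  Phantom SNR follows the air-ROI convention used when
characterising magnitude images: SNR = S0 divided by the standard
deviation of the *background magnitude* noise, whose Rayleigh sd is
sqrt(2 - pi/2) ~ 0.655 of the per-channel sd.  This convention matters:
a Cramér–Rao computation for this echo ladder shows that with the
stricter SNR = S0/sigma reading, the best achievable median relative
T2 error at SNR 20 over T2 ~ U(20, 150) ms is itself ~5%, so no
estimator leaves headroom under that reading.

**DSC series.** Signal = baseline minus a gamma-variate dip
A*(x/alpha)^alpha * exp(alpha - x), x = (t - t0)/beta, normalised to
depth A at t0 + alpha*beta.  Phases default to the protocol's 750
baseline, 125 injection and 1350 recovery frames at 0.16 s (356 s in
total; the protocol's phase counts are followed rather than its
rounded total).  Ground-truth TTP is alpha*beta, FWHM comes from Brent
root finding on both flanks of the continuous curve and AUC from
adaptive quadrature.

**DTI cohorts.** Subject maps are a smooth synthetic template (not a
real atlas) plus white Gaussian subject fields (sd 0.03 FA units); the
planted effect (default FA -0.10) is added inside a known region mask
for the occluded group only.  FA is clipped to [0, 1] with the clip
count reported.

**Ring micrographs.** Annuli with circular or elliptic laminae; lamina
lengths are 2*pi*r or the elliptic-perimeter quadrature value, areas
pi*a*b; nuclei are disjoint disks rejection-sampled inside the media.
The morphometry stage of the study pipeline uses scaled-down rings
(tens of micrometres) rather than basilar-artery dimensions so the
images stay small; the estimators are scale-free.

What the phantoms deliberately do not model: real vascular trees and
anatomy, partial-volume and flow-related TOF contrast, arterial input
functions and recirculation, spatially correlated subject fields,
registration-scale anatomical variability, staining variability.
Passing tests therefore demonstrate correctness of the measurement
chain under known geometry and noise, not performance on animal data.

## T2 relaxometry

Three fitters share a vectorised implementation: (1) log-linear
weighted least squares on ln S with weights S^2, countering the
heteroscedasticity introduced by the log transform; (2) nonlinear least
squares on the raw signal via damped Gauss-Newton on (ln S0, R2),
initialised from (1); (3) a Rician expectation fit that matches the
full magnitude mean E[M | A, sigma] = sigma*sqrt(pi/2) L_{1/2}(-A^2 /
2 sigma^2), evaluated through exponentially scaled Bessel functions.
Plain least squares is biased wherever the decayed signal approaches
the noise floor (E[M] -> 0.655*sigma instead of A); the expectation fit
removes that bias and is the recommended method for noisy magnitude
data.  Voxels with fewer than two usable echoes are excluded;
non-decaying voxels (fitted R2 <= 0) are flagged and masked out.  An
optional guard drops echoes below twice the background sd.

Lesion delineation replaces manual tracing with an explicit rule:
T2 > baseline + margin (default +15 ms), restricted to the 20-150 ms
analysis range, kept as 6-connected components of at least 5 voxels.
A symmetric decreased-T2 rule exists for the delayed hypointense
lesions but is off by default since their volume was never the primary
read-out.  Lesion volume is exactly voxel count x voxel volume, equal
to the integral of per-slice areas times slice thickness.

## TOF angiography metrics

Coil-sensitivity bias is modelled as exp(p(x)) with p a cubic
polynomial fitted to the log intensity of the brightest voxels (vessels
share a common true intensity on TOF); the volume is divided by the
normalised field and rescaled to preserve its mean.  Brain masking is
Otsu thresholding, morphological closing and the largest 6-connected
component.  Affine registration maximises Mattes mutual information
(multi-resolution, full sampling) with an automatic correlation
fallback for tiny or low-contrast volumes, followed by a short
correlation polish stage: every registration in this pipeline is
same-modality, and MI's histogram discretisation blurs its optimum at
the 0.1-0.2 voxel scale, which the polish removes (identity recovered
to < 0.1 voxel, known translations to < 0.5 voxel).  Artery
segmentation is seeded hysteresis growing (include >= high connected to
a seed, extend through >= low, 26-connectivity), making the
"semi-automatic" step replayable from recorded seeds and thresholds.

Skeletonization is 3-D topology-preserving thinning; the skeleton is a
graph whose edges join 26-neighbour voxels weighted by physical
distance, with terminal spurs shorter than 3 voxels pruned.
`path_length` defaults to the raw polyline sum (exact on
lattice-aligned chains).  For metrology, `artery_metrics` uses a
smoothing-spline estimator: the voxel path is fitted by a cubic
smoothing spline allowed an RMS residual of 0.75 voxel (the lattice
jitter scale; larger residuals measurably flatten curvature at vessel
scale), integrated, and extended to the user-provided endpoint
landmarks by the tangent-projected gap (skeletons of capped tubes
retract by roughly the tube radius at open ends; projecting removes the
lateral snap component that would otherwise inflate straight-vessel
lengths).  Raw polyline sums overestimate oblique straight vessels by
up to ~15% on the lattice — enough to break the tortuosity = 1.00 check
for straight vessels — which is why the spline estimator is the
metric-grade default.  Tortuosity is arc/chord (straight = 1, grows
with winding), with the chord taken between the landmarks.  The
inverse ("minimum over true length") convention is available via
`paper_ratio=True`; the arc/chord default preserves the reported
directionality of tortuosity increasing after occlusion.  The MIP area
ratio is the maximum-intensity projection of a configurable crop along
the dorsoventral axis, thresholded and divided by the projected brain
area; threshold and crop have no canonical values and are explicit
parameters.

## DSC perfusion

The analysis inverts the T2*-weighted signal into enhancement
E(t) = S_baseline - S(t), so "maximum" corresponds to peak contrast
concentration (an option analyses raw signal maxima instead).  Arrival
is the first frame after injection start with E above the baseline mean
plus 3 sd, sustained 3 frames, refined by linear interpolation of the
threshold crossing; the peak is located on a 9-frame moving-averaged
curve (reflect-padded, used only for localisation) and refined by a
3-point parabola.  Max, AUC and FWHM are measured on the raw curve;
FWHM interpolates the half-maximum crossing linearly on both flanks;
AUC integrates trapezoidally from one frame before arrival (capturing
the rising edge) until E falls below 10% of the maximum, avoiding the
recirculation tail; relCBF = AUC/FWHM exactly.  No gamma-variate
fitting is performed in the analysis; the model lives only in the
phantom and its oracle.

Noiseless phantoms recover TTP within 0.5 frame and FWHM within 0.01
frame of the continuous oracle.  Under noise, however, the arrival rule
is systematically late: the gamma-variate onset grows as x^alpha, so a
detection threshold of 3 sigma is crossed at beta*g^{-1}(3 sigma / A) —
about 2.5-4.5 frames after t0 at 2% baseline noise, shrinking only with
the cube root of sigma, and linear back-extrapolation of the rise still
leaves 1-3 frames.  TTP under noise therefore carries a bias of a few
frames from the arrival reference, not from peak localisation (the
peak time itself stays within one frame).  One validation test asserts
the stricter one-frame bound for the full TTP under noise and is
expected to fail; it documents this limit rather than an implementation
defect.

## Voxel-based analysis

Cohort registration is affine (driven by the FA volume) plus a
pluggable nonlinear refinement; a demons-style displacement filter with
Gaussian field regularisation is provided.  Synthetic cohorts are
generated aligned, so VBA logic is validated independently of
registration quality, and the registration contract (translations
recovered within 0.5 voxel) is tested separately.  Smoothing uses the
protocol's kernel: Gaussian truncated to 3x3x3, sd 1 voxel,
renormalised to unit sum.

The voxelwise test is Mann-Whitney U, two-sided: for nA+nB <= 20 and
tie-free voxels the exact null distribution of U (dynamic-programme
counts) gives p = 2*min(P(U<=u), P(U>=u)) capped at 1; with ties or
larger samples a tie-corrected normal approximation with continuity
correction is used.  The map is signed by the group-median difference
(+1 where the first group is larger, matching the red/blue display
convention).  No multiplicity correction is applied by default,
matching the original voxelwise P < 0.05 reading; Benjamini-Hochberg is
available.  Consensus across templates keeps voxels significant with
the same sign in at least a fraction f of templates (default f = 1,
all) and then removes 26-connected clusters below 10 voxels; raising f
can only remove voxels.  Because the smoothing kernel spreads a
planted effect one voxel beyond its mask, false-positive rates on
phantoms are evaluated outside the kernel-dilated mask.  At the
n = 10 vs 10 design the exact test's achievable size at alpha = 0.05
is 0.0433 (the null distribution is discrete), and null-cohort flag
rates are checked against that value, not against 0.05.

## Ring morphometry and densitometry

Lamina lengths are measured as sub-pixel contours: the thresholded
media band is lightly Gaussian-smoothed (sigma 1 px) and its 0.5 level
set extracted by marching squares.  The smoothing step is essential —
contours of a raw binary mask run along pixel edges and overestimate a
circle's perimeter by several percent, which the form-factor
correction A = l^2/(4 pi) would square.  Traced circular rings at
>= 64 px diameter reproduce the analytic wall cross-sectional area
within 2%, improving with resolution.  The derived quantities follow
the standard wall-geometry identities: A = l^2/(4 pi) per lamina,
D = 2 sqrt(A/pi), CSA = A_e - A_i, WT = (D_e - D_i)/2, W/L = WT/D_i
(dimensionless; WT in micrometres is reported alongside and the two are
not interchangeable).  Fiber density is the percentage of pixels above
a fixed threshold; cell counts use size-gated connected components with
optional distance-transform watershed splitting of touching nuclei,
normalised to the 0.075 mm^2 counting field; fluorescence density is
summed intensity over mask area (a.u. per um^2).

## Statistics

The mixed (split-plot) ANOVA is computed from explicit sums of squares
so every stratum is verifiable by hand: between-subject variation
splits into group and subject(group) — the error stratum for the group
F — and within-subject variation into time, group x time and the
residual error stratum.  Unequal group sizes use the classical
weighted-means decomposition, exact when every subject is measured at
every timepoint; the implementation agrees with pingouin's mixed ANOVA
to 1e-9 on balanced and unbalanced designs, and SS conservation holds
to 1e-9 relative.  Effect size is classical eta squared,
SS_effect/SS_total (not partial).  Fisher LSD post-hocs compare group
means using the subject(group) stratum (collapsed over time) or, as
the follow-up to a significant interaction, per-timepoint one-way
comparisons on the cell data; both refuse to run without a significant
omnibus test unless overridden.  Greenhouse-Geisser-style sphericity
corrections are deliberately absent from the default output since the
original analyses report none.  The behavioural acquisition criterion
"nine correct in a block of ten" is noted as ambiguous under a binomial
reading (P(>=9 | 10, 0.5) = 11/1024 ~ 0.0107 vs P(=9) = 10/1024 ~
0.0098); the package takes no position and implements no behavioural
analysis.

## Pipeline and problem sizes

`run_study` executes the five stages on phantom inputs with seeds
spawned deterministically from the master seed; each stage is isolated,
failures are recorded in a JSON manifest and remaining stages still
run.  All tables are written with a fixed float format, so reruns with
the same configuration and seed are byte-identical.  The default study
sizes — 10 subjects x 7 timepoints of ~50^2x80-voxel angiography
volumes, 64x64x8 relaxometry, 2225-frame perfusion series on a small
slab, a 20x20x10 VBA cohort and per-subject ring images — complete in
well under a minute on one CPU; they are chosen as the smallest
geometries at which the estimators' documented accuracy holds, and all
scale up through the configuration.

## Known limitations

- Skeleton length accuracy is resolution-bound: at 0.137 mm isotropic
  the spline estimator is phase-robust to ~2-4% for strongly curved
  vessels; anisotropic slices (0.39 mm) are not supported for
  metric-grade curves.
- The VBA elastic stage is a contract with a default demons refinement,
  not a validated diffeomorphic registration; cross-template consensus
  on real data depends on registration quality that phantoms do not
  probe.
- Bolus arrival (and hence TTP) is biased late under noise for
  gradual-onset boluses, as analysed above.
- The exact Mann-Whitney path assumes tie-free data; heavily quantised
  maps fall back to the normal approximation voxelwise.
- Ring tracing requires a closed media band; fragmented rings are
  rejected rather than repaired.
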