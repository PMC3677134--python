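# Methods

`mpmrepro` implements the quantitative multi-parameter mapping (MPM)
estimation chain — R1, effective proton density (PD\*), magnetization transfer
saturation (MT) and R2\* from three multi-echo FLASH acquisitions — together
with the multi-centre reproducibility analysis built on it (inter-site and
intra-site coefficients of variation, inter-site bias, GM-probability
reproducibility, repeated-measures ANOVA and paired t-tests).  Because no raw
multi-site scans are available, the package also implements the forward
problem: a digital brain phantom and a scanner/session model that emulate a
five-volunteer, three-site study.

## Signal model

The three acquisitions are spoiled gradient-echo (FLASH) scans in steady
state.  Per repetition the simulator applies the event cycle
*MT saturation → excitation → relaxation*:

    m  = (1 − δ)(1 − E1) / (1 − (1 − δ) E1 cos α),   E1 = exp(−TR·R1)
    S  = A · sin α · m · exp(−TE·R2*)

with `A ∝ PD × receive sensitivity`, the local flip angle `α = f_T · α_nom`
(`f_T` the transmit field), and the applied saturation δ only in the
MT-weighted scan.  With δ = 0 this is the Ernst equation; a closed-form vs
fixed-point-iteration identity is enforced in the tests to 1e−10.
The intra-TR event order (saturation pulse immediately before excitation,
relaxation lumped into one interval) is a modelling choice; it is used
consistently by the forward model and, implicitly, by the estimation chain.

Protocol defaults: TR/α = 18.7 ms/20° (T1w) and 23.7 ms/6° (PDw, MTw); six
equidistant echoes 2.2–14.7 ms for T1w and MTw, eight echoes 2.2–19.7 ms for
PDw.  The first six echo times coincide across scans, so the R2\* decay factor
of the averaged images cancels in every ratio the estimators form.

### Transmit-field dependence of the applied MT saturation

The estimation side applies the semi-empirical correction
`MT_corr = MT_uncorr (1 − 0.4)/(1 − 0.4 f_T)`.  The forward law is defined as
its exact inverse, `δ_app = δ_true (1 − 0.4 f_T)/0.6`, so that the published
correction recovers the ground truth by construction; the physically motivated
quadratic-in-B1 alternative (`δ_app = δ_true f_T²`) is available as a config
option for robustness experiments.  The constant 0.4 is taken as exact.

### RF spoiling

The default forward model assumes ideal spoiling (Ernst closed form), and the
estimation-side spoiling correction defaults to the identity.  An isochromat
ensemble (256 isochromats, quadratic RF phase with the protocol's 50°
increment, uniform 2π gradient dephasing per TR, T2 = 70 ms) simulates
realistically imperfect spoiling; from it the package derives the linear
correction `T1_corr = a(f_T) + b(f_T) · T1_app` with cubic polynomials in the
transmit field, fitted over T1 ∈ [0.6, 2.2] s and f_T ∈ [0.7, 1.3].  A round
trip (imperfectly spoiled forward, matching correction) recovers white-matter
R1 within 1%.

## Phantom and site model

The phantom is a parametric ellipsoid-shell head (CSF envelope, 10 mm cortical
GM ribbon, WM core, CSF ventricles, bilateral caudate blobs, a callosal bridge
crossing the midline) — not an atlas, because every statistic in the analysis
is ROI- or mask-based.  Tissue means are the published group means
(GM R1 0.609 1/s, PD\* 84.44 p.u., MT 0.794 p.u., R2\* 15.2 1/s; WM 1.036,
68.35, 1.764, 21.0; caudate 0.683, 82.67, 0.836, 18.2; callosum 1.158, 64.65,
1.978, 25.0).  Within-tissue variation is Gaussian with the across-volunteer
SDs scaled by √5 (they are SDs of five-volunteer means), clipped at ±3 SD.
CSF is not tabulated in the source; literature-typical 3T values are used
(R1 0.25 1/s, PD 100 p.u., MT ≈ 0, R2\* 3 1/s).  Volunteer individuality
enters through seed-varied within-tissue noise, ±3% ellipsoid scaling and
±2 mm structure jitter.

Each (volunteer, site) cell draws: a transmit field scaled to a max deviation
of 20–30% inside the head; a receive field with max/min ratio 2–3; a rigid
pose of 10–20 mm and 3–5°; and a measured-B1 map `f_T (1 + ε)` with ε a smooth
zero-mean field of 3% SD (the stated accuracy of SE/STE B1 mapping, which is
not itself simulated).  All fields are exponentials of band-limited Gaussian
random fields (hard spectral cutoff, default wavelength 120 mm), guaranteeing
positivity and verifiable smoothness.  Fields, pose and noise are drawn per
cell: in a multi-centre study each session re-positions the head in the coil,
so the coil profile relative to the anatomy changes per session.  Noise is
Rician (magnitude data) with SD calibrated so the first PDw echo has SNR 50 in
white matter; the source study reports no raw-echo SNR, so this value was
chosen once such that the pipeline's intra-site CoVs fall in the reported
2–16% range, and is documented as a calibration, not a measurement.

Acquisition at a displaced head position is simulated by trilinear resampling
of the noise-free signal; the analysis side resamples maps back with 4th-order
B-splines using the known inverse pose (registration *estimation* is out of
scope).  The default grid is 64³ at 2.5 mm for the full experiment and 48³ in
most tests; the acquisition-resolution 1 mm matrix is a config option not used
by default, purely for runtime reasons — all statistics are means over ROIs of
hundreds of voxels, which the coarse grid supports.

## Estimation chain

1. **Echo averaging.**  Arithmetic mean of the first six echoes per weighting
   (effective TE 8.45 ms) for SNR.
2. **R2\*.**  Ordinary least squares of ln S on TE over the eight PDw echoes;
   R2\* = −slope.  Voxels with non-positive signals are invalid (NaN).
3. **A and apparent R1.**  Exact two-point inversion of the rational FLASH
   approximation `S ≈ A α TR·R1/(α²/2 + TR·R1)` from the T1w/PDw mean images
   at nominal angles.  Against an exact-Ernst forward model this
   approximation biases GM R1 by ≈ −1.3% — within the error the chain's
   acceptance bounds absorb.
4. **Transmit and spoiling correction.**  Re-estimating with local angles is
   algebraically equivalent to `R1 ← R1_app f_T²` and `A ← A_app / f_T` (the
   package uses the closed form; the equivalence is asserted in tests), with
   the measured B1 map as f_T.  The 6%-for-3% quadratic error propagation is
   an acceptance identity.  The optional spoiling correction then maps
   apparent to true T1.
5. **MT saturation.**  `δ = (A α/S_MT − 1) TR·R1 − α²/2` with the
   transmit-corrected A and R1 and the *local* excitation angle `f_T α_MT`,
   followed by the published B1 correction (factor `0.6/(1 − 0.4 f_T)`).
   Using the nominal angle here would leave a residual transmit dependence
   far larger than the correction handles (verified numerically: recovery
   errors up to ±50% at ±25% B1 versus ≤3% with the local angle).  The
   printed first-order formula overestimates δ by ≈ (1 + TR·R1 + α²/2):
   +2.4% in WM, +0.8% in GM, independent of f_T — an inherent property of the
   semi-quantitative definition, visible in the round-trip numbers.
6. **Receive-bias removal.**  A generative model in the log domain —
   tissue-class means plus a band-limited smooth field (separable cosine
   basis, 60 mm shortest wavelength) — estimated by EM, with the phantom's
   spatial priors anchoring the classes (the same reliance on generative
   segmentation as UNICORT).  A |k|⁴ ridge penalty (weight 0.5 of the mean
   Gram diagonal) acts as the smoothness prior; without it the 216-dof basis
   chases noise.  Known-field recovery: r > 0.998, residual range < 5%;
   a checkerboard perturbation is out of model and stays in the residual.
7. **PD\* calibration.**  One global scale so that the mean over the
   white-matter calibration mask (MT-based WM probability > 99%) is exactly
   69 p.u.  No TE → 0 extrapolation is applied: PD\* deliberately retains the
   R2\* weighting of the 8.45 ms effective TE (≈15% signal loss at
   T2\* = 50 ms), which is why GM PD\* evaluates to the attenuation-consistent
   expectation (~89 p.u. for this ground truth) rather than the nominal GM
   proton density.

Invalid-voxel policy: estimates outside physical plausibility bounds
(R1 ∉ (0.001, 10] 1/s, amplitude ∉ (0, 10⁴], MT ∉ [−10, 30] p.u.,
R2\* ∉ [−100, 500] 1/s) become NaN, are excluded by downstream masks and are
counted in the log.

## Segmentation and ROIs

Tissue probabilities come from a prior-guided three-class Gaussian mixture
with a co-estimated multiplicative smooth bias field (EM, at most 100
iterations, posterior tolerance 1e−5), the same generative structure unified
segmentation uses.  This suffices because the analysis only needs consistent
tissue posteriors and the priors derive from the known phantom geometry
(labels blurred by a 4 mm FWHM Gaussian).  Segmentation is intensity-scale invariant
and reduces to the priors for constant images.

ROIs per volunteer: GM and WM as voxels with probability > 99% in the
across-site mean MT-based segmentation (the conservative reading of a
per-volunteer ROI from three registered maps); the brain mask as probability
sum > 90%; caudate and callosal ROIs from the ground-truth labels eroded by
one voxel (in a study without ground truth these would be delineated manually
on the MT-weighted images; with ground truth available, using it is unbiased
by construction).  The GM mask for the
GM-probability analysis contains voxels with GM probability > 90% *at every
site* from the corresponding map type; requiring consistency across sites is
the same partial-volume caution the 99% ROI threshold expresses.  (Under the
alternative mean-probability>90% reading the group-level MT-vs-T1w contrast
is unchanged, but the per-volunteer ordering can invert for a volunteer whose
receive fields happen to be well correctable, because interpolation smoothing
at mask-boundary voxels hits the sharp MT posteriors hardest.)

## Reproducibility statistics

* **Inter-site CoV** = 100·SD(N−1)/mean of the per-site ROI means, per
  volunteer; ROI summaries are across-volunteer mean ± SD.  Voxel-wise CoV
  maps use the same convention (display only).
* **Intra-site CoV** = voxel SD/mean within the caudate head or callosal genu
  (homogeneous ROIs only — in mixed ROIs tissue architecture, not noise,
  dominates the spread), averaged across sites.
* **Inter-site bias** = percent deviation of each site's mean from the grand
  mean over all sites and volunteers (unweighted), averaged over the GM and
  WM ROIs — GM only for PD\*, whose WM value is pinned by the calibration.
* **GM-probability CoV**: per-voxel across-site CoV of GM probability,
  averaged within the GM mask, per volunteer and map type, with a t-based 95%
  CI across volunteers (the CI construction is not specified upstream; the
  t-interval is this package's choice).
* **Tests**: two-way within-subject ANOVA (ROI × image type, statsmodels
  `AnovaRM`; hand-computed sums of squares serve as the oracle in tests) per
  parameter, one-tailed paired t-tests post hoc, no multiple-comparison
  correction across the four parameters.  On a collapsed design F = t²
  (asserted to 1e−8); both tests hold their 5% type-I rate in null
  simulations (±1.5%).

## Problem sizes and runtime

The default experiment (5 volunteers × 3 sites, 64³ at 2.5 mm) runs in about
two minutes on one CPU; the test suite uses 48³ for pipeline properties.
`scripts/acceptance.py` re-runs the full default experiment from scratch.

## Known limitations

* The phantom has no cortical folding, lesions or atlas realism; partial
  volume exists only at smooth ellipsoid boundaries.  Passing recovery tests
  demonstrates the correctness of the estimation chain under the stated
  forward model, not performance on real anatomy.
* k-space effects (GRAPPA, partial Fourier), susceptibility-induced B0
  effects, within-scan motion and physiological noise are not simulated; the
  single noise SD stands in for net SNR.  Consequently the simulated R2\*
  inter-site CoV is far smaller than reported on real scanners, where R2\*
  reproducibility is limited by shim and susceptibility differences the
  phantom does not model.  No acceptance bound depends on reproducing that
  excess variance.
* The MT pulse's off-resonance Bloch dynamics are abstracted into the
  saturation fraction δ; MT values are semi-quantitative and tied to this
  pulse abstraction exactly as the real parameter is tied to its pulse.
* Registration transforms are known, not estimated; B1 mapping is modelled
  only through its 3% error level.
* The receive-bias estimator leans on spatial priors from the known geometry.
  On real data the equivalent step (generative unified segmentation) brings
  its own priors; the prior-free intensity-clustering path is implemented but
  weaker, and is not what the pipeline uses.
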