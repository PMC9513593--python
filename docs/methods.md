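# Methods

`lutac` studies the use of the intrinsic Lu-176 background of
LYSO-based PET scanners as a transmission source for 511 keV
attenuation correction (AC), with emphasis on long-axial-FOV
scanners and ultralow-dose scans.  Everything runs at *desk scale*: a
reduced-crystal scanner model and sinogram-domain count simulation
replace photon-tracking Monte Carlo, while the coincidence policy,
energy models, reconstruction algorithms and quantification pipeline
are implemented in full.

## Physical model

**Source.** Lu-176 (2.6% of natural lutetium) beta-decays in a
crystal and promptly emits gammas at 307 keV (100%), 202 keV (83.3%)
and 88 keV (15.5%).  A transmission coincidence pairs the local beta
deposit (broad "beta window", 250-645 or 290-645 keV) with the
307 keV photon detected across the bore (250-350 or 290-350 keV).
Only the 307 keV line can reach the gamma windows used; the other
line probabilities are kept for rate bookkeeping.  The blank-rate
anchor is the measured 92.2 cps per cc of LYSO in the 430-645 keV
window; the unmodelled beta spectrum is folded into a single
beta-window detection probability.

**Scanner.** A cylindrical lattice of crystal rings grouped into
axial units (eight 242.5 mm units for the 194 cm scanner; four for
the one-meter variant; one for the conventional 24 cm scanner).
Coincidences obey a maximum-unit-difference (MUD) policy — MUD 4 for
the long scanner, unrestricted for the short ones.  The acceptance
angle implied by a policy is `arctan(span / ring diameter)` with the
span in unit lengths; on a 786 mm ring this reproduces the
57/51/43/32/17-degree ladder for 5..1 unit spans.

**Energies.** Mu-maps are stored at 511 keV everywhere.  All 307 keV
physics scales line integrals by `eta = 1.2276`, the linear fit of
tissue attenuation at 307 vs 511 keV.  Measured energies are
Gaussian with fractional FWHM `0.117 * sqrt(511/E)` (anchored by the
11.7% resolution at 511 keV).

**Depth of interaction.** An LOR endpoint is the crystal front-face
centre pushed deeper into the crystal *along its radial axis* by the
truncated-exponential depth
`-ln(1 - Y(1 - e^{-eta mu_LYSO D})) / (eta mu_LYSO)` with
`mu_LYSO = 0.0815 /mm`, `D = 18.1 mm` — the DOI parallax, which
shifts the effective line for off-centre LORs.  The fixed quantile
`Y = 0.6` gives ~7.6 mm at 511 keV and ~7.0 mm at 307 keV.  Per-LOR
uniform sampling of `Y` (the inverse-CDF sampler of the truncated
exponential) is available and used by the study drivers: the
endpoint jitter is a physical effect and, at desk-scale sampling
density, additionally decorrelates the transaxial aliasing pattern
between random-seed replicates.

**TOF.** Gaussian kernel with FWHM equal to the 430 ps coincidence
timing resolution, integrated exactly over 273 ps bins and truncated
at 3.5 sigma (keeping the marginalization error below 1e-3; the bin
range covers the longest policy-allowed LOR so the TOF model
marginalizes to the non-TOF model for every voxel).  The
transmission TOF-acceptance rule keeps only coincidences whose |TOF|
exceeds the LOR flight time minus 500 ps, which removes body-origin
(scattered emission) events while keeping crystal-origin events.

## Desk-scale simulation

Instead of tracking photons, expected counts per sinogram bin are
computed from the geometric pair sensitivity, attenuation factors and
energy-window survivals, and Poisson samples are drawn.  Energy
windows, Klein-Nishina single scatter and the TOF rule act on sampled
per-event attributes; scatter and contamination categories are kept
separate so "no scatter" data sets are exact subsets.  Randoms are
never generated.  The single-scatter samplers draw the scatter vertex
along the primary chord proportionally to the local attenuation
coefficient (first order in optical depth), sample the scattering
angle from the Klein-Nishina kernel, redirect the photon to the
detector cylinder and apply the energy-resolution window test;
multiple scatter and fluorescence are not modelled.  This is
sufficient to reproduce the qualitative scatter artifact that the
water-peak rescaling mitigates, not a quantitative scatter estimate.

A single exposure factor scales all expectations to desk-level
counts; it multiplies blank and object scans alike so count-statistics
comparisons stay internally consistent.  The default study conditions
are a 20-minute transmission scan scaled to 1e7 unscattered
transmission counts (with a 200-minute-equivalent blank), and a
21 MBq F-18 activity whose 20-minute emission scan is scaled to 5e7
true coincidences; F-18 decay enters as the time-integrated factor
(0.9394 for 20 min).  The emission level is a study-condition
choice: well below what the shared exposure factor would give
against the physical desk-geometry rates (several 1e8), but high
enough that the organ-VOI analysis measures reconstruction bias
rather than low-count rectification — at a few 1e7 counts the small
bone VOIs show tens-of-percent per-replicate swings even with
ground-truth attenuation correction.

## Reconstruction

**TOF-OSEM.**  Multiplicative update with subset sensitivity
`sum p_ij a_i n_i`; 10 non-overlapping subsets ordered equidistant in
angle (4 for the 24 cm scanner); 3 iterations (2 for the shorter
scanners).  The start image is the smoothed normalized
backprojection of the counts, masked to the attenuating-body support
of the mu-map: a data-derived, regionally count-matched start.  A
flat start converges visibly unevenly at 30 equivalent MLEM
iterations (regions whose local count level differs from the global
mean are still converging), which at desk scale leaves 10%-level
residuals in the head.

**Penalized MLTR.**  Additive separable-quadratic-surrogate (SQS)
update of the mu-map from blank/transmission pairs, with the
quadratic 26-neighbour penalty (inverse-distance weights 1, 1/sqrt2,
1/sqrt3) applied to the 511 keV map; non-negativity clamp after every
update; 50 iterations; beta defaults 10000/20000/80000 per geometry
and 40000/20000/10000 for 5/10/20-minute scans.  Curvatures use the
optimal-curvature bound of the separable surrogate for the Poisson
transmission likelihood,

    c = 2 (psi(0) - psi(Z) + Z psi'(Z)) / Z^2   (Z > 0),
    c = psi''(0)                                 (Z = 0),

floored at 1e-12, which guarantees monotone surrogate descent with a
single subset.  With ordered subsets the penalty is scaled by
1/n_subsets and the denominator is the subset share of a
*precomputed* full-data denominator, with curvatures evaluated at
the data-consistent line integrals (the ordered-subsets
separable-paraboloid convention): rebuilding the denominator from
each subset alone produces unstable steps in voxels that subset
barely covers.  The mu-map starts at zero (the converged result is
initialization-independent at the default iteration counts).

The regularization weight was calibrated for the desk count level by
the prescribed procedure — scanning a range of weights and selecting
by SSIM and ground-truth-range NRMSE: both select beta = 10000 for
the 20-minute default-scanner scan, so the full-scale defaults are
kept unchanged.

**MLAA-TX.**  Joint estimation interleaves one TOF-MLEM activity
update with five SQS mu updates per iteration; the mu update combines
the emission-derived likelihood term (non-TOF-collapsed counts,
forward-projected activity as the Poisson "blank") and the
transmission term weighted by `alpha` (0.1/1/10; default 1), each
through its own system matrix (511 and 307 keV DOI endpoints
respectively).  Initialization is the regularized MLTR map.  With
`alpha -> infinity` the mu update reduces to unpenalized MLTR; with
`alpha = 0` it degenerates to emission-only MLAA.

## Quantification

Voxel bias `(x - x_ref)/x_ref` against the ground-truth maps; NRMSE
normalized by the evaluated image's dynamic range (a switch offers
the conventional ground-truth range); SSIM with unit exponents on
luminance/contrast/structure, 3-D Gaussian window of sigma 1.5
voxels, reflect boundaries, edge crop of the filter radius, constants
C1=(0.01L)^2, C2=(0.03L)^2, C3=C2/2 with L the ground-truth range
(pinned against scikit-image's implementation to 1e-6).  VOI
statistics are boxplot records (mean, median, quartiles, 1.5 IQR
whiskers, outlier counts) of the voxel-bias distribution; the
headline statistic is the maximum over organs of the absolute mean
bias.  Lesion SUVmax is the maximum voxel in the lesion sphere
dilated by one voxel, per image; the SUV normalization constant
cancels in percentage bias and is fixed to one.  Water-peak
rescaling finds the highest histogram mode in [0.007, 0.012] /mm (bin
width 2e-4, 3-bin smoothing) and scales the map so the mode matches
water (0.0096 /mm).

## Synthetic phantom

A geometric-primitive stand-in for an anthropomorphic voxel phantom:
a 200 x 200 x 800 mm torso-plus-head on 50 x 50 x 200 voxels of 4 mm,
with subcutaneous fat, soft torso, a neck bridging torso and head
(the junction would otherwise create an artificial mu discontinuity
that contaminates nearby lesion quantification), skull/brain,
ribcage, lungs, liver, myocardium/LV blood pool, spine, hip bones
with marrow cores and a hot bladder; FDG-like concentrations (soft tissue 1, liver 2.2,
LV blood 1.8, whole-brain 2.5, lung 0.5, marrow 1.3, cortical bone
0.5, skeleton with trabecular uptake 0.7-0.9, bladder contents 10),
normalized to 21 MBq total at scan time; twenty-two activity-only
spherical lesions (8-12 mm, contrast 2.4-24: 5 liver, 3 per lung, 4
pelvic nodes, 4 neck nodes, 3 brain) and 23 spherical VOIs.

Two desk-scale design rules shape the default body, and they are the
main way this phantom differs from an anthropomorphic one:

* organ structures carrying VOIs are sized so that every VOI interior
  keeps >= ~11 mm clearance from the nearest tissue boundary —
  thin shells (ribs, 10 mm hip-bone rings, the fat layer) exist for
  attenuation realism but carry no VOI, because at the desk system's
  resolution their VOI means would measure spill, not bias;
* rasterization is by voxel-centre inclusion (exactly testable);
  organ overlaps resolve by a documented priority order.

What passing tests on this phantom do show: the consistency and
convergence of the transmission/emission models and reconstructions,
the directional findings (acceptance-angle and duration trends,
crosstalk vs alpha, scatter/threshold effects) and quantification
within the stated bounds at desk scale.  What they cannot show:
performance on anatomical detail finer than the desk sampling
distance, scatter quantitation, randoms, dead time, or detector
non-uniformities.

## Desk-scale sampling choices

The default desk scanner keeps ring diameter (786 mm), unit structure
and MUD policy exact, with 80 crystals per ring and 24 rings per unit
(10.1 mm axial pitch).  Sinograms use 40 angle bins (two crystal
columns mashed per bin), 39 radial bins (15.4 mm) and axial mashing
of 3 (mid-plane sampling 15.2 mm).  These numbers balance the LOR
count (~1.5 million object-crossing bins) against per-pass cost on
one CPU; axial mid-plane density was prioritized after it proved to
be the binding constraint for hot-sphere recovery.  Residual
VOI-level biases of up to ~10% at matched conditions are structured
aliasing of this sampling, not model inconsistency: they persist for
noiseless data and wander with iteration number.  Per-seed DOI jitter
turns this deterministic floor into a zero-mean component across
replicates, which is why the study drivers enable random DOI
sampling and report seed-averaged VOI statistics.

## Replication bounds at desk scale

With the frozen study conditions, three noise replicates give a
maximum organ-level |mean bias| of roughly 5% for activity and 9% for
the mu-maps (57- and 32-degree acceptance angles), inside the +/-10%
band the method targets.  The per-lesion SUVmax comparison against
the ground-truth-mu reference is harder at desk scale: the maximum
over soft-tissue lesions of the 3-replicate mean lands around 13%,
driven by two lesions (a low-contrast pelvic node and a neck node)
whose per-replicate values swing by +/-10-20% — a max statistic over
small, noisy regions; most soft-tissue lesions sit well inside 10%.
More replicates would shrink this estimator but do not fit the
validation-runtime budget.

## Known limitations

* Sinogram-domain expectations with representative-LOR bins; no
  per-event list-mode semantics, no coincidence-window or multiplexing
  ("takeAllGoods") modelling.
* Single scatter only, first-order vertex sampling, no scatter
  correction algorithm (scatter-contaminated mu-maps are only
  rescaled at the water peak).
* No PSF modelling, randoms, dead time or pileup.
* The 24 cm multi-bed protocol uses abutting beds; overlap is a
  configuration degree of freedom.
* The component-based normalization assumes a separable
  crystal-pair efficiency model and a thin analytic annulus.
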