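# Methods

`uotcnr` models how deeply four detection methods for ultrasound optical
tomography (UOT) can image an absorbing inclusion in tissue, by computing the
shot-noise-limited contrast-to-noise ratio (CNR) of each method as a function
of depth.  This note records the models, the numerical choices, and what the
synthetic data do and do not capture.

## The imaging problem

A focused ultrasound pulse (cubic 3x3x3 mm^3 focal volume, 2 MPa peak
pressure) frequency-shifts ("tags") a small fraction of the diffuse laser
light passing through it.  Scanning the pulse and detecting tagged photons
localizes optical absorption at the pulse position.  The study compares probe
position A (background tissue) against position B (inside an absorbing
inclusion of the same scattering but 1-2.5x the background absorption) and
asks at which depth the CNR

    CNR = |S_A - S_B| / sqrt(sigma_A^2 + sigma_B^2)

falls below 1, for four detection chains: spectral hole burning filters
(SHB), photorefractive two-beam detection (PR), single-shot off-axis
holography (HOL) and speckle contrast imaging (SC).

## Tissue model and geometry

Muscle-like background: reduced scattering mu_s' = 5 /cm at 800 nm
(power-law anchored, mu_s = 50 /cm with g = 0.9), absorption mu_a = 0.2 /cm,
index-matched boundary.  Reflection mode: 1 cm^2 source and 1 cm^2 detection
apertures on the surface.  The published layout fixes only the combination
entering the minimum geometric path, 2 sqrt(1.25^2 + 0.25^2 + z^2); we
decompose it as source at (+0.25, +1.25) cm and detector at (+0.25, -1.25)
cm from position B, with A displaced +0.5 cm along x.  This decomposition
preserves the path formula and places the source and detector on the
perpendicular bisector plane of the A-B segment, so the two probe positions
are geometrically equivalent: with no absorption contrast the expected A-B
signal difference is exactly zero, which both the estimators and the tests
exploit.

## Monte-Carlo transport

Weighted packets: exponential free paths at rate mu_s, Henyey-Greenstein
deflections, continuous absorption weighting applied piecewise per region
(segment clipping against the inclusion and voxel boxes is analytic, so
mm-scale features are exact), Russian roulette below weight 1e-4 with
survival probability 0.1.  Roulette gains and losses are folded into the
absorbed-weight ledger, so detected + absorbed + escaped equals the launched
weight to roundoff on every run, not just in expectation.  All packets
exiting the surface inside the aperture are recorded regardless of angle;
the numerical-aperture collection loss (NA 0.7, loss sin^2 45deg ~ 0.5) is
applied analytically in the detection chain, with the rounded 0.5 as the
default so the stated chain efficiencies (7.5% SHB, 30% HOL, 40% PR) are
reproduced exactly (an exact NA^2 mode differs by 2%).

Validation: total diffuse reflectance of the homogeneous medium agrees with
the semi-infinite diffusion closed form (extrapolated-boundary dipole) to
~5%; HG sampling reproduces mean cosine g and the analytic density;
identical seeds give bit-identical runs.

## Acousto-optic tagging

The voxel converts a fraction of a packet's weight into +/-1st-order
sidebands as a function of its geometric path l inside the voxel.  Two
models: a phase-modulation model, +1st-order fraction J1(m P l)^2 with
modulation index m (rad/(cm Pa)), the default; and a parametric model,
fraction c l (P/P_ref)^2, whose single coefficient is calibratable.  The
absolute conversion efficiency in tissue at 2 MPa is not derivable from the
study parameters; it is the model's one free scale.  We pin it by requiring
that the SHB 30 dB variant - the configuration tied to an experimentally
realized filter - reaches CNR = 1 at its published 3.3 cm depth.  The
anchored scale is expressed as the +1st-order tagged/untagged photon ratio
at the z = 1 cm reference depth (default 5.0e-3); the corresponding
modulation index, 6.9e-7 rad/(cm Pa) (phi ~ 1.4 rad per cm of in-voxel path
at 2 MPa), is of the magnitude expected from the piezo-optic response of
water-like media at this pressure once the random-walk decorrelation of the
accumulated phase is accounted for.  With that single number fixed, the
other seven variants' imaging depths are parameter-free predictions.

## Photon levels at depth: the hybrid engine

Tagged transmittances in reflection mode fall to ~1e-10 of the launched
photons at 4-5 cm depth, far beyond direct Monte-Carlo reach.  The default
("hybrid") engine therefore factorizes the problem:

1. **Reference run.**  One homogeneous paired transport at z_ref = 1 cm
   scores, per detected packet, the weight and the in-voxel paths for both
   probe positions along the same trajectory (the voxel never alters
   propagation, so A and B share one path set).
2. **Exact contrast reweighting.**  The inclusion differs from the
   background only in absorption, so the levels for any absorption contrast
   follow by multiplying each packet by exp(-dmu_a l_B); tagging weights the
   packet additionally by l_X (parametric) or l_X^2 (small-modulation phase
   model).  Estimators are symmetrized over the mirror reflection about the
   A-B bisector plane - an exact symmetry of the homogeneous transport under
   which l_A and l_B exchange - which turns the A-B difference into a
   packet-wise non-negative statistic,
   (w/2)(l_A - l_B)(e^(-dmu l_B) - e^(-dmu l_A)).  This removes the
   cancellation noise of subtracting two nearly equal sums (relative
   standard error ~1% at 6e5 packets, versus ~100% unsymmetrized) and makes
   the zero-contrast CNR identically zero.
3. **Depth shape from diffusion.**  The unperturbed depth dependence of the
   untagged density N_U(z) (nearly depth-independent in reflection) and of
   the in-voxel path integral W0(z) = int Phi(r) R_d(r) d^3r (the fluence x
   escape product over the voxel) comes from semi-infinite diffusion
   Green's functions with the extrapolated boundary, quadrature-integrated
   over the apertures and the voxel; the absolute scale is pinned to the
   reference run (agreement before pinning: ~4% for N_U, ~10-15% for W0).
   The in-voxel path-length *distribution* (which sets the contrast factors
   and the l^2/l moment ratio) is taken from the reference depth and
   assumed depth-independent - it is a local property of diffusion around
   the voxel; direct MC at 1.5 cm is consistent with this.

A full per-depth MC engine (paired runs, adaptive packet boosting, quality
flags) remains available and validates the hybrid levels at shallow depth;
it cannot reach the deep half of the scan at sensible cost.

A first-Born perturbation treatment of the inclusion is also implemented in
the diffusion module.  It underestimates the tagged A-B contrast by ~30%
(0.051 versus the measured 0.074 at contrast 2): tagging weights packets by
the same in-voxel path that the inclusion attenuates, a correlation the
factorized first-order expansion cannot represent.  It is kept for
structural studies only; the pipeline uses the exact reweighting.

## CNR models

With N_T,X the +1st-order tagged photons per cm^2 (both orders detected
where applicable), N_U the untagged density, S the collection area and
eta_det the chain efficiency:

* **SHB**: CNR = sqrt(2 S eta) |dN_T| / sqrt(N_T,A + N_T,B + T_U N_U), with
  filter leak T_U = 1e-3 (30 dB, best reported) or 1e-8 (80 dB, the
  theoretical contrast of a 1.2 cm thulium-doped crystal at 15 /cm).
* **PR**: CNR = sqrt(2 S eta) c_pr |dN_T| / ((1 + c_pr) sqrt(N_U)), with
  c_pr the relative diffracted-reference amplitude.  Config switches cover
  the two published ambiguities: amplitude (c_pr = eta_pr, default) versus
  intensity (sqrt(eta_pr)) reading of the diffraction efficiency, and a
  noiseless (averaged, default) versus shot-noisy ultrasound-off baseline
  (sqrt 2 lower CNR).
* **HOL** (per-speckle numbers Nbar, n = 16 pixels per speckle):
  CNR = sqrt(N_px) (eta |dNbar|/n) / sqrt(4 eta (Nbar_A + Nbar_B)/n + 2).
  The regime changes at ~1 detected tagged photon per pixel: below it most
  pixels carry only noise and CNR is linear in the level, above it the
  usual square-root scaling holds.  A simulated quarter-plane hologram
  estimator (Poisson pixels, FFT, crop, bias subtraction) is uniformly
  1.3-2x better than this form, whose denominator charges the shot noise of
  all N_px pixels against a single reconstructed sideband lobe; the
  quarter-crop bookkeeping (floor 2 -> 1/2, cross term 4 -> 2) is available
  as `hol_noise_model="quarter-crop"` and matches the simulation within
  15%.  The printed form is the default because the published depth curves
  were computed with it.
* **SC**: contrast signal C = 1 - 2 N_T/N_U against the stochastic contrast
  floor c/sqrt(N_px): CNR = sqrt(2 N_px) |dN_T| / (c N_U).  The default
  c = 1 reproduces the published curves; the measured coefficient for
  2-px-wide speckles is ~1.5 (pixels within a speckle are correlated), and
  can be supplied via `sc_noise_coefficient`.

Each form is validated against an independent measurement simulation
(Poisson counting for SHB/PR; the hologram estimator for HOL; contrast
measurements on synthetic modulated speckle for SC) to 20%.

## Speckle statistics

Fully developed speckle is synthesized by the random-phase circular-pupil
FFT method; the pupil radius is set so the intensity autocorrelation FWHM
equals the requested speckle width (2 px for the noise-floor study, checked
to 0.05).  Intensities are exponential (KS-tested on decorrelated
subsamples) with ensemble contrast 1.  The contrast spread over independent
patterns scales as N_px^-1/2 (fitted exponent 0.50 +- 0.05) with coefficient
~1.5 as above.  Ultrasound modulation is simulated by adding two sideband
speckle fields at +/-f_US and integrating over >= 8 uniform phases, which
cancels all beats exactly and reproduces C = 1 - 2f.

## Study defaults and problem sizes

Depth grid 0.5-5.0 cm in 0.25 cm steps; absorption contrast 2 (sweep 1-2.5);
1e15 input photons per voxel (the 300 mW/cm^2, 1 s, 1 cm^2 safety budget
divided over a 30x30 voxel image); CNR always expressed for that full
budget via transmittance scaling.  The packaged study uses 2e6 reference
packets (crossing-depth statistical error ~0.02 cm); unit tests use
1.5e5-6e5 for speed.  Reproducibility is bit-exact given (seed, packet
count, chunk size).

## Known limitations

* The absolute tagging efficiency is anchored, not predicted; consequently
  statements that depend on the absolute tagged level inherit its
  uncertainty.  Two published qualitative scales shift accordingly: the
  30/80 dB SHB curves separate from ~1.4 cm here (published: ~2 cm), and
  the depth gain from contrast 1.5 -> 2.5 is 2.7-4.3 mm across methods
  (published: 4-5 mm), uniform across methods as published.  Matching both
  would require a tagged A-B relative contrast of ~0.04, smaller than the
  0.074 (linear) / 0.105 (quadratic) this transport model measures.
* Diffusion supplies the depth shape beyond the reference depth; its
  accuracy is a few-percent in log-slope at these albedos, worth <~0.1 cm
  at the crossings, but it is a modelling step, not a measurement.
* No detector dark counts or read noise (shot-noise limit throughout), no
  speckle decorrelation dynamics, no polarization, no time-resolved
  transport, no acoustic field structure beyond a uniform-pressure cube,
  transmission geometry out of scope.
* The synthetic data share the model's own assumptions; passing tests
  demonstrate internal consistency and agreement with diffusion theory and
  published depths, not agreement with measurements on real tissue.
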