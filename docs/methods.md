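# Methods

## The analysis pipeline

The package analyses per-subject task and control BOLD-contrast volumes on
a common MNI-like grid (it starts downstream of acquisition,
normalization and first-level modelling). Stages, in order:

1. **Behavioral screening.** Per subject, percent correct over task trials
   and mean latency (speech onset − scan onset, ms) over correct task
   trials. Subjects whose mean latency exceeds the cohort mean + 2 SD are
   excluded — one-sided and single-pass: the threshold is computed once
   over all subjects, not re-iterated after exclusions, and fast subjects
   are never excluded.
2. **LOSO ROI definition.** For each subject, a voxelwise one-sample
   t-map of task−control over the other N−1 subjects (df = N−2;
   zero-variance voxels are flagged missing rather than ±∞ so peak
   searches stay well-defined). Within a 10-mm sphere around each of 22
   canonical catalog centres, the maximal-t voxel is the subject's peak;
   ties break by distance to the canonical centre, then lexicographic
   voxel index, which makes the definition deterministic across
   platforms. An optional mirrored mode instead reflects each
   left-hemisphere peak's x for the right-hemisphere ROI, for users who
   read "symmetrically defined" strictly.
3. **Extraction.** Mean task and control values over a 6-mm sphere at the
   subject's peak; the contrast column is exactly task − control.
4. **Indices.** The 22 contrasts collapse into LA, RA (means of 5
   anterior ROIs per hemisphere) and LP, RP (means of 6 posterior ROIs),
   then L_AP = LA−LP, R_AP = RA−RP, A_LR = LA−RA, P_LR = LP−RP. Anterior
   = {IFG, MFG, SFG, SMA, insula}; posterior = {FG, ITG, MTG, ATL,
   hippocampus, IPL}. The divisors 5 and 6 are fixed by membership; the
   module refuses incomplete tables rather than renormalizing, because
   renormalization would silently change the statistic. Negative L_AP
   means posterior-dominant left-hemisphere activity.
5. **Group statistics.** Median splits (strictly below the
   midpoint-interpolated median → first group; ties at the median go
   up). Mann-Whitney U per index: U1 counts favorable (x, y) pairs with ½
   per tie; Z = (U1 − n1n2/2)/σ with the tie-corrected σ and no
   continuity correction; p is exact (full enumeration of the null U
   distribution by the standard recurrence) when the samples are untied
   and small (max(n1,n2) ≤ 10 or n1+n2 ≤ 12), else normal. Z is negative
   when the first group tends lower. No correction across the four
   indices is applied; the report says so. The ANCOVA fits
   `index ~ 1 + group + covariate` by OLS and tests the group term by
   extra sum of squares on df (1, n−3); a zero residual with a nonzero
   group effect is flagged as exact separation (F = ∞). The report also
   carries the alternative residual-df convention (n−2) because published
   ANCOVA tables sometimes count df as if the covariate were absorbed;
   with n = 27 the difference is df 24 vs 26 and does not change any
   qualitative conclusion.

## The synthetic cohort generator

No public dataset accompanies this design, so the generator is a
first-class, tested component that emits cohorts with the statistical
structure the analysis is meant to detect.

**Subjects.** n_young = 13 and n_old = 14 by default; ages uniform on
30–55 and 60–85 years, so the pooled age median always separates the true
groups. Mean naming latencies are normal (truncated positive):
818.59 ± 72.06 ms young, 917.56 ± 107.83 ms old.

**Behavior.** One run of 8 alternating 20-trial blocks (task first),
TR = 2.5 s (2 s stimulus + 0.5 s ISI), one scan window per trial. Trial
latencies are lognormal (log-SD 0.25) calibrated to the subject's mean
and truncated to [150 ms, TR]: a response can neither precede perception
nor leave its scan window. Correctness is Bernoulli with rate 0.985.

**Volumes.** The default grid is the MNI bounding box at 3-mm isotropic
voxels (61×73×61, origin voxel at (−90, −126, −72) mm, RAS+). A subject's
task volume is a sum of Gaussian foci (FWHM 12 mm) at the catalog centres
displaced by per-subject isotropic jitter (SD 2 mm), plus i.i.d. voxel
noise (SD 2.5 contrast units), smoothed with a 6-mm FWHM kernel; the
control volume is smoothed noise only. With these values a 26-subject
group t-map peaks around t ≈ 7–8, the range reported for group naming
contrasts at this sample size.

**Amplitude model.** Each ROI's amplitude is its hemisphere×category cell
value plus two planted effects:

```
amp(s, r) = base[hemi, cat]
          + lapa_delta              if s is old and r is left posterior
          + harold_gain · z_s       if s is old and r is right anterior
```

where z_s is the subject's negated standardized latency within the older
group — faster older subjects get a larger right-anterior boost, hence a
smaller A_LR. Defaults: base = (LA 0.79, RA 0.66, LP 1.00, RP 0.98),
solved from the target young-group index means (L_AP −0.21, R_AP −0.32,
A_LR 0.13, P_LR 0.02) with the left-posterior cell anchored at 1;
lapa_delta = 0.27 so the old-group expected L_AP is −0.48;
harold_gain = 0.08 so the expected faster-minus-slower A_LR gap is about
−0.13. The latency coupling is planted only within the older group, where
the effect is hypothesized.

**Calibration of focus coefficients.** Planting each focus with its raw
amplitude would not survive the pipeline: smoothing plus sphere-averaging
attenuates an isolated focus by ~30–40%, and nearby foci overlap (the
right SFG and SMA centres are under 3 mm apart, so their spheres read
each other almost fully). The generator therefore solves a linear
calibration: a coupling operator M — the sphere-mean each smoothed unit
focus induces at the locations where the peak search is expected to land
— is computed once per geometry by a short fixed-point iteration (render
the expected field, locate each ROI's in-sphere maximum, recompute M
there, re-solve), and each subject's focus coefficients solve
M b = amp via pseudoinverse (ROIs whose expected peaks coincide give
duplicate rows; the system stays consistent because such ROIs share a
cell amplitude). The expected define→extract output then equals the
planted amplitudes.

**What the pipeline can and cannot recover.** One distortion is
irreducible by construction: selecting the maximum of a noisy t-map lets
the peak wander within the zone where the signal's decrease is offset by
sampling fluctuation of the voxelwise SD (relative SD ≈ 1/√(2(N−2)),
about 14% at N = 27, maximized over the ~10-mm search sphere). The
extracted value is therefore biased downward — median closed-loop error
is well under 15% of the planted amplitude, worst rows reach ~25–35%,
and the bias is always a loss, never inflation. This selection loss is a
property of peak-based ROI definition itself, not of the generator;
because it is shared across ROIs of a category cell it largely cancels in
the asymmetry indices, and group comparisons are unaffected (verified by
the calibration and sign-recovery tests). Per-ROI absolute amplitudes
from any peak-based sphere analysis should be read with the same caution
on real data.

**Table-level fast path.** Monte-Carlo checks that need hundreds of
cohorts (sign recovery of the planted age effect; type-I error with all
effects zeroed) skip volume rendering: `generate_roi_contrast_table`
draws contrast(s, r) = amp(s, r) + N(0, roi_noise_sd) with
roi_noise_sd = 0.4, chosen so the per-group index SDs land in the
0.2–0.3 range of the target means. Sign recovery (old L_AP below young at
13+14) succeeds in ≥95% of seeds; with effects zeroed the groups are
exchangeable and the L_AP comparison rejects at 5% ± 2% over 1000
cohorts.

**Determinism and seeding.** One master seed; profiles, each subject's
volumes, each subject's session and the table path draw from independent
`numpy` SeedSequence streams keyed by (seed, stream-tag, subject-index),
so identical configs give bit-identical cohorts regardless of generation
order, and tables round-trip bit-exactly through TSV (volumes through
NIfTI within float32 tolerance).

**What the generator does not emulate.** No BOLD time series, HRF
convolution, motion or physiological noise; no anatomical variability
beyond focus jitter; noise is stationary Gaussian, not spatially
heteroscedastic; behavior has no learning or fatigue trends. Passing
tests therefore validate the analysis machinery and its statistical
calibration, not robustness to those real-data complications.

## Numerical choices

* Sphere membership: voxel-centre Euclidean distance ≤ radius, boundary
  inclusive — deterministic and mirror-symmetric on symmetric grids.
* Smoothing: separable Gaussian, σ = FWHM/(2√(2 ln 2)) per axis in voxel
  units, kernel truncated at 4σ and renormalized to unit sum, reflective
  boundary — constants are preserved exactly.
* Coordinates: voxel indices 0-based; mm coordinates RAS+; all
  user-facing ROI coordinates in mm.
* The Left MTG catalog y-coordinate is set to −35 mm (mid-temporal,
  between ITG and ATL, consistent with its ventral z); the right MTG is
  the x-mirror of the left.
* Monte-Carlo problem sizes: the full volumetric pipeline is exercised at
  the study scale (27 subjects, 3-mm grid); repeated-cohort calibration
  checks use the table-level fast path (200 and 1000 cohorts), and
  structural unit tests use a 6-mm grid — the properties they check are
  geometry- and size-independent.

## Known limitations

* The exact Mann-Whitney path covers only untied samples; ties always go
  through the midrank-corrected normal approximation (the field
  convention, but an approximation at very small n).
* The mirrored ROI mode can place a right-hemisphere sphere slightly
  outside the right ROI's own search radius when the catalog is
  asymmetric (e.g. SFG); the independent per-hemisphere search is the
  default.
* The outlier screen is deliberately single-pass; a masked outlier
  surviving because another inflates the SD is accepted behavior, not a
  bug.
* `compare_groups` reports uncorrected p-values across the four indices
  by design; users wanting familywise control should apply their own
  correction.
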