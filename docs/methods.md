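# Methods

## The problem the package models

Hand and face somatosensory signals are relayed through pairs of abutting
nuclei: cuneate vs. spinal trigeminal in the dorsal medulla, VPL vs. VPM in
the thalamus, and the hand and face areas of S1. At 3T, the brainstem
members of this chain are a few millimetres wide, sit next to large vessels
and the fourth ventricle, and therefore show the lowest task SNR; S1 shows
the highest. The package simulates exactly this situation and runs the full
analysis chain used on such data, so that the chain's statistical
properties (calibration of permutation nulls, familywise error control of
the cluster corrections, sensitivity ordering across regions, the
dissociation between univariate and multivariate separability of adjacent
nuclei) can be verified by direct simulation.

## Phantom geometry

The atlas is a set of axis-aligned boxes in millimetre coordinates on a
configurable grid whose voxel centres are symmetric about the midline
(x = 0): brainstem, thalamus and S1 parent regions, and ten nuclei
(left/right cuneate, left/right spinal trigeminal, left/right VPL, VPM,
left/right S1-hand, S1-face). Right-hemisphere nuclei are exact index
mirrors of the left ones. Construction validates every invariant: all
masks nonempty, nuclei inside their parents and pairwise disjoint, cuneate
face-adjacent to the ipsilateral spinal trigeminal nucleus (at least one
shared 6-neighbour voxel pair), VPL adjacent to VPM. Default nucleus boxes
are 3.6–5.5 mm across — a few voxels at the 1.8 mm acquisition-like
resolution, matching the scale of the real nuclei. Violations raise a
`GeometryError` naming the offending mask.

Laterality wiring: hand movement drives the **ipsilateral** cuneate (the
dorsal-column pathway decussates above the nucleus) but the
**contralateral** VPL and S1-hand; face movement drives the trigeminal
pathway bilaterally (both spinal trigeminal nuclei, VPM, S1-face). The
wiring is a table and can be overridden.

## Generative model

For each condition a *template* amplitude map is drawn once per cohort:
within each wired nucleus a fraction `active_fraction` (default 0.7) of
voxels receives amplitudes uniform in [0.5, 1.5] × `amplitude`. For each
adjacent nucleus pair, a fraction `pattern_overlap` (default 0.3) of the
home condition's active voxels is additionally activated by the
neighbouring condition with independently drawn amplitudes; at overlap 1
the two conditions activate identical voxel sets with equal mean amplitude,
so the univariate contrast within the nucleus is centred on zero while the
voxelwise pattern geometry remains decodable — the brainstem-style
dissociation.

Subject s's map is `template × (1 + N(0, sv)) + N(0, sv·amplitude)` on the
template support, with `sv = subject_variability` (default 1.0). This is
the across-subject "partial sharing" knob: the subject-specific pattern
component is as strong as the shared one, which is what keeps
leave-one-subject-out decoding of the noisier regions well below ceiling,
standing in for the inter-subject misalignment and idiosyncrasy of real
group data that the phantom does not model geometrically.

A run's signal is the subject's amplitude map times the condition boxcar
convolved with the canonical HRF (so the GLM beta of an active voxel equals
its injected amplitude exactly; the noiseless round-trip test checks this
to 1e-6 relative error). Additive components:

* thermal Gaussian noise with per-region sd `amplitude / SNR_region`
  (defaults below);
* cardiac and respiratory sinusoids of the instantaneous physiological
  phase with random voxelwise gain and phase (default amplitude 0.4 on a
  baseline of 100);
* linear drift and a slow cosine (period 300 s) with random voxelwise
  coefficients.

Physiological traces: cardiac peaks at jittered intervals around 1 Hz; a
respiratory waveform as a sinusoid with slowly varying instantaneous
frequency around 0.3 Hz, sampled at 100 Hz (ample for a 0.3 Hz signal).
Per-run head motion is summarised by a scalar mean absolute displacement
drawn from a Gamma(2, 0.22) distribution, putting about 5% of runs above
the 1-mm exclusion threshold so the exclusion rule is exercised. Every
stochastic operation is a pure function of its inputs and a seed.

### Effect-size defaults and their calibration

`EffectSpec` defaults are `snr_s1 = 0.5`, `snr_thalamus = 0.16`,
`snr_brainstem = 0.05`, `subject_variability = 1.0`,
`pattern_overlap = 0.3`, `amplitude = 1.0`. The SNRs are in units of the
canonical regression coefficient over the thermal noise sd. The true
amplitude and granularity of nucleus activity is unknown, so these are
calibration knobs, not claims about physiology: they were chosen once, in
a pilot sweep, to realise the qualitative structure the phantom is meant
to embody — near-ceiling S1 decoding, intermediate thalamic decoding,
brainstem decoding modestly but reliably above the 33.3% chance level,
searchlight clusters that recover the active nuclei, and monotone
dependence of accuracy on SNR — and then frozen. They are not fit to any
empirical dataset.

## Analysis chain

* **Design**: 24 movement blocks per run (8 per condition), 12 s each
  followed by 6 s rest (432 s of task structure), counterbalanced order
  with no condition three times in a row and every condition present in
  every quarter of the run; a 15.5-s lead-in rest pads the run to
  179 × 2.5 s. Nominal volume bookkeeping uses ceil(12/2.5) = 5 volumes
  per block: 160 movement volumes per condition and 236 rest volumes over
  four runs.
* **HRF basis**: canonical double-gamma (peak delay 6 s, undershoot 16 s,
  ratio 6) with its temporal derivative (finite difference) and dispersion
  derivative (finite difference in the peak dispersion), each normalised
  to unit peak absolute value. Only the canonical coefficient is carried
  to contrasts and decoding features; the derivatives absorb latency and
  width variability.
* **High-pass**: discrete-cosine drift regressors with periods above 90 s
  (9 cosines for a 447.5-s run) plus an intercept, an exactly testable
  equivalent of a running-line filter.
* **Physio regression**: Glover-style phases — cardiac phase linear
  between peaks, respiratory phase from the histogram-equalised amplitude
  transfer signed by the waveform slope — evaluated at volume
  mid-acquisition times (slicewise assignment is not modelled, as the
  phantom has no slice-timing structure). Harmonics sin/cos(kφ) to order
  c and r; interaction columns sin/cos(mφc ± nφr) for all pairs m, n ≤ i
  (4i² columns — the only reading consistent with the 34-column total of
  the 4/4/2 + {HR, RVT} configuration); heart rate as the smoothed inverse
  inter-beat interval, RVT as breath amplitude over breath period, HRV as
  a 6-beat moving sd of inter-beat intervals, each linearly interpolated
  to volume times and not convolved with a response function.
* **GLM**: voxelwise OLS without prewhitening — the simulator's thermal
  noise is white, so autocorrelation modelling would be inert here.
  Contrasts are t statistics mapped through the t→normal probability
  transform to z. The movement-vs-all contrast uses weights +1 on the
  target and −0.5 on each other condition. Runs with mean absolute
  displacement strictly greater than 1 mm are excluded from the
  fixed-effects (univariate) path; decoding uses all runs. Fixed effects
  combine runs by inverse-variance weighting.
* **ROI statistics**: per-cell outlier replacement is a single pass (mean
  and sd computed once on the full cell; values beyond 2.5 sd replaced by
  that mean — an extreme value can therefore mask itself by inflating the
  sd, which is a property of the rule, not a bug). Shapiro-Wilk gates each
  condition cell at α = .05: any violation routes to Friedman's ANOVA
  with Kendall's W and Dunn's post-hoc; otherwise RM-ANOVA (pingouin) with
  Mauchly's test and Greenhouse–Geisser correction on violation, η²
  effect size, and planned paired contrasts (target vs. each non-target)
  with Bonferroni correction within ROI. Degenerate inputs (zero between-
  and within-condition variance) report F = 0, p = 1.
* **Group inference**: one-sample pseudo-t (variance Gaussian-smoothed at
  5 mm FWHM within the mask) under random sign flips of subject effect
  maps (default 5000; tests use 200), TFCE with E = 0.5, H = 2,
  26-connectivity, and `dh` = each map's max/100 — computing `dh` per map
  keeps the permutation statistics exactly exchangeable with the observed
  one — and FWE p values from the max-TFCE null with the identity flip
  included, so p ≥ 1/n_perm.
* **Decoding**: LinearSVC (L2, C = 1, one-vs-rest, no scaling or tuning)
  with leave-one-subject-out folds; pooled confusion matrix; permutation
  p from within-subject label shuffles (the exchangeable unit under LOSO),
  p = proportion of null ≥ observed with a 1/n_perm display floor.
* **Searchlight**: 3-mm spheres (offset sets enumerated exactly in world
  units), decoder identical to the ROI decoder, accuracy written at the
  centre voxel. One label shuffle per permutation map, reused across all
  centres. Cluster correction: the voxelwise accuracy cutoff is the 95th
  percentile of the pooled accuracies of all voxels of all permutation
  maps; observed and permutation maps are thresholded at it; the
  cluster-size cutoff is the smallest size whose exceedance probability
  under the per-map max-cluster-size null is ≤ .05 (26-connectivity);
  surviving clusters have at least that size.

## Problem sizes used in tests and the acceptance script

The full study conditions are 20 subjects × 4 runs × 179 volumes. The test
suite exercises the identical code paths at reduced scale, chosen as the
smallest sizes at which each property is still a sharp test: a
22³-voxel 1.8-mm grid throughout; 10 subjects × 4 runs for the decoding
ordering and searchlight checks (20 searchlight permutation maps); 10 × 2
for the permutation-null calibration (200 permutations); 50 replicates ×
200 permutations on 10³ masks for the sign-flip false-positive rate; 30
replicates × 200 permutation maps for the cluster-correction
false-positive rate. The acceptance script runs the full 20 × 4 cohort for
the sample bookkeeping and the 10 × 2 cohort for the null calibration.

## What passing tests do and do not show

The phantom has no EPI distortion, slice timing, k-space or registration
model; motion is a scalar per run, not an image transform; noise is white
(an AR structure can be added but is off by default, and no prewhitening
is applied); inter-subject variability is statistical (pattern
perturbation), not geometric (warps). Passing tests therefore establish
that the *analysis chain* is correct and calibrated — nulls centre on
chance, FWE procedures control error at their nominal level on
exchangeable data, recovery works when signal is present at the assumed
scale — not that real brainstem fMRI has decodable signal, which only real
data can show.

## Known limitations

* Searchlight permutation maps are computed serially; at full cohort scale
  they are the slowest step (minutes per hundred permutations).
* The Friedman path's Dunn post-hoc uses the large-sample normal
  approximation; exact small-sample tables are not implemented.
* Respiratory phase uses the empirical amplitude CDF of the whole run
  (equivalent to the histogram transfer in the limit of many bins) rather
  than a binned histogram.
* The t→z transform saturates at |z| ≈ 38 (double-precision tail limit).
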