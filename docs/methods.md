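# Methods

This note documents the models, algorithms and design choices behind
`vepasl`, in the spirit of the methods documentation of packages such as
statsmodels or msprime: what is computed, under which assumptions, and
where genuinely open choices were resolved.

## Signal model

A VEPCASL acquisition cycles through `E = 8` encoding configurations. For
encoding `e`, the measured volume at one PLD is modeled as

    S_e(v) = static(v) − Σ_a (1 − w_ea) · ΔM_a(v, t)

where `w_ea ∈ [−1, +1]` is the labeling efficiency of artery `a` under
cycle `e` (−1 fully labeled, +1 control) and `ΔM_a` the arterial difference
signal. With this convention, the all-control minus all-label volume equals
`2 Σ_a ΔM_a`. The static term subsumes un-subtracted tissue magnetization;
it is estimated and discarded during decoding.

Selective cycles use the standard sinusoidal efficiency model: an artery at
position `p` along the cycle's modulation direction gets
`w = −cos(π (p − p_low) / L)`, with the half-period `L` fixed so the two
targeted arteries sit at −1 and +1. The two cycles of each pair are exact
sign flips. The orientation of the diagonal pair is not uniquely
determined by the protocol description; the default scheme targets the
RICA/LVA axis and is fully configurable (`protocol.default_cycle_scheme`).
An idealized ±1/0 matrix is available (`build_encoding_matrix(...,
ideal=True)`) for controlled experiments. The augmented matrix (weights
plus a constant column) must have full column rank; degenerate geometries
are rejected.

Arterial kinetics follow the single-compartment continuous-labeling
solution: nothing before arrival (`t < Δt`), an inflow ramp during bolus
delivery (`Δt ≤ t < Δt + τ`), exponential decay afterwards, with flow
converted from ml/100 g/min via `f/6000`. Label decays with the blood T1
until arrival and with an apparent tissue T1′ afterwards. Bolus dispersion
and macrovascular signal are not modeled. Defaults (3 T conventions, all
configurable): T1b = 1.65 s, T1′ = 1.6 s, α = 0.85, T2csf = 0.75 s,
T2b = 0.15 s, blood/water density ratio 0.87, TE = 14 ms. Whether
post-arrival decay is governed by a tissue or blood T1 is ambiguous in
practice; T1′ is exposed in the configuration for exactly this reason.

With a 2D ascending multi-slice readout (24 slices in 1085 ms), slice `k`
experiences a PLD of `nominal + k·(readout/n_slices)`; the brain-average
effective PLD is `nominal + readout/2`, which reproduces the protocol's
printed 0.79–2.04 s schedule. All fitting uses the slice-specific times.

## Decoding

Each voxel's support class (which arteries feed it) is selected by MAP
estimation over a small class set: the empty set, all singletons and all
pairs (11 classes for 4 arteries). Supports of ≥3 major arteries are
physiologically rare and under-determined with 8 encodings; the maximum
support size is configurable. For each class the restricted linear system
(selected `−(1−w)` columns plus a static column) is solved by least
squares; the class score is the Gaussian log-likelihood of the residuals at
the voxel's noise level, plus a log class prior (flat by default), minus a
BIC complexity penalty of `(k/2)·ln N` per free parameter. The penalty
makes the nested-class comparison well-posed (a superset never loses on
residuals alone); ties resolve to the smaller support. Class selection is
shared across PLDs (log-posteriors summed) because a voxel's feeding
anatomy does not depend on the readout delay; per-PLD selection is a
trivial restriction if wanted.

Noise is estimated per voxel from paired repetition differences
(`Var(v₁−v₂) = 2σ²`), floored at the global median and at a tiny fraction
of the signal scale so noiseless simulations remain well-defined. Negative
per-artery estimates are clipped to zero after solving (rather than solving
a constrained problem); clipping beyond the noise level is counted and
logged. Decoding is equivariant under artery relabeling, and the
vectorized series decoder is exactly equivalent to the per-voxel routine
(both are tested against exhaustive class enumeration).

Detection limit: a collateral component whose signal energy across
encodings and PLDs is comparable to `2σ²·penalty` will not enter the
selected class and is reported as zero flow. On the phantom at temporal
SNR 5 this suppresses per-artery components below roughly 15–20
ml/100 g/min in mixed voxels — visible as a deficit in the 10–20 bin of
measured-Indirect-CBF histograms relative to ground truth. Real
acquisitions share this limit; the survival analysis is interpreted on the
*measured* axis.

## CBF/ATT fitting

The kinetic model is linear in flow, so the fit profiles CBF out in closed
form and searches ATT in one dimension: a deterministic 0.05 s grid over
the ATT bounds ([0, 3] s default) brackets the optimum, then vectorized
golden-section refinement converges to 1e−8. The objective is penalized
least squares, `RSS + σ²((Δt − μ)/s)²`, i.e. the MAP of a Gaussian-noise
model with a weak Gaussian ATT prior (μ = 1.3 s, s = 1.0 s) and a flat
non-negative prior on flow — the same posterior a variational inference
engine would target; the point estimates coincide at this scale. With
noiseless input the penalty vanishes and the fit is maximum likelihood.
Voxels whose peak |ΔM| is below 2× the noise SD are flagged low-signal and
reported with f = 0 at the prior-mean ATT — the practical limit for tissue
with very prolonged arrival. Estimates at the ATT bounds are flagged.

Identifiability caveat: once every sampled time point of a voxel lies after
the bolus has fully arrived (`t_min > Δt + τ`), CBF and ATT trade off along
a near-flat ridge (residual ATT sensitivity only through
`exp(Δt(1/T1′ − 1/T1b))`) and the split between them is unreliable even
without noise. With the default schedule this affects ATTs shorter than
about 1.2 s in the last slices; the weak prior regularizes the noisy case.

Absolute scaling: `M0 blood = trimmed-mean CSF signal × exp(TE(1/T2csf −
1/T2blood)) × 0.87`. The ventricular mean uses a 10% two-sided trimmed
mean against partial-volume contamination at the mask edge.

## Derived maps and ROIs

Weighted ATT is `Σ CBF_a·ATT_a / Σ CBF_a` (undefined where total CBF is
zero); in single-artery voxels it equals that artery's ATT. Direct CBF is
the ipsilateral-ICA component; Indirect CBF is the sum of the rest. For
contralateral ROIs the roles mirror: their "Direct" artery is the ICA of
their own hemisphere.

The ischemic core is `ADC < 620×10⁻⁶ mm²/s` with only the largest
26-connected component retained — a deterministic stand-in for
semi-automated delineation; an optional manual-edit mask can be
intersected. Shell ROIs dilate a mask with the set of voxel offsets whose
center-to-center physical distance is ≤ the radius (inclusive, honoring
anisotropic voxels) and subtract the original: 10 mm around the final
infarct (Surviving tissue), 20 mm around the core (Peri-core).
Contralateral equivalents mirror the *masks* about the mid-sagittal plane
first (nearest-voxel rounding; out-of-volume reflections dropped and
logged) and apply the gray-matter restriction afterwards — the order is not
dictated by the analysis description, and mirroring first keeps the two
hemispheres' ROIs geometrically congruent. Every ROI is restricted to gray
matter (partial volume strictly > 0.5) and clipped to its own hemisphere,
which replaces a manual opposite-hemisphere check; clipped voxel counts are
logged.

## Statistics

The survival analysis keeps Peri-core voxels, excludes those with Direct
CBF strictly greater than 25 ml/100 g/min (a voxel at exactly 25 is
retained, following the wording "more than 25"), bins the rest by Indirect
CBF in 10 ml/100 g/min ranges (top bin open at 80; bins with fewer than 10
voxels report no fraction), and computes the fraction outside the final
infarct. The above/below-25 comparison is a pooled two-proportion z-test
(two-sided); since 25 is not an edge of the 10-wide bins, the test is run
on an auxiliary 5-wide binning. A variant without the Direct-CBF exclusion
bins by either axis for Direct-vs-Indirect comparisons.

The Indirect-CBF fraction of an ROI is the ratio of ROI sums
(`ΣIndirect / ΣTotal`) rather than the mean of voxelwise ratios — robust to
near-zero-flow voxels; the voxelwise-mean variant is available. Patient
level comparisons use a two-way ANOVA (factors ROI and timepoint, with
interaction) on an OLS fit with Type-II sums of squares, appropriate for
the unbalanced designs that patient dropout produces. When the ROI effect
is significant at α = 0.05, per-timepoint two-sample t-tests follow;
they are unpaired because dropout breaks pairing in general. Voxels pool
across patients with equal weight.

## The phantom

The phantom emulates the study's input data, not its anatomy: an ellipsoid
brain (axes scaled to the field of view; 90×100×55 mm on the default
64×64×24 grid of 3.4×3.4×5 mm voxels) with a thick gray-matter shell
(PV 0.85 outside 0.4 of the normalized radius, 0.25 inside, 0 in a small
ventricular region), four soft vascular territories (sigmoid watersheds,
10 mm width: ICAs anterior right/left, VAs posterior), GM/WM CBF of
50/20 ml/100 g/min, ICA/VA transit times of 1.2/1.4 s plus a 0.2 s
center-to-surface gradient. Everything is mirror-symmetric about the
mid-sagittal plane so mirrored-ROI code is exactly testable.

Stroke scenarios modify a spherical MCA lesion (default center
(−55, 10, 0) mm, radius 30 mm): `no-collateral` multiplies the ipsilateral
ICA supply by 0.25; `collateral` additionally adds contralateral-ICA flow
that ramps from zero at the lesion's posterior side to up to
80 ml/100 g/min, with a smooth in-plane modulation (±25%) so intermediate
collateral levels are represented; `ica-occlusion` zeroes the RICA
everywhere, cross-fills its territory from the LICA at 80% and routes the
lesion collateral through the posterior circulation. All arteries gain a
0.3 s transit delay within 20 mm of the lesion — echoing the reported
peri-lesional arrival delay at presentation. The ischemic core is the
lesion subregion with total CBF below 15 ml/100 g/min; the ADC map is
800×10⁻⁶ mm²/s (3000 in ventricles) and 500×10⁻⁶ inside the core. The
final infarct is drawn per voxel in the lesion-plus-margin zone: survival
probability `logistic(0.15·(totalCBF − 20))`, seeded — so survival rises
with collateral supply by construction, and the statistics module can be
validated against a known generative rule. Static tissue is 100× the peak
difference signal; the noise SD is set for a target temporal SNR (default
5) on the repeat-averaged non-selective difference in normal gray matter.
The calibration image contains the CSF signal consistent with the
phantom's true blood M0, so the calibration chain closes exactly.

What the phantom does **not** emulate: realistic anatomy and texture,
motion, distortion, coil non-uniformity, registration error between
modalities or timepoints, bolus dispersion, partial-volume mixtures beyond
the GM map, or physiological noise. Passing tests therefore demonstrate
the correctness and statistical behaviour of the *analysis*, not clinical
performance on patient data. The study's patient-level values (e.g. its
Indirect-CBF fractions or ATT means) depend on unavailable clinical data;
the phantom cohort reproduces the direction and approximate structure of
those effects, not their magnitudes.

## Problem sizes and determinism

The default grid is the acquisition matrix (64×64×24, 96 volumes); the
test suite uses a 24×24×12 miniature for pipeline-level tests and the full
grid for the recovery checks. The acceptance script runs one full-grid
recovery experiment (SNR 5 and noiseless), a 10-patient × 2-timepoint
cohort at the full grid, and pools roughly 3×10⁴ peri-core voxels for the
survival analysis. Every stochastic step takes an explicit integer seed
(NumPy `default_rng`); pipelines rerun with the same seed are
byte-identical in their tabular outputs.

## Known limitations

- Class supports are capped at two arteries; genuinely three-fed voxels
  (rare watershed points) split their flow between the best pair.
- Non-negativity of decoded signals is enforced by clipping, not
  constrained estimation; at very low SNR this biases small components up.
- The ATT prior weakly shrinks estimates toward 1.3 s in noisy, poorly
  identified voxels; bias is negligible for voxels whose inflow is sampled.
- The two-proportion z-test treats voxels as independent; spatial
  correlation makes its p-values optimistic, as in the original analysis
  strategy it mirrors.
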