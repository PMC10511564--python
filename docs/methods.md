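# Methods

## Signal model

Magnitude Look-Locker inversion-recovery images are modeled with the
standard three-parameter form

    S(TI) = |A − B·exp(−TI / T1*)|

where `A` is the equilibrium amplitude, `B` the inversion amplitude and
`T1*` the apparent relaxation time under continuous readout. The
two-parameter ideal-inversion model is the special case `B/A = 2`,
`T1* = T1`. We use the three-parameter form because magnitude MOLLI
images are shaped by readout perturbation, and because it lets the
simulator shift the parenchyma null — and with it the peak-contrast
window — toward short TIs, as observed clinically.

Two knobs describe the readout in simulation and are deliberately
independent:

- `kappa` (default **1.4**): apparent relaxation `T1* = T1/kappa`.
  Vendor readout details are not public, so the factor is exposed
  rather than hard-coded; 1.4 places the parenchyma null near 324 ms
  for a 654 ms liver, inside the empirically favorable short-TI window.
- `b_over_a` (default **2.0**): inversion amplitude ratio, ideal
  inversion.

A consequence worth stating explicitly: the Look-Locker correction
`T1 = T1*(B/A − 1)` recovers the true T1 only when the readout
shortening is expressed through the fitted `B/A` (as it is in real
Look-Locker data, where `B/A ≈ 1 + T1*/T1`). With the decoupled
simulator defaults (`kappa = 1.4`, `B/A = 2`), a fit of simulated data
correctly recovers `A`, `B` and `T1*`, and the corrected value equals
`T1/kappa`, not `T1`. Simulations intended to validate T1 *recovery*
therefore use the self-consistent configuration `kappa = 1` (then
`T1* = T1` and the correction is exact); the default `kappa = 1.4` is
the configuration for *contrast* studies. For real data `B/A` is always
fitted, never assumed.

The VIBE comparator uses the spoiled-gradient-echo steady state
`S = M0·sin α·(1 − E1)/(1 − cos α·E1)`, `E1 = exp(−TR/T1)`, with
protocol defaults TR = 3.5 ms, α = 10°. TE/T2* decay is not modeled:
lesion-to-liver contrast in this framework is purely T1-driven, and the
short protocol TE (~1.4 ms) makes T2* effects second-order for the
tissues involved.

## Synthetic cohort

The generator emulates the statistical structure of a 1.5 T MR-guided
ablation population: 51 lesions in 44 patients with entity mix
CRC 20 / HCC 12 / melanoma 9 / breast 5 / NET 2 / pancreatic 1 /
CCC 1 / uveal melanoma 1, and six multi-lesion patients (five CRC
patients with two lesions, one breast-cancer patient with three —
the unique small-integer structure consistent with 51 lesions, 44
patients and 6 multi-lesion patients when only CRC and breast counts
allow multiplicity).

All continuous quantities are truncated normals whose *post-truncation*
mean is calibrated by root finding, so configured targets are exact
population means:

| quantity | mean ± sd (ms or mm) | bounds |
|---|---|---|
| lesion T1, CRC | 1319 ± 545 | [200, 4000] |
| lesion T1, HCC | 1063 ± 381 | [200, 4000] |
| lesion T1, other entities | 1126 ± 360 | [200, 4000] |
| liver T1, CRC patients | 609 ± 69 | [300, 1200] |
| liver T1, HCC patients | 712 ± 115 | [300, 1200] |
| liver T1, other patients | 665 ± 96 | [300, 1200] |
| lesion diameter | 19.1 ± 8.0 | [6, 41] |

The "other entities" parameters are not free: they are solved from the
published group means so that the 20/12/19 entity mixture reproduces
both the overall lesion mean (1187 ms; mixture sd then ≈ 490 vs the
reported 456) and the excluding-HCC mean (1225 ms), and likewise the
lesion-weighted liver mixture reproduces 654 ms overall and 636 ms
excluding HCC patients. The diameter sd of 8 mm is a choice — the
source population reports only mean and range, and ±2 sd ≈ the 6–41 mm
range. Liver T1 is drawn once per patient and shared by that patient's
lesions, so HCC patients carry the cirrhosis-typical elevated
parenchymal T1 into every comparison.

Each lesion becomes a single-slice digital phantom: nested discs
(parenchyma of radius 110 mm, lesion, optional necrotic core, optional
vessels) rasterized by pixel-center membership on a 256×256 grid at
400/256 ≈ 1.5625 mm spacing. Necrosis occurs with probability 0.2, at
0.45 of the lesion diameter, with T1 drawn 1.2–1.8× the lesion value;
cores below grid resolution or leaving a viable rim thinner than
~2.5 px are omitted, since the measurement model requires a placeable
ROI in viable tumor (clinically, lesions with ROI-defeating necrosis
would not have entered a signal-intensity analysis). Noise is Rician —
magnitude of the complex signal with equal per-channel Gaussian sigma;
the default sigma = 0.05 per unit M0 is SNR 20, at which the Rayleigh
floor `sigma·√(π/2)` visibly regularizes contrast near the parenchyma
null, the mechanism that keeps measured LLC finite there. The VIBE
comparator receives a channel sigma scaled so the reference liver
tissue (654 ms) has the same SNR as in the IR series.

### What the generator does not emulate

No anatomy (organ shape, vessels by default, bile ducts), no
respiratory motion, no coil profiles, no partial volume beyond binary
rasterization, no T2*/proton-density differences (lesion:liver M0 ratio
defaults to 1 and is exposed as a sensitivity knob), no vendor
reconstruction. Passing tests therefore demonstrate internal
correctness and calibration of the simulation chain — not that the
printed clinical contrast magnitudes are predictable from T1 physics
alone. Direction-of-effect checks (where the contrast peak sits, how it
decays at long TI) are the strongest claims the synthetic setup
supports.

## T1 fitting

Per sample vector, the fitter minimizes the RSS of the signed model
over an exhaustive polarity search: for each flip candidate
`k = 0..n`, negate the first `k` magnitude samples and run bounded
least squares (`scipy.optimize.least_squares`, trf) on
`A − B·exp(−TI/T1*)`; keep the lowest RSS, ties toward smaller `k`.
Starts: `A0 = max(S)`, `B0 = A0 + S[0]`, `T1*0` from a log-linear fit
of `log(A0 − S)` on the tail; bounds `T1* ∈ [50, 5000]` ms, `A, B > 0`;
tolerances 1e−12, at most 500 function evaluations. Non-convergence
(including the all-zero-signal pixel) is a flagged state carried
through maps, never an exception. Rician bias is not corrected —
magnitude least squares as-is, matching what vendor ROI tools do; at
SNR 50 the median relative T1 error over the 8-point protocol grid is
under 5% (verified for T1 ∈ {400, 654, 1184, 2000} ms, 500 replicates
each). Correctness is established against a brute-force oracle (1 ms
T1* grid with closed-form linear subproblems, locally refined to
0.01 ms): noiseless per-pixel agreement within 1 ms everywhere on a
16×16 phantom.

## ROI placement and LLC

"As large as possible, avoiding necrosis/vessels" is operationalized
deterministically: the lesion ROI is the largest pixel-center disc
inscribed in (lesion − necrosis) after a one-pixel erosion margin
(radius `ceil(EDT) − 2` maximized over centers, ties to the smallest
(row, col)); the parenchyma ROI has the identical radius and the valid
center nearest the lesion boundary. ROIs are placed once per lesion on
the label map and frozen across all conditions of that series. LLC is
`|SI_liver − SI_lesion| / SI_liver` from ROI means; records with an
exactly zero liver signal (possible only noise-free at the exact null
TI) are emitted as missing-with-reason, and downstream tests delete
pairwise. LLC is scale-invariant, so the pipeline is unaffected by
global image scaling — asserted exactly end-to-end.

## Statistics

Normality is screened with Shapiro–Wilk (flag = p > 0.05; constant
samples are an error, not a flag). Paired condition-vs-comparator
contrasts use a two-sided paired t when the differences pass the
screen, otherwise Wilcoxon signed-rank: exact null distribution for
n ≤ 25 without ties, else normal approximation with continuity
correction. The omnibus across the 9 repeated conditions is the
mid-rank Friedman chi-square with tie correction
(`1 − Σ(t³−t)/(nk(k²−1))`; a fully tied block reports statistic 0,
p = 1), followed by Dunn z-tests on mean ranks with
`SE = √(k(k+1)/6n)` and Bonferroni adjustment over the requested
family — by default the 8 "TI vs VIBE" contrasts; an all-pairs family
(m = 36) is available by flag, since which family the original analysis
used cannot be determined. Kruskal–Wallis (tie-corrected H) handles
independent groups, with an exact enumeration p-value for pooled
n ≤ 12. Calibration is verified by simulation: Friedman (n = 51,
k = 9) and Kruskal–Wallis empirical type-I errors fall in
[0.035, 0.065] at 5000 null replicates, and the Dunn–Bonferroni
family-wise error under the global null stays within the Bonferroni
bound at 2000 replicates. Exactness at small n is verified against
full-enumeration oracles (all 2ⁿ sign assignments; all group
partitions).

The significance threshold is 0.05 throughout (configurable). The
"rank-sum test for dependent samples" wording that sometimes appears in
clinical methods sections is internally inconsistent; for paired data
this package implements the signed-rank test.

## TI optimizer

Noise-free expected LLC is closed-form and diverges at the liver null
(that grid point is flagged undefined). With noise, expected LLC is
defined as `E|m_liv − m_les| / E[m_liv]` over ROI means of `roi_size`
(default 50) Rician pixels, estimated by Monte-Carlo with ≥ 10⁴ draws
per grid point and a fixed seed — matching the pipeline's measurement
(ROI means), not single-pixel statistics. Default grid 10–2000 ms in
2 ms steps, which resolves nulls at hepatic T1 scales. Argmax ties
break toward the smaller TI; an identical tissue pair returns the
smallest TI with a `no_contrast` flag rather than raising. Recommended
TIs transfer across field strength multiplicatively
(`scale_to_field`, default factor 1.3 for 1.5 T → 3 T, reflecting
longer tissue T1 at higher field).

The optimizer's noise-aware optimum for the default tissue pair sits at
the apparent parenchyma null (~320 ms), between the protocol's 228 and
548 ms samples. This is a model prediction about where contrast is
maximized under the stated assumptions, not a claim to reproduce
measured patient LLC magnitudes, which are shaped by factors the model
excludes (proton density, T2*, vendor reconstruction).

## Determinism and problem sizes

One master seed fans out to named sub-seeds
(`SeedSequence([seed, crc32(name)])`), so cohort sampling, per-lesion
noise and Monte-Carlo statistics are independently reproducible; equal
seeds give bit-identical images, tables and reports (hash-compared in
tests, including NIfTI round trips at float32). Default verification
sizes: 5000-lesion calibration cohorts (means checked within 2
standard errors), 500 noisy fit replicates per T1 value, 5000 null
simulations for omnibus calibration and 2000 for family-wise error,
51-lesion image cohorts at 256×256. These sizes give stable Monte-Carlo
estimates at interactive runtimes on a single core.

## Known limitations

- The MOLLI beat scheme (5(3)3), ECG-free timing jitter and
  phase-sensitive reconstruction are not simulated; the 8 printed TIs
  are taken as given sample times.
- Rician bias in T1 fitting is uncorrected by default (a noise-floor
  term can be enabled); at the default SNRs the residual bias is small
  relative to the 5% recovery criterion but systematic.
- Whether the vendor T1 map implements the same three-parameter fit is
  unknowable from public information; agreement asserted here is
  internal (fit vs oracle), not scanner equivalence.
- The single-slice, disc-geometry phantom cannot probe through-plane
  effects or ROI-placement ambiguity in real anatomy.
- Melanoma lesions can be T1-hyperintense in vivo; the generator draws
  all non-HCC/CRC entities from one hypointense-lesion distribution,
  and no melanoma-specific behavior is modeled.
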