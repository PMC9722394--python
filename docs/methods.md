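# Methods

## Scope

`nirsfc` implements a resting-state fNIRS functional-connectivity
screening analysis for amnestic mild cognitive impairment (aMCI): from raw
dual-wavelength light intensity to whole-brain / ROI / channel Fisher-z
connectivity, mass-univariate group statistics with FDR control, ROC-based
edge screening, and repeated cross-validated LDA classification.  Because
no public recording accompanies this kind of clinical cohort, the package
ships a synthetic cohort generator calibrated so that the full pipeline
reproduces the cohort-level group moments the analysis is designed to
detect.  Everything below is computed by the package itself; the test
suite and `scripts/acceptance.py` re-derive every number quoted here.

## Montage

71 measurement channels cover prefrontal, temporal, parietal and occipital
cortex and are partitioned into nine ROIs (LPF, RPF, LT, P, RT, LIP, RIP,
LO, RO; sizes 10/10/9/8/9/3/3/9/10).  The bundled table reproduces the
source montage verbatim, including three known typesetting quirks that are
handled explicitly rather than silently edited:

* channel 62 carries a stray "MO" (medial-occipital) tag although the
  partition defines nine ROIs; it is normalised to "RO" at load with a
  logged warning, and the alias map is configurable;
* rows 33-35 repeat the coordinates of rows 1-3; ROI membership, not
  coordinates, drives all computation, so the rows are kept as printed and
  the duplication is surfaced in a validation report;
* several right-occipital rows have negative x; coordinates are metadata
  and are stored verbatim.

## Preprocessing

The chain is QC -> optical density -> motion correction -> band-pass ->
modified Beer-Lambert inversion, in that order.

**Channel QC.** SNR of the raw intensity is mean(d)/std(d) expressed in
dB.  The dB convention is not uniquely determined by "a logarithmic
operation"; the amplitude-ratio form `20 log10` is the default (under
which realistic simulated intensities land near the conventional ~39 dB
channel quality), with `10 log10` available via `db_factor`.  A channel
fails QC when either wavelength falls below 10 dB; a subject is dropped
when more than 20% of channels fail (configurable), otherwise failing
channels propagate as missing edges.

**Motion artifacts.** Detection follows the moving-SD parameterisation
(`SDThresh=20`, `AMPThresh=3`, `tMotion=0.5 s`, `tMask=1 s`): a sliding
window of `tMotion` is artifactual when the max-min range of the
first-differenced OD inside it exceeds `SDThresh` times a robust scale of
the differenced series (1.4826 x MAD), or when the OD range exceeds
`AMPThresh` absolutely.  Operating on the differenced series is what makes
the moving-range statistic insensitive to smooth in-band excursions while
still catching spikes and baseline steps; the robust scale keeps the
threshold stable when artifacts are present.  Flagged windows are dilated
by `tMask` and merged.  Correction fits a cubic smoothing spline
(`p=0.99`, csaps convention mapped to `lambda=(1-p)/p` on a sample-index
abscissa) to each artifact segment, subtracts the fit, re-anchors the
segment to the preceding sample and level-shifts all subsequent samples
for continuity.  This removes slow motion bumps and baseline steps;
single-sample spikes are intrinsically outside what a near-interpolating
spline can model (the usual argument for wavelet or PCA methods, which are
out of scope here).  Correction operates on OD — standard practice for
spline methods — although the raw-intensity domain would be an easy
variant.

**Filtering.** Zero-phase 3rd-order Butterworth band-pass, 0.01-0.1 Hz,
applied forward-backward (`sosfiltfilt`), so the effective order is 6 and
stopband attenuation at the cardiac (~1.1 Hz) and respiratory (~0.25 Hz)
bands exceeds 20 dB while passband ripple at 0.05 Hz stays below 1 dB.
Tests verify the spectral specification and the zero-lag property.

**Beer-Lambert inversion.** Per time point the 2x2 system
`dOD(lambda) = [eps_HbO(lambda) dHbO + eps_HbR(lambda) dHbR] * DPF * L`
is solved with DPF = 6.0 and L = 3 cm.  The extinction coefficients at
730/850 nm are the Prahl/Gratzer compilation values, stored as a data file
and used identically by the simulator's forward model, so the forward and
inverse directions are exactly consistent (tested to 1e-12).

## Connectivity

Pearson correlation of HbO time courses over the full recording, Fisher
r-to-z (`z = atanh r`), with |r| clipped at 1-1e-7 before the transform so
z stays finite (clip value atanh(1-1e-7) = 8.406; immaterial for any
statistic).  All analysis uses HbO only, the convention justified by its
higher SNR and closer coupling to cerebral blood flow; HbR is simulated
only to make the two-wavelength inversion well-posed.  Levels:

* channel: 71 x 71, i.e. 71*70/2 = 2485 undirected edges; the whole-brain
  summary is the mean over those 2485 upper-triangle entries (missing
  entries excluded and counted);
* ROI: each ROI's passing member channels are averaged in the time domain
  first, then the nine mean series are correlated (9 x 9, 36 edges).  The
  sentence ordering "average the time series, then correlate" is the
  chosen reading of an ambiguous convention; averaging channel-level z
  values over ROI blocks is available via `roi_fc(..., average="edges")`
  for sensitivity analysis.

## Group statistics

Per edge: equal-variance pooled two-sample t (df = n1+n2-2 = 126 at
64/64 — the printed df is what forces the pooled rather than Welch form;
Welch is not offered because the df contract would silently change),
two-sided p, Benjamini-Hochberg FDR within each analysis level's edge
family (2485 channel edges; 36 ROI edges), and ROC screening.  AUC uses
the Mann-Whitney identity oriented so edges weakened in the patient group
score above 0.5; the operating point maximises Youden's J, with
sensitivity = fraction of MCI below threshold and specificity = fraction
of HC at or above it (the operating-point convention is not uniquely
fixed by a sensitivity/specificity table alone, so Youden is used and
recorded in the output).  Screening rules: ROI edges with FDR < 0.05 and
AUC > 0.65; channel edges with FDR-adjusted p < 0.01.

## Classification

Two-class LDA from class means, pooled within-class covariance and
training-fraction priors (ridge jitter 1e-8 on a singular covariance).
Accuracy comes from stratified 5-fold cross-validation, repeated N = 10
times with fresh fold partitions; the per-repeat accuracy pools
correct/total over the concatenated validation folds (mean-of-fold-means
via `aggregate="fold_mean"`), and reports give the ten per-repeat values,
mean +/- SD and maximum.  Feature sets are each screened edge alone plus
the per-level union ("All above").  Edge screening is frozen on the full
cohort before cross-validation — deliberately reproducing the screening
procedure, which is optimistically biased; a nested-selection variant
would be the leakage-free alternative and is out of scope.  One master
seed derives all per-repeat fold seeds.

## Synthetic cohort generator

The generator emulates: nine-ROI latent band-limited (0.01-0.1 Hz)
Gaussian hemodynamics with group-dependent inter-ROI correlation;
within-ROI channel mixing (each channel carries `channel_mix` = 0.85 of
its ROI signal variance plus independent band-limited noise); HbO
fluctuations of 0.2 uM RMS with HbR = -0.3 HbO plus noise; forward
Beer-Lambert to dual-wavelength OD (DPF 6.0, L 3 cm); cardiac (~1.1 Hz),
respiratory (~0.25 Hz) and Mayer-band (~0.095 Hz) sinusoids with
per-subject frequency jitter and per-channel random phase, in OD units;
linear drift; multiplicative-baseline sensor noise (1e-3 of baseline
intensity, ~40 dB channel SNR); and Poisson motion events (1/min across
the probe; 60% Gaussian spikes of 0.05-0.2 OD, 40% baseline steps of
0.02-0.08 OD), logged in the ground truth.

**Calibration.** Group coupling is specified on the observed Fisher-z
scale.  Channel mixing attenuates ROI-level correlation by
`alpha_AB = m / sqrt((m+(1-m)/k_A)(m+(1-m)/k_B))` (k = ROI sizes), which
`simulate_subject` inverts analytically per subject, so the expected
post-pipeline ROI z equals the specified coupling.  Six long-range pairs
(RPF-RO, RPF-LIP, LPF-LO, RPF-P, LPF-P, RPF-LO) take the tabulated group
means (e.g. RPF-LO: HC 0.77, MCI 0.60); the remaining 30 pairs share a
per-group baseline solved by root-finding so the channel-level whole-brain
mean z equals 0.85 (HC) / 0.74 (MCI).  Between-subject heterogeneity is a
global z offset shared by all edges (SD 0.225, matching the printed
between-subject SDs of the whole-brain mean, ~0.21-0.22) plus independent
per-edge jitter (SD 0.05); together with the ~1/sqrt(n_eff) sampling
noise of a band-limited correlation (n_eff ~ 2 x bandwidth x duration ~
100) this reproduces per-edge between-subject SDs of ~0.25.  A small
residual attenuation of the full pipeline (nuisance leakage at the band
edge, motion residue, finite-sample curvature) was measured with the
calibration oracle on replicate cohorts -- 0.009 in z for the
stronger-coupled group and 0.018 for the weaker-coupled one -- and is
compensated additively when the coupling targets are built.  Jittered
subject matrices are projected to the nearest unit-diagonal PSD matrix by
eigenvalue clipping when needed.

**What the generator does not emulate** — and hence what passing tests do
not show about real recordings: scalp/skull partial-volume and photon
transport (no Monte Carlo light model, no short-separation channels),
non-sinusoidal and spatially coherent systemic physiology (Mayer phases
are randomised per channel, so systemic confounds cannot masquerade as
connectivity here, which they can in vivo), non-Gaussian heavy-tailed
artifacts, non-stationarity, and any structured relationship between
disease status and data quality.  Recovery of the printed moments by
this pipeline on synthetic cohorts validates the pipeline's statistical
machinery and calibration, not the clinical effect itself.

## Problem sizes and numerical choices

Acceptance-style runs use 10 cohort replicates of 64+64 subjects at the
full 71 x 2 x 11400-sample recording size; the scaled-down calibration
property test uses 12 replicates of 12+12 subjects at 300 s.  Seeds:
every cohort draws from `SeedSequence([master_seed, group_index,
subject_index])`, so any subject is reproducible in isolation; CV fold
seeds derive from one master seed.  Degenerate inputs are handled
explicitly: zero-variance series yield missing edges (logged), segments
shorter than four samples fall back to linear detrending, singular pooled
covariance gets ridge jitter, non-positive simulated intensities are
clipped at 1e-6 with a warning.

## Known limitations

* The accuracy granularity of the reference report (multiples of ~1/88)
  implies a validation-set bookkeeping that cannot be reconstructed from
  its description; accuracies here are pooled over 128 subjects per
  repeat.  (The reference's "62 MCI samples" in one place conflicts with
  n=64 elsewhere; n=64 per group is used, consistent with df=126.)
* Feature screening before CV (by design, see above) inflates accuracy
  relative to nested selection.
* Under the shared-Gaussian model, a single edge's t statistic, ROC AUC
  and optimal classification accuracy are all monotone functions of one
  standardized effect size d; they cannot be calibrated independently.
  The calibration fixes the group means and between-subject SDs (hence
  d ~ 0.68 for the strongest edge), and AUC (~0.69) and single-edge LDA
  accuracy (~63-65%) follow from it.
* Spline correction leaves sub-sample spikes untouched by construction.
* The SNIRF writer emits a minimal continuous-wave subset (intensity,
  measurement list, wavelengths), not the full standard.
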