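# Methods

`qusrm` re-implements a quantitative-ultrasound (QUS) treatment-response
monitoring analysis as a tested pipeline on synthetic data: RF frames are
reduced to parametric maps of seven spectral/scatterer parameters, maps to
texture features, features to a multi-feature SVM response classification,
and response groups to recurrence-free-survival curves.  This note records
the models, the numerical choices made where the method description left
the design open, and what the synthetic generators do and do not emulate.

## RF simulation

Each scan line is synthesized in the frequency domain as a linear
superposition of point-scatterer echoes,

    S(f) = P(f) · sqrt(F(f)) · Σ_j A_j · 10^(−2 α f z_j / 20) · e^(−i 2π f t_j)

with `P` a Gaussian-envelope pulse at the 7 MHz center frequency whose
−6 dB (half-amplitude) full width is `pulse_bandwidth_fraction · f_c`
(default 5/7, matching a 4–9 MHz band), `F` the Gaussian form factor
`exp(−0.827 k² a_eff²)` of the medium's effective scatterer radius,
`t_j = 2 z_j / c` the round-trip delay and `α` the attenuation slope in
dB/(cm·MHz).  Scatterer positions are uniform, amplitudes zero-mean normal
with the configured impedance-contrast variance; a volumetric number
density is converted to per-line counts through a nominal 1 mm elevational
slice.  Assumptions: single scattering, no beamforming or aberration, no
elevational dimension, attenuation applied exactly in the frequency domain
per scatterer depth.

Two deliberate simplifications matter for interpretation:

* The frequency-flat Rayleigh prefactor (`f⁴` in intensity) is absorbed
  into the pulse rather than applied per scatterer.  Every estimator in the
  package is reference-phantom normalized, so only frequency dependence
  *relative to the reference* is observable; the analytic reference
  backscatter model supplies the `f⁴` explicitly.  A side effect is that
  the simulated spectral peak sits at the pulse center rather than being
  pushed toward the upper band edge.
* Attenuation bookkeeping uses the dB convention throughout: one-way
  amplitude loss `α f z` dB implies a round-trip *power* loss of
  `2 α f z` dB.  (The familiar factor 4 belongs to the Np-amplitude
  convention, `exp(−4 α_Np f z)` in intensity; the two agree through
  `α_dB = 8.686 α_Np`.)  Simulator, normalization and attenuation
  estimation all share this constant, which the self-normalization nullity
  tests pin down.

The periodic phantom superimposes an axial lattice of strong scatterers
(10× the diffuse amplitude) at spacing `d`, each position independently
perturbed by `jitter · d · N(0,1)` with jitter restricted to [0, 0.5); the
lattice corrugates the spectrum with period `Δf = c / 2d`, which must fit
inside the analysis band.

## Spectral QUS estimation

ROIs are tiled into 10λ × 10λ windows (λ = c/f_c; 2.2 mm at 7 MHz) with 94%
overlap; the hop is rounded to whole samples/lines with a floor of one, and
the grid count along an axis is `floor((L − W)/hop) + 1`.  Per window the
power spectrum is the line-averaged Hann periodogram with FFT length the
next power of two at or above the window height (the source description is
silent on taper and FFT length; Hann is standard leakage control).

Normalization subtracts the matched reference-phantom window spectrum (in
dB) and adds the attenuation compensation `2 (α_s − α_r) f z` at the
window-center depth (point compensation).  The reference phantom is modeled
on a glass-bead calibration phantom: attenuation 0.576 dB/(cm·MHz), sound
speed 1488 m/s, bead radii small enough that its form factor is nearly flat
over 4–9 MHz.

* **MBF / SS / SI** — ordinary least squares of normalized power (dB)
  against frequency (MHz) over the 4–9 MHz band; SS is the slope, SI the
  0 MHz intercept, MBF the fitted value at the 6.5 MHz band midpoint, so
  `MBF = SI + SS · 6.5` holds identically.
* **ACE** — spectral difference method: per band frequency, the
  sample-minus-reference dB difference is regressed on depth (cm); those
  slopes are linear in frequency with slope `−2 (ACE − α_ref)`, solved for
  ACE.  The package estimates ACE per lateral grid column (each column
  supplies the depth series) and re-uses the ROI-mean ACE to compensate the
  MBF/SS/SI/BSC windows — attenuation before backscatter, since the
  compensation needs it.  Estimates outside a configurable physical range
  (default 0–3 dB/(cm·MHz)) are flagged.

## Scatterer models

**ASD / AAC.**  The sample backscatter coefficient is the analytic
reference BSC times the linear power ratio of the normalized spectrum.  The
spherical Gaussian model `bsc(f) = A · f⁴ · exp(−0.827 k² a_eff²)` is
fitted in linearized form: `ln(bsc) − 4 ln f` regressed on `f²`; the slope
maps to the effective radius (ASD = 2 a_eff, reported in μm) and the
intercept to the acoustic concentration (AAC, reported as 10·log10 in
dB/cm³).  A positive slope is non-physical (form factors only decay) and
returns ASD = 0 with a cleared convergence flag; the `f⁴ · const` Rayleigh
limit correctly lands at ASD = 0.  The model prefactor is a configuration
constant; it cancels in the round trip between the phantom spec
(`AAC = 10 log10(n σ²)`) and the fit.

**SAS.**  The RF segment of each line is modeled as an autoregressive
process (Burg coefficients via statsmodels), its all-pole spectrum
evaluated on a fine in-band grid and normalized by a planar-reflector
reference (emulated by the pulse spectrum).  Prominent peaks (≥ 3 dB) are
located; the per-line spacing estimate is `c / (2 Δf)` with `Δf` the
*median adjacent-peak spacing* — a true lattice corrugates the whole band
periodically, so the median is robust against single spurious peaks.  The
block estimate is the median across lines, flagged undefined when fewer
than half the lines yield a spacing or when the per-line spacings disagree
(relative IQR > 0.15): diffuse speckle produces incidental AR peaks with
inconsistent spacing, a lattice locks every line to the same corrugation.
The default Burg order scales with the gate (one pole pair per ~15
samples, clipped to [12, 60]); a fixed low order cannot hold enough
in-band poles to represent a ~0.8 MHz corrugation, and its intrinsic
peak spacing would masquerade as a spacing estimate.

## Texture features

Each parametric map is min–max quantized to 16 gray levels (uniform bins,
maximum mapped to the top level — making all texture features invariant to
affine rescaling of the map).  Sixteen symmetric, normalized gray-level
co-occurrence matrices are built (distances 1–4 pixels × angles
0°/45°/90°/135°, with 0° the lateral neighbor and 90° the axial neighbor;
diagonal offsets step the full distance per axis).  Masked cells contribute
no pairs.  From each GLCM the Haralick contrast, correlation, energy and
homogeneity are computed and averaged over the sixteen configurations.
Correlation of a zero-variance marginal is reported as 1 with a warning;
constant maps yield the degenerate set CON = 0, ENE = HOM = COR = 1.
Textures are computed for the MBF, SS, SI, SAS, ASD and AAC maps (24
features); ACE carries no textures.

## Feature vectors and response labels

The response rule: complete responder (CR) when there is no clinical tumor
evidence and no invasive residual carcinoma; partial responder (PR) when
the tumor shrank by at least half with significantly decreased cellularity
(a pathology-supplied input flag); non-responder (NR) otherwise.  The
per-scan classifier input has exactly 65 named entries in fixed order: 7
baseline QUS means, 24 baseline textures, their 31 week-minus-baseline
changes (absolute differences, not percents), and ER/PR/HER2 encoded +1/0.
Names use `MBF0` for baseline and `dMBF` / `dAAC-ENE` for changes.

## Classification protocol

The cohort is imbalanced, so the protocol draws `n_subsets` (default 10)
random class-balanced subsets, each class subsampled without replacement to
the minimum class size.  Per subset: exhaustive RBF-SVM grid search over
C ∈ {2⁸…2¹⁵} and γ ∈ {2⁻¹⁸…2⁻⁵} by leave-one-out accuracy (ties to the
smallest C then γ); sequential forward selection to six features by the
same LOO criterion (ties to the lowest column index); LOO validation of the
selected model.  Standardization is refit on the training fold of every
split; the multiclass rule is SVC's one-vs-one voting.  Reported accuracy
is the mean over subsets (pooling across subsets is not offered, since
subsets overlap).  Features selected across subsets pool into an occurrence
histogram whose top entries, ties broken by fixed feature order, form the
consensus set.  The binary task merges CR + PR into R before balancing.

Two practical notes on LOO with small balanced samples, both established
empirically during development and reflected in the tests:

* Greedy SFS does not guarantee a non-decreasing LOO-accuracy sequence —
  a forced extra noise feature can lower the attainable accuracy.  The
  guaranteed property is per-step greedy optimality, and that is what the
  suite asserts.
* Under label permutation, LOO accuracy is biased a few points *below*
  1/k, because the held-out sample's class is always the training
  minority; with a near-flat kernel (tiny γ) the classifier degenerates to
  training-majority voting and the null accuracy collapses toward zero.
  Permutation-null checks therefore use balanced classes and the most
  local γ of the grid (2⁻⁵), where the residual bias is within the
  sampling error of 50 permutations.

## Statistics and survival

Group comparisons gate on Shapiro–Wilk normality at α = 0.05, requiring
every group to pass (the conjunction was unspecified; "all pass" is the
conservative reading): then unpaired equal-variance t-test or one-way ANOVA,
otherwise Mann–Whitney U or Kruskal–Wallis.  A Welch flag exists but is off
by default to mirror the plain unpaired test.  Post-hoc pairwise p-values
are Bonferroni-multiplied and capped at one when correction is requested.
Survival uses the Kaplan–Meier product-limit estimator (lifelines) with
right censoring and the (multivariate) log-rank test; times are months from
treatment start and "5-year" queries evaluate S(60).

## Synthetic cohort

The cohort generator emulates a 96-patient three-group cohort (21 CR,
52 PR, 23 NR by default).  Per group it draws molecular receptor statuses
from fixed prevalences (e.g. ER+ 28.6% / 63.5% / 82.6% for CR/PR/NR),
tumor sizes consistent with the group's label rule (CR shrink to zero, PR
shrink 50–66%, NR shrink ≤ 10%), per-scan features as population baseline +
patient random effect + group trajectory effect + noise, and exponential
recurrence times censored at a 60-month horizon.  Default trajectory
effects are qualitative: backscatter parameters (MBF, SI, AAC) and their
energy/contrast textures rise over weeks 1–8 for responders, roughly
half-strength for PR, flat for NR; magnitudes are configuration, not
clinical claims.  Default hazards are calibrated so the 5-year
recurrence-free survival is ≈ 100% / 89.7% / 66.4%.  The generator does not
emulate: scanner drift, intra-tumor heterogeneity of trajectories, missing
scans, correlated features (features are independent given the group
effect), or informative censoring — so passing tests demonstrate protocol
correctness and recoverability of planted effects, not clinical
performance.

## Problem sizes and determinism

Simulation-backed tests use compact phantoms (8–20 mm extents, ~150
scatterers/mm³), 5–20 seeded replicates, and reduced classifier settings
(cohorts of ~30–40, 8 features, 2×2 parameter grids, 5 subsets) chosen as
the smallest problems that still exercise every protocol stage; the full
8×14 grid, the 21/52/23 cohort and the 65-feature table are exercised where
they are cheap (enumeration, balancing, assembly) and in the acceptance
script's cohort classification.  Every stochastic component takes an
explicit seed; the pipeline derives per-stage sub-seeds from one run seed
via `numpy.random.SeedSequence.spawn`, and reruns with identical config and
seed are byte-identical.

## Known limitations

* No full-wave acoustics, beamforming, or elevational focusing; diffraction
  and depth-dependent system effects are absent, so reference-phantom
  normalization is exact by construction rather than approximately so.
* ACE is estimated per lateral column and applied as a single ROI mean
  (point compensation); distribution compensation is not implemented.
* SAS on clinical-scale 10λ gates is under-resolved for ~1 mm spacings;
  reliable recovery needs longer gates, as used in the tests.
* The SGM prefactor and the acoustic-concentration scale are internal
  conventions; AAC values are comparable within the package, not absolute.
* No missing-scan imputation, no Cox regression, no probability
  calibration, no alternative learners.
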