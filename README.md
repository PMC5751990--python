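# qusrm — quantitative ultrasound response monitoring

`qusrm` is a testable re-implementation of a quantitative-ultrasound (QUS)
pipeline for monitoring breast-tumor response to neoadjuvant chemotherapy.
Clinical studies of this kind record raw radio-frequency (RF) ultrasound
frames of locally advanced tumors before and during treatment, reduce them
to tissue-microstructure parameters, and ask whether those parameters —
well before any size change — predict which patients will respond.  The
package implements every computational stage of that analysis and pairs it
with synthetic RF-phantom and patient-cohort simulators with known ground
truth, so that each estimator can be validated end to end without clinical
data.

It is aimed at researchers in ultrasound tissue characterization and
quantitative imaging who need a reference implementation of the estimation
chain, the classification protocol, or the simulators.

## What it computes

From each tumor ROI, tiled into 10λ × 10λ windows with 94% overlap, the
pipeline estimates seven QUS parameters:

* **MBF, SS, SI** — midband fit (dBr), spectral slope (dBr/MHz) and 0-MHz
  intercept (dBr) of a line fitted to the reference-phantom-normalized
  backscatter power spectrum over the 4–9 MHz band; `MBF = SI + SS·f_mid`
  identically.
* **ACE** — attenuation coefficient estimate, dB/(cm·MHz), by the spectral
  difference method (depth rate of the sample-minus-reference spectrum is
  linear in frequency with slope −2·(ACE − α_ref)).
* **ASD, AAC** — effective scatterer diameter (μm) and acoustic
  concentration (dB/cm³) from a spherical Gaussian scatterer-model fit,
  `bsc(f) ∝ A·f⁴·exp(−0.827 k² a_eff²)`, to the backscatter coefficient.
* **SAS** — scatterer spacing (mm) from autoregressive (Burg) spectral
  analysis: a quasi-periodic scatterer lattice corrugates the spectrum
  with period Δf, and `SAS = c / (2Δf)`.

Parameter maps feed gray-level co-occurrence textures (contrast,
correlation, energy, homogeneity averaged over 16 distance–angle
configurations), which combine with week-minus-baseline changes and
ER/PR/HER2 receptor status into a 65-entry feature vector per patient per
scan time.  An RBF-SVM protocol (10 class-balanced subsets, C/γ grid
search, sequential forward selection to six features, leave-one-out
validation, consensus feature histogram) classifies complete / partial /
non-responders, and Kaplan–Meier + log-rank analysis compares
recurrence-free survival between groups.  Group statistics use a
Shapiro–Wilk normality gate that chooses t-test/ANOVA or their rank-based
alternatives.

See `docs/methods.md` for models, conventions and design decisions.

## Worked example

Simulate a tumor-like phantom (120 μm scatterers, attenuation
1.0 dB/(cm·MHz)), extract maps against reference-phantom frames, and read
off textures:

```python
from qusrm import (AcquisitionConfig, PhantomSpec, REFERENCE_PHANTOM,
                   simulate_phantom_rf, QusExtractor, ExtractionConfig,
                   texture_features)

acq = AcquisitionConfig()          # 40 MHz sampling, 7 MHz center, 4-9 MHz band
tumor = PhantomSpec(effective_radius=60e-6, attenuation_slope=1.0,
                    extent=(12e-3, 6e-3), number_density=300.0)
ref = PhantomSpec(effective_radius=REFERENCE_PHANTOM.effective_radius,
                  attenuation_slope=0.576, sound_speed=1488.0,
                  extent=(12e-3, 6e-3), number_density=150.0)

frame = simulate_phantom_rf(tumor, acq, seed=11)
refs = [simulate_phantom_rf(ref, acq, seed=100 + i) for i in range(2)]
extractor = QusExtractor(acq, refs, ExtractionConfig(overlap=0.8))
maps = extractor.maps(frame, (0, 0, frame.n_samples, frame.n_lines),
                      params=("MBF", "SS", "SI", "ACE", "ASD", "AAC"))
for name, pmap in maps.items():
    print(f"{name:4s} mean = {pmap.mean:8.3f} {pmap.units}")
tex = texture_features(maps["AAC"])
print(f"AAC textures: CON={tex.con:.3f} COR={tex.cor:.3f} "
      f"ENE={tex.ene:.3f} HOM={tex.hom:.3f}")
```

```
ACE  mean =    1.030 dB/(cm MHz)
ASD  mean =  117.949 um
MBF  mean =   -5.843 dBr
SI   mean =   10.810 dBr
AAC  mean =   26.054 dB/cm^3
SS   mean =   -2.562 dBr/MHz
AAC textures: CON=12.263 COR=0.247 ENE=0.016 HOM=0.389
```

The attenuation round-trips to 1.03 dB/(cm·MHz) against a true 1.0, and
the scatterer diameter to 118 μm against a true 120 μm — the residuals are
speckle noise, which shrinks with more reference frames and windows.

Classify a synthetic 96-patient cohort (21 CR / 52 PR / 23 NR, responder
groups given rising backscatter trajectories) at week 4:

```python
from qusrm import (CohortSpec, simulate_cohort, cohort_feature_table,
                   ClassifierConfig, run_response_classification)

records = simulate_cohort(CohortSpec(seed=0))
table = cohort_feature_table(records, "week4")   # 96 rows x 65 features
config = ClassifierConfig(c_grid=(2**8, 2**12), gamma_grid=(2**-14, 2**-8),
                          n_subsets=5, seed=0)
for mode in ("combined", "molecular"):
    res = run_response_classification(table, config, mode=mode)
    print(f"{mode:9s} mean LOO accuracy = {res['mean_accuracy']:.1f}%")
    if mode == "combined":
        print("consensus features:", res["consensus_features"])
```

```
combined  mean LOO accuracy = 82.2%
consensus features: ['dMBF', 'dAAC-ENE', 'SI-ENE0', 'dSI', 'dMBF-ENE', 'HER2']
molecular mean LOO accuracy = 52.4%
```

Combined QUS + texture + molecular features beat receptor status alone, and
the consensus histogram surfaces the planted trajectory features (changes
in MBF, SI and AAC energy) together with HER2.  The full 8 × 14 parameter
grid (`ClassifierConfig()` defaults) behaves identically and takes a few
minutes.

A `qusrm` command-line interface wraps the stages
(`simulate`, `extract`, `texture`, `classify`, `survival`, `run-all`);
`qusrm run-all --seed 3 --out run/` executes the whole pipeline and writes
a checksummed manifest for reproducibility.

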