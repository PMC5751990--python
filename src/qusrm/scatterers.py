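"""Backscatter-coefficient scatterer-property estimation.

Two families of estimates:

* **ASD / AAC** — effective scatterer diameter and acoustic concentration
  from a spherical Gaussian scatterer model (SGM).  The model backscatter
  coefficient is ``bsc(f) = A * g0 * f^4 * exp(-0.827 k^2 a_eff^2)`` with
  ``A`` the linear acoustic concentration, ``k = 2 pi f / c`` and ``a_eff``
  the effective radius.  Taking ``ln(bsc) - 4 ln(f)`` linearizes the fit:
  the slope against f^2 maps to the radius, the intercept to the
  concentration (reported as 10 log10, dB/cm^3).
* **SAS** — the mean axial spacing of quasi-periodic scatterers, from
  autoregressive (Burg) spectral analysis of the RF segment: a lattice of
  spacing d corrugates the spectrum with period ``delta_f = c / (2 d)``, so
  the spacing of dominant AR-spectrum peaks inverts to SAS = c / (2 delta_f).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, peak_prominences
from statsmodels.regression.linear_model import burg

from .acquisition import AcquisitionConfig, PhantomSpec
from .simulate import FORM_FACTOR_CONSTANT, gaussian_pulse_spectrum
from .spectral import PowerSpectrum, WindowBlock

__all__ = [
    "BackscatterCoefficient",
    "ScattererEstimate",
    "SpacingEstimate",
    "sgm_bsc",
    "reference_bsc",
    "estimate_bsc",
    "fit_sgm",
    "planar_reference_spectrum",
    "ar_power_spectrum",
    "spacing_from_peak_frequencies",
    "estimate_sas",
]


@dataclass
class BackscatterCoefficient:
    frequencies: np.ndarray  # Hz
    bsc: np.ndarray          # relative linear units
    depth: float = 0.0
    valid: bool = True

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.bsc = np.asarray(self.bsc, dtype=float)
        if self.frequencies.shape != self.bsc.shape:
            raise ValueError("frequency and bsc arrays must match")


@dataclass(frozen=True)
class ScattererEstimate:
    asd: float           # effective scatterer diameter, um
    aac: float           # acoustic concentration, dB/cm^3
    fit_residual: float
    converged: bool = True


@dataclass(frozen=True)
class SpacingEstimate:
    sas: float               # mm; NaN when undefined
    peak_prominence: float   # dB prominence supporting the estimate
    ar_order: int
    defined: bool = True


# Dimensionless prefactor of the SGM backscatter model (f in MHz).  The
# absolute scale cancels in reference-phantom ratios; only its consistency
# between the analytic reference model and the fit matters.
SGM_PREFACTOR = 1.0


def sgm_bsc(freqs_hz: np.ndarray, asd_um: float, aac_db: float,
            sound_speed: float, prefactor: float = SGM_PREFACTOR) -> np.ndarray:
    """Model backscatter coefficient of the spherical Gaussian model."""
    f = np.asarray(freqs_hz, dtype=float)
    a_eff = 0.5 * asd_um * 1e-6
    k = 2.0 * np.pi * f / sound_speed
    return (10.0 ** (aac_db / 10.0) * prefactor * (f / 1e6) ** 4
            * np.exp(-FORM_FACTOR_CONSTANT * (k * a_eff) ** 2))


def phantom_aac_db(spec: PhantomSpec) -> float:
    """Acoustic concentration of a phantom spec: 10 log10(n sigma^2)."""
    return 10.0 * np.log10(spec.number_density
                           * spec.impedance_contrast_variance)


def reference_bsc(spec: PhantomSpec, freqs_hz: np.ndarray
                  ) -> BackscatterCoefficient:
    """Analytic SGM backscatter coefficient of a known phantom."""
    return BackscatterCoefficient(
        frequencies=np.asarray(freqs_hz, dtype=float),
        bsc=sgm_bsc(freqs_hz, 2.0 * spec.effective_radius * 1e6,
                    phantom_aac_db(spec), spec.sound_speed))


def estimate_bsc(normalized: PowerSpectrum,
                 reference_bsc_model: BackscatterCoefficient
                 ) -> BackscatterCoefficient:
    """Sample BSC = reference BSC x linear ratio of the normalized spectrum."""
    if not np.allclose(normalized.frequencies,
                       reference_bsc_model.frequencies):
        raise ValueError("normalized spectrum and reference BSC grids differ")
    ratio = 10.0 ** (normalized.power_db / 10.0)
    bsc = reference_bsc_model.bsc * ratio
    # the model itself vanishes at f = 0; validity concerns the ratio only
    ok = normalized.valid and bool(np.all(np.isfinite(ratio))
                                   and np.all(ratio > 0))
    return BackscatterCoefficient(normalized.frequencies, bsc,
                                  depth=0.0, valid=ok)


def fit_sgm(bsc: BackscatterCoefficient, band: tuple[float, float],
            sound_speed: float, prefactor: float = SGM_PREFACTOR
            ) -> ScattererEstimate:
    """Linearized spherical-Gaussian-model fit for ASD and AAC.

    Regresses ``ln(bsc) - 4 ln(f_MHz)`` on f^2; a positive slope is
    non-physical (form factors only attenuate with frequency) and yields
    ASD = 0 with the converged flag cleared.
    """
    f = bsc.frequencies
    sel = (f >= band[0]) & (f <= band[1])
    if sel.sum() < 4:
        raise ValueError("need at least 4 frequency bins inside the band")
    y = bsc.bsc[sel]
    if not (np.all(np.isfinite(y)) and np.all(y > 0)):
        return ScattererEstimate(np.nan, np.nan, np.nan, converged=False)
    fb = f[sel]
    lin = np.log(y) - 4.0 * np.log(fb / 1e6)
    x = fb ** 2
    slope, intercept = np.polyfit(x, lin, 1)
    resid = lin - (slope * x + intercept)
    rms = float(np.sqrt(np.mean(resid ** 2)))
    aac_db = 10.0 * (intercept - np.log(prefactor)) / np.log(10.0)
    if slope > 0:
        return ScattererEstimate(0.0, float(aac_db), rms, converged=False)
    a_eff = np.sqrt(-slope * sound_speed ** 2
                    / (FORM_FACTOR_CONSTANT * 4.0 * np.pi ** 2))
    return ScattererEstimate(float(2.0 * a_eff * 1e6), float(aac_db), rms)


def planar_reference_spectrum(acq: AcquisitionConfig, freqs_hz: np.ndarray
                              ) -> PowerSpectrum:
    """Planar-reflector power spectrum stand-in: the pulse power spectrum."""
    p = gaussian_pulse_spectrum(np.asarray(freqs_hz, dtype=float), acq)
    return PowerSpectrum(freqs_hz, 20.0 * np.log10(p + 1e-300))


def ar_power_spectrum(x: np.ndarray, order: int, fs: float,
                      eval_freqs: np.ndarray) -> np.ndarray:
    """Burg AR power spectrum of a real segment, evaluated at eval_freqs (dB)."""
    rho, sigma2 = burg(np.asarray(x, dtype=float), order=order, demean=True)
    omega = 2.0 * np.pi * np.asarray(eval_freqs) / fs
    k = np.arange(1, order + 1)
    a = 1.0 - np.exp(-1j * np.outer(omega, k)) @ rho
    psd = sigma2 / np.abs(a) ** 2
    return 10.0 * np.log10(psd + 1e-300)


def spacing_from_peak_frequencies(peak_freqs_hz: np.ndarray,
                                  sound_speed: float) -> float:
    """Scatterer spacing (mm) from adjacent spectral peak positions."""
    pf = np.sort(np.asarray(peak_freqs_hz, dtype=float))
    if pf.size < 2:
        raise ValueError("need at least two spectral peaks")
    delta_f = float(np.median(np.diff(pf)))
    return sound_speed / (2.0 * delta_f) * 1e3


def _line_spacing(x: np.ndarray, acq: AcquisitionConfig,
                  planar_db: np.ndarray, eval_freqs: np.ndarray,
                  ar_order: int, min_prominence_db: float
                  ) -> tuple[float, float]:
    """(spacing_mm, prominence) for one RF line; (nan, 0) when undefined."""
    psd_db = ar_power_spectrum(x, ar_order, acq.sampling_rate, eval_freqs)
    norm_db = psd_db - planar_db
    peaks, props = find_peaks(norm_db, prominence=min_prominence_db)
    if peaks.size < 2:
        return np.nan, 0.0
    # a true lattice corrugates the whole band, so the median adjacent-peak
    # spacing is the robust periodicity estimate
    delta_f = float(np.median(np.diff(eval_freqs[peaks])))
    if delta_f <= 0:
        return np.nan, 0.0
    return (acq.sound_speed / (2.0 * delta_f) * 1e3,
            float(np.median(props["prominences"])))


def default_ar_order(n_samples: int) -> int:
    """Gate-scaled Burg order: one pole pair per ~15 samples, in [12, 60]."""
    return int(np.clip(n_samples // 15, 12, 60))


def estimate_sas(block: WindowBlock, acq: AcquisitionConfig,
                 planar_reference: PowerSpectrum | None = None,
                 ar_order: int | None = None, min_prominence_db: float = 3.0,
                 n_eval: int = 2048,
                 max_relative_iqr: float = 0.15) -> SpacingEstimate:
    """Autoregressive scatterer-spacing estimate for one window block.

    Per line the RF segment is Burg-AR modeled, its spectrum normalized by
    the planar-reflector reference and searched for prominent peaks in the
    analysis band; the median adjacent-peak spacing inverts to a per-line
    spacing (SAS = c / (2 delta_f)) and the block value is the median across
    lines.  The estimate is flagged undefined when fewer than half the lines
    yield a spacing or when the per-line spacings disagree (relative IQR
    above ``max_relative_iqr``) — diffuse media produce incidental AR peaks
    whose spacing is inconsistent from line to line, a periodic medium locks
    all lines to the lattice corrugation.
    """
    samples = block.samples
    if ar_order is None:
        ar_order = default_ar_order(samples.shape[0])
    if ar_order < 2:
        raise ValueError("ar_order must be >= 2")
    if samples.shape[0] < ar_order + 10:
        raise ValueError("block too short for the requested AR order")
    f_lo, f_hi = acq.band
    eval_freqs = np.linspace(f_lo, f_hi, n_eval)
    if planar_reference is None:
        planar = planar_reference_spectrum(acq, eval_freqs)
        planar_db = planar.power_db
    else:
        planar_db = np.interp(eval_freqs, planar_reference.frequencies,
                              planar_reference.power_db)
    spacings, proms = [], []
    for j in range(samples.shape[1]):
        s, p = _line_spacing(samples[:, j], acq, planar_db, eval_freqs,
                             ar_order, min_prominence_db)
        if np.isfinite(s):
            spacings.append(s)
            proms.append(p)
    if len(spacings) < max(2, samples.shape[1] // 2):
        return SpacingEstimate(np.nan, 0.0, ar_order, defined=False)
    spacings = np.asarray(spacings)
    med = float(np.median(spacings))
    iqr = float(np.percentile(spacings, 75) - np.percentile(spacings, 25))
    if med <= 0 or iqr / med > max_relative_iqr:
        return SpacingEstimate(np.nan, float(np.median(proms)), ar_order,
                               defined=False)
    return SpacingEstimate(med, float(np.median(proms)), ar_order)
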