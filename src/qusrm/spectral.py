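"""Sliding-window backscatter spectral analysis.

The tumor ROI is tiled into 10-lambda square windows with 94% overlap; each
window yields a line-averaged power spectrum which is normalized against a
reference phantom of known attenuation to cancel the system response.  A
straight line fitted to the normalized spectrum over the transducer band
gives the spectral slope (SS, dBr/MHz), 0-MHz intercept (SI, dBr) and
midband fit (MBF, dBr; the fitted value at the band midpoint, so
MBF = SI + SS * f_mid identically).  Tumor attenuation (ACE) comes from a
spectral difference method: the depth rate of the sample-minus-reference
spectrum is itself linear in frequency with slope -2 (ACE - alpha_ref) in
the dB convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .acquisition import AcquisitionConfig, RFFrame

__all__ = [
    "WindowBlock",
    "PowerSpectrum",
    "SpectralFit",
    "AttenuationEstimate",
    "ParametricMap",
    "window_positions",
    "tile_roi",
    "block_power_spectrum",
    "average_spectra",
    "normalize_spectrum",
    "fit_spectral_parameters",
    "estimate_ace",
]


@dataclass
class WindowBlock:
    """One analysis window cut from an RF frame."""

    samples: np.ndarray  # axial samples x lines
    axial_index: int
    lateral_index: int
    depth: float  # absolute depth of the window center, m


@dataclass
class PowerSpectrum:
    frequencies: np.ndarray  # Hz, strictly increasing
    power_db: np.ndarray
    n_lines_averaged: int = 1
    valid: bool = True

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power_db = np.asarray(self.power_db, dtype=float)
        if self.frequencies.shape != self.power_db.shape:
            raise ValueError("frequency and power arrays must match")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")

    def band_slice(self, band: tuple[float, float]) -> np.ndarray:
        f_lo, f_hi = band
        return (self.frequencies >= f_lo) & (self.frequencies <= f_hi)


@dataclass(frozen=True)
class SpectralFit:
    """Linear-fit summary of a normalized backscatter spectrum."""

    mbf: float   # dBr, fitted value at the band midpoint
    ss: float    # dBr/MHz
    si: float    # dBr, intercept at 0 MHz
    band: tuple[float, float]


@dataclass(frozen=True)
class AttenuationEstimate:
    ace: float           # dB/(cm MHz)
    fit_quality: float   # R^2 of the slope-vs-frequency regression
    in_range: bool = True


@dataclass
class ParametricMap:
    """Per-window QUS parameter values on the regular window grid."""

    values: np.ndarray
    parameter_name: str
    mask: np.ndarray = None  # True where the cell is valid
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values")

    @property
    def mean(self) -> float:
        """Mean over unmasked cells — the per-scan 'mean QUS value' feature."""
        if not self.mask.any():
            raise ValueError(f"all cells of {self.parameter_name} map invalid")
        return float(self.values[self.mask].mean())


def window_positions(length: int, window: int, overlap: float) -> np.ndarray:
    """Start indices of overlapped windows along one axis.

    The hop is ``(1 - overlap) * window`` rounded to a whole sample with a
    floor of one; the count is ``floor((length - window) / hop) + 1``.
    """
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must lie in [0, 1)")
    if window > length:
        raise ValueError(f"window ({window}) exceeds available length ({length})")
    hop = max(1, int(round((1.0 - overlap) * window)))
    n = (length - window) // hop + 1
    return np.arange(n) * hop


def window_size_samples(acq: AcquisitionConfig, window_lambdas: float = 10.0
                        ) -> tuple[int, int]:
    """Window side in (axial samples, lateral lines) for a 10-lambda block."""
    side_m = window_lambdas * acq.wavelength
    axial = max(1, int(round(side_m / acq.axial_sample_interval)))
    lateral = max(1, int(round(side_m / acq.line_pitch)))
    return axial, lateral


def tile_roi(frame: RFFrame, roi: tuple[int, int, int, int],
             window_lambdas: float = 10.0, overlap: float = 0.94
             ) -> list[WindowBlock]:
    """Cut a rectangular ROI into the regular overlapped window grid.

    ``roi`` is (axial_start, lateral_start, axial_length, lateral_length) in
    samples and lines.  Blocks carry their grid coordinates and the absolute
    depth of their axial center.
    """
    a0, l0, na, nl = roi
    if a0 < 0 or l0 < 0 or a0 + na > frame.n_samples or l0 + nl > frame.n_lines:
        raise ValueError("roi does not fit inside the frame")
    w_ax, w_lat = window_size_samples(frame.acquisition, window_lambdas)
    if na < w_ax or nl < w_lat:
        raise ValueError(
            f"roi ({na} samples x {nl} lines) smaller than one analysis "
            f"window ({w_ax} x {w_lat}); enlarge the roi or reduce "
            "window_lambdas"
        )
    ax_starts = window_positions(na, w_ax, overlap)
    lat_starts = window_positions(nl, w_lat, overlap)
    blocks = []
    for i, a in enumerate(ax_starts):
        depth = frame.depth_of_sample(a0 + a + w_ax / 2.0)
        for j, l in enumerate(lat_starts):
            blocks.append(WindowBlock(
                samples=frame.samples[a0 + a:a0 + a + w_ax,
                                      l0 + l:l0 + l + w_lat],
                axial_index=i, lateral_index=j, depth=depth))
    return blocks


def grid_shape(frame: RFFrame, roi: tuple[int, int, int, int],
               window_lambdas: float = 10.0, overlap: float = 0.94
               ) -> tuple[int, int]:
    _, _, na, nl = roi
    w_ax, w_lat = window_size_samples(frame.acquisition, window_lambdas)
    return (len(window_positions(na, w_ax, overlap)),
            len(window_positions(nl, w_lat, overlap)))


_DB_FLOOR = 1e-300


def block_power_spectrum(block: WindowBlock | np.ndarray,
                         acq: AcquisitionConfig) -> PowerSpectrum:
    """Line-averaged Hann periodogram of a window block, in dB.

    FFT length is the next power of two at or above the axial window size.
    A zero-variance (constant) block is flagged invalid.
    """
    samples = block.samples if isinstance(block, WindowBlock) else np.asarray(block)
    if samples.ndim == 1:
        samples = samples[:, None]
    n = samples.shape[0]
    nfft = int(2 ** np.ceil(np.log2(max(n, 2))))
    freqs, pxx = signal.periodogram(samples, fs=acq.sampling_rate,
                                    window="hann", nfft=nfft, axis=0,
                                    detrend=False)
    mean_power = pxx.mean(axis=1)
    if np.ptp(samples) == 0:
        return PowerSpectrum(freqs, np.full_like(freqs, np.nan),
                             n_lines_averaged=samples.shape[1], valid=False)
    return PowerSpectrum(freqs, 10.0 * np.log10(mean_power + _DB_FLOOR),
                         n_lines_averaged=samples.shape[1])


def average_spectra(spectra: list[PowerSpectrum]) -> PowerSpectrum:
    """Average power spectra in the linear domain (matched grids)."""
    valid = [s for s in spectra if s.valid]
    if not valid:
        raise ValueError("no valid spectra to average")
    f0 = valid[0].frequencies
    for s in valid[1:]:
        if not np.allclose(s.frequencies, f0):
            raise ValueError("mismatched frequency grids")
    linear = np.mean([10.0 ** (s.power_db / 10.0) for s in valid], axis=0)
    return PowerSpectrum(f0, 10.0 * np.log10(linear + _DB_FLOOR),
                         n_lines_averaged=sum(s.n_lines_averaged for s in valid))


def attenuation_compensation_db(freqs_hz: np.ndarray, depth_m: float,
                                sample_attenuation: float,
                                ref_attenuation: float) -> np.ndarray:
    """Round-trip attenuation difference in dB at depth, for power spectra.

    With attenuation slopes in dB/(cm MHz) the round-trip power loss at
    depth z is 2 alpha f z dB, so the compensation restoring the sample
    spectrum relative to the reference is +2 (alpha_s - alpha_r) f z.
    """
    f_mhz = np.asarray(freqs_hz) / 1e6
    z_cm = depth_m * 100.0
    return 2.0 * (sample_attenuation - ref_attenuation) * f_mhz * z_cm


def normalize_spectrum(sample: PowerSpectrum, reference: PowerSpectrum,
                       depth: float = 0.0, ref_attenuation: float = 0.0,
                       sample_attenuation: float = 0.0) -> PowerSpectrum:
    """Reference-phantom normalization with attenuation compensation."""
    if not np.allclose(sample.frequencies, reference.frequencies):
        raise ValueError("sample and reference frequency grids differ")
    comp = attenuation_compensation_db(sample.frequencies, depth,
                                       sample_attenuation, ref_attenuation)
    return PowerSpectrum(sample.frequencies,
                         sample.power_db - reference.power_db + comp,
                         n_lines_averaged=sample.n_lines_averaged,
                         valid=sample.valid and reference.valid)


def fit_spectral_parameters(normalized: PowerSpectrum,
                            band: tuple[float, float]) -> SpectralFit:
    """OLS line fit of power (dB) versus frequency (MHz) on the band.

    SS is the slope, SI the 0-MHz intercept and MBF the fitted value at the
    band midpoint, so MBF = SI + SS * f_mid holds by construction.
    """
    sel = normalized.band_slice(band)
    if sel.sum() < 3:
        raise ValueError("need at least 3 frequency bins inside the band")
    f_mhz = normalized.frequencies[sel] / 1e6
    p = normalized.power_db[sel]
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite power inside the analysis band")
    ss, si = np.polyfit(f_mhz, p, 1)
    f_mid = 0.5 * (band[0] + band[1]) / 1e6
    return SpectralFit(mbf=float(si + ss * f_mid), ss=float(ss), si=float(si),
                       band=band)


def estimate_ace(sample_spectra: list[PowerSpectrum], depths: list[float],
                 reference_spectra: list[PowerSpectrum],
                 ref_attenuation: float, band: tuple[float, float],
                 physical_range: tuple[float, float] = (0.0, 3.0)
                 ) -> AttenuationEstimate:
    """Spectral-difference attenuation estimate over a set of depths.

    For each band frequency the sample-minus-reference power difference is
    regressed on depth (cm); those per-frequency slopes regressed on
    frequency (MHz) have slope -2 (ACE - alpha_ref), from which ACE follows.
    """
    if len(sample_spectra) != len(depths) or len(reference_spectra) != len(depths):
        raise ValueError("spectra and depth lists must have equal length")
    uniq = np.unique(np.round(np.asarray(depths, dtype=float), 12))
    if uniq.size < 2:
        raise ValueError("spectral difference method needs >= 2 depth levels")
    f0 = sample_spectra[0].frequencies
    sel = sample_spectra[0].band_slice(band)
    diffs = np.empty((len(depths), sel.sum()))
    for i, (s, r) in enumerate(zip(sample_spectra, reference_spectra)):
        if not (np.allclose(s.frequencies, f0) and np.allclose(r.frequencies, f0)):
            raise ValueError("mismatched frequency grids")
        diffs[i] = (s.power_db - r.power_db)[sel]
    z_cm = np.asarray(depths, dtype=float) * 100.0
    # dB/cm at each band frequency
    slopes = np.polyfit(z_cm, diffs, 1)[0]
    f_mhz = f0[sel] / 1e6
    if not np.all(np.isfinite(slopes)):
        return AttenuationEstimate(np.nan, 0.0, in_range=False)
    m, b = np.polyfit(f_mhz, slopes, 1)
    resid = slopes - (m * f_mhz + b)
    ss_tot = np.sum((slopes - slopes.mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid ** 2) / ss_tot) if ss_tot > 0 else 1.0
    ace = ref_attenuation - m / 2.0
    lo, hi = physical_range
    return AttenuationEstimate(float(ace), r2, in_range=bool(lo <= ace <= hi))
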