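"""Synthetic RF frame generation for diffuse and periodic scattering media.

Each scan line is synthesized in the frequency domain as a linear
superposition of point-scatterer echoes

    S(f) = P(f) * sqrt(F(f)) * sum_j A_j * a_j(f) * exp(-i 2 pi f t_j)

with P the band-limited pulse spectrum, F the Gaussian form factor of the
medium's effective scatterer radius, t_j = 2 z_j / c the round-trip delay of
scatterer j and a_j(f) = 10^(-2 alpha f z_j / 20) the round-trip amplitude
attenuation (alpha in dB/(cm MHz)).  Single scattering, no beamforming, no
elevational dimension.  The frequency-flat part of the scattering response
is absorbed into the pulse: downstream estimation is reference-phantom
normalized, so only frequency dependence relative to the reference matters.
"""

from __future__ import annotations

import numpy as np

from .acquisition import AcquisitionConfig, PhantomSpec, RFFrame

__all__ = [
    "gaussian_pulse_spectrum",
    "gaussian_form_factor",
    "simulate_phantom_rf",
    "simulate_periodic_phantom",
]

# Conventional Gaussian form-factor exponent constant (in k^2 a_eff^2 units).
FORM_FACTOR_CONSTANT = 0.827

# Assumed elevational slice thickness (m) converting volumetric scatterer
# density to a per-line-strip count.
ELEVATION_THICKNESS = 1e-3


def gaussian_pulse_spectrum(freqs: np.ndarray, acq: AcquisitionConfig) -> np.ndarray:
    """One-sided amplitude spectrum of the emitted pulse.

    Gaussian envelope centered at the transducer center frequency with the
    -6 dB (half-amplitude) full width equal to
    ``pulse_bandwidth_fraction * center_frequency``.
    """
    fwhm = acq.pulse_bandwidth_fraction * acq.center_frequency
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((freqs - acq.center_frequency) / sigma) ** 2)


def gaussian_form_factor(freqs: np.ndarray, effective_radius: float,
                         sound_speed: float) -> np.ndarray:
    """Gaussian form factor F(f) = exp(-0.827 k^2 a_eff^2), k = 2 pi f / c."""
    k = 2.0 * np.pi * np.asarray(freqs) / sound_speed
    return np.exp(-FORM_FACTOR_CONSTANT * (k * effective_radius) ** 2)


def _attenuation_amplitude(freqs_hz: np.ndarray, depths_m: np.ndarray,
                           slope_db_cm_mhz: float) -> np.ndarray:
    """Round-trip amplitude factor, shape (n_freq, n_scatterers)."""
    f_mhz = freqs_hz[:, None] / 1e6
    z_cm = depths_m[None, :] * 100.0
    att_db = 2.0 * slope_db_cm_mhz * f_mhz * z_cm
    return 10.0 ** (-att_db / 20.0)


def _synthesize_lines(scatterer_depths: list[np.ndarray],
                      scatterer_amps: list[np.ndarray],
                      spec: PhantomSpec, acq: AcquisitionConfig,
                      n_samples: int, origin_depth: float) -> np.ndarray:
    nfft = int(2 ** np.ceil(np.log2(max(n_samples, 64))))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / acq.sampling_rate)
    pulse = gaussian_pulse_spectrum(freqs, acq)
    ff_amp = np.sqrt(
        gaussian_form_factor(freqs, spec.effective_radius, spec.sound_speed)
    )
    common = pulse * ff_amp
    out = np.zeros((n_samples, len(scatterer_depths)))
    for i, (z, amps) in enumerate(zip(scatterer_depths, scatterer_amps)):
        if z.size == 0:
            continue
        t = 2.0 * (z - origin_depth) / spec.sound_speed
        att = _attenuation_amplitude(freqs, z, spec.attenuation_slope)
        phase = np.exp(-2j * np.pi * freqs[:, None] * t[None, :])
        spectrum = common * ((att * phase) @ amps)
        out[:, i] = np.fft.irfft(spectrum, n=nfft)[:n_samples]
    return out


def _frame_geometry(spec: PhantomSpec, acq: AcquisitionConfig):
    axial_extent, lateral_extent = spec.extent
    dz = spec.sound_speed / (2.0 * acq.sampling_rate)
    n_samples = int(np.floor(axial_extent / dz))
    n_lines = int(np.floor(lateral_extent / acq.line_pitch))
    window_m = 10.0 * spec.sound_speed / acq.center_frequency
    if axial_extent < window_m or lateral_extent < window_m:
        raise ValueError(
            "phantom extent smaller than one 10-lambda analysis window "
            f"({window_m * 1e3:.2f} mm)"
        )
    return n_samples, n_lines


def simulate_phantom_rf(spec: PhantomSpec, acq: AcquisitionConfig,
                        seed: int, origin_depth: float = 0.0) -> RFFrame:
    """Simulate an RF frame from a diffuse random-scatterer phantom.

    Scatterer positions are uniform in the phantom volume; amplitudes are
    zero-mean normal with variance ``impedance_contrast_variance``.  Output
    is a pure function of (spec, acq, seed, origin_depth).
    """
    rng = np.random.default_rng(seed)
    n_samples, n_lines = _frame_geometry(spec, acq)
    axial_extent = spec.extent[0]
    strip_volume_mm3 = (axial_extent * 1e3) * (acq.line_pitch * 1e3) * (
        ELEVATION_THICKNESS * 1e3)
    n_per_line = rng.poisson(spec.number_density * strip_volume_mm3,
                             size=n_lines)
    sigma = np.sqrt(spec.impedance_contrast_variance)
    depths, amps = [], []
    for n in n_per_line:
        depths.append(origin_depth + rng.uniform(0.0, axial_extent, size=n))
        amps.append(rng.normal(0.0, sigma, size=n))
    samples = _synthesize_lines(depths, amps, spec, acq, n_samples,
                                origin_depth)
    return RFFrame(samples=samples, acquisition=acq, origin_depth=origin_depth)


def simulate_periodic_phantom(spacing_mm: float, jitter: float,
                              acq: AcquisitionConfig, seed: int,
                              spec: PhantomSpec | None = None,
                              lattice_amplitude: float = 10.0,
                              origin_depth: float = 0.0) -> RFFrame:
    """Diffuse background plus an axial lattice of strong scatterers.

    The lattice period sets a spectral corrugation of spacing
    ``delta_f = c / (2 spacing)`` which must fit within the analysis band;
    each lattice position is perturbed independently by
    ``jitter * spacing * N(0, 1)``.
    """
    if spec is None:
        spec = PhantomSpec(number_density=50.0,
                           impedance_contrast_variance=1.0,
                           attenuation_slope=0.0)
    if not (0.0 <= jitter < 0.5):
        raise ValueError("lattice jitter must lie in [0, 0.5)")
    spacing = spacing_mm * 1e-3
    dz = spec.sound_speed / (2.0 * acq.sampling_rate)
    if spacing <= dz:
        raise ValueError(
            f"spacing {spacing_mm} mm not above the axial sample interval "
            f"({dz * 1e3:.4f} mm)"
        )
    f_lo, f_hi = acq.band
    delta_f = spec.sound_speed / (2.0 * spacing)
    if delta_f > (f_hi - f_lo):
        raise ValueError(
            "lattice spacing unresolvable: spectral corrugation "
            f"{delta_f / 1e6:.2f} MHz exceeds the band span"
        )
    rng = np.random.default_rng(seed)
    n_samples, n_lines = _frame_geometry(spec, acq)
    axial_extent = spec.extent[0]
    strip_volume_mm3 = (axial_extent * 1e3) * (acq.line_pitch * 1e3) * (
        ELEVATION_THICKNESS * 1e3)
    n_per_line = rng.poisson(spec.number_density * strip_volume_mm3,
                             size=n_lines)
    sigma = np.sqrt(spec.impedance_contrast_variance)
    lattice_z = np.arange(spacing, axial_extent - spacing / 2, spacing)
    depths, amps = [], []
    for n in n_per_line:
        z_diffuse = origin_depth + rng.uniform(0.0, axial_extent, size=n)
        a_diffuse = rng.normal(0.0, sigma, size=n)
        z_lat = origin_depth + lattice_z + (
            jitter * spacing * rng.standard_normal(lattice_z.size))
        a_lat = np.full(lattice_z.size, lattice_amplitude * sigma)
        depths.append(np.concatenate([z_diffuse, z_lat]))
        amps.append(np.concatenate([a_diffuse, a_lat]))
    samples = _synthesize_lines(depths, amps, spec, acq, n_samples,
                                origin_depth)
    return RFFrame(samples=samples, acquisition=acq, origin_depth=origin_depth)
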