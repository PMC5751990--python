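"""Acquisition geometry and phantom descriptions.

The acquisition model is a linear-array pulse-echo scan: RF echo lines are
recorded at a fixed sampling rate, one line per lateral transducer position.
Physical axial distance maps to sample index through the round-trip delay
``z -> 2 z f_s / c``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionConfig", "PhantomSpec", "RFFrame"]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Transducer and digitizer settings for one pulse-echo acquisition.

    Parameters
    ----------
    sampling_rate : float
        RF digitization rate in Hz.
    center_frequency : float
        Transducer center frequency in Hz.
    band : tuple of float
        Usable analysis band ``(f_lo, f_hi)`` in Hz.
    sound_speed : float
        Assumed propagation speed in m/s.
    line_pitch : float
        Lateral distance between adjacent scan lines in m.
    pulse_bandwidth_fraction : float
        Fractional -6 dB (half-amplitude) bandwidth of the emitted pulse,
        relative to the center frequency.
    """

    sampling_rate: float = 40e6
    center_frequency: float = 7e6
    band: tuple[float, float] = (4e6, 9e6)
    sound_speed: float = 1540.0
    line_pitch: float = 0.25e-3
    pulse_bandwidth_fraction: float = 5.0 / 7.0

    def __post_init__(self) -> None:
        f_lo, f_hi = self.band
        if not (0 < f_lo < self.center_frequency < f_hi):
            raise ValueError(
                f"band {self.band} must straddle the center frequency "
                f"{self.center_frequency}"
            )
        if self.sampling_rate <= 2 * f_hi:
            raise ValueError(
                "sampling_rate must exceed twice the upper band edge "
                f"(got {self.sampling_rate} <= 2*{f_hi})"
            )
        for name in ("sampling_rate", "center_frequency", "sound_speed",
                     "line_pitch", "pulse_bandwidth_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def wavelength(self) -> float:
        """Center-frequency wavelength lambda = c / f_c, in m."""
        return self.sound_speed / self.center_frequency

    @property
    def axial_sample_interval(self) -> float:
        """Axial distance per RF sample, c / (2 f_s), in m."""
        return self.sound_speed / (2.0 * self.sampling_rate)


@dataclass(frozen=True)
class PhantomSpec:
    """Diffuse (optionally latticed) scattering medium description.

    ``effective_radius`` is the Gaussian-form-factor effective scatterer
    radius in m; ``number_density`` is scatterers per mm^3;
    ``attenuation_slope`` is in dB/(cm MHz); ``extent`` is
    (axial, lateral) in m.  When ``lattice_spacing`` is set an axial lattice
    of strong scatterers is superimposed, with positions perturbed by
    ``lattice_jitter_fraction`` of the spacing.
    """

    effective_radius: float = 12e-6
    number_density: float = 200.0
    impedance_contrast_variance: float = 1.0
    attenuation_slope: float = 0.576
    sound_speed: float = 1540.0
    extent: tuple[float, float] = (20e-3, 15e-3)
    lattice_spacing: float | None = None
    lattice_jitter_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.effective_radius < 0:
            raise ValueError("effective_radius must be >= 0")
        if self.number_density <= 0:
            raise ValueError("number_density must be positive")
        if self.impedance_contrast_variance <= 0:
            raise ValueError("impedance_contrast_variance must be positive")
        if self.attenuation_slope < 0:
            raise ValueError("attenuation_slope must be >= 0")
        if self.sound_speed <= 0:
            raise ValueError("sound_speed must be positive")
        if any(e <= 0 for e in self.extent):
            raise ValueError("extent must be positive")
        if not (0.0 <= self.lattice_jitter_fraction < 1.0):
            raise ValueError("lattice_jitter_fraction must lie in [0, 1)")


# Reference phantom of the normalization chain: glass microbeads in a
# homogeneous background, attenuation 0.576 dB/(cm MHz), c = 1488 m/s.
REFERENCE_PHANTOM = PhantomSpec(
    effective_radius=12e-6,
    number_density=200.0,
    impedance_contrast_variance=1.0,
    attenuation_slope=0.576,
    sound_speed=1488.0,
)


@dataclass
class RFFrame:
    """A single RF frame: real echo samples, axial samples x lateral lines."""

    samples: np.ndarray
    acquisition: AcquisitionConfig
    origin_depth: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D array (samples x lines)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.origin_depth < 0:
            raise ValueError("origin_depth must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_lines(self) -> int:
        return self.samples.shape[1]

    def depth_of_sample(self, index: float) -> float:
        """Absolute depth (m) of an axial sample index."""
        return self.origin_depth + index * self.acquisition.axial_sample_interval
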