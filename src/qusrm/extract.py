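"""Parametric-map extraction: frame + reference phantom -> QUS maps.

For each 10-lambda window of the ROI the sample spectrum is normalized
against the matched window of one or more reference-phantom frames.  The
attenuation estimate (ACE) is computed first — per lateral grid column by
the spectral difference method — and its ROI mean is then reused to
attenuation-compensate every window before the spectral-fit (MBF/SS/SI)
and backscatter-coefficient (ASD/AAC) estimates.  SAS uses the per-window
RF segment against a planar-reflector reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acquisition import AcquisitionConfig, PhantomSpec, RFFrame, REFERENCE_PHANTOM
from .scatterers import (estimate_bsc, estimate_sas, fit_sgm,
                         planar_reference_spectrum, reference_bsc)
from .spectral import (AttenuationEstimate, ParametricMap, block_power_spectrum,
                       average_spectra, estimate_ace, fit_spectral_parameters,
                       grid_shape, normalize_spectrum, tile_roi)

__all__ = ["ExtractionConfig", "QusExtractor", "build_parametric_map"]

PARAM_UNITS = {
    "MBF": "dBr", "SS": "dBr/MHz", "SI": "dBr", "ACE": "dB/(cm MHz)",
    "SAS": "mm", "ASD": "um", "AAC": "dB/cm^3",
}

ALL_PARAMS = tuple(PARAM_UNITS)


@dataclass
class ExtractionConfig:
    window_lambdas: float = 10.0
    overlap: float = 0.94
    reference_phantom: PhantomSpec = field(
        default_factory=lambda: REFERENCE_PHANTOM)
    ar_order: int | None = None      # None: gate-scaled default
    ace_physical_range: tuple[float, float] = (0.0, 3.0)

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap < 1.0):
            raise ValueError("overlap must lie in [0, 1)")


class QusExtractor:
    """Computes the seven QUS parametric maps for ROIs of an RF frame.

    Parameters
    ----------
    acq : AcquisitionConfig
        Shared acquisition settings of sample and reference frames.
    reference_frames : list of RFFrame
        One or more frames scanned from the reference phantom with the same
        geometry as the sample frame; their window spectra are averaged.
    config : ExtractionConfig
    """

    def __init__(self, acq: AcquisitionConfig,
                 reference_frames: list[RFFrame],
                 config: ExtractionConfig | None = None):
        if not reference_frames:
            raise ValueError("need at least one reference frame")
        self.acq = acq
        self.reference_frames = reference_frames
        self.config = config or ExtractionConfig()

    def _window_spectra(self, frame: RFFrame, roi):
        blocks = tile_roi(frame, roi, self.config.window_lambdas,
                          self.config.overlap)
        return blocks, [block_power_spectrum(b, self.acq) for b in blocks]

    def maps(self, frame: RFFrame, roi: tuple[int, int, int, int],
             params: tuple[str, ...] = ALL_PARAMS
             ) -> dict[str, ParametricMap]:
        """All requested parametric maps on the ROI window grid."""
        unknown = set(params) - set(ALL_PARAMS)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        cfg = self.config
        shape = grid_shape(frame, roi, cfg.window_lambdas, cfg.overlap)
        blocks, sample_spectra = self._window_spectra(frame, roi)
        ref_spectra_all = [self._window_spectra(rf, roi)[1]
                           for rf in self.reference_frames]
        ref_spectra = [average_spectra([rs[i] for rs in ref_spectra_all])
                       for i in range(len(blocks))]
        ref_att = cfg.reference_phantom.attenuation_slope
        band = self.acq.band

        # --- ACE first: per lateral column, spectral difference over depth
        ace_map = np.full(shape, np.nan)
        by_col: dict[int, list[int]] = {}
        for i, b in enumerate(blocks):
            by_col.setdefault(b.lateral_index, []).append(i)
        ace_values = []
        for col, idxs in by_col.items():
            depths = [blocks[i].depth for i in idxs]
            if len(set(depths)) < 2:
                continue
            est = estimate_ace([sample_spectra[i] for i in idxs], depths,
                               [ref_spectra[i] for i in idxs], ref_att,
                               band, cfg.ace_physical_range)
            if np.isfinite(est.ace):
                ace_values.append(est.ace)
                for i in idxs:
                    ace_map[blocks[i].axial_index, blocks[i].lateral_index] = est.ace
        if not ace_values and ("ACE" in params or
                               {"MBF", "SS", "SI", "ASD", "AAC"} & set(params)):
            raise ValueError("no lateral column offered >= 2 depths for ACE")
        ace_mean = float(np.mean(ace_values)) if ace_values else ref_att

        out: dict[str, ParametricMap] = {}
        if "ACE" in params:
            out["ACE"] = ParametricMap(ace_map, "ACE", units=PARAM_UNITS["ACE"])

        need_fit = {"MBF", "SS", "SI"} & set(params)
        need_sgm = {"ASD", "AAC"} & set(params)
        if need_fit or need_sgm:
            grids = {p: np.full(shape, np.nan) for p in
                     ("MBF", "SS", "SI", "ASD", "AAC")}
            f0 = sample_spectra[0].frequencies
            ref_bsc_model = reference_bsc(cfg.reference_phantom, f0)
            for i, b in enumerate(blocks):
                if not (sample_spectra[i].valid and ref_spectra[i].valid):
                    continue
                norm = normalize_spectrum(sample_spectra[i], ref_spectra[i],
                                          depth=b.depth,
                                          ref_attenuation=ref_att,
                                          sample_attenuation=ace_mean)
                fit = fit_spectral_parameters(norm, band)
                grids["MBF"][b.axial_index, b.lateral_index] = fit.mbf
                grids["SS"][b.axial_index, b.lateral_index] = fit.ss
                grids["SI"][b.axial_index, b.lateral_index] = fit.si
                if need_sgm:
                    bsc = estimate_bsc(norm, ref_bsc_model)
                    if bsc.valid:
                        sgm = fit_sgm(bsc, band, self.acq.sound_speed)
                        grids["ASD"][b.axial_index, b.lateral_index] = sgm.asd
                        grids["AAC"][b.axial_index, b.lateral_index] = sgm.aac
            for p in need_fit | need_sgm:
                out[p] = ParametricMap(grids[p], p, units=PARAM_UNITS[p])

        if "SAS" in params:
            sas_map = np.full(shape, np.nan)
            planar = planar_reference_spectrum(
                self.acq, np.linspace(band[0], band[1], 2048))
            for b in blocks:
                try:
                    est = estimate_sas(b, self.acq, planar,
                                       ar_order=cfg.ar_order)
                except ValueError:
                    continue
                if est.defined:
                    sas_map[b.axial_index, b.lateral_index] = est.sas
            out["SAS"] = ParametricMap(sas_map, "SAS", units=PARAM_UNITS["SAS"])

        for p, m in out.items():
            if not m.mask.any() and p != "SAS":
                raise ValueError(f"all cells of the {p} map are invalid")
        return out


def build_parametric_map(frame: RFFrame, roi, parameter_name: str,
                         reference_frames: list[RFFrame],
                         config: ExtractionConfig | None = None
                         ) -> ParametricMap:
    """Single-map convenience wrapper over :class:`QusExtractor`."""
    extractor = QusExtractor(frame.acquisition, reference_frames, config)
    return extractor.maps(frame, roi, params=(parameter_name,))[parameter_name]
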