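"""GLCM texture features of QUS parametric maps.

Each parametric map is min-max quantized to a small number of gray levels
and described by four Haralick features — contrast (CON), correlation
(COR), energy (ENE) and homogeneity (HOM) — each averaged over sixteen
symmetric gray-level co-occurrence matrices: pixel distances 1-4 at angles
0/45/90/135 degrees.  Masked map cells never contribute pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .spectral import ParametricMap

__all__ = [
    "QuantizedMap",
    "GLCM",
    "TextureSet",
    "GLCM_DISTANCES",
    "GLCM_ANGLES",
    "quantize_map",
    "compute_glcm",
    "glcm_features",
    "texture_features",
]

GLCM_DISTANCES = (1, 2, 3, 4)
GLCM_ANGLES = (0, 45, 90, 135)

# angle convention: 0 deg = lateral neighbor (same row, next column),
# 90 deg = axial neighbor (next row, same column); rows are axial.
_ANGLE_OFFSETS = {0: (0, 1), 45: (1, 1), 90: (1, 0), 135: (1, -1)}

TEXTURE_NAMES = ("CON", "COR", "ENE", "HOM")


@dataclass
class QuantizedMap:
    levels: np.ndarray       # integer levels, masked cells arbitrary
    n_levels: int
    value_range: tuple[float, float]
    mask: np.ndarray         # True where valid
    degenerate: bool = False  # constant source map


@dataclass
class GLCM:
    matrix: np.ndarray
    distance: int
    angle: int
    symmetric: bool = True
    empty: bool = False


@dataclass(frozen=True)
class TextureSet:
    con: float
    cor: float
    ene: float
    hom: float
    source_parameter: str = ""

    def as_dict(self) -> dict[str, float]:
        return {"CON": self.con, "COR": self.cor, "ENE": self.ene,
                "HOM": self.hom}


def quantize_map(pmap: ParametricMap | np.ndarray, n_levels: int = 16,
                 mask: np.ndarray | None = None) -> QuantizedMap:
    """Uniform min-max quantization of the unmasked map values.

    Bin edges split [min, max] into ``n_levels`` equal bins; the maximum
    maps to the top level, making the result invariant to affine transforms
    of the source values.  A constant map is flagged degenerate.
    """
    if isinstance(pmap, ParametricMap):
        values, mask = pmap.values, pmap.mask
    else:
        values = np.asarray(pmap, dtype=float)
        mask = np.ones_like(values, dtype=bool) if mask is None else np.asarray(mask, bool)
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    v = values[mask]
    if v.size == 0:
        raise ValueError("no unmasked cells to quantize")
    vmin, vmax = float(v.min()), float(v.max())
    levels = np.zeros_like(values, dtype=int)
    if vmax == vmin:
        return QuantizedMap(levels, n_levels, (vmin, vmax), mask,
                            degenerate=True)
    scaled = (values - vmin) / (vmax - vmin) * n_levels
    levels = np.clip(scaled.astype(int), 0, n_levels - 1)
    return QuantizedMap(levels, n_levels, (vmin, vmax), mask)


def compute_glcm(qmap: QuantizedMap, distance: int, angle: int) -> GLCM:
    """Symmetric, normalized co-occurrence matrix at one offset.

    Every valid pixel pair at the offset is counted in both directions;
    pairs with a masked member are skipped.  Entries sum to one unless no
    valid pair exists, in which case the GLCM is flagged empty.
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    if angle not in _ANGLE_OFFSETS:
        raise ValueError(f"angle must be one of {sorted(_ANGLE_OFFSETS)}")
    dr, dc = _ANGLE_OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    lv, mask = qmap.levels, qmap.mask
    n_rows, n_cols = lv.shape
    counts = np.zeros((qmap.n_levels, qmap.n_levels), dtype=float)

    r0a, r0b = max(0, -dr), min(n_rows, n_rows - dr)
    c0a, c0b = max(0, -dc), min(n_cols, n_cols - dc)
    if r0a < r0b and c0a < c0b:
        src = (slice(r0a, r0b), slice(c0a, c0b))
        dst = (slice(r0a + dr, r0b + dr), slice(c0a + dc, c0b + dc))
        ok = mask[src] & mask[dst]
        i = lv[src][ok]
        j = lv[dst][ok]
        np.add.at(counts, (i, j), 1.0)
        np.add.at(counts, (j, i), 1.0)
    total = counts.sum()
    if total == 0:
        return GLCM(counts, distance, angle, empty=True)
    return GLCM(counts / total, distance, angle)


def glcm_features(glcm: GLCM) -> TextureSet:
    """Haralick CON / COR / ENE / HOM of one normalized GLCM.

    COR is reported as 1 when either marginal has zero variance (single
    occupied level), with a warning.
    """
    if glcm.empty:
        raise ValueError("empty GLCM has no texture features")
    p = glcm.matrix
    n = p.shape[0]
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    con = float(np.sum(p * (i - j) ** 2))
    ene = float(np.sum(p ** 2))
    hom = float(np.sum(p / (1.0 + np.abs(i - j))))
    pi = p.sum(axis=1)
    mu_i = float(np.sum(np.arange(n) * pi))
    var_i = float(np.sum((np.arange(n) - mu_i) ** 2 * pi))
    # symmetric GLCM: both marginals coincide
    if var_i <= 0:
        warnings.warn("zero-variance GLCM marginal; correlation reported as 1",
                      stacklevel=2)
        cor = 1.0
    else:
        cor = float(np.sum((i - mu_i) * (j - mu_i) * p) / var_i)
    return TextureSet(con, cor, ene, hom)


def texture_features(pmap: ParametricMap | np.ndarray, n_levels: int = 16,
                     mask: np.ndarray | None = None,
                     distances=GLCM_DISTANCES, angles=GLCM_ANGLES
                     ) -> TextureSet:
    """CON/COR/ENE/HOM averaged over the 16 (distance, angle) GLCMs.

    Empty GLCMs (no valid pair at an offset) are excluded from the average;
    a constant map returns the degenerate values CON = 0, ENE = 1, HOM = 1,
    COR = 1 (by convention, with a warning).
    """
    name = pmap.parameter_name if isinstance(pmap, ParametricMap) else ""
    qmap = quantize_map(pmap, n_levels, mask=mask)
    if qmap.degenerate:
        warnings.warn(f"constant map {name or '(unnamed)'}: degenerate "
                      "textures CON=0, ENE=1, HOM=1, COR=1", stacklevel=2)
        return TextureSet(0.0, 1.0, 1.0, 1.0, source_parameter=name)
    feats = []
    for d in distances:
        for a in angles:
            g = compute_glcm(qmap, d, a)
            if not g.empty:
                feats.append(glcm_features(g))
    if not feats:
        raise ValueError("all GLCMs empty: map too small for every offset")
    return TextureSet(
        con=float(np.mean([f.con for f in feats])),
        cor=float(np.mean([f.cor for f in feats])),
        ene=float(np.mean([f.ene for f in feats])),
        hom=float(np.mean([f.hom for f in feats])),
        source_parameter=name)
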