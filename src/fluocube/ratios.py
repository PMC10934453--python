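"""Chlorophyll fluorescence ratio maps and their masked pixel statistics.

The red/far-red fluorescence ratio (classically F690/F735, here also
F685/F730 and the peak/shoulder pair F673/F717) is inversely related to
chlorophyll content and rises under stress. A ratio map divides the band
nearest the numerator wavelength by the band nearest the denominator
wavelength, pixelwise on the leaf mask; off-mask pixels are NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cube_io import Cube, Mask, band_index
from .errors import EmptyMapError

__all__ = ["RatioMap", "RatioStats", "ratio_map", "ratio_pixel_stats"]

#: Ratio pairs (numerator nm, denominator nm) used throughout the package.
STANDARD_PAIRS: dict[str, tuple[float, float]] = {
    "F690/F735": (690.0, 735.0),
    "F685/F730": (685.0, 730.0),
    "F673/F717": (673.0, 717.0),
}


@dataclass
class RatioMap:
    """An (H, W) dimensionless ratio image, NaN off-mask."""

    values: np.ndarray
    ratio_name: str
    matched_bands: tuple[float, float]
    n_zero_denominator: int = 0
    degenerate: bool = False  # numerator and denominator matched the same band


@dataclass
class RatioStats:
    """Trimmed summary of a map's finite pixels (sample SD)."""

    mean: float
    sd: float
    min: float
    max: float
    n: int


def ratio_map(cube: Cube, num_wl: float, den_wl: float, mask: Mask) -> RatioMap:
    """Compute band(num_wl)/band(den_wl) on mask pixels of a calibrated cube.

    Bands are chosen by nearest-wavelength matching; the wavelengths actually
    used are recorded on the result. Zero denominators become NaN and are
    counted. If both queries match the same band the map is identically one
    on the mask and flagged degenerate (with a warning).
    """
    num = band_index(cube, num_wl)
    den = band_index(cube, den_wl)
    degenerate = num.index == den.index
    if degenerate:
        warnings.warn(
            f"ratio {num_wl:g}/{den_wl:g} nm matched the same band "
            f"({num.wavelength:g} nm); map is identically 1",
            stacklevel=2,
        )
    a = cube.band(num.index)
    b = cube.band(den.index)
    values = np.full(a.shape, np.nan)
    m = mask.values
    with np.errstate(divide="ignore", invalid="ignore"):
        values[m] = a[m] / b[m]
    n_zero = int(np.sum(m & (b == 0)))
    values[m & (b == 0)] = np.nan
    return RatioMap(
        values=values,
        ratio_name=f"F{num_wl:g}/F{den_wl:g}",
        matched_bands=(num.wavelength, den.wavelength),
        n_zero_denominator=n_zero,
        degenerate=degenerate,
    )


def ratio_pixel_stats(map_values: RatioMap | np.ndarray, trim: tuple[float, float] = (0.5, 99.5)) -> RatioStats:
    """Mean/SD/range of a map's finite pixels after two-sided percentile trim.

    ``trim`` is a (low, high) percentile pair; values strictly outside the
    trimmed percentile band are dropped before computing statistics, removing
    boundary pixels and specular noise. SD is the sample SD (n−1).
    """
    values = map_values.values if isinstance(map_values, RatioMap) else np.asarray(map_values)
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise EmptyMapError("map has no finite pixels")
    lo, hi = trim
    plo, phi = np.percentile(finite, [lo, hi])
    kept = finite[(finite >= plo) & (finite <= phi)]
    if kept.size == 0:  # pathological trim; fall back to untrimmed
        kept = finite
    sd = float(np.std(kept, ddof=1)) if kept.size > 1 else 0.0
    return RatioStats(
        mean=float(np.mean(kept)),
        sd=sd,
        min=float(np.min(kept)),
        max=float(np.max(kept)),
        n=int(kept.size),
    )
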