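"""Flat-field correction, leaf masking, and random ROI spectrum extraction.

Flat-fielding normalizes a raw cube against a white reference panel and a
capped-lens dark frame::

    calibrated = (raw - dark) / (white - dark)

which removes illumination nonuniformity and dark current in one step.
Pixel-bands where white equals dark (a clipped or dead reference) become NaN
and are counted rather than raising, so the pipeline stays total on real
panels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .cube_io import Cube, Mask, band_index
from .errors import CalibrationError, DimensionError, SamplingError

__all__ = ["SpectraMatrix", "flat_field", "make_mask", "extract_roi_spectra"]


@dataclass
class SpectraMatrix:
    """ROI spectra: an (n, B) matrix with labels and pixel provenance.

    ``provenance`` is a DataFrame with columns ``scene_id``, ``row``, ``col``
    aligned row-for-row with ``X``.
    """

    X: np.ndarray
    labels: np.ndarray
    wavelengths: np.ndarray
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2:
            raise DimensionError(f"spectra matrix must be 2-D, got {self.X.shape}")
        if len(self.labels) != self.X.shape[0]:
            raise DimensionError("labels length must match number of rows")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "SpectraMatrix":
        prov = self.provenance.iloc[idx].reset_index(drop=True) if len(self.provenance) else self.provenance
        return SpectraMatrix(self.X[idx], self.labels[idx], self.wavelengths, prov)


def concat_spectra(parts: list[SpectraMatrix]) -> SpectraMatrix:
    """Stack several spectra matrices sharing a band grid."""
    wl = parts[0].wavelengths
    for p in parts[1:]:
        if not np.array_equal(p.wavelengths, wl):
            raise DimensionError("cannot concatenate spectra on different band grids")
    prov = pd.concat([p.provenance for p in parts], ignore_index=True)
    return SpectraMatrix(
        np.vstack([p.X for p in parts]),
        np.concatenate([p.labels for p in parts]),
        wl,
        prov,
    )


def flat_field(raw: Cube, white: Cube, dark: Cube) -> Cube:
    """Flat-field correct ``raw``: (raw − dark) / (white − dark) elementwise.

    Degenerate pixel-bands (white == dark) are set to NaN; their count is
    recorded in ``meta['n_degenerate']``. If every pixel-band is degenerate a
    :class:`CalibrationError` is raised.
    """
    for other, name in ((white, "white"), (dark, "dark")):
        if other.shape != raw.shape:
            raise DimensionError(
                f"{name} cube shape {other.shape} does not match raw shape {raw.shape}"
            )
        if not np.array_equal(other.wavelengths, raw.wavelengths):
            raise DimensionError(f"{name} cube wavelengths do not match raw cube")

    denom = white.data - dark.data
    degenerate = denom == 0
    n_deg = int(degenerate.sum())
    if n_deg == denom.size:
        raise CalibrationError("white and dark references are identical everywhere")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (raw.data - dark.data) / denom
    out[degenerate] = np.nan
    meta = dict(raw.meta)
    meta.update(kind="calibrated", n_degenerate=n_deg)
    return Cube(out, raw.wavelengths, meta)


def make_mask(
    cube: Cube,
    band_wl: float = 673.0,
    method: str = "otsu",
    threshold: float | None = None,
) -> Mask:
    """Threshold one band of a calibrated cube into a leaf mask.

    The default band is the one nearest the 673 nm chlorophyll emission peak,
    where leaf/background contrast is maximal. ``method='otsu'`` computes the
    threshold from the band's histogram; ``method='fixed'`` uses ``threshold``.
    An empty result is flagged with a warning, not an error.
    """
    match = band_index(cube, band_wl)
    img = cube.band(match.index)
    finite = np.isfinite(img)
    if method == "otsu":
        thr = float(threshold_otsu(img[finite]))
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown mask method {method!r}")
    values = finite & (img > thr)
    mask = Mask(
        values,
        source={
            "band_wl_query": band_wl,
            "band_wl_used": match.wavelength,
            "band_index": match.index,
            "method": method,
            "threshold": thr,
        },
    )
    if mask.empty:
        warnings.warn(f"mask is empty (threshold {thr:g} above band maximum)", stacklevel=2)
    return mask


def extract_roi_spectra(
    cube: Cube,
    mask: Mask,
    n: int,
    seed: int,
    label: str,
) -> SpectraMatrix:
    """Sample ``n`` pixel spectra uniformly without replacement from the mask.

    Provenance (scene id, row, col) is recorded per row; the draw is
    deterministic per seed.
    """
    if mask.values.shape != cube.shape[:2]:
        raise DimensionError("mask shape does not match cube")
    rows, cols = np.nonzero(mask.values)
    avail = len(rows)
    if n > avail:
        raise SamplingError(f"requested {n} ROI pixels but mask has only {avail}")
    rng = np.random.default_rng(seed)
    pick = rng.choice(avail, size=n, replace=False)
    r, c = rows[pick], cols[pick]
    X = cube.data[r, c, :]
    sid = cube.meta.get("scene_id", "")
    prov = pd.DataFrame({"scene_id": sid, "row": r, "col": c})
    return SpectraMatrix(X, np.full(n, label, dtype=object), cube.wavelengths, prov)
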