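"""Multispectral cube container, on-disk format, and wavelength→band lookup.

A :class:`Cube` is an (H, W, B) intensity array with band-center wavelengths
in nanometres and free-form metadata. Cubes are persisted as a single ``.npz``
file holding the data array, the wavelength vector, and the metadata as JSON
(lossless for float64). An optional export to multi-page TIFF (one page per
band) is provided for viewing in external tools.

Named query wavelengths (e.g. the 690 nm of the F690/F735 ratio) rarely
coincide with the camera's band centers; :func:`band_index` maps a query to
the nearest band and reports the matched wavelength so callers can log the
substitution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, NamedTuple

import numpy as np

from .errors import DimensionError, FormatError

__all__ = ["Cube", "Mask", "BandMatch", "band_index", "read_cube", "write_cube", "export_tiff"]


@dataclass
class Cube:
    """An (H, W, B) fluorescence intensity cube with band wavelengths.

    Parameters
    ----------
    data:
        Intensity array, shape (H, W, B). Arbitrary fluorescence units for
        raw/white/dark cubes; dimensionless after flat-field calibration.
    wavelengths:
        Strictly increasing band-center wavelengths in nm, length B.
    meta:
        Free-form metadata. Conventional keys: ``scene_id``, ``kind``
        (one of ``raw``, ``white``, ``dark``, ``calibrated``), ``group``.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.data.ndim != 3:
            raise DimensionError(f"cube data must be 3-D (H, W, B), got shape {self.data.shape}")
        h, w, b = self.data.shape
        if min(h, w, b) < 1:
            raise DimensionError(f"cube dimensions must all be >= 1, got {self.data.shape}")
        if self.wavelengths.shape != (b,):
            raise DimensionError(
                f"wavelengths length {self.wavelengths.shape} does not match band count {b}"
            )
        if not np.all(np.diff(self.wavelengths) > 0):
            raise DimensionError("wavelengths must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band(self, i: int) -> np.ndarray:
        """Return the (H, W) image of band ``i``."""
        return self.data[:, :, i]


@dataclass
class Mask:
    """A boolean leaf/background map tied to a cube's (H, W) grid.

    ``source`` records how the mask was made (band, method, threshold);
    ``empty`` flags a mask with no true pixel (a warning, not an error).
    """

    values: np.ndarray
    source: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise DimensionError(f"mask must be 2-D, got shape {self.values.shape}")

    @property
    def empty(self) -> bool:
        return not bool(self.values.any())

    @property
    def n_true(self) -> int:
        return int(self.values.sum())


class BandMatch(NamedTuple):
    """Result of a wavelength→band query."""

    index: int
    wavelength: float
    out_of_range: bool


def band_index(cube: Cube, query_wl: float) -> BandMatch:
    """Map a query wavelength (nm) to the nearest band of ``cube``.

    Ties between two equidistant bands break toward the lower wavelength.
    Queries outside the cube's wavelength range still match the nearest edge
    band, with ``out_of_range`` set so callers can warn.
    """
    if not np.isfinite(query_wl):
        raise ValueError(f"query wavelength must be finite, got {query_wl}")
    wls = cube.wavelengths
    idx = int(np.argmin(np.abs(wls - query_wl)))  # argmin → first (lower) band on ties
    oob = bool(query_wl < wls[0] or query_wl > wls[-1])
    return BandMatch(index=idx, wavelength=float(wls[idx]), out_of_range=oob)


def write_cube(cube: Cube, path: str | Path) -> None:
    """Persist a cube to a single ``.npz`` file (data, wavelengths, JSON meta)."""
    path = Path(path)
    np.savez(
        path,
        data=cube.data,
        wavelengths=cube.wavelengths,
        meta_json=np.array(json.dumps(cube.meta)),
    )


def read_cube(path: str | Path) -> Cube:
    """Read a cube written by :func:`write_cube`.

    Raises
    ------
    FormatError
        If the file is missing one of the required records (the message names
        the missing field) or shapes are inconsistent.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"cube file not found: {path}")
    with np.load(path, allow_pickle=False) as npz:
        for key in ("data", "wavelengths"):
            if key not in npz:
                raise FormatError(f"cube file {path} is missing required record '{key}'")
        data = npz["data"]
        wavelengths = npz["wavelengths"]
        meta = json.loads(str(npz["meta_json"])) if "meta_json" in npz else {}
    try:
        return Cube(data=data, wavelengths=wavelengths, meta=meta)
    except DimensionError as exc:
        raise FormatError(f"cube file {path} is malformed: {exc}") from exc


def export_tiff(cube: Cube, path: str | Path) -> None:
    """Export one page per band to a multi-page TIFF (viewing convenience).

    Wavelengths and meta go into the TIFF description tag as JSON. Requires
    ``tifffile``; the ``.npz`` container remains the authoritative format.
    """
    import tifffile

    desc = json.dumps({"wavelengths": cube.wavelengths.tolist(), "meta": cube.meta})
    pages = np.moveaxis(cube.data.astype(np.float32), 2, 0)
    tifffile.imwrite(str(path), pages, description=desc)
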