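"""Spectral pretreatments: smoothing, MSC, and SNV.

The three methods are mutually exclusive alternatives applied row-wise to a
spectra matrix:

* **smoothing** — Savitzky–Golay (default) or moving-average convolution,
  edges handled by symmetric reflection so the band count is preserved;
* **MSC** (multiplicative scatter correction) — each spectrum x is regressed
  on a reference spectrum, x ≈ a + b·ref, and corrected to (x − a)/b; the
  reference is the calibration-set mean, frozen and reused on prediction
  rows so no information leaks across the split;
* **SNV** (standard normal variate) — each spectrum is centered and scaled
  to unit sample SD, removing per-spectrum offset and gain without any
  reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.signal import savgol_filter

from .calibration import SpectraMatrix
from .errors import InvalidConfigError

__all__ = ["PreprocessSpec", "Preprocessor", "smooth", "msc", "snv", "MSCResult", "SNVResult"]

Method = Literal["none", "smoothing", "msc", "snv"]


@dataclass(frozen=True)
class PreprocessSpec:
    """Which pretreatment to apply and its parameters."""

    method: Method = "none"
    smoothing_window: int = 5
    smoothing_kind: Literal["moving_average", "savitzky_golay"] = "savitzky_golay"
    sg_polyorder: int = 2

    def validate(self, n_bands: int) -> None:
        if self.method not in ("none", "smoothing", "msc", "snv"):
            raise InvalidConfigError(f"unknown preprocessing method {self.method!r}")
        if self.method == "smoothing":
            w = self.smoothing_window
            if w % 2 == 0 or w < 3 or w > n_bands:
                raise InvalidConfigError(
                    f"smoothing window must be odd, >= 3 and <= {n_bands}, got {w}"
                )
            if self.smoothing_kind == "savitzky_golay" and self.sg_polyorder >= w:
                raise InvalidConfigError("sg_polyorder must be < smoothing window")


def _smooth_rows(X: np.ndarray, spec: PreprocessSpec) -> np.ndarray:
    w = spec.smoothing_window
    half = w // 2
    padded = np.pad(X, ((0, 0), (half, half)), mode="symmetric")
    if spec.smoothing_kind == "moving_average":
        kernel = np.ones(w) / w
        out = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="valid"), 1, padded)
    elif spec.smoothing_kind == "savitzky_golay":
        out = savgol_filter(padded, window_length=w, polyorder=spec.sg_polyorder, axis=1)
        out = out[:, half : padded.shape[1] - half]
    else:
        raise InvalidConfigError(f"unknown smoothing kind {spec.smoothing_kind!r}")
    return out


def smooth(X: SpectraMatrix, spec: PreprocessSpec | None = None) -> SpectraMatrix:
    """Convolve each spectrum with the configured smoothing kernel.

    Edges are reflected (edge value repeated) so output length equals the
    band count; any linear smoother preserves constant rows exactly.
    """
    spec = spec or PreprocessSpec(method="smoothing")
    spec = replace(spec, method="smoothing")
    spec.validate(X.n_bands)
    return SpectraMatrix(_smooth_rows(X.X, spec), X.labels, X.wavelengths, X.provenance)


@dataclass
class MSCResult:
    spectra: SpectraMatrix
    coefficients: np.ndarray  # (n, 2) columns (a, b)
    flagged: np.ndarray       # rows left unchanged because b ≈ 0
    reference: np.ndarray


def msc(
    X: SpectraMatrix, reference: np.ndarray | None = None, min_gain: float = 0.05
) -> MSCResult:
    """Multiplicative scatter correction against a reference spectrum.

    Each row x is fit by least squares as x ≈ a + b·ref and corrected to
    (x − a)/b. The reference defaults to the column mean of ``X`` (callers
    fitting a model should pass the calibration-set mean when transforming
    prediction rows).

    Rows whose fitted gain satisfies |b| < ``min_gain`` are flagged and
    returned unchanged: with b near zero the spectrum carries essentially
    none of the reference shape (a noise-dominated or background pixel), the
    affine scatter model is unidentifiable, and dividing by b would amplify
    noise without bound. The degenerate case b == 0 (e.g. a constant
    reference) is subsumed.
    """
    ref = np.mean(X.X, axis=0) if reference is None else np.asarray(reference, dtype=float)
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    n = X.n
    out = X.X.copy()
    coefs = np.zeros((n, 2))
    flagged = np.zeros(n, dtype=bool)
    for i in range(n):
        x = X.X[i]
        if denom == 0.0:
            flagged[i] = True
            coefs[i] = (0.0, 0.0)
            continue
        b = float(ref_c @ (x - x.mean())) / denom
        a = float(x.mean() - b * ref.mean())
        coefs[i] = (a, b)
        if abs(b) < min_gain:
            flagged[i] = True
            continue
        out[i] = (x - a) / b
    spectra = SpectraMatrix(out, X.labels, X.wavelengths, X.provenance)
    return MSCResult(spectra=spectra, coefficients=coefs, flagged=flagged, reference=ref)


@dataclass
class SNVResult:
    spectra: SpectraMatrix
    excluded: np.ndarray  # original row indices dropped for zero SD
    n_excluded: int


def snv(X: SpectraMatrix) -> SNVResult:
    """Standard normal variate: per-row centering and scaling to unit SD.

    SD uses the sample (n−1) convention, so every output row has mean 0 and
    sample SD exactly 1. Zero-SD (constant) rows cannot be scaled; they are
    excluded and their original indices reported.
    """
    means = X.X.mean(axis=1, keepdims=True)
    sds = X.X.std(axis=1, ddof=1, keepdims=True)
    ok = sds[:, 0] > 0
    out = (X.X[ok] - means[ok]) / sds[ok]
    keep_idx = np.nonzero(ok)[0]
    excluded = np.nonzero(~ok)[0]
    prov = X.provenance.iloc[keep_idx].reset_index(drop=True) if len(X.provenance) else X.provenance
    spectra = SpectraMatrix(out, X.labels[ok], X.wavelengths, prov)
    return SNVResult(spectra=spectra, excluded=excluded, n_excluded=int(excluded.size))


@dataclass
class Preprocessor:
    """Fit-once / apply-many wrapper around the three pretreatments.

    ``fit`` learns any data-dependent state from the calibration rows (only
    MSC has state: its reference spectrum) and freezes it; ``transform``
    applies the frozen pretreatment to new rows, as required when scoring
    prediction rows or whole-image pixels.
    """

    spec: PreprocessSpec
    msc_reference: np.ndarray | None = field(default=None)

    def fit(self, X: SpectraMatrix) -> "Preprocessor":
        self.spec.validate(X.n_bands)
        if self.spec.method == "msc":
            self.msc_reference = np.mean(X.X, axis=0)
        return self

    def transform(self, X: SpectraMatrix) -> SpectraMatrix:
        m = self.spec.method
        if m == "none":
            return X
        if m == "smoothing":
            return smooth(X, self.spec)
        if m == "msc":
            if self.msc_reference is None:
                raise InvalidConfigError("MSC preprocessor must be fit before transform")
            return msc(X, reference=self.msc_reference).spectra
        if m == "snv":
            res = snv(X)
            if res.n_excluded:
                # constant rows cannot be normalized; keep matrix aligned by
                # filling them with zeros (mean spectrum in SNV space)
                full = np.zeros_like(X.X)
                keep = np.setdiff1d(np.arange(X.n), res.excluded)
                full[keep] = res.spectra.X
                return SpectraMatrix(full, X.labels, X.wavelengths, X.provenance)
            return res.spectra
        raise InvalidConfigError(f"unknown preprocessing method {m!r}")

    def fit_transform(self, X: SpectraMatrix) -> SpectraMatrix:
        return self.fit(X).transform(X)
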