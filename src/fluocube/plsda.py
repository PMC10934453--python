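"""Pairwise PLS-DA: NIPALS fitting, component selection, and prediction.

PLS-DA regresses a 0/1 class code on the spectra with partial least squares
and thresholds the continuous prediction at 0.5. Fitting uses the classical
NIPALS PLS1 algorithm on column-centered X and centered y: each component
extracts a weight vector w ∝ Xᵀy, scores t = Xw, loadings p = Xᵀt/tᵀt and
q = yᵀt/tᵀt, then deflates X. The fitted model collapses to a single
regression vector β = W(PᵀW)⁻¹q, so pixel-wise maps are one matrix product.

The pairwise driver mirrors the usual chemometric protocol: a stratified
75/25 calibration/prediction split per class pair, preprocessing fit on the
calibration rows only, the number of latent variables chosen by stratified
cross-validation on the calibration set, and accuracy/R²/RMSE reported for
both splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .calibration import SpectraMatrix
from .cube_io import Cube, Mask
from .errors import (
    DegenerateResponseError,
    ModelCompatibilityError,
    RankError,
    SplitError,
)
from .preprocess import Preprocessor, PreprocessSpec

__all__ = [
    "PLSModel",
    "PairResult",
    "PairwiseResults",
    "fit_pls",
    "select_components",
    "top_wavelengths",
    "split_calibration",
    "train_pairwise",
    "predict_map",
]


@dataclass
class PLSModel:
    """A fitted pairwise PLS-DA model.

    ``class_pair`` maps (name0, name1) to codes (0, 1). Prediction is
    ``x·beta + intercept`` with ``intercept = y_mean − x_mean·beta``; the
    latent-score path W(PᵀW)⁻¹q gives the identical value (algebraic
    identity, checked in tests to 1e−10).
    """

    weights: np.ndarray       # W, (B, k)
    x_loadings: np.ndarray    # P, (B, k)
    y_loadings: np.ndarray    # q, (k,)
    x_mean: np.ndarray
    y_mean: float
    beta: np.ndarray
    intercept: float
    n_components: int
    class_pair: tuple[str, str] = ("0", "1")
    preprocess: PreprocessSpec = field(default_factory=PreprocessSpec)
    preprocessor: Preprocessor | None = None
    wavelengths: np.ndarray | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Continuous class score for rows of (already preprocessed) X."""
        X = np.asarray(X, dtype=float)
        return X @ self.beta + self.intercept

    def predict_scores_path(self, X: np.ndarray) -> np.ndarray:
        """Prediction via latent scores t = Xc·R, ŷ = t·q + ȳ (cross-check)."""
        Xc = np.asarray(X, dtype=float) - self.x_mean
        R = self.weights @ np.linalg.inv(self.x_loadings.T @ self.weights)
        return (Xc @ R) @ self.y_loadings + self.y_mean

    def classify(self, X: np.ndarray, cutoff: float = 0.5) -> np.ndarray:
        return (self.predict(X) >= cutoff).astype(int)


def fit_pls(X: np.ndarray, y: np.ndarray, k: int, class_pair: tuple[str, str] = ("0", "1")) -> PLSModel:
    """Fit a k-component PLS1 regression of the 0/1 code ``y`` on ``X``.

    NIPALS for a univariate response needs no iteration or random start:
    each component's weight vector is the (normalized) covariance Xᵀy of the
    deflated X with the response.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, b = X.shape
    if n < 2:
        raise RankError(f"need at least 2 samples, got {n}")
    if np.unique(y).size < 2:
        raise DegenerateResponseError("response contains a single class")
    if k < 1 or k > min(n - 1, b):
        raise RankError(f"k must be in [1, min(n-1, B)] = [1, {min(n - 1, b)}], got {k}")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    W = np.zeros((b, k))
    P = np.zeros((b, k))
    q = np.zeros(k)
    Xd = Xc.copy()
    for a in range(k):
        w = Xd.T @ yc
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            raise RankError(f"X is exhausted after {a} components; requested k={k}")
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-28:
            raise RankError(f"zero-variance score at component {a + 1}")
        p = Xd.T @ t / tt
        q_a = float(yc @ t) / tt
        Xd = Xd - np.outer(t, p)
        W[:, a], P[:, a], q[a] = w, p, q_a

    beta = W @ np.linalg.solve(P.T @ W, q)
    intercept = y_mean - float(x_mean @ beta)
    return PLSModel(
        weights=W,
        x_loadings=P,
        y_loadings=q,
        x_mean=x_mean,
        y_mean=y_mean,
        beta=beta,
        intercept=intercept,
        n_components=k,
        class_pair=class_pair,
    )


def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Deterministic stratified fold assignment; returns test-index arrays."""
    assignment = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        idx = rng.permutation(idx)
        assignment[idx] = np.arange(len(idx)) % folds
    return [np.nonzero(assignment == f)[0] for f in range(folds)]


def select_components(
    X: np.ndarray,
    y: np.ndarray,
    k_max: int = 10,
    folds: int = 5,
    seed: int = 0,
) -> int:
    """Choose the number of latent variables by stratified k-fold CV.

    Minimizes cross-validated misclassification at the 0.5 cutoff; ties
    break toward the smallest k. ``k_max`` is capped by what the smallest
    training fold supports.
    """
    if k_max < 1:
        raise RankError(f"k_max must be >= 1, got {k_max}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    test_folds = _stratified_folds(y, folds, rng)
    n, b = X.shape
    min_train = min(n - len(f) for f in test_folds)
    k_cap = min(k_max, min_train - 1, b)
    if k_cap < 1:
        return 1
    errors = np.zeros(k_cap)
    for test_idx in test_folds:
        if len(test_idx) == 0:
            continue
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        if np.unique(y[train_idx]).size < 2:
            continue
        for k in range(1, k_cap + 1):
            try:
                m = fit_pls(X[train_idx], y[train_idx], k)
            except RankError:
                errors[k - 1 :] += len(test_idx)  # unreachable k counts as failure
                break
            pred = (m.predict(X[test_idx]) >= 0.5).astype(float)
            errors[k - 1] += float(np.sum(pred != y[test_idx]))
    return int(np.argmin(errors)) + 1  # argmin takes the first (smallest) k on ties


def top_wavelengths(model: PLSModel, m: int = 4) -> list[tuple[float, float]]:
    """The ``m`` wavelengths with largest |beta|, sorted by wavelength.

    These are the discriminant bands a spectroscopist would report from the
    beta-coefficient curve.
    """
    if model.wavelengths is None:
        raise ValueError("model carries no wavelengths")
    b = len(model.beta)
    if not 1 <= m <= b:
        raise ValueError(f"m must be in [1, {b}], got {m}")
    order = np.argsort(np.abs(model.beta))[::-1][:m]
    chosen = sorted(order, key=lambda i: model.wavelengths[i])
    return [(float(model.wavelengths[i]), float(model.beta[i])) for i in chosen]


def split_calibration(
    X: SpectraMatrix, fraction: float = 0.75, seed: int = 0
) -> tuple[SpectraMatrix, SpectraMatrix]:
    """Stratified random calibration/prediction split.

    Per class, ``round(fraction · n_class)`` rows go to the calibration set;
    the rest form the prediction set. Deterministic per seed.
    """
    if not 0.0 < fraction < 1.0:
        raise SplitError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    cal_idx: list[np.ndarray] = []
    pred_idx: list[np.ndarray] = []
    for cls in pd.unique(pd.Series(X.labels)):
        idx = np.nonzero(X.labels == cls)[0]
        if len(idx) < 2:
            raise SplitError(f"class {cls!r} has {len(idx)} rows; need >= 2 to split")
        idx = rng.permutation(idx)
        n_cal = int(round(fraction * len(idx)))
        n_cal = min(max(n_cal, 1), len(idx) - 1)  # both splits stay nonempty
        cal_idx.append(idx[:n_cal])
        pred_idx.append(idx[n_cal:])
    return X.subset(np.concatenate(cal_idx)), X.subset(np.concatenate(pred_idx))


@dataclass
class PairResult:
    """Per-pair metrics: accuracies in percent, R²/RMSE on the prediction set."""

    pair: tuple[str, str]
    n_components: int
    calibration_accuracy: float
    prediction_accuracy: float
    r2: float
    rmse: float
    model: PLSModel


@dataclass
class PairwiseResults:
    """All one-vs-one results for a group list, lower-triangular tables."""

    groups: list[str]
    pairs: list[PairResult]
    preprocess: PreprocessSpec

    def _table(self, attr: str) -> pd.DataFrame:
        tab = pd.DataFrame(index=self.groups, columns=self.groups, dtype=float)
        for pr in self.pairs:
            g0, g1 = pr.pair
            i0, i1 = self.groups.index(g0), self.groups.index(g1)
            lo, hi = (i0, i1) if i0 > i1 else (i1, i0)
            tab.iloc[lo, hi] = getattr(pr, attr)
        return tab

    @property
    def calibration_table(self) -> pd.DataFrame:
        """Lower-triangular % accuracy on the calibration set."""
        return self._table("calibration_accuracy")

    @property
    def prediction_table(self) -> pd.DataFrame:
        """Lower-triangular % accuracy on the prediction set."""
        return self._table("prediction_accuracy")

    def mean_metrics(self) -> dict[str, float]:
        """Averages over all pairs (one summary number per model family)."""
        return {
            "calibration_accuracy": float(np.mean([p.calibration_accuracy for p in self.pairs])),
            "prediction_accuracy": float(np.mean([p.prediction_accuracy for p in self.pairs])),
            "r2": float(np.mean([p.r2 for p in self.pairs])),
            "rmse": float(np.mean([p.rmse for p in self.pairs])),
        }


def _accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    return 100.0 * float(np.mean((pred >= 0.5).astype(float) == truth))


def train_pairwise(
    spectra: SpectraMatrix,
    spec: PreprocessSpec | None = None,
    fraction: float = 0.75,
    k_max: int = 10,
    seed: int = 0,
) -> PairwiseResults:
    """Train one PLS-DA model per unordered group pair.

    For each pair: stratified split, preprocessing fit on calibration rows
    only (MSC reference frozen there), component count by 5-fold CV on the
    calibration set, then accuracy on both sets and R²/RMSE of the continuous
    predictions against the 0/1 codes on the prediction set. All per-pair
    seeds derive from the master seed.
    """
    spec = spec or PreprocessSpec()
    groups = list(pd.unique(pd.Series(spectra.labels)))
    if len(groups) < 2:
        raise DegenerateResponseError("need at least two groups")
    seeds = np.random.SeedSequence(seed).generate_state(2 * len(groups) ** 2, dtype=np.uint32)
    results: list[PairResult] = []
    si = 0
    for g0, g1 in combinations(groups, 2):
        idx = np.nonzero((spectra.labels == g0) | (spectra.labels == g1))[0]
        sub = spectra.subset(idx)
        cal, pred = split_calibration(sub, fraction=fraction, seed=int(seeds[si])); si += 1
        prep = Preprocessor(spec).fit(cal)
        Xc = prep.transform(cal).X
        Xp = prep.transform(pred).X
        yc = (cal.labels == g1).astype(float)
        yp = (pred.labels == g1).astype(float)
        k = select_components(Xc, yc, k_max=k_max, seed=int(seeds[si])); si += 1
        model = fit_pls(Xc, yc, k, class_pair=(g0, g1))
        model.preprocess = spec
        model.preprocessor = prep
        model.wavelengths = np.asarray(spectra.wavelengths, dtype=float)
        yhat_c = model.predict(Xc)
        yhat_p = model.predict(Xp)
        ss_res = float(np.sum((yp - yhat_p) ** 2))
        ss_tot = float(np.sum((yp - yp.mean()) ** 2))
        results.append(
            PairResult(
                pair=(g0, g1),
                n_components=k,
                calibration_accuracy=_accuracy(yhat_c, yc),
                prediction_accuracy=_accuracy(yhat_p, yp),
                r2=1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan"),
                rmse=float(np.sqrt(np.mean((yp - yhat_p) ** 2))),
                model=model,
            )
        )
    return PairwiseResults(groups=groups, pairs=results, preprocess=spec)


def predict_map(model: PLSModel, cube: Cube, mask: Mask) -> np.ndarray:
    """Score every mask pixel of a calibrated cube with a fitted model.

    Each pixel spectrum is preprocessed with the model's frozen pretreatment
    and scored with beta + intercept. Returns an (H, W) array of raw scores,
    NaN off-mask; callers may clip to [0, 1] for display.
    """
    if model.wavelengths is not None and not np.array_equal(
        np.asarray(cube.wavelengths), np.asarray(model.wavelengths)
    ):
        raise ModelCompatibilityError("cube wavelengths do not match model wavelengths")
    rows, cols = np.nonzero(mask.values)
    out = np.full(cube.shape[:2], np.nan)
    if len(rows) == 0:
        return out
    X = SpectraMatrix(
        cube.data[rows, cols, :],
        np.full(len(rows), "?", dtype=object),
        cube.wavelengths,
    )
    if model.preprocessor is not None:
        X = model.preprocessor.transform(X)
    out[rows, cols] = model.predict(X.X)
    return out
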