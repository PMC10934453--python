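"""Group statistics: one-way ANOVA, Tukey HSD with compact letters, and
model R²/RMSE comparison.

Map pixel values are treated as independent observations, matching common
practice in imaging phenotyping tables; the spatial-autocorrelation caveat is
documented rather than modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ratios import RatioMap, ratio_pixel_stats

__all__ = ["AnovaResult", "TukeyResult", "GroupStats", "anova_oneway", "tukey_hsd", "model_r2_rmse", "summarize_maps"]


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass
class TukeyResult:
    """Pairwise Tukey HSD at ``alpha`` plus a compact letter display.

    ``significant`` maps each unordered index pair (i, j) to a bool;
    ``letters`` shares a letter between groups that are *not* significantly
    different (insert-and-absorb display, groups ranked by descending mean).
    """

    alpha: float
    significant: dict[tuple[int, int], bool] = field(default_factory=dict)
    p_values: dict[tuple[int, int], float] = field(default_factory=dict)
    letters: list[str] = field(default_factory=list)


def anova_oneway(groups: list[np.ndarray]) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA.

    F = (SSB/df_between) / (SSW/df_within), p from the F distribution.
    With zero within-group variance and unequal means the statistic is
    reported as +inf with p = 0 (perfect separation sentinel).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least two values")
    ns = np.array([len(g) for g in groups])
    means = np.array([g.mean() for g in groups])
    grand = float(np.concatenate(groups).mean())
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(np.sum((g - g.mean()) ** 2) for g in groups))
    df_b = len(groups) - 1
    df_w = int(ns.sum()) - len(groups)
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(F=0.0, df_between=df_b, df_within=df_w, p=1.0)
        return AnovaResult(F=float("inf"), df_between=df_b, df_within=df_w, p=0.0)
    F = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w, p=p)


def _compact_letters(n_groups: int, means: np.ndarray, sig: dict[tuple[int, int], bool]) -> list[str]:
    """Insert-and-absorb compact letter display, groups ranked by mean desc."""
    order = list(np.argsort(-means))
    # letter sets: each is the set of (ranked) groups sharing that letter
    letter_sets: list[set[int]] = [set(order)]
    for i, j in [(a, b) for a in range(n_groups) for b in range(a + 1, n_groups)]:
        if not sig.get((i, j), False):
            continue
        new_sets: list[set[int]] = []
        for s in letter_sets:
            if i in s and j in s:
                new_sets.extend([s - {j}, s - {i}])  # split the conflicting set
            else:
                new_sets.append(s)
        # absorb: drop sets contained in another
        letter_sets = [
            s for k, s in enumerate(new_sets)
            if not any(s < t or (s == t and k2 < k) for k2, t in enumerate(new_sets) if k2 != k)
        ]
    # assign letters in mean-descending order of each set's best group
    letter_sets.sort(key=lambda s: min(order.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    labels = ["" for _ in range(n_groups)]
    for li, s in enumerate(letter_sets):
        for g in s:
            labels[g] += alphabet[li % len(alphabet)]
    return ["".join(sorted(l)) for l in labels]


def tukey_hsd(groups: list[np.ndarray], alpha: float = 0.05) -> TukeyResult:
    """Tukey honestly-significant-difference pairwise comparisons.

    Uses the studentized range distribution with the pooled within-group
    variance (Tukey–Kramer for unequal n). Letters are shared by groups that
    are statistically indistinguishable at ``alpha``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least two values")
    ns = np.array([len(g) for g in groups])
    means = np.array([g.mean() for g in groups])
    df_w = int(ns.sum()) - k
    msw = float(sum(np.sum((g - g.mean()) ** 2) for g in groups)) / df_w
    res = TukeyResult(alpha=alpha)
    for i, j in combinations(range(k), 2):
        diff = abs(means[i] - means[j])
        if msw == 0.0:
            p = 0.0 if diff > 0 else 1.0
        else:
            se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            qstat = diff / se
            p = float(sps.studentized_range.sf(qstat, k, df_w))
        res.p_values[(i, j)] = p
        res.significant[(i, j)] = p < alpha
    res.letters = _compact_letters(k, means, res.significant)
    return res


def model_r2_rmse(predicted: np.ndarray, coded_truth: np.ndarray) -> tuple[float, float]:
    """R² = 1 − SS_res/SS_tot and RMSE of predictions against 0/1 codes."""
    predicted = np.asarray(predicted, dtype=float)
    truth = np.asarray(coded_truth, dtype=float)
    if predicted.shape != truth.shape or predicted.size < 2:
        raise ValueError("vectors must share a length >= 2")
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R² undefined for a constant truth vector")
    ss_res = float(np.sum((truth - predicted) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(np.mean((truth - predicted) ** 2)))
    return r2, rmse


@dataclass
class GroupStats:
    """Per-group trimmed map statistics plus ANOVA/Tukey, in group order."""

    table: pd.DataFrame          # columns: group, mean, sd, min, max, n, letters
    anova: AnovaResult
    tukey: TukeyResult

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["F"] = self.anova.F
        out["p_value"] = self.anova.p
        out.to_csv(path, index=False)


def summarize_maps(
    maps: dict[str, list[RatioMap | np.ndarray]],
    trim: tuple[float, float] = (0.5, 99.5),
    alpha: float = 0.05,
) -> GroupStats:
    """Summarize labeled maps: trimmed per-group pixel stats + ANOVA + Tukey.

    ``maps`` maps a group name to one or more maps; pixel vectors are pooled
    within a group. Group order in the output follows insertion order of
    ``maps`` (the configured group order).
    """
    if len(maps) < 2:
        raise ValueError("need at least two labeled groups")
    groups = list(maps)
    pooled: list[np.ndarray] = []
    rows = []
    for g in groups:
        vals = []
        for m in maps[g]:
            arr = m.values if isinstance(m, RatioMap) else np.asarray(m)
            arr = arr[np.isfinite(arr)]
            vals.append(arr)
        v = np.concatenate(vals)
        st = ratio_pixel_stats(v, trim=trim)
        lo, hi = np.percentile(v, trim)
        pooled.append(v[(v >= lo) & (v <= hi)])
        rows.append({"group": g, "mean": st.mean, "sd": st.sd, "min": st.min, "max": st.max, "n": st.n})
    anova = anova_oneway(pooled)
    tukey = tukey_hsd(pooled, alpha=alpha)
    table = pd.DataFrame(rows)
    table["letters"] = tukey.letters
    return GroupStats(table=table, anova=anova, tukey=tukey)
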