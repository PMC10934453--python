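"""End-to-end orchestration: simulate → calibrate → mask → extract →
ratios → preprocess/train → score maps → group statistics.

A single :class:`PipelineConfig` (constructible from a YAML file) drives the
whole chain deterministically; every stage seed derives from the master seed.
The run directory receives the scene manifest, the ROI spectra as CSV, the
per-ratio group-statistics tables, the pairwise PLS-DA accuracy tables (one
per pretreatment, calibration and prediction blocks), the score-map group
statistics, a model-comparison table (mean R²/RMSE per model family), and a
log recording every nearest-band substitution and flagged row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import SpectraMatrix, concat_spectra, extract_roi_spectra, flat_field, make_mask
from .cube_io import band_index
from .errors import InvalidConfigError
from .plsda import PairwiseResults, predict_map, split_calibration, train_pairwise
from .preprocess import PreprocessSpec
from .ratios import STANDARD_PAIRS, ratio_map
from .stats import GroupStats, model_r2_rmse, summarize_maps
from .synthetic import SimConfig, generate_dataset

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one run needs; all seeds explicit (no wall-clock seeding)."""

    sim: SimConfig = field(default_factory=SimConfig)
    scenes_per_group: int = 2
    n_spectra_per_group: int = 400
    mask_band_wl: float = 673.0
    mask_method: str = "otsu"
    ratio_pairs: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(STANDARD_PAIRS))
    preprocess_methods: tuple[str, ...] = ("smoothing", "msc", "snv")
    fraction: float = 0.75
    k_max: int = 10
    trim: tuple[float, float] = (0.5, 99.5)
    alpha: float = 0.05
    seed: int = 0
    out_dir: str | Path = "fluocube_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        if sim_raw is None and "manifest" not in raw:
            raise InvalidConfigError("config must contain a 'sim' block (no input manifest given)")
        sim = SimConfig(**sim_raw) if sim_raw else SimConfig()
        if "ratio_pairs" in raw:
            raw["ratio_pairs"] = {k: tuple(v) for k, v in raw["ratio_pairs"].items()}
        if "preprocess_methods" in raw:
            raw["preprocess_methods"] = tuple(raw["preprocess_methods"])
        if "trim" in raw:
            raw["trim"] = tuple(raw["trim"])
        known = {f for f in cls.__dataclass_fields__} - {"sim"}
        unknown = set(raw) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(sim=sim, **raw)


@dataclass
class PipelineResult:
    out_dir: Path
    manifest: pd.DataFrame
    spectra: SpectraMatrix
    ratio_stats: dict[str, GroupStats]
    pairwise: dict[str, PairwiseResults]
    map_stats: dict[str, GroupStats]
    comparison: pd.DataFrame


def _fmt_stats_csv(gs: GroupStats, path: Path) -> None:
    out = gs.table.copy()
    out["mean_sd"] = out.apply(lambda r: f"{r['mean']:.3f} ± {r['sd']:.3f}", axis=1)
    out["range"] = out.apply(lambda r: f"{r['min']:.3f}–{r['max']:.3f}", axis=1)
    out["F"] = gs.anova.F
    out["p_value"] = gs.anova.p
    out.to_csv(path, index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis chain; deterministic per config seeds."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    seeds = np.random.SeedSequence(config.seed).generate_state(4, dtype=np.uint32)

    # 1. simulate
    scenes, manifest = generate_dataset(config.sim, config.scenes_per_group, seed=int(seeds[0]))
    manifest.to_csv(out / "manifest.csv", index=False)
    groups = list(config.sim.groups)

    # 2. calibrate + mask
    calibrated = []
    for sc in scenes:
        cal = flat_field(sc.raw, sc.white, sc.dark)
        mask = make_mask(cal, band_wl=config.mask_band_wl, method=config.mask_method)
        log_lines.append(
            f"scene {sc.scene_id}: mask band {config.mask_band_wl:g} nm -> "
            f"{mask.source['band_wl_used']:g} nm, threshold {mask.source['threshold']:.4g}, "
            f"{mask.n_true} leaf pixels, {cal.meta.get('n_degenerate', 0)} degenerate pixel-bands"
        )
        calibrated.append((sc, cal, mask))

    # 3. ROI spectra: n_spectra_per_group split across the group's scenes
    roi_seed_root = np.random.SeedSequence(int(seeds[1]))
    roi_seeds = roi_seed_root.generate_state(len(calibrated), dtype=np.uint32)
    per_scene = {}
    for g in groups:
        g_scenes = [t for t in calibrated if t[0].label == g]
        base, rem = divmod(config.n_spectra_per_group, len(g_scenes))
        for j, t in enumerate(g_scenes):
            per_scene[t[0].scene_id] = base + (1 if j < rem else 0)
    parts = []
    for i, (sc, cal, mask) in enumerate(calibrated):
        n = per_scene[sc.scene_id]
        parts.append(extract_roi_spectra(cal, mask, n=n, seed=int(roi_seeds[i]), label=sc.label))
    spectra = concat_spectra(parts)
    spectra_df = spectra.provenance.copy()
    spectra_df["label"] = spectra.labels
    for bi, wl in enumerate(spectra.wavelengths):
        spectra_df[f"{wl:.3f}nm"] = spectra.X[:, bi]
    spectra_df.to_csv(out / "spectra.csv", index=False, float_format="%.8g")

    # 4. ratio maps + per-ratio group statistics
    ratio_stats: dict[str, GroupStats] = {}
    ratio_maps_by_pair: dict[str, dict[str, list]] = {name: {g: [] for g in groups} for name in config.ratio_pairs}
    for sc, cal, mask in calibrated:
        for name, (num, den) in config.ratio_pairs.items():
            rm = ratio_map(cal, num, den, mask)
            ratio_maps_by_pair[name][sc.label].append(rm)
    for name in config.ratio_pairs:
        num, den = config.ratio_pairs[name]
        m0 = calibrated[0][1]
        bn, bd = band_index(m0, num), band_index(m0, den)
        log_lines.append(
            f"ratio {name}: {num:g} nm -> band {bn.index} ({bn.wavelength:g} nm), "
            f"{den:g} nm -> band {bd.index} ({bd.wavelength:g} nm)"
        )
        gs = summarize_maps(ratio_maps_by_pair[name], trim=config.trim, alpha=config.alpha)
        ratio_stats[name] = gs
        _fmt_stats_csv(gs, out / f"ratio_stats_{name.replace('/', '_')}.csv")

    # 5. pairwise PLS-DA per pretreatment
    pairwise: dict[str, PairwiseResults] = {}
    train_seeds = np.random.SeedSequence(int(seeds[2])).generate_state(
        len(config.preprocess_methods), dtype=np.uint32
    )
    for mi, method in enumerate(config.preprocess_methods):
        spec = PreprocessSpec(method=method)
        res = train_pairwise(
            spectra, spec=spec, fraction=config.fraction, k_max=config.k_max, seed=int(train_seeds[mi])
        )
        pairwise[method] = res
        res.calibration_table.to_csv(out / f"plsda_{method}_calibration.csv", float_format="%.1f")
        res.prediction_table.to_csv(out / f"plsda_{method}_prediction.csv", float_format="%.1f")
        for pr in res.pairs:
            log_lines.append(
                f"plsda[{method}] {pr.pair[0]} vs {pr.pair[1]}: k={pr.n_components}, "
                f"cal {pr.calibration_accuracy:.1f}%, pred {pr.prediction_accuracy:.1f}%"
            )

    # 6. score maps from the extreme-pair model (first vs last group), per method
    map_stats: dict[str, GroupStats] = {}
    for method, res in pairwise.items():
        extreme = next(
            (p.model for p in res.pairs if set(p.pair) == {groups[0], groups[-1]}), res.pairs[0].model
        )
        maps = {g: [] for g in groups}
        for sc, cal, mask in calibrated:
            score = predict_map(extreme, cal, mask)
            maps[sc.label].append(np.clip(score, 0.0, 1.0))
        gs = summarize_maps(maps, trim=config.trim, alpha=config.alpha)
        map_stats[method] = gs
        _fmt_stats_csv(gs, out / f"plsda_map_stats_{method}.csv")

    # 7. model comparison: mean R²/RMSE per family over all pairs
    comp_rows = []
    ratio_seed = int(seeds[3])
    for name, (num, den) in config.ratio_pairs.items():
        r2s, rmses = [], []
        m0 = calibrated[0][1]
        ni, di = band_index(m0, num).index, band_index(m0, den).index
        from itertools import combinations as _comb

        pair_seeds = np.random.SeedSequence(ratio_seed).generate_state(
            len(groups) * (len(groups) - 1) // 2, dtype=np.uint32
        )
        for pi, (g0, g1) in enumerate(_comb(groups, 2)):
            idx = np.nonzero((spectra.labels == g0) | (spectra.labels == g1))[0]
            sub = spectra.subset(idx)
            cal_s, pred_s = split_calibration(sub, fraction=config.fraction, seed=int(pair_seeds[pi]))
            r_cal = cal_s.X[:, ni] / cal_s.X[:, di]
            r_pred = pred_s.X[:, ni] / pred_s.X[:, di]
            # winsorize to the calibration trim band: stray background pixels
            # yield unbounded ratios, as in the map statistics' noise removal
            lo, hi = np.percentile(r_cal, config.trim)
            r_cal = np.clip(r_cal, lo, hi)
            r_pred = np.clip(r_pred, lo, hi)
            y_cal = (cal_s.labels == g1).astype(float)
            y_pred = (pred_s.labels == g1).astype(float)
            slope, icpt = np.polyfit(r_cal, y_cal, 1)
            r2, rmse = model_r2_rmse(slope * r_pred + icpt, y_pred)
            r2s.append(r2)
            rmses.append(rmse)
        comp_rows.append(
            {"family": "chlorophyll_ratio", "model": name, "r2": float(np.mean(r2s)), "rmse": float(np.mean(rmses))}
        )
    for method, res in pairwise.items():
        mm = res.mean_metrics()
        comp_rows.append({"family": "plsda", "model": method, "r2": mm["r2"], "rmse": mm["rmse"]})
    comparison = pd.DataFrame(comp_rows)
    comparison.to_csv(out / "model_comparison.csv", index=False, float_format="%.6g")

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return PipelineResult(
        out_dir=out,
        manifest=manifest,
        spectra=spectra,
        ratio_stats=ratio_stats,
        pairwise=pairwise,
        map_stats=map_stats,
        comparison=comparison,
    )
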