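"""Synthetic multispectral fluorescence scenes for a five-group stress study.

Emulates a dark-room chlorophyll-fluorescence imaging experiment: leaves of a
control group (Cg), two heat-stress levels (HL-1, HL-2) and two combined
moisture+heat levels (MHL-1, MHL-2) imaged by a 25-band camera spanning
603–870 nm, together with a white PTFE reference panel and a capped-lens dark
frame.

The emission model is a sum of two Gaussian bumps — the chlorophyll red peak
near 673 nm and the far-red shoulder near 717 nm. Stress attenuates the two
amplitudes multiplicatively, optionally by different factors, so stressed
leaves are dimmer overall and their band ratios shift. On top of the clean
per-group signature the generator applies per-leaf multiplicative gain and
additive offset (scatter between leaves), a radial illumination falloff,
additive dark current, and i.i.d. Gaussian sensor noise.

All ground truth (true mask, per-leaf gain/offset, clean signature) is kept on
the returned :class:`Scene` so downstream stages can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .cube_io import Cube, Mask, write_cube
from .errors import InvalidConfigError

__all__ = ["SimConfig", "Scene", "make_band_grid", "class_signature", "generate_scene", "generate_dataset"]

#: Default study groups: (peak attenuation at 673 nm, shoulder attenuation at
#: 717 nm). Control is unattenuated; stress dims both amplitudes, the shoulder
#: more than the peak, so both total intensity and band ratios carry the group
#: signal. Combined moisture+heat (MHL-2) is the most attenuated.
DEFAULT_GROUPS: dict[str, tuple[float, float]] = {
    "Cg": (1.00, 1.00),
    "HL-1": (0.85, 0.80),
    "HL-2": (0.72, 0.65),
    "MHL-1": (0.80, 0.72),
    "MHL-2": (0.55, 0.45),
}


@dataclass
class SimConfig:
    """Parameters of the synthetic imaging experiment.

    Attributes
    ----------
    n_bands, wl_min, wl_max:
        Uniform band grid: ``n_bands`` centers from ``wl_min`` to ``wl_max``
        nm inclusive (default 25 bands over 603–870 nm).
    image_height, image_width:
        Scene size in pixels.
    groups:
        Mapping of group name → stress attenuation, either a scalar in [0, 1]
        applied to both emission peaks or a ``(peak, shoulder)`` pair.
    peak_center_1, peak_width_1, amp1:
        Red chlorophyll emission peak (nm, nm, arbitrary fluorescence units).
    peak_center_2, peak_width_2, amp2:
        Far-red shoulder.
    scatter_sd, offset_sd:
        SDs of the per-leaf multiplicative gain (around 1) and additive
        offset (around 0) emulating leaf-to-leaf scatter variation.
    illum_gradient:
        Maximal fractional illumination falloff from image center to the
        farthest corner, in [0, 1).
    dark_level:
        Additive dark current (same units as amplitudes).
    noise_sd:
        Per-pixel-band Gaussian sensor noise SD.
    panel_level:
        Flat spectral response of the white reference panel; calibrated leaf
        intensities land roughly in [0, 1] when it exceeds the emission peak.
    seed:
        Default seed used when an operation is not given one explicitly.
    """

    n_bands: int = 25
    wl_min: float = 603.0
    wl_max: float = 870.0
    image_height: int = 64
    image_width: int = 64
    groups: Mapping[str, float | tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS)
    )
    peak_center_1: float = 673.0
    peak_width_1: float = 12.0
    amp1: float = 1.0
    peak_center_2: float = 717.0
    peak_width_2: float = 28.0
    amp2: float = 0.55
    scatter_sd: float = 0.08
    offset_sd: float = 0.01
    illum_gradient: float = 0.25
    dark_level: float = 0.05
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bands < 2:
            raise InvalidConfigError(f"n_bands must be >= 2, got {self.n_bands}")
        if not self.wl_min < self.wl_max:
            raise InvalidConfigError(f"need wl_min < wl_max, got {self.wl_min} >= {self.wl_max}")
        if min(self.image_height, self.image_width) < 1:
            raise InvalidConfigError("image dimensions must be positive")
        for name in ("scatter_sd", "offset_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.illum_gradient < 1.0:
            raise InvalidConfigError("illum_gradient must be in [0, 1)")
        for g, att in self.groups.items():
            for a in np.atleast_1d(np.asarray(att, dtype=float)):
                if not 0.0 <= a <= 1.0:
                    raise InvalidConfigError(f"stress attenuation for group {g!r} must be in [0, 1]")

    def attenuation(self, group: str) -> tuple[float, float]:
        """Return the (peak, shoulder) attenuation pair for ``group``."""
        if group not in self.groups:
            raise KeyError(f"unknown group {group!r}; configured groups: {list(self.groups)}")
        att = self.groups[group]
        if np.isscalar(att):
            return float(att), float(att)
        a1, a2 = att  # type: ignore[misc]
        return float(a1), float(a2)


@dataclass
class Scene:
    """One simulated acquisition with its ground truth."""

    raw: Cube
    white: Cube
    dark: Cube
    mask_truth: Mask
    label: str
    scene_id: str
    #: per-leaf multiplicative gain and additive offset actually drawn
    gain: float = 1.0
    offset: float = 0.0
    #: clean per-band signature before gain/offset/illumination/noise
    signature: np.ndarray | None = None
    panel_level: float = 1.0


def make_band_grid(cfg: SimConfig) -> np.ndarray:
    """Uniform band-center grid: ``n_bands`` wavelengths over [wl_min, wl_max]."""
    return np.linspace(cfg.wl_min, cfg.wl_max, cfg.n_bands)


def class_signature(group: str, cfg: SimConfig, wavelengths: np.ndarray) -> np.ndarray:
    """Clean emission spectrum of ``group`` on the given band grid.

    Sum of two Gaussians centered at the red peak and the far-red shoulder,
    with the group's stress attenuation applied to the respective amplitudes.
    """
    a1, a2 = cfg.attenuation(group)
    wl = np.asarray(wavelengths, dtype=float)
    peak = cfg.amp1 * a1 * np.exp(-0.5 * ((wl - cfg.peak_center_1) / cfg.peak_width_1) ** 2)
    shoulder = cfg.amp2 * a2 * np.exp(-0.5 * ((wl - cfg.peak_center_2) / cfg.peak_width_2) ** 2)
    return peak + shoulder


def _illumination_field(cfg: SimConfig) -> np.ndarray:
    """Radial falloff: 1 at image center, 1 − illum_gradient at the corners."""
    h, w = cfg.image_height, cfg.image_width
    rows = np.arange(h)[:, None] - (h - 1) / 2.0
    cols = np.arange(w)[None, :] - (w - 1) / 2.0
    r = np.hypot(rows, cols)
    rmax = r.max() if r.max() > 0 else 1.0
    return 1.0 - cfg.illum_gradient * (r / rmax)


def _leaf_mask(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Random leaf blob: union of 2–3 overlapping ellipses near image center."""
    h, w = cfg.image_height, cfg.image_width
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=bool)
    n_ell = int(rng.integers(2, 4))
    cy0, cx0 = h / 2.0, w / 2.0
    for _ in range(n_ell):
        cy = cy0 + rng.uniform(-0.1, 0.1) * h
        cx = cx0 + rng.uniform(-0.1, 0.1) * w
        ay = rng.uniform(0.18, 0.32) * h
        ax = rng.uniform(0.18, 0.32) * w
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (yy - cy) * ct + (xx - cx) * st
        v = -(yy - cy) * st + (xx - cx) * ct
        mask |= (u / ay) ** 2 + (v / ax) ** 2 <= 1.0
    return mask


def generate_scene(
    group: str, cfg: SimConfig, seed: int | None = None, scene_id: str | None = None
) -> Scene:
    """Simulate one acquisition: raw, white-reference and dark cubes + truth.

    Raw leaf pixels carry ``illum × (gain × signature + offset)`` plus dark
    current and noise; background pixels only dark current and noise. The
    white cube is the illumination field times the flat panel response (plus
    dark and noise), so flat-fielding recovers ``(gain·signature + offset) /
    panel`` on leaf pixels in expectation — illumination cancels, stress
    ordering is preserved.
    """
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    wl = make_band_grid(cfg)
    sig = class_signature(group, cfg, wl)
    h, w, b = cfg.image_height, cfg.image_width, cfg.n_bands

    mask = _leaf_mask(cfg, rng)
    gain = float(1.0 + rng.normal(0.0, cfg.scatter_sd)) if cfg.scatter_sd > 0 else 1.0
    offset = float(rng.normal(0.0, cfg.offset_sd)) if cfg.offset_sd > 0 else 0.0
    gain = max(gain, 0.05)  # a leaf never has negative brightness

    illum = _illumination_field(cfg)
    panel_level = 1.2 * (cfg.amp1 + cfg.amp2)

    signal = gain * sig[None, None, :] + offset          # (1,1,B) broadcast
    raw = illum[:, :, None] * signal * mask[:, :, None]
    raw = raw + cfg.dark_level
    white = illum[:, :, None] * panel_level + cfg.dark_level
    dark = np.full((h, w, b), cfg.dark_level)
    if cfg.noise_sd > 0:
        raw = raw + rng.normal(0.0, cfg.noise_sd, size=(h, w, b))
        white = white + rng.normal(0.0, cfg.noise_sd, size=(h, w, b))
        dark = dark + rng.normal(0.0, cfg.noise_sd, size=(h, w, b))
    else:
        white = np.broadcast_to(white, (h, w, b)).copy()

    sid = scene_id or f"{group}-s{seed}"
    meta = {"scene_id": sid, "group": group, "seed": int(seed)}
    return Scene(
        raw=Cube(raw, wl, {**meta, "kind": "raw"}),
        white=Cube(white, wl, {**meta, "kind": "white"}),
        dark=Cube(dark, wl, {**meta, "kind": "dark"}),
        mask_truth=Mask(mask, {"origin": "ground_truth"}),
        label=group,
        scene_id=sid,
        gain=gain,
        offset=offset,
        signature=sig,
        panel_level=panel_level,
    )


def generate_dataset(
    cfg: SimConfig,
    scenes_per_group: int = 2,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[Scene], pd.DataFrame]:
    """Simulate ``scenes_per_group`` acquisitions for every configured group.

    Per-scene seeds are derived reproducibly from the master seed via
    ``numpy.random.SeedSequence``, so regeneration with the same (config,
    seed) is bit-identical and different master seeds give different cubes.

    Returns the scene list and a manifest DataFrame (scene_id, group, seed and
    — if ``out_dir`` is given — the paths of the persisted cubes and mask).
    """
    if scenes_per_group < 1:
        raise InvalidConfigError(f"scenes_per_group must be >= 1, got {scenes_per_group}")
    if seed is None:
        seed = cfg.seed
    groups = list(cfg.groups)
    n = len(groups) * scenes_per_group
    child_seeds = [int(s) for s in np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)]

    scenes: list[Scene] = []
    rows = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    i = 0
    for group in groups:
        for rep in range(scenes_per_group):
            sid = f"{group}-{rep:02d}"
            scene = generate_scene(group, cfg, seed=child_seeds[i], scene_id=sid)
            scenes.append(scene)
            row = {"scene_id": sid, "group": group, "seed": child_seeds[i]}
            if out is not None:
                paths = {}
                for kind in ("raw", "white", "dark"):
                    p = out / f"{sid}_{kind}.npz"
                    write_cube(getattr(scene, kind), p)
                    paths[f"{kind}_path"] = str(p)
                mp = out / f"{sid}_mask.npz"
                np.savez(mp, values=scene.mask_truth.values)
                paths["mask_path"] = str(mp)
                row.update(paths)
            rows.append(row)
            i += 1
    manifest = pd.DataFrame(rows)
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
    return scenes, manifest


def iter_group_scenes(scenes: list[Scene]) -> Iterator[tuple[str, list[Scene]]]:
    """Yield (group, scenes) preserving first-appearance group order."""
    order: dict[str, list[Scene]] = {}
    for s in scenes:
        order.setdefault(s.label, []).append(s)
    yield from order.items()
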