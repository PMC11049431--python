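"""Synthetic avocado ripening cohorts with labeled two-sided fruit images.

This module emulates the statistical structure of a post-harvest ripening
study on 'Hass' avocado: fruits are distributed into three storage groups
(T10 at 10 degC, T20 at 20 degC, Tamb at fluctuating room temperature),
photographed daily from two opposing sides, and assigned an ordinal
Ripening Index (RI) on a 10-stage scale (each of the classical 5 stages
halved).  End of shelf-life is the first attainment of stage 9 of 10
(equivalently stage 5 of 5); stage 10 marks visible contamination.

Each storage group carries a slope preset ``alpha`` (days per stage,
negative) such that the cohort's emergent ``Days Left`` annotation follows
the linear forced-endpoint law

    Days Left = alpha * (RI - E),   E = 5 (5-stage) or 9 (10-stage),

in expectation over fruits.  Because fruits are photographed on every day
of a multi-day stage dwell, the per-stage dwell time that realizes a given
regression slope is *not* simply ``|alpha|`` days; see
:func:`calibrated_dwell10` for the inversion.

Rendering is deliberately schematic (an ellipse of stage-interpolated skin
color with purple speckles, mold spots and optional one-sided blemish on a
near-white backdrop): the aim is a cohort whose color statistics separate
the stages the way real skins do, not photorealism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage import color as skcolor

__all__ = [
    "StorageGroup",
    "FruitParams",
    "FruitTrajectory",
    "RenderConfig",
    "CohortConfig",
    "GROUP_PRESETS",
    "DEFAULT_STAGE_PALETTE",
    "calibrated_dwell10",
    "sample_fruit_params",
    "stage_timeline",
    "render_fruit_image",
    "fruit_mask",
    "simulate_cohort",
    "render_cohort",
]

END_STAGE10 = 9     # end of shelf-life on the 10-stage index
END_STAGE5 = 5      # end of shelf-life on the 5-stage index
MAX_STAGE10 = 10


@dataclass(frozen=True)
class StorageGroup:
    """A storage arm with its shelf-life slope presets.

    ``alpha5``/``alpha9`` are the Days-Left-per-stage regression slopes
    (days/stage, negative) that the simulated cohort is calibrated to
    reproduce under the 5-stage and 10-stage index respectively.  A
    5-stage step spans two 10-stage steps, so the two magnitudes must
    agree within 10% of a factor two.
    """

    name: str
    alpha5: float
    alpha9: float
    temperature_mean_c: float
    temperature_sd_c: float = 0.0

    def __post_init__(self) -> None:
        if not (self.alpha5 < 0 and self.alpha9 < 0):
            raise ValueError("slope presets must be negative (days decrease per stage)")
        if abs(abs(self.alpha5) / (2.0 * abs(self.alpha9)) - 1.0) > 0.10:
            raise ValueError("|alpha5| must be ~2*|alpha9| within 10%")

    def temperature_profile(self, days: int, rng: np.random.Generator | None = None) -> np.ndarray:
        """Daily temperature series (degC); oscillates only for Tamb-like groups."""
        if self.temperature_sd_c == 0.0:
            return np.full(days, self.temperature_mean_c)
        rng = rng or np.random.default_rng(0)
        t = np.arange(days)
        osc = self.temperature_sd_c * np.sqrt(2.0) * np.cos(2 * np.pi * t / 7.0)
        return self.temperature_mean_c + osc + rng.normal(0.0, 0.3, size=days)


#: Slope presets per storage group (days/stage; 5-stage and 10-stage index).
GROUP_PRESETS: dict[str, StorageGroup] = {
    "T10": StorageGroup("T10", alpha5=-4.390, alpha9=-2.392, temperature_mean_c=10.0),
    "T20": StorageGroup("T20", alpha5=-2.116, alpha9=-1.156, temperature_mean_c=20.0),
    "Tamb": StorageGroup("Tamb", alpha5=-1.929, alpha9=-1.045,
                         temperature_mean_c=18.7, temperature_sd_c=1.2),
}


@dataclass(frozen=True)
class FruitParams:
    sample_id: int
    group: StorageGroup
    speed_factor: float          # multiplicative ripening-rate jitter, > 0
    start_stage10: int           # 1..3: stage on the first photographed day
    blemish_side: str            # "none" | "front" | "back"
    blemish_intensity: float     # 0..1

    def __post_init__(self) -> None:
        if self.speed_factor <= 0:
            raise ValueError("speed_factor must be positive")
        if self.blemish_side not in ("none", "front", "back"):
            raise ValueError(f"invalid blemish side {self.blemish_side!r}")


@dataclass
class FruitTrajectory:
    params: FruitParams
    stage_by_day: np.ndarray     # shape (n_days,), RI10 per day starting day 0
    endpoint_day9: int | None    # first day RI10 >= 9 (None if censored)
    end_day10: int | None        # first day RI10 == 10 (None if censored)
    censored: bool = False

    @property
    def n_days(self) -> int:
        return len(self.stage_by_day)

    def stage10_at(self, day: int) -> int:
        if not (0 <= day < self.n_days):
            raise ValueError(f"day {day} outside observed range 0..{self.n_days - 1}")
        return int(self.stage_by_day[day])

    def days_left9(self, day: int) -> float | None:
        """Days until first stage-9 day, clipped at 0; None when censored."""
        if self.endpoint_day9 is None:
            return None
        return float(max(0, self.endpoint_day9 - day))


# 10 CIELAB anchors: yellow-green -> olive/brown -> scattered purple ->
# homogeneous dark purple -> senescent (mold handled separately).
DEFAULT_STAGE_PALETTE: np.ndarray = np.array([
    [62.0, -20.0, 48.0],
    [58.0, -16.0, 42.0],
    [52.0, -11.0, 34.0],
    [46.0, -5.0, 27.0],
    [39.0, 2.0, 19.0],
    [33.0, 8.0, 10.0],
    [28.0, 12.0, 2.0],
    [24.0, 14.0, -4.0],
    [23.0, 13.0, -5.0],
    [22.0, 12.0, -6.0],
])


@dataclass(frozen=True)
class RenderConfig:
    """Controls the schematic fruit renderer."""

    image_size: int = 96
    stage_palette: np.ndarray = field(default_factory=lambda: DEFAULT_STAGE_PALETTE.copy())
    # fraction of fruit pixels covered by purple speckles, per RI10 stage:
    # rises through the scattered-purple phase, drops once the skin is a
    # homogeneous purple.
    patch_density_by_stage: tuple[float, ...] = (
        0.0, 0.0, 0.03, 0.08, 0.20, 0.35, 0.10, 0.05, 0.04, 0.04)
    mold_spot_rate: float = 12.0      # expected spots per image at RI10 >= 9
    background: float = 0.97          # white level of the backdrop (0..1 sRGB)
    noise_sd: float = 0.012           # per-channel gaussian noise (sRGB units)

    def __post_init__(self) -> None:
        pal = np.asarray(self.stage_palette, dtype=float)
        if pal.shape != (10, 3):
            raise ValueError("stage_palette must hold 10 CIELAB anchors")
        L = pal[:8, 0]
        if not np.all(np.diff(L) <= 0):
            raise ValueError("anchor L* must be nonincreasing over stages 1..8")


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a simulated cohort.

    Defaults reproduce the study conditions: 192 + 143 + 143 fruits across
    the three storage arms, two sides photographed per day, observation
    until the fruit reaches stage 10.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"T10": 192, "T20": 143, "Tamb": 143})
    speed_sd: float = 0.2            # sd of log speed_factor (lognormal, median 1)
    dwell_cv: float = 0.15           # CV of the gamma per-stage dwell
    start_probs: tuple[float, ...] = (0.60, 0.25, 0.15)   # P(start stage10 = 1,2,3)
    blemish_prob: float = 0.30       # fraction of fruits with a one-sided blemish
    drive_index: int = 10            # 5 or 10: which slope preset paces the dwell
    max_days: int | None = None      # observation cap; beyond it fruits are censored
    start_date: str = "2022-03-15"   # ISO date of day 0 (cosmetic date stamps)

    def __post_init__(self) -> None:
        if self.drive_index not in (5, 10):
            raise ValueError("drive_index must be 5 or 10")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")
        if not math.isclose(sum(self.start_probs), 1.0, abs_tol=1e-9):
            raise ValueError("start_probs must sum to 1")


def _stage5_of(stage10: np.ndarray | int):
    return np.ceil(np.asarray(stage10) / 2).astype(int)


def calibrated_dwell10(alpha: float, index_system: int, cfg: CohortConfig) -> float:
    """Mean 10-stage dwell (days) realizing regression slope ``alpha``.

    A fruit is photographed on every day of a stage dwell, so Days Left at a
    stage-``s`` record averages ``dwell * (E - s - 1/2)``-ish rather than
    ``dwell * (E - s)``; pooling fruits whose dwell scales with a lognormal
    speed factor further reweights the through-origin estimator.  Writing
    ``x(s)`` for the regressor ``RI - E`` of a record at 10-stage ``s`` and
    averaging over the start-stage mix, the estimator's expectation is

        alpha_hat = [R*(S1 + c^2*S2/2) + S2/2] / W,
        S1 = E[sum_s x(s)*(8.5 - s)],  S2 = E[sum_s x(s)],  W = E[sum_s x(s)^2],

    with ``c`` the dwell CV and ``R = dwell * E[m^2]/E[m]`` the
    heterogeneity-weighted dwell (``m`` the lognormal speed factor).
    Inverting for ``R`` and dividing out the lognormal moment ratio gives
    the base dwell.  The inversion is exact for alpha9 = -1 (unit dwell).
    """
    if index_system not in (5, 10):
        raise ValueError("index_system must be 5 or 10")
    a = -abs(alpha)
    S1 = S2 = W = 0.0
    for s0, p in zip((1, 2, 3), cfg.start_probs):
        for s in range(s0, END_STAGE10):
            x = (math.ceil(s / 2) - END_STAGE5) if index_system == 5 else (s - END_STAGE10)
            S1 += p * x * (8.5 - s)
            S2 += p * x
            W += p * x * x
    c2 = cfg.dwell_cv ** 2
    R = (a * W - S2 / 2.0) / (S1 + c2 * S2 / 2.0)
    # lognormal with median 1, sd(log) = sigma: E[m^2]/E[m] = exp(3 sigma^2 / 2)
    return R * math.exp(-1.5 * cfg.speed_sd ** 2)


def sample_fruit_params(
    group: StorageGroup | str,
    rng_seed: int | np.random.Generator,
    *,
    sample_id: int = 0,
    cfg: CohortConfig | None = None,
) -> FruitParams:
    """Draw one fruit's heterogeneity parameters (deterministic per seed).

    ``speed_factor`` is lognormal with median 1 and ``cfg.speed_sd`` on the
    log scale; at ``speed_sd = 0`` it is exactly 1.  A blemish (wind-rub /
    sunburn texture) is assigned to at most one side.
    """
    if isinstance(group, str):
        try:
            group = GROUP_PRESETS[group]
        except KeyError:
            raise ValueError(f"unknown storage group {group!r}") from None
    cfg = cfg or CohortConfig()
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    speed = float(np.exp(cfg.speed_sd * rng.standard_normal())) if cfg.speed_sd > 0 else 1.0
    start = int(rng.choice([1, 2, 3], p=cfg.start_probs))
    if rng.random() < cfg.blemish_prob:
        side = "front" if rng.random() < 0.5 else "back"
        intensity = float(rng.uniform(0.3, 1.0))
    else:
        side, intensity = "none", 0.0
    return FruitParams(sample_id=sample_id, group=group, speed_factor=speed,
                       start_stage10=start, blemish_side=side, blemish_intensity=intensity)


def stage_timeline(
    params: FruitParams,
    rng: np.random.Generator | int | None = None,
    *,
    cfg: CohortConfig | None = None,
) -> FruitTrajectory:
    """Simulate one fruit's day-indexed 10-stage trajectory.

    Per-stage dwell is gamma-distributed with mean
    ``calibrated_dwell10(alpha) * speed_factor`` and CV ``cfg.dwell_cv``
    (deterministic at CV 0).  The trajectory runs from the start stage to
    stage 10; photography stops the day stage 10 is reached, or at
    ``cfg.max_days`` (censoring) if configured.
    """
    cfg = cfg or CohortConfig()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    g = params.group
    alpha = g.alpha5 if cfg.drive_index == 5 else g.alpha9
    dwell = calibrated_dwell10(alpha, cfg.drive_index, cfg) * params.speed_factor

    n_steps = MAX_STAGE10 - params.start_stage10   # dwells for start..9
    if cfg.dwell_cv > 0:
        shape = 1.0 / cfg.dwell_cv ** 2
        dwells = rng.gamma(shape, dwell / shape, size=n_steps)
    else:
        dwells = np.full(n_steps, dwell)
    entry = np.concatenate([[0.0], np.cumsum(dwells)])   # entry times of start..10

    last_day = int(math.ceil(entry[-1]))
    if cfg.max_days is not None:
        last_day = min(last_day, cfg.max_days)

    days = np.arange(last_day + 1)
    stage = params.start_stage10 + np.searchsorted(entry[1:], days, side="right")
    stage = np.minimum(stage, MAX_STAGE10).astype(int)

    def first_day_at(target: int) -> int | None:
        idx = np.nonzero(stage >= target)[0]
        return int(idx[0]) if idx.size else None

    ep9 = first_day_at(END_STAGE10)
    ep10 = first_day_at(MAX_STAGE10)
    return FruitTrajectory(params=params, stage_by_day=stage,
                           endpoint_day9=ep9, end_day10=ep10,
                           censored=ep9 is None)


# ---------------------------------------------------------------------------
# rendering

def fruit_mask(cfg: RenderConfig) -> np.ndarray:
    """Ground-truth boolean fruit-ellipse mask for a given render config."""
    n = cfg.image_size
    yy, xx = np.mgrid[0:n, 0:n]
    cy = cx = (n - 1) / 2.0
    ry, rx = 0.40 * n, 0.31 * n
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _lab_to_srgb01(lab: np.ndarray) -> np.ndarray:
    return np.clip(skcolor.lab2rgb(lab.reshape(1, -1, 3)).reshape(-1, 3), 0, 1)


def render_fruit_image(
    trajectory: FruitTrajectory,
    day: int,
    side: str,
    cfg: RenderConfig | None = None,
    rng_seed: int | np.random.Generator = 0,
):
    """Render one labeled photograph; returns ``(image_uint8, record_dict)``.

    The fruit ellipse is filled with the CIELAB anchor of its current RI10,
    overlaid with purple speckles (density per stage), dark mold spots at
    RI10 >= 9, and a brownish blemish patch when this side carries one.
    """
    cfg = cfg or RenderConfig()
    if side not in ("front", "back"):
        raise ValueError(f"side must be 'front' or 'back', got {side!r}")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    stage = trajectory.stage10_at(day)   # raises on out-of-range day
    n = cfg.image_size
    mask = fruit_mask(cfg)

    anchor = np.asarray(cfg.stage_palette, dtype=float)[stage - 1]
    base_rgb = _lab_to_srgb01(anchor)[0]
    img = np.full((n, n, 3), cfg.background, dtype=float)
    img[mask] = base_rgb

    fruit_idx = np.flatnonzero(mask.ravel())
    dens = cfg.patch_density_by_stage[stage - 1]
    if dens > 0 and fruit_idx.size:
        patch_rgb = _lab_to_srgb01(np.asarray(cfg.stage_palette, dtype=float)[7])[0]
        n_seeds = max(1, int(dens * fruit_idx.size / 25))
        centers = rng.choice(fruit_idx, size=n_seeds, replace=True)
        yy, xx = np.mgrid[0:n, 0:n]
        flat = img.reshape(-1, 3)
        for cpix in centers:
            cy, cx = divmod(int(cpix), n)
            r = rng.uniform(1.5, 4.0)
            blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
            sel = blob & mask
            flat[sel.ravel()] = patch_rgb
        img = flat.reshape(n, n, 3)

    if stage >= END_STAGE10 and cfg.mold_spot_rate > 0 and fruit_idx.size:
        n_spots = max(1, rng.poisson(cfg.mold_spot_rate))
        mold_rgb = _lab_to_srgb01(np.array([15.0, 2.0, 2.0]))[0]
        yy, xx = np.mgrid[0:n, 0:n]
        flat = img.reshape(-1, 3)
        for cpix in rng.choice(fruit_idx, size=n_spots, replace=True):
            cy, cx = divmod(int(cpix), n)
            r = rng.uniform(1.0, 2.5)
            sel = ((yy - cy) ** 2 + (xx - cx) ** 2 <= r * r) & mask
            flat[sel.ravel()] = mold_rgb
        img = flat.reshape(n, n, 3)

    p = trajectory.params
    if p.blemish_side == side and p.blemish_intensity > 0:
        yy, xx = np.mgrid[0:n, 0:n]
        bcy, bcx = 0.35 * n, 0.40 * n
        blem = (((yy - bcy) / (0.12 * n)) ** 2 + ((xx - bcx) / (0.08 * n)) ** 2 <= 1.0) & mask
        blem_rgb = _lab_to_srgb01(np.array([35.0, 12.0, 25.0]))[0]
        w = p.blemish_intensity
        img[blem] = (1 - w) * img[blem] + w * blem_rgb

    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    img8 = (np.clip(img, 0, 1) * 255.0 + 0.5).astype(np.uint8)

    record = {
        "sample_id": p.sample_id,
        "side": side,
        "group": p.group.name,
        "day": int(day),
        "ri10": stage,
        "ri5": int(_stage5_of(stage)),
    }
    return img8, record


# ---------------------------------------------------------------------------
# cohort assembly

def simulate_cohort(cohort_cfg: CohortConfig | None = None, rng_seed: int = 0):
    """Simulate trajectories and the daily two-sided metadata table.

    Returns ``(trajectories, records)`` where ``records`` is a DataFrame
    with columns sample_id, side, group, day, date_stamp, ri5, ri10,
    days_left5, days_left9, censored (two rows per fruit per observed day).
    Fully deterministic for a fixed seed.
    """
    cfg = cohort_cfg or CohortConfig()
    trajectories: list[FruitTrajectory] = []
    rows = []
    base_date = pd.Timestamp(cfg.start_date)
    sample_id = 0
    for gidx, gname in enumerate(sorted(cfg.group_sizes)):
        n_fruits = cfg.group_sizes[gname]
        for _ in range(n_fruits):
            sample_id += 1
            child = np.random.default_rng(np.random.SeedSequence(entropy=rng_seed,
                                                                 spawn_key=(gidx, sample_id)))
            params = sample_fruit_params(gname, child, sample_id=sample_id, cfg=cfg)
            traj = stage_timeline(params, child, cfg=cfg)
            trajectories.append(traj)
            ep = traj.endpoint_day9
            for day in range(traj.n_days):
                ri10 = int(traj.stage_by_day[day])
                dl = None if ep is None else float(max(0, ep - day))
                for side in ("front", "back"):
                    rows.append({
                        "sample_id": sample_id,
                        "side": side,
                        "group": gname,
                        "day": day,
                        "date_stamp": (base_date + pd.Timedelta(days=day)).date().isoformat(),
                        "ri5": int(_stage5_of(ri10)),
                        "ri10": ri10,
                        "days_left5": dl,
                        "days_left9": dl,
                        "censored": traj.censored,
                    })
    records = pd.DataFrame(rows, columns=["sample_id", "side", "group", "day", "date_stamp",
                                          "ri5", "ri10", "days_left5", "days_left9", "censored"])
    return trajectories, records


def render_cohort(
    trajectories: list[FruitTrajectory],
    records: pd.DataFrame,
    render_cfg: RenderConfig | None = None,
    rng_seed: int = 0,
) -> dict[tuple[int, str, int], np.ndarray]:
    """Render every record's image in memory, keyed by (sample_id, side, day)."""
    cfg = render_cfg or RenderConfig()
    by_id = {t.params.sample_id: t for t in trajectories}
    images: dict[tuple[int, str, int], np.ndarray] = {}
    for row in records.itertuples(index=False):
        key = (row.sample_id, row.side, row.day)
        child = np.random.default_rng(np.random.SeedSequence(
            entropy=rng_seed, spawn_key=(row.sample_id, 0 if row.side == "front" else 1, row.day)))
        img, _ = render_fruit_image(by_id[row.sample_id], row.day, row.side, cfg, child)
        images[key] = img
    return images
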