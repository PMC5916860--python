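"""Scanner-style synthetic rice-leaf images with exact ground truth.

The generator emulates the statistical structure of a hydroponic
nitrogen-response trial: four ammonium-nitrate treatments (N1 extreme
deficiency, 0 mg/L, up to N4 normal supply, 114.30 mg/L), five replicate
plants per treatment, leaves scanned every 3 days from DAT 20 to DAT 44
(9 time points) at four leaf positions (FIL = first incomplete leaf, then
the 1st-3rd fully expanded leaves).

Blade expansion follows a sigmoidal logistic law A/(1+exp(-k(t-t0))) whose
asymptote and rate increase with nitrogen supply; leaves are greener (lower
RGB) under high nitrogen; the 3rd (oldest) leaf etiolates tip-first, with
the yellow front advancing faster under low nitrogen, and is recorded
missing after its senescence day.  Plant-to-plant variability is lognormal
around treatment means; pixel noise is additive Gaussian.

The blade is a symmetric lanceolate outline with half-width profile
w/2 * sin(pi * s**0.75) along the normalized axis s in [0, 1] (s = 1 at the
tip); the exponent < 1 makes the tip taper longer than the base so tip
detection is well posed.  Length and width are solved from the target
logistic area under a fixed length:width ratio.  Ground truth (masks,
areas, perimeter, region-mean colours) is computed from the rendered mask,
not from the formulas alone, so extraction tests isolate extraction error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.integrate import quad

from .errors import MissingObservation
from .imaging import (
    FEATURE_COLUMNS,
    LEAF_POSITIONS,
    LeafImage,
    LeafMask,
    indices_from_rgb,
    measure_perimeter,
)

#: half-width profile exponent; < 1 puts the widest point toward the base
PROFILE_ALPHA = 0.75

#: fraction of the L*w bounding box covered by the blade outline
AREA_FRACTION = quad(lambda s: np.sin(np.pi * s ** PROFILE_ALPHA), 0.0, 1.0)[0]

#: colour of fully etiolated tissue (hue ~ 52 deg, scanner yellow)
YELLOW_RGB = np.array([210.0, 190.0, 60.0])

#: senescence drift of healthy 3rd-leaf tissue saturates here (stays green side)
DRIFT_CAP = np.array([130.0, 155.0, 60.0])

#: leaf-position modifiers: older leaves emerged earlier and are smaller
POSITION_T0_OFFSET = {"FIL": 0.0, "1st": -4.0, "2nd": -8.0, "3rd": -12.0}
POSITION_AREA_SCALE = {"FIL": 1.0, "1st": 0.95, "2nd": 0.90, "3rd": 0.80}
POSITION_INDEX = {p: i for i, p in enumerate(LEAF_POSITIONS)}


@dataclass(frozen=True)
class TreatmentProfile:
    """Treatment-level means of every generator parameter.

    area asymptote A (cm^2), logistic rate k (1/day) and inflection t0
    (DAT) describe FIL blade expansion; per-position offsets are applied on
    top.  front_speed is the etiolation-front advance as a fraction of leaf
    length per day on the 3rd leaf; senescence_dat is the DAT after which
    the 3rd leaf is recorded missing (None = never).
    """

    n_level: str
    n_conc: float                   # mg/L ammonium nitrate
    area_A: float                   # cm^2
    area_k: float                   # 1/day
    area_t0: float                  # DAT
    perimeter_scale: float          # multiplies the length:width ratio
    base_rgb: tuple                 # healthy leaf colour, 0-255
    rgb_drift: tuple                # per-day senescence drift of healthy tissue
    etiolation_onset: float         # DAT at which 3rd-leaf tip yellowing begins
    front_speed: float              # fraction of leaf length per day
    senescence_dat: Optional[float] = None

    def __post_init__(self):
        if self.area_A <= 0 or self.area_k <= 0:
            raise ValueError("logistic A and k must be positive")
        if not 0.0 <= self.front_speed <= 1.0:
            raise ValueError("front_speed must be in [0, 1] per day")


#: default study conditions; greener/larger/faster with more nitrogen,
#: faster tip etiolation and earlier senescence under deficiency
DEFAULT_PROFILES = {
    "N1": TreatmentProfile("N1", 0.00, area_A=12.0, area_k=0.35, area_t0=29.0,
                           perimeter_scale=1.15, base_rgb=(90, 140, 60),
                           rgb_drift=(1.0, 0.5, 0.0), etiolation_onset=14.0,
                           front_speed=0.030, senescence_dat=41.0),
    "N2": TreatmentProfile("N2", 57.20, area_A=18.0, area_k=0.42, area_t0=28.0,
                           perimeter_scale=1.05, base_rgb=(80, 133, 53),
                           rgb_drift=(0.8, 0.4, 0.0), etiolation_onset=16.0,
                           front_speed=0.022, senescence_dat=43.0),
    "N3": TreatmentProfile("N3", 85.70, area_A=22.0, area_k=0.48, area_t0=27.5,
                           perimeter_scale=1.00, base_rgb=(70, 127, 47),
                           rgb_drift=(0.6, 0.3, 0.0), etiolation_onset=18.0,
                           front_speed=0.016, senescence_dat=None),
    "N4": TreatmentProfile("N4", 114.30, area_A=26.0, area_k=0.55, area_t0=27.0,
                           perimeter_scale=0.95, base_rgb=(60, 120, 40),
                           rgb_drift=(0.5, 0.25, 0.0), etiolation_onset=19.0,
                           front_speed=0.010, senescence_dat=None),
}


def scaled_profiles(effect: float, base: dict | None = None) -> dict:
    """Profiles with the between-treatment effect shrunk toward the mean.

    ``effect=1`` returns the defaults; ``effect=0`` makes all four
    treatments identical (the across-treatment mean), giving a null
    condition for calibration experiments.  Senescence days are kept from
    the base profiles (missingness pattern is not part of the effect).
    """
    base = dict(base or DEFAULT_PROFILES)
    numeric = ["n_conc", "area_A", "area_k", "area_t0", "perimeter_scale",
               "etiolation_onset", "front_speed"]
    means = {f: np.mean([getattr(p, f) for p in base.values()]) for f in numeric}
    mean_rgbv = np.mean([p.base_rgb for p in base.values()], axis=0)
    mean_drift = np.mean([p.rgb_drift for p in base.values()], axis=0)
    out = {}
    for level, p in base.items():
        kw = {f: means[f] + effect * (getattr(p, f) - means[f]) for f in numeric}
        kw["base_rgb"] = tuple(mean_rgbv + effect * (np.asarray(p.base_rgb) - mean_rgbv))
        kw["rgb_drift"] = tuple(mean_drift + effect * (np.asarray(p.rgb_drift) - mean_drift))
        out[level] = replace(p, **kw)
    return out


@dataclass(frozen=True)
class PlantParams:
    """Realized parameters of one replicate plant after lognormal perturbation."""

    plant_id: str
    treatment: str
    area_A: float
    area_k: float
    area_t0: float
    perimeter_scale: float
    base_rgb: tuple
    rgb_drift: tuple
    etiolation_onset: float
    front_speed: float
    senescence_dat: Optional[float]
    rng_seed: int


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size) if size else 1.0
    sigma2 = np.log1p(cv ** 2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def sample_plant_parameters(
    profile: TreatmentProfile,
    seed: int,
    cv: float = 0.10,
    plant_id: str = "",
) -> PlantParams:
    """Draw one plant's parameters around the treatment profile.

    Size and rate parameters (A, k, perimeter scale, front speed) get
    lognormal multiplicative noise with the given CV; timing parameters
    (t0, etiolation onset) use CV/5 and colour channels CV/3 — replicate
    plants of one cultivar differ far more in size than in developmental
    timing or pigmentation.  cv=0 reproduces the profile exactly.
    Deterministic given (profile, seed).
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    draws = _lognormal_factor(rng, cv, size=4)
    timing = _lognormal_factor(rng, cv / 5.0, size=2)
    rgb_f = _lognormal_factor(rng, cv / 3.0, size=3)
    drift_f = _lognormal_factor(rng, cv / 3.0, size=3)
    return PlantParams(
        plant_id=plant_id or f"{profile.n_level}-plant",
        treatment=profile.n_level,
        area_A=profile.area_A * draws[0],
        area_k=profile.area_k * draws[1],
        area_t0=profile.area_t0 * timing[0],
        perimeter_scale=profile.perimeter_scale * draws[2],
        base_rgb=tuple(np.asarray(profile.base_rgb, float) * rgb_f),
        rgb_drift=tuple(np.asarray(profile.rgb_drift, float) * drift_f),
        etiolation_onset=profile.etiolation_onset * timing[1],
        front_speed=float(min(profile.front_speed * draws[3], 1.0)),
        senescence_dat=profile.senescence_dat,
        rng_seed=int(seed),
    )


@dataclass
class ExperimentConfig:
    """Cohort layout and render settings of one synthetic experiment."""

    schedule: tuple = tuple(range(20, 45, 3))     # DATs, strictly increasing
    profiles: dict = field(default_factory=lambda: dict(DEFAULT_PROFILES))
    replicates: int = 5
    years: tuple = (2014,)
    positions: tuple = LEAF_POSITIONS
    dpi: float = 300.0
    background_rgb: tuple = (245, 245, 242)
    noise_sigma: float = 2.0
    edge_blur_px: float = 1.0
    length_width_ratio: float = 12.0
    cv: float = 0.10
    master_seed: int = 0

    def __post_init__(self):
        sched = tuple(self.schedule)
        if any(b <= a for a, b in zip(sched, sched[1:])):
            raise ValueError("schedule must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        self.schedule = sched


@dataclass
class GroundTruth:
    """Exact per-observation truth computed from the rendered masks."""

    leaf_mask: np.ndarray
    etiolated_mask: np.ndarray
    tip_third_mask: np.ndarray
    la: float                      # cm^2
    lp: float                      # cm, mask-contour convention
    lp_analytic: float             # cm, polygon arc length
    ea: float                      # cm^2
    ed: float
    mean_rgb_leaf: tuple
    mean_rgb_tip: tuple


def _blade_geometry(params: PlantParams, dat: float, position: str, ratio: float):
    """Logistic target area -> (area cm^2, length cm, max width cm)."""
    t0 = params.area_t0 + POSITION_T0_OFFSET[position]
    a_max = params.area_A * POSITION_AREA_SCALE[position]
    area = a_max / (1.0 + np.exp(-params.area_k * (dat - t0)))
    width = np.sqrt(area / (AREA_FRACTION * ratio))
    return area, ratio * width, width


def _front_fraction(params: PlantParams, dat: float, position: str) -> float:
    """Etiolated fraction of axis length, measured from the tip."""
    if position != "3rd":
        return 0.0
    return float(np.clip(params.front_speed * (dat - params.etiolation_onset), 0.0, 1.0))


def _healthy_rgb(params: PlantParams, dat: float, position: str) -> np.ndarray:
    rgb = np.asarray(params.base_rgb, float)
    if position == "3rd":
        days = max(dat - params.etiolation_onset, 0.0)
        rgb = np.minimum(rgb + np.asarray(params.rgb_drift, float) * days, DRIFT_CAP)
    return rgb


def _analytic_perimeter(length: float, width: float, n: int = 2000) -> float:
    s = np.linspace(0.0, 1.0, n)
    x = s * length
    y = 0.5 * width * np.sin(np.pi * s ** PROFILE_ALPHA)
    arc = np.sqrt(np.diff(x) ** 2 + np.diff(y) ** 2).sum()
    return 2.0 * arc


def render_leaf_image(
    params: PlantParams,
    dat: int,
    position: str,
    cfg: ExperimentConfig,
    angle_deg: float = 0.0,
) -> tuple[LeafImage, GroundTruth]:
    """Rasterize one leaf at one DAT, with its exact ground truth.

    The blade axis runs base-to-tip at ``angle_deg`` from the image x axis.
    For the 3rd leaf past the etiolation onset, pixels distal to the front
    get the yellow etiolation colour; the green/yellow transition is a hard
    edge softened by a small Gaussian blur of the colour weight (the blade
    outline itself stays crisp).  Raises :class:`MissingObservation` when
    the 3rd leaf has senesced.
    """
    if position not in LEAF_POSITIONS:
        raise ValueError(f"unknown position {position!r}")
    if (
        position == "3rd"
        and params.senescence_dat is not None
        and dat > params.senescence_dat
    ):
        raise MissingObservation("senescence")

    ratio = cfg.length_width_ratio * params.perimeter_scale
    _, length_cm, width_cm = _blade_geometry(params, dat, position, ratio)
    px_per_cm = cfg.dpi / 2.54
    l_px = length_cm * px_per_cm
    w_px = width_cm * px_per_cm

    theta = np.deg2rad(angle_deg)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    margin = 8
    half_x = 0.5 * (l_px * abs(cos_t) + w_px * abs(sin_t)) + margin
    half_y = 0.5 * (l_px * abs(sin_t) + w_px * abs(cos_t)) + margin
    h, w = int(np.ceil(2 * half_y)), int(np.ceil(2 * half_x))
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0

    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - cx, yy - cy
    u = 0.5 + (dx * cos_t + dy * sin_t) / l_px          # 0 at base, 1 at tip
    v = -dx * sin_t + dy * cos_t
    inside = (u >= 0.0) & (u <= 1.0)
    half_width = 0.5 * w_px * np.sin(np.pi * np.clip(u, 0.0, 1.0) ** PROFILE_ALPHA)
    mask = inside & (np.abs(v) <= half_width)

    frac = _front_fraction(params, dat, position)
    etiolated = mask & (u > 1.0 - frac)
    tip_third = mask & (u > 2.0 / 3.0)

    weight = etiolated.astype(float)
    if cfg.edge_blur_px > 0:
        weight = ndi.gaussian_filter(weight, cfg.edge_blur_px)
    weight = np.where(mask, np.clip(weight, 0.0, 1.0), 0.0)

    healthy = _healthy_rgb(params, dat, position)
    img = np.empty((h, w, 3), float)
    img[:] = np.asarray(cfg.background_rgb, float)
    leaf_rgb = healthy[None, :] * (1.0 - weight[mask, None]) + YELLOW_RGB[None, :] * weight[mask, None]
    img[mask] = leaf_rgb

    cm2_per_px = (2.54 / cfg.dpi) ** 2
    la = mask.sum() * cm2_per_px
    ea = etiolated.sum() * cm2_per_px
    truth = GroundTruth(
        leaf_mask=mask,
        etiolated_mask=etiolated,
        tip_third_mask=tip_third,
        la=la,
        lp=measure_perimeter(LeafMask(mask), cfg.dpi),
        lp_analytic=_analytic_perimeter(length_cm, width_cm),
        ea=ea,
        ed=ea / la if la > 0 else 0.0,
        mean_rgb_leaf=tuple(img[mask].mean(axis=0)) if mask.any() else (np.nan,) * 3,
        mean_rgb_tip=tuple(img[tip_third].mean(axis=0)) if tip_third.any() else (np.nan,) * 3,
    )

    if cfg.noise_sigma > 0:
        rng = np.random.default_rng(
            [params.rng_seed & 0x7FFFFFFF, int(dat), POSITION_INDEX[position], 97]
        )
        img = img + rng.normal(0.0, cfg.noise_sigma, img.shape)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)

    leaf_image = LeafImage(
        pixels=pixels,
        dpi=cfg.dpi,
        plant_id=params.plant_id,
        treatment=params.treatment,
        dat=int(dat),
        leaf_position=position,
    )
    return leaf_image, truth


# ---------------------------------------------------------------------------
# whole-experiment generation
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = [
    "plant_id", "treatment", "year", "dat", "leaf_position", "missing", "reason",
    "la", "lp", "lp_analytic", "ea", "ed",
    "r_leaf", "g_leaf", "b_leaf", "r_tip", "g_tip", "b_tip",
]


@dataclass
class SyntheticExperiment:
    """In-memory result of :func:`generate_experiment`."""

    config: ExperimentConfig
    plants: list
    images: list                  # LeafImage (empty when written to disk)
    truth_table: pd.DataFrame
    metadata: pd.DataFrame


def _plant_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def iter_plants(cfg: ExperimentConfig):
    """Deterministic plant roster: (year, treatment level, replicate) order."""
    idx = 0
    for year in cfg.years:
        for level, profile in cfg.profiles.items():
            for rep in range(1, cfg.replicates + 1):
                plant_id = f"{year}-{level}-r{rep}"
                yield sample_plant_parameters(
                    profile, _plant_seed(cfg.master_seed, idx), cv=cfg.cv,
                    plant_id=plant_id,
                ), year
                idx += 1


def generate_experiment(
    cfg: ExperimentConfig, out_dir: str | Path | None = None
) -> SyntheticExperiment:
    """Render the full cohort: one image (or missing record) per
    plant x DAT x position.

    With ``out_dir`` set, images are written as 8-bit PNGs plus a sidecar
    metadata CSV and the ground-truth CSV (layout:
    ``out_dir/images/<plant>_d<dat>_<position>.png``, ``out_dir/meta.csv``,
    ``out_dir/truth.csv``) and are not kept in memory.
    """
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        (out_path / "images").mkdir(parents=True, exist_ok=True)

    plants, images, truth_rows, meta_rows = [], [], [], []
    for params, year in iter_plants(cfg):
        plants.append(params)
        for dat in cfg.schedule:
            for position in cfg.positions:
                base = {
                    "plant_id": params.plant_id, "treatment": params.treatment,
                    "year": year, "dat": dat, "leaf_position": position,
                }
                try:
                    img, truth = render_leaf_image(params, dat, position, cfg)
                except MissingObservation as miss:
                    truth_rows.append({**base, "missing": True, "reason": miss.reason})
                    continue
                img.year = year
                truth_rows.append({
                    **base, "missing": False, "reason": "",
                    "la": truth.la, "lp": truth.lp, "lp_analytic": truth.lp_analytic,
                    "ea": truth.ea, "ed": truth.ed,
                    "r_leaf": truth.mean_rgb_leaf[0], "g_leaf": truth.mean_rgb_leaf[1],
                    "b_leaf": truth.mean_rgb_leaf[2],
                    "r_tip": truth.mean_rgb_tip[0], "g_tip": truth.mean_rgb_tip[1],
                    "b_tip": truth.mean_rgb_tip[2],
                })
                name = f"{params.plant_id}_d{dat}_{position}.png"
                meta_rows.append({
                    "image_path": f"images/{name}", "plant_id": params.plant_id,
                    "treatment": params.treatment, "year": year, "dat": dat,
                    "leaf_position": position, "dpi": cfg.dpi,
                })
                if out_path is not None:
                    from PIL import Image

                    Image.fromarray(img.pixels).save(out_path / "images" / name)
                else:
                    images.append(img)

    truth = pd.DataFrame(truth_rows)
    for col in TRUTH_COLUMNS:
        if col not in truth.columns:
            truth[col] = np.nan
    truth = truth[TRUTH_COLUMNS]
    meta = pd.DataFrame(meta_rows)
    if out_path is not None:
        truth.to_csv(out_path / "truth.csv", index=False, float_format="%.10g")
        meta.to_csv(out_path / "meta.csv", index=False, float_format="%.10g")
    return SyntheticExperiment(cfg, plants, images, truth, meta)


# ---------------------------------------------------------------------------
# analytic fast path (no rasterization)
# ---------------------------------------------------------------------------

_S_GRID = np.linspace(0.0, 1.0, 4001)
_CUM = np.concatenate(
    [[0.0], np.cumsum(np.diff(_S_GRID) *
                      0.5 * (np.sin(np.pi * _S_GRID[:-1] ** PROFILE_ALPHA)
                             + np.sin(np.pi * _S_GRID[1:] ** PROFILE_ALPHA)))]
)
_CUM /= _CUM[-1]


def _tail_area_fraction(q: float) -> float:
    """Fraction of blade area with axis coordinate s > q."""
    return float(1.0 - np.interp(q, _S_GRID, _CUM))


def simulate_features(cfg: ExperimentConfig) -> pd.DataFrame:
    """Per-observation feature table computed from the parametric model.

    Skips rasterization entirely: LA, LP, EA, ED come from the blade
    geometry in closed/quadrature form and region-mean colours from the
    piecewise colour model.  Useful for power analyses and calibration
    studies where rendering every image would dominate the runtime; the
    rendered path remains the reference for extraction tests.
    """
    rows = []
    for params, year in iter_plants(cfg):
        ratio = cfg.length_width_ratio * params.perimeter_scale
        for dat in cfg.schedule:
            for position in cfg.positions:
                if (
                    position == "3rd"
                    and params.senescence_dat is not None
                    and dat > params.senescence_dat
                ):
                    continue
                area, length_cm, width_cm = _blade_geometry(params, dat, position, ratio)
                lp = _analytic_perimeter(length_cm, width_cm, n=600)
                frac = _front_fraction(params, dat, position)
                ea = ed = None
                if position == "3rd":
                    ea = area * _tail_area_fraction(1.0 - frac)
                    ed = ea / area
                healthy = _healthy_rgb(params, dat, position)
                if position == "FIL":
                    yellow_share = _tail_area_fraction(1.0 - frac)  # 0: FIL never etiolates
                    region_tag = "whole_leaf"
                else:
                    tip_area = _tail_area_fraction(2.0 / 3.0)
                    yellow_share = _tail_area_fraction(max(2.0 / 3.0, 1.0 - frac)) / tip_area
                    region_tag = "tip_third"
                rgb = healthy * (1.0 - yellow_share) + YELLOW_RGB * yellow_share
                idx = indices_from_rgb(*rgb)
                rows.append({
                    "plant_id": params.plant_id, "treatment": params.treatment,
                    "year": year, "dat": dat, "leaf_position": position,
                    "LA": area, "LP": lp, "EA": ea, "ED": ed,
                    "G": idx["G"], "NRI": idx["NRI"], "NGI": idx["NGI"],
                    "NBI": idx["NBI"], "ExR": idx["ExR"], "ExG": idx["ExG"],
                    "DGCI": idx["DGCI"], "hue": idx["hue"],
                    "saturation": idx["saturation"], "brightness": idx["brightness"],
                    "region_tag": region_tag, "qc_flags": idx["qc"],
                })
    df = pd.DataFrame(rows)
    return df[FEATURE_COLUMNS]
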