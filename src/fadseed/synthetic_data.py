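"""Synthetic inputs with ground truth for the whole pipeline.

Generates every input the analyses consume: seed photographs with exact
truth masks, plant populations whose mean seed spot cover rises linearly
with total flower count, germination tables with category-dependent rate
and spread, and ant-assay removal logs (paired trials and checkerboard
grids) with a tunable preference for one seed category.

Every generator is a pure function of its parameter object, including the
RNG seed: identical parameters give bit-identical output.  Category labels
in generated tables are explicit ground truth; downstream quantile
classification never defines them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.special import expit, logit

from fadseed.ant_preference import GridAssay
from fadseed.phenotype import plant_fitness
from fadseed.seed_imaging import MaskSet, SeedImage


# --------------------------------------------------------------------------
# parameter objects
# --------------------------------------------------------------------------

@dataclass
class ImageGenParams:
    """Rendering parameters for one synthetic seed photograph.

    The seed is an ellipse (semi-axes ``axes``, rotated by
    ``orientation_deg``) centred in the image, with mottled dark spots and
    a pale, yellow-shifted elaiosome disk at one pole.  Spot texture comes
    from Gaussian-smoothed noise thresholded at the exact quantile that
    hits ``target_cover``, so the truth masks are exact.

    target_cover is the spot-area fraction of the seed body, in [0, 0.5]
    (covers above half the coat do not occur in this system).
    spot_granularity is the characteristic blob diameter in pixels.
    """

    size: tuple[int, int] = (256, 256)
    axes: tuple[float, float] = (80.0, 55.0)  # semi-axes, px
    orientation_deg: float = 0.0
    background_shade: int = 205
    seed_rgb: tuple[int, int, int] = (140, 110, 85)
    spot_rgb: tuple[int, int, int] = (60, 40, 30)
    elaiosome_rgb: tuple[int, int, int] = (235, 225, 150)
    target_cover: float = 0.30
    spot_granularity: float = 9.0
    elaiosome_area: int = 1100
    elaiosome_angle_deg: float = 0.0  # pole position relative to major axis
    noise_sd: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_cover <= 0.5:
            raise ValueError("target_cover must lie in [0, 0.5]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        _check_ellipse_fits(self)


def _check_ellipse_fits(p: ImageGenParams) -> None:
    """Reject seed + elaiosome geometry that would clip the image border."""
    a, b = p.axes
    h, w = p.size
    r_ela = math.sqrt(p.elaiosome_area / math.pi)
    reach = max(a, b) + 2.0 * r_ela + 3.0
    if reach > min(h, w) / 2.0:
        raise ValueError(
            f"ellipse (semi-axes {p.axes}) plus elaiosome does not fit a "
            f"{p.size} image"
        )


@dataclass
class PopulationGenParams:
    """Plant population in which mean seed spot cover tracks fitness.

    The fitness proxy is the total flower count excluding the top whorl.
    Expected mean cover of a plant is ``intercept + slope * total_flowers``
    (percent); per-plant deviations have s.d. ``plant_noise_sd`` and
    individual seeds scatter around the plant mean with
    ``seed_noise_sd``.  One seed row is produced per whorl per plant.
    """

    n_plants: int = 30
    whorls_range: tuple[int, int] = (12, 20)  # inclusive bounds
    flowers_per_whorl_mean: float = 8.0  # Poisson mean
    slope: float = 0.078  # percent cover per flower
    intercept: float = 18.0  # percent
    plant_noise_sd: float = 3.2
    seed_noise_sd: float = 6.0
    elaiosome_base: float = 900.0  # px
    elaiosome_per_flower: float = 2.0  # px per flower, positive association
    elaiosome_sd: float = 60.0
    seed_area_mean: float = 14000.0  # px
    seed_area_sd: float = 1200.0
    light_regime: str = "low"
    seed: int = 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.slope):
            raise ValueError("slope must be finite")
        if self.whorls_range[0] < 1:
            raise ValueError("plants need at least one whorl")


@dataclass
class AssayGenParams:
    """Parameters for the germination and ant-preference generators.

    Paired trials: ``n_trials`` choices with probability
    ``p_unspotted_removed`` that the unspotted seed of the pair is taken,
    spread over ``n_sessions`` sessions whose logit-scale effects have
    s.d. ``session_sd``.

    Grid: an even-sided checkerboard; at each step the next removal is
    drawn from the remaining unspotted seeds with probability
    ``grid_preference`` (from the remaining spotted otherwise), falling
    back to the non-empty category once one is exhausted.

    Germination: per-category germination probability and day-of-event
    distribution (normal location/spread, rounded to whole days, censored
    at ``horizon_days``).
    """

    # paired trials
    n_trials: int = 212
    p_unspotted_removed: float = 129 / 212
    n_sessions: int = 3
    session_sd: float = 0.3
    # grid
    grid_side: int = 8
    grid_preference: float = 0.75
    # germination
    n_seeds_per_category: int = 108
    germ_p: dict[str, float] = field(
        default_factory=lambda: {"unspotted": 0.74, "spotted": 0.898}
    )
    germ_time_mean: dict[str, float] = field(
        default_factory=lambda: {"unspotted": 9.0, "spotted": 7.0}
    )
    germ_time_sd: dict[str, float] = field(
        default_factory=lambda: {"unspotted": 4.0, "spotted": 1.8}
    )
    horizon_days: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [self.p_unspotted_removed, self.grid_preference, *self.germ_p.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.grid_side % 2 != 0:
            raise ValueError("grid side must be even for a balanced checkerboard")


# --------------------------------------------------------------------------
# seed images
# --------------------------------------------------------------------------

def _ellipse_mask(p: ImageGenParams) -> np.ndarray:
    h, w = p.size
    a, b = p.axes
    theta = math.radians(p.orientation_deg)
    rr, cc = np.mgrid[0:h, 0:w]
    dr, dc = rr - h / 2.0, cc - w / 2.0
    # rotate into the ellipse frame: u along the major axis
    u = dc * math.cos(theta) + dr * math.sin(theta)
    v = -dc * math.sin(theta) + dr * math.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_seed_image(params: ImageGenParams) -> tuple[np.ndarray, MaskSet]:
    """Render one seed photograph and its exact truth masks.

    Returns the ``(H, W, 3)`` uint8 raster and a :class:`MaskSet` whose
    spot mask is a subset of the seed body, whose elaiosome is disjoint
    from it, and whose spot area matches ``target_cover`` to within one
    percentage point (the spot threshold is the empirical quantile of the
    smoothed noise field over the body, so the match is exact up to pixel
    rounding).
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.size

    seed_mask = _ellipse_mask(params)
    n_seed = int(seed_mask.sum())

    # mottled spots: smoothed noise field, thresholded at the target quantile
    if params.target_cover > 0:
        field_ = ndi.gaussian_filter(
            rng.standard_normal(params.size), sigma=params.spot_granularity / 2.0
        )
        thr = np.quantile(field_[seed_mask], params.target_cover)
        spot_mask = seed_mask & (field_ <= thr)
    else:
        rng.standard_normal(params.size)  # keep the RNG stream aligned
        spot_mask = np.zeros_like(seed_mask)

    # elaiosome: disk just outside the pole of the major axis
    r_ela = math.sqrt(params.elaiosome_area / math.pi)
    phi = math.radians(params.orientation_deg + params.elaiosome_angle_deg)
    dist = params.axes[0] + 0.8 * r_ela
    cr = h / 2.0 + dist * math.sin(phi)
    cc_ = w / 2.0 + dist * math.cos(phi)
    rr, cc = np.mgrid[0:h, 0:w]
    ela_mask = ((rr - cr) ** 2 + (cc - cc_) ** 2 <= r_ela**2) & ~seed_mask

    img = np.full((h, w, 3), params.background_shade, dtype=np.float64)
    img[seed_mask] = params.seed_rgb
    img[spot_mask] = params.spot_rgb
    img[ela_mask] = params.elaiosome_rgb
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    masks = MaskSet(seed=seed_mask, spot=spot_mask, elaiosome=ela_mask)
    actual = masks.spot.sum() / n_seed
    assert abs(actual - params.target_cover) <= 0.01, "spot-cover calibration drifted"
    return img, masks


# --------------------------------------------------------------------------
# plant population
# --------------------------------------------------------------------------

def generate_population(
    params: PopulationGenParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate plants and one sampled seed per flowering whorl.

    Returns ``(plants, seeds)`` tables.  ``plants`` carries the flower
    counts per whorl (space-separated, base to top), the fitness proxy
    (total flowers excluding the top whorl) and the expected mean cover on
    the generating line; ``seeds`` carries one row per whorl per plant with
    true spot cover (clipped to [0, 100]), seed area and elaiosome area.
    """
    if params.n_plants < 2:
        raise ValueError("need at least 2 plants")
    lo, hi = params.whorls_range
    if lo < 1:
        raise ValueError("plants need at least one whorl")
    rng = np.random.default_rng(params.seed)

    plant_rows, seed_rows = [], []
    for i in range(params.n_plants):
        plant_id = f"plant_{i:03d}"
        n_whorls = int(rng.integers(lo, hi + 1))
        whorl_flowers = rng.poisson(params.flowers_per_whorl_mean, size=n_whorls)
        total = plant_fitness(list(whorl_flowers))
        mean_cover = (
            params.intercept
            + params.slope * total
            + rng.normal(0.0, params.plant_noise_sd)
        )
        for j in range(n_whorls):
            cover = np.clip(
                mean_cover + rng.normal(0.0, params.seed_noise_sd), 0.0, 100.0
            )
            seed_rows.append(
                {
                    "seed_id": f"{plant_id}_w{j:02d}",
                    "plant_id": plant_id,
                    "whorl_index": j,
                    "seed_area_px": max(
                        1.0,
                        rng.normal(params.seed_area_mean, params.seed_area_sd),
                    ),
                    "spot_cover_pct": float(cover),
                    "elaiosome_area_px": max(
                        0.0,
                        params.elaiosome_base
                        + params.elaiosome_per_flower * total
                        + rng.normal(0.0, params.elaiosome_sd),
                    ),
                    "category": "unassigned",
                }
            )
        plant_rows.append(
            {
                "plant_id": plant_id,
                "light_regime": params.light_regime,
                "flowers_per_whorl": " ".join(str(int(f)) for f in whorl_flowers),
                "n_whorls": n_whorls,
                "total_flowers": total,
                "true_mean_cover": float(mean_cover),
            }
        )
    return pd.DataFrame(plant_rows), pd.DataFrame(seed_rows)


# --------------------------------------------------------------------------
# germination
# --------------------------------------------------------------------------

def generate_germination(params: AssayGenParams) -> pd.DataFrame:
    """Simulate per-seed germination outcomes for each category.

    Germination is Bernoulli with the category's probability; event days
    are normal (location/spread per category), rounded to whole days and
    clipped to at least day 1.  Seeds that do not germinate — or whose
    drawn day falls beyond the horizon — are right-censored at
    ``horizon_days``.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    for cat, p in params.germ_p.items():
        mu = params.germ_time_mean[cat]
        sd = params.germ_time_sd[cat]
        for i in range(params.n_seeds_per_category):
            germinates = rng.random() < p
            day = max(1.0, float(np.round(rng.normal(mu, sd))))
            if germinates and day <= params.horizon_days:
                rows.append(
                    {
                        "seed_id": f"{cat}_{i:04d}",
                        "category": cat,
                        "day": day,
                        "germinated": True,
                    }
                )
            else:
                rows.append(
                    {
                        "seed_id": f"{cat}_{i:04d}",
                        "category": cat,
                        "day": params.horizon_days,
                        "germinated": False,
                    }
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# ant assays
# --------------------------------------------------------------------------

def generate_trials(params: AssayGenParams) -> pd.DataFrame:
    """Simulate a paired-choice removal log.

    Each trial presents one unspotted and one spotted seed; exactly one is
    removed.  The per-session removal probability for the unspotted seed is
    the base probability shifted on the logit scale by a session effect
    with s.d. ``session_sd`` (degenerate base probabilities 0 and 1 are
    kept deterministic).
    """
    if params.n_trials < 1:
        raise ValueError("need at least one trial")
    rng = np.random.default_rng(params.seed)
    base = params.p_unspotted_removed
    per_session = np.array_split(np.arange(params.n_trials), params.n_sessions)
    rows = []
    for s, trial_ids in enumerate(per_session):
        if base in (0.0, 1.0) or params.session_sd == 0.0:
            p_s = base
            rng.normal()  # keep the RNG stream aligned across settings
        else:
            p_s = float(expit(logit(base) + rng.normal(0.0, params.session_sd)))
        for t in trial_ids:
            removed = "unspotted" if rng.random() < p_s else "spotted"
            rows.append(
                {
                    "trial_id": int(t),
                    "session": f"day_{s + 1}",
                    "time": int(t),
                    "removed_category": removed,
                }
            )
    return pd.DataFrame(rows)


def checkerboard_layout(side: int) -> pd.DataFrame:
    """Balanced two-coloring of a ``side x side`` grid (side must be even)."""
    if side % 2 != 0:
        raise ValueError("grid side must be even for a balanced checkerboard")
    rows = [
        {
            "row": r,
            "col": c,
            "category": "unspotted" if (r + c) % 2 == 0 else "spotted",
        }
        for r in range(side)
        for c in range(side)
    ]
    return pd.DataFrame(rows)


def generate_grid(params: AssayGenParams) -> GridAssay:
    """Simulate the removal order of a checkerboard grid assay.

    At every step the next seed is taken uniformly from the remaining
    unspotted seeds with probability ``grid_preference`` and from the
    remaining spotted seeds otherwise; an exhausted category forfeits its
    draws.  The log is a permutation of all occupied cells.
    """
    layout = checkerboard_layout(params.grid_side)
    rng = np.random.default_rng(params.seed)
    remaining = {
        "unspotted": list(
            layout[layout.category == "unspotted"][["row", "col"]].itertuples(
                index=False, name=None
            )
        ),
        "spotted": list(
            layout[layout.category == "spotted"][["row", "col"]].itertuples(
                index=False, name=None
            )
        ),
    }
    events = []
    k = 0
    while remaining["unspotted"] or remaining["spotted"]:
        if not remaining["spotted"]:
            cat = "unspotted"
        elif not remaining["unspotted"]:
            cat = "spotted"
        else:
            cat = "unspotted" if rng.random() < params.grid_preference else "spotted"
        cells = remaining[cat]
        r, c = cells.pop(int(rng.integers(len(cells))))
        k += 1
        events.append(
            {"event_index": k, "time": float(k), "row": r, "col": c, "category": cat}
        )
    return GridAssay(layout=layout, events=pd.DataFrame(events))
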