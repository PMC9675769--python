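"""Synthetic camera-trap communities with known diel ground truth.

Emulates multi-site tropical camera-trap surveys: each site is a
protected area at a given latitude running ~60-90 cameras for ~30
consecutive days; each species carries a body mass, a diet-derived
trophic guild, and a diel activity mixture on the sun-anchored circle
built from von Mises components (nocturnal centred at 0 == 2*pi,
diurnal at pi, crepuscular split between pi/2 and 3*pi/2).

The nocturnal mixture weight is a logistic function of log10 body mass
(kg) with guild-specific intercept and slope — the structure the diel
multinomial model estimates — so parameter recovery can be checked
against exact truth. Detections are emitted as clustered photo bursts
(exponential 2-min gaps within a visit) so the >1 h independence filter
has real work to do, and visit times are drawn on the sun-anchored
circle then inverted through the solar transform, which guarantees
round-trip consistency with the solar module.

``simulate_interaction`` generates paired predator/prey hourly count
tables with a tunable log-linear coupling coefficient for validating
the Poisson GLMM stage, and ``simulate_diel_categories`` draws
event-level diel categories directly from the ground-truth multinomial
(with Gaussian area intercepts) for clean recovery studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from . import solar

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_community",
    "simulate_detections",
    "simulate_interaction",
    "simulate_diel_categories",
]

GUILDS = ("carnivore", "herbivore", "insectivore", "omnivore")


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SyntheticConfig:
    """Study-design and ground-truth parameters for the generator.

    Defaults describe a downscale-faithful tropical survey: 8 protected
    areas within +/-20 deg latitude, 60 cameras per area for 30 days,
    a 20-species community spanning 75 g to 300 kg. Guild-specific
    nocturnality slopes are per decade of body mass (kg) on the logit
    scale, with signs as found for tropical mammals (herbivores and
    insectivores more nocturnal when large, carnivores and omnivores
    less so).
    """

    n_sites: int = 8
    site_latitudes: Optional[list[float]] = None      # default: spread in [-20, 20]
    site_longitudes: Optional[list[float]] = None     # default: spread in [-70, 30]
    n_cameras_per_site: int = 60
    deployment_days: int = 30
    n_species: int = 20
    mass_range_g: tuple[float, float] = (80.0, 300_000.0)
    guild_proportions: dict = field(
        default_factory=lambda: {"carnivore": 0.15, "herbivore": 0.45, "insectivore": 0.15, "omnivore": 0.25}
    )
    nocturnality_intercept_per_guild: dict = field(
        default_factory=lambda: {g: 0.0 for g in GUILDS}
    )
    nocturnality_slope_per_guild: dict = field(
        default_factory=lambda: {"carnivore": -1.2, "herbivore": 1.0, "insectivore": 0.8, "omnivore": -0.5}
    )
    crepuscular_share: float = 0.15
    kappa_activity: float = 3.0
    kappa_crepuscular: float = 8.0
    coupling_beta: float = 0.2
    photos_per_visit_mean: float = 3.0
    burst_gap_minutes: float = 2.0
    base_visit_rate: float = 0.02      # expected visits per camera-day per species
    species_rate_sd: float = 0.5       # lognormal heterogeneity of species detection rates
    start_date: str = "2019-03-01"
    seed: int = 0

    def __post_init__(self) -> None:
        props = self.guild_proportions
        if set(props) - set(GUILDS):
            raise ValueError(f"unknown guilds in proportions: {set(props) - set(GUILDS)}")
        total = sum(props.values())
        if abs(total - 1.0) > 1e-8 or min(props.values()) < 0:
            raise ValueError(f"guild_proportions must be a simplex (sum={total})")
        if self.mass_range_g[0] < 75.0:
            raise ValueError("mass_range_g lower bound must be >= 75 g (analysis threshold)")
        if self.deployment_days < 1:
            raise ValueError("deployment_days must be >= 1")
        if self.site_latitudes is None:
            self.site_latitudes = list(np.linspace(-20.0, 20.0, self.n_sites))
        if self.site_longitudes is None:
            self.site_longitudes = list(np.linspace(-70.0, 30.0, self.n_sites))
        if len(self.site_latitudes) != self.n_sites or len(self.site_longitudes) != self.n_sites:
            raise ValueError("site coordinate lists must have length n_sites")
        if max(abs(l) for l in self.site_latitudes) > 30.0:
            raise ValueError("site latitudes must lie within the tropics band [-30, 30]")
        if not 0.0 <= self.crepuscular_share < 1.0:
            raise ValueError("crepuscular_share must be in [0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def site_ids(self) -> list[str]:
        return [f"PA{i + 1:02d}" for i in range(self.n_sites)]


@dataclass
class GroundTruth:
    """Exact generating parameters: per-species mixture weights and guild curves."""

    species: pd.DataFrame          # species, guild, body_mass_g, log10_mass_kg, w_nocturnal, w_diurnal, w_crepuscular
    guild_intercepts: dict
    guild_slopes: dict
    crepuscular_share: float
    kappa_activity: float
    kappa_crepuscular: float
    coupling_beta: float

    def nocturnal_weight(self, guild: str, log10_mass_kg: float, area_intercept: float = 0.0) -> float:
        return float(
            _invlogit(self.guild_intercepts[guild] + self.guild_slopes[guild] * log10_mass_kg + area_intercept)
        )

    def to_json(self, path) -> None:
        payload = {
            "guild_intercepts": self.guild_intercepts,
            "guild_slopes": self.guild_slopes,
            "crepuscular_share": self.crepuscular_share,
            "kappa_activity": self.kappa_activity,
            "kappa_crepuscular": self.kappa_crepuscular,
            "coupling_beta": self.coupling_beta,
            "species": self.species.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _diet_for_guild(guild: str, rng: np.random.Generator) -> tuple[float, float, float, float]:
    """Diet fractions (vertebrate, plant, invertebrate, other) consistent with a guild.

    Specialist guilds put >= 0.80 on their defining component; omnivores
    are drawn with every component below 0.80 (rejection-free by
    construction: dominant component capped at 0.75).
    """
    if guild == "omnivore":
        w = rng.dirichlet(np.ones(4))
        w = 0.75 * w / w.max() if w.max() >= 0.75 else w  # cap below the 0.80 threshold
        w = w / w.sum()
        return tuple(float(v) for v in w)
    main = float(rng.uniform(0.80, 0.97))
    rest = rng.dirichlet(np.ones(3)) * (1.0 - main)
    if guild == "carnivore":
        return main, float(rest[0]), float(rest[1]), float(rest[2])
    if guild == "herbivore":
        return float(rest[0]), main, float(rest[1]), float(rest[2])
    return float(rest[0]), float(rest[1]), main, float(rest[2])


def generate_community(
    config: SyntheticConfig, rng: np.random.Generator | None = None, include_filtered_decoys: bool = True
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a species community: traits table plus exact ground truth.

    Masses are log-uniform on ``mass_range_g``; guilds follow the
    configured proportions (at least one species per positive-weight
    guild is enforced by multinomial sampling at n_species draws); diet
    fractions are generated to map back to the intended guild under the
    >=80% rules. With ``include_filtered_decoys`` two out-of-scope
    species (an arboreal monkey analogue and a sub-75 g rodent) are
    appended so the species filter is exercised end-to-end; they carry
    no activity ground truth and ``w_nocturnal`` is NaN for them.
    """
    rng = config.rng() if rng is None else rng
    n = config.n_species
    guild_names = [g for g in GUILDS if config.guild_proportions.get(g, 0.0) > 0]
    probs = np.array([config.guild_proportions[g] for g in guild_names])
    guilds = rng.choice(guild_names, size=n, p=probs / probs.sum())
    lo, hi = config.mass_range_g
    masses = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    rate_mult = np.exp(rng.normal(0.0, config.species_rate_sd, size=n))

    rows, truth_rows = [], []
    for i in range(n):
        g = str(guilds[i])
        mass = float(masses[i])
        dv, dp, di, do = _diet_for_guild(g, rng)
        x = np.log10(mass / 1000.0)
        w_n = _invlogit(
            config.nocturnality_intercept_per_guild[g] + config.nocturnality_slope_per_guild[g] * x
        )
        w_c = config.crepuscular_share * (1.0 - w_n)
        w_d = (1.0 - config.crepuscular_share) * (1.0 - w_n)
        sp = f"species_{i + 1:03d}"
        rows.append(
            {
                "species": sp,
                "body_mass_g": mass,
                "diet_vertebrate": dv,
                "diet_plant": dp,
                "diet_invertebrate": di,
                "diet_other": do,
                "stratum": "ground" if rng.uniform() < 0.7 else "scansorial",
                "rate_multiplier": float(rate_mult[i]),
            }
        )
        truth_rows.append(
            {
                "species": sp,
                "guild": g,
                "body_mass_g": mass,
                "log10_mass_kg": float(x),
                "w_nocturnal": float(w_n),
                "w_diurnal": float(w_d),
                "w_crepuscular": float(w_c),
            }
        )
    if include_filtered_decoys:
        rows.append(
            {
                "species": "decoy_arboreal",
                "body_mass_g": 2000.0,
                "diet_vertebrate": 0.05,
                "diet_plant": 0.85,
                "diet_invertebrate": 0.05,
                "diet_other": 0.05,
                "stratum": "arboreal",
                "rate_multiplier": 1.0,
            }
        )
        rows.append(
            {
                "species": "decoy_tiny",
                "body_mass_g": 50.0,
                "diet_vertebrate": 0.0,
                "diet_plant": 0.3,
                "diet_invertebrate": 0.65,
                "diet_other": 0.05,
                "stratum": "ground",
                "rate_multiplier": 1.0,
            }
        )
        for d in rows[-2:]:
            truth_rows.append(
                {
                    "species": d["species"],
                    "guild": "omnivore" if d["species"] == "decoy_tiny" else "herbivore",
                    "body_mass_g": d["body_mass_g"],
                    "log10_mass_kg": float(np.log10(d["body_mass_g"] / 1000.0)),
                    "w_nocturnal": np.nan,
                    "w_diurnal": np.nan,
                    "w_crepuscular": np.nan,
                }
            )
    traits = pd.DataFrame(rows)
    truth = GroundTruth(
        species=pd.DataFrame(truth_rows),
        guild_intercepts=dict(config.nocturnality_intercept_per_guild),
        guild_slopes=dict(config.nocturnality_slope_per_guild),
        crepuscular_share=config.crepuscular_share,
        kappa_activity=config.kappa_activity,
        kappa_crepuscular=config.kappa_crepuscular,
        coupling_beta=config.coupling_beta,
    )
    return traits, truth


def _sample_sun_times(weights: np.ndarray, config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw sun-anchored activity times from a species' three-component mixture."""
    n = weights.shape[0]
    u = rng.uniform(size=n)
    comp = np.where(u < weights[:, 0], 0, np.where(u < weights[:, 0] + weights[:, 1], 1, 2))
    theta = np.empty(n)
    noct = comp == 0
    diur = comp == 1
    crep = comp == 2
    theta[noct] = rng.vonmises(0.0, config.kappa_activity, size=int(noct.sum()))
    theta[diur] = rng.vonmises(np.pi, config.kappa_activity, size=int(diur.sum()))
    n_crep = int(crep.sum())
    centres = np.where(rng.uniform(size=n_crep) < 0.5, np.pi / 2, 3 * np.pi / 2)
    theta[crep] = centres + rng.vonmises(0.0, config.kappa_crepuscular, size=n_crep)
    return np.remainder(theta, 2 * np.pi)


def _invert_anchor_for_site(theta, day_offset, lat, lon, start: pd.Timestamp):
    """Vectorised inverse of the sun-anchoring transform for one site.

    ``day_offset`` indexes the anchor date relative to ``start``; the
    returned timestamps may spill into the previous civil date for
    pre-dawn angles, exactly as the forward transform expects.
    """
    days = np.arange(-1, int(day_offset.max()) + 2)
    ordinals = start.toordinal() + days
    tz_min = np.round(lon / 15.0) * 60.0
    _, sunrise, sunset, _ = solar._sun_minutes_vec(lat, lon, ordinals.astype(float), tz_min)
    if np.isnan(sunrise).any() or np.isnan(sunset).any():
        raise solar.PolarDayNightError(f"no sunrise/sunset at latitude {lat} for requested dates")
    idx = day_offset + 1  # position of the anchor date in `days`
    sr = sunrise[idx]
    ss = sunset[idx]
    sr_next = sunrise[idx + 1]
    minutes = np.empty_like(theta)
    day_m = (theta >= np.pi / 2) & (theta <= 1.5 * np.pi)
    night = ~day_m  # whole night arc maps onto [sunset, next sunrise)
    minutes[day_m] = sr[day_m] + (theta[day_m] - np.pi / 2) / np.pi * (ss[day_m] - sr[day_m])
    frac = np.remainder(theta[night] - 1.5 * np.pi, 2 * np.pi) / np.pi
    minutes[night] = ss[night] + frac * (sr_next[night] + 1440.0 - ss[night])
    base = pd.Timestamp(start).value  # ns at local midnight of start
    ns = base + (day_offset.astype(np.int64) * 1440 + 0) * 60_000_000_000 + (minutes * 6e10).astype(np.int64)
    return pd.to_datetime(ns)


def simulate_detections(
    traits: pd.DataFrame,
    truth: GroundTruth,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the raw detection stream and the deployment table.

    Visits per camera-day are Poisson(base_visit_rate x species rate
    multiplier); each visit draws a sun-anchored activity time from the
    species mixture, inverts it to clock time for the site and date, and
    emits a burst of 1 + Poisson(photos_per_visit_mean - 1) photos with
    exponential 2-min gaps. Anchor dates keep one buffer day inside the
    deployment window so bursts and pre-dawn spillover stay in range.
    """
    rng = config.rng() if rng is None else rng
    start = pd.Timestamp(config.start_date)
    n_days = config.deployment_days
    sp_truth = truth.species.set_index("species")
    records = []
    deployments = []
    for s_i, (site, lat, lon) in enumerate(
        zip(config.site_ids(), config.site_latitudes, config.site_longitudes)
    ):
        site_start = start + pd.Timedelta(days=7 * s_i)  # staggered surveys across areas
        cameras = [f"{site}_cam{j + 1:03d}" for j in range(config.n_cameras_per_site)]
        for cam in cameras:
            deployments.append(
                {"camera": cam, "start_date": site_start.date().isoformat(),
                 "end_date": (site_start + pd.Timedelta(days=n_days)).date().isoformat()}
            )
        usable_days = max(n_days - 2, 1)
        for sp, row in traits.set_index("species").iterrows():
            weights_row = sp_truth.loc[sp]
            if np.isnan(weights_row["w_nocturnal"]):
                # decoy species: simple uniform clock-time activity, low rate
                n_vis = rng.poisson(0.2 * config.base_visit_rate * config.n_cameras_per_site * usable_days)
                if n_vis == 0:
                    continue
                day_off = rng.integers(1, usable_days + 1, size=n_vis)
                minutes = rng.uniform(0, 1440, size=n_vis)
                ts = pd.to_datetime(
                    (site_start + pd.Timedelta(0)).value
                    + day_off * 86_400_000_000_000
                    + (minutes * 6e10).astype(np.int64)
                )
            else:
                rate = config.base_visit_rate * float(row["rate_multiplier"])
                n_vis = rng.poisson(rate * config.n_cameras_per_site * usable_days)
                if n_vis == 0:
                    continue
                day_off = rng.integers(1, usable_days + 1, size=n_vis)
                w = weights_row[["w_nocturnal", "w_diurnal", "w_crepuscular"]].to_numpy(dtype=float)
                theta = _sample_sun_times(np.broadcast_to(w, (n_vis, 3)), config, rng)
                ts = _invert_anchor_for_site(theta, day_off, lat, lon, site_start)
            cams = rng.integers(0, config.n_cameras_per_site, size=n_vis)
            n_photos = 1 + rng.poisson(max(config.photos_per_visit_mean - 1.0, 0.0), size=n_vis)
            for v in range(n_vis):
                gaps = rng.exponential(config.burst_gap_minutes, size=n_photos[v] - 1)
                offsets = np.concatenate([[0.0], np.cumsum(gaps)])
                for off in offsets:
                    records.append(
                        {
                            "protected_area": site,
                            "camera": cameras[cams[v]],
                            "latitude": lat,
                            "longitude": lon,
                            "species": sp,
                            "timestamp": ts[v] + pd.Timedelta(minutes=float(off)),
                        }
                    )
    detections = pd.DataFrame(
        records, columns=["protected_area", "camera", "latitude", "longitude", "species", "timestamp"]
    )
    detections = detections.sort_values(["protected_area", "camera", "species", "timestamp"]).reset_index(drop=True)
    return detections, pd.DataFrame(deployments)


def simulate_interaction(
    config: SyntheticConfig,
    scenario: str,
    rng: np.random.Generator | None = None,
    predator_mean: float = 3.0,
    prey_base_mean: float = 2.0,
    site_sd: float = 0.3,
) -> pd.DataFrame:
    """Paired predator/prey hourly count tables under a coupling scenario.

    Predator counts per site x anchored hour are Poisson around a smooth
    nocturnal von Mises profile (mean ``predator_mean`` per bin); prey
    counts are Poisson with log-mean alpha_site + beta * predator_count,
    where alpha_site ~ N(log(prey_base_mean), site_sd^2) and beta is
    +|coupling_beta|, -|coupling_beta| or 0 for scenarios 'bottom_up',
    'top_down' and 'independent' respectively.
    """
    scenarios = {"bottom_up": abs(config.coupling_beta), "top_down": -abs(config.coupling_beta), "independent": 0.0}
    if scenario not in scenarios:
        raise ValueError(f"scenario must be one of {sorted(scenarios)}")
    beta = scenarios[scenario]
    rng = config.rng() if rng is None else rng
    hours = np.arange(24)
    centres = (hours + 0.5) * 2 * np.pi / 24
    profile = np.exp(1.5 * np.cos(centres))  # nocturnal predator peak at anchored midnight
    profile = profile / profile.mean() * predator_mean
    rows = []
    for site in config.site_ids():
        alpha = rng.normal(np.log(prey_base_mean), site_sd)
        pred = rng.poisson(profile)
        prey = rng.poisson(np.exp(alpha + beta * pred))
        for h in hours:
            rows.append(
                {
                    "protected_area": site,
                    "anchored_hour": int(h),
                    "predictor_count": int(pred[h]),
                    "response_count": int(prey[h]),
                }
            )
    return pd.DataFrame(rows)


def simulate_diel_categories(
    truth: GroundTruth,
    n_events: int,
    n_areas: int = 8,
    area_sd: float = 0.3,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Event-level diel categories drawn from the exact generating multinomial.

    Each event picks a species and a protected area uniformly; its
    category is multinomial with nocturnal probability
    invlogit(intercept_guild + slope_guild * log10 mass + b_area),
    b_area ~ N(0, area_sd^2) on the night logit, and the remaining
    probability split (1 - crepuscular_share) : crepuscular_share
    between day and twilight. The returned frame is ready for
    :func:`dielkit.diel_model.fit_diel_model` with ``logmass`` =
    log10 body mass in kg, so fitted night slopes estimate the guild
    slopes directly.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    sp = truth.species.dropna(subset=["w_nocturnal"]).reset_index(drop=True)
    b_area = rng.normal(0.0, area_sd, size=n_areas)
    sp_idx = rng.integers(0, len(sp), size=n_events)
    ar_idx = rng.integers(0, n_areas, size=n_events)
    x = sp["log10_mass_kg"].to_numpy()[sp_idx]
    guilds = sp["guild"].to_numpy()[sp_idx]
    eta = (
        np.array([truth.guild_intercepts[g] for g in guilds])
        + np.array([truth.guild_slopes[g] for g in guilds]) * x
        + b_area[ar_idx]
    )
    w_n = _invlogit(eta)
    w_t = truth.crepuscular_share * (1.0 - w_n)
    u = rng.uniform(size=n_events)
    cat = np.where(u < w_n, "night", np.where(u < w_n + w_t, "twilight", "day"))
    return pd.DataFrame(
        {
            "protected_area": [f"PA{i + 1:02d}" for i in ar_idx],
            "species": sp["species"].to_numpy()[sp_idx],
            "guild": guilds,
            "logmass": x,
            "diel_category": cat,
        }
    )
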