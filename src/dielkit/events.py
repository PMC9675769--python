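"""From raw camera-trap detections to the analysis event set.

The analysis set keeps ground-dwelling and scansorial mammals heavier
than 75 g, collapses photo bursts into independent events (gap to the
last retained event of the same species at the same camera must exceed
1 h), annotates each event with its diel category and sun-anchored time,
and classifies species into trophic guilds (>=80% diet-fraction rules)
and body-size classes (20 kg cut; species above 580 kg are excluded from
the predator-prey coupling analysis only).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import solar

__all__ = [
    "filter_species",
    "independent_events",
    "assign_guild",
    "assign_size_class",
    "add_species_classes",
    "hourly_counts",
    "MASS_THRESHOLD_G",
    "SIZE_CUTOFF_G",
    "PREDATION_EXEMPT_MASS_G",
]

MASS_THRESHOLD_G = 75.0
SIZE_CUTOFF_G = 20_000.0
PREDATION_EXEMPT_MASS_G = 580_000.0
RETAINED_STRATA = ("ground", "scansorial")
GUILDS = ("carnivore", "herbivore", "insectivore", "omnivore")
DIET_THRESHOLD = 0.80
_DIET_SUM_TOL = 1e-6

DETECTION_COLUMNS = ["protected_area", "camera", "latitude", "longitude", "species", "timestamp"]


def filter_species(detections: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Keep detections of species heavier than 75 g that are ground-dwelling or scansorial.

    Raises ``KeyError`` listing any detected species missing from the
    trait table — a silent drop would bias every downstream count.
    """
    missing = sorted(set(detections["species"]) - set(traits["species"]))
    if missing:
        raise KeyError(f"species missing from trait table: {missing}")
    tr = traits.set_index("species")
    keep = tr.index[(tr["body_mass_g"] > MASS_THRESHOLD_G) & tr["stratum"].isin(RETAINED_STRATA)]
    return detections[detections["species"].isin(keep)].reset_index(drop=True)


def _independent_mask(ts_minutes: np.ndarray, window_minutes: float, mode: str) -> np.ndarray:
    keep = np.zeros(len(ts_minutes), dtype=bool)
    last = -np.inf
    for i, t in enumerate(ts_minutes):
        if t - last > window_minutes:
            keep[i] = True
            last = t
        elif mode == "photo":
            last = t  # gap measured to the most recent photo, retained or not
    return keep


def independent_events(
    detections: pd.DataFrame,
    window: pd.Timedelta | str = "1h",
    mode: str = "retained",
    annotate: bool = True,
) -> pd.DataFrame:
    """Collapse photo bursts into independent events (>1 h rule).

    Greedy scan per species x camera: a photo is retained iff its gap to
    the last *retained* event exceeds ``window`` (``mode="retained"``,
    the default, which guarantees all retained events are pairwise more
    than the window apart). ``mode="photo"`` instead measures the gap to
    the most recent photo of any kind. Duplicate timestamps collapse to
    one event. When ``annotate`` each event gains ``diel_category``,
    ``sun_time_rad`` and ``anchored_hour``.
    """
    if mode not in ("retained", "photo"):
        raise ValueError(f"unknown independence mode {mode!r}")
    window = pd.Timedelta(window)
    df = detections.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df = df.sort_values(["species", "camera", "timestamp"], kind="mergesort")
    df = df.drop_duplicates(subset=["species", "camera", "timestamp"]).reset_index(drop=True)

    win_min = window.total_seconds() / 60.0
    keep_parts = []
    for _, grp in df.groupby(["species", "camera"], sort=False):
        t = grp["timestamp"].astype("int64").to_numpy() / 60e9  # minutes
        keep_parts.append(grp.index[_independent_mask(t, win_min, mode)])
    kept = df.loc[np.concatenate(keep_parts) if keep_parts else []]
    kept = kept.sort_values(["protected_area", "camera", "species", "timestamp"]).reset_index(drop=True)
    if annotate:
        kept = solar.annotate_frame(kept)
    return kept


def assign_guild(row: pd.Series | dict) -> str:
    """Trophic guild from fractional diet composition.

    Carnivore if >=80% vertebrate, herbivore if >=80% plant, insectivore
    if >=80% invertebrate; everything else is an omnivore. Thresholds are
    inclusive (a plant fraction of exactly 0.80 is a herbivore).
    """
    v = float(row["diet_vertebrate"])
    p = float(row["diet_plant"])
    i = float(row["diet_invertebrate"])
    o = float(row.get("diet_other", 0.0) or 0.0)
    for frac in (v, p, i, o):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"diet fraction outside [0, 1]: {frac}")
    if v + p + i + o > 1.0 + _DIET_SUM_TOL:
        raise ValueError(f"diet fractions sum to {v + p + i + o:.4f} > 1")
    if v >= DIET_THRESHOLD:
        return "carnivore"
    if p >= DIET_THRESHOLD:
        return "herbivore"
    if i >= DIET_THRESHOLD:
        return "insectivore"
    return "omnivore"


def assign_size_class(
    row: pd.Series | dict,
    cutoff_g: float = SIZE_CUTOFF_G,
    predation_exempt_mass_g: float = PREDATION_EXEMPT_MASS_G,
) -> str:
    """Body-size class: 'small' (<=20 kg), 'large' (20-580 kg), or 'excluded'.

    'excluded' marks megaherbivore-scale species (>580 kg) that face
    negligible predation risk; the exclusion applies to the predator-prey
    coupling analysis only, not to the diel multinomial model.
    """
    mass = float(row["body_mass_g"])
    if mass <= cutoff_g:
        return "small"
    if mass <= predation_exempt_mass_g:
        return "large"
    return "excluded"


def add_species_classes(traits: pd.DataFrame) -> pd.DataFrame:
    """Return the trait table with derived ``guild`` and ``size_class`` columns."""
    out = traits.copy()
    out["guild"] = out.apply(assign_guild, axis=1)
    out["size_class"] = out.apply(assign_size_class, axis=1)
    return out


def hourly_counts(
    events: pd.DataFrame,
    species: "list[str] | pd.Index | None" = None,
    areas: "list | None" = None,
) -> pd.DataFrame:
    """Site x 24 matrix of independent-event counts on anchored-hour bins.

    Rows are protected areas, columns anchored hours 0-23 (equal arcs of
    the sun-time circle); bins without events are explicit zeros. An
    empty selection yields an all-zero matrix with a warning.
    """
    sel = events if species is None else events[events["species"].isin(species)]
    if areas is None:
        areas = sorted(events["protected_area"].unique())
    if sel.empty:
        warnings.warn("no events for the requested group; returning a zero matrix")
        return pd.DataFrame(0, index=pd.Index(areas, name="protected_area"), columns=range(24))
    mat = (
        sel.groupby(["protected_area", "anchored_hour"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(index=areas, columns=range(24), fill_value=0)
    )
    mat.index.name = "protected_area"
    return mat.astype(int)
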