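"""End-to-end orchestration: data -> events -> models -> tables.

A run is described by a flat key-value configuration (YAML). Inputs are
either CSV paths (detections, traits, deployments) or a synthetic block
forwarded to :class:`dielkit.synthetic.SyntheticConfig`. All randomness
descends from one root seed split per stage, so a rerun with the same
configuration produces byte-identical outputs; the manifest records the
seeds, the record counts surviving each filter stage, and a SHA-256 hash
of every file written.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, coupling, diel_model, events, overlap, synthetic

logger = logging.getLogger("dielkit.pipeline")

__all__ = ["load_config", "run_pipeline", "plot_activity", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "detections": None,           # CSV path; None -> synthetic
    "traits": None,
    "deployments": None,
    "synthetic": {},              # SyntheticConfig overrides
    "run_multinomial": True,
    "run_glmm": True,
    "run_overlap": True,
    "make_plots": False,
    "independence_window_hours": 1.0,
    "independence_mode": "retained",
    "overlap_n_boot": 500,
    "min_plot_events": 25,
    "seed": 0,
    "outdir": "dielkit_run",
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise KeyError(f"unknown configuration keys: {sorted(unknown)}")
    cfg = {**DEFAULT_CONFIG, **user}
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, index=False)
    manifest["outputs"][path.name] = {"sha256": _sha256(path), "rows": int(len(df))}


def _prepare_model_frame(ev: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    tr = traits.set_index("species")
    df = ev.join(tr[["guild", "body_mass_g"]], on="species")
    df["logmass"] = np.log(df["body_mass_g"])  # natural log for model fitting
    return df


def run_pipeline(config: dict, outdir: str | Path | None = None) -> dict:
    """Execute the configured stages and return the run manifest.

    Stage order mirrors the analysis: species filter -> independent
    events (with diel classification and sun anchoring) -> multinomial
    diel model / coupling GLMM suite / pairwise overlap, each optional.
    A stage failure raises with the stage name; partial outputs written
    before the failure remain on disk for inspection.
    """
    cfg = {**DEFAULT_CONFIG, **config}
    out = Path(outdir if outdir is not None else cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(int(cfg["seed"]))
    stage_seeds = {
        name: np.random.default_rng(ss)
        for name, ss in zip(["simulate", "model", "overlap"], root.spawn(3))
    }
    manifest: dict = {
        "dielkit_version": __version__,
        "seed": int(cfg["seed"]),
        "config": {k: v for k, v in cfg.items() if k != "outdir"},
        "counts": {},
        "outputs": {},
        "stages": [],
    }

    # --- input stage -------------------------------------------------
    if cfg["detections"] is None:
        syn = synthetic.SyntheticConfig(**{**cfg["synthetic"], "seed": int(cfg["seed"])})
        traits, truth = synthetic.generate_community(syn, rng=stage_seeds["simulate"])
        detections, deployments = synthetic.simulate_detections(traits, truth, syn, rng=stage_seeds["simulate"])
        truth.to_json(out / "ground_truth.json")
        manifest["outputs"]["ground_truth.json"] = {"sha256": _sha256(out / "ground_truth.json")}
        manifest["stages"].append("simulate")
    else:
        for key in ("traits",):
            if cfg[key] is None:
                raise FileNotFoundError(f"config key {key!r} required when detections are provided")
        detections = pd.read_csv(cfg["detections"], parse_dates=["timestamp"])
        traits = pd.read_csv(cfg["traits"])
        deployments = pd.read_csv(cfg["deployments"]) if cfg["deployments"] else pd.DataFrame()
    _write(detections, out / "detections.csv", manifest)
    _write(traits, out / "traits.csv", manifest)
    if len(deployments):
        _write(deployments, out / "deployments.csv", manifest)
    manifest["counts"]["detections"] = int(len(detections))

    # --- events stage ------------------------------------------------
    manifest["stages"].append("events")
    traits_cls = events.add_species_classes(traits)
    filtered = events.filter_species(detections, traits_cls)
    manifest["counts"]["after_species_filter"] = int(len(filtered))
    ev = events.independent_events(
        filtered,
        window=pd.Timedelta(hours=float(cfg["independence_window_hours"])),
        mode=cfg["independence_mode"],
    )
    manifest["counts"]["independent_events"] = int(len(ev))
    _write(traits_cls, out / "traits_classified.csv", manifest)
    _write(ev, out / "events.csv", manifest)

    # --- diel multinomial --------------------------------------------
    if cfg["run_multinomial"]:
        manifest["stages"].append("diel_model")
        frame = _prepare_model_frame(ev, traits_cls)
        fits = diel_model.fit_candidates(frame)
        ranking = diel_model.select_model(fits)
        _write(ranking.table, out / "model_ranking.csv", manifest)
        best = fits[ranking.best]
        coef = best.coef.reset_index()
        _write(coef, out / "coefficients.csv", manifest)
        grids = []
        lm_lo, lm_hi = best.logmass_range if best.logmass_range else (np.log(75), np.log(3e5))
        mass_grid = np.exp(np.linspace(lm_lo, lm_hi, 25))
        for g in sorted(frame["guild"].unique()):
            nd = pd.DataFrame({"guild": g, "body_mass_g": mass_grid, "logmass": np.log(mass_grid)})
            grids.append(diel_model.predict_probabilities(best, nd, seed=stage_seeds["model"]))
        _write(pd.concat(grids, ignore_index=True), out / "predictions.csv", manifest)
        manifest["best_model"] = ranking.best

    # --- coupling GLMM -----------------------------------------------
    if cfg["run_glmm"]:
        manifest["stages"].append("coupling")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                suite = coupling.run_pairwise_suite(ev, traits_cls)
        except coupling.FitError as e:
            # a community without large carnivores has no coupling suite to run
            logger.warning("coupling stage skipped: %s", e)
            suite = pd.DataFrame(
                columns=["response_group", "predictor_group", "n_response", "n_predictor",
                         "sites_used", "status", "beta", "ci_lo", "ci_hi", "direction"]
            )
        _write(suite, out / "coupling.csv", manifest)

    # --- pairwise overlap --------------------------------------------
    if cfg["run_overlap"]:
        manifest["stages"].append("overlap")
        _write(
            _overlap_stage(ev, traits_cls, int(cfg["overlap_n_boot"]), stage_seeds["overlap"]),
            out / "overlap.csv",
            manifest,
        )

    # --- plots -------------------------------------------------------
    if cfg["make_plots"]:
        manifest["stages"].append("plots")
        plot_dir = out / "plots"
        plot_dir.mkdir(exist_ok=True)
        for sp, grp in ev.groupby("species"):
            plot_activity(grp, str(sp), plot_dir, min_n=int(cfg["min_plot_events"]))

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest


def _overlap_stage(ev: pd.DataFrame, traits_cls: pd.DataFrame, n_boot: int, rng: np.random.Generator) -> pd.DataFrame:
    """Per-area overlap of each prey/subordinate group against the carnivore groups.

    Areas are never pooled (pooling inflates overlap); pairs with fewer
    than 25 events in either group are skipped.
    """
    grouped = coupling.group_events(ev, traits_cls)
    rows = []
    for area, sub in grouped.groupby("protected_area"):
        for pred in ("large_carnivore", "small_carnivore"):
            pred_times = sub.loc[sub["group"] == pred, "sun_time_rad"].to_numpy()
            if pred_times.size < 25:
                continue
            for resp in coupling.GROUP_LABELS:
                if resp == pred:
                    continue
                resp_times = sub.loc[sub["group"] == resp, "sun_time_rad"].to_numpy()
                if resp_times.size < 25:
                    continue
                seed = int(rng.integers(0, 2**31 - 1))
                res = overlap.compare_activity(resp_times, pred_times, n_boot=n_boot, seed=seed)
                rows.append(
                    {
                        "protected_area": area,
                        "group_a": resp,
                        "group_b": pred,
                        "n_a": res.n_a,
                        "n_b": res.n_b,
                        "dhat_type": res.dhat_type,
                        "estimate": res.estimate,
                        "ci_lo": res.ci_low,
                        "ci_hi": res.ci_high,
                        "p_null": res.p_null,
                        "seed": seed,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["protected_area", "group_a", "group_b", "n_a", "n_b",
                 "dhat_type", "estimate", "ci_lo", "ci_hi", "p_null", "seed"],
    )


def plot_activity(ev: pd.DataFrame, label: str, outdir: str | Path, min_n: int = 25) -> Path | None:
    """Circular-KDE activity profile on the sun-anchored axis, saved to file.

    Groups with fewer than ``min_n`` independent events are refused
    (returns None with a log entry): sparse samples give misleading
    density curves. File name derives deterministically from the label.
    """
    times = ev["sun_time_rad"].to_numpy()
    if times.size < min_n:
        logger.info("skipping activity plot for %s: %d events < %d", label, times.size, min_n)
        return None
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    kde = overlap.fit_circular_kde(times, n_grid=512)
    fig, ax = plt.subplots(figsize=(6, 3.2))
    ax.plot(kde.grid, kde.density, lw=1.5)
    ax.fill_between(kde.grid, 0, kde.density, alpha=0.25)
    ax.set_xticks([0, np.pi / 2, np.pi, 3 * np.pi / 2, 2 * np.pi])
    ax.set_xticklabels(["midnight", "sunrise", "noon", "sunset", "midnight"])
    ax.set_ylabel("activity density")
    ax.set_title(f"{label} (n = {times.size})")
    ax.set_xlim(0, 2 * np.pi)
    fig.tight_layout()
    safe = "".join(c if c.isalnum() or c in "-_" else "_" for c in label)
    path = Path(outdir) / f"activity_{safe}.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
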