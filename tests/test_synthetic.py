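"""Generator ground truth: determinism, guild consistency, diel structure."""

import numpy as np
import pandas as pd
import pytest

from dielkit import events, solar, synthetic


class TestConfig:
    def test_invalid_simplex_rejected(self):
        with pytest.raises(ValueError, match="simplex"):
            synthetic.SyntheticConfig(guild_proportions={"carnivore": 0.5, "herbivore": 0.2,
                                                         "insectivore": 0.1, "omnivore": 0.1})

    def test_mass_floor_enforced(self):
        with pytest.raises(ValueError, match="75"):
            synthetic.SyntheticConfig(mass_range_g=(50.0, 1000.0))

    def test_latitudes_must_be_tropical(self):
        with pytest.raises(ValueError, match="tropics"):
            synthetic.SyntheticConfig(n_sites=2, site_latitudes=[0.0, 45.0], site_longitudes=[0.0, 0.0])


class TestCommunity:
    def test_same_seed_gives_identical_community(self):
        cfg = synthetic.SyntheticConfig(seed=9)
        t1, g1 = synthetic.generate_community(cfg)
        t2, g2 = synthetic.generate_community(cfg)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(g1.species, g2.species)

    def test_masses_within_range_and_guilds_consistent(self, small_community):
        traits, truth = small_community
        core = traits[~traits["species"].str.startswith("decoy")]
        lo, hi = 80.0, 300_000.0
        assert core["body_mass_g"].between(lo, hi).all()
        # generated diets must map back to the intended guild under the >=80% rules
        derived = events.add_species_classes(core)
        merged = derived.merge(truth.species[["species", "guild"]], on="species", suffixes=("_derived", "_truth"))
        assert (merged["guild_derived"] == merged["guild_truth"]).all()

    def test_single_guild_community_feeds_on_plants(self):
        cfg = synthetic.SyntheticConfig(guild_proportions={"herbivore": 1.0}, seed=2)
        traits, truth = synthetic.generate_community(cfg, include_filtered_decoys=False)
        assert (truth.species["guild"] == "herbivore").all()
        assert (traits["diet_plant"] >= 0.80).all()

    def test_nocturnal_weight_is_monotone_in_mass_for_positive_slope(self):
        cfg = synthetic.SyntheticConfig(seed=0)
        _, truth = synthetic.generate_community(cfg)
        w_small = truth.nocturnal_weight("herbivore", np.log10(0.1))
        w_big = truth.nocturnal_weight("herbivore", np.log10(100.0))
        assert w_big > w_small

    def test_mixture_weights_sum_to_one(self, small_community):
        _, truth = small_community
        sp = truth.species.dropna(subset=["w_nocturnal"])
        total = sp[["w_nocturnal", "w_diurnal", "w_crepuscular"]].sum(axis=1)
        np.testing.assert_allclose(total, 1.0, atol=1e-12)


class TestDetections:
    def test_same_seed_gives_identical_detections(self, small_config, small_community):
        traits, truth = small_community
        d1, _ = synthetic.simulate_detections(traits, truth, small_config)
        d2, _ = synthetic.simulate_detections(traits, truth, small_config)
        pd.testing.assert_frame_equal(d1, d2)

    def test_zero_rate_gives_empty_table(self, small_community):
        traits, truth = small_community
        cfg = synthetic.SyntheticConfig(
            n_sites=3, n_cameras_per_site=15, n_species=14, base_visit_rate=0.0, seed=1
        )
        det, _ = synthetic.simulate_detections(traits, truth, cfg)
        assert det[~det["species"].str.startswith("decoy")].empty

    def test_timestamps_inside_deployment_windows(self, small_detections):
        det, dep = small_detections
        dep = dep.copy()
        dep["start"] = pd.to_datetime(dep["start_date"])
        dep["end"] = pd.to_datetime(dep["end_date"]) + pd.Timedelta(days=1)
        merged = det.merge(dep, on="camera")
        assert (merged["timestamp"] >= merged["start"]).all()
        assert (merged["timestamp"] <= merged["end"]).all()

    def test_bursts_exercise_the_independence_filter(self, small_detections, small_community):
        traits, _ = small_community
        det, _ = small_detections
        traits_cls = events.add_species_classes(traits)
        ev = events.independent_events(events.filter_species(det, traits_cls))
        assert 0 < len(ev) < len(det)

    def test_nocturnal_species_classified_night(self):
        """A species with nocturnal weight 1 and tight concentration yields >95%
        night events at equatorial sites after the full clock-time round trip."""
        cfg = synthetic.SyntheticConfig(
            n_sites=2, site_latitudes=[0.0, 2.0], site_longitudes=[10.0, 20.0],
            n_cameras_per_site=40, n_species=1, seed=6,
            guild_proportions={"herbivore": 1.0},
            nocturnality_intercept_per_guild={g: 30.0 for g in synthetic.GUILDS},
            nocturnality_slope_per_guild={g: 0.0 for g in synthetic.GUILDS},
            kappa_activity=12.0,
            base_visit_rate=0.5,
        )
        traits, truth = synthetic.generate_community(cfg, include_filtered_decoys=False)
        assert truth.species["w_nocturnal"].iloc[0] > 0.999
        det, _ = synthetic.simulate_detections(traits, truth, cfg)
        ann = solar.annotate_frame(det)
        assert (ann["diel_category"] == "night").mean() > 0.95

    def test_fixed_photo_burst_count(self, small_community):
        traits, truth = small_community
        cfg = synthetic.SyntheticConfig(
            n_sites=3, n_cameras_per_site=15, n_species=14,
            photos_per_visit_mean=1.0, base_visit_rate=0.05, seed=3,
        )
        det, _ = synthetic.simulate_detections(traits, truth, cfg)
        core = det[~det["species"].str.startswith("decoy")]
        # burst size 1 + Poisson(0): every visit emits exactly one photo, so the
        # retained-event count equals the visit count after filtering
        assert not core.duplicated(["camera", "species", "timestamp"]).any()


class TestInteraction:
    def test_independent_scenario_uncorrelated(self):
        cfg = synthetic.SyntheticConfig(n_sites=30, seed=8)
        pairs = synthetic.simulate_interaction(cfg, "independent")
        r = np.corrcoef(pairs["predictor_count"], pairs["response_count"])[0, 1]
        assert abs(r) < 0.1

    def test_scenarios_set_coupling_sign(self):
        cfg = synthetic.SyntheticConfig(n_sites=20, coupling_beta=0.3, seed=8)
        up = synthetic.simulate_interaction(cfg, "bottom_up")
        down = synthetic.simulate_interaction(cfg, "top_down")
        r_up = np.corrcoef(up["predictor_count"], up["response_count"])[0, 1]
        r_down = np.corrcoef(down["predictor_count"], down["response_count"])[0, 1]
        assert r_up > 0.15 and r_down < -0.15

    def test_structure_24_rows_per_site(self):
        cfg = synthetic.SyntheticConfig(n_sites=5, seed=8)
        pairs = synthetic.simulate_interaction(cfg, "independent")
        assert len(pairs) == 5 * 24
        assert set(pairs.groupby("protected_area").size()) == {24}

    def test_unknown_scenario_rejected(self):
        cfg = synthetic.SyntheticConfig(seed=0)
        with pytest.raises(ValueError):
            synthetic.simulate_interaction(cfg, "sideways")


class TestCategorySampler:
    def test_empirical_nocturnal_fraction_matches_truth(self):
        cfg = synthetic.SyntheticConfig(seed=21)
        _, truth = synthetic.generate_community(cfg, include_filtered_decoys=False)
        df = synthetic.simulate_diel_categories(truth, 60_000, n_areas=6, area_sd=0.0, rng=5)
        sp = truth.species.set_index("species")
        merged = df.groupby("species")["diel_category"].value_counts(normalize=True).unstack(fill_value=0)
        for s, row in merged.iterrows():
            if df["species"].value_counts()[s] > 2000:
                assert row.get("night", 0) == pytest.approx(sp.loc[s, "w_nocturnal"], abs=0.04)
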