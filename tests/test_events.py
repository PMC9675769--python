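"""Species filtering, burst collapsing, guild and size classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dielkit import events

from conftest import make_traits_row


def _detections(times, species="sp1", camera="c1"):
    return pd.DataFrame(
        {
            "protected_area": "PA01",
            "camera": camera,
            "latitude": 0.0,
            "longitude": 0.0,
            "species": species,
            "timestamp": pd.to_datetime(times),
        }
    )


class TestFilterSpecies:
    TRAITS = pd.DataFrame(
        [
            {"species": "tiny", "body_mass_g": 70.0, "stratum": "ground"},
            {"species": "edge", "body_mass_g": 75.0, "stratum": "ground"},
            {"species": "ok", "body_mass_g": 80.0, "stratum": "ground"},
            {"species": "climber", "body_mass_g": 5000.0, "stratum": "scansorial"},
            {"species": "monkey", "body_mass_g": 2000.0, "stratum": "arboreal"},
            {"species": "otter", "body_mass_g": 8000.0, "stratum": "aquatic"},
        ]
    )

    def test_mass_and_stratum_rules(self):
        det = _detections(["2021-01-01 10:00"] * 6)
        det["species"] = self.TRAITS["species"].to_list()
        kept = events.filter_species(det, self.TRAITS)
        # strictly greater than 75 g, terrestrial or scansorial only
        assert sorted(kept["species"]) == ["climber", "ok"]

    def test_missing_trait_row_is_a_hard_error(self):
        det = _detections(["2021-01-01 10:00"], species="ghost")
        with pytest.raises(KeyError, match="ghost"):
            events.filter_species(det, self.TRAITS)


class TestIndependentEvents:
    def test_gap_to_last_retained_event(self):
        """00:00, 00:30, 01:30 -> two events under the retained-gap rule
        (00:30 is absorbed; 01:30 is 1.5 h after the retained 00:00)."""
        det = _detections(["2021-01-01 00:00", "2021-01-01 00:30", "2021-01-01 01:30"])
        ev = events.independent_events(det, annotate=False)
        assert list(ev["timestamp"].dt.strftime("%H:%M")) == ["00:00", "01:30"]

    def test_gap_to_last_photo_mode(self):
        """The same burst collapses to one event when the gap is measured to the
        most recent photo (00:30->01:30 is exactly 1 h, not > 1 h)."""
        det = _detections(["2021-01-01 00:00", "2021-01-01 00:30", "2021-01-01 01:30"])
        ev = events.independent_events(det, mode="photo", annotate=False)
        assert len(ev) == 1

    def test_single_photo_and_wide_gaps(self):
        assert len(events.independent_events(_detections(["2021-01-01 08:00"]), annotate=False)) == 1
        ev = events.independent_events(
            _detections(["2021-01-01 08:00", "2021-01-01 10:00"]), annotate=False
        )
        assert len(ev) == 2

    def test_duplicate_timestamps_collapse(self):
        det = _detections(["2021-01-01 08:00", "2021-01-01 08:00"])
        assert len(events.independent_events(det, annotate=False)) == 1

    def test_species_and_cameras_are_independent_streams(self):
        a = _detections(["2021-01-01 08:00", "2021-01-01 08:20"], species="a")
        b = _detections(["2021-01-01 08:10"], species="b")
        c = _detections(["2021-01-01 08:25"], species="a", camera="c2")
        ev = events.independent_events(pd.concat([a, b, c]), annotate=False)
        assert len(ev) == 3

    @given(
        gaps=st.lists(st.floats(min_value=0.01, max_value=300.0), min_size=1, max_size=40),
    )
    @settings(max_examples=50, deadline=None)
    def test_filter_is_idempotent_and_pairwise_separated(self, gaps):
        """Property: the retained-gap filter is idempotent, never grows the set,
        and leaves all retained events pairwise > 1 h apart."""
        times = pd.Timestamp("2021-01-01") + pd.to_timedelta(np.cumsum(gaps), unit="m")
        det = _detections(times)
        ev1 = events.independent_events(det, annotate=False)
        ev2 = events.independent_events(ev1, annotate=False)
        assert len(ev1) <= len(det)
        pd.testing.assert_frame_equal(ev1, ev2)
        diffs = ev1["timestamp"].diff().dropna().dt.total_seconds() / 60.0
        assert (diffs > 60.0).all()

    def test_annotation_columns_present(self):
        ev = events.independent_events(_detections(["2021-01-01 12:00"]))
        assert {"diel_category", "sun_time_rad", "anchored_hour"} <= set(ev.columns)
        assert ev.loc[0, "diel_category"] == "day"


class TestGuilds:
    @pytest.mark.parametrize(
        "diet,expected",
        [
            (dict(diet_vertebrate=0.85), "carnivore"),
            (dict(diet_plant=0.80), "herbivore"),  # inclusive threshold
            (dict(diet_invertebrate=0.9), "insectivore"),
            (dict(diet_plant=0.5, diet_invertebrate=0.5), "omnivore"),
            (dict(diet_vertebrate=0.79, diet_plant=0.21), "omnivore"),
        ],
    )
    def test_threshold_rules(self, diet, expected):
        assert events.assign_guild(make_traits_row(**diet)) == expected

    def test_invalid_fractions_raise(self):
        with pytest.raises(ValueError):
            events.assign_guild(make_traits_row(diet_plant=0.7, diet_vertebrate=0.5))
        with pytest.raises(ValueError):
            events.assign_guild(make_traits_row(diet_plant=1.2))

    @given(w=st.lists(st.floats(min_value=0.0, max_value=10.0), min_size=4, max_size=4))
    @settings(max_examples=100, deadline=None)
    def test_every_valid_diet_gets_exactly_one_guild(self, w):
        total = sum(w) or 1.0
        frac = [v / total for v in w]
        row = make_traits_row(
            diet_vertebrate=frac[0], diet_plant=frac[1], diet_invertebrate=frac[2], diet_other=frac[3]
        )
        assert events.assign_guild(row) in ("carnivore", "herbivore", "insectivore", "omnivore")


class TestSizeClasses:
    @pytest.mark.parametrize(
        "mass_g,expected",
        [
            (5_000, "small"),
            (20_000, "small"),  # boundary: 20 kg is small
            (61_000, "large"),
            (580_000, "large"),
            (600_000, "excluded"),
        ],
    )
    def test_cutoffs(self, mass_g, expected):
        assert events.assign_size_class(make_traits_row(body_mass_g=mass_g)) == expected


class TestHourlyCounts:
    def test_uniform_events_give_row_of_ones(self):
        ev = pd.DataFrame(
            {"protected_area": "PA01", "species": "sp1", "anchored_hour": np.arange(24)}
        )
        mat = events.hourly_counts(ev)
        assert mat.shape == (1, 24)
        assert (mat.to_numpy() == 1).all()

    def test_empty_group_warns_and_returns_zeros(self):
        ev = pd.DataFrame(
            {"protected_area": ["PA01"], "species": ["sp1"], "anchored_hour": [3]}
        )
        with pytest.warns(UserWarning):
            mat = events.hourly_counts(ev, species=["absent"])
        assert (mat.to_numpy() == 0).all()
        assert mat.shape == (1, 24)

    def test_zero_bins_are_explicit(self):
        ev = pd.DataFrame(
            {"protected_area": ["PA01", "PA02"], "species": "sp1", "anchored_hour": [0, 12]}
        )
        mat = events.hourly_counts(ev)
        assert mat.shape == (2, 24)
        assert mat.loc["PA01", 0] == 1 and mat.loc["PA01", 12] == 0
        assert int(mat.to_numpy().sum()) == 2
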