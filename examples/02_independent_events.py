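"""From raw photo bursts to independent events.

Simulates a small survey, then applies the analysis filters: drop
species of 75 g or less and arboreal/aquatic species, and collapse
bursts so consecutive events of a species at a camera are >1 h apart.
Each surviving event carries its diel class and sun-anchored time.
"""

from dielkit import events, synthetic

cfg = synthetic.SyntheticConfig(n_sites=2, n_cameras_per_site=20, n_species=12, seed=3)
traits, truth = synthetic.generate_community(cfg)
detections, deployments = synthetic.simulate_detections(traits, truth, cfg)
print(f"raw detections: {len(detections)} (bursts of ~{cfg.photos_per_visit_mean:.0f} photos per visit)")

traits = events.add_species_classes(traits)  # adds guild and size_class
filtered = events.filter_species(detections, traits)
print(f"after the >75 g + terrestrial/scansorial filter: {len(filtered)}")

ev = events.independent_events(filtered, window="1h")
print(f"independent events (>1 h rule): {len(ev)}")
print("\nDiel composition of the event set:")
print(ev["diel_category"].value_counts().to_string())
print("\nFirst events with their sun-anchored annotations:")
print(ev[["species", "camera", "timestamp", "diel_category", "sun_time_rad", "anchored_hour"]].head(5).to_string(index=False))
# sun_time_rad near 0 (or 2*pi) is solar midnight, pi is solar noon.
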