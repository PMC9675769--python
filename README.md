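# dielkit

Tools for analysing the **diel activity** of tropical forest mammal
communities from camera-trap data: when in the 24-hour cycle species are
active, how that depends on body mass and trophic guild, and whether
predators and prey share or avoid each other's active hours.

The package takes raw time-stamped detections (site, camera,
coordinates, species, timestamp) plus a species trait table (body mass,
fractional diet, forest stratum) and produces:

1. **Independent events on a sun-anchored clock.** Detections are
   filtered to ground-dwelling/scansorial species above 75 g, photo
   bursts are collapsed so consecutive events of a species at a camera
   are more than 1 h apart, and each event is classified as day,
   twilight or night (sunrise/sunset at solar altitude −0.833°,
   nautical dawn/dusk at −12°, computed from NOAA solar-position
   geometry). Event times are mapped to a circular scale anchored at
   sunrise (π/2) and sunset (3π/2), removing photoperiod differences
   across sites and seasons.
2. **Diel multinomial mixed models.** The probability that an event is
   diurnal, nocturnal or crepuscular is modelled as a multinomial logit
   in log body mass and trophic guild (carnivore / herbivore /
   insectivore / omnivore, assigned at ≥ 80 % diet fractions), with a
   protected-area random intercept per non-reference category,
   estimated by Laplace-approximated maximum likelihood. A nested
   candidate set (intercept-only up to mass × guild) is ranked by AIC;
   models within ΔAIC < 2 are reported as equally supported.
3. **Predator–prey temporal coupling.** Sun-anchored hourly counts of a
   prey or subordinate group are regressed on those of a predator group
   with a Poisson GLMM (log link, area random intercept). A 95 % CI
   above zero is read as bottom-up coupling (activity overlap), below
   zero as top-down (temporal avoidance). Groups use a 20 kg size cut;
   species above 580 kg are exempt from predation and excluded here.
4. **Activity overlap coefficients.** Group activity densities are von
   Mises kernel density estimates (Ridout–Linkie optimal smoothing) and
   pairwise overlap is Δ ("Dhat") ∈ [0, 1]: Dhat1 (∫ min(f̂, ĝ)) below
   75 events per group, Dhat4 (mean density ratios at sample points)
   at 75 or more, with 500-iteration smoothed-bootstrap CIs and a
   randomisation pNull.

A synthetic camera-trap generator (`dielkit.synthetic`) produces
multi-site detection streams with latitude-dependent photoperiod,
guild/mass-dependent nocturnality with exact ground truth, clustered
repeat photos, and tunable predator–prey coupling, so every stage can
be validated against known truth without any data download.

## Worked example

`examples/03_diel_multinomial_model.py` generates 8 000 events from a
community whose nocturnal probability is a guild-specific logistic
function of log10 body mass, fits the candidate set and recovers the
generating slopes:

```
Night-vs-day slope per decade of body mass (estimate vs generating truth):
      guild     slope       se  truth
  carnivore -0.824761 0.238145   -1.2
  herbivore  0.995239 0.040598    1.0
insectivore  0.836915 0.081701    0.8
   omnivore -0.415005 0.070091   -0.5

p_night at 0.24 kg: 0.34; at 210 kg: 0.91; ratio 2.7x more nocturnal when large
```

Positive slopes mean larger-bodied species in that guild are more
nocturnal; each estimate lies within two standard errors of the value
that generated the data, and the mass × guild interaction wins the AIC
ranking. `examples/04_predator_prey_coupling.py` shows the coupling
GLMM calling the generating scenario correctly in each direction:

```
  bottom_up: beta = +0.205  CI [+0.193, +0.218]  -> called bottom_up
   top_down: beta = -0.180  CI [-0.227, -0.134]  -> called top_down
independent: beta = +0.000  CI [-0.025, +0.026]  -> called none
```

The other examples cover sun times and anchoring, event filtering,
overlap coefficients, and the one-call pipeline. The pipeline is also
exposed as a thin CLI (`dielkit run-all --seed 12 --out demo_run`, plus
per-stage verbs `simulate`, `events`, `diel-model`, `coupling`,
`overlap`, `plot`), driven by a flat YAML configuration; a manifest
records seeds, filter-stage counts and SHA-256 hashes of every output,
and reruns with the same seed are byte-identical.

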