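"""Bottom-up vs top-down coupling of hourly activity.

Generates paired predator/prey hourly count tables under known coupling
scenarios and fits the Poisson GLMM (log link, protected-area random
intercept). A 95% CI above zero reads as bottom-up (prey and predator
activity overlap); below zero as top-down (temporal avoidance).
"""

import numpy as np

from dielkit import coupling, synthetic

cfg = synthetic.SyntheticConfig(n_sites=11, coupling_beta=0.2, seed=2)

for scenario in ("bottom_up", "top_down", "independent"):
    pairs = synthetic.simulate_interaction(cfg, scenario, rng=np.random.default_rng(42))
    res = coupling.fit_coupling(pairs, response_group="large_herbivore",
                                predictor_group="large_carnivore")
    print(f"{scenario:>11}: beta = {res.beta:+.3f}  CI [{res.ci_low:+.3f}, {res.ci_high:+.3f}]"
          f"  -> called {res.direction}")

# beta is the change in log expected prey events per predator event in the
# same sun-anchored hour; the generator used +0.2 / -0.2 / 0.
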