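"""Layman niche metrics and their bootstrap comparison at a common n.

Raw metrics (especially the convex-hull total area) grow with sample
size, so two species are compared by resampling both down to a common n
and reporting the probability that one species' bootstrapped metric
exceeds the other's across paired draws.
"""

import numpy as np

from isoniche import (
    bootstrap_metrics,
    exceedance_probability,
    generate_community,
    layman_metrics,
    nz_odontocetes_scenario,
)
from isoniche.layman import METRIC_NAMES

species = ("Common dolphin", "Pygmy sperm whale")
configs = [c for c in nz_odontocetes_scenario() if c.species in species]
samples = generate_community(configs, seed=3)
pts = {
    sp: np.array([[s.d13C, s.d15N] for s in samples if s.species == sp]) for sp in species
}
n_common = min(p.shape[0] for p in pts.values())

draws = {
    sp: bootstrap_metrics(p, n_common=n_common, n_draws=10_000, seed=3, species=sp)
    for sp, p in pts.items()
}
probs = exceedance_probability(draws[species[0]], draws[species[1]])

print(f"bootstrapped to common n = {n_common}, 10,000 draws\n")
print(f"{'metric':>7} {'CD raw':>8} {'CD boot':>8} {'PSW raw':>8} {'PSW boot':>8}  P(CD > PSW)")
raw = {sp: layman_metrics(p).as_array() for sp, p in pts.items()}
boot = {sp: d.mean().as_array() for sp, d in draws.items()}
for i, name in enumerate(METRIC_NAMES):
    print(
        f"{name:>7} {raw[species[0]][i]:>8.2f} {boot[species[0]][i]:>8.2f} "
        f"{raw[species[1]][i]:>8.2f} {boot[species[1]][i]:>8.2f}  {probs[name]:6.1f}%"
    )

print(
    "\nProbabilities near 100% mean the first species' niche metric is"
    "\nalmost certainly larger once sample-size effects are removed."
)
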