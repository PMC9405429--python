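# isoniche

Isotopic-niche analysis for stable-isotope ecology, built for multi-species
communities sampled opportunistically (e.g. odontocete strandings) where
per-species sample sizes are small and measurements need correcting before
any niche statistics are meaningful.

Bulk-tissue δ¹³C and δ¹⁵N (‰, vs VPDB and air N₂) place each individual in
a two-dimensional isotope space: δ¹³C tracks carbon source and foraging
habitat, δ¹⁵N trophic level.  `isoniche` covers the full analysis chain:

1. **Measurement corrections.**  Lipids are ¹³C-depleted, so samples with a
   C:N mass ratio > 3.5 are normalised with a correction calibrated by
   averaged bootstrapped OLS of the extraction offset on C:N,
   Δδ¹³C = β₀ + β₁·C:N, fitted on paired bulk/lipid-extracted samples.
   The oceanic **Suess effect** is removed by shifting δ¹³C by
   −0.022‰ yr⁻¹ to a common reference year (default 2021).
2. **Randomisation tests** on mean δ¹³C/δ¹⁵N between species: the observed
   |mean difference| against 10,000 random reallocations of the pooled
   values (Phipson–Smyth add-one p-value; exact enumeration available).
3. **Layman metrics** — δ¹³C range, δ¹⁵N range, convex-hull total area
   (TA), mean distance to centroid (CD), mean and SD of nearest-neighbour
   distances (MNND, SDNND) — bootstrapped to a common sample size with
   pairwise exceedance probabilities.
4. **Standard ellipse areas.**  SEA = π√det(Σ̂) (the r = 1 ellipse holding
   ≈ 39.35%, "40%", of a bivariate normal), the small-sample correction
   SEA_C = SEA·(n−1)/(n−2), and the Bayesian SEA_B via exact sampling of
   the covariance posterior Σ | data ~ Inverse-Wishart(n−1, S) under the
   noninformative prior p(μ,Σ) ∝ |Σ|^−(d+1)/2.  Niche overlap is the
   ellipse-intersection area as a proportion of each species' own ellipse.
5. **A synthetic community generator** that emulates the statistical
   structure of a real stranding data set (per-species bivariate-normal
   clouds, lognormal C:N with a lipid effect on bulk δ¹³C, Suess drift
   over a 2010–2021 sampling window), so the whole pipeline is testable
   end-to-end without access to raw tissue data.

## Worked example

```python
import numpy as np
from isoniche import (generate_community, nz_odontocetes_scenario,
                      fit_ellipse, posterior_sea, sea_b_probability)

samples = generate_community(nz_odontocetes_scenario(), seed=6)
pts = {sp: np.array([[s.d13C, s.d15N] for s in samples if s.species == sp])
       for sp in ("Gray's beaked whale", "Sperm whale")}

for sp, p in pts.items():
    fit = fit_ellipse(p, species=sp)
    post = posterior_sea(p, n_draws=1000, seed=6, species=sp)
    print(sp, fit.n, round(fit.sea, 2), round(fit.sea_c, 2), round(post.median, 2))
```

prints

```
Gray's beaked whale 11 1.99 2.21 2.27
Sperm whale 16 1.21 1.3 1.31
```

i.e. from 11 Gray's beaked whale and 16 sperm whale records the
maximum-likelihood niche widths (SEA) are 1.99 and 1.21 ‰², the
small-sample-corrected widths (SEA_C) 2.21 and 1.30 ‰², and the Bayesian
posterior medians (SEA_B) 2.27 and 1.31 ‰².  Continuing with
`sea_b_probability` on the two posteriors gives 92.8%: the probability
that the beaked whale's isotopic niche is the wider of the two.

The `examples/` directory holds one short script per capability
(simulation, corrections, randomisation tests, Layman metrics, ellipses
and overlap, full pipeline); `isoniche run-all` drives the whole analysis
from a CSV of per-individual records and writes the community tables plus
a reproducibility manifest.

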