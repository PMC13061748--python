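# diebackmap

Spatial point-pattern diagnostics for plant dieback in mapped survey plots.

When an established shrub or cushion-plant population starts dying back, the
*spatial arrangement* of the dead individuals carries information about the
cause: mortality clustered at particular micro-sites points to localised
environmental stress (soil texture, moisture, salinity), while dead plants
interleaved at random with the living point away from density-dependent or
contagious mechanisms. `diebackmap` packages the complete analysis chain for
stem-map surveys of this kind — built around a 12-site survey design for
*Astragalus verus* dieback in semi-arid rangelands (10 × 10 m plots, every
perennial individual mapped in cm with species, live/dead status, and crown
diameter) — and a synthetic survey generator so every stage is testable
without field data.

## What it computes

**Ripley's K/L with Monte Carlo envelopes.** The edge-corrected estimator

    K̂(r) = A · Σᵢ Σⱼ≠ᵢ wᵢⱼ · 1[dᵢⱼ ≤ r] / n²,   L̂(r) = √(K̂(r)/π) − r

with Ripley's isotropic correction (wᵢⱼ = reciprocal of the in-window
fraction of the circle centred at *i* through *j*; exact closed form for
rectangles, weights capped at 4). L̂ = 0 under complete spatial randomness
(CSR); positive = clustering, negative = regularity. Departures are judged
against pointwise envelopes from 500 null simulations at the 95% level
(rank-13 order statistics): CSR for univariate analyses, and for the
live–dead bivariate K̂₁₂ an independence null simulated by random toroidal
shifts of one component (random labelling available as an option).

**Nearest-neighbour structural indices** (4 nearest neighbours, each index
in {0, ¼, ½, ¾, 1}): mingling *M* (fraction of heterospecific neighbours),
dominance *U* (fraction of neighbours not smaller in crown diameter — high
*U* means the reference plant is dominated), and uniform angle *W*
(fraction of successive azimuthal gaps below α₀ = 72°; modal *W* = 0.5
under CSR). Plot edges are handled with the NN1 correction: a plant is a
valid reference only if the boundary is no closer than its 4th neighbour.

**Community statistics**: Shannon, Simpson/dominance, evenness, Pielou
equitability, Brillouin, Menhinick, Margalef, Berger–Parker, Fisher's
log-series α (root of S = α ln(1 + N/α)), Chao-1; per-site dieback
percentages; Kruskal–Wallis and pairwise Mann–Whitney group comparisons.

**Soil gradients**: depth-weighted site predictors from two sampling layers,
correlation-matrix PCA with dieback projected as a *supplementary* (passive)
variable, and Spearman screening of dieback against each soil property.

**Synthetic surveys**: CSR / Thomas-cluster / hard-core point processes,
random-labelling or covariate mortality, and a latent soil-stress axis that
raises sand and EC while lowering moisture, silt and clay — with dieback
rising along it.

## Worked example

```python
>>> import diebackmap as dm
>>> dm.fisher_alpha(5, 121)          # site with 5 species, 121 individuals
1.0517476988898133
>>> dm.dieback_percentage(25, 28)    # 25 dead of 28 mapped focal plants
89.3
```

A clustered synthetic stand flagged by the envelope test:

```python
>>> p = dm.simulate_pattern(dm.ProcessSpec("thomas", parent_intensity=5e-5,
...                         mean_offspring=4, offspring_sd=50), seed=7)
>>> env = dm.monte_carlo_envelope(p, grid=dm.DistanceGrid.regular(300, 50),
...                               n_sims=199, seed=8)
>>> from diebackmap.ripley import envelope_to_frame
>>> print(envelope_to_frame(env).to_string(index=False))
 r_cm         k_hat     l_hat     lower    upper classification
 50.0  12345.675221 12.687722 -4.374668 3.767750        clumped
100.0  43814.706118 18.095953 -3.861051 3.664535        clumped
150.0  82402.504089 11.955339 -3.917836 4.879010        clumped
200.0 132546.325505  5.404006 -4.661377 4.038619        clumped
250.0 198699.768099  1.491750 -5.910091 5.590121         random
300.0 284971.020625  1.179503 -6.328703 7.179864         random
```

The observed L̂ sits far above the simulation envelope at 50–200 cm (the
cluster scale of the generating process) and falls back inside it at larger
distances — the clumped-to-random transition typical of patchy vegetation.

The bundled reference tables reproduce the source survey's group averages
exactly:

```python
>>> from diebackmap import datasets
>>> counts = datasets.site_counts()
>>> dm.group_summary(counts[["group", "n_total", "richness", "focal_total",
...                          "focal_live", "focal_dead"]])
    n_total  richness  focal_total  focal_live  focal_dead
G1    212.0      13.4         62.8        42.0        20.4
G2    136.7       9.0         50.0        25.3        24.7
G3    215.5      13.5         26.0         6.0        20.0
```

## Command line

```bash
diebackmap simulate --seed 1 --out survey/        # synthetic 12-site survey
diebackmap ripley --input survey/stems.csv --site 3 --mode bivariate \
    --nsims 500 --rmax 500 --dr 10 --seed 1 --out k3.csv
diebackmap structure --input survey/stems.csv --site 7 --subgroup dead \
    --out structure7.csv
diebackmap diversity --input survey/stems.csv --out diversity.csv
diebackmap run --config pipeline.yml            # full pipeline + manifest
```

A three-site fixture survey ships under `examples/fixture_survey/`.

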