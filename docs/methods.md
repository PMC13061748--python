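# Methods

This note records the statistical models the package implements, the
conventions adopted where the literature admits more than one, and what the
synthetic-data tests do and do not establish.

## Data model

A survey is a set of sites; each site holds a *marked point pattern* — every
perennial plant in a rectangular plot, with planar coordinates in cm,
species label, live/dead status, and crown diameter — plus a two-layer soil
profile and metadata. Defaults mirror the survey design the package was
built around: 10 × 10 m plots (window 1000 × 1000 cm), twelve sites in three
regional groups of 5/3/4, live/dead status recorded only for the focal
cushion shrub (*Astragalus verus*; other species carry status `na`).

Conventions: the coordinate origin is the lower-left plot corner; the window
is closed, so plants exactly on the border belong to the plot (field
protocols rarely state a rule; inclusion is the simplest consistent choice).
Plant ids follow file row order and break all ties, making every result
deterministic. Duplicate coordinates are legal (two plants at one stake) but
logged.

## Ripley's K and L

The univariate estimator is

K̂(r) = A Σᵢ Σ_{j≠i} wᵢⱼ 1[d(i,j) ≤ r] / n²,

with the isotropic edge correction: wᵢⱼ is the reciprocal of the fraction of
the circumference of the circle centred at plant *i* through plant *j* that
lies inside the window. For a rectangle and r ≤ min(W, H)/2 only the two
nearest (adjacent) edges can cut the circle and the correction has the exact
closed form

- one edge at distance b < d: exterior angle 2·arccos(b/d);
- two edges, corner outside the circle (d² ≤ bₓ² + b_y²): the two exterior
  angles add;
- corner inside the circle (d² > bₓ² + b_y²): exterior angle
  arccos(bₓ/d) + arccos(b_y/d) + π/2.

The implementation was verified against numerical integration of the circle
before freezing, and the test suite holds an independently coded plain-loop
oracle that must agree to 10⁻⁹. Weights are capped at 4 (the rectangle-corner
supremum) to bound the variance of near-corner pairs; the cap is
configurable. The distance grid runs 10–500 cm in 10 cm steps by default
(half the shorter plot side is the validity limit of the correction, and the
grid constructor enforces it).

The centred transform L̂(r) = √(K̂(r)/π) − r is used for display and testing:
0 under CSR, positive = clustering, negative = regularity.

The bivariate K̂₁₂ sums ordered pairs from two mark classes (live × dead),
normalised by n₁n₂, and is symmetrised as the n-weighted average of K̂₁₂ and
K̂₂₁, so swapping the classes changes nothing.

## Monte Carlo envelopes

Envelopes are *pointwise*: at each grid distance the bounds are the k-th
smallest and k-th largest of n_sims simulated L̂ values, with
k = ⌈n_sims (100 − level)/200⌉ (k = 13 for 500 simulations at 95%). The
observed pattern is not added to the simulated ensemble (pure parametric
bootstrap). Values exactly on a bound classify as inside — conservative
toward the null. Univariate labels: clumped / random / uniform; bivariate:
attraction / independence / repulsion.

Null models:

- **CSR** (univariate): n points redrawn uniformly per simulation.
- **Independence** (bivariate): one mark class is shifted by a uniformly
  random toroidal translation while the other stays fixed. This preserves
  each component's internal structure and randomises only their relative
  position — the appropriate null for "are live and dead plants arranged
  independently?". Random labelling (statuses reshuffled over fixed
  positions) is provided as an option; it answers the different question of
  random mortality given the stem positions.

Because the envelope is pointwise, about 5% of grid distances exit under the
null by chance, and exits are correlated across distances (K is cumulative).
Global rank envelopes would control the family-wise level and are a noted
future option.

## Structural indices (k = 4 neighbours)

For each reference plant and its four nearest neighbours (ties in distance
broken by ascending id):

- **Mingling M** — fraction of neighbours of a different species.
- **Dominance U** — computed from crown diameters with the indicator
  "neighbour not smaller than the reference scores 1" (ties count as not
  smaller), so *high U means the reference is dominated*. The complementary
  convention (proportion of smaller neighbours) exists in the literature; a
  flag flips it. Raw diameters are compared, not ranks.
- **Uniform angle W** — neighbours' azimuths are sorted; the four successive
  gaps (wrap-around included) partition 360°, and W is the fraction strictly
  below the standard angle α₀ = 360°/(k+1) = 72°. A perfect cross scores
  W = 0. Under CSR the W distribution is unimodal at 0.5 — the classical
  calibration of α₀ and a property test in the suite.

Edge handling is the NN1 rule: a plant is retained as a reference iff its
distance to the nearest boundary is at least the distance to its 4th
neighbour; every plant remains eligible as a neighbour. Subgroup summaries
(all / live / dead focal plants) restrict only the references — neighbours
always come from the full community, since mingling of dead plants with
other species is itself the quantity of interest. References with missing
crowns or coincident neighbours are skipped with a warning.

## Community statistics

Dominance D = Σpᵢ², Simpson 1 − D, Shannon H = −Σpᵢ ln pᵢ (natural log),
evenness e^H/S, Pielou equitability H/ln S, Brillouin
(ln N! − Σ ln nᵢ!)/N, Menhinick S/√N, Margalef (S−1)/ln N, Berger–Parker
max nᵢ/N, Chao-1 = S + F₁²/(2F₂) (bias-corrected S + F₁(F₁−1)/2 when
F₂ = 0), and Fisher's α solved from S = α ln(1 + N/α) by Brent bracketing in
[10⁻⁶, 10⁶] with residual ≤ 10⁻⁸ (α reported as infinite when S is so close
to N that no finite root exists). Evenness and equitability as defined above
were confirmed by back-computation from the reference survey's printed
table; note that table's cells are truncated, not rounded, to 2 dp — the
package reports round-half-away-from-zero values and the tests compare at
one unit in the last printed place.

Dieback per site is 100 × dead / all mapped focal individuals (live + dead +
unclassified — the reference survey contains one site whose live + dead
counts fall short of its focal total, which status `na` represents).

Group comparisons are non-parametric: Kruskal–Wallis with midranks and tie
correction (chi-square p by default; exact enumeration of label permutations
for total n ≤ 9, Monte Carlo otherwise, as an option) and pairwise
Mann–Whitney (exact p when n₁ + n₂ ≤ 12 and tie-free, tie-corrected normal
approximation otherwise). Published p-values from proprietary software could
not be reproduced exactly and are not asserted anywhere.

## Soil gradient

Layer values are combined by thickness-weighted means (two equal 25 cm
layers → arithmetic mean). The ordination is a correlation-matrix PCA —
variables are on incommensurate units (%, pH, dS/m), so covariance PCA would
let variance units dictate the axes. Axis signs follow a deterministic
convention (largest-magnitude loading positive). Dieback is a *supplementary*
variable: projected after the decomposition as its Pearson correlation with
the site scores, never influencing eigenvalues or loadings (a contract
tested explicitly); a flag allows active inclusion for comparison. Screening
correlations are Spearman — with 12 sites no distributional claim is
warranted. No detrending/gradient-length step is performed; the pipeline
always proceeds with PCA (a short compositional gradient is assumed, as in
the reference design).

## Synthetic data: what it emulates

The generator reproduces the *statistical* features the analysis assumes,
with defaults fixed from the reference design before any testing:

- **Point processes.** Thomas clusters (parents Poisson with intensity κ,
  offspring Poisson(μ) with Gaussian displacement sd 50 cm) for the clumped
  community structure; per-group κA·μ of 212/136/216 expected plants matches
  the groups' mean community sizes. Offspring are wrapped toroidally so the
  realised intensity equals κμ exactly — discarding them would thin the
  pattern near edges. CSR and hard-core (dart-throwing) processes serve as
  calibration and power baselines.
- **Marks.** Species are i.i.d.: the focal species receives its group's
  share (0.30 / 0.37 / 0.12), companions split the remainder by a symmetric
  Dirichlet over a richness drawn uniformly from the group's range (5–18
  overall) — no abundance model for companion species is implied by the
  design, so exchangeability is the neutral choice. Status is random
  labelling with site-level P(dead) = logistic(β₀ + β₁·stress), β₀ = 0,
  β₁ = 1.2, group stress means −0.8 / 0 / 1.0 (sd 0.4), giving group dieback
  around 0.31 / 0.50 / 0.77. A covariate model (within-plot spatial mortality
  gradient) is available for power studies. Crowns are log-normal
  (meanlog = ln 40, sdlog = 0.35, truncated to [10, 120] cm) — positive and
  right-skewed, spanning the focal shrub's 20–70 cm typical canopy.
- **Soil.** One latent stress value per site moves sand (+10 %/unit) and EC
  (+0.6 dS/m) up and SP (−6), silt (−6), clay (−4) down, with independent
  noise and a small fixed depth offset; texture slopes sum to zero and
  closure at 100% is renormalised. pH is pure noise — it defines the "weak
  second axis" role.

Sites are redrawn (bounded retries) until richness is in range and at least
two live and two dead focal plants exist, so every downstream analysis is
well-posed. All randomness stems from one master seed via per-site derived
streams (CRC-32 of stage name + site id), so adding a site never perturbs
another.

What passing the synthetic tests does *not* show: real stem maps have
interspecific interactions, inhomogeneous intensity, size-dependent
mortality and spatially autocorrelated soil error, none of which the
generator produces. The synthetic soil gradient is also much cleaner than
field data — its first PCA axis explains ~80% of the variance versus ~29%
in the reference survey — so gradient-recovery tests demonstrate
correctness of the machinery, not field-level power.

## Numerical and reporting choices

- Tolerances: brute-force K oracle agreement 10⁻⁹; Fisher-α residual 10⁻⁸;
  PCA reconstruction 10⁻⁸.
- Reporting rounds half away from zero at each table's printed precision;
  computation is full precision throughout.
- Monte Carlo problem sizes in the test suite (500 replicates for closed-form
  CSR calibration at n = 200; 20 replicates of 500-simulation envelopes for
  level and power; 500-point patterns for structural calibration) were chosen
  as the smallest sizes at which the binomial/3-SE tolerances are meaningful.
- Degenerate inputs: single-species sites report equitability as missing;
  empty mark classes, empty subgroups, constant PCA variables, and
  unattainable hard-core packings raise errors that name the offender.

## Known limitations

- Envelopes are pointwise, not global; interpret multi-distance exits with
  the usual simultaneity caveat.
- The isotropic correction is exact only for rectangles and r ≤ half the
  shorter side; irregular plot shapes are out of scope.
- Inhomogeneous K, pair-correlation g(r), O-ring statistics, rarefaction
  and beta diversity, and DCA/CCA ordinations are deliberately not
  implemented.
- Numeric equality with the reference survey's envelope figures cannot be
  claimed (the underlying stem maps are unpublished and the original
  software's conventions are unknown); only qualitative classification
  behaviour is asserted.
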