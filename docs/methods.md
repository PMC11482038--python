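# Methods

`ivgrass` is a desk-scale virtual experiment on the role of intraspecific
genetic variation (IV) in binary forage mixtures.  It combines (i) a
quantitative-genetics trait sampler, (ii) an enumerated community design
along a mean-trait-divergence gradient, (iii) a reduced-order, spatially
explicit individual-based stand simulator, and (iv) a suite of community-,
population- and plant-level indices.  This note records the model, its
assumptions, the parameter choices that matter, and what the package's
passing tests do and do not demonstrate about real grasslands.

## Trait model

A species' population is parameterised by per-trait means `mu`, a
coefficient-of-variation vector `CV` (sigma/mu) and a correlation matrix
`Mc`.  Individual genotypes are single multivariate-normal draws with
covariance

    M[i,j] = (mu_i CV_i)(mu_j CV_j) Mc[i,j],

consistent with the infinitesimal model of quantitative genetics for
polygenic traits.  Three IV levels are used throughout: CV = 0.001 (a
technically non-degenerate stand-in for "no variation"), 0.15 (moderate) and
0.30 (high).  `Mc` defaults to the identity (independent traits); any
positive semi-definite matrix is accepted and validated (eigenvalues below
−1e−10 are a hard error rather than being silently repaired — a silently
"nearest-PSD" matrix would no longer be the matrix the user specified).

Because trait values are physical lengths, rates and thresholds, vectors
with any component at or below 1% of its mean are rejected and redrawn
whole.  At CV = 0.30 roughly 0.04% of single-trait draws are affected, so
the truncation bias on means and CVs is far below the Monte-Carlo
resolution of any test in the suite.

Each individual is summarised by the score

    p_score = mean_n( S_n (P_n − mu_n) / sigma_n ),

the sign-adjusted average of its standardised trait values; `S_n` is +1 for
traits whose larger values aid resource acquisition (`L_max_L`, `L_max_In`,
`Vmax_2`, `EL_max_R`) and −1 for the phyllochron `Phyllo_1` (faster organ
production = smaller value) and the photoperiod threshold `PPtresh_H`
(later autumn slowdown = smaller value).

## Community design

Species 1 (Sp1) is the reference population.  Species 2 is derived by
shifting the means of a diverging trait set by `mu2 = mu1 (1 + S d * 0.15)`
per divergence step, where `d = delta` except for the nitrogen traits of
the six-trait trade-off set T6, which take `d = −delta` (better light
access bought with worse N access).  The grid
`delta ∈ {−1.5, −1, −0.5, 0, 0.5, 1, 1.5}` crossed with nine diverging sets
(six single-trait T1 variants, the three light traits T3L, the three N
traits T3N, and T6) yields 63 communities; each is run at the three IV
levels, in two N environments (0N unfertilised, N+ at 40 g N m⁻² yr⁻¹ =
400 kg ha⁻¹), with seeded replicates.  One divergence step equals a
relative mean shift of 0.15 (the moderate CV), so neighbouring communities'
trait distributions overlap substantially at moderate/high IV — the regime
where IV effects are expected to matter.  Pure stands of Sp1 and of every
distinct Sp2 are enumerated under matching conditions because the
overyielding partition is defined against pure-stand references grown in
the same environment.

Per-run seeds are CRC32 hashes of (master seed, community id, CV level,
environment, replicate), so a run's seed never depends on which other runs
are enumerated; replicate pairing across IV levels (needed for the
stabilising effect) is therefore stable.

## Stand simulator

The simulator is a deliberately reduced-order surrogate: it preserves the
causal chain *traits → local resource capture → individual growth →
population structure → community outcome* on a lattice, without 3D
morphogenesis, radiative transfer, water limitation (the transpirable-water
fraction is fixed at 1), photomorphogenetic red:far-red responses or
symbiotic N fixation.  Its outputs are meaningful as directions and
contrasts, not as absolute yields.

Plants sit one per node of a toroidal 20×20 lattice at 400 plants m⁻²
(1 m² domain; mixtures get exactly half the nodes per species by a seeded
permutation).  Each day:

1. **Development.** Thermal time advances with a sinusoidal temperature
   climatology (base 5 °C).  A new phytomer appears every `Phyllo_1`
   degree-days, adding potential leaf area ∝ `L_max_L`² and potential stem
   length ∝ `L_max_In`.  On shortening days with photoperiod below the
   individual's `PPtresh_H`, a development multiplier of 0.2 slows both
   thermal accumulation and growth (the autumn slowdown; implemented as a
   multiplier, not a hard stop).
2. **Light.** Every plant spreads its leaf area over its nine-cell zone of
   influence (own cell + Moore ring).  A cell intercepts
   `I0 · area · (1 − exp(−k LAI))` (k = 0.6) and shares it among
   contributing plants ∝ `a_i exp(β (H_i − H̄))` with β = 5 m⁻¹ — taller
   plants take disproportionate shares, the classic size-asymmetric light
   competition.
3. **Growth.** Potential growth is RUE · PARi (RUE = 2 g MJ⁻¹); N demand is
   `0.03 · dM_pot` (critical N concentration).
4. **Nitrogen.** Roots colonise the own cell plus Moore rings as root mass
   grows (rate ∝ `EL_max_R`); per-cell uptake capacity is
   `Vmax_2 · effective root mass`, where effective root mass scales with
   `EL_max_R` (faster-elongating roots are longer per unit mass).  Cells
   whose summed demands exceed their pool share N in proportion to
   capacities; uptake never exceeds demand and the soil is decremented by
   exactly what is taken.
5. **Stress.** NNI = min(1, uptake/demand); realised growth is
   `dM_pot · NNI · dev_multiplier` (multiplicative, systemic stresses).
6. **Allocation.** 8% of growth goes to reserves; the rest splits
   shoot/root from 70:30 at NNI ≥ 1 down to 50:50 at NNI ≤ 0.5.  Leaf area
   and height expansion are carbon-limited against their phytomer-derived
   potential pools (SLA = 0.02 m² g⁻¹; stem extension per gram scales with
   `L_max_In`).  Reserves are remobilised into shoot regrowth for ten days
   after sowing and after each cut.
7. **Maintenance.** Temperature-scaled maintenance respiration
   (0.004 g g⁻¹ day⁻¹ at 10 °C effective) is drawn from reserves, then
   shoot, then root.  This creates a light-compensation point: persistently
   overshadowed plants shrink instead of idling.
8. **Senescence.** Leaf area decays at 1.5% day⁻¹.

Four harvests (days 60, 120, 180, 240 after a day-90 sowing) cut living
shoots, leaf area and height to a 20% residual and credit the removed mass
to per-species partial yields.  Thirty days after each harvest, plants
below 5% of the mean living shoot mass die; dead plants are frozen (zero
leaf area, no further uptake or growth) but keep their realised state for
the population indices.

The only stochastic elements are species placement and genotype draws;
all dynamics are deterministic, so identical (design, seed) pairs produce
bit-identical plant tables.

### Calibration choices

Constants are generic forage-canopy magnitudes, not a calibration to any
dataset; the package's acceptance surface is property- and
direction-based.  Choices that required judgement:

- **Initial mineral N = 1.5 g m⁻², mineralisation = 0.04 g m⁻² day⁻¹**
  (≈ 146 kg N ha⁻¹ yr⁻¹).  These make the unfertilised environment
  N-limited from canopy closure onwards — the stated contrast of the 0N
  treatment — while N+ (40 g m⁻² fertiliser split over sowing and the
  first three cuts) stays mostly N-sufficient.  A large spring pool would
  let light-driven early growth dominate root-mass accumulation and wash
  out the N-trait contrast.
- **`PPtresh_H` mean = 11.5 h.** The threshold distribution must sit below
  the site's maximal daylength (≈ 15.6 h at 46.4° N, the latitude used for
  the photoperiod series); individuals with thresholds above it would be
  "slowed" from the summer solstice, turning an autumn trait into a
  mid-season handicap and inflating its apparent importance.
- **Height growth is carbon-limited** (0.4 m per g shoot growth, scaled by
  relative internode length) rather than purely developmental.  With
  genotype-determined heights, the exponential height advantage multiplies
  both species' weights by the same variance factor and cancels from the
  shares; size asymmetry must be allowed to *compound* through realised
  growth for local dominance and suppression to emerge.
- **Mortality threshold = 5% of mean living shoot mass**, checked 30 days
  after each cut.  Combined with maintenance respiration this makes
  post-harvest self-thinning demographically active (dense sown swards thin
  strongly in their first year), which is the survival channel through
  which IV acts on species balance.  At a threshold low enough to never
  fire, that mechanism would be silently absent.

## Indices

- **Ytot, p50s.** Total annual yield and the species-2 share
  `p50s = Yp2/Ytot` of it; 0.5 marks a mixture holding its 50/50 sowing
  proportion.
- **Overyielding and its partition.** `OY = Ytot − (Ypur1 + Ypur2)/2`;
  with relative-yield deviations `ΔRY_i = Yp_i/Ypur_i − 0.5`,
  `CE = 2 mean(ΔRY) mean(Ypur)` and `SE = 2 Cov(ΔRY, Ypur)` with the
  population (1/n) covariance, so `OY = CE + SE` is an exact identity at
  n = 2 (the sample covariance would break it).  Covariance shift-invariance
  makes Cov(ΔRY, Ypur) identical to Cov(RY, Ypur).
- **Stabilising effect.** `S_IV = (p50s_low − 0.5) − (p50s_high − 0.5)` when
  the low-IV reference is ≥ 0.5, and the mirrored form below 0.5; positive
  values mean IV kept the community closer to the sowing balance.  The
  low-IV (CV = 0.001) replicate-matched run is always the reference.
- **Gini coefficient** of surviving individuals' annual production
  (sorted-vector form, equal to the pairwise mean-difference definition):
  size inequality, a proxy of competition asymmetry, per species.
- **D5.** Share of a species' annual production contributed by the half of
  its *sown* individuals (dead ones included with their frozen realised
  production) with the highest values of one trait; ties broken by plant id
  for determinism, odd populations take the upper ⌈n/2⌉.  0.5 = no
  within-species selection on that trait.  Per-plant "production" is
  cumulative harvested mass, so the species' values sum exactly to its
  partial yield.
- **Local partition variances.** For each living focal plant, the mean
  cumulative PARi (or N uptake) of its living first-order kin and non-kin
  neighbours; the index is the variance of these local means *pooled within
  focal species* (pooling removes the between-species offset, so a
  two-phase mosaic in which every plant of a species faces the same class
  mean scores zero — the degenerate checkerboard case).  The estimator
  behind this index is genuinely under-determined; a per-pair pooled
  variant is available via `mode="pairwise"`, and neither is asserted to be
  canonical.  Pure stands report the non-kin variance as missing, not zero.

## What the tests show — and what they cannot

The suite verifies: exact/analytic values for every index (including an
O(n²) brute-force Gini oracle and a 1500-shuffle permutation null for D5);
sampler moment recovery at Monte-Carlo precision; conservation of soil N,
dry matter and light on every simulated day; bit-level determinism; and the
qualitative findings of the virtual experiment — null (delta = 0) mixtures
hold p50s = 0.5 at every IV level, dominance is monotone in divergence for
single-function trait sets (and non-monotone for the T6 trade-off),
size inequality and biomass–p_score coupling appear only when IV does,
within-species selection targets N-acquisition traits under 0N and
light-acquisition traits under N+, and the mean stabilising effect of high
IV across non-neutral communities is positive.

These are statements about the surrogate, under its synthetic climatology
and generic constants.  They do not validate absolute yields
(the full-order model this design descends from predicts ~1650 g m⁻² under
N+; this surrogate is not expected to and does not reproduce such
magnitudes), nor water- or disease-mediated effects, nor multi-year
dynamics.  Replicate counts are deliberately desk-scale: 9 replicates for
the null-model campaign, 3 for the direction sweep — sizes at which every
asserted contrast is several Monte-Carlo standard errors wide.

## Numerical notes

- Sampling uses the eigen-decomposition path of the multivariate normal so
  zero-variance traits (CV = 0) are handled exactly.
- Soil cells are never driven negative; allocation is capped by both desire
  and capacity share, and the mass-balance diagnostic closes to ~1e−15
  relative on full runs (asserted < 1e−9).
- p50s is undefined (error) at zero total yield; Gini requires ≥ 2
  survivors and positive mean; D5 and the overyielding partition reject
  non-positive denominators with diagnostics rather than returning NaN
  silently.
- All RNG flows from `numpy` `SeedSequence`s spawned off the per-run seed;
  no global random state is touched.
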