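# Methods

## Colour model

The hexagon model represents trichromatic hymenopteran colour vision.
Receptor sensitivities are built from the Govardovskii et al. (2000)
vitamin-A1 alpha-band template, peak-normalized on the model grid, with
nominal peaks at 350 (UV), 440 (B) and 540 nm (G). The beta (cis) band is
available behind a flag but off by default: at these λmax values it adds
only a small UV shoulder, and published bee-vision work is split on
including it. All spectral functions are tabulated on a 300–650 nm grid at
10 nm steps (36 points); integrals are left Riemann sums on that grid, and
spectra measured on finer grids or out to 700 nm are linearly interpolated
and truncated. Receptor excitation uses the hyperbolic transduction
E = P/(P+1), so the adapting background (P = 1 for every receptor by the
von Kries normalization) maps to E = 0.5 on all three axes and hence to
the hexagon centre.

A note on the coordinate formula: the y coordinate implemented is
y = E_B − ½(E_G + E_UV). A sign variant, y = E_B − ½(E_G − E_UV),
circulates in parts of the literature; it would place the adapting
background at y = 0.5 rather than the centre, contradicting the model's
own construction, and is therefore not used.

### Hue, sectors and degenerate loci

Hue is measured counter-clockwise with the BLUE vertex (0, 1) at 90°.
The six colour categories are 60° sectors: BG = [0°, 60°), B = [60°, 120°),
UB = [120°, 180°), U = [180°, 240°), UG = [240°, 300°), G = [300°, 360°),
with a boundary hue assigned to the counter-clockwise sector. This
convention is declared, not derived: sector boundaries differ slightly
between published category schemes, which is why downstream contingency
statistics are tolerant to near-boundary species. Below a chromatic
contrast of 1e-9 the hue (and sector) are reported as undefined rather
than as an arbitrary angle.

### Illuminant and background

The illuminant is the CIE D65 relative power table converted to photon
flux by multiplying by λ; its absolute scale is irrelevant because von
Kries adaptation cancels any constant factor (a tested invariant). The
default background is a parametric green-leaf reflectance (a 0.035
floor plus a Gaussian bump of 0.12 at 550 nm), standing in for an
averaged field-measured leaf spectrum; any user-supplied two-column CSV
can replace it. Colour loci computed from spectra therefore depend on
this choice, which is why a species table with *measured* hexagon
coordinates takes precedence over spectra when both are supplied to the
pipeline.

### Multi-patch flowers

When a species has several patch spectra with stated area fractions, the
largest patch's locus is used for classification (all loci are computed);
without area fractions the patches are averaged. This is a declared
convention — field practice varies.

## Reward statistics

Species are classed high/low in soluble sugar relative to the subset
median; a species exactly at the median goes to "low" (relevant only for
odd subset sizes). The MAD is reported with the R-style 1.4826 normal
consistency constant by default (configurable to 1.0); no reported
statistic depends on that constant.

The contingency test is Pearson's χ² on the 2×K reward-by-sector table
(K = non-empty sectors; the UV sector, typically a single species, is
excluded by the SS1 subsetting and empty sectors are dropped). Because
several sectors are small, the p-value is Monte-Carlo: tables are drawn
uniformly over all tables with both margins fixed (Patefield's algorithm
via `scipy.stats.random_table`, matching the convention of R's
`chisq.test(simulate.p.value = TRUE)`), with the add-one estimator
p = (1 + c)/(n_sim + 1), which can never be zero and is reproducible
under a fixed seed. Default n_sim = 100 000.

Sugar–contrast association uses Kendall's τ-b (tie-corrected; sugar data
contain ties), two-sided. P-values are reported unadjusted across
subsets, matching standard practice for this design where the subsets
are nested sensitivity analyses rather than independent hypotheses.

## Phylogenetic signal

The Brownian covariance C is built from shared root-to-MRCA path lengths;
polytomies are handled natively (no random resolution), and tips without
trait data are pruned with a logged count. Pagel's λ multiplies the
off-diagonal of C. The profile likelihood concentrates out the root state
(GLS) and σ² (ML), leaving a 1-D problem in λ solved by bounded Brent
search on [0, 1] to 1e-8, with the endpoints checked explicitly and ties
broken toward smaller λ. The cap at λ = 1 reflects the usual
interpretation of λ against the Brownian expectation of unity; values
above 1 are rarely identifiable on ultrametric trees.

Significance is tested two ways: a likelihood-ratio test against λ = 0
with χ²₁ (the default, matching the practice of the standard R tooling
for this statistic) and an explicit tip-shuffle permutation test with the
add-one p estimator. The LR p-value at the λ = 0 boundary is conservative
(the usual boundary caveat); the permutation option sidesteps it.

## Synthetic data

The generator emulates a 59-species, two-site community: six parametric
reflectance archetypes (sigmoid plateaus, Gaussian peaks, UV bumps) cover
the five well-populated sectors densely and UV sparsely — the default
sector mix (BG 21, B 10, UG 11, G 9, UB 7, U 1) and family structure
(3 Asteraceae, 28 Orchidaceae) reproduce the subset-size pattern
59/58/55/27/28 of the study design. Sector labels are realized through
the colour model itself by rejection sampling jittered archetypes, so
generated records are always self-consistent with the vision module.

Per-flower sugar is log-normal with a 392 μg median and log-scale 0.9,
chosen so the median and MAD are of comparable magnitude (hundreds of
μg), as observed in field nectar data; colour effects enter as
multiplicative per-sector offsets on the median, with the default of no
offset defining the null. Trees are pure-birth (Yule) and ultrametric;
traits are drawn exactly from N(μ·1, σ²·C_λ).

What the generator does *not* emulate: measurement noise in
spectrophotometry, within-species variation in nectar (records are
species-level), spatial or temporal flowering structure, realistic petal
optics, and any real phylogeny's imbalance or node-age structure. Tests
passing on synthetic data therefore validate the statistical machinery
and its calibration, not field-data idiosyncrasies.

## Numerical and design notes

- Riemann (not trapezoid) quadrature matches the declared 10 nm step
  convention; the two differ only by endpoint half-weights (~1% here),
  and a test pins the exact relationship.
- The Monte-Carlo χ² and the permutation test both use the add-one
  estimator; their p-values have floor 1/(n_sim+1).
- `bm_loglik` reports a degenerate (+inf) likelihood limit for a
  constant trait rather than failing, with σ² = 0 and the constant as
  root state.
- All randomness flows through `numpy.random.default_rng` seeds carried
  in results objects and manifests; re-running any analysis with the
  same config is byte-identical.
- Problem sizes in the test suite (e.g. 500 null communities at
  n_sim = 2000 for type-I calibration; 100 replicates of 64-tip trees
  for λ recovery) are desk-scale choices that keep Monte-Carlo standard
  errors small relative to the tested tolerances.

## Known limitations

- Receptor-noise colour distances (ΔS), tetrachromatic observers and
  discrimination thresholds are out of scope.
- The green-leaf background is parametric, not a measured average; loci
  computed from spectra shift slightly with the background choice
  (measured hexagon coordinates are unaffected).
- The sector-boundary convention is fixed; species within a degree or two
  of a boundary can change category under other published conventions.
- The λ estimator assumes the supplied tree's branch lengths are in
  consistent (time) units and the trait is approximately Gaussian on the
  tree; heavy-tailed traits such as raw sugar amounts may warrant a log
  transform, which is left to the caller.
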