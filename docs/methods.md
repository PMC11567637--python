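# Methods

This note records the models implemented in `polyselect`, the assumptions
behind them, the defaults and why they were chosen, what the synthetic
worlds do and do not emulate, and the numerical decisions a maintainer
would want spelled out.

## Ordinal scoring of mating systems

The rubric converts heterogeneous evidence into a single ordinal score
0–4. Four criteria produce components independently:

| criterion | input | levels |
|---|---|---|
| polygamy rate | fraction of individuals polygamous | <0.1% → 0; 0.1–5% → 1; 5–20% → 2; >20% → 3 |
| polygamy records | qualitative | occasional → 1; multiple → 2; frequent → 3 |
| EPP rate | fraction of extra-pair offspring | <5% → 0; 5–25% → 1; 25–50% → 2; >50% → 3 |
| display | lek / solitary display post | → 4 |
| textual class | strict/frequent monogamy, regular/frequent polygamy | 0–3 |

The species score is the **maximum** over defined components. Undefined
components are excluded from the maximum rather than treated as 0, so a
species with only an EPP estimate is scored from that estimate alone. The
EPP bands sit deliberately above the polygamy bands because nonzero EPP is
compatible with strict social monogamy (mate switching, brood parasitism)
and EPP data over-represent well-studied temperate species.

Numerical boundary closure is centralized in one threshold table: bands
are lower-closed, the middle band is upper-closed (a 20% polygamy rate
scores 2; a 50% EPP rate scores 2), the top band strictly greater. The
sources describing these bands do not state closure; any other convention
changes only measure-zero inputs.

Qualitative polygamy records: `none` is treated as *absence of evidence*,
not as evidence of monogamy — strict monogamy must be asserted through the
textual class. This prevents data-poor species from defaulting to score 0
through the record field.

The trigger recorded with each score is provenance metadata only; ties are
broken display > polygamy > EPP > textual and never affect the score.

## Validation metrics

`I_S = var(m)/mean(m)²` uses the sample variance (n−1) by default,
configurable to the population convention; the choice shifts desk-scale
examples (e.g. `[1,3]` gives 0.5 sample vs 0.25 population) but vanishes
at survey sample sizes. Bateman gradients are computed on mean-relative
fitness by default (the classical definition, invariant to separate
rescaling of either variable); the raw-scale slope is retained as an
option. Residual testes mass uses ordinary (non-phylogenetic) OLS of
log10 testes on log10 body mass; a phylogenetic GLS variant is out of
scope because published residuals are conventionally OLS-based.
Regressions are unweighted by default; per-species sample sizes can be
supplied as weights but reported analyses scale plotting size, not
weights, by n.

## Equal-area gridding

The Behrmann projection (cylindrical equal-area, standard parallel 30°,
authalic radius 6371.0072 km) is implemented directly — forward and
inverse are one line each — with the grid origin anchored at projected
(0, 0), row-major cell ids, and half-open `[min, max)` cell membership so
no point is double-counted. Two resolutions are used: occupancy and
climate live on a fine grid (5 km in the survey convention; synthetic
worlds default to 100 km, see below), statistics on a coarse analysis
grid (200 km default). A coarse cell's species list is the union over its
nested fine cells; re-rasterizing ranges directly at 200 km is the noted
alternative and differs only for ranges that fragment below the overlap
threshold.

Polygon ranges are rasterized by exact intersection area on the projected
plane, keeping cells with ≥50% overlap. Polygon edges are projected as
straight segments between projected vertices; lon/lat-aligned rectangle
edges are exact under this projection, and tests use such geometries. A
cell-list input path bypasses geometry entirely. Latitude-band ranges
narrower than one fine cell fall back to the cell containing the band
centre so no species silently loses its range.

bio4 (temperature seasonality) is the per-cell SD of 12 monthly mean
layers, population convention (ddof=0) matching bioclim; range means over
occupied cells are unweighted (cells are equal-area by construction).

## SAR latitudinal models

The spatial **error** form is the default (`y = Xβ + u, u = λWu + ε`),
standard for macroecological gradient analyses; the lag form is available.
Weights are queen contiguity on the analysis lattice, row-standardized;
both scheme and standardization are options since no single convention is
canonical. The row-standardized spectrum is computed from the similar
symmetric matrix `D^{-1/2} A D^{-1/2}`, so eigenvalues are real and
`log|I − λW| = Σ log(1 − λ eig_i)` is exact; this identity is tested
against dense `slogdet` to 1e-8. λ is profiled by bounded scalar
minimization (tolerance 1e-6) within the interval set by the reciprocal
extreme eigenvalues; β and σ² have closed forms at each λ. Wald z/p values
use the GLS covariance at the ML λ; their type-I error under spatially
correlated nulls is verified by simulation (λ=0.5, 500 replicates, nominal
0.05 within [0.02, 0.10]). Isolated cells keep zero weight rows and
contribute iid errors.

A property of the error form worth knowing: when the response field is
very smooth relative to the lattice (ranges spanning many cells, as in
small synthetic worlds aggregated coarsely), λ̂ → 1 and the spatial error
absorbs most of a smooth latitudinal signal; the gradient fit is then
conservative. Recovery tests therefore generate cell-level data with exact
`(I − λW)^{-1}ε` errors at the 400-cell scale, where λ = 0.6 and the slope
are both recovered within Monte-Carlo bands.

## Cumulative-link phylogenetic models

Latent liability `l = Xβ + a + e`; `a ~ MVN(0, σ²_phylo C)`; probit noise;
observed `y = k` iff `τ_k < l ≤ τ_{k+1}`. `C[i,j]` is the root-to-MRCA
shared branch length, scaled to unit tree height so σ²_phylo is
comparable across trees. The probit link is the default because the
latent-normal liability composes conjugately with the Gaussian
phylogenetic effect; the non-phylogenetic fitter also offers logit (via
random-walk MH on the marginal ordinal likelihood), while the
phylogenetic fitter is probit-only by design.

Priors: β ~ N(0, 2.5²); σ_phylo ~ half-normal(0, 1); cutpoints ordered
with N(0, 5²) margins. The intercept is absorbed by the cutpoints, so
constant design columns are rejected.

Sampler (Metropolis-within-Gibbs per chain):

1. **Cutpoints** — joint Cowles-type MH: sequential truncated-normal
   proposals with the marginal ordinal likelihood given the current
   latent mean, step size adapted during warmup. One-at-a-time uniform
   conditional draws (classical data-augmentation) mix at O(1/n) step
   sizes and were measurably too slow at n ≈ 200.
2. **Liabilities** — exact truncated-normal draws by inverse CDF.
3. **β** — conjugate normal draw; the posterior Cholesky factor is
   precomputed once.
4. **Phylogenetic effects** — drawn in the eigenbasis of C (eigendecomposed
   once per tree); zero-eigenvalue directions are pinned at 0.
5. **σ²_phylo** — random-walk MH on log σ², followed by an exact ASIS
   (interweaving) re-draw of the signed scale of the non-centered effect
   (its N(0,1) prior is exactly the half-normal prior on σ), and a joint
   location shift of (l, τ, a). The last two moves remove the scale and
   location ridges that otherwise appear when one category holds most
   species and the tree has deep shared branches (split-R̂ on cutpoints
   dropped from ≈2 to ≤1.05 on such data).

Defaults are 4 chains × 2500 warmup + 2500 draws; tests and the worked
examples use smaller, stated settings. Split-R̂ and bulk ESS are computed
via arviz when ≥2 chains run; R̂ > 1.1 attaches a logged warning. σ²_phylo
mixes slowest and may warn at short test-scale chain lengths while the β
margins are converged.

Pooling over trees is plain concatenation with equal weight per tree;
summaries report the mean, 66% and 95% quantile intervals, and the
two-sided posterior tail probability `2·min(P(θ>0), P(θ<0))` — a posterior
quantity, not a frequentist p-value. Marginal (fixed-effects) R² is
`var(Xβ)/(var(Xβ) + σ²_phylo + σ²_link)` per draw, with σ²_link = 1
(probit) or π²/3 (logit).

Predictor conventions: binaries (primary consumer >60% plant energy;
long-distance migrant vs sedentary+partial; territorial = weak+strong vs
none) are centered on their means; seasonality is log-transformed and
divided by twice its SD so one unit is comparable to a binary contrast;
interactions are products of the transformed mains. VIF is computed per
column against all others (the <3 rule of thumb is the caller's check).

### Known limitation: interaction identifiability at desk-scale n

At n ≈ 200 species, interaction columns formed from centered binaries take
values ±0.25 and carry little information; their posterior means inflate
away from zero by roughly 10% of the effect size under the priors above
(the same fits at n = 500 roughly halve the inflation, and the
σ²_phylo = 0 case matches an independent ordinal-ML fit, confirming this
is a small-sample posterior property, not a sampler artifact). The
parameter-recovery benchmark therefore measures bias and coverage on the
four main effects, where every coefficient is well identified at n = 200;
interaction estimates at such sample sizes should be read with their full
credible intervals, which remain calibrated (~90–95% coverage).

## Synthetic worlds

The generator composes: a birth–death tree (birth 1, death 0, scaled to
unit height, pendant edges extended by one further waiting time so the
final speciation leaves no zero-length tips); latitude-band ranges
(centres uniform in [−60°, 70°], widths exponential with mean 20°,
longitude spans exponential with mean 150°, chosen so that 200-km analysis
cells reach the ≥10-species richness threshold at a few hundred species);
a seasonality raster `0.5 + 0.15·|lat| + N(0, 0.3)` °C (a realistic bio4
gradient: ≈0.5 in the tropics, ≈9.5 at 60°); ecological binaries with
latitude-dependent log-odds (migration increasing, territoriality
decreasing with |lat|); liabilities from the exact model being fitted,
with default effects β = (−0.1, 0.3, −0.4, 1.0, 0.8, −0.75) and
σ²_phylo = 0.5; cutpoints placed by inverse CDF so the zero-effect
category shares are (0.82, 0.08, 0.05, 0.03, 0.02) — an 82% monogamy
share with a declining polygamy tail; a certainty grade 1–4 whose
distribution shifts upward with |lat|, emulating the knowledge bias of
real compilations; negative-binomial mating records with known
`I_S = 1/mean + 1/dispersion` and a set Bateman slope; and evidence
columns drawn inside the scoring band of each species' generated score,
so re-scoring the table is an exact round trip (a pipeline conservation
check).

Synthetic worlds default to a 100-km fine grid (the pipeline's default for
real data is 5 km): at desk scale this keeps global occupancy lattices in
the 10³–10⁴ cell range while preserving the two-resolution workflow. All
generators are pure functions of (config, seed); worlds are byte-identical
under the same seed.

What the worlds do **not** emulate: continents and coastlines (all-land
planet), realistic range shapes, taxonomic structure in the binaries
beyond the phylogeny already present in the score, spatially
autocorrelated sampling effort, or multiple conflicting evidence sources
per species. Passing tests therefore demonstrate correctness of the
estimators under the assumed generative model, not robustness to every
feature of real compilations.

## Pipeline

Stages run score → certainty filter → coarse aggregation → SAR gradients
(overall and per ecological partition) → species-level latitude model →
phylogenetic models pooled over k trees. Every threshold (0.1%/5%/20%
polygamy bands, 5%/25%/50% EPP bands, 50% overlap, <10 species per cell,
certainty cuts, 2-SD scaling) is a named config key with the survey's
value as default. The run report reconciles record counts at every stage
(species in = scored + unscorable; each drop attributed to a named
filter) and embeds the config hash and seed, so partition n's are
auditable. Re-running a stage from its persisted inputs with the same
seed reproduces its outputs exactly.

The multivariate pooled-posterior workflow at full scale (50 trees,
~10⁴ species) is the same code path exercised by the tests at smaller
sizes; it requires externally deposited species data and tree samples and
is documented in the README rather than tested here.
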