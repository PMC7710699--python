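# Methods

This note documents the models implemented in `trophlink`, their
assumptions, the defaults that matter, and the numerical choices made where
the design was genuinely open. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Gut-content statistics

The vacuity index is `VI = Nv/Ne × 100` over examined stomachs; reported
tables round VI to the nearest integer and the importance indices (%FO, %N,
%W) to one decimal, matching field-survey reporting practice. %FO is taken
over stomachs **with content** (NSC), %N over all prey individuals, %W over
total prey wet weight as recorded — partially digested weights are used as
measured, with no reconstruction from prey lengths. Contents of mouth,
oesophagus and intestine are excluded by schema: a `StomachRecord` only
ever holds stomach contents.

Levin's standardized niche breadth `Bj = (1/(n−1))(1/Σp² − 1)` uses the
weight proportions. The number of categories `n` defaults to the number of
categories present in the group's own table; a study-wide `n` can be fixed
via `levins_n` because the two conventions differ for subgroup tables and
published tables rarely say which was used. Size classes split at
L50 = 15 cm; a fish of exactly 15 cm goes to the **large** class (the
"< 15 / > 15" wording leaves the boundary unassigned; one consistent rule
is applied and documented here). Day/night vacuity cells with no stomach
for that period are reported as missing, never as zero.

An exact identity ties the cells together: pooled VI times pooled Ne equals
the sum of the period VIs times their Ne — the suite tests it.

## Isotope preprocessing

δ values follow `δ = (Rsample/Rstandard − 1)·10³` (VPDB for carbon,
atmospheric N₂ for nitrogen; the constants only matter when raw ratios are
ingested — the pipeline normally receives δ values). Lipid screening uses
the mass C:N ratio with a **strict** threshold: a sample is normalized only
when C:N > 3.5, by adding `Δδ¹³C = −3.32 + 0.99·C:N` to the raw δ¹³C. The
correction always starts from the preserved raw value, so it is idempotent,
and it never touches δ¹⁵N. Because the additive form crosses zero at
C:N = 3.32/0.99 ≈ 3.354 < 3.5, every sample actually corrected moves
upward (lipid-depleted ¹³C is restored). POM is never corrected with the
animal equation — carbonate bias in POM is handled at the bench by
acidification, which is outside computational scope. Correction is applied
per sample, not to group means. Single-sample taxa report a missing SD
rather than 0; the Bayesian modules then demand an explicit `sd_floor`.

## Bayesian trophic position

One-baseline model. Observations are normal within groups,

    baseline_i ~ Normal(mu_b, sigma_b)
    consumer_i ~ Normal(mu_b + (TP − TP_base)·TDF, sigma_c)

with priors TP ~ Uniform(1, 8) (wide enough for any marine food web),
TDF ~ Normal(3.15, 1.28) truncated positive, a weakly informative
Normal(0, 100) on the baseline mean, and half-normal(5 ‰) priors on the
observation SDs. The baseline is the 200–500 µm zooplankton fraction
treated as primary consumers (TP_base = 2).

Sampling uses the shared adaptive Metropolis-within-Gibbs sampler on a
**non-centered** parameterization: standardized group-mean offsets
`t = (mu − x̄)/sigma` together with log-SDs and the TDF. Two pathologies
motivated this. First, (TP, TDF) jointly sit on the curved ridge
`(TP−2)·TDF ≈ const`, which component-wise proposals cannot traverse.
Second, each (mu, log sigma) pair forms a funnel that mixes arbitrarily
slowly when the data are nearly constant. Non-centering removes both; TP is
derived per draw and its split-R̂/ESS are reported. Log-SDs are hard-bounded
in [log 1e−3, log 50] so that degenerate inputs (all observations
identical, where a half-normal prior would make the sigma posterior
improper at zero) remain well-posed; in that limit the TP posterior
collapses onto the closed-form value, which the suite verifies to within
Monte-Carlo error.

With the full TDF prior the TP posterior is wide (SD ≈ 1 level) and
right-skewed, since TP depends on 1/TDF; the posterior mean therefore sits
above the plug-in estimate. This is a property of propagating TDF
uncertainty, not a sampler artifact. `tp_compare(a, b)` estimates
Pr(TP_a > TP_b) by resampling draws; it is meaningful when both posteriors
share the same TDF treatment, and for between-group contrasts the TDF
should be fixed (its uncertainty is common to both groups and would cancel
in a joint model).

Default MCMC: 4 chains × 10 000 iterations, 5 000 burn-in, thinning 1,
proposal scales tuned per-coordinate toward 0.44 acceptance by
Robbins-Monro during burn-in only (so retained transitions are exactly
Markov). Non-convergence (split-R̂ ≥ 1.05) is flagged on the result, never
silent.

## Bayesian mixing model

Standard process-error SIMM on two isotopes: consumer observation i,
isotope j is `Normal(Σ_k p_k(μ_kj+λ_j), Σ_k p_k²(σ_kj²+τ_j²))`, optionally
plus a residual variance with half-normal(5) prior on its scale (off by
default). Sources enter as summary statistics (mean/SD), matching what a
published source table provides. The prior on `p` is Dirichlet(1,…,1),
configurable.

TDF defaults: nitrogen λ_N = 3.15 ± 1.28 ‰; carbon λ_C = 0 ± 1 ‰ as a
neutral default because no tissue-specific carbon TDF is established for
this consumer — both are explicit, mandatory configuration so every run
states its assumptions.

Sampling works on the isometric log-ratio transform of `p` (orthonormal
Helmert basis); the transform's Jacobian contributes `Σ log p_k` to the log
target, and every retained draw lies on the simplex to machine precision. A
deterministic grid-integration oracle (trapezoid in 1-D, midpoint lattice on
the 2-simplex) computes posterior means for ≤3-source problems; the suite
requires MCMC–oracle agreement within 0.02 and grid-halving stability
within 1e−3.

Identifiability caveat: sources that are isotopically near-collinear (for
example two myctophids 0.4 ‰ apart against a distant euphausiid) leave
individual contributions weakly identified, and single-dataset posterior
means can sit > 0.1 from the simulating truth while averaging out across
replicates; the recovery experiment therefore reports the across-replicate
bias together with component-wise CI coverage.

## Vertical habitat

Day extends from one hour after sunrise to one hour before sunset; night
from one hour after sunset to one hour before sunrise; anything else is
twilight and excluded from day/night statistics. CPUE is catch (or summed
specimen weight, g→kg) per trawl-hour scaled by 120/mouth-area, making
trawls with different gear geometry comparable; splitting a tow in half
preserves the mean, and the suite tests this. Depth strata are half-open
100-m bins tiling 10–1000 m (`[10,100), [100,200), …`), and a trawl is
assigned to the stratum containing its target-depth midpoint — gear without
opening/closing mechanisms samples during lowering and hoisting, and the
midpoint rule is the documented simplification. Mean CTD profiles are built
by linear interpolation of each cast onto a 1-m grid with truncated casts
contributing only over their observed range; the habitat envelope is the
min/max of mean temperature and oxygen over the occupied depth intervals.

## Synthetic survey generator

The generator encodes the study conditions the analysis assumes.
Temperature is a monotone PCHIP curve through anchors (28 °C mixed layer to
50 m, 15.7 °C at the 130 m thermocline base, 11.5 °C at 400 m, 7.0 °C at
700 m, 4.8 °C at 1000 m); the deep anchors are the generator's own
calibration chosen so the 400–1000 m occupancy spans roughly 5–12 °C, as
observed for this species at sea. Oxygen dips to ~2.4 ml l⁻¹ near 100, 300
and 450 m and recovers below 550 m; salinity has its maximum inside the
thermocline; fluorescence peaks at the upper thermocline. Gaussian noise
(0.15 °C, 0.05 ml l⁻¹ by default) is added per cast.

Isotope samples are independent normals per axis per taxon: only marginal
mean ± SD are available for the field populations, so no covariance is
imposed. Stomachs are empty with probability 0.61; non-empty stomachs hold
1 + Poisson(0.35) items with multinomial categories (myctophid-dominated)
and lognormal per-category weights whose means follow the weight-to-count
ratios of the field diet table. Catches are Poisson with mean proportional
to stratum weight × tow duration (the simplest count model consistent with
a relative abundance index; the observed CPUE dispersion of real surveys is
not targeted), with abundance modes at 700–900 m (day) and 600–700 m
(night) and mean length offsets placing larger fish below 500 m, more
strongly by day. Specimen weights follow TW = 0.0019·SL^3.1 with lognormal
scatter, giving ~10 g fish at maturity length.

What the generator does **not** emulate: spatial (lat/lon) abundance
structure, acoustic backscatter, covariance between isotopes, gear
selectivity, and overdispersed catches (a negative-binomial knob exists in
design but Poisson is the default). Passing tests therefore demonstrate
correctness of the estimators under these idealized conditions, not field
realism.

Seeding: one global seed expands into fixed-offset child streams per
component (CTD, isotopes, stomachs, trawls, stations), so adding a
generator never perturbs existing streams and identical (specs, seed) give
identical surveys across platforms.

## Problem sizes and runtime choices

The validation experiments use sizes chosen to make their statistical
checks sharp while keeping a full run interactive on a laptop: 3 two-source
oracle problems at the default 4 × 10 000 sampler settings; 30 mixing
recovery replicates (n = 50 consumers, 2 × 5 000 iterations each); 50 TP
recovery replicates (n = 30 per group, 2 × 3 000); 3 degenerate TP triples
(2 × 4 000). The synthetic survey uses 6 stations, ~40 trawls, 197 examined
stomachs and each taxon's field sample size for isotopes.

## Known limitations

- One baseline and one consumer group per TP fit; no two-baseline
  (pelagic/benthic) model and no joint ontogenetic model.
- Mixing model has no concentration dependence, no hierarchical individual
  effects, and no informative priors from gut contents.
- The printed trophic positions of published tables cannot generally be
  reproduced from the tables alone (the exact baseline fraction's δ¹⁵N is
  usually not printed separately); the package treats such values as
  consistency notes, not targets — the deterministic group-mean TP for the
  small class works out to 4.0 with the defaults.
- Levin's Bj printed in published diet tables is typically irreproducible
  from rounded %W columns; both `n` conventions are exposed instead.
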