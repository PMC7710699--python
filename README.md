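# trophlink

Trophic ecology and vertical-habitat analysis for deep-sea micronekton
surveys, built around the viperfish (*Chauliodus sloani*) — an abundant
mesopelagic micronektivore — and the kind of multidisciplinary survey used
to study it: midwater trawls, stomach contents, bulk carbon/nitrogen stable
isotopes, and CTD hydrography. It is aimed at fish and ecosystem ecologists
who want the full chain — dietary indices, isotope preprocessing, Bayesian
trophic inference, and depth-stratified abundance — as tested, seeded,
reusable code rather than one-off scripts.

## What it computes

**Gut contents.** Vacuity index `VI = Nv/Ne × 100`; prey importance as
frequency of occurrence (%FO), numerical abundance (%N) and weight
percentage (%W); and Levin's standardized niche breadth

    Bj = 1/(n−1) · (1/Σ p_i² − 1)

on the weight proportions `p_i` of `n` prey categories (0 = single-prey
diet, 1 = uniform use), with size classes split at the length at maturity
(L50 = 15 cm).

**Isotope preprocessing.** δ notation `δX = (Rsample/Rstandard − 1)·10³`;
lipid normalization of δ¹³C for samples with mass C:N strictly above 3.5
via the aquatic-animal relation `Δδ¹³C = −3.32 + 0.99·C:N`; per-taxon
mean ± SD source summaries and a biplot-ready table.

**Trophic position.** `TP = (δ¹⁵N_consumer − δ¹⁵N_baseline)/TDF + TP_baseline`
with 200–500 µm zooplankton as the TP-2 baseline and a trophic
discrimination factor of 3.15 ± 1.28 ‰ treated as uncertain in a one-baseline
Bayesian model sampled by adaptive Metropolis-within-Gibbs (non-centered
parameterization; split-R̂ and ESS always reported).

**Diet mixing.** A two-isotope Bayesian stable-isotope mixing model in the
standard process-error form: consumer observation i on isotope j is
`Normal(Σ_k p_k(μ_kj+λ_j), Σ_k p_k²(σ_kj²+τ_j²))` with a Dirichlet prior on
the contribution vector `p`, sampled on the isometric log-ratio transform.
A deterministic grid-integration oracle validates the sampler on ≤3-source
problems.

**Vertical habitat.** Day/night classification (±1 h around sunrise/sunset,
twilight discarded), CPUE standardized to catch·h⁻¹ for a 120 m² net mouth,
100-m depth-stratum abundance and size tables, and temperature/oxygen
habitat envelopes from mean CTD profiles.

**Synthetic surveys.** A seeded generator reproduces the statistical
structure this analysis assumes — 28 °C mixed layer to ~50 m, thermocline
to 130 m with a 12.3 °C drop, oxygen minima near 100/300/450 m, viperfish
abundance peaking at 700–900 m by day and 600–700 m at night, myctophid-
dominated stomachs with 61 % vacuity, and per-taxon isotope distributions —
so every downstream stage is testable without any field data.

## Worked example

```python
from trophlink import (make_survey, stratify, habitat_envelope, diet_table,
                       lipid_screen_and_correct, fit_tp, TPModelSpec,
                       MCMCSettings, tp_point)
from trophlink.vertical_habitat import label_trawls, occupied_intervals

ds = make_survey(seed=1)              # fully linked synthetic survey
label_trawls(ds)

tables = diet_table(ds.stomachs, ds.specimens)
t = tables["pooled"]
print(t.summary.Ne, t.summary.NSC, round(t.VI_pooled), round(t.Bj, 2))
# 197 66 66 0.29   -> 197 stomachs examined, 66 with content, VI 66 %, Bj 0.29

cpue = stratify(ds)
env = habitat_envelope(occupied_intervals(cpue), ds.ctd)
print(round(env.temp_min, 1), round(env.temp_max, 1))
# 4.7 11.5   -> occupied 400-1000 m water spans 4.7-11.5 degC

corr = [lipid_screen_and_correct(s) for s in ds.isotopes]
baseline = [s.d15N for s in corr if s.taxon == "Zooplankton"]
small = [s.d15N for s in corr if s.group == "consumer-small"]
post = fit_tp(TPModelSpec(consumer_d15N=small, baseline_d15N=baseline),
              MCMCSettings(seed=42))
print(f"{post.mean:.2f} +/- {post.sd:.2f}")
# 4.62 +/- 1.13  -> small-class trophic position; the width reflects the
#                   3.15 +/- 1.28 permil TDF prior (the deterministic
#                   group-mean estimate is 4.01)
```

The same stages run from the shell: `trophlink synth|diet|isotopes|tp|mix|
habitat|run-all|report` (see `trophlink --help`).

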