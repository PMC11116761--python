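# sociodep

Social-unit detection and spatio-temporal depredation analysis from
photo-identification data.

Longline fisheries create feeding opportunities for marine top
predators: killer whales (*Orcinus orca*) take hooked fish during
hauling ("depredation").  In small, individually catalogued populations
this behaviour is organised by *social units* — sets of individuals with
strong long-term associations — and units may differ widely in how
often, and over how large an area, they depredate.  `sociodep` is a
pipeline for quantifying that heterogeneity from photo-ID records
collected from shore and from fishing vessels:

1. **Sightings** — chain photo logs into sightings (shore: <1 h photo
   gaps within a bay; vessel: one longline-set haul), band photographic
   effort, and apply restriction filters (individual tenure ≥ 6 years,
   last seen after 2019; ≥ 42 photographs per sighting).
2. **Association network** — Simple Ratio Index under the gambit of the
   group, SRI = x/(x + y_i + y_j + y_AB); data-stream permutation test
   for preferred association (day-constrained 2×2 checkerboard swaps
   preserving group sizes and individual sighting frequencies); Mantel
   test between platforms; social differentiation S and estimation power
   r by beta-binomial maximum likelihood.
3. **Social units** — Leiden optimisation of the Constant Potts Model,
   Q = Σ_c [w_c − γ·n_c(n_c−1)/2], with a stability-plateau scan for
   the resolution γ.
4. **Spatial range** — per-unit minimum convex polygons, 0.1° grid-cell
   occupancy and kernel utilisation distributions (UD50/UD95) of
   depredation sightings, as shares of the pooled fishing area, with
   annual and cumulative expansion curves.
5. **Occurrence model** — binomial-logit GLMM of unit presence at
   depredation events, logit P = Xβ + Zu (year + month + unit fixed,
   photographic-effort random intercept; 12-h same-vessel exclusion),
   fitted by Laplace/adaptive Gauss–Hermite maximum likelihood, selected
   by AICc, validated by simulated scaled residuals, and summarised as
   estimated marginal means with Holm-adjusted pairwise contrasts.
6. **Synthetic data** — a generator with planted units, occurrence
   probabilities, spatial ranges and effort-driven detection, so every
   stage is verifiable by parameter recovery without any external data.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

```python
import sociodep as sd

ds, truth = sd.generate(n_vessel_sightings=600, n_shore_sightings=80, seed=1)
res = sd.restrict_dataset(ds, min_years=6, min_last_year=2019,
                          min_photos_per_sighting=42)
print(f"{len(res)} sightings, {len(res.individuals)} individuals "
      f"({res.counts_by_platform()})")

am = sd.compute_sri(res, "sighting")
perm = sd.permutation_test(res, "cv_sri", n_permutations=1000, seed=1)
print(f"CV of SRI: observed {perm.observed:.2f}, "
      f"mean permuted {perm.mean_permuted:.2f}, p = {perm.p_value:.3f}")

part = sd.detect_units(am, gamma=0.28, n_restarts=20, seed=1)
print(f"{part.n_units} social units, stability {part.stability:.2f}, "
      f"ARI vs truth = {sd.recovery_report(truth, part)['ari']:.2f}")

records = sd.build_occurrence_table(res, part, dedup_hours=12)
fit = sd.fit_glmm(records)
print(f"GLMM: K = {fit.K}, logLik = {fit.loglik:.2f}, AICc = {fit.aicc:.2f}")

emm = sd.emmeans_units(fit).emmeans
print(f"unit occurrence probabilities: {emm.prob.min():.3f} "
      f"to {emm.prob.max():.3f}")
```

prints

```
294 sightings, 79 individuals ({'shore': 30, 'vessel': 264})
CV of SRI: observed 1.91, mean permuted 1.86, p = 0.000
17 social units, stability 1.00, ARI vs truth = 1.00
GLMM: K = 46, logLik = -1591.69, AICc = 3276.36
unit occurrence probabilities: 0.041 to 0.269
```

The observed coefficient of variation of the SRI exceeds every permuted
value (p < 0.001): individuals associate preferentially, not at random.
Leiden-CPM at γ = 0.28 recovers all 17 planted units exactly (adjusted
Rand index 1.0 across 20 restarts).  The full occurrence model carries
K = 46 parameters (intercept + 17 year + 11 month + 16 unit contrasts +
1 variance), and the marginal unit probabilities span roughly 4%–27%:
some units attend a quarter of all depredation events, others almost
none.

A `sociodep` console script exposes the same stages
(`sociodep simulate|ingest|filter|network|units|spatial|occurrence`);
run any subcommand with `--help`.

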