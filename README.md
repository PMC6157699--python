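# fursealpop

Population genomics of the New Zealand fur seal (*Arctocephalus forsteri*),
a marine mammal that was hunted close to extinction — first by Polynesian
settlers, then by the 19th-century European sealing industry — and has since
rapidly recolonized its former range from a handful of refugium colonies.
Recolonizing, highly vagile species like this leave only subtle genetic
structure, which makes every routine analysis a small-signal problem.

`fursealpop` implements the full analysis chain for SNP datasets of this
kind, end to end and fully seeded:

* **QC** — PLINK-style filter chain (individual/locus missingness, MAF,
  per-population Hardy–Weinberg exact test, windowed LD pruning) on PED/MAP
  or VCF input.
* **Diversity & structure** — Ho/He/FIS with permutation tests,
  pairwise Weir–Cockerham θ and Slatkin's linearized FST, Mantel
  isolation-by-distance, three-level AMOVA, marker-set concordance, PCA.
* **Demographic inference** — coalescent ABC comparing a *two-decline*
  history (Polynesian decline, European collapse to a ~100-breeder
  refugium, recolonization, North/South divergence) against a constant-size
  null, with DIYABC-style summary statistics, rejection + direct/logistic
  scenario choice, local-linear posterior adjustment, and type I/II error
  estimation from pseudo-observed datasets.
* **Outlier scan** — FDIST-style FST-vs-He scan against a coalescent
  island-model null with BH q-values and a 0.99 CI envelope.
* **Assignment** — leave-one-out home-likelihood assignment of individuals
  to colonies or clusters, with Monte-Carlo home p-values.
* **Synthetic studies** — a seeded eight-colony generator emulating the
  survey design (167 pups, He ≈ 0.26, pairwise FST 0.003–0.022, an admixed
  colony pair, weak isolation by distance), so everything runs without any
  data download.

The core model: for the two-decline history, backward in time the two
descendant demes (sizes N_N, N_S) merge at t_post-seal generations into a
refugium of size N_ref, which is resized to N_hist at t_Europeans and to
N_pre at t_Polynesian (priors: N_N, N_S ~ U[10², 10⁴]; N_ref ~
U[10², 2.5·10³]; N_hist, N_pre ~ U[10³, 5·10⁶]; t_Polynesian ~ U[100, 200];
t_Europeans ~ U[25, 50]; t_post-seal ~ U[1, 25] generations, with
t_Europeans > t_post-seal and N_pre > N_N, N_S). Unlinked SNPs carry a
single mutation placed uniformly on each genealogy, ascertained at pooled
MAF ≥ 0.05. Estimation is likelihood-free: datasets are reduced to eight
summaries (per-sample gene diversities over polymorphic/all loci; pairwise
Weir–Cockerham FST and Nei's 1972 distance, "nonnull" and all-loci means)
and the simulations nearest the observation are retained.

See `docs/methods.md` for the full model description, numerical choices and
known limitations.

## Worked example

Generate a synthetic eight-colony study, run QC, and look at structure:

```python
from fursealpop.synth import SynthConfig, generate_study
from fursealpop.genotypes import QCConfig, apply_qc
from fursealpop.popstats import diversity_table, pairwise_fst_matrix, ibd_test

g, pops, truth = generate_study(SynthConfig(n_loci=2000, seed=1))
filtered, report = apply_qc(g, pops, QCConfig())
print(report.to_frame().to_string(index=False))
```

```
                  name  n_individuals_removed  n_loci_removed  n_individuals_after  n_loci_after
individual_missingness                      0               0                  167          2000
     locus_missingness                      0               0                  167          2000
                   maf                      0             101                  167          1899
                   hwe                      0               0                  167          1899
                    ld                      0               0                  167          1899
```

101 loci fall below 5% minor-allele frequency; nothing else is flagged in
six or more colonies. Diversity is flat across colonies, as in the real
survey:

```python
div = diversity_table(filtered, pops)
print(div[div.level == "colony"].round(3).to_string(index=False))
```

```
 level group  n    Ho    He    FIS  FIS_p
colony   OBI 28 0.272 0.270 -0.007    NaN
colony    CF 23 0.271 0.272  0.001    NaN
colony    WP 21 0.270 0.272  0.004    NaN
colony    CP 14 0.275 0.274 -0.005    NaN
colony    OP 15 0.272 0.273  0.002    NaN
colony    HB 22 0.276 0.276 -0.001    NaN
colony    VB 22 0.275 0.275  0.001    NaN
colony    NP 22 0.273 0.273  0.002    NaN
```

Slatkin-linearized FST (×1000) shows the two clusters with the admixed
CP/OP pair in between — differentiation is real but tiny (max ~0.02):

```python
theta, lin, _ = pairwise_fst_matrix(filtered, pops)
print((lin * 1000).round(1).to_string())
m = ibd_test(filtered, pops, n_perm=999, seed=7)
print(f"IBD Mantel r = {m.r:.3f}, p = {m.p:.3f}")
```

```
      OBI    CF    WP    CP   OP    HB    VB    NP
OBI   0.0   3.7   3.1   6.0  7.8  18.2  19.6  17.7
CF    3.7   0.0   5.3   7.1  8.2  18.7  19.4  18.5
WP    3.1   5.3   0.0   6.0  7.5  17.8  18.0  15.8
CP    6.0   7.1   6.0   0.0  2.8   6.8  10.0   9.1
OP    7.8   8.2   7.5   2.8  0.0   6.1   6.5   7.4
HB   18.2  18.7  17.8   6.8  6.1   0.0   2.5   2.8
VB   19.6  19.4  18.0  10.0  6.5   2.5   0.0   5.0
NP   17.7  18.5  15.8   9.1  7.4   2.8   5.0   0.0
```

```
IBD Mantel r = 0.348, p = 0.065
```

Demographic inference follows the statsmodels Model/Results convention:
build a `DemographicABC` from observed summary statistics (or directly
`from_genotypes`), call `fit()`, and read scenario probabilities and
parameter posteriors off the results object. Here the "observed" dataset is
simulated under the two-decline history at its published posterior-mode
parameters (refugium of 110, divergence ~20 generations ago):

```python
from fursealpop.abc import (DemographicABC, TWO_DECLINE_POSTERIOR_MODES,
                            summary_stats_from_derived)
from fursealpop.coalsim import (SimConfig, ScenarioParams,
                                build_two_decline_scenario, simulate_derived)

sc = build_two_decline_scenario(ScenarioParams(**TWO_DECLINE_POSTERIOR_MODES), 101, 66)
obs = summary_stats_from_derived(simulate_derived(sc, SimConfig(1000, seed=3)), 101, 66)
model = DemographicABC(obs, (101, 66), sim_config=SimConfig(n_loci=1000))
res = model.fit(n_sims_per_scenario=5000, tolerance=0.01, seed=42)
print(res.summary())
```

```
Demographic scenario comparison (ABC)
======================================================
retained: 100 of 10000 simulations (tolerance 0.01)

Scenario posterior probabilities:
             direct  logistic
two_decline    0.95    0.9491
null           0.05    0.0509

selected scenario: two_decline

Parameter posterior (mode, 5%, 95%):
                          mode         q05          q95
parameter
Ne_NZ_S               2930.163     672.220     8790.922
Ne_NZ_N                463.579      92.655     1598.621
Ne_refugium            179.285     113.500      305.688
Ne_historical_NZ    790867.616   72389.180  3511179.181
Ne_pre_historical  4219784.470  489661.846  5663451.329
t_Polynesian           114.383     101.325      188.839
t_Europeans             44.160      30.278       47.458
t_post_seal            14.434       3.829       20.039
```

The bottleneck is decisively preferred (scenario probability ~0.95 both
ways), and the posterior recovers the generating regime: a refugium of
order 10², divergence ~15-20 generations ago, and historical sizes orders
of magnitude larger — the 10-fold and 250-fold declines the real analysis
reported. Single-dataset probabilities fluctuate with the observation's
sampling noise; the reliability of the choice is what
`ABCResults.scenario_confidence()` (type I/II errors from pseudo-observed
datasets) quantifies.

A command-line interface wraps each stage (`fursealpop qc / stats / ibd /
amova / abc / outliers / assign / simulate-study / run`); `fursealpop run
--config pipeline.yaml` executes the whole chain with per-stage seeds and
writes TSV/JSON reports plus a manifest.

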