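# ncmkit

Neutral community model (NCM) analysis for microbiome count tables, with a
neutral-assembly simulator for validation.

Who it is for: microbial ecologists asking how much of a community's assembly —
an infant gut, a tongue swab, any set of local communities sampled from a
shared species pool — is explained by neutral dispersal and drift rather than
local selection, working from standard ASV/OTU count tables.

## The model

Sloan's neutral community model treats each local community as N individuals
undergoing random death and replacement, where a death is replaced by an
immigrant from the regional species pool with probability m (the migration
rate) or by local reproduction otherwise. At stationarity the relative
abundance x of a taxon with pool abundance p is Beta-distributed,

    x ~ Beta(N m p, N m (1 − p)),

so the probability of observing the taxon in a sample with detection limit d
(its predicted occurrence frequency, or prevalence) is

    P(detect) = 1 − I_d(N m p, N m (1 − p)),

with I the regularised incomplete beta function. `ncmkit`:

- estimates the regional species pool by pooling samples and fits the single
  free parameter m by bounded nonlinear least squares against observed
  occurrence frequencies (`NeutralCommunityModel`, a scikit-learn-style
  estimator; `fit_ncm` for the table-level wrapper);
- classifies each taxon as **above** / **within** / **below** a
  Wilson-score-based band around its predicted prevalence — taxa above are
  candidates for positive local selection, taxa below for negative selection;
- bootstraps the whole fit over one-sample-per-subject permutations of
  longitudinal cohorts and derives consistency labels
  (neutral / above / below / variable) per taxon;
- refits per country × age-bin partition with bootstrap CIs on m, and compares
  classification sets across partitions (Jaccard distance + principal
  coordinates);
- quantifies mother–infant dyad sharing: source attribution of infant taxa,
  shared vs non-shared abundance contrasts, sharing rate vs prevalence
  stratified by maternal abundance, mother–mother village overlap;
- simulates neutral (Dirichlet stationary or individual-based Hubbell
  dynamics) and selective communities, longitudinal cohorts, and dyads with a
  tunable maternal coupling α — the ground truth behind every test.

## Worked example

```python
import ncmkit as nk

meta = nk.MetacommunityConfig(n_taxa=300, sigma=2.0, seed=11)
assembly = nk.AssemblyConfig(N=10_000, m=0.2)
design = nk.CohortSimConfig(n_subjects=40, samples_per_subject=3,
                            read_depth=5000, seed=12)
cohort, truth = nk.simulate_cohort(meta, assembly, design)

pool = nk.build_source_pool(cohort)        # regional species pool
freq = nk.occurrence_frequency(cohort)     # per-taxon prevalence
fit = nk.fit_ncm(pool, freq, N=10_000.0, detection="reads", depth=5000)
print(f"true m = {truth.m_true}, fitted m = {fit.params.m:.3f}, RMSE = {fit.rmse:.3f}")

summary = nk.run_bootstrap(
    cohort, nk.BootstrapConfig(n_permutations=200, seed=0),
    N=10_000.0, detection="reads",
)
fr = summary.label_fractions()
print(f"bootstrap RMSE = {summary.rmse_mean:.3f} +/- {summary.rmse_sd:.3f}")
print(f"consistency labels: {fr['neutral']:.1%} neutral, "
      f"{fr['above']:.1%} above, {fr['below']:.1%} below, {fr['variable']:.1%} variable")
```

prints

```
true m = 0.2, fitted m = 0.201, RMSE = 0.025
bootstrap RMSE = 0.044 +/- 0.002
consistency labels: 94.0% neutral, 0.0% above, 0.0% below, 6.0% variable
```

The fitted migration rate recovers the simulator's truth (0.201 vs 0.2); the
RMSE between observed and predicted prevalences is the goodness-of-fit
statistic (0 = perfect fit), reported as mean ± sd over the one-per-subject
bootstrap; and on this fully neutral cohort 94% of taxa are consistently
classified neutral, with none consistently above or below the prediction band.

The same pipeline runs from the shell on TSV/BIOM + CSV inputs:

```sh
ncmkit simulate --out-dir sim --seed 3 --n-subjects 40 --samples-per-subject 3
ncmkit fit       --counts sim/counts.tsv --metadata sim/metadata.csv --out-dir fit
ncmkit bootstrap --counts sim/counts.tsv --metadata sim/metadata.csv \
                 --out-dir boot --n-permutations 1000 --seed 0
ncmkit partitions --counts ... --metadata ... --bin-edges 1,4,7,10,13 --out-dir parts
ncmkit dyads      --counts ... --metadata ... --body-site stool --out-dir dyads
```

All outputs are TSV with `#`-prefixed header lines recording the package
version, seed, and a configuration hash; identical inputs and options give
byte-identical outputs.

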