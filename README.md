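# thermsds

Phylogenetic comparative analysis of reptile **sex-determination systems**
(SDS) and **breeding-season climate**.

Reptiles determine offspring sex either genotypically (GSD) or by egg
incubation temperature (TSD). Classic theory predicts that fluctuating or
cold climates should select against TSD, because temperature-dependent sex
ratios become erratic when the thermal environment is unstable. Testing
this across many species requires mapping decades of monthly gridded
climate onto each species' geographic range, restricting attention to the
months the species actually breeds in, and then comparing TSD and GSD
lineages while accounting for their shared phylogenetic history — closely
related species are not independent data points.

`thermsds` implements that pipeline end to end for anyone doing
phylogenetic comparative work on trait–environment associations:

* **Breeding-window climate statistics** — for each species, the climate
  grid cells of its range are averaged into a `(year x 12)` series and
  summarised over the breeding window *w*: the ambient value
  `median{x_{y,m} : all years y, m in w}`, the *seasonality*
  `mean_y Var_m(x_{y,m})` (within-year spread across the window's months),
  and the *interannual fluctuation* `mean_m Var_y(x_{y,m})` (across-year
  spread of each window month). Windows may wrap the year boundary; an
  unknown season end closes in December. A consecutive-month
  randomisation null compares each observed window with all 12 same-length
  placements.
* **Phylogenetic GLS** with Ornstein–Uhlenbeck residual correlation
  `corr(i,j) = exp(-alpha * d_ij)` (patristic distance `d_ij`, reversion
  rate `alpha` profiled by maximum likelihood) or Pagel's lambda structure;
  optional range-size variance weights `w_i = log10(area_i)/min_j
  log10(area_j)` so species with huge, climatically heterogeneous ranges
  carry less weight. Likelihood-ratio contrasts for group-specific
  residual variances, a factor x covariate ANCOVA, Pagel's lambda signal
  (`lambda` up to 1.1), and a Firth-penalised phylogenetic logistic
  regression for binary responses.
* **d-separation path analysis** — candidate causal DAGs over SDS,
  ambient temperature and breeding-season length; each DAG's basis set of
  conditional-independence claims is tested by phylogenetic regression,
  combined into Fisher's `C = -2 * sum(ln p_i)` (chi-square, `2k` df), ranked
  by `CICc = C + 2qn/(n-1-q)`, and models within 2 CICc of the best are
  averaged (`full` averaging: a model lacking an edge contributes zero).
* **A synthetic-study generator** — birth–death phylogenies, a one-way Mk
  process conditioned on an exact number of GSD→TSD transitions (11 by
  default), seasonal latitudinal climate grids, phylogenetically conserved
  range blobs with a configurable TSD warm shift, breeding windows placed
  on the warmest / stablest / random months, and OU life-history traits —
  so every stage of the pipeline runs and is testable fully offline.

## Worked example

```python
import pandas as pd
from thermsds import (SimConfig, simulate_study, assemble_records,
                      fit_sds_model, phylosig_lambda, builtin_hypotheses,
                      fit_dag, rank_and_weight, average_paths)

study = simulate_study(SimConfig(seed=7))     # 213 species, 30 years of climate
records, _ = assemble_records(study.traits, study.tree, study.grid_temp,
                              study.grid_precip, study.masks)

fit = fit_sds_model(records, study.tree, "median_breeding_temperature")
lam = phylosig_lambda(records.loc[study.tree.tip_labels, "sds"]
                      .astype(float).values, study.tree)

data = pd.DataFrame({"sds": records["sds"],
                     "ambient_temperature": records["median_breeding_temperature"],
                     "breeding_length": records["window_length"]}
                    ).loc[study.tree.tip_labels]
fits = rank_and_weight([fit_dag(d, data, study.tree)
                        for d in builtin_hypotheses("ABCD")])

print(f"n = {fit.n} species, {int(records['sds'].sum())} TSD / "
      f"{int((1 - records['sds']).sum())} GSD, "
      f"{study.true_params['n_transitions']} GSD->TSD transitions")
print(f"breeding temperature ~ SDS: slope = {fit.params['sds']:.2f} degC, "
      f"alpha = {fit.corr_param:.1f}, P = {fit.pvalues['sds']:.4f}")
print(f"phylogenetic signal of SDS: lambda = {lam.lambda_hat:.3f}, "
      f"P = {lam.pvalue:.2e}")
for f in fits:
    print(f"model {f.dag.name}: C = {f.C:.2f}, P = {f.C_pvalue:.3f}, "
          f"CICc = {f.CICc:.2f}, weight = {f.weight:.2f}, retained = {f.retained}")
for (u, v), c in sorted(average_paths([f for f in fits if f.retained]).items()):
    print(f"averaged path {u} -> {v}: {c:+.3f}")
```

This prints:

```
n = 213 species, 40 TSD / 173 GSD, 11 GSD->TSD transitions
breeding temperature ~ SDS: slope = 3.30 degC, alpha = 8.7, P = 0.0001
phylogenetic signal of SDS: lambda = 1.000, P = 5.10e-66
model D: C = 3.72, P = 0.156, CICc = 7.78, weight = 0.74, retained = True
model A: C = 5.88, P = 0.053, CICc = 9.94, weight = 0.25, retained = False
model B: C = 12.05, P = 0.002, CICc = 16.11, weight = 0.01, retained = False
model C: C = 43.22, P = 0.000, CICc = 47.28, weight = 0.00, retained = False
averaged path ambient_temperature -> breeding_length: -0.394
averaged path breeding_length -> sds: +0.008
```

Reading this: TSD species breed at temperatures ~3.3 °C warmer than GSD
species (the generator's configured effect is 3 °C), the OU rate
`alpha = 8.7` says residual correlation decays quickly along the tree, and
the binary SDS trait itself is maximally conserved (`lambda = 1`). Among
the four causal orderings, the chain models that let temperature and SDS
drive breeding-season length fit the data (models D and A have the
smallest Fisher's C); model C — temperature causing SDS transitions — is
firmly rejected.

There is also a command-line interface mirroring the library:

```sh
thermsds simulate --out study/ --seed 7
thermsds extract  --tree study/tree.nwk --traits study/traits.csv \
                  --climate study/ --ranges study/ranges.csv --out records.csv
thermsds fit      --records records.csv --tree study/tree.nwk --out fits.json
thermsds pathfit  --records records.csv --tree study/tree.nwk --out paths.json
```

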