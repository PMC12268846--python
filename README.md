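# stcarlocal

Bayesian spatio-temporal **localized** conditional autoregressive (CAR)
disease mapping for small-area count panels — the model family used to map
province-level stunting risk in Indonesia and, more generally, any
area-by-time table of case counts with a known population at risk.

Standard CAR smoothing assumes neighbouring areas have similar risk. That
assumption blurs real discontinuities: a province can sit next to one with
several times its risk. The localized model keeps the smooth field but adds
a piecewise-constant cluster component so adjacent units may belong to
different risk groups:

    y_ij ~ Poisson(E_ij * theta_ij)
    log theta_ij = x_ij' beta + u_ij + lambda_{Z_ij}

* `E_ij` — expected counts: overall rate times local population at risk
  (`sum E = sum y` by construction), so `theta_ij` is the relative risk.
* `beta` — covariate effects (e.g. log-risk per percentage point of
  poverty), Gaussian prior.
* `u_ij` — intrinsic CAR (ICAR) field with AR(1) temporal evolution:
  `u_1 ~ N(0, tau2 Q^-)`, `u_j | u_{j-1} ~ N(rhoT u_{j-1}, tau2 Q^-)`,
  `Q = D - W`.
* `Z_ij in {1..G}` — cluster labels with ordered intercepts
  `lambda_1 < ... < lambda_G` (uniform order prior) and a penalty process
  shrinking labels towards the middle group `G*` and towards temporal
  persistence, with strength `delta ~ U(1, 100)`.

Estimation is Metropolis-within-Gibbs MCMC (with additional
likelihood-preserving interweaving moves that make the latent
decomposition mix well; see `docs/methods.md`). Model comparison sweeps a
grid of cluster counts G, variance hyperpriors and covariate subsets and
ranks fits by DIC and WAIC. Outputs are posterior relative-risk surfaces,
cluster ("localized structure") maps, exceedance probabilities
Pr(theta > 1), area rankings and CSV/GeoJSON exports.

## Worked example

Simulate a 36-area, 3-year panel from the model itself (two covariates
with effects 0.02 and 0.04 per raw unit, three risk groups at log-risk
-1/0/+1, field variance 0.1, temporal autocorrelation 0.5), then fit it:

```python
import stcarlocal as sc

graph = sc.make_lattice_graph(6, 6)
frame, truth = sc.simulate_dataset(graph, J=3, seed=11)

cfg = sc.ModelConfig(G=3, n_iter=22_000, burnin=2_000, thin=10, seed=12)
samples = sc.run_mcmc(frame, graph, cfg)
summ = sc.summarize_fit(samples, frame)
surface = sc.posterior_risk(samples)
```

This prints (via the obvious `print` calls):

```
DIC  = 1409.32  (pD = 124.2)
WAIC = 1473.45 (pWAIC = 116.3)
cluster sizes: [36, 56, 16]  (truth: [36, 56, 16])
beta_X1  median  0.0194  95% CI ( 0.0159,  0.0232)  ESS 1685
beta_X2  median  0.0449  95% CI ( 0.0371,  0.0528)  ESS 1052
tau2     median  0.0853  95% CI ( 0.0646,  0.1146)  ESS 1824
rhoT     median  0.6049  95% CI ( 0.3763,  0.8315)  ESS 1546
delta    median  1.0349  95% CI ( 1.0012,  1.1687)  ESS 1473
top 3 areas by RR in t2: [('a031', 2.038), ('a025', 1.931), ('a003', 1.848)]
```

Reading it: the fitted cluster sizes reproduce the planted grouping
exactly; both credible intervals cover the generating coefficients
(0.02, 0.04); the field variance and temporal autocorrelation are
recovered; and the ranking surfaces the highest-risk cells. DIC/WAIC are
comparative quantities — rerun with other `G` or covariate subsets (or use
`run_model_grid`) to rank specifications.

The package also ships the published province-level posterior estimates
for Indonesian stunting (2020-2022) as a small reference table:

```python
surface = sc.RiskSurface.from_table(sc.published_indonesia_stunting_risk())
sc.rank_areas(surface, "2022", k=3)
# [('Sulawesi Barat', 2.768), ('Nusa Tenggara Timur', 2.676),
#  ('Nusa Tenggara Barat', 2.221)]
```

## Command line

```bash
stcarlocal simulate --rows 6 --cols 6 --J 3 --G 3 --seed 1 --out sim/
stcarlocal screen sim/counts.csv --threshold 0.5
stcarlocal fit sim/counts.csv sim/adjacency.gal --G 3 --covariates X1,X2 --out fit/
stcarlocal grid sim/counts.csv sim/adjacency.gal --G 2,3,5 --covariates X1,X2 --out grid.csv
stcarlocal summarize sim/counts.csv sim/adjacency.gal --G 3 --top-k 3 --out surface/
```

Formats: counts as long CSV (`area,time,y,n,<covariates...>`), adjacency
as GAL spatial weights or 2-column edge list, outputs as CSV/JSON/GeoJSON.

## Layout

```
src/stcarlocal/
  dataio.py      panels, adjacency, expected counts, Spearman screening
  synthetic.py   model-structured simulation with ground truth
  model.py       the localized CAR sampler (Metropolis-within-Gibbs)
  selection.py   DIC/WAIC, ESS, Geweke, model grid
  mapping.py     risk surfaces, rankings, cluster tables, export
  validation.py  enumeration / prior-recovery / coverage studies
  datasets.py    published Indonesian province risk table
  cli.py         typer CLI
docs/methods.md  model, estimation and design notes
```
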