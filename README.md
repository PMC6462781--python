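# fermkit

Analysis of microbial fermentation time courses, for metabolic engineers and
microbial physiologists who characterise strains in batch culture — shake
flasks, microtiter plates or bioreactors — and want their raw analyte exports
turned into physiology, reproducibly, without spreadsheet templates.

`fermkit` parses raw quantification tables (HPLC concentration exports,
plate-reader OD matrices, or a canonical tidy format) into a hierarchical
schema — time point → analyte course → single trial → replicate trial →
experiment — extracts physiological features at each level, optionally
integrates measured rates with a stoichiometric model, and persists
everything to a single-file SQLite store for sharing and SQL queries.

## The science in brief

**Metadata.** Every measurement carries a flat, typeable identifier suitable
for instrument sample fields:

```
strain:MG1655|media:M9|strain__plasmid:pTrc99a|rep:2|time:4.5
```

describing the strain (wild type, knockouts, plasmids), the medium and its
formulation, the environment (labware, temperature, shaking speed), the
replicate index and the sample time in hours. Assembly groups measurements
into trials by this metadata alone.

**Feature ladder.**

- *Analyte*: numerical rates dX/dt (second-order finite differences on
  non-uniform grids) and growth-model fits — exponential
  X(t) = X₀e^{μt}, a generalised logistic
  X(t) = A / (1 + exp(4μ_max(λ − t)/A + 2)), and a 5-parameter Richards
  curve, all in the biological parameterisation (asymptote A, maximum
  specific growth rate μ_max in 1/h, lag λ in h).
- *Trial*: product yield Y_P/S = ΔP/(−ΔS), biomass normalisation, and the
  specific productivity q = (dP/dt)/X in mmol/gDW/h — the quantity that
  constrains genome-scale metabolic models (for biomass itself, q = μ).
- *Replicate*: missing-data-aware mean and sample standard deviation
  (n−1 denominator, NaN observations excluded pointwise), plus
  leave-one-out outlier flagging with a tunable aggressiveness threshold.
- *Experiment*: automatic blank (cell-free background) assignment and
  subtraction, and slicing a fermentation into stages (e.g. growth vs
  production phase) so yields can be computed per stage.

**Flux integration.** Measured specific exchange rates constrain a
stoichiometric model (reaction-table CSV or SBML); the steady state S·v = 0
is closed by linear programming, which estimates unmeasured exchanges —
typically CO₂ evolution — and supports a carbon recovery check
(C-mmol out / C-mmol in, with biomass converted at 24.6 g per C-mol).

## Worked example

The bundled worked example is a three-replicate OD course with ragged
missing values (times 0/2/4/6 h; replicate 2 missing at 2 h and 6 h,
replicate 3 missing at 6 h):

```python
import fermkit as fk

e = fk.assemble_experiment(fk.table1_fixture(), "demo")
stats = fk.replicate_statistics(e.replicates[0])["OD600"]
print(stats.mean)   # [0.5        0.75       1.03333333 1.2       ]
print(stats.std)    # [0.1        0.07071068 0.15275252        nan]
print(stats.n_obs)  # [3 2 3 1]
```

Means average whatever observations exist at each time; the standard
deviation at 6 h is undefined (`nan`) because only one replicate was still
measured there. Feature extraction on a synthetic fermentation:

```python
points, truth = fk.generate_experiment(fk.SyntheticConfig(seed=1))
e = fk.assemble_experiment(points, "synthetic")
s = e.replicates[0].singles[0]
fk.compute_yield(s.courses["product"], s.courses["glucose"]).endpoint_yield
# 0.4  (== the generator's ground-truth Y_PS)
fk.fit_growth_model(s.courses["OD600"], "gen_logistic").params
# {'A': 2.0, 'mu_max': 0.5, 'lam': 1.0}
```

And closing a carbon balance on the bundled toy network (glucose → 2
pyruvate; pyruvate → ethanol + CO₂), having measured glucose uptake 10 and
ethanol export 20 mmol/gDW/h:

```python
m = fk.toy_model_fixture()
fk.estimate_co2(m, {"EX_glc": -10.0, "EX_etoh": 20.0}, "EX_co2")  # 20.0
fk.carbon_recovery({"glc": (10, 6), "etoh": (20, 2), "co2": (20, 1)}, {"glc"}).recovery
# 1.0
```

## Command line

```bash
fermkit synthgen --seed 1 --out run.csv        # synthetic data + ground truth
fermkit features run.csv --store study.db      # pipeline + SQLite store
fermkit plot run.csv --outdir figs             # mean ± std per analyte/strain
fermkit db load --store study.db --label experiment --out export.csv
```

Exit codes: 0 success, 2 format error, 3 feature error, 4 store error.

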