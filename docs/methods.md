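# Methods

## Data model

The schema follows the logical structure of a fermentation study. A *time
point* is one quantification event (value + unit + full metadata). Time
points of one analyte in one vessel form an *analyte course* (strictly
increasing times in hours; values may be NaN). A *single trial* is one
independent fermentation volume and holds one course per analyte. Single
trials that agree on all metadata except the replicate index form a
*replicate trial*; replicate trials are grouped under an *experiment*
label, and one replicate trial may belong to several experiments
(many-to-many in the store).

Assembly is purely metadata-driven and deterministic: groups are ordered
lexicographically by serialized identifier, so shuffling the input stream
produces an identical experiment. Repeated observations of the same
(trial, analyte, time) are averaged with a warning — repeated HPLC
injections of one sample are routine, and rejecting them would force manual
curation upstream. Missing values travel through assembly untouched;
dropping them is the responsibility of each downstream feature, so that
replicate statistics can use every observation that exists at each time.

## Identifier grammar

The flat identifier is a `|`-separated list of `key:value` tokens. Keys are
case-insensitive (this includes media-component names, which are embedded
in keys); values preserve case and may not contain `|` or `:` — no escaping,
because the string must survive instrument sample-name fields. `strain`,
`media`, `environment__*`, `experiment`, `rep`, `time` and `analyte` are
scalar (duplicates with conflicting values are an error); `strain__knockout`
and `strain__plasmid` repeat and preserve order. A cell-free background
trial is marked either by the sentinel `strain:blank` or an explicit
`blank:true`. Serialization emits tokens in a fixed canonical order and
omits absent fields, so `parse ∘ serialize` is the identity; this canonical
string is also the storage key (see Persistence). Shorthand expansion
replaces a leading bare name by its registry entry and merges any further
inline tokens, inline winning on scalar conflicts.

## Feature computations

**Gradients.** Rates are second-order central differences on the
(generally non-uniform) grid of finite points, with first-order one-sided
differences at the ends — exact for affine data everywhere and for
quadratics at interior points. This is `numpy.gradient`'s scheme; the
implementation delegates to it.

**Growth models.** Three closed forms are fitted, all in the biological
parameterisation (asymptote `A`, maximum specific rate `mu_max`, lag `lam`):

- exponential `X = X0·exp(mu·t)`, solved exactly by OLS on log-values
  (requires positive values; a constant course yields mu = 0);
- generalised logistic `X = A / (1 + exp(4·mu_max/A·(lam − t) + 2))`;
- 5-parameter Richards
  `X = X0 + (A − X0)·[1 + nu·exp(1+nu)·exp((mu_max/A)·(1+nu)^(1+1/nu)·(lam − t))]^(−1/nu)`,
  whose shape parameter `nu > 0` moves the inflection point.

The sigmoid fits use bounded trust-region least squares with a fully
deterministic initialisation — `A₀ = max(y)`, `mu₀` = steepest
finite-difference chord, `lam₀` = chord midpoint − A₀/(2·mu₀), `nu₀ = 1`,
`X0₀ = min(y)` — and tight (1e−15) convergence tolerances, so refitting the
same data always returns identical parameters. Minimum point counts are 3
(exponential), 5 (logistic) and 6 (Richards). Non-convergence raises an
error carrying the last iterate.

**Trial features.** Yield uses the product's finite time grid; substrate is
interpolated linearly onto it (no extrapolation — points outside the other
course's span are dropped with a warning, since plate-reader and HPLC grids
rarely align). The cumulative yield is reported only where net consumption
exceeds 1e−9 (same units as the substrate), avoiding 0/0 early in the run.
Specific rates divide the analyte gradient by interpolated biomass and
convert g/L/h to mmol/gDW/h as q·1000/M when a molar mass M is supplied
(the input course is assumed to be a mass concentration in that case).

**Replicate statistics.** Courses are aligned on the union time grid; at
each time the mean is taken over finite observations and the sample
standard deviation uses the n−1 denominator, undefined (NaN) below two
observations. A single replicate therefore still yields a mean course and
no std. On the bundled ragged worked example ({0.5, 0.6, 0.4} at t = 0) the
n−1 convention gives std 0.1, which is the check that fixed this choice.

**Outlier flagging.** For each replicate, the deviation score is the median
over shared finite times of |y_r(t) − m₋r(t)| / max(|m₋r(t)|, ε) with
m₋r the leave-one-out mean and ε = 1e−6 guarding near-zero baselines.
Replicates scoring above the threshold `tau` (default 0.5, i.e. flagged
when typically 50 % away from peers) are flagged, largest score first, but
never more than n − 2 — two replicates always survive, because with heavy
contamination the leave-one-out means themselves are corrupted and flagging
everything is worse than flagging the worst. The median (not mean) over
time makes a single bad time point insufficient to flag a replicate.

**Blanks and stages.** Blank assignment matches each non-blank replicate to
a blank sharing its media and environment, breaking ties lexicographically
with a warning. Subtraction removes the blank's mean course, linearly
interpolated (edge-held) at each sample time; values may go negative — no
clipping, since clipping would bias subsequent statistics. On complete
grids, subtracting then averaging equals averaging then subtracting the
blank mean. Stage slicing uses half-open intervals [b_k, b_{k+1}) with the
final stage closed on the right, so a sample on a boundary belongs to the
later stage and the last sample is never lost; each stage is returned as a
first-class experiment on which every feature works unchanged.

## Flux integration

The stoichiometric model is a plain metabolites × reactions matrix with
bounds, an objective vector and a declared exchange set; it can be read
from a five-column reaction-table CSV or from SBML via cobrapy. Exchange
fluxes are positive for export and negative for uptake. Measured rates are
applied as equality bounds by default (`rate·(1 ∓ slack)` bands when a
slack fraction is given, acknowledging measurement noise), and the LP
max c·v s.t. S·v = 0, lb ≤ v ≤ ub is solved with HiGHS at 1e−9 feasibility
tolerance — deterministic, no restarts. CO₂ estimation fixes all measured
exchanges and maximises the declared objective; a model with no objective
falls back to minimising Σ|v| (via the standard variable split). On the
bundled toy network the CO₂ flux is uniquely determined by the
constraints, so both objectives agree — a property the tests assert.

Carbon recovery is Σ products c_p·ΔP_p / Σ substrates c_s·ΔS_s over
C-mmol; a biomass term measured in grams dry weight is converted with the
standard elemental composition CH₁.₈O₀.₅N₀.₂ at 24.6 g per C-mol
(configurable). The ratio is invariant under uniform rescaling of all
amounts.

## Persistence

A single-file SQLite store (stdlib driver), chosen for zero-configuration
sharing: one file is the whole study. Strain, media and environment records
are normalised into their own tables; trials and courses are keyed on their
canonical serialized identifiers, making saves idempotent upserts (saving
twice inserts nothing) and letting one replicate trial belong to several
experiments through a membership table. Missing values are stored as SQL
NULL and come back as NaN at their original time points, so `load ∘ save`
is structural identity. The schema carries a version number; an
incompatible store fails before any write. Two *different* data sets that
reuse byte-identical identifiers are indistinguishable to the store — the
identifier is the identity, by design; distinct experiments must differ
somewhere in their metadata (the `experiment` key suffices). Computed
features are never persisted: they are cheap to recompute and stored copies
go stale.

## Synthetic data generator

The generator emulates a small batch-fermentation screen: per strain,
biomass follows the generalised-logistic form above (so fits have an exact
target), substrate falls stoichiometrically as S = S0 − ΔX/Y_XS with the
generator refusing configurations that would drive S below zero, and
product is substrate-coupled, P = Y_PS·(S0 − S). Product formation is
deliberately *not* Luedeking–Piret: constant coupling keeps the
ground-truth endpoint yield exactly Y_PS at every seed, which is what makes
the yield oracle exact. Optional additive Gaussian noise, independent
missing-completely-at-random dropout, and constant-level blank trials
complete the picture; everything derives from a single seed and equal
configurations are byte-identical.

Defaults — two strains (A = 2.0/1.8 gDW/L, μ_max = 0.5/0.4 1/h,
λ = 1/2 h), triplicates, 2-h sampling over 24 h, S0 = 10 g/L, Y_XS = 0.5,
Y_PS = 0.4, no noise — describe a routine shake-flask screen on a glucose
minimal medium. Not emulated: instrument drift, injection carryover,
co-elution, correlated noise, diauxie, death phase. Passing tests on this
generator therefore demonstrate correctness of the computations, not
robustness to every failure mode of real instruments.

Two printed fixtures accompany the generator: the ragged three-replicate OD
table used as the missing-data worked example, and the 4-metabolite,
5-reaction anaerobic toy network (glucose → 2 pyruvate → ethanol + CO₂)
whose flux solution is checkable by hand.

## Problem sizes and test scope

The test-suite and the acceptance script run on desk-scale inputs chosen so
every expected value is computable by hand or by an independent oracle:
12-point worked-example tables, 13–49-point synthetic courses, 100-seed
noise ensembles for fit recovery, 50 generated experiments for the store
round trip, and the 5-reaction network for flux integration. Genome-scale
models are accepted through the same SBML interface but are deliberately
not part of the suite.

## Known limitations

- Interpolation between analyte grids is linear only; strongly curved
  courses sampled sparsely will bias yields slightly.
- The outlier score assumes replicates share most time points; fully
  disjoint grids yield no shared times and no flagging.
- The exponential fit weights log-residuals, i.e. relative error; this is
  usually what growth data want but differs from absolute least squares.
- No fed-batch or chemostat schema elements (feed profiles, dilution
  rates); stages are the supported way to segment a run.
- The store treats the canonical identifier as identity (see Persistence).
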