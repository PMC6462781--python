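"""Synthetic fermentation experiments with known ground truth.

Everything downstream (assembly, features, persistence, flux integration)
is exercised against data generated here, so each module can be tested
against the exact parameters that produced its input.

The generative model is a batch fermentation per strain:

* biomass follows the generalised-logistic closed form (asymptote ``A``
  gDW/L, maximum specific rate ``mu_max`` 1/h, lag ``lam`` h) on top of an
  optional inoculum baseline ``X0``;
* substrate is consumed stoichiometrically, S(t) = S0 - (X(t) - X(0))/Y_XS;
* product is substrate-coupled with constant yield, P(t) = Y_PS*(S0 - S(t)),
  so the endpoint product yield of noiseless output equals ``Y_PS`` exactly
  by construction (deliberately not Luedeking-Piret kinetics, which would
  make the ground-truth yield time-dependent);
* optional additive Gaussian noise, missing-completely-at-random dropout,
  and cell-free blank trials at a constant background level.

All randomness flows from the single ``seed``; equal configurations produce
identical output. Defaults describe a routine small shake-flask screen: two
strains, triplicates, 2 h sampling over 24 h, 10 g/L substrate, yields
Y_XS = 0.5 and Y_PS = 0.4 g/g.

Not emulated: measurement drift, carryover between injections, co-elution,
or any correlation structure in the noise — real instrument data can
violate all of these.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import GeneratorError
from .identifiers import Environment, Media, Strain, TrialIdentifier
from .fluxlink import StoichiometricModel
from .schema import TimePoint

_DEFAULT_GROWTH = ((2.0, 0.5, 1.0), (1.8, 0.4, 2.0))


@dataclass
class SyntheticConfig:
    """Ground-truth parameters for one generated experiment."""

    strains: int = 2
    replicates: int = 3
    times: tuple[float, ...] = tuple(float(t) for t in range(0, 25, 2))
    growth: tuple[tuple[float, float, float], ...] = _DEFAULT_GROWTH  # (A, mu_max, lam)
    X0: float = 0.0  # inoculum baseline, gDW/L
    S0: float = 10.0  # initial substrate, g/L
    Y_XS: float = 0.5  # biomass yield, gDW/g
    Y_PS: float = 0.4  # product yield, g/g
    noise_sd: float = 0.0
    missing_frac: float = 0.0
    blank_level: float = 0.0
    media_name: str = "M9"
    experiment_label: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        if self.Y_XS <= 0 or self.Y_PS <= 0:
            raise GeneratorError("yields must be positive")
        if not (0 <= self.missing_frac < 1):
            raise GeneratorError("missing_frac must lie in [0, 1)")
        if self.noise_sd < 0 or self.blank_level < 0:
            raise GeneratorError("noise_sd and blank_level must be >= 0")
        if len(self.growth) < self.strains:
            raise GeneratorError(
                f"need growth parameters for {self.strains} strains, got {len(self.growth)}"
            )


def _logistic(t: np.ndarray, A: float, mu: float, lam: float) -> np.ndarray:
    return A / (1.0 + np.exp(4.0 * mu / A * (lam - t) + 2.0))


def generate_experiment(cfg: SyntheticConfig) -> tuple[list[TimePoint], dict]:
    """Generate time points plus the ground-truth record that produced them."""
    rng = np.random.default_rng(cfg.seed)
    t = np.asarray(cfg.times, dtype=float)
    points: list[TimePoint] = []
    truth: dict = {
        "S0": cfg.S0, "Y_XS": cfg.Y_XS, "Y_PS": cfg.Y_PS, "X0": cfg.X0,
        "noise_sd": cfg.noise_sd, "missing_frac": cfg.missing_frac,
        "seed": cfg.seed, "strains": {},
    }

    def emit(ident_base: TrialIdentifier, rep: int, analyte: str, values: np.ndarray, unit: str):
        for time, value in zip(t, values):
            noisy = value + (rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0)
            if cfg.missing_frac > 0 and rng.random() < cfg.missing_frac:
                noisy = float("nan")
            ident = TrialIdentifier(
                strain=ident_base.strain, media=ident_base.media,
                environment=ident_base.environment,
                experiment_label=ident_base.experiment_label,
                replicate_index=rep, sample_time=float(time),
                analyte_name=analyte, is_blank=ident_base.is_blank,
            )
            points.append(TimePoint(ident, float(noisy), unit))

    media = Media(name=cfg.media_name)
    env = Environment()
    for s in range(cfg.strains):
        A, mu, lam = cfg.growth[s]
        name = f"strain{s + 1}"
        X = cfg.X0 + _logistic(t, A, mu, lam)
        consumed = (X - X[0]) / cfg.Y_XS
        S = cfg.S0 - consumed
        if np.any(S < 0):
            raise GeneratorError(
                f"substrate exhausted for {name} (min S = {S.min():.3g}); "
                "reduce A or increase S0"
            )
        P = cfg.Y_PS * consumed
        truth["strains"][name] = {"A": A, "mu_max": mu, "lam": lam}
        base = TrialIdentifier(
            strain=Strain(name=name), media=media, environment=env,
            experiment_label=cfg.experiment_label,
        )
        for rep in range(1, cfg.replicates + 1):
            emit(base, rep, "OD600", X, "gDW/L")
            emit(base, rep, "glucose", S, "g/L")
            emit(base, rep, "product", P, "g/L")

    if cfg.blank_level > 0:
        blank_base = TrialIdentifier(
            strain=Strain(name="blank"), media=media, environment=env,
            experiment_label=cfg.experiment_label, is_blank=True,
        )
        for rep in range(1, cfg.replicates + 1):
            emit(blank_base, rep, "OD600", np.full(t.size, cfg.blank_level), "gDW/L")
        truth["blank_level"] = cfg.blank_level

    return points, truth


def write_synthetic(cfg: SyntheticConfig, csv_path: str | Path) -> tuple[int, Path]:
    """Emit tidy long CSV plus a ground-truth JSON sidecar; returns (rows, sidecar)."""
    from .ingest import write_tidy_long
    from .schema import assemble_experiment

    points, truth = generate_experiment(cfg)
    e = assemble_experiment(points, cfg.experiment_label)
    n = write_tidy_long(e, csv_path)
    sidecar = Path(csv_path).with_suffix(".truth.json")
    sidecar.write_text(json.dumps(truth, indent=2))
    return n, sidecar


def table1_fixture() -> list[TimePoint]:
    """Three-replicate OD course with ragged missing values.

    Times 0/2/4/6 h; replicate 1 = 0.5, 0.8, 0.9, 1.2; replicate 2 = 0.6,
    nan, 1.0, nan; replicate 3 = 0.4, 0.7, 1.2, nan — 12 points, 9 finite.
    The worked example used throughout the docs for missing-data-aware
    replicate statistics.
    """
    nan = float("nan")
    rows = {
        1: [0.5, 0.8, 0.9, 1.2],
        2: [0.6, nan, 1.0, nan],
        3: [0.4, 0.7, 1.2, nan],
    }
    times = [0.0, 2.0, 4.0, 6.0]
    points = []
    for rep, values in rows.items():
        for t, v in zip(times, values):
            ident = TrialIdentifier(
                strain=Strain(name="demo"), media=Media(name="M9"),
                replicate_index=rep, sample_time=t, analyte_name="OD600",
            )
            points.append(TimePoint(ident, v, "OD"))
    return points


def toy_model_fixture() -> StoichiometricModel:
    """Desk-scale anaerobic toy network for flux integration tests.

    Four metabolites, five reactions: glucose exchange; glucose -> 2
    pyruvate; pyruvate -> ethanol + CO2; ethanol exchange; CO2 exchange.
    Bounds +/-1000, objective on ethanol export. Fixing glucose uptake at 10
    forces ethanol and CO2 export of 20 each (1 glc -> 2 etoh + 2 co2).
    """
    mets = ["glc", "pyr", "etoh", "co2"]
    rxns = ["EX_glc", "GLC2PYR", "PYR2ETOH", "EX_etoh", "EX_co2"]
    S = np.array([
        # EX_glc  GLC2PYR  PYR2ETOH  EX_etoh  EX_co2
        [-1.0,    -1.0,     0.0,      0.0,     0.0],   # glc
        [0.0,      2.0,    -1.0,      0.0,     0.0],   # pyr
        [0.0,      0.0,     1.0,     -1.0,     0.0],   # etoh
        [0.0,      0.0,     1.0,      0.0,    -1.0],   # co2
    ])
    lb = np.full(5, -1000.0)
    ub = np.full(5, 1000.0)
    objective = np.array([0.0, 0.0, 0.0, 1.0, 0.0])
    return StoichiometricModel(mets, rxns, S, lb, ub, objective,
                               exchanges={"EX_glc", "EX_etoh", "EX_co2"})


def toy_model_reaction_table(path: str | Path) -> Path:
    """Write the toy network as a reaction-table CSV (for the file-based API)."""
    path = Path(path)
    path.write_text(
        "reaction_id,equation,lb,ub,objective\n"
        "EX_glc,glc ->,-1000,1000,0\n"
        "GLC2PYR,glc -> 2 pyr,-1000,1000,0\n"
        "PYR2ETOH,pyr -> etoh + co2,-1000,1000,0\n"
        "EX_etoh,etoh ->,-1000,1000,1\n"
        "EX_co2,co2 ->,-1000,1000,0\n"
    )
    return path
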