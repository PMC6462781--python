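"""Integration of measured exchange rates with a stoichiometric model.

Measured specific rates (mmol/gDW/h, from the features module) are applied
as bounds on the exchange reactions of a stoichiometric model; the steady
state ``S v = 0`` then closes the balance by linear programming, which lets
unmeasured gaseous exchanges — CO2 evolution in particular — be estimated,
and a carbon recovery checked.

Sign convention: exchange flux > 0 means export (secretion), < 0 means
uptake, the standard constraint-based convention. Consumption rates are
therefore entered as negative numbers.

Models come from a plain reaction-table CSV (``reaction_id,equation,lb,ub,
objective`` with equations like ``glc -> 2 pyr``; a one-sided equation marks
an exchange) or from SBML via cobrapy.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linprog

from .errors import FluxError

#: Standard cell elemental composition CH1.8O0.5N0.2: grams dry weight per C-mol.
BIOMASS_G_PER_CMOL = 24.6

_FEAS_TOL = 1e-9
_STEADY_TOL = 1e-6


@dataclass
class StoichiometricModel:
    """Metabolites x reactions stoichiometry with flux bounds and objective."""

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    objective: np.ndarray
    exchanges: set[str] = field(default_factory=set)

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self.objective = np.asarray(self.objective, dtype=float)
        m, n = self.S.shape
        if m != len(self.metabolite_ids) or n != len(self.reaction_ids):
            raise FluxError("stoichiometric matrix dimensions inconsistent with id lists")
        if self.lb.shape != (n,) or self.ub.shape != (n,) or self.objective.shape != (n,):
            raise FluxError("bound/objective vector length inconsistent with reactions")
        if np.any(self.lb > self.ub):
            raise FluxError("lower bound exceeds upper bound for some reaction")

    def reaction_index(self, rxn_id: str) -> int:
        try:
            return self.reaction_ids.index(rxn_id)
        except ValueError as exc:
            raise FluxError(
                f"unknown reaction {rxn_id!r}; model has {self.reaction_ids}"
            ) from exc


@dataclass
class FluxSolution:
    """One LP solve: flux vector, objective value and solver status."""

    v: np.ndarray | None
    objective_value: float | None
    status: str  # optimal | infeasible | unbounded

    def flux(self, model: StoichiometricModel, rxn_id: str) -> float:
        if self.v is None:
            raise FluxError(f"no flux vector available (status={self.status})")
        return float(self.v[model.reaction_index(rxn_id)])


@dataclass
class CarbonLedger:
    """Carbon bookkeeping: C-mmol consumed vs produced, and the recovery fraction."""

    consumed_cmmol: float
    produced_cmmol: dict[str, float]
    recovery: float


def _constrained_bounds(
    m: StoichiometricModel, constraints: dict[str, float], slack: float
) -> list[tuple[float, float]]:
    lb, ub = m.lb.copy(), m.ub.copy()
    for rxn, rate in constraints.items():
        j = m.reaction_index(rxn)
        band = abs(rate) * slack
        lb[j], ub[j] = rate - band, rate + band
    return list(zip(lb, ub))


_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def solve_fba(
    m: StoichiometricModel,
    constraints: dict[str, float] | None = None,
    slack: float = 0.0,
    minimize_total_flux: bool = False,
) -> FluxSolution:
    """Solve max c.v subject to S.v = 0, lb <= v <= ub.

    Measured rates in ``constraints`` are applied as ``rate*(1 -/+ slack)``
    bands (default slack 0, i.e. equality). With ``minimize_total_flux`` the
    objective is replaced by min sum(|v|) — used as the fallback when a model
    declares no objective. Deterministic (HiGHS, no restarts).
    """
    constraints = constraints or {}
    bounds = _constrained_bounds(m, constraints, slack)
    n = len(m.reaction_ids)

    if minimize_total_flux:
        # split |v|: variables [v, u], u >= |v|, minimize sum u
        c = np.concatenate([np.zeros(n), np.ones(n)])
        A_eq = np.hstack([m.S, np.zeros_like(m.S)])
        eye = np.eye(n)
        A_ub = np.vstack([np.hstack([eye, -eye]), np.hstack([-eye, -eye])])
        b_ub = np.zeros(2 * n)
        full_bounds = bounds + [(0.0, None)] * n
        res = linprog(
            c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=np.zeros(m.S.shape[0]),
            bounds=full_bounds, method="highs",
            options={"primal_feasibility_tolerance": _FEAS_TOL},
        )
        v = res.x[:n] if res.x is not None else None
    else:
        res = linprog(
            -m.objective, A_eq=m.S, b_eq=np.zeros(m.S.shape[0]), bounds=bounds,
            method="highs", options={"primal_feasibility_tolerance": _FEAS_TOL},
        )
        v = res.x

    status = _STATUS.get(res.status, "unknown")
    if status == "infeasible":
        return FluxSolution(
            v=None, objective_value=None,
            status="infeasible",
        )
    if status == "unbounded":
        return FluxSolution(v=None, objective_value=None, status="unbounded")
    if v is None:
        raise FluxError(f"LP solve failed: {res.message}")
    obj = float(m.objective @ v)
    return FluxSolution(v=np.asarray(v), objective_value=obj, status="optimal")


def estimate_co2(
    m: StoichiometricModel, measured: dict[str, float], co2_id: str
) -> float:
    """Estimate the unmeasured CO2 evolution rate (mmol/gDW/h).

    All measured exchange rates are fixed; the model objective is maximised
    (falling back to minimum total flux when no objective is declared) and
    the CO2 exchange flux of the optimum returned.
    """
    if co2_id not in m.exchanges:
        raise FluxError(f"{co2_id!r} is not an exchange reaction of the model")
    if co2_id in measured:
        raise FluxError(f"{co2_id!r} is already measured; nothing to estimate")
    use_fallback = not np.any(m.objective)
    sol = solve_fba(m, constraints=measured, minimize_total_flux=use_fallback)
    if sol.status != "optimal":
        raise FluxError(
            f"constraint set infeasible or unbounded (status={sol.status}); "
            f"binding constraints: {sorted(measured.items())}"
        )
    return sol.flux(m, co2_id)


def carbon_recovery(
    deltas: dict[str, tuple[float, int]],
    substrate_ids: set[str] | list[str],
    biomass_grams: float | None = None,
    biomass_g_per_cmol: float = BIOMASS_G_PER_CMOL,
) -> CarbonLedger:
    """Fraction of consumed substrate carbon recovered in products.

    ``deltas`` maps species -> (amount in mmol, carbon atoms per molecule);
    amounts are magnitudes (consumed for substrates, produced for products).
    An OD-derived biomass contribution in grams dry weight is converted to
    C-mmol via the standard composition (24.6 g per C-mol by default).
    Homogeneous of degree zero: scaling all amounts uniformly leaves the
    recovery unchanged.
    """
    substrate_ids = set(substrate_ids)
    consumed = 0.0
    produced: dict[str, float] = {}
    for species, (amount, carbons) in deltas.items():
        if amount < 0 or carbons < 0:
            raise FluxError(f"negative amount or carbon count for {species!r}")
        cmmol = amount * carbons
        if species in substrate_ids:
            consumed += cmmol
        else:
            produced[species] = cmmol
    if biomass_grams is not None:
        if biomass_grams < 0:
            raise FluxError("negative biomass amount")
        produced["biomass"] = biomass_grams / biomass_g_per_cmol * 1000.0
    if consumed <= 0:
        raise FluxError("zero carbon consumed; recovery undefined")
    recovery = sum(produced.values()) / consumed
    return CarbonLedger(consumed_cmmol=consumed, produced_cmmol=produced, recovery=recovery)


# ---------------------------------------------------------------------------
# model I/O


def _parse_side(side: str) -> list[tuple[float, str]]:
    terms = []
    side = side.strip()
    if not side:
        return terms
    for chunk in side.split("+"):
        parts = chunk.strip().split()
        if len(parts) == 1:
            terms.append((1.0, parts[0]))
        elif len(parts) == 2:
            terms.append((float(parts[0]), parts[1]))
        else:
            raise FluxError(f"cannot parse equation term {chunk.strip()!r}")
    return terms


def read_reaction_table(path: str | Path) -> StoichiometricModel:
    """Read a reaction-table CSV: ``reaction_id,equation,lb,ub,objective``.

    Equations use ``->`` with ``+``-separated, optionally coefficiented
    terms (``glc -> 2 pyr``). A one-sided equation is an exchange reaction;
    its metabolite appears with coefficient -1, so positive flux exports.
    """
    met_ids: list[str] = []
    rxn_ids: list[str] = []
    entries: list[tuple[list[tuple[float, str]], float, float, float, bool]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"reaction_id", "equation", "lb", "ub", "objective"}
        if reader.fieldnames is None or not required.issubset(
            {c.strip().lower() for c in reader.fieldnames}
        ):
            raise FluxError(f"reaction table {path} must have columns {sorted(required)}")
        for row in reader:
            row = {k.strip().lower(): (v or "").strip() for k, v in row.items()}
            eq = row["equation"]
            if "->" not in eq:
                raise FluxError(f"reaction {row['reaction_id']!r}: equation lacks '->'")
            left, right = eq.split("->", 1)
            reactants, products = _parse_side(left), _parse_side(right)
            coeffs = [(-c, m) for c, m in reactants] + [(c, m) for c, m in products]
            is_exchange = not reactants or not products
            for _, met in coeffs:
                if met not in met_ids:
                    met_ids.append(met)
            rxn_ids.append(row["reaction_id"])
            entries.append(
                (coeffs, float(row["lb"]), float(row["ub"]),
                 float(row["objective"] or 0), is_exchange)
            )
    S = np.zeros((len(met_ids), len(rxn_ids)))
    lb, ub, obj = np.zeros(len(rxn_ids)), np.zeros(len(rxn_ids)), np.zeros(len(rxn_ids))
    exchanges: set[str] = set()
    for j, (coeffs, lo, hi, c, is_ex) in enumerate(entries):
        for coeff, met in coeffs:
            S[met_ids.index(met), j] += coeff
        lb[j], ub[j], obj[j] = lo, hi, c
        if is_ex:
            exchanges.add(rxn_ids[j])
    return StoichiometricModel(met_ids, rxn_ids, S, lb, ub, obj, exchanges)


def read_sbml_model(path: str | Path) -> StoichiometricModel:
    """Import an SBML (Level 3) model via cobrapy."""
    try:
        import cobra.io
    except ImportError as exc:  # pragma: no cover
        raise FluxError("SBML import requires the 'cobra' package") from exc
    return from_cobra_model(cobra.io.read_sbml_model(str(path)))


def from_cobra_model(model) -> StoichiometricModel:
    """Convert a cobra.Model into the package's matrix representation."""
    met_ids = [m.id for m in model.metabolites]
    rxn_ids = [r.id for r in model.reactions]
    S = np.zeros((len(met_ids), len(rxn_ids)))
    lb = np.zeros(len(rxn_ids))
    ub = np.zeros(len(rxn_ids))
    obj = np.zeros(len(rxn_ids))
    try:
        exchanges = {r.id for r in model.exchanges}
    except Exception:
        # compartment annotations absent: fall back to structural detection
        # (a boundary reaction has all stoichiometric coefficients of one sign)
        exchanges = {
            r.id for r in model.reactions
            if r.metabolites and (
                all(c > 0 for c in r.metabolites.values())
                or all(c < 0 for c in r.metabolites.values())
            )
        }
    for j, rxn in enumerate(model.reactions):
        for met, coeff in rxn.metabolites.items():
            S[met_ids.index(met.id), j] = coeff
        lb[j], ub[j] = rxn.lower_bound, rxn.upper_bound
        obj[j] = rxn.objective_coefficient
    return StoichiometricModel(met_ids, rxn_ids, S, lb, ub, obj, exchanges)


def steady_state_residual(m: StoichiometricModel, v: np.ndarray) -> float:
    """Max-norm of S.v — zero (within tolerance) at any feasible steady state."""
    return float(np.max(np.abs(m.S @ np.asarray(v, dtype=float))))
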