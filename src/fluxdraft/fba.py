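"""Steady-state flux balance analysis.

The FBA problem: optimize c . v subject to S v = 0 over the internal
metabolites and lb <= v <= ub per reaction.  Every problem this package
formulates is a linear program; it is solved with scipy's HiGHS backend.
Optima are unique in objective value but generally not in the flux
vector, so analyses built on top (GAM fitting, production envelopes,
scenario comparisons) always work with objective values or with a
secondary optimization at a fixed primary optimum, never with raw
witness vectors.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model import (
    MetabolicModel,
    ModelError,
    ObjectiveSpec,
    build_stoichiometric_matrix,
)
from .reconstruction import BIOMASS_REACTION_ID, set_biomass

#: mass-balance residual tolerance on reported optima
STEADY_STATE_TOL = 1e-6


class FluxAnalysisError(ValueError):
    """Ill-posed flux analysis request (not a solver status)."""


@dataclass
class FluxDistribution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float | None = None
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]


@dataclass
class TradeoffCurve:
    """Max attainable target flux as a function of fixed growth rate."""

    target_reaction: str
    points: list[tuple[float, float]]  # (growth rate 1/h, optimal flux)

    @property
    def growth_rates(self) -> list[float]:
        return [g for g, _ in self.points]

    @property
    def fluxes(self) -> list[float]:
        return [f for _, f in self.points]

    def as_tsv(self) -> str:
        lines = ["growth_rate\t" + self.target_reaction]
        for g, f in self.points:
            lines.append(f"{g:.6g}\t{f:.6g}")
        return "\n".join(lines) + "\n"


def solve_fba(
    model: MetabolicModel, objective: ObjectiveSpec | None = None
) -> FluxDistribution:
    """Solve the FBA linear program and report the status faithfully."""
    objective = objective or model.objective
    if objective is None:
        raise FluxAnalysisError("no objective set on model or call")
    unknown = [rid for rid in objective.coefficients if rid not in model.reactions]
    if unknown:
        raise FluxAnalysisError(f"objective references unknown reaction(s): {unknown}")
    S = build_stoichiometric_matrix(model)
    n = len(S.reaction_ids)
    c = np.zeros(n)
    for rid, coeff in objective.coefficients.items():
        c[S.reaction_ids.index(rid)] = coeff
    sign = -1.0 if objective.direction == "maximize" else 1.0
    bounds = [
        (model.reactions[rid].lower_bound, model.reactions[rid].upper_bound)
        for rid in S.reaction_ids
    ]
    res = linprog(
        sign * c,
        A_eq=S.matrix if S.matrix.size else None,
        b_eq=np.zeros(len(S.metabolite_ids)) if S.matrix.size else None,
        bounds=bounds,
        method="highs",
    )
    if res.status == 2:
        return FluxDistribution(status="infeasible")
    if res.status == 3:
        return FluxDistribution(status="unbounded")
    if res.status != 0:
        raise FluxAnalysisError(f"LP solver failed: {res.message}")
    v = np.asarray(res.x)
    residual = np.abs(S.matrix @ v) if S.matrix.size else np.zeros(0)
    if residual.size and residual.max() > STEADY_STATE_TOL:
        raise FluxAnalysisError(
            f"steady-state residual {residual.max():.3g} exceeds tolerance"
        )
    fluxes = {rid: float(v[j]) for j, rid in enumerate(S.reaction_ids)}
    return FluxDistribution(
        status="optimal",
        objective_value=float(-res.fun) if objective.direction == "maximize" else float(res.fun),
        fluxes=fluxes,
    )


def fix_flux(model: MetabolicModel, reaction_id: str, value: float) -> MetabolicModel:
    """Pin a flux: lb = ub = value (a measured rate becomes a constraint)."""
    if reaction_id not in model.reactions:
        raise FluxAnalysisError(f"unknown reaction {reaction_id!r}")
    rxn = model.reactions[reaction_id]
    if not rxn.reversible and value < 0:
        raise FluxAnalysisError(
            f"cannot fix irreversible reaction {reaction_id!r} at {value} < 0"
        )
    out = model.copy()
    out.reactions[reaction_id].lower_bound = value
    out.reactions[reaction_id].upper_bound = value
    return out


def constrain_and_resolve(
    model: MetabolicModel,
    fixes: dict[str, tuple[float, float]],
    objective: ObjectiveSpec | None = None,
) -> FluxDistribution:
    """Solve under temporary bounds; the input model is untouched."""
    scenario = model.copy()
    for rid, (lb, ub) in fixes.items():
        if rid not in scenario.reactions:
            raise FluxAnalysisError(f"unknown reaction {rid!r} in fixes")
        if lb > ub:
            raise FluxAnalysisError(f"fix for {rid!r}: lb {lb} > ub {ub}")
        scenario.reactions[rid].lower_bound = lb
        scenario.reactions[rid].upper_bound = ub
        scenario.reactions[rid].reversible = lb < 0
    return solve_fba(scenario, objective)


@dataclass
class GamFitResult:
    gam: float  # mmol ATP/g DCW
    growth: float  # 1/h at the fitted gam
    curve: list[tuple[float, float]]  # sampled (gam, growth) pairs


def fit_gam(
    model: MetabolicModel,
    target_growth: float,
    gam_range: tuple[float, float] = (0.0, 1000.0),
    tolerance: float = 1e-4,
    max_iterations: int = 60,
    n_curve_points: int = 21,
) -> GamFitResult:
    """Fit growth-associated maintenance to a measured growth rate.

    Growth is a monotone non-increasing function of GAM (every extra mmol
    of ATP per g DCW is taken from the same capped supply), so bisection
    on the bracket converges; the substrate uptake must have been fixed
    beforehand.  Also returns a sampled (gam, growth) curve suitable for
    plotting the scan.
    """
    if model.biomass_composition is None:
        raise FluxAnalysisError(
            "model has no biomass composition; call set_biomass first"
        )
    lo, hi = gam_range
    if not lo < hi:
        raise FluxAnalysisError("gam_range must satisfy low < high")

    def growth_at(gam: float) -> float:
        comp = dataclasses.replace(model.biomass_composition, gam=gam)
        sol = solve_fba(
            set_biomass(model, comp), ObjectiveSpec({BIOMASS_REACTION_ID: 1.0})
        )
        if not sol.optimal:
            return 0.0
        return sol.objective_value

    g_lo, g_hi = growth_at(lo), growth_at(hi)
    if not (g_hi - tolerance <= target_growth <= g_lo + tolerance):
        raise FluxAnalysisError(
            f"target growth {target_growth} outside achievable range "
            f"[{g_hi:.6g}, {g_lo:.6g}] on gam bracket [{lo}, {hi}]"
        )
    curve = [
        (g, growth_at(g)) for g in np.linspace(lo, hi, n_curve_points)
    ]
    if abs(g_lo - target_growth) <= tolerance:
        return GamFitResult(gam=lo, growth=g_lo, curve=curve)
    if abs(g_hi - target_growth) <= tolerance:
        return GamFitResult(gam=hi, growth=g_hi, curve=curve)
    a, b = lo, hi
    for _ in range(max_iterations):
        mid = 0.5 * (a + b)
        g_mid = growth_at(mid)
        if abs(g_mid - target_growth) <= tolerance:
            return GamFitResult(gam=mid, growth=g_mid, curve=curve)
        if g_mid > target_growth:
            a = mid
        else:
            b = mid
    mid = 0.5 * (a + b)
    return GamFitResult(gam=mid, growth=growth_at(mid), curve=curve)


def production_envelope(
    model: MetabolicModel,
    target_reaction: str,
    n_points: int = 20,
) -> TradeoffCurve:
    """Trade-off curve between growth rate and a product flux.

    Computes the maximal growth rate mu*, then for each mu on a uniform
    grid over [0, mu*] fixes the biomass flux at mu and maximizes the
    target reaction.
    """
    if target_reaction not in model.reactions:
        raise FluxAnalysisError(f"unknown target reaction {target_reaction!r}")
    if BIOMASS_REACTION_ID not in model.reactions:
        raise FluxAnalysisError("model has no biomass reaction")
    base = solve_fba(model, ObjectiveSpec({BIOMASS_REACTION_ID: 1.0}))
    if not base.optimal:
        raise FluxAnalysisError(f"model is {base.status}; no envelope")
    mu_star = base.objective_value
    points: list[tuple[float, float]] = []
    target_objective = ObjectiveSpec({target_reaction: 1.0})
    for mu in np.linspace(0.0, mu_star, n_points):
        sol = constrain_and_resolve(
            model, {BIOMASS_REACTION_ID: (mu, mu)}, target_objective
        )
        if sol.optimal:
            points.append((float(mu), sol.objective_value))
    return TradeoffCurve(target_reaction=target_reaction, points=points)


def flux_table(model: MetabolicModel, solution: FluxDistribution) -> str:
    """Flux result as TSV: reaction_id, name, flux, lb, ub."""
    lines = ["reaction_id\tname\tflux\tlower_bound\tupper_bound"]
    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        flux = solution.fluxes.get(rid, float("nan"))
        lines.append(
            f"{rid}\t{rxn.name}\t{flux:.6g}\t{rxn.lower_bound:.6g}\t{rxn.upper_bound:.6g}"
        )
    return "\n".join(lines) + "\n"
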