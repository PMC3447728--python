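"""Dynamic FBA by the static optimization approach (SOA).

The fermentation time course is split into fixed intervals; each interval
is solved as an ordinary steady-state FBA ("mini-FBA") whose exchange
bounds come either from user-supplied piecewise-constant profiles (the
measured-rates mode) or from Monod kinetics on tracked substrate
concentrations (the kinetic mode).  Between intervals, biomass is
integrated exactly for the interval's constant growth rate,
X_{k+1} = X_k exp(mu_k dt), and tracked substrate pools are depleted by
the interval's uptake flux times the interval-average biomass.

Units: biomass g DCW/L, substrate mmol/L, fluxes mmol/g DCW/h, so
dS/dt = -v X is dimensionally consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .fba import FluxAnalysisError, FluxDistribution, solve_fba
from .model import MetabolicModel
from .reconstruction import BIOMASS_REACTION_ID


class DFBAError(ValueError):
    """Invalid dynamic-FBA specification."""


@dataclass
class MonodSpec:
    """Saturable uptake kinetics: ub = vmax * S / (ks + S)."""

    vmax: float  # mmol/g DCW/h
    ks: float  # mmol/L

    def __post_init__(self) -> None:
        if self.vmax < 0:
            raise DFBAError("vmax must be >= 0")
        if self.ks <= 0:
            raise DFBAError("ks must be > 0")

    def uptake_bound(self, concentration: float) -> float:
        s = max(0.0, concentration)
        return self.vmax * s / (self.ks + s)


@dataclass
class TrackedSubstrate:
    initial_concentration: float  # mmol/L
    uptake_reaction: str


@dataclass
class TimeCourseSpec:
    t0: float = 0.0
    t_end: float = 10.0
    dt: float = 0.1
    initial_biomass: float = 0.01  # g DCW/L
    #: reaction id -> list of (time, lb, ub) breakpoints OR a MonodSpec
    bound_profiles: dict[str, list[tuple[float, float, float]] | MonodSpec] = field(
        default_factory=dict
    )
    tracked_substrates: dict[str, TrackedSubstrate] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise DFBAError("dt must be > 0")
        if self.t_end <= self.t0:
            raise DFBAError("t_end must be > t0")
        if self.initial_biomass <= 0:
            raise DFBAError("initial_biomass must be > 0")
        uptake_reactions = {
            ts.uptake_reaction for ts in self.tracked_substrates.values()
        }
        for rid, profile in self.bound_profiles.items():
            if isinstance(profile, MonodSpec):
                if rid not in uptake_reactions:
                    raise DFBAError(
                        f"Monod profile for {rid!r} has no tracked substrate "
                        "linked to that uptake reaction"
                    )
            else:
                if not profile:
                    raise DFBAError(f"empty bound profile for {rid!r}")
                times = [t for t, _, _ in profile]
                if any(t < self.t0 or t > self.t_end for t in times):
                    raise DFBAError(
                        f"profile for {rid!r} has breakpoints outside "
                        f"[{self.t0}, {self.t_end}]"
                    )
                if times != sorted(times):
                    raise DFBAError(f"profile for {rid!r} not time-sorted")


@dataclass
class DFBATrajectory:
    times: list[float]
    biomass: list[float]
    substrate_conc: dict[str, list[float]]
    interval_solutions: list[FluxDistribution]
    terminated_early: bool = False
    termination_reason: str = ""

    def as_tsv(self) -> str:
        substrates = sorted(self.substrate_conc)
        header = ["time", "biomass"] + substrates + ["objective_flux"]
        lines = ["\t".join(header)]
        for k, t in enumerate(self.times):
            row = [f"{t:.6g}", f"{self.biomass[k]:.6g}"]
            row += [f"{self.substrate_conc[s][k]:.6g}" for s in substrates]
            if k < len(self.interval_solutions):
                row.append(f"{self.interval_solutions[k].objective_value:.6g}")
            else:
                row.append("")
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


def resolve_bounds(
    spec: TimeCourseSpec,
    reaction_id: str,
    t: float,
    state: dict[str, float] | None = None,
) -> tuple[float, float]:
    """Bounds for one reaction at time t.

    Piecewise-constant tables are left-closed step functions (the value at
    the last breakpoint <= t holds); Monod profiles return lb = 0 and the
    kinetic upper bound from the current tracked concentration in
    ``state``.
    """
    if not spec.t0 <= t <= spec.t_end:
        raise DFBAError(f"t={t} outside [{spec.t0}, {spec.t_end}]")
    profile = spec.bound_profiles.get(reaction_id)
    if profile is None:
        raise DFBAError(f"no profile for reaction {reaction_id!r}")
    if isinstance(profile, MonodSpec):
        for mid, ts in spec.tracked_substrates.items():
            if ts.uptake_reaction == reaction_id:
                if state is None or mid not in state:
                    raise DFBAError(
                        f"no current concentration for substrate {mid!r}"
                    )
                return (0.0, profile.uptake_bound(state[mid]))
        raise DFBAError(f"Monod profile for {reaction_id!r} has no substrate")
    current = None
    for time, lb, ub in profile:
        if time <= t:
            current = (lb, ub)
        else:
            break
    if current is None:
        # before the first breakpoint: hold its value backwards
        _, lb, ub = profile[0]
        current = (lb, ub)
    return current


def run_dfba(model: MetabolicModel, spec: TimeCourseSpec) -> DFBATrajectory:
    """Run the SOA time course.

    Each interval solves a mini-FBA with bounds resolved at its left edge;
    an infeasible interval terminates the simulation gracefully with a
    partial trajectory (late-time infeasibility usually means the model
    cannot cover maintenance any more, which is biologically meaningful).
    """
    if model.objective is None:
        raise DFBAError("model needs an objective (typically biomass)")
    for rid in spec.bound_profiles:
        if rid not in model.reactions:
            raise DFBAError(f"profile for unknown reaction {rid!r}")
    for mid, ts in spec.tracked_substrates.items():
        if ts.uptake_reaction not in model.reactions:
            raise DFBAError(
                f"tracked substrate {mid!r} links unknown reaction "
                f"{ts.uptake_reaction!r}"
            )

    mu_reaction = BIOMASS_REACTION_ID if BIOMASS_REACTION_ID in model.reactions else None

    times = [spec.t0]
    biomass = [spec.initial_biomass]
    conc: dict[str, list[float]] = {
        mid: [ts.initial_concentration] for mid, ts in spec.tracked_substrates.items()
    }
    solutions: list[FluxDistribution] = []
    terminated = False
    reason = ""

    t = spec.t0
    working = model.copy()
    while t < spec.t_end - 1e-12:
        dt = min(spec.dt, spec.t_end - t)
        state = {mid: series[-1] for mid, series in conc.items()}
        for rid in spec.bound_profiles:
            lb, ub = resolve_bounds(spec, rid, t, state)
            rxn = working.reactions[rid]
            rxn.lower_bound = lb
            rxn.upper_bound = ub
            rxn.reversible = lb < 0
        sol = solve_fba(working)
        if not sol.optimal:
            terminated = True
            reason = f"mini-FBA {sol.status} at t={t:.6g} h"
            break
        solutions.append(sol)
        mu = sol.fluxes.get(mu_reaction, 0.0) if mu_reaction else 0.0
        x_k = biomass[-1]
        x_next = x_k * math.exp(mu * dt)
        # interval-average biomass: exact for exponential growth
        x_avg = (x_next - x_k) / (mu * dt) if mu > 1e-12 else x_k
        for mid, ts in spec.tracked_substrates.items():
            v_uptake = sol.fluxes.get(ts.uptake_reaction, 0.0)
            s_next = conc[mid][-1] - v_uptake * x_avg * dt
            conc[mid].append(max(0.0, s_next))
        t += dt
        times.append(t)
        biomass.append(x_next)

    return DFBATrajectory(
        times=times,
        biomass=biomass,
        substrate_conc=conc,
        interval_solutions=solutions,
        terminated_early=terminated,
        termination_reason=reason,
    )


def parse_profile_tsv(text: str) -> dict[str, list[tuple[float, float, float]]]:
    """Parse a bound-profile TSV with columns time, reaction_id, lb, ub."""
    profiles: dict[str, list[tuple[float, float, float]]] = {}
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    start = 1 if lines and lines[0].lower().startswith("time") else 0
    for ln in lines[start:]:
        parts = ln.split("\t")
        if len(parts) < 4:
            raise DFBAError(f"profile line needs 4 columns: {ln!r}")
        time, rid, lb, ub = parts[0], parts[1], parts[2], parts[3]
        profiles.setdefault(rid, []).append((float(time), float(lb), float(ub)))
    for rid in profiles:
        profiles[rid].sort(key=lambda row: row[0])
    return profiles
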