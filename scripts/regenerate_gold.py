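"""Regenerate the gold reference file for the packaged surrogate model.

The surrogate ships with a JSON file of reference quantities (growth
rate, fitted GAM, production-envelope points, acetate-restriction
scenario) computed by this script from the model itself.  Tests compare
fresh recomputations against this file; rerun it after any deliberate
change to the surrogate's stoichiometry or defaults:

    python scripts/regenerate_gold.py
"""

from __future__ import annotations

import json
from pathlib import Path

from fluxdraft.fba import constrain_and_resolve, fit_gam, production_envelope, solve_fba
from fluxdraft.model import ObjectiveSpec
from fluxdraft.reconstruction import BIOMASS_REACTION_ID
from fluxdraft.surrogate import (
    ACETATE_OUTFLOW_ID,
    DEFAULT_GAM,
    DEFAULT_GLUCOSE_UPTAKE,
    DEFAULT_NGAM,
    ETHANOL_OUTFLOW_ID,
    build_x514_surrogate,
)

TARGET_GROWTH = 0.042  # 1/h, the measured chemostat growth rate
ENVELOPE_POINTS = 15
ACETATE_CAPS = (2.0, 0.6)  # mmol/g DCW/h


def scenario(model, acetate_cap: float) -> dict:
    grow = constrain_and_resolve(
        model,
        {ACETATE_OUTFLOW_ID: (0.0, acetate_cap)},
        ObjectiveSpec({BIOMASS_REACTION_ID: 1.0}),
    )
    mu = grow.objective_value
    etoh = constrain_and_resolve(
        model,
        {ACETATE_OUTFLOW_ID: (0.0, acetate_cap), BIOMASS_REACTION_ID: (mu, mu)},
        ObjectiveSpec({ETHANOL_OUTFLOW_ID: 1.0}),
    )
    return {"acetate_cap": acetate_cap, "max_growth": mu, "ethanol": etoh.objective_value}


def main() -> None:
    model = build_x514_surrogate()
    kind_counts: dict[str, int] = {}
    for rxn in model.reactions.values():
        kind_counts[rxn.kind.value] = kind_counts.get(rxn.kind.value, 0) + 1

    base = solve_fba(model)
    fit = fit_gam(model, TARGET_GROWTH)
    envelope = production_envelope(model, ETHANOL_OUTFLOW_ID, n_points=ENVELOPE_POINTS)
    reference, restricted = (scenario(model, cap) for cap in ACETATE_CAPS)
    gain_pct = 100.0 * (restricted["ethanol"] - reference["ethanol"]) / reference["ethanol"]

    gold = {
        "species": len(model.metabolites),
        "reactions": len(model.reactions),
        "kind_counts": dict(sorted(kind_counts.items())),
        "conditions": {
            "glucose_uptake": DEFAULT_GLUCOSE_UPTAKE,
            "ngam": DEFAULT_NGAM,
            "gam": DEFAULT_GAM,
            "target_growth": TARGET_GROWTH,
        },
        "max_growth": base.objective_value,
        "fitted_gam": fit.gam,
        "fitted_growth": fit.growth,
        "envelope": {
            "n_points": ENVELOPE_POINTS,
            "growth": envelope.growth_rates,
            "ethanol": envelope.fluxes,
        },
        "acetate_restriction": {
            "reference": reference,
            "restricted": restricted,
            "ethanol_gain_pct": gain_pct,
        },
    }
    out = Path(__file__).resolve().parent.parent / "src" / "fluxdraft" / "data"
    out.mkdir(parents=True, exist_ok=True)
    path = out / "x514_surrogate_gold.json"
    path.write_text(json.dumps(gold, indent=2) + "\n")
    print(f"wrote {path}")
    print(
        f"max_growth={base.objective_value:.6g}  fitted_gam={fit.gam:.6g}  "
        f"ethanol_gain={gain_pct:.1f}%"
    )


if __name__ == "__main__":
    main()
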