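"""Generate the synthetic sickness-absence registry used by the analysis.

Writes raw records, person covariates, company table and the exact ground
truth (intensities, assignment model, oracle state-probability curves) under
results/registry/.  The scenario is the confounded beneficial-effect one: the
workplace agreement speeds transitions into work and slows relapse, and
company covariates drive both agreement uptake and prognosis.
"""

import json
from pathlib import Path

import rtwstates as rs
from rtwstates.simulate import truth_to_json

OUT = Path(__file__).resolve().parent.parent / "results" / "registry"
N_PERSONS = 10_000
SEED = 2024


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = rs.SimConfig.for_n_persons(N_PERSONS, seed=SEED, scenario="beneficial")
    sim = rs.simulate_cohort(cfg)
    sim.records.to_csv(OUT / "records.csv", index=False)
    sim.persons.to_csv(OUT / "persons.csv", index=False)
    sim.companies.to_csv(OUT / "companies.csv", index=False)
    (OUT / "truth.json").write_text(json.dumps(truth_to_json(sim.truth, cfg), indent=2))
    (OUT / "run_config.json").write_text(
        json.dumps(
            {
                "inclusion_window": list(cfg.inclusion_window),
                "admin_end_day": cfg.admin_end_day,
                "resolution_window": [0, cfg.calendar_end + 40],
                "horizon_days": cfg.horizon_days,
                "seed": SEED,
            },
            indent=2,
        )
    )
    n_sa = (sim.records["record_type"] == "sickness_absence").sum()
    print(f"simulated {len(sim.persons)} persons in {len(sim.companies)} companies")
    print(f"{len(sim.records)} raw records, of which {n_sa} sickness-absence spells")
    print(f"agreement uptake among companies: {sim.companies['ia'].mean():.3f}")
    print(f"wrote registry files to {OUT}")


if __name__ == "__main__":
    main()
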