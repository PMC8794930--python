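"""Validate the cohort engine against an independent microsimulation.

The cohort engine multiplies occupancy vectors by transition matrices; the
oracle instead simulates 100,000 individual patients by sequential event
sampling (death, then major stroke, then detection) with the same reward
timing, sharing no matrix code.  Agreement within Monte Carlo error is
evidence both encode the same stochastic process.
"""

from strokecea import (
    default_parameters,
    initial_cohort,
    microsim_oracle,
    run_cohort,
    strategy_by_name,
    synthetic_life_table,
)

params = default_parameters()
life_table = synthetic_life_table()

for name in ("no_additional_imaging", "additional_short_protocol_mri"):
    init = initial_cohort(strategy_by_name(name, params), params)
    engine = run_cohort(init, params, life_table)
    sim = microsim_oracle(init, params, life_table, n_individuals=100_000, seed=7)
    z_cost = (sim.total_cost - engine.total_cost) / sim.se_cost
    z_qaly = (sim.total_qalys - engine.total_qalys) / sim.se_qalys
    print(f"{name}")
    print(f"  engine:   cost ${engine.total_cost:,.2f}  QALYs {engine.total_qalys:.4f}")
    print(
        f"  microsim: cost ${sim.total_cost:,.2f} (SE {sim.se_cost:.2f})  "
        f"QALYs {sim.total_qalys:.4f} (SE {sim.se_qalys:.4f})"
    )
    print(f"  z-scores: cost {z_cost:+.2f}, QALYs {z_qaly:+.2f}  (|z| < 3 expected)")
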