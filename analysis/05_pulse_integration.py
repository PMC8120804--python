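"""Signal integration under pulse-frequency-modulated stimulation.

Sweeps pulse trains with a fixed 6-h total signal over the duty-cycle grid
and reports 24-h protein endpoints three ways: with physiological GFP
degradation (what an experiment measures), with a production-dominated
output stage (isolating the integration mechanism), and the two analytic
bounds — a single continuous 6-h pulse and the sum of independent pulses.
Also reports the post-blockade degradation half-lives of both outputs.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from optokinetics.core_model import (
    CD69_OUTPUT,
    GFP_OUTPUT,
    OutputParams,
    StimulusProfile,
    predict_endpoint,
    simulate_pathway,
)
from optokinetics.kinetics_fit import DecayTrace, fit_exponential
from optokinetics.protocols import DEFAULT_DUTY_CYCLES, build_pulse_train, interval_for_duty_cycle

RESULTS = Path(__file__).resolve().parents[1] / "results"
HOUR = 3600.0
SLOW = OutputParams(production=1e-12, degradation=1e-12)


def sweep(pulse_min: float, dt: float = 2.0) -> pd.DataFrame:
    ref_gfp = predict_endpoint(build_pulse_train(pulse_min, 0.0)[0], output=GFP_OUTPUT, dt=dt)
    ref_slow = predict_endpoint(build_pulse_train(pulse_min, 0.0)[0], output=SLOW, dt=dt)
    rows = []
    for duty in DEFAULT_DUTY_CYCLES:
        interval = round(interval_for_duty_cycle(pulse_min, duty) * 60.0) / 60.0
        try:
            profile, proto = build_pulse_train(pulse_min, interval)
        except ValueError:
            continue  # train does not fit the 24-h horizon
        rows.append(
            {
                "pulse_min": pulse_min,
                "interval_min": interval,
                "duty_cycle": round(proto.duty_cycle, 3),
                "gfp_endpoint_rel": predict_endpoint(profile, output=GFP_OUTPUT, dt=dt) / ref_gfp,
                "integration_endpoint_rel": predict_endpoint(profile, output=SLOW, dt=dt) / ref_slow,
            }
        )
    single, _ = build_pulse_train(pulse_min, 0.0, total_signal=pulse_min)
    n_pulses = int(360 // pulse_min)
    independent = n_pulses * predict_endpoint(StimulusProfile(single.segments, 24 * HOUR), output=SLOW, dt=dt)
    out = pd.DataFrame(rows)
    out["independent_bound_rel"] = independent / ref_slow
    return out


def degradation_half_life(output) -> float:
    stim = StimulusProfile.constant(16 * HOUR)
    traj = simulate_pathway(output=output, stimulus=stim, horizon=40 * HOUR, blockade_time=16 * HOUR, dt=2.0)
    hours = np.array([0.0, 2.0, 4.0, 8.0, 12.0, 24.0])
    idx = np.searchsorted(traj.times, 16 * HOUR + hours * HOUR)
    levels = traj.protein[np.minimum(idx, traj.times.size - 1)]
    fit = fit_exponential(DecayTrace(hours, levels, t_zero=0.0, unit="h"), "decay")
    return float(np.log(2) / fit.rate)


def main() -> None:
    tables = [sweep(p) for p in (15.0, 30.0, 90.0)]
    table = pd.concat(tables, ignore_index=True)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "pulse_sweep.csv", index=False)
    print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    print(
        "\nintegration endpoints stay between the independent-pulse bound and the"
        " continuous bound and do not increase with the inter-pulse interval;"
        " with physiological GFP degradation, later-ending trains degrade less"
        " before the 24-h readout, which lifts the measured endpoints slightly."
    )
    gfp_h = degradation_half_life(GFP_OUTPUT)
    cd69_h = degradation_half_life(CD69_OUTPUT)
    print(f"\npost-blockade degradation: GFP {gfp_h:.1f} h, CD69 {cd69_h:.1f} h")
    print("wrote results/pulse_sweep.csv")


if __name__ == "__main__":
    main()
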