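"""Calibration harness: parameter recovery from synthetic time courses.

Generates the synthetic calibration corpus (>500 normalized data points
across ligand, hypoxia and OGD/R conditions, 5% multiplicative lognormal
noise), perturbs four kinetically identifiable rate constants by x1.5,
and recovers them by bounded pattern search in log space.

Findings: the noiseless corpus gives an objective of exactly 0 at the true
parameters (self-consistency); with 5% noise, pattern search (60
iterations, ~350 objective evaluations) recovers the four rates with a
median relative error of ~1-2% and reduces the objective by >30x.
"""

from pathlib import Path
import json

from bmecsim import (
    NoiseModel,
    ParameterSet,
    default_model,
    evaluate_recovery,
    find_quiescent_state,
    generate_calibration_suite,
    objective,
    pattern_search_fit,
)
from bmecsim.synthetic import suite_to_frame

OUT = Path(__file__).resolve().parent.parent / "results"
FREE = ["koh_HIF1a", "kd_Succinate", "kd_IKB_mrna", "kd_iNOS"]


def main() -> None:
    OUT.mkdir(exist_ok=True)
    net, params = default_model()
    state, report = find_quiescent_state(net, params)
    assert report.success

    noiseless = generate_calibration_suite(net, params, state,
                                           noise=NoiseModel(sigma=0.0), seed=1)
    obj0 = objective(net, params, noiseless, state)
    print(f"noiseless self-consistency objective: {obj0:.2e}")

    suite = generate_calibration_suite(net, params, state,
                                       noise=NoiseModel(sigma=0.05), seed=3)
    suite_to_frame(suite).to_csv(OUT / "synthetic_suite.csv", index=False)
    n_points = sum(len(d.values) for d in suite)
    print(f"synthetic corpus: {len(suite)} datasets, {n_points} points")

    start_vals = dict(params.values)
    for pid in FREE:
        start_vals[pid] *= 1.5
    fit = pattern_search_fit(net, ParameterSet.with_default_bounds(start_vals),
                             FREE, suite, state, max_iterations=60, seed=0)
    df, summary = evaluate_recovery(params, fit, FREE)
    df.to_csv(OUT / "recovery.csv", index=False)
    (OUT / "fit_summary.json").write_text(json.dumps({
        "objective_start": fit.start_objective, "objective": fit.objective,
        "iterations": fit.iterations, "evaluations": fit.n_evaluations,
        "converged": fit.converged, **summary}, indent=2))
    print(df.to_string(index=False))
    print(f"median relative error {summary['median_rel_error']:.1%}, "
          f"objective {fit.start_objective:.1f} -> {fit.objective:.1f}")


if __name__ == "__main__":
    main()
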