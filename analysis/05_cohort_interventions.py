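"""Virtual-cell cohort screening of target interventions under OGD/R.

Simulates a standard-cell dose response for each candidate target
(succinate, p53, HIF1a, IkB), then a heterogeneous 100-cell cohort with
paired control vs succinate-inhibition (0.5x-0.8x) runs, and summarizes
the population-level cell-function (CF) fold changes.

Findings: on the standard cell, reducing succinate availability gives the
strongest CF rescue (monotone in inhibition strength); p53 and HIF1a
inhibition are protective at moderate strength (the benefit saturates and
reverses at very strong inhibition because the p53 -> TIGAR -> NADPH
antioxidant arm is lost); IkB-synthesis inhibition unleashes NFkB and
lowers CF.  In the seeded cohort, succinate inhibition improves the
endpoint CF in ~100% of cells with a median fold change > 2.
"""

from pathlib import Path
import json

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from bmecsim import (
    DEFAULT_VARIED_PARAMETERS,
    apply_intervention,
    default_model,
    find_quiescent_state,
    generate_cohort,
    simulate_cohort,
    simulate_target_modulation,
    summarize_cohort,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    net, params = default_model()
    state, report = find_quiescent_state(net, params)
    assert report.success

    print("standard-cell target modulation (endpoint CF, OGD 6 h / R 24 h):")
    rows = []
    for target in ("succinate", "p53", "HIF1a", "IkB"):
        for strength in (0.8, 0.6, 0.4):
            treated, control = simulate_target_modulation(
                net, params, state, target, strength
            )
            rows.append({"target": target, "strength": strength,
                         "cf_treated": treated.cell_function[-1],
                         "cf_control": control.cell_function[-1]})
            print(f"  {target:10s} x{strength}: CF "
                  f"{treated.cell_function[-1]:.4f} "
                  f"(control {control.cell_function[-1]:.4f})")
    import pandas as pd

    pd.DataFrame(rows).to_csv(OUT / "target_modulation.csv", index=False)

    cells = generate_cohort(params, DEFAULT_VARIED_PARAMETERS, 100, seed=7)
    treated_cells = apply_intervention(cells, "succinate", 0.5, 0.8, seed=11)
    control = simulate_cohort(net, params, cells, state)
    treated = simulate_cohort(net, params, treated_cells, state)
    summary = summarize_cohort(treated, control)
    control.endpoints().merge(
        treated.endpoints(), on="cell_id", suffixes=("_control", "_treated")
    ).to_csv(OUT / "cohort_endpoints.csv", index=False)
    (OUT / "cohort_summary.json").write_text(json.dumps(
        {k: v for k, v in summary.items() if k != "cell_ids"}, indent=2))

    folds = np.array(summary["fold_changes"])
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    for cid in list(control.scores)[:40]:
        axes[0].plot(control.scores[cid].times,
                     control.scores[cid].cell_function, color="0.6", lw=0.6)
        axes[0].plot(treated.scores[cid].times,
                     treated.scores[cid].cell_function, color="#27ae60",
                     lw=0.6)
    axes[0].set(yscale="log", xlabel="time since OGD onset (h)",
                ylabel="CF score", title="per-cell CF (grey ctrl, green rx)")
    axes[1].hist(np.log2(folds), bins=20, color="#27ae60")
    axes[1].axvline(0, color="k")
    axes[1].set(xlabel="log2 CF fold change", title="succinate inhibition")
    axes[2].boxplot([np.log2(folds)], tick_labels=["succinate 0.5-0.8x"])
    axes[2].axhline(0, color="k", lw=0.5)
    axes[2].set(ylabel="log2 CF fold change")
    fig.tight_layout()
    fig.savefig(OUT / "cohort_summary.png", dpi=150)

    print(f"\ncohort (n=100): median CF fold change {summary['median']:.2f}, "
          f"IQR [{summary['q1']:.2f}, {summary['q3']:.2f}], "
          f"fraction improved {summary['fraction_improved']:.2f}")


if __name__ == "__main__":
    main()
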