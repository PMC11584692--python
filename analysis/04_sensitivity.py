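"""Global sensitivity analysis of the OGD/R response.

Latin-hypercube samples all rate constants on 0.5x-2x multipliers
(default 1000 runs here; pass --samples 5000 for the full-depth analysis)
and computes PRCC against the four outputs: inflammation, growth-factor
and tight-junction module products, and the composite cell-function (CF)
score, each at the end of reoxygenation after OGD 6 h / reox 24 h.

Findings (seed 1, n=1000): succinate synthesis/turnover (kt_Succinate,
kd_Succinate), reverse-electron-transport ROS production (k_ROS_RET) and
the Keap1/NRF2 antioxidant axis dominate the tight-junction and CF
outputs; the inflammation output adds the IkB-mRNA feedback (kd_IKB_mrna)
and PHD/HIF parameters dominate the growth-factor output.  This ranking
motivates the virtual-cohort target set in 05_cohort_interventions.py.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from bmecsim import default_model, find_quiescent_state
from bmecsim.sensitivity import evaluate_design, lhs_sample, prcc, rank_targets

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--samples", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    OUT.mkdir(exist_ok=True)
    net, params = default_model()
    state, report = find_quiescent_state(net, params)
    assert report.success

    pids = sorted(params.values)
    design = lhs_sample(pids, args.samples, seed=args.seed)
    outputs = evaluate_design(net, params, design, state)
    result = prcc(design, outputs)
    result.to_frame().to_csv(OUT / "prcc.csv", index=False)

    fig, axes = plt.subplots(1, 4, figsize=(16, 5))
    for ax, oid in zip(axes, result.output_ids):
        top = rank_targets(result, oid, top_k=12)
        names = [p for p, _, _ in top][::-1]
        vals = [r for _, r, _ in top][::-1]
        ax.barh(names, vals, color=["#c0392b" if v > 0 else "#2980b9"
                                    for v in vals])
        ax.set_title(oid)
        ax.set_xlabel("PRCC")
        ax.axvline(0, color="k", lw=0.5)
    fig.tight_layout()
    fig.savefig(OUT / "prcc_tornado.png", dpi=150)

    for oid in result.output_ids:
        top = rank_targets(result, oid, top_k=10)
        print(f"{oid}: " + ", ".join(f"{p} ({r:+.2f})" for p, r, _ in top))
    print(f"\nwrote {OUT / 'prcc.csv'}")


if __name__ == "__main__":
    main()
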