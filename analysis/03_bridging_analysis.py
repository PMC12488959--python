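#!/usr/bin/env python
"""Run the within-subject bridging analysis on the simulated cohort.

Reads scratch/bridging_cohort.csv, produces group summaries of the
original/revised raw scores and their paired differences, signed-rank and
rank-sum tests, direction counts and Bland-Altman agreement, and — using
the packaged published revised-test norms together with the synthetic norm
set from 02 as a stand-in for the original test's norms — the
percentile-scale comparison.  Writes results/bridging_result.json and the
Bland-Altman scatter data.

Usage: python analysis/03_bridging_analysis.py
"""

import json
from pathlib import Path

from upsit_norms import load_norms, read_participants, run_bridging

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    src = ROOT / "scratch" / "bridging_cohort.csv"
    norms_path = ROOT / "results" / "synthetic_norms.json"
    if not src.exists() or not norms_path.exists():
        raise SystemExit("run analysis/01 and analysis/02 first")

    records = read_participants(src)
    norms_revised = load_norms("upsit_r_2020")
    norms_original = load_norms(norms_path)  # synthetic stand-in

    result = run_bridging(records, norms_original=norms_original,
                          norms_revised=norms_revised)

    out = ROOT / "results" / "bridging_result.json"
    out.write_text(json.dumps(result.to_dict(), indent=1) + "\n", encoding="utf-8")

    ba = result.bland_altman
    with (ROOT / "results" / "bland_altman_pairs.csv").open("w", encoding="utf-8") as fh:
        fh.write("pair_mean,pair_diff,group\n")
        complete = [r for r in records if r.complete]
        for r, m, d in zip(complete, ba.pair_means, ba.pair_diffs):
            fh.write(f"{m:g},{d:g},{r.group}\n")

    print("raw-score results (revised minus original):")
    for g, summ in result.group_summaries.items():
        d = summ["difference"]
        sr = result.signed_rank[g]
        print(f"  {g}: mean diff {d.mean:+.2f} (SD {d.sd:.2f}), "
              f"median {d.median:g} (IQR {d.q1:g}-{d.q3:g}), "
              f"signed-rank p = {sr.p_value:.2e} [{sr.method}]")
    dc = result.directions
    print(f"  direction: {dc.higher} higher ({dc.percentages[0]}%), "
          f"{dc.lower} lower ({dc.percentages[1]}%), "
          f"{dc.same} same ({dc.percentages[2]}%)")
    print(f"  Bland-Altman: mean difference {ba.mean_difference:.2f}, "
          f"limits [{ba.loa_low:.2f}, {ba.loa_high:.2f}]")
    if result.between_group_rank_sum is not None:
        print(f"  HC vs PD difference-of-differences rank-sum p = "
              f"{result.between_group_rank_sum.p_value:.4f}")
    if result.block_order_rank_sum is not None:
        print(f"  block-order rank-sum p = {result.block_order_rank_sum.p_value:.4f}")
    print("wrote results/bridging_result.json and results/bland_altman_pairs.csv")


if __name__ == "__main__":
    main()
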