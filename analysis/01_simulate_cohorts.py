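#!/usr/bin/env python
"""Simulate the two study cohorts at the published conditions.

Generates (i) the within-subject bridging cohort (89 healthy controls, 48
Parkinson's participants, paired original/revised smell-test scores) and
(ii) the large sex x age stratified normative cohort (16,972 subjects,
revised-test scores only), writes both as CSV under scratch/, and prints a
demographic summary table to results/.

Usage: python analysis/01_simulate_cohorts.py [--seed 1] [--scale 1.0]
"""

import argparse
from pathlib import Path

from upsit_norms import (
    default_bridging_params,
    default_cohort_params,
    demographic_summary,
    generate_bridging_cohort,
    generate_normative_cohort,
    stratified_score_summary,
    write_participants,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--scale", type=float, default=1.0,
                        help="shrink normative cell sizes for quick runs")
    args = parser.parse_args()

    scratch = ROOT / "scratch"
    results = ROOT / "results"
    scratch.mkdir(exist_ok=True)
    results.mkdir(exist_ok=True)

    bridging = generate_bridging_cohort(default_bridging_params(args.seed))
    write_participants(bridging, scratch / "bridging_cohort.csv")
    print(f"bridging cohort: {len(bridging)} records "
          f"({sum(r.group == 'HC' for r in bridging)} HC, "
          f"{sum(r.group == 'PD' for r in bridging)} PD) "
          f"-> scratch/bridging_cohort.csv")

    cohort = generate_normative_cohort(default_cohort_params(args.seed, scale=args.scale))
    write_participants(cohort, scratch / "normative_cohort.csv")
    print(f"normative cohort: {len(cohort)} records -> scratch/normative_cohort.csv")

    demo = demographic_summary(cohort, ["sex"])
    demo.to_csv(results / "cohort_demographics.csv", index=False)

    cells = stratified_score_summary(cohort)
    print("\nper-cell revised-score summaries (n, mean, sd):")
    for (sex, cat), s in cells.items():
        print(f"  {sex:6s} {cat:5s}  n={s.n:5d}  mean={s.mean:5.2f}  sd={s.sd:4.2f}")


if __name__ == "__main__":
    main()
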