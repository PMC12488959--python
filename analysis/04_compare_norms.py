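#!/usr/bin/env python
"""Compare the packaged published norms against the synthetic norm set.

For each sex x age cell: the difference in summary mean raw scores and the
shifts in the raw scores defining the <=25th/20th/15th/10th percentile
screening cutoffs (synthetic minus published).  This mirrors how an updated
test's norms are compared against an older edition's; here the second norm
set is the synthetic one from 02, so the values characterise the generator,
not a real test revision.

Usage: python analysis/04_compare_norms.py
"""

import json
from pathlib import Path

from upsit_norms import compare_norm_sets, load_norms

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    norms_path = ROOT / "results" / "synthetic_norms.json"
    if not norms_path.exists():
        raise SystemExit("run analysis/02_build_norms.py first")

    published = load_norms("upsit_r_2020")
    synthetic = load_norms(norms_path)
    comparison = compare_norm_sets(published, synthetic)

    out = ROOT / "results" / "norm_comparison.json"
    out.write_text(json.dumps(comparison.to_dict(), indent=1) + "\n", encoding="utf-8")
    comparison.to_dataframe().to_csv(ROOT / "results" / "norm_comparison.csv", index=False)

    print("cell-wise differences (synthetic minus published):")
    print(comparison.to_dataframe().to_string(index=False))
    print("wrote results/norm_comparison.json and results/norm_comparison.csv")


if __name__ == "__main__":
    main()
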