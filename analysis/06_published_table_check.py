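#!/usr/bin/env python
"""Recompute the published shift-table p-values from their (k, n) counts
under both tail conventions, showing that the asymmetric convention
reproduces every printed value and the symmetric one does not.
"""

import argparse
from pathlib import Path

from c3c4niche import pipeline

parser = argparse.ArgumentParser()
parser.add_argument("--workdir", type=Path, default=Path("results/analysis"))
args = parser.parse_args()
args.workdir.mkdir(parents=True, exist_ok=True)

for method in ("paper", "symmetric"):
    table = pipeline.reproduce_table4(sign_method=method)
    table.to_csv(
        args.workdir / f"shift_table_{method}.csv", index=False, float_format="%.6g"
    )
    n_match = int(table["match"].sum())
    print(f"{method:10s}: {n_match}/{len(table)} printed p-values reproduced; "
          f"stars reproduced: {bool(table['star_match'].all())}")

table = pipeline.reproduce_table4()
stars = table[table["significant"]]
print("\nsignificant shifts at p < 0.00625 (all in the intermediates-vs-C3 "
      "comparison restricted to lineages with C4 relatives):")
print(stars[["variable", "k", "n", "p"]].to_string(index=False))
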