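#!/usr/bin/env python
"""Overlay the retained occurrences onto the environmental rasters and write
the occurrence x variable environment matrix.
"""

import argparse
from pathlib import Path

from c3c4niche import env_extraction as ee
from c3c4niche import occurrence_qc as qc
from c3c4niche import rasters

parser = argparse.ArgumentParser()
parser.add_argument("--indir", type=Path, default=Path("results/analysis/synthetic"))
parser.add_argument("--workdir", type=Path, default=Path("results/analysis"))
args = parser.parse_args()

records = qc.read_occurrences(args.workdir / "occurrences_qc.csv")
retained = []
for rec in records:
    status = rec.extra.get("status", "retained")
    if status == "retained":
        retained.append(rec)

layers = {}
for path in sorted((args.indir / "rasters").glob("*.asc")):
    if path.stem == "landmask":
        continue
    layers[path.stem] = rasters.read_ascii_grid(path)

matrix = ee.assemble_env_matrix(retained, layers)
ee.write_env_matrix(matrix, args.workdir / "env_matrix.csv")

n_missing = int(matrix[ee.env_variables(matrix)].isna().sum().sum())
print(f"environment matrix: {matrix.shape[0]} occurrences x "
      f"{len(ee.env_variables(matrix))} variables ({n_missing} missing lookups)")
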