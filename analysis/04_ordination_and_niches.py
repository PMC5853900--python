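#!/usr/bin/env python
"""Summarize occurrence-level environments: correlation-matrix PCAs of the
climate and soil variables, per-species medians, lineage mean-of-medians,
the descriptive range table, and a MAT-MAP biome quicklook figure.
"""

import argparse
from pathlib import Path

from c3c4niche import env_extraction as ee
from c3c4niche import niche_summary as ns
from c3c4niche import ordination as ord_
from c3c4niche import pipeline

parser = argparse.ArgumentParser()
parser.add_argument("--indir", type=Path, default=Path("results/analysis/synthetic"))
parser.add_argument("--workdir", type=Path, default=Path("results/analysis"))
args = parser.parse_args()

matrix = ee.read_env_matrix(args.workdir / "env_matrix.csv")
groups = ns.read_membership(args.indir / "membership.csv")

climate_vars = [v for v in ee.CLIMATE_VARIABLES if v in matrix.columns]
soil_vars = [v for v in ee.SOIL_VARIABLES if v in matrix.columns]
climate_pca = ord_.fit_pca(matrix, climate_vars)
soil_pca = ord_.fit_pca(matrix, soil_vars)
matrix = ord_.pc_scores_as_variables(climate_pca, matrix, "climate")
matrix = ord_.pc_scores_as_variables(soil_pca, matrix, "soil")
ee.write_env_matrix(matrix, args.workdir / "env_matrix_pca.csv")
(args.workdir / "pca_climate.json").write_text(climate_pca.to_json())
(args.workdir / "pca_soil.json").write_text(soil_pca.to_json())

niches = ns.all_species_medians(matrix)
ns.group_niche_table(niches, groups).to_csv(
    args.workdir / "group_niches.csv", index=False, float_format="%.12g"
)
ns.range_table(matrix, groups).to_csv(
    args.workdir / "range_table.csv", index=False, float_format="%.12g"
)
pipeline.quicklook_plot(matrix, args.workdir / "mat_map_biomes.png")

print(f"climate PCA: PC1 explains {climate_pca.explained_pct[0]:.2f}% "
      f"(PC2 {climate_pca.explained_pct[1]:.2f}%) of {len(climate_vars)} variables")
print(f"soil PCA: PC1 explains {soil_pca.explained_pct[0]:.2f}% "
      f"(PC2 {soil_pca.explained_pct[1]:.2f}%) of {len(soil_vars)} variables")
print(f"species medians: {len(niches)}; outputs in {args.workdir}")
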