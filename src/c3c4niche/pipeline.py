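"""End-to-end orchestration: QC -> extraction -> ordination -> summaries -> tests.

A single :class:`RunConfig` drives the whole chain and every artifact it
writes carries the config hash, so two runs with equal hashes are byte
identical (CSV floats are formatted to 12 significant digits, JSON keys are
sorted).
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import occurrence_qc as qc
from . import env_extraction as ee
from . import niche_summary as ns
from . import ordination as ord_
from . import contrast_tests as ct
from . import rasters

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    occurrences: str = ""
    membership: str = ""
    rasters: dict = field(default_factory=dict)      # variable -> raster path
    monthly_tmean: list = field(default_factory=list)  # 12 paths or 1 multiband
    monthly_tmin: list = field(default_factory=list)
    monthly_prec: list = field(default_factory=list)
    landmask: str = ""
    radius_km: float = qc.DEFAULT_RADIUS_KM
    digits: int = 2  # rounding resolution of the deduplication filter
    variables: list = field(default_factory=lambda: list(ct.DEFAULT_TEST_VARIABLES))
    alpha: float = 0.05
    m: int | None = None
    sign_method: str = "paper"
    pca_axes: int = 2
    seed: int = 0
    outdir: str = "results"

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _load_stack(paths, variable) -> rasters.MonthlyStack:
    if len(paths) == 1:
        stack = rasters.read_raster(paths[0], variable)
        if not isinstance(stack, rasters.MonthlyStack):
            raise ValueError(f"{paths[0]} is not a 12-band stack")
        return stack
    return rasters.stack_from_files(paths, variable)


def _build_layers(config: RunConfig) -> dict[str, rasters.EnvGrid]:
    layers: dict[str, rasters.EnvGrid] = {}
    if config.monthly_tmean and config.monthly_prec:
        tmean = _load_stack(config.monthly_tmean, "tmean")
        prec = _load_stack(config.monthly_prec, "prec")
        layers.update(ee.derive_bioclim(tmean, prec))
        layers["rainfall_seasonality"] = ee.rainfall_seasonality(prec)
        if config.monthly_tmin:
            tmin = _load_stack(config.monthly_tmin, "tmin")
            layers["minimum_temperature"] = ee.derive_bioclim(tmin, prec)[
                "minimum_temperature"
            ]
    for variable, path in sorted(config.rasters.items()):
        grid = rasters.read_raster(path, variable)
        if not isinstance(grid, rasters.EnvGrid):
            raise ValueError(f"{path}: expected a single-band layer for {variable}")
        layers[variable] = grid
    return layers


def _load_mask(config: RunConfig) -> rasters.LandMask | None:
    if not config.landmask:
        return None
    grid = rasters.read_raster(config.landmask, "landmask")
    return rasters.LandMask(grid.spec, grid.values > 0.5)


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the in-memory artifact bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        records = qc.read_occurrences(config.occurrences)
        groups = ns.read_membership(config.membership)
    except (OSError, ValueError) as e:
        raise StageError("inputs", str(e)) from e

    try:
        mask = _load_mask(config)
        qc_cfg = qc.QcConfig(radius_km=config.radius_km, digits=config.digits)
        records, report = qc.clean(records, mask, qc_cfg)
        report.to_csv(outdir / "qc_report.csv")
        _write_json(report.totals, outdir / "qc_totals.json")
        qc.write_occurrences(records, outdir / "occurrences_qc.csv")
    except (OSError, ValueError) as e:
        raise StageError("qc", str(e)) from e

    try:
        layers = _build_layers(config)
        matrix = ee.assemble_env_matrix(records, layers)
    except (OSError, ValueError) as e:
        raise StageError("extract", str(e)) from e

    models = {}
    try:
        climate_vars = [v for v in ee.CLIMATE_VARIABLES if v in matrix.columns]
        soil_vars = [v for v in ee.SOIL_VARIABLES if v in matrix.columns]
        if len(climate_vars) >= 2:
            models["climate"] = ord_.fit_pca(matrix, climate_vars)
            matrix = ord_.pc_scores_as_variables(
                models["climate"], matrix, "climate", config.pca_axes
            )
        if len(soil_vars) >= 2:
            models["soil"] = ord_.fit_pca(matrix, soil_vars)
            matrix = ord_.pc_scores_as_variables(
                models["soil"], matrix, "soil", config.pca_axes
            )
        for name, model in models.items():
            (outdir / f"pca_{name}.json").write_text(model.to_json())
        ee.write_env_matrix(matrix, outdir / "env_matrix.csv")
    except ValueError as e:
        raise StageError("ordination", str(e)) from e

    try:
        niches = ns.all_species_medians(matrix)
        gn_table = ns.group_niche_table(niches, groups)
        gn_table.sort_values(["lineage", "type", "variable"]).to_csv(
            outdir / "group_niches.csv", index=False, float_format=FLOAT_FMT
        )
        ranges = ns.range_table(matrix, groups)
        ranges.to_csv(outdir / "range_table.csv", index=False, float_format=FLOAT_FMT)
        group_niches = [
            ns.group_mean_of_medians(niches, g, t)
            for g in groups
            for t in ns.PHOTOSYNTHETIC_TYPES
            if g.members[t]
        ]
    except (KeyError, ValueError) as e:
        raise StageError("summarize", str(e)) from e

    try:
        test_vars = [
            v
            for v in config.variables
            if any(v in gn.values for gn in group_niches if gn is not None)
        ]
        suite = ct.run_contrast_suite(
            group_niches,
            variables=test_vars,
            alpha=config.alpha,
            m=config.m if config.m is not None else len(config.variables),
            sign_method=config.sign_method,
        )
        suite.to_csv(outdir / "suite_report.csv", index=False, float_format=FLOAT_FMT)
        _write_json(
            {"tests": suite.to_dict(orient="records")}, outdir / "suite_report.json"
        )
    except ValueError as e:
        raise StageError("contrasts", str(e)) from e

    _write_json(
        {
            "config": asdict(config),
            "config_hash": config.hash(),
            "seed": config.seed,
            "versions": {
                "c3c4niche": __version__,
                "python": platform.python_version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        },
        outdir / "run_log.json",
    )
    return {
        "records": records,
        "matrix": matrix,
        "models": models,
        "niches": niches,
        "group_niches": group_niches,
        "range_table": ranges,
        "suite": suite,
        "qc_report": report,
    }


# ---------------------------------------------------------------------------
# In-table worked example: the shift-count table

def load_table4_counts() -> pd.DataFrame:
    """Packaged shift counts (k, n) and printed p-values of the published table."""
    ref = resources.files("c3c4niche.data").joinpath("table4_counts.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, dtype={"printed_p": str})


def _decimals(printed: str) -> int:
    return len(printed.split(".")[1]) if "." in printed else 0


def reproduce_table4(sign_method: str = "paper") -> pd.DataFrame:
    """Recompute every published sign-test p-value from its (k, n) counts.

    A row matches when the recomputed p, rounded to the printed number of
    decimals, equals the printed value, and the significance flag at the
    0.00625 threshold equals the printed star.
    """
    counts = load_table4_counts()
    threshold = ct.corrected_threshold(0.05, 8)
    rows = []
    for row in counts.itertuples(index=False):
        p = ct.sign_test(int(row.k), int(row.n), method=sign_method)
        rounded = round(p, _decimals(row.printed_p))
        match = rounded == float(row.printed_p)
        sig = p < threshold
        rows.append(
            {
                "variable": row.variable,
                "comparison": row.comparison,
                "k": row.k,
                "n": row.n,
                "p": p,
                "printed_p": float(row.printed_p),
                "match": match,
                "significant": sig,
                "printed_significant": bool(row.printed_significant),
                "star_match": sig == bool(row.printed_significant),
            }
        )
    return pd.DataFrame(rows)


def quicklook_plot(matrix: pd.DataFrame, path) -> None:
    """MAT-MAP scatter over the packaged biome polygons (descriptive only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for name, poly in ns._biome_polygons():
        xs, ys = poly.exterior.xy
        ax.fill(xs, ys, alpha=0.15)
        cx, cy = poly.centroid.x, poly.centroid.y
        ax.annotate(name, (cx, cy), ha="center", fontsize=8)
    sub = matrix.dropna(subset=["MAT", "MAP"])
    ax.scatter(sub["MAT"], sub["MAP"], s=4, c="k", alpha=0.4)
    ax.set_xlabel("MAT (degC)")
    ax.set_ylabel("MAP (mm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
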