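"""Synthetic worlds, lineages and occurrence records with full ground truth.

No machine-readable occurrence/raster bundle accompanies the study design
this package implements, so every pipeline stage is validated against data
generated here.  The generator emulates the statistical structure the
analysis assumes, with dials for exactly the quantities the inference is
about:

* a regional raster world with latitude-driven temperature, an equatorial
  precipitation belt, latitude-scaled seasonal amplitude, and smooth random
  soil/elevation fields within plausible topsoil ranges;
* lineages whose per-variable base niche ``b_l`` carries a lineage-level
  spread ``sigma_L`` and whose member species scatter around it with spread
  ``sigma_S``; the conservatism index ``rho = sigma_L^2 / (sigma_L^2 +
  sigma_S^2)`` interpolates between fully independent sister niches (0) and
  perfectly conserved ones (1);
* additive type shifts ``delta`` applied to C3-C4 and C4 species optima;
* per-species occurrence sampling over land cells with a separable Gaussian
  suitability kernel (width ``tau_v`` per variable), uniform jitter within
  the cell;
* injected record errors (duplicates, off-land points, institution-proximity
  points, out-of-range coordinates) at configured rates, logged one-to-one
  in the ground truth.

Clean records are generated collision-free at the QC rounding resolution and
outside the institution-proximity zone, so "clean" in the ground truth means
"should survive QC" and recovery rates are exact bookkeeping, not luck.

Randomness: one integer seed feeds a ``numpy.random.SeedSequence``; children
are spawned in the fixed order (world, lineages, occurrences, errors), so
each stage's stream is independent and reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage

from .occurrence_qc import (
    GBIF_HEADQUARTERS,
    DEFAULT_RADIUS_KM,
    OccurrenceRecord,
    haversine_km,
    round_half_away,
)
from .niche_summary import ComparisonGroup, GroupNiche, PHOTOSYNTHETIC_TYPES
from .rasters import EnvGrid, GridSpec, LandMask, MonthlyStack
from .env_extraction import derive_bioclim, rainfall_seasonality

#: Natural per-variable scales (1 sigma of a "typical" niche spread) and global
#: centres used by the world-free lineage simulation.  Units follow the
#: variable registry.
VARIABLE_BASELINES = {
    "climate_PC1": (0.0, 1.5),
    "soil_PC1": (0.0, 1.5),
    "MAT": (18.0, 6.0),
    "MAP": (1200.0, 600.0),
    "growing_season_temperature": (20.0, 5.0),
    "minimum_temperature": (8.0, 7.0),
    "minimum_precipitation": (40.0, 25.0),
    "rainfall_seasonality": (45.0, 18.0),
    "organic_carbon": (2.0, 1.2),
    "TEB": (25.0, 12.0),
    "CEC": (25.0, 12.0),
    "pH": (6.5, 0.8),
}


@dataclass
class WorldConfig:
    """Geometry and texture of the synthetic raster world.

    The default extent (lon -25..65, lat -40..70 at 2 degree cells) is
    regional on purpose: it contains the Copenhagen institution-proximity
    centre and leaves off-extent space for planted off-land errors.
    """

    west: float = -25.0
    north: float = 70.0
    cell_size: float = 2.0
    nrows: int = 55
    ncols: int = 45
    nodata: float = -9999.0
    equator_temperature: float = 28.0   # degC at lat 0
    lapse_per_degree: float = 0.55      # degC cooling per degree |lat|
    seasonal_amp_per_degree: float = 0.25   # monthly amplitude growth with |lat|
    diurnal_offset: float = 6.0         # tmean minus monthly minimum, degC
    map_equator: float = 2500.0         # mm, peak of the wet equatorial belt
    map_base: float = 150.0             # mm, background precipitation
    belt_width_degrees: float = 40.0
    temperature_noise_sd: float = 2.0
    precipitation_noise_sd: float = 0.25  # log-scale multiplicative noise
    smoothing_cells: float = 3.0
    ocean_fraction: float = 0.0         # all-land unless blobs requested
    seed: int = 0

    @property
    def grid_spec(self) -> GridSpec:
        return GridSpec(
            west=self.west, north=self.north, cell_size=self.cell_size,
            nrows=self.nrows, ncols=self.ncols, nodata=self.nodata,
        )


@dataclass
class SyntheticWorld:
    config: WorldConfig
    tmean: MonthlyStack        # monthly mean temperature, degC
    tmin: MonthlyStack         # monthly minimum temperature, degC
    prec: MonthlyStack         # monthly precipitation totals, mm
    soils: dict[str, EnvGrid]  # organic_carbon, TEB, CEC, pH
    elevation: EnvGrid
    mask: LandMask

    def env_layers(self) -> dict[str, EnvGrid]:
        """All derivable EnvGrids keyed by registry name."""
        layers = derive_bioclim(self.tmean, self.prec)
        # conventional minimum temperature uses the monthly-minimum stack
        layers["minimum_temperature"] = derive_bioclim(self.tmin, self.prec)[
            "minimum_temperature"
        ]
        layers["rainfall_seasonality"] = rainfall_seasonality(self.prec)
        layers.update(self.soils)
        layers["altitude"] = self.elevation
        return layers


def _smooth_field(rng: np.random.Generator, shape, scale_cells: float) -> np.ndarray:
    """Unit-variance spatially smooth Gaussian field."""
    noise = rng.standard_normal(shape)
    if scale_cells > 0:
        noise = ndimage.gaussian_filter(noise, sigma=scale_cells, mode="reflect")
        sd = noise.std()
        if sd > 0:
            noise = noise / sd
    return noise


def _squash(field: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Map a ~N(0,1) field into (lo, hi) through a logistic curve."""
    return lo + (hi - lo) / (1.0 + np.exp(-field))


def make_world(config: WorldConfig | None = None) -> SyntheticWorld:
    """Deterministically generate the raster world for a config (and its seed)."""
    config = config or WorldConfig()
    spec = config.grid_spec
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    lat, _lon = spec.cell_centers()
    shape = lat.shape

    t_annual = (
        config.equator_temperature
        - config.lapse_per_degree * np.abs(lat)
        + config.temperature_noise_sd * _smooth_field(rng, shape, config.smoothing_cells)
    )
    amplitude = config.seasonal_amp_per_degree * np.abs(lat)
    months = np.arange(12)
    # warm peak in July north of the equator, January south of it
    phase = np.cos(2.0 * np.pi * (months[:, None, None] - 6) / 12.0)
    tmean_layers = t_annual[None] + np.sign(lat)[None] * amplitude[None] * phase
    tmin_layers = tmean_layers - config.diurnal_offset

    map_field = (
        config.map_base
        + config.map_equator * np.exp(-((lat / config.belt_width_degrees) ** 2))
    ) * np.exp(
        config.precipitation_noise_sd * _smooth_field(rng, shape, config.smoothing_cells)
    )
    concentration = np.clip(
        0.2 + np.abs(lat) / 90.0 + 0.3 * _smooth_field(rng, shape, config.smoothing_cells),
        0.0, 0.95,
    )
    weights = (1.0 + concentration[None] * phase) / 12.0
    prec_layers = map_field[None] * weights

    soils = {
        "organic_carbon": _squash(_smooth_field(rng, shape, config.smoothing_cells) * 1.5, 0.05, 40.0),
        "TEB": _squash(_smooth_field(rng, shape, config.smoothing_cells), 0.5, 80.0),
        "CEC": _squash(_smooth_field(rng, shape, config.smoothing_cells), 0.5, 90.0),
        "pH": _squash(_smooth_field(rng, shape, config.smoothing_cells), 3.0, 10.0),
    }
    elevation = 500.0 * np.maximum(_smooth_field(rng, shape, config.smoothing_cells) + 1.0, 0.0) ** 2

    if config.ocean_fraction > 0:
        blob = _smooth_field(rng, shape, config.smoothing_cells)
        cut = np.quantile(blob, config.ocean_fraction)
        land = blob >= cut
    else:
        land = np.ones(shape, dtype=bool)

    return SyntheticWorld(
        config=config,
        tmean=MonthlyStack(spec, "tmean", tmean_layers),
        tmin=MonthlyStack(spec, "tmin", tmin_layers),
        prec=MonthlyStack(spec, "prec", prec_layers),
        soils={k: EnvGrid(spec, k, v) for k, v in soils.items()},
        elevation=EnvGrid(spec, "altitude", elevation),
        mask=LandMask(spec, land),
    )


# ---------------------------------------------------------------------------
# Lineages

@dataclass
class LineageConfig:
    """Generative knobs for comparison lineages and their species niches.

    ``sigma_L`` / ``sigma_S`` are in units of each variable's natural scale
    (see VARIABLE_BASELINES), so the conservatism index rho is variable-free.
    Defaults mirror the study design: 19 lineages of which 5 lack a close C4
    sister, tested on the suite's variable roster.
    """

    n_lineages: int = 19
    fraction_without_c4: float = 5.0 / 19.0
    species_per_type: int = 3
    occurrences_per_species: int = 100
    sigma_L: float = 1.0
    sigma_S: float = 1.0
    variables: tuple[str, ...] = (
        "growing_season_temperature",
        "minimum_temperature",
        "minimum_precipitation",
        "rainfall_seasonality",
        "organic_carbon",
        "TEB",
        "climate_PC1",
        "soil_PC1",
    )
    delta_c3c4: dict = field(default_factory=dict)   # variable -> shift for C3-C4
    delta_c4: dict = field(default_factory=dict)     # variable -> shift for C4
    #: Gaussian suitability widths; also selects the variables the sampler uses.
    #: The default is a single thermal axis: with a multi-variable kernel over
    #: spatially correlated fields, the occurrence median is an
    #: availability-confounded estimator of the optimum, whereas the
    #: one-variable kernel keeps median recovery a clean consistency check.
    tau: dict = field(default_factory=lambda: {"MAT": 1.0})
    # error-injection rates per clean record, mimicking typical aggregator noise
    duplicate_rate: float = 0.05
    off_land_rate: float = 0.02
    institution_rate: float = 0.01
    out_of_range_rate: float = 0.02
    radius_km: float = DEFAULT_RADIUS_KM
    seed: int = 0

    @property
    def rho(self) -> float:
        tot = self.sigma_L**2 + self.sigma_S**2
        return self.sigma_L**2 / tot if tot > 0 else 0.0


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    lineage_bases: dict[str, dict[str, float]]            # lineage -> var -> b_l
    species_optima: dict[str, dict[str, float]]           # species -> var -> optimum
    species_type: dict[str, str]
    species_lineage: dict[str, str]
    applied_delta: dict[str, dict[str, float]]            # type -> var -> delta
    injected_errors: list[dict] = field(default_factory=list)
    n_clean_records: int = 0

    def group_niches(self, groups: Sequence[ComparisonGroup]) -> list[GroupNiche]:
        """Mean-of-optima group niches (the noise-free analogue of the pipeline's
        mean of occurrence medians)."""
        out = []
        for g in groups:
            for t in PHOTOSYNTHETIC_TYPES:
                members = g.members[t]
                if not members:
                    continue
                variables = self.species_optima[members[0]].keys()
                values = {
                    v: float(np.mean([self.species_optima[s][v] for s in members]))
                    for v in variables
                }
                out.append(GroupNiche(lineage=g.lineage, type=t, values=values))
        return out


def _type_tag(t: str) -> str:
    return t.replace("-", "")


def simulate_lineages(
    config: LineageConfig, world: SyntheticWorld | None = None
) -> tuple[list[ComparisonGroup], GroundTruth]:
    """Draw lineage base niches and per-species optima.

    With a world, each lineage's base niche is the environment of a random
    land cell, and each species optimum is the environment of a land cell
    drawn with a Gaussian kernel of width ``sigma_S`` (in baseline units)
    around the base-plus-shift target.  Optima therefore always lie on the
    jointly realizable environmental manifold, which is what makes
    median-recovery against ground truth meaningful.  Without a world, bases
    and optima are free Gaussian draws around the global baselines.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    for d in (config.delta_c3c4, config.delta_c4):
        unknown = set(d) - set(config.variables) - set(config.tau)
        if unknown:
            raise ValueError(f"type shift references unknown variables: {sorted(unknown)}")

    if world is not None:
        env = {name: g.masked() for name, g in world.env_layers().items()}
        land_idx = np.argwhere(world.mask.values)
        variables = list(config.tau)
    else:
        variables = list(config.variables)

    n_without_c4 = int(round(config.fraction_without_c4 * config.n_lineages))
    groups: list[ComparisonGroup] = []
    truth = GroundTruth(
        lineage_bases={}, species_optima={}, species_type={}, species_lineage={},
        applied_delta={"C3": {}, "C3-C4": dict(config.delta_c3c4), "C4": dict(config.delta_c4)},
    )
    for li in range(config.n_lineages):
        lineage = f"lineage{li + 1:02d}"
        if world is not None:
            r, c = land_idx[rng.integers(len(land_idx))]
            base = {v: float(env[v][r, c]) for v in variables}
        else:
            base = {
                v: VARIABLE_BASELINES[v][0]
                + config.sigma_L * VARIABLE_BASELINES[v][1] * rng.standard_normal()
                for v in variables
            }
        truth.lineage_bases[lineage] = base
        has_c4 = li >= n_without_c4
        members = {t: [] for t in PHOTOSYNTHETIC_TYPES}
        for t in PHOTOSYNTHETIC_TYPES:
            if t == "C4" and not has_c4:
                continue
            delta = truth.applied_delta[t]
            for si in range(config.species_per_type):
                species = f"{lineage}_{_type_tag(t)}_sp{si + 1}"
                if world is not None:
                    target = {v: base[v] + delta.get(v, 0.0) for v in variables}
                    dist2 = np.zeros(len(land_idx))
                    for v in variables:
                        scale = VARIABLE_BASELINES.get(v, (0.0, 1.0))[1]
                        vals = env[v][land_idx[:, 0], land_idx[:, 1]]
                        dist2 = dist2 + ((vals - target[v]) / scale) ** 2
                    if config.sigma_S > 0:
                        logw = -0.5 * dist2 / config.sigma_S**2
                        w = np.exp(logw - logw.max())
                        cell = rng.choice(len(land_idx), p=w / w.sum())
                    else:
                        cell = int(np.argmin(dist2))
                    r, c = land_idx[cell]
                    opt = {v: float(env[v][r, c]) for v in variables}
                else:
                    opt = {
                        v: base[v]
                        + delta.get(v, 0.0)
                        + config.sigma_S * VARIABLE_BASELINES.get(v, (0.0, 1.0))[1]
                        * rng.standard_normal()
                        for v in variables
                    }
                truth.species_optima[species] = opt
                truth.species_type[species] = t
                truth.species_lineage[species] = lineage
                members[t].append(species)
        groups.append(ComparisonGroup(lineage=lineage, members=members))
    return groups, truth


# ---------------------------------------------------------------------------
# Occurrences

def _within_institution(lat, lon, config: LineageConfig) -> bool:
    return haversine_km(lat, lon, *GBIF_HEADQUARTERS) <= config.radius_km


def simulate_occurrences(
    groups: Sequence[ComparisonGroup],
    truth: GroundTruth,
    world: SyntheticWorld,
    config: LineageConfig,
) -> list[OccurrenceRecord]:
    """Sample error-free records per species, then append planted errors.

    Clean records avoid the institution zone, the (0, 0) placeholder, and
    rounded-coordinate collisions within a taxon, so the QC ground truth is
    exact.  Error records are appended after the clean block (duplicates thus
    always follow the record they copy) and logged in ``truth``.
    """
    ss = np.random.SeedSequence(config.seed).spawn(4)
    rng = np.random.default_rng(ss[2])
    err_rng = np.random.default_rng(ss[3])
    spec = world.mask.spec
    env = {name: g.masked() for name, g in world.env_layers().items()}
    land_idx = np.argwhere(world.mask.values)

    records: list[OccurrenceRecord] = []
    seen_keys: set[tuple[str, float, float]] = set()
    for species in sorted(truth.species_optima):
        opt = truth.species_optima[species]
        logw = np.zeros(len(land_idx))
        for v, tau in config.tau.items():
            vals = env[v][land_idx[:, 0], land_idx[:, 1]]
            logw = logw - 0.5 * ((vals - opt[v]) / tau) ** 2
        w = np.exp(logw - logw.max())
        if not np.isfinite(w).all() or w.sum() <= 0:
            raise ValueError(f"species {species} has zero positive-suitability cells")
        w = w / w.sum()
        placed = 0
        while placed < config.occurrences_per_species:
            r, c = land_idx[rng.choice(len(land_idx), p=w)]
            for _ in range(200):
                lat = spec.north - (r + rng.random()) * spec.cell_size
                lon = spec.west + (c + rng.random()) * spec.cell_size
                key = (species, round_half_away(lat), round_half_away(lon))
                if (
                    key not in seen_keys
                    and not (lat == 0.0 and lon == 0.0)
                    and not _within_institution(lat, lon, config)
                ):
                    break
            else:
                continue  # cell exhausted at rounding resolution; draw a fresh cell
            seen_keys.add(key)
            records.append(OccurrenceRecord(taxon=species, latitude=lat, longitude=lon))
            placed += 1
    truth.n_clean_records = len(records)

    species_pool = sorted(truth.species_optima)
    n_clean = len(records)

    def n_errors(rate: float) -> int:
        return int(round(rate * n_clean))

    for _ in range(n_errors(config.duplicate_rate)):
        src = records[err_rng.integers(n_clean)]
        truth.injected_errors.append(
            {"kind": "duplicate", "taxon": src.taxon,
             "latitude": src.latitude, "longitude": src.longitude}
        )
    for _ in range(n_errors(config.off_land_rate)):
        taxon = species_pool[err_rng.integers(len(species_pool))]
        sea = np.argwhere(~world.mask.values)
        if len(sea):
            r, c = sea[err_rng.integers(len(sea))]
            lat, lon = spec.cell_center(int(r), int(c))
        else:  # all-land world: plant the point off the grid extent
            lat = float(err_rng.uniform(max(-89, spec.south - 20), spec.south - 1))
            lon = float(err_rng.uniform(spec.west, spec.east))
        truth.injected_errors.append(
            {"kind": "off_land", "taxon": taxon, "latitude": lat, "longitude": lon}
        )
    for _ in range(n_errors(config.institution_rate)):
        taxon = species_pool[err_rng.integers(len(species_pool))]
        while True:
            d = err_rng.uniform(0, 0.9 * config.radius_km)
            b = err_rng.uniform(0, 2 * np.pi)
            lat = GBIF_HEADQUARTERS[0] + (d / 111.19) * np.cos(b)
            lon = GBIF_HEADQUARTERS[1] + (
                d / (111.19 * np.cos(np.radians(GBIF_HEADQUARTERS[0])))
            ) * np.sin(b)
            if _within_institution(lat, lon, config) and spec.index_of(lat, lon) is not None:
                break
        truth.injected_errors.append(
            {"kind": "institution_proximity", "taxon": taxon,
             "latitude": float(lat), "longitude": float(lon)}
        )
    for _ in range(n_errors(config.out_of_range_rate)):
        taxon = species_pool[err_rng.integers(len(species_pool))]
        form = err_rng.integers(3)
        if form == 0:
            lat, lon = float(err_rng.uniform(90.5, 150)), 10.0
        elif form == 1:
            lat, lon = 10.0, float(err_rng.uniform(180.5, 300))
        else:
            lat, lon = 0.0, 0.0
        truth.injected_errors.append(
            {"kind": "out_of_range", "taxon": taxon, "latitude": lat, "longitude": lon}
        )

    for err in truth.injected_errors:
        records.append(
            OccurrenceRecord(
                taxon=err["taxon"], latitude=err["latitude"], longitude=err["longitude"]
            )
        )
    return records


# ---------------------------------------------------------------------------
# Recovery harness

def recover_parameters(
    species_medians: dict, truth: GroundTruth, config: LineageConfig
) -> dict:
    """Compare pipeline outputs with ground truth.

    Returns per-species median errors in units of tau_v for the suitability
    variables, plus realized lineage/species variance components (in baseline
    units) for the simulated niche variables.
    """
    errors = []
    for species, opt in truth.species_optima.items():
        niche = species_medians.get(species)
        if niche is None:
            continue
        for v, tau in config.tau.items():
            if v in niche.medians and v in opt:
                errors.append(
                    {
                        "species": species, "variable": v,
                        "abs_error_tau": abs(niche.medians[v] - opt[v]) / tau,
                    }
                )
    bases = truth.lineage_bases
    realized = {}
    for v in next(iter(bases.values())).keys():
        scale = VARIABLE_BASELINES.get(v, (0.0, 1.0))[1]
        base_vals = np.array([b[v] for b in bases.values()])
        resid = np.array(
            [
                truth.species_optima[s][v]
                - bases[truth.species_lineage[s]][v]
                - truth.applied_delta[truth.species_type[s]].get(v, 0.0)
                for s in truth.species_optima
            ]
        )
        var_l = base_vals.var(ddof=1) / scale**2
        var_s = resid.var(ddof=1) / scale**2
        realized[v] = {
            "sigma_L": float(np.sqrt(var_l)),
            "sigma_S": float(np.sqrt(var_s)),
            "rho": float(var_l / (var_l + var_s)) if var_l + var_s > 0 else 0.0,
        }
    return {
        "median_errors": errors,
        "realized_variance": realized,
        "configured_rho": config.rho,
        "config": asdict(config),
    }
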