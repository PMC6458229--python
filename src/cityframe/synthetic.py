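"""Synthetic country generator with known ground truth.

Every input the other modules consume can be generated here for a fully
synthetic country: a nested unit geography (city / sub-city / neighborhood
rectangles), a binary built-up raster with planted clusters, raw mortality
records with planted data-quality defects (garbage-coded causes, missing
values, registration undercount), sub-city population tables, and a pair of
city lists with planted match/absorb/standalone/contiguity structure. A
:class:`TruthLedger` records the pre-defect truth — true stratum death
rates and counts, cluster memberships and separations, reconciliation
labels — so recovery tests can score every pipeline stage without
re-generation.

Study conditions are the generator defaults: 10 sub-city units, 500,000
inhabitants, 5% missing age, 5% missing sex, 10% garbage-coded causes, and
registration completeness 0.85. Deaths are drawn per stratum as Poisson
with mean population × rate, the standard generative assumption for vital
statistics, which makes rate-recovery tests well-defined. Missingness is
completely at random by default (a conditional mode varying by age is
available to stress the conditional imputation). Every generator is a pure
function of its configuration, and each draws from a named substream of the
single seed, so adding one generator never perturbs another's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Point, box

from . import geo
from .correct import substream
from .extent import BuiltUpRaster
from .harmonize import AGE5_BANDS
from .reconcile import CityRecord

COUNTRY = "XX"


class SyntheticConfigError(ValueError):
    pass


#: age-band population shares: a young-leaning pyramid typical of the region
AGE_STRUCTURE = np.array(
    [8.7, 8.8, 9.0, 9.0, 8.6, 8.2, 7.6, 7.0, 6.4, 5.7,
     4.9, 4.1, 3.3, 2.6, 2.0, 1.5, 1.1, 1.5]
)
AGE_STRUCTURE = AGE_STRUCTURE / AGE_STRUCTURE.sum()

#: all-cause death rates per person-year by age band (male, female) —
#: a schedule with child mortality, an injury hump, and Gompertz-like old-age rates
DEATH_RATE_MALE = np.array(
    [0.0035, 0.0004, 0.0005, 0.0012, 0.0022, 0.0024, 0.0026, 0.0030, 0.0038,
     0.0052, 0.0075, 0.0112, 0.0170, 0.0262, 0.0407, 0.0646, 0.1040, 0.1900]
)
DEATH_RATE_FEMALE = np.array(
    [0.0028, 0.0003, 0.0003, 0.0005, 0.0007, 0.0009, 0.0012, 0.0017, 0.0024,
     0.0035, 0.0052, 0.0078, 0.0120, 0.0190, 0.0307, 0.0512, 0.0870, 0.1700]
)

#: cause-group mix among well-defined deaths and a representative ICD-10 code each
CAUSE_MIX = {
    "cardiovascular": (0.30, "I21"),
    "cancer": (0.20, "C50"),
    "infectious": (0.10, "A09"),
    "respiratory": (0.10, "J18"),
    "endocrine": (0.08, "E11"),
    "digestive": (0.07, "K70"),
    "road injury": (0.06, "V89"),
    "homicide": (0.05, "X95"),
    "suicide": (0.04, "X70"),
}

GARBAGE_DISEASE_CODES = ["R99", "R54", "R09"]
GARBAGE_INJURY_CODES = ["Y34", "Y10", "Y872"]

DEMO_SEX_CODEBOOK = {"1": "male", "2": "female"}
DEMO_EDUCATION_CODEBOOK = {
    "ed1": "less than primary",
    "ed2": "primary completed",
    "ed3": "secondary completed",
    "ed4": "more than secondary",
}


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic country; defaults are the study conditions."""

    seed: int = 0
    year: int = 2010
    # geography
    n_l1admin: int = 1
    n_l2: int = 10
    l3_per_l2: int = 4
    l2_tile_size: float = 5_000.0  # meters
    # population and mortality
    total_population: int = 500_000
    l2_rate_spread: float = 0.2  # ± relative spread of sub-city rate multipliers
    missing_age_rate: float = 0.05
    missing_sex_rate: float = 0.05
    missing_location_rate: float = 0.0
    garbage_rate: float = 0.10
    garbage_injury_share: float = 0.25
    completeness: float = 0.85
    age_dependent_missingness: bool = False
    # raster
    # blocks sized above the 1-km² classification window and separated by
    # more than its smearing scale, so the planted cluster count is recoverable
    raster_shape: tuple[int, int] = (400, 400)
    cell_size: float = 12.0
    planted_blocks: tuple[tuple[int, int, int, int], ...] = (
        (50, 40, 100, 100),   # (row0, col0, height, width)
        (50, 260, 100, 100),
        (260, 80, 100, 120),
    )
    noise_rate: float = 0.0
    # city-list reconciliation scenario
    n_matches: int = 12
    n_absorbed: int = 3
    n_standalone: int = 2
    n_contiguous_pairs: int = 1
    population_threshold: float = 100_000.0

    def __post_init__(self) -> None:
        for name in ("missing_age_rate", "missing_sex_rate", "missing_location_rate",
                     "garbage_rate", "garbage_injury_share", "noise_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SyntheticConfigError(f"{name}={v} outside [0, 1]")
        if not 0 < self.completeness <= 1:
            raise SyntheticConfigError(f"completeness={self.completeness} outside (0, 1]")
        if self.n_l2 % self.n_l1admin:
            raise SyntheticConfigError("n_l2 must divide evenly among L1Admin units")


@dataclass
class TruthLedger:
    """Planted ground truth, sufficient to score every recovery test."""

    true_rates: pd.DataFrame | None = None        # l2_code × age5 × sex → rate
    true_counts: pd.DataFrame | None = None       # pre-defect death counts per stratum
    pre_defect_records: pd.DataFrame | None = None
    completeness: float | None = None
    population: pd.DataFrame | None = None
    cluster_cells: list[np.ndarray] = field(default_factory=list)
    cluster_gaps_m: dict[tuple[int, int], float] = field(default_factory=dict)
    consolidated_city_ids: list[str] = field(default_factory=list)
    match_labels: dict[str, str] = field(default_factory=dict)
    contiguity_pairs: list[tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# geography

def generate_geography(config: SyntheticConfig):
    """Rectangular L3 tiles nested in L2 squares nested in L1Admin blocks.

    Returns (units, hierarchy, country_boundary). Deterministic per seed
    (layout is a fixed tiling; the seed only enters downstream generators).
    """
    units: list[geo.GeoUnit] = []
    links: list[tuple[str, str]] = []
    ts = config.l2_tile_size
    n_cols = int(np.ceil(np.sqrt(config.n_l2)))
    l2_per_l1 = config.n_l2 // config.n_l1admin

    for i in range(config.n_l1admin):
        units.append(
            geo.GeoUnit(
                unit_id=f"{COUNTRY}-L1-{i:02d}", level="L1Admin", country=COUNTRY,
                name=f"City {i}", crs="synthetic-metric",
            )
        )
    for j in range(config.n_l2):
        row, col = divmod(j, n_cols)
        l2_geom = box(col * ts, row * ts, (col + 1) * ts, (row + 1) * ts)
        l2_id = f"{COUNTRY}-L2-{j:03d}"
        l1_id = f"{COUNTRY}-L1-{j // l2_per_l1:02d}"
        units.append(
            geo.GeoUnit(
                unit_id=l2_id, level="L2", country=COUNTRY, name=f"Municipio {j}",
                geometry=l2_geom, crs="synthetic-metric",
            )
        )
        links.append((l2_id, l1_id))
        # L3 tiles split the L2 square into vertical strips
        strip = ts / config.l3_per_l2
        for k in range(config.l3_per_l2):
            l3_id = f"{COUNTRY}-L3-{j:03d}-{k:02d}"
            l3_geom = box(
                col * ts + k * strip, row * ts, col * ts + (k + 1) * strip, (row + 1) * ts
            )
            units.append(
                geo.GeoUnit(
                    unit_id=l3_id, level="L3", country=COUNTRY,
                    name=f"Tract {j}-{k}", geometry=l3_geom, crs="synthetic-metric",
                )
            )
            links.append((l3_id, l2_id))

    hierarchy = geo.build_hierarchy(units, links)
    n_rows = int(np.ceil(config.n_l2 / n_cols))
    country_boundary = box(0, 0, n_cols * ts, n_rows * ts)
    return units, hierarchy, country_boundary


def l2_ids(config: SyntheticConfig) -> list[str]:
    return [f"{COUNTRY}-L2-{j:03d}" for j in range(config.n_l2)]


# ---------------------------------------------------------------------------
# population and mortality

def generate_population(config: SyntheticConfig) -> pd.DataFrame:
    """Sub-city population by age band and sex (deterministic).

    Population is split evenly across sub-cities, by the regional age
    structure across bands, and 50/50 by sex.
    """
    per_l2 = config.total_population / config.n_l2
    rows = [
        {"geography": l2, "age5": band, "sex": sex, "count": per_l2 * share / 2}
        for l2 in l2_ids(config)
        for band, share in zip(AGE5_BANDS, AGE_STRUCTURE)
        for sex in ("male", "female")
    ]
    return pd.DataFrame(rows)


def true_rate_table(config: SyntheticConfig) -> pd.DataFrame:
    """Planted stratum death rates: age-sex schedule × sub-city multiplier.

    Sub-city multipliers are evenly spaced in [1−spread, 1+spread] so
    geographic variation is known exactly.
    """
    ids = l2_ids(config)
    mult = np.linspace(1 - config.l2_rate_spread, 1 + config.l2_rate_spread, len(ids))
    rows = []
    for l2, m in zip(ids, mult):
        for band, rm, rf in zip(AGE5_BANDS, DEATH_RATE_MALE, DEATH_RATE_FEMALE):
            rows.append({"l2_code": l2, "age5": band, "sex": "male", "rate": rm * m})
            rows.append({"l2_code": l2, "age5": band, "sex": "female", "rate": rf * m})
    return pd.DataFrame(rows)


def generate_mortality(config: SyntheticConfig) -> tuple[pd.DataFrame, TruthLedger]:
    """Raw death records with planted defects, plus the truth ledger.

    Deaths are drawn per (sub-city, age band, sex) stratum as
    Poisson(population × rate); each death receives a single-year age within
    its band, an education level, and a well-defined ICD-10 cause from the
    configured mix. Defects are then applied in order: garbage coding
    (cause replaced by an ill-defined code at the garbage rate, age and sex
    preserved), missingness masks, and undercount thinning (each record kept
    with probability equal to the completeness).
    """
    rng = substream(config.seed, "mortality")
    population = generate_population(config)
    rates = true_rate_table(config)
    merged = population.rename(columns={"geography": "l2_code"}).merge(
        rates, on=["l2_code", "age5", "sex"]
    )
    if (merged["count"] * merged["rate"] > merged["count"]).any():
        raise SyntheticConfigError("stratum rate implies more deaths than people")

    cause_names = list(CAUSE_MIX)
    cause_p = np.array([CAUSE_MIX[c][0] for c in cause_names])
    cause_p = cause_p / cause_p.sum()
    band_lo = {band: int(band.split("-")[0]) if band != "85+" else 85 for band in AGE5_BANDS}

    rows = []
    true_counts = []
    for rec in merged.itertuples():
        n = int(rng.poisson(rec.count * rec.rate))
        true_counts.append(
            {"l2_code": rec.l2_code, "age5": rec.age5, "sex": rec.sex, "true_deaths": n}
        )
        if n == 0:
            continue
        lo = band_lo[rec.age5]
        width = 15 if rec.age5 == "85+" else 5
        ages = lo + rng.integers(0, width, size=n)
        causes = rng.choice(len(cause_names), size=n, p=cause_p)
        edus = rng.choice(["ed1", "ed2", "ed3", "ed4"], size=n, p=[0.3, 0.3, 0.25, 0.15])
        for a, ci, ed in zip(ages, causes, edus):
            rows.append(
                {
                    "country": COUNTRY,
                    "year": config.year,
                    "l2_code": rec.l2_code,
                    "age": int(a),
                    "sex": "1" if rec.sex == "male" else "2",
                    "education": ed,
                    "icd_code": CAUSE_MIX[cause_names[ci]][1],
                    "icd_revision": 10,
                }
            )
    records = pd.DataFrame(rows)
    records["age"] = records["age"].astype(float)  # NaN marks missingness later
    pre_defect = records.copy()

    n = len(records)
    # garbage coding: cause replaced, age/sex untouched
    garbage = rng.random(n) < config.garbage_rate
    injury = rng.random(n) < config.garbage_injury_share
    disease_codes = rng.choice(GARBAGE_DISEASE_CODES, size=n)
    injury_codes = rng.choice(GARBAGE_INJURY_CODES, size=n)
    records.loc[garbage & ~injury, "icd_code"] = disease_codes[garbage & ~injury]
    records.loc[garbage & injury, "icd_code"] = injury_codes[garbage & injury]

    # missingness masks
    if config.age_dependent_missingness:
        # missingness rising with age stresses the conditional imputation
        age_scale = records["age"].to_numpy() / 130.0
        p_age = np.clip(config.missing_age_rate * (0.5 + 2.0 * age_scale), 0, 1)
    else:
        p_age = np.full(n, config.missing_age_rate)
    miss_age = rng.random(n) < p_age
    miss_sex = rng.random(n) < config.missing_sex_rate
    miss_loc = rng.random(n) < config.missing_location_rate
    records.loc[miss_age, "age"] = np.nan
    records.loc[miss_sex, "sex"] = None
    records.loc[miss_loc, "l2_code"] = None

    # undercount thinning
    kept = rng.random(n) < config.completeness
    observed = records[kept].reset_index(drop=True)

    ledger = TruthLedger(
        true_rates=true_rate_table(config),
        true_counts=pd.DataFrame(true_counts),
        pre_defect_records=pre_defect,
        completeness=config.completeness,
        population=generate_population(config),
    )
    return observed, ledger


def true_standardized_rates(config: SyntheticConfig, standard_weights: pd.Series,
                            scale: float = 100_000) -> pd.DataFrame:
    """Planted-truth age-standardized all-cause rate per sub-city.

    ASR(l2) = Σ_a w_a · r_a(l2) · scale with r_a the population-weighted
    (over sex) planted rate in band a.
    """
    rates = true_rate_table(config)
    pop = generate_population(config).rename(columns={"geography": "l2_code"})
    merged = rates.merge(pop, on=["l2_code", "age5", "sex"])
    rows = []
    for l2, grp in merged.groupby("l2_code"):
        asr = 0.0
        for band, w in standard_weights.items():
            sub = grp[grp["age5"] == band]
            r = (sub["rate"] * sub["count"]).sum() / sub["count"].sum()
            asr += w * r * scale
        rows.append({"l2_code": l2, "true_asr": asr})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# built-up raster

def generate_builtup_raster(config: SyntheticConfig) -> tuple[BuiltUpRaster, TruthLedger]:
    """Planted rectangular built-up blocks with known separations.

    Optional salt noise flips isolated non-planted cells to built at the
    configured rate. The ledger records true cluster cells and pairwise
    edge-to-edge gaps in meters.
    """
    nrows, ncols = config.raster_shape
    grid = np.zeros((nrows, ncols), dtype=bool)
    blocks = config.planted_blocks
    for idx, (r0, c0, h, w) in enumerate(blocks):
        if r0 < 0 or c0 < 0 or r0 + h > nrows or c0 + w > ncols:
            raise SyntheticConfigError(f"planted block {idx} does not fit the grid")
        if grid[r0 : r0 + h, c0 : c0 + w].any():
            raise SyntheticConfigError(f"planted block {idx} overlaps an earlier block")
        grid[r0 : r0 + h, c0 : c0 + w] = True

    ledger = TruthLedger()
    ledger.cluster_cells = [
        np.array([(r, c) for r in range(r0, r0 + h) for c in range(c0, c0 + w)])
        for r0, c0, h, w in blocks
    ]
    cs = config.cell_size
    for i in range(len(blocks)):
        for j in range(i + 1, len(blocks)):
            r0i, c0i, hi, wi = blocks[i]
            r0j, c0j, hj, wj = blocks[j]
            dr = max(0, max(r0i - (r0j + hj), r0j - (r0i + hi)))
            dc = max(0, max(c0i - (c0j + wj), c0j - (c0i + wi)))
            ledger.cluster_gaps_m[(i, j)] = float(np.hypot(dr, dc) * cs)

    if config.noise_rate > 0:
        rng = substream(config.seed, "raster-noise")
        noise = (rng.random(grid.shape) < config.noise_rate) & ~grid
        grid = grid | noise

    raster = BuiltUpRaster(
        grid=grid, cell_size=cs, origin=(0.0, nrows * cs), crs="synthetic-metric"
    )
    return raster, ledger


# ---------------------------------------------------------------------------
# city lists

def generate_city_lists(config: SyntheticConfig) -> tuple[list[CityRecord], list[CityRecord], TruthLedger]:
    """Two city lists with planted match/absorb/standalone/contiguity structure.

    Extent-list cities get square footprints on a sparse grid; matched
    census records share (name, admin, country) with population drawn above
    the threshold (the first match sits exactly at the threshold to pin the
    ≥ boundary); absorbed census satellites are points inside a footprint;
    standalone census cities sit far from every footprint; contiguous pairs
    are sub-threshold towns whose footprints touch and whose combined
    population clears the threshold.
    """
    rng = substream(config.seed, "city-lists")
    spacing = 200_000.0  # meters between planted city centers
    extent_list: list[CityRecord] = []
    census_list: list[CityRecord] = []
    ledger = TruthLedger()

    def grid_center(i: int) -> tuple[float, float]:
        return (i % 8) * spacing, (i // 8) * spacing

    for i in range(config.n_matches):
        cx, cy = grid_center(i)
        footprint = box(cx - 10_000, cy - 10_000, cx + 10_000, cy + 10_000)
        # first match pinned at the threshold boundary; others log-uniform above it
        pop = (
            config.population_threshold
            if i == 0
            else float(np.round(config.population_threshold * 10 ** rng.uniform(0.05, 1.5)))
        )
        name, admin = f"Ciudad {i}", f"Provincia {i % 5}"
        ext = CityRecord(
            source="extent_list", name=name, admin_subdivision=admin, country=COUNTRY,
            population=pop * rng.uniform(0.9, 1.1), footprint=footprint,
        )
        cen = CityRecord(
            source="census_list", name=name, admin_subdivision=admin, country=COUNTRY,
            population=pop, location=Point(cx, cy),
        )
        extent_list.append(ext)
        census_list.append(cen)
        ledger.match_labels[cen.record_id] = "matched"
        ledger.consolidated_city_ids.append(ext.record_id)

    for i in range(config.n_absorbed):
        host = extent_list[i % config.n_matches]
        hx, hy = host.footprint.centroid.x, host.footprint.centroid.y
        cen = CityRecord(
            source="census_list", name=f"Satelite {i}", admin_subdivision="Provincia 9",
            country=COUNTRY, population=float(rng.integers(100_000, 250_000)),
            location=Point(hx + 5_000, hy + 5_000),  # inside the 20 km footprint
        )
        census_list.append(cen)
        ledger.match_labels[cen.record_id] = "absorbed"

    for i in range(config.n_standalone):
        cx, cy = grid_center(40 + i)
        cen = CityRecord(
            source="census_list", name=f"Pueblo Grande {i}", admin_subdivision="Provincia 8",
            country=COUNTRY, population=float(rng.integers(120_000, 400_000)),
            location=Point(cx, cy), footprint=box(cx - 5_000, cy - 5_000, cx + 5_000, cy + 5_000),
        )
        census_list.append(cen)
        ledger.match_labels[cen.record_id] = "standalone"
        ledger.consolidated_city_ids.append(cen.record_id)

    for i in range(config.n_contiguous_pairs):
        cx, cy = grid_center(60 + i)
        twins = []
        for k, pop in enumerate((60_000.0, 55_000.0)):
            cen = CityRecord(
                source="census_list", name=f"Gemelo {i}-{k}", admin_subdivision="Provincia 7",
                country=COUNTRY, population=pop, location=Point(cx + k * 8_000, cy),
                footprint=box(cx + k * 8_000 - 4_000, cy - 4_000, cx + k * 8_000 + 4_000, cy + 4_000),
            )
            census_list.append(cen)
            ledger.match_labels[cen.record_id] = "contiguous_candidate"
            twins.append(cen.record_id)
        ledger.contiguity_pairs.append((twins[0], twins[1]))
        ledger.consolidated_city_ids.append(f"{min(twins)}+merged")

    return extent_list, census_list, ledger


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """The same study conditions under a different seed."""
    return replace(config, seed=seed)
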