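"""Synthetic ridge landscapes and forward-time microsatellite genotypes.

The generator emulates the study design every pipeline stage expects: nine
demes in three clusters ("mountain ranges") strung along an east-west axis,
separated by valleys below the 1280 m migration threshold but connected by a
lower passable corridor, three demes per cluster along an elevational
gradient with temperatures tied to elevation.  Gene flow between demes
follows one of four known-truth regimes:

* ``ibd`` — migration decays with great-circle distance;
* ``ibr`` — migration decays with least-cost distance over the raster;
* ``ibe`` — migration decays with minimum-temperature dissimilarity;
* ``null`` — uniform migration between all demes.

Genotypes evolve forward in time under Wright-Fisher reproduction with the
planted migration matrix and stepwise mutation (one repeat up or down,
reflecting at repeat sizes 5 and 60).  Optional null-allele masking hides
each allele copy independently; under Hardy-Weinberg this is exactly a null
allele segregating at the masking rate (one hidden copy makes an apparent
homozygote, two a missing call).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .distances import environment_matrix, geographic_matrix, least_cost_matrix
from .genotypes import MISSING, GenotypeTable, SiteTable, write_genepop
from .raster import ElevationRaster, write_esri_ascii

__all__ = ["ScenarioConfig", "TruthRecord", "make_landscape",
           "migration_matrix", "simulate_genotypes", "scenario_bundle"]

SCENARIOS = ("ibd", "ibr", "ibe", "null")


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic run.

    Defaults mirror the emulated design: 9 demes in 3 ridge clusters, 8
    microsatellite loci, 20 sampled diploids per deme, Ne = 100, 500
    generations, stepwise mutation at 3e-4 per copy per generation (within
    the range reported for plant microsatellites), total emigration 0.15 per
    deme per generation split by the scenario kernel, with decay scales
    calibrated so each planted driver leaves an identifiable signature at
    this sample size.
    """

    scenario: str = "ibd"
    n_demes: int = 9
    layout: str = "ridges"            # 3 x 3 clusters on three massifs
    ne: int = 100
    n_loci: int = 8
    mu: float = 3e-4
    m_total: float = 0.15
    distance_decay_km: float = 15.0   # ibd kernel scale
    cost_decay_km: float = 30.0       # ibr kernel scale (least-cost km)
    env_decay_c: float = 0.3          # ibe kernel scale (deg C of tmin)
    null_allele_rate: float = 0.0
    generations: int = 500
    n_sample: int = 20
    elevation_threshold_m: float = 1280.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        for rate in (self.mu, self.m_total, self.null_allele_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.ne < 2 or self.generations < 1:
            raise ValueError("need Ne >= 2 and generations >= 1")
        if self.n_sample > self.ne:
            raise ValueError("cannot sample more individuals than Ne")


@dataclass
class TruthRecord:
    """What the generator actually did: the planted driver and migration."""

    scenario: str
    migration: np.ndarray            # rows sum to <= 1 off-diagonal total
    driver: str                      # expected top-supported hypothesis label
    seed: int

    def to_json(self) -> str:
        return json.dumps({
            "scenario": self.scenario,
            "driver": self.driver,
            "seed": self.seed,
            "migration": self.migration.tolist(),
        }, indent=2)


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

# three ridge centers along an E-W axis (lon, lat), degrees
_RIDGE_CENTERS = [(-5.7, 40.55), (-4.8, 40.55), (-3.9, 40.55)]
_CORRIDOR_LAT = 40.40        # southern corridor, the central massif's only link
_BRIDGE_LAT = 40.88          # northern route joining the two edge massifs
_PEAK_M = 2400.0
_BASE_M = 900.0
_SIGMA_DEG = 0.16


def make_landscape(cfg: ScenarioConfig, rng: np.random.Generator | None = None
                   ) -> tuple[ElevationRaster, SiteTable]:
    """Build the ridge-structured elevation raster and its nine-site table.

    Three Gaussian massifs (peak 2400 m) sit on a 900 m plain with valleys
    below the migration threshold between them.  The eastern two massifs are
    joined by a direct high saddle, while the western massif connects only
    through a long passable corridor to the south — so least-cost and
    straight-line distances rank population pairs differently, which is what
    makes resistance distinguishable from plain distance downstream.  Three
    sites per massif sit at ~1850, ~2000 and ~2400 m; Tmin and Tmax are
    linear in elevation plus noise.
    """
    import pandas as pd

    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    cell = 0.02
    lon0, lon1, lat0, lat1 = -6.2, -3.4, 39.96, 41.0
    n_cols = int(round((lon1 - lon0) / cell))
    n_rows = int(round((lat1 - lat0) / cell))
    lon_c = lon0 + (np.arange(n_cols) + 0.5) * cell
    lat_c = lat1 - (np.arange(n_rows) + 0.5) * cell
    LON, LAT = np.meshgrid(lon_c, lat_c)

    elev = np.full((n_rows, n_cols), _BASE_M)
    for cx, cy in _RIDGE_CENTERS:
        r2 = (LON - cx) ** 2 + (LAT - cy) ** 2
        elev = np.maximum(elev, _BASE_M + (_PEAK_M - _BASE_M) * np.exp(-r2 / (2 * _SIGMA_DEG ** 2)))
    # radial barrier walls on the western and eastern massifs: each cuts the
    # short arc between two same-massif sites, so some within-massif pairs
    # have a least-cost detour around the far flank while staying close in
    # straight-line terms — the contrasts that let resistance and plain
    # distance be told apart downstream
    for k, wall_bearing in ((0, 92.5), (1, 132.5), (2, 172.5)):
        cx, cy = _RIDGE_CENTERS[k]
        u = np.array([np.sin(np.radians(wall_bearing)), np.cos(np.radians(wall_bearing))])
        rel_x, rel_y = LON - cx, LAT - cy
        along = rel_x * u[0] + rel_y * u[1]
        perp = np.abs(rel_x * u[1] - rel_y * u[0])
        wall = (np.abs(along) <= 0.40) & (perp < 1.2 * cell)
        gap = (along >= -0.26) & (along <= -0.20)     # crossing at the outer flank
        elev = np.where(wall & ~gap, _BASE_M, elev)

    # passable links between massifs.  The two edge massifs are joined by a
    # direct high route to the north; the central massif reaches its
    # neighbours only through a corridor to the south.  Least-cost distance
    # therefore penalizes the geographically central massif — the opposite
    # of what plain distance predicts — which is what makes resistance and
    # plain distance separable downstream.  All bands stop short of the
    # barrier walls so each wall's flank gap stays the only way across it.
    def _band(lon_lo, lon_hi, lat_lo, lat_hi):
        return (LON >= lon_lo) & (LON <= lon_hi) & (LAT >= lat_lo) & (LAT <= lat_hi)

    half = 1.5 * cell
    (x1, y1), (x2, y2), (x3, y3) = _RIDGE_CENTERS
    links = [
        _band(x1 - half, x3 + 0.10 + half, _BRIDGE_LAT - half, _BRIDGE_LAT + half),
        _band(x1 - half, x1 + half, y1 + 0.05, _BRIDGE_LAT),                # R1 north
        _band(x3 + 0.10 - half, x3 + 0.10 + half, y3 + 0.05, _BRIDGE_LAT),  # R3 north
        _band(x1 - half, x3 - 0.10 + half, _CORRIDOR_LAT - half, _CORRIDOR_LAT + half),
        _band(x1 - half, x1 + half, _CORRIDOR_LAT, y1 - 0.05),              # R1 south
        _band(x2 - half, x2 + half, _CORRIDOR_LAT, y2 - 0.05),              # R2 south
        _band(x3 - 0.10 - half, x3 - 0.10 + half, _CORRIDOR_LAT, y3 - 0.05),  # R3 south
    ]
    for band in links:
        elev = np.where(band, np.maximum(elev, 1350.0), elev)

    raster = ElevationRaster(values=elev, xll=lon0, yll=lat0, cell_size=cell,
                             geographic=True)

    # sites: per massif at ~1850 / ~2000 / ~2350 m; the near-summit site sits
    # a couple of cells off-center so it clears the barrier walls
    targets = (1850.0, 2000.0, _PEAK_M)
    # flank sites sit on either side of the massif's barrier wall: close in
    # straight-line terms, far by least-cost
    bearings = (60.0, 125.0, 0.0)           # degrees clockwise from north
    summit_bearing = (315.0, 25.0, 90.0)
    rows = []
    names = []
    for k, (cx, cy) in enumerate(_RIDGE_CENTERS):
        for s, (target, bearing) in enumerate(zip(targets, bearings)):
            if target >= _PEAK_M:
                radius, theta = 0.05, np.radians(summit_bearing[k])
            else:
                frac = (target - _BASE_M) / (_PEAK_M - _BASE_M)
                radius = _SIGMA_DEG * np.sqrt(-2.0 * np.log(frac))
                theta = np.radians(bearing + 40.0 * k)
            lon = cx + radius * np.sin(theta)
            lat = cy + radius * np.cos(theta)
            r, c = raster.cell_of(lon, lat)
            elevation = float(raster.values[r, c])
            # lapse rates and residual scatter match the elevational regression
            # of the packaged site table (tmin tightly coupled to elevation,
            # tmax much noisier)
            tmin = 0.8 - 0.0035 * elevation + rng.normal(0.0, 0.25)
            tmax = 31.0 - 0.0026 * elevation + rng.normal(0.0, 1.0)
            names.append(f"R{k + 1}S{s + 1}")
            rows.append(dict(lat=lat, lon=lon, elevation=elevation,
                             tmax=round(tmax, 2), tmin=round(tmin, 2),
                             mountain_range=f"R{k + 1}",
                             env_class="optimal" if target == _PEAK_M else "marginal"))
    data = pd.DataFrame(rows, index=pd.Index(names, name="population"))
    sites = SiteTable(data)
    if cfg.n_demes != 9:
        if cfg.n_demes > 9:
            raise ValueError("the ridge layout provides at most 9 demes")
        sites = SiteTable(data.iloc[:cfg.n_demes].copy())
    return raster, sites


# ---------------------------------------------------------------------------
# Migration
# ---------------------------------------------------------------------------

def migration_matrix(cfg: ScenarioConfig, sites: SiteTable,
                     raster: ElevationRaster | None = None) -> TruthRecord:
    """Planted migration matrix under the scenario's kernel.

    ``m_ij ∝ exp(-d_ij / scale)`` with d the scenario's distance (geographic
    km, least-cost km, or |ΔTmin| deg C); the null scenario is uniform.  Rows
    are rescaled so each deme's total emigration is ``cfg.m_total``; the
    diagonal holds the staying probability.
    """
    n = len(sites)
    if cfg.scenario == "null":
        w = np.ones((n, n))
    elif cfg.scenario == "ibd":
        d = geographic_matrix(sites).values
        w = np.exp(-d / cfg.distance_decay_km)
    elif cfg.scenario == "ibr":
        if raster is None:
            raise ValueError("ibr scenario needs the elevation raster")
        d = least_cost_matrix(raster, sites, cfg.elevation_threshold_m).values / 1000.0
        w = np.exp(-d / cfg.cost_decay_km)
    else:  # ibe
        d = environment_matrix(sites, "tmin").values
        w = np.exp(-d / cfg.env_decay_c)
    np.fill_diagonal(w, 0.0)
    m = w / w.sum(axis=1, keepdims=True) * cfg.m_total
    np.fill_diagonal(m, 1.0 - m.sum(axis=1))
    driver = {"ibd": "IBD", "ibr": "IBR", "ibe": "IBE-tmin", "null": "none"}[cfg.scenario]
    return TruthRecord(scenario=cfg.scenario, migration=m, driver=driver,
                       seed=cfg.seed)


# ---------------------------------------------------------------------------
# Forward-time Wright-Fisher with stepwise mutation
# ---------------------------------------------------------------------------

_REPEAT_MIN, _REPEAT_MAX = 5, 60


def _mutate(state: np.ndarray, mu: float, rng: np.random.Generator) -> None:
    hit = rng.random(state.shape) < mu
    if not hit.any():
        return
    step = rng.choice((-1, 1), size=int(hit.sum()))
    vals = state[hit] + step
    vals = np.where(vals < _REPEAT_MIN, 2 * _REPEAT_MIN - vals, vals)
    vals = np.where(vals > _REPEAT_MAX, 2 * _REPEAT_MAX - vals, vals)
    state[hit] = vals


def simulate_genotypes(cfg: ScenarioConfig, truth: TruthRecord,
                       rng: np.random.Generator | None = None,
                       deme_names: list[str] | None = None) -> GenotypeTable:
    """Evolve the metapopulation and sample a genotype table.

    Each generation every deme is refilled with Ne offspring: each offspring
    draws a source deme from the migration row, two parents at random from
    that deme, one allele per parent per locus (free recombination), then
    stepwise mutation.  After ``cfg.generations`` generations ``cfg.n_sample``
    diploids per deme are genotyped; null-allele masking (if configured)
    hides each allele copy independently.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    nd, ne, L = truth.migration.shape[0], cfg.ne, cfg.n_loci
    # ancestral state: a diverse refugial gene pool (repeat counts spread
    # around a per-locus mode), so starting heterozygosity matches the high
    # values typical of outcrossing alpine perennials rather than a
    # monomorphic founder
    mode = rng.integers(25, 36, size=L)
    spread = rng.integers(-3, 4, size=(nd, ne, 2, L))
    state = (mode[None, None, None, :] + spread).astype(np.int16)
    cum_m = np.cumsum(truth.migration, axis=1)
    for _ in range(cfg.generations):
        u = rng.random((nd, ne))
        src = (u[:, :, None] < cum_m[:, None, :]).argmax(axis=2)      # (nd, ne)
        p1 = rng.integers(0, ne, size=(nd, ne))
        p2 = rng.integers(0, ne, size=(nd, ne))
        c1 = rng.integers(0, 2, size=(nd, ne, L))
        c2 = rng.integers(0, 2, size=(nd, ne, L))
        loc = np.arange(L)[None, None, :]
        new = np.empty_like(state)
        new[:, :, 0, :] = state[src[:, :, None], p1[:, :, None], c1, loc]
        new[:, :, 1, :] = state[src[:, :, None], p2[:, :, None], c2, loc]
        _mutate(new, cfg.mu, rng)
        state = new

    individuals, populations, rows = [], [], []
    if deme_names is None:
        deme_names = [f"D{d + 1}" for d in range(nd)]
    elif len(deme_names) != nd:
        raise ValueError("one deme name per deme required")
    for d in range(nd):
        pick = rng.choice(ne, size=cfg.n_sample, replace=False)
        sample = state[d, pick].astype(np.int32)                      # (n, 2, L)
        if cfg.null_allele_rate > 0:
            hidden = rng.random(sample.shape) < cfg.null_allele_rate
            both = hidden.all(axis=1)                                 # (n, L)
            one = hidden[:, 0, :] != hidden[:, 1, :]
            visible = np.where(hidden[:, 0, :], sample[:, 1, :], sample[:, 0, :])
            sample[:, 0, :] = np.where(one, visible, sample[:, 0, :])
            sample[:, 1, :] = np.where(one, visible, sample[:, 1, :])
            sample[:, 0, :] = np.where(both, MISSING, sample[:, 0, :])
            sample[:, 1, :] = np.where(both, MISSING, sample[:, 1, :])
        for k in range(cfg.n_sample):
            individuals.append(f"{deme_names[d]}_{k + 1:03d}")
            populations.append(deme_names[d])
            rows.append(sample[k].T)                                  # (L, 2)
    return GenotypeTable(
        individuals=individuals,
        loci=[f"ms{l + 1:02d}" for l in range(L)],
        calls=np.stack(rows),
        populations=populations,
    )


def scenario_bundle(cfg: ScenarioConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete pipeline input set for one scenario.

    Produces Genepop genotypes, a site CSV, an ESRI ASCII elevation raster
    and a truth JSON under ``out_dir``; two runs with the same config are
    byte-identical.  Deme names are rewritten to the site names so the
    genotype and site tables align.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    raster, sites = make_landscape(cfg, rng)
    truth = migration_matrix(cfg, sites, raster)
    gt = simulate_genotypes(cfg, truth, rng, deme_names=sites.populations)
    gt.hierarchy = sites.hierarchy()
    paths = {
        "genotypes": out / "genotypes.gen",
        "sites": out / "sites.csv",
        "raster": out / "elevation.asc",
        "truth": out / "truth.json",
    }
    write_genepop(gt, paths["genotypes"], title=f"synthetic {cfg.scenario} scenario")
    sites.data.to_csv(paths["sites"])
    write_esri_ascii(raster, paths["raster"])
    paths["truth"].write_text(truth.to_json() + "\n", encoding="utf-8")
    return paths
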