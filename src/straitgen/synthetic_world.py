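"""Synthetic archipelago worlds with recoverable ground truth.

A world is a rectangular lon/lat grid with rectangular land units, a strait
configuration with merges, a small climate stack (one signal variable with a
species threshold, one decoy correlated with the signal, one independent
noise layer), two deeply divergent parapatric species with star-like
haplotype clouds, planted over-sea colonizations of known number and length,
and presence points drawn from logistic suitability.

All randomness flows from one root seed through named substreams (world,
haplotypes, presences) so each stage is independently reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import (Alignment, ConfigError, LocalityTable, Raster,
                      StraitGraph, write_fasta, write_locality_csv,
                      write_raster, write_strait_config)

SEQ_LENGTH = 658  # barcode fragment length


@dataclass
class SpeciesConfig:
    name: str
    units: list[str]                      # occupied land units (original names)
    colonizations: list[tuple[str, str]]  # ordered (from, to) crossings
    n_localities_per_unit: int = 3
    n_specimens_per_locality: int = 3
    colonization_rate: float = 1.0        # expected substitutions per crossing
    satellite_prob: float = 0.25          # per-specimen single-step mutation
    n_presences: int = 150
    wet_adapted: bool = True              # occupies climate > threshold


@dataclass
class WorldConfig:
    lon_min: float = 0.0
    lat_min: float = 40.0
    lon_max: float = 10.0
    lat_max: float = 45.0
    cell_size: float = 0.1
    units: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)
    strait_km: dict[tuple[str, str], float] = field(default_factory=dict)
    merges: list[tuple[str, str]] = field(default_factory=list)
    # climate: signal = base + slope * lon + N(0, noise_sd) per cell
    climate_base: float = 100.0
    climate_slope: float = -5.0
    climate_noise_sd: float = 25.0
    decoy_noise_sd: float = 10.0
    threshold: float = 77.0
    softening_scale: float = 8.0
    species: list[SpeciesConfig] = field(default_factory=list)
    inter_species_divergence: int = 30    # fixed differences between ancestors
    ensure_min_one_substitution: bool = True
    seed: int = 0

    def validate(self) -> None:
        names = list(self.units)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if _rects_overlap(self.units[a], self.units[b]):
                    raise ConfigError(f"land units {a!r} and {b!r} overlap")
        for (u, v) in self.strait_km:
            if u not in self.units or v not in self.units:
                raise ConfigError(f"strait references unknown unit: {(u, v)}")
        for sp in self.species:
            occupied = set(sp.units)
            for u, v in sp.colonizations:
                if u not in occupied or v not in occupied:
                    raise ConfigError(
                        f"colonization {(u, v)} outside {sp.name} units")
        if self.inter_species_divergence < 25:
            raise ConfigError("cryptic pairs must differ by >= 25 sites")


def _rects_overlap(a, b) -> bool:
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    return ax0 < bx1 and bx0 < ax1 and ay0 < by1 and by0 < ay1


def default_config(seed: int = 0) -> WorldConfig:
    """Two mainlands and four islands; strait widths contrast short
    unobserved crossings (3, 5 km) with long observed ones (up to 140 km)."""
    # each species keeps its islands on its own flank so the world has a
    # single inter-species contact strait (the mainland gap at lon ~4.55)
    units = {
        "west_main": (0.2, 42.4, 4.4, 44.8),
        "east_main": (4.7, 42.4, 9.8, 44.8),
        "shelf_isle": (0.4, 41.6, 1.2, 42.1),
        "isla_a": (0.6, 40.4, 1.6, 41.1),
        "isla_b": (2.2, 40.4, 3.2, 41.1),
        "isla_c": (7.0, 40.4, 8.0, 41.1),
        "isla_d": (8.6, 40.4, 9.6, 41.1),
    }
    strait_km = {
        ("west_main", "east_main"): 3.0,
        ("west_main", "isla_a"): 12.0,
        ("west_main", "isla_b"): 90.0,
        ("east_main", "isla_c"): 5.0,
        ("east_main", "isla_d"): 140.0,
        ("isla_a", "isla_b"): 100.0,
        ("isla_c", "isla_d"): 150.0,
    }
    species = [
        SpeciesConfig(
            name="species_west", wet_adapted=True,
            units=["west_main", "shelf_isle", "isla_a", "isla_b"],
            colonizations=[("west_main", "isla_a"), ("west_main", "isla_b")],
        ),
        SpeciesConfig(
            name="species_east", wet_adapted=False,
            units=["east_main", "isla_c", "isla_d"],
            colonizations=[("east_main", "isla_c"), ("east_main", "isla_d")],
        ),
    ]
    return WorldConfig(units=units, strait_km=strait_km,
                       merges=[("shelf_isle", "west_main")],
                       species=species, seed=seed)


# ---------------------------------------------------------------------------
# Truth record
# ---------------------------------------------------------------------------

@dataclass
class TruthRecord:
    threshold: float
    signal_variable: str = "precip_dry"
    uncorrelated_subset: list[str] = field(default_factory=list)
    colonizations: dict[str, list[dict]] = field(default_factory=dict)
    species_of_specimen: dict[str, str] = field(default_factory=dict)
    contact_region: tuple[float, float, float, float] | None = None
    contact_units: tuple[str, str] | None = None

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "signal_variable": self.signal_variable,
            "uncorrelated_subset": self.uncorrelated_subset,
            "colonizations": self.colonizations,
            "species_of_specimen": self.species_of_specimen,
            "contact_region": self.contact_region,
            "contact_units": self.contact_units,
        }


# ---------------------------------------------------------------------------
# World generation
# ---------------------------------------------------------------------------

@dataclass
class World:
    cfg: WorldConfig
    rasters: dict[str, Raster]
    land_unit_grid: np.ndarray  # unit name per cell, "" for sea
    strait_graph: StraitGraph
    truth: TruthRecord

    def template(self) -> Raster:
        return next(iter(self.rasters.values()))


def _substream(seed: int, name: str) -> np.random.Generator:
    # crc32 keyring: stable across processes, unlike Python's str hash
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(
        entropy=seed, spawn_key=(key,)))


def generate_world(cfg: WorldConfig) -> World:
    """Build rasters, the strait graph and the climate truth for a config."""
    cfg.validate()
    rng = _substream(cfg.seed, "world")
    ncols = int(round((cfg.lon_max - cfg.lon_min) / cfg.cell_size))
    nrows = int(round((cfg.lat_max - cfg.lat_min) / cfg.cell_size))
    nodata = -9999.0
    template = Raster(nrows, ncols, cfg.lon_min, cfg.lat_min, cfg.cell_size,
                      nodata, np.zeros((nrows, ncols)))
    lon, lat = template.cell_centers()

    unit_grid = np.full((nrows, ncols), "", dtype=object)
    for name, (x0, y0, x1, y1) in cfg.units.items():
        inside = (lon >= x0) & (lon < x1) & (lat >= y0) & (lat < y1)
        unit_grid[inside] = name
    land = unit_grid != ""

    signal = cfg.climate_base + cfg.climate_slope * lon \
        + rng.normal(0.0, cfg.climate_noise_sd, size=lon.shape)
    noise = rng.normal(50.0, 20.0, size=lon.shape)
    # the decoy tracks the signal (|r| > 0.9) but also picks up a little of
    # the noise layer, so it always loses the selection tie-break to the
    # true signal variable
    decoy = signal + 0.25 * (noise - 50.0) \
        + rng.normal(0.0, cfg.decoy_noise_sd, size=lon.shape)

    rasters = {}
    for name, grid in (("precip_dry", signal), ("precip_decoy", decoy),
                       ("temp_noise", noise)):
        vals = np.where(land, grid, nodata)
        rasters[name] = template.copy_with(vals)

    units = list(cfg.units)
    n = len(units)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for (a, b), km in cfg.strait_km.items():
        i, j = units.index(a), units.index(b)
        dist[i, j] = dist[j, i] = km
    sg = StraitGraph(units=units, merges=list(cfg.merges), distances=dist)

    truth = TruthRecord(threshold=cfg.threshold,
                        uncorrelated_subset=["precip_dry", "temp_noise"])
    for sp in cfg.species:
        truth.colonizations[sp.name] = [
            {"from": u, "to": v, "km": sg.distance(u, v)}
            for u, v in sp.colonizations
        ]
    if len(cfg.species) == 2:
        wet = [s for s in cfg.species if s.wet_adapted]
        dry = [s for s in cfg.species if not s.wet_adapted]
        if wet and dry:
            ua, ub, gap = _closest_unit_pair(cfg, wet[0], dry[0])
            truth.contact_units = (ua, ub)
            truth.contact_region = gap
    return World(cfg=cfg, rasters=rasters, land_unit_grid=unit_grid,
                 strait_graph=sg, truth=truth)


def _closest_unit_pair(cfg: WorldConfig, sa: SpeciesConfig, sb: SpeciesConfig):
    """Closest rectangles between the two species; the gap between them."""
    best = None
    for ua in sa.units:
        for ub in sb.units:
            ra, rb = cfg.units[ua], cfg.units[ub]
            dx = max(rb[0] - ra[2], ra[0] - rb[2], 0.0)
            dy = max(rb[1] - ra[3], ra[1] - rb[3], 0.0)
            d = np.hypot(dx, dy)
            if best is None or d < best[0]:
                best = (d, ua, ub)
    _, ua, ub = best
    ra, rb = cfg.units[ua], cfg.units[ub]
    gx0, gx1 = sorted((min(ra[2], rb[2]), max(ra[0], rb[0])))
    gy0 = max(ra[1], rb[1])
    gy1 = min(ra[3], rb[3])
    if gy0 > gy1:
        gy0, gy1 = min(ra[3], rb[3]), max(ra[1], rb[1])
    return ua, ub, (gx0, gy0, gx1, gy1)


# ---------------------------------------------------------------------------
# Haplotype simulation
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _mutate(seq: np.ndarray, sites: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    for s in sites:
        choices = [b for b in "ACGT" if b != out[s]]
        out[s] = choices[rng.integers(0, 3)]
    return out


def simulate_haplotypes(cfg: WorldConfig, world: World
                        ) -> tuple[Alignment, LocalityTable, TruthRecord]:
    """Sequences and localities with planted colonization history.

    Mutation sites are allocated without replacement per species (and the
    inter-species difference sites are reserved first), so Hamming distances
    are additive along the colonization tree and each planted crossing is
    recoverable as exactly one network edge or shared haplotype.
    """
    rng = _substream(cfg.seed, "haplotypes")
    site_pool = rng.permutation(SEQ_LENGTH)
    inter_sites = site_pool[:cfg.inter_species_divergence]
    remaining = site_pool[cfg.inter_species_divergence:]
    pool_split = np.array_split(remaining, max(1, len(cfg.species)))

    ancestor = _BASES[rng.integers(0, 4, size=SEQ_LENGTH)]
    merge_map = {u: u for u in cfg.units}
    for a, b in cfg.merges:
        merge_map[a] = b

    records: list[tuple[str, str]] = []
    rows: list[dict] = []
    truth = world.truth
    for si, sp in enumerate(cfg.species):
        pool = list(pool_split[si % len(pool_split)])
        if si == 0:
            root_seq = ancestor
        else:
            root_seq = _mutate(ancestor, inter_sites, rng)

        # founder haplotype per effective unit along the colonization tree
        founders: dict[str, np.ndarray] = {}
        root_unit = (sp.colonizations[0][0] if sp.colonizations
                     else sp.units[0])
        founders[merge_map[root_unit]] = root_seq
        for u, v in sp.colonizations:
            eu, ev = merge_map[u], merge_map[v]
            if eu not in founders:
                raise ConfigError(
                    f"colonization {(u, v)} from unoccupied unit for {sp.name}")
            n_sub = int(rng.poisson(sp.colonization_rate))
            if cfg.ensure_min_one_substitution:
                n_sub = max(1, n_sub)
            sites = np.array([pool.pop() for _ in range(n_sub)], dtype=int)
            founders[ev] = _mutate(founders[eu], sites, rng)

        for unit in sp.units:
            eu = merge_map[unit]
            founder = founders.get(eu)
            if founder is None:
                raise ConfigError(
                    f"unit {unit!r} of {sp.name} never colonized")
            x0, y0, x1, y1 = cfg.units[unit]
            nl = sp.n_localities_per_unit
            for li in range(nl):
                # spread localities across the unit's longitude span (coast
                # to coast) so contact straits are sampled on both sides
                frac = 0.5 if nl == 1 else li / (nl - 1)
                plon = float(x0 + (0.08 + 0.84 * frac) * (x1 - x0)
                             + rng.uniform(-0.02, 0.02) * (x1 - x0))
                plat = float(rng.uniform(y0 + 0.1 * (y1 - y0),
                                         y1 - 0.1 * (y1 - y0)))
                for pi in range(sp.n_specimens_per_locality):
                    sid = f"{sp.name}_{unit}_L{li}_{pi}"
                    seq = founder
                    if rng.uniform() < sp.satellite_prob and pool:
                        seq = _mutate(founder, np.array([pool.pop()]), rng)
                    records.append((sid, "".join(seq)))
                    rows.append({
                        "specimen_id": sid, "species": sp.name,
                        "lat": plat, "lon": plon,
                        "locality_name": f"{unit}_L{li}",
                        "land_unit": unit,
                    })
                    truth.species_of_specimen[sid] = sp.name
    aln = Alignment(records)
    loc = LocalityTable(pd.DataFrame(rows))
    return aln, loc, truth


# ---------------------------------------------------------------------------
# Presence simulation
# ---------------------------------------------------------------------------

def simulate_presences(cfg: WorldConfig, world: World
                       ) -> dict[str, np.ndarray]:
    """Presence points per species from logistic climate suitability.

    Species are mutually exclusive across land units: each species is drawn
    only within its own units, with per-cell inclusion probability
    proportional to a logistic function of the signal variable around the
    threshold (hard split as the softening scale goes to 0).  Expected
    point count equals the configured n.
    """
    rng = _substream(cfg.seed, "presences")
    signal = world.rasters["precip_dry"]
    lon, lat = signal.cell_centers()
    out: dict[str, np.ndarray] = {}
    for sp in cfg.species:
        in_units = np.isin(world.land_unit_grid, sp.units)
        vals = signal.values
        delta = vals - cfg.threshold
        if not sp.wet_adapted:
            delta = -delta
        if cfg.softening_scale <= 0:
            suit = (delta > 0).astype(float)
        else:
            z = np.clip(delta / cfg.softening_scale, -50.0, 50.0)
            suit = 1.0 / (1.0 + np.exp(-z))
        suit = np.where(in_units, suit, 0.0)
        total = suit.sum()
        if total <= 0:
            raise ConfigError(f"no suitable cells for {sp.name}")
        p = np.minimum(1.0, suit * (sp.n_presences / total))
        draw = rng.uniform(size=p.shape) < p
        plon = lon[draw] + rng.uniform(-0.4, 0.4, draw.sum()) * cfg.cell_size
        plat = lat[draw] + rng.uniform(-0.4, 0.4, draw.sum()) * cfg.cell_size
        out[sp.name] = np.column_stack([plon, plat])
    return out


# ---------------------------------------------------------------------------
# Emission in io_core formats
# ---------------------------------------------------------------------------

def write_world(out_dir: str | Path, cfg: WorldConfig) -> dict[str, Path]:
    """Generate everything and emit it in the formats the readers consume."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    world = generate_world(cfg)
    aln, loc, truth = simulate_haplotypes(cfg, world)
    presences = simulate_presences(cfg, world)

    paths: dict[str, Path] = {}
    paths["alignment"] = out_dir / "sequences.fasta"
    write_fasta(paths["alignment"], aln)
    paths["localities"] = out_dir / "localities.csv"
    write_locality_csv(paths["localities"], loc)
    paths["straits"] = out_dir / "straits.csv"
    write_strait_config(paths["straits"], world.strait_graph)
    for name, r in world.rasters.items():
        p = out_dir / f"{name}.asc"
        write_raster(p, r)
        paths[f"raster:{name}"] = p
    occ_rows = []
    for species, pts in presences.items():
        for plon, plat in pts:
            occ_rows.append({"species": species, "lon": plon, "lat": plat})
    paths["occurrences"] = out_dir / "occurrences.csv"
    pd.DataFrame(occ_rows).to_csv(paths["occurrences"], index=False)
    paths["truth"] = out_dir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2)
    return paths
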