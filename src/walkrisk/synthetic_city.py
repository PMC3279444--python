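"""Seeded synthetic city and travel-diary cohort generator.

The generator builds a stylized monocentric city on planar coordinates
(meters, origin at the domain's south-west corner) with the statistical
structure the downstream comparative risk assessment assumes:

* PM2.5 and NOx concentration fields peak at the urban core and near the
  freeway; O3 shows the opposite radial gradient.
* Road-network density, population density and land-use mix all decline
  from core to periphery, so the three walkability variables are
  positively correlated.
* Weekly physical activity follows a zero-inflated log-normal: most
  participants report zero minutes, the probability of being nonsedentary
  and the active-transport share rise with central-ness, and nonsedentary
  minutes are heavy tailed.

Everything is driven by one integer seed; identical config + seed yields
identical tables and fixture files.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from shapely.geometry import MultiLineString, Polygon, box, mapping, shape

from .config import POLLUTANTS, PollutantFieldParams, SyntheticCityConfig, dump_config

SEX_VOCAB = ("male", "female")
ETHNICITY_VOCAB = ("white", "hispanic", "black", "asian", "other")
INCOME_VOCAB = ("<35k", "35-50k", "50-75k", ">75k")
LAND_USE_CLASSES = ("residential", "commercial", "retail", "institutional", "other")
PRIMARY_LAND_USES = LAND_USE_CLASSES[:4]


@dataclass
class Tract:
    tract_id: str
    polygon: Polygon
    population: float


@dataclass
class Parcel:
    parcel_id: str
    polygon: Polygon
    land_use: str


@dataclass
class City:
    config: SyntheticCityConfig
    roads: nx.Graph
    tracts: list[Tract]
    parcels: list[Parcel]
    monitors: pd.DataFrame  # monitor_id, x, y, pollutant
    center: tuple[float, float]
    freeway_lines: MultiLineString | None = field(default=None)

    @property
    def extent_m(self) -> float:
        return self.config.extent_m

    def centralness(self, x, y) -> np.ndarray:
        """Latent central-ness covariate: 1 at the core, 0 at the corner."""
        cx, cy = self.center
        d = np.hypot(np.asarray(x) - cx, np.asarray(y) - cy)
        d_max = np.hypot(cx, cy)
        return 1.0 - d / d_max

    def distance_to_freeway(self, x, y) -> np.ndarray:
        if self.freeway_lines is None or self.freeway_lines.is_empty:
            return np.full(np.broadcast(np.asarray(x), np.asarray(y)).shape, np.inf)
        import shapely

        pts = shapely.points(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
        return shapely.distance(pts, self.freeway_lines)


def _validate(config: SyntheticCityConfig) -> None:
    # pydantic already enforces the field constraints; this guards direct
    # construction with model_construct or mutated objects.
    if config.extent_km <= 0 or config.n_participants < 1 or config.tract_grid_size < 1:
        raise ValueError("invalid synthetic city configuration")


def _build_road_grid(
    config: SyntheticCityConfig, rng: np.random.Generator
) -> tuple[nx.Graph, MultiLineString | None]:
    """Street grid whose density declines from core to periphery.

    A coarse uniform grid (the configured spacing) covers the whole domain;
    lattice nodes at half spacing are kept with a probability that rises
    with central-ness, so the count of intersections within a fixed network
    buffer varies continuously across the city. The graph stays connected:
    coarse nodes are always present, half-spacing "mid" nodes sit on coarse
    edges, and interior fine nodes are kept only when attached to a kept
    neighbor. One straight east-west line of edges is flagged as freeway.
    """
    extent = config.extent_m
    h = config.road_grid_spacing_m / 2.0  # fine lattice pitch
    n = int(round(extent / h))
    cx = cy = extent / 2.0
    d_max = np.hypot(cx, cy)

    ii, jj = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
    c = 1.0 - np.hypot(ii * h - cx, jj * h - cy) / d_max
    # fine-node keep probability: 0 beyond mid-city, 1 at the core
    p_keep = np.clip((c - (1.0 - 2.0 * config.core_radius_fraction)) / (2.0 * config.core_radius_fraction), 0.0, 1.0)
    rand = rng.random((n + 1, n + 1))
    even = (ii % 2 == 0) & (jj % 2 == 0)
    odd_odd = (ii % 2 == 1) & (jj % 2 == 1)
    keep = even | (rand < p_keep)
    # interior fine nodes need a kept lattice neighbor to attach to
    neigh = np.zeros_like(keep)
    neigh[1:, :] |= keep[:-1, :]
    neigh[:-1, :] |= keep[1:, :]
    neigh[:, 1:] |= keep[:, :-1]
    neigh[:, :-1] |= keep[:, 1:]
    keep &= ~odd_odd | neigh

    def kept(i: int, j: int) -> bool:
        return 0 <= i <= n and 0 <= j <= n and bool(keep[i, j])

    g = nx.Graph()
    for i, j in zip(*np.nonzero(keep)):
        g.add_node((int(i), int(j)), x=i * h, y=j * h)
    # freeway along one coarse east-west line at 1/4 of the extent
    j_fw = 2 * int(round(extent / 4.0 / (2 * h)))
    for i, j in list(g.nodes):
        for di, dj in ((1, 0), (0, 1)):
            if kept(i + di, j + dj):
                g.add_edge((i, j), (i + di, j + dj), length=h,
                           freeway=(dj == 0 and j == j_fw))
            elif kept(i + 2 * di, j + 2 * dj):
                g.add_edge((i, j), (i + 2 * di, j + 2 * dj), length=2 * h,
                           freeway=(dj == 0 and j == j_fw))
    lines = [
        ((g.nodes[u]["x"], g.nodes[u]["y"]), (g.nodes[v]["x"], g.nodes[v]["y"]))
        for u, v, d in g.edges(data=True)
        if d["freeway"]
    ]
    return g, (MultiLineString(lines) if lines else None)


def _build_tracts(config: SyntheticCityConfig) -> list[Tract]:
    extent = config.extent_m
    g = config.tract_grid_size
    side = extent / g
    cx = cy = extent / 2.0
    tracts = []
    for iy in range(g):
        for ix in range(g):
            x0, y0 = ix * side, iy * side
            poly = box(x0, y0, x0 + side, y0 + side)
            d_km = np.hypot(x0 + side / 2 - cx, y0 + side / 2 - cy) / 1000.0
            density = config.density_edge + (config.density_center - config.density_edge) * np.exp(
                -d_km / config.density_scale_km
            )  # people/km2
            pop = density * (side / 1000.0) ** 2
            tracts.append(Tract(f"T{iy:02d}{ix:02d}", poly, float(round(pop))))
    return tracts


def _land_use_weights(c: float) -> np.ndarray:
    """Class weights (residential, commercial, retail, institutional, other)
    as a function of central-ness: near-core cells are a balanced mix of the
    four primary uses, peripheral cells are dominated by residential."""
    w = np.array(
        [0.85 - 0.45 * c, 0.05 + 0.15 * c, 0.04 + 0.13 * c, 0.03 + 0.12 * c, 0.03 + 0.05 * c]
    )
    return w / w.sum()


def _build_parcels(config: SyntheticCityConfig, tracts: list[Tract], rng: np.random.Generator) -> list[Parcel]:
    p = config.parcel_grid_per_tract
    extent = config.extent_m
    cx = cy = extent / 2.0
    d_max = np.hypot(cx, cy)
    parcels = []
    for tract in tracts:
        x0, y0, x1, y1 = tract.polygon.bounds
        side = (x1 - x0) / p
        for iy in range(p):
            for ix in range(p):
                px0, py0 = x0 + ix * side, y0 + iy * side
                cxp, cyp = px0 + side / 2, py0 + side / 2
                c = max(0.0, 1.0 - np.hypot(cxp - cx, cyp - cy) / d_max)
                use = rng.choice(LAND_USE_CLASSES, p=_land_use_weights(c))
                parcels.append(
                    Parcel(f"{tract.tract_id}P{iy:02d}{ix:02d}", box(px0, py0, px0 + side, py0 + side), str(use))
                )
    return parcels


def _place_monitors(config: SyntheticCityConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Stratified-jittered monitor placement per pollutant (good spatial
    coverage without a regular lattice)."""
    extent = config.extent_m
    rows = []
    for pollutant in POLLUTANTS:
        m = config.n_monitors_per_pollutant
        g = int(np.ceil(np.sqrt(m)))
        cells = [(i, j) for i in range(g) for j in range(g)]
        idx = rng.permutation(len(cells))[:m]
        for k, ci in enumerate(sorted(idx)):
            i, j = cells[ci]
            x = (i + rng.uniform(0.1, 0.9)) * extent / g
            y = (j + rng.uniform(0.1, 0.9)) * extent / g
            rows.append(
                {"monitor_id": f"{pollutant}-{k:03d}", "x": x, "y": y, "pollutant": pollutant}
            )
    return pd.DataFrame(rows)


def generate_city(config: SyntheticCityConfig) -> City:
    """Generate the deterministic city bundle: roads, tracts, parcels,
    monitor sites."""
    _validate(config)
    rng = np.random.default_rng(config.seed)
    roads, freeway_lines = _build_road_grid(config, rng)
    tracts = _build_tracts(config)
    parcels = _build_parcels(config, tracts, rng)
    monitors = _place_monitors(config, rng)
    return City(
        config=config,
        roads=roads,
        tracts=tracts,
        parcels=parcels,
        monitors=monitors,
        center=(config.extent_m / 2.0, config.extent_m / 2.0),
        freeway_lines=freeway_lines,
    )


def field_value(city: City, x, y, pollutant: str) -> np.ndarray:
    """Deterministic (noise-free) concentration field at (x, y), ug/m3."""
    params = city.config.pollutant_field_params.get(pollutant)
    if params is None:
        raise KeyError(f"unknown pollutant {pollutant!r}")
    cx, cy = city.center
    d_km = np.hypot(np.asarray(x, dtype=float) - cx, np.asarray(y, dtype=float) - cy) / 1000.0
    val = params.center_level + params.gradient_per_km * d_km
    if params.road_increment > 0:
        d_road = city.distance_to_freeway(x, y)
        val = val + params.road_increment * np.exp(-np.asarray(d_road) / params.road_scale_m)
    return np.maximum(val, 0.0)


def generate_pollution_daily(city: City, config: SyntheticCityConfig | None = None) -> pd.DataFrame:
    """365 daily values per monitor: the spatial field at the site plus
    seeded Gaussian noise, clipped at zero. Long table with columns
    monitor_id, x, y, pollutant, date, value."""
    config = config or city.config
    for pollutant in config.pollutant_field_params:
        if pollutant not in POLLUTANTS:
            raise KeyError(f"unknown pollutant {pollutant!r}")
    rng = np.random.default_rng(config.seed + 1)
    dates = pd.date_range("2001-01-01", periods=365, freq="D")
    frames = []
    for _, row in city.monitors.sort_values("monitor_id").iterrows():
        base = float(field_value(city, row.x, row.y, row.pollutant))
        sd = config.pollutant_field_params[row.pollutant].noise_sd
        values = np.maximum(base + rng.normal(0.0, sd, size=365), 0.0) if sd > 0 else np.full(365, base)
        frames.append(
            pd.DataFrame(
                {
                    "monitor_id": row.monitor_id,
                    "x": row.x,
                    "y": row.y,
                    "pollutant": row.pollutant,
                    "date": dates,
                    "value": values,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _sample_homes(city: City, n: int, rng: np.random.Generator) -> pd.DataFrame:
    pops = np.array([t.population for t in city.tracts], dtype=float)
    probs = pops / pops.sum()
    tract_idx = rng.choice(len(city.tracts), size=n, p=probs)
    xs = np.empty(n)
    ys = np.empty(n)
    for i, ti in enumerate(tract_idx):
        x0, y0, x1, y1 = city.tracts[ti].polygon.bounds
        xs[i] = rng.uniform(x0, x1)
        ys[i] = rng.uniform(y0, y1)
    return pd.DataFrame({"home_x": xs, "home_y": ys, "tract_idx": tract_idx})


def generate_participants(
    city: City, config: SyntheticCityConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample the cohort: home locations with density proportional to tract
    population, demographics from fixed vocabularies, and one weekday diary
    per participant from the zero-inflated activity model.

    Returns (participants, diary).
    """
    config = config or city.config
    _validate(config)
    n = config.n_participants
    am = config.activity_model
    rng = np.random.default_rng(config.seed + 2)

    homes = _sample_homes(city, n, rng)
    c = np.clip(city.centralness(homes.home_x.values, homes.home_y.values), 0.0, 1.0)

    age = np.clip(np.round(rng.normal(42.0 - 9.0 * c, 18.0)), 0, 95).astype(int)
    sex = rng.choice(SEX_VOCAB, size=n)
    p_white = np.clip(0.77 - 0.55 * c, 0.05, 0.95)
    is_white = rng.uniform(size=n) < p_white
    other_eth = rng.choice(ETHNICITY_VOCAB[1:], size=n, p=(0.55, 0.2, 0.17, 0.08))
    ethnicity = np.where(is_white, "white", other_eth)
    p_high_income = np.clip(0.62 - 0.35 * c, 0.05, 0.95)
    high_inc = rng.uniform(size=n) < p_high_income
    income_band = np.where(
        high_inc,
        rng.choice(INCOME_VOCAB[2:], size=n),
        rng.choice(INCOME_VOCAB[:2], size=n),
    )
    education_flag = rng.uniform(size=n) < np.clip(0.52 - 0.12 * c, 0.0, 1.0)

    # zero-inflated log-normal weekly minutes
    p_nonsed = am.p_nonsedentary_low + (am.p_nonsedentary_high - am.p_nonsedentary_low) * c
    nonsed = rng.uniform(size=n) < p_nonsed
    mean_min = am.mean_minutes_low + (am.mean_minutes_high - am.mean_minutes_low) * c
    mu = np.log(mean_min) - am.log_sd_minutes**2 / 2.0
    weekly = np.where(nonsed, rng.lognormal(mu, am.log_sd_minutes), 0.0)
    share = np.clip(
        am.transport_share_low + (am.transport_share_high - am.transport_share_low) * c, 0.0, 1.0
    )
    conc = 5.0  # Beta concentration for person-level variation in purpose split
    tshare = rng.beta(np.maximum(share * conc, 1e-6), np.maximum((1 - share) * conc, 1e-6))
    transport_daily = weekly * tshare / 7.0
    recreation_daily = weekly * (1 - tshare) / 7.0

    pid = np.array([f"P{i:06d}" for i in range(n)])
    participants = pd.DataFrame(
        {
            "participant_id": pid,
            "home_x": homes.home_x.values,
            "home_y": homes.home_y.values,
            "age": age,
            "sex": sex,
            "ethnicity": ethnicity,
            "income_band": income_band,
            "education_flag": education_flag,
            "diary_day_type": "weekday",
        }
    )
    diary = pd.DataFrame(
        {
            "participant_id": np.repeat(pid, 2),
            "purpose": np.tile(["transport", "recreation"], n),
            "minutes_per_day": np.column_stack([transport_daily, recreation_daily]).ravel(),
        }
    )
    return participants, diary


def lognormal_params_from_mean_p10(mean: float, p10: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given arithmetic mean and 10th
    percentile — used to emulate a right-skewed cohort exposure distribution
    calibrated to two printed summary statistics."""
    if not 0 < p10 < mean:
        raise ValueError("need 0 < p10 < mean for a right-skewed log-normal")
    from scipy.stats import norm

    z10 = norm.ppf(0.10)
    sigma = z10 + np.sqrt(z10**2 + 2.0 * np.log(mean / p10))
    mu = np.log(mean) - sigma**2 / 2.0
    return float(mu), float(sigma)


def calibrated_exposure_sample(
    mean: float, p10: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n exposures (ug/m3) from the log-normal calibrated to the given
    mean and 10th percentile."""
    mu, sigma = lognormal_params_from_mean_p10(mean, p10)
    return rng.lognormal(mu, sigma, size=n)


# ---------------------------------------------------------------------------
# fixture I/O


def _feature_collection(features: list[dict]) -> dict:
    return {"type": "FeatureCollection", "features": features}


def write_fixture(
    city: City,
    participants: pd.DataFrame,
    diary: pd.DataFrame,
    monitors_daily: pd.DataFrame,
    outdir: str | Path,
) -> Path:
    """Write the city + cohort to CSV/GeoJSON files with a YAML manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    participants.to_csv(outdir / "participants.csv", index=False)
    diary.to_csv(outdir / "diary.csv", index=False)
    monitors_daily.to_csv(outdir / "monitors.csv", index=False)

    tract_features = [
        {
            "type": "Feature",
            "geometry": mapping(t.polygon),
            "properties": {"tract_id": t.tract_id, "population": t.population},
        }
        for t in city.tracts
    ]
    parcel_features = [
        {
            "type": "Feature",
            "geometry": mapping(p.polygon),
            "properties": {"parcel_id": p.parcel_id, "land_use": p.land_use},
        }
        for p in city.parcels
    ]
    road_features = []
    for u, v, d in sorted(city.roads.edges(data=True)):
        cu = (city.roads.nodes[u]["x"], city.roads.nodes[u]["y"])
        cv = (city.roads.nodes[v]["x"], city.roads.nodes[v]["y"])
        road_features.append(
            {
                "type": "Feature",
                "geometry": {"type": "LineString", "coordinates": [cu, cv]},
                "properties": {"freeway": bool(d["freeway"])},
            }
        )
    for name, features in (
        ("tracts", tract_features),
        ("parcels", parcel_features),
        ("roads", road_features),
    ):
        with open(outdir / f"{name}.geojson", "w") as fh:
            json.dump(_feature_collection(features), fh)
    manifest = {"seed": city.config.seed, "config": dump_config(city.config)}
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return outdir


def load_roads(path: str | Path) -> nx.Graph:
    """Rebuild the road graph from a roads.geojson written by write_fixture."""
    with open(path) as fh:
        fc = json.load(fh)
    g = nx.Graph()
    node_ids: dict[tuple[float, float], int] = {}

    def nid(pt):
        key = (round(pt[0], 3), round(pt[1], 3))
        if key not in node_ids:
            node_ids[key] = len(node_ids)
            g.add_node(node_ids[key], x=key[0], y=key[1])
        return node_ids[key]

    for feat in fc["features"]:
        coords = feat["geometry"]["coordinates"]
        for a, b in zip(coords[:-1], coords[1:]):
            u, v = nid(a), nid(b)
            g.add_edge(u, v, length=float(np.hypot(b[0] - a[0], b[1] - a[1])),
                       freeway=bool(feat["properties"].get("freeway", False)))
    return g


def read_fixture(indir: str | Path) -> dict:
    """Load a fixture directory back into in-memory tables and geometries."""
    indir = Path(indir)
    out = {
        "participants": pd.read_csv(indir / "participants.csv"),
        "diary": pd.read_csv(indir / "diary.csv"),
        "monitors": pd.read_csv(indir / "monitors.csv", parse_dates=["date"]),
        "roads": load_roads(indir / "roads.geojson"),
    }
    with open(indir / "tracts.geojson") as fh:
        out["tracts"] = [
            Tract(f["properties"]["tract_id"], shape(f["geometry"]), f["properties"]["population"])
            for f in json.load(fh)["features"]
        ]
    with open(indir / "parcels.geojson") as fh:
        out["parcels"] = [
            Parcel(f["properties"]["parcel_id"], shape(f["geometry"]), f["properties"]["land_use"])
            for f in json.load(fh)["features"]
        ]
    with open(indir / "manifest.yaml") as fh:
        out["manifest"] = yaml.safe_load(fh)
    return out
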