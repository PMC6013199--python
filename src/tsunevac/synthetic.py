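"""Seeded synthetic coastal-city scenarios.

Generates a small coastal city with the statistical shape of the study
area, so the whole pipeline (routing, hazard queries, assignment, timing,
sensitivity) runs end-to-end without any GIS download: a grid road network
with random edge dropout, a straight coastline at y=0 with inundation-level
and 30-cm arrival-time bands parallel to it (the tsunami advances inland,
so arrival time grows with distance from the coast), and recipients placed
so that their network distances to the nearest station and eligible shelter
fall in the ranges observed in the study (station 50-2,700 m, shelter
300-4,600 m).

Everything is drawn from a single numpy Generator keyed by the seed, in a
fixed order, so a seed reproduces a scenario byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import networkx as nx
import numpy as np
from shapely.geometry import box

from .geodata_io import SiteRecord, write_sites
from .hazard_fields import HazardFields, flood_level_at, write_hazard_geojson
from .road_network import RoadGraph, build_graph, write_roads_geojson

__all__ = ["ScenarioConfig", "SyntheticScenario", "generate"]

SEISMIC_BANDS = ("6-", "6+", "7")


@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs of the synthetic city.

    Distances in metres, times in minutes.  The coastline is the x-axis;
    ``level_band_depths`` are the inland extents of inundation levels
    3, 2, 1 (worst nearest the sea) and ``arrival_bands`` the inland
    extents of the arrival-time zones, both strictly increasing from the
    coast.  Beyond the last arrival band no 30-cm arrival is predicted.
    """

    seed: int = 0
    extent: tuple[float, float] = (5000.0, 5000.0)
    grid_spacing: float = 250.0
    edge_dropout: float = 0.10
    n_recipients: int = 21
    n_stations: int = 9
    n_shelters: int = 33
    level_band_depths: tuple[float, float, float] = (800.0, 1800.0, 3000.0)
    arrival_bands: tuple[tuple[float, float], ...] = (
        (1200.0, 35.0),
        (2400.0, 50.0),
        (3600.0, 60.0),
    )
    station_range: tuple[float, float] = (50.0, 2700.0)
    shelter_range: tuple[float, float] = (300.0, 4600.0)
    site_jitter: float = 50.0
    force_level3_shelters: bool = False
    max_retries: int = 50

    def __post_init__(self) -> None:
        if min(self.n_recipients, self.n_stations, self.n_shelters) < 1:
            raise ValueError("site counts must all be >= 1")
        if not 0 <= self.edge_dropout < 1:
            raise ValueError("edge_dropout must be in [0, 1)")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        depths = self.level_band_depths
        if not (0 < depths[0] < depths[1] < depths[2]):
            raise ValueError("level_band_depths must increase strictly from the coast")
        limits = [limit for limit, _ in self.arrival_bands]
        minutes = [m for _, m in self.arrival_bands]
        if sorted(limits) != limits or len(set(limits)) != len(limits) or limits[0] <= 0:
            raise ValueError("arrival band limits must increase strictly from the coast")
        if sorted(minutes) != minutes:
            raise ValueError("arrival minutes must be non-decreasing away from the coast")
        for lo, hi in (self.station_range, self.shelter_range):
            if not 0 <= lo < hi:
                raise ValueError("distance ranges must satisfy 0 <= lo < hi")
        if not 0 <= self.site_jitter < self.grid_spacing / 2:
            raise ValueError("site_jitter must be < grid_spacing / 2 so sites snap home")


@dataclass
class SyntheticScenario:
    """Generated city: sites, road polylines, hazard fields, road graph."""

    config: ScenarioConfig
    recipients: list[SiteRecord]
    stations: list[SiteRecord]
    shelters: list[SiteRecord]
    polylines: list[list[tuple[float, float]]]
    fields: HazardFields
    graph: RoadGraph = field(repr=False, default=None)

    @property
    def sites(self) -> list[SiteRecord]:
        return [*self.recipients, *self.stations, *self.shelters]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the scenario in the formats the pipeline consumes."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "recipients": outdir / "recipients.csv",
            "stations": outdir / "stations.csv",
            "shelters": outdir / "shelters.csv",
            "roads": outdir / "roads.geojson",
            "levels": outdir / "levels.geojson",
            "arrival": outdir / "arrival.geojson",
        }
        write_sites(paths["recipients"], self.recipients)
        write_sites(paths["stations"], self.stations)
        write_sites(paths["shelters"], self.shelters)
        write_roads_geojson(paths["roads"], self.polylines)
        write_hazard_geojson(paths["levels"], paths["arrival"], self.fields)
        return paths


def _hazard_bands(config: ScenarioConfig) -> HazardFields:
    width, _ = config.extent
    pad = config.grid_spacing  # bands overhang the grid so edge sites are covered
    d3, d2, d1 = config.level_band_depths
    level_zones = [
        (box(-pad, 0.0, width + pad, d3), 3),
        (box(-pad, d3, width + pad, d2), 2),
        (box(-pad, d2, width + pad, d1), 1),
    ]
    arrival_zones = []
    y0 = 0.0
    for limit, minutes in config.arrival_bands:
        arrival_zones.append((box(-pad, y0, width + pad, limit), minutes))
        y0 = limit
    return HazardFields(level_zones=level_zones, arrival_zones=arrival_zones)


def _grid_polylines(
    config: ScenarioConfig, rng: np.random.Generator
) -> tuple[list[list[tuple[float, float]]], RoadGraph]:
    """Grid streets with edge dropout, redrawn until connected."""
    width, height = config.extent
    s = config.grid_spacing
    nx_, ny_ = int(width // s) + 1, int(height // s) + 1
    segments: list[tuple[tuple[float, float], tuple[float, float]]] = []
    for i in range(nx_):
        for j in range(ny_):
            p = (i * s, j * s)
            if i + 1 < nx_:
                segments.append((p, ((i + 1) * s, j * s)))
            if j + 1 < ny_:
                segments.append((p, (i * s, (j + 1) * s)))
    for _ in range(config.max_retries):
        keep = rng.random(len(segments)) >= config.edge_dropout
        polylines = [list(seg) for seg, k in zip(segments, keep) if k]
        graph = build_graph(polylines, snap_tolerance=min(1.0, s / 4))
        if graph.n_nodes == nx_ * ny_ and nx.is_connected(graph.graph):
            return polylines, graph
    raise RuntimeError(
        f"road grid not connected after {config.max_retries} dropout draws; "
        "lower edge_dropout"
    )


def _jitter(
    pos: tuple[float, float], rng: np.random.Generator, config: ScenarioConfig
) -> tuple[float, float]:
    j = config.site_jitter
    dx, dy = rng.uniform(-j, j, size=2)
    x = float(np.clip(pos[0] + dx, 0.0, config.extent[0]))
    y = float(max(pos[1] + dy, 0.0))
    return (x, y)


def generate(config: ScenarioConfig) -> SyntheticScenario:
    """Generate a complete scenario, deterministic in ``config.seed``.

    Placement order (fixed for reproducibility): road grid, shelters,
    stations, recipients.  Shelters: random grid nodes, at least one in a
    level<=2 position — unless ``force_level3_shelters``, which pins every
    shelter inside the level-3 band (the degenerate, everyone-unassignable
    case).  Recipients are drawn from nodes whose network distance to the
    nearest station and nearest eligible shelter fall inside the configured
    ranges.
    """
    rng = np.random.default_rng(config.seed)
    fields = _hazard_bands(config)
    polylines, graph = _grid_polylines(config, rng)
    nodes = sorted(graph.graph.nodes)
    pos = {n: graph.position(n) for n in nodes}
    d3 = config.level_band_depths[0]

    # --- shelters ------------------------------------------------------
    j = config.site_jitter
    if config.force_level3_shelters:
        shelter_pool = [n for n in nodes if pos[n][1] + j < d3 and pos[n][1] - j >= 0]
    else:
        shelter_pool = nodes
    if len(shelter_pool) < config.n_shelters:
        raise RuntimeError("not enough nodes to place shelters; shrink counts or bands")
    shelter_nodes = [
        shelter_pool[int(i)]
        for i in rng.choice(len(shelter_pool), size=config.n_shelters, replace=False)
    ]
    if not config.force_level3_shelters and all(pos[n][1] - j < d3 for n in shelter_nodes):
        # guarantee at least one eligible shelter: move the last pick inland
        inland = [n for n in nodes if pos[n][1] - j >= d3]
        shelter_nodes[-1] = inland[int(rng.integers(len(inland)))]
    shelters = [
        SiteRecord(id=f"S{k}", role="shelter", x=xy[0], y=xy[1])
        for k, xy in enumerate(
            (_jitter(pos[n], rng, config) for n in shelter_nodes), start=1
        )
    ]

    # --- stations ------------------------------------------------------
    station_nodes = [
        nodes[int(i)] for i in rng.choice(len(nodes), size=config.n_stations, replace=False)
    ]
    stations = [
        SiteRecord(id=f"N{k}", role="station", x=xy[0], y=xy[1])
        for k, xy in enumerate(
            (_jitter(pos[n], rng, config) for n in station_nodes), start=1
        )
    ]

    # --- recipients ----------------------------------------------------
    d_station = nx.multi_source_dijkstra_path_length(
        graph.graph, set(station_nodes), weight="length"
    )
    eligible_shelter_nodes = {
        node
        for node, site in zip(shelter_nodes, shelters)
        if flood_level_at(fields, site.location) != 3
    }
    lo_st, hi_st = config.station_range
    if eligible_shelter_nodes:
        d_shelter = nx.multi_source_dijkstra_path_length(
            graph.graph, eligible_shelter_nodes, weight="length"
        )
        lo_sh, hi_sh = config.shelter_range
        candidates = [
            n
            for n in nodes
            if lo_st <= d_station.get(n, np.inf) <= hi_st
            and lo_sh <= d_shelter.get(n, np.inf) <= hi_sh
        ]
    else:  # degenerate case: no eligible shelter anywhere
        candidates = [n for n in nodes if lo_st <= d_station.get(n, np.inf) <= hi_st]
    if len(candidates) < config.n_recipients:
        raise RuntimeError(
            f"only {len(candidates)} nodes satisfy the distance ranges for "
            f"{config.n_recipients} recipients; relax ranges or add facilities"
        )
    recipient_nodes = [
        candidates[int(i)]
        for i in rng.choice(len(candidates), size=config.n_recipients, replace=False)
    ]
    recipients = []
    for k, node in enumerate(recipient_nodes, start=1):
        xy = _jitter(pos[node], rng, config)
        level = flood_level_at(fields, xy)
        recipients.append(
            SiteRecord(
                id=f"R{k}",
                role="recipient",
                x=xy[0],
                y=xy[1],
                attributes={
                    "seismic_intensity": SEISMIC_BANDS[int(rng.integers(3))],
                    "max_inundation_m": "" if level is None else f"level-{level}",
                },
            )
        )

    return SyntheticScenario(
        config=config,
        recipients=recipients,
        stations=stations,
        shelters=shelters,
        polylines=polylines,
        fields=fields,
        graph=graph,
    )
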