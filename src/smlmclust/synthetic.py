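"""Ground-truth synthetic two-channel localization scenes.

Generates bacterial cells (2D capsules), substrate particles (polygons) and
cell-particle contact zones, decorates them with planted emitter clusters
according to a condition preset, and renders localization tables with
blinking (geometric localization multiplicity), Gaussian localization error
and uniform Poisson background. Every localization is tied to a generating
emitter and planted cluster, so clustering output can be scored against
ground truth.

Channel A emitters mark scaffoldin CBM3a labels; channel B emitters mark
unoccupied type I cohesins. The stoichiometry couples the two: each planted
"CipA" contributes a channel-A emitter with probability ``label_eff_A`` and
``Binomial(cipA_cohesins, 1 - occupancy_prob)`` unoccupied cohesins, each
yielding a channel-B emitter with probability ``label_eff_B``.

Preset magnitudes are synthetic, not calibrated to any dataset: ``log_*``
presets paint a dense, partially merging decoration on the cell perimeter,
``stationary_detached`` few small clusters, and ``stationary_bound`` shifts
cluster mass into the contact zones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point, Polygon

from smlmclust.dbscan import ClusterLabeling
from smlmclust.errors import ArgumentError, ConfigError
from smlmclust.io import Channel, LocalizationTable

BACKGROUND = -1

PRESET_NAMES = ("log_bound", "stationary_bound", "log_detached", "stationary_detached")

SURFACE_CELL = "cell"
SURFACE_PARTICLE = "particle"
SURFACE_CONTACT = "contact"


# ---------------------------------------------------------------------------
# stoichiometry


@dataclass(frozen=True)
class CellulosomeStoichiometry:
    """Counts and probabilities coupling planted CipA to the two channels."""

    cipA_cohesins: int = 9
    anchor_valency: int = 7
    occupancy_prob: float = 0.7
    label_eff_A: float = 0.8
    label_eff_B: float = 0.8

    def __post_init__(self):
        if self.cipA_cohesins < 0 or self.anchor_valency < 0:
            raise ArgumentError("cohesin counts must be >= 0")
        for p in (self.occupancy_prob, self.label_eff_A, self.label_eff_B):
            if not 0 <= p <= 1:
                raise ArgumentError("probabilities must lie in [0, 1]")


def max_enzyme_capacity(stoich: CellulosomeStoichiometry) -> int:
    """Maximum enzymes on one cell-anchored complex: valency x cohesins."""
    return stoich.anchor_valency * stoich.cipA_cohesins


# ---------------------------------------------------------------------------
# geometry


@dataclass(frozen=True)
class Capsule:
    """Projected rod-shaped cell: segment (p0, p1) dilated by radius (nm)."""

    p0: tuple[float, float]
    p1: tuple[float, float]
    radius: float

    def __post_init__(self):
        if not self.radius > 0:
            raise ArgumentError("capsule radius must be > 0")

    @property
    def length(self) -> float:
        return math.dist(self.p0, self.p1)

    @property
    def perimeter(self) -> float:
        return 2 * self.length + 2 * math.pi * self.radius

    def as_polygon(self, quad_segs: int = 32) -> Polygon:
        return LineString([self.p0, self.p1]).buffer(self.radius, quad_segs=quad_segs)

    def outline_point(self, s: float) -> tuple[float, float]:
        """Point at arc length ``s`` (mod perimeter) along the outline.

        Traversal: side at +radius offset from p0 to p1, cap around p1,
        side back, cap around p0.
        """
        s = s % self.perimeter
        p0 = np.asarray(self.p0, dtype=float)
        p1 = np.asarray(self.p1, dtype=float)
        L, r = self.length, self.radius
        if L > 0:
            u = (p1 - p0) / L
        else:
            u = np.array([1.0, 0.0])
        nvec = np.array([-u[1], u[0]])
        cap = math.pi * r
        if s < L:
            pt = p0 + u * s + nvec * r
        elif s < L + cap:
            ang = (s - L) / r
            base = math.atan2(nvec[1], nvec[0])
            pt = p1 + r * np.array([math.cos(base - ang), math.sin(base - ang)])
        elif s < 2 * L + cap:
            t = s - L - cap
            pt = p1 - u * t - nvec * r
        else:
            ang = (s - 2 * L - cap) / r
            base = math.atan2(-nvec[1], -nvec[0])
            pt = p0 + r * np.array([math.cos(base - ang), math.sin(base - ang)])
        return (float(pt[0]), float(pt[1]))

    def contains(self, x: float, y: float, band: float = 0.0) -> bool:
        """Whether (x, y) lies within the capsule dilated by ``band``."""
        return LineString([self.p0, self.p1]).distance(Point(x, y)) <= self.radius + band


@dataclass
class SceneGeometry:
    """Field extent plus cell capsules, particle and contact-zone polygons."""

    field_extent: tuple[float, float]
    cells: list[Capsule] = field(default_factory=list)
    particles: list[np.ndarray] = field(default_factory=list)  # (k, 2) vertex arrays
    contact_zones: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self):
        w, h = self.field_extent
        if not (w > 0 and h > 0):
            raise ArgumentError("field_extent must be positive")
        frame = Polygon([(0, 0), (w, 0), (w, h), (0, h)])
        for cell in self.cells:
            if not frame.covers(cell.as_polygon()):
                raise ArgumentError("cell outline extends beyond field_extent")
        self._particle_polys = [Polygon(np.asarray(p, dtype=float)) for p in self.particles]
        self._contact_polys = [Polygon(np.asarray(z, dtype=float)) for z in self.contact_zones]
        for poly in self._particle_polys + self._contact_polys:
            if not poly.is_valid or poly.area <= 0:
                raise ArgumentError("degenerate particle/contact polygon")
            if not frame.covers(poly):
                raise ArgumentError("polygon extends beyond field_extent")
        cell_polys = [c.as_polygon() for c in self.cells]
        for zone in self._contact_polys:
            if not any(zone.intersects(c) for c in cell_polys):
                raise ArgumentError("contact zone touches no cell")
            if not any(zone.intersects(p) for p in self._particle_polys):
                raise ArgumentError("contact zone touches no particle")

    @property
    def particle_polys(self) -> list[Polygon]:
        return self._particle_polys

    @property
    def contact_polys(self) -> list[Polygon]:
        return self._contact_polys


def default_geometry(preset: str, n_cells: int = 1) -> SceneGeometry:
    """Deterministic layout: vertical cells side by side; ``*_bound`` presets
    add a substrate slab below the cells plus one contact zone per cell."""
    if preset not in PRESET_NAMES:
        raise ConfigError(f"unknown preset {preset!r}")
    if n_cells < 1:
        raise ConfigError("n_cells must be >= 1")
    pitch = 3000.0
    width = pitch * n_cells
    height = 6000.0
    bound = preset.endswith("_bound")
    cells = []
    zones = []
    for i in range(n_cells):
        cx = pitch / 2 + pitch * i
        cells.append(Capsule(p0=(cx, 1500.0), p1=(cx, 3300.0), radius=250.0))
        if bound:
            zones.append(
                np.array([[cx - 300, 3300], [cx + 300, 3300], [cx + 300, 3900], [cx - 300, 3900]], dtype=float)
            )
    particles = []
    if bound:
        particles.append(
            np.array([[200, 3700], [width - 200, 3700], [width - 200, 5400], [200, 5400]], dtype=float)
        )
    return SceneGeometry(
        field_extent=(width, height), cells=cells, particles=particles, contact_zones=zones
    )


# ---------------------------------------------------------------------------
# planting


@dataclass(frozen=True)
class CountSpec:
    """Point-mass (``fixed``) or Poisson count distribution."""

    kind: str
    value: float

    def __post_init__(self):
        if self.kind not in ("fixed", "poisson"):
            raise ArgumentError(f"unknown count distribution {self.kind!r}")
        if self.value < 0:
            raise ArgumentError("count distribution mean must be >= 0")

    def sample(self, rng: np.random.Generator) -> int:
        if self.kind == "fixed":
            return int(round(self.value))
        return int(rng.poisson(self.value))


@dataclass(frozen=True)
class SurfaceParams:
    """Cluster count/size distributions for one surface class."""

    n_clusters: CountSpec
    cipa_per_cluster: CountSpec
    dispersion: float  # nm, isotropic Gaussian around the cluster center

    def __post_init__(self):
        if not self.dispersion > 0:
            raise ArgumentError("dispersion must be > 0")


PlantParams = dict  # surface class -> SurfaceParams

#: Default planting parameters per condition preset. Magnitudes are
#: synthetic; the presets only encode the qualitative contrasts (dense large
#: decoration in log phase, sparse small clusters on detached stationary
#: cells, contact-zone enrichment on bound stationary cells).
PRESETS: dict[str, PlantParams] = {
    "log_bound": {
        SURFACE_CELL: SurfaceParams(CountSpec("fixed", 25), CountSpec("poisson", 55), 35.0),
        SURFACE_PARTICLE: SurfaceParams(CountSpec("poisson", 3), CountSpec("poisson", 12), 40.0),
    },
    "stationary_bound": {
        SURFACE_CELL: SurfaceParams(CountSpec("poisson", 4), CountSpec("poisson", 8), 30.0),
        SURFACE_CONTACT: SurfaceParams(CountSpec("fixed", 8), CountSpec("poisson", 35), 40.0),
        SURFACE_PARTICLE: SurfaceParams(CountSpec("poisson", 6), CountSpec("poisson", 20), 40.0),
    },
    "log_detached": {
        SURFACE_CELL: SurfaceParams(CountSpec("fixed", 22), CountSpec("poisson", 28), 35.0),
    },
    "stationary_detached": {
        SURFACE_CELL: SurfaceParams(CountSpec("fixed", 6), CountSpec("poisson", 5), 25.0),
    },
}


@dataclass(frozen=True)
class PlantedCluster:
    cluster_id: int
    center: tuple[float, float]
    dispersion: float
    n_cipa: int
    surface_class: str


def plant_clusters(
    geometry: SceneGeometry,
    preset: str,
    params: PlantParams | None = None,
    seed: int = 0,
) -> list[PlantedCluster]:
    """Draw planted clusters on the preset's surface classes.

    Cell clusters sit on the capsule outline, particle clusters on the
    particle boundary, contact clusters uniformly inside the contact zone.
    Raises :class:`ConfigError` when params name a surface class the
    geometry does not provide (e.g. a ``*_bound`` preset with no particles).
    """
    if preset not in PRESET_NAMES:
        raise ConfigError(f"unknown preset {preset!r}")
    if params is None:
        params = PRESETS[preset]
    _check_surfaces(geometry, params)
    rng = np.random.default_rng(seed)
    clusters: list[PlantedCluster] = []
    cid = 0
    for surface in (SURFACE_CELL, SURFACE_PARTICLE, SURFACE_CONTACT):
        if surface not in params:
            continue
        sp = params[surface]
        if surface == SURFACE_CELL:
            # count distribution is per cell ("clusters per bacterial cell")
            centers = []
            for cell in geometry.cells:
                centers.extend(_cell_centers(cell, sp.n_clusters.sample(rng), rng))
        else:
            k = sp.n_clusters.sample(rng)
            centers = [_sample_on_surface(geometry, surface, rng) for _ in range(k)]
        for center in centers:
            n_cipa = max(1, sp.cipa_per_cluster.sample(rng))
            clusters.append(
                PlantedCluster(
                    cluster_id=cid,
                    center=center,
                    dispersion=sp.dispersion,
                    n_cipa=n_cipa,
                    surface_class=surface,
                )
            )
            cid += 1
    return clusters


def _cell_centers(cell: Capsule, kc: int, rng: np.random.Generator):
    """Jittered-regular arc-length placement around one cell outline.

    Regular spacing with +-25% jitter and a random phase: an approximately
    even decoration of the perimeter with controlled inter-cluster gaps.
    """
    if kc <= 0:
        return []
    spacing = cell.perimeter / kc
    phase = float(rng.uniform(0, cell.perimeter))
    jitter = rng.uniform(-0.25, 0.25, size=kc)
    return [cell.outline_point(phase + (i + jitter[i]) * spacing) for i in range(kc)]


def plant_separated_clusters(
    geometry: SceneGeometry,
    k: int,
    n_cipa: int,
    dispersion: float,
    min_separation: float,
    seed: int = 0,
    max_attempts: int = 10000,
) -> list[PlantedCluster]:
    """k cell-surface clusters with pairwise center separation > min_separation.

    Rejection sampling on the cell outlines; used by recovery validation.
    """
    if not geometry.cells:
        raise ConfigError("geometry has no cells")
    rng = np.random.default_rng(seed)
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < k:
        attempts += 1
        if attempts > max_attempts:
            raise ConfigError(
                f"could not place {k} clusters at separation {min_separation} nm"
            )
        c = _sample_on_surface(geometry, SURFACE_CELL, rng)
        if all(math.dist(c, o) > min_separation for o in centers):
            centers.append(c)
    return [
        PlantedCluster(cluster_id=i, center=c, dispersion=dispersion, n_cipa=n_cipa, surface_class=SURFACE_CELL)
        for i, c in enumerate(centers)
    ]


def _check_surfaces(geometry: SceneGeometry, params: PlantParams):
    needs = {
        SURFACE_CELL: bool(geometry.cells),
        SURFACE_PARTICLE: bool(geometry.particles),
        SURFACE_CONTACT: bool(geometry.contact_zones),
    }
    for surface, sp in params.items():
        if surface not in needs:
            raise ConfigError(f"unknown surface class {surface!r}")
        if sp.n_clusters.value > 0 and not needs[surface]:
            raise ConfigError(f"preset requests {surface!r} clusters but geometry has none")


def _sample_on_surface(geometry: SceneGeometry, surface: str, rng: np.random.Generator):
    if surface == SURFACE_CELL:
        cell = geometry.cells[int(rng.integers(len(geometry.cells)))]
        return cell.outline_point(float(rng.uniform(0, cell.perimeter)))
    if surface == SURFACE_PARTICLE:
        poly = geometry.particle_polys[int(rng.integers(len(geometry.particles)))]
        ring = poly.exterior
        pt = ring.interpolate(float(rng.uniform(0, ring.length)))
        return (pt.x, pt.y)
    if surface == SURFACE_CONTACT:
        poly = geometry.contact_polys[int(rng.integers(len(geometry.contact_zones)))]
        minx, miny, maxx, maxy = poly.bounds
        while True:  # rejection sampling; zones are convex-ish, terminates fast
            x = float(rng.uniform(minx, maxx))
            y = float(rng.uniform(miny, maxy))
            if poly.covers(Point(x, y)):
                return (x, y)
    raise ArgumentError(f"unknown surface class {surface!r}")


# ---------------------------------------------------------------------------
# rendering


@dataclass(frozen=True)
class EmitterModel:
    """Blinking multiplicity, localization precision and background level."""

    mean_localizations: float = 4.0  # geometric, support >= 1
    precision_sigma: float = 20.0  # nm
    background_density: float = 0.5  # localizations per um^2 per channel

    def __post_init__(self):
        if not self.mean_localizations >= 1:
            raise ArgumentError("mean_localizations must be >= 1")
        if not self.precision_sigma > 0:
            raise ArgumentError("precision_sigma must be > 0")
        if self.background_density < 0:
            raise ArgumentError("background_density must be >= 0")


@dataclass
class RenderResult:
    """Per-channel tables plus the emitter ground truth."""

    table_a: LocalizationTable
    table_b: LocalizationTable
    emitters: pd.DataFrame  # emitter_id, true_x, true_y, channel, cluster_id
    truth_cluster: dict[Channel, np.ndarray]  # per-localization planted id (-1 bg)
    truth_emitter: dict[Channel, np.ndarray]  # per-localization emitter id


@dataclass
class SyntheticScene:
    geometry: SceneGeometry
    clusters: list[PlantedCluster]
    emitters: pd.DataFrame
    tables: dict[Channel, LocalizationTable]
    truth_cluster: dict[Channel, np.ndarray]
    truth_emitter: dict[Channel, np.ndarray]
    preset: str
    seed: int
    stoichiometry: CellulosomeStoichiometry
    emitter_model: EmitterModel


def render_localizations(
    clusters: list[PlantedCluster],
    stoich: CellulosomeStoichiometry,
    emitter_model: EmitterModel,
    seed: int,
    field_extent: tuple[float, float],
    n_frames: int = 15000,
) -> RenderResult:
    """Render two localization tables from planted clusters.

    Per CipA: one channel-A emitter with probability ``label_eff_A`` and
    ``Binomial(cipA_cohesins, 1 - occupancy_prob)`` unoccupied cohesins,
    each a channel-B emitter with probability ``label_eff_B``. Each emitter
    produces a geometric number of localizations displaced by isotropic
    Gaussian noise; background is a homogeneous Poisson process, one
    localization per background emitter. Coordinates are clipped to the
    field. Fully reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    w, h = field_extent
    em_x: list[float] = []
    em_y: list[float] = []
    em_channel: list[Channel] = []
    em_cluster: list[int] = []

    for cl in clusters:
        pos = np.asarray(cl.center) + rng.normal(0.0, cl.dispersion, size=(cl.n_cipa, 2))
        has_a = rng.random(cl.n_cipa) < stoich.label_eff_A
        unoccupied = rng.binomial(stoich.cipA_cohesins, 1.0 - stoich.occupancy_prob, size=cl.n_cipa)
        b_emitters = rng.binomial(unoccupied, stoich.label_eff_B)
        for i in range(cl.n_cipa):
            if has_a[i]:
                em_x.append(pos[i, 0])
                em_y.append(pos[i, 1])
                em_channel.append(Channel.A_AF647)
                em_cluster.append(cl.cluster_id)
            for _ in range(int(b_emitters[i])):
                em_x.append(pos[i, 0])
                em_y.append(pos[i, 1])
                em_channel.append(Channel.B_PAGFP)
                em_cluster.append(cl.cluster_id)

    area_um2 = w * h * 1e-6
    for channel in (Channel.A_AF647, Channel.B_PAGFP):
        n_bg = int(rng.poisson(emitter_model.background_density * area_um2))
        bx = rng.uniform(0, w, size=n_bg)
        by = rng.uniform(0, h, size=n_bg)
        em_x.extend(bx)
        em_y.extend(by)
        em_channel.extend([channel] * n_bg)
        em_cluster.extend([BACKGROUND] * n_bg)

    emitters = pd.DataFrame(
        {
            "emitter_id": np.arange(len(em_x)),
            "true_x": np.asarray(em_x, dtype=float),
            "true_y": np.asarray(em_y, dtype=float),
            "channel": [c.value for c in em_channel],
            "cluster_id": np.asarray(em_cluster, dtype=np.int64),
        }
    )

    geom_p = 1.0 / emitter_model.mean_localizations
    tables: dict[Channel, LocalizationTable] = {}
    truth_cluster: dict[Channel, np.ndarray] = {}
    truth_emitter: dict[Channel, np.ndarray] = {}
    for channel in (Channel.A_AF647, Channel.B_PAGFP):
        mask = emitters["channel"] == channel.value
        ex = emitters.loc[mask, "true_x"].to_numpy()
        ey = emitters.loc[mask, "true_y"].to_numpy()
        eid = emitters.loc[mask, "emitter_id"].to_numpy()
        ecl = emitters.loc[mask, "cluster_id"].to_numpy()
        is_bg = ecl == BACKGROUND
        n_locs = np.where(is_bg, 1, rng.geometric(geom_p, size=len(ex)))
        total = int(n_locs.sum())
        sx = np.repeat(ex, n_locs) + rng.normal(0.0, emitter_model.precision_sigma, size=total)
        sy = np.repeat(ey, n_locs) + rng.normal(0.0, emitter_model.precision_sigma, size=total)
        np.clip(sx, 0.0, w, out=sx)
        np.clip(sy, 0.0, h, out=sy)
        unc = rng.uniform(0.5 * emitter_model.precision_sigma, 1.5 * emitter_model.precision_sigma, size=total)
        frames = rng.integers(1, n_frames + 1, size=total)
        tables[channel] = LocalizationTable(
            x=sx,
            y=sy,
            frame=frames,
            uncertainty=unc,
            channel=channel,
            field_extent=(w, h),
            provenance="synthetic",
        )
        truth_cluster[channel] = np.repeat(ecl, n_locs)
        truth_emitter[channel] = np.repeat(eid, n_locs)

    return RenderResult(
        table_a=tables[Channel.A_AF647],
        table_b=tables[Channel.B_PAGFP],
        emitters=emitters,
        truth_cluster=truth_cluster,
        truth_emitter=truth_emitter,
    )


def generate_scene(
    preset: str,
    seed: int,
    geometry: SceneGeometry | None = None,
    stoich: CellulosomeStoichiometry = CellulosomeStoichiometry(),
    emitter_model: EmitterModel = EmitterModel(),
    params: PlantParams | None = None,
    n_cells: int = 1,
    n_frames: int = 15000,
) -> SyntheticScene:
    """Plant and render a full scene under a named condition preset."""
    if preset not in PRESET_NAMES:
        raise ConfigError(f"unknown preset {preset!r}")
    if geometry is None:
        geometry = default_geometry(preset, n_cells=n_cells)
    ss = np.random.SeedSequence(seed)
    seed_plant, seed_render = (int(s.generate_state(1)[0]) for s in ss.spawn(2))
    clusters = plant_clusters(geometry, preset, params=params, seed=seed_plant)
    rendered = render_localizations(
        clusters, stoich, emitter_model, seed_render, geometry.field_extent, n_frames=n_frames
    )
    return SyntheticScene(
        geometry=geometry,
        clusters=clusters,
        emitters=rendered.emitters,
        tables={Channel.A_AF647: rendered.table_a, Channel.B_PAGFP: rendered.table_b},
        truth_cluster=rendered.truth_cluster,
        truth_emitter=rendered.truth_emitter,
        preset=preset,
        seed=seed,
        stoichiometry=stoich,
        emitter_model=emitter_model,
    )


# ---------------------------------------------------------------------------
# recovery scoring


@dataclass(frozen=True)
class RecoveryReport:
    n_detected: int
    n_planted: int  # planted clusters with >= 1 localization
    matched_fraction: float
    background_noise_fraction: float


def evaluate_recovery(labeling: ClusterLabeling, scene: SyntheticScene, channel: Channel) -> RecoveryReport:
    """Score a labeling against the scene's planted ground truth.

    A planted cluster is matched when more than half of its localizations
    carry one common detected (non-noise) cluster id. The background
    fraction is the share of background localizations labeled noise
    (1.0 when the scene has no background localizations).
    """
    if channel not in scene.tables:
        raise ArgumentError(f"channel {channel} not present in scene")
    truth = scene.truth_cluster[channel]
    if len(truth) != len(labeling.labels):
        raise ArgumentError("labeling does not index the scene's table for this channel")
    planted_ids = np.unique(truth[truth != BACKGROUND])
    matched = 0
    for pid in planted_ids:
        member_labels = labeling.labels[truth == pid]
        detected = member_labels[member_labels != -1]
        if len(detected) == 0:
            continue
        _, counts = np.unique(detected, return_counts=True)
        if counts.max() > 0.5 * len(member_labels):
            matched += 1
    bg = truth == BACKGROUND
    bg_noise = float(np.mean(labeling.labels[bg] == -1)) if bg.any() else 1.0
    return RecoveryReport(
        n_detected=labeling.n_clusters,
        n_planted=len(planted_ids),
        matched_fraction=matched / len(planted_ids) if len(planted_ids) else 1.0,
        background_noise_fraction=bg_noise,
    )
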