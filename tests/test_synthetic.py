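import numpy as np
import pytest
from shapely.geometry import LineString, Point, Polygon

from smlmclust.dbscan import ClusterLabeling, ClusterParams, Role, dbscan
from smlmclust.errors import ArgumentError, ConfigError
from smlmclust.io import Channel
from smlmclust.synthetic import (
    BACKGROUND,
    Capsule,
    CellulosomeStoichiometry,
    CountSpec,
    EmitterModel,
    PRESETS,
    SceneGeometry,
    SurfaceParams,
    default_geometry,
    evaluate_recovery,
    generate_scene,
    max_enzyme_capacity,
    plant_clusters,
    plant_separated_clusters,
    render_localizations,
)

import oracles


@pytest.fixture
def simple_geometry():
    return SceneGeometry(
        field_extent=(8000.0, 8000.0),
        cells=[Capsule(p0=(4000.0, 2000.0), p1=(4000.0, 5000.0), radius=300.0)],
        particles=[np.array([[1000.0, 6000.0], [7000.0, 6000.0], [7000.0, 7500.0], [1000.0, 7500.0]])],
        contact_zones=[np.array([[3500.0, 5200.0], [4500.0, 5200.0], [4500.0, 6200.0], [3500.0, 6200.0]])],
    )


class TestStoichiometry:
    def test_heptavalent_anchor_nine_cohesins(self):
        assert max_enzyme_capacity(CellulosomeStoichiometry(cipA_cohesins=9, anchor_valency=7)) == 63

    def test_single_cipa(self):
        assert max_enzyme_capacity(CellulosomeStoichiometry(cipA_cohesins=9, anchor_valency=1)) == 9

    def test_zero_valency(self):
        assert max_enzyme_capacity(CellulosomeStoichiometry(cipA_cohesins=9, anchor_valency=0)) == 0

    @pytest.mark.parametrize("a,b", [(3, 5), (7, 9), (1, 12)])
    def test_multiplicative_and_symmetric(self, a, b):
        s1 = CellulosomeStoichiometry(cipA_cohesins=a, anchor_valency=b)
        s2 = CellulosomeStoichiometry(cipA_cohesins=b, anchor_valency=a)
        assert max_enzyme_capacity(s1) == max_enzyme_capacity(s2) == a * b

    def test_bad_probability_rejected(self):
        with pytest.raises(ArgumentError):
            CellulosomeStoichiometry(occupancy_prob=1.5)


class TestGeometry:
    def test_cell_outside_field_rejected(self):
        with pytest.raises(ArgumentError):
            SceneGeometry(field_extent=(1000.0, 1000.0), cells=[Capsule((500, 500), (2000, 500), 100)])

    def test_contact_zone_must_touch_cell_and_particle(self):
        with pytest.raises(ArgumentError, match="contact"):
            SceneGeometry(
                field_extent=(8000.0, 8000.0),
                cells=[Capsule((4000, 1000), (4000, 2000), 200)],
                particles=[np.array([[100, 7000], [500, 7000], [500, 7500], [100, 7500]])],
                contact_zones=[np.array([[6000, 6000], [6500, 6000], [6500, 6500], [6000, 6500]])],
            )

    def test_capsule_outline_points_on_boundary(self):
        cap = Capsule(p0=(100.0, 100.0), p1=(400.0, 100.0), radius=50.0)
        seg = LineString([cap.p0, cap.p1])
        for s in np.linspace(0, cap.perimeter, 57):
            pt = cap.outline_point(float(s))
            assert seg.distance(Point(pt)) == pytest.approx(cap.radius, abs=1e-6)

    def test_default_bound_geometry_has_particle_and_contacts(self):
        geom = default_geometry("stationary_bound", n_cells=2)
        assert len(geom.cells) == 2
        assert len(geom.particles) == 1
        assert len(geom.contact_zones) == 2


class TestPlantClusters:
    def test_zero_clusters(self, simple_geometry):
        params = {"cell": SurfaceParams(CountSpec("fixed", 0), CountSpec("fixed", 5), 30.0)}
        assert plant_clusters(simple_geometry, "log_detached", params=params, seed=1) == []

    def test_same_seed_identical(self, simple_geometry):
        a = plant_clusters(simple_geometry, "log_bound", seed=42)
        b = plant_clusters(simple_geometry, "log_bound", seed=42)
        assert a == b

    def test_fixed_count_centers_on_surface_class(self, simple_geometry):
        params = {
            "cell": SurfaceParams(CountSpec("fixed", 7), CountSpec("fixed", 5), 30.0),
            "particle": SurfaceParams(CountSpec("fixed", 4), CountSpec("fixed", 5), 30.0),
            "contact": SurfaceParams(CountSpec("fixed", 3), CountSpec("fixed", 5), 30.0),
        }
        clusters = plant_clusters(simple_geometry, "stationary_bound", params=params, seed=3)
        by_class = {}
        for c in clusters:
            by_class.setdefault(c.surface_class, []).append(c)
        assert len(by_class["cell"]) == 7
        assert len(by_class["particle"]) == 4
        assert len(by_class["contact"]) == 3
        # point-in-region oracles per class
        cell = simple_geometry.cells[0]
        seg = LineString([cell.p0, cell.p1])
        for c in by_class["cell"]:
            assert seg.distance(Point(c.center)) == pytest.approx(cell.radius, abs=1e-6)
        particle = Polygon(simple_geometry.particles[0])
        for c in by_class["particle"]:
            assert particle.exterior.distance(Point(c.center)) < 1e-6
        zone = Polygon(simple_geometry.contact_zones[0])
        for c in by_class["contact"]:
            assert zone.covers(Point(c.center))

    def test_bound_preset_without_particles_rejected(self):
        geom = SceneGeometry(
            field_extent=(8000.0, 8000.0),
            cells=[Capsule((4000, 2000), (4000, 5000), 300)],
        )
        with pytest.raises(ConfigError):
            plant_clusters(geom, "stationary_bound", seed=0)

    def test_unknown_preset_rejected(self, simple_geometry):
        with pytest.raises(ConfigError):
            plant_clusters(simple_geometry, "exponential_phase", seed=0)

    def test_separated_clusters_respect_min_distance(self, simple_geometry):
        clusters = plant_separated_clusters(
            simple_geometry, k=5, n_cipa=10, dispersion=30.0, min_separation=600.0, seed=9
        )
        assert len(clusters) == 5
        centers = np.array([c.center for c in clusters])
        d = oracles.distance_matrix(centers)
        np.fill_diagonal(d, np.inf)
        assert d.min() > 600.0


class TestRender:
    def test_no_clusters_no_background_empty(self):
        model = EmitterModel(background_density=0.0)
        res = render_localizations([], CellulosomeStoichiometry(), model, 1, (5000.0, 5000.0))
        assert len(res.table_a) == 0
        assert len(res.table_b) == 0

    def test_full_occupancy_no_channel_b_cluster_emitters(self, simple_geometry):
        stoich = CellulosomeStoichiometry(occupancy_prob=1.0, label_eff_B=1.0)
        model = EmitterModel(background_density=0.0)
        clusters = plant_clusters(simple_geometry, "log_bound", seed=5)
        res = render_localizations(clusters, stoich, model, 2, simple_geometry.field_extent)
        assert len(res.table_b) == 0

    def test_deterministic_counting_limit(self, simple_geometry):
        # point-mass N=1 (geometric mean 1), full channel-A labeling
        stoich = CellulosomeStoichiometry(label_eff_A=1.0, occupancy_prob=1.0)
        model = EmitterModel(mean_localizations=1.0, precision_sigma=1e-9, background_density=0.0)
        params = {"cell": SurfaceParams(CountSpec("fixed", 6), CountSpec("fixed", 11), 30.0)}
        clusters = plant_clusters(simple_geometry, "log_detached", params=params, seed=7)
        total_cipa = sum(c.n_cipa for c in clusters)
        res = render_localizations(clusters, stoich, model, 3, simple_geometry.field_extent)
        assert len(res.table_a) == total_cipa

    def test_seed_determinism_bit_identical(self):
        a = generate_scene("stationary_bound", seed=11, n_cells=1)
        b = generate_scene("stationary_bound", seed=11, n_cells=1)
        for ch in (Channel.A_AF647, Channel.B_PAGFP):
            np.testing.assert_array_equal(a.tables[ch].x, b.tables[ch].x)
            np.testing.assert_array_equal(a.tables[ch].y, b.tables[ch].y)
            np.testing.assert_array_equal(a.tables[ch].frame, b.tables[ch].frame)
            np.testing.assert_array_equal(a.truth_cluster[ch], b.truth_cluster[ch])
        assert a.emitters.equals(b.emitters)

    def test_different_seeds_differ(self):
        a = generate_scene("stationary_bound", seed=11)
        b = generate_scene("stationary_bound", seed=12)
        assert len(a.tables[Channel.A_AF647]) != len(b.tables[Channel.A_AF647]) or not np.array_equal(
            a.tables[Channel.A_AF647].x, b.tables[Channel.A_AF647].x
        )

    def test_emitters_lie_on_declared_surface_band(self, simple_geometry):
        # non-background true emitter positions stay near their surface class:
        # cluster center on the surface + Gaussian(dispersion) => within 6 sigma
        params = {"cell": SurfaceParams(CountSpec("fixed", 8), CountSpec("fixed", 10), 25.0)}
        clusters = plant_clusters(simple_geometry, "log_detached", params=params, seed=13)
        res = render_localizations(
            clusters, CellulosomeStoichiometry(), EmitterModel(background_density=0.0), 4, simple_geometry.field_extent
        )
        cell = simple_geometry.cells[0]
        seg = LineString([cell.p0, cell.p1])
        planted = res.emitters[res.emitters["cluster_id"] != BACKGROUND]
        for _, row in planted.iterrows():
            d = seg.distance(Point(row["true_x"], row["true_y"]))
            assert abs(d - cell.radius) < 6 * 25.0

    def test_expected_channel_a_emitters_per_cluster(self, simple_geometry):
        # mean over 200 seeds within 3 standard errors of n_cipa * label_eff_A
        n_cipa, p = 20, 0.8
        stoich = CellulosomeStoichiometry(label_eff_A=p)
        model = EmitterModel(background_density=0.0)
        params = {"cell": SurfaceParams(CountSpec("fixed", 1), CountSpec("fixed", n_cipa), 25.0)}
        counts = []
        for seed in range(200):
            clusters = plant_clusters(simple_geometry, "log_detached", params=params, seed=seed)
            res = render_localizations(clusters, stoich, model, seed + 10_000, simple_geometry.field_extent)
            em = res.emitters
            counts.append(((em["channel"] == Channel.A_AF647.value) & (em["cluster_id"] == 0)).sum())
        mean = np.mean(counts)
        se = np.sqrt(n_cipa * p * (1 - p) / 200)
        assert abs(mean - n_cipa * p) < 3 * se

    def test_expected_unoccupied_cohesins(self, simple_geometry):
        # channel-B emitters per CipA ~ Binomial(9, 1-occupancy) with label_eff_B=1
        occ = 0.7
        stoich = CellulosomeStoichiometry(occupancy_prob=occ, label_eff_B=1.0)
        model = EmitterModel(background_density=0.0)
        params = {"cell": SurfaceParams(CountSpec("fixed", 1), CountSpec("fixed", 10), 25.0)}
        per_cipa = []
        for seed in range(200):
            clusters = plant_clusters(simple_geometry, "log_detached", params=params, seed=seed)
            res = render_localizations(clusters, stoich, model, seed + 20_000, simple_geometry.field_extent)
            em = res.emitters
            n_b = ((em["channel"] == Channel.B_PAGFP.value) & (em["cluster_id"] == 0)).sum()
            per_cipa.append(n_b / 10)
        expected = 9 * (1 - occ)
        se = np.sqrt(9 * (1 - occ) * occ / (10 * 200))
        assert abs(np.mean(per_cipa) - expected) < 3 * se


class TestEvaluateRecovery:
    @pytest.fixture
    def scene(self):
        return generate_scene("stationary_detached", seed=21)

    def test_ground_truth_labeling_perfect(self, scene):
        truth = scene.truth_cluster[Channel.A_AF647]
        labels = truth.copy()
        roles = np.array([Role.NOISE if t == -1 else Role.CORE for t in truth], dtype=object)
        ids = np.unique(truth[truth != -1])
        remap = {old: new for new, old in enumerate(ids)}
        labels = np.array([remap.get(t, -1) for t in truth])
        labeling = ClusterLabeling(labels=labels, roles=roles, params=ClusterParams(75.0, 10), n_clusters=len(ids))
        rep = evaluate_recovery(labeling, scene, Channel.A_AF647)
        assert rep.matched_fraction == 1.0
        assert rep.background_noise_fraction == 1.0

    def test_all_noise_labeling(self, scene):
        n = len(scene.tables[Channel.A_AF647])
        labeling = ClusterLabeling(
            labels=np.full(n, -1),
            roles=np.array([Role.NOISE] * n, dtype=object),
            params=ClusterParams(75.0, 10),
            n_clusters=0,
        )
        rep = evaluate_recovery(labeling, scene, Channel.A_AF647)
        assert rep.matched_fraction == 0.0
        assert rep.background_noise_fraction == 1.0

    def test_matched_fraction_equals_contingency_oracle(self):
        geom = SceneGeometry(
            field_extent=(12000.0, 12000.0),
            cells=[Capsule((6000.0, 2000.0), (6000.0, 10000.0), 400.0)],
        )
        clusters = plant_separated_clusters(geom, k=6, n_cipa=12, dispersion=30.0, min_separation=600.0, seed=31)
        res = render_localizations(
            clusters, CellulosomeStoichiometry(), EmitterModel(background_density=0.1), 32, geom.field_extent
        )
        labeling = dbscan(res.table_a.coords(), ClusterParams(eps=75.0, mnm=10))
        scene = generate_scene("stationary_detached", seed=0)  # shell to score against
        scene.tables[Channel.A_AF647] = res.table_a
        scene.truth_cluster[Channel.A_AF647] = res.truth_cluster[Channel.A_AF647]
        rep = evaluate_recovery(labeling, scene, Channel.A_AF647)
        expected = oracles.overlap_match_fraction(res.truth_cluster[Channel.A_AF647], labeling.labels)
        assert rep.matched_fraction == pytest.approx(expected)

    def test_channel_mismatch_rejected(self, scene):
        n = len(scene.tables[Channel.B_PAGFP])
        labeling = ClusterLabeling(
            labels=np.full(n + 3, -1),
            roles=np.array([Role.NOISE] * (n + 3), dtype=object),
            params=ClusterParams(75.0, 10),
            n_clusters=0,
        )
        with pytest.raises(ArgumentError):
            evaluate_recovery(labeling, scene, Channel.B_PAGFP)
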