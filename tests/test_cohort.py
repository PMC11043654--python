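"""Synthetic cohort: atlas geometry, correlation targets, planted effects."""

import json

import numpy as np
import pytest

from sfc_aging.cohort import (
    CapacityError,
    CohortConfig,
    ConfigError,
    build_phantom_atlas,
    build_plan,
    factor_covariance,
    generate_cohort,
    simulate_timeseries,
)
from sfc_aging.io import build_node_table, read_regional_table, read_volume
from sfc_aging.sfc import partition_caudate


class TestConfig:
    def test_defaults_are_study_conditions(self):
        cfg = CohortConfig()
        assert cfg.n_per_group == (52, 42, 58)
        assert sum(cfg.n_per_group) == 152

    def test_validation(self):
        with pytest.raises(ConfigError, match="n_timepoints"):
            CohortConfig(n_timepoints=5)
        with pytest.raises(ConfigError, match="pairing infeasible"):
            CohortConfig(pair_r=0.5, n_pairs_per_target=4)
        with pytest.raises(ConfigError, match="noise_sd"):
            CohortConfig(noise_sd=0.0)

    def test_hash_round_trip(self):
        cfg = CohortConfig(seed=9)
        again = CohortConfig.from_jsonable(json.loads(json.dumps(cfg.to_jsonable())))
        assert again.content_hash() == cfg.content_hash()
        assert again.aging_edge_deltas == cfg.aging_edge_deltas


class TestPhantomAtlas:
    def test_structure(self, small_config):
        atlas = build_phantom_atlas(small_config.grid_dims, small_config.n_parcels, small_config.seed)
        assert set(np.unique(atlas.labels)) - {0} == set(atlas.dictionary)
        assert atlas.mask_of_class("ventricle").any()
        assert atlas.mask_of_class("caudate_left").any()
        assert atlas.mask_of_class("caudate_right").any()
        assert len(atlas.region_names("cortical_parcel", "subcortical_parcel")) == small_config.n_parcels

    def test_medial_wall_is_face_layer(self, small_config):
        atlas = build_phantom_atlas(small_config.grid_dims, small_config.n_parcels, small_config.seed)
        nt = build_node_table(atlas)
        medial, lateral = partition_caudate(atlas, 6, nt)
        cx = small_config.grid_dims[0] // 2
        med_x = {int(nt.coords[i][0]) for i in medial.nodes}
        lat_x = {int(nt.coords[i][0]) for i in lateral.nodes}
        assert med_x == {cx - 1, cx + 1}  # the layers touching the ventricle slab
        assert lat_x == {cx - 2, cx + 2}
        assert len(medial) == len(lateral)

    def test_too_small_grid_names_limiting_structure(self):
        with pytest.raises(CapacityError, match="caudate"):
            build_phantom_atlas((2, 2, 2), 4)

    def test_deterministic_in_seed(self):
        a1 = build_phantom_atlas((8, 8, 8), 10, seed=3)
        a2 = build_phantom_atlas((8, 8, 8), 10, seed=3)
        a3 = build_phantom_atlas((8, 8, 8), 10, seed=4)
        np.testing.assert_array_equal(a1.labels, a2.labels)
        assert not np.array_equal(a1.labels, a3.labels)


class TestCovariance:
    def test_psd_projection_threshold(self):
        cfg = CohortConfig()
        communities = ["caudate", "dmn", "frontoparietal", "sensorimotor", "visual", "limbic", "subcortical"]
        psi = factor_covariance(cfg, "young", communities)
        assert np.linalg.eigvalsh(psi)[0] >= -1e-10
        np.testing.assert_allclose(np.diag(psi), [cfg.within_r.get(c, 0.5) for c in communities])

    def test_grossly_indefinite_raises(self):
        cfg = CohortConfig(seed_community_r={"dmn": 0.9, "frontoparietal": 0.9},
                           aging_edge_deltas={"elderly": {("dmn", "frontoparietal"): -0.95}})
        communities = ["caudate", "dmn", "frontoparietal"]
        with pytest.raises(ConfigError, match="positive semidefinite"):
            factor_covariance(cfg, "elderly", communities)


@pytest.fixture(scope="module")
def long_run():
    cfg = CohortConfig(
        n_per_group=(1, 0, 0), grid_dims=(8, 8, 8), n_parcels=10, n_timepoints=10_000, seed=21
    )
    atlas = build_phantom_atlas(cfg.grid_dims, cfg.n_parcels, cfg.seed)
    plan = build_plan(atlas, cfg)
    rng = np.random.default_rng([cfg.seed, 1, 0])
    x = simulate_timeseries(atlas, cfg, "young", rng, plan)
    return cfg, plan, x


class TestTimeseriesModel:
    def test_within_community_correlation(self, long_run):
        cfg, plan, x = long_run
        dmn = np.flatnonzero(plan.node_community == "dmn")[:12]
        r = np.corrcoef(x[dmn])
        off = r[np.triu_indices(len(dmn), 1)]
        assert abs(off.mean() - cfg.within_r["dmn"]) < 0.05

    def test_seed_community_correlation(self, long_run):
        cfg, plan, x = long_run
        caud = np.flatnonzero(plan.node_community == "caudate")[:10]
        dmn = np.flatnonzero(plan.node_community == "dmn")[:10]
        r = np.corrcoef(np.vstack([x[caud], x[dmn]]))[:10, 10:]
        assert abs(r.mean() - cfg.seed_community_r["dmn"]) < 0.05

    def test_pairing_correlation_exact_target(self, long_run):
        cfg, plan, x = long_run
        rs = []
        others = []
        medial = set(plan.medial_nodes.tolist())
        for node, partners in list(plan.pair_partners.items())[:20]:
            for p in partners:
                rs.append(np.corrcoef(x[node], x[p])[0, 1])
            pool = plan.medial_nodes if int(partners[0]) in medial else plan.lateral_nodes
            non_partner = [s for s in pool if s not in set(int(q) for q in partners)][:2]
            for q in non_partner:
                others.append(np.corrcoef(x[node], x[q])[0, 1])
        assert abs(np.mean(rs) - cfg.pair_r) < 0.05
        assert abs(np.mean(others)) < 0.05  # no leakage to non-partner seed voxels

    def test_target_uncorrelated_with_communities(self, long_run):
        cfg, plan, x = long_run
        mcr = np.flatnonzero(plan.node_community == "mcr_target")
        dmn = np.flatnonzero(plan.node_community == "dmn")[:8]
        r = np.corrcoef(np.vstack([x[mcr], x[dmn]]))[: len(mcr), len(mcr):]
        assert abs(r.mean()) < 0.05

    def test_group_delta_recovery(self):
        cfg = CohortConfig(n_per_group=(1, 0, 1), grid_dims=(8, 8, 8), n_parcels=10,
                           n_timepoints=5000, seed=22)
        atlas = build_phantom_atlas(cfg.grid_dims, cfg.n_parcels, cfg.seed)
        plan = build_plan(atlas, cfg)
        x = simulate_timeseries(atlas, cfg, "elderly", np.random.default_rng(5), plan)
        caud = np.flatnonzero(plan.node_community == "caudate")[:10]
        dmn = np.flatnonzero(plan.node_community == "dmn")[:10]
        r = np.corrcoef(np.vstack([x[caud], x[dmn]]))[:10, 10:]
        target = cfg.seed_community_r["dmn"] + cfg.aging_edge_deltas["elderly"][("caudate", "dmn")]
        assert abs(r.mean() - target) < 0.06

    def test_unit_variance_and_zero_mean(self, long_run):
        _, _, x = long_run
        assert abs(x.mean()) < 0.02
        assert abs(x.std() - 1.0) < 0.02


class TestCohortGeneration:
    def test_determinism_and_subject_streams(self, small_config):
        c1 = generate_cohort(small_config)
        c2 = generate_cohort(small_config)
        np.testing.assert_array_equal(c1.subjects[3].timeseries, c2.subjects[3].timeseries)
        assert c1.thickness.values.equals(c2.thickness.values)
        assert c1.manifest == c2.manifest
        assert not np.array_equal(c1.subjects[0].timeseries, c1.subjects[1].timeseries)

    def test_records_demographics(self, small_config):
        c = generate_cohort(small_config, with_timeseries=False)
        recs = c.records()
        assert len(recs) == sum(small_config.n_per_group)
        assert len(c.records("young")) == small_config.n_per_group[0]
        for r in recs:
            assert r.age_years is not None

    def test_morphometry_shift_recovery(self):
        cfg = CohortConfig(n_per_group=(58, 0, 58), grid_dims=(8, 8, 8), n_parcels=10,
                           n_timepoints=60, seed=33)
        c = generate_cohort(cfg, with_timeseries=False)
        from sfc_aging.morphometry import normative_stats, standardize

        norms = normative_stats(c.thickness.subset("young"))
        z = standardize(c.thickness.subset("elderly"), norms)
        shifts = cfg.atrophy_spec["elderly"]
        mcr_z = z.group_mean("elderly")[c.planted_sets.mcr].mean()
        lcr_z = z.group_mean("elderly")[[r for r in c.planted_sets.lcr if r in z.regions]].mean()
        # SE of a 3-region set mean with region_effect_sd and subject noise
        se = 3 * np.sqrt((cfg.region_effect_sd**2 + 1.0 / 58) / 3)
        assert abs(mcr_z - shifts["MCR"]) < se + 0.1
        assert abs(lcr_z - shifts["LCR"]) < se + 0.1

    def test_bundle_round_trip(self, tmp_path, small_config):
        cfg = CohortConfig(n_per_group=(2, 1, 1), grid_dims=(8, 8, 8), n_parcels=10,
                           n_timepoints=40, seed=2)
        c = generate_cohort(cfg, out_dir=tmp_path / "bundle")
        atlas = read_volume(tmp_path / "bundle" / "atlas.nii.gz")
        np.testing.assert_array_equal(atlas.labels, c.atlas.labels)
        thick = read_regional_table(tmp_path / "bundle" / "thickness.tsv")
        np.testing.assert_allclose(thick.values.to_numpy(), c.thickness.values.to_numpy(), rtol=1e-8)
        manifest = json.loads((tmp_path / "bundle" / "manifest.json").read_text())
        assert manifest["config_hash"] == cfg.content_hash()
        ts = np.loadtxt(tmp_path / "bundle" / "timeseries" / "sub-0000.tsv")
        assert ts.shape == c.subjects[0].timeseries.shape
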