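import json

import numpy as np
import pandas as pd
import pytest

from fcgraph import clinical, synth
from fcgraph.synth import ConfigurationError, SimulationConfig


def tiny_config(**kw):
    base = dict(n_nodes=16, n_timepoints=40, n_motor=2, n_control=2,
                n_modules=4, seed=5)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_defaults_mirror_study_design(self):
        cfg = SimulationConfig()
        assert (cfg.n_nodes, cfg.n_timepoints) == (264, 180)
        assert (cfg.n_motor, cfg.n_control) == (6, 7)
        assert cfg.tr == 2.0

    @pytest.mark.parametrize("kw", [
        dict(n_nodes=2), dict(n_timepoints=5), dict(n_motor=0, n_control=1),
        dict(ar_coefficient=1.0), dict(ar_coefficient=-1.0),
        dict(effect_strength=-0.1), dict(behavior_coupling=1.5),
        dict(noise_sd=0.0), dict(uefm_baseline_range=(50, 70)),
        dict(lesion_side_mode="up"), dict(delta_assignment="sorted"),
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            tiny_config(**kw)

    def test_target_nodes_out_of_range(self):
        with pytest.raises(ConfigurationError, match="target_nodes"):
            tiny_config(target_nodes=(1, 99))

    def test_partition_length_checked(self):
        with pytest.raises(ConfigurationError, match="module_partition"):
            tiny_config(module_partition=np.zeros(5, dtype=int))


class TestToyGraphs:
    def test_complete_4(self):
        a = synth.make_toy_graph("complete", 4)
        assert a.sum() // 2 == 6
        assert np.all(a.sum(axis=1) == 3)

    def test_star_5(self):
        a = synth.make_toy_graph("star", 5)
        deg = a.sum(axis=1)
        assert deg[0] == 4 and np.all(deg[1:] == 1)

    def test_empty_3(self):
        assert synth.make_toy_graph("empty", 3).sum() == 0

    def test_path_and_ring(self):
        p = synth.make_toy_graph("path", 4)
        assert list(p.sum(axis=1)) == [1, 2, 2, 1]
        r = synth.make_toy_graph("ring", 4)
        assert np.all(r.sum(axis=1) == 2)

    def test_unknown_family(self):
        with pytest.raises(ValueError, match="family"):
            synth.make_toy_graph("torus", 4)

    def test_symmetry_zero_diag(self):
        for name in synth.TOY_FAMILIES:
            a = synth.make_toy_graph(name, 5)
            assert np.array_equal(a, a.T)
            assert np.all(np.diag(a) == 0)


class TestCohortStructure:
    def test_default_cohort_shape(self):
        cohort = synth.simulate_cohort(SimulationConfig(seed=3))
        assert len(cohort.subjects) == 13
        mats = [ts.data for s in cohort.subjects for ts in (s.ts1, s.ts2)]
        assert len(mats) == 26
        assert all(m.shape == (180, 264) for m in mats)

    def test_sessions_share_node_count(self, small_cohort):
        for s in small_cohort.subjects:
            assert s.ts1.n_nodes == s.ts2.n_nodes
            assert np.array_equal(s.ts1.node_ids, s.ts2.node_ids)

    def test_control_only_cohort(self):
        cohort = synth.simulate_cohort(tiny_config(n_motor=0, n_control=2))
        assert len(cohort.subjects) == 2
        assert cohort.clinical["uefm_t1"].isna().all()
        assert cohort.clinical["uefm_t2"].isna().all()

    def test_group_assignment_round_trip(self, small_cohort):
        groups = clinical.assign_groups(small_cohort.clinical)
        assert list(groups) == list(small_cohort.clinical["group"])

    def test_ground_truth_bounds(self, small_cohort):
        clin = small_cohort.clinical
        motor = clin[clin["group"] == "motor"]
        assert motor["uefm_t1"].between(0, 66).all()
        assert motor["uefm_t2"].between(0, 66).all()
        assert motor["lefm_t1"].between(0, 34).all()
        assert motor["barthel_t1"].lt(100).all()
        control = clin[clin["group"] == "control"]
        assert (control["barthel_t1"] == 100).all()
        assert control["rankin_t1"].isin([0, 1]).all()
        truth = small_cohort.truth
        dm = truth.loc[truth["group"] == "motor", "delta_uefm"]
        assert dm.abs().le(66).all()

    def test_stratified_doses_increase_with_rank(self):
        cfg = tiny_config(n_motor=4, effect_strength=0.5,
                          delta_assignment="stratified")
        cohort = synth.simulate_cohort(cfg)
        deltas = cohort.truth.loc[cohort.truth["group"] == "motor", "delta_s"]
        assert list(deltas) == sorted(deltas)
        spread = cfg.effect_spread
        lo = cfg.effect_strength * (1 - spread)
        hi = cfg.effect_strength * (1 + spread)
        assert deltas.between(lo, hi).all()

    def test_control_deltas_zero(self, small_cohort):
        truth = small_cohort.truth
        assert (truth.loc[truth["group"] == "control", "delta_s"] == 0).all()


class TestDeterminism:
    def test_same_seed_bit_identical(self, tmp_path):
        cfg = tiny_config()
        m1 = synth.write_cohort(synth.simulate_cohort(cfg), tmp_path / "a")
        m2 = synth.write_cohort(synth.simulate_cohort(cfg), tmp_path / "b")
        assert m1["files"] == m2["files"]  # sha256 per file

    def test_different_seeds_differ(self):
        c1 = synth.simulate_cohort(tiny_config(seed=1))
        c2 = synth.simulate_cohort(tiny_config(seed=2))
        assert not np.array_equal(c1.subjects[0].ts1.data,
                                  c2.subjects[0].ts1.data)

    def test_subject_seed_offsets_fixed(self):
        cfg = tiny_config(seed=100)
        seeds = synth.subject_seeds(cfg)
        assert len(set(seeds)) == len(seeds)
        assert seeds == [100 + synth._SEED_STRIDE * (i + 1)
                         for i in range(len(seeds))]


class TestEffectMechanics:
    def test_null_effect_sessions_exchangeable(self):
        """effect_strength=0: expected betweenness change at targets ~ 0."""
        from fcgraph import connectivity, metrics
        diffs = []
        for seed in range(12):
            cfg = SimulationConfig(n_nodes=48, n_timepoints=80, n_motor=1,
                                   n_control=1, effect_strength=0.0,
                                   lesion_side_mode="right", seed=seed)
            cohort = synth.simulate_cohort(cfg)
            sub = cohort.motor_subjects[0]
            tg = np.asarray(cohort.target_nodes) - 1
            bcs = []
            for ts in (sub.ts1, sub.ts2):
                adj = connectivity.proportional_threshold(
                    connectivity.pearson_matrix(ts))
                bcs.append(metrics.betweenness(
                    metrics.shortest_paths(adj.values)).values)
            diffs.append(np.mean(bcs[1][tg] - bcs[0][tg]))
        assert abs(np.mean(diffs)) < 0.02

    def test_zero_coupling_decorrelates_behavior(self):
        cfg = SimulationConfig(n_nodes=16, n_timepoints=40, n_modules=4,
                               n_motor=40, n_control=1, effect_strength=0.5,
                               behavior_coupling=0.0,
                               delta_assignment="random", seed=42)
        truth = synth.simulate_cohort(cfg).truth
        motor = truth[truth["group"] == "motor"]
        r = np.corrcoef(motor["delta_s"], motor["delta_uefm"])[0, 1]
        assert abs(r) < 0.35

    def test_coupling_monotone_in_strength(self):
        """Truth-level recovery: correlation rises toward 1 with coupling."""
        rs = []
        for coupling in (0.2, 0.6, 1.0):
            vals = []
            for seed in (1, 2, 3):
                cfg = SimulationConfig(
                    n_nodes=16, n_timepoints=40, n_modules=4, n_motor=30,
                    n_control=1, effect_strength=0.5,
                    behavior_coupling=coupling, recovery_noise_sd=2.0,
                    uefm_baseline_range=(40, 50),
                    delta_assignment="random", seed=seed)
                truth = synth.simulate_cohort(cfg).truth
                motor = truth[truth["group"] == "motor"]
                vals.append(np.corrcoef(motor["delta_s"],
                                        motor["delta_uefm"])[0, 1])
            rs.append(np.mean(vals))
        assert rs[0] < rs[1] < rs[2]
        assert rs[2] > 0.9


class TestNodeGeometry:
    def test_node_table_sizes(self):
        for n in (8, 64, 264, 300):
            df = synth.make_node_table(n)
            assert len(df) == n
            assert df["node_id"].is_unique

    def test_lattice_fill_symmetric(self):
        df = synth.make_node_table(300)
        lattice = df[df["abbreviation"] == ""]
        xs = lattice["x"].to_numpy()
        assert len(xs) > 0
        # filler nodes come in +/-x pairs (up to one odd leftover)
        pos = np.sort(xs[xs > 0])
        neg = np.sort(-xs[xs < 0])
        m = min(len(pos), len(neg))
        assert abs(len(pos) - len(neg)) <= 1
        assert np.array_equal(pos[:m], neg[:m])

    def test_default_targets_are_left_sensorimotor(self):
        df = synth.make_node_table(64)
        targets = synth.default_target_nodes(df)
        sel = df[df["node_id"].isin(targets)]
        assert set(sel["abbreviation"]) <= {"PrCG", "PoCG"}
        assert set(sel["side"]) == {"Left"}
        assert len(targets) == 6

    def test_targets_require_provenance(self):
        bare = pd.DataFrame({"node_id": [1, 2], "x": [0.0, 1.0],
                             "y": [0.0, 1.0], "z": [0.0, 1.0]})
        with pytest.raises(ConfigurationError, match="provenance"):
            synth.default_target_nodes(bare)


class TestSerialization:
    def test_write_and_load_round_trip(self, tmp_path, small_cohort):
        outdir = tmp_path / "cohort"
        manifest = synth.write_cohort(small_cohort, outdir)
        assert (outdir / "manifest.json").exists()
        with open(outdir / "manifest.json") as fh:
            on_disk = json.load(fh)
        assert on_disk["files"] == manifest["files"]
        back = synth.load_cohort(outdir)
        assert len(back.subjects) == len(small_cohort.subjects)
        for a, b in zip(back.subjects, small_cohort.subjects):
            assert a.subject_id == b.subject_id
            assert a.group == b.group
            assert a.scrub == b.scrub
            assert np.allclose(a.ts1.data, b.ts1.data, atol=1e-6)
        pd.testing.assert_series_equal(back.clinical["group"],
                                       small_cohort.clinical["group"])

    def test_expected_file_inventory(self, tmp_path, small_cohort):
        outdir = tmp_path / "cohort"
        synth.write_cohort(small_cohort, outdir)
        names = {p.name for p in outdir.iterdir()}
        n_sub = len(small_cohort.subjects)
        assert {"nodes.csv", "clinical.csv", "scrub.csv", "ground_truth.csv",
                "manifest.json"} <= names
        assert sum(1 for n in names if n.endswith(".tsv")) == 2 * n_sub

    def test_load_missing_clinical_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="clinical"):
            synth.load_cohort(tmp_path)
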