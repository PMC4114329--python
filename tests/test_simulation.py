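"""Sample-size planning, balanced sampling, replicates and aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rehosim as rs
from rehosim.masking import group_mask
from rehosim.simulation import draw_balanced_sample, run_replicate, summary_matrix


class TestPlanner:
    def test_beijing_within_study_grid(self, table1):
        sizes, test_size = rs.plan_sample_sizes(table1, "within_study", "Beijing")
        assert sizes == [20, 30, 40, 50, 60, 70]
        assert test_size == "equal_to_train"

    def test_beijing_cross_study_max_is_140(self, table1):
        sizes, test_size = rs.plan_sample_sizes(table1, "study_to_pooled", "Beijing")
        assert max(sizes) == 140
        assert sizes == list(range(20, 141, 10))
        assert test_size == 200

    def test_icbm_as_test_study_gets_80(self, table1):
        _, test_size = rs.plan_sample_sizes(table1, "study_pair", "Beijing", "ICBM")
        assert test_size == 80

    def test_oulu_within_study_tops_at_30(self, table1):
        sizes, _ = rs.plan_sample_sizes(table1, "within_study", "Oulu")
        assert sizes == [20, 30]

    def test_cambridge_uses_published_override(self, table1):
        # the 2*min(F,M) rule would give 150; the published value is 140
        assert rs.max_balanced_size(table1, "Cambridge") == 140
        assert rs.max_balanced_size(table1, "Cambridge", overrides={}) == 150

    def test_pooled_grids_run_20_to_200(self, table1):
        sizes, test_size = rs.plan_sample_sizes(table1, "pooled_to_pooled")
        assert sizes == list(range(20, 201, 10))
        assert test_size == 200

    def test_study_too_small_is_rejected(self, table1):
        with pytest.raises(ValueError, match="PaloAlto"):
            rs.plan_sample_sizes(table1, "within_study", "PaloAlto")

    def test_works_on_subject_level_demographics(self, fast_store):
        sizes, test_size = rs.plan_sample_sizes(
            fast_store.demographics, "within_study", "Demo"
        )
        assert sizes == [20, 30, 40, 50]  # 50 F + 50 M -> max 100, half = 50
        assert test_size == "equal_to_train"


class TestBalancedSampling:
    @staticmethod
    def _pool(n_f, n_m):
        return pd.DataFrame(
            {
                "subject_id": [f"f{i}" for i in range(n_f)] + [f"m{i}" for i in range(n_m)],
                "sex": ["female"] * n_f + ["male"] * n_m,
            }
        )

    def test_forced_draw_returns_whole_pool(self, rng):
        ids = draw_balanced_sample(self._pool(10, 10), 20, rng=rng)
        assert sorted(ids) == sorted(self._pool(10, 10)["subject_id"])

    def test_excluding_whole_pool_errors(self, rng):
        pool = self._pool(10, 10)
        with pytest.raises(ValueError, match="available"):
            draw_balanced_sample(pool, 4, exclude_ids=set(pool["subject_id"]), rng=rng)

    def test_odd_size_rejected(self, rng):
        with pytest.raises(ValueError, match="even"):
            draw_balanced_sample(self._pool(5, 5), 5, rng=rng)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_every_draw_is_balanced(self, seed):
        pool = self._pool(15, 12)
        ids = draw_balanced_sample(pool, 16, rng=np.random.default_rng(seed))
        sexes = pool.set_index("subject_id").loc[ids, "sex"]
        assert (sexes == "female").sum() == 8 and (sexes == "male").sum() == 8

    def test_inclusion_frequency_matches_hypergeometric(self):
        # each of 100 subjects should appear with frequency ~ 20/100
        pool = self._pool(50, 50)
        rng = np.random.default_rng(4)
        counts = pd.Series(0, index=pool["subject_id"])
        n_draws = 10_000
        for _ in range(n_draws):
            for sid in draw_balanced_sample(pool, 20, rng=rng):
                counts[sid] += 1
        freq = counts / n_draws
        se = np.sqrt(0.2 * 0.8 / n_draws)
        assert np.all(np.abs(freq - 0.2) < 5 * se)


class TestReplicates:
    def test_no_overlap_and_balance(self, fast_store):
        cfg = rs.SimulationConfig(
            family="within_study", train_source="Demo",
            train_sizes=[20], n_replicates=1, seed=5,
        )
        res = run_replicate(cfg, 20, 0, fast_store)
        assert not set(res.train_subject_ids) & set(res.test_subject_ids)
        sex = dict(zip(fast_store.demographics["subject_id"], fast_store.demographics["sex"]))
        for ids in (res.train_subject_ids, res.test_subject_ids):
            assert sum(sex[i] == "female" for i in ids) == len(ids) // 2

    def test_group_mask_depends_only_on_training_masks(self, fast_store):
        cfg = rs.SimulationConfig(
            family="within_study", train_source="Demo", train_sizes=[20], seed=5
        )
        res = run_replicate(cfg, 20, 3, fast_store)
        recomputed = group_mask(
            [fast_store.masks[i] for i in res.train_subject_ids], cfg.mask_threshold
        )
        assert res.p_dim == recomputed.n_voxels

    def test_reproducible_given_config_seed(self, fast_store):
        cfg = dict(family="within_study", train_source="Demo",
                   train_sizes=[20], n_replicates=5, seed=17)
        a = rs.run_configuration(rs.SimulationConfig(**cfg), fast_store, keep_replicates=True)
        b = rs.run_configuration(rs.SimulationConfig(**cfg), fast_store, keep_replicates=True)
        assert a.mean_accuracy == b.mean_accuracy
        assert np.array_equal(a.replicates[20], b.replicates[20])

    def test_single_replicate_sd_zero_and_flagged(self, fast_store):
        cfg = rs.SimulationConfig(family="within_study", train_source="Demo",
                                  train_sizes=[20], n_replicates=1, seed=2)
        res = rs.run_configuration(cfg, fast_store)
        assert res.sd_accuracy[20] == 0.0
        assert res.metadata["single_replicate"] is True

    def test_oversized_test_request_aborts_with_context(self, fast_store):
        cfg = rs.SimulationConfig(family="within_study", train_source="Demo",
                                  train_sizes=[100], n_replicates=1, seed=2)
        with pytest.raises(RuntimeError, match="replicate 0"):
            run_replicate(cfg, 100, 0, fast_store)

    def test_learning_curve_mean_accuracy_grows_with_train_size(self):
        # a weak-effect site so accuracy is far from ceiling at small n
        spec = rs.CohortSpec(
            studies=[rs.StudySpec("Weak", 50, 50, effect_strength=0.02)],
            grid_shape=(12, 12, 12), seed=101,
        )
        store = rs.DataStore.from_subject_maps(rs.make_reho_maps(spec))
        accs = {}
        for size in (10, 40):
            cfg = rs.SimulationConfig(family="within_study", train_source="Weak",
                                      train_sizes=[size], n_replicates=60, seed=9)
            res = rs.run_configuration(cfg, store, keep_replicates=True)
            accs[size] = res.replicates[size]
        lo, hi = accs[10], accs[40]
        se = np.hypot(lo.std() / np.sqrt(lo.size), hi.std() / np.sqrt(hi.size))
        assert hi.mean() - lo.mean() > 3 * se


class TestSummaryMatrix:
    @staticmethod
    def _summary(family, train, test, acc):
        cfg = rs.SimulationConfig(family=family, train_source=train, test_source=test,
                                  train_sizes=[20], n_replicates=2, seed=0)
        return rs.SummaryResult(config=cfg, sizes=[20], mean_accuracy={20: acc},
                                sd_accuracy={20: 0.0}, mean_p_dim={20: 10.0}, n_replicates=2)

    def test_four_studies_give_twelve_ordered_pairs_and_5x5_table(self):
        studies = ["A", "B", "C", "D"]
        results = []
        pairs = [(a, b) for a in studies for b in studies if a != b]
        assert len(pairs) == 12
        for a, b in pairs:
            results.append(self._summary("study_pair", a, b, 0.6))
        for s in studies:
            results.append(self._summary("within_study", s, s, 0.7))
            results.append(self._summary("study_to_pooled", s, "pooled", 0.55))
            results.append(self._summary("pooled_to_study", "pooled", s, 0.62))
        results.append(self._summary("pooled_to_pooled", "pooled", "pooled", 0.65))
        mat = summary_matrix(results)
        assert mat.shape == (5, 5)
        assert mat.loc["A", "A"] == 0.7
        assert mat.loc["All/Others", "All/Others"] == 0.65
        assert mat.notna().all().all()

    def test_duplicate_pair_rejected(self):
        results = [self._summary("study_pair", "A", "B", 0.6)] * 2
        with pytest.raises(ValueError, match="duplicate"):
            summary_matrix(results)

    def test_holding_out_one_of_27_studies_leaves_26(self, table1):
        remaining = table1[table1["study"] != "Beijing_Zang"]
        assert len(remaining) == 26
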