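import numpy as np
import pytest

from rbfrce import ClusteringConfig, EnsembleConfig, RCEConfig, run_rbf_rce, score_cluster
from rbfrce.feature_clustering import FeatureCluster
from rbfrce.rce_selector import SelectionState, eliminate_round, initial_state
from rbfrce.synthetic_data import SyntheticSpec, make_dataset


def _fast_config(**kwargs):
    defaults = dict(
        target_features=20,
        clustering=ClusteringConfig(seed=0),
        ensemble=EnsembleConfig(n_trees=60, n_candidate_bits=256,
                                n_selected_bits=64, seed=0),
        seed=0,
    )
    defaults.update(kwargs)
    return RCEConfig(**defaults)


class TestScoreCluster:
    def test_max_member_fip(self):
        cl = FeatureCluster(0, frozenset({"a", "b", "c"}))
        assert score_cluster(cl, {"a": 0.5, "b": 1.2, "c": 0.3}) == 1.2

    def test_singleton_negative(self):
        cl = FeatureCluster(0, frozenset({"x"}))
        assert score_cluster(cl, {"x": -0.2}) == -0.2

    def test_all_zero(self):
        cl = FeatureCluster(0, frozenset({"a", "b"}))
        assert score_cluster(cl, {"a": 0.0, "b": 0.0}) == 0.0

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            score_cluster(FeatureCluster(0, frozenset()), {})

    def test_missing_importance_rejected(self):
        with pytest.raises(ValueError, match="without importance"):
            score_cluster(FeatureCluster(0, frozenset({"a", "b"})), {"a": 1.0})


class TestEliminateRound:
    """Deletion arithmetic, tie-breaks and the phase switch, with importances
    stubbed so cluster scores are fully controlled."""

    @staticmethod
    def _stub_state(n_clusters, members_per_cluster=2):
        feats = [
            f"f{c:02d}_{j}" for c in range(n_clusters) for j in range(members_per_cluster)
        ]
        clusters = [
            FeatureCluster(
                c,
                frozenset(
                    f"f{c:02d}_{j}" for j in range(members_per_cluster)
                ),
            )
            for c in range(n_clusters)
        ]
        return SelectionState(0, feats, clusters, "cluster_elimination", [])

    @pytest.fixture()
    def stubbed_fips(self, monkeypatch):
        holder = {}

        def fake(_data, active, _config, _seed):
            return {f: holder["fips"][f] for f in active}

        monkeypatch.setattr("rbfrce.rce_selector._fit_and_score", fake)
        return holder

    def test_ten_clusters_drop_fraction_deletes_exactly_one(self, stubbed_fips, small_planted):
        data, _ = small_planted
        state = self._stub_state(10)
        # cluster c gets score ~c; cluster 0 is the minimum
        stubbed_fips["fips"] = {
            f: int(f[1:3]) + 0.1 * int(f[-1]) for f in state.active_features
        }
        new = eliminate_round(state, data, _fast_config(target_features=5, drop_fraction=0.1))
        assert len(new.elimination_log) == 1
        assert new.elimination_log[0].deleted_ids == ["f00_0", "f00_1"]
        assert new.iteration == 1

    def test_score_tie_deletes_lexicographically_smallest(self, stubbed_fips, small_planted):
        data, _ = small_planted
        state = self._stub_state(10)
        stubbed_fips["fips"] = {f: 1.0 for f in state.active_features}  # all tied
        new = eliminate_round(state, data, _fast_config(target_features=5, drop_fraction=0.1))
        assert set(new.elimination_log[0].deleted_ids) == {"f00_0", "f00_1"}

    def test_phase_switches_below_threshold(self, stubbed_fips, small_planted):
        data, _ = small_planted
        state = self._stub_state(30)
        stubbed_fips["fips"] = {
            f: int(f[1:3]) + 0.1 * int(f[-1]) for f in state.active_features
        }
        cfg = _fast_config(target_features=5, drop_fraction=0.1, switch_threshold=30)
        new = eliminate_round(state, data, cfg)
        assert len(new.clusters) == 27  # ceil(0.1*30)=3 clusters deleted
        assert new.phase == "feature_elimination"

    def test_never_deletes_below_target(self, stubbed_fips, small_planted):
        data, _ = small_planted
        state = self._stub_state(10)  # 20 features
        stubbed_fips["fips"] = {
            f: int(f[1:3]) + 0.1 * int(f[-1]) for f in state.active_features
        }
        # huge drop fraction would delete 18 features; target allows only 2
        cfg = _fast_config(target_features=18, drop_fraction=0.9)
        new = eliminate_round(state, data, cfg)
        assert len(new.active_features) == 18
        # partial batch keeps the better-scoring members
        assert new.elimination_log[0].deleted_ids == ["f00_0", "f00_1"]

    def test_feature_phase_deletes_lowest_fips(self, stubbed_fips, small_planted):
        data, _ = small_planted
        state = self._stub_state(5)
        state.phase = "feature_elimination"
        fips = {f: float(i) for i, f in enumerate(state.active_features)}
        stubbed_fips["fips"] = fips
        new = eliminate_round(state, data, _fast_config(target_features=2,
                                                        feature_drop_fraction=0.3))
        assert new.elimination_log[0].deleted_ids == state.active_features[:3]

    def test_noop_at_target_warns(self, stubbed_fips, small_planted):
        data, _ = small_planted
        state = self._stub_state(3)
        with pytest.warns(UserWarning, match="no-op"):
            out = eliminate_round(state, data, _fast_config(target_features=6))
        assert out is state


class TestRunRbfRce:
    def test_end_to_end_recovery_and_contracts(self):
        data, truth = make_dataset(
            SyntheticSpec(n_samples=60, n_features=200, n_informative=10,
                          n_blocks=20, effect_size=2.0, seed=21)
        )
        records, state = run_rbf_rce(data, _fast_config(target_features=30, seed=21))
        # full ranking is a permutation of all features
        assert sorted(r.feature_id for r in records) == sorted(data.feature_ids)
        assert [r.rank for r in records] == list(range(1, 201))
        # counts strictly decrease to <= target
        counts = [200]
        for e in state.elimination_log:
            counts.append(counts[-1] - len(e.deleted_ids))
        assert all(a > b for a, b in zip(counts, counts[1:]))
        assert counts[-1] <= 30
        top = {r.feature_id for r in records[:30]}
        assert len(top & truth.informative_ids) >= 6

    def test_deterministic_end_to_end(self, small_planted):
        data, _ = small_planted
        cfg = _fast_config(target_features=50)
        r1, _ = run_rbf_rce(data, cfg)
        r2, _ = run_rbf_rce(data, cfg)
        assert r1 == r2

    def test_target_at_p_is_single_fit_importance_order(self, small_planted):
        data, _ = small_planted
        cfg = _fast_config(target_features=data.n_features)
        records, state = run_rbf_rce(data, cfg)
        assert state.elimination_log == []
        fips = state.final_fips
        expected = sorted(data.feature_ids, key=lambda f: (-fips[f], f))
        assert [r.feature_id for r in records] == list(expected)

    def test_carried_partition_respects_initial_clusters(self, small_planted):
        data, _ = small_planted
        cfg = _fast_config(target_features=120, recluster_each_round=False)
        st0 = initial_state(data, cfg)
        membership = {
            f: c.cluster_index for c in st0.clusters for f in c.member_ids
        }
        state = st0
        while len(state.active_features) > cfg.target_features:
            state = eliminate_round(state, data, cfg)
        for c in state.clusters:
            owners = {membership[f] for f in c.member_ids}
            assert owners == {c.cluster_index}

    def test_initial_phase_honors_switch_threshold(self, small_planted):
        data, _ = small_planted
        st_feat = initial_state(data, _fast_config(switch_threshold=1000))
        assert st_feat.phase == "feature_elimination"
        st_clus = initial_state(data, _fast_config(switch_threshold=2))
        assert st_clus.phase == "cluster_elimination"

    @pytest.mark.parametrize(
        "kwargs", [dict(target_features=0), dict(drop_fraction=0.0),
                   dict(feature_drop_fraction=1.0)]
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            _fast_config(**kwargs)
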