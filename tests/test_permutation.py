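import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from srnanet.network import Network
from srnanet.permutation import (
    NullSpec,
    evaluate,
    null_distribution,
    run_significance_suite,
    sample_null,
)
from srnanet.targets import TargetMap

from conftest import random_network


def _kn(n):
    g = nx.relabel_nodes(nx.complete_graph(n), {i: f"k{i}" for i in range(n)})
    return Network(g)


class TestSampling:
    def test_reproducible_from_seed(self):
        spec = NullSpec(universe=tuple(f"g{i}" for i in range(10)),
                        size_profile=3, n_sims=1, seed=42)
        assert sample_null(spec) == sample_null(spec)

    def test_size_profile_respected(self):
        spec = NullSpec(universe=tuple(f"g{i}" for i in range(12)),
                        size_profile=(2, 2, 5), n_sims=1, seed=0)
        sets = sample_null(spec)
        assert [len(s) for s in sets] == [2, 2, 5]
        for s in sets:
            assert len(set(s)) == len(s)  # without replacement

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError):
            NullSpec(universe=("a", "b"), size_profile=(3,), n_sims=1, seed=0)

    def test_uniformity_chi_square(self):
        universe = tuple(f"g{i}" for i in range(5))
        spec = NullSpec(universe=universe, size_profile=1, n_sims=1, seed=7)
        rng = np.random.default_rng(7)
        counts = {g: 0 for g in universe}
        for _ in range(10_000):
            (draw,) = sample_null(spec, rng)
            counts[draw[0]] += 1
        chi2 = stats.chisquare(list(counts.values()))
        assert chi2.pvalue > 1e-3


class TestNullDistribution:
    def test_complete_graph_density_degenerate(self):
        spec = NullSpec(universe=tuple(f"k{i}" for i in range(8)),
                        size_profile=(3, 4), n_sims=20, seed=1)
        null = null_distribution(_kn(8), "density", spec)
        assert np.allclose(null, 1.0)

    def test_cycle_degree_degenerate(self):
        g = nx.relabel_nodes(nx.cycle_graph(10), {i: f"c{i}" for i in range(10)})
        net = Network(g)
        spec = NullSpec(universe=tuple(net.node_order()), size_profile=4,
                        n_sims=20, seed=2)
        null = null_distribution(net, "degree", spec)
        assert np.allclose(null, 2.0)

    def test_er_density_null_mean_near_p(self):
        net = random_network(200, 0.05, seed=3)
        spec = NullSpec(universe=tuple(net.node_order()),
                        size_profile=tuple([5] * 10), n_sims=400, seed=3)
        null = null_distribution(net, "density", spec)
        assert np.nanmean(null) == pytest.approx(0.05, abs=0.01)

    def test_deterministic_given_seed(self):
        net = random_network(50, 0.1, seed=4)
        spec = NullSpec(universe=tuple(net.node_order()),
                        size_profile=(3, 3), n_sims=50, seed=9)
        a = null_distribution(net, "density", spec)
        b = null_distribution(net, "density", spec)
        assert np.array_equal(a, b)


class TestEvaluate:
    def test_extreme_observation_add_one_rule(self):
        null = np.arange(1000, dtype=float)
        res = evaluate(2000.0, null, tail="greater")
        assert res.p == pytest.approx(1 / 1001)

    def test_all_ties_give_p_one(self):
        res = evaluate(5.0, [5.0] * 100, tail="greater")
        assert res.p == 1.0
        assert math.isnan(res.z)  # degenerate null

    def test_95th_percentile_near_005(self):
        rng = np.random.default_rng(5)
        null = rng.normal(size=2000)
        obs = float(np.quantile(null, 0.95))
        res = evaluate(obs, null, tail="greater")
        assert res.p == pytest.approx(0.05, abs=0.01)

    def test_less_tail(self):
        res = evaluate(0.0, [1.0, 2.0, 3.0], tail="less")
        assert res.p == pytest.approx(1 / 4)

    def test_single_sim_p_bounds(self):
        assert evaluate(10.0, [1.0], tail="greater").p == 0.5
        assert evaluate(0.0, [1.0], tail="greater").p == 1.0

    def test_all_undefined_rejected(self):
        with pytest.raises(ValueError):
            evaluate(1.0, [float("nan")] * 5)

    def test_undefined_replicates_excluded(self):
        null = [1.0, 2.0, float("nan"), 3.0]
        res = evaluate(4.0, null, tail="greater")
        assert res.n_sims == 3
        assert res.n_undefined == 1
        assert res.p == pytest.approx(1 / 4)


class TestSuite:
    def _bundle(self):
        net = random_network(60, 0.08, seed=6)
        order = net.node_order()
        tmap = TargetMap({
            "s1": {g: "experimental" for g in order[:4]},
            "s2": {g: "experimental" for g in order[10:13]},
            "s3": {order[20]: "predicted"},  # ineligible for subnet stats
        })
        return net, tmap

    def test_bit_identical_given_seed(self):
        net, tmap = self._bundle()
        a = run_significance_suite(net, tmap, n_sims=50, seed=11)
        b = run_significance_suite(net, tmap, n_sims=50, seed=11)
        assert a == b

    def test_single_sim_p_values(self):
        net, tmap = self._bundle()
        res = run_significance_suite(net, tmap, n_sims=1, seed=12)
        for r in res:
            if math.isfinite(r.p):
                assert r.p in (0.5, 1.0)

    def test_tails_follow_defaults(self):
        net, tmap = self._bundle()
        res = {r.statistic: r for r in
               run_significance_suite(net, tmap, n_sims=20, seed=13)}
        assert res["cpl"].tail == "less"
        assert res["density"].tail == "greater"

    def test_directed_metric_set(self):
        net = random_network(60, 0.05, seed=7, directed=True)
        order = net.node_order()
        tmap = TargetMap({"s1": {g: "experimental" for g in order[:4]}})
        res = run_significance_suite(net, tmap, n_sims=20, seed=14)
        names = {r.statistic for r in res}
        assert names == {"in_degree", "out_degree", "closeness",
                         "betweenness", "density", "in_degree_ratio"}

    def test_supplied_gene_list_universe(self):
        net, tmap = self._bundle()
        universe = net.node_order() + [f"off{i}" for i in range(20)]
        res = run_significance_suite(net, tmap, n_sims=30, seed=15,
                                     universe_mode="supplied-gene-list",
                                     universe=universe,
                                     metrics=["degree", "density"])
        for r in res:
            assert math.isfinite(r.p)

    def test_calibration_on_null_targets(self):
        """Targets drawn from the null give roughly uniform p-values."""
        net = random_network(120, 0.05, seed=8)
        order = net.node_order()
        rng = np.random.default_rng(99)
        ps = []
        for rep in range(60):
            sets = {f"s{j}": {order[i]: "experimental"
                              for i in rng.choice(120, 4, replace=False)}
                    for j in range(5)}
            res = run_significance_suite(net, TargetMap(sets), n_sims=99,
                                         seed=int(rng.integers(2**31)),
                                         metrics=["cpl"])
            ps.append(res[0].p)
        frac = np.mean([p <= 0.2 for p in ps])
        assert 0.05 <= frac <= 0.4  # coarse binomial band around 0.2
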