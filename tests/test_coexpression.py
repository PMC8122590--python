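"""Network construction and module detection: closed forms, independent
brute-force oracles, and planted-structure recovery."""

import numpy as np
import pandas as pd
import pytest

from tfcensus import coexpression as cx
from tfcensus import synthetic
from tfcensus.io_formats import STAGES


def collapse(sim):
    return cx.collapse_replicates(sim.matrix, STAGES)


def planted(sim, genes):
    return [sim.truth.planted_module_per_gene[g] for g in genes]


def adjusted_rand(labels_a, labels_b):
    from sklearn.metrics import adjusted_rand_score

    return adjusted_rand_score(labels_a, labels_b)


class TestNormalize:
    def test_closed_forms(self):
        m = pd.DataFrame([[0.0, 9.0, 99.0]], index=["g"], columns=["a", "b", "c"])
        out = cx.normalize_log10(m)
        assert out.values.tolist() == [[0.0, 1.0, 2.0]]

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.uniform(0, 500, size=(20, 7)))
        back = 10.0 ** cx.normalize_log10(m) - 1.0
        assert np.allclose(back.values, m.values, atol=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cx.normalize_log10(pd.DataFrame([[-1.0]]))


class TestExpressedCalls:
    def test_strict_threshold_and_proportion(self):
        m = pd.DataFrame(
            {"gast": [10.0, 10.1, 50.0]}, index=["g1", "g2", "g3"]
        )
        assert cx.call_expressed(m, 10.0, "gast") == {"g2", "g3"}
        assert cx.percentage(290, 553) == 52.44

    def test_infinite_threshold_empty(self):
        m = pd.DataFrame({"gast": [1e12]}, index=["g"])
        assert cx.call_expressed(m, np.inf, "gast") == set()
        assert cx.expressed_proportion(m, 10, np.inf, "gast") == 0.0

    def test_unknown_stage(self):
        with pytest.raises(KeyError):
            cx.call_expressed(pd.DataFrame({"gast": [1.0]}), 10, "nope")

    def test_planted_fraction_recovered(self):
        sim = synthetic.simulate_expression(
            200, [(80, "2-8cells", 0.95)], seed=3
        )
        m = collapse(sim)
        expressed = cx.call_expressed(m, 10.0, "2-8cells")
        planted_set = {
            g for g, mod in sim.truth.planted_module_per_gene.items() if mod == "M1"
        }
        # module genes peak near FPKM 100 at their peak stage; background stays low
        assert len(expressed & planted_set) >= 0.9 * len(planted_set)


class TestCorrelation:
    def test_closed_forms(self):
        m = pd.DataFrame(
            [[1, 2, 3, 4, 5, 6, 7],
             [2, 4, 6, 8, 10, 12, 14],
             [7, 6, 5, 4, 3, 2, 1]],
            index=["g1", "g2", "g3"], columns=list(STAGES), dtype=float,
        )
        net = cx.correlation_matrix(m, normalized=True)
        assert net.correlation[0, 0] == 1.0
        assert net.correlation[0, 1] == pytest.approx(1.0)
        assert net.correlation[0, 2] == pytest.approx(-1.0)

    def test_matches_bruteforce_covariance(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.uniform(0, 100, size=(20, 7)), columns=list(STAGES))
        net = cx.correlation_matrix(m)
        log = np.log10(m.values + 1)
        for i in range(20):  # double-loop covariance/sigma oracle
            for j in range(20):
                xi, xj = log[i] - log[i].mean(), log[j] - log[j].mean()
                expected = (xi * xj).sum() / np.sqrt((xi**2).sum() * (xj**2).sum())
                assert net.correlation[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_flagged(self):
        m = pd.DataFrame(
            [[5.0] * 7, list(range(7))], index=["flat", "g"], columns=list(STAGES)
        )
        net = cx.correlation_matrix(m)
        assert net.zero_variance_genes == {"flat"}
        assert net.correlation[0, 1] == 0.0
        assert net.correlation[0, 0] == 1.0

    def test_too_few_columns(self):
        with pytest.raises(ValueError):
            cx.correlation_matrix(pd.DataFrame(np.ones((3, 2))))

    def test_affine_invariance_of_log_profile(self):
        """Correlation is exactly invariant to affine rescaling of a gene's
        log-normalized profile."""
        rng = np.random.default_rng(12)
        log = pd.DataFrame(rng.uniform(0, 3, size=(5, 7)), columns=list(STAGES))
        net = cx.correlation_matrix(log, normalized=True)
        scaled = log.copy()
        scaled.iloc[0] = 3.7 * scaled.iloc[0] + 1.2
        net2 = cx.correlation_matrix(scaled, normalized=True)
        assert np.allclose(net.correlation, net2.correlation, atol=1e-12)


class TestAdjacencyAndTom:
    def params(self, **kw):
        kw.setdefault("min_module_size", 5)
        return cx.ModuleDetectionParams(**kw)

    def test_soft_adjacency_closed_forms(self):
        c = np.array([[1.0, 0.5], [0.5, 1.0]])
        net = cx.CoexpressionNetwork(["a", "b"], c)
        cx.soft_adjacency(net, self.params(soft_power=12))
        assert net.adjacency[0, 1] == pytest.approx(0.5**12)
        assert net.adjacency[0, 0] == 1.0
        cx.soft_adjacency(net, self.params(soft_power=12, network_sign="signed"))
        assert net.adjacency[0, 1] == pytest.approx(0.75**12)

    def test_adjacency_monotone_in_abs_correlation(self):
        grid = np.linspace(-1, 1, 41)
        for beta in (1, 6, 12):
            a = np.abs(grid) ** beta
            order = np.argsort(np.abs(grid), kind="stable")
            assert (np.diff(a[order]) >= -1e-15).all()

    def test_tom_two_gene_hand_case(self):
        # no shared neighbors: TOM_12 = a / (a + 1 - a) = a
        c = np.array([[1.0, 0.5], [0.5, 1.0]])
        net = cx.CoexpressionNetwork(["a", "b"], c)
        cx.soft_adjacency(net, self.params(soft_power=1))
        cx.compute_tom(net)
        assert net.tom[0, 1] == pytest.approx(0.5)

    @pytest.mark.parametrize("value,expected", [(1.0, 1.0), (0.0, 0.0)])
    def test_tom_extremes(self, value, expected):
        n = 5
        a = np.full((n, n), value)
        np.fill_diagonal(a, 1.0)
        net = cx.CoexpressionNetwork([str(i) for i in range(n)], a, adjacency=a)
        cx.compute_tom(net)
        off = ~np.eye(n, dtype=bool)
        assert np.allclose(net.tom[off], expected)
        assert np.allclose(np.diag(net.tom), 1.0)

    def test_tom_matches_double_loop_oracle(self):
        """Vectorized TOM equals the textbook double-loop evaluation to 1e-10
        on random 30-gene networks, and stays within [0, 1]."""
        rng = np.random.default_rng(21)
        for _ in range(3):
            c = rng.uniform(-1, 1, size=(30, 30))
            c = (c + c.T) / 2
            np.fill_diagonal(c, 1.0)
            net = cx.CoexpressionNetwork([str(i) for i in range(30)], c)
            cx.soft_adjacency(net, self.params(soft_power=6))
            cx.compute_tom(net)
            a = net.adjacency
            for i in range(30):
                for j in range(30):
                    if i == j:
                        continue
                    l_ij = sum(
                        a[i, u] * a[u, j] for u in range(30) if u not in (i, j)
                    )
                    k_i = sum(a[i, u] for u in range(30) if u != i)
                    k_j = sum(a[j, u] for u in range(30) if u != j)
                    expected = (l_ij + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
                    assert abs(net.tom[i, j] - expected) < 1e-10
            off = ~np.eye(30, dtype=bool)
            assert ((net.tom[off] >= 0) & (net.tom[off] <= 1)).all()
            assert np.allclose(net.tom, net.tom.T)


class TestModuleDetection:
    def test_noiseless_planted_modules_recovered_exactly(self):
        sim = synthetic.simulate_expression(
            150,
            [(50, "2-8cells", 1.0), (50, "tb", 1.0), (50, "mj", 1.0)],
            noise_sd=0.0, seed=1,
        )
        m = collapse(sim)
        params = cx.ModuleDetectionParams(min_module_size=20)
        part = cx.detect_modules(cx.build_network(m, params), params)
        assert part.labels.nunique() == 3
        assert adjusted_rand(planted(sim, part.labels.index), part.labels.values) == 1.0

    def test_identical_profiles_single_module(self):
        m = pd.DataFrame(
            np.tile(np.array([1.0, 5, 20, 80, 20, 5, 1]), (10, 1)),
            index=[f"g{i}" for i in range(10)], columns=list(STAGES),
        )
        params = cx.ModuleDetectionParams(min_module_size=2)
        part = cx.detect_modules(cx.build_network(m, params), params)
        assert part.labels.nunique() == 1
        assert set(part.labels) == {"turquoise"}

    def test_background_only_goes_grey(self):
        sim = synthetic.simulate_expression(80, [], seed=6)
        m = collapse(sim)
        params = cx.ModuleDetectionParams(min_module_size=30, cut_height=0.9)
        part = cx.detect_modules(cx.build_network(m, params), params)
        assert (part.labels == cx.GREY).all()

    def test_noisy_modules_recovered(self):
        """Median adjusted Rand over 20 seeded runs at within-module r = 0.8,
        n = 300, four stage-peaked modules."""
        aris = []
        for seed in range(20):
            sim = synthetic.simulate_expression(
                300,
                [(70, "2-8cells", 0.8), (70, "neu", 0.8), (70, "tb", 0.8),
                 (70, "mj", 0.8)],
                seed=seed,
            )
            m = collapse(sim)
            params = cx.ModuleDetectionParams(min_module_size=30, cut_height=0.9)
            part = cx.detect_modules(cx.build_network(m, params), params)
            aris.append(
                adjusted_rand(planted(sim, part.labels.index), part.labels.values)
            )
        assert np.median(aris) >= 0.9

    def test_too_small_input(self):
        net = cx.CoexpressionNetwork(["a"], np.ones((1, 1)), tom=np.ones((1, 1)))
        with pytest.raises(ValueError):
            cx.detect_modules(net, cx.ModuleDetectionParams(min_module_size=1))


class TestGroups:
    def module_with_peak(self, peak):
        sim = synthetic.simulate_expression(40, [(40, peak, 1.0)], noise_sd=0.0, seed=2)
        m = collapse(sim)
        params = cx.ModuleDetectionParams(min_module_size=10)
        part = cx.detect_modules(cx.build_network(m + 0.01, params), params)
        return cx.assign_groups(part, m), part

    @pytest.mark.parametrize(
        "peak,group", [("2-8cells", "I"), ("gast", "I"), ("neu", "I"),
                       ("tb", "II"), ("hsl", "III"), ("mj", "III")]
    )
    def test_peak_stage_determines_group(self, peak, group):
        sim = synthetic.simulate_expression(30, [(30, peak, 1.0)], noise_sd=0.0, seed=2)
        m = collapse(sim)
        labels = pd.Series("turquoise", index=m.index)
        part = cx.ModulePartition(labels=labels)
        part = cx.assign_groups(part, m)
        assert part.groups["turquoise"] == group

    def test_flat_profile_ties_to_earliest_stage(self):
        m = pd.DataFrame(
            np.ones((5, 7)), index=[f"g{i}" for i in range(5)], columns=list(STAGES)
        )
        part = cx.ModulePartition(labels=pd.Series("blue", index=m.index))
        part = cx.assign_groups(part, m)
        assert part.groups["blue"] == "I"


class TestFamilyModuleTable:
    def test_matches_bruteforce_crosstab(self):
        rng = np.random.default_rng(17)
        genes = [f"g{i}" for i in range(60)]
        modules = rng.choice(["turquoise", "blue", "grey"], size=60)
        families = rng.choice(["zf-C2H2", "Homeodomain", "bHLH"], size=60)
        part = cx.ModulePartition(labels=pd.Series(modules, index=genes))
        table = cx.family_module_table(part, dict(zip(genes, families)))
        for fam in set(families):
            for mod in set(modules):
                expected = sum(
                    1 for f, m in zip(families, modules) if f == fam and m == mod
                )
                got = table.loc[fam, mod] if mod in table.columns else 0
                assert got == expected
        assert table.sum().sum() == 60

    def test_missing_family_is_contract_error(self):
        part = cx.ModulePartition(labels=pd.Series({"g1": "turquoise"}))
        with pytest.raises(ValueError, match="without family"):
            cx.family_module_table(part, {})


class TestHeatmapOrdering:
    def build(self, seed=13):
        sim = synthetic.simulate_expression(
            80, [(35, "2-8cells", 1.0), (35, "mj", 1.0)], noise_sd=0.0, seed=seed
        )
        m = collapse(sim)
        params = cx.ModuleDetectionParams(min_module_size=10)
        net = cx.build_network(m, params)
        part = cx.assign_groups(cx.detect_modules(net, params), m)
        return sim, m, net, part

    def test_two_planted_modules_two_blocks(self):
        _, _, net, part = self.build()
        ordered, boundaries = cx.order_for_heatmap(part, net)
        n_modules = part.labels.nunique()
        assert len(boundaries) == n_modules
        assert sorted(ordered) == sorted(part.labels.index)
        within, between = cx.mean_block_correlations(ordered, boundaries, net)
        assert within > between

    def test_single_module_single_block(self):
        m = pd.DataFrame(
            np.tile([1.0, 4, 30, 90, 30, 4, 1], (8, 1)),
            index=[f"g{i}" for i in range(8)], columns=list(STAGES),
        )
        params = cx.ModuleDetectionParams(min_module_size=2)
        net = cx.build_network(m, params)
        part = cx.assign_groups(cx.detect_modules(net, params), m)
        ordered, boundaries = cx.order_for_heatmap(part, net)
        assert boundaries == [0]
        assert len(ordered) == 8

    def test_input_order_invariance_of_blocks(self):
        sim, m, net, part = self.build()
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(m))
        m2 = m.iloc[perm]
        params = cx.ModuleDetectionParams(min_module_size=10)
        net2 = cx.build_network(m2, params)
        part2 = cx.assign_groups(cx.detect_modules(net2, params), m2)
        o1, b1 = cx.order_for_heatmap(part, net)
        o2, b2 = cx.order_for_heatmap(part2, net2)
        blocks1 = [frozenset(o1[s:e]) for s, e in zip(b1, b1[1:] + [len(o1)])]
        blocks2 = [frozenset(o2[s:e]) for s, e in zip(b2, b2[1:] + [len(o2)])]
        assert blocks1 == blocks2
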