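"""Synthetic generator, dataset sampler, metrics and the experiment grid."""

import numpy as np
import pytest

from synstable import (
    DatasetSpec,
    FusionGene,
    NetworkValidationError,
    SyntheticNetworkSpec,
    evaluate_ranking,
    generate_synthetic_network,
    interval_distribution,
    recognition_rate,
    recognition_rates,
    roc_and_auc,
    run_experiment_grid,
    sample_fusion_dataset,
)
from synstable.fusion import FusionScore


def scored(pairs):
    """Build FusionScore rows from (name_a, name_b, label, score) tuples."""
    ranked = sorted(pairs, key=lambda t: (-t[3], t[0], t[1]))
    return [
        FusionScore(FusionGene(a, b, lab), sc, rank, "SYN")
        for rank, (a, b, lab, sc) in enumerate(ranked, start=1)
    ]


class TestSyntheticNetwork:
    def test_same_seed_reproduces_edge_list(self):
        spec = SyntheticNetworkSpec(n_genes=50, susceptible_fraction=0.2, seed=42)
        n1, p1 = generate_synthetic_network(spec)
        n2, p2 = generate_synthetic_network(spec)
        assert n1.edge_items() == n2.edge_items() and p1 == p2

    def test_different_seeds_differ(self):
        base = dict(n_genes=50, susceptible_fraction=0.2)
        n1, _ = generate_synthetic_network(SyntheticNetworkSpec(**base, seed=1))
        n2, _ = generate_synthetic_network(SyntheticNetworkSpec(**base, seed=2))
        assert n1.edge_items() != n2.edge_items()

    def test_weights_in_range_and_no_self_loops(self):
        net, _ = generate_synthetic_network(
            SyntheticNetworkSpec(n_genes=80, susceptible_fraction=0.15, seed=3)
        )
        assert all(0.0 < w <= 1.0 for _, _, w in net.edge_items())

    def test_planted_genes_have_larger_weighted_degree(self):
        """Monte-Carlo check of the generator's own hub construction."""
        wins = 0
        replicates = 500
        for seed in range(replicates):
            net, planted = generate_synthetic_network(
                SyntheticNetworkSpec(n_genes=200, susceptible_fraction=0.15, seed=seed)
            )
            g = net.graph
            wdeg = {
                v: sum(d["weight"] for _, _, d in g.edges(v, data=True)) for v in g.nodes
            }
            pl = set(planted)
            mean_pl = np.mean([wdeg[v] for v in pl])
            mean_bg = np.mean([wdeg[v] for v in g.nodes if v not in pl])
            wins += mean_pl > mean_bg
        assert wins >= 0.95 * replicates

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(susceptible_fraction=0.0),
            dict(susceptible_fraction=1.0),
            dict(n_genes=100, susceptible_fraction=0.03),  # backbone too small
            dict(edge_density=0.0001),  # below structural minimum
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(NetworkValidationError):
            spec = SyntheticNetworkSpec(**{"n_genes": 100, **kwargs})
            generate_synthetic_network(spec)

    def test_edge_density_adds_background_edges(self):
        lean = generate_synthetic_network(
            SyntheticNetworkSpec(n_genes=60, susceptible_fraction=0.2, seed=0)
        )[0]
        dense = generate_synthetic_network(
            SyntheticNetworkSpec(
                n_genes=60, susceptible_fraction=0.2, seed=0, edge_density=0.08
            )
        )[0]
        assert dense.n_edges == round(0.08 * 60 * 59 / 2) > lean.n_edges


class TestDatasetSampler:
    POOL_S = [f"s{i}" for i in range(40)]
    POOL_B = [f"b{i}" for i in range(400)]

    def test_counts_and_slots(self):
        spec = DatasetSpec(150, 15, seed=7)
        data = sample_fusion_dataset(self.POOL_S, self.POOL_B, spec)
        assert len(data) == 150
        assert sum(f.label for f in data) == 15
        # 300 partner slots, distinct within each pool draw
        sus_partners = [g for f in data if f.label == 1 for g in f.pair]
        ord_partners = [g for f in data if f.label == 0 for g in f.pair]
        assert len(sus_partners) == 30 == len(set(sus_partners))
        assert len(ord_partners) == 270 == len(set(ord_partners))

    def test_no_fusion_appears_twice(self):
        data = sample_fusion_dataset(self.POOL_S, self.POOL_B, DatasetSpec(100, 10, 3))
        pairs = [f.pair for f in data]
        assert len(pairs) == len(set(pairs))

    def test_same_seed_is_deterministic(self):
        spec = DatasetSpec(50, 5, seed=9)
        a = sample_fusion_dataset(self.POOL_S, self.POOL_B, spec)
        b = sample_fusion_dataset(self.POOL_S, self.POOL_B, spec)
        assert [(f.pair, f.label) for f in a] == [(f.pair, f.label) for f in b]

    def test_collision_redraw_until_disjoint(self):
        """Adversarial fixture: ordinary draws come from the susceptible
        pool itself, forcing the duplicate re-draw loop to run."""
        pool = [f"g{i}" for i in range(12)]
        for seed in range(30):
            data = sample_fusion_dataset(pool, pool, DatasetSpec(10, 5, seed))
            sus = {f.pair for f in data if f.label == 1}
            ordinary = {f.pair for f in data if f.label == 0}
            assert not sus & ordinary

    def test_pool_exhaustion_rejected(self):
        with pytest.raises(NetworkValidationError):
            sample_fusion_dataset(["a", "b"], self.POOL_B, DatasetSpec(10, 5, 0))
        with pytest.raises(NetworkValidationError):
            sample_fusion_dataset(self.POOL_S, ["a", "b"], DatasetSpec(10, 5, 0))


class TestIntervalDistribution:
    def test_positives_at_ranks_one_and_five_of_ten(self):
        rows = [("a", "b", 1, 1.0), ("c", "d", 0, 0.9), ("e", "f", 0, 0.8),
                ("g", "h", 0, 0.7), ("i", "j", 1, 0.6), ("k", "l", 0, 0.5),
                ("m", "n", 0, 0.4), ("o", "p", 0, 0.3), ("q", "r", 0, 0.2),
                ("s", "t", 0, 0.1)]
        counts = interval_distribution(scored(rows))
        assert counts.tolist() == [1, 0, 0, 0, 1, 0, 0, 0, 0, 0]

    def test_all_positives_ranked_last(self):
        rows = [(f"a{i}", f"b{i}", 0, 1.0 - i / 100) for i in range(18)]
        rows += [(f"p{i}", f"q{i}", 1, 0.0) for i in range(2)]
        counts = interval_distribution(scored(rows))
        assert counts.tolist() == [0] * 9 + [2]

    def test_conservation_for_awkward_nf(self):
        # Nf = 17 is not a multiple of 10: real-valued interval edges
        rng = np.random.default_rng(5)
        rows = [
            (f"a{i}", f"b{i}", int(rng.random() < 0.3), float(rng.random()))
            for i in range(17)
        ]
        counts = interval_distribution(scored(rows))
        assert counts.sum() == sum(r[2] for r in rows)

    def test_bad_ranks_rejected(self):
        rows = scored([("a", "b", 1, 1.0), ("c", "d", 0, 0.5)])
        broken = [FusionScore(r.fusion, r.score, 5, r.algorithm) for r in rows]
        with pytest.raises(NetworkValidationError):
            interval_distribution(broken)


class TestRecognitionRate:
    def test_worked_example(self):
        counts = np.array([13, 0, 2, 0, 0, 0, 0, 0, 0, 0])
        assert recognition_rate(counts, 15, 1) == pytest.approx(13 / 15)
        assert recognition_rate(counts, 15, 10) == pytest.approx(1.0)

    def test_monotone_and_terminal_one(self):
        counts = np.array([3, 1, 0, 2, 0, 0, 1, 0, 0, 3])
        rates = recognition_rates(counts, 10)
        assert all(b >= a for a, b in zip(rates, rates[1:]))
        assert rates[-1] == pytest.approx(1.0)

    def test_zero_positives_is_a_domain_error(self):
        with pytest.raises(NetworkValidationError):
            recognition_rate(np.zeros(10, dtype=int), 0, 1)


class TestRocAndAuc:
    def test_perfect_separation(self):
        rows = [("a", "b", 1, 0.9), ("c", "d", 1, 0.8), ("e", "f", 0, 0.2),
                ("g", "h", 0, 0.1)]
        _, _, auc = roc_and_auc(scored(rows))
        assert auc == pytest.approx(1.0)

    def test_all_scores_tied_is_chance(self):
        rows = [("a", "b", 1, 0.5), ("c", "d", 0, 0.5), ("e", "f", 1, 0.5),
                ("g", "h", 0, 0.5)]
        _, _, auc = roc_and_auc(scored(rows))
        assert auc == pytest.approx(0.5)

    def test_hand_worked_four_items(self):
        # scores 0.9+, 0.8-, 0.7+, 0.1-: 3 of 4 positive-negative pairs ordered
        rows = [("a", "b", 1, 0.9), ("c", "d", 0, 0.8), ("e", "f", 1, 0.7),
                ("g", "h", 0, 0.1)]
        _, _, auc = roc_and_auc(scored(rows))
        assert auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        rows = [("a", "b", 1, 0.9), ("c", "d", 1, 0.8)]
        with pytest.raises(NetworkValidationError):
            roc_and_auc(scored(rows))

    def test_auc_equals_mann_whitney_pair_count(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            rows = [
                (f"a{i}", f"b{i}", int(rng.random() < 0.4), float(rng.integers(0, 6)))
                for i in range(24)
            ]
            labels = [r[2] for r in rows]
            if len(set(labels)) < 2:
                continue
            _, _, auc = roc_and_auc(scored(rows))
            pos = [r[3] for r in rows if r[2] == 1]
            neg = [r[3] for r in rows if r[2] == 0]
            pairs = sum(
                1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
            )
            assert auc == pytest.approx(pairs / (len(pos) * len(neg)), abs=1e-12)


class TestExperimentGrid:
    def test_single_cell_single_replicate(self):
        grid = run_experiment_grid(
            network_spec=SyntheticNetworkSpec(n_genes=60, susceptible_fraction=0.2),
            nf_grid=(20,),
            ni_grid=(5,),
            replicates=1,
            seed=5,
        )
        assert grid.n_datasets == 1
        assert len(grid.results) == 3  # one row per algorithm
        assert {r.algorithm for r in grid.results} == {"SYN", "DEG", "BET"}
        assert not grid.failures

    def test_conservation_and_terminal_recognition(self):
        grid = run_experiment_grid(
            network_spec=SyntheticNetworkSpec(n_genes=60, susceptible_fraction=0.2),
            nf_grid=(20, 25),
            ni_grid=(5,),
            replicates=2,
            seed=8,
        )
        assert grid.n_datasets == 4
        for r in grid.results:
            assert sum(r.interval_counts) == r.n_susceptible
            assert r.recognition[-1] == pytest.approx(1.0)
            assert 0.0 <= r.auc <= 1.0

    def test_summary_means_match_figure_aggregation(self):
        grid = run_experiment_grid(
            network_spec=SyntheticNetworkSpec(n_genes=60, susceptible_fraction=0.2),
            nf_grid=(20,),
            ni_grid=(5,),
            replicates=3,
            seed=2,
        )
        summary = grid.summary()
        manual = np.mean(
            [r.auc for r in grid.results if r.algorithm == "SYN"]
        )
        row = summary[(summary.algorithm == "SYN") & (summary.metric == "auc")]
        assert row.value.iloc[0] == pytest.approx(manual)
        assert grid.mean_auc("SYN") == pytest.approx(manual)

    def test_deterministic_under_fixed_seed(self):
        kwargs = dict(
            network_spec=SyntheticNetworkSpec(n_genes=60, susceptible_fraction=0.2),
            nf_grid=(20,),
            ni_grid=(5,),
            replicates=2,
            seed=13,
        )
        a = run_experiment_grid(**kwargs)
        b = run_experiment_grid(**kwargs)
        assert a.to_frame().equals(b.to_frame())
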