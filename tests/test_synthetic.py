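"""Planted-truth generators: determinism, construction invariants, null behavior."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netkda import bridging_driver_rank, neighborhood
from netkda import synthetic


class TestGenerateNetwork:
    def test_acyclic_by_construction(self):
        net, _ = synthetic.generate_network(n_genes=500, driver_out=10, seed=0)
        assert nx.is_directed_acyclic_graph(net.graph)

    def test_driver_cone_contains_planted_roots(self):
        net, truth = synthetic.generate_network(n_genes=500, driver_out=10,
                                                depth=2, seed=1)
        roots = {f"G{i:05d}" for i in range(1, 11)}
        two_layer = neighborhood(net, {truth.driver}, 2, "downstream")
        assert roots <= two_layer
        assert truth.cone == frozenset(two_layer - {truth.driver})

    def test_same_seed_identical_edges(self):
        n1, _ = synthetic.generate_network(n_genes=400, driver_out=8, seed=5)
        n2, _ = synthetic.generate_network(n_genes=400, driver_out=8, seed=5)
        assert n1.edges == n2.edges
        n3, _ = synthetic.generate_network(n_genes=400, driver_out=8, seed=6)
        assert n1.edges != n3.edges

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_network(n_genes=50, driver_out=40, depth=2)


class TestGenerateSignatures:
    def test_sizes_and_small_raw_overlap(self):
        overlaps = []
        for seed in range(5):
            net, truth = synthetic.generate_network(seed=30 + seed)
            sig_a, sig_b = synthetic.generate_signatures(truth)
            assert len(sig_a) == 359 and len(sig_b) == 223
            overlaps.append(len(sig_a.genes & sig_b.genes))
        assert max(overlaps) < 0.1 * 223

    def test_cone_fraction_honored(self):
        net, truth = synthetic.generate_network(seed=31)
        sig_a, sig_b = synthetic.generate_signatures(truth, frac_in_cone=0.5)
        assert len(sig_a.genes & truth.cone) == round(0.5 * 359)
        assert len(sig_b.genes & truth.cone) == round(0.5 * 223)

    def test_same_seed_identical(self):
        net, truth = synthetic.generate_network(seed=32)
        s1 = synthetic.generate_signatures(truth, seed=9)
        s2 = synthetic.generate_signatures(truth, seed=9)
        assert s1[0].genes == s2[0].genes and s1[1].genes == s2[1].genes

    def test_zero_cone_fraction_is_negative_control(self):
        """Signatures independent of the driver: it should not reliably
        rank first (it still can by chance on occasion)."""
        wins = 0
        for seed in range(5):
            net, truth = synthetic.generate_network(n_genes=800, driver_out=15,
                                                    seed=40 + seed)
            sig_a, sig_b = synthetic.generate_signatures(
                truth, size_a=120, size_b=80, frac_in_cone=0.0)
            res = bridging_driver_rank(net, sig_a, sig_b)
            if not res.empty and res.iloc[0]["gene"] == truth.driver:
                wins += 1
        assert wins <= 2


class TestGenerateExpression:
    def test_low_noise_limit_gives_near_perfect_correlation(self):
        net, truth = synthetic.generate_network(n_genes=300, driver_out=10,
                                                seed=50)
        expr = synthetic.generate_expression(truth, n_samples=60, n_pos=20,
                                             n_neg=10, noise_sd=1e-6, seed=50)
        drv = expr.data.loc[truth.driver]
        for g in list(truth.pos_genes)[:5]:
            assert np.corrcoef(expr.data.loc[g], drv)[0, 1] > 0.999

    def test_zero_beta_effect_genes_look_like_noise(self):
        net, truth = synthetic.generate_network(n_genes=300, driver_out=10,
                                                seed=51)
        expr = synthetic.generate_expression(truth, n_samples=200, beta=0.0,
                                             n_pos=40, n_neg=20, seed=51)
        drv = expr.data.loc[truth.driver].to_numpy()
        effect = [g for g in truth.pos_genes | truth.neg_genes]
        rs = [abs(np.corrcoef(expr.data.loc[g], drv)[0, 1]) for g in effect]
        # |r| of "effect" genes stays at the null scale ~1/sqrt(n)
        assert np.mean(rs) < 3.0 / np.sqrt(200)

    def test_group_delta_plants_cohort(self):
        net, truth = synthetic.generate_network(n_genes=300, driver_out=10,
                                                seed=52)
        expr = synthetic.generate_expression(truth, n_samples=90, n_pos=20,
                                             n_neg=10, group_delta=4.0, seed=52)
        groups = truth.sample_groups
        assert groups.value_counts()["high"] == 30  # frac_high = 1/3
        drv = expr.data.loc[truth.driver]
        assert drv[groups == "high"].mean() - drv[groups == "low"].mean() > 2.0

    def test_determinism(self):
        net, truth = synthetic.generate_network(n_genes=300, driver_out=10,
                                                seed=53)
        e1 = synthetic.generate_expression(truth, n_samples=40, n_pos=20,
                                           n_neg=10, seed=7)
        e2 = synthetic.generate_expression(truth, n_samples=40, n_pos=20,
                                           n_neg=10, seed=7)
        assert e1.data.equals(e2.data)


class TestGenerateSurvival:
    @staticmethod
    def _groups(n: int) -> pd.Series:
        return pd.Series(np.where(np.arange(n) % 3 == 0, "high", "low"),
                         index=[f"S{i:04d}" for i in range(n)], name="group")

    def test_no_censoring_all_events(self):
        rec = synthetic.generate_survival(self._groups(50), censor_rate=0.0,
                                          max_follow_up=np.inf, seed=1)
        assert (rec["event"] == 1).all()

    def test_administrative_censoring_caps_times(self):
        rec = synthetic.generate_survival(self._groups(300), censor_rate=0.0,
                                          max_follow_up=5.0, seed=2)
        assert rec["time"].max() <= 5.0
        assert (rec.loc[rec["time"] == 5.0, "event"] == 0).all()

    def test_planted_benefit_only_in_low_group(self):
        """The default hazards mirror the published design: treatment halves
        the hazard in the driver-low group and does nothing in the high."""
        from netkda import compare_groups

        low_sig, high_sig = 0, 0
        n_rep = 20
        for seed in range(n_rep):
            rec = synthetic.generate_survival(self._groups(500), seed=100 + seed)
            comp = compare_groups(rec, by="arm", within="group").set_index("stratum")
            low_sig += comp.loc["low", "p"] < 0.05
            high_sig += comp.loc["high", "p"] < 0.05
        assert low_sig >= 0.9 * n_rep
        assert high_sig <= 0.2 * n_rep

    def test_missing_hazard_and_bad_rate_rejected(self):
        with pytest.raises(KeyError):
            synthetic.generate_survival(self._groups(10),
                                        hazards={("low", "treated"): 0.1})
        with pytest.raises(ValueError):
            synthetic.generate_survival(
                self._groups(4),
                hazards={(g, a): 0.0 for g in ("low", "high")
                         for a in ("treated", "untreated")})

    def test_determinism(self):
        r1 = synthetic.generate_survival(self._groups(40), seed=9)
        r2 = synthetic.generate_survival(self._groups(40), seed=9)
        assert r1.equals(r2)


class TestPublishedScaleSignatures:
    def test_published_margins(self):
        sig_a, sig_b, universe = synthetic.published_scale_signatures(seed=0)
        assert len(sig_a) == 359
        assert len(sig_b) == 223
        assert len(sig_a.genes & sig_b.genes) == 9
        assert universe == 24_700

    def test_infeasible_margins_rejected(self):
        with pytest.raises(ValueError):
            synthetic.published_scale_signatures(universe=100)
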