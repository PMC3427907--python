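"""Correlation-aware weighted parametric closure: constants, consonance, delta."""

import numpy as np
import pytest
from scipy.optimize import brentq

import mcpgraph as mg
from mcpgraph.parametric import ConsonanceError, parametric_vs_bonferroni

from conftest import random_graph, random_pvalues

P_GMCP = np.array([0.0131, 0.1, 0.012, 0.01])


def block_model(rho):
    corr = np.full((4, 4), np.nan)
    np.fill_diagonal(corr, 1.0)
    corr[0, 1] = corr[1, 0] = corr[2, 3] = corr[3, 2] = rho
    return mg.CorrelationModel(corr)


class TestCorrelationModel:
    def test_block_partition_derived(self, block_corr):
        assert block_corr.blocks == ((0, 1), (2, 3))

    def test_fully_known_is_single_block(self):
        cm = mg.CorrelationModel.fully_known(np.eye(3) * 0.5 + 0.5)
        assert cm.blocks == ((0, 1, 2),)

    def test_all_unknown_gives_singletons(self):
        cm = mg.CorrelationModel.unknown(3)
        assert cm.blocks == ((0,), (1,), (2,))

    def test_non_block_pattern_rejected(self):
        corr = np.full((3, 3), np.nan)
        np.fill_diagonal(corr, 1.0)
        corr[0, 1] = corr[1, 0] = 0.5
        corr[1, 2] = corr[2, 1] = 0.5  # 0-2 unknown inside the {0,1,2} component
        with pytest.raises(mg.GraphValidationError, match="block"):
            mg.CorrelationModel(corr)

    def test_asymmetric_rejected(self):
        corr = np.eye(2)
        corr[0, 1] = 0.5
        with pytest.raises(mg.GraphValidationError, match="symmetric"):
            mg.CorrelationModel(corr)

    def test_non_psd_block_rejected(self):
        corr = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(mg.GraphValidationError, match="semidefinite"):
            mg.CorrelationModel(corr)

    def test_csv_round_trip(self, block_corr, tmp_path):
        path = tmp_path / "corr.csv"
        block_corr.to_csv(path)
        again = mg.CorrelationModel.from_csv(path)
        assert again.blocks == block_corr.blocks
        assert np.allclose(
            np.nan_to_num(again.matrix), np.nan_to_num(block_corr.matrix)
        )


class TestCriticalConstant:
    def test_bivariate_dunnett_constant(self, block_corr):
        c = mg.critical_constant([0.5, 0.5], block_corr.restrict([0, 1]), 0.025)
        assert round(c, 4) == 1.0783

    def test_three_independent_equal_weights(self):
        cm = mg.CorrelationModel.independent(3)
        c = mg.critical_constant([1 / 3] * 3, cm, 0.05)
        assert round(c / 3 * 0.05, 5) == 0.01695
        # closed form: 1 - (1 - c a/3)^3 = a
        c_exact = (1 - (1 - 0.05) ** (1 / 3)) * 3 / 0.05
        assert c == pytest.approx(c_exact, abs=1e-6)

    def test_singleton_full_weight(self):
        cm = mg.CorrelationModel.independent(1)
        assert mg.critical_constant([1.0], cm, 0.025) == pytest.approx(1.0)

    def test_unequal_weights_closed_form(self):
        """Independent pair with weights (1/3, 2/3): per-hypothesis level of the
        lighter hypothesis drops below the equal-weight Sidak level."""
        cm = mg.CorrelationModel.independent(2)
        c = mg.critical_constant([1 / 3, 2 / 3], cm, 0.05)
        # oracle: (1 - a)(1 - 2a) = 0.95 with a = c*alpha/3
        a = brentq(lambda a: (1 - a) * (1 - 2 * a) - 0.95, 0, 0.4, xtol=1e-14)
        assert c * 0.05 / 3 == pytest.approx(a, abs=1e-8)
        assert round(c * 0.05 / 3, 6) == 0.016856
        assert c * 0.05 / 3 < 0.016952

    def test_singleton_blocks_sum_one_is_bonferroni(self):
        cm = mg.CorrelationModel.unknown(2)
        assert mg.critical_constant([0.5, 0.5], cm, 0.025) == pytest.approx(1.0)

    def test_all_zero_weights_error(self):
        cm = mg.CorrelationModel.independent(2)
        with pytest.raises(mg.GraphValidationError, match="zero"):
            mg.critical_constant([0.0, 0.0], cm, 0.025)

    def test_equal_weight_independent_closed_form_various_k(self):
        for k in (2, 3, 4, 5):
            cm = mg.CorrelationModel.independent(k)
            c = mg.critical_constant([1 / k] * k, cm, 0.05)
            c_exact = (1 - 0.95 ** (1 / k)) * k / 0.05
            assert c == pytest.approx(c_exact, abs=1e-6)

    def test_constant_at_least_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            k = int(rng.integers(1, 4))
            rho = float(rng.uniform(0, 0.9))
            cm = mg.CorrelationModel.fully_known(np.eye(k) * (1 - rho) + rho)
            w = rng.dirichlet(np.ones(k)) * rng.uniform(0.3, 1.0)
            c = mg.critical_constant(w, cm, 0.025)
            assert c >= 1.0 - 1e-12


class TestLocalPvalue:
    def test_full_intersection_union_probability(self, hierarchical, block_corr):
        table = mg.closure_weights(hierarchical)
        local = mg.local_pvalue_parametric((0, 1, 2, 3), P_GMCP, table, block_corr)
        assert round(local, 8) == 0.02431856

    def test_singleton(self, hierarchical, block_corr):
        table = mg.closure_weights(hierarchical)
        assert mg.local_pvalue_parametric(
            (1,), P_GMCP, table, block_corr
        ) == pytest.approx(0.1)

    def test_unknown_cross_pair_is_bonferroni(self, hierarchical, block_corr):
        table = mg.closure_weights(hierarchical)
        local = mg.local_pvalue_parametric((0, 3), P_GMCP, table, block_corr)
        assert local == pytest.approx(min(2 * min(0.0131, 0.01), 1.0))

    def test_matches_smallest_rejecting_level(self, block_corr):
        """Local p equals the root of c(q) w_j q = min ratio — the smallest
        level at which the intersection is rejected."""
        rng = np.random.default_rng(17)
        table_graph = mg.make_standard_graph("hierarchical")
        table = mg.closure_weights(table_graph)
        for _ in range(20):
            p = random_pvalues(rng, 4)
            for J in [(0, 1), (0, 1, 2, 3), (0, 2, 3), (2, 3)]:
                q = mg.local_pvalue_parametric(J, p, table, block_corr)
                if not 1e-8 < q < 1.0 - 1e-8:
                    continue
                w = table.weights(J)
                pos = w > 0
                t = np.min(p[list(J)][pos] / w[pos])
                c = mg.critical_constant(w, block_corr.restrict(J), q)
                assert c * q == pytest.approx(t, rel=1e-6)


class TestClosedParametric:
    def test_gmcp_example_rejections_and_dominance(self, hierarchical, block_corr):
        out = mg.closed_parametric(hierarchical, P_GMCP, block_corr, 0.025)
        assert out.rejected_names == ("H1", "H3")
        assert np.allclose(
            np.round(out.adjusted_p, 8), [0.02431856, 0.1, 0.02431856, 0.1]
        )
        bon = mg.closed_bonferroni(hierarchical, P_GMCP, 0.025)
        assert not bon.rejected.any()

    def test_all_p_one(self, hierarchical, block_corr):
        out = mg.closed_parametric(hierarchical, np.ones(4), block_corr, 0.025)
        assert not out.rejected.any()
        assert np.allclose(out.adjusted_p, 1.0)

    def test_comparison_frame(self, hierarchical, block_corr):
        frame = parametric_vs_bonferroni(hierarchical, P_GMCP, block_corr, 0.025)
        assert frame["parametric_rejected"].sum() == 2
        assert frame["bonferroni_rejected"].sum() == 0

    def test_dominates_bonferroni_on_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            m = 4
            g = random_graph(rng, m)
            p = random_pvalues(rng, m)
            rho = float(rng.uniform(0, 0.9))
            corr = block_model(rho)
            par = mg.closed_parametric(g, p, corr, 0.025).rejected
            bon = mg.closed_bonferroni(g, p, 0.025).rejected
            assert np.all(bon <= par)


class TestLocalLevels:
    def test_printed_levels(self, hierarchical, block_corr):
        levels = mg.local_levels_table(hierarchical, block_corr, 0.025) * 100
        assert round(levels.loc["H1 ∩ H2 ∩ H3 ∩ H4", "H1"], 2) == 1.35
        assert round(levels.loc["H1 ∩ H3", "H1"], 2) == 2.50
        assert round(levels.loc["H1 ∩ H3 ∩ H4", "H1"], 2) == 1.25

    def test_delta_graph_level(self, block_corr):
        g = mg.make_standard_graph("hierarchical_delta", delta=0.0783)
        levels = mg.local_levels_table(g, block_corr, 0.025) * 100
        assert round(levels.loc["H1 ∩ H3 ∩ H4", "H4"], 2) == 1.15


class TestConsonance:
    def test_hierarchical_not_consonant(self, hierarchical, block_corr):
        rep = mg.check_consonance_parametric(hierarchical, block_corr, 0.025)
        assert not rep.passed
        # H1's level shrinks from 1.35% to 1.25% when H2 leaves the intersection
        assert any(
            j == 0 and set(J) == {0, 1, 2, 3} and set(Jp) == {0, 2, 3}
            for J, Jp, j in rep.violations
        )

    def test_delta_graph_consonant(self, block_corr):
        g = mg.make_standard_graph("hierarchical_delta", delta=0.0783)
        assert mg.check_consonance_parametric(g, block_corr, 0.025).passed

    def test_sidak_style_cycle_not_consonant(self):
        """Equal initial weights with pair weights (1/3, 2/3) violate level
        monotonicity for the lighter hypothesis under independence."""
        g = mg.new_graph(
            ["H1", "H2", "H3"],
            [1 / 3] * 3,
            [[0, 1, 0], [0, 0, 1], [1, 0, 0]],
        )
        cm = mg.CorrelationModel.independent(3)
        rep = mg.check_consonance_parametric(g, cm, 0.05)
        assert not rep.passed


class TestSequentialParametric:
    def test_fully_known_noninferiority_superiority_sequence(self, hierarchical):
        # same-population setting: rho=1 within dose, 0.5 across
        corr = np.array(
            [
                [1.0, 0.5, 1.0, 0.5],
                [0.5, 1.0, 0.5, 1.0],
                [1.0, 0.5, 1.0, 0.5],
                [0.5, 1.0, 0.5, 1.0],
            ]
        )
        cm = mg.CorrelationModel.fully_known(corr)
        out = mg.sequential_parametric(
            hierarchical, [0.01, 0.02, 0.005, 0.5], cm, 0.025
        )
        assert [j for j, _ in out.trace] == [0, 2, 1]
        assert out.rejected_names == ("H1", "H2", "H3")

    def test_all_p_one_stops_immediately(self, block_corr):
        g = mg.make_standard_graph("hierarchical_delta", delta=0.0783)
        out = mg.sequential_parametric(g, np.ones(4), block_corr, 0.025)
        assert out.trace == () and not out.rejected.any()

    def test_consonant_delta_graph_rejects_only_h1(self, block_corr):
        g = mg.make_standard_graph("hierarchical_delta", delta=0.0783)
        out = mg.sequential_parametric(g, P_GMCP, block_corr, 0.025)
        assert out.rejected_names == ("H1",)

    def test_refuses_non_consonant_graph(self, hierarchical, block_corr):
        with pytest.raises(ConsonanceError, match="closed_parametric"):
            mg.sequential_parametric(hierarchical, P_GMCP, block_corr, 0.025)

    def test_agrees_with_closure_when_consonant(self, block_corr):
        rng = np.random.default_rng(123)
        g = mg.make_standard_graph("hierarchical_delta", delta=0.0783)
        for _ in range(20):
            p = random_pvalues(rng, 4)
            seq = mg.sequential_parametric(g, p, block_corr, 0.025)
            clo = mg.closed_parametric(g, p, block_corr, 0.025)
            assert np.array_equal(seq.rejected, clo.rejected)


class TestMinConsonanceDelta:
    def test_reference_value(self, block_corr):
        assert round(mg.min_consonance_delta(block_corr, 0.025), 4) == 0.0783

    def test_grows_with_primary_correlation(self):
        deltas = [
            mg.min_consonance_delta(block_model(rho), 0.025)
            for rho in (0.0, 0.5, 0.9)
        ]
        assert deltas[0] < deltas[1] < deltas[2]
        # independent case: the excess of the two-hypothesis constant over 1
        cm0 = mg.CorrelationModel.independent(2)
        c0 = mg.critical_constant([0.5, 0.5], cm0, 0.025)
        assert deltas[0] == pytest.approx(c0 - 1.0, abs=1e-5)

    def test_perfect_correlation_degenerates(self):
        assert mg.min_consonance_delta(block_model(1.0), 0.025) == pytest.approx(
            1.0, abs=1e-5
        )


class TestDunnettCorrelation:
    def test_balanced_design(self):
        assert mg.dunnett_correlation(50, 50, 50) == pytest.approx(0.5)

    def test_unbalanced_closed_form(self):
        assert mg.dunnett_correlation(100, 50, 50) == pytest.approx(1 / 3)

    def test_large_control_limit(self):
        assert mg.dunnett_correlation(1e9, 50, 50) < 1e-3

    def test_invalid_sizes(self):
        with pytest.raises(mg.GraphValidationError):
            mg.dunnett_correlation(0, 10, 10)
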