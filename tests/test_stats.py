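"""Spearman correlation, BH adjustment, feature screening, network build."""

import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutflux.pipeline import ContributionRecord
from gutflux.stats import (
    ClinicalSeries,
    CorrelationEdge,
    build_network,
    correlate_features,
    derived_ratio,
    fdr_bh,
    spearman,
)


def closed_form_rho(x_ranks, y_ranks):
    n = len(x_ranks)
    d2 = sum((a - b) ** 2 for a, b in zip(x_ranks, y_ranks))
    return 1.0 - 6.0 * d2 / (n * (n * n - 1))


def brute_force_bh(p):
    """BH from the definition: p_(i) * m / i with a cumulative minimum."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = running
    return adjusted


class TestSpearman:
    def test_three_cycle_permutation(self):
        x = np.arange(1, 8)
        y = np.array([2, 3, 1, 4, 5, 6, 7])  # sum d^2 = 6
        res = spearman(x, y)
        assert res.rho == pytest.approx(1 - 36 / 336, abs=1e-15)

    def test_t_approximation_matches_printed_value(self):
        # rho = 0.8929 at n = 7 gives the two-sided p ~ 0.0068 reported
        # for the BMI-leptin pair
        res = spearman(np.arange(1, 8), np.array([2, 3, 1, 4, 5, 6, 7]))
        assert f"{res.p:.2g}" == "0.0068"

    def test_perfect_correlations(self):
        x = np.arange(1, 8, dtype=float)
        res = spearman(x, x)
        assert res.rho == 1.0 and res.p == 0.0 and res.perfect
        res = spearman(x, x[::-1])
        assert res.rho == -1.0 and res.p == 0.0 and res.perfect

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman(np.arange(5.0), np.ones(5))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spearman(np.arange(5.0), np.arange(6.0))

    @given(st.integers(min_value=5, max_value=50), st.integers(0, 2 ** 30))
    @settings(max_examples=200)
    def test_matches_closed_form_on_random_permutations(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.permutation(n) + 1.0
        y = rng.permutation(n) + 1.0
        res = spearman(x, y)
        assert res.rho == pytest.approx(closed_form_rho(x, y), abs=1e-12)

    def test_exact_p_agrees_with_full_enumeration(self):
        x = np.arange(1, 8, dtype=float)
        y = np.array([2, 3, 1, 4, 5, 6, 7], dtype=float)
        res = spearman(x, y, method="exact")
        null = []
        for perm in permutations(range(1, 8)):
            null.append(closed_form_rho(x, perm))
        expected = sum(1 for r in null if abs(r) >= abs(res.rho) - 1e-12) \
            / math.factorial(7)
        assert res.p == pytest.approx(expected, abs=1e-15)


class TestFdrBH:
    def test_hand_example(self):
        assert fdr_bh([0.01, 0.02, 0.03, 0.04]) == \
            pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_and_empty(self):
        assert fdr_bh([0.37]) == pytest.approx([0.37])
        assert fdr_bh([]) == []

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.1, 1.5])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40), st.integers())
    @settings(max_examples=200)
    def test_matches_brute_force(self, p, _):
        assert fdr_bh(p) == pytest.approx(brute_force_bh(p), abs=1e-12)


class TestDerivedRatio:
    def test_day0_and_day105_values(self):
        # adipokine values at intervention start and end
        clin = ClinicalSeries(
            ["d0", "d105"],
            {"leptin": [63.8, 34.5], "adiponectin": [2.17, 5.39]},
        )
        ratio = derived_ratio(clin)
        assert ratio[0] == pytest.approx(29.40, abs=0.005)
        assert ratio[1] == pytest.approx(6.40, abs=0.005)

    def test_equal_series_gives_ones(self):
        clin = ClinicalSeries(
            ["a", "b"], {"leptin": [2.0, 3.0], "adiponectin": [2.0, 3.0]})
        np.testing.assert_allclose(derived_ratio(clin), [1.0, 1.0])

    def test_zero_adiponectin_names_timepoint(self):
        clin = ClinicalSeries(
            ["a", "b"], {"leptin": [1.0, 1.0], "adiponectin": [1.0, 0.0]})
        with pytest.raises(ValueError, match="'b'"):
            derived_ratio(clin)


def _table(series: dict[str, list[float]], timepoints) -> pd.DataFrame:
    return pd.DataFrame(series, index=timepoints)


class TestCorrelateFeatures:
    def test_planted_identical_ranks_retained(self):
        tps = [f"d{i}" for i in range(7)]
        met = [1.0, 2, 3, 4, 5, 6, 7]
        clin = ClinicalSeries(tps, {"BMI": met,
                                    "noise": [3, 1, 4, 1.5, 9, 2, 6]})
        edges = correlate_features(_table({"fol": met}, tps), clin,
                                   include_ratio=False)
        assert any(e.feature_a == "fol" and e.feature_b == "BMI"
                   and e.rho == 1.0 for e in edges)

    def test_constant_feature_skipped(self):
        tps = [f"d{i}" for i in range(7)]
        clin = ClinicalSeries(tps, {"BMI": [1, 2, 3, 4, 5, 6, 7]})
        edges = correlate_features(
            _table({"flat": [2.0] * 7}, tps), clin, include_ratio=False)
        assert edges == []

    def test_too_few_timepoints_rejected(self):
        tps = ["a", "b", "c"]
        clin = ClinicalSeries(tps, {"BMI": [1, 2, 3]})
        with pytest.raises(ValueError, match="4"):
            correlate_features(_table({"m": [1, 2, 3]}, tps), clin)

    def test_null_retention_rate_below_threshold(self, rng):
        """Independent noise features at n = 7 rarely survive the
        |rho| > 0.7 + FDR < 0.1 screen."""
        tps = [f"d{i}" for i in range(7)]
        retained = tested = 0
        for _ in range(50):
            table = _table(
                {f"m{j}": rng.uniform(size=7) for j in range(3)}, tps)
            clin = ClinicalSeries(
                tps, {name: list(rng.uniform(size=7))
                      for name in ("BMI", "leptin")})
            edges = correlate_features(table, clin, include_ratio=False)
            retained += len(edges)
            tested += 6
        rate = retained / tested
        assert rate <= 0.1 + 1.96 * math.sqrt(0.1 * 0.9 / tested)


class TestBuildNetwork:
    def _edge(self, met="fol", clin="BMI", rho=-0.9):
        return CorrelationEdge(met, clin, rho, 0.005, 0.04)

    def _contrib(self, met="fol", strain="B_longum", share=1.0):
        return ContributionRecord("all", met, strain, 0.0, 5.0, share)

    def test_three_nodes_two_edges(self):
        g = build_network([self._edge()], [self._contrib()])
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 2
        assert g.nodes["fol"]["type"] == "metabolite"
        assert g.nodes["BMI"]["type"] == "clinical"
        assert g.nodes["B_longum"]["type"] == "strain"
        assert g.edges["fol", "BMI"]["sign"] == -1
        assert g.edges["fol", "B_longum"]["share"] == 1.0

    def test_unthresholded_metabolite_absent_with_its_producer(self):
        g = build_network([self._edge(met="fol")],
                          [self._contrib(met="3mop", strain="B_t")])
        assert "3mop" not in g and "B_t" not in g

    def test_duplicate_contributions_merged(self):
        g = build_network(
            [self._edge()],
            [self._contrib(share=0.4), self._contrib(share=0.35)],
        )
        assert g.edges["fol", "B_longum"]["share"] == pytest.approx(0.75)

    def test_empty_inputs_give_empty_graph(self):
        g = build_network([], [])
        assert g.number_of_nodes() == 0

    def test_every_production_edge_touches_a_correlated_metabolite(self):
        g = build_network(
            [self._edge()],
            [self._contrib(), self._contrib(strain="other", share=0.0)],
        )
        for a, b, data in g.edges(data=True):
            if data["type"] == "production":
                met = a if g.nodes[a]["type"] == "metabolite" else b
                corr = [d for _, _, d in g.edges(met, data=True)
                        if d["type"] == "correlation"]
                assert corr
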