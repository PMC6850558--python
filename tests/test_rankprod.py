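"""Rank-product statistic, permutation null, FDR and significance calls.

The permutation machinery is checked against an independent brute-force
oracle that enumerates every equiprobable combination of per-pair ranks.
"""

import math
from itertools import product

import numpy as np
import pandas as pd
import pytest

from splicerank.rankprod import (
    Contrast,
    bh_fdr,
    call_significant,
    delta_pir_pairs,
    permutation_p,
    rank_product,
    relabel_p,
    rescue_scatter,
    analyze_contrast,
)

from conftest import inclusion_table


def oracle_exhaustive_p(rp_values, n_events, n_pairs):
    """Brute force: every rank combination is equiprobable under the
    independent-permutation null."""
    null = [
        math.prod(ranks) ** (1.0 / n_pairs)
        for ranks in product(range(1, n_events + 1), repeat=n_pairs)
    ]
    total = len(null)
    return [sum(nv <= rp + 1e-12 for nv in null) / total for rp in rp_values]


class TestDeltaPairs:
    def test_all_cross_condition_pairs(self):
        table = inclusion_table(
            {"ev1": {"a1": 0.5, "a2": 0.6, "b1": 0.2, "b2": 0.3}}
        )
        dm = delta_pir_pairs(table, Contrast(["a1", "a2"], ["b1", "b2"]))
        assert sorted(np.round(dm.delta[0], 6)) == [0.2, 0.3, 0.3, 0.4]
        assert dm.delta[0].mean() == pytest.approx(0.3)

    def test_identical_groups_give_zero_deltas(self):
        table = inclusion_table({"ev1": {"a1": 0.4, "b1": 0.4, "a2": 0.4, "b2": 0.4}})
        dm = delta_pir_pairs(table, Contrast(["a1", "a2"], ["b1", "b2"]))
        assert np.allclose(dm.delta, 0.0)

    def test_single_replicate_pair(self):
        table = inclusion_table({"ev1": {"a1": 0.9, "b1": 0.2}})
        dm = delta_pir_pairs(table, Contrast(["a1"], ["b1"]))
        assert dm.delta.shape == (1, 1)
        assert dm.delta[0, 0] == pytest.approx(0.7)

    def test_missing_sample_named_in_error(self):
        table = inclusion_table({"ev1": {"a1": 0.5, "b1": 0.5}})
        with pytest.raises(ValueError, match="b9"):
            delta_pir_pairs(table, Contrast(["a1"], ["b9"]))

    def test_undefined_values_drop_event_and_report_it(self):
        table = inclusion_table(
            {
                "ev1": {"a1": float("nan"), "b1": 0.5},
                "ev2": {"a1": 0.2, "b1": 0.1},
            }
        )
        dm = delta_pir_pairs(table, Contrast(["a1"], ["b1"]))
        assert dm.event_ids == ["ev2"]
        assert dm.dropped_events == ["ev1"]

    def test_disjoint_groups_required(self):
        with pytest.raises(ValueError, match="disjoint"):
            Contrast(["a1"], ["a1"])


class TestRankProduct:
    def test_extreme_ranks(self):
        # event 0 largest delta in both pairs; event 2 smallest
        delta = np.array([[0.9, 0.8], [0.5, 0.4], [0.1, 0.0]])
        rp = rank_product(delta, "increased")
        assert rp[0] == pytest.approx(1.0)
        assert rp[2] == pytest.approx(3.0)

    def test_geometric_mean_of_ranks(self):
        # 8 events; target event ranked 2nd in pair 1 and 8th in pair 2
        delta = np.zeros((8, 2))
        delta[:, 0] = [0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2]
        delta[:, 1] = [0.9, 0.1, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3]
        rp = rank_product(delta, "increased")
        assert rp[1] == pytest.approx(math.sqrt(2 * 8))  # ranks (2, 8) -> 4

    def test_direction_flip_reverses_ranks(self):
        delta = np.array([[0.9, 0.8], [0.1, 0.0]])
        assert rank_product(delta, "decreased")[0] == pytest.approx(2.0)

    def test_ties_get_average_ranks(self):
        delta = np.array([[0.5, 0.5], [0.5, 0.5]])
        assert np.allclose(rank_product(delta, "increased"), 1.5)


class TestPermutationP:
    def test_exhaustive_matches_brute_force_enumeration(self):
        n_events, n_pairs = 3, 2
        rp = np.array([1.0, math.sqrt(2), 3.0])
        p = permutation_p(rp, n_events, n_pairs, n_perm=1)
        assert list(p) == pytest.approx(oracle_exhaustive_p(rp, n_events, n_pairs))
        assert p[0] == pytest.approx(1 / 9)  # both null ranks = 1

    @pytest.mark.parametrize("n_events", [4, 5, 6])
    def test_exhaustive_oracle_across_catalog_sizes(self, n_events):
        rng = np.random.default_rng(n_events)
        delta = rng.uniform(-1, 1, size=(n_events, 2))
        rp = rank_product(delta, "increased")
        p = permutation_p(rp, n_events, 2, n_perm=1)
        assert list(p) == pytest.approx(oracle_exhaustive_p(rp, n_events, 2))

    def test_worst_rank_product_has_p_one(self):
        p = permutation_p(np.array([4.0]), 4, 2, n_perm=1)
        assert p[0] == pytest.approx(1.0)

    def test_monte_carlo_agrees_with_exhaustive_within_3_se(self):
        n_events, n_pairs, n_perm = 6, 2, 10_000
        rng = np.random.default_rng(5)
        delta = rng.uniform(-1, 1, size=(n_events, n_pairs))
        rp = rank_product(delta, "increased")
        exact = np.array(oracle_exhaustive_p(rp, n_events, n_pairs))
        mc = permutation_p(
            rp, n_events, n_pairs, n_perm=n_perm, seed=11, exhaustive_bound=1
        )
        se = np.sqrt(exact * (1 - exact) / (n_events * n_perm))
        assert np.all(np.abs(mc - exact) <= 3 * se + 1 / (n_events * n_perm))

    def test_p_monotone_in_rank_product(self):
        rng = np.random.default_rng(7)
        delta = rng.uniform(-1, 1, size=(50, 3))
        rp = rank_product(delta, "increased")
        p = permutation_p(rp, 50, 3, n_perm=50, seed=1, exhaustive_bound=1)
        order = np.argsort(rp)
        assert np.all(np.diff(p[order]) >= 0)

    def test_invalid_n_perm_rejected(self):
        with pytest.raises(ValueError, match="n_perm"):
            permutation_p(np.array([1.0]), 10, 2, n_perm=0, exhaustive_bound=1)


class TestBhFdr:
    def test_hand_computed_step_up(self):
        assert list(bh_fdr(np.array([0.01, 0.02, 0.03]))) == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    def test_all_ones_stay_one(self):
        assert list(bh_fdr(np.ones(5))) == pytest.approx([1.0] * 5)

    def test_single_p_unchanged(self):
        assert bh_fdr(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=100)
        fdr = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(fdr[order]) >= -1e-12)
        assert np.all(fdr >= p)


class TestSignificanceCall:
    def _frame(self, p, fdr, mean_delta, direction="increased"):
        return pd.DataFrame(
            {
                "event_id": ["ev"],
                "direction": [direction],
                "mean_delta": [mean_delta],
                "rp": [1.0],
                "p": [p],
                "fdr": [fdr],
            }
        )

    def test_thresholds_jointly_required(self):
        assert call_significant(self._frame(1e-4, 0.01, 0.39))["significant"].iloc[0]
        assert not call_significant(self._frame(1e-4, 0.01, 0.05))["significant"].iloc[0]
        assert not call_significant(self._frame(0.01, 0.01, 0.39))["significant"].iloc[0]

    def test_sign_must_match_direction(self):
        frame = self._frame(1e-4, 0.01, -0.39, direction="increased")
        assert not call_significant(frame)["significant"].iloc[0]
        frame = self._frame(1e-4, 0.01, -0.39, direction="decreased")
        assert call_significant(frame)["significant"].iloc[0]


class TestContrastSymmetry:
    def test_group_swap_with_direction_flip_is_identity(self, rng):
        samples_a, samples_b = ["a1", "a2", "a3"], ["b1", "b2", "b3"]
        values = {
            f"ev{i}": {s: float(rng.uniform(0, 1)) for s in samples_a + samples_b}
            for i in range(40)
        }
        table = inclusion_table(values)
        fwd = analyze_contrast(
            table, Contrast(samples_a, samples_b), directions=("increased",),
            n_perm=40, seed=9,
        )
        rev = analyze_contrast(
            table, Contrast(samples_b, samples_a), directions=("decreased",),
            n_perm=40, seed=9,
        )
        fwd = fwd.sort_values("event_id", ignore_index=True)
        rev = rev.sort_values("event_id", ignore_index=True)
        assert np.allclose(fwd["rp"], rev["rp"])
        assert np.allclose(fwd["p"], rev["p"])
        assert np.allclose(fwd["mean_delta"], -rev["mean_delta"])

    def test_relabel_null_matches_rank_null_direction_symmetry(self, rng):
        samples = ["a1", "a2", "b1", "b2"]
        table = inclusion_table(
            {f"ev{i}": {s: float(rng.uniform(0, 1)) for s in samples} for i in range(30)}
        )
        dm = delta_pir_pairs(table, Contrast(["a1", "a2"], ["b1", "b2"]))
        p_inc = relabel_p(dm, "increased", n_perm=10, seed=2)
        assert np.all((p_inc > 0) & (p_inc <= 1))


class TestRescueScatter:
    def _results(self, entries):
        rows = [
            {
                "event_id": eid,
                "direction": d,
                "mean_delta": md,
                "rp": 1.0,
                "p": 1e-4 if sig else 0.5,
                "fdr": 0.01 if sig else 0.9,
                "significant": sig,
            }
            for eid, d, md, sig in entries
        ]
        return pd.DataFrame(rows)

    def test_opposite_direction_significance_is_rescue(self):
        res1 = self._results([("ev1", "increased", 0.3, True)])
        res2 = self._results([("ev1", "decreased", -0.3, True)])
        out = rescue_scatter(res1, res2)
        assert out.iloc[0]["rescued"]
        assert out.iloc[0]["delta_2"] == pytest.approx(-0.3)

    def test_significant_in_first_contrast_only_is_not_rescued(self):
        res1 = self._results([("ev1", "increased", 0.3, True)])
        res2 = self._results([("ev1", "decreased", -0.02, False)])
        assert not rescue_scatter(res1, res2).iloc[0]["rescued"]

    def test_empty_significant_set_gives_empty_report(self):
        res1 = self._results([("ev1", "increased", 0.02, False)])
        res2 = self._results([("ev1", "decreased", -0.3, True)])
        assert rescue_scatter(res1, res2).empty
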