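"""Tests for interaction extraction, mechanism classification, the
correlation baseline, benchmark scoring and overlap counting."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcadet import (
    SimConfig,
    classify_mechanism,
    correlation_baseline,
    extract_interactions,
    f1_score,
    from_blocks,
    overlap_counts,
    pair_auroc,
    score_predictions,
    simulate,
    two_proportion_z,
)


def triple(pi, n_mirna, n_mrna):
    return (
        pi,
        [f"miR_{k}" for k in range(n_mirna)],
        [f"g{o:03d}" for o in range(n_mrna)],
    )


class TestExtractInteractions:
    def test_top_five_percent_of_100_keeps_five(self):
        rng = np.random.default_rng(0)
        pi = rng.normal(0, 1, (100, 3))
        table = extract_interactions(triple(pi, 3, 100), quantile=0.05)
        kept = table.table.groupby("mirna_id")["kept"].sum()
        assert (kept == 5).all()

    def test_all_zero_column_keeps_lexicographic_first(self):
        pi = np.zeros((10, 1))
        table = extract_interactions(triple(pi, 1, 10), quantile=0.3)
        kept = sorted(
            table.table[table.table["kept"]]["mrna_id"]
        )
        assert kept == ["g000", "g001", "g002"]

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(4)
        pi = rng.normal(0, 2, (37, 5))
        mrna_ids = [f"g{o:03d}" for o in range(37)]
        table = extract_interactions(triple(pi, 5, 37), quantile=0.1)
        n_keep = int(np.ceil(0.1 * 37))
        for k in range(5):
            expect = {
                m for _, m in sorted(
                    ((-abs(pi[o, k]), mrna_ids[o]) for o in range(37))
                )[:n_keep]
            }
            got = set(
                table.table[
                    (table.table["mirna_id"] == f"miR_{k}")
                    & table.table["kept"]
                ]["mrna_id"]
            )
            assert got == expect

    def test_invalid_quantile_rejected(self):
        with pytest.raises(ValueError):
            extract_interactions(triple(np.zeros((4, 2)), 2, 4), quantile=0.0)


class TestClassifyMechanism:
    def test_zero_model_is_none(self, small_fit):
        res, data, _ = small_fit
        res.bottom.W[:] = 0.0
        res.bottom.Pi[:] = 0.0
        if res.autoencoder is not None:
            res.autoencoder.Pi[:] = 0.0
        out = classify_mechanism(
            res, data.mirna_ids[0], data.mrna_ids[0],
            causal_threshold=0.5, loading_threshold=0.5,
        )
        assert out == "none"

    def test_strong_pi_is_causal(self, small_fit):
        res, data, _ = small_fit
        res.bottom.W[:] = 0.0
        pi = res.pi
        pi[:] = 0.0
        pi[0, 0] = -3.0
        out = classify_mechanism(
            res, data.mirna_ids[0], data.mrna_ids[0],
            causal_threshold=1.0, loading_threshold=0.5,
        )
        assert out == "causal"

    def test_shared_hidden_loading_is_confounded(self, small_fit):
        res, data, _ = small_fit
        res.bottom.W[:] = 0.0
        res.pi[:] = 0.0
        n_mrna = res.bottom.n_mrna
        res.bottom.W[0, 2] = 2.0  # mRNA row
        res.bottom.W[n_mrna + 0, 2] = 2.0  # miRNA row, same hidden unit
        out = classify_mechanism(
            res, data.mirna_ids[0], data.mrna_ids[0],
            causal_threshold=1.0, loading_threshold=1.0,
        )
        assert out == "confounded"

    def test_end_to_end_separates_causal_from_confounded(self):
        """On the default planted scenario, every planted edge classifies
        as causal (or both), while shared-regulator pairs almost never
        earn the causal label — and earn the confounded label more often
        than the causal one."""
        from mcadet import MCadet
        from mcadet.benchmark import (
            scenario_architecture,
            scenario_train_config,
        )
        data, truth = simulate(SimConfig(seed=0))
        res = MCadet(data, scenario_architecture()).fit(
            scenario_train_config(10_000)
        )
        table = extract_interactions(res)
        causal_calls = [
            classify_mechanism(res, m, t, interactions=table)
            for m, t, _ in truth.causal_edges
        ]
        assert all(c in ("causal", "both") for c in causal_calls)
        conf_calls = [
            classify_mechanism(res, m, t, interactions=table)
            for m, t in truth.confounded_pairs
        ]
        n = len(conf_calls)
        causal_rate = sum(
            c in ("causal", "both") for c in conf_calls
        ) / n
        confounded_rate = sum(
            c in ("confounded", "both") for c in conf_calls
        ) / n
        assert causal_rate < 0.5  # majority of confounded pairs: no edge
        assert confounded_rate > causal_rate

    def test_unknown_ids_raise_key_error(self, small_fit):
        res, data, _ = small_fit
        with pytest.raises(KeyError):
            classify_mechanism(res, "nope", data.mrna_ids[0])
        with pytest.raises(KeyError):
            classify_mechanism(res, data.mirna_ids[0], "nope")


class TestCorrelationBaseline:
    def toy(self, x_col, y_col):
        x = np.asarray(x_col).reshape(-1, 1)
        y = np.asarray(y_col).reshape(-1, 1)
        n = len(x)
        return from_blocks(
            y, x, [f"s{i}" for i in range(n)], ["gA"], ["miR-1"],
        )

    def test_perfect_anticorrelation_retained_with_negative_slope(self):
        x = [0, 1] * 5
        y = [1 - v for v in x]
        out = correlation_baseline(self.toy(x, y), alpha=0.05)
        row = out.iloc[0]
        assert row["p"] < 1e-8
        assert row["slope"] < 0
        assert bool(row["retained"])

    def test_identical_feature_has_unit_slope(self):
        x = [0, 1, 1, 0, 1, 0, 0, 1, 1, 0]
        out = correlation_baseline(self.toy(x, x))
        assert out.iloc[0]["slope"] == pytest.approx(1.0)

    def test_constant_feature_skipped(self):
        out = correlation_baseline(self.toy([1] * 10, [0, 1] * 5))
        assert len(out) == 0

    def test_false_positive_rate_controlled_on_independent_noise(self):
        # 50 replicates of 10x10 independent-noise pairs at alpha 0.05:
        # BH keeps the expected retained fraction at or below ~alpha
        rates = []
        for rep in range(50):
            rng = np.random.default_rng(1000 + rep)
            data = from_blocks(
                (rng.random((30, 10)) < 0.4).astype(int),
                (rng.random((30, 10)) < 0.4).astype(int),
                [f"s{i}" for i in range(30)],
                [f"g{i}" for i in range(10)],
                [f"m{i}" for i in range(10)],
            )
            out = correlation_baseline(data, alpha=0.05)
            rates.append(out["retained"].mean())
        assert np.mean(rates) <= 0.06

    def test_alpha_limits(self, small_data):
        data, _ = small_data
        none = correlation_baseline(data, alpha=1e-300)
        assert not none["retained"].any()
        all_ = correlation_baseline(data, alpha=1.0)
        assert all_["retained"].all()

    def test_requires_three_samples(self):
        with pytest.raises(ValueError):
            correlation_baseline(self.toy([0, 1], [1, 0]))


class TestScorePredictions:
    def test_perfect_prediction(self):
        gold = {("m1", "g1"), ("m2", "g2")}
        rep = score_predictions(gold, gold)
        assert rep.recall == rep.ppv == rep.f1 == 1.0
        assert rep.tp == 2 and rep.fp == 0 and rep.fn == 0

    def test_counts(self):
        pred = {("m1", "g1"), ("m1", "g2")}
        gold = {("m1", "g1"), ("m2", "g3")}
        rep = score_predictions(pred, gold)
        assert (rep.tp, rep.fp, rep.fn) == (1, 1, 1)
        assert rep.recall == 0.5 and rep.ppv == 0.5

    def test_zero_denominators_flagged(self):
        rep = score_predictions(set(), set())
        assert rep.recall == rep.ppv == rep.f1 == 0.0
        assert set(rep.undefined) == {"recall", "ppv", "f1"}

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.01, 1.0), st.floats(0.01, 1.0))
    def test_f1_is_harmonic_mean(self, recall, ppv):
        f1 = f1_score(recall, ppv)
        assert min(recall, ppv) - 1e-12 <= f1 <= max(recall, ppv) + 1e-12


class TestTwoProportionZ:
    def test_equal_proportions_give_zero(self):
        z, p = two_proportion_z(0.3, 50, 0.3, 80)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_antisymmetric_under_group_swap(self):
        z1, _ = two_proportion_z(0.5, 100, 0.25, 100)
        z2, _ = two_proportion_z(0.25, 100, 0.5, 100)
        assert z1 == pytest.approx(-z2)

    def test_reference_value(self):
        # pooled p = 0.375, se = sqrt(0.375*0.625*(2/100)), z = 0.25/se
        z, p = two_proportion_z(0.5, 100, 0.25, 100)
        assert z == pytest.approx(3.6515, abs=5e-4)
        assert p < 0.001

    def test_degenerate_pool_handled(self):
        # pooled proportion 0 or 1 implies both groups agree: z = 0, not NaN
        for p_common in (0.0, 1.0):
            z, p = two_proportion_z(p_common, 10, p_common, 25)
            assert z == 0.0 and p == pytest.approx(1.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_z(1.2, 10, 0.5, 10)
        with pytest.raises(ValueError):
            two_proportion_z(0.5, 0, 0.5, 10)


class TestOverlapCounts:
    def test_two_disjoint_sets(self):
        out = overlap_counts({"A": {"a"}, "B": {"b"}})
        assert out[("A",)] == 1
        assert out[("B",)] == 1
        assert out[("A", "B")] == 0

    def test_identical_sets_concentrate_in_intersection(self):
        s = {1, 2, 3}
        out = overlap_counts({"A": set(s), "B": set(s)})
        assert out[("A", "B")] == 3
        assert out[("A",)] == out[("B",)] == 0

    def test_regions_sum_to_union_and_match_bitmask_oracle(self):
        rng = np.random.default_rng(12)
        names = ["w", "x", "y", "z"]
        sets = {
            n: set(rng.choice(40, size=rng.integers(5, 25), replace=False))
            for n in names
        }
        out = overlap_counts(sets)
        assert sum(out.values()) == len(set.union(*sets.values()))
        # independent bitmask enumeration
        for membership in itertools.product((False, True), repeat=4):
            if not any(membership):
                continue
            count = sum(
                1 for e in set.union(*sets.values())
                if all((e in sets[n]) == m
                       for n, m in zip(names, membership))
            )
            key = tuple(n for n, m in zip(sorted(names), membership))
            # regions are keyed by sorted name tuples
            key = tuple(sorted(
                n for n, m in zip(names, membership) if m
            ))
            assert out[key] == count

    def test_single_set_rejected(self):
        with pytest.raises(ValueError):
            overlap_counts({"A": {1}})


class TestPairAuroc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.1, 0.2])
        labels = np.array([True, True, False, False])
        assert pair_auroc(scores, labels) == 1.0

    def test_needs_both_classes(self):
        with pytest.raises(ValueError):
            pair_auroc(np.array([1.0, 2.0]), np.array([True, True]))
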