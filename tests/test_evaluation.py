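"""Metrics and downstream analyses against hand and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from gecsi import BinnedGenome, IntervalSet, SoftAnnotation, StateAnnotation, StateGrouping
from gecsi.evaluation import (
    accuracy,
    auprc,
    auroc,
    calibration_all_states,
    calibration_curve,
    calibration_from_pairs,
    composition_by_probability,
    f1_per_state,
    fold_enrichment,
    fold_enrichment_soft,
    genome_fraction,
    group_mismatch_analysis,
    group_summary,
    jaccard_per_state,
    mean_signal_per_state,
    mean_state_sizes,
    pairwise_agreement,
    pairwise_relationships,
    weighted_state_average,
)

ALPHA3 = ("1_TssA", "2_TssFlnk", "3_TssFlnkU")


def _genome(n_bins):
    return BinnedGenome(("chr1",), (n_bins * 200,), bin_size=200)


def _ann(states, sid="s", alphabet=ALPHA3):
    states = np.asarray(states, dtype=np.int16)
    return StateAnnotation(sid, states, _genome(len(states)), alphabet)


# --- independent oracles ----------------------------------------------------


def auprc_oracle(scores, labels):
    """Literal evaluation of the stepwise-interpolation area formula over
    all unique thresholds, by explicit loops."""
    thresholds = sorted(set(scores), reverse=True)
    area, prev_recall = 0.0, 0.0
    P = sum(labels)
    for t in thresholds:
        tp = sum(1 for s, y in zip(scores, labels) if s >= t and y)
        npred = sum(1 for s in scores if s >= t)
        precision = tp / npred
        recall = tp / P
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def auroc_oracle(scores, labels):
    """P(score_pos > score_neg) + 0.5 P(equal), by explicit pair loops."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRankingMetrics:
    def test_perfect_separation(self):
        assert auprc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == pytest.approx(1.0)
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_constant_scores_give_prevalence(self):
        assert auprc([0.5] * 10, [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]) == pytest.approx(0.3)

    def test_reversed_ranking_gives_zero_auroc(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0]) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracles(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 40))
        scores = np.round(rng.random(n), 2)  # duplicates likely
        labels = rng.random(n) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        assert auprc(scores, labels) == pytest.approx(
            auprc_oracle(list(scores), list(labels)), abs=1e-12
        )
        assert auroc(scores, labels) == pytest.approx(
            auroc_oracle(list(scores), list(labels)), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auprc([0.1, 0.2], [1, 1])
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [0, 0])


class TestHardMetrics:
    def test_accuracy_hand_counts(self):
        assert accuracy(_ann([0, 1, 2, 0, 1]), _ann([0, 1, 2, 0, 2])) == pytest.approx(0.8)
        assert accuracy(_ann([0, 1]), _ann([0, 1])) == 1.0
        assert accuracy(_ann([0, 0]), _ann([1, 1])) == 0.0

    def test_accuracy_ignores_missing(self):
        assert accuracy(_ann([0, -1, 1]), _ann([0, 1, -1])) == 1.0

    def test_jaccard_f1_sliding_window(self):
        # state 0 on bins 0..9 predicted, 5..14 observed, filler elsewhere
        pred = np.full(20, 1)
        obs = np.full(20, 1)
        pred[0:10] = 0
        obs[5:15] = 0
        jac = jaccard_per_state(_ann(pred), _ann(obs))
        f1 = f1_per_state(_ann(pred), _ann(obs))
        assert jac[0] == pytest.approx(5 / 15)
        assert f1[0] == pytest.approx(0.5)
        assert np.isnan(jac[2]) and np.isnan(f1[2])  # state absent from both

    def test_state_in_obs_only_scores_zero(self):
        jac = jaccard_per_state(_ann([0, 0]), _ann([0, 1]))
        f1 = f1_per_state(_ann([0, 0]), _ann([0, 1]))
        assert jac[1] == 0.0 and f1[1] == 0.0

    def test_identical_tracks_score_one_everywhere_defined(self):
        ann = _ann([0, 1, 1, 2, 0])
        jac = jaccard_per_state(ann, ann)
        assert np.nanmin(jac) == 1.0

    def test_weighted_average(self):
        assert weighted_state_average([1.0, 0.0], [3.0, 1.0]) == pytest.approx(0.75)
        assert weighted_state_average([0.2, 0.8], [1.0, 1.0]) == pytest.approx(0.5)
        assert weighted_state_average([0.4, 0.4, 0.4], [1, 5, 2]) == pytest.approx(0.4)
        with pytest.raises(ValueError):
            weighted_state_average([1.0], [0.0])

    def test_weighted_average_renormalizes_over_defined(self):
        # NaN state's weight is dropped
        assert weighted_state_average([1.0, np.nan, 0.0], [2, 100, 2]) == pytest.approx(0.5)

    def test_mean_state_sizes(self):
        sizes = mean_state_sizes([_ann([0, 0, 1]), _ann([0, 1, 1])])
        np.testing.assert_allclose(sizes, [1.5, 1.5, 0.0])

    def test_genome_fraction_hand_counts(self):
        frac = genome_fraction(_ann([0, 0, 0, 1, 1, 2, 2, 2, 2, 2]))
        np.testing.assert_allclose(frac, [0.3, 0.2, 0.5])
        rng = np.random.default_rng(0)
        soft = rng.dirichlet(np.ones(4), 50)
        assert genome_fraction(soft).sum() == pytest.approx(1.0)


class TestCalibration:
    def test_perfectly_calibrated_constant_bins(self):
        # predictions exactly equal to per-bin empirical frequencies
        probs = np.repeat([0.1, 0.5, 0.9], 200)
        rng = np.random.default_rng(0)
        matched = np.concatenate(
            [np.r_[np.ones(20), np.zeros(180)],
             np.r_[np.ones(100), np.zeros(100)],
             np.r_[np.ones(180), np.zeros(20)]]
        )
        curve = calibration_from_pairs(probs, matched, n_bins=50)
        assert curve.pearson_r == pytest.approx(1.0)
        np.testing.assert_allclose(
            curve.observed_frequency[curve.nonempty], [0.1, 0.5, 0.9]
        )

    def test_labels_drawn_from_predictions_are_calibrated(self):
        rng = np.random.default_rng(1)
        n = 100_000
        probs = rng.random(n)  # every bin well populated
        matched = rng.random(n) < probs
        curve = calibration_from_pairs(probs, matched, n_bins=50)
        assert curve.pearson_r >= 0.99

    def test_single_occupied_bin_is_flagged(self):
        curve = calibration_from_pairs(np.full(10, 0.5), np.ones(10), n_bins=50)
        assert np.isnan(curve.pearson_r)

    def test_per_state_curve_uses_state_indicator(self):
        obs = _ann([0, 0, 1, 1])
        probs = np.array(
            [[0.9, 0.1, 0.0], [0.8, 0.2, 0.0], [0.1, 0.9, 0.0], [0.2, 0.8, 0.0]]
        )
        g = obs.genome
        soft = SoftAnnotation("q", probs, g, ALPHA3)
        curve = calibration_curve(soft, obs, state=0, n_bins=10)
        occupied = np.flatnonzero(curve.nonempty)
        np.testing.assert_array_equal(occupied, [1, 2, 8, 9])
        np.testing.assert_allclose(
            curve.observed_frequency[occupied], [0.0, 0.0, 1.0, 1.0]
        )

    def test_pooled_curve_covers_all_states(self):
        rng = np.random.default_rng(2)
        n = 5000
        probs = rng.dirichlet(np.ones(3), n)
        cdf = probs.cumsum(axis=1)
        obs_codes = (rng.random(n)[:, None] > cdf).sum(axis=1).astype(np.int16)
        curve = calibration_all_states(probs, obs_codes, n_bins=20)
        assert curve.pearson_r > 0.95


class TestComposition:
    def test_one_hot_soft_gives_pure_bins(self):
        rng = np.random.default_rng(0)
        codes = rng.integers(0, 3, 500).astype(np.int16)
        probs = np.eye(3)[codes]
        comp = composition_by_probability(
            probs, codes, state=0,
            grouping=StateGrouping({"a": (0, 1), "b": (2,)}, n_states=3),
            n_bins=10, min_count=20,
        )
        # positions in the top bin are all truly state 0
        top = np.argmax(comp.bin_centers)
        assert comp.composition[top, 0] == pytest.approx(1.0)

    def test_low_count_bins_dropped(self):
        p = np.linspace(0, 1, 300) ** 2  # sparse high-probability bins
        probs = np.column_stack([p, 1 - p])
        codes = np.zeros(300, dtype=np.int16)
        comp = composition_by_probability(
            probs, codes, state=0,
            grouping=StateGrouping({"a": (0,), "b": (1,)}, n_states=2),
            n_bins=30, min_count=8,
        )
        assert (comp.counts >= 8).all()
        assert len(comp.counts) < 30  # boundary bins fell below the floor

    def test_group_mates_rise_with_probability_gives_positive_r(self):
        # when state 0's probability is high, wrong positions are mostly its
        # group-mate state 1; when low, mostly out-of-group state 2
        rng = np.random.default_rng(3)
        n = 20_000
        p0 = rng.random(n)
        codes = np.where(
            rng.random(n) < p0, 1, 2  # all "incorrect" for state 0
        ).astype(np.int16)
        probs = np.column_stack([p0, (1 - p0) / 2, (1 - p0) / 2])
        comp = composition_by_probability(
            probs, codes, state=0,
            grouping=StateGrouping({"a": (0, 1), "b": (2,)}, n_states=3),
            n_bins=20, min_count=50,
        )
        assert comp.group_fraction_r > 0.9


class TestGroupMismatch:
    def test_all_mismatches_within_group(self):
        grouping = StateGrouping({"a": (0, 1), "b": (2,)}, n_states=3)
        res = group_mismatch_analysis(
            _ann([0] * 10), _ann([1] * 10), grouping, variant="all"
        )
        assert res.observed_proportion == 1.0

    def test_two_state_single_group_degenerate(self):
        grouping = StateGrouping({"a": (0, 1)}, n_states=2)
        pred = _ann([0, 0, 1, 1], alphabet=ALPHA3[:2])
        obs = _ann([1, 0, 0, 1], alphabet=ALPHA3[:2])
        res = group_mismatch_analysis(pred, obs, grouping, variant="all",
                                      quiescent_state=1)
        assert res.observed_proportion == 1.0
        assert res.expected_proportion == pytest.approx(1.0)
        assert res.fold == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "variant", ["all", "exclude_pred_quiescent", "exclude_obs_quiescent"]
    )
    def test_expected_matches_sampling_oracle(self, variant):
        # 4-state toy, 2 groups; Monte-Carlo draw from the stated
        # distribution must agree with the analytic expectation within 3 SE
        rng = np.random.default_rng(4)
        alpha4 = ("1_TssA", "2_TssFlnk", "3_TssFlnkU", "4_TssFlnkD")
        grouping = StateGrouping({"a": (0, 1), "b": (2, 3)}, n_states=4)
        pred = _ann(rng.integers(0, 4, 2000), alphabet=alpha4)
        obs = _ann(rng.choice(4, 2000, p=[0.4, 0.3, 0.2, 0.1]), alphabet=alpha4)
        res = group_mismatch_analysis(pred, obs, grouping, variant=variant,
                                      quiescent_state=3)
        group_of = grouping.group_of
        p, o = pred.states, obs.states
        mism = p != o
        if variant == "exclude_pred_quiescent":
            mism &= p != 3
        elif variant == "exclude_obs_quiescent":
            mism &= o != 3
        pm = p[mism]
        if variant == "all":
            freq = np.bincount(o, minlength=4) / len(o)
        else:
            freq = np.bincount(o[mism], minlength=4) / mism.sum()
        n_draw = 400_000
        hits = []
        draw_rng = np.random.default_rng(5)
        # draw one state per mismatched position from the variant's law
        for chunk in np.array_split(pm, 10):
            if variant == "all":
                for ps in chunk:
                    f = freq.copy()
                    f[ps] = 0
                    f /= f.sum()
                    draws = draw_rng.choice(4, n_draw // len(pm) + 1, p=f)
                    hits.append(np.mean(group_of[draws] == group_of[ps]))
            else:
                draws = draw_rng.choice(4, n_draw // 10, p=freq)
                hits.extend(
                    np.mean(group_of[draws][None, :] == group_of[chunk][:, None], axis=1)
                )
        mc = float(np.mean(hits))
        se = np.sqrt(mc * (1 - mc) / n_draw)
        assert res.expected_proportion == pytest.approx(mc, abs=max(3 * se, 5e-3))

    def test_no_mismatches_flagged(self):
        with pytest.raises(ValueError, match="no mismatched"):
            group_mismatch_analysis(
                _ann([0, 1]), _ann([0, 1]),
                StateGrouping({"a": (0, 1), "b": (2,)}, n_states=3),
            )


class TestFoldEnrichment:
    def _intervals(self, spans, name="ann"):
        return IntervalSet(
            name,
            np.array(["chr1"] * len(spans), dtype=object),
            np.array([s for s, _ in spans]),
            np.array([e for _, e in spans]),
        )

    def test_whole_genome_annotation_gives_fold_one(self):
        ann = _ann([0, 1, 2, 0, 1])
        ivs = self._intervals([(0, 1000)])
        table = fold_enrichment(ann, ivs, min_state_coverage=0.0)
        np.testing.assert_allclose(table.fold, 1.0)

    def test_documented_toy_gives_fold_ten(self):
        # state 0 on 10 of 100 bins; annotation covers 5 of those bins
        states = np.full(100, 1, dtype=np.int16)
        states[0:10] = 0
        ann = _ann(states)
        ivs = self._intervals([(0, 1000)])  # bins 0..4
        table = fold_enrichment(ann, ivs, min_state_coverage=0.0)
        assert table.fold[0] == pytest.approx(10.0)

    def test_disjoint_state_and_annotation(self):
        states = np.full(100, 1, dtype=np.int16)
        states[0:10] = 0
        table = fold_enrichment(_ann(states), self._intervals([(5000, 6000)]),
                                min_state_coverage=0.0)
        assert table.fold[0] == 0.0

    def test_independence_gives_fold_near_one(self):
        rng = np.random.default_rng(5)
        n = 20_000
        states = rng.integers(0, 3, n).astype(np.int16)
        # random half of the genome annotated, independent of states
        ann_bins = np.sort(rng.choice(n, n // 2, replace=False))
        spans = [(int(b) * 200, int(b) * 200 + 200) for b in ann_bins]
        table = fold_enrichment(
            StateAnnotation("s", states, _genome(n), ALPHA3),
            self._intervals(spans),
        )
        p = 0.5
        for s in range(3):
            ns = (states == s).sum()
            se = np.sqrt(p * (1 - p) / (ns * p))  # rough SE on the ratio
            assert table.fold[s] == pytest.approx(1.0, abs=3 * se + 0.02)

    def test_coverage_floor_suppresses_rare_states(self):
        states = np.full(1000, 1, dtype=np.int16)
        states[0] = 0  # 0.1% coverage
        table = fold_enrichment(_ann(states), self._intervals([(0, 200)]),
                                min_state_coverage=0.01)
        assert np.isnan(table.fold[0])

    def test_soft_one_hot_reduces_to_hard(self):
        rng = np.random.default_rng(6)
        codes = rng.integers(0, 3, 400).astype(np.int16)
        ann = _ann(codes)
        soft = SoftAnnotation("s", np.eye(3)[codes], ann.genome, ALPHA3)
        ivs = self._intervals([(0, 20_000)])
        hard_table = fold_enrichment(ann, ivs, min_state_coverage=0.0)
        soft_table = fold_enrichment_soft(soft, ivs, min_state_coverage=0.0)
        np.testing.assert_allclose(soft_table.fold, hard_table.fold, atol=1e-12)

    def test_truncation_zeroes_and_renormalizes(self):
        probs = np.tile([0.04, 0.96, 0.0], (10, 1))
        soft = SoftAnnotation("s", probs, _genome(10), ALPHA3)
        table = fold_enrichment_soft(soft, self._intervals([(0, 400)]),
                                     floor=0.05, min_state_coverage=0.0)
        assert table.state_fraction[0] == 0.0
        assert table.state_fraction[1] == pytest.approx(1.0)

    def test_soft_matches_mass_counting_oracle(self):
        rng = np.random.default_rng(7)
        n = 300
        probs = rng.dirichlet(np.ones(3), n)
        soft = SoftAnnotation("s", probs, _genome(n), ALPHA3)
        spans = [(0, 200 * 60), (200 * 100, 200 * 140)]
        ivs = self._intervals(spans)
        table = fold_enrichment_soft(soft, ivs, floor=0.05, min_state_coverage=0.0)
        # oracle: explicit truncation + mass counting
        t = probs.copy()
        t[t < 0.05] = 0
        t /= t.sum(axis=1, keepdims=True)
        in_ann = np.zeros(n, bool)
        in_ann[:60] = True
        in_ann[100:140] = True
        for s in range(3):
            joint = t[in_ann, s].sum() / n
            expected = joint / ((t[:, s].sum() / n) * (in_ann.mean()))
            assert table.fold[s] == pytest.approx(expected, abs=1e-10)


class TestPairwiseRelationships:
    def test_identical_annotations(self):
        rng = np.random.default_rng(8)
        codes = rng.integers(0, 3, 100).astype(np.int16)
        g = _genome(100)
        tracks = {
            "a": StateAnnotation("a", codes, g, ALPHA3),
            "b": StateAnnotation("b", codes.copy(), g, ALPHA3),
        }
        agree = pairwise_relationships(tracks, "agreement")
        assert agree.loc["a", "b"] == 1.0
        binr = pairwise_relationships(tracks, "state_binary_pearson", state=0)
        assert binr.loc["a", "b"] == pytest.approx(1.0)

    def test_half_matching_toy(self):
        g = _genome(10)
        a = StateAnnotation("a", np.array([0] * 10, dtype=np.int16), g, ALPHA3)
        b = StateAnnotation("b", np.array([0] * 5 + [1] * 5, dtype=np.int16), g, ALPHA3)
        agree = pairwise_relationships({"a": a, "b": b}, "agreement")
        assert agree.loc["a", "b"] == pytest.approx(0.5)

    def test_symmetric_and_unit_diagonal(self):
        rng = np.random.default_rng(9)
        g = _genome(200)
        tracks = {
            f"s{i}": StateAnnotation(
                f"s{i}", rng.integers(0, 3, 200).astype(np.int16), g, ALPHA3
            )
            for i in range(4)
        }
        m = pairwise_relationships(tracks, "agreement").to_numpy()
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(m), 1.0)

    def test_soft_mode_and_zero_variance_flagged(self):
        g = _genome(50)
        rng = np.random.default_rng(10)
        p1 = rng.dirichlet(np.ones(3), 50)
        p2 = np.tile([0.2, 0.3, 0.5], (50, 1))  # zero variance per state
        tracks = {
            "a": SoftAnnotation("a", p1, g, ALPHA3),
            "b": SoftAnnotation("b", p2, g, ALPHA3),
        }
        m = pairwise_relationships(tracks, "state_soft_pearson", state=0)
        assert np.isnan(m.loc["a", "b"])


class TestGroupSummary:
    def _block_matrix(self):
        ids = ["a1", "a2", "b1", "b2"]
        m = np.full((4, 4), 0.1)
        m[:2, :2] = 0.9
        m[2:, 2:] = 0.9
        np.fill_diagonal(m, 1.0)
        return pd.DataFrame(m, index=ids, columns=ids), {
            "a1": "a", "a2": "a", "b1": "b", "b2": "b"
        }

    def test_block_structure_gives_auprc_one(self):
        matrix, groups = self._block_matrix()
        res = group_summary(matrix, groups)
        assert res.same_group_auprc == pytest.approx(1.0)
        assert res.within_mean == pytest.approx(0.9)
        assert res.between_mean == pytest.approx(0.1)
        assert res.difference == pytest.approx(0.8)

    def test_hand_means_on_asymmetric_values(self):
        ids = ["a1", "a2", "b1", "b2"]
        m = np.eye(4)
        vals = {(0, 1): 0.8, (2, 3): 0.6, (0, 2): 0.3, (0, 3): 0.1,
                (1, 2): 0.2, (1, 3): 0.4}
        for (i, j), v in vals.items():
            m[i, j] = m[j, i] = v
        res = group_summary(
            pd.DataFrame(m, index=ids, columns=ids),
            {"a1": "a", "a2": "a", "b1": "b", "b2": "b"},
        )
        assert res.within_mean == pytest.approx(0.7)
        assert res.between_mean == pytest.approx(0.25)

    def test_shuffled_labels_have_near_zero_difference_in_expectation(self):
        rng = np.random.default_rng(11)
        ids = [f"s{i}" for i in range(12)]
        m = rng.random((12, 12))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        df = pd.DataFrame(m, index=ids, columns=ids)
        diffs = []
        for _ in range(300):
            labels = rng.permutation([0] * 6 + [1] * 6)
            groups = {i: str(l) for i, l in zip(ids, labels)}
            diffs.append(group_summary(df, groups).difference)
        assert abs(np.mean(diffs)) < 0.02


class TestMeanSignal:
    def test_constant_signal_recovered(self):
        ann = _ann([0, 1, 2, 0, 1])
        vals = np.full(5, 0.8)
        cov = np.full(5, 10)
        out = mean_signal_per_state(ann, vals, cov)
        np.testing.assert_allclose(out, 0.8)

    def test_low_coverage_positions_excluded(self):
        ann = _ann([0, 0, 1])
        vals = np.array([0.2, 0.9, 0.5])
        cov = np.array([2, 5, 5])
        out = mean_signal_per_state(ann, vals, cov, min_coverage=3)
        assert out[0] == pytest.approx(0.9)  # the cov=2 position dropped

    def test_hand_two_state_average_and_undefined_state(self):
        ann = _ann([0, 0, 1, 1])
        vals = np.array([0.1, 0.3, 0.6, 1.0])
        cov = np.full(4, 3)
        out = mean_signal_per_state(ann, vals, cov)
        assert out[0] == pytest.approx(0.2)
        assert out[1] == pytest.approx(0.8)
        assert np.isnan(out[2])
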