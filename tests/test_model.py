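"""Core model factors against exact-arithmetic oracles; grouping; regularity;
classification properties."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleostates import (ModelParams, StateClassifier, classify_states,
                          default_state_rules, group_feature_table,
                          group_nucleosomes, histone_factor,
                          local_mean_spacing, positioning_factor,
                          regularity_score, similarity_ratio,
                          summarize_groups)


def nuc_table(dyads, scores, chrom="chr1", width=147):
    dyads = np.asarray(dyads)
    return pd.DataFrame({
        "chrom": chrom, "dyad": dyads, "start": dyads - 73,
        "end": dyads + 74, "score": np.asarray(scores, float),
        "width": width, "dop": 0.7,
    })


class TestPositioningFactor:
    def test_weight_off_identity(self):
        assert positioning_factor(300, 150, 0.0, 187, 402) == 2.0

    def test_hand_arithmetic(self):
        assert positioning_factor(300, 150, 0.01, 187, 180) == pytest.approx(
            2.07, abs=1e-12)

    def test_d_equals_mu_cancels_omega(self):
        for omega in (0.0, 0.005, 3.0):
            assert positioning_factor(10, 5, omega, 187, 187) == 2.0

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            positioning_factor(10, 0, 0.005, 187, 187)

    def test_matches_exact_fraction_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            S, W = rng.integers(1, 1000), rng.integers(1, 400)
            mu, d = rng.integers(0, 400), rng.integers(0, 400)
            om_num = rng.integers(0, 100)
            exact = Fraction(int(S), int(W)) + \
                Fraction(int(om_num), 1000) * (int(mu) - int(d))
            got = positioning_factor(S, W, om_num / 1000, mu, d)
            assert got == pytest.approx(float(exact), abs=1e-12)


class TestHistoneFactor:
    def test_all_marks_zero(self):
        assert histone_factor({"m1": 0, "m2": 0}, 3.0, {}) == 0.0

    def test_hand_arithmetic(self):
        assert histone_factor({"m": 2.0}, 3.0, {"m": 1.0}) == 6.0

    def test_homogeneous_in_weights(self):
        a = {"m1": 2.0, "m2": 0.5}
        w1 = {"m1": 1.0, "m2": 3.0}
        w2 = {k: 2 * v for k, v in w1.items()}
        assert histone_factor(a, 1.5, w2) == 2 * histone_factor(a, 1.5, w1)

    def test_negative_signal_rejected(self):
        with pytest.raises(ValueError):
            histone_factor({"m": -1.0}, 1.0, {})
        with pytest.raises(ValueError):
            histone_factor({"m": 1.0}, -2.0, {})

    def test_matches_exact_fraction_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            a = {f"m{k}": int(rng.integers(0, 50)) for k in range(4)}
            w = {f"m{k}": int(rng.integers(0, 10)) for k in range(4)}
            b = int(rng.integers(0, 20))
            exact = sum(Fraction(w[k]) * a[k] * b for k in a)
            assert histone_factor(a, b, w) == pytest.approx(float(exact),
                                                            abs=1e-12)


class TestSimilarityRatio:
    def test_equal_products_zero(self):
        assert similarity_ratio([3.5, 3.5]) == 0.0

    def test_hand_arithmetic_three(self):
        assert similarity_ratio([2, 2, 1]) == pytest.approx(0.25, abs=1e-12)

    def test_hand_arithmetic_two(self):
        assert similarity_ratio([4, 2]) == pytest.approx(0.5, abs=1e-12)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            similarity_ratio([0.0, 1.0])

    def test_matches_exact_fraction_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            n = rng.integers(2, 8)
            p = rng.integers(1, 100, n)
            exact = Fraction(int(p[-2]) - int(p[-1]), int(p[:-1].sum()))
            assert similarity_ratio(p) == pytest.approx(float(exact),
                                                        abs=1e-12)


class TestGrouping:
    def test_identical_products_one_group(self):
        nucs = nuc_table(np.arange(5) * 187 + 1000, [300] * 5)
        grouped = group_nucleosomes(nucs)
        assert grouped["group_id"].nunique() == 1

    def test_gamma_above_threshold_splits(self):
        # products (2, 2, 1): gamma at the third nucleosome is 0.25 >= 0.10
        nucs = nuc_table([1000, 1187, 1374], [294, 294, 147])
        grouped = group_nucleosomes(nucs, params=ModelParams(omega=0.0))
        gids = grouped["group_id"].to_numpy()
        assert gids[0] == gids[1]
        assert gids[2] != gids[1]

    def test_distant_arrays_never_merge(self):
        dyads = np.concatenate([np.arange(3) * 187 + 1000,
                                np.arange(3) * 187 + 6000])
        nucs = nuc_table(dyads, [300] * 6)
        grouped = group_nucleosomes(nucs)
        assert grouped["group_id"].nunique() == 2

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_grouping_partitions_input(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 40))
        dyads = np.cumsum(rng.integers(150, 500, n)) + 500
        nucs = nuc_table(dyads, rng.integers(50, 500, n))
        grouped = group_nucleosomes(nucs)
        assert len(grouped) == n
        assert set(grouped["dyad"]) == set(dyads)
        # group ids are contiguous runs along the chromosome
        gids = grouped.sort_values("dyad")["group_id"].to_numpy()
        changes = np.nonzero(np.diff(gids))[0]
        assert (np.diff(gids) >= 0).all()
        assert len(set(gids)) == len(changes) + 1

    def test_score_scaling_invariance_with_omega_zero(self):
        rng = np.random.default_rng(3)
        dyads = np.cumsum(rng.integers(150, 400, 30)) + 500
        scores = rng.integers(100, 600, 30)
        params = ModelParams(omega=0.0)
        g1 = group_nucleosomes(nuc_table(dyads, scores), params=params)
        g2 = group_nucleosomes(nuc_table(dyads, scores * 7.3), params=params)
        assert (g1["group_id"].to_numpy() == g2["group_id"].to_numpy()).all()


class TestLocalMeanSpacing:
    def test_uniform_array(self):
        dyads = np.arange(20) * 187
        mu = local_mean_spacing(dyads)
        assert mu == pytest.approx(187.0)

    def test_desert_gaps_excluded(self):
        dyads = np.concatenate([np.arange(5) * 180,
                                np.arange(5) * 180 + 5000])
        mu = local_mean_spacing(dyads, window=2000)
        assert mu == pytest.approx(180.0)


class TestRegularity:
    def test_noise_reduces_cosine_score(self):
        x = np.arange(2000)
        clean = 100 + 50 * np.cos(2 * np.pi * x / 187)
        noisy = clean + np.random.default_rng(0).normal(0, 50, x.size)
        assert regularity_score(clean, 187) > regularity_score(noisy, 187)

    def test_score_decreases_with_dyad_jitter(self):
        def score(jitter, seed):
            rng = np.random.default_rng(seed)
            dyads = np.arange(10) * 187.0
            if jitter:
                dyads = dyads + rng.normal(0, jitter, 10)
            mids = np.repeat(dyads, 150) + rng.normal(0, 20, 1500)
            lo = int(mids.min()) - 100
            counts = np.bincount((mids - lo).astype(int)).astype(float)
            return regularity_score(counts, 187)
        means = [np.mean([score(j, s) for s in range(20)])
                 for j in (0, 10, 30)]
        assert means[0] > means[1] > means[2]

    def test_white_noise_scores_near_one(self):
        scores = [regularity_score(
            np.random.default_rng(s).normal(0, 1, 2048), 187)
            for s in range(50)]
        assert np.mean(scores) == pytest.approx(1.0, abs=0.5)

    def test_short_or_degenerate_signal_scores_zero(self):
        assert regularity_score(np.zeros(4), 187) == 0.0
        assert regularity_score(np.zeros(600), 187) == 0.0


@pytest.fixture(scope="module")
def features():
    rng = np.random.default_rng(10)
    rules = default_state_rules()
    rows = []
    for s in rules.index:
        base = rules.loc[s].to_numpy(float)
        rows.append(base + rng.normal(0, 0.02, base.size)
                    * np.maximum(np.abs(base), 1.0))
    feats = []
    for i, s in enumerate(rules.index):
        block = np.tile(rows[i], (40, 1)) + rng.normal(
            0, 0.05, (40, rules.shape[1]))
        feats.append(pd.DataFrame(block, columns=rules.columns))
    df = pd.concat(feats, ignore_index=True)
    df["true"] = np.repeat(list(rules.index), 40)
    return df


class TestClassifier:
    def test_well_separated_archetypes_recovered(self, features):
        X = features.drop(columns="true")
        assign = classify_states(X)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(features["true"], assign["state"]) >= 0.9

    def test_duplicated_groups_get_identical_labels(self, features):
        X = features.drop(columns="true")
        doubled = pd.concat([X, X], ignore_index=True)
        assign = classify_states(doubled)
        n = len(X)
        assert (assign["state"].to_numpy()[:n]
                == assign["state"].to_numpy()[n:]).all()

    def test_same_seed_same_assignment(self, features):
        X = features.drop(columns="true")
        a1 = classify_states(X)
        a2 = classify_states(X)
        assert a1.equals(a2)

    def test_cluster_state_map_is_bijection(self, features):
        X = features.drop(columns="true")
        clf = StateClassifier().fit(X)
        assert sorted(clf.state_map_.values()) == sorted(
            default_state_rules().index)

    def test_too_few_groups_rejected(self, features):
        with pytest.raises(ValueError, match="at least"):
            StateClassifier().fit(features.drop(columns="true").head(5))

    def test_zero_variance_feature_dropped_with_warning(self, features):
        X = features.drop(columns="true").copy()
        X["mark_H3K9me3"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            StateClassifier().fit(X)


def test_summarize_groups_spans_and_spacing():
    nucs = nuc_table([1000, 1187, 1374], [300] * 3)
    grouped = group_nucleosomes(nucs)
    summary = summarize_groups(grouped)
    assert summary.loc[0, "n_members"] == 3
    assert summary.loc[0, "spacing"] == pytest.approx(187.0)
    assert summary.loc[0, "start"] == 1000 - 73
    assert summary.loc[0, "end"] == 1374 + 74
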