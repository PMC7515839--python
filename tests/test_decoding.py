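import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from feardecode.binning import build_binned_dataset
from feardecode.config import DecoderConfig, GeneratorConfig
from feardecode.decoding import (
    DecodingError,
    LeakageError,
    LinearDecoder,
    apply_to_cohort,
    audit_no_leakage,
    auc_concordance,
    cross_decode,
    evaluate_single_trial,
    loso_cv,
    permutation_null,
    predict,
    train_decoder,
)
from feardecode.pipeline import fear_labels
from feardecode.synth import simulate_cohort
from conftest import tiny_generator_config


def brute_force_auc(predictions, levels):
    """Independent oracle: explicit enumeration of unequal-level pairs."""
    num = den = 0.0
    n = len(predictions)
    for i in range(n):
        for j in range(n):
            if levels[i] < levels[j]:
                den += 1
                if predictions[j] > predictions[i]:
                    num += 1
                elif predictions[j] == predictions[i]:
                    num += 0.5
    return num / den


class TestAUC:
    def test_perfectly_ordered(self):
        assert auc_concordance([1.0, 2.0, 3.0], [0, 1, 2]) == 1.0

    def test_worked_example(self):
        """preds [0.5,0.2,0.7,0.4] against levels [0,1,1,2]: 2 of the 5
        unequal-level pairs are concordant."""
        assert auc_concordance([0.5, 0.2, 0.7, 0.4], [0, 1, 1, 2]) == pytest.approx(0.4)

    def test_binary_case_matches_roc_auc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        preds = rng.standard_normal(40)
        labels = rng.integers(0, 2, 40)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert auc_concordance(preds, labels) == pytest.approx(roc_auc_score(labels, preds))

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = rng.integers(4, 31)
            preds = np.round(rng.standard_normal(n), 1)  # induce ties
            levels = rng.integers(0, rng.integers(2, 7), n)
            while np.unique(levels).size < 2:
                levels = rng.integers(0, 6, n)
            assert auc_concordance(preds, levels) == pytest.approx(
                brute_force_auc(preds, levels), abs=1e-12
            )

    @given(st.lists(st.floats(-5, 5), min_size=4, max_size=20))
    @settings(deadline=None, max_examples=50)
    def test_reversal_antisymmetry(self, preds):
        preds = np.asarray(preds)
        levels = np.arange(len(preds)) % 3
        a = auc_concordance(preds, levels)
        assert auc_concordance(-preds, levels) == pytest.approx(1 - a)

    def test_constant_levels_rejected(self):
        with pytest.raises(DecodingError):
            auc_concordance([1.0, 2.0], [1, 1])


class TestPermutationNull:
    def test_p_lower_bound_when_observed_beats_all(self):
        preds = np.arange(12, dtype=float)
        levels = np.arange(12) % 6
        # perfectly anti-ordered labels cannot beat ordered observed
        subj = np.zeros(12, dtype=int)
        res = permutation_null(preds, np.sort(levels), subj, 1000, np.random.default_rng(0))
        assert res["observed"] == 1.0
        assert res["p"] == pytest.approx(1 / 1001)

    def test_null_mean_near_half(self):
        rng = np.random.default_rng(2)
        preds = rng.standard_normal(30)
        levels = rng.integers(0, 6, 30)
        subj = np.repeat(np.arange(5), 6)
        res = permutation_null(preds, levels, subj, 2000, rng)
        assert abs(res["null"].mean() - 0.5) < 0.02

    def test_tiny_case_support_matches_enumeration(self):
        """3 images, one subject: every sampled null AUC is one of the 6
        exhaustively enumerated permutation AUCs, and their average
        matches the enumeration mean."""
        from itertools import permutations

        preds = np.array([0.1, 0.9, 0.5])
        levels = np.array([0, 1, 2])
        enum = {round(brute_force_auc(preds, p), 12) for p in permutations(levels)}
        enum_mean = np.mean(
            [brute_force_auc(preds, p) for p in permutations(levels)]
        )
        res = permutation_null(preds, levels, np.zeros(3), 600, np.random.default_rng(3))
        assert {round(v, 12) for v in res["null"]} <= enum
        assert abs(res["null"].mean() - enum_mean) < 0.05

    def test_labels_permuted_within_subject_only(self):
        """Across-subject label mixing would let between-subject offsets
        leak; each permutation must preserve each subject's level multiset."""
        preds = np.arange(8, dtype=float)
        levels = np.array([0, 0, 1, 1, 2, 2, 3, 3])
        subj = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        rng = np.random.default_rng(4)
        groups = [np.flatnonzero(subj == s) for s in (0, 1)]
        # reimplement one permutation step and check invariance of multisets
        perm = levels.copy()
        for idx in groups:
            perm[idx] = levels[idx][rng.permutation(idx.size)]
        for idx in groups:
            assert sorted(perm[idx]) == sorted(levels[idx])


class TestTrainPredict:
    def test_separable_linear_case(self):
        X = np.linspace(-1, 1, 10)[:, None]
        y = 2 * X.ravel()
        dec = train_decoder(X, y, config=DecoderConfig(scale_features=False))
        preds = predict(dec, X)
        assert np.corrcoef(preds, y)[0, 1] > 0.999

    def test_constant_labels_rejected(self):
        with pytest.raises(DecodingError):
            train_decoder(np.eye(3), np.ones(3))

    def test_predict_matches_dot_product_oracle(self):
        rng = np.random.default_rng(5)
        dec = LinearDecoder(rng.standard_normal(6), 0.3, "fear", ())
        X = rng.standard_normal((4, 6))
        assert np.allclose(predict(dec, X), X @ dec.w + dec.b)
        assert predict(dec, np.zeros(6))[0] == pytest.approx(dec.b)
        # affine linearity
        u, v = rng.standard_normal(6), rng.standard_normal(6)
        assert predict(dec, u + v)[0] == pytest.approx(
            predict(dec, u)[0] + predict(dec, v)[0] - dec.b
        )

    def test_dimension_mismatch(self):
        dec = LinearDecoder(np.ones(4), 0.0, "fear", ())
        with pytest.raises(DecodingError):
            predict(dec, np.ones((2, 5)))

    def test_weight_map_recovers_planted_encoding(self, small_cohort, small_binned):
        """The fear decoder's weights correlate positively with the planted
        fear encoding on informative voxels."""
        ds = small_binned["fear"]
        X, y, _ = ds.stacked()
        dec = train_decoder(X, y, "fear", tuple(ds.subjects))
        w_true = small_cohort.encoding.w_fear
        mask = w_true != 0
        r = np.corrcoef(dec.w[mask], w_true[mask])[0, 1]
        assert r > 0.5


class TestLoso:
    def test_fold_count_and_no_leakage(self, small_binned, decoder_config):
        res = loso_cv(small_binned["fear"], decoder_config)
        assert len(res.fold_decoders) == len(small_binned["fear"].subjects)
        assert audit_no_leakage(res)
        for s, dec in res.fold_decoders.items():
            assert s not in dec.train_subjects
            assert len(dec.train_subjects) == len(small_binned["fear"].subjects) - 1

    def test_needs_three_subjects(self, small_binned):
        from feardecode.binning import BinnedDataset

        two = BinnedDataset(
            "fear",
            {s: small_binned["fear"].bins[s] for s in small_binned["fear"].subjects[:2]},
        )
        with pytest.raises(DecodingError):
            loso_cv(two)

    def test_planted_signal_decodes_well(self, small_binned, decoder_config):
        res = loso_cv(small_binned["fear"], decoder_config)
        assert res.auc > 0.8

    def test_monotone_in_effect_size(self):
        """Pooled AUC does not decrease as the planted fear effect grows
        (common random numbers via a shared seed)."""
        aucs = []
        for scale in (0.0, 0.5, 1.0, 2.0):
            cfg = tiny_generator_config(
                n_subjects=6, n_voxels=120, n_regions=4,
                n_runs=2, presentations_per_run=120,
                chunk_size_counts={2: 6, 3: 6, 4: 6, 6: 11},
                effect_size_fear=scale, noise_sd=2.0, seed=17,
            )
            cohort = simulate_cohort(cfg)
            ds = build_binned_dataset(cohort.betas, fear_labels(cohort), "fear")
            aucs.append(loso_cv(ds).auc)
        assert all(b >= a - 0.05 for a, b in zip(aucs, aucs[1:]))
        assert aucs[-1] > aucs[0]


class TestCrossDecode:
    def test_leakage_raises(self, small_binned):
        ds = small_binned["scr"]
        bad = {
            s: LinearDecoder(np.zeros(400), 0.0, "fear", (s,))
            for s in ds.subjects
        }
        with pytest.raises(LeakageError):
            cross_decode(bad, ds)

    def test_missing_fold_decoder_raises(self, small_binned):
        with pytest.raises(DecodingError):
            cross_decode({}, small_binned["scr"])

    def test_cross_uses_held_out_decoders(self, small_binned, decoder_config):
        res_fear = loso_cv(small_binned["fear"], decoder_config)
        res = cross_decode(res_fear.fold_decoders, small_binned["scr"])
        assert audit_no_leakage(res)
        assert 0.0 <= res.auc <= 1.0


class TestCategoricalAndCohort:
    def test_degenerate_constant_predictions_standardize_to_zero(self):
        from feardecode.scr import _zscore, winsorize

        with pytest.warns(UserWarning, match="zero-variance"):
            z = _zscore(winsorize(np.full(30, 2.5)), "categorical predictions")
        assert np.allclose(z, 0.0)

    def test_apply_to_cohort_deterministic_and_null_transfer(self):
        cfg = tiny_generator_config(
            n_subjects=5, n_voxels=100, n_regions=4,
            n_runs=2, presentations_per_run=120,
            chunk_size_counts={2: 6, 3: 6, 4: 6, 6: 11}, noise_sd=2.0, seed=23,
        )
        cohort = simulate_cohort(cfg)
        ds = build_binned_dataset(cohort.betas, fear_labels(cohort), "fear")
        X, y, _ = ds.stacked()
        frozen = train_decoder(X, y, "fear", tuple(ds.subjects))
        # same-distribution held-out cohort: decodable
        val = simulate_cohort(
            tiny_generator_config(
                n_subjects=4, n_voxels=100, n_regions=4,
                n_runs=2, presentations_per_run=120,
                chunk_size_counts={2: 6, 3: 6, 4: 6, 6: 11}, noise_sd=2.0, seed=24,
            )
        )
        val_ds = build_binned_dataset(val.betas, fear_labels(val), "fear")
        a = apply_to_cohort(frozen, val_ds)
        b = apply_to_cohort(frozen, val_ds)
        pd.testing.assert_frame_equal(a.predictions, b.predictions)
        assert a.auc > 0.7
        # a cohort with no planted effects is at chance
        null = simulate_cohort(
            tiny_generator_config(
                n_subjects=4, n_voxels=100, n_regions=4,
                n_runs=2, presentations_per_run=120,
                chunk_size_counts={2: 6, 3: 6, 4: 6, 6: 11},
                effect_size_fear=0.0, effect_size_scr=0.0, noise_sd=2.0, seed=25,
            )
        )
        null_ds = build_binned_dataset(null.betas, fear_labels(null), "fear")
        res = apply_to_cohort(frozen, null_ds)
        assert abs(res.auc - 0.5) < 0.2

    def test_single_trial_evaluation_runs_and_centers(self, small_cohort, small_binned,
                                                      decoder_config):
        res_fear = loso_cv(small_binned["fear"], decoder_config)
        labels = fear_labels(small_cohort)
        images = {s: small_cohort.betas[s].betas for s in small_cohort.design.subjects}
        res = evaluate_single_trial(res_fear.fold_decoders, images, labels)
        assert len(res.predictions) == 720 * len(small_cohort.design.subjects)
        assert res.auc > 0.55  # weaker than binned, above chance
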