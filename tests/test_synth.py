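import numpy as np
import pandas as pd
import pytest

from feardecode.config import ConfigurationError, GeneratorConfig
from feardecode.synth import (
    expand_chunk_amplitudes,
    generate_bold,
    generate_design,
    generate_encoding,
    generate_fear_ratings,
    generate_outcomes,
    generate_parcellation,
    generate_scr_amplitudes,
    generate_scr_trace,
    generate_trial_betas,
    signal_matrix,
    simulate_cohort,
)
from feardecode.lss import canonical_hrf, convolve_onsets
from conftest import tiny_generator_config


class TestDesign:
    def test_default_design_has_720_chunk_first_trials(self):
        design = generate_design(GeneratorConfig(n_subjects=2))
        assert design.n_chunk_first == 720
        assert len(design.schedule) == 3600

    def test_chunk_arithmetic(self):
        """12+12+18+78 chunks of sizes 2/3/4/6 tile one 600-presentation run."""
        design = generate_design(GeneratorConfig(n_subjects=1, n_runs=1))
        run = design.schedule
        assert run["chunk_id"].nunique() == 120
        assert len(run) == 600
        sizes = run.groupby("chunk_id")["chunk_size"].agg(["first", "size"])
        assert (sizes["first"] == sizes["size"]).all()

    def test_minimal_design(self):
        cfg = GeneratorConfig(
            n_subjects=1, n_runs=1, presentations_per_run=2,
            chunk_size_counts={2: 1}, n_categories=1, n_voxels=2, n_regions=1,
        )
        design = generate_design(cfg)
        assert len(design.schedule) == 2
        assert design.n_chunk_first == 1

    def test_one_chunk_first_per_chunk_and_increasing_onsets(self, tiny_config):
        design = generate_design(tiny_config)
        per_chunk = design.schedule.groupby("chunk_id")["chunk_first"].sum()
        assert (per_chunk == 1).all()
        for _, run in design.schedule.groupby("run"):
            assert (np.diff(run["onset"]) > 0).all()
        # chunk_first marks the earliest presentation of its chunk
        firsts = design.schedule[design.schedule["chunk_first"]]
        mins = design.schedule.groupby("chunk_id")["presentation"].min()
        assert (firsts.set_index("chunk_id")["presentation"] == mins).all()

    def test_onsets_follow_tr(self, tiny_config):
        design = generate_design(tiny_config)
        assert np.allclose(
            design.schedule["onset"],
            design.schedule["presentation"] * tiny_config.tr,
        )

    def test_determinism(self, tiny_config):
        a = generate_design(tiny_config)
        b = generate_design(tiny_config)
        pd.testing.assert_frame_equal(a.schedule, b.schedule)


class TestRatings:
    def test_values_are_ordinal_0_to_5(self, tiny_config):
        design = generate_design(tiny_config)
        ratings = generate_fear_ratings(design, tiny_config)
        assert ratings.shape == (tiny_config.n_subjects, tiny_config.n_categories)
        assert ratings.to_numpy().min() >= 0 and ratings.to_numpy().max() <= 5

    def test_degenerate_all_no_fear(self):
        cfg = tiny_generator_config(fear_zero_target=1.0)
        design = generate_design(cfg)
        ratings = generate_fear_ratings(design, cfg)
        assert (ratings.to_numpy() == 0).all()

    def test_determinism(self, tiny_config):
        design = generate_design(tiny_config)
        a = generate_fear_ratings(design, tiny_config)
        b = generate_fear_ratings(design, tiny_config)
        pd.testing.assert_frame_equal(a, b)


class TestSCRAmplitudes:
    def test_zero_inflated_and_nonnegative(self, tiny_config):
        design = generate_design(tiny_config)
        ratings = generate_fear_ratings(design, tiny_config)
        scr = generate_scr_amplitudes(design, ratings, tiny_config)
        amp = scr["amplitude"].to_numpy()
        assert (amp >= 0).all()
        assert (amp == 0).any()
        # positive responses clear the scoring floor by construction
        assert (amp[amp > 0] >= 0.2).all()

    def test_subfloor_fraction_matches_target(self):
        cfg = GeneratorConfig(n_subjects=10, seed=2)
        design = generate_design(cfg)
        ratings = generate_fear_ratings(design, cfg)
        scr = generate_scr_amplitudes(design, ratings, cfg)
        frac = (scr["amplitude"].to_numpy() < 0.2).mean()
        assert abs(frac - cfg.scr_zero_target) < 0.02

    def test_no_coupling_decouples_ratings(self):
        """With coupling 0 and no category reactivity, amplitude response
        rates do not depend on the trial's rating."""
        cfg = GeneratorConfig(n_subjects=10, seed=4, coupling=0.0, scr_category_sd=0.0)
        design = generate_design(cfg)
        ratings = generate_fear_ratings(design, cfg)
        scr = generate_scr_amplitudes(design, ratings, cfg)
        firsts = design.chunk_first_trials
        rates = []
        for s in design.subjects:
            r = ratings.loc[s].to_numpy()[firsts["category"].to_numpy()]
            a = scr[scr["subject"] == s]["amplitude"].to_numpy()
            rates.append([np.mean(a[r == k] > 0) for k in (0, 3) if (r == k).sum() > 30])
        rates = np.array([x for x in rates if len(x) == 2])
        assert abs(np.mean(rates[:, 0] - rates[:, 1])) < 0.05


class TestParcellation:
    def test_even_split(self):
        cfg = GeneratorConfig(n_voxels=2140, n_regions=214)
        parc = generate_parcellation(cfg)
        sizes = np.bincount(parc.voxel_region)
        assert (sizes == 10).all()

    def test_remainder_distribution(self):
        cfg = GeneratorConfig(n_voxels=100, n_regions=3)
        parc = generate_parcellation(cfg)
        assert sorted(np.bincount(parc.voxel_region), reverse=True) == [34, 33, 33]

    def test_partition_property(self, tiny_config):
        parc = generate_parcellation(tiny_config)
        assert parc.voxel_region.shape == (tiny_config.n_voxels,)
        assert set(parc.voxel_region) == set(range(tiny_config.n_regions))


class TestEncoding:
    def test_pure_fear_roles_zero_scr_weights(self):
        cfg = tiny_generator_config(
            region_role_fractions={"fear_only": 1.0, "scr_only": 0.0, "both": 0.0, "null": 0.0}
        )
        enc = generate_encoding(cfg, generate_parcellation(cfg))
        assert (enc.w_scr == 0).all()
        assert (enc.w_fear != 0).any()

    def test_role_zero_constraints_hold_exactly(self, small_cohort):
        enc, parc = small_cohort.encoding, small_cohort.parcellation
        role_per_voxel = enc.region_role[parc.voxel_region]
        assert (enc.w_scr[np.isin(role_per_voxel, ["fear_only", "null"])] == 0).all()
        assert (enc.w_fear[np.isin(role_per_voxel, ["scr_only", "null"])] == 0).all()
        assert (enc.w_fear[role_per_voxel == "both"] != 0).all()

    def test_null_effect_size_silences_fear_signal(self):
        cfg = tiny_generator_config(effect_size_fear=0.0)
        enc = generate_encoding(cfg, generate_parcellation(cfg))
        assert (enc.w_fear == 0).all()

    def test_determinism(self, tiny_config):
        parc = generate_parcellation(tiny_config)
        a = generate_encoding(tiny_config, parc)
        b = generate_encoding(tiny_config, parc)
        assert np.array_equal(a.w_fear, b.w_fear)
        assert np.array_equal(a.w_scr, b.w_scr)


class TestTrialBetas:
    def test_noiseless_betas_equal_closed_form(self):
        cfg = tiny_generator_config(noise_sd=0.0)
        cohort = simulate_cohort(cfg)
        s = 0
        sig = signal_matrix(cohort.design, cohort.outcomes, cohort.encoding, s)
        assert np.allclose(cohort.betas[s].betas, sig)
        # rating-0, zero-SCR trials give an all-zero row on fear-only voxels
        ratings = cohort.outcomes.trial_ratings(cohort.design, s)
        amp = cohort.outcomes.subject_scr(s)["amplitude"].to_numpy()
        idx = np.flatnonzero((ratings == 0) & (amp == 0))
        if idx.size:
            assert np.allclose(cohort.betas[s].betas[idx], 0.0)

    def test_noise_averages_out_across_voxels(self):
        cfg = tiny_generator_config(n_voxels=3000, n_regions=5, noise_sd=2.0)
        design = generate_design(cfg)
        outcomes = generate_outcomes(design, cfg)
        enc = generate_encoding(cfg, generate_parcellation(cfg))
        betas = generate_trial_betas(design, outcomes, enc, cfg, 0)
        resid = betas.betas - signal_matrix(design, outcomes, enc, 0)
        row_means = resid.mean(axis=1)
        assert np.abs(row_means).max() < 5 * cfg.noise_sd / np.sqrt(cfg.n_voxels)


class TestBold:
    def test_zero_amplitudes_give_zero_series(self, tiny_config):
        design = generate_design(tiny_config)
        bold = generate_bold(design, np.zeros(len(design.schedule)), tiny_config)
        for series in bold.values():
            assert np.allclose(series, 0.0)

    def test_single_trial_is_shifted_hrf(self):
        cfg = tiny_generator_config(
            n_runs=1, presentations_per_run=2, chunk_size_counts={2: 1}, n_categories=1
        )
        design = generate_design(cfg)
        amps = np.array([1.0, 0.0])
        series = generate_bold(design, amps, cfg)[1][:, 0]
        n_scans = series.shape[0]
        expected = convolve_onsets([0.0], [1.0], n_scans, cfg.tr)
        assert np.allclose(series, expected)
        # the response peaks where the canonical response peaks (~5 s)
        assert abs(np.argmax(series) * cfg.tr - 5.0) <= cfg.tr

    def test_superposition(self, tiny_config):
        """BOLD is linear in trial amplitudes (brute-force shifted-HRF sum)."""
        design = generate_design(tiny_config)
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 2, len(design.schedule))
        b = rng.uniform(0, 2, len(design.schedule))
        ya = generate_bold(design, a, tiny_config)
        yb = generate_bold(design, b, tiny_config)
        yab = generate_bold(design, a + b, tiny_config)
        for run in ya:
            assert np.allclose(ya[run] + yb[run], yab[run], atol=1e-10)
        # and matches an explicit sum of singly-convolved sticks
        run1 = design.schedule[design.schedule["run"] == 1]
        n_scans = ya[1].shape[0]
        brute = sum(
            convolve_onsets([row["onset"]], [a[i]], n_scans, tiny_config.tr)
            for i, (_, row) in zip(run1.index, run1.iterrows())
        )
        assert np.allclose(ya[1][:, 0], brute, atol=1e-10)

    def test_expand_chunk_amplitudes(self, tiny_config):
        design = generate_design(tiny_config)
        firsts = design.chunk_first_trials
        amps = np.arange(len(firsts), dtype=float)
        per_pres = expand_chunk_amplitudes(design.schedule, amps)
        assert per_pres.shape[0] == len(design.schedule)
        lookup = dict(zip(firsts["chunk_id"], amps))
        expected = design.schedule["chunk_id"].map(lookup).to_numpy()
        assert np.array_equal(per_pres, expected)


class TestSCRTrace:
    def test_flat_trace_without_responses(self, tiny_config):
        design = generate_design(tiny_config)
        scr = pd.DataFrame(
            {"run": design.chunk_first_trials["run"],
             "presentation": design.chunk_first_trials["presentation"],
             "amplitude": 0.0}
        )
        traces = generate_scr_trace(design, scr, tiny_config, baseline=2.0)
        for trace in traces.values():
            assert np.allclose(trace.samples, 2.0)

    def test_single_bump_round_trip(self):
        from feardecode.scr import score_design

        cfg = tiny_generator_config(n_runs=1, presentations_per_run=6,
                                    chunk_size_counts={6: 1}, n_categories=1)
        design = generate_design(cfg)
        scr = pd.DataFrame({"run": [1], "presentation": [0], "amplitude": [0.5]})
        traces = generate_scr_trace(design, scr, cfg)
        table = score_design(traces, design.schedule)
        assert len(table) == 1
        assert abs(table["raw"].iloc[0] - 0.5) < 0.01

    def test_determinism_with_noise(self, tiny_config):
        design = generate_design(tiny_config)
        scr = generate_outcomes(design, tiny_config).scr_true
        sub = scr[scr["subject"] == 0]
        a = generate_scr_trace(design, sub, tiny_config, noise_sd=0.05)
        b = generate_scr_trace(design, sub, tiny_config, noise_sd=0.05)
        for run in a:
            assert np.array_equal(a[run].samples, b[run].samples)


def test_cohort_determinism(tiny_config):
    """Identical config + seed reproduce the cohort bit for bit."""
    a = simulate_cohort(tiny_config)
    b = simulate_cohort(tiny_config)
    pd.testing.assert_frame_equal(a.design.schedule, b.design.schedule)
    pd.testing.assert_frame_equal(a.outcomes.ratings, b.outcomes.ratings)
    pd.testing.assert_frame_equal(a.outcomes.scr_true, b.outcomes.scr_true)
    for s in a.design.subjects:
        assert np.array_equal(a.betas[s].betas, b.betas[s].betas)


def test_scr_missing_subjects_flagged():
    cfg = tiny_generator_config(scr_missing=2)
    cohort = simulate_cohort(cfg)
    assert len(cohort.scr_subjects) == cfg.n_subjects - 2


def test_hrf_shape():
    t = np.linspace(0, 32, 32001)
    h = canonical_hrf(t)
    assert h[0] == 0.0
    assert abs(t[np.argmax(h)] - 5.0) < 0.05
    assert np.isclose(h.max(), 1.0, atol=1e-6)
    pos = np.trapezoid(np.clip(h, 0, None), t)
    neg = np.trapezoid(np.clip(h, None, 0), t)
    assert pos > abs(neg)


def test_parcellation_exceeding_voxels_rejected():
    with pytest.raises(ConfigurationError):
        GeneratorConfig(n_voxels=4, n_regions=5)
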