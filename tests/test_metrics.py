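"""Learning metrics: ClassDis, Fisher scores, PSD features, MDM, trends."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riemannbci.evaluate import run_metrics
from riemannbci.geometry import InvalidInputError, estimate_covariance
from riemannbci.metrics import (
    DegenerateDispersionError,
    class_distinctiveness,
    crossval_accuracy,
    discriminancy_map,
    fisher_score,
    laplacian_derivation,
    learning_trend,
    load_default_montage,
    mdm_fit,
    mdm_predict,
    psd_features,
)
from riemannbci.synth import (
    FEEDBACK_CHANNELS,
    GeneratorConfig,
    generate_session,
)

from conftest import random_spd


class TestClassDis:
    def test_identical_sets_give_zero(self, rng):
        covs = [random_spd(rng, 4) for _ in range(5)]
        assert class_distinctiveness(covs, list(covs)) == pytest.approx(0.0, abs=1e-7)

    def test_commuting_scaled_classes_closed_form(self, rng):
        # class B = c * class A (commuting family): numerator is
        # sqrt(n) * log c, dispersions are equal, checked directly
        n, c = 4, 3.0
        covsA = [np.diag(rng.uniform(0.5, 2.0, n)) for _ in range(6)]
        covsB = [c * P for P in covsA]
        val = class_distinctiveness(covsA, covsB)
        from riemannbci.geometry import riemannian_mean

        stA = riemannian_mean(covsA)
        expected = np.sqrt(n) * np.log(c) / (0.5 * (stA.dispersion * 2))
        assert val == pytest.approx(expected, rel=1e-6)

    def test_relabeling_symmetry(self, rng):
        covsA = [random_spd(rng, 3) for _ in range(4)]
        covsB = [random_spd(rng, 3) for _ in range(4)]
        assert class_distinctiveness(covsA, covsB) == pytest.approx(
            class_distinctiveness(covsB, covsA), rel=1e-9
        )

    def test_degenerate_dispersion(self, spd_factory):
        P = spd_factory(3)
        with pytest.raises(DegenerateDispersionError):
            class_distinctiveness([P, P], [P, P])

    def test_channel_permutation_invariance(self, rng):
        covsA = [random_spd(rng, 5) for _ in range(4)]
        covsB = [random_spd(rng, 5) for _ in range(4)]
        perm = rng.permutation(5)
        pA = [P[np.ix_(perm, perm)] for P in covsA]
        pB = [P[np.ix_(perm, perm)] for P in covsB]
        assert class_distinctiveness(pA, pB) == pytest.approx(
            class_distinctiveness(covsA, covsB), rel=1e-6
        )


class TestFisherScore:
    def test_identical_distributions_zero(self):
        v = [1.0, 2.0, 3.0, 4.0]
        assert fisher_score(v, list(v)) == 0.0

    def test_constructed_value(self):
        # mu1 = 1, mu2 = 0, s1 = s2 = 0.5 -> 1 / (0.25 + 0.25) = 2
        v1 = [0.5, 1.5]  # mean 1, population sd 0.5
        v2 = [-0.5, 0.5]
        assert fisher_score(v1, v2) == pytest.approx(2.0)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_independent_formula(self, seed):
        r = np.random.default_rng(seed)
        v1, v2 = r.normal(0, 1, 20), r.normal(0.5, 2, 25)
        expected = abs(v1.mean() - v2.mean()) / (
            ((v1 - v1.mean()) ** 2).mean() + ((v2 - v2.mean()) ** 2).mean()
        )
        assert fisher_score(v1, v2) == pytest.approx(expected, abs=1e-12)

    def test_classical_variant_squares_numerator(self):
        v1, v2 = [0.5, 1.5], [-0.5, 0.5]
        assert fisher_score(v1, v2, classical=True) == pytest.approx(2.0)
        v1 = [2.5, 3.5]  # mean diff 3 -> printed 6, classical 18
        assert fisher_score(v1, v2) == pytest.approx(6.0)
        assert fisher_score(v1, v2, classical=True) == pytest.approx(18.0)


class TestLaplacian:
    def test_identical_channels_cancel(self):
        X = np.tile(np.sin(np.linspace(0, 10, 100)), (10, 1))
        out = laplacian_derivation(X, FEEDBACK_CHANNELS)
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_zero_neighbors_leave_channel(self):
        montage = {"A": ["B", "C"], "B": ["A"], "C": ["A"]}
        X = np.zeros((3, 50))
        X[0] = np.sin(np.linspace(0, 5, 50))
        out = laplacian_derivation(X, ["A", "B", "C"], montage)
        assert np.allclose(out[0], X[0])

    def test_hand_built_three_channel(self):
        montage = {"A": ["B", "C"], "B": ["A"], "C": ["A"]}
        X = np.array([[4.0] * 5, [2.0] * 5, [0.0] * 5])
        out = laplacian_derivation(X, ["A", "B", "C"], montage)
        assert np.allclose(out[0], 4.0 - (2.0 + 0.0) / 2)

    def test_missing_channel(self):
        with pytest.raises(InvalidInputError):
            laplacian_derivation(np.zeros((2, 50)), ["A", "X"], {"A": ["X"]})

    def test_default_montage_covers_feedback_channels(self):
        montage = load_default_montage()
        assert set(FEEDBACK_CHANNELS) <= set(montage)


class TestPSD:
    def test_figure_window_count(self):
        # 6-s signal, 1-s window, 0.1-s step -> 51 windows
        x = np.zeros((2, 1500))
        p, _ = psd_features(x, fs=250.0, step=0.1)
        assert p.shape[0] == 51

    def test_default_step_count_formula(self):
        x = np.zeros((2, 1000))  # 4 s at 250 Hz, 62.5-ms step
        p, _ = psd_features(x, fs=250.0)
        assert p.shape[0] == int(np.floor((1000 - 250) / (0.0625 * 250))) + 1

    def test_sinusoid_concentrates_in_its_bin(self):
        # Hann-windowed on-bin tone: amplitude leaks 0.5 to each adjacent
        # 1-Hz FFT bin, so the host 2-Hz bin holds (1 + 1/4)/(3/2) = 5/6
        # of the total power (analytic spectrum of a windowed sinusoid)
        t = np.arange(500) / 250.0
        x = np.sin(2 * np.pi * 11.0 * t)[None, :]
        p, edges = psd_features(x, fs=250.0, band=(8.0, 14.0))
        binpow = p.mean(axis=0)[0]
        assert edges[np.argmax(binpow)] == 10.0  # 10-12 Hz bin
        assert binpow.max() / binpow.sum() == pytest.approx(5.0 / 6.0, abs=0.02)

    def test_white_noise_flat_spectrum(self):
        powers = []
        for seed in (0, 1):
            x = np.random.default_rng(seed).standard_normal((1, 30000))
            p, _ = psd_features(x, fs=250.0, band=(8.0, 30.0))
            powers.append(p.mean(axis=0)[0])
        for bp in powers:
            assert bp.max() / bp.min() < 1.5  # flat within Monte-Carlo noise

    def test_window_longer_than_signal(self):
        with pytest.raises(InvalidInputError):
            psd_features(np.zeros((1, 100)), fs=250.0)


class TestDiscriminancyMap:
    def test_class_independent_features_zero(self):
        feats = np.tile(np.arange(12.0).reshape(1, 3, 4), (10, 1, 1))
        feats = np.concatenate([feats, feats])
        labels = ["left"] * 10 + ["right"] * 10
        with pytest.raises(DegenerateDispersionError):
            # identical constant features: zero variance is degenerate
            discriminancy_map(feats, labels, ["a", "b", "c"])

    def test_duplicated_population_gives_zero_scores(self, rng):
        half = rng.random((10, 3, 4))
        feats = np.concatenate([half, half])
        labels = ["left"] * 10 + ["right"] * 10
        table, per_ch, avg = discriminancy_map(feats, labels, ["a", "b", "c"])
        assert np.allclose(table.values, 0.0)
        assert avg == 0.0

    def test_erd_channels_dominate(self, rng):
        # mean shift only on channels C4 and C2 in one frequency bin
        n = 40
        feats = rng.random((2 * n, 10, 11))
        labels = ["left"] * n + ["right"] * n
        idx = [FEEDBACK_CHANNELS.index("C4"), FEEDBACK_CHANNELS.index("C2")]
        for i in idx:
            feats[:n, i, 1] += 2.0
        _, per_ch, _ = discriminancy_map(feats, labels, FEEDBACK_CHANNELS)
        others = per_ch.drop(["C4", "C2"])
        assert per_ch["C4"] > others.max()
        assert per_ch["C2"] > others.max()


class TestMDM:
    def test_exact_class_mean_assigned(self, rng):
        covsA = [random_spd(rng, 3) for _ in range(4)]
        covsB = [random_spd(rng, 3, scale=5.0) for _ in range(4)]
        means = mdm_fit(covsA + covsB, ["A"] * 4 + ["B"] * 4)
        assert mdm_predict(means, means["A"]) == "A"
        assert mdm_predict(means, means["B"]) == "B"

    def test_tie_breaks_lexicographically(self, spd_factory):
        P = spd_factory(3)
        means = {"b": P.copy(), "a": P.copy()}
        assert mdm_predict(means, P) == "a"

    def test_separable_classes_perfect_training_accuracy(self, rng):
        covsA = [random_spd(rng, 3) for _ in range(6)]
        covsB = [100.0 * random_spd(rng, 3) for _ in range(6)]
        labels = ["A"] * 6 + ["B"] * 6
        means = mdm_fit(covsA + covsB, labels)
        preds = [mdm_predict(means, P) for P in covsA + covsB]
        assert preds == labels

    def test_missing_class(self, spd_factory):
        with pytest.raises(InvalidInputError):
            mdm_fit([spd_factory(2)], ["A"])


class TestCrossval:
    def test_identical_covariances_chance_level(self, spd_factory):
        P = spd_factory(3)
        covs = [P.copy() for _ in range(40)]
        rng = np.random.default_rng(1)
        accs = [
            crossval_accuracy(covs, rng.permutation(["L"] * 20 + ["R"] * 20),
                              seed=s)
            for s in range(10)
        ]
        assert abs(np.mean(accs) - 0.5) < 0.05

    def test_strong_effect_high_accuracy(self):
        cfg = GeneratorConfig(seed=2, trials_per_run=10, runs_per_session=1,
                              erd_effect=0.6)
        session = generate_session(cfg)
        segs = list(session.mi_segments())
        from riemannbci.engine import bandpass

        covs = [
            estimate_covariance(bandpass(s, (8.0, 30.0)), shrinkage=0.01)
            for s in segs
        ]
        ca = crossval_accuracy(covs, [s.label for s in segs], seed=0)
        assert ca >= 0.9

    def test_trial_split_requires_ids(self, spd_factory):
        covs = [spd_factory(2) for _ in range(10)]
        with pytest.raises(InvalidInputError):
            crossval_accuracy(covs, ["A", "B"] * 5, split="trial")


class TestLearningTrend:
    def test_monotone_series(self):
        r, p = learning_trend([1.0, 2.0, 3.0, 4.0, 5.0])
        assert r == pytest.approx(1.0)
        r, _ = learning_trend([5.0, 4.0, 3.0, 2.0, 1.0])
        assert r == pytest.approx(-1.0)

    def test_hand_computed_fixture(self):
        v = np.array([0.31, 0.29, 0.35, 0.33, 0.40])
        x = np.arange(5.0)
        expected = (((x - x.mean()) * (v - v.mean())).sum()
                    / np.sqrt(((x - x.mean()) ** 2).sum()
                              * ((v - v.mean()) ** 2).sum()))
        r, p = learning_trend(v)
        assert r == pytest.approx(expected, abs=1e-12)
        assert 0.0 < p < 1.0

    def test_constant_series_undefined(self):
        with pytest.raises(InvalidInputError):
            learning_trend([1.0, 1.0, 1.0])


class TestRunMetricsCoupling:
    def test_metrics_move_together_across_effect_sizes(self):
        # joint sweep over effect sizes with paired seeds: CA couples
        # tightly to ClassDis; the FS average trends the same way
        rows = []
        for g in (0.0, 0.3, 0.6):
            for seed in (0, 1, 2):
                cfg = GeneratorConfig(seed=seed, trials_per_run=12,
                                      runs_per_session=1, erd_effect=g)
                s = generate_session(cfg)
                m = run_metrics(list(s.mi_segments()), (8.0, 30.0),
                                FEEDBACK_CHANNELS, cv_seed=seed)
                rows.append((g, m["ClassDis"], m["FS_avg"], m["CA"]))
        arr = np.asarray(rows)
        r_ca = np.corrcoef(arr[:, 1], arr[:, 3])[0, 1]
        assert r_ca > 0.5
        # FS is a weaker signal: require its per-g medians to rise with
        # the ClassDis medians
        med_cd = [np.median(arr[arr[:, 0] == g, 1]) for g in (0.0, 0.3, 0.6)]
        med_fs = [np.median(arr[arr[:, 0] == g, 2]) for g in (0.0, 0.3, 0.6)]
        assert med_cd == sorted(med_cd)
        assert med_fs == sorted(med_fs)
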