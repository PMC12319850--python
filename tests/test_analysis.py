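"""Tests for the analysis toolkit: gain spectra, peaks, probes, relevance."""

import numpy as np
import pytest

from eegspd.analysis import (
    GainSpectrum,
    bimap_gain,
    count_peaks,
    eig_below_threshold,
    electrode_frequency_relevance,
    frequency_gain,
    layer_by_layer,
)
from eegspd.model import EEGSPDNet, NetworkConfig


def _net(**kw):
    base = dict(Ne=4, n_classes=3, fs=250.0, Nf=1, NBiRe=1, kernel_len=63, seed=0)
    base.update(kw)
    return EEGSPDNet(NetworkConfig(**base))


class TestFrequencyGain:
    def test_identity_filter_is_zero_db(self, rng):
        net = _net(kernel_len=5)
        k = np.zeros(5)
        k[2] = 1.0
        net.filterbank.kernels.value[...] = k
        X = rng.normal(size=(64, 4, 400))
        gs = frequency_gain(net, X)[0]
        assert not gs.discarded
        assert np.max(np.abs(gs.gain_db)) < 0.1

    def test_sinc_bandpass_gain_profile(self, rng):
        net = _net(kind="sinc")
        # force an 8-30 Hz filter
        from eegspd.model import _softplus_inv

        net.filterbank.theta_low.value[...] = _softplus_inv(np.array([8.0]))
        net.filterbank.theta_band.value[...] = _softplus_inv(np.array([21.0]))
        X = rng.normal(size=(64, 4, 500))
        gs = frequency_gain(net, X)[0]
        inband = gs.gain_db[(gs.freqs >= 12) & (gs.freqs <= 26)]
        stop = gs.gain_db[(gs.freqs >= 60) & (gs.freqs <= 120)]
        assert np.abs(inband.mean()) < 3.0
        assert stop.max() < -20.0

    def test_zero_signal_discards_not_raises(self):
        net = _net(kernel_len=5)
        X = np.zeros((4, 4, 200))
        spectra = frequency_gain(net, X)
        assert all(gs.discarded for gs in spectra)

    def test_chspec_yields_per_electrode_spectra(self, rng):
        net = _net(specificity="ChSpec", Nf=2)
        spectra = frequency_gain(net, rng.normal(size=(8, 4, 300)))
        assert len(spectra) == 8  # Nf * Ne
        assert {gs.electrode for gs in spectra} == {0, 1, 2, 3}


def _bump(freqs, centre, width, height):
    return height * np.exp(-0.5 * ((freqs - centre) / width) ** 2)


class TestCountPeaks:
    freqs = np.linspace(0, 125, 126)

    def test_single_bump_counts_one(self):
        gs = GainSpectrum(self.freqs, _bump(self.freqs, 20, 4, 30.0))
        assert count_peaks(gs) == 1

    def test_two_separated_bumps_count_two(self):
        g = _bump(self.freqs, 15, 3, 30.0) + _bump(self.freqs, 70, 3, 25.0)
        assert count_peaks(GainSpectrum(self.freqs, g)) == 2

    def test_flat_noise_counts_zero(self, rng):
        g = rng.normal(0, 0.2, self.freqs.size)
        assert count_peaks(GainSpectrum(self.freqs, g)) == 0

    def test_constant_offset_invariance(self):
        g = _bump(self.freqs, 30, 4, 25.0)
        a = count_peaks(GainSpectrum(self.freqs, g))
        b = count_peaks(GainSpectrum(self.freqs, g + 40.0))
        assert a == b == 1

    def test_flat_top_plateau_with_ripple_is_single_band(self, rng):
        g = np.where((self.freqs > 10) & (self.freqs < 40), 60.0, 0.0)
        g = g + rng.normal(0, 0.05, g.size)
        assert count_peaks(GainSpectrum(self.freqs, g)) == 1

    def test_discarded_spectrum_rejected(self):
        gs = GainSpectrum(self.freqs, None, discarded=True)
        with pytest.raises(ValueError):
            count_peaks(gs)


class TestNegInfHandling:
    def test_majority_neg_inf_discarded(self):
        from eegspd.analysis import _interp_neg_inf

        g = np.full(100, -np.inf)
        g[:40] = 1.0  # 60% -inf
        interp, bad = _interp_neg_inf(g)
        assert interp is None
        assert bad.sum() == 60

    def test_minority_neg_inf_interpolated(self):
        from eegspd.analysis import _interp_neg_inf

        g = np.linspace(0, 9.0, 10)
        g[4] = -np.inf
        interp, bad = _interp_neg_inf(g)
        assert interp is not None
        assert interp[4] == pytest.approx(4.0)


class TestLayerByLayer:
    def test_table_shape_and_probe_rows(self, easy4_small):
        trials, _ = easy4_small
        net = _net(Ne=trials.n_electrodes, n_classes=4, NBiRe=2)
        n = len(trials)
        Xtr, ytr = trials.X[: n // 2], trials.y[: n // 2]
        Xte, yte = trials.X[n // 2 :], trials.y[n // 2 :]
        table = layer_by_layer(net, Xtr, ytr, Xte, yte)
        stages = 1 + 2 * net.config.NBiRe
        assert len(table) == 2 * stages
        assert set(table["probe"]) == {"SVM", "rSVM"}
        assert np.allclose(
            table["probe_minus_network"], table["accuracy"] - table["network_accuracy"]
        )

    def test_first_stage_rsvm_beats_chance_on_planted_fixture(self, easy4_small):
        trials, _ = easy4_small
        net = _net(Ne=trials.n_electrodes, n_classes=4, NBiRe=1)
        n = len(trials)
        Xtr, ytr = trials.X[: n // 2], trials.y[: n // 2]
        Xte, yte = trials.X[n // 2 :], trials.y[n // 2 :]
        table = layer_by_layer(net, Xtr, ytr, Xte, yte)
        first = table[(table.stage == "pool") & (table.probe == "rSVM")].accuracy.iloc[0]
        sigma = 100.0 * np.sqrt(0.25 * 0.75 / len(yte))
        assert first > 25.0 + 3 * sigma


class TestEigBelowThreshold:
    def test_zero_percent_after_every_reeig(self, rng):
        net = _net(Ne=6, NBiRe=2, kernel_len=9)
        table = eig_below_threshold(net, rng.normal(size=(6, 6, 100)))
        after = table[table.stage.str.startswith("reeig")]
        assert np.all(after.pct_below_eps.to_numpy() == 0.0)

    def test_rank_deficient_pool_reports_half(self, rng):
        # 4 rows from only 3 independent samples after centering: at least
        # one zero eigenvalue per pooled matrix lands below the threshold
        net = _net(Ne=4, NBiRe=0, kernel_len=5)
        X = rng.normal(size=(3, 4, 8))
        table = eig_below_threshold(net, X)
        pool_pct = table[table.stage == "pool"].pct_below_eps.iloc[0]
        assert pool_pct >= 25.0

    def test_batch_aggregation_is_mean_of_trials(self, rng):
        net = _net(Ne=4, NBiRe=1, kernel_len=9)
        X = rng.normal(size=(4, 4, 60))
        full = eig_below_threshold(net, X)
        singles = [eig_below_threshold(net, X[i : i + 1]) for i in range(4)]
        for stage in full.stage:
            vals = [s[s.stage == stage].pct_below_eps.iloc[0] for s in singles]
            ref = full[full.stage == stage].pct_below_eps.iloc[0]
            assert np.isclose(np.mean(vals), ref)


class TestBiMapGain:
    def test_identity_weight_gives_all_ones(self):
        G, per_e = bimap_gain(np.eye(4))
        assert np.array_equal(G, np.ones((4, 4)))
        assert np.array_equal(per_e, np.full(4, 4.0))

    def test_double_sum_definition_matches_closed_form(self, make_stiefel):
        W = make_stiefel(6, 3)
        G, _ = bimap_gain(W)
        # independent oracle: the explicit double sum over output indices
        n, m = W.shape
        G_ref = np.zeros((n, n))
        for p in range(n):
            for q in range(n):
                G_ref[p, q] = np.outer(W[p], W[q]).sum()
        assert np.allclose(G, G_ref, atol=1e-12)
        assert np.allclose(G, G.T, atol=1e-12)

    def test_band_major_electrode_aggregation(self, rng):
        W = rng.normal(size=(6, 2))  # Nf=2, Ne=3
        G, per_e = bimap_gain(W, Nf=2, Ne=3)
        manual = G.sum(axis=1).reshape(2, 3).sum(axis=0)
        assert np.allclose(per_e, manual)

    def test_inconsistent_shape_rejected(self, rng):
        with pytest.raises(ValueError):
            bimap_gain(rng.normal(size=(5, 2)), Nf=2, Ne=3)


class TestRelevance:
    def test_zero_classifier_gives_zero_relevance(self, rng):
        net = _net(Ne=4, NBiRe=1, kernel_len=9)
        net.affine.Wc.value[...] = 0.0
        net.affine.bc.value[...] = 0.0
        rel, freqs = electrode_frequency_relevance(net, rng.normal(size=(4, 4, 200)))
        assert np.allclose(rel, 0.0)

    def test_output_shape(self, rng):
        net = _net(Ne=4, n_classes=3, NBiRe=1, kernel_len=9)
        rel, freqs = electrode_frequency_relevance(net, rng.normal(size=(4, 4, 200)))
        assert rel.shape == (3, 4, freqs.size)

    def test_relevance_concentrates_on_planted_electrodes(self):
        from eegspd.synthetic import make_fixture
        from eegspd.training import TrainConfig, train

        # all class information lives at electrodes 0-1 (20-30 Hz): across
        # classes, relevance mass must favour the planted electrodes
        trials, truth = make_fixture("singleband", seed=2, n_trials_per_class=20)
        net = _net(Ne=trials.n_electrodes, n_classes=4, NBiRe=2, seed=1)
        train(net, trials.X, trials.y, TrainConfig(epochs=40, seeds=(1,), shuffle_seed=1))
        rel, freqs = electrode_frequency_relevance(net, trials.X)
        mass = np.abs(rel).sum(axis=(0, 2))
        planted = list(truth.electrodes)
        silent = [e for e in range(trials.n_electrodes) if e not in planted]
        assert mass[planted].mean() > mass[silent].mean()
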