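import itertools

import numpy as np
import pytest

from expressome import states as st
from expressome import synthgen as sg
from expressome.traceio import Trace, compute_fret
from reference_impls import reference_merge_short_runs, reference_threshold_labels


def _markov_series(means, sds, stay, n_series, n_frames, seed):
    """Gaussian-emission Markov chains used as controlled HMM inputs."""
    rng = np.random.default_rng(seed)
    K = len(means)
    series, paths = [], []
    for _ in range(n_series):
        s = rng.integers(K)
        path = np.empty(n_frames, dtype=int)
        for t in range(n_frames):
            path[t] = s
            if rng.random() > stay:
                s = (s + 1 + rng.integers(K - 1)) % K if K > 1 else s
        E = np.asarray(means)[path] + rng.normal(0, 1, n_frames) * np.asarray(sds)[path]
        series.append(E)
        paths.append(path)
    return series, paths


class TestFitHmm:
    def test_two_state_parameter_recovery(self):
        series, _ = _markov_series([0.3, 0.7], [0.05, 0.05], 0.95, 100, 300, 1)
        model = st.fit_hmm(series, 2, seed=0)
        assert np.allclose(model.means, [0.3, 0.7], atol=0.02)
        assert model.converged

    def test_k1_mean_is_pooled_mean(self):
        rng = np.random.default_rng(2)
        series = [rng.normal(0.4, 0.05, 200) for _ in range(5)]
        model = st.fit_hmm(series, 1, seed=0)
        pooled = np.concatenate(series).mean()
        assert abs(model.means[0] - pooled) < 1e-6

    def test_three_state_recovery_with_occupancies(self):
        series, paths = _markov_series([0.0, 0.1, 0.3], [0.03] * 3, 0.95, 100, 300, 3)
        model = st.fit_hmm(series, 3, seed=0)
        assert np.allclose(model.means, [0.0, 0.1, 0.3], atol=0.02)
        # stationary occupancy of the fitted chain vs the empirical truth
        evals, evecs = np.linalg.eig(model.transmat.T)
        pi = np.real(evecs[:, np.argmin(np.abs(evals - 1))])
        pi = pi / pi.sum()
        truth = np.bincount(np.concatenate(paths), minlength=3) / sum(map(len, paths))
        assert np.allclose(pi, truth, atol=0.05)


class TestSelectModel:
    def test_constant_series_selects_one_state(self):
        rng = np.random.default_rng(4)
        series = [rng.normal(0.5, 0.01, 200) for _ in range(3)]
        K, _ = st.select_model(series, 3, seed=0)
        assert K == 1

    def test_recovers_two_and_three_states(self):
        s2, _ = _markov_series([0.3, 0.7], [0.05, 0.05], 0.95, 40, 300, 5)
        assert st.select_model(s2, 4, seed=0)[0] == 2
        s3, _ = _markov_series([0.0, 0.1, 0.3], [0.03] * 3, 0.95, 40, 300, 6)
        assert st.select_model(s3, 4, seed=0)[0] == 3

    def test_never_overshoots_truth_by_more_than_one(self):
        for true_k, (means, sds) in enumerate(
                [((0.4,), (0.05,)), ((0.3, 0.7), (0.05, 0.05)),
                 ((0.0, 0.1, 0.3), (0.03, 0.03, 0.03))], start=1):
            series, _ = _markov_series(means, sds, 0.95, 30, 200, 10 + true_k)
            K, _ = st.select_model(series, 4, seed=0)
            assert K <= true_k + 1

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            st.select_model([np.full(20, 0.3)], 2)


class TestDecode:
    def test_noiseless_two_level_exact(self):
        series, paths = _markov_series([0.3, 0.7], [1e-4, 1e-4], 0.9, 5, 200, 7)
        model = st.fit_hmm(series, 2, seed=0)
        for s, p in zip(series, paths):
            assert np.array_equal(st.decode(model, s).labels, p)

    @pytest.mark.parametrize("means,sds,min_acc", [
        ([0.3, 0.7], [0.05, 0.05], 0.98),
        ([0.0, 0.1, 0.3], [0.03, 0.03, 0.03], 0.90),
    ])
    def test_frame_accuracy(self, means, sds, min_acc):
        series, paths = _markov_series(means, sds, 0.95, 100, 300, 8)
        model = st.fit_hmm(series, len(means), seed=0)
        correct = total = 0
        for s, p in zip(series, paths):
            lab = st.decode(model, s).labels
            correct += int(np.sum(lab == p))
            total += len(p)
        assert correct / total >= min_acc

    def test_accuracy_degrades_with_emission_noise(self):
        accs = []
        for sd in (0.01, 0.03, 0.05, 0.10):
            series, paths = _markov_series([0.3, 0.7], [sd, sd], 0.95, 40, 300, 9)
            model = st.fit_hmm(series, 2, seed=0)
            correct = total = 0
            for s, p in zip(series, paths):
                lab = st.decode(model, s).labels
                correct += int(np.sum(lab == p))
                total += len(p)
            accs.append(correct / total)
        # monotone within Monte-Carlo slack
        for a, b in zip(accs, accs[1:]):
            assert b <= a + 0.005
        assert accs[0] > accs[-1]

    def test_all_invalid_series_yields_empty_path(self):
        series, _ = _markov_series([0.3, 0.7], [0.05, 0.05], 0.9, 3, 100, 10)
        model = st.fit_hmm(series, 2, seed=0)
        path = st.decode(model, np.full(50, np.nan))
        assert len(path) == 0

    def test_noiseless_simulation_round_trip_exact(self):
        cfg = sg.SimConfig(n_traces=5, n_frames=600, seed=30,
                           state_fret_sd=0.0, noise_sd=0.0, fluct_fraction=0.0)
        traces, truths = sg.simulate_dataset(cfg)
        frets = [compute_fret(t) for t in traces]
        model = st.fit_hmm(frets, 2, seed=0)
        # model state 1 is the higher-FRET (non-rotated) = truth state 0
        for f, gt in zip(frets, truths):
            decoded = st.decode(model, f).labels
            assert np.array_equal(1 - decoded, gt.path)


class TestThresholdAssign:
    def test_single_dwell_above_threshold(self):
        path = st.threshold_assign(np.full(30, 0.8), [0.5])
        assert np.all(path.labels == 1)

    def test_square_wave_exact_crossings(self):
        values = np.tile([0.9] * 5 + [0.1] * 5, 4)
        path = st.threshold_assign(values, [0.5])
        assert np.array_equal(path.labels, (values > 0.5).astype(int))

    def test_spikes_absorbed_by_min_dwell(self):
        clean = np.array([1] * 6 + [0] * 6 + [1] * 6)
        noisy = clean.copy()
        noisy[3] = 0   # 1-frame spike down
        noisy[9] = 1   # 1-frame spike up
        values = np.where(noisy == 1, 0.9, 0.1)
        path = st.threshold_assign(values, [0.5], min_dwell_frames=2)
        assert np.array_equal(path.labels, clean)

    def test_unsorted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            st.threshold_assign(np.ones(5), [0.5, 0.2])

    def test_brute_force_equivalence_all_binary_series(self):
        """Exhaustive oracle equivalence on all 2^12 binary series."""
        levels = np.array([0.1, 0.9])
        for min_dwell in (1, 2):
            for bits in itertools.product([0, 1], repeat=12):
                values = levels[list(bits)]
                got = st.threshold_assign(values, [0.5],
                                          min_dwell_frames=min_dwell).labels
                want = reference_merge_short_runs(
                    reference_threshold_labels(values, [0.5]), min_dwell)
                assert got.tolist() == want, (bits, min_dwell)


class TestAnticorrelationScreen:
    def _trace(self, donor, acceptor):
        return Trace("m", 0.2, {"donor_em": np.asarray(donor, float),
                                "acceptor_em": np.asarray(acceptor, float)})

    def _path(self, labels):
        labels = np.asarray(labels, int)
        return st.StatePath("m", np.arange(len(labels)), labels,
                            np.array([0.3, 0.7]), "hmm", 0.2)

    def test_true_transition_retained(self):
        donor = [700] * 10 + [300] * 10
        acceptor = [300] * 10 + [700] * 10
        path = self._path([0] * 10 + [1] * 10)
        out = st.correct_anticorrelated(path, self._trace(donor, acceptor))
        assert np.array_equal(out.labels, path.labels)
        assert out.log == []

    def test_acceptor_blink_removed(self):
        donor = [700.0] * 20              # donor flat
        acceptor = [300.0] * 10 + [80.0] * 10  # acceptor drops alone
        path = self._path([1] * 10 + [0] * 10)
        out = st.correct_anticorrelated(path, self._trace(donor, acceptor))
        assert np.all(out.labels == out.labels[0])
        assert out.log and out.log[0]["action"] == "remove_transition"

    def test_no_transitions_is_identity(self):
        path = self._path([1] * 15)
        out = st.correct_anticorrelated(path, self._trace([700] * 15, [300] * 15))
        assert np.array_equal(out.labels, path.labels)


def test_resolve_intermediate_flanked_by_high():
    labels = [2] * 5 + [1] * 2 + [2] * 5 + [0] * 4 + [1] * 3
    path = st.StatePath("m", np.arange(len(labels)), np.array(labels),
                        np.array([0.1, 0.4, 0.7]), "hmm", 0.2)
    out = st.resolve_intermediate(path, high_label=2, mid_label=1)
    assert np.array_equal(out.labels[:12], [2] * 12)   # flanked run absorbed
    assert np.array_equal(out.labels[12:], [0] * 4 + [1] * 3)  # others untouched
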