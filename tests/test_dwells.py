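import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from expressome import dwells as dw
from expressome import synthgen as sg
from expressome.states import StatePath
from reference_impls import reference_fluctuation_filter


def _path(labels, frame_time=0.2, mol="m0"):
    labels = np.asarray(labels, int)
    return StatePath(mol, np.arange(len(labels)), labels,
                     np.array([0.45, 0.75]), "hmm", frame_time)


NAMES = {0: "rotated", 1: "non_rotated"}


def _table_from_durations(seq, mol="m0"):
    """Dwell table from [(state_name, duration_s), ...]."""
    rows, t = [], 0.0
    for i, (state, dur) in enumerate(seq):
        rows.append({"molecule_id": mol, "state": state,
                     "codon_index": np.nan, "start_frame": int(t / 0.2),
                     "start_s": t, "duration_s": dur,
                     "censored": "left" if i == 0 else
                                 ("right" if i == len(seq) - 1 else "none")})
        t += dur
    df = pd.DataFrame(rows, columns=dw.DWELL_COLUMNS)
    codon = 0
    for idx in df.index[df["state"] == "non_rotated"]:
        codon += 1
        df.loc[idx, "codon_index"] = codon
    return df


class TestExtractDwells:
    def test_five_frame_example(self):
        # NR,NR,NR,R,R at 0.2 s -> (NR 0.6 s, left) and (R 0.4 s, right)
        table = dw.extract_dwells(_path([1, 1, 1, 0, 0]), state_names=NAMES)
        assert len(table) == 2
        assert table.iloc[0]["state"] == "non_rotated"
        assert table.iloc[0]["duration_s"] == pytest.approx(0.6)
        assert table.iloc[0]["censored"] == "left"
        assert table.iloc[1]["duration_s"] == pytest.approx(0.4)
        assert table.iloc[1]["censored"] == "right"

    def test_empty_path_empty_table(self):
        empty = StatePath("m", np.array([], int), np.array([], int),
                          np.array([0.45, 0.75]), "hmm", 0.2)
        assert dw.extract_dwells(empty).empty

    def test_codon_indices_count_incorporations(self):
        labels = sum([[1] * 3 + [0] * 2] * 3, []) + [1] * 3  # 7 alternating runs
        table = dw.extract_dwells(_path(labels), state_names=NAMES)
        assert len(table) == 7
        nr = table[table["state"] == "non_rotated"]
        assert nr["codon_index"].tolist() == [1, 2, 3, 4]


class TestPercentileThreshold:
    def test_linear_interpolation_oracle(self):
        assert dw.percentile_threshold(np.arange(1, 101), 0.05) == pytest.approx(5.95)

    def test_constant_sample(self):
        assert dw.percentile_threshold(np.full(25, 3.3), 0.5) == 3.3

    def test_exponential_closed_form(self):
        rng = np.random.default_rng(12)
        x = rng.exponential(7.0, 10000)
        q = dw.percentile_threshold(x, 0.01)
        expect = -7.0 * np.log(0.99)
        assert abs(q - expect) / expect < 0.15

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            dw.percentile_threshold(np.arange(10), 0.05)


class TestConsecutiveSubthresholdProb:
    def test_published_false_stop_rate(self):
        assert dw.consecutive_subthreshold_prob(0.05, 2) == pytest.approx(0.0025)

    def test_k1_is_q(self):
        assert dw.consecutive_subthreshold_prob(0.3, 1) == 0.3

    def test_one_percent_pair(self):
        assert dw.consecutive_subthreshold_prob(0.01, 2) == pytest.approx(1e-4)

    @pytest.mark.parametrize("q,k", [(0.0, 2), (1.0, 2), (0.05, 0)])
    def test_invalid_inputs(self, q, k):
        with pytest.raises(ValueError):
            dw.consecutive_subthreshold_prob(q, k)


class TestFluctuationFilter:
    def test_consecutive_short_pair_stops_translation_count(self):
        seq = [("non_rotated", 5.0), ("rotated", 2.0), ("non_rotated", 1.0),
               ("rotated", 2.0), ("non_rotated", 1.2), ("rotated", 2.0),
               ("non_rotated", 6.0)]
        out, log = dw.fluctuation_filter(_table_from_durations(seq), 2.18, 0.936)
        nr = out[out["state"] == "non_rotated"]
        assert len(nr) == 1
        assert nr.iloc[0]["duration_s"] == pytest.approx(5.0)
        assert log[0]["action"] == "stop_translation_count"

    def test_identity_when_all_dwells_long(self):
        seq = [("non_rotated", 5.0), ("rotated", 2.0), ("non_rotated", 6.0)]
        table = _table_from_durations(seq)
        out, log = dw.fluctuation_filter(table, 2.18, 0.936)
        pd.testing.assert_frame_equal(out.reset_index(drop=True), table)
        assert log == []

    def test_isolated_subpercentile_dwell_removed_and_merged(self):
        seq = [("non_rotated", 5.0), ("rotated", 2.0), ("non_rotated", 0.4),
               ("rotated", 3.0), ("non_rotated", 6.0)]
        out, log = dw.fluctuation_filter(_table_from_durations(seq), 2.18, 0.936)
        states = out["state"].tolist()
        assert states == ["non_rotated", "rotated", "non_rotated"]
        assert out.iloc[1]["duration_s"] == pytest.approx(2.0 + 0.4 + 3.0)
        assert any(e["action"] == "remove_short_dwell" for e in log)

    def test_codon_indices_renumbered(self):
        seq = [("non_rotated", 0.4), ("rotated", 3.0), ("non_rotated", 6.0),
               ("rotated", 3.0), ("non_rotated", 7.0)]
        out, _ = dw.fluctuation_filter(_table_from_durations(seq), 2.18, 0.936)
        nr = out[out["state"] == "non_rotated"]
        assert nr["codon_index"].tolist() == [1, 2]

    def test_exhaustive_brute_force_equivalence(self):
        """Oracle equivalence over every alternating dwell sequence of
        length <= 5 with durations from a 5-value set (3,905 cases)."""
        durations = [0.3, 0.8, 1.5, 3.0, 10.0]
        thresh5, thresh1 = 2.18, 0.936
        n_cases = 0
        for length in range(1, 6):
            for durs in itertools.product(durations, repeat=length):
                seq = [("non_rotated" if i % 2 == 0 else "rotated", d)
                       for i, d in enumerate(durs)]
                table = _table_from_durations(seq)
                got, _ = dw.fluctuation_filter(table, thresh5, thresh1)
                want = reference_fluctuation_filter(seq, thresh5, thresh1)
                assert [(r["state"], pytest.approx(r["duration_s"]))
                        for _, r in got.iterrows()] == [
                            (s, pytest.approx(d)) for s, d in want], seq
                n_cases += 1
        assert n_cases == 3905

    @given(hst.lists(hst.sampled_from([0.3, 0.8, 1.5, 3.0, 10.0]),
                     min_size=1, max_size=9))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_idempotent(self, durs):
        seq = [("non_rotated" if i % 2 == 0 else "rotated", d)
               for i, d in enumerate(durs)]
        once, _ = dw.fluctuation_filter(_table_from_durations(seq), 2.18, 0.936)
        twice, _ = dw.fluctuation_filter(once, 2.18, 0.936)
        assert once["state"].tolist() == twice["state"].tolist()
        assert np.allclose(once["duration_s"], twice["duration_s"])

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            dw.fluctuation_filter(_table_from_durations([("rotated", 1.0)]),
                                  0.5, 0.9)


class TestFitExponential:
    def test_single_recovery(self):
        x = np.random.default_rng(1).exponential(10.0, 1000)
        fit = dw.fit_exponential(x, n_boot=50, seed=0)
        assert fit.model == "single"
        assert abs(fit.taus[0] - 10.0) / 10.0 < 0.10
        lo, hi = fit.ci95["tau1"]
        assert lo < 10.0 < hi

    def test_minor_population_rule_classifies_single(self):
        rng = np.random.default_rng(2)
        x = np.where(rng.random(1000) < 0.97,
                     rng.exponential(10.0, 1000), rng.exponential(100.0, 1000))
        fit = dw.fit_exponential(x, n_boot=0)
        assert fit.model == "single"
        assert fit.minor_amplitude < 0.10

    def test_balanced_mixture_classified_double(self):
        rng = np.random.default_rng(3)
        x = np.where(rng.random(1000) < 0.5,
                     rng.exponential(2.0, 1000), rng.exponential(50.0, 1000))
        fit = dw.fit_exponential(x, n_boot=0)
        assert fit.model == "double"
        assert abs(fit.taus[0] - 2.0) / 2.0 < 0.20
        assert abs(fit.taus[1] - 50.0) / 50.0 < 0.20

    def test_censored_dwells_excluded(self):
        x = np.concatenate([np.random.default_rng(4).exponential(5.0, 100),
                            np.full(50, 500.0)])
        cens = np.concatenate([np.zeros(100, bool), np.ones(50, bool)])
        fit = dw.fit_exponential(x, censored=cens, n_boot=0)
        assert fit.taus[0] < 10.0

    def test_asymptotically_unbiased(self):
        taus = []
        for seed in range(50):
            x = np.random.default_rng(seed).exponential(10.0, 2000)
            taus.append(dw.fit_exponential(x, model="single", n_boot=0).taus[0])
        assert abs(np.mean(taus) - 10.0) / 10.0 < 0.03

    def test_too_few_dwells_rejected(self):
        with pytest.raises(ValueError):
            dw.fit_exponential(np.ones(5))


class TestCodonStats:
    def test_identical_conditions_give_p_near_one(self):
        rng = np.random.default_rng(5)
        seq = []
        for c in range(3):
            seq.append(("non_rotated", float(rng.exponential(10) + 0.1)))
            seq.append(("rotated", float(rng.exponential(5) + 0.1)))
        tab = _table_from_durations(seq)
        out = dw.codon_dwell_stats({"a": tab, "b": tab.copy()})
        a = out[out["condition"] == "a"]
        b = out[out["condition"] == "b"]
        assert np.allclose(a["median"].to_numpy(), b["median"].to_numpy())
        assert np.all(out["p_value"].to_numpy() > 0.5)

    def test_single_dwell_median_is_that_dwell(self):
        tab = _table_from_durations([("non_rotated", 4.2)])
        out = dw.codon_dwell_stats({"x": tab})
        assert out.iloc[0]["median"] == pytest.approx(4.2)
        assert out.iloc[0]["n"] == 1

    def test_collision_slowdown_visible_in_median_ratio(self):
        sched = (1, 1, 1, 2, 4, 8)
        base = dict(n_traces=120, n_frames=1200, seed=42, dwell_means=(2.0, 1.0),
                    fluct_fraction=0.0)
        tables = {}
        for cond, extra in [("elongating", {}),
                            ("colliding", {"codon_schedule": sched, "stall_codon": 6})]:
            cfg = sg.SimConfig(**base, **extra)
            rows = []
            for i in range(cfg.n_traces):
                _, gt = sg.simulate_translation_trace(cfg, i)
                d = gt.dwells[~gt.dwells["spurious"]].copy()
                d["state"] = np.where(d["state"] == 0, "non_rotated", "rotated")
                d["molecule_id"] = f"m{i}"
                d["censored"] = "none"
                rows.append(d)
            tables[cond] = pd.concat(rows, ignore_index=True)
        out = dw.codon_dwell_stats(tables, max_codon=6)
        nr = out[out["state"] == "non_rotated"]
        ratios = []
        for c in (4, 5, 6):
            e = nr[(nr["condition"] == "elongating") & (nr["codon_index"] == c)]["median"].iloc[0]
            k = nr[(nr["condition"] == "colliding") & (nr["codon_index"] == c)]["median"].iloc[0]
            ratios.append(k / e)
        assert ratios[0] < ratios[1] < ratios[2]
        assert ratios[2] > 4


def test_amino_acid_count_matches_stop_codon():
    """Completed translation cycles per trace peak at the stop position."""
    cfg = sg.SimConfig(n_traces=60, n_frames=1000, seed=55,
                       dwell_means=(2.0, 1.0), stall_codon=31,
                       codon_schedule=(1.0,) * 31, fluct_fraction=0.0)
    counts = []
    for i in range(cfg.n_traces):
        _, gt = sg.simulate_translation_trace(cfg, i)
        nr = gt.dwells[(gt.dwells["state"] == 0) & (~gt.dwells["spurious"])]
        counts.append(len(nr))
    modal = np.bincount(counts).argmax()
    assert modal == 31
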