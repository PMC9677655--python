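"""Similarity metrics, spike-pattern statistics and their oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from patsep import (
    BinnedTrain,
    ParameterError,
    RecordingSet,
    SpikeTrain,
    ValidationError,
    compactness,
    dispersion_summary,
    firing_rate,
    input_output_similarity,
    ndp,
    occupancy,
    p_burst,
    pairwise_input_similarity,
    pearson_r,
    scaling_factor,
    separation_summary,
    simulate_granule_cell,
    spike_probability,
)
from patsep.metrics import PairSimilarity, p_burst_summary


def bt(counts, w=1.0):
    counts = np.asarray(counts, dtype=int)
    return BinnedTrain(counts, bin_width=w, duration=w * len(counts))


# ---------------------------------------------------------------------------
# textbook brute-force oracles (independent code path: pure python)
# ---------------------------------------------------------------------------


def _pearson_ref(a, b):
    n = len(a)
    ma, mb = math.fsum(a) / n, math.fsum(b) / n
    cov = math.fsum((x - ma) * (y - mb) for x, y in zip(a, b))
    va = math.fsum((x - ma) ** 2 for x in a)
    vb = math.fsum((y - mb) ** 2 for y in b)
    if va == 0 or vb == 0:
        return float("nan")
    return cov / math.sqrt(va * vb)


def _cosine_ref(a, b):
    dot = math.fsum(x * y for x, y in zip(a, b))
    na = math.sqrt(math.fsum(x * x for x in a))
    nb = math.sqrt(math.fsum(y * y for y in b))
    if na == 0 or nb == 0:
        return float("nan")
    return dot / (na * nb)


def _sf_ref(a, b):
    na = math.sqrt(math.fsum(x * x for x in a))
    nb = math.sqrt(math.fsum(y * y for y in b))
    if na == 0 or nb == 0:
        return float("nan")
    return min(na, nb) / max(na, nb)


class TestScalarMetrics:
    def test_pearson_hand_example_orthogonal_after_centering(self):
        assert pearson_r(bt([1, 0, 2, 1]), bt([0, 1, 1, 2])) == pytest.approx(0.0)

    def test_pearson_self_correlation(self):
        a = bt([1, 0, 2, 1])
        assert pearson_r(a, a) == pytest.approx(1.0)

    def test_pearson_undefined_for_zero_variance(self):
        assert math.isnan(pearson_r(bt([0, 0, 0, 0]), bt([1, 0, 2, 1])))
        assert math.isnan(pearson_r(bt([2, 2, 2, 2]), bt([1, 0, 2, 1])))

    def test_ndp_orthogonal_and_colinear(self):
        assert ndp(bt([1, 0]), bt([0, 1])) == pytest.approx(0.0)
        assert ndp(bt([1, 1]), bt([2, 2])) == pytest.approx(1.0)

    def test_ndp_hand_example(self):
        assert ndp(bt([1, 0, 2, 1]), bt([0, 1, 1, 2])) == pytest.approx(4 / 6)

    def test_ndp_undefined_for_zero_norm(self):
        assert math.isnan(ndp(bt([0, 0]), bt([1, 0])))

    def test_sf_norm_ratio_and_symmetry(self):
        assert scaling_factor(bt([2, 0]), bt([1, 0])) == pytest.approx(0.5)
        assert scaling_factor(bt([1, 0]), bt([2, 0])) == pytest.approx(0.5)
        a = bt([1, 0, 2, 1])
        assert scaling_factor(a, a) == pytest.approx(1.0)

    def test_sf_hand_example_equal_norms(self):
        assert scaling_factor(bt([1, 0, 2, 1]), bt([0, 1, 1, 2])) == pytest.approx(1.0)

    def test_mismatched_binning_rejected(self):
        with pytest.raises(ParameterError):
            pearson_r(bt([1, 0]), bt([1, 0, 0]))
        with pytest.raises(ParameterError):
            ndp(bt([1, 0], w=1.0), BinnedTrain(np.array([1, 0]), 0.5, 1.0))

    def test_oracle_equivalence_on_random_small_vectors(self, rng):
        """R/NDP/SF match textbook formulas to 1e-12 on 200 random vectors."""
        for _ in range(200):
            n = rng.integers(2, 21)
            a = rng.integers(0, 6, n)
            b = rng.integers(0, 6, n)
            for fn, ref in (
                (pearson_r, _pearson_ref),
                (ndp, _cosine_ref),
                (scaling_factor, _sf_ref),
            ):
                got = fn(bt(a), bt(b))
                want = ref(a.tolist(), b.tolist())
                if math.isnan(want):
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("k", [1, 2, 3, 5])
    def test_scale_law(self, k):
        a = np.array([1, 0, 2, 1, 3])
        assert ndp(bt(a), bt(k * a)) == pytest.approx(1.0)
        assert scaling_factor(bt(a), bt(k * a)) == pytest.approx(1.0 / k)

    @given(
        counts=hst.lists(hst.integers(min_value=0, max_value=5), min_size=2,
                         max_size=15),
        counts2=hst.lists(hst.integers(min_value=0, max_value=5), min_size=2,
                          max_size=15),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_metric_symmetry(self, counts, counts2):
        n = min(len(counts), len(counts2))
        a, b = bt(counts[:n]), bt(counts2[:n])
        for fn in (pearson_r, ndp, scaling_factor):
            x, y = fn(a, b), fn(b, a)
            assert (math.isnan(x) and math.isnan(y)) or x == pytest.approx(y)


class TestPairwiseInputSimilarity:
    def test_identical_trains_give_unit_similarity(self):
        trains = [bt([1, 0, 2, 1, 0])] * 5
        for m in ("R", "NDP", "SF"):
            res = pairwise_input_similarity(trains, m)
            assert len(res.values) == 10
            assert all(v == pytest.approx(1.0) for v in res.values.values())

    def test_orthogonal_single_spike_trains_have_zero_ndp(self):
        trains = [bt(np.eye(5, dtype=int)[i]) for i in range(5)]
        res = pairwise_input_similarity(trains, "NDP")
        assert all(v == pytest.approx(0.0) for v in res.values.values())

    def test_generator_set_matches_calibration_target(self, default_input_set):
        from patsep import bin_spike_train

        binned = [bin_spike_train(t, 0.01) for t in default_input_set.trains]
        res = pairwise_input_similarity(binned, "R")
        cfg = default_input_set.config
        assert abs(res.mean - cfg.target_r) <= cfg.tolerance

    def test_undefined_pairs_flagged_and_excluded(self):
        trains = [bt([0, 0, 0]), bt([1, 0, 2]), bt([2, 1, 0])]
        res = pairwise_input_similarity(trains, "NDP")
        assert res.n_undefined == 2
        assert res.mean == pytest.approx(
            ndp(trains[1], trains[2])
        )


class TestInputOutputSimilarity:
    def test_identity_responder_sits_on_diagonal(self, identity_recording):
        for m in ("R", "NDP", "SF"):
            pairs = input_output_similarity(identity_recording, m)
            assert len(pairs) == 10
            assert all(p.s_output == p.s_input for p in pairs)
            assert separation_summary(pairs).fraction_below_diagonal == 0.0

    def test_full_protocol_combinatorics(self, stochastic_recording):
        pairs = input_output_similarity(stochastic_recording, "NDP")
        assert len(pairs) == 10
        assert all(p.n_output_pairs + p.n_undefined == 100 for p in pairs)

    def test_input_independent_outputs_decorrelate(self, default_input_set):
        """Outputs ignoring the input give mean R s_output near zero."""
        rng = np.random.default_rng(5)
        duration = 2.0
        vals = []
        for _ in range(20):
            outputs = {}
            for iid in range(1, 6):
                for rep in range(1, 11):
                    n = rng.poisson(10 * duration)
                    times = np.unique(np.round(np.sort(
                        rng.uniform(0, duration, n)), 6))
                    outputs[(iid, rep)] = SpikeTrain(times, duration)
            rec = RecordingSet("c", "SH", default_input_set.trains, outputs)
            vals += [p.s_output for p in input_output_similarity(rec, "R")]
        assert abs(np.nanmean(vals)) < 0.02

    def test_missing_sweeps_flagged_incomplete(self, default_input_set):
        outputs = {
            (1, 1): default_input_set.trains[0],
            (2, 1): default_input_set.trains[1],
        }
        rec = RecordingSet("c", "SH", default_input_set.trains, outputs)
        pairs = input_output_similarity(rec, "NDP")
        flags = {p.input_pair: p.incomplete for p in pairs}
        assert flags[(1, 2)] is False
        assert flags[(3, 4)] is True and math.isnan(
            [p for p in pairs if p.input_pair == (3, 4)][0].s_output
        )


class TestSeparationSummary:
    def _pair(self, s_in, s_out):
        return PairSimilarity("R", 0.01, (1, 2), s_in, s_out, 100, 0)

    def test_mixed_set_arithmetic(self):
        pairs = [self._pair(0.8, 0.3), self._pair(0.7, 0.9)]
        ss = separation_summary(pairs)
        assert ss.fraction_below_diagonal == pytest.approx(0.5)
        assert ss.mean_s_output == pytest.approx(0.6)
        assert ss.mean_s_input == pytest.approx(0.75)

    def test_full_separation(self):
        pairs = [self._pair(0.5, 0.0), self._pair(0.9, 0.0)]
        assert separation_summary(pairs).fraction_below_diagonal == 1.0

    def test_all_undefined_is_an_error(self):
        with pytest.raises(ValidationError):
            separation_summary([self._pair(0.5, float("nan"))])


class TestFiringRate:
    def test_uniform_sweeps(self, default_input_set):
        times = np.round(np.linspace(0.05, 1.95, 20), 6)
        outputs = {
            (iid, rep): SpikeTrain(times, 2.0)
            for iid in range(1, 6)
            for rep in range(1, 11)
        }
        rec = RecordingSet("c", "SH", default_input_set.trains, outputs)
        fr = firing_rate(rec)
        assert fr.mean_spikes_per_sweep == pytest.approx(20.0)
        assert fr.mean_rate_hz == pytest.approx(10.0)

    def test_two_sweep_mean(self, default_input_set):
        outputs = {
            (1, 1): SpikeTrain(np.round(np.linspace(0.1, 1.9, 10), 6), 2.0),
            (1, 2): SpikeTrain(np.round(np.linspace(0.05, 1.95, 30), 6), 2.0),
        }
        rec = RecordingSet("c", "SH", default_input_set.trains, outputs)
        assert firing_rate(rec).mean_spikes_per_sweep == pytest.approx(20.0)

    def test_all_empty_sweeps_give_zero_hz(self, default_input_set):
        outputs = {(1, 1): SpikeTrain(np.array([]), 2.0)}
        rec = RecordingSet("c", "SH", default_input_set.trains, outputs)
        assert firing_rate(rec).mean_rate_hz == 0.0


class TestPBurst:
    def test_counts_of_two_one_zero_give_one_third(self):
        stim = SpikeTrain(np.array([0.1, 0.5, 0.9]), 2.0)
        out = SpikeTrain(np.array([0.105, 0.11, 0.505]), 2.0)
        assert p_burst(out, stim) == pytest.approx(1 / 3)

    def test_identity_responder_never_bursts(self, identity_recording):
        assert p_burst_summary(identity_recording) == 0.0

    def test_doublet_responder_always_bursts(self, default_input_set):
        rec = simulate_granule_cell(
            default_input_set.trains,
            cfg=__import__("patsep").ResponderConfig(
                p_spike=1.0, latency_mean=0.003, latency_sd=0.0, p_extra=1.0,
                refractory=0.0, spontaneous_rate=0.0, seed=0,
            ),
            cell_id="burst",
        )
        assert p_burst_summary(rec) == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            p_burst(SpikeTrain(np.array([0.1]), 2.0), SpikeTrain(np.array([]), 2.0))

    def test_window_truncated_at_next_stimulus(self):
        # second spike of the pair lands after the next stimulus: no burst
        stim = SpikeTrain(np.array([0.1, 0.12]), 2.0)
        out = SpikeTrain(np.array([0.105, 0.125]), 2.0)
        assert p_burst(out, stim) == 0.0


class TestCompactnessOccupancy:
    def test_fraction_of_occupied_bins(self):
        counts = np.zeros(200, dtype=int)
        counts[[3, 50, 120]] = 1
        assert compactness(bt(counts, w=0.01)) == pytest.approx(0.015)

    def test_spikes_per_occupied_bin(self):
        counts = np.zeros(10, dtype=int)
        counts[[0, 4, 7]] = [2, 2, 1]
        assert occupancy(bt(counts)) == pytest.approx(5 / 3)

    def test_empty_train_conventions(self):
        b = bt(np.zeros(10, dtype=int))
        assert compactness(b) == 0.0
        assert math.isnan(occupancy(b))


class TestDispersion:
    def test_identical_sweeps_have_zero_variation(self, default_input_set):
        times = np.round(np.linspace(0.1, 1.9, 15), 6)
        outputs = {(1, r): SpikeTrain(times, 2.0) for r in range(1, 6)}
        rec = RecordingSet("c", "SH", default_input_set.trains, outputs)
        d = dispersion_summary(rec)
        assert d.occupancy_variation == 0.0
        assert d.fr_variation == 0.0

    def test_two_sweep_fr_variation(self, default_input_set):
        outputs = {
            (1, 1): SpikeTrain(np.round(np.linspace(0.1, 1.9, 10), 6), 2.0),
            (1, 2): SpikeTrain(np.round(np.linspace(0.1, 1.9, 14), 6), 2.0),
        }
        rec = RecordingSet("c", "SH", default_input_set.trains, outputs)
        assert dispersion_summary(rec).fr_variation == pytest.approx(4.0)

    def test_mean_compactness_over_sweeps(self, default_input_set):
        t1 = np.round(np.arange(20) * 0.05 + 0.001, 6)   # 20 occupied bins
        t2 = np.round(np.arange(40) * 0.045 + 0.001, 6)  # 40 occupied bins
        outputs = {
            (1, 1): SpikeTrain(t1, 2.0),
            (1, 2): SpikeTrain(t2, 2.0),
        }
        rec = RecordingSet("c", "SH", default_input_set.trains, outputs)
        assert dispersion_summary(rec).binwise_compactness == pytest.approx(
            (0.10 + 0.20) / 2
        )

    def test_single_sweep_is_an_error(self, default_input_set):
        outputs = {(1, 1): SpikeTrain(np.array([0.5]), 2.0)}
        rec = RecordingSet("c", "SH", default_input_set.trains, outputs)
        with pytest.raises(ValidationError):
            dispersion_summary(rec)


class TestSpikeProbability:
    def test_identity_responder_fails_qc_at_unit_probability(
        self, identity_recording
    ):
        sp = spike_probability(identity_recording)
        assert sp.probability == 1.0 and not sp.qc_pass

    def test_silent_cell_fails_qc_at_zero(self, default_input_set):
        rec = simulate_granule_cell(
            default_input_set.trains,
            cfg=__import__("patsep").ResponderConfig(
                p_spike=0.0, spontaneous_rate=0.0, seed=0
            ),
        )
        sp = spike_probability(rec)
        assert sp.probability == 0.0 and not sp.qc_pass

    def test_default_responder_passes_qc(self, stochastic_recording):
        assert spike_probability(stochastic_recording).qc_pass
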