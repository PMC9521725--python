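import itertools

import numpy as np
import pytest

from deepmap import ChannelSpec, SimulationConfig, generate_recording
from deepmap.core import Outcome
from deepmap.ep import assess_stability, detect_s1_eps, detect_s2_ep
from deepmap.stimulus import classify_train, detect_pacing_artifacts


def _train_of(rec):
    return classify_train(detect_pacing_artifacts(rec))


class TestS1Detection:
    def test_clean_latencies_within_one_sample(self, clean_case):
        _, rec, truth = clean_case
        train = _train_of(rec)
        eps = detect_s1_eps(rec, train, "B1")
        assert not isinstance(eps, Outcome)
        assert len(eps) == 3
        for ep in eps:
            assert abs(ep.latency - 40.0) <= rec.sample_period_ms

    def test_s1_latencies_identical_despite_decrement(self, clean_case):
        _, rec, _ = clean_case
        train = _train_of(rec)
        eps = detect_s1_eps(rec, train, "B3")  # planted decrement 35 ms
        lats = [ep.latency for ep in eps]
        assert max(lats) - min(lats) <= 1e-9

    def test_flat_channel_insufficient(self, clean_case):
        _, rec, _ = clean_case
        train = _train_of(rec)
        rec2_bip = dict(rec.bipolar_channels)
        rec2_bip["FLAT"] = np.zeros(rec.n_samples)
        from deepmap import Recording
        rec2 = Recording(rec.sampling_rate, rec.surface_channels, rec2_bip,
                         {**rec.electrode_positions, "FLAT": np.zeros(3)})
        assert detect_s1_eps(rec2, train, "FLAT") is Outcome.INSUFFICIENT_S1

    def test_latency_inside_search_window(self, noisy_case):
        _, rec, _ = noisy_case
        train = _train_of(rec)
        for ch in rec.bipolar_channels:
            eps = detect_s1_eps(rec, train, ch)
            assert not isinstance(eps, Outcome)
            for ep in eps:
                assert 10.0 <= ep.latency <= 0.9 * train.s1_interval


class TestStability:
    def test_identical_eps_perfectly_stable(self, clean_case):
        _, rec, _ = clean_case
        eps = detect_s1_eps(rec, _train_of(rec), "B1")
        res = assess_stability(eps)
        assert res.latency_sd == pytest.approx(0.0, abs=1e-9)
        assert res.mean_pairwise_morphology_correlation == pytest.approx(1.0)
        assert res.stable

    def test_latency_sd_matches_hand_computation(self, clean_case):
        _, rec, _ = clean_case
        eps = detect_s1_eps(rec, _train_of(rec), "B1")
        eps[0].latency, eps[1].latency, eps[2].latency = 40.0, 46.0, 52.0
        res = assess_stability(eps)
        # population sd of {40, 46, 52} = sqrt(24) = 4.899
        assert res.latency_sd == pytest.approx(np.sqrt(24.0))
        assert res.stable  # 4.90 ms sits just inside the 5-ms default

    def test_noise_morphology_breaks_stability(self, clean_case, rng):
        _, rec, _ = clean_case
        eps = detect_s1_eps(rec, _train_of(rec), "B1")
        noisy = [eps[0], eps[1], eps[2]]
        noisy[2].morphology = rng.normal(0, 1, len(eps[2].morphology))
        res = assess_stability(noisy)
        assert res.mean_pairwise_morphology_correlation < 0.85
        assert not res.stable

    def test_permutation_invariant(self, clean_case):
        _, rec, _ = clean_case
        eps = detect_s1_eps(rec, _train_of(rec), "B2")
        base = assess_stability(eps)
        for perm in itertools.permutations(eps):
            res = assess_stability(list(perm))
            assert res.latency_sd == pytest.approx(base.latency_sd)
            assert (res.mean_pairwise_morphology_correlation
                    == pytest.approx(base.mean_pairwise_morphology_correlation))

    def test_wrong_cardinality_is_typed_outcome(self, clean_case):
        _, rec, _ = clean_case
        eps = detect_s1_eps(rec, _train_of(rec), "B1")
        assert assess_stability(eps[:2]) is Outcome.INSUFFICIENT_S1


class TestS2Detection:
    def test_planted_decrement_recovered(self, clean_case):
        _, rec, _ = clean_case
        train = _train_of(rec)
        eps = detect_s1_eps(rec, train, "B3")
        s2 = detect_s2_ep(rec, train, "B3", eps[-1])
        assert not isinstance(s2, Outcome)
        assert abs(s2.latency - (45.0 + 35.0)) <= rec.sample_period_ms

    def test_zero_decrement_means_equal_latency(self, clean_case):
        _, rec, _ = clean_case
        train = _train_of(rec)
        eps = detect_s1_eps(rec, train, "B1")
        s2 = detect_s2_ep(rec, train, "B1", eps[-1])
        assert abs(s2.latency - eps[-1].latency) <= rec.sample_period_ms

    def test_blocked_channel_reports_absent(self, clean_case):
        _, rec, _ = clean_case
        train = _train_of(rec)
        eps = detect_s1_eps(rec, train, "B4")
        assert detect_s2_ep(rec, train, "B4", eps[-1]) is Outcome.S2_EP_ABSENT

    def test_no_s2_train_is_typed_outcome(self):
        cfg = SimulationConfig(noise_sd=0.0, include_s2=False)
        rec, _ = generate_recording(cfg)
        train = _train_of(rec)
        assert not train.has_s2
        eps = detect_s1_eps(rec, train, "B1")
        assert detect_s2_ep(rec, train, "B1", eps[-1]) is Outcome.NO_S2

    @pytest.mark.parametrize("shift", [0.0, 5.0, 10.0, 25.0, 50.0, 100.0])
    def test_template_lag_equals_planted_shift(self, shift):
        cfg = SimulationConfig(
            noise_sd=0.0,
            channels=[ChannelSpec("B1", base_ep_latency=40.0,
                                  planted_decrement=shift)],
            rng_seed=1)
        rec, _ = generate_recording(cfg)
        train = _train_of(rec)
        eps = detect_s1_eps(rec, train, "B1")
        s2 = detect_s2_ep(rec, train, "B1", eps[-1])
        assert abs((s2.latency - eps[-1].latency) - shift) \
            <= rec.sample_period_ms
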