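import numpy as np
import pytest
from scipy import stats

from synaptoquant import synthetic_data as sd
from synaptoquant.errors import ParameterError, PlacementError

from oracles import train_recursion


class TestPunctaFieldSpec:
    def test_invalid_fraction_rejected(self):
        with pytest.raises(ParameterError):
            sd.PunctaFieldSpec(coloc_fraction=1.2)

    def test_pairs_exceeding_partners_rejected(self):
        with pytest.raises(ParameterError):
            sd.PunctaFieldSpec(n_puncta_a=100, n_puncta_b=10,
                               coloc_fraction=0.5)


class TestGenPunctaImagePair:
    def test_zero_fraction_no_pairs(self):
        spec = sd.PunctaFieldSpec(coloc_fraction=0.0)
        _, _, truth = sd.gen_puncta_image_pair(spec, 0)
        assert truth["pairs"] == []

    def test_full_fraction_all_paired(self):
        spec = sd.PunctaFieldSpec(n_puncta_a=50, n_puncta_b=50,
                                  coloc_fraction=1.0,
                                  image_size=(512, 512))
        _, _, truth = sd.gen_puncta_image_pair(spec, 1)
        assert len(truth["pairs"]) == 50

    def test_rounded_pair_count(self):
        spec = sd.PunctaFieldSpec(n_puncta_a=200, n_puncta_b=200,
                                  coloc_fraction=0.3,
                                  image_size=(768, 768))
        _, _, truth = sd.gen_puncta_image_pair(spec, 2)
        assert len(truth["pairs"]) == 60

    def test_centers_inside_image(self):
        spec = sd.PunctaFieldSpec(image_size=(128, 128), n_puncta_a=10,
                                  n_puncta_b=10)
        _, _, truth = sd.gen_puncta_image_pair(spec, 3)
        h, w = spec.image_size
        for (r, c) in truth["centers_a"] + truth["centers_b"]:
            assert 0 <= r <= h - 1 and 0 <= c <= w - 1

    def test_pair_offsets_bounded(self):
        spec = sd.PunctaFieldSpec(max_center_offset_px=2.0)
        _, _, truth = sd.gen_puncta_image_pair(spec, 4)
        for ia, ib in truth["pairs"]:
            ar, ac = truth["centers_a"][ia]
            br, bc = truth["centers_b"][ib]
            assert np.hypot(ar - br, ac - bc) <= 2.0 + 1e-9

    def test_non_pair_separation(self):
        spec = sd.PunctaFieldSpec()
        _, _, truth = sd.gen_puncta_image_pair(spec, 5)
        paired_a = {ia for ia, _ in truth["pairs"]}
        min_sep = 4.0 * spec.punctum_radius_px
        a = np.array(truth["centers_a"])
        b = np.array(truth["centers_b"])
        for i, ctr in enumerate(a):
            if i in paired_a:
                continue
            d = np.hypot(*(b - ctr).T)
            assert d.min() >= min_sep - 1e-9

    def test_reproducible(self):
        spec = sd.PunctaFieldSpec()
        a1, b1, t1 = sd.gen_puncta_image_pair(spec, 7)
        a2, b2, t2 = sd.gen_puncta_image_pair(spec, 7)
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_array_equal(b1, b2)
        assert t1["pairs"] == t2["pairs"]

    def test_impossible_packing_raises(self):
        spec = sd.PunctaFieldSpec(image_size=(64, 64), n_puncta_a=200,
                                  n_puncta_b=200, coloc_fraction=0.0)
        with pytest.raises(PlacementError):
            sd.gen_puncta_image_pair(spec, 0)


class TestSimulateTrain:
    def test_full_release_no_replenish(self):
        spec = sd.TrainSimSpec(n0=100.0, p_release=1.0, r_replenish=0.0,
                               q_amp=2.0, noise_sd=0.0, n_sweeps=1,
                               n_pulses=10)
        table = sd.simulate_train(spec, 0)
        assert table[0, 0] == pytest.approx(200.0)
        np.testing.assert_allclose(table[0, 1:], 0.0, atol=1e-12)

    def test_steady_state_from_first_pulse(self):
        # r*dt == p*n0 -> all amplitudes equal
        spec = sd.TrainSimSpec(n0=100.0, p_release=0.2, r_replenish=400.0,
                               rate_hz=20.0, q_amp=1.0, noise_sd=0.0,
                               n_sweeps=1)
        table = sd.simulate_train(spec, 0)
        np.testing.assert_allclose(table[0], table[0, 0], rtol=1e-12)

    def test_matches_recursion_oracle(self, default_train_spec):
        table = sd.simulate_train(default_train_spec, 0)
        oracle = train_recursion(
            default_train_spec.n0, default_train_spec.p_release,
            default_train_spec.r_replenish, default_train_spec.q_amp,
            default_train_spec.n_pulses, default_train_spec.rate_hz)
        np.testing.assert_allclose(table[0], oracle, rtol=1e-14)

    def test_matches_closed_form(self, default_train_spec):
        table = sd.simulate_train(default_train_spec, 0)
        amps, cum = sd.train_closed_form(default_train_spec)
        np.testing.assert_allclose(table[0], amps, rtol=1e-10)
        np.testing.assert_allclose(np.cumsum(table[0]), cum, rtol=1e-10)

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
    def test_invalid_release_prob(self, p):
        with pytest.raises(ParameterError):
            sd.TrainSimSpec(p_release=p)

    def test_reproducible(self):
        spec = sd.TrainSimSpec(noise_sd=10.0)
        np.testing.assert_array_equal(sd.simulate_train(spec, 5),
                                      sd.simulate_train(spec, 5))


class TestSimulateMiniTrace:
    def test_zero_rate_pure_noise(self):
        spec = sd.MiniTrainSpec(duration_s=2.0, event_rate_hz=0.0,
                                noise_sd=1.0)
        trace, truth = sd.simulate_mini_trace(spec, 0)
        assert len(truth) == 0
        assert abs(np.std(trace) - 1.0) < 0.05

    def test_zero_amp_sd_constant_amplitudes(self):
        spec = sd.MiniTrainSpec(duration_s=10.0, amp_sd=0.0, amp_mean=20.0)
        _, truth = sd.simulate_mini_trace(spec, 1)
        assert (truth["amplitude"] == 20.0).all()

    def test_event_times_within_duration(self):
        spec = sd.MiniTrainSpec(duration_s=5.0)
        _, truth = sd.simulate_mini_trace(spec, 2)
        assert ((truth["time_s"] >= 0) & (truth["time_s"] <= 5.0)).all()
        assert truth["time_s"].is_monotonic_increasing

    def test_mean_count_in_poisson_interval(self):
        # 100 seeds at 120 s x 3 Hz: mean count within the 95% interval
        # for the mean of 100 Poisson(360) draws
        spec = sd.MiniTrainSpec(duration_s=120.0, event_rate_hz=3.0,
                                noise_sd=0.0)
        counts = [len(sd.simulate_mini_trace(spec, s)[1])
                  for s in range(100)]
        lam = 360.0
        se = np.sqrt(lam / 100)
        assert lam - 1.96 * se <= np.mean(counts) <= lam + 1.96 * se

    def test_counts_poisson_chisquare(self):
        # chi-square goodness of fit of event counts over 1000 seeds
        spec = sd.MiniTrainSpec(duration_s=4.0, event_rate_hz=5.0,
                                noise_sd=0.0, fs_hz=1000.0)
        lam = 20.0
        counts = np.array([len(sd.simulate_mini_trace(spec, s)[1])
                           for s in range(1000)])
        lo, hi = int(lam - 3 * np.sqrt(lam)), int(lam + 3 * np.sqrt(lam))
        edges = np.arange(lo, hi + 1)
        obs = np.array([(counts == k).sum() for k in edges], dtype=float)
        obs = np.concatenate([[np.sum(counts < lo)], obs,
                              [np.sum(counts > hi)]])
        pmf = stats.poisson.pmf(edges, lam)
        probs = np.concatenate([[stats.poisson.cdf(lo - 1, lam)], pmf,
                                [stats.poisson.sf(hi, lam)]])
        chi2, p = stats.chisquare(obs, probs * 1000)
        assert p > 0.01

    def test_invalid_taus(self):
        with pytest.raises(ParameterError):
            sd.MiniTrainSpec(tau_rise_ms=5.0, tau_decay_ms=2.0)


class TestSimulateLfp:
    def test_single_component_periodogram_peak(self):
        spec = sd.LfpSpec(duration_s=4.0, components=((6.0, 10.0),),
                          noise_sd=0.0, spike_times_s=())
        trace, _ = sd.simulate_lfp(spec, 0)
        freqs = np.fft.rfftfreq(len(trace), 1 / spec.fs_hz)
        power = np.abs(np.fft.rfft(trace)) ** 2
        assert abs(freqs[np.argmax(power)] - 6.0) < 0.3

    def test_truth_sorted(self):
        spec = sd.LfpSpec(duration_s=2.0, spike_times_s=(1.5, 0.3, 0.9))
        _, truth = sd.simulate_lfp(spec, 0)
        assert truth["time_s"].is_monotonic_increasing

    def test_artifact_flagged(self):
        spec = sd.LfpSpec(duration_s=2.0, spike_times_s=(0.5, 1.0),
                          spike_amp_sd_units=(10.0, 40.0))
        _, truth = sd.simulate_lfp(spec, 0)
        assert list(truth["excluded"]) == [False, True]

    def test_spike_beyond_duration_rejected(self):
        with pytest.raises(ParameterError):
            sd.LfpSpec(duration_s=1.0, spike_times_s=(2.0,))

    def test_component_beyond_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            sd.LfpSpec(fs_hz=1000.0, components=((600.0, 1.0),))

    def test_spike_amplitude_scaling(self):
        spec = sd.LfpSpec(duration_s=1.0, components=(), noise_sd=2.0,
                          spike_times_s=(0.5,), spike_amp_sd_units=10.0)
        trace, _ = sd.simulate_lfp(spec, 3)
        # negative peak near the planted time should approach -20
        i = int(0.5 * spec.fs_hz)
        seg = trace[i - 40: i + 40]
        assert seg.min() < -20.0 + 6.0  # template -20 plus noise


class TestGenGroupSamples:
    def test_identical_specs_give_same_family(self):
        spec = sd.GroupSampleSpec(n1=5000, n2=5000, nu=30.0)
        g1, g2, _ = sd.gen_group_samples(spec, 0)
        ks = stats.ks_2samp(g1, g2)
        assert ks.pvalue > 0.01

    def test_outlier_truth_count(self):
        spec = sd.GroupSampleSpec(n1=10, n2=10, n_outliers=2)
        _, _, truth = sd.gen_group_samples(spec, 1)
        assert len(truth["outlier_indices"]) == 2

    def test_outlier_values_exact(self):
        spec = sd.GroupSampleSpec(n1=10, n2=10, mu1=5.0, sd1=2.0,
                                  n_outliers=1, outlier_sd_offset=10.0)
        g1, _, truth = sd.gen_group_samples(spec, 2)
        idx = truth["outlier_indices"][0]
        assert g1[idx] == pytest.approx(25.0)

    def test_sd_matches_spec(self):
        spec = sd.GroupSampleSpec(n1=10_000, n2=10_000, sd1=3.0, sd2=3.0,
                                  nu=30.0)
        g1, _, _ = sd.gen_group_samples(spec, 3)
        assert abs(np.std(g1, ddof=1) - 3.0) / 3.0 < 0.03

    def test_invalid_nu(self):
        with pytest.raises(ParameterError):
            sd.GroupSampleSpec(nu=0.0)


class TestGenTree:
    def test_unbranched_path(self):
        spec = sd.TreeSpec(n_branches=0, total_length_um=300.0)
        nodes = sd.gen_tree(spec, 0)
        counts = nodes["parent"].value_counts()
        assert (counts[counts.index != -1] <= 1).all()

    def test_total_length(self):
        spec = sd.TreeSpec(n_branches=4, total_length_um=300.0)
        nodes = sd.gen_tree(spec, 1)
        xyz = nodes.set_index("id")[["x", "y", "z"]]
        total = 0.0
        for _, r in nodes.iterrows():
            if r["parent"] == -1:
                continue
            total += np.linalg.norm(
                xyz.loc[int(r["id"])].to_numpy()
                - xyz.loc[int(r["parent"])].to_numpy())
        assert abs(total - 300.0) / 300.0 < 0.01

    @pytest.mark.parametrize("n_branches", [0, 1, 3, 8])
    def test_branch_count(self, n_branches):
        spec = sd.TreeSpec(n_branches=n_branches)
        nodes = sd.gen_tree(spec, 2)
        counts = nodes["parent"].value_counts()
        n_bif = int((counts[counts.index != -1] >= 2).sum())
        assert n_bif == n_branches

    def test_connected_acyclic(self):
        spec = sd.TreeSpec(n_branches=5)
        nodes = sd.gen_tree(spec, 3)
        seen = set()
        for _, r in nodes.iterrows():
            p = int(r["parent"])
            assert p == -1 or p in seen  # parents precede children
            seen.add(int(r["id"]))

    def test_reproducible(self):
        spec = sd.TreeSpec()
        n1 = sd.gen_tree(spec, 9)
        n2 = sd.gen_tree(spec, 9)
        assert n1.equals(n2)
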