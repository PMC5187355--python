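"""Synthetic-data generator: design validation and sampling statistics."""

import numpy as np
import pytest
from scipy import stats

import spikemix as sm
from spikemix._kernels import simulate_bernoulli
from spikemix.design import DesignError, build_design, simulate_paired_neurons
from spikemix.likelihood import MS_TO_S


class TestBuildDesign:
    def test_defaults_match_experiment(self):
        d = build_design()
        assert d.n_directions == 12
        assert d.trials_per_cell == {"fix1": 4, "fix2": 4, "attend-fix": 4,
                                     "attend-in": 12}
        assert d.window_length == 500.0 and d.dt == 1.0
        assert d.aperture2_offset == pytest.approx(-2 * np.pi / 3)

    def test_long_window_for_boundary_study(self):
        assert build_design(window_length=2000.0).n_bins == 2000

    def test_too_few_trials_rejected(self):
        with pytest.raises(DesignError, match=r"trials_per_cell\[fix1\]"):
            build_design(trials_per_cell={"fix1": 1})

    def test_empty_conditions_rejected(self):
        with pytest.raises(DesignError, match="empty condition"):
            build_design(conditions=())

    def test_fractional_window_rejected(self):
        with pytest.raises(DesignError, match="window_length"):
            build_design(window_length=500.5)


class TestSimulateTrial:
    def test_constant_rate_mean_count(self):
        # Bernoulli-thinned constant intensity: E[N] = r * T
        r, n_trials = 20.0, 1000
        rng = np.random.default_rng(0)
        u = rng.random((n_trials, 500))
        spikes, n_clamped = simulate_bernoulli(u, np.full(n_trials, r), 0.0,
                                               np.zeros(10), 1.0)
        counts = spikes.sum(axis=1)
        expected = r * 0.5
        se = counts.std(ddof=1) / np.sqrt(n_trials)
        assert abs(counts.mean() - expected) < 3 * se
        assert n_clamped == 0

    def test_absolute_refractoriness(self):
        # gamma1 = -20 suppresses spiking in the next bin by e^-20
        rng = np.random.default_rng(1)
        u = rng.random((200, 500))
        gammas = np.array([-20.0] + [0.0] * 9)
        spikes, _ = simulate_bernoulli(u, np.full(200, 80.0), 0.0, gammas, 1.0)
        adjacent = np.sum(spikes[:, 1:] * spikes[:, :-1])
        assert adjacent == 0

    def test_degenerate_mixture_all_labels_one(self):
        design = build_design(
            conditions=("attend-fix",), trials_per_cell={"attend-fix": 4}
        )
        truth = sm.default_ground_truth("mixing", p_attend_fix=1.0)
        _, labels = sm.simulate_dataset(design, truth, 1, seed=3)
        assert set(labels.values()) == {1}

    def test_isi_distribution_is_geometric(self):
        # constant rate, no history: ISIs (in bins) are geometric with
        # success probability r * dt.  To avoid window-censoring bias,
        # compare ISIs from spikes at least `horizon` bins before the
        # window end, restricted to lengths <= horizon, against the
        # geometric CDF conditioned on the same event (exact).
        r, T, horizon = 20.0, 500, 300
        p = r * MS_TO_S
        rng = np.random.default_rng(2)
        u = rng.random((3500, T))
        spikes, _ = simulate_bernoulli(u, np.full(3500, r), 0.0, np.zeros(1), 1.0)
        isis = []
        for row in spikes:
            idx = np.flatnonzero(row)
            ok = idx[:-1] < T - horizon
            d = np.diff(idx)[ok]
            isis.append(d[d <= horizon])
        isis = np.concatenate(isis)
        assert isis.size > 10_000
        ks = np.arange(1, horizon + 1)
        emp = np.searchsorted(np.sort(isis), ks, side="right") / isis.size
        theo = (1 - (1 - p) ** ks) / (1 - (1 - p) ** horizon)
        # alpha=0.01 KS critical value for this n
        assert np.max(np.abs(emp - theo)) < 1.63 / np.sqrt(isis.size)


class TestSimulateDataset:
    def test_determinism(self):
        design = build_design()
        truth = sm.default_ground_truth("mixing")
        rec1, lab1 = sm.simulate_dataset(design, truth, 2, seed=9)
        rec2, lab2 = sm.simulate_dataset(design, truth, 2, seed=9)
        assert lab1 == lab2
        for a, b in zip(rec1, rec2):
            assert np.array_equal(a.train.times, b.train.times)

    def test_latent_label_frequency(self):
        design = build_design(
            conditions=("attend-in",), trials_per_cell={"attend-in": 40}
        )
        truth = sm.default_ground_truth("mixing", p_attend_in=0.7)
        _, labels = sm.simulate_dataset(design, truth, 1, seed=4)
        freq = np.mean([v == 1 for v in labels.values()])
        n = len(labels)
        assert n == 480
        se = np.sqrt(0.7 * 0.3 / n)
        assert abs(freq - 0.7) < 3 * se

    def test_grid_is_complete(self):
        design = build_design()
        records, _ = sm.simulate_dataset(design, sm.default_ground_truth("mixing"),
                                         1, seed=5)
        assert len(records) == 12 * (4 + 4 + 4 + 12)
        # per-cell trial counts follow the design
        per = {}
        for r in records:
            per[(r.condition, r.direction_index)] = per.get(
                (r.condition, r.direction_index), 0) + 1
        assert per[("attend-in", 7)] == 12 and per[("fix1", 7)] == 4

    def test_averaging_spike_counts_are_unimodal_mixing_bimodal(self):
        # per-trial spike counts: bimodal under mixing with separated
        # rates, unimodal under averaging with the same marginal mean
        design = build_design(conditions=("attend-fix",),
                              trials_per_cell={"attend-fix": 200})
        counts = {}
        dither = np.random.default_rng(0)
        for kind in ("mixing", "averaging"):
            truth = sm.default_ground_truth(kind)
            records, _ = sm.simulate_dataset(design, truth, 1, seed=6)
            recs = [r for r in records if r.direction_index == 1]
            c = np.array([r.train.n_spikes for r in recs], dtype=float)
            # dither integer counts: the dip test reads exact ties as
            # discreteness (spurious modes)
            counts[kind] = c + dither.uniform(-0.5, 0.5, c.size)
        mix = sm.dip_test(counts["mixing"], n_boot=500, seed=0)
        avg = sm.dip_test(counts["averaging"], n_boot=500, seed=0)
        assert mix.p_value < 0.05
        assert avg.p_value > 0.05


class TestPairedNeurons:
    def _truths(self, offset_b=0.0):
        a = sm.default_ground_truth("mixing")
        # neuron B: equal amplitudes in both apertures, so its preferred
        # direction (offset_b) alone decides which stimulus drives it more
        tun_b = sm.TuningParams(A1=30, sigma1=1.2, A2=30, sigma2=1.2, r0=5,
                                D=offset_b)
        params_b = sm.ModelParams("mixing", tun_b, a.params.attn, a.params.history)
        return a, sm.GroundTruth("mixing", params_b)

    def _design(self, n=120):
        return build_design(conditions=("attend-fix",),
                            trials_per_cell={"attend-fix": n})

    def _rho_at(self, records_a, records_b, k):
        ra = [r.train.n_spikes for r in records_a if r.direction_index == k]
        rb = [r.train.n_spikes for r in records_b if r.direction_index == k]
        return stats.spearmanr(ra, rb)

    def test_full_coupling_positive_correlation(self):
        a, b = self._truths()
        rec_a, rec_b, _ = simulate_paired_neurons(self._design(200), a, b,
                                                  coupling=1.0, seed=7)
        rho, p = self._rho_at(rec_a, rec_b, 1)  # preferred direction: rates differ
        assert rho > 0.3 and p < 1e-3

    def test_zero_coupling_uncorrelated(self):
        a, b = self._truths()
        rec_a, rec_b, _ = simulate_paired_neurons(self._design(200), a, b,
                                                  coupling=0.0, seed=8)
        rho, p = self._rho_at(rec_a, rec_b, 1)
        assert abs(rho) < 0.2

    def test_opposed_preferences_negative_correlation(self):
        # neuron B prefers 60 deg clockwise: at configuration k=2 neuron A
        # responds more to stimulus 1, neuron B to stimulus 2
        a, b = self._truths(offset_b=-np.pi / 3)
        rec_a, rec_b, _ = simulate_paired_neurons(self._design(200), a, b,
                                                  coupling=1.0, seed=9)
        rho, p = self._rho_at(rec_a, rec_b, 2)
        assert rho < -0.3 and p < 1e-3

    def test_averaging_truth_rejected(self):
        a = sm.default_ground_truth("mixing")
        b = sm.default_ground_truth("averaging")
        with pytest.raises(DesignError, match="mixing ground truths"):
            simulate_paired_neurons(self._design(), a, b, coupling=0.5)

    def test_coupling_bounds(self):
        a, b = self._truths()
        with pytest.raises(DesignError, match="coupling"):
            simulate_paired_neurons(self._design(), a, b, coupling=1.5)
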