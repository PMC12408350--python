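"""Viterbi decoding, time-rescaling R^2, phi estimation, choice prediction,
LONO and unit selection.

Oracles: exhaustive path search on a tiny grid, the deterministic flow
limit, closed-form Poisson moments, and gamma-renewal CV^2 = 1/shape.
"""

import itertools

import numpy as np
import pytest
import scipy.stats

from latentspike.data import SpikeData, Trial
from latentspike.grid import _build_grid_unchecked, build_grid
from latentspike.model import LatentModel
from latentspike.validation import (
    balanced_accuracy,
    baseline_decoder,
    compute_psth,
    estimate_phi,
    lono_rate,
    orient_to_choices,
    path_log_joint,
    predict_choice,
    rescale_spikes,
    spike_time_r2,
    unit_selection,
    viterbi_path,
    _count_features,
)


class TestViterbi:
    def test_exhaustive_search_tiny_grid(self):
        g = _build_grid_unchecked(5)
        model = LatentModel(
            grid=g,
            forces=np.array([[0.4, 0.1, -0.2, 0.3, 0.2]]),
            D=0.5,
            F0=np.array([0.2, 0.1, 0.0, -0.1, 0.0]),
            tuning_aux=np.vstack([np.full(5, 0.5), np.full(5, -0.4)]),
            tuning_C=np.array([6.0, 9.0]),
        )
        trial = Trial(0.0, 0.5, np.array([0.1, 0.25, 0.4]),
                      np.array([0, 1, 0]), 0)
        path = viterbi_path(model, trial, 0)
        best = -np.inf
        best_combo = None
        for combo in itertools.product(range(3), repeat=4):
            for b in (-1, 1):
                idx = np.array(list(combo) + [-1])
                lj = path_log_joint(model, trial, 0, idx, b)
                if lj > best:
                    best, best_combo = lj, (idx.copy(), b)
        np.testing.assert_array_equal(path.node_indices[:-1], best_combo[0][:-1])
        assert path.terminal_boundary() == best_combo[1]
        assert abs(path.log_joint - best) < 1e-9

    def test_terminal_state_is_boundary(self, grid32):
        model = LatentModel.blank(grid32, 1, 1, D=0.3, rates=np.array([10.0]))
        trial = Trial(0.0, 0.4, np.array([0.2]), np.array([0]), 0)
        path = viterbi_path(model, trial, 0)
        assert path.states[-1] in (-1.0, 1.0)

    def test_strong_drift_tracks_deterministic_flow(self):
        # D small, constant force: x(t) ~ x0 + D F t until absorption
        g = build_grid(64)
        D, F = 0.15, 6.0
        model = LatentModel(
            grid=g,
            forces=np.full((1, g.n), F),
            D=D,
            F0=-(g.nodes + 0.8) / 0.05**2,
            tuning_aux=np.zeros((1, g.n)),
            tuning_C=np.array([30.0]),
        )
        tE = 1.8 / (D * F)  # time to travel from -0.8 to +1
        st = np.linspace(0.1, 0.9, 7) * tE
        trial = Trial(0.0, tE, st, np.zeros(7, int), 0)
        path = viterbi_path(model, trial, 0)
        expected = -0.8 + D * F * st
        assert np.abs(path.states[1:-1] - expected).max() < 0.2

    def test_beats_random_paths(self, toy_model):
        rng = np.random.default_rng(8)
        trial = Trial(0.0, 0.5, np.array([0.15, 0.3]), np.array([0, 1]), 0)
        path = viterbi_path(toy_model, trial, 0)
        m = toy_model.grid.n - 2
        for _ in range(300):
            idx = np.append(rng.integers(0, m, 3), -1)
            b = rng.choice([-1, 1])
            assert path.log_joint >= path_log_joint(toy_model, trial, 0, idx, b) - 1e-9


class TestTimeRescaling:
    def test_constant_rate_r2_exactly_zero(self):
        # a constant rate prediction is the baseline: R^2 = 0 identically
        rng = np.random.default_rng(0)
        trials, rates = [], []
        for _ in range(100):
            st = np.sort(rng.uniform(0.01, 0.99, 12))
            trials.append(Trial(0.0, 1.0, st, np.zeros(12, int), 0))
            tg = np.linspace(0, 1, 5)
            rates.append((tg, np.full(5, 13.0)))
        out = spike_time_r2(SpikeData(trials, 1), rates, 0, min_spikes=100)
        # a constant rescaling is a linear time change: identical CV^2
        assert out.r2 == pytest.approx(0.0, abs=1e-12)

    def test_true_rate_rescaling_gives_unit_poisson(self):
        # inhomogeneous Poisson rescaled with its own rate: unit-rate
        # homogeneous Poisson (rate 1 Hz, CV^2 of rescaled ISIs ~ 1).  One
        # long realization avoids window-truncation bias in the ISI pool.
        rng = np.random.default_rng(1)
        T = 1200.0
        tg = np.arange(0, T + 1e-9, 2e-3)
        lam = 20 + 15 * np.sin(2 * np.pi * tg)
        thin = 35.0
        cand = np.sort(rng.uniform(0, T, rng.poisson(thin * T)))
        keep = cand[rng.random(cand.size) < np.interp(cand, tg, lam) / thin]
        op = rescale_spikes(keep, tg, lam)
        total_op = rescale_spikes(np.array([T]), tg, lam)[0]
        rate_hat = keep.size / total_op
        se = np.sqrt(keep.size) / total_op
        assert keep.size > 20000
        assert abs(rate_hat - 1.0) < 2 * se
        isis = np.diff(op)
        assert abs(isis.var(ddof=1) / isis.mean() ** 2 - 1.0) < 0.03
        # KS: rescaled ISIs are Exp(1)
        stat = scipy.stats.kstest(isis, "expon")
        assert stat.pvalue > 0.01

    def test_shuffled_rates_degrade_r2(self):
        # rate traces permuted across trials predict worse than the truth
        rng = np.random.default_rng(2)
        tg = np.linspace(0, 1, 201)
        trials, rates = [], []
        for k in range(300):
            peak = rng.uniform(0.2, 0.8)
            lam = 5 + 60 * np.exp(-((tg - peak) ** 2) / 0.005)
            thin = 70.0
            cand = np.sort(rng.uniform(0, 1, rng.poisson(thin)))
            keep = cand[rng.random(cand.size) < np.interp(cand, tg, lam) / thin]
            if keep.size < 2:
                continue
            trials.append(Trial(0.0, 1.0, keep, np.zeros(keep.size, int), 0))
            rates.append((tg, lam))
        data = SpikeData(trials, 1)
        true_r2 = spike_time_r2(data, rates, 0, min_spikes=100).r2
        perm = [rates[i] for i in rng.permutation(len(rates))]
        shuf_r2 = spike_time_r2(data, perm, 0, min_spikes=100).r2
        assert true_r2 > 0.2
        assert shuf_r2 < true_r2 - 0.2

    def test_low_count_condition_excluded(self):
        tr = Trial(0.0, 1.0, np.array([0.3, 0.6]), np.zeros(2, int), 0)
        out = spike_time_r2(SpikeData([tr], 1), [(np.array([0, 1.0]), np.array([5.0, 5.0]))], 0)
        assert out.excluded_conditions == [0]
        assert np.isnan(out.r2)


def _gamma_renewal_stream(rng, shape, rate, duration):
    """Stationary gamma-renewal spike train of mean rate ``rate`` Hz."""
    scale = 1.0 / (rate * shape)
    n = int(duration * rate * 1.5) + 100
    isis = rng.gamma(shape, scale, n)
    t = np.cumsum(isis)
    t = t[t < duration + 1.0]
    return t[t > 1.0] - 1.0  # drop warm-up to approach equilibrium


class TestPhi:
    def test_exact_poisson_moment_roots(self):
        # analytic moments E[N_T]=mu, Var=mu, E[N_2T]=2mu, Var=2mu force the
        # quadratic's roots to {1, 4mu - 1}; the admissible root is phi = 1
        mu = 2.0
        a, b, c = 0.5, -(4 * mu - 2 * mu), 4 * mu - 2 * mu - 0.5
        r = np.roots([a, b, c])
        assert set(np.round(np.sort(r), 9)) == {1.0, 4 * mu - 1}

    def test_gamma_renewal_shape_four(self):
        # CV^2 of gamma(4) ISIs = 0.25, recovered within 0.05 at 1e4 bins
        rng = np.random.default_rng(3)
        trains = [_gamma_renewal_stream(rng, 4.0, 20.0, 51.0) for _ in range(20)]
        est = estimate_phi(trains, [50.0] * 20, bin_size=0.1)
        assert est.ok
        assert abs(est.phi - 0.25) <= 0.05

    def test_poisson_stream_phi_one(self):
        rng = np.random.default_rng(4)
        trains = [np.sort(rng.uniform(0, 50, rng.poisson(20 * 50))) for _ in range(20)]
        est = estimate_phi(trains, [50.0] * 20, bin_size=0.1)
        assert est.ok and abs(est.phi - 1.0) <= 0.06

    def test_doubly_stochastic_poisson_phi_one_cv2_high(self):
        # strong trial-to-trial rate variance: raw CV^2 >> 1, phi stays ~ 1
        rng = np.random.default_rng(5)
        trains, durs = [], []
        for _ in range(200):
            lam = rng.uniform(5, 60)
            trains.append(np.sort(rng.uniform(0, 8, rng.poisson(lam * 8))))
            durs.append(8.0)
        est = estimate_phi(trains, durs, bin_size=0.1)
        assert est.ok and abs(est.phi - 1.0) <= 0.1
        assert est.plug_in_cv2 > 1.2

    @pytest.mark.parametrize("shape,phi", [(4.0, 0.25), (2.0, 0.5), (1.0, 1.0)])
    def test_bias_across_regularity(self, shape, phi):
        rng = np.random.default_rng(int(10 * shape))
        trains = [_gamma_renewal_stream(rng, shape, 20.0, 51.0) for _ in range(20)]
        est = estimate_phi(trains, [50.0] * 20, bin_size=0.1)
        assert est.ok and abs(est.phi - phi) <= 0.05


class TestChoicePrediction:
    def test_balanced_accuracy_trivial_cases(self):
        assert balanced_accuracy([1, 1, -1, -1], [1, 1, -1, -1]) == 1.0
        # constant prediction on a two-class set scores 0.5
        assert balanced_accuracy([1, 1, 1, 1], [1, 1, -1, -1]) == 0.5

    def test_relabel_invariance(self):
        rng = np.random.default_rng(0)
        pred = rng.choice([-1, 1], 50)
        truth = rng.choice([-1, 1], 50)
        assert balanced_accuracy(pred, truth) == balanced_accuracy(-pred, -truth)

    def test_drifting_model_predicts_its_own_direction(self, grid32):
        model = LatentModel(
            grid=grid32,
            forces=np.full((1, grid32.n), 6.0),
            D=0.2,
            F0=-grid32.nodes / 0.2**2,
            tuning_aux=np.zeros((1, grid32.n)),
            tuning_C=np.array([15.0]),
        )
        trial = Trial(0.0, 0.6, np.array([0.2, 0.4]), np.zeros(2, int), 0)
        assert predict_choice(model, trial, 0) == 1

    def test_orient_to_choices_flips_misoriented_model(self, grid32):
        model = LatentModel(
            grid=grid32,
            forces=np.full((1, grid32.n), 6.0),
            D=0.2,
            F0=-grid32.nodes / 0.2**2,
            tuning_aux=np.zeros((1, grid32.n)),
            tuning_C=np.array([15.0]),
        )
        trials = [Trial(0.0, 0.6, np.array([0.2, 0.4]), np.zeros(2, int), 0,
                        choice=-1) for _ in range(6)]
        oriented, flipped = orient_to_choices(model, SpikeData(trials, 1))
        assert flipped
        assert predict_choice(oriented, trials[0], 0) == -1


class TestLono:
    def test_requires_two_neurons(self, grid32):
        m = LatentModel.blank(grid32, 1, 1, D=0.3, rates=np.array([5.0]))
        with pytest.raises(ValueError):
            lono_rate(m, Trial(0.0, 0.5, np.empty(0), np.empty(0, int), 0), 0, 0)

    def test_constant_tuning_closed_form(self, grid64):
        # held-out neuron with flat tuning: likelihood is the constant-rate
        # Poisson closed form regardless of the decoded path
        C = 8.0
        m = LatentModel.blank(grid64, 1, 2, D=0.3, rates=np.array([12.0, C]))
        st = np.array([0.1, 0.2, 0.3, 0.45])
        ids = np.array([0, 1, 0, 1])
        trial = Trial(0.0, 0.5, st, ids, 0)
        _, _, ll = lono_rate(m, trial, 1, 0)
        expected = -C * 0.5 + 2 * np.log(C)
        assert abs(ll - expected) < 1e-6

    def test_twin_neurons_consistent_rates(self, grid64):
        # identical tuning: the LONO rate for one twin matches the rate
        # decoded from its sibling's spikes
        aux = np.vstack([0.8 * np.ones(grid64.n)] * 2)
        m = LatentModel(
            grid=grid64,
            forces=np.full((1, grid64.n), 3.0),
            D=0.3,
            F0=-grid64.nodes / 0.2**2,
            tuning_aux=aux,
            tuning_C=np.array([10.0, 10.0]),
        )
        st = np.array([0.1, 0.15, 0.3, 0.35, 0.5])
        ids = np.array([0, 1, 0, 1, 0])
        trial = Trial(0.0, 0.6, st, ids, 0)
        t1, lam1, _ = lono_rate(m, trial, 1, 0)
        path0 = viterbi_path(m, trial, 0, neuron_subset=[0])
        own = m.grid.interpolate(m.tuning(1), path0.states)
        lam_at_events = np.interp(path0.times, t1, lam1)
        assert np.abs(lam_at_events - own).max() < 0.35 * own.max()


class TestBaselineDecoder:
    def _make_data(self, rng, separable=True, n=120):
        trials = []
        # alternate in blocks of two so both classes land in each half of
        # the even/odd cross-fitting split
        pattern = [1, 1, -1, -1]
        for k in range(n):
            choice = pattern[k % 4]
            lam = (30.0 if choice == 1 else 6.0) if separable else 15.0
            st = np.sort(rng.uniform(0.001, 0.55, rng.poisson(lam * 0.55)))
            trials.append(
                Trial(0.0, 0.6, st, np.zeros(st.size, int), 0, choice=choice)
            )
        return SpikeData(trials, 1)

    def test_feature_dimension_is_42_bins(self):
        rng = np.random.default_rng(0)
        data = self._make_data(rng, n=4)
        X, _, _ = _count_features(data)
        assert X.shape[1] == 42  # 0.5 s window, 75-ms bins, 10-ms steps

    def test_separable_counts_perfect_accuracy(self):
        rng = np.random.default_rng(1)
        assert baseline_decoder(self._make_data(rng)) == 1.0

    def test_label_shuffle_near_chance(self):
        rng = np.random.default_rng(2)
        data = self._make_data(rng, separable=False, n=200)
        acc = baseline_decoder(data)
        assert abs(acc - 0.5) < 0.12


class TestUnitSelection:
    def _trials(self, rng, n_trials, rates=(25.0, 0.2), selective=True):
        trials = []
        for k in range(n_trials):
            choice = 1 if k % 2 == 0 else -1
            spikes, ids = [], []
            for i, base in enumerate(rates):
                lam = base * (2.0 if (selective and i == 0 and choice == 1) else 1.0)
                st = np.sort(rng.uniform(0.001, 0.59, rng.poisson(lam * 0.59)))
                spikes.append(st)
                ids.append(np.full(st.size, i))
            st = np.concatenate(spikes)
            ids = np.concatenate(ids)
            order = np.argsort(st, kind="stable")
            trials.append(Trial(0.0, 0.6, st[order], ids[order], 0, choice=choice))
        return SpikeData(trials, len(rates))

    def test_silent_unit_fails_rate_criterion(self):
        rng = np.random.default_rng(3)
        data = self._trials(rng, 600)
        ok = unit_selection(data)
        assert not ok[1]  # ~0.2 Hz unit can never reach 15 Hz

    def test_trial_count_boundary(self):
        rng = np.random.default_rng(4)
        ok559 = unit_selection(self._trials(rng, 559))
        assert not ok559.any()
        ok560 = unit_selection(self._trials(np.random.default_rng(4), 560))
        assert ok560[0]

    def test_unselective_unit_fails_roc(self):
        rng = np.random.default_rng(5)
        data = self._trials(rng, 600, rates=(25.0, 25.0), selective=False)
        ok = unit_selection(data)
        assert not ok[1]


class TestPsth:
    def test_constant_rate_recovered(self):
        rng = np.random.default_rng(6)
        trials = []
        for _ in range(300):
            st = np.sort(rng.uniform(0.001, 0.999, rng.poisson(20)))
            trials.append(Trial(0.0, 1.0, st, np.zeros(st.size, int), 0))
        centers, rates = compute_psth(trials, 0)
        assert abs(rates.mean() - 20.0) < 1.0
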