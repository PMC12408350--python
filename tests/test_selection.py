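"""Feature complexity, Jensen-Shannon consistency, selection and outcomes.

Oracles: closed-form KL for the entropy term with zero force, and a
Monte-Carlo path-integral estimate of the force-dependent term.
"""

import numpy as np
import pytest

from latentspike.data import SpikeData
from latentspike.model import LatentModel
from latentspike.optimize import FitConfig, FitTrace, fit
from latentspike.selection import (
    SelectionResult,
    bootstrap_bands,
    classify_outcome,
    feature_complexity,
    js_divergence,
    select,
)

from conftest import fabricate_trials


def _model(grid, F=None, D=0.3, F0=None, rates=(10.0,)):
    n = grid.n
    return LatentModel(
        grid=grid,
        forces=np.atleast_2d(F if F is not None else np.zeros(n)),
        D=D,
        F0=F0 if F0 is not None else np.zeros(n),
        tuning_aux=np.zeros((len(rates), n)),
        tuning_C=np.asarray(rates, dtype=float),
    )


class TestFeatureComplexity:
    def test_reference_model_zero(self, grid64):
        # constant potential with uniform p0 has zero feature complexity
        m = _model(grid64)
        assert abs(feature_complexity(m, 0)) <= 1e-6

    def test_kl_term_against_quadrature(self, grid64):
        # zero force: complexity reduces to KL(p0 || uniform)
        F0 = -grid64.nodes / 0.3**2  # truncated-Gaussian p0
        m = _model(grid64, F0=F0)
        p0 = m.p0()
        pos = p0 > 0
        kl = np.sum(grid64.weights[pos] * p0[pos] * np.log(2 * p0[pos]))
        assert abs(feature_complexity(m, 0) - kl) < 1e-10

    def test_force_term_against_monte_carlo(self, grid64):
        # (D/4) int dt int dx F^2 p(x,t) vs a path-wise Euler-Maruyama sum
        D = 0.3
        F = 1.5 * np.ones(grid64.n)
        F0 = -grid64.nodes / 0.2**2
        m = _model(grid64, F=F, D=D, F0=F0)
        M = feature_complexity(m, 0)
        p0 = m.p0()
        pos = p0 > 0
        kl = np.sum(grid64.weights[pos] * p0[pos] * np.log(2 * p0[pos]))
        force_term = M - kl

        rng = np.random.default_rng(12)
        n, dt = 20000, 5e-4
        cdf = np.concatenate(([0], np.cumsum(0.5 * (p0[1:] + p0[:-1]) * np.diff(grid64.nodes))))
        x = np.interp(rng.random(n) * cdf[-1], cdf, grid64.nodes)
        alive = np.ones(n, bool)
        acc = np.zeros(n)
        t = 0.0
        while alive.any() and t < 12.0:
            Fx = 1.5  # constant force
            acc[alive] += 0.25 * D * Fx**2 * dt
            x[alive] += D * Fx * dt + np.sqrt(2 * D * dt) * rng.standard_normal(alive.sum())
            alive &= np.abs(x) < 1
            t += dt
        mc = acc.mean()
        se = acc.std(ddof=1) / np.sqrt(n)
        assert abs(force_term - mc) < 3 * se + 0.01 * mc

    def test_nonnegative(self, grid64):
        rng = np.random.default_rng(3)
        for _ in range(3):
            m = _model(grid64, F=rng.standard_normal(grid64.n),
                       F0=rng.standard_normal(grid64.n))
            assert feature_complexity(m, 0) >= 0


class TestJsDivergence:
    def test_identical_models_zero(self, grid64):
        m = _model(grid64, F=np.sin(grid64.nodes))
        assert js_divergence(m, m, 0) < 1e-12

    def test_symmetry(self, grid64):
        a = _model(grid64, F=np.sin(grid64.nodes))
        b = _model(grid64, F=-0.5 * np.ones(grid64.n), D=0.4)
        assert abs(js_divergence(a, b, 0) - js_divergence(b, a, 0)) < 1e-12

    def test_bounded_by_ln2_and_attained_for_disjoint(self, grid64):
        # p0 concentrated at opposite sides with strong outward drift:
        # occupation densities nearly disjoint -> D_JS near ln 2
        a = _model(grid64, F=np.full(grid64.n, 8.0), D=0.4,
                   F0=(-(grid64.nodes - 0.7) / 0.05**2))
        b = _model(grid64, F=np.full(grid64.n, -8.0), D=0.4,
                   F0=(-(grid64.nodes + 0.7) / 0.05**2))
        val = js_divergence(a, b, 0)
        assert val <= np.log(2) + 1e-12
        assert val > 0.9 * np.log(2)


def _trace_from_models(models, complexities, cfg):
    t = FitTrace(config=cfg, split_id=1)
    t.epochs = np.arange(1, len(models) + 1)
    t.loglik = np.zeros(len(models))
    t.complexity = np.asarray(complexities, dtype=float)
    t.snapshot_epochs = list(range(1, len(models) + 1))
    t.snapshots = list(models)
    return t


class TestSelect:
    def _models(self, grid, scales):
        return [
            _model(grid, F=s * np.sin(np.pi * grid.nodes), D=0.3) for s in scales
        ]

    def test_identical_traces_select_highest(self, grid32):
        cfg = FitConfig(n_epochs=4)
        models = self._models(grid32, [0.0, 0.5, 1.0, 2.0])
        comps = [feature_complexity(m, 0) for m in models]
        tA = _trace_from_models(models, comps, cfg)
        tB = _trace_from_models(models, comps, cfg)
        sel = select(tA, tB, threshold=0.0015)
        assert sel.converged
        assert sel.M_star == pytest.approx(comps[-1])

    def test_divergent_tail_caps_selected_complexity(self, grid32):
        cfg = FitConfig(n_epochs=4)
        mA = self._models(grid32, [0.0, 0.5, 1.0, 2.0])
        # split B agrees at low complexity, diverges beyond the second model
        mB = self._models(grid32, [0.0, 0.5])
        mB += [
            _model(grid32, F=s * np.cos(np.pi * grid32.nodes), D=0.3)
            for s in (1.0, 2.0)
        ]
        cA = [feature_complexity(m, 0) for m in mA]
        cB = [feature_complexity(m, 0) for m in mB]
        tA = _trace_from_models(mA, cA, cfg)
        tB = _trace_from_models(mB, cB, cfg)
        sel = select(tA, tB, threshold=0.0015, align_gauge=False)
        assert sel.M_star <= cA[1] + 1e-9

    def test_infinite_threshold_selects_maximum(self, grid32):
        cfg = FitConfig(n_epochs=3)
        mA = self._models(grid32, [0.0, 1.0, 2.0])
        mB = self._models(grid32, [0.0, -1.0, -2.0])  # mirrored fits
        cA = [feature_complexity(m, 0) for m in mA]
        tA = _trace_from_models(mA, cA, cfg)
        tB = _trace_from_models(mB, cA, cfg)
        sel = select(tA, tB, threshold=np.inf, align_gauge=False)
        assert sel.M_star == pytest.approx(max(cA))

    def test_gauge_alignment_recovers_mirrored_split(self, grid32):
        # split B converged to the reflected solution: without alignment the
        # divergence is large, with alignment the traces agree
        cfg = FitConfig(n_epochs=3)
        mA = [
            _model(grid32, F=s * (np.sin(np.pi * grid32.nodes) + 0.6),
                   F0=-s * (grid32.nodes - 0.2) / 0.3**2, D=0.3)
            for s in (0.1, 1.0, 2.0)
        ]
        mB = [m.mirror() for m in mA]
        cA = [feature_complexity(m, 0) for m in mA]
        tA = _trace_from_models(mA, cA, cfg)
        tB = _trace_from_models(mB, cA, cfg)
        assert js_divergence(mA[-1], mB[-1], 0) > 0.0015  # genuinely reflected
        sel = select(tA, tB, threshold=0.0015)
        assert sel.gauge_flipped and sel.converged
        assert sel.M_star == pytest.approx(max(cA))

    def test_no_consistent_pair_warns_and_flags(self, grid32):
        cfg = FitConfig(n_epochs=2)
        mA = self._models(grid32, [1.0, 2.0])
        mB = [
            _model(grid32, F=s * np.cos(np.pi * grid32.nodes), D=0.5)
            for s in (1.0, 2.0)
        ]
        cA = [feature_complexity(m, 0) for m in mA]
        cB = [feature_complexity(m, 0) for m in mB]
        tA = _trace_from_models(mA, cA, cfg)
        tB = _trace_from_models(mB, cB, cfg)
        with pytest.warns(UserWarning):
            sel = select(tA, tB, threshold=1e-9, align_gauge=False)
        assert not sel.converged

    def test_idempotent(self, grid32):
        cfg = FitConfig(n_epochs=3)
        models = self._models(grid32, [0.0, 1.0, 2.0])
        comps = [feature_complexity(m, 0) for m in models]
        tA = _trace_from_models(models, comps, cfg)
        tB = _trace_from_models(models, comps, cfg)
        s1 = select(tA, tB)
        s2 = select(tA, tB)
        assert s1.M_star == s2.M_star and s1.snapshot_index == s2.snapshot_index


def _sel_from(m1, m2):
    return SelectionResult(
        model1=m1, model2=m2, M_star=1.0,
        pair_complexity=np.array([1.0]), pair_djs=np.array([0.0]),
        threshold=0.0015, converged=True,
    )


class TestClassifyOutcome:
    def _tilted(self, grid, slopes, D=0.3):
        return LatentModel(
            grid=grid,
            forces=np.stack([np.full(grid.n, s) for s in slopes]),
            D=D,
            F0=np.zeros(grid.n),
            tuning_aux=np.zeros((1, grid.n)),
            tuning_C=np.array([10.0]),
        )

    def test_same_side_tilt_is_no_signal(self, grid32):
        # force > 0 in all conditions: potential tilts to the same boundary
        m = self._tilted(grid32, [2.0, 3.0, 1.0])
        assert classify_outcome(_sel_from(m, m.copy())) == "underfit_no_signal"

    def test_opposite_tilts_between_splits(self, grid32):
        m1 = self._tilted(grid32, [2.0, -2.0])
        m2 = self._tilted(grid32, [2.0, 2.0])
        label = classify_outcome(_sel_from(m1, m2))
        assert label == "underfit_split_disagreement"

    def test_condition_dependent_tilts_are_good(self, grid32):
        m = self._tilted(grid32, [2.0, -2.0, 1.0, -1.0])
        assert classify_outcome(_sel_from(m, m.copy())) == "good"

    def test_overfit_signature(self, grid32):
        # huge rates + pathological D + deep scaled wells
        m = LatentModel(
            grid=grid32,
            forces=np.stack([40 * np.sin(np.pi * grid32.nodes),
                             -40 * np.sin(np.pi * grid32.nodes)]),
            D=4.0,
            F0=np.zeros(grid32.n),
            tuning_aux=np.vstack([np.full(grid32.n, 2.0)]),
            tuning_C=np.array([300.0]),
        )
        assert classify_outcome(_sel_from(m, m.copy())) == "overfit"


class TestComplexityGrowth:
    def test_complexity_grows_through_training(self):
        # fitted feature complexity rises essentially monotonically with
        # optimization epochs on synthetic data
        from latentspike.simulate import ground_truth_library, simulate_trials

        gt = ground_truth_library("single_barrier_hard", n_nodes=64)
        data = simulate_trials(gt, n_trials=40, seed=9, conditions=[0, 1])
        cfg = FitConfig(n_epochs=40, n_batches=4, n_line_searches=2,
                        grid_size=32, seed=2, n_snapshots=5)
        trace = fit(data, cfg)
        c = trace.complexity
        assert c[-1] > c[0]
        rho = np.corrcoef(np.argsort(np.argsort(c)), np.arange(c.size))[0, 1]
        assert rho > 0.9


class TestBootstrap:
    def test_zero_bootstrap_is_empty(self, grid32):
        rng = np.random.default_rng(0)
        data = SpikeData(fabricate_trials(rng, n_trials=8), 2)
        out = bootstrap_bands(data, FitConfig(), n_boot=0)
        assert out["models"] == [] and out["sd_potential"] is None

    def test_bands_shape_and_magnitude(self):
        rng = np.random.default_rng(1)
        data = SpikeData(fabricate_trials(rng, n_trials=16, n_conditions=1), 2)
        cfg = FitConfig(n_epochs=3, n_batches=2, n_line_searches=0,
                        grid_size=32, seed=5, n_snapshots=2)
        out = bootstrap_bands(data, cfg, n_boot=2)
        assert len(out["models"]) == 4
        assert out["sd_potential"].shape == (1, 32)
        assert np.all(out["sd_potential"] >= 0)
        # with almost-unmoved models (3 epochs) bands are small
        assert out["sd_potential"].max() < 1.0
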