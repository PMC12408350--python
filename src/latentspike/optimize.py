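"""Model fitting by likelihood ascent with a function-space ADAM variant.

Function-valued components (the condition forces F^l and the auxiliaries
F0, F_i) are updated with a single scalar step scale per function — the
running average of the gradient's squared L2 norm — rather than
per-node scaling; scalar parameters D and {C_i} use standard per-parameter
ADAM and are rectified at zero after each update.  Trials are split into
mini-batches per condition on every epoch; in shared optimization the
batches of all conditions are pooled and visited in random order, the
condition force being updated only on its own condition's batches and all
shared components on every batch.  A small number of L-BFGS-B line
searches over (D, {C_i}), scheduled log-spaced over epochs, complements
the ADAM updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import scipy.optimize

from .data import SpikeData
from .grid import build_grid
from .likelihood import CondEngine, GradientBundle
from .model import LatentModel

__all__ = [
    "FitConfig",
    "FitTrace",
    "AdamState",
    "adam_functional_step",
    "fit",
    "two_split_fit",
    "FitDivergedError",
]


class FitDivergedError(RuntimeError):
    def __init__(self, msg: str, snapshot: Optional[LatentModel] = None):
        super().__init__(msg)
        self.snapshot = snapshot


@dataclass
class FitConfig:
    """Hyperparameters of the fitting procedure.

    Defaults: alpha = 0.05 (single neuron;
    0.01-0.05 for populations), beta1 = 0.9, beta2 = 0.99, epsilon = 1e-8,
    20 batches per condition, 5000 epochs, 30 line searches, D_JS
    selection threshold 0.0015.
    """

    alpha: float = 0.05
    beta1: float = 0.9
    beta2: float = 0.99
    epsilon: float = 1e-8
    n_batches: int = 20
    n_epochs: int = 5000
    n_line_searches: int = 30
    seed: int = 0
    grid_size: int = 256
    djs_threshold: float = 0.0015
    shared: bool = True
    D_init: float = 0.1
    n_snapshots: int = 40
    line_search_maxiter: int = 10
    scalars_in_adam: bool = True  # D, C_i also take ADAM steps between searches
    # function gradients are projected onto Legendre polynomials up to this
    # degree before the update (None -> grid_size // 3).  The collocation
    # likelihood is insensitive to node-scale oscillations near the
    # absorbing boundaries; the projection keeps updates in the resolvable
    # smooth subspace.
    grad_smooth_degree: Optional[int] = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FitConfig":
        return cls(**d)


@dataclass
class FitTrace:
    """Per-epoch training record plus thinned model snapshots."""

    config: FitConfig
    split_id: int
    epochs: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    loglik: np.ndarray = field(default_factory=lambda: np.empty(0))
    complexity: np.ndarray = field(default_factory=lambda: np.empty(0))
    snapshot_epochs: list[int] = field(default_factory=list)
    snapshots: list[LatentModel] = field(default_factory=list)

    @property
    def final_model(self) -> LatentModel:
        return self.snapshots[-1]


class AdamState:
    """First/second-moment accumulators for all model components."""

    def __init__(self, n_conditions: int, n_neurons: int, n_nodes: int):
        self.t = 0
        self.m_F = np.zeros((n_conditions, n_nodes))
        self.v_F = np.zeros(n_conditions)
        self.t_F = np.zeros(n_conditions, dtype=int)
        self.m_F0 = np.zeros(n_nodes)
        self.v_F0 = 0.0
        self.m_Fi = np.zeros((n_neurons, n_nodes))
        self.v_Fi = np.zeros(n_neurons)
        self.m_D = 0.0
        self.v_D = 0.0
        self.m_C = np.zeros(n_neurons)
        self.v_C = np.zeros(n_neurons)


def _func_update(m, v, t, g, cfg: FitConfig):
    """One functional ADAM update; returns (step, m, v).

    ``v`` is the running average of the squared L2 norm of the gradient
    (one scalar per function), so the whole function shares a single
    adaptive scale.
    """
    m = cfg.beta1 * m + (1 - cfg.beta1) * g
    v = cfg.beta2 * v + (1 - cfg.beta2) * float(np.sum(g * g))
    mhat = m / (1 - cfg.beta1**t)
    vhat = v / (1 - cfg.beta2**t)
    step = cfg.alpha * mhat / (np.sqrt(vhat) + cfg.epsilon)
    return step, m, v


def _scalar_update(m, v, t, g, cfg: FitConfig):
    m = cfg.beta1 * m + (1 - cfg.beta1) * g
    v = cfg.beta2 * v + (1 - cfg.beta2) * g * g
    mhat = m / (1 - cfg.beta1**t)
    vhat = v / (1 - cfg.beta2**t)
    return cfg.alpha * mhat / (np.sqrt(vhat) + cfg.epsilon), m, v


def smoothing_projector(grid, degree: int) -> np.ndarray:
    """Orthogonal projector onto Legendre polynomials of degree <= degree
    in the quadrature inner product."""
    from scipy.special import eval_legendre

    V = np.stack(
        [
            np.sqrt((2 * l + 1) / 2.0) * eval_legendre(l, grid.nodes)
            for l in range(degree + 1)
        ],
        axis=1,
    )
    return V @ (V.T * grid.weights[None, :])


def adam_functional_step(
    state: AdamState,
    grads: GradientBundle,
    model: LatentModel,
    config: FitConfig,
    conditions: Optional[list[int]] = None,
    update_scalars: bool = True,
    projector: Optional[np.ndarray] = None,
) -> None:
    """Apply one ascent step in place (gradients are of the log-likelihood).

    ``conditions`` restricts the force update to the listed conditions (a
    mini-batch updates only its own condition's force); shared components
    are always updated.  D and C_i are rectified at zero after the update.
    ``projector`` optionally smooths the function-space gradients.
    """
    state.t += 1
    t = state.t
    if conditions is None:
        conditions = list(range(model.n_conditions))

    def _smooth(g):
        return projector @ g if projector is not None else g

    for c in conditions:
        state.t_F[c] += 1
        step, state.m_F[c], state.v_F[c] = _func_update(
            state.m_F[c], state.v_F[c], state.t_F[c], _smooth(grads.dF[c]), config
        )
        model.forces[c] += step
    step, state.m_F0, state.v_F0 = _func_update(
        state.m_F0, state.v_F0, t, _smooth(grads.dF0), config
    )
    model.F0 += step
    for i in range(model.n_neurons):
        step, state.m_Fi[i], state.v_Fi[i] = _func_update(
            state.m_Fi[i], state.v_Fi[i], t, _smooth(grads.dFi[i]), config
        )
        model.tuning_aux[i] += step
    if update_scalars:
        step, state.m_D, state.v_D = _scalar_update(
            state.m_D, state.v_D, t, grads.dD, config
        )
        model.D = max(model.D + step, 0.0)
        for i in range(model.n_neurons):
            step, state.m_C[i], state.v_C[i] = _scalar_update(
                state.m_C[i], state.v_C[i], t, grads.dCi[i], config
            )
            model.tuning_C[i] = max(model.tuning_C[i] + step, 0.0)


def _batch_gradient(model: LatentModel, trials, condition: int):
    """Log-likelihood and gradients of one mini-batch (single condition)."""
    eng = CondEngine(model, condition)
    total, _, (g_F, g_F0, g_Fi, g_D, g_Ci) = eng.batch_gradients(trials)
    dF = np.zeros((model.n_conditions, model.grid.n))
    dF[condition] = g_F
    return total, GradientBundle(dF=dF, dF0=g_F0, dFi=g_Fi, dD=g_D, dCi=g_Ci)


def _scalar_objective(model: LatentModel, data_by_cond):
    """(negative loglik, grad wrt [D, C_1..C_M]) for the line search."""

    def fun(theta):
        m = model.copy()
        m.D = max(float(theta[0]), 1e-8)
        m.tuning_C = np.maximum(theta[1:], 0.0)
        total = 0.0
        gD = 0.0
        gC = np.zeros(m.n_neurons)
        for c, trials in data_by_cond.items():
            eng = CondEngine(m, c)
            ll, _, (_, _, _, g_D, g_Ci) = eng.batch_gradients(trials)
            total += ll
            gD += g_D
            gC += g_Ci
        if not np.isfinite(total):
            return 1e12, np.zeros(theta.size)
        return -total, -np.concatenate([[gD], gC])

    return fun


def _empirical_rates(data: SpikeData) -> np.ndarray:
    total_t = sum(tr.duration for tr in data)
    return np.array(
        [max(data.total_spikes(i) / total_t, 0.5) for i in range(data.n_neurons)]
    )


def fit(data: SpikeData, config: FitConfig) -> FitTrace | dict[int, FitTrace]:
    """Fit all model components to ``data``.

    With ``config.shared`` (default) a single model with one shared p0,
    tuning set and D but per-condition forces is fitted to all conditions
    jointly.  With ``shared=False`` each condition is fitted independently
    and a mapping {condition: FitTrace} is returned.
    """
    conditions = data.conditions
    if not conditions:
        raise ValueError("no trials")
    for c in conditions:
        if len(data.by_condition(c)) == 0:
            raise ValueError(f"condition {c} is empty")
    if not config.shared and len(conditions) > 1:
        out = {}
        for k, c in enumerate(conditions):
            sub = data.by_condition(c)
            relabelled = SpikeData(
                [type(tr)(tr.t0, tr.tE, tr.spike_times, tr.neuron_ids, 0, tr.choice)
                 for tr in sub],
                data.n_neurons,
            )
            cfg = FitConfig(**{**config.to_dict(), "seed": config.seed + 9973 * (k + 1)})
            out[c] = fit(relabelled, cfg)
        return out
    return _fit_shared(data, config, split_id=0)


def _fit_shared(data: SpikeData, config: FitConfig, split_id: int) -> FitTrace:
    from .selection import feature_complexity

    rng = np.random.default_rng(config.seed)
    conditions = data.conditions
    cond_map = {c: k for k, c in enumerate(conditions)}
    grid = build_grid(config.grid_size)
    model = LatentModel.blank(
        grid,
        n_conditions=len(conditions),
        n_neurons=data.n_neurons,
        D=config.D_init,
        rates=_empirical_rates(data),
    )
    state = AdamState(len(conditions), data.n_neurons, grid.n)
    trials_by_cond = {cond_map[c]: list(data.by_condition(c)) for c in conditions}

    ls_epochs = set(
        np.unique(
            np.geomspace(1, max(config.n_epochs, 1), config.n_line_searches).astype(int)
        )
        if config.n_line_searches > 0
        else []
    )
    snap_epochs = set(
        np.unique(
            np.geomspace(1, max(config.n_epochs, 1), config.n_snapshots).astype(int)
        )
    )
    snap_epochs.add(config.n_epochs)

    deg = config.grad_smooth_degree
    if deg is None:
        deg = max(8, config.grid_size // 3)
    projector = smoothing_projector(grid, min(deg, grid.n - 2))

    trace = FitTrace(config=config, split_id=split_id)
    epochs, logliks, complexities = [], [], []
    for epoch in range(1, config.n_epochs + 1):
        batches = []
        for c, trials in trials_by_cond.items():
            order = rng.permutation(len(trials))
            nb = min(config.n_batches, len(trials))
            for idx in np.array_split(order, nb):
                if idx.size:
                    batches.append((c, [trials[i] for i in idx]))
        rng.shuffle(batches)
        epoch_ll = 0.0
        for c, batch in batches:
            ll, grads = _batch_gradient(model, batch, c)
            epoch_ll += ll
            adam_functional_step(
                state,
                grads,
                model,
                config,
                conditions=[c],
                update_scalars=config.scalars_in_adam,
                projector=projector,
            )
        if np.isnan(epoch_ll):
            raise FitDivergedError(
                f"non-finite loss at epoch {epoch}", snapshot=model.copy()
            )
        if epoch in ls_epochs:
            fun = _scalar_objective(model, trials_by_cond)
            theta0 = np.concatenate([[model.D], model.tuning_C])
            res = scipy.optimize.minimize(
                fun,
                theta0,
                jac=True,
                method="L-BFGS-B",
                bounds=[(1e-6, None)] * theta0.size,
                options={"maxiter": config.line_search_maxiter},
            )
            if np.isfinite(res.fun) and res.fun < 1e11:
                model.D = float(res.x[0])
                model.tuning_C = np.maximum(res.x[1:], 0.0)
        epochs.append(epoch)
        logliks.append(epoch_ll)
        complexities.append(
            float(
                np.mean(
                    [feature_complexity(model, k) for k in range(model.n_conditions)]
                )
            )
        )
        if epoch in snap_epochs:
            trace.snapshot_epochs.append(epoch)
            trace.snapshots.append(model.copy())
    trace.epochs = np.asarray(epochs)
    trace.loglik = np.asarray(logliks)
    trace.complexity = np.asarray(complexities)
    return trace


def two_split_fit(data: SpikeData, config: FitConfig) -> tuple[FitTrace, FitTrace]:
    """Independent fits on the deterministic even/odd trial split.

    Trials are assigned alternately (by index within each condition) to the
    two halves; the two fits run with seeds derived from ``config.seed``.
    """
    d1, d2 = data.split_even_odd()
    ss = np.random.SeedSequence(config.seed).spawn(2)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss]
    cfg1 = FitConfig(**{**config.to_dict(), "seed": seeds[0]})
    cfg2 = FitConfig(**{**config.to_dict(), "seed": seeds[1]})
    t1 = _fit_shared(d1, cfg1, split_id=1)
    t2 = _fit_shared(d2, cfg2, split_id=2)
    return t1, t2
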