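"""Synthetic spike data from latent Langevin dynamics.

Euler-Maruyama integration of dx = D F(x) dt + sqrt(2 D) dW from
x0 ~ p0, with the trial ending at the first passage of x = +-1 (the
reaction time).  Boundary-crossing times are refined by a linear bridge
so reaction times are unbiased at the integration step.  Spikes are drawn
by thinning against the neuron tuning functions f_i(x(t)).

``ground_truth_library`` provides deterministic fixture models echoing
the dynamics found in premotor decision data: a nearly linear potential
slope towards the correct-choice boundary plus a single barrier guarding
the incorrect-choice boundary, with easier stimulus conditions having a
higher barrier and steeper slope than harder ones.
"""

from __future__ import annotations

import numpy as np

from .data import SpikeData, Trial
from .grid import Grid, build_grid
from .model import LatentModel

__all__ = ["simulate_trials", "ground_truth_library"]


def simulate_trials(
    model: LatentModel,
    n_trials: int,
    dt: float = 5e-4,
    seed: int = 0,
    conditions: list[int] | None = None,
    max_duration: float = 10.0,
    correct_side: dict[int, int] | None = None,
) -> SpikeData:
    """Simulate ``n_trials`` per condition from the generative model.

    Trials exceeding ``max_duration`` are flagged as truncated and
    excluded.  The integration step must satisfy the stability heuristic
    dt <= 1e-3 * 4 / D.  Fully seeded and bit-reproducible.
    """
    if dt > 1e-3 * 4.0 / model.D:
        raise ValueError(f"dt={dt} too large for D={model.D}")
    rng = np.random.default_rng(seed)
    grid = model.grid
    if conditions is None:
        conditions = list(range(model.n_conditions))
    p0 = model.p0()
    cdf = np.concatenate(
        ([0.0], np.cumsum(0.5 * (p0[1:] + p0[:-1]) * np.diff(grid.nodes)))
    )
    cdf /= cdf[-1]
    f_all = model.tuning_all()
    trials = []
    sq = np.sqrt(2 * model.D * dt)
    for c in conditions:
        F = model.forces[c]
        x = np.interp(rng.random(n_trials), cdf, grid.nodes)
        active = np.ones(n_trials, dtype=bool)
        rt = np.full(n_trials, np.nan)
        side = np.zeros(n_trials, dtype=int)
        spikes: list[list[tuple[float, int]]] = [[] for _ in range(n_trials)]
        t = 0.0
        while active.any() and t < max_duration:
            xa = x[active]
            # spike thinning against current rates
            rates = np.stack([np.interp(xa, grid.nodes, f_all[i]) for i in range(model.n_neurons)])
            u = rng.random(rates.shape)
            hit = u < rates * dt
            if hit.any():
                act_idx = np.where(active)[0]
                jitter = rng.random(int(hit.sum()))
                jj = 0
                for i, k in zip(*np.where(hit)):
                    spikes[act_idx[k]].append((t + jitter[jj] * dt, i))
                    jj += 1
            drift = model.D * np.interp(xa, grid.nodes, F)
            xn = xa + drift * dt + sq * rng.standard_normal(xa.size)
            crossed = np.abs(xn) >= 1.0
            if crossed.any():
                act_idx = np.where(active)[0]
                for k in np.where(crossed)[0]:
                    b = 1.0 if xn[k] > 0 else -1.0
                    frac = (b - xa[k]) / (xn[k] - xa[k])
                    rt[act_idx[k]] = t + np.clip(frac, 0.0, 1.0) * dt
                    side[act_idx[k]] = int(b)
            x[active] = np.clip(xn, -1.0, 1.0)
            newly_done = np.zeros_like(active)
            newly_done[np.where(active)[0][crossed]] = True
            active &= ~newly_done
            t += dt
        for k in range(n_trials):
            if not np.isfinite(rt[k]):
                continue  # truncated at max_duration: flagged by exclusion
            ev = sorted((s for s in spikes[k] if s[0] < rt[k]), key=lambda s: (s[0], s[1]))
            st = np.array([s[0] for s in ev])
            ids = np.array([s[1] for s in ev], dtype=int)
            keep = st > 0
            correct = None
            if correct_side is not None:
                correct = bool(side[k] == correct_side.get(c, side[k]))
            trials.append(
                Trial(
                    t0=0.0,
                    tE=float(rt[k]),
                    spike_times=st[keep],
                    neuron_ids=ids[keep],
                    condition=c,
                    choice=int(side[k]),
                    correct=correct,
                )
            )
    return SpikeData(trials, model.n_neurons)


def _barrier_force(grid: Grid, slope: float, height: float, center: float, width: float = 0.25):
    """Force for Phi(x) = -slope*x + height*gauss(center, width)."""
    x = grid.nodes
    bump = height * np.exp(-((x - center) ** 2) / (2 * width**2))
    dphi = -slope - bump * (x - center) / width**2
    return -dphi


def ground_truth_library(name: str, n_nodes: int = 256) -> LatentModel:
    """Deterministic fixture models with documented parameters.

    ``single_barrier_easy`` / ``single_barrier_hard``: four stimulus
    conditions (right-easy, left-easy, right-hard, left-hard); the correct
    side has a linear downhill slope and a single barrier guards the
    incorrect boundary; the easy variant has the higher barrier and
    steeper slope.  ``ramping_linear``: constant force per condition.
    ``flat``: free diffusion, uniform p0, two constant-tuning neurons.
    """
    grid = build_grid(n_nodes)
    x = grid.nodes
    # shared components: narrow p0 at the centre, one ramp and one bump neuron
    F0 = -x / 0.15**2
    aux_ramp = np.full(grid.n, 1.2)
    aux_bump = -4.0 * (x - 0.3)
    C_ramp, C_bump = 4.0, 30.0 * np.exp(-2 * (-1 - 0.3) ** 2)
    tuning_aux = np.vstack([aux_ramp, aux_bump])
    tuning_C = np.array([C_ramp, C_bump])
    D = 0.3

    def barrier_model(slopes, heights, centers):
        forces = np.stack(
            [_barrier_force(grid, s, h, c) for s, h, c in zip(slopes, heights, centers)]
        )
        return LatentModel(
            grid=grid, forces=forces, D=D, F0=F0, tuning_aux=tuning_aux, tuning_C=tuning_C
        )

    if name == "single_barrier_easy":
        # conditions: right-easy, left-easy, right-hard, left-hard
        return barrier_model(
            slopes=[5.0, -5.0, 3.0, -3.0],
            heights=[3.0, 3.0, 1.8, 1.8],
            centers=[-0.55, 0.55, -0.55, 0.55],
        )
    if name == "single_barrier_hard":
        return barrier_model(
            slopes=[3.0, -3.0, 2.0, -2.0],
            heights=[1.8, 1.8, 1.0, 1.0],
            centers=[-0.55, 0.55, -0.55, 0.55],
        )
    if name == "ramping_linear":
        forces = np.stack([np.full(grid.n, s) for s in (4.0, -4.0, 2.0, -2.0)])
        return LatentModel(
            grid=grid, forces=forces, D=D, F0=F0, tuning_aux=tuning_aux, tuning_C=tuning_C
        )
    if name == "flat":
        return LatentModel(
            grid=grid,
            forces=np.zeros((1, grid.n)),
            D=D,
            F0=np.zeros(grid.n),
            tuning_aux=np.zeros((2, grid.n)),
            tuning_C=np.array([10.0, 20.0]),
        )
    raise ValueError(f"unknown ground-truth model {name!r}")


def correct_sides(name: str) -> dict[int, int]:
    """Correct-choice boundary per condition for the library models."""
    if name in ("single_barrier_easy", "single_barrier_hard", "ramping_linear"):
        return {0: 1, 1: -1, 2: 1, 3: -1}
    return {}
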