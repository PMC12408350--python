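"""Trial-by-trial likelihood of spikes and reaction times, with gradients.

For one trial with events {t_0, t_1, ..., t_N, t_E} the joint density of
spikes and the first passage at t_E factorizes into

    p0 . [prod_j emission f_{i_j} o ISI propagation with spike decay]
       . final propagation . boundary absorption,

evaluated as a chain of matrix-vector products in the generator's
eigenbasis.  The chain is rescaled per inter-spike interval (log-scale
accumulated separately) so products over hundreds of spikes do not
underflow.

Gradients of the data log-likelihood with respect to every model
component (condition forces F^l, shared F0, per-neuron auxiliaries F_i,
noise D, boundary rates C_i) are computed by an adjoint backward pass;
the derivative of the matrix exponential is taken in the eigenbasis via
the Daleckii-Krein divided-difference formula.  The gradients are exact
for the discretized model and are cross-checked against central finite
differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .data import SpikeData, Trial
from .model import LatentModel

__all__ = [
    "TrialLikelihood",
    "GradientBundle",
    "trial_loglik",
    "dataset_loglik",
    "psth_loglik",
    "likelihood_gradients",
]

_D_FLOOR = 1e-8


@dataclass
class TrialLikelihood:
    """Joint, reaction-time-only, and spikes-only (normalized) log-likelihoods."""

    log_full: float
    log_tE: float

    @property
    def log_normalized(self) -> float:
        return self.log_full - self.log_tE


@dataclass
class GradientBundle:
    """Gradients of the dataset log-likelihood.

    ``dF`` has shape (n_conditions, n_nodes); shared components are summed
    over the per-condition contributions.
    """

    dF: np.ndarray
    dF0: np.ndarray
    dFi: np.ndarray
    dD: float
    dCi: np.ndarray


class CondEngine:
    """Per-condition assembled operators for likelihood evaluation.

    Rebuilt whenever the model changes; shared by the likelihood, the
    optimizer and the Viterbi decoder.
    """

    def __init__(self, model: LatentModel, condition: int):
        grid = model.grid
        self.grid = grid
        self.condition = condition
        self.D = max(float(model.D), _D_FLOOR)
        n = grid.n
        self.F = model.forces[condition]
        self.f_full = model.tuning_all()              # (M, n)
        self.f_int = self.f_full[:, 1:-1]
        self.p0_full = model.p0()
        self.p0_int = self.p0_full[1:-1]
        w = grid.weights
        self.w_int = w[1:-1]
        phi_raw = -grid.cumint @ self.F
        self.phi0 = phi_raw - phi_raw.mean()
        phi_i = self.phi0[1:-1]
        sqw = np.sqrt(self.w_int)
        self.E_diag = np.exp(phi_i / 2)
        self.to_sym = sqw * self.E_diag
        self.from_sym = np.exp(-phi_i / 2) / sqw
        self.Dxc = grid.diff[:, 1:-1]
        self.W_diag = w * np.exp(-self.phi0)
        Pm = self.Dxc * (self.E_diag / sqw)[None, :]
        self.Pm = Pm
        self.K = -self.D * (Pm.T * self.W_diag[None, :]) @ Pm
        decay = self.f_int.sum(axis=0)
        H = -self.K + np.diag(decay)
        self.H = 0.5 * (H + H.T)
        self.lam, self.Q = scipy.linalg.eigh(self.H)
        self._plain_eig: tuple[np.ndarray, np.ndarray] | None = None
        self.u_left = self.D * grid.diff[0, 1:-1] * self.from_sym
        self.u_right = -self.D * grid.diff[-1, 1:-1] * self.from_sym
        self.u = self.u_left + self.u_right
        self.sqw = sqw
        self._p0_full = self.p0_full
        self._tuning_C = np.asarray(model.tuning_C, dtype=float)

    # ----------------------------------------------------------- forward

    def _intervals(self, trial: Trial) -> np.ndarray:
        times = np.concatenate(([trial.t0], trial.spike_times, [trial.tE]))
        return np.diff(times)

    def forward(self, trial: Trial):
        """Rescaled forward chain.

        Returns (log_full, phis, psis, scales, psi_final): ``phis`` are the
        rescaled states entering each propagator, ``psis`` the propagated
        states before each emission, ``scales`` the recorded rescale
        constants (treated as fixed in the adjoint pass — division by a
        constant is linear, so this is exact).
        """
        dts = self._intervals(trial)
        ids = trial.neuron_ids
        phi = self.to_sym * self.p0_int
        log_scale = 0.0
        phis, psis, scales = [], [], []
        for j, dt in enumerate(dts[:-1]):
            phis.append(phi)
            a = self.Q.T @ phi
            psi = self.Q @ (np.exp(-self.lam * dt) * a)
            psis.append(psi)
            phi = self.f_int[ids[j]] * psi
            s = np.abs(phi).max()
            if s <= 0 or not np.isfinite(s):
                return -np.inf, phis, psis, scales, None
            scales.append(s)
            log_scale += np.log(s)
            phi = phi / s
        phis.append(phi)
        a = self.Q.T @ phi
        psi_final = self.Q @ (np.exp(-self.lam * dts[-1]) * a)
        lin = float(self.u @ psi_final)
        if lin <= 0 or not np.isfinite(lin):
            return -np.inf, phis, psis, scales, psi_final
        return log_scale + np.log(lin), phis, psis, scales, psi_final

    @property
    def plain_eig(self):
        """Eigendecomposition of the drift-diffusion operator (no decay),
        used only for the reaction-time marginal; computed on demand."""
        if self._plain_eig is None:
            K0 = 0.5 * (self.K + self.K.T)
            self._plain_eig = scipy.linalg.eigh(-K0)
        return self._plain_eig

    def log_tE(self, trial: Trial, boundary: str = "either") -> float:
        lam0, Q0 = self.plain_eig
        phi = self.to_sym * self.p0_int
        a = Q0.T @ phi
        psi = Q0 @ (np.exp(-lam0 * trial.duration) * a)
        if boundary == "either":
            u = self.u
        elif boundary == "left":
            u = self.u_left
        elif boundary == "right":
            u = self.u_right
        elif boundary == "choice":
            if trial.choice is None:
                raise ValueError("trial has no choice label")
            u = self.u_left if trial.choice < 0 else self.u_right
        else:
            raise ValueError(f"unknown boundary mode {boundary!r}")
        lin = float(u @ psi)
        return np.log(lin) if lin > 0 else -np.inf

    # ---------------------------------------------------------- backward

    def trial_gradient(self, trial: Trial, accum: "_GradAccumulator") -> float:
        """Adjoint pass; accumulates grad of log L_full into ``accum``.

        Returns the trial's log_full.  Trials with -inf likelihood
        contribute no gradient.
        """
        dts = self._intervals(trial)
        ids = trial.neuron_ids
        log_full, phis, psis, scales, psi_final = self.forward(trial)
        if not np.isfinite(log_full):
            return log_full
        lin = float(self.u @ psi_final)
        inv = 1.0 / lin
        # absorption-vector contributions
        accum.g_phi_int += -0.5 * inv * (self.u * psi_final)
        accum.g_D += 1.0 / self.D  # u scales linearly with D
        # walk backward
        b = self.u.copy()
        n_ev = len(dts) - 1
        self._accumulate_interval(b, phis[n_ev], dts[-1], inv, accum)
        b = self.Q @ (np.exp(-self.lam * dts[-1]) * (self.Q.T @ b))
        for j in range(n_ev - 1, -1, -1):
            i = ids[j]
            b = b / scales[j]
            accum.g_f[i] += inv * (b * psis[j])
            b = self.f_int[i] * b
            self._accumulate_interval(b, phis[j], dts[j], inv, accum)
            b = self.Q @ (np.exp(-self.lam * dts[j]) * (self.Q.T @ b))
        accum.g_p0_int += inv * (self.to_sym * b)
        accum.g_phi_int += 0.5 * inv * (b * phis[0])
        return log_full

    def _accumulate_interval(self, b, phi_in, dt, inv, accum) -> None:
        alpha = self.Q.T @ b
        beta = self.Q.T @ phi_in
        eb = np.exp(-self.lam * dt)
        dl = self.lam[:, None] - self.lam[None, :]
        num = eb[:, None] - eb[None, :]
        small = np.abs(dl) < 1e-12
        with np.errstate(divide="ignore", invalid="ignore"):
            gamma = np.where(small, -dt * eb[:, None], num / np.where(small, 1.0, dl))
        accum.g_eig += inv * (alpha[:, None] * beta[None, :]) * gamma

    # -------------------------------------------------- batched kernels

    def batch_loglik(self, trials) -> tuple[float, int]:
        """Summed log_full over the valid trials of a batch (compiled path)."""
        from ._kernels import batch_forward_backward, pack_trials

        m = self.grid.n - 2
        dts, ids, off_dt, off_id = pack_trials(trials)
        total, n_valid = batch_forward_backward(
            self.Q, self.lam, self.to_sym, self.u, self.p0_int,
            np.ascontiguousarray(self.f_int), dts, ids, off_dt, off_id, False,
            np.zeros((m, m)), np.zeros(m), np.zeros(m),
            np.zeros((self.f_int.shape[0], m)),
        )
        return float(total), int(n_valid)

    def batch_gradients(self, trials):
        """Summed log_full and model-component gradients (compiled path)."""
        from ._kernels import batch_forward_backward, pack_trials

        m = self.grid.n - 2
        M = self.f_int.shape[0]
        dts, ids, off_dt, off_id = pack_trials(trials)
        accum = _GradAccumulator(m, M)
        total, n_valid = batch_forward_backward(
            self.Q, self.lam, self.to_sym, self.u, self.p0_int,
            np.ascontiguousarray(self.f_int), dts, ids, off_dt, off_id, True,
            accum.g_eig, accum.g_phi_int, accum.g_p0_int, accum.g_f,
        )
        accum.g_D = n_valid / self.D
        return float(total), int(n_valid), self.finish_gradients(accum)

    # ------------------------------------------------ gradient finishing

    def finish_gradients(self, accum: "_GradAccumulator"):
        """Convert accumulated adjoints into model-component gradients."""
        m = self.grid.n - 2
        G_H = self.Q @ accum.g_eig @ self.Q.T
        G_H = 0.5 * (G_H + G_H.T)
        # decay term: dH/df_i(x_m) = e_m e_m^T for every neuron
        g_decay = np.diag(G_H).copy()
        # K term: dH/dK = -1
        Gp = -G_H
        # D via K (K proportional to D)
        g_D = accum.g_D + float(np.sum(Gp * self.K)) / self.D
        # potential dependence of K
        C = Gp / (self.sqw[:, None] * self.sqw[None, :])
        M1 = (self.Dxc.T * self.W_diag[None, :]) @ self.Dxc
        EM1 = self.E_diag[:, None] * M1
        diag_CEM1 = np.einsum("mk,km->m", C, EM1)
        g_phi_int = accum.g_phi_int - self.D * self.E_diag * diag_CEM1
        PG = self.Pm @ Gp
        diag_PGP = np.einsum("pk,pk->p", PG, self.Pm)
        g_phi_full = np.zeros(self.grid.n)
        g_phi_full[1:-1] = g_phi_int
        g_phi_full += self.D * self.W_diag * diag_PGP
        g_phi_full -= g_phi_full.mean()  # constant shifts of Phi are a gauge
        g_F = -self.grid.cumint.T @ g_phi_full
        # p0 chain (softmax-with-weights); boundary nodes carry no adjoint
        g_p0_full = np.zeros(self.grid.n)
        g_p0_full[1:-1] = accum.g_p0_int
        p0 = self._p0_full
        inner = float(np.sum(g_p0_full * p0))
        g_S = p0 * g_p0_full - self.grid.weights * p0 * inner
        g_F0 = self.grid.cumint.T @ g_S
        # tuning chain f_i = C_i exp(A F_i)
        g_f_full = np.zeros((accum.g_f.shape[0], self.grid.n))
        g_f_full[:, 1:-1] = accum.g_f + g_decay[None, :]
        g_Fi = np.empty_like(g_f_full)
        g_Ci = np.empty(accum.g_f.shape[0])
        for i in range(accum.g_f.shape[0]):
            fg = self.f_full[i] * g_f_full[i]
            g_Fi[i] = self.grid.cumint.T @ fg
            Ci = self._tuning_C[i]
            g_Ci[i] = float(np.sum(g_f_full[i] * self.f_full[i])) / Ci if Ci > 0 else float(
                np.sum(g_f_full[i])
            )
        return g_F, g_F0, g_Fi, g_D, g_Ci


class _GradAccumulator:
    def __init__(self, m: int, n_neurons: int):
        self.g_eig = np.zeros((m, m))
        self.g_phi_int = np.zeros(m)
        self.g_p0_int = np.zeros(m)
        self.g_f = np.zeros((n_neurons, m))
        self.g_D = 0.0


# ------------------------------------------------------------------ API


def trial_loglik(
    model: LatentModel, trial: Trial, condition: int, te_boundary: str = "either"
) -> TrialLikelihood:
    """Exact joint log-likelihood of one trial's spikes and reaction time."""
    eng = CondEngine(model, condition)
    log_full, *_ = eng.forward(trial)
    return TrialLikelihood(log_full=log_full, log_tE=eng.log_tE(trial, te_boundary))


def dataset_loglik(
    model: LatentModel,
    data: SpikeData,
    which: str = "full",
    te_boundary: str = "either",
) -> float:
    """Sum of per-trial log-likelihoods (``full`` or ``normalized``)."""
    if which not in ("full", "normalized"):
        raise ValueError(f"unknown likelihood kind {which!r}")
    engines = {c: CondEngine(model, c) for c in {tr.condition for tr in data}}
    total = 0.0
    for tr in data:
        if tr.condition >= model.n_conditions:
            raise ValueError(f"condition {tr.condition} not in model")
        eng = engines[tr.condition]
        lf, *_ = eng.forward(tr)
        total += lf
        if which == "normalized":
            total -= eng.log_tE(tr, te_boundary)
    return float(total)


def psth_loglik(
    bin_times: np.ndarray, rate: np.ndarray, trial: Trial, neuron: int
) -> float:
    """Inhomogeneous-Poisson log-likelihood of one neuron's spikes under a
    binned rate trace: -int lambda dt + sum_j log lambda(t_j).

    The trace is linearly interpolated to spike times; beyond its range the
    nearest value is used; the time integral uses the trapezoidal rule on
    the trace's own bins restricted to [t0, tE].
    """
    bin_times = np.asarray(bin_times, dtype=float)
    rate = np.asarray(rate, dtype=float)
    spikes = trial.spike_times[trial.neuron_ids == neuron]
    tgrid = np.unique(
        np.concatenate(
            [[trial.t0, trial.tE], bin_times[(bin_times > trial.t0) & (bin_times < trial.tE)]]
        )
    )
    lam_grid = np.interp(tgrid, bin_times, rate)
    integral = np.trapezoid(lam_grid, tgrid)
    lam_spk = np.interp(spikes, bin_times, rate)
    if np.any(lam_spk <= 0):
        return -np.inf
    return float(-integral + np.sum(np.log(lam_spk)))


def likelihood_gradients(model: LatentModel, data: SpikeData) -> GradientBundle:
    """Analytic gradients of the dataset log-likelihood.

    Matches central finite differences of :func:`dataset_loglik` under
    pointwise perturbations; shared-component gradients are the sum of the
    per-condition contributions.
    """
    n = model.grid.n
    M = model.n_neurons
    dF = np.zeros((model.n_conditions, n))
    dF0 = np.zeros(n)
    dFi = np.zeros((M, n))
    dD = 0.0
    dCi = np.zeros(M)
    for c in sorted({tr.condition for tr in data}):
        eng = CondEngine(model, c)
        accum = _GradAccumulator(n - 2, M)
        for tr in data:
            if tr.condition != c:
                continue
            eng.trial_gradient(tr, accum)
        g_F, g_F0, g_Fi, g_D, g_Ci = eng.finish_gradients(accum)
        dF[c] = g_F
        dF0 += g_F0
        dFi += g_Fi
        dD += g_D
        dCi += g_Ci
    return GradientBundle(dF=dF, dF0=dF0, dFi=dFi, dD=dD, dCi=dCi)
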