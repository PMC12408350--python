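"""Decoding and validation of fitted latent-dynamics models.

Includes: a max-sum Viterbi decoder generalized to the continuous-state
continuous-time latent model (paths over grid values at event times, with
absorbing boundaries so decoded trajectories terminate at +-1); spike-time
R^2 via the time-rescaling theorem; an independent renewal-theory
estimator of point-process variability phi from spike-count moments at
two bin sizes; choice prediction with balanced accuracy; leave-one-neuron
-out (LONO) rate prediction; PSTH baselines; a supervised logistic
decoder baseline; and the unit-selection filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import CubicSpline
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score, roc_auc_score

from .data import SpikeData, Trial
from .fokker_planck import _assemble
from .model import LatentModel

__all__ = [
    "LatentPath",
    "viterbi_path",
    "path_log_joint",
    "RescaledISIs",
    "spike_time_r2",
    "PhiEstimate",
    "estimate_phi",
    "predict_choice",
    "balanced_accuracy",
    "lono_rate",
    "compute_psth",
    "baseline_decoder",
    "unit_selection",
]


# ----------------------------------------------------------------- Viterbi


@dataclass
class LatentPath:
    """Most probable latent path at event times, terminating on a boundary."""

    times: np.ndarray           # t0, spike times, tE
    states: np.ndarray          # latent values; last entry is -1 or +1
    node_indices: np.ndarray    # interior node index per event; -1 for tE
    log_joint: float

    def terminal_boundary(self) -> int:
        return int(np.sign(self.states[-1]))


def _decode_engine(model: LatentModel, condition: int, subset: np.ndarray):
    """Generator whose spike-decay covers only the observed neuron subset."""
    f_all = model.tuning_all()
    decay = f_all[subset].sum(axis=0)
    return _assemble(model.grid, max(model.D, 1e-8), model.forces[condition], decay), f_all


def viterbi_path(
    model: LatentModel,
    trial: Trial,
    condition: int,
    neuron_subset: Optional[Sequence[int]] = None,
) -> LatentPath:
    """Max-sum Viterbi decoding of the most probable latent path.

    Maximizes the discretized joint log-density of the latent values at
    the event times (initial density, ISI transition kernels with spike
    decay restricted to the observed subset, spike emissions, terminal
    boundary flux) with backtracking.  The terminal state is a boundary.
    Exact ties at the terminal resolve to the boundary on the side of the
    last interior state (left if that state is exactly 0).
    """
    if neuron_subset is None:
        subset = np.arange(model.n_neurons)
    else:
        subset = np.asarray(sorted(neuron_subset), dtype=int)
        if subset.size == 0:
            raise ValueError("neuron subset must be non-empty")
    spike_mask = np.isin(trial.neuron_ids, subset)
    st = trial.spike_times[spike_mask]
    ids = trial.neuron_ids[spike_mask]
    gen, f_all = _decode_engine(model, condition, subset)
    grid = model.grid
    xi = grid.nodes[1:-1]
    with np.errstate(divide="ignore"):
        log_f = np.log(np.maximum(f_all[:, 1:-1], 0.0))
        score = np.log(np.maximum(model.p0()[1:-1], 0.0))
    times = np.concatenate(([trial.t0], st, [trial.tE]))
    dts = np.diff(times)
    back = []
    for j, dt in enumerate(dts[:-1]):
        logK = gen.transition_log_kernel(dt)  # [to, from]
        tot = logK + score[None, :]
        back.append(np.argmax(tot, axis=1))
        score = np.max(tot, axis=1) + log_f[ids[j]]
    term_l, term_r = gen.terminal_log_flux(dts[-1])
    cand_l = term_l + score
    cand_r = term_r + score
    ml, mr = np.max(cand_l), np.max(cand_r)
    if np.isneginf(ml) and np.isneginf(mr):
        raise ValueError("impossible data: all paths have zero density")
    if abs(ml - mr) < 1e-12:
        last = xi[int(np.argmax(cand_l))]
        boundary = 1 if last > 0 else -1
    else:
        boundary = -1 if ml > mr else 1
    cand = cand_l if boundary < 0 else cand_r
    k = int(np.argmax(cand))
    idx = np.empty(len(times), dtype=int)
    idx[-1] = -1
    idx[-2] = k
    for j in range(len(back) - 1, -1, -1):
        idx[j] = back[j][idx[j + 1]]
    states = np.empty(len(times))
    states[:-1] = xi[idx[:-1]]
    states[-1] = float(boundary)
    return LatentPath(
        times=times, states=states, node_indices=idx, log_joint=float(np.max(cand))
    )


def path_log_joint(
    model: LatentModel,
    trial: Trial,
    condition: int,
    node_indices: np.ndarray,
    boundary: int,
    neuron_subset: Optional[Sequence[int]] = None,
) -> float:
    """Joint log-density of an arbitrary grid-valued path (for cross-checks)."""
    if neuron_subset is None:
        subset = np.arange(model.n_neurons)
    else:
        subset = np.asarray(sorted(neuron_subset), dtype=int)
    spike_mask = np.isin(trial.neuron_ids, subset)
    st = trial.spike_times[spike_mask]
    ids = trial.neuron_ids[spike_mask]
    gen, f_all = _decode_engine(model, condition, subset)
    times = np.concatenate(([trial.t0], st, [trial.tE]))
    dts = np.diff(times)
    with np.errstate(divide="ignore"):
        total = float(np.log(max(model.p0()[1:-1][node_indices[0]], 0.0)))
        for j, dt in enumerate(dts[:-1]):
            logK = gen.transition_log_kernel(dt)
            total += logK[node_indices[j + 1], node_indices[j]]
            total += np.log(max(f_all[ids[j], 1:-1][node_indices[j + 1]], 0.0))
        term_l, term_r = gen.terminal_log_flux(dts[-1])
        total += (term_l if boundary < 0 else term_r)[node_indices[-2]]
    return total


def dense_path(
    model: LatentModel,
    trial: Trial,
    condition: int,
    path: LatentPath,
    step: float = 0.01,
    neuron_subset: Optional[Sequence[int]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Kernel-bridge interpolation of a decoded path to a dense time grid.

    Between consecutive decoded states the intermediate state at time t
    maximizes K(x_b | m; t_b - t) K(m | x_a; t - t_a); the terminal
    interval bridges to the boundary via the flux kernel.
    """
    if neuron_subset is None:
        subset = np.arange(model.n_neurons)
    else:
        subset = np.asarray(sorted(neuron_subset), dtype=int)
    gen, _ = _decode_engine(model, condition, subset)
    xi = model.grid.nodes[1:-1]
    t_out = [path.times[0]]
    x_out = [path.states[0]]
    for seg in range(len(path.times) - 1):
        ta, tb = path.times[seg], path.times[seg + 1]
        terminal = seg == len(path.times) - 2
        interior_ts = np.arange(ta + step, tb - 1e-12, step)
        a_idx = path.node_indices[seg]
        for t in interior_ts:
            fwd = gen.transition_log_kernel(t - ta)[:, a_idx]
            if terminal:
                term_l, term_r = gen.terminal_log_flux(tb - t)
                bwd = term_l if path.states[-1] < 0 else term_r
            else:
                bwd = gen.transition_log_kernel(tb - t)[path.node_indices[seg + 1], :]
            m = int(np.argmax(fwd + bwd))
            t_out.append(t)
            x_out.append(xi[m])
        t_out.append(tb)
        x_out.append(path.states[seg + 1])
    return np.asarray(t_out), np.asarray(x_out)


# ---------------------------------------------------- time rescaling / R^2


@dataclass
class RescaledISIs:
    """Spike-time R^2 summary from operational-time rescaling.

    R^2 = 1 - CV^2_residual / CV^2_total, per condition and averaged.
    """

    cv2_total: float
    cv2_residual: float
    r2: float
    per_condition: dict = field(default_factory=dict)
    n_isis: int = 0
    excluded_conditions: list = field(default_factory=list)


def _cv2(isis: np.ndarray) -> float:
    if isis.size < 2:
        return np.nan
    mu = isis.mean()
    return float(isis.var(ddof=1) / mu**2)


def rescale_spikes(
    spike_times: np.ndarray, t_grid: np.ndarray, rate: np.ndarray
) -> np.ndarray:
    """Map spike times to operational time t' = int_0^t lambda ds (trapezoid)."""
    cum = np.concatenate(([0.0], cumulative_trapezoid(rate, t_grid)))
    return np.interp(spike_times, t_grid, cum)


def spike_time_r2(
    data: SpikeData,
    predicted: Sequence[tuple[np.ndarray, np.ndarray]],
    neuron: int,
    min_spikes: int = 600,
) -> RescaledISIs:
    """Fraction of single-trial spike-time variation explained by a model.

    ``predicted[k]`` is a (times, rate) trace covering trial k.  CV^2 of
    raw ISIs gives the total variation; CV^2 of ISIs rescaled with the
    predicted rate gives the residual.  Conditions are analysed separately
    and the R^2 values averaged; conditions with fewer than ``min_spikes``
    spikes (across trials) are excluded and reported.
    """
    per_cond: dict = {}
    excluded = []
    r2s, cv2t_all, cv2r_all, n_tot = [], [], [], 0
    for c in data.conditions:
        raw, resc, n_spk = [], [], 0
        for k, tr in enumerate(data.trials):
            if tr.condition != c:
                continue
            st = tr.spike_times[tr.neuron_ids == neuron]
            n_spk += st.size
            if st.size >= 2:
                raw.append(np.diff(st))
                tg, lam = predicted[k]
                if np.any(lam < 0) or not np.all(np.isfinite(lam)):
                    raise ValueError("predicted rate must be finite and >= 0")
                resc.append(np.diff(rescale_spikes(st, tg, lam)))
        if n_spk < min_spikes:
            excluded.append(c)
            continue
        if not raw:
            excluded.append(c)
            continue
        cv2t = _cv2(np.concatenate(raw))
        cv2r = _cv2(np.concatenate(resc))
        r2 = 1.0 - cv2r / cv2t
        per_cond[c] = {"cv2_total": cv2t, "cv2_residual": cv2r, "r2": r2}
        r2s.append(r2)
        cv2t_all.append(cv2t)
        cv2r_all.append(cv2r)
        n_tot += sum(x.size for x in raw)
    if not r2s:
        return RescaledISIs(np.nan, np.nan, np.nan, per_cond, 0, excluded)
    return RescaledISIs(
        cv2_total=float(np.mean(cv2t_all)),
        cv2_residual=float(np.mean(cv2r_all)),
        r2=float(np.mean(r2s)),
        per_condition=per_cond,
        n_isis=n_tot,
        excluded_conditions=excluded,
    )


# --------------------------------------------------------- phi estimation


@dataclass
class PhiEstimate:
    """Point-process variability phi (CV^2 of ISIs in operational time)."""

    phi: float
    roots: tuple
    ok: bool
    plug_in_cv2: float


def estimate_phi(
    spike_trains: Sequence[np.ndarray],
    durations: Sequence[float],
    bin_size: float = 0.1,
) -> PhiEstimate:
    """Estimate phi from spike-count moments at bin sizes T and 2T.

    Solves 1/2 (phi^2 - 1) - (4 E[N_T] - E[N_2T]) phi
           + 4 Var(N_T) - Var(N_2T) = 0
    and returns the admissible root: within (0, 2], nearer the plug-in
    CV^2 of raw ISIs.  Both roots are reported; complex roots or no
    admissible root flag an estimation failure.
    """
    def counts(T):
        out = []
        for st, dur in zip(spike_trains, durations):
            nb = int(np.floor(dur / T))
            if nb == 0:
                continue
            edges = np.arange(nb + 1) * T
            out.append(np.histogram(st, bins=edges)[0])
        return np.concatenate(out) if out else np.empty(0)

    nT = counts(bin_size)
    n2T = counts(2 * bin_size)
    if nT.size < 10 or n2T.size < 5:
        return PhiEstimate(np.nan, (np.nan, np.nan), False, np.nan)
    eT, vT = nT.mean(), nT.var(ddof=1)
    e2T, v2T = n2T.mean(), n2T.var(ddof=1)
    # quadratic: 0.5 phi^2 - (4 eT - e2T) phi + (4 vT - v2T - 0.5) = 0
    a, b, c = 0.5, -(4 * eT - e2T), 4 * vT - v2T - 0.5
    disc = b * b - 4 * a * c
    isis = [np.diff(st) for st in spike_trains if st.size >= 2]
    plug = _cv2(np.concatenate(isis)) if isis else 1.0
    if disc < 0:
        return PhiEstimate(np.nan, (np.nan, np.nan), False, plug)
    r1 = (-b - np.sqrt(disc)) / (2 * a)
    r2 = (-b + np.sqrt(disc)) / (2 * a)
    admissible = [r for r in (r1, r2) if 0 < r <= 2]
    if not admissible:
        return PhiEstimate(np.nan, (r1, r2), False, plug)
    target = min(max(plug, 1e-6), 2.0)
    phi = min(admissible, key=lambda r: abs(r - target))
    return PhiEstimate(float(phi), (float(r1), float(r2)), True, float(plug))


# ------------------------------------------------------- choice prediction


def predict_choice(model: LatentModel, trial: Trial, condition: int) -> int:
    """Choice = boundary reached by the decoded path at the reaction time."""
    return viterbi_path(model, trial, condition).terminal_boundary()


def balanced_accuracy(pred: Sequence[int], truth: Sequence[int]) -> float:
    """Average of true-positive and true-negative rates."""
    return float(balanced_accuracy_score(np.asarray(truth), np.asarray(pred)))


def orient_to_choices(
    model: LatentModel, data: SpikeData, max_trials: int = 200
) -> tuple[LatentModel, bool]:
    """Fix the reflection gauge using choice labels.

    The fitted latent sign is arbitrary; decode a subsample of labelled
    trials and keep the orientation whose predicted boundary agrees with
    the reported choices (mirroring the model exactly negates every
    prediction).  Returns (oriented model, whether it was flipped).
    """
    labelled = [tr for tr in data.trials if tr.choice is not None]
    if not labelled:
        return model, False
    step = max(1, len(labelled) // max_trials)
    sub = labelled[::step][:max_trials]
    preds = [predict_choice(model, tr, tr.condition) for tr in sub]
    truths = [tr.choice for tr in sub]
    if len(set(truths)) < 2:
        agree = np.mean([p == t for p, t in zip(preds, truths)])
        flip = agree < 0.5
    else:
        flip = balanced_accuracy(preds, truths) < 0.5
    return (model.mirror(), True) if flip else (model, False)


# ------------------------------------------------------------------- LONO


def lono_rate(
    model: LatentModel, trial: Trial, held_out_neuron: int, condition: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """Leave-one-neuron-out rate prediction and its Poisson log-likelihood.

    Decodes the path from the other M-1 neurons' spikes, reads the
    held-out neuron's tuning along the path at the event times, and
    interpolates with a cubic spline (clipped at zero) to evaluate the
    inhomogeneous-Poisson likelihood of the held-out spikes (trapezoidal
    time integral).
    """
    M = model.n_neurons
    if M < 2:
        raise ValueError("LONO requires at least 2 neurons")
    others = [i for i in range(M) if i != held_out_neuron]
    path = viterbi_path(model, trial, condition, neuron_subset=others)
    f = model.tuning(held_out_neuron)
    lam_events = model.grid.interpolate(f, path.states)
    t, lam = path.times, np.maximum(lam_events, 0.0)
    if t.size >= 3:
        tt, uu = np.unique(t, return_index=True)
        spline = CubicSpline(tt, lam[uu])
    else:
        spline = lambda q: np.interp(q, t, lam)  # noqa: E731
    tgrid = np.union1d(np.linspace(trial.t0, trial.tE, 101), t)
    lam_grid = np.maximum(np.asarray(spline(tgrid), dtype=float), 0.0)
    held_spikes = trial.spike_times[trial.neuron_ids == held_out_neuron]
    lam_spk = np.maximum(np.asarray(spline(held_spikes), dtype=float), 0.0)
    integral = np.trapezoid(lam_grid, tgrid)
    with np.errstate(divide="ignore"):
        ll = float(-integral + np.sum(np.log(lam_spk)))
    return tgrid, lam_grid, ll


# ------------------------------------------------------------------- PSTH


def compute_psth(
    trials: Sequence[Trial],
    neuron: int,
    window: float = 0.075,
    step: float = 0.01,
    t_max: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged firing rate in sliding bins (bin centres, Hz).

    Each bin averages spike counts over the trials still active in that
    bin, normalized by the covered duration.
    """
    if t_max is None:
        t_max = max(tr.tE for tr in trials)
    starts = np.arange(0.0, max(t_max - window, step), step)
    rates = np.zeros(starts.size)
    for k, s in enumerate(starts):
        e = s + window
        tot, cov = 0.0, 0.0
        for tr in trials:
            hi = min(e, tr.tE)
            if hi <= s + 1e-12:
                continue
            st = tr.spike_times[tr.neuron_ids == neuron]
            tot += np.count_nonzero((st >= s) & (st < hi))
            cov += hi - s
        rates[k] = tot / cov if cov > 0 else 0.0
    return starts + window / 2, rates


# -------------------------------------------------------- decoder baseline


def _count_features(
    data: SpikeData, t_max: float = 0.5, window: float = 0.075, step: float = 0.01
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spike counts in sliding bins, truncated at ``t_max`` after window start."""
    n_bins = int(np.floor((t_max - window) / step))
    starts = np.arange(n_bins) * step
    X = np.zeros((len(data.trials), data.n_neurons * n_bins))
    y = np.zeros(len(data.trials), dtype=int)
    conds = np.zeros(len(data.trials), dtype=int)
    for k, tr in enumerate(data.trials):
        y[k] = tr.choice if tr.choice is not None else 0
        conds[k] = tr.condition
        rel = tr.spike_times - tr.t0
        for i in range(data.n_neurons):
            st = rel[tr.neuron_ids == i]
            for b, s in enumerate(starts):
                X[k, i * n_bins + b] = np.count_nonzero((st >= s) & (st < s + window))
    return X, y, conds


def baseline_decoder(
    data: SpikeData,
    t_max: float = 0.5,
    window: float = 0.075,
    step: float = 0.01,
    min_errors: int = 5,
) -> float:
    """Cross-fitted logistic-regression choice decoder; balanced accuracy.

    Features are spike counts in 75-ms bins sliding at 10-ms steps,
    truncated 0.5 s after the window start (42 bins per neuron), z-scored
    per condition per bin on the training half.  The decoder is trained on
    one even/odd half and evaluated on the other, both ways, averaging the
    balanced accuracy.  Conditions lacking ``min_errors`` incorrect
    choices in either half are excluded when correctness labels exist.
    """
    X, y, conds = _count_features(data, t_max, window, step)
    labelled = y != 0
    half = np.zeros(len(data.trials), dtype=int)
    counters: dict[int, int] = {}
    for k, tr in enumerate(data.trials):
        c = counters.get(tr.condition, 0)
        half[k] = c % 2
        counters[tr.condition] = c + 1
    keep_cond = set(np.unique(conds))
    if any(tr.correct is not None for tr in data.trials):
        for c in set(conds):
            for h in (0, 1):
                m = (conds == c) & (half == h)
                errs = sum(
                    1
                    for k in np.where(m)[0]
                    if data.trials[k].correct is False
                )
                if errs < min_errors:
                    keep_cond.discard(c)
    keep = labelled & np.isin(conds, list(keep_cond))
    if keep.sum() < 10 or len(np.unique(y[keep])) < 2:
        raise ValueError("not enough labelled trials for the baseline decoder")
    accs = []
    for train_h in (0, 1):
        tr_m = keep & (half == train_h)
        te_m = keep & (half == 1 - train_h)
        Xtr, Xte = X[tr_m].copy(), X[te_m].copy()
        # z-score per condition per bin using training statistics
        for c in np.unique(conds[tr_m]):
            sel_tr = conds[tr_m] == c
            sel_te = conds[te_m] == c
            mu = Xtr[sel_tr].mean(axis=0)
            sd = Xtr[sel_tr].std(axis=0)
            sd[sd == 0] = 1.0
            Xtr[sel_tr] = (Xtr[sel_tr] - mu) / sd
            if sel_te.any():
                Xte[sel_te] = (Xte[sel_te] - mu) / sd
        clf = LogisticRegression(max_iter=2000)
        clf.fit(Xtr, y[tr_m])
        accs.append(balanced_accuracy(clf.predict(Xte), y[te_m]))
    return float(np.mean(accs))


# ---------------------------------------------------------- unit selection


def unit_selection(
    data: SpikeData,
    rate_threshold: float = 15.0,
    min_trials: int = 560,
    selectivity_threshold: float = 0.6,
    count_window: tuple[float, float] = (0.2, 0.35),
) -> np.ndarray:
    """Three-criterion unit filter.

    A unit passes iff (1) its choice-sorted PSTH reaches ``rate_threshold``
    Hz for at least one side between stimulus onset and the median
    reaction time, (2) the dataset has at least ``min_trials`` trials, and
    (3) the ROC-AUC for discriminating chosen side from spike counts in
    ``count_window`` exceeds ``selectivity_threshold``.
    """
    med_rt = float(np.median([tr.duration for tr in data.trials]))
    ok = np.zeros(data.n_neurons, dtype=bool)
    labelled = [tr for tr in data.trials if tr.choice is not None]
    for i in range(data.n_neurons):
        # criterion 1: PSTH peak by chosen side
        peak = 0.0
        for side in (-1, 1):
            side_tr = [tr for tr in labelled if tr.choice == side]
            if not side_tr:
                continue
            centers, rates = compute_psth(side_tr, i, t_max=med_rt)
            if rates.size:
                peak = max(peak, float(rates.max()))
        crit1 = peak >= rate_threshold
        crit2 = len(data.trials) >= min_trials
        # criterion 3: ROC-AUC selectivity
        counts, sides = [], []
        for tr in labelled:
            rel = tr.spike_times[tr.neuron_ids == i] - tr.t0
            counts.append(
                np.count_nonzero((rel >= count_window[0]) & (rel < count_window[1]))
            )
            sides.append(tr.choice)
        crit3 = False
        if len(set(sides)) == 2:
            auc = roc_auc_score((np.asarray(sides) > 0).astype(int), counts)
            auc = max(auc, 1 - auc)  # selectivity is side-symmetric
            crit3 = auc > selectivity_threshold
        ok[i] = crit1 and crit2 and crit3
    return ok
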