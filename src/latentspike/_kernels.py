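"""Compiled inner loops for likelihood evaluation and gradients.

The per-trial forward/backward chains are small dense linear-algebra
loops executed millions of times during fitting; this module provides a
numba-compiled batch kernel with a pure-numpy fallback selected at import
time.  Both paths implement the same arithmetic and are cross-checked in
the test suite.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    import numba

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False


def _batch_fb_py(
    Q, lam, to_sym, u, p0_int, f_int,
    dts, ids, off_dt, off_id, want_grad,
    g_eig, g_phi, g_p0, g_f,
):
    """Batch forward(+backward) over packed trials.

    Returns (total_loglik_of_valid_trials, n_valid).  Gradients of the
    summed log-likelihood are accumulated into the g_* arrays when
    ``want_grad``; each valid trial also contributes 1/D to the D-gradient
    via the caller (count = n_valid).
    """
    m = lam.size
    n_trials = off_dt.size - 1
    total = 0.0
    n_valid = 0
    for k in range(n_trials):
        a0, a1 = off_dt[k], off_dt[k + 1]
        b0 = off_id[k]
        n_ev = a1 - a0 - 1
        phis = np.empty((n_ev + 1, m))
        psis = np.empty((n_ev, m))
        scales = np.empty(n_ev)
        phi = to_sym * p0_int
        log_scale = 0.0
        ok = True
        for j in range(n_ev):
            phis[j] = phi
            dt = dts[a0 + j]
            psi = Q @ (np.exp(-lam * dt) * (Q.T @ phi))
            psis[j] = psi
            phi = f_int[ids[b0 + j]] * psi
            s = np.abs(phi).max()
            if not (s > 0.0 and np.isfinite(s)):
                ok = False
                break
            scales[j] = s
            log_scale += np.log(s)
            phi = phi / s
        if not ok:
            continue
        phis[n_ev] = phi
        dtE = dts[a1 - 1]
        psi_final = Q @ (np.exp(-lam * dtE) * (Q.T @ phi))
        lin = float(u @ psi_final)
        if not (lin > 0.0 and np.isfinite(lin)):
            continue
        total += log_scale + np.log(lin)
        n_valid += 1
        if not want_grad:
            continue
        inv = 1.0 / lin
        g_phi += -0.5 * inv * (u * psi_final)
        b = u.copy()
        _accum_interval_py(Q, lam, b, phis[n_ev], dtE, inv, g_eig)
        b = Q @ (np.exp(-lam * dtE) * (Q.T @ b))
        for j in range(n_ev - 1, -1, -1):
            i = ids[b0 + j]
            b = b / scales[j]
            g_f[i] += inv * (b * psis[j])
            b = f_int[i] * b
            dt = dts[a0 + j]
            _accum_interval_py(Q, lam, b, phis[j], dt, inv, g_eig)
            b = Q @ (np.exp(-lam * dt) * (Q.T @ b))
        g_p0 += inv * (to_sym * b)
        g_phi += 0.5 * inv * (b * phis[0])
    return total, n_valid


def _accum_interval_py(Q, lam, b, phi_in, dt, inv, g_eig):
    alpha = Q.T @ b
    beta = Q.T @ phi_in
    eb = np.exp(-lam * dt)
    dl = lam[:, None] - lam[None, :]
    num = eb[:, None] - eb[None, :]
    small = np.abs(dl) < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma = np.where(small, -dt * eb[:, None], num / np.where(small, 1.0, dl))
    g_eig += inv * (alpha[:, None] * beta[None, :]) * gamma


if HAVE_NUMBA:

    @numba.njit(cache=True)
    def _accum_interval_nb(Q, lam, b, phi_in, dt, inv, g_eig):  # pragma: no cover
        m = lam.size
        alpha = Q.T @ b
        beta = Q.T @ phi_in
        eb = np.exp(-lam * dt)
        for i in range(m):
            ai = inv * alpha[i]
            for j in range(m):
                dl = lam[i] - lam[j]
                if abs(dl) < 1e-12:
                    g = -dt * eb[i]
                else:
                    g = (eb[i] - eb[j]) / dl
                g_eig[i, j] += ai * beta[j] * g

    @numba.njit(cache=True)
    def _batch_fb_nb(
        Q, lam, to_sym, u, p0_int, f_int,
        dts, ids, off_dt, off_id, want_grad,
        g_eig, g_phi, g_p0, g_f,
    ):  # pragma: no cover - mirrored by _batch_fb_py
        m = lam.size
        Qt = Q.T.copy()
        n_trials = off_dt.size - 1
        total = 0.0
        n_valid = 0
        for k in range(n_trials):
            a0, a1 = off_dt[k], off_dt[k + 1]
            b0 = off_id[k]
            n_ev = a1 - a0 - 1
            phis = np.empty((n_ev + 1, m))
            psis = np.empty((n_ev, m))
            scales = np.empty(n_ev)
            phi = to_sym * p0_int
            log_scale = 0.0
            ok = True
            for j in range(n_ev):
                phis[j] = phi
                dt = dts[a0 + j]
                psi = Q @ (np.exp(-lam * dt) * (Qt @ phi))
                psis[j] = psi
                phi = f_int[ids[b0 + j]] * psi
                s = np.abs(phi).max()
                if not (s > 0.0 and np.isfinite(s)):
                    ok = False
                    break
                scales[j] = s
                log_scale += np.log(s)
                phi = phi / s
            if not ok:
                continue
            phis[n_ev] = phi
            dtE = dts[a1 - 1]
            psi_final = Q @ (np.exp(-lam * dtE) * (Qt @ phi))
            lin = np.dot(u, psi_final)
            if not (lin > 0.0 and np.isfinite(lin)):
                continue
            total += log_scale + np.log(lin)
            n_valid += 1
            if not want_grad:
                continue
            inv = 1.0 / lin
            for q in range(m):
                g_phi[q] += -0.5 * inv * u[q] * psi_final[q]
            b = u.copy()
            _accum_interval_nb(Q, lam, b, phis[n_ev], dtE, inv, g_eig)
            b = Q @ (np.exp(-lam * dtE) * (Qt @ b))
            for j in range(n_ev - 1, -1, -1):
                i = ids[b0 + j]
                b = b / scales[j]
                for q in range(m):
                    g_f[i, q] += inv * b[q] * psis[j, q]
                b = f_int[i] * b
                dt = dts[a0 + j]
                _accum_interval_nb(Q, lam, b, phis[j], dt, inv, g_eig)
                b = Q @ (np.exp(-lam * dt) * (Qt @ b))
            for q in range(m):
                g_p0[q] += inv * to_sym[q] * b[q]
                g_phi[q] += 0.5 * inv * b[q] * phis[0, q]
        return total, n_valid

    batch_forward_backward = _batch_fb_nb
else:  # pragma: no cover
    batch_forward_backward = _batch_fb_py


def pack_trials(trials):
    """Pack trial event times into flat arrays for the batch kernel."""
    dts_list, ids_list = [], []
    off_dt = np.zeros(len(trials) + 1, dtype=np.int64)
    off_id = np.zeros(len(trials) + 1, dtype=np.int64)
    for k, tr in enumerate(trials):
        times = np.concatenate(([tr.t0], tr.spike_times, [tr.tE]))
        dts_list.append(np.diff(times))
        ids_list.append(tr.neuron_ids.astype(np.int64))
        off_dt[k + 1] = off_dt[k] + times.size - 1
        off_id[k + 1] = off_id[k] + tr.neuron_ids.size
    dts = np.concatenate(dts_list) if dts_list else np.empty(0)
    ids = np.concatenate(ids_list) if ids_list else np.empty(0, dtype=np.int64)
    return dts, ids, off_dt, off_id
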