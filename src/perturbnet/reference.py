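"""Independent first-order reference solver for the sCGGM problem.

A monotone FISTA (accelerated proximal gradient with backtracking and restart)
on the same convex objective that :mod:`perturbnet.solver` minimizes with
second-order coordinate descent.  It shares no code with the Newton path and is
used purely for cross-validation of solutions in tests and the acceptance
checks.  Suitable only for small instances; convergence is driven to a very
tight objective-change tolerance.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg as sla

from .model import SCGGMLayer, l1_offdiag

__all__ = ["reference_fit", "reference_objective"]


def _smooth(Lam, Th, Sii, Sio, Soo):
    sign, logdet = np.linalg.slogdet(Lam)
    if sign <= 0:
        return np.inf
    try:
        L = sla.cholesky(Lam, lower=True)
    except sla.LinAlgError:
        return np.inf
    val = -logdet + float(np.sum(Soo * Lam)) + 2.0 * float(np.sum(Sio * Th))
    if Th.shape[0]:
        W = sla.solve_triangular(L, Th.T, lower=True)
        val += float(np.sum((W @ Sii) * W))
    return val


def _grads(Lam, Th, Sii, Sio, Soo):
    Sigma = np.linalg.inv(Lam)
    Sigma = 0.5 * (Sigma + Sigma.T)
    ThSig = Th @ Sigma
    if Th.shape[0]:
        SiiThSig = Sii @ ThSig
        Psi = ThSig.T @ SiiThSig
        gT = 2.0 * (Sio + SiiThSig)
    else:
        Psi = np.zeros_like(Lam)
        gT = np.zeros_like(Th)
    gL = Soo - Sigma - 0.5 * (Psi + Psi.T)
    return gL, gT


def _prox(Lam, Th, t, lam_L, lam_T):
    q = Lam.shape[0]
    P = np.sign(Lam) * np.maximum(np.abs(Lam) - t * lam_L, 0.0)
    P[np.arange(q), np.arange(q)] = np.diag(Lam)  # diagonal unpenalized
    P = 0.5 * (P + P.T)
    T = np.sign(Th) * np.maximum(np.abs(Th) - t * lam_T, 0.0)
    return P, T


def reference_objective(layer: SCGGMLayer, Sii, Sio, Soo) -> float:
    val = _smooth(layer.Lambda, layer.Theta, Sii, Sio, Soo)
    return (
        val
        + layer.lambda_Lambda * l1_offdiag(layer.Lambda)
        + layer.lambda_Theta * float(np.abs(layer.Theta).sum())
    )


def reference_fit(
    S_in_in,
    S_in_out,
    S_out_out,
    lambda_Lambda: float,
    lambda_Theta: float,
    max_iter: int = 200_000,
    tol: float = 1e-13,
) -> SCGGMLayer:
    """Minimize the penalized sCGGM objective with monotone FISTA."""
    Sii = np.asarray(S_in_in, dtype=float)
    Sio = np.asarray(S_in_out, dtype=float)
    Soo = np.asarray(S_out_out, dtype=float)
    p, q = Sio.shape

    d = np.diag(Soo)
    Lam = np.diag(np.maximum(np.where(d > 0, 1.0 / np.maximum(d, 1e-300), 1.0), 1e-3))
    Th = np.zeros((p, q))

    def pen(Lam, Th):
        return lambda_Lambda * l1_offdiag(Lam) + lambda_Theta * float(
            np.abs(Th).sum()
        )

    f_best = _smooth(Lam, Th, Sii, Sio, Soo) + pen(Lam, Th)
    yL, yT = Lam.copy(), Th.copy()
    t_mom = 1.0
    step = 1.0
    patience = 0
    for _ in range(max_iter):
        g_val = _smooth(yL, yT, Sii, Sio, Soo)
        if not np.isfinite(g_val):
            # momentum point left the PD cone: restart from the last iterate
            yL, yT, t_mom = Lam.copy(), Th.copy(), 1.0
            g_val = _smooth(yL, yT, Sii, Sio, Soo)
        gL, gT = _grads(yL, yT, Sii, Sio, Soo)
        # backtracking on the proximal-gradient step from (yL, yT)
        while True:
            cL, cT = _prox(yL - step * gL, yT - step * gT, step, lambda_Lambda, lambda_Theta)
            g_new = _smooth(cL, cT, Sii, Sio, Soo)
            if np.isfinite(g_new):
                dL, dT = cL - yL, cT - yT
                quad = (
                    g_val
                    + float(np.sum(gL * dL))
                    + float(np.sum(gT * dT))
                    + (float(np.sum(dL * dL)) + float(np.sum(dT * dT))) / (2.0 * step)
                )
                if g_new <= quad + 1e-15 * max(1.0, abs(quad)):
                    break
            step *= 0.5
            if step < 1e-18:
                raise RuntimeError("reference solver step underflow")
        f_new = g_new + pen(cL, cT)
        if f_new > f_best:
            # monotone safeguard: restart momentum at the best iterate; a
            # restart that cannot improve counts toward stagnation
            patience += 1
            if patience >= 25:
                break
            yL, yT, t_mom = Lam.copy(), Th.copy(), 1.0
            continue
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom * t_mom))
        accel = (t_mom - 1.0) / t_next
        yL = cL + accel * (cL - Lam)
        yT = cT + accel * (cT - Th)
        gap = f_best - f_new
        Lam, Th, t_mom = cL, cT, t_next
        f_best = f_new
        step *= 1.1  # allow the step to grow back
        if 0 <= gap <= tol * max(1.0, abs(f_new)):
            patience += 1
            if patience >= 25:
                break
        else:
            patience = 0
    return SCGGMLayer(
        Lambda=0.5 * (Lam + Lam.T),
        Theta=Th,
        lambda_Lambda=lambda_Lambda,
        lambda_Theta=lambda_Theta,
    )
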