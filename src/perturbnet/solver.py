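"""Alternating Newton coordinate descent for one sCGGM layer.

Minimizes the penalized objective

    f(Λ, Θ) = -log|Λ| + tr(S_oo Λ + 2 S_io' Θ + Λ^-1 Θ' S_ii Θ)
              + λ_Λ ||Λ||_1,offdiag + λ_Θ ||Θ||_1

by alternating (i) coordinate-descent soft-thresholding on Θ (a Lasso problem
once Λ is fixed) and (ii) a generalized Newton step on Λ: coordinate descent on
the L1-regularized second-order model with Hessian Σ ⊗ (Σ + 2Ψ), followed by a
backtracking Armijo line search that also guards positive definiteness.

Updates are restricted to an active set (currently-nonzero entries plus entries
whose gradient magnitude exceeds the penalty), products U = ΔΣ and M = S_ii Θ
are cached and updated per-coordinate, and each outer iteration warm-starts
from the previous one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .model import (
    SCGGMLayer,
    cholesky_pd,
    l1_offdiag,
    penalized_objective,
    scggm_gradients,
)

__all__ = [
    "ActiveSets",
    "SolverState",
    "SolverOptions",
    "compute_active_sets",
    "update_theta",
    "newton_direction_lambda",
    "line_search_lambda",
    "fit_scggm",
    "kkt_residual",
]


@dataclass
class SolverOptions:
    tol: float = 1e-6          # relative objective change for convergence
    max_iter: int = 100        # outer (alternating) iterations
    sweeps: int = 1            # coordinate passes over each active set
    beta: float = 0.5          # line-search backtracking factor
    sigma: float = 1e-4        # Armijo sufficient-decrease constant
    alpha_min: float = 1e-10   # below this step size the Λ update stagnates
    shuffle: bool = False      # randomize coordinate visitation order
    seed: int | None = None
    verbose: bool = False


@dataclass
class ActiveSets:
    """Coordinates eligible for update.

    ``set_Lambda`` holds (i, j) with i <= j only (a symmetric pair is updated
    jointly; all diagonals included), ``set_Theta`` holds (i, j) of Θ.
    """

    set_Lambda: np.ndarray  # (m_Lambda, 2) int array, i <= j
    set_Theta: np.ndarray   # (m_Theta, 2) int array

    @property
    def m_Lambda(self) -> int:
        return len(self.set_Lambda)

    @property
    def m_Theta(self) -> int:
        return len(self.set_Theta)


@dataclass
class SolverState:
    Sigma: np.ndarray
    Psi: np.ndarray
    iteration: int = 0
    objective_trajectory: list = field(default_factory=list)


def soft_threshold(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


def compute_active_sets(
    layer: SCGGMLayer,
    grad_Lambda: np.ndarray,
    grad_Theta: np.ndarray,
) -> ActiveSets:
    """Gradient/support rule: keep (i,j) with |grad| > λ or a nonzero entry.

    Entries exactly at |grad| = λ are excluded (ties favour sparsity).  All Λ
    diagonal entries are always active.
    """
    q = layer.n_outputs
    lam_L, lam_T = layer.lambda_Lambda, layer.lambda_Theta
    mask_L = (np.abs(grad_Lambda) > lam_L) | (layer.Lambda != 0.0)
    iu, ju = np.triu_indices(q, k=1)
    keep = mask_L[iu, ju]
    pairs = np.column_stack([iu[keep], ju[keep]])
    diag = np.column_stack([np.arange(q), np.arange(q)])
    set_L = np.vstack([diag, pairs])
    # lexicographic deterministic order
    order = np.lexsort((set_L[:, 1], set_L[:, 0]))
    set_L = set_L[order]
    mask_T = (np.abs(grad_Theta) > lam_T) | (layer.Theta != 0.0)
    it, jt = np.nonzero(mask_T)
    set_T = np.column_stack([it, jt])
    return ActiveSets(set_Lambda=set_L, set_Theta=set_T)


def update_theta(
    layer: SCGGMLayer,
    S_in_in: np.ndarray,
    S_in_out: np.ndarray,
    Sigma: np.ndarray,
    active: ActiveSets,
    sweeps: int = 1,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Coordinate descent on the Θ Lasso subproblem (Λ fixed).

    Minimizes ``tr(2 S_io' Θ + Σ Θ' S_ii Θ) + λ_Θ ||Θ||_1`` over the active
    coordinates, caching ``M = S_ii Θ`` so each coordinate costs O(q) for the
    gradient plus O(p) for the cache update.  Returns the updated Θ (in place).
    """
    Theta = layer.Theta
    lam = layer.lambda_Theta
    if active.m_Theta == 0:
        return Theta
    M = S_in_in @ Theta  # p x q cache
    d_in = np.diag(S_in_in)
    coords = active.set_Theta
    skipped: set[int] = set()
    for _ in range(max(1, sweeps)):
        order = np.arange(len(coords))
        if rng is not None:
            rng.shuffle(order)
        for k in order:
            i, j = int(coords[k, 0]), int(coords[k, 1])
            a = 2.0 * d_in[i] * Sigma[j, j]
            if a <= 0.0:
                if i not in skipped:
                    warnings.warn(
                        f"input {i} has zero variance; its Theta row is skipped",
                        stacklevel=2,
                    )
                    skipped.add(i)
                continue
            g = 2.0 * (S_in_out[i, j] + float(M[i] @ Sigma[:, j]))
            old = Theta[i, j]
            new = soft_threshold(old - g / a, lam / a)
            if new != old:
                Theta[i, j] = new
                M[:, j] += (new - old) * S_in_in[:, i]
    return Theta


def newton_direction_lambda(
    layer: SCGGMLayer,
    grad_Lambda: np.ndarray,
    Sigma: np.ndarray,
    Psi: np.ndarray,
    active: ActiveSets,
    sweeps: int = 1,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Coordinate descent on the L1-regularized quadratic model of the Λ step.

    The model is ``vec(G)' vec(Δ) + 1/2 vec(Δ)' (Σ ⊗ Φ) vec(Δ)
    + λ_Λ ||Λ + Δ||_1,offdiag`` with ``G = S_oo - Σ - Ψ`` and ``Φ = Σ + 2Ψ``.
    A symmetric pair (i, j) is moved jointly; the cache ``U = ΔΣ`` has rows i
    and j refreshed after each update.  Returns symmetric D_Λ.
    """
    q = layer.n_outputs
    lam = layer.lambda_Lambda
    Phi = Sigma + 2.0 * Psi
    Delta = np.zeros((q, q))
    U = np.zeros((q, q))  # U = Δ Σ
    coords = active.set_Lambda
    for _ in range(max(1, sweeps)):
        order = np.arange(len(coords))
        if rng is not None:
            rng.shuffle(order)
        for k in order:
            i, j = int(coords[k, 0]), int(coords[k, 1])
            if i == j:
                a = Phi[i, i] * Sigma[i, i]
                if a <= 0.0:
                    continue
                b = grad_Lambda[i, i] + float(Phi[i] @ U[:, i])
                mu = -b / a
                if mu != 0.0:
                    Delta[i, i] += mu
                    U[i, :] += mu * Sigma[i, :]
            else:
                a = (
                    Sigma[i, i] * Phi[j, j]
                    + Sigma[j, j] * Phi[i, i]
                    + 2.0 * Sigma[i, j] * Phi[i, j]
                )
                if a <= 0.0:
                    continue
                b = 2.0 * grad_Lambda[i, j] + float(Phi[i] @ U[:, j]) + float(
                    Phi[j] @ U[:, i]
                )
                c = layer.Lambda[i, j] + Delta[i, j]
                # minimize 1/2 a μ^2 + b μ + 2λ|c + μ| over μ
                z = soft_threshold(c - b / a, 2.0 * lam / a)
                mu = z - c
                if mu != 0.0:
                    Delta[i, j] += mu
                    Delta[j, i] += mu
                    U[i, :] += mu * Sigma[j, :]
                    U[j, :] += mu * Sigma[i, :]
    return Delta


class LineSearchError(RuntimeError):
    pass


def line_search_lambda(
    layer: SCGGMLayer,
    S_in_in: np.ndarray,
    S_in_out: np.ndarray,
    S_out_out: np.ndarray,
    D_Lambda: np.ndarray,
    grad_Lambda: np.ndarray,
    options: SolverOptions,
) -> tuple[float, float]:
    """Backtracking Armijo line search on Λ <- Λ + α D_Λ.

    Accepts the largest α in {1, β, β², ...} for which Λ + α D_Λ is positive
    definite and the penalized objective satisfies the sufficient-decrease
    condition ``f(Λ+αD) <= f(Λ) + σ α δ`` with
    ``δ = tr(G D) + λ_Λ (||Λ+D||_1,off - ||Λ||_1,off)``.
    Mutates ``layer.Lambda``; returns (α, new objective value).
    """
    lam = layer.lambda_Lambda
    f0 = penalized_objective(layer, S_in_in, S_in_out, S_out_out)
    if not np.any(D_Lambda):
        return 0.0, f0
    delta = float(np.sum(grad_Lambda * D_Lambda)) + lam * (
        l1_offdiag(layer.Lambda + D_Lambda) - l1_offdiag(layer.Lambda)
    )
    Lam0 = layer.Lambda.copy()
    alpha = 1.0
    while alpha >= options.alpha_min:
        cand = Lam0 + alpha * D_Lambda
        try:
            cholesky_pd(cand)
        except ValueError:
            alpha *= options.beta
            continue
        layer.Lambda = cand
        f1 = penalized_objective(layer, S_in_in, S_in_out, S_out_out)
        if f1 <= f0 + options.sigma * alpha * delta:
            return alpha, f1
        alpha *= options.beta
    layer.Lambda = Lam0
    raise LineSearchError(
        f"line search stagnated (alpha < {options.alpha_min:g}, "
        f"f0={f0:.6g}, delta={delta:.3g})"
    )


def _init_layer(
    S_out_out: np.ndarray,
    p: int,
    lambdas: tuple[float, float],
    input_ids=None,
    output_ids=None,
) -> SCGGMLayer:
    d = np.diag(S_out_out).copy()
    with np.errstate(divide="ignore"):
        inv = np.where(d > 0, 1.0 / np.maximum(d, 1e-300), 1.0)
    diag = np.maximum(inv, 1e-3)
    q = S_out_out.shape[0]
    return SCGGMLayer(
        Lambda=np.diag(diag),
        Theta=np.zeros((p, q)),
        lambda_Lambda=lambdas[0],
        lambda_Theta=lambdas[1],
        input_ids=input_ids,
        output_ids=output_ids,
    )


def fit_scggm(
    S_in_in: np.ndarray,
    S_in_out: np.ndarray,
    S_out_out: np.ndarray,
    lambda_Lambda: float,
    lambda_Theta: float,
    options: SolverOptions | None = None,
    init: SCGGMLayer | None = None,
    input_ids=None,
    output_ids=None,
) -> tuple[SCGGMLayer, SolverState]:
    """Fit one sCGGM layer by alternating Newton coordinate descent.

    ``init`` warm-starts both parameter blocks (used along regularization
    paths and in EM).  Returns the fitted layer and the solver state; the
    objective trajectory and a convergence flag live in the state / fit info.
    """
    opts = options or SolverOptions()
    S_in_in = np.asarray(S_in_in, dtype=float)
    S_in_out = np.asarray(S_in_out, dtype=float)
    S_out_out = np.asarray(S_out_out, dtype=float)
    p = S_in_in.shape[0]
    if S_in_out.shape != (p, S_out_out.shape[0]):
        raise ValueError("sufficient-statistic dimensions are inconsistent")
    if lambda_Lambda < 0 or lambda_Theta < 0:
        raise ValueError("penalties must be nonnegative")

    if init is not None:
        layer = SCGGMLayer(
            Lambda=init.Lambda.copy(),
            Theta=init.Theta.copy(),
            lambda_Lambda=lambda_Lambda,
            lambda_Theta=lambda_Theta,
            input_ids=input_ids if input_ids is not None else init.input_ids,
            output_ids=output_ids if output_ids is not None else init.output_ids,
        )
    else:
        layer = _init_layer(
            S_out_out, p, (lambda_Lambda, lambda_Theta), input_ids, output_ids
        )
    rng = np.random.default_rng(opts.seed) if opts.shuffle else None

    state = SolverState(Sigma=np.empty(0), Psi=np.empty(0))
    f_prev = penalized_objective(layer, S_in_in, S_in_out, S_out_out)
    state.objective_trajectory.append(f_prev)
    converged = False
    message = "max iterations reached"
    for it in range(1, opts.max_iter + 1):
        grad_L, grad_T, Sigma, Psi = scggm_gradients(
            layer, S_in_in, S_in_out, S_out_out
        )
        active = compute_active_sets(layer, grad_L, grad_T)
        # Θ step (Lasso given Λ)
        update_theta(
            layer, S_in_in, S_in_out, Sigma, active, sweeps=opts.sweeps, rng=rng
        )
        # Λ step: Newton direction + line search (Ψ, grad refresh after Θ move)
        grad_L, _, Sigma, Psi = scggm_gradients(layer, S_in_in, S_in_out, S_out_out)
        D = newton_direction_lambda(
            layer, grad_L, Sigma, Psi, active, sweeps=opts.sweeps, rng=rng
        )
        try:
            _, f_new = line_search_lambda(
                layer, S_in_in, S_in_out, S_out_out, D, grad_L, opts
            )
        except LineSearchError as exc:
            message = str(exc)
            f_new = penalized_objective(layer, S_in_in, S_in_out, S_out_out)
            state.objective_trajectory.append(f_new)
            state.iteration = it
            break
        state.objective_trajectory.append(f_new)
        state.iteration = it
        if opts.verbose:
            print(f"iter {it:3d}  objective {f_new:.10g}")
        if abs(f_prev - f_new) <= opts.tol * max(1.0, abs(f_new)):
            converged = True
            message = f"converged in {it} iterations"
            break
        f_prev = f_new

    state.Sigma, state.Psi = scggm_gradients(layer, S_in_in, S_in_out, S_out_out)[2:]
    layer_info = {
        "objective_trajectory": state.objective_trajectory,
        "iterations": state.iteration,
        "converged": converged,
        "message": message,
    }
    # stash fit metadata on the layer for ChainModel bookkeeping
    layer.fit_info = layer_info  # type: ignore[attr-defined]
    if not converged and "stagnated" not in message:
        warnings.warn("fit_scggm did not converge; returning best iterate", stacklevel=2)
    return layer, state


def kkt_residual(
    layer: SCGGMLayer,
    S_in_in: np.ndarray,
    S_in_out: np.ndarray,
    S_out_out: np.ndarray,
) -> float:
    """Max violation of the subgradient optimality conditions at (Λ, Θ).

    For a zero entry the gradient must lie in [-λ, λ]; for a nonzero entry it
    must equal -λ sign(entry).  Λ diagonal entries must have zero gradient.
    """
    grad_L, grad_T, _, _ = scggm_gradients(layer, S_in_in, S_in_out, S_out_out)
    lam_L, lam_T = layer.lambda_Lambda, layer.lambda_Theta
    res = 0.0
    q = layer.n_outputs
    for i in range(q):
        res = max(res, abs(grad_L[i, i]))
    off = ~np.eye(q, dtype=bool)
    zero = (layer.Lambda == 0.0) & off
    nonz = (layer.Lambda != 0.0) & off
    if zero.any():
        res = max(res, float(np.max(np.abs(grad_L[zero])) - lam_L))
    if nonz.any():
        res = max(
            res,
            float(
                np.max(np.abs(grad_L[nonz] + lam_L * np.sign(layer.Lambda[nonz])))
            ),
        )
    zero_t = layer.Theta == 0.0
    if zero_t.any():
        res = max(res, float(np.max(np.abs(grad_T[zero_t])) - lam_T))
    if (~zero_t).any():
        res = max(
            res,
            float(
                np.max(
                    np.abs(
                        grad_T[~zero_t] + lam_T * np.sign(layer.Theta[~zero_t])
                    )
                )
            ),
        )
    return res
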