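"""Whole-chain estimation: decoupled layer fits, BIC selection, and EM.

The penalized chain objective separates into the SNP->gene and gene->trait
layer problems, so :func:`fit_chain` simply solves the two sCGGM problems
independently.  Penalty weights are selected by maximizing a BIC score over a
per-layer grid with warm starts along the path.  When expression rows are
missing for a subset of samples, :func:`em_fit` runs an EM algorithm whose
E-step is the Gaussian posterior

    Σ_y|x,z = (Λ_y + Θ_yz Λ_z^-1 Θ_yz')^-1
    μ_y|x,z = -Σ_y|x,z (Θ_yz z + Θ_xy' x)

and whose M-step re-runs the layer solvers on expected sufficient statistics.
For large gene sets the posterior covariance can be applied column-by-column
through conjugate gradients on the low-rank form Λ_y + K K', K = Θ_yz L_z^-T,
without materializing any dense q x q matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse.linalg as spla

from .model import (
    ChainModel,
    DataBundle,
    SCGGMLayer,
    SufficientStats,
    center,
    chain_objective,
    compute_suffstats,
    penalized_objective,
    scggm_neg_loglik,
)
from .solver import SolverOptions, fit_scggm

__all__ = [
    "ChainLambdas",
    "RegularizationGrid",
    "EMState",
    "fit_chain",
    "bic_score",
    "select_lambdas",
    "em_fit",
    "implicit_posterior_solve",
]


@dataclass(frozen=True)
class ChainLambdas:
    """The four penalty weights of the chain problem."""

    lambda_Lambda_y: float
    lambda_Theta_xy: float
    lambda_Lambda_z: float
    lambda_Theta_yz: float


@dataclass
class RegularizationGrid:
    """Per-penalty candidate lists (each sorted descending before use)."""

    lambda_Lambda_y: tuple = (1.0, 0.3, 0.1)
    lambda_Theta_xy: tuple = (1.0, 0.3, 0.1)
    lambda_Lambda_z: tuple = (1.0, 0.3, 0.1)
    lambda_Theta_yz: tuple = (1.0, 0.3, 0.1)
    strategy: str = "grid"

    def __post_init__(self) -> None:
        for name in (
            "lambda_Lambda_y",
            "lambda_Theta_xy",
            "lambda_Lambda_z",
            "lambda_Theta_yz",
        ):
            vals = tuple(sorted(getattr(self, name), reverse=True))
            if not vals:
                raise ValueError(f"{name} grid is empty")
            if any(v <= 0 for v in vals):
                raise ValueError(f"{name} candidates must be positive")
            setattr(self, name, vals)


def _fit_layer(
    stats_slice, lambdas, options, init=None, input_ids=None, output_ids=None
) -> SCGGMLayer:
    Sii, Sio, Soo = stats_slice
    layer, _ = fit_scggm(
        Sii,
        Sio,
        Soo,
        lambdas[0],
        lambdas[1],
        options=options,
        init=init,
        input_ids=input_ids,
        output_ids=output_ids,
    )
    return layer


def fit_chain(
    data: DataBundle,
    lambdas: ChainLambdas,
    options: SolverOptions | None = None,
    stats: SufficientStats | None = None,
) -> ChainModel:
    """Fit both layers on complete data (the two problems decouple)."""
    if stats is None:
        stats = compute_suffstats(data)
    layer_xy = _fit_layer(
        stats.layer_xy(),
        (lambdas.lambda_Lambda_y, lambdas.lambda_Theta_xy),
        options,
        input_ids=data.snp_ids,
        output_ids=data.gene_ids,
    )
    layer_yz = _fit_layer(
        stats.layer_yz(),
        (lambdas.lambda_Lambda_z, lambdas.lambda_Theta_yz),
        options,
        input_ids=data.gene_ids,
        output_ids=data.trait_ids,
    )
    if layer_xy.output_ids is None or layer_yz.input_ids is None or list(
        layer_xy.output_ids
    ) != list(layer_yz.input_ids):
        layer_yz.input_ids = layer_xy.output_ids
    model = ChainModel(layer_xy=layer_xy, layer_yz=layer_yz)
    model.fit_info = {
        "xy": getattr(layer_xy, "fit_info", {}),
        "yz": getattr(layer_yz, "fit_info", {}),
        "objective": chain_objective(model, stats),
    }
    return model


def _param_count(layer: SCGGMLayer) -> int:
    q = layer.n_outputs
    off = layer.Lambda[np.triu_indices(q, k=1)]
    return int(np.count_nonzero(layer.Theta)) + int(np.count_nonzero(off)) + q


def bic_score(layer: SCGGMLayer, stats_slice, n: int, criterion: str = "bic") -> float:
    """Model-selection score; higher is better.

    ``loglik - (k/2) log n`` with k = nnz(Θ) + nnz off-diagonal pairs of Λ +
    dim(Λ), where loglik is the exact Gaussian log-likelihood of the layer.
    ``criterion="aic"`` replaces (k/2) log n with k.
    """
    Sii, Sio, Soo = stats_slice
    q = layer.n_outputs
    neg = scggm_neg_loglik(layer, Sii, Sio, Soo)
    loglik = -0.5 * n * (neg + q * np.log(2.0 * np.pi))
    k = _param_count(layer)
    if criterion == "bic":
        return float(loglik - 0.5 * k * np.log(n))
    if criterion == "aic":
        return float(loglik - k)
    raise ValueError(f"unknown criterion {criterion!r}")


def _select_layer(
    stats_slice, grid_net, grid_pert, n, options, criterion, input_ids, output_ids
):
    """Warm-started grid search over one layer's (λ_Λ, λ_Θ) pairs."""
    rows = []
    best = None
    col_init = {}
    for lam_net in grid_net:  # descending
        for lam_pert in grid_pert:
            init = col_init.get(lam_pert)
            layer = _fit_layer(
                stats_slice,
                (lam_net, lam_pert),
                options,
                init=init,
                input_ids=input_ids,
                output_ids=output_ids,
            )
            col_init[lam_pert] = layer
            score = bic_score(layer, stats_slice, n, criterion)
            rows.append(
                {
                    "lambda_Lambda": lam_net,
                    "lambda_Theta": lam_pert,
                    "score": score,
                    "nnz_Lambda_offdiag": int(
                        np.count_nonzero(
                            layer.Lambda[np.triu_indices(layer.n_outputs, k=1)]
                        )
                    ),
                    "nnz_Theta": int(np.count_nonzero(layer.Theta)),
                    "converged": getattr(layer, "fit_info", {}).get("converged"),
                }
            )
            if best is None or score > best[0]:
                best = (score, layer)
    table = pd.DataFrame(rows)
    assert best is not None
    return best[1], table


def select_lambdas(
    data: DataBundle,
    grid: RegularizationGrid,
    options: SolverOptions | None = None,
    criterion: str = "bic",
    stats: SufficientStats | None = None,
) -> tuple[ChainModel, dict[str, pd.DataFrame]]:
    """BIC-maximizing penalties per layer (the decoupled objective justifies
    independent per-layer searches).  Returns the selected model and the full
    per-layer score tables."""
    if stats is None:
        stats = compute_suffstats(data)
    layer_xy, table_xy = _select_layer(
        stats.layer_xy(),
        grid.lambda_Lambda_y,
        grid.lambda_Theta_xy,
        stats.n,
        options,
        criterion,
        data.snp_ids,
        data.gene_ids,
    )
    layer_yz, table_yz = _select_layer(
        stats.layer_yz(),
        grid.lambda_Lambda_z,
        grid.lambda_Theta_yz,
        stats.n,
        options,
        criterion,
        data.gene_ids,
        data.trait_ids,
    )
    layer_yz.input_ids = layer_xy.output_ids
    model = ChainModel(layer_xy=layer_xy, layer_yz=layer_yz)
    model.fit_info = {
        "selected": {
            "lambda_Lambda_y": layer_xy.lambda_Lambda,
            "lambda_Theta_xy": layer_xy.lambda_Theta,
            "lambda_Lambda_z": layer_yz.lambda_Lambda,
            "lambda_Theta_yz": layer_yz.lambda_Theta,
        }
    }
    return model, {"xy": table_xy, "yz": table_yz}


# ---------------------------------------------------------------------------
# semi-supervised EM
# ---------------------------------------------------------------------------


@dataclass
class EMState:
    posterior_mean: np.ndarray  # (n_hidden, q), in centered coordinates
    posterior_cov: np.ndarray   # (q, q), shared across hidden samples
    expected_objective: list = field(default_factory=list)
    observed_objective: list = field(default_factory=list)
    iterations: int = 0
    converged: bool = False


def _posterior_precision(model: ChainModel) -> np.ndarray:
    Lz = model.layer_yz.chol()
    K = sla.solve_triangular(Lz, model.layer_yz.Theta.T, lower=True).T  # Θ_yz L_z^-T
    return model.layer_xy.Lambda + K @ K.T


def _posterior(model: ChainModel, Xh: np.ndarray, Zh: np.ndarray):
    """Posterior mean/covariance of hidden (centered) expression rows."""
    P = _posterior_precision(model)
    Lp = sla.cholesky(P, lower=True)
    Sig = sla.cho_solve((Lp, True), np.eye(P.shape[0]))
    Sig = 0.5 * (Sig + Sig.T)
    rhs = Zh @ model.layer_yz.Theta.T + Xh @ model.layer_xy.Theta  # (n_h, q)
    mu = -rhs @ Sig
    return mu, Sig


def _observed_objective(model: ChainModel, Xc, Yc, Zc, hidden, penalties=True) -> float:
    """Penalized observed-data negative log-likelihood, scaled by 2/n.

    Observed rows contribute -2 log p(y,z|x); hidden rows -2 log p(z|x)
    obtained from the marginal z | x ~ N(B_xz' x, Λ_z^-1 + Λ_z^-1 Θ_yz' Λ_y^-1
    Θ_yz Λ_z^-1).  Used to verify EM monotonicity.
    """
    from .inference import inf1_snp_trait_effects

    n = Xc.shape[0]
    obs = ~hidden
    lxy, lyz = model.layer_xy, model.layer_yz
    total = 0.0
    if obs.any():
        for layer, A, B in ((lxy, Xc[obs], Yc[obs]), (lyz, Yc[obs], Zc[obs])):
            L = layer.chol()
            R = B + A @ layer.Theta @ sla.cho_solve((L, True), np.eye(layer.n_outputs))
            # -2 log N(b; B'a, Λ^-1) = const - log|Λ| + (b - B'a)' Λ (b - B'a)
            quad = float(np.sum((R @ layer.Lambda) * R))
            logdet = 2.0 * float(np.log(np.diag(L)).sum())
            total += obs.sum() * (layer.n_outputs * np.log(2 * np.pi) - logdet) + quad
    if hidden.any():
        B_xz, cov = inf1_snp_trait_effects(model)
        Lc = sla.cholesky(cov, lower=True)
        R = Zc[hidden] - Xc[hidden] @ B_xz
        W = sla.solve_triangular(Lc, R.T, lower=True)
        logdet = 2.0 * float(np.log(np.diag(Lc)).sum())
        total += hidden.sum() * (model.r * np.log(2 * np.pi) + logdet) + float(
            np.sum(W * W)
        )
    val = total / n * 1.0
    if penalties:
        from .model import l1_offdiag

        for layer in (lxy, lyz):
            val += layer.lambda_Lambda * l1_offdiag(layer.Lambda)
            val += layer.lambda_Theta * float(np.abs(layer.Theta).sum())
    return val


def em_fit(
    data: DataBundle,
    lambdas: ChainLambdas,
    options: SolverOptions | None = None,
    max_em_iter: int = 50,
    em_tol: float = 1e-5,
) -> tuple[ChainModel, EMState]:
    """Semi-supervised fit with whole-row-missing expression.

    With no hidden rows this is exactly :func:`fit_chain`.  Column means are
    fixed once (Y over observed rows, X and Z over all rows) and all internal
    computation is done in centered coordinates, so the EM monotonicity
    guarantee applies to the recorded observed-data objective.
    """
    hidden = ~data.observed
    if not hidden.any():
        model = fit_chain(data, lambdas, options=options)
        state = EMState(
            posterior_mean=np.zeros((0, data.q)),
            posterior_cov=np.zeros((data.q, data.q)),
            iterations=0,
            converged=True,
        )
        return model, state

    n, q = data.n, data.q
    obs = data.observed
    Xc = data.X - data.X.mean(axis=0, keepdims=True)
    Zc = data.Z - data.Z.mean(axis=0, keepdims=True)
    ybar = data.Y[obs].mean(axis=0, keepdims=True)
    Yc = np.zeros((n, q))
    Yc[obs] = data.Y[obs] - ybar

    S_xx = Xc.T @ Xc / n
    S_zz = Zc.T @ Zc / n

    # initialize from the observed-complete subset
    sub = DataBundle(
        X=data.X[obs],
        Y=data.Y[obs],
        Z=data.Z[obs],
        snp_ids=data.snp_ids,
        gene_ids=data.gene_ids,
        trait_ids=data.trait_ids,
    )
    model = fit_chain(sub, lambdas, options=options)
    state = EMState(posterior_mean=np.zeros((int(hidden.sum()), q)), posterior_cov=np.eye(q))
    f_prev = _observed_objective(model, Xc, Yc, Zc, hidden)
    state.observed_objective.append(f_prev)
    n_h = int(hidden.sum())

    for it in range(1, max_em_iter + 1):
        # E-step
        mu, Sig = _posterior(model, Xc[hidden], Zc[hidden])
        state.posterior_mean, state.posterior_cov = mu, Sig
        Yfill = Yc.copy()
        Yfill[hidden] = mu
        stats = SufficientStats(
            S_xx=S_xx,
            S_xy=Xc.T @ Yfill / n,
            S_yy=(Yfill.T @ Yfill + n_h * Sig) / n,
            S_yz=Yfill.T @ Zc / n,
            S_zz=S_zz,
            n=n,
        )
        # M-step, warm-started from the current model
        layer_xy, _ = fit_scggm(
            *stats.layer_xy(),
            lambdas.lambda_Lambda_y,
            lambdas.lambda_Theta_xy,
            options=options,
            init=model.layer_xy,
            input_ids=data.snp_ids,
            output_ids=data.gene_ids,
        )
        layer_yz, _ = fit_scggm(
            *stats.layer_yz(),
            lambdas.lambda_Lambda_z,
            lambdas.lambda_Theta_yz,
            options=options,
            init=model.layer_yz,
            input_ids=data.gene_ids,
            output_ids=data.trait_ids,
        )
        layer_yz.input_ids = layer_xy.output_ids
        model = ChainModel(layer_xy=layer_xy, layer_yz=layer_yz)
        state.expected_objective.append(chain_objective(model, stats))
        f_new = _observed_objective(model, Xc, Yc, Zc, hidden)
        state.observed_objective.append(f_new)
        state.iterations = it
        if f_new > f_prev + 1e-8 * max(1.0, abs(f_prev)):
            warnings.warn(
                f"EM objective increased at iteration {it} "
                f"({f_prev:.8g} -> {f_new:.8g})",
                stacklevel=2,
            )
        if abs(f_prev - f_new) <= em_tol * max(1.0, abs(f_new)):
            state.converged = True
            break
        f_prev = f_new

    model.fit_info = {
        "em_iterations": state.iterations,
        "em_converged": state.converged,
        "observed_objective": state.observed_objective,
    }
    return model, state


def implicit_posterior_solve(
    model: ChainModel,
    column: int,
    tol: float = 1e-8,
    max_iter: int | None = None,
) -> np.ndarray:
    """One column of Σ_y|x,z via conjugate gradients on Λ_y + K K'.

    ``K = Θ_yz L_z^-T`` with ``L_z L_z' = Λ_z``; the dense q x q posterior
    covariance is never formed.  Raises on CG non-convergence.
    """
    q = model.q
    Lz = model.layer_yz.chol()
    K = sla.solve_triangular(Lz, model.layer_yz.Theta.T, lower=True).T
    Lam_y = model.layer_xy.Lambda

    def matvec(v):
        return Lam_y @ v + K @ (K.T @ v)

    op = spla.LinearOperator((q, q), matvec=matvec, dtype=float)
    e = np.zeros(q)
    e[column] = 1.0
    v, info = spla.cg(op, e, rtol=0.0, atol=tol, maxiter=max_iter or 10 * q)
    if info != 0:
        res = float(np.linalg.norm(matvec(v) - e))
        raise RuntimeError(
            f"conjugate gradients did not converge (info={info}, residual={res:.3e})"
        )
    return v
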