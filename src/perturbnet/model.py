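"""Parameter containers, densities and objectives for sparse Gaussian chain graphs.

The chain-graph model factorizes as ``p(y, z | x) = p(y | x) p(z | y)`` where each
factor is a sparse conditional Gaussian graphical model (sCGGM)::

    p(y | x) ∝ exp(-1/2 y' Λ_y y - x' Θ_xy y)
    p(z | y) ∝ exp(-1/2 z' Λ_z z - y' Θ_yz z)

``Λ`` is the (positive-definite) precision of the output network and ``Θ`` maps
inputs onto outputs as direct perturbations.  All estimation routines consume
mean-centered, 1/n-scaled cross-product matrices (:class:`SufficientStats`)
rather than raw data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

__all__ = [
    "SCGGMLayer",
    "ChainModel",
    "SufficientStats",
    "DataBundle",
    "compute_suffstats",
    "scggm_neg_loglik",
    "scggm_gradients",
    "penalized_objective",
    "chain_objective",
]

#: symmetry violations above this (relative to matrix scale) raise instead of
#: being silently symmetrized
SYMMETRY_TOL = 1e-8


def _as_dense(a) -> np.ndarray:
    if sp.issparse(a):
        return a.toarray()
    return np.asarray(a, dtype=float)


def check_symmetric(a: np.ndarray, name: str = "matrix") -> None:
    scale = max(1.0, float(np.abs(a).max(initial=0.0)))
    dev = float(np.abs(a - a.T).max(initial=0.0))
    if dev > SYMMETRY_TOL * scale:
        raise ValueError(
            f"{name} is not symmetric (max |A - A'| = {dev:.3e}); refusing to "
            "symmetrize silently"
        )


def cholesky_pd(a: np.ndarray, name: str = "Lambda") -> np.ndarray:
    """Lower Cholesky factor; raises ``ValueError`` if not positive definite."""
    try:
        return sla.cholesky(a, lower=True)
    except sla.LinAlgError as exc:
        raise ValueError(f"{name} is not positive definite") from exc


@dataclass
class SCGGMLayer:
    """One sCGGM: output network precision ``Lambda`` and perturbation map ``Theta``.

    Parameters are stored dense internally (problem sizes here are moderate);
    ``Theta`` is expected to be sparse in content, not storage.
    """

    Lambda: np.ndarray
    Theta: np.ndarray
    lambda_Lambda: float = 0.0
    lambda_Theta: float = 0.0
    input_ids: Sequence[str] | None = None
    output_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.Lambda = _as_dense(self.Lambda)
        self.Theta = _as_dense(self.Theta)
        if self.Theta.ndim != 2 or self.Lambda.ndim != 2:
            raise ValueError("Lambda and Theta must be 2-d")
        if self.Lambda.shape[0] != self.Lambda.shape[1]:
            raise ValueError("Lambda must be square")
        if self.Theta.shape[1] != self.Lambda.shape[0]:
            raise ValueError(
                f"Theta has {self.Theta.shape[1]} columns but Lambda is "
                f"{self.Lambda.shape[0]} x {self.Lambda.shape[0]}"
            )
        if self.lambda_Lambda < 0 or self.lambda_Theta < 0:
            raise ValueError("penalty weights must be nonnegative")
        check_symmetric(self.Lambda, "Lambda")
        if self.input_ids is None:
            self.input_ids = [f"in{i}" for i in range(self.Theta.shape[0])]
        if self.output_ids is None:
            self.output_ids = [f"out{j}" for j in range(self.Lambda.shape[0])]
        if len(self.input_ids) != self.Theta.shape[0]:
            raise ValueError("input_ids length mismatch")
        if len(self.output_ids) != self.Lambda.shape[0]:
            raise ValueError("output_ids length mismatch")

    @property
    def n_inputs(self) -> int:
        return self.Theta.shape[0]

    @property
    def n_outputs(self) -> int:
        return self.Lambda.shape[0]

    def chol(self) -> np.ndarray:
        return cholesky_pd(self.Lambda)


@dataclass
class FitInfo:
    objective_trajectory: list = field(default_factory=list)
    iterations: int = 0
    converged: bool = False
    message: str = ""


@dataclass
class ChainModel:
    """Two stacked sCGGM layers: SNPs -> genes (xy) and genes -> traits (yz)."""

    layer_xy: SCGGMLayer
    layer_yz: SCGGMLayer
    fit_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.layer_xy.output_ids) != list(self.layer_yz.input_ids):
            raise ValueError("gene identifiers of the two layers disagree")

    @property
    def p(self) -> int:
        return self.layer_xy.n_inputs

    @property
    def q(self) -> int:
        return self.layer_xy.n_outputs

    @property
    def r(self) -> int:
        return self.layer_yz.n_outputs


@dataclass
class SufficientStats:
    """Mean-centered, 1/n-scaled cross products of the three data matrices."""

    S_xx: np.ndarray
    S_xy: np.ndarray
    S_yy: np.ndarray
    S_yz: np.ndarray
    S_zz: np.ndarray
    n: int

    def layer_xy(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(S_in_in, S_in_out, S_out_out) slice for the SNP->gene layer."""
        return self.S_xx, self.S_xy, self.S_yy

    def layer_yz(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.S_yy, self.S_yz, self.S_zz


@dataclass
class DataBundle:
    """Raw data: genotypes X (n x p), expression Y (n x q), traits Z (n x r).

    ``observed`` marks the samples whose expression row is available; in the
    fully supervised case it is all-True.  Y rows for unobserved samples are
    ignored (they may be NaN).
    """

    X: np.ndarray
    Z: np.ndarray
    Y: np.ndarray | None = None
    observed: np.ndarray | None = None
    sample_ids: Sequence[str] | None = None
    snp_ids: Sequence[str] | None = None
    gene_ids: Sequence[str] | None = None
    trait_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Z = np.asarray(self.Z, dtype=float)
        n = self.X.shape[0]
        if self.Z.shape[0] != n:
            raise ValueError("X and Z sample counts differ")
        if self.Y is None:
            raise ValueError("expression matrix Y is required")
        self.Y = np.asarray(self.Y, dtype=float)
        if self.observed is None:
            self.observed = np.ones(n, dtype=bool)
        else:
            self.observed = np.asarray(self.observed, dtype=bool)
            if self.observed.shape != (n,):
                raise ValueError("observed mask must have one entry per sample")
        if self.Y.shape[0] != n:
            raise ValueError("Y must have one row per sample (hidden rows may be NaN)")
        if not self.observed.any():
            raise ValueError("at least one sample must have observed expression")
        for nm, m in (("X", self.X), ("Z", self.Z)):
            if np.isnan(m).any():
                raise ValueError(f"{nm} contains missing values")
        if np.isnan(self.Y[self.observed]).any():
            raise ValueError("observed Y rows contain missing values")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Y.shape[1]

    @property
    def r(self) -> int:
        return self.Z.shape[1]


def center(a: np.ndarray) -> np.ndarray:
    """Column-mean centering (means taken over the rows given)."""
    return a - a.mean(axis=0, keepdims=True)


def compute_suffstats(data: DataBundle, observed_only: bool = False) -> SufficientStats:
    """Cross-product statistics ``(1/n) A_centered' B_centered``.

    With ``observed_only`` the expression-bearing statistics (S_xy, S_yy, S_yz)
    are formed from the expression-observed rows only (centered and scaled by
    the number of contributing rows); S_xx and S_zz always use all rows.
    """
    n_all = data.n
    if n_all < 2:
        raise ValueError("need at least 2 samples")
    Xc = center(data.X)
    Zc = center(data.Z)
    if observed_only:
        obs = data.observed
        n_obs = int(obs.sum())
        if n_obs == 0:
            raise ValueError("no samples with observed expression")
        if n_obs < 2:
            raise ValueError("need at least 2 expression-observed samples")
        Yo = center(data.Y[obs])
        Xo = center(data.X[obs])
        Zo = center(data.Z[obs])
        S_xy = Xo.T @ Yo / n_obs
        S_yy = Yo.T @ Yo / n_obs
        S_yz = Yo.T @ Zo / n_obs
    else:
        if not data.observed.all():
            raise ValueError(
                "expression is missing for some samples; use observed_only=True "
                "or the EM fitter"
            )
        Yc = center(data.Y)
        S_xy = Xc.T @ Yc / n_all
        S_yy = Yc.T @ Yc / n_all
        S_yz = Yc.T @ Zc / n_all
    return SufficientStats(
        S_xx=Xc.T @ Xc / n_all,
        S_xy=S_xy,
        S_yy=S_yy,
        S_yz=S_yz,
        S_zz=Zc.T @ Zc / n_all,
        n=n_all,
    )


def scggm_neg_loglik(
    layer: SCGGMLayer,
    S_in_in: np.ndarray,
    S_in_out: np.ndarray,
    S_out_out: np.ndarray,
) -> float:
    """Smooth part of the per-layer objective (no penalties):

    ``-log|Λ| + tr(S_oo Λ + 2 S_io' Θ + Λ^-1 Θ' S_ii Θ)``

    which equals ``(2/n) Σ_i -log N(y_i; B' x_i, Λ^-1)`` up to an additive
    constant independent of (Λ, Θ).
    """
    L = layer.chol()
    logdet = 2.0 * float(np.log(np.diag(L)).sum())
    Lam, Th = layer.Lambda, layer.Theta
    val = -logdet + float(np.sum(S_out_out * Lam)) + 2.0 * float(np.sum(S_in_out * Th))
    if Th.shape[0]:
        # tr(Λ^-1 Θ' S_ii Θ) via triangular solves, no explicit inverse
        W = sla.solve_triangular(L, Th.T, lower=True)  # L^-1 Θ'
        val += float(np.sum((W @ S_in_in) * W))
    return val


def scggm_gradients(
    layer: SCGGMLayer,
    S_in_in: np.ndarray,
    S_in_out: np.ndarray,
    S_out_out: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of the smooth part and the (Sigma, Psi) caches.

    Returns ``(grad_Lambda, grad_Theta, Sigma, Psi)`` with
    ``grad_Lambda = S_oo - Σ - Ψ``, ``grad_Theta = 2 (S_io + S_ii Θ Σ)``,
    ``Σ = Λ^-1`` and ``Ψ = Σ Θ' S_ii Θ Σ``.
    """
    L = layer.chol()
    q = layer.n_outputs
    Sigma = sla.cho_solve((L, True), np.eye(q))
    Sigma = 0.5 * (Sigma + Sigma.T)
    ThSig = layer.Theta @ Sigma
    if layer.Theta.shape[0]:
        SiiThSig = S_in_in @ ThSig
        Psi = ThSig.T @ SiiThSig
        Psi = 0.5 * (Psi + Psi.T)
        grad_T = 2.0 * (S_in_out + SiiThSig)
    else:
        Psi = np.zeros((q, q))
        grad_T = np.zeros_like(layer.Theta)
    grad_L = S_out_out - Sigma - Psi
    return grad_L, grad_T, Sigma, Psi


def l1_offdiag(a: np.ndarray) -> float:
    return float(np.abs(a).sum() - np.abs(np.diag(a)).sum())


def penalized_objective(
    layer: SCGGMLayer,
    S_in_in: np.ndarray,
    S_in_out: np.ndarray,
    S_out_out: np.ndarray,
) -> float:
    """Negative log-likelihood plus L1 penalties; Λ diagonal is unpenalized."""
    val = scggm_neg_loglik(layer, S_in_in, S_in_out, S_out_out)
    val += layer.lambda_Lambda * l1_offdiag(layer.Lambda)
    val += layer.lambda_Theta * float(np.abs(layer.Theta).sum())
    return val


def chain_objective(model: ChainModel, stats: SufficientStats) -> float:
    """Sum of the two penalized layer objectives (the problem decouples)."""
    return penalized_objective(model.layer_xy, *stats.layer_xy()) + penalized_objective(
        model.layer_yz, *stats.layer_yz()
    )
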