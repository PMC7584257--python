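"""Memory-budgeted sCGGM fitting by block coordinate descent.

Solves the identical convex problem as :func:`perturbnet.solver.fit_scggm`
but never materializes a dense q x q (Σ, Ψ) or p x p (S_xx) cache: columns of
Σ and Ψ are computed per block via factor solves, and rows of S_xx are
recomputed on demand from the centered data for each input block.  A
:class:`BlockPlan` partitions the index ranges so that the estimated peak
working set of the large caches stays below a user-set byte budget; a
:class:`CacheLedger` audits the actual allocations.  With a budget large
enough for the dense caches the plan has a single block and the in-memory
fast path is called directly (identical code path, identical result);
otherwise the block sweep visits the same active coordinates in a
block-grouped order and converges to the same optimum within solver
tolerance.

Parameter storage (Λ, Θ, the sparse Newton direction) and factorization
workspace are exempt from the budget accounting, which covers the large
caches only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .model import SCGGMLayer, center, l1_offdiag
from .solver import LineSearchError, SolverOptions, SolverState, fit_scggm, soft_threshold

__all__ = ["BlockPlan", "CacheLedger", "plan_blocks", "fit_scggm_blockwise"]

_F8 = 8  # bytes per float64


class CapacityError(ValueError):
    pass


@dataclass
class CacheLedger:
    """Byte accounting for the large matrix caches."""

    current: dict = field(default_factory=dict)
    peak: int = 0

    def alloc(self, name: str, arr: np.ndarray) -> np.ndarray:
        self.current[name] = int(arr.nbytes)
        total = sum(self.current.values())
        self.peak = max(self.peak, total)
        return arr

    def free(self, *names: str) -> None:
        for name in names:
            self.current.pop(name, None)


@dataclass
class BlockPlan:
    col_blocks: list          # output-index blocks (Λ / Σ work)
    row_blocks: list          # input-index blocks (Θ / S_xx work)
    est_peak: int
    budget: int

    @property
    def n_col_blocks(self) -> int:
        return len(self.col_blocks)

    @property
    def n_row_blocks(self) -> int:
        return len(self.row_blocks)


def _cost_lambda(b: int, q: int, n: int) -> int:
    # block-pair pass: S_yy/Σ/Ψ row caches for two blocks + an n x 2b transient
    return (6 * b * q + 2 * n * b) * _F8


def _cost_theta(br: int, b: int, q: int, p: int, n: int) -> int:
    # S_xx and S_xy row blocks + Σ row block + U = ΘΣ_B cache + n x b transient
    return (br * p + br * q + b * q + p * b + n * b) * _F8


def _dense_requirement(p: int, q: int, n: int) -> int:
    # what the in-memory path holds: Σ, Ψ, Φ, U, Δ (q x q each), M and S_xy
    # (p x q), S_xx (p x p), S_yy (q x q)
    return (6 * q * q + 2 * p * q + p * p) * _F8


def _partition(nidx: int, block: int) -> list:
    return [np.arange(s, min(s + block, nidx)) for s in range(0, nidx, block)]


def plan_blocks(p: int, q: int, budget: int, n: int = 0) -> BlockPlan:
    """Deterministic block plan whose estimated peak fits the budget.

    Shrinks to a single block when the budget covers the full dense working
    set.  Raises :class:`CapacityError` (naming the minimal feasible budget)
    when even single-index blocks do not fit.
    """
    if budget >= _dense_requirement(p, q, n):
        return BlockPlan(
            col_blocks=[np.arange(q)],
            row_blocks=[np.arange(p)],
            est_peak=_dense_requirement(p, q, n),
            budget=budget,
        )
    minimal = max(_cost_lambda(1, q, n), _cost_theta(1, 1, q, p, n))
    if budget < minimal:
        raise CapacityError(
            f"memory budget {budget} bytes infeasible; minimal feasible budget "
            f"is {minimal} bytes for p={p}, q={q}, n={n}"
        )
    b = 1
    while b < q:
        nb = min(b + 1, q)
        if (
            _cost_lambda(nb, q, n) <= budget
            and _cost_theta(1, nb, q, p, n) <= budget
        ):
            b = nb
        else:
            break
    br = 1
    while br < p:
        nbr = min(br + 1, p)
        if _cost_theta(nbr, b, q, p, n) <= budget:
            br = nbr
        else:
            break
    est = max(_cost_lambda(b, q, n), _cost_theta(br, b, q, p, n))
    return BlockPlan(
        col_blocks=_partition(q, b),
        row_blocks=_partition(p, br),
        est_peak=est,
        budget=budget,
    )


def _objective(Lam, Theta, Xc, Yc, n, lam_L, lam_T, chunk=4096):
    """Penalized objective from data, with only chunked n x q transients.

    Returns (value, lower Cholesky factor) or (inf, None) if Λ is not PD.
    """
    try:
        L = sla.cholesky(Lam, lower=True)
    except sla.LinAlgError:
        return np.inf, None
    logdet = 2.0 * float(np.log(np.diag(L)).sum())
    val = -logdet
    for s in range(0, n, chunk):
        Ychunk = Yc[s : s + chunk]
        Xchunk = Xc[s : s + chunk]
        YL = Ychunk @ Lam
        val += float(np.sum(YL * Ychunk)) / n           # tr(S_yy Λ)
        R = Xchunk @ Theta                              # rows of X̃Θ
        val += 2.0 * float(np.sum(R * Ychunk)) / n      # 2 tr(S_xy' Θ)
        W = sla.solve_triangular(L, R.T, lower=True)
        val += float(np.sum(W * W)) / n                 # tr(Λ^-1 Θ' S_xx Θ)
    val += lam_L * l1_offdiag(Lam) + lam_T * float(np.abs(Theta).sum())
    return val, L


def _sigma_psi_cols(chol_L, Theta, Xc, cols, n, ledger: CacheLedger):
    """Σ[:, cols] and Ψ[:, cols] via factor solves (no dense q x q)."""
    q = chol_L.shape[0]
    E = np.zeros((q, len(cols)))
    E[cols, np.arange(len(cols))] = 1.0
    Sig = sla.cho_solve((chol_L, True), E)
    ledger.alloc("Sigma_block", Sig)
    A1 = Theta @ Sig                     # p x b
    A2 = Xc @ A1                         # n x b transient
    ledger.alloc("Xc_transient", A2)
    A3 = (Xc.T @ A2) / n                 # p x b
    A4 = Theta.T @ A3                    # q x b
    Psi = sla.cho_solve((chol_L, True), A4)
    ledger.free("Xc_transient")
    ledger.alloc("Psi_block", Psi)
    return Sig, Psi


def _phi_delta_sigma(i, j, delta, Sig_rows, Psi_rows, loc):
    """(Φ Δ Σ)_ij with Δ a sparse dict {(k,l): val, k<=l}, Φ = Σ + 2Ψ.

    Needs rows i and j of Σ and Φ, provided via ``Sig_rows``/``Psi_rows``
    indexed through ``loc`` (global index -> cached row)."""
    li = loc[i]
    lj = loc[j]
    phi_i = None  # computed lazily per nonzero access
    total = 0.0
    for (k, l), v in delta.items():
        if v == 0.0:
            continue
        phi_ik = Sig_rows[li, k] + 2.0 * Psi_rows[li, k]
        sig_lj = Sig_rows[lj, l]
        total += v * phi_ik * sig_lj
        if k != l:
            phi_il = Sig_rows[li, l] + 2.0 * Psi_rows[li, l]
            sig_kj = Sig_rows[lj, k]
            total += v * phi_il * sig_kj
    return total


def fit_scggm_blockwise(
    X: np.ndarray,
    Y: np.ndarray,
    lambda_Lambda: float,
    lambda_Theta: float,
    budget: int,
    options: SolverOptions | None = None,
    ledger: CacheLedger | None = None,
) -> tuple[SCGGMLayer, SolverState]:
    """Fit one sCGGM from raw data under a memory budget (bytes).

    Same convergence criteria and solution as :func:`fit_scggm`; the returned
    state's trajectory and the ledger's ``peak`` document the run.
    """
    opts = options or SolverOptions()
    ledger = ledger if ledger is not None else CacheLedger()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, p = X.shape
    q = Y.shape[1]
    if Y.shape[0] != n:
        raise ValueError("X and Y disagree on sample count")
    plan = plan_blocks(p, q, budget, n)
    Xc = center(X)
    Yc = center(Y)

    if budget >= _dense_requirement(p, q, n):
        # budget covers the dense working set: identical in-memory code path
        S_xx = ledger.alloc("S_xx", Xc.T @ Xc / n)
        S_xy = ledger.alloc("S_xy", Xc.T @ Yc / n)
        S_yy = ledger.alloc("S_yy", Yc.T @ Yc / n)
        layer, state = fit_scggm(
            S_xx, S_xy, S_yy, lambda_Lambda, lambda_Theta, options=opts
        )
        ledger.peak = max(ledger.peak, _dense_requirement(p, q, n))
        return layer, state

    # --- blockwise path ---
    d_yy = np.einsum("ij,ij->j", Yc, Yc) / n
    with np.errstate(divide="ignore"):
        inv = np.where(d_yy > 0, 1.0 / np.maximum(d_yy, 1e-300), 1.0)
    Lam = np.diag(np.maximum(inv, 1e-3))
    Theta = np.zeros((p, q))
    d_xx = np.einsum("ij,ij->j", Xc, Xc) / n
    lam_L, lam_T = lambda_Lambda, lambda_Theta

    state = SolverState(Sigma=np.empty(0), Psi=np.empty(0))
    f_prev, chol_L = _objective(Lam, Theta, Xc, Yc, n, lam_L, lam_T)
    state.objective_trajectory.append(f_prev)
    converged = False
    message = "max iterations reached"
    warned_zero = set()

    for it in range(1, opts.max_iter + 1):
        chol_L = sla.cholesky(Lam, lower=True)

        # ---- active sets (block-computed gradients) ----
        act_T_rows: list = []
        for R in plan.row_blocks:
            S_xxR = ledger.alloc("S_xx_rows", Xc[:, R].T @ Xc / n)
            S_xyR = ledger.alloc("S_xy_rows", Xc[:, R].T @ Yc / n)
            GT = 2.0 * (
                S_xyR + sla.cho_solve((chol_L, True), (S_xxR @ Theta).T).T
            )
            mask = (np.abs(GT) > lam_T) | (Theta[R, :] != 0.0)
            ii, jj = np.nonzero(mask)
            act_T_rows.append(np.column_stack([R[ii], jj]))
            ledger.free("S_xx_rows", "S_xy_rows")
        act_T = (
            np.vstack(act_T_rows) if act_T_rows else np.zeros((0, 2), dtype=int)
        )

        act_L_mask_cols = []
        for B in plan.col_blocks:
            Sig_B, Psi_B = _sigma_psi_cols(chol_L, Theta, Xc, B, n, ledger)
            S_yyB = ledger.alloc("S_yy_block", Yc.T @ Yc[:, B] / n)
            GB = S_yyB - Sig_B - Psi_B
            act_L_mask_cols.append((np.abs(GB) > lam_L) | (Lam[:, B] != 0.0))
            ledger.free("Sigma_block", "Psi_block", "S_yy_block")
        mask_L = np.hstack(act_L_mask_cols)
        mask_L = mask_L | mask_L.T
        np.fill_diagonal(mask_L, True)

        # ---- Θ step: Lasso coordinate descent per (row, column) block ----
        for _ in range(max(1, opts.sweeps)):
            for B in plan.col_blocks:
                E = np.zeros((q, len(B)))
                E[B, np.arange(len(B))] = 1.0
                Sig_cols = ledger.alloc(
                    "Sigma_block", sla.cho_solve((chol_L, True), E)
                )  # q x b; row j of Σ is Sig_cols[:, loc].T by symmetry
                U = ledger.alloc("U_block", Theta @ Sig_cols)  # p x b
                locB = {int(j): k for k, j in enumerate(B)}
                setB = set(int(j) for j in B)
                for R in plan.row_blocks:
                    coords = act_T[np.isin(act_T[:, 0], R) & np.isin(act_T[:, 1], B)]
                    if not len(coords):
                        continue
                    S_xxR = ledger.alloc("S_xx_rows", Xc[:, R].T @ Xc / n)
                    S_xyR = ledger.alloc("S_xy_rows", Xc[:, R].T @ Yc[:, B] / n)
                    locR = {int(i): k for k, i in enumerate(R)}
                    for i, j in coords:
                        i, j = int(i), int(j)
                        a = 2.0 * d_xx[i] * Sig_cols[j, locB[j]]
                        if a <= 0.0:
                            if i not in warned_zero:
                                warnings.warn(
                                    f"input {i} has zero variance; skipped",
                                    stacklevel=2,
                                )
                                warned_zero.add(i)
                            continue
                        g = 2.0 * (
                            S_xyR[locR[i], locB[j]]
                            + float(S_xxR[locR[i]] @ U[:, locB[j]])
                        )
                        old = Theta[i, j]
                        new = soft_threshold(old - g / a, lam_T / a)
                        if new != old:
                            Theta[i, j] = new
                            U[i, :] += (new - old) * Sig_cols[j, :]
                    ledger.free("S_xx_rows", "S_xy_rows")
                ledger.free("Sigma_block", "U_block")

        # ---- Λ step: Newton direction over block pairs, then line search ----
        delta: dict = {}
        trGD = 0.0
        for a_idx in range(plan.n_col_blocks):
            for b_idx in range(a_idx, plan.n_col_blocks):
                Ba, Bb = plan.col_blocks[a_idx], plan.col_blocks[b_idx]
                BB = Ba if a_idx == b_idx else np.concatenate([Ba, Bb])
                Sig_B, Psi_B = _sigma_psi_cols(chol_L, Theta, Xc, BB, n, ledger)
                Sig_rows = Sig_B.T  # rows of Σ for BB (symmetry)
                Psi_rows = Psi_B.T
                S_yyB = ledger.alloc("S_yy_block", (Yc[:, BB].T @ Yc) / n)
                loc = {int(g): k for k, g in enumerate(BB)}
                pairs = []
                if a_idx == b_idx:
                    for ii_, i in enumerate(Ba):
                        for j in Ba[ii_:]:
                            if mask_L[i, j]:
                                pairs.append((int(i), int(j)))
                else:
                    for i in Ba:
                        for j in Bb:
                            if mask_L[i, j]:
                                pairs.append((int(i), int(j)))
                for i, j in pairs:
                    li, lj = loc[i], loc[j]
                    G_ij = S_yyB[li, j] - Sig_rows[li, j] - Psi_rows[li, j]
                    if i == j:
                        phi_ii = Sig_rows[li, i] + 2.0 * Psi_rows[li, i]
                        a_coef = phi_ii * Sig_rows[li, i]
                        if a_coef <= 0.0:
                            continue
                        b_coef = G_ij + _phi_delta_sigma(
                            i, i, delta, Sig_rows, Psi_rows, loc
                        )
                        mu = -b_coef / a_coef
                        if mu != 0.0:
                            delta[(i, i)] = delta.get((i, i), 0.0) + mu
                    else:
                        phi_ii = Sig_rows[li, i] + 2.0 * Psi_rows[li, i]
                        phi_jj = Sig_rows[lj, j] + 2.0 * Psi_rows[lj, j]
                        phi_ij = Sig_rows[li, j] + 2.0 * Psi_rows[li, j]
                        a_coef = (
                            Sig_rows[li, i] * phi_jj
                            + Sig_rows[lj, j] * phi_ii
                            + 2.0 * Sig_rows[li, j] * phi_ij
                        )
                        if a_coef <= 0.0:
                            continue
                        b_coef = (
                            2.0 * G_ij
                            + _phi_delta_sigma(i, j, delta, Sig_rows, Psi_rows, loc)
                            + _phi_delta_sigma(j, i, delta, Sig_rows, Psi_rows, loc)
                        )
                        c = Lam[i, j] + delta.get((i, j), 0.0)
                        z = soft_threshold(c - b_coef / a_coef, 2.0 * lam_L / a_coef)
                        mu = z - c
                        if mu != 0.0:
                            delta[(i, j)] = delta.get((i, j), 0.0) + mu
                for i, j in pairs:
                    li = loc[i]
                    d_ij = delta.get((i, j), 0.0)
                    if d_ij:
                        G_ij = S_yyB[li, j] - Sig_rows[li, j] - Psi_rows[li, j]
                        trGD += (1.0 if i == j else 2.0) * G_ij * d_ij
                ledger.free("Sigma_block", "Psi_block", "S_yy_block")

        # line search on Λ <- Λ + α D
        D = np.zeros((q, q))
        for (i, j), v in delta.items():
            D[i, j] += v
            if i != j:
                D[j, i] += v
        if np.any(D):
            pen0 = l1_offdiag(Lam)
            pen1 = l1_offdiag(Lam + D)
            delta_dec = trGD + lam_L * (pen1 - pen0)
            f0, _ = _objective(Lam, Theta, Xc, Yc, n, lam_L, lam_T)
            alpha = 1.0
            accepted = False
            while alpha >= opts.alpha_min:
                f1, chol_try = _objective(
                    Lam + alpha * D, Theta, Xc, Yc, n, lam_L, lam_T
                )
                if np.isfinite(f1) and f1 <= f0 + opts.sigma * alpha * delta_dec:
                    Lam = Lam + alpha * D
                    f_new = f1
                    accepted = True
                    break
                alpha *= opts.beta
            if not accepted:
                message = "line search stagnated"
                f_new, _ = _objective(Lam, Theta, Xc, Yc, n, lam_L, lam_T)
                state.objective_trajectory.append(f_new)
                state.iteration = it
                break
        else:
            f_new, _ = _objective(Lam, Theta, Xc, Yc, n, lam_L, lam_T)

        state.objective_trajectory.append(f_new)
        state.iteration = it
        if abs(f_prev - f_new) <= opts.tol * max(1.0, abs(f_new)):
            converged = True
            message = f"converged in {it} iterations"
            break
        f_prev = f_new

    layer = SCGGMLayer(
        Lambda=0.5 * (Lam + Lam.T),
        Theta=Theta,
        lambda_Lambda=lam_L,
        lambda_Theta=lam_T,
    )
    layer.fit_info = {  # type: ignore[attr-defined]
        "objective_trajectory": state.objective_trajectory,
        "iterations": state.iteration,
        "converged": converged,
        "message": message,
        "peak_cache_bytes": ledger.peak,
        "n_col_blocks": plan.n_col_blocks,
        "n_row_blocks": plan.n_row_blocks,
    }
    if not converged:
        warnings.warn("fit_scggm_blockwise did not converge", stacklevel=2)
    return layer, state
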