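"""Recovery scoring, mediator categorization, baselines, robustness.

Recovery of true edges / perturbations / SNP-trait paths is scored by ranking
|score| and sweeping thresholds, reporting sensitivity (TP / P) against false
discovery rate (FP / (TP + FP)); curves from replicate simulations are
averaged pointwise on a fixed FDR grid.  Mediator genes are categorized by
whether the perturbation they receive from a SNP and pass to a trait is
direct (a nonzero Θ entry) or indirect (only the propagated B entry is
nonzero).  A two-layer Lasso (each gene on X, each trait on Y, effects
composed by coefficient-matrix product) serves as the network-free baseline.
Robustness refits on subsampled / noise-injected data and scores nonzero-
pattern agreement with the reference fit by ROC-AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LinearRegression

from .chain import ChainLambdas, fit_chain
from .model import ChainModel, DataBundle
from .solver import SolverOptions

__all__ = [
    "RecoveryCurve",
    "recovery_curve",
    "average_curves",
    "sensitivity_at_fdr",
    "MediatorCategory",
    "categorize_mediators",
    "two_layer_lasso_baseline",
    "path_sensitivity_envelope",
    "path_recovery_auc",
    "support_auc",
    "robustness_suite",
]


@dataclass
class RecoveryCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    fdr: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    n_replicates: int = 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "fdr": self.fdr,
                "tp": self.tp,
                "fp": self.fp,
                "fn": self.fn,
            }
        )


def recovery_curve(scores: np.ndarray, truth_mask: np.ndarray) -> RecoveryCurve:
    """Sensitivity/FDR sweep over |score| thresholds (ties grouped)."""
    s = np.abs(np.asarray(scores, dtype=float)).ravel()
    t = np.asarray(truth_mask, dtype=bool).ravel()
    if s.shape != t.shape:
        raise ValueError("scores and truth mask must have the same shape")
    P = int(t.sum())
    if P == 0:
        raise ValueError("truth mask has no positives")
    if not s.any():
        warnings.warn("all scores are zero; recovery curve is degenerate", stacklevel=2)
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    t_sorted = t[order]
    cum_tp = np.cumsum(t_sorted)
    cum_fp = np.cumsum(~t_sorted)
    # group exact ties: keep the last index of each distinct threshold
    last = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    idx = np.where(last)[0]
    tp = cum_tp[idx].astype(float)
    fp = cum_fp[idx].astype(float)
    thr = s_sorted[idx]
    sens = tp / P
    fdr = fp / np.maximum(tp + fp, 1.0)
    return RecoveryCurve(
        thresholds=thr,
        sensitivity=sens,
        fdr=fdr,
        tp=tp,
        fp=fp,
        fn=P - tp,
    )


def sensitivity_at_fdr(curve: RecoveryCurve, fdr: float = 0.05) -> float:
    """Highest sensitivity attained at an FDR not exceeding the target."""
    ok = curve.fdr <= fdr
    return float(curve.sensitivity[ok].max()) if ok.any() else 0.0


def curve_on_grid(curve: RecoveryCurve, grid: np.ndarray) -> np.ndarray:
    """Best sensitivity at each FDR grid point (step interpolation)."""
    out = np.zeros_like(grid, dtype=float)
    for k, g in enumerate(grid):
        ok = curve.fdr <= g
        out[k] = curve.sensitivity[ok].max() if ok.any() else 0.0
    return out


def average_curves(curves: list[RecoveryCurve], n_grid: int = 101):
    """Pointwise average over a fixed FDR grid; returns (grid, mean, lo, hi)."""
    grid = np.linspace(0.0, 1.0, n_grid)
    mat = np.vstack([curve_on_grid(c, grid) for c in curves])
    return grid, mat.mean(axis=0), mat.min(axis=0), mat.max(axis=0)


def path_sensitivity_envelope(
    masks: list[np.ndarray], truth_mask: np.ndarray, n_grid: int = 101
) -> tuple[np.ndarray, np.ndarray]:
    """Sensitivity/FDR envelope of a family of estimated supports.

    Network recovery is scored over a regularization path: each path point
    (an estimated edge set at one penalty level) yields one
    (FDR, sensitivity) operating point, and the envelope records the best
    sensitivity achieved at or below each FDR grid value.  Scoring a single
    penalized estimate by coefficient magnitude instead would conflate
    ranking quality with how many coefficients survive the penalty.
    """
    t = np.asarray(truth_mask, dtype=bool).ravel()
    P = int(t.sum())
    if P == 0:
        raise ValueError("truth mask has no positives")
    pts = []
    for m in masks:
        e = np.asarray(m, dtype=bool).ravel()
        tp = int((e & t).sum())
        fp = int((e & ~t).sum())
        sens = tp / P
        fdr = fp / max(tp + fp, 1)
        pts.append((fdr, sens))
    grid = np.linspace(0.0, 1.0, n_grid)
    env = np.zeros_like(grid)
    for k, g in enumerate(grid):
        vals = [s for f, s in pts if f <= g]
        env[k] = max(vals) if vals else 0.0
    return grid, env


def path_recovery_auc(
    masks: list[np.ndarray], truth_mask: np.ndarray, n_grid: int = 101
) -> float:
    """Area under the path sensitivity/FDR envelope on [0, 1]."""
    grid, env = path_sensitivity_envelope(masks, truth_mask, n_grid)
    return float(np.trapezoid(env, grid))


@dataclass
class MediatorCategory:
    """(SNP, gene, trait) triplets on nonzero paths with direct/indirect labels."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)


def categorize_mediators(
    model: ChainModel, zero_tol: float = 0.0, max_triplets: int | None = None
) -> MediatorCategory:
    """Label each mediated (SNP, gene, trait) path.

    A gene mediates SNP k -> trait i when both B_xy[k, gene] and
    B_yz[gene, i] are nonzero.  ``receives`` is "direct" iff Θ_xy[k, gene] is
    nonzero; ``passes`` is "direct" iff Θ_yz[gene, i] is nonzero.
    """
    from .inference import indirect_xy, indirect_yz

    B_xy = indirect_xy(model.layer_xy)
    B_yz = indirect_yz(model.layer_yz)
    Th_xy, Th_yz = model.layer_xy.Theta, model.layer_yz.Theta
    snps = list(model.layer_xy.input_ids)
    genes = list(model.layer_xy.output_ids)
    traits = list(model.layer_yz.output_ids)
    rows = []
    ks, js = np.nonzero(np.abs(B_xy) > zero_tol)
    recv_direct = Th_xy != 0.0
    pass_direct = Th_yz != 0.0
    for k, j in zip(ks, js):
        out_traits = np.nonzero(np.abs(B_yz[j]) > zero_tol)[0]
        for i in out_traits:
            rows.append(
                {
                    "snp": snps[k],
                    "gene": genes[j],
                    "trait": traits[i],
                    "receives": "direct" if recv_direct[k, j] else "indirect",
                    "passes": "direct" if pass_direct[j, i] else "indirect",
                }
            )
            if max_triplets is not None and len(rows) >= max_triplets:
                return MediatorCategory(table=pd.DataFrame(rows))
    return MediatorCategory(table=pd.DataFrame(rows))


def two_layer_lasso_baseline(
    data: DataBundle,
    alpha_xy: float | None = None,
    alpha_yz: float | None = None,
) -> dict:
    """Network-free baseline: per-response L1 regression, effects composed.

    Each gene is regressed on X and each trait on Y independently (Lasso with
    the given alpha; ``alpha=None`` or 0 falls back to OLS).  Returns dense
    coefficient matrices W_xy (p x q), W_yz (q x r) and their product W_xz.
    Per-response solver failures are recorded, not fatal.
    """
    if not data.observed.all():
        raise ValueError("baseline requires complete data")
    X, Y, Z = data.X, data.Y, data.Z
    failures: list[str] = []

    def fit_block(A, B, alpha):
        coef = np.zeros((A.shape[1], B.shape[1]))
        for j in range(B.shape[1]):
            try:
                if alpha is None or alpha == 0.0:
                    est = LinearRegression()
                else:
                    est = Lasso(alpha=alpha, max_iter=50_000)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(A, B[:, j])
                coef[:, j] = est.coef_
            except Exception as exc:  # pragma: no cover - defensive
                failures.append(f"response {j}: {exc}")
        return coef

    W_xy = fit_block(X, Y, alpha_xy)
    W_yz = fit_block(Y, Z, alpha_yz)
    return {
        "W_xy": W_xy,
        "W_yz": W_yz,
        "W_xz": W_xy @ W_yz,
        "failures": failures,
    }


def support_auc(scores: np.ndarray, reference_mask: np.ndarray) -> float:
    """ROC-AUC of |scores| against a reference nonzero pattern."""
    from sklearn.metrics import roc_auc_score

    y = np.asarray(reference_mask, dtype=bool).ravel()
    s = np.abs(np.asarray(scores, dtype=float)).ravel()
    if y.all() or not y.any():
        raise ValueError("reference pattern must contain both classes")
    return float(roc_auc_score(y, s))


def _param_blocks(model: ChainModel) -> dict:
    q, r = model.q, model.r
    iu_q = np.triu_indices(q, k=1)
    iu_r = np.triu_indices(r, k=1)
    return {
        "Lambda_y": model.layer_xy.Lambda[iu_q],
        "Theta_xy": model.layer_xy.Theta.ravel(),
        "Lambda_z": model.layer_yz.Lambda[iu_r],
        "Theta_yz": model.layer_yz.Theta.ravel(),
    }


def robustness_suite(
    data: DataBundle,
    lambdas: ChainLambdas,
    fractions=(0.5, 0.75, 1.0),
    noise_sds=(0.0, 0.25, 0.5),
    seed: int = 0,
    options: SolverOptions | None = None,
    reference: ChainModel | None = None,
) -> pd.DataFrame:
    """Stability of the estimated support under subsampling and added noise.

    For each (fraction, noise sd) cell the model is refit on data subsampled
    without replacement (stratified over expression-observed and unobserved
    rows) with independent N(0, sd^2) noise added to Y and Z, and each
    parameter block's |estimate| is scored by ROC-AUC against the reference
    fit's nonzero pattern.  The (1.0, 0.0) cell is the reference itself.
    """
    rng = np.random.default_rng(seed)
    if reference is None:
        reference = fit_chain(data, lambdas, options=options)
    ref_blocks = {k: v != 0.0 for k, v in _param_blocks(reference).items()}
    rows = []
    for frac in fractions:
        for sd in noise_sds:
            if frac == 1.0 and sd == 0.0:
                fit = reference
            else:
                idx = []
                for group in (np.where(data.observed)[0], np.where(~data.observed)[0]):
                    if len(group):
                        m = max(2, int(round(frac * len(group))))
                        idx.append(rng.choice(group, size=min(m, len(group)), replace=False))
                idx = np.sort(np.concatenate(idx))
                Y = data.Y[idx].copy()
                Z = data.Z[idx].copy()
                if sd > 0:
                    Y = Y + rng.normal(0.0, sd, size=Y.shape)
                    Z = Z + rng.normal(0.0, sd, size=Z.shape)
                sub = DataBundle(
                    X=data.X[idx],
                    Y=Y,
                    Z=Z,
                    observed=data.observed[idx],
                    snp_ids=data.snp_ids,
                    gene_ids=data.gene_ids,
                    trait_ids=data.trait_ids,
                )
                if sub.n < 4:
                    rows.append(
                        {"fraction": frac, "noise_sd": sd, "note": "subsample too small"}
                    )
                    continue
                try:
                    fit = fit_chain(sub, lambdas, options=options)
                except Exception as exc:
                    rows.append(
                        {"fraction": frac, "noise_sd": sd, "note": f"fit failed: {exc}"}
                    )
                    continue
            est_blocks = _param_blocks(fit)
            row = {"fraction": frac, "noise_sd": sd, "note": ""}
            aucs = []
            for name, ref_mask in ref_blocks.items():
                if ref_mask.all() or not ref_mask.any():
                    row[f"auc_{name}"] = np.nan
                    continue
                row[f"auc_{name}"] = support_auc(est_blocks[name], ref_mask)
                aucs.append(row[f"auc_{name}"])
            row["auc_mean"] = float(np.mean(aucs)) if aucs else np.nan
            rows.append(row)
    return pd.DataFrame(rows)
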