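"""Post-fit inference on the chain model.

Direct perturbations are the nonzero entries of Θ; *indirect* (overall)
effects arise from propagation through the networks:

* ``B_xy = -Θ_xy Λ_y^-1`` — overall SNP effects on expression,
* ``B_yz = -Θ_yz Λ_z^-1`` — overall expression effects on traits,
* ``B_xz = B_xy B_yz``   — SNP effects on traits mediated by the gene network,
  with ``z | x ~ N(B_xz' x, Λ_z^-1 + Λ_z^-1 Θ_yz' Λ_y^-1 Θ_yz Λ_z^-1)``.

``B_xz`` decomposes exactly over gene modules
(``B_xz^(M) = Σ_{j∈M} B_xy[:, j] B_yz[j, :]``), the posterior gene network
after conditioning on traits is ``Λ_y|x,z = Λ_y + Θ_yz Λ_z^-1 Θ_yz'``
(moralization: extra edges between genes influencing the same or connected
traits), and the model admits a joint sCGGM representation over (z, y).
Module/trait-group summaries use the score ``S(A[I,J]) = Σ |A_ij|``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .model import ChainModel, SCGGMLayer

__all__ = [
    "EffectSet",
    "ModuleAssignment",
    "JointRepresentation",
    "indirect_xy",
    "indirect_yz",
    "inf1_snp_trait_effects",
    "inf2_module_decomposition",
    "inf3_posterior_network",
    "moralized_edges",
    "build_joint",
    "compute_effects",
    "score_summary",
    "rank_snps",
    "connected_component_modules",
]

#: effects below this magnitude are truncated to exact zero in sparse outputs
EFFECT_NOISE_FLOOR = 1e-12


def _solve_pd(Lam: np.ndarray, B: np.ndarray, name: str) -> np.ndarray:
    try:
        L = sla.cholesky(Lam, lower=True)
    except sla.LinAlgError as exc:
        raise ValueError(f"{name} is not positive definite") from exc
    return sla.cho_solve((L, True), B)


def indirect_xy(layer_xy: SCGGMLayer) -> np.ndarray:
    """Overall SNP -> expression effects ``B_xy = -Θ_xy Λ_y^-1``.

    Computed by solves against Λ_y (never an explicit dense inverse).  A SNP
    with an all-zero Θ row has an all-zero B row: indirect effects only flow
    through a SNP's own direct targets.
    """
    return -_solve_pd(layer_xy.Lambda, layer_xy.Theta.T, "Lambda_y").T


def indirect_yz(layer_yz: SCGGMLayer) -> np.ndarray:
    """Overall expression -> trait effects ``B_yz = -Θ_yz Λ_z^-1``."""
    return -_solve_pd(layer_yz.Lambda, layer_yz.Theta.T, "Lambda_z").T


def inf1_snp_trait_effects(model: ChainModel) -> tuple[np.ndarray, np.ndarray]:
    """SNP effects on traits mediated by the gene network, plus cov(z | x).

    Returns ``(B_xz, Λ_z^-1 + Λ_z^-1 Θ_yz' Λ_y^-1 Θ_yz Λ_z^-1)``.
    """
    B_xy = indirect_xy(model.layer_xy)
    B_yz = indirect_yz(model.layer_yz)
    B_xz = B_xy @ B_yz
    r = model.r
    Sig_z = _solve_pd(model.layer_yz.Lambda, np.eye(r), "Lambda_z")
    W = _solve_pd(model.layer_xy.Lambda, model.layer_yz.Theta @ Sig_z, "Lambda_y")
    cov = Sig_z + (model.layer_yz.Theta @ Sig_z).T @ W
    return B_xz, 0.5 * (cov + cov.T)


@dataclass
class ModuleAssignment:
    """Disjoint gene modules covering all genes (singletons allowed)."""

    labels: dict  # gene index or id -> module label

    @classmethod
    def from_labels(cls, labels) -> "ModuleAssignment":
        return cls(labels=dict(labels))

    def groups(self, gene_ids) -> dict:
        """module label -> list of gene positions, validating full coverage."""
        idx = {g: i for i, g in enumerate(gene_ids)}
        out: dict = {}
        seen = set()
        for key, lab in self.labels.items():
            pos = idx[key] if key in idx else (key if isinstance(key, (int, np.integer)) else None)
            if pos is None or not (0 <= int(pos) < len(gene_ids)):
                raise ValueError(f"module assignment names unknown gene {key!r}")
            pos = int(pos)
            if pos in seen:
                raise ValueError(f"gene {key!r} assigned to more than one module")
            seen.add(pos)
            out.setdefault(lab, []).append(pos)
        if len(seen) != len(gene_ids):
            missing = sorted(set(range(len(gene_ids))) - seen)
            raise ValueError(f"module assignment does not cover genes {missing[:5]}...")
        return out


@dataclass
class EffectSet:
    B_xy: np.ndarray
    B_yz: np.ndarray
    B_xz: np.ndarray
    B_xz_by_module: dict = field(default_factory=dict)
    snp_ids: list | None = None
    gene_ids: list | None = None
    trait_ids: list | None = None


def compute_effects(
    model: ChainModel, modules: ModuleAssignment | None = None
) -> EffectSet:
    B_xy = indirect_xy(model.layer_xy)
    B_yz = indirect_yz(model.layer_yz)
    es = EffectSet(
        B_xy=B_xy,
        B_yz=B_yz,
        B_xz=B_xy @ B_yz,
        snp_ids=list(model.layer_xy.input_ids),
        gene_ids=list(model.layer_xy.output_ids),
        trait_ids=list(model.layer_yz.output_ids),
    )
    if modules is not None:
        es.B_xz_by_module = inf2_module_decomposition(es, modules)
    return es


def inf2_module_decomposition(
    effects: EffectSet, modules: ModuleAssignment
) -> dict:
    """Per-module components ``B_xz^(M) = Σ_{j∈M} B_xy[:, j] B_yz[j, :]``.

    The components sum exactly to B_xz (telescoping over the disjoint cover).
    """
    gene_ids = effects.gene_ids or list(range(effects.B_xy.shape[1]))
    groups = modules.groups(gene_ids)
    out = {}
    for lab, pos in groups.items():
        pos = np.asarray(pos, dtype=int)
        out[lab] = effects.B_xy[:, pos] @ effects.B_yz[pos, :]
    return out


def inf3_posterior_network(model: ChainModel) -> np.ndarray:
    """Posterior gene network ``Λ_y|x,z = Λ_y + Θ_yz Λ_z^-1 Θ_yz'``."""
    Th = model.layer_yz.Theta
    add = Th @ _solve_pd(model.layer_yz.Lambda, Th.T, "Lambda_z")
    P = model.layer_xy.Lambda + add
    return 0.5 * (P + P.T)


def moralized_edges(model: ChainModel, tol: float = EFFECT_NOISE_FLOOR) -> pd.DataFrame:
    """Edge list of the posterior network, flagging edges absent from Λ_y."""
    P = inf3_posterior_network(model)
    Lam = model.layer_xy.Lambda
    genes = list(model.layer_xy.output_ids)
    rows = []
    q = len(genes)
    for i in range(q):
        for j in range(i + 1, q):
            w = P[i, j]
            if abs(w) > tol:
                rows.append(
                    {
                        "gene_i": genes[i],
                        "gene_j": genes[j],
                        "weight": w,
                        "is_moralized": Lam[i, j] == 0.0,
                    }
                )
    return pd.DataFrame(rows, columns=["gene_i", "gene_j", "weight", "is_moralized"])


@dataclass
class JointRepresentation:
    """Joint sCGGM over (z, y) given x: ``p(z,y|x) = N(-Λ_zy^-1 Θ_zy,x' x, Λ_zy^-1)``."""

    Lambda_zy: np.ndarray   # (r+q) x (r+q), z block first
    Theta_zy_x: np.ndarray  # p x (r+q), leading p x r zero block
    Lambda_y_given_xz: np.ndarray


def build_joint(model: ChainModel) -> JointRepresentation:
    r, q, p = model.r, model.q, model.p
    Lam_z = model.layer_yz.Lambda
    Th_yz = model.layer_yz.Theta
    post = inf3_posterior_network(model)
    top = np.hstack([Lam_z, Th_yz.T])
    bot = np.hstack([Th_yz, post])
    Lam_zy = np.vstack([top, bot])
    try:
        sla.cholesky(Lam_zy, lower=True)
    except sla.LinAlgError as exc:
        raise ValueError("assembled joint precision is not positive definite") from exc
    Theta_zy_x = np.hstack([np.zeros((p, r)), model.layer_xy.Theta])
    return JointRepresentation(
        Lambda_zy=Lam_zy, Theta_zy_x=Theta_zy_x, Lambda_y_given_xz=post
    )


def score_summary(A: np.ndarray, rows=None, cols=None) -> float:
    """``S(A[I, J]) = Σ_{i∈I, j∈J} |A_ij|`` (empty group -> 0 with a warning)."""
    A = np.asarray(A)
    rows = np.arange(A.shape[0]) if rows is None else np.asarray(rows, dtype=int)
    cols = np.arange(A.shape[1]) if cols is None else np.asarray(cols, dtype=int)
    if rows.size == 0 or cols.size == 0:
        warnings.warn("empty row or column group in score_summary", stacklevel=2)
        return 0.0
    return float(np.abs(A[np.ix_(rows, cols)]).sum())


def rank_snps(effects: EffectSet, top_k: int | None = None) -> pd.DataFrame:
    """SNPs ordered by overall trait effect ``S(B_xz[i, :])`` (descending).

    Exact ties are broken by SNP identifier so the ranking is deterministic.
    """
    scores = np.abs(effects.B_xz).sum(axis=1)
    ids = effects.snp_ids or [str(i) for i in range(len(scores))]
    df = pd.DataFrame({"snp": ids, "score": scores})
    df = df.sort_values(["score", "snp"], ascending=[False, True], kind="mergesort")
    df = df.reset_index(drop=True)
    if top_k is not None:
        df = df.head(top_k)
    return df


def connected_component_modules(layer_xy: SCGGMLayer) -> ModuleAssignment:
    """Convenience labeler: connected components of the Λ_y support graph."""
    from scipy.sparse import csgraph, csr_matrix

    Lam = layer_xy.Lambda.copy()
    np.fill_diagonal(Lam, 0.0)
    n_comp, labels = csgraph.connected_components(
        csr_matrix(Lam != 0.0), directed=False
    )
    return ModuleAssignment(labels={i: int(lab) for i, lab in enumerate(labels)})
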