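"""Ground-truth simulators for the chain model and its evaluation.

The generator mimics the structure of a module-organized transcriptome under
genetic perturbation: scale-free gene and trait networks with a fixed average
degree and a fixed fraction of within-module edges, Gaussian edge weights
N(0.5, 0.1^2), precision diagonals shifted so the minimum eigenvalue is
exactly 0.3, and sparse module-targeted perturbation maps in which every
output is hit by exactly three perturbants whose signs are random with
probability 1/2.  Three ground-truth families are provided: the chain sCGGM
itself, a two-layer linear regression (mediators acting independently, noise
variance 0.5), and a two-layer GGM with no genetic perturbation.  Genotypes
are simulated as independent binomial minor-allele counts (no linkage
disequilibrium).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import scipy.linalg as sla

from .model import ChainModel, DataBundle, SCGGMLayer

__all__ = [
    "SimConfig",
    "GroundTruth",
    "make_scalefree_precision",
    "make_perturbation",
    "genotype_simulator",
    "make_ground_truth",
    "sample_dataset",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation constants; the defaults are the reference study conditions.

    ``p``/``q``/``r`` are SNP/gene/trait counts.  ``module_size`` applies to
    both networks; final smaller modules absorb any remainder.  Half of the
    gene modules are SNP-perturbed; a fifth have no influence on traits; the
    remaining trait-influencing modules are split into halves that wire 90% of
    their trait edges to their primary trait module and 10% to the rest.
    """

    p: int = 10_000
    q: int = 5_000
    r: int = 100
    module_size: int = 50
    avg_degree: float = 3.0
    within_module_edge_frac: float = 0.9
    edge_weight_mean: float = 0.5
    edge_weight_sd: float = 0.1
    min_eigenvalue: float = 0.3
    perturbants_per_target: int = 3
    sign_flip_prob: float = 0.5
    n_snps_perturbing: int = 1_000
    frac_gene_modules_unperturbed: float = 0.5
    frac_gene_modules_no_trait_influence: float = 0.2
    trait_wiring_primary_frac: float = 0.9
    noise_variance: float = 0.5
    network_sign_flips: bool = False
    maf_range: tuple = (0.1, 0.5)
    family: Literal["chain", "regression", "ggm"] = "chain"
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "within_module_edge_frac",
            "sign_flip_prob",
            "frac_gene_modules_unperturbed",
            "frac_gene_modules_no_trait_influence",
            "trait_wiring_primary_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.edge_weight_sd <= 0:
            raise ValueError("edge_weight_sd must be positive")
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")

    def scaled(self, **kw) -> "SimConfig":
        """A copy with some dimensions/constants replaced."""
        return replace(self, **kw)


def module_labels(dim: int, module_size: int) -> np.ndarray:
    """Consecutive blocks of ``module_size``; the last block may be smaller."""
    return np.arange(dim) // max(1, module_size)


def _pref_attach_edges(
    nodes: np.ndarray, n_edges: int, degree: np.ndarray, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Preferential-attachment edges among ``nodes`` (global degree array).

    Grows a connected scaffold over the nodes first (each new node attaches to
    a degree-weighted earlier node), then adds the remaining quota by
    degree-weighted endpoint sampling, avoiding duplicates and self-loops.
    """
    m = len(nodes)
    max_edges = m * (m - 1) // 2
    n_edges = min(n_edges, max_edges)
    edges: set[tuple[int, int]] = set()
    if m < 2 or n_edges == 0:
        return []

    def weight(sub):
        return degree[sub] + 1.0

    scaffold = min(n_edges, m - 1)
    order = rng.permutation(nodes)
    for k in range(1, scaffold + 1):
        prev = order[:k]
        w = weight(prev)
        tgt = int(rng.choice(prev, p=w / w.sum()))
        a, b = (int(order[k]), tgt) if order[k] < tgt else (tgt, int(order[k]))
        if a != b and (a, b) not in edges:
            edges.add((a, b))
            degree[a] += 1
            degree[b] += 1
    attempts = 0
    while len(edges) < n_edges and attempts < 200 * n_edges:
        attempts += 1
        w = weight(nodes)
        u, v = rng.choice(nodes, size=2, replace=False, p=w / w.sum())
        a, b = (int(u), int(v)) if u < v else (int(v), int(u))
        if (a, b) in edges:
            continue
        edges.add((a, b))
        degree[a] += 1
        degree[b] += 1
    return sorted(edges)


def make_scalefree_precision(
    dim: int, config: SimConfig, rng: np.random.Generator, module_size: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Sparse PD precision with scale-free modular topology.

    Returns ``(precision, module_labels)``.  The edge count is fixed at
    ``round(dim * avg_degree / 2)`` with the stated within-module fraction;
    edge weights are N(mean, sd^2); the diagonal is ``c I`` with c chosen so
    the minimum eigenvalue equals ``min_eigenvalue`` exactly.
    """
    if dim < 2:
        raise ValueError("network dimension must be at least 2")
    ms = module_size if module_size is not None else config.module_size
    labels = module_labels(dim, ms)
    mods = np.unique(labels)
    e_total = int(round(dim * config.avg_degree / 2.0))
    if e_total > dim * (dim - 1) // 2:
        raise ValueError("average degree infeasible for this dimension")
    if len(mods) > 1:
        e_within = int(round(config.within_module_edge_frac * e_total))
        e_between = e_total - e_within
    else:
        e_within, e_between = e_total, 0

    degree = np.zeros(dim)
    edges: list[tuple[int, int]] = []
    # within-module quotas proportional to module size
    sizes = np.array([(labels == m).sum() for m in mods], dtype=float)
    quota = np.floor(e_within * sizes / sizes.sum()).astype(int)
    for k in np.argsort(-(e_within * sizes / sizes.sum() - quota))[: e_within - quota.sum()]:
        quota[k] += 1
    for m, nq in zip(mods, quota):
        edges.extend(_pref_attach_edges(np.where(labels == m)[0], int(nq), degree, rng))
    # between-module edges: degree-weighted endpoints in different modules
    attempts = 0
    eset = set(edges)
    all_nodes = np.arange(dim)
    while e_between > 0 and attempts < 500 * e_between:
        attempts += 1
        w = degree + 1.0
        u, v = rng.choice(all_nodes, size=2, replace=False, p=w / w.sum())
        if labels[u] == labels[v]:
            continue
        a, b = (int(u), int(v)) if u < v else (int(v), int(u))
        if (a, b) in eset:
            continue
        eset.add((a, b))
        degree[a] += 1
        degree[b] += 1
        e_between -= 1
    edges = sorted(eset)

    A = np.zeros((dim, dim))
    if edges:
        ii, jj = np.array(edges).T
        w = rng.normal(config.edge_weight_mean, config.edge_weight_sd, size=len(edges))
        if config.network_sign_flips:
            w *= np.where(rng.random(len(edges)) < config.sign_flip_prob, 1.0, -1.0)
        A[ii, jj] = w
        A[jj, ii] = w
    lam_min = float(np.linalg.eigvalsh(A)[0]) if dim <= 2500 else _lam_min_sparse(A)
    np.fill_diagonal(A, config.min_eigenvalue - lam_min)
    return A, labels


def _lam_min_sparse(A: np.ndarray) -> float:
    import scipy.sparse as sp
    import scipy.sparse.linalg as spla

    val = spla.eigsh(
        sp.csr_matrix(A), k=1, which="SA", tol=1e-10, maxiter=20000
    )[0][0]
    return float(val)


def make_perturbation(
    n_in: int,
    n_out: int,
    out_module_labels: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    eligible_inputs_by_out_module: dict | None = None,
    unperturbed_out_modules: set | None = None,
) -> np.ndarray:
    """Sparse perturbation map: each perturbed output column has exactly
    ``perturbants_per_target`` nonzeros with N(0.5, 0.1^2) magnitudes and
    random signs.

    ``eligible_inputs_by_out_module`` maps an output-module label to a list of
    per-slot candidate input pools (one pool is drawn per nonzero slot, which
    implements the 90/10 module-wiring split); by default all inputs are
    eligible.  Outputs in ``unperturbed_out_modules`` get all-zero columns.
    """
    k = config.perturbants_per_target
    if n_in < k:
        raise ValueError(f"need at least {k} candidate inputs, got {n_in}")
    Theta = np.zeros((n_in, n_out))
    unpert = unperturbed_out_modules or set()
    for j in range(n_out):
        mod = int(out_module_labels[j])
        if mod in unpert:
            continue
        chosen: list[int] = []
        guard = 0
        while len(chosen) < k:
            guard += 1
            if guard > 100 * k:
                raise ValueError("could not draw distinct perturbants; pools too small")
            if eligible_inputs_by_out_module is None:
                cand = int(rng.integers(n_in))
            else:
                pools, probs = eligible_inputs_by_out_module[mod]
                pool = pools[int(rng.choice(len(pools), p=probs))]
                cand = int(pool[rng.integers(len(pool))])
            if cand not in chosen:
                chosen.append(cand)
        mags = rng.normal(config.edge_weight_mean, config.edge_weight_sd, size=k)
        signs = np.where(rng.random(k) < config.sign_flip_prob, 1.0, -1.0)
        Theta[np.array(chosen), j] = mags * signs
    return Theta


def genotype_simulator(
    p: int, n: int, maf_range=(0.1, 0.5), rng: np.random.Generator | None = None, seed=None
) -> tuple[np.ndarray, np.ndarray]:
    """Independent-SNP genotypes: entries Binomial(2, maf_j).  Returns (X, mafs)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie in (0, 0.5]")
    mafs = rng.uniform(lo, hi, size=p)
    X = rng.binomial(2, mafs, size=(n, p)).astype(float)
    return X, mafs


@dataclass
class GroundTruth:
    """A simulator's true model plus recovery-target masks."""

    family: str
    model: ChainModel | None
    W_xy: np.ndarray | None  # regression family coefficients
    W_yz: np.ndarray | None
    noise_variance: float
    gene_modules: np.ndarray
    trait_modules: np.ndarray
    perturbing_snps: np.ndarray
    mask_network_y: np.ndarray = field(default=None)  # type: ignore[assignment]
    mask_network_z: np.ndarray = field(default=None)  # type: ignore[assignment]
    mask_direct_xy: np.ndarray = field(default=None)  # type: ignore[assignment]
    mask_direct_yz: np.ndarray = field(default=None)  # type: ignore[assignment]
    mask_snp_trait: np.ndarray = field(default=None)  # type: ignore[assignment]
    config: SimConfig | None = None

    def effects(self):
        from .inference import compute_effects

        if self.family == "regression":
            B_xz = self.W_xy @ self.W_yz
            from .inference import EffectSet

            return EffectSet(B_xy=self.W_xy, B_yz=self.W_yz, B_xz=B_xz)
        return compute_effects(self.model)


def _wire_trait_modules(cfg: SimConfig, gene_labels, trait_labels, rng):
    """Per trait-module candidate gene pools implementing the 90/10 split."""
    gene_mods = np.unique(gene_labels)
    n_silent = int(round(cfg.frac_gene_modules_no_trait_influence * len(gene_mods)))
    silent = set(rng.choice(gene_mods, size=n_silent, replace=False).tolist())
    active = [m for m in gene_mods if m not in silent]
    trait_mods = np.unique(trait_labels)
    # split active gene modules as evenly as possible across trait modules
    assign = {tm: [] for tm in trait_mods}
    for k, gm in enumerate(rng.permutation(active)):
        assign[trait_mods[k % len(trait_mods)]].append(int(gm))
    pools = {}
    for tm in trait_mods:
        primary = [g for g in assign[tm]]
        other = [g for g in active if g not in primary]
        primary_genes = np.where(np.isin(gene_labels, primary))[0]
        other_genes = np.where(np.isin(gene_labels, other))[0]
        if len(other_genes) == 0 or len(trait_mods) == 1:
            pools[int(tm)] = ([primary_genes], np.array([1.0]))
        elif len(primary_genes) == 0:
            pools[int(tm)] = ([other_genes], np.array([1.0]))
        else:
            pools[int(tm)] = (
                [primary_genes, other_genes],
                np.array(
                    [cfg.trait_wiring_primary_frac, 1.0 - cfg.trait_wiring_primary_frac]
                ),
            )
    return pools, silent


def make_ground_truth(config: SimConfig, seed: int | None = None) -> GroundTruth:
    """Build a full ground-truth model of the configured family."""
    cfg = config
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    Lam_y, gene_labels = make_scalefree_precision(cfg.q, cfg, rng)
    Lam_z, trait_labels = make_scalefree_precision(cfg.r, cfg, rng)

    gene_mods = np.unique(gene_labels)
    n_unpert = int(round(cfg.frac_gene_modules_unperturbed * len(gene_mods)))
    unperturbed = set(rng.choice(gene_mods, size=n_unpert, replace=False).tolist())
    n_pert_snps = min(cfg.n_snps_perturbing, cfg.p)
    perturbing = np.sort(rng.choice(cfg.p, size=n_pert_snps, replace=False))
    snp_pools = {
        int(m): ([perturbing], np.array([1.0])) for m in gene_mods
    }
    Theta_xy = make_perturbation(
        cfg.p,
        cfg.q,
        gene_labels,
        cfg,
        rng,
        eligible_inputs_by_out_module=snp_pools,
        unperturbed_out_modules=unperturbed,
    )
    trait_pools, _ = _wire_trait_modules(cfg, gene_labels, trait_labels, rng)
    Theta_yz = make_perturbation(
        cfg.q, cfg.r, trait_labels, cfg, rng, eligible_inputs_by_out_module=trait_pools
    )

    if cfg.family == "ggm":
        Theta_xy = np.zeros_like(Theta_xy)

    if cfg.family == "regression":
        W_xy, W_yz = Theta_xy, Theta_yz
        model = None
        mask_snp_trait = np.abs(W_xy @ W_yz) > 1e-12
        gt = GroundTruth(
            family=cfg.family,
            model=None,
            W_xy=W_xy,
            W_yz=W_yz,
            noise_variance=cfg.noise_variance,
            gene_modules=gene_labels,
            trait_modules=trait_labels,
            perturbing_snps=perturbing,
            mask_network_y=np.zeros((cfg.q, cfg.q), bool),
            mask_network_z=np.zeros((cfg.r, cfg.r), bool),
            mask_direct_xy=W_xy != 0,
            mask_direct_yz=W_yz != 0,
            mask_snp_trait=mask_snp_trait,
            config=cfg,
        )
        return gt

    layer_xy = SCGGMLayer(Lambda=Lam_y, Theta=Theta_xy)
    layer_yz = SCGGMLayer(
        Lambda=Lam_z, Theta=Theta_yz, input_ids=layer_xy.output_ids
    )
    model = ChainModel(layer_xy=layer_xy, layer_yz=layer_yz)
    off_y = Lam_y.copy()
    np.fill_diagonal(off_y, 0.0)
    off_z = Lam_z.copy()
    np.fill_diagonal(off_z, 0.0)
    from .inference import compute_effects

    B_xz = compute_effects(model).B_xz
    return GroundTruth(
        family=cfg.family,
        model=model,
        W_xy=None,
        W_yz=None,
        noise_variance=cfg.noise_variance,
        gene_modules=gene_labels,
        trait_modules=trait_labels,
        perturbing_snps=perturbing,
        mask_network_y=off_y != 0,
        mask_network_z=off_z != 0,
        mask_direct_xy=Theta_xy != 0,
        mask_direct_yz=Theta_yz != 0,
        mask_snp_trait=np.abs(B_xz) > 1e-12,
        config=cfg,
    )


def _sample_gaussian_rows(mean: np.ndarray, Lam: np.ndarray, rng) -> np.ndarray:
    """Rows ~ N(mean_row, Λ^-1) via a triangular solve on the Cholesky factor."""
    L = sla.cholesky(Lam, lower=True)
    W = rng.standard_normal(mean.shape)
    return mean + sla.solve_triangular(L.T, W.T, lower=False).T


def sample_dataset(
    truth: GroundTruth,
    n: int,
    seed: int | None = None,
    X: np.ndarray | None = None,
) -> DataBundle:
    """Ancestral sampling: x, then y | x, then z | y (seeded, reproducible)."""
    cfg = truth.config or SimConfig()
    rng = np.random.default_rng(seed)
    if X is None:
        X, _ = genotype_simulator(
            truth.mask_direct_xy.shape[0], n, cfg.maf_range, rng=rng
        )
    else:
        X = np.asarray(X, dtype=float)
        if X.shape[0] != n:
            raise ValueError("X row count must equal n")
    if truth.family == "regression":
        Y = X @ truth.W_xy + rng.standard_normal((n, truth.W_xy.shape[1])) * np.sqrt(
            truth.noise_variance
        )
        Z = Y @ truth.W_yz + rng.standard_normal((n, truth.W_yz.shape[1])) * np.sqrt(
            truth.noise_variance
        )
    else:
        from .inference import indirect_xy, indirect_yz

        B_xy = indirect_xy(truth.model.layer_xy)
        B_yz = indirect_yz(truth.model.layer_yz)
        Y = _sample_gaussian_rows(X @ B_xy, truth.model.layer_xy.Lambda, rng)
        Z = _sample_gaussian_rows(Y @ B_yz, truth.model.layer_yz.Lambda, rng)
    p, q, r = X.shape[1], Y.shape[1], Z.shape[1]
    return DataBundle(
        X=X,
        Y=Y,
        Z=Z,
        snp_ids=[f"snp{i}" for i in range(p)],
        gene_ids=[f"gene{i}" for i in range(q)],
        trait_ids=[f"trait{i}" for i in range(r)],
    )
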