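"""File interchange: TSV matrices, PLINK .raw genotypes, model bundles.

Dense data travel as TSV (header row of feature ids, first column sample
ids); sparse model parameters as 1-based Matrix Market coordinate files (Λ
with symmetric storage); metadata as JSON.  Every CLI run writes a manifest
(config, seed, package version, input checksums) next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .model import ChainModel, SCGGMLayer

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_plink_raw",
    "write_model_bundle",
    "read_model_bundle",
    "read_modules_tsv",
    "RunConfig",
    "write_manifest",
]

BUNDLE_VERSION = "1"


def read_matrix_tsv(path, orientation: str = "samples_by_features"):
    """Read a TSV matrix; returns (values, row_ids, col_ids).

    The file must be rectangular with a header of feature ids and sample ids
    in the first column.  ``orientation="features_by_samples"`` transposes.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set = set()
    for h in header:
        if h in seen:
            raise ValueError(f"duplicate column id {h!r} in {path}")
        seen.add(h)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate row id {dup!r} in {path}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        bad = df.apply(pd.to_numeric, errors="coerce")
        r, c = np.argwhere(bad.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r} "
            f"in {path}"
        ) from exc
    if orientation == "features_by_samples":
        values = values.T
        return values, list(df.columns), list(df.index)
    return values, list(df.index), list(df.columns)


def write_matrix_tsv(path, values, row_ids, col_ids) -> None:
    pd.DataFrame(values, index=row_ids, columns=col_ids).to_csv(
        path, sep="\t", index_label="id"
    )


def read_plink_raw(path):
    """PLINK .raw additive dosages; returns (X, sample_ids, snp_ids).

    NA entries are imputed to the column mean (count logged via warning).
    """
    df = pd.read_csv(path, sep=r"\s+")
    expected = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    if list(df.columns[:6]) != expected:
        raise ValueError(
            f"malformed .raw header: expected leading columns {expected}, "
            f"got {list(df.columns[:6])}"
        )
    snp_cols = list(df.columns[6:])
    X = df[snp_cols].to_numpy(dtype=float)
    n_missing = int(np.isnan(X).sum())
    if n_missing:
        col_means = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = np.take(col_means, idx[1])
        warnings.warn(
            f"imputed {n_missing} missing genotype entries to column means",
            stacklevel=2,
        )
    sample_ids = [f"{f}_{i}" for f, i in zip(df["FID"], df["IID"])]
    return X, sample_ids, snp_cols


def _write_mtx(path: Path, mat: np.ndarray, symmetric: bool) -> None:
    s = sp.coo_matrix(mat)
    sio.mmwrite(str(path), s, symmetry="symmetric" if symmetric else "general")


def write_model_bundle(path, model: ChainModel) -> None:
    """Directory bundle: four .mtx parameter files + model.json metadata."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    _write_mtx(out / "Lambda_y.mtx", model.layer_xy.Lambda, symmetric=True)
    _write_mtx(out / "Theta_xy.mtx", model.layer_xy.Theta, symmetric=False)
    _write_mtx(out / "Lambda_z.mtx", model.layer_yz.Lambda, symmetric=True)
    _write_mtx(out / "Theta_yz.mtx", model.layer_yz.Theta, symmetric=False)
    meta = {
        "version": BUNDLE_VERSION,
        "snp_ids": list(model.layer_xy.input_ids),
        "gene_ids": list(model.layer_xy.output_ids),
        "trait_ids": list(model.layer_yz.output_ids),
        "hyperparameters": {
            "lambda_Lambda_y": model.layer_xy.lambda_Lambda,
            "lambda_Theta_xy": model.layer_xy.lambda_Theta,
            "lambda_Lambda_z": model.layer_yz.lambda_Lambda,
            "lambda_Theta_yz": model.layer_yz.lambda_Theta,
        },
        "fit_info": _jsonable(model.fit_info),
    }
    (out / "model.json").write_text(json.dumps(meta, indent=1))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


def read_model_bundle(path) -> ChainModel:
    src = Path(path)
    meta_path = src / "model.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing model.json in {src}")
    meta = json.loads(meta_path.read_text())
    if meta.get("version") != BUNDLE_VERSION:
        warnings.warn(
            f"model bundle version {meta.get('version')!r} != {BUNDLE_VERSION!r}; "
            "attempting best-effort load",
            stacklevel=2,
        )
    mats = {}
    for name in ("Lambda_y", "Theta_xy", "Lambda_z", "Theta_yz"):
        f = src / f"{name}.mtx"
        if not f.exists():
            raise FileNotFoundError(f"missing {f.name} in {src}")
        m = sio.mmread(str(f))
        mats[name] = np.asarray(m.todense() if sp.issparse(m) else m, dtype=float)
    hp = meta["hyperparameters"]
    q = len(meta["gene_ids"])
    r = len(meta["trait_ids"])
    p = len(meta["snp_ids"])
    for name, shape in (
        ("Lambda_y", (q, q)),
        ("Theta_xy", (p, q)),
        ("Lambda_z", (r, r)),
        ("Theta_yz", (q, r)),
    ):
        if mats[name].shape != shape:
            raise ValueError(
                f"{name} has shape {mats[name].shape}, JSON metadata implies {shape}"
            )
    layer_xy = SCGGMLayer(
        Lambda=mats["Lambda_y"],
        Theta=mats["Theta_xy"],
        lambda_Lambda=hp["lambda_Lambda_y"],
        lambda_Theta=hp["lambda_Theta_xy"],
        input_ids=meta["snp_ids"],
        output_ids=meta["gene_ids"],
    )
    layer_yz = SCGGMLayer(
        Lambda=mats["Lambda_z"],
        Theta=mats["Theta_yz"],
        lambda_Lambda=hp["lambda_Lambda_z"],
        lambda_Theta=hp["lambda_Theta_yz"],
        input_ids=meta["gene_ids"],
        output_ids=meta["trait_ids"],
    )
    model = ChainModel(layer_xy=layer_xy, layer_yz=layer_yz)
    model.fit_info = meta.get("fit_info", {})
    return model


def read_modules_tsv(path) -> dict:
    """gene_id<TAB>module table -> {gene_id: module_label}."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "module"])
    return dict(zip(df["gene"].astype(str), df["module"]))


@dataclass
class RunConfig:
    """Provenance record serialized into every CLI output directory."""

    command: str
    inputs: dict = field(default_factory=dict)
    output_dir: str = "."
    hyperparameters: dict = field(default_factory=dict)
    seed: int | None = None
    memory_budget: int | None = None
    verbosity: int = 1

    def to_dict(self) -> dict:
        return asdict(self)


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: RunConfig) -> Path:
    from importlib.metadata import PackageNotFoundError, version

    try:
        ver = version("perturbnet")
    except PackageNotFoundError:  # pragma: no cover
        ver = "unknown"
    manifest = {
        "package_version": ver,
        "config": _jsonable(config.to_dict()),
        "input_checksums": {
            str(p): _checksum(p)
            for p in config.inputs.values()
            if p and Path(str(p)).is_file()
        },
    }
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dest = out / "manifest.json"
    dest.write_text(json.dumps(manifest, indent=1))
    return dest
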