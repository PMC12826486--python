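"""Hierarchical profile aggregation, sphering batch correction, similarity.

Image-level embeddings are averaged up the experimental hierarchy (cell or
site -> field of view -> well -> treatment).  Batch correction uses a
sphering (ZCA whitening) transform fit on negative-control wells and is
applied to well-level profiles *before* treatment-level aggregation, the
placement evaluated by the batch-correction ablation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .errors import ConfigurationError

#: metadata keys defining each aggregation level
LEVEL_KEYS = {
    "cell": ["plate", "well", "site", "cell_id"],
    "fov": ["plate", "well", "site"],
    "well": ["plate", "well"],
    "treatment": ["treatment"],
}

#: metadata columns carried through aggregation when constant within a group
CARRY_COLUMNS = ["batch", "treatment", "moa_group", "is_control", "cell_line", "labels"]


@dataclass
class ProfileTable:
    """Profiles (one vector per row) keyed by hierarchy metadata."""

    features: np.ndarray
    meta: pd.DataFrame
    level: str = "fov"

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        if len(self.features) != len(self.meta):
            raise ConfigurationError("features and metadata row counts differ")


def aggregate(table: ProfileTable, level: str) -> ProfileTable:
    """Arithmetic mean of member vectors per group at ``level``."""
    if level not in LEVEL_KEYS:
        raise ConfigurationError(f"unknown level {level!r}")
    keys = [k for k in LEVEL_KEYS[level] if k in table.meta.columns]
    if not keys:
        raise ConfigurationError(f"no key columns for level {level!r} in metadata")
    df = table.meta.reset_index(drop=True)
    groups = df.groupby(keys, sort=True, dropna=False).indices
    feats, rows = [], []
    for key, idx in sorted(groups.items(), key=lambda kv: str(kv[0])):
        feats.append(table.features[idx].mean(axis=0))
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row["n_members"] = len(idx)
        sub = df.iloc[idx]
        for col in CARRY_COLUMNS:
            if col in sub.columns and col not in row and sub[col].nunique() == 1:
                row[col] = sub[col].iloc[0]
        rows.append(row)
    return ProfileTable(np.asarray(feats), pd.DataFrame(rows), level)


@dataclass
class SpheringTransform:
    """ZCA whitening map fit on a control population: x' = W (x - mu)."""

    mean: np.ndarray
    whitening: np.ndarray
    reg: float
    fit_population: str = "controls"


def fit_sphering(controls: np.ndarray, reg: float | None = None,
                 fit_population: str = "controls") -> SpheringTransform:
    """Fit ZCA whitening on control profiles.

    ``reg`` is added to every eigenvalue of the control covariance before
    the inverse square root (default: 1e-6 times the mean eigenvalue, which
    handles rank deficiency gracefully).
    """
    controls = np.asarray(controls, dtype=np.float64)
    if controls.ndim != 2 or controls.shape[0] < 2:
        raise ConfigurationError("sphering needs >= 2 control rows")
    mu = controls.mean(axis=0)
    cov = np.cov(controls - mu, rowvar=False, bias=False)
    cov = np.atleast_2d(cov)
    evals, evecs = np.linalg.eigh(cov)
    if reg is None:
        reg = 1e-6 * float(evals.mean())
    w = evecs @ np.diag(1.0 / np.sqrt(np.maximum(evals, 0.0) + reg)) @ evecs.T
    return SpheringTransform(mu, w, reg, fit_population)


def apply_sphering(t: SpheringTransform, profiles: np.ndarray) -> np.ndarray:
    return (np.asarray(profiles) - t.mean) @ t.whitening.T


def cosine_similarity_matrix(profiles: np.ndarray) -> np.ndarray:
    """S_ij = <x_i, x_j> / (|x_i| |x_j|); unit diagonal, zero rows flagged."""
    x = np.asarray(profiles, dtype=np.float64)
    norms = np.linalg.norm(x, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-norm profile rows; similarities set to 0")
    safe = np.where(zero, 1.0, norms)
    s = (x / safe[:, None]) @ (x / safe[:, None]).T
    s[zero, :] = 0.0
    s[:, zero] = 0.0
    np.fill_diagonal(s, 1.0)
    return np.clip(s, -1.0, 1.0)


def cluster_order(s: np.ndarray) -> np.ndarray:
    """Dendrogram leaf order of average-linkage clustering on distance 1 - S."""
    s = np.asarray(s)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ConfigurationError("similarity matrix must be square")
    n = s.shape[0]
    if n == 1:
        return np.array([0])
    d = 1.0 - (s + s.T) / 2.0
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(np.maximum(d, 0.0), checks=False), method="average")
    return leaves_list(z)


def mean_within_batch_control_similarity(table: ProfileTable) -> float:
    """Mean cosine similarity between control wells of the same batch."""
    mask = table.meta["is_control"].astype(bool).to_numpy()
    feats = table.features[mask]
    batches = table.meta.loc[mask, "batch"].to_numpy()
    s = cosine_similarity_matrix(feats)
    vals = []
    for b in np.unique(batches):
        idx = np.nonzero(batches == b)[0]
        for i in range(len(idx)):
            for j in range(i + 1, len(idx)):
                vals.append(s[idx[i], idx[j]])
    return float(np.mean(vals))


def export_for_harmonization(table: ProfileTable, path) -> None:
    """Write a harmonization-ready CSV: one row per profile with the batch
    column first, then the hierarchy metadata, then the feature columns.

    External embedding-integration tools (Harmony and relatives) consume
    exactly this layout; the integration itself is out of scope here.
    """
    if "batch" not in table.meta.columns:
        raise ConfigurationError("harmonization export needs a 'batch' column")
    feats = pd.DataFrame(table.features,
                         columns=[f"f{i}" for i in range(table.features.shape[1])])
    cols = ["batch"] + [c for c in table.meta.columns if c != "batch"]
    out = pd.concat([table.meta[cols].reset_index(drop=True), feats], axis=1)
    out.to_csv(path, index=False)


def batch_correction_ablation(well_table: ProfileTable, evaluator,
                              reg: float | None = None) -> dict:
    """Run the treatment-profiling pipeline with and without sphering.

    ``evaluator`` maps a treatment-level :class:`ProfileTable` to a scalar
    score (e.g. mechanism-retrieval performance).  Sphering is fit on the
    control wells of the input table and applied to well-level profiles
    before treatment aggregation; the only difference between the two
    branches is that application.
    """
    controls = well_table.features[well_table.meta["is_control"].astype(bool).to_numpy()]
    transform = fit_sphering(controls, reg)

    def run(correct: bool) -> float:
        feats = apply_sphering(transform, well_table.features) if correct \
            else well_table.features
        wt = ProfileTable(feats, well_table.meta, "well")
        treated = wt.meta.index[~wt.meta["is_control"].astype(bool)].to_numpy()
        tt = aggregate(ProfileTable(wt.features[treated],
                                    wt.meta.iloc[treated], "well"), "treatment")
        return float(evaluator(tt))

    with_bc = run(True)
    without_bc = run(False)
    percent_change = 100.0 * (without_bc - with_bc) / with_bc if with_bc else float("nan")
    return {"with_bc": with_bc, "without_bc": without_bc,
            "percent_change": percent_change, "sphering": transform}
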