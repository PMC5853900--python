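"""Correlation-matrix PCA of occurrence-level environmental variables.

Columns are standardized to zero mean and unit (sample) variance before the
decomposition, so the PCA operates on the correlation matrix and variables
with different units contribute equally.  Rows with any missing value among
the selected variables are excluded listwise at fit time; projection returns
missing scores for such rows.  Eigenvector signs are fixed so that each
loading vector's largest-magnitude entry is positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA


@dataclass
class PcaModel:
    variables: list[str]
    means: np.ndarray          # per-variable centering mean
    scales: np.ndarray         # per-variable sample standard deviation (ddof=1)
    loadings: np.ndarray       # (n_variables, n_axes), orthonormal columns
    eigenvalues: np.ndarray    # correlation-matrix eigenvalues, descending
    explained_pct: np.ndarray  # per-axis variance share, sums to 100

    @property
    def n_axes(self) -> int:
        return self.loadings.shape[1]

    def to_json(self) -> str:
        return json.dumps(
            {
                "variables": self.variables,
                "means": self.means.tolist(),
                "scales": self.scales.tolist(),
                "loadings": self.loadings.tolist(),
                "eigenvalues": self.eigenvalues.tolist(),
                "explained_pct": self.explained_pct.tolist(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PcaModel":
        d = json.loads(text)
        return cls(
            variables=d["variables"],
            means=np.asarray(d["means"]),
            scales=np.asarray(d["scales"]),
            loadings=np.asarray(d["loadings"]),
            eigenvalues=np.asarray(d["eigenvalues"]),
            explained_pct=np.asarray(d["explained_pct"]),
        )


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    out = loadings.copy()
    for j in range(out.shape[1]):
        if out[np.argmax(np.abs(out[:, j])), j] < 0:
            out[:, j] = -out[:, j]
    return out


def fit_pca(matrix: pd.DataFrame, variables: list[str]) -> PcaModel:
    """Fit a correlation-matrix PCA on the selected columns (listwise deletion)."""
    if len(variables) < 2:
        raise ValueError("PCA needs at least two variables")
    data = matrix[list(variables)].dropna().to_numpy(dtype=float)
    if data.shape[0] < 2:
        raise ValueError("PCA needs at least two complete rows")
    means = data.mean(axis=0)
    scales = data.std(axis=0, ddof=1)
    for var, s in zip(variables, scales):
        if s == 0 or not np.isfinite(s):
            raise ValueError(f"variable {var!r} has zero variance; cannot standardize")
    z = (data - means) / scales
    pca = _SkPCA(n_components=min(z.shape), svd_solver="full")
    pca.fit(z)
    loadings = _fix_signs(pca.components_.T)
    return PcaModel(
        variables=list(variables),
        means=means,
        scales=scales,
        loadings=loadings,
        eigenvalues=pca.explained_variance_.copy(),
        explained_pct=100.0 * pca.explained_variance_ratio_,
    )


def project(model: PcaModel, rows: pd.DataFrame) -> np.ndarray:
    """(n_rows, n_axes) score matrix; rows with missing values give NaN scores."""
    missing = [v for v in model.variables if v not in rows.columns]
    if missing:
        raise ValueError(f"rows lack PCA variables: {missing}")
    data = rows[model.variables].to_numpy(dtype=float)
    z = (data - model.means) / model.scales
    scores = z @ model.loadings
    scores[np.isnan(z).any(axis=1)] = np.nan
    return scores


def pc_scores_as_variables(
    model: PcaModel, matrix: pd.DataFrame, prefix: str, axes: int = 2
) -> pd.DataFrame:
    """Append per-occurrence PC score columns (`{prefix}_PC1`, ...).

    Downstream aggregation (species median, group mean of medians) then
    treats the scores like any other environmental variable.
    """
    axes = min(axes, model.n_axes)
    scores = project(model, matrix)
    out = matrix.copy()
    for j in range(axes):
        out[f"{prefix}_PC{j + 1}"] = scores[:, j]
    return out
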