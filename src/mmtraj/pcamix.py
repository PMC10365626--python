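"""Factor analysis of mixed data (PCAmix) and eigenvalue retention.

PCAmix generalizes principal component analysis to tables that mix
quantitative and categorical variables: quantitative columns are centered
and scaled to unit (population) variance as in correlation-matrix PCA,
categorical variables are expanded to centered indicator columns weighted
by the inverse square root of the category proportion as in multiple
correspondence analysis, and the combined matrix is factorized by a
singular value decomposition with uniform row weights 1/n.  With only
quantitative columns the eigenvalues equal those of the correlation
matrix; with only categorical columns they equal the indicator-matrix
correspondence-analysis eigenvalues times the number of variables.

Dimension retention uses the Karlis-Saporta-Spinaki rule: keep dimensions
whose eigenvalue exceeds ``mean(eigenvalues) * (1 + 2 * sqrt((p - 1) / (n - 1)))``.
The published rule targets correlation-matrix PCA where the mean
eigenvalue is 1; scaling the threshold by the mean eigenvalue preserves
its "significantly above average" semantics for mixed tables and reduces
to the published formula in the pure-PCA case.  At least two dimensions
are always retained so that downstream clustering has a usable space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from mmtraj.status import FeatureMatrix


@dataclass
class PCAmixModel:
    """Fitted factorization with everything needed to project new rows."""

    eigenvalues: np.ndarray          # non-increasing, >= 0
    loadings: np.ndarray             # expanded-column x dimension (right singular vectors)
    scores: np.ndarray               # training rows x dimension (principal coordinates)
    quantitative: list[str]
    categorical: list[str]
    quant_mean: np.ndarray
    quant_scale: np.ndarray
    cat_levels: dict[str, list[float]]   # observed levels per categorical column
    cat_proportions: dict[str, list[float]]
    expanded_columns: list[str]
    n_rows: int
    n_vars: int
    total_inertia: float
    n_retained: int = 0
    kss_threshold: float = float("nan")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "eigenvalues": self.eigenvalues.tolist(),
            "loadings": self.loadings.tolist(),
            "quantitative": self.quantitative,
            "categorical": self.categorical,
            "quant_mean": self.quant_mean.tolist(),
            "quant_scale": self.quant_scale.tolist(),
            "cat_levels": self.cat_levels,
            "cat_proportions": self.cat_proportions,
            "expanded_columns": self.expanded_columns,
            "n_rows": self.n_rows,
            "n_vars": self.n_vars,
            "total_inertia": self.total_inertia,
            "n_retained": self.n_retained,
            "kss_threshold": self.kss_threshold,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PCAmixModel":
        d = json.loads(Path(path).read_text())
        return cls(
            eigenvalues=np.array(d["eigenvalues"]),
            loadings=np.array(d["loadings"]),
            scores=np.empty((0, len(d["eigenvalues"]))),
            quantitative=d["quantitative"],
            categorical=d["categorical"],
            quant_mean=np.array(d["quant_mean"]),
            quant_scale=np.array(d["quant_scale"]),
            cat_levels=d["cat_levels"],
            cat_proportions=d["cat_proportions"],
            expanded_columns=d["expanded_columns"],
            n_rows=d["n_rows"],
            n_vars=d["n_vars"],
            total_inertia=d["total_inertia"],
            n_retained=d["n_retained"],
            kss_threshold=d["kss_threshold"],
        )


def _expand(
    df: pd.DataFrame,
    quantitative: list[str],
    categorical: list[str],
    quant_mean: np.ndarray,
    quant_scale: np.ndarray,
    cat_levels: dict[str, list[float]],
    cat_proportions: dict[str, list[float]],
) -> np.ndarray:
    """Apply the stored centering/weighting; columns ordered quant then levels."""
    blocks = []
    if quantitative:
        z = (df[quantitative].to_numpy(dtype=float) - quant_mean) / quant_scale
        blocks.append(z)
    for col in categorical:
        x = df[col].to_numpy()
        levels = cat_levels[col]
        props = np.asarray(cat_proportions[col])
        ind = np.column_stack([(x == lv).astype(float) for lv in levels])
        if not np.isclose(ind.sum(axis=1), 1.0).all():
            raise ValueError(f"column {col!r} contains levels unseen in training")
        blocks.append((ind - props) / np.sqrt(props))
    return np.hstack(blocks)


def fit_pcamix(features: FeatureMatrix | pd.DataFrame,
               quantitative: list[str] | None = None,
               categorical: list[str] | None = None) -> PCAmixModel:
    """Fit the mixed-data factorization.

    Accepts a :class:`FeatureMatrix` or a raw DataFrame plus explicit column
    roles.  Raises a named-variable error for zero-variance quantitative
    columns or single-level categorical columns.
    """
    if isinstance(features, FeatureMatrix):
        df = features.data
        quantitative = features.quantitative
        categorical = features.categorical
    else:
        df = features
        quantitative = quantitative or []
        categorical = categorical or []
    n = len(df)
    if n < 2:
        raise ValueError("PCAmix requires at least 2 rows")
    if not quantitative and not categorical:
        raise ValueError("PCAmix requires at least 1 variable")

    quant_mean = df[quantitative].to_numpy(dtype=float).mean(axis=0) if quantitative else np.array([])
    quant_scale = df[quantitative].to_numpy(dtype=float).std(axis=0) if quantitative else np.array([])
    for name, s in zip(quantitative, quant_scale):
        if s == 0:
            raise ValueError(f"quantitative variable {name!r} has zero variance")

    cat_levels: dict[str, list[float]] = {}
    cat_proportions: dict[str, list[float]] = {}
    expanded = list(quantitative)
    for col in categorical:
        counts = df[col].value_counts().sort_index()
        if len(counts) < 2:
            raise ValueError(f"categorical variable {col!r} has a single level")
        cat_levels[col] = counts.index.tolist()
        cat_proportions[col] = (counts / n).tolist()
        expanded += [f"{col}={lv}" for lv in counts.index]

    Z = _expand(df, quantitative, categorical, quant_mean, quant_scale,
                cat_levels, cat_proportions)
    _, s, Vt = np.linalg.svd(Z / np.sqrt(n), full_matrices=False)
    eigenvalues = s**2
    keep = eigenvalues > max(1e-12, eigenvalues[0] * 1e-12)
    eigenvalues = eigenvalues[keep]
    V = Vt[keep].T
    scores = Z @ V

    n_levels = sum(len(v) for v in cat_levels.values())
    total_inertia = len(quantitative) + (n_levels - len(categorical))
    return PCAmixModel(
        eigenvalues=eigenvalues,
        loadings=V,
        scores=scores,
        quantitative=list(quantitative),
        categorical=list(categorical),
        quant_mean=quant_mean,
        quant_scale=quant_scale,
        cat_levels=cat_levels,
        cat_proportions=cat_proportions,
        expanded_columns=expanded,
        n_rows=n,
        n_vars=len(quantitative) + len(categorical),
        total_inertia=float(total_inertia),
    )


def kss_retain(eigenvalues: np.ndarray, n_rows: int, n_vars: int) -> tuple[int, float]:
    """Karlis-Saporta-Spinaki retention: count of eigenvalues above threshold.

    Threshold = ``mean(eigenvalues) * (1 + 2 * sqrt((p - 1) / (n - 1)))`` with
    p = number of original variables and n = number of rows; a floor of 2
    retained dimensions is applied.  Returns (n_retained, threshold).
    """
    if n_rows <= 1:
        raise ValueError("KSS rule requires more than one row")
    lam = np.asarray(eigenvalues, dtype=float)
    threshold = lam.mean() * (1.0 + 2.0 * np.sqrt((n_vars - 1) / (n_rows - 1)))
    n_retained = int((lam > threshold).sum())
    return max(2, n_retained), float(threshold)


def retain(model: PCAmixModel) -> PCAmixModel:
    """Apply the KSS rule to a fitted model (records n_retained/threshold)."""
    n_ret, thr = kss_retain(model.eigenvalues, model.n_rows, model.n_vars)
    model.n_retained = min(n_ret, len(model.eigenvalues))
    model.kss_threshold = thr
    return model


def project(model: PCAmixModel, new_rows: pd.DataFrame, n_dims: int | None = None) -> np.ndarray:
    """Project new rows into the factor space using the stored parameters."""
    needed = model.quantitative + model.categorical
    missing = [c for c in needed if c not in new_rows.columns]
    if missing:
        raise ValueError(f"new rows are missing columns: {missing}")
    Z = _expand(new_rows, model.quantitative, model.categorical,
                model.quant_mean, model.quant_scale,
                model.cat_levels, model.cat_proportions)
    scores = Z @ model.loadings
    if n_dims is not None:
        scores = scores[:, :n_dims]
    return scores
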