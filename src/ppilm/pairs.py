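"""Pair vectors and principal-component reduction.

A protein pair is described by concatenating the two per-protein
Legendre-moment descriptors (441 + 441 = 882 values under the default
order).  Principal component analysis, fitted on training pairs only,
reduces the concatenation to n_components coordinates (default 100)
ordered by decreasing explained variance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.decomposition import PCA

from .legendre import LMFeatureVector

__all__ = [
    "make_pair_vector",
    "build_pair_matrix",
    "ProjectionModel",
    "fit_projection",
    "apply_projection",
    "save_projection",
    "load_projection",
]


def make_pair_vector(fa: LMFeatureVector, fb: LMFeatureVector) -> np.ndarray:
    """Concatenate two per-protein descriptors in pair-list order."""
    if fa.values.size != fb.values.size:
        raise ValueError(
            f"descriptor length mismatch: {fa.values.size} vs {fb.values.size}"
        )
    return np.concatenate([fa.values, fb.values])


def build_pair_matrix(
    pairs: Sequence[tuple[str, str, int]],
    features: Mapping[str, LMFeatureVector],
    swap_augment: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack pair vectors into (X, y) for a list of labelled pairs.

    With ``swap_augment`` each pair also contributes the swapped
    concatenation [fb || fa] as an extra row with the same label
    (the concatenation is order-dependent; augmentation symmetrizes
    training without changing the descriptor).
    """
    if not pairs:
        raise ValueError("empty pair list")
    missing = {p for a, b, _ in pairs for p in (a, b) if p not in features}
    if missing:
        raise KeyError(f"no descriptor for protein(s): {sorted(missing)[:5]}")
    rows, labels = [], []
    for a, b, lab in pairs:
        rows.append(make_pair_vector(features[a], features[b]))
        labels.append(lab)
        if swap_augment:
            rows.append(make_pair_vector(features[b], features[a]))
            labels.append(lab)
    return np.vstack(rows), np.asarray(labels, dtype=int)


@dataclass
class ProjectionModel:
    """A fitted centering + orthonormal projection (PCA).

    components has shape (d, k) with orthonormal columns ordered by
    decreasing explained variance; the sign of each column is fixed by
    making its largest-magnitude loading positive, so the fit is
    deterministic.
    """

    mean: np.ndarray = field(repr=False)
    components: np.ndarray = field(repr=False)
    explained_variance: np.ndarray = field(repr=False)
    n_components: int = 100
    fitted_on: str = ""

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.components = np.asarray(self.components, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        if self.components.shape != (self.mean.size, self.n_components):
            raise ValueError(
                f"components shape {self.components.shape} inconsistent with "
                f"d={self.mean.size}, k={self.n_components}"
            )

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.explained_variance / self._total_variance

    _total_variance: float = field(default=0.0, repr=False)


def fit_projection(
    X: np.ndarray, n_components: int = 100, fitted_on: str = ""
) -> ProjectionModel:
    """Fit a PCA projection on training pair vectors.

    Centering only (no standardization); components are the top
    eigenvectors of the sample covariance.  Requires
    1 <= n_components <= min(n_samples, n_features).
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if not 1 <= n_components <= min(n, d):
        raise ValueError(
            f"n_components={n_components} must be in [1, min(n={n}, d={d})]"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    comps = pca.components_.T.copy()  # d x k
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(n_components):
        i = int(np.argmax(np.abs(comps[:, j])))
        if comps[i, j] < 0:
            comps[:, j] = -comps[:, j]
    model = ProjectionModel(
        mean=pca.mean_,
        components=comps,
        explained_variance=pca.explained_variance_,
        n_components=n_components,
        fitted_on=fitted_on,
    )
    model._total_variance = float(np.var(X, axis=0, ddof=1).sum())
    return model


def apply_projection(model: ProjectionModel, X: np.ndarray) -> np.ndarray:
    """Project rows of X onto the fitted components: (X - mean) @ W."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.mean.size:
        raise ValueError(
            f"feature width {X.shape[1]} does not match projection "
            f"width {model.mean.size}"
        )
    return (X - model.mean) @ model.components


def save_projection(model: ProjectionModel, path: str | Path) -> None:
    """Serialize a projection to a portable JSON file."""
    payload = {
        "mean": model.mean.tolist(),
        "components": model.components.tolist(),
        "explained_variance": model.explained_variance.tolist(),
        "n_components": model.n_components,
        "fitted_on": model.fitted_on,
        "total_variance": model._total_variance,
    }
    Path(path).write_text(json.dumps(payload))


def load_projection(path: str | Path) -> ProjectionModel:
    payload = json.loads(Path(path).read_text())
    model = ProjectionModel(
        mean=np.array(payload["mean"]),
        components=np.array(payload["components"]),
        explained_variance=np.array(payload["explained_variance"]),
        n_components=int(payload["n_components"]),
        fitted_on=payload.get("fitted_on", ""),
    )
    model._total_variance = float(payload.get("total_variance", 0.0))
    return model
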