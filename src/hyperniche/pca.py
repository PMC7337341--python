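"""Correlation-matrix principal component analysis of climate variables.

The niche hypervolumes are delineated in an orthogonal space, so the (highly
collinear) bioclimatic variables are first standardized and rotated by PCA of
the correlation matrix.  Components are retained by the Kaiser rule
(eigenvalue > 1); with K variables the eigenvalues sum to K, so the explained
variance of component i is simply eigenvalue_i / K.

Loadings are reported as Pearson correlations between each variable and each
retained component (loading = rotation column × sqrt(eigenvalue)), the form
in which PCA summaries of climate predictors are conventionally tabulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PCSpace", "fit_pca", "transform"]


@dataclass
class PCSpace:
    """Fitted standardization + rotation with Kaiser retention.

    ``rotation`` holds all K orthonormal eigenvector columns (descending
    eigenvalue order, sign-fixed); ``m`` is the retained dimensionality.
    """

    means: np.ndarray  # (K,)
    sds: np.ndarray  # (K,) sample sd, ddof=1
    rotation: np.ndarray  # (K, K), columns orthonormal
    eigenvalues: np.ndarray  # (K,), descending, sum = K
    m: int
    names: tuple[str, ...] = ()

    @property
    def k(self) -> int:
        return self.means.size

    @property
    def explained_variance(self) -> np.ndarray:
        """Fraction of total variance per component: eigenvalue_i / K."""
        return self.eigenvalues / self.k

    @property
    def loadings(self) -> np.ndarray:
        """(K, m) Pearson correlations between variables and retained PCs."""
        return self.rotation[:, : self.m] * np.sqrt(self.eigenvalues[: self.m])

    def summary(self) -> pd.DataFrame:
        """Loadings table with eigenvalue and explained-variance rows."""
        cols = [f"PC{i + 1}" for i in range(self.m)]
        idx = list(self.names) if self.names else [f"var{i + 1}" for i in range(self.k)]
        df = pd.DataFrame(self.loadings, index=idx, columns=cols)
        df.loc["Eigenvalue"] = self.eigenvalues[: self.m]
        df.loc["Explained Variance (%)"] = 100 * self.explained_variance[: self.m]
        return df

    def to_json(self, path: str | Path) -> None:
        payload = {
            "names": list(self.names),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "rotation": self.rotation.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "m": self.m,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PCSpace":
        payload = json.loads(Path(path).read_text())
        return cls(
            means=np.asarray(payload["means"]),
            sds=np.asarray(payload["sds"]),
            rotation=np.asarray(payload["rotation"]),
            eigenvalues=np.asarray(payload["eigenvalues"]),
            m=int(payload["m"]),
            names=tuple(payload["names"]),
        )


def fit_pca(
    values: np.ndarray,
    names: tuple[str, ...] = (),
    eigenvalue_threshold: float = 1.0,
) -> PCSpace:
    """Fit correlation-matrix PCA with Kaiser retention.

    Requires more rows than variables and no constant column (a constant
    variable has no defined correlation).  The sign of each component is
    fixed so that its largest-magnitude loading is positive, making results
    reproducible across eigen-solvers.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("values must be a 2-D matrix")
    n, k = x.shape
    if n < k + 1:
        raise ValueError(f"need at least K+1 = {k + 1} rows, got {n}")
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    constant = np.nonzero(sds == 0)[0]
    if constant.size:
        which = names[constant[0]] if names else f"column {constant[0]}"
        raise ValueError(f"constant variable {which!r}: correlation undefined")
    z = (x - means) / sds
    corr = (z.T @ z) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # sign convention: largest-|loading| entry of each column made positive
    for j in range(k):
        pivot = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[pivot, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    m = int(np.sum(eigvals > eigenvalue_threshold))
    m = max(m, 1)
    return PCSpace(
        means=means,
        sds=sds,
        rotation=eigvecs,
        eigenvalues=eigvals,
        m=m,
        names=tuple(names),
    )


def transform(space: PCSpace, values: np.ndarray) -> np.ndarray:
    """Project rows of *values* into the retained PC space (n, m)."""
    x = np.atleast_2d(np.asarray(values, dtype=float))
    if x.shape[1] != space.k:
        raise ValueError(f"expected {space.k} variables, got {x.shape[1]}")
    z = (x - space.means) / space.sds
    return z @ space.rotation[:, : space.m]
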