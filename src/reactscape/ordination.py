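"""Dissimilarities and principal coordinates analysis.

Bray–Curtis (abundance-based) and Sørensen (incidence-based) dissimilarities
feed a classical PCoA: Gower double-centering of -d²/2 followed by an
eigendecomposition.  Axes with negative eigenvalues are dropped but their
total magnitude is reported so users can judge the distortion of a
non-Euclidean input; explained-variance proportions are taken over the sum
of positive eigenvalues.  The ``n75`` rule picks the smallest number of
leading axes whose cumulative explained variance reaches a threshold
(default 75%).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .tables import CountTable, NormalizedTable

_EIG_TOL_FACTOR = 1e-12


@dataclasses.dataclass
class DissimilarityMatrix:
    values: np.ndarray
    sample_ids: list[str]
    metric: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if np.isnan(v).any():
            raise ValueError("dissimilarity matrix contains NaN")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.abs(np.diag(v)).max() > 1e-12:
            raise ValueError("diagonal must be zero")
        if v.min() < -1e-12 or v.max() > 1 + 1e-9:
            raise ValueError("dissimilarities must lie in [0, 1]")
        self.values = v

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def to_tsv(self, path) -> None:
        self.to_dataframe().rename_axis("sample_id").to_csv(path, sep="\t")


def _matrix_of(table) -> tuple[np.ndarray, list[str]]:
    df = table.values if isinstance(table, NormalizedTable) else table.counts
    x = df.to_numpy(dtype=float).T  # samples x OTUs
    if (x.sum(axis=1) == 0).any():
        raise ValueError("all-zero samples have undefined dissimilarity")
    return x, list(df.columns)


def bray_curtis(table: CountTable | NormalizedTable) -> DissimilarityMatrix:
    """Bray–Curtis dissimilarity Σ|x−y| / Σ(x+y) between all sample pairs."""
    x, ids = _matrix_of(table)
    d = squareform(pdist(x, metric="braycurtis"))
    return DissimilarityMatrix(d, ids, "bray_curtis")


def sorensen(table: CountTable | NormalizedTable) -> DissimilarityMatrix:
    """Sørensen dissimilarity (b+c)/(2a+b+c) on presence/absence (> 0)."""
    x, ids = _matrix_of(table)
    # Dice dissimilarity on booleans is exactly Sørensen
    d = squareform(pdist(x > 0, metric="dice"))
    return DissimilarityMatrix(d, ids, "sorensen")


@dataclasses.dataclass
class Ordination:
    """PCoA result: coordinates on positive axes plus eigen spectrum."""

    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    proportion_explained: np.ndarray
    negative_eigenvalue_mass: float
    metric: str = ""

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    def sample_coords(self, sample_id: str, k: int | None = None) -> np.ndarray:
        v = self.coordinates.loc[sample_id].to_numpy()
        return v if k is None else v[:k]


def pcoa(d: DissimilarityMatrix, metric: str | None = None) -> Ordination:
    """Classical (metric) multidimensional scaling of a dissimilarity matrix."""
    dv = d.values
    n = dv.shape[0]
    b = dv**2 * -0.5
    # Gower double-centering
    row_mean = b.mean(axis=1, keepdims=True)
    b = b - row_mean - row_mean.T + b.mean()
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), abs(eigval[-1]), 1.0) * _EIG_TOL_FACTOR * n
    pos = eigval > tol
    neg_mass = float(-eigval[eigval < -tol].sum())
    ev = eigval[pos]
    coords = eigvec[:, pos] * np.sqrt(ev)
    # fix arbitrary axis signs: first entry of largest magnitude made positive
    for j in range(coords.shape[1]):
        col = coords[:, j]
        lead = col[np.argmax(np.abs(col))]
        if lead < 0:
            coords[:, j] = -col
    total = ev.sum() if ev.size else 1.0
    return Ordination(
        coordinates=pd.DataFrame(
            coords, index=d.sample_ids, columns=[f"PC{i+1}" for i in range(coords.shape[1])]
        ),
        eigenvalues=ev,
        proportion_explained=ev / total,
        negative_eigenvalue_mass=neg_mass,
        metric=metric or d.metric,
    )


def n75_axes(ordination: Ordination, threshold: float = 0.75) -> int:
    """Smallest k with cumulative explained variance >= threshold.

    Falls back to the number of positive axes when the threshold is never
    reached (e.g. degenerate two-sample ordinations).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    props = ordination.proportion_explained
    if props.size == 0:
        return 0
    cum = np.cumsum(props)
    hit = np.nonzero(cum >= threshold - 1e-12)[0]
    return int(hit[0]) + 1 if hit.size else int(props.size)
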