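"""Principal Coordinates Analysis of overlap-derived dissimilarities.

Similarity matrices (values in [0, 1], unit diagonal) are converted to
distances (``1 - S`` by default, ``sqrt(1 - S)`` for guaranteed better
embeddability) and ordinated by classical metric MDS via Gower double
centering. Negative eigenvalues are reported and their axes dropped; an
optional Cailliez correction makes the matrix Euclidean-embeddable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = ["PcoaResult", "similarity_to_distance", "pcoa", "group_separation"]

_EIG_TOL = 1e-9


@dataclass(frozen=True)
class PcoaResult:
    unit_ids: list
    coordinates: np.ndarray  # units x kept axes
    eigenvalues: np.ndarray  # descending, kept (positive) axes
    proportion_explained: np.ndarray
    n_negative_eigenvalues: int
    most_negative_eigenvalue: float

    def as_frame(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.unit_ids, columns=cols)


def similarity_to_distance(similarity: pd.DataFrame, variant: str = "one-minus-s") -> pd.DataFrame:
    """Convert an overlap similarity matrix to a dissimilarity matrix.

    ``one-minus-s``: D = 1 - S. ``sqrt``: D = sqrt(1 - S), which is
    Euclidean-embeddable for a wider class of similarity matrices.
    """
    s = similarity.to_numpy(dtype=float)
    if s.shape[0] != s.shape[1] or not np.allclose(s, s.T, atol=1e-9):
        raise ValueError("similarity matrix must be square and symmetric")
    if s.min() < -1e-12 or s.max() > 1 + 1e-12:
        raise ValueError("similarity values must lie in [0, 1]")
    if not np.allclose(np.diag(s), 1.0, atol=1e-9):
        raise ValueError("self-similarity must be 1 on the diagonal")
    d = np.clip(1.0 - s, 0.0, None)
    if variant == "sqrt":
        d = np.sqrt(d)
    elif variant != "one-minus-s":
        raise ValueError(f"unknown variant {variant!r}")
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=similarity.index, columns=similarity.columns)


def pcoa(distance, n_axes: int | None = None, correction: str | None = None) -> PcoaResult:
    """Classical PCoA of a symmetric zero-diagonal distance matrix.

    Gower-centers ``-0.5 * J D^2 J`` and eigendecomposes; coordinates are
    eigenvectors scaled by the square root of their (positive)
    eigenvalues, so the configuration is centered at the origin. Axes with
    negative eigenvalues are dropped and counted; ``correction="cailliez"``
    adds the minimal constant to off-diagonal distances that removes them.
    """
    ids = list(distance.index) if isinstance(distance, pd.DataFrame) else None
    d = np.asarray(getattr(distance, "values", distance), dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-9):
        raise ValueError("distance matrix must have a zero diagonal")
    if d.min() < 0:
        raise ValueError("distances must be non-negative")
    n = d.shape[0]
    if ids is None:
        ids = list(range(n))

    if correction == "cailliez":
        d = _cailliez(d)
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")

    b = _gower_center(d)
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    neg = eigvals[eigvals < -_EIG_TOL]
    pos_mask = eigvals > _EIG_TOL
    lam = eigvals[pos_mask]
    vec = eigvecs[:, pos_mask]
    coords = vec * np.sqrt(lam)
    # orient axes deterministically: largest-magnitude loading positive
    for j in range(coords.shape[1]):
        k = np.argmax(np.abs(coords[:, j]))
        if coords[k, j] < 0:
            coords[:, j] = -coords[:, j]
    if n_axes is not None:
        coords = coords[:, :n_axes]
        lam = lam[:n_axes]
    total = eigvals[pos_mask].sum()
    prop = lam / total if total > 0 else np.zeros_like(lam)
    return PcoaResult(
        unit_ids=ids,
        coordinates=coords,
        eigenvalues=lam,
        proportion_explained=prop,
        n_negative_eigenvalues=int(neg.size),
        most_negative_eigenvalue=float(neg.min()) if neg.size else 0.0,
    )


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    a = -0.5 * d * d
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _cailliez(d: np.ndarray) -> np.ndarray:
    """Smallest c so that d_ij + c (i != j) is Euclidean-embeddable."""
    n = d.shape[0]
    b1 = _gower_center(d)
    # c = largest eigenvalue of [[0, 2 B1], [-I, -4 B2]] with B2 the Gower
    # centering of the plain (unsquared) distances
    a2 = -0.5 * d
    j = np.eye(n) - np.ones((n, n)) / n
    b_lin = j @ a2 @ j
    top = np.hstack([np.zeros((n, n)), 2.0 * b1])
    bot = np.hstack([-np.eye(n), -4.0 * b_lin])
    eig = np.linalg.eigvals(np.vstack([top, bot]))
    c = float(np.max(eig.real))
    if c <= 0:
        return d
    out = d + c
    np.fill_diagonal(out, 0.0)
    return out


def group_separation(result: PcoaResult, labels, axis_sets=((0, 1), (2,))) -> dict:
    """Between/within mean pairwise distance ratios per axis subset.

    ``labels`` assigns one group label per ordinated unit. For each axis
    subset the ratio of the mean pairwise distance between units of
    different groups to that between units of the same group is reported
    (keys like ``"axes_1-2"``); ratios >> 1 indicate separation.
    """
    labels = list(labels)
    if len(labels) != len(result.unit_ids):
        raise ValueError("one label required per ordinated unit")
    out = {}
    for axes in axis_sets:
        axes = tuple(a for a in axes if a < result.coordinates.shape[1])
        if not axes:
            continue
        pts = result.coordinates[:, list(axes)]
        within, between = [], []
        for i, j in combinations(range(len(labels)), 2):
            dist = float(np.linalg.norm(pts[i] - pts[j]))
            (within if labels[i] == labels[j] else between).append(dist)
        key = "axes_" + "-".join(str(a + 1) for a in axes)
        if within and between:
            denom = np.mean(within)
            out[key] = float(np.mean(between) / denom) if denom > 0 else float("inf")
        else:
            out[key] = float("nan")
    return out
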