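"""Manifold summaries: classical MDS, principal geodesic analysis,
single-link clustering of taxa from their pairwise Riemannian distances.

Classical (Torgerson) MDS is used rather than a stress-minimising
variant: it is deterministic, exact on Euclidean-realizable distance
matrices, and adequate for the low-dimensional overview plots these
analyses feed.  PGA maps all Ω matrices to the tangent space at their
Fréchet mean (where the affine-invariant inner product is Frobenius) and
runs ordinary PCA there.  Single-link clustering is cut at the same
1.645σ critical value the transect analysis uses, so the groups it
reports are "indistinguishable at the replicate-sampling noise scale".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .omega import OmegaMatrix
from .spd import frechet_mean, spd_distance, spd_log, spd_power, _sym

__all__ = [
    "DistanceMatrix",
    "distance_matrix",
    "mds_embed",
    "pga",
    "single_link_cluster",
    "linkage_to_newick",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(v < -1e-12):
            raise ValueError("distances must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def distance_matrix(omegas: dict[str, OmegaMatrix]) -> DistanceMatrix:
    """Pairwise affine-invariant distances between labelled Ω matrices."""
    labels = tuple(sorted(omegas))
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = spd_distance(omegas[labels[i]].matrix, omegas[labels[j]].matrix)
    return DistanceMatrix(labels=labels, values=d)


def mds_embed(d: DistanceMatrix, dims: int = 2) -> tuple[pd.DataFrame, dict]:
    """Classical (Torgerson) MDS embedding of a distance matrix.

    Double-centres the squared distances, takes the top ``dims``
    eigenpairs, and fixes the sign convention by making the first
    label's first coordinate nonnegative (each axis independently).
    Returns ``(coordinates, info)``; ``info['negative_mass']`` is the
    fraction of total absolute eigenvalue mass on negative eigenvalues —
    above 0.5 the distances embed poorly in Euclidean space and
    ``info['poor_embedding']`` is set.
    """
    dd = d.values**2
    n = dd.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ dd @ j
    w, v = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    neg_mass = float(np.sum(np.abs(w[w < 0])) / max(np.sum(np.abs(w)), 1e-300))
    coords = np.zeros((n, dims))
    for k in range(min(dims, n)):
        if w[k] > 0:
            coords[:, k] = v[:, k] * np.sqrt(w[k])
    for k in range(dims):
        if coords[0, k] < 0:
            coords[:, k] = -coords[:, k]
    frame = pd.DataFrame(
        coords, index=d.labels, columns=[f"mds{k + 1}" for k in range(dims)]
    )
    info = {
        "eigenvalues": w,
        "negative_mass": neg_mass,
        "poor_embedding": neg_mass > 0.5,
    }
    return frame, info


def pga(omegas: dict[str, OmegaMatrix], dims: int = 2) -> tuple[pd.DataFrame, dict]:
    """Principal geodesic analysis of labelled Ω matrices.

    All matrices are log-mapped to the tangent space at their Fréchet
    mean M (as whitened logs log(M^{-1/2} X M^{-1/2}), in which the
    affine-invariant inner product is Frobenius), vectorized, and
    decomposed by PCA.  Returns the per-label scores on the first
    ``dims`` components and an info dict with the explained-variance
    fractions, the tangent principal directions (as symmetric matrices)
    and the Fréchet convergence report.
    """
    if len(omegas) < 3:
        raise ValueError("PGA needs at least three matrices")
    labels = tuple(sorted(omegas))
    mats = [omegas[lab].matrix for lab in labels]
    mean, finfo = frechet_mean(mats)
    m_isqrt = spd_power(mean, -0.5)
    tangents = np.stack(
        [spd_log(_sym(m_isqrt @ x @ m_isqrt)) for x in mats]
    )  # (n, d, d)
    n, dim, _ = tangents.shape
    vecs = tangents.reshape(n, dim * dim)  # full vec ⇒ Frobenius inner product
    centred = vecs - vecs.mean(axis=0)
    # SVD of the (n, d²) tangent cloud; right singular vectors are the directions
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    var = s**2
    total = float(var.sum())
    explained = var / total if total > 0 else np.zeros_like(var)
    scores = u * s
    k = min(dims, scores.shape[1])
    frame = pd.DataFrame(
        scores[:, :dims] if scores.shape[1] >= dims else np.pad(scores, ((0, 0), (0, dims - k))),
        index=labels,
        columns=[f"pga{i + 1}" for i in range(dims)],
    )
    for col in range(dims):
        c = frame.iloc[:, col].to_numpy()
        if c[np.argmax(np.abs(c))] < 0:
            frame.iloc[:, col] = -c
    directions = [vt[i].reshape(dim, dim) for i in range(min(dims, vt.shape[0]))]
    info = {
        "explained": explained[:dims],
        "directions": directions,
        "frechet": finfo,
        "mean": mean,
    }
    return frame, info


def single_link_cluster(
    d: DistanceMatrix, critical: float
) -> tuple[np.ndarray, dict[str, int]]:
    """Single-linkage dendrogram plus groups cut at the critical distance.

    Returns ``(linkage_matrix, groups)`` where ``groups`` maps each label
    to a 0-based group id; groups are exactly the connected components of
    the distance graph thresholded at ``critical`` (edges with distance
    ≤ critical connect).
    """
    n = len(d.labels)
    if n == 1:
        return np.empty((0, 4)), {d.labels[0]: 0}
    iu = np.triu_indices(n, 1)
    condensed = d.values[iu]
    link = hierarchy.linkage(condensed, method="single")
    assignments = hierarchy.fcluster(link, t=critical, criterion="distance")
    # renumber groups by first appearance in label order
    seen: dict[int, int] = {}
    groups: dict[str, int] = {}
    for lab, a in zip(d.labels, assignments):
        if a not in seen:
            seen[a] = len(seen)
        groups[lab] = seen[a]
    return link, groups


def linkage_to_newick(link: np.ndarray, labels: tuple[str, ...]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree.

    The dendrogram is read as an ultrametric: each internal node sits at
    its merge height, leaves at height 0, and a branch length is the
    height difference between a node and its parent.
    """
    tree = hierarchy.to_tree(link)

    def recurse(node) -> tuple[str, float]:
        if node.is_leaf():
            return labels[node.id], 0.0
        ls, lh = recurse(node.get_left())
        rs, rh = recurse(node.get_right())
        s = f"({ls}:{node.dist - lh:.10g},{rs}:{node.dist - rh:.10g})"
        return s, node.dist

    return recurse(tree)[0] + ";"
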