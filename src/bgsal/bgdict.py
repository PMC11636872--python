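"""Boundary conductivity and background-dictionary refinement.

Each superpixel's boundary conductivity is the soft length of its
homogeneous region along the image border divided by the square root of
the region's soft area::

    bc(p) = length(p) / sqrt(area(p))
    area(p)   = sum_i exp(-d_geo(p, i)^2 / (2 sigma^2))
    length(p) = sum_i exp(-d_geo(p, i)^2 / (2 sigma^2)) * [i on border]

where ``d_geo`` is the shortest-path distance over the superpixel
adjacency graph with appearance-distance edge weights.  Superpixels
strongly conducting to the border are likely background; boundary
superpixels whose normalized conductivity falls below the adaptive
threshold ``tau = bc_max - K * var`` are dropped from the dictionary,
which is what rescues salient objects touching the image border.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from bgsal.abstraction import BoundarySet, FeatureMatrix, SuperpixelMap
from bgsal.errors import DisconnectedGraphError

__all__ = [
    "SuperpixelGraph",
    "ConductivityField",
    "RefinedDictionary",
    "build_graph",
    "geodesic_distances",
    "boundary_conductivity",
    "refine_dictionary",
]

logger = logging.getLogger(__name__)

#: Minimum number of dictionary atoms kept so the PCA / L1 stages never
#: degenerate, even when thresholding would discard nearly all of B.
MIN_DICT_ATOMS = 8


@dataclass(frozen=True)
class SuperpixelGraph:
    """Undirected appearance-weighted adjacency graph over superpixels."""

    n_nodes: int
    edges: np.ndarray  # (m, 2) int array, each row (p, q) with p < q
    weights: np.ndarray  # (m,) non-negative reals

    def weight_matrix(self) -> coo_matrix:
        p, q = self.edges[:, 0], self.edges[:, 1]
        return coo_matrix(
            (
                np.concatenate([self.weights, self.weights]),
                (np.concatenate([p, q]), np.concatenate([q, p])),
            ),
            shape=(self.n_nodes, self.n_nodes),
        )


@dataclass(frozen=True)
class ConductivityField:
    """Geodesic affinities and the derived conductivity of every superpixel."""

    d_geo: np.ndarray  # (k, k) shortest-path appearance distances
    A: np.ndarray  # (k, k) affinities exp(-d_geo^2 / 2 sigma^2)
    area: np.ndarray  # (k,) soft areas
    length: np.ndarray  # (k,) soft border lengths
    bc: np.ndarray  # (k,) conductivities
    bc_norm: np.ndarray  # (k,) min-max normalized conductivities
    sigma: float


@dataclass(frozen=True)
class RefinedDictionary:
    """The initial border dictionary B and its refined subset B*."""

    initial: BoundarySet
    kept: tuple[int, ...]
    tau: float
    K: float
    bc_values: dict[int, float]  # bc_norm restricted to the initial set

    @property
    def kept_array(self) -> np.ndarray:
        return np.asarray(self.kept, dtype=int)


def _adjacent_label_pairs(labels: np.ndarray) -> np.ndarray:
    """Unique (p, q) pairs of 4-adjacent distinct labels, p < q."""
    horiz = np.stack([labels[:, :-1].ravel(), labels[:, 1:].ravel()], axis=1)
    vert = np.stack([labels[:-1, :].ravel(), labels[1:, :].ravel()], axis=1)
    pairs = np.concatenate([horiz, vert], axis=0)
    pairs = pairs[pairs[:, 0] != pairs[:, 1]]
    pairs = np.sort(pairs, axis=1)
    return np.unique(pairs, axis=0)


def build_graph(
    spmap: SuperpixelMap,
    features: FeatureMatrix,
    feature_subset: str = "lab",
) -> SuperpixelGraph:
    """Adjacency graph with Euclidean appearance-distance edge weights.

    Parameters
    ----------
    feature_subset
        ``"lab"`` (default) measures appearance distance on the CIE-Lab
        columns only; ``"full"`` uses the whole 8-dim feature vector.
    """
    if features.k != spmap.k:
        raise ValueError("feature matrix and superpixel map disagree on k")
    if feature_subset == "lab":
        X = features.lab
    elif feature_subset == "full":
        X = features.F
    else:
        raise ValueError(f"unknown feature_subset {feature_subset!r}")
    edges = _adjacent_label_pairs(spmap.labels)
    diffs = X[edges[:, 0]] - X[edges[:, 1]]
    weights = np.linalg.norm(diffs, axis=1)
    return SuperpixelGraph(n_nodes=spmap.k, edges=edges, weights=weights)


def geodesic_distances(graph: SuperpixelGraph) -> np.ndarray:
    """All-pairs shortest-path distances over the appearance graph."""
    W = graph.weight_matrix().tocsr()
    n_comp, _ = connected_components(W, directed=False)
    if graph.n_nodes > 1 and n_comp != 1:
        raise DisconnectedGraphError(
            f"superpixel graph has {n_comp} components; expected 1"
        )
    d = dijkstra(W, directed=False)
    return np.minimum(d, d.T)  # enforce exact symmetry


def boundary_conductivity(
    d_geo: np.ndarray,
    boundary: BoundarySet,
    sigma: float = 10.0,
) -> ConductivityField:
    """Soft area, border length and conductivity for every superpixel.

    ``bc_norm`` is the min-max normalization of ``bc`` over all ``k``
    superpixels; if all conductivities are equal the normalization is
    degenerate and ``bc_norm`` is set to all ones.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d_geo = np.asarray(d_geo, dtype=float)
    k = d_geo.shape[0]
    A = np.exp(-(d_geo**2) / (2.0 * sigma**2))
    delta = np.zeros(k)
    delta[boundary.as_array()] = 1.0
    area = A.sum(axis=1)
    length = A @ delta
    bc = length / np.sqrt(area)
    span = bc.max() - bc.min()
    if span <= 0:
        logger.info("all conductivities equal; bc_norm set to ones")
        bc_norm = np.ones(k)
    else:
        bc_norm = (bc - bc.min()) / span
    return ConductivityField(
        d_geo=d_geo, A=A, area=area, length=length, bc=bc, bc_norm=bc_norm,
        sigma=float(sigma),
    )


def refine_dictionary(
    field: ConductivityField,
    boundary: BoundarySet,
    K: float = 4.0,
    min_atoms: int = MIN_DICT_ATOMS,
) -> RefinedDictionary:
    """Drop low-conductivity border superpixels from the dictionary.

    The adaptive threshold is ``tau = max(bc_norm over B) - K * var``,
    with the population variance of ``bc_norm`` over B.  Members with
    ``bc_norm >= tau`` are kept.  If fewer than ``min_atoms`` survive,
    the ``min_atoms`` highest-conductivity members are kept instead (all
    of B when B itself is smaller); pass ``min_atoms=0`` for the pure
    threshold rule.
    """
    idx = boundary.as_array()
    if idx.size == 0:
        raise ValueError("boundary set is empty")
    vals = field.bc_norm[idx]
    tau = float(vals.max() - K * vals.var())
    kept_mask = vals >= tau
    if kept_mask.sum() < min_atoms:
        order = np.argsort(vals)[::-1]
        keep_n = min(min_atoms, idx.size)
        kept = tuple(int(i) for i in np.sort(idx[order[:keep_n]]))
    else:
        kept = tuple(int(i) for i in idx[kept_mask])
    return RefinedDictionary(
        initial=boundary,
        kept=kept,
        tau=tau,
        K=float(K),
        bc_values={int(i): float(v) for i, v in zip(idx, vals)},
    )
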