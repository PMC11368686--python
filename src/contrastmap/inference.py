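"""Spatial predictions from encoder representations.

Given representations of query (SC) and reference (ST) cells, this module
derives: cosine-similarity neighbor predictions among the query cells,
pseudo-space coordinates by metric MDS on 1 - cosine dissimilarities, a
weighted SC->ST similarity that optionally smooths over predicted SC
neighbors, hard coordinate assignment by maximum weighted similarity, an
entropy-based confidence score per assignment, and a per-gene sensitivity
(contribution) table for the encoder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .contrastive import EncoderState, build_spatial_knn, encode
from .data_io import ExpressionProfile, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class SimilarityMatrix:
    values: np.ndarray
    row_ids: Optional[np.ndarray] = None
    col_ids: Optional[np.ndarray] = None


@dataclass
class MappingResult:
    """Per-query-cell reference assignment with coordinates and confidence."""

    assigned_st_index: np.ndarray
    coords: np.ndarray
    confidence: Optional[np.ndarray] = None
    weighted_similarity: Optional[np.ndarray] = None


@dataclass
class GeneContributionTable:
    values: np.ndarray  # n_cells x n_genes, non-negative
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    epsilon: float = 0.01


def _normalize_rows(X: np.ndarray, what: str, ids=None) -> np.ndarray:
    X = np.asarray(X, float)
    norms = np.linalg.norm(X, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        name = ids[zero[0]] if ids is not None else zero[0]
        raise ValidationError(f"zero-norm {what} row for cell {name!r}")
    return X / norms[:, None]


def cosine_similarity_matrix(A: np.ndarray, B: np.ndarray,
                             row_ids=None, col_ids=None) -> SimilarityMatrix:
    """Pairwise cosine similarities between the rows of A and B."""
    A = _normalize_rows(A, "representation", row_ids)
    B = _normalize_rows(B, "representation", col_ids)
    if A.shape[1] != B.shape[1]:
        raise ValidationError("representation dimensions differ")
    values = np.clip(A @ B.T, -1.0, 1.0)
    return SimilarityMatrix(values=values, row_ids=row_ids, col_ids=col_ids)


def predict_neighbors(reps: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k most cosine-similar cells per cell (self excluded).

    Ties are broken toward the lower index; row order is descending
    similarity.
    """
    reps = np.asarray(reps, float)
    n = reps.shape[0]
    if k >= n:
        raise ValidationError(f"k={k} must be smaller than n={n}")
    sim = cosine_similarity_matrix(reps, reps).values
    np.fill_diagonal(sim, -np.inf)
    return np.argsort(-sim, axis=1, kind="stable")[:, :k]


def mds_embed(reps: np.ndarray, seed: int) -> np.ndarray:
    """Pseudo-space coordinates by metric MDS on 1 - cosine similarity."""
    from sklearn.manifold import MDS

    reps = np.asarray(reps, float)
    if reps.shape[0] < 3:
        raise ValidationError("MDS embedding needs at least 3 cells")
    sim = cosine_similarity_matrix(reps, reps).values
    diss = 1.0 - sim
    np.fill_diagonal(diss, 0.0)
    if not np.isfinite(diss).all():
        raise ValidationError("non-finite dissimilarities")
    mds = MDS(
        n_components=2,
        metric="precomputed",
        metric_mds=True,
        n_init=1,
        init="random",
        random_state=seed,
    )
    return mds.fit_transform(diss)


def weighted_similarity(sc_reps: np.ndarray, st_reps: np.ndarray,
                        K: int = 1) -> np.ndarray:
    """Neighbor-smoothed SC->ST similarity.

    s_{i,j} = cos(R_i, R_j)
              + (1/K) * sum_k exp(-(1 - cos(R_i, R_k))^2) * cos(R_k, R_j)

    where k runs over the K nearest SC neighbors of cell i under SC-SC
    cosine similarity, the cell itself ranking first. K=1 therefore uses
    only the cell itself and reduces to twice the plain cosine similarity,
    leaving the per-row argmax unchanged.
    """
    sc_reps = np.asarray(sc_reps, float)
    n_sc = sc_reps.shape[0]
    if K < 1 or K > n_sc:
        raise ValidationError(f"K={K} must be in [1, n_sc={n_sc}]")
    cos_st = cosine_similarity_matrix(sc_reps, st_reps).values
    cos_sc = cosine_similarity_matrix(sc_reps, sc_reps).values
    ranking = cos_sc.copy()
    np.fill_diagonal(ranking, np.inf)  # the cell itself always ranks first
    nbr = np.argsort(-ranking, axis=1, kind="stable")[:, :K]
    w = np.exp(-(1.0 - np.take_along_axis(cos_sc, nbr, axis=1)) ** 2)
    smooth = np.einsum("ik,ikj->ij", w, cos_st[nbr]) / K
    return cos_st + smooth


def map_to_reference(S: np.ndarray, st_coords: np.ndarray) -> MappingResult:
    """Assign each query cell the reference location of its max similarity.

    Ties resolve to the lower reference index; several query cells may map
    to one location (cell clumping).
    """
    S = np.asarray(S, float)
    st_coords = np.asarray(st_coords, float)
    if st_coords.shape[0] == 0:
        raise ValidationError("empty reference")
    if not np.isfinite(S).all():
        raise ValidationError("similarity matrix contains NaN/inf")
    if S.shape[1] != st_coords.shape[0]:
        raise ValidationError("similarity columns do not match reference size")
    assigned = np.argmax(S, axis=1)
    row_max = S[np.arange(S.shape[0]), assigned]
    n_tied = int(((S == row_max[:, None]).sum(axis=1) > 1).sum())
    if n_tied:
        logger.info("%d cells had tied maxima; lower index chosen", n_tied)
    return MappingResult(
        assigned_st_index=assigned,
        coords=st_coords[assigned].copy(),
        weighted_similarity=S,
    )


def confidence_scores(S: np.ndarray, st_coords: np.ndarray,
                      n_top: int = 20, m_exclude: int = 80) -> np.ndarray:
    """Entropy-based assignment confidence in [0, 1] per query cell.

    For each cell, up to ``n_top`` reference locations are greedily chosen
    in descending similarity, skipping any location within the spatial
    ``m_exclude``-NN of an already chosen one (mutual exclusion), so the
    chosen locations represent distinct spatial modes. Softmax over their
    similarities gives probabilities, whose Shannon entropy H (natural log)
    is normalized across cells: C = 1 - H / max(H). A cell with fewer than
    two selectable locations gets NaN and is flagged in the log.
    """
    S = np.asarray(S, float)
    st_coords = np.asarray(st_coords, float)
    n_st = st_coords.shape[0]
    if n_top >= n_st:
        raise ValidationError(f"n_top={n_top} must be below n_st={n_st}")
    if m_exclude >= n_st:
        raise ValidationError(f"m_exclude={m_exclude} must be below n_st={n_st}")
    graph = build_spatial_knn(st_coords, m_exclude)
    nbr = graph.neighbor_idx
    entropies = np.full(S.shape[0], np.nan)
    for i in range(S.shape[0]):
        order = np.argsort(-S[i], kind="stable")
        blocked = np.zeros(n_st, dtype=bool)
        selected_mask = np.zeros(n_st, dtype=bool)
        selected = []
        for cand in order:
            if blocked[cand] or selected_mask[nbr[cand]].any():
                continue
            selected.append(cand)
            selected_mask[cand] = True
            blocked[nbr[cand]] = True
            if len(selected) == n_top:
                break
        if len(selected) < 2:
            logger.warning("cell %d: fewer than 2 selectable locations", i)
            continue
        s = S[i, selected]
        p = np.exp(s - s.max())
        p /= p.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.sum(np.where(p > 0, p * np.log(p), 0.0))
        entropies[i] = h
    finite = np.isfinite(entropies)
    conf = np.full_like(entropies, np.nan)
    if finite.any():
        h_max = entropies[finite].max()
        if h_max == 0:
            conf[finite] = 1.0
        else:
            conf[finite] = 1.0 - entropies[finite] / h_max
    return conf


def gene_contribution(state: EncoderState, profile: ExpressionProfile,
                      epsilon: float = 0.01) -> GeneContributionTable:
    """Per-gene sensitivity of the encoder representation.

    C_{i,j} = ||R_i - R_i^j||_2 / epsilon, where R_i^j is the
    representation after adding ``epsilon`` to gene j of cell i only. A
    larger value means gene j moves cell i's representation more, i.e.,
    contributes more spatial signal.
    """
    if epsilon <= 0:
        raise ValidationError("epsilon must be positive")
    base = encode(state, profile)
    n_cells, n_genes = profile.values.shape
    contrib = np.empty((n_cells, n_genes))
    for j in range(n_genes):
        perturbed = profile.values.copy()
        perturbed[:, j] += epsilon
        reps = state.network.forward(perturbed, train=False)
        contrib[:, j] = np.linalg.norm(reps - base, axis=1) / epsilon
    return GeneContributionTable(
        values=contrib,
        gene_ids=profile.gene_ids.copy(),
        cell_ids=profile.cell_ids.copy(),
        epsilon=epsilon,
    )
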