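"""Orthogonal Procrustes alignment of embedding models onto an anchor.

Every word2vec training run lands in its own arbitrary coordinate space, so
vectors from different models cannot be compared directly.  The orthogonal
Procrustes solution Q = UVᵀ (from the SVD XᵀY = UΣVᵀ) is the rotation (or
rotoreflection) minimizing ‖XQ − Y‖_F over orthogonal matrices; rotating each
model onto a single anchor model puts the whole ensemble into one shared
space.  Because Q is orthogonal, all within-model cosine distances — and
hence every token's local neighborhood — are preserved exactly.

The rotation is fit on the vocabulary shared with the anchor but applied to
the model's full vocabulary, so tokens absent from the anchor stay covered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy.linalg import orthogonal_procrustes

from .embedding import EmbeddingModel, YearEnsemble

logger = logging.getLogger(__name__)

__all__ = [
    "Rotation",
    "AlignedEnsemble",
    "shared_vocabulary",
    "procrustes_rotation",
    "align_model",
    "align_all",
]


@dataclass(frozen=True)
class Rotation:
    """A dim × dim orthogonal matrix Q, applied to row vectors as X @ Q."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        q = self.matrix
        if q.ndim != 2 or q.shape[0] != q.shape[1]:
            raise ValueError("rotation matrix must be square")

    def apply(self, vectors: np.ndarray) -> np.ndarray:
        return vectors @ self.matrix

    def orthogonality_error(self) -> float:
        q = self.matrix
        return float(np.linalg.norm(q.T @ q - np.eye(q.shape[0]), "fro"))


@dataclass
class AlignedEnsemble(YearEnsemble):
    """A year's replicate models after rotation into the anchor space."""

    anchor_id: tuple[int, int] = (0, 0)  # (year, replicate)


def shared_vocabulary(a: EmbeddingModel, b: EmbeddingModel) -> list[str]:
    """Sorted intersection of two models' vocabularies (deterministic order).

    Procrustes needs row-matched matrices; a tiny intersection leaves the
    rotation under-determined (warned below dim, error below 2).
    """
    shared = sorted(set(a.vocab) & set(b.vocab))
    if len(shared) < 2:
        raise ValueError(
            f"models share only {len(shared)} token(s); rotation impossible"
        )
    if len(shared) < a.dim:
        logger.warning(
            "shared vocabulary (%d) smaller than dim (%d): rotation under-determined",
            len(shared),
            a.dim,
        )
    return shared


def procrustes_rotation(X: np.ndarray, Y: np.ndarray) -> Rotation:
    """Orthogonal matrix Q minimizing ‖XQ − Y‖_F (closed form via SVD)."""
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.shape != Y.shape or X.ndim != 2:
        raise ValueError(f"shape mismatch: {X.shape} vs {Y.shape}")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 matched rows")
    q, _scale = orthogonal_procrustes(X, Y)
    s = np.linalg.svd(X.T @ Y, compute_uv=False)
    if s[-1] <= s[0] * 1e-12 or s[0] == 0.0:
        logger.warning("procrustes_rotation: rank-deficient cross-covariance; "
                       "solution not unique")
    return Rotation(matrix=q)


def align_model(model: EmbeddingModel, anchor: EmbeddingModel) -> EmbeddingModel:
    """Rotate one model into the anchor's space.

    Fit on the shared vocabulary, applied to every row of the model.
    """
    shared = shared_vocabulary(model, anchor)
    idx_m = [model.index(t) for t in shared]
    idx_a = [anchor.index(t) for t in shared]
    rot = procrustes_rotation(model.vectors[idx_m], anchor.vectors[idx_a])
    # rotate in float64, return in the model's own storage dtype
    rotated = rot.apply(model.vectors.astype(np.float64)).astype(model.vectors.dtype)
    return replace(model, vectors=rotated, _index=dict(model._index))


def align_all(
    ensembles: Mapping[int, YearEnsemble], anchor: tuple[int, int] | None = None
) -> dict[int, AlignedEnsemble]:
    """Align every replicate of every year onto one anchor model.

    The default anchor is replicate 0 of the latest year.  The anchor model
    itself is passed through unchanged.  Models sharing fewer than 2 tokens
    with the anchor are excluded (logged), not silently misaligned.
    """
    if not ensembles:
        return {}
    if anchor is None:
        anchor = (max(ensembles), 0)
    anchor_year, anchor_rep = anchor
    try:
        anchor_model = ensembles[anchor_year].models[anchor_rep]
    except (KeyError, IndexError):
        raise ValueError(f"anchor model {anchor} not found")

    aligned: dict[int, AlignedEnsemble] = {}
    for year in sorted(ensembles):
        models = []
        for m in ensembles[year].models:
            if m.year == anchor_year and m.replicate == anchor_rep:
                models.append(m)
                continue
            try:
                models.append(align_model(m, anchor_model))
            except ValueError as exc:
                logger.warning(
                    "excluding model (year=%d, replicate=%d): %s",
                    m.year,
                    m.replicate,
                    exc,
                )
        if models:
            aligned[year] = AlignedEnsemble(
                year=year, models=models, anchor_id=anchor
            )
    return aligned
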