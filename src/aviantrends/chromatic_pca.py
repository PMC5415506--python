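"""Per-species PCA of chromatic coordinates.

Each species' specimens occupy a cloud in (x, y, z) jnd space; a principal
component analysis of the covariance matrix (no rescaling, so scores stay
in jnd units) condenses that cloud to a single colour score per specimen.
The sign of PC1 is anchored so that it correlates positively with
carotenoid chroma: higher PC1 means more intensely carotenoid-coloured
plumage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .visual_model import ChromaticCoords

__all__ = ["PcaSummary", "fit_species_pca"]


@dataclass(frozen=True)
class PcaSummary:
    """PCA of one species' chromatic cloud.

    ``loadings`` columns are the orthonormal principal axes (descending
    eigenvalue order); ``variance_explained`` the matching proportions;
    ``scores`` the PC1 value of each specimen in jnd units after sign
    anchoring; ``sign_anchor`` the Pearson correlation of the anchored PC1
    scores with carotenoid chroma (non-negative by construction).
    """

    loadings: np.ndarray
    variance_explained: np.ndarray
    scores: np.ndarray
    sign_anchor: float


def fit_species_pca(
    coords: Sequence[ChromaticCoords] | np.ndarray,
    chroma: Sequence[float],
) -> PcaSummary:
    """Covariance-matrix PCA of xyz coordinates with chroma sign anchoring.

    Requires at least three specimens and non-degenerate variance.  Scores
    are centred within the species (the PCA is fitted per species, sexes
    pooled).  If the correlation of raw PC1 scores with carotenoid chroma
    is negative, every score and the first axis are negated.
    """
    if isinstance(coords, np.ndarray):
        xyz = np.asarray(coords, dtype=float)
    else:
        xyz = np.array([c.as_array() for c in coords])
    chroma = np.asarray(chroma, dtype=float)
    if xyz.ndim != 2 or xyz.shape[1] != 3:
        raise ValueError("coords must be n x 3")
    if xyz.shape[0] != chroma.shape[0]:
        raise ValueError("coords and chroma must be aligned by specimen")
    n = xyz.shape[0]
    if n < 3:
        raise ValueError(f"PCA needs at least 3 specimens, got {n}")

    centred = xyz - xyz.mean(axis=0)
    cov = centred.T @ centred / (n - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval, kind="stable")[::-1]  # stable tie-break
    eigval, eigvec = eigval[order], eigvec[:, order]
    total = eigval.sum()
    if total <= 0:
        raise ValueError("zero chromatic variance: PCA undefined")
    eigval = np.clip(eigval, 0.0, None)

    scores = centred @ eigvec[:, 0]
    anchor = _safe_corr(scores, chroma)
    if anchor < 0:
        scores = -scores
        eigvec = eigvec.copy()
        eigvec[:, 0] = -eigvec[:, 0]
        anchor = -anchor
    return PcaSummary(
        loadings=eigvec,
        variance_explained=eigval / total,
        scores=scores,
        sign_anchor=float(anchor),
    )


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])
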