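"""Centered PCA via SVD with a reproducible sign convention.

Scores are U*S (sample coordinates); each score column's sign is fixed so
that its largest-magnitude entry is positive, making results independent of
the linear-algebra backend's arbitrary sign choices.
"""

from __future__ import annotations

import numpy as np


def svd_scores(x: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """PCA sample scores of an already column-centered matrix.

    Returns ``(scores, explained_variance)`` where scores is samples x n and
    explained_variance is the fraction of total variance per retained
    component (computed against all components, so the retained fractions
    sum to at most 1).

    Raises
    ------
    ValueError
        If ``n`` exceeds the numerical rank of ``x``.
    """
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    tol = s[0] * max(x.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    if n > rank:
        raise ValueError(f"requested PCs exceed rank: n={n}, rank={rank}")
    scores = u[:, :n] * s[:n]
    scores = fix_signs(scores)
    total = float(np.sum(s**2))
    ev = (s[:n] ** 2) / total if total > 0 else np.zeros(n)
    return scores, ev


def fix_signs(scores: np.ndarray) -> np.ndarray:
    """Flip columns so each column's largest-magnitude entry is positive."""
    scores = scores.copy()
    for j in range(scores.shape[1]):
        col = scores[:, j]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            scores[:, j] = -col
    return scores
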