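"""Collapse the seven descriptors into a single structural-importance index.

A principal coordinate ordination (classical metric scaling) of the
Euclidean distances between per-host descriptor rows reduces the
seven-dimensional descriptor space to its leading axis.  Axis-1 scores are
shifted so their minimum is zero and square-rooted; the result is the
per-species structural-contribution index.  On Euclidean distances PCO is
equivalent to principal components, which the test-suite exploits as an
independent cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .species_descriptors import DescriptorTable

logger = logging.getLogger("reefguest")


@dataclass
class PcoResult:
    scores: np.ndarray          # n_samples x n_positive_axes
    eigenvalues: np.ndarray     # positive eigenvalues, descending
    variance_explained: np.ndarray  # percentage per positive axis
    hosts: list[str]
    dropped_columns: list[str]


@dataclass
class ImportanceScores:
    """Axis-1 ordination scores transformed into the importance index."""

    hosts: list[str]
    pco1_raw: np.ndarray
    pco1_shifted: np.ndarray
    importance: np.ndarray
    variance_explained_axis1: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pco1_raw": self.pco1_raw,
                "pco1_shifted": self.pco1_shifted,
                "importance": self.importance,
            },
            index=pd.Index(self.hosts, name="host_species"),
        )


def pco(
    descriptors: DescriptorTable | pd.DataFrame,
    standardize: bool = False,
) -> PcoResult:
    """Principal coordinate ordination of the descriptor rows.

    Euclidean distances between descriptor rows (z-scored per column when
    ``standardize``), Gower double-centering, eigendecomposition; axis
    scores are eigenvector * sqrt(eigenvalue), and percent variance is each
    positive eigenvalue over the sum of positive eigenvalues.  Axis 1 is
    sign-oriented so that its correlation with degree is positive.
    """
    df = descriptors.table if isinstance(descriptors, DescriptorTable) else descriptors
    if len(df) < 2:
        raise ValueError("PCO needs at least 2 hosts")
    if df.isna().any().any():
        raise ValueError("descriptor table contains missing cells")
    x = df.to_numpy(dtype=float)
    cols = list(df.columns)
    dropped: list[str] = []
    if standardize:
        sd = x.std(axis=0, ddof=0)
        keep = sd > 0
        for name, k in zip(cols, keep):
            if not k:
                dropped.append(name)
                logger.warning("constant descriptor column %r dropped", name)
        x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
        cols = [c for c, k in zip(cols, keep) if k]
    # squared Euclidean distances -> Gower double-centering
    sq = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    n = sq.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ sq @ j
    evals, evecs = scipy.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # Euclidean input cannot produce genuinely negative eigenvalues
    tol = max(1e-8, 1e-10 * max(abs(evals[0]), 1.0))
    if evals[-1] < -tol:
        raise AssertionError(
            f"negative PCoA eigenvalue {evals[-1]} from Euclidean distances"
        )
    pos = evals > tol
    evals = evals[pos]
    scores = evecs[:, pos] * np.sqrt(evals)
    var_pct = 100.0 * evals / evals.sum()
    # orient axis 1 toward increasing degree
    if "degree" in df.columns:
        deg = df["degree"].to_numpy(dtype=float)
        if np.corrcoef(scores[:, 0], deg)[0, 1] < 0:
            scores[:, 0] = -scores[:, 0]
    return PcoResult(
        scores=scores,
        eigenvalues=evals,
        variance_explained=var_pct,
        hosts=list(df.index),
        dropped_columns=dropped,
    )


def importance_transform(
    pco1_raw: np.ndarray,
    hosts: list[str] | None = None,
    variance_explained_axis1: float = float("nan"),
) -> ImportanceScores:
    """Zero-shift and square-root the axis-1 scores.

    shifted = raw - min(raw); importance = sqrt(shifted).  A monotone
    transform, so the importance ranking equals the axis-1 ranking.
    """
    raw = np.asarray(pco1_raw, dtype=float)
    if not np.isfinite(raw).all():
        raise ValueError("axis-1 scores must be finite")
    shifted = raw - raw.min()
    return ImportanceScores(
        hosts=hosts if hosts is not None else [str(i) for i in range(len(raw))],
        pco1_raw=raw,
        pco1_shifted=shifted,
        importance=np.sqrt(shifted),
        variance_explained_axis1=float(variance_explained_axis1),
    )


def importance_index(
    descriptors: DescriptorTable,
    standardize: bool = False,
) -> ImportanceScores:
    """Full pipeline: PCO axis 1 -> zero-shift -> square root."""
    res = pco(descriptors, standardize=standardize)
    return importance_transform(
        res.scores[:, 0],
        hosts=res.hosts,
        variance_explained_axis1=float(res.variance_explained[0]),
    )
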