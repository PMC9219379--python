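"""Compositional ordination and community-level testing.

Count profiles are compositions: only relative information is meaningful.
This module provides the centred log-ratio (clr) transform, principal
component analysis in clr space (so that score-space Euclidean distances
are Aitchison distances), a permutation PERMANOVA implemented from first
principles on the Gower-centred inner-product matrix, Bray-Curtis
dissimilarity, and the per-subject adjacent-site similarity summaries
(Bray-Curtis + Spearman) along the CCT -> EMT -> FTT -> OCT axis.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations as _all_permutations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .profiles_io import SITES, AbundanceTable, to_relative_abundance

logger = logging.getLogger("tractome")

#: Adjacent site pairs along the reproductive tract, lower to upper.
ADJACENT_PAIRS = (("CCT", "EMT"), ("EMT", "FTT"), ("FTT", "OCT"))


@dataclass
class ClrMatrix:
    """clr-transformed abundance matrix; every row sums to zero."""

    values: np.ndarray
    pseudocount: float
    zero_strategy: str
    sample_ids: list[str] = field(default_factory=list)
    taxon_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        sums = np.abs(self.values.sum(axis=1))
        if sums.size and sums.max() > 1e-9 * max(1.0, np.abs(self.values).max()):
            raise ValueError("clr rows must sum to zero")


@dataclass(frozen=True)
class PermanovaResult:
    """One factor's row of a PERMANOVA decomposition."""

    factor: str
    ss: float
    df: int
    pseudo_F: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int | None


@dataclass(frozen=True)
class AdjacentSimilarity:
    """Similarity of one subject's two adjacent-site profiles."""

    subject_id: str
    pair: str
    bray_curtis: float
    spearman_rho: float


@dataclass
class PcaResult:
    scores: np.ndarray
    explained: np.ndarray  # variance fractions, non-increasing
    sample_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# clr / Aitchison geometry
# ---------------------------------------------------------------------------


def clr_transform(
    table: AbundanceTable | np.ndarray,
    zero_strategy: str = "pseudocount",
    pseudocount: float = 1.0,
) -> ClrMatrix:
    """Centred log-ratio transform of a count (or composition) matrix.

    ``pseudocount`` strategy: row i,j -> ln((c_ij + k) / g_i) with g_i the
    geometric mean of the shifted row; this handles zeros directly on
    counts. ``multiplicative`` strategy: rows are first closed to
    proportions, zeros replaced by 0.65 x the row's smallest nonzero
    proportion, nonzeros rescaled to preserve the unit sum, then clr'd —
    the usual multiplicative zero replacement on proportions.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if isinstance(table, AbundanceTable):
        counts = table.counts.astype(float)
        sample_ids = table.sample_ids
        taxon_names = table.taxon_names
    else:
        counts = np.asarray(table, dtype=float)
        sample_ids, taxon_names = [], []
    if counts.size == 0:
        raise ValueError("empty table")
    if zero_strategy == "pseudocount":
        x = counts + pseudocount
    elif zero_strategy == "multiplicative":
        totals = counts.sum(axis=1, keepdims=True)
        if (totals == 0).any():
            raise ValueError("zero-sum row; cannot close to proportions")
        props = counts / totals
        x = props.copy()
        for i in range(x.shape[0]):
            row = x[i]
            zeros = row == 0
            if zeros.any():
                if zeros.all():
                    raise ValueError("all-zero row")
                delta = 0.65 * row[~zeros].min()
                row[zeros] = delta
                row[~zeros] *= 1.0 - delta * zeros.sum()
    else:
        raise ValueError(f"unknown zero strategy {zero_strategy!r}")
    logx = np.log(x)
    values = logx - logx.mean(axis=1, keepdims=True)
    return ClrMatrix(
        values=values,
        pseudocount=pseudocount,
        zero_strategy=zero_strategy,
        sample_ids=sample_ids,
        taxon_names=taxon_names,
    )


def aitchison_distance_matrix(clr: ClrMatrix) -> np.ndarray:
    """Pairwise Euclidean distances between clr rows (Aitchison distance)."""
    return squareform(pdist(clr.values, metric="euclidean"))


def aitchison_pca(clr: ClrMatrix) -> PcaResult:
    """PCA of the column-centred clr matrix via singular value
    decomposition. Scores over all components preserve the pairwise
    Aitchison distances exactly (column centring does not change row
    differences, and the rotation is orthogonal)."""
    n = clr.values.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    centred = clr.values - clr.values.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    scores = u * s
    var = s**2
    total = var.sum()
    explained = var / total if total > 0 else np.zeros_like(var)
    return PcaResult(scores=scores, explained=explained, sample_ids=clr.sample_ids)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def _gower_center(dist: np.ndarray) -> np.ndarray:
    a = -0.5 * dist**2
    n = dist.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return j @ a @ j


def _hat(design: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection matrix onto the column space of ``design`` and its rank.

    Dummy-coded designs with an intercept are rank-deficient by
    construction, so the projector is built from the SVD's leading
    singular vectors rather than a QR factorisation.
    """
    u, s, _ = np.linalg.svd(design, full_matrices=False)
    tol = s.max() * max(design.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    q = u[:, :rank]
    return q @ q.T, rank


def _one_hot(labels: Sequence) -> np.ndarray:
    labels = np.asarray(labels)
    levels = np.unique(labels)
    return (labels[:, None] == levels[None, :]).astype(float)


def permanova(
    dist: np.ndarray,
    factors: Mapping[str, Sequence],
    n_perm: int = 999,
    seed: int | None = 0,
    permutations: str = "sampled",
) -> list[PermanovaResult]:
    """Permutational multivariate ANOVA on a distance matrix.

    The squared-distance matrix is Gower-centred to an inner-product
    matrix G whose trace is the total sum of squares; each factor's SS is
    the trace of G projected onto the increment of its design hat matrix
    (sequential decomposition in the order the factors are given, as in
    by-terms ANOVA). pseudo-F = (SS_f / df_f) / (SS_res / df_res);
    significance comes from permuting sample labels: p = (#{F_perm >=
    F_obs} + 1) / (n_perm + 1). With ``permutations="exact"`` (n <= 9) all
    n! relabelings are enumerated and p is the exact tail fraction.

    ``factors`` maps factor name -> per-sample labels; each factor needs
    at least two levels.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.abs(np.diag(d)).max() > 1e-10:
        raise ValueError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    if not factors:
        raise ValueError("at least one factor required")
    names = list(factors)
    label_arrays = []
    for name in names:
        labels = np.asarray(factors[name])
        if labels.shape[0] != n:
            raise ValueError(f"factor {name!r} has {labels.shape[0]} labels for {n} samples")
        if np.unique(labels).size < 2:
            raise ValueError(f"factor {name!r} has fewer than 2 levels")
        label_arrays.append(labels)

    g = _gower_center(d)
    ss_total = float(np.trace(g))

    # Sequential hat matrices: intercept, then each factor added in order.
    designs = [np.ones((n, 1))]
    for labels in label_arrays:
        designs.append(np.hstack([designs[-1], _one_hot(labels)]))
    hats, ranks = zip(*(_hat(x) for x in designs))
    increments = [hats[k + 1] - hats[k] for k in range(len(names))]
    dfs = [ranks[k + 1] - ranks[k] for k in range(len(names))]
    resid_proj = np.eye(n) - hats[-1]
    df_res = n - ranks[-1]
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    def stat_all(gp: np.ndarray) -> tuple[np.ndarray, float]:
        ss = np.array([float((inc * gp).sum()) for inc in increments])
        ss_res = float((resid_proj * gp).sum())
        return ss, ss_res

    ss_obs, ss_res_obs = stat_all(g)
    f_obs = (ss_obs / dfs) / (ss_res_obs / df_res)
    # permuted statistics equal to the observed one (e.g. permutations that
    # preserve the grouping) must count as ties despite rounding
    f_tol = np.maximum(1e-12, 1e-9 * np.abs(f_obs))

    if permutations == "exact":
        if n > 9:
            raise ValueError("exact enumeration supported for n <= 9 only")
        count = np.zeros(len(names))
        total = 0
        for perm in _all_permutations(range(n)):
            gp = g[np.ix_(perm, perm)]
            ss_p, ss_res_p = stat_all(gp)
            f_p = (ss_p / dfs) / (ss_res_p / df_res)
            count += f_p >= f_obs - f_tol
            total += 1
        pvals = count / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(names))
        idx = np.arange(n)
        for _ in range(n_perm):
            perm = rng.permutation(idx)
            gp = g[np.ix_(perm, perm)]
            ss_p, ss_res_p = stat_all(gp)
            f_p = (ss_p / dfs) / (ss_res_p / df_res)
            exceed += f_p >= f_obs - f_tol
        pvals = (exceed + 1.0) / (n_perm + 1.0)
        n_used = n_perm

    return [
        PermanovaResult(
            factor=names[k],
            ss=float(ss_obs[k]),
            df=int(dfs[k]),
            pseudo_F=float(f_obs[k]),
            r_squared=float(ss_obs[k] / ss_total),
            p_value=float(pvals[k]),
            n_permutations=int(n_used),
            seed=seed,
        )
        for k in range(len(names))
    ]


# ---------------------------------------------------------------------------
# Bray-Curtis and adjacent-site similarity
# ---------------------------------------------------------------------------


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i); 0 for identical
    profiles, 1 for disjoint supports."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = (x + y).sum()
    if denom <= 0:
        raise ValueError("Bray-Curtis undefined for two empty profiles")
    return float(np.abs(x - y).sum() / denom)


def bray_curtis_matrix(table: AbundanceTable | np.ndarray) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarities between sample rows.

    An :class:`AbundanceTable` is converted to relative abundances first;
    a plain matrix is used as given (rows must be non-negative with
    positive sums).
    """
    if isinstance(table, AbundanceTable):
        mat = to_relative_abundance(table)
    else:
        mat = np.asarray(table, dtype=float)
        if (mat < 0).any():
            raise ValueError("rows must be non-negative")
        if (mat.sum(axis=1) <= 0).any():
            raise ValueError("every row must have a positive sum")
    n = mat.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(mat[i + 1 :] - mat[i]).sum(axis=1)
        tot = (mat[i + 1 :] + mat[i]).sum(axis=1)
        out[i, i + 1 :] = diff / tot
    return out + out.T


def adjacent_similarity(
    table: AbundanceTable, shared_only: bool = False
) -> list[AdjacentSimilarity]:
    """Per-subject similarity of adjacent-site profiles.

    For every subject and each adjacent pair (CCT-EMT, EMT-FTT, FTT-OCT)
    with both sites sampled, returns the Bray-Curtis dissimilarity of the
    two relative-abundance profiles and the Spearman correlation over the
    union of taxa detected in either sample (zeros included, ties
    mid-ranked). ``shared_only=True`` restricts Spearman to taxa detected
    in both samples. Subjects lacking a pair are skipped with a log entry.
    """
    ra = to_relative_abundance(table)
    index = table.subject_site_index()
    subjects = sorted({s.subject_id for s in table.samples})
    out: list[AdjacentSimilarity] = []
    for subject in subjects:
        for a, b in ADJACENT_PAIRS:
            ia = index.get((subject, a))
            ib = index.get((subject, b))
            if ia is None or ib is None:
                logger.debug("subject %s lacks pair %s-%s; skipped", subject, a, b)
                continue
            va, vb = ra[ia], ra[ib]
            bc = bray_curtis(va, vb)
            union = (va > 0) | (vb > 0)
            if shared_only:
                union = (va > 0) & (vb > 0)
            if union.sum() < 2:
                rho = float("nan")
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # constant input -> nan
                    rho = float(stats.spearmanr(va[union], vb[union]).statistic)
                if math.isnan(rho):  # constant vector (e.g. identical ranks)
                    rho = 1.0 if np.allclose(va[union], vb[union]) else float("nan")
            out.append(
                AdjacentSimilarity(
                    subject_id=subject,
                    pair=f"{a}-{b}",
                    bray_curtis=bc,
                    spearman_rho=rho,
                )
            )
    return out
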