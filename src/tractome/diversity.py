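"""Rarefaction, alpha diversity, and the rank tests used to compare it.

Alpha diversity is computed on counts rarefied to a common depth (default
6172 reads per sample, the floor set by the lowest valid-read sample in
the cohort this pipeline was designed around). Four measures are reported
per sample: observed richness, Shannon index (natural log), inverse
Simpson, and the bias-corrected Chao1 richness estimator.

Two-group comparisons use the Wilcoxon rank-sum (Mann-Whitney) test;
multi-group comparisons use Dunn's post hoc test on joint ranks with a
configurable multiplicity adjustment (Benjamini-Hochberg by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .profiles_io import AbundanceTable

logger = logging.getLogger("tractome")

DEFAULT_RAREFACTION_DEPTH = 6172


@dataclass(frozen=True)
class AlphaResult:
    """Alpha-diversity measures for one sample.

    Invariants: observed <= chao1; shannon <= ln(observed); and
    1 <= inv_simpson <= observed whenever the sample has any reads.
    """

    sample_id: str
    observed: int
    shannon: float
    inv_simpson: float
    chao1: float


def rarefy(
    table: AbundanceTable,
    depth: int | str = DEFAULT_RAREFACTION_DEPTH,
    seed: int | None = 0,
) -> AbundanceTable:
    """Rarefy every sample to ``depth`` reads by uniform subsampling
    without replacement (multivariate hypergeometric draw per sample).

    ``depth="auto"`` uses the smallest sample total, so no sample is
    dropped. Samples whose total is below a fixed depth are dropped with a
    warning; a sample exactly at depth is returned unchanged. The draw is
    fully determined by ``seed``.
    """
    totals = table.counts.sum(axis=1)
    if depth == "auto":
        depth = int(totals.min())
    depth = int(depth)
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    keep = totals >= depth
    if not keep.any():
        raise ValueError(
            f"all {table.n_samples} samples are below rarefaction depth {depth}"
        )
    for i in np.flatnonzero(~keep):
        logger.warning(
            "sample %s dropped at rarefaction: %d < %d reads",
            table.samples[i].sample_id,
            totals[i],
            depth,
        )
    sub = table.select_samples(keep)
    rng = np.random.default_rng(seed)
    out = np.empty_like(sub.counts)
    for i in range(sub.n_samples):
        row = sub.counts[i]
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return AbundanceTable(
        counts=out, taxa=list(sub.taxa), samples=list(sub.samples),
        rank_level=sub.rank_level,
    )


def alpha_diversity(
    counts: np.ndarray, sample_id: str = "", bias_corrected_chao1: bool = True
) -> AlphaResult:
    """Alpha-diversity measures for one count vector.

    observed = number of taxa with a positive count; shannon =
    -sum p_i ln p_i; inv_simpson = 1 / sum p_i^2; chao1 = S +
    F1(F1-1)/(2(F2+1)) with F1/F2 the singleton/doubleton counts (the
    bias-corrected form, defined even when no doubletons exist). Pass
    ``bias_corrected_chao1=False`` for the classical S + F1^2/(2 F2) form,
    which requires F2 > 0 when F1 > 0.
    """
    c = np.asarray(counts)
    if c.ndim != 1:
        raise ValueError("expected a single sample's count vector")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("sample has no reads; alpha diversity undefined")
    pos = c[c > 0]
    observed = int(pos.size)
    p = pos / total
    shannon = float(-(p * np.log(p)).sum())
    inv_simpson = float(1.0 / (p * p).sum())
    f1 = int((pos == 1).sum())
    f2 = int((pos == 2).sum())
    if bias_corrected_chao1:
        chao1 = observed + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    else:
        if f1 and not f2:
            raise ValueError(
                "classical Chao1 undefined with singletons but no doubletons; "
                "use the bias-corrected form"
            )
        chao1 = observed + (f1 * f1 / (2.0 * f2) if f2 else 0.0)
    return AlphaResult(
        sample_id=sample_id,
        observed=observed,
        shannon=shannon,
        inv_simpson=inv_simpson,
        chao1=float(chao1),
    )


def alpha_table(table: AbundanceTable, **kwargs) -> pd.DataFrame:
    """Per-sample alpha diversity as a tidy table."""
    rows = [
        alpha_diversity(table.counts[i], table.samples[i].sample_id, **kwargs)
        for i in range(table.n_samples)
    ]
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in rows],
            "observed": [r.observed for r in rows],
            "shannon": [r.shannon for r in rows],
            "inv_simpson": [r.inv_simpson for r in rows],
            "chao1": [r.chao1 for r in rows],
        }
    )


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when the pooled size is at most 12
    and there are no ties, otherwise the normal approximation with tie and
    continuity corrections. Returns (U statistic of ``x``, p-value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def adjust_pvalues(pvalues, method: str = "BH") -> np.ndarray:
    """Multiplicity adjustment: "BH" (Benjamini-Hochberg step-up),
    "bonferroni", or "none". Adjusted values are clipped at 1."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if method == "none" or m == 0:
        return p.copy()
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method != "BH":
        raise ValueError(f"unknown adjustment method {method!r}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def dunn_posthoc(
    groups: list, labels: list[str] | None = None, adjust: str = "BH"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dunn's post hoc test for all pairs of three or more groups.

    All values are ranked jointly (ties mid-ranked); for groups i, j the
    statistic is z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))
    with the tie term T = sum(t^3 - t) / (12(N - 1)) over tie-group sizes t.
    Two-sided p-values come from the standard normal and are adjusted
    across the pairs. Returns (z, adjusted p) as symmetric DataFrames.
    """
    if len(groups) < 3:
        raise ValueError(
            "Dunn's test needs >= 3 groups; use wilcoxon_rank_sum for two"
        )
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [a.size for a in arrays]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(arrays))
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    k = len(arrays)
    z = np.zeros((k, k))
    raw = []
    pairs = list(combinations(range(k), 2))
    for i, j in pairs:
        denom = math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        zij = (mean_ranks[i] - mean_ranks[j]) / denom if denom > 0 else 0.0
        z[i, j] = zij
        z[j, i] = -zij
        raw.append(2.0 * stats.norm.sf(abs(zij)))
    adj = adjust_pvalues(raw, method=adjust)
    pmat = np.ones((k, k))
    for (i, j), pv in zip(pairs, adj):
        pmat[i, j] = pmat[j, i] = pv
    zdf = pd.DataFrame(z, index=labels, columns=labels)
    pdf = pd.DataFrame(pmat, index=labels, columns=labels)
    return zdf, pdf


def compare_alpha_by(
    alpha: pd.DataFrame,
    table: AbundanceTable,
    by: str = "condition",
    adjust: str = "BH",
) -> pd.DataFrame:
    """Compare each alpha metric across the levels of a metadata factor.

    Two levels: Wilcoxon rank-sum per metric. Three or more (e.g. the four
    swab sites): Dunn's post hoc per metric, one row per site pair.
    """
    labels = {s.sample_id: getattr(s, by) for s in table.samples}
    grouped = alpha.assign(_level=[labels[s] for s in alpha["sample_id"]])
    levels = sorted(grouped["_level"].unique())
    metrics = ["observed", "shannon", "inv_simpson", "chao1"]
    rows = []
    if len(levels) < 2:
        raise ValueError(f"factor {by!r} has fewer than 2 levels")
    if len(levels) == 2:
        a, b = levels
        for metric in metrics:
            x = grouped.loc[grouped["_level"] == a, metric].to_numpy()
            y = grouped.loc[grouped["_level"] == b, metric].to_numpy()
            stat, p = wilcoxon_rank_sum(x, y)
            rows.append(
                {
                    "metric": metric,
                    "comparison": f"{a} vs {b}",
                    "test": "wilcoxon",
                    "statistic": stat,
                    "p_value": p,
                }
            )
    else:
        for metric in metrics:
            vecs = [
                grouped.loc[grouped["_level"] == lv, metric].to_numpy()
                for lv in levels
            ]
            zdf, pdf = dunn_posthoc(vecs, labels=levels, adjust=adjust)
            for a, b in combinations(levels, 2):
                rows.append(
                    {
                        "metric": metric,
                        "comparison": f"{a} vs {b}",
                        "test": "dunn",
                        "statistic": zdf.loc[a, b],
                        "p_value": pdf.loc[a, b],
                    }
                )
    return pd.DataFrame(rows)
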