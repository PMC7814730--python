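"""Interpretation of protein-target features.

DILI-enriched targets are found with a one-sided Wilcoxon rank-sum test
(higher values in the DILI class), Benjamini-Hochberg adjusted at FDR < 0.05.
Per-fold feature importances are aggregated by the median across the outer
train/test splits. Selected features are interpreted by over-representation
analysis (hypergeometric upper tail) against geneset collections on the full
feature list as background, scanning across importance-quantile cutoffs.

The exact rank-sum path enumerates every assignment of group membership to
midranks (valid under ties) and is used for small groups; two-valued columns
(binary activity calls) use the exact hypergeometric form of the permutation
distribution at any sample size; everything else falls back to the normal
approximation with tie correction and continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, erfc, sqrt

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import Geneset

#: Maximum total sample size for the exact (enumeration) rank-sum path.
EXACT_MAX_TOTAL = 20


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest rank down
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def rank_sum_greater(x_dili: np.ndarray, x_nodili: np.ndarray) -> float:
    """One-sided rank-sum p for higher values in the DILI group.

    Constant pooled samples give p = 1. Small samples (total ≤ 20) are tested
    by full enumeration over group assignments using midranks; larger samples
    use the tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x_dili, dtype=float)
    z = np.asarray(x_nodili, dtype=float)
    pooled = np.concatenate([x, z])
    if np.ptp(pooled) == 0:
        return 1.0
    n1, n2 = len(x), len(z)
    uniq = np.unique(pooled)
    if uniq.size == 2:
        # two-valued data: the rank sum is monotone in the count of high
        # values in the DILI group, so its permutation distribution is
        # exactly hypergeometric — exact at any sample size
        k_obs = int((x == uniq[1]).sum())
        k_total = int((pooled == uniq[1]).sum())
        return float(stats.hypergeom.sf(k_obs - 1, n1 + n2, k_total, n1))
    ranks = stats.rankdata(pooled)
    w_obs = ranks[:n1].sum()
    if n1 + n2 <= EXACT_MAX_TOTAL:
        total = n1 + n2
        count = 0
        n_comb = comb(total, n1)
        for idx in combinations(range(total), n1):
            if ranks[list(idx)].sum() >= w_obs - 1e-9:
                count += 1
        return count / n_comb
    # normal approximation with tie correction and continuity correction
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z_stat = (w_obs - mu - 0.5) / sqrt(var)
    return erfc(z_stat / sqrt(2)) / 2.0


@dataclass(frozen=True)
class EnrichmentResult:
    feature_name: str
    statistic: float  # rank sum of the DILI group
    p: float
    q: float
    enriched_in_dili: bool  # significant at q < 0.05 with higher DILI values


def wilcoxon_enrichment(
    values: np.ndarray,
    labels: np.ndarray,
    feature_names: list[str],
    fdr: float = 0.05,
) -> list[EnrichmentResult]:
    """Per-feature one-sided rank-sum enrichment with BH adjustment.

    `values` is compounds × features (binary calls or continuous
    probabilities both work — the test is rank-based); `labels` is the binary
    DILI vector. Constant features are emitted with p = 1, never dropped.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    if (labels == 1).sum() < 2 or (labels == 0).sum() < 2:
        raise ValueError("need at least 2 compounds per class")
    pos, neg = values[labels == 1], values[labels == 0]
    stats_w, pvals = [], []
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j])
        stats_w.append(float(ranks[labels == 1].sum()))
        pvals.append(rank_sum_greater(pos[:, j], neg[:, j]))
    q = benjamini_hochberg(np.array(pvals))
    return [
        EnrichmentResult(
            feature_name=feature_names[j],
            statistic=stats_w[j],
            p=pvals[j],
            q=float(q[j]),
            enriched_in_dili=bool(q[j] < fdr),
        )
        for j in range(values.shape[1])
    ]


def median_importance(
    importance_matrix: np.ndarray,
    feature_names: list[str],
    signed: bool = False,
) -> pd.DataFrame:
    """Median per-feature importance across folds plus a rank column.

    Ranking is by |median| when `signed` (linear-model coefficients, where
    the sign only encodes the favored class) and by the median itself for
    non-negative tree-ensemble importances; rank 1 is the most important.
    """
    m = np.asarray(importance_matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] != len(feature_names):
        raise ValueError("importance matrix inconsistent with feature names")
    med = np.median(m, axis=0)
    key = np.abs(med) if signed else med
    order = np.argsort(-key, kind="stable")
    rank = np.empty(len(med), dtype=int)
    rank[order] = np.arange(1, len(med) + 1)
    return pd.DataFrame(
        {"feature_name": feature_names, "median_importance": med, "rank": rank}
    )


@dataclass(frozen=True)
class ORAResult:
    geneset: str
    overlap: int  # k
    set_size: int  # K (within background)
    selected: int  # n
    background: int  # N
    p: float
    q: float


def ora(
    selected: set[str],
    genesets: list[Geneset],
    background: set[str],
    min_set_size: int = 10,
) -> list[ORAResult]:
    """Hypergeometric over-representation of a selected feature set.

    Genesets are intersected with the background and those with fewer than
    `min_set_size` background members are excluded. p is the upper tail
    P(X ≥ k) for drawing n features from a background of N containing K set
    members; BH adjustment runs across the retained sets.
    """
    if not selected <= background:
        raise ValueError("selected features must be a subset of the background")
    n_bg, n_sel = len(background), len(selected)
    rows = []
    for gs in genesets:
        members = set(gs.members) & background
        if len(members) < min_set_size:
            continue
        k = len(members & selected)
        p = float(stats.hypergeom.sf(k - 1, n_bg, len(members), n_sel))
        rows.append((gs.name, k, len(members), p))
    if not rows:
        return []
    q = benjamini_hochberg(np.array([r[3] for r in rows]))
    return [
        ORAResult(name, k, size, n_sel, n_bg, p, float(qv))
        for (name, k, size, p), qv in zip(rows, q)
    ]


def threshold_scan(
    enrichment: list[EnrichmentResult],
    importance: pd.DataFrame,
    genesets: list[Geneset],
    background: set[str],
    quantiles: list[float] | None = None,
    top_k: int | None = None,
) -> pd.DataFrame:
    """ORA across importance cutoffs over the significantly enriched features.

    At each quantile cutoff the selection is the enriched features whose
    |median importance| lies at or above that quantile of the enriched
    features' importances; ``top_k`` instead selects the k enriched features
    with the best importance rank (the headline analysis uses 19). Returns a
    long-format table (one row per cutoff × geneset).
    """
    enriched = {e.feature_name for e in enrichment if e.enriched_in_dili}
    imp = importance.set_index("feature_name")
    rows = []

    def scan_one(tag: str, selected: set[str]):
        for r in ora(selected, genesets, background):
            rows.append(
                {
                    "cutoff": tag,
                    "n_selected": len(selected),
                    "geneset": r.geneset,
                    "overlap": r.overlap,
                    "set_size": r.set_size,
                    "p": r.p,
                    "q": r.q,
                }
            )

    if top_k is not None:
        ranked = sorted(enriched, key=lambda f: imp.loc[f, "rank"])
        scan_one(f"top{top_k}", set(ranked[:top_k]))
    for qt in quantiles or []:
        vals = np.abs(imp.loc[sorted(enriched), "median_importance"])
        cut = np.quantile(vals, qt) if len(vals) else np.inf
        selected = {f for f in enriched if abs(imp.loc[f, "median_importance"]) >= cut}
        scan_one(f"q{qt:g}", selected)
    return pd.DataFrame(rows)
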