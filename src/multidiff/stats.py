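"""Overlap/enrichment statistics and rank-based classification metrics.

The overlap between a compound's target set and the disease protein set is
tested with the upper-tail hypergeometric probability P(X >= k), computed
in log space for numerical stability. Gene-set enrichment applies the same
test across a collection with Benjamini–Hochberg adjustment. AUROC and AUPR
are computed from scratch: AUROC as pairwise ranking concordance (the
Mann–Whitney U relation, ties half-credited) and AUPR as average precision
with tied score blocks processed jointly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapTest:
    """Hypergeometric overlap between a target set and the disease set.

    ``k`` of the ``n`` in-universe targets fall inside the ``K`` disease
    proteins drawn from a universe of ``N``.
    """

    k: int
    n: int
    K: int
    N: int
    p_value: float


@dataclass(frozen=True)
class EnrichmentRow:
    set_name: str
    overlap: int
    set_size: int
    p_value: float
    adjusted_p: float


@dataclass
class ClassificationEval:
    """AUROC/AUPR of a score ranking against binary labels, with curve points."""

    auroc: float
    aupr: float
    n_positive: int
    n_total: int
    ranked: pd.DataFrame  # columns: id (optional), score, label, rank
    roc_points: pd.DataFrame = field(default_factory=pd.DataFrame)
    pr_points: pd.DataFrame = field(default_factory=pd.DataFrame)


def _log_comb(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(np.asarray(k) + 1) - gammaln(
        np.asarray(n) - np.asarray(k) + 1
    )


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact in log space.

    ``N`` universe size, ``K`` marked elements, ``n`` draws, ``k`` observed
    overlap. Returns 1.0 for k <= max(0, n + K - N) and raises on parameter
    violations.
    """
    if not (0 < n <= N and 0 < K <= N):
        raise ValueError(f"require 0 < n, K <= N; got n={n}, K={K}, N={N}")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"require 0 <= k <= min(n, K); got k={k}, n={n}, K={K}")
    if k <= max(0, n + K - N):
        return 1.0  # the whole support lies in the tail
    lo = k
    hi = min(n, K)
    i = np.arange(lo, hi + 1)
    log_terms = _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
    # log-sum-exp over the tail
    m = log_terms.max()
    p = float(np.exp(m) * np.exp(log_terms - m).sum())
    return min(p, 1.0)


def overlap_test(
    targets: set[str] | frozenset[str],
    disease_proteins: set[str] | frozenset[str],
    universe: set[str] | frozenset[str],
) -> OverlapTest:
    """Hypergeometric overlap of two sets restricted to a universe."""
    if not universe:
        raise ValueError("universe is empty")
    t = set(targets) & set(universe)
    d = set(disease_proteins) & set(universe)
    if not t or not d:
        raise ValueError("both sets must intersect the universe")
    k = len(t & d)
    p = hypergeom_upper_tail(k, len(t), len(d), len(universe))
    return OverlapTest(k=k, n=len(t), K=len(d), N=len(universe), p_value=p)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running = min(running, p[i] * m / (pos + 1))
        adj[i] = running
    return adj


def enrich_gene_sets(
    targets: set[str] | frozenset[str],
    collection: dict[str, set[str]],
    universe: set[str] | frozenset[str],
) -> list[EnrichmentRow]:
    """Hypergeometric overrepresentation of ``targets`` in each gene set.

    Sets entirely outside the universe are skipped with a warning; adjusted
    p-values are BH across the tested sets; rows sorted by raw p then name.
    """
    if not collection:
        raise ValueError("gene-set collection is empty")
    t = set(targets) & set(universe)
    names, raw = [], []
    sizes, overlaps = [], []
    for name in sorted(collection):
        members = set(collection[name]) & set(universe)
        if not members:
            logger.warning("gene set %r lies entirely outside the universe; skipped", name)
            continue
        k = len(t & members)
        p = hypergeom_upper_tail(k, len(t), len(members), len(universe)) if t else 1.0
        names.append(name)
        raw.append(p)
        sizes.append(len(members))
        overlaps.append(k)
    adj = benjamini_hochberg(raw) if names else np.array([])
    rows = [
        EnrichmentRow(set_name=nm, overlap=k, set_size=sz, p_value=p, adjusted_p=float(a))
        for nm, k, sz, p, a in zip(names, overlaps, sizes, raw, adj)
    ]
    rows.sort(key=lambda r: (r.p_value, r.set_name))
    return rows


def _check_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one positive and one negative label")
    return s, y


def auroc(scores, labels) -> float:
    """AUROC as pairwise concordance: (concordant + 0.5 * tied) / (P * N).

    Computed via mid-ranks (Mann–Whitney U), so ties are half-credited.
    """
    s, y = _check_labels(scores, labels)
    order = np.argsort(s, kind="mergesort")
    s_sorted = s[order]
    ranks = np.empty(len(s))
    i = 0
    while i < len(s):  # mid-rank for each tied block
        j = i
        while j + 1 < len(s) and s_sorted[j + 1] == s_sorted[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def aupr(scores, labels) -> float:
    """Average precision; tied score blocks are processed jointly.

    AP = sum over distinct descending thresholds of
    precision(threshold) * delta-recall(threshold).
    """
    s, y = _check_labels(scores, labels)
    order = np.argsort(-s, kind="mergesort")
    s_desc = s[order]
    y_desc = y[order]
    n_pos = int(y.sum())
    ap = 0.0
    tp = 0
    seen = 0
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and s_desc[j + 1] == s_desc[i]:
            j += 1
        block_tp = int(y_desc[i : j + 1].sum())
        tp += block_tp
        seen += j - i + 1
        if block_tp:
            ap += (tp / seen) * (block_tp / n_pos)
        i = j + 1
    return float(ap)


def roc_curve_points(scores, labels) -> pd.DataFrame:
    """(FPR, TPR) at each distinct score threshold, descending."""
    s, y = _check_labels(scores, labels)
    order = np.argsort(-s, kind="mergesort")
    s_desc, y_desc = s[order], y[order]
    n_pos = y.sum()
    n_neg = len(y) - n_pos
    pts = [(0.0, 0.0, np.inf)]
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and s_desc[j + 1] == s_desc[i]:
            j += 1
        tp += int(y_desc[i : j + 1].sum())
        fp += (j - i + 1) - int(y_desc[i : j + 1].sum())
        pts.append((fp / n_neg, tp / n_pos, s_desc[i]))
        i = j + 1
    return pd.DataFrame(pts, columns=["fpr", "tpr", "threshold"])


def pr_curve_points(scores, labels) -> pd.DataFrame:
    """(recall, precision) at each distinct score threshold, descending."""
    s, y = _check_labels(scores, labels)
    order = np.argsort(-s, kind="mergesort")
    s_desc, y_desc = s[order], y[order]
    n_pos = y.sum()
    pts = []
    tp = seen = 0
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and s_desc[j + 1] == s_desc[i]:
            j += 1
        tp += int(y_desc[i : j + 1].sum())
        seen += j - i + 1
        pts.append((tp / n_pos, tp / seen, s_desc[i]))
        i = j + 1
    return pd.DataFrame(pts, columns=["recall", "precision", "threshold"])


def evaluate_known_positives(score_table, positive_ids) -> ClassificationEval:
    """Label a ranked score table by known-positive membership and evaluate.

    ``score_table`` is a :class:`~multidiff.scoring.ScoreTable` or its
    DataFrame; rows are labeled 1 if ``compound_id`` is in ``positive_ids``.
    """
    df = score_table.table if hasattr(score_table, "table") else score_table
    positives = set(positive_ids)
    labels = df["compound_id"].isin(positives).astype(int).to_numpy()
    if labels.sum() == 0:
        raise ValueError("no known positive appears in the score table")
    scores = df["score"].to_numpy()
    ranked = df[["compound_id", "score"]].copy()
    ranked["label"] = labels
    ranked["rank"] = np.arange(1, len(df) + 1)
    return ClassificationEval(
        auroc=auroc(scores, labels),
        aupr=aupr(scores, labels),
        n_positive=int(labels.sum()),
        n_total=len(labels),
        ranked=ranked,
        roc_points=roc_curve_points(scores, labels),
        pr_points=pr_curve_points(scores, labels),
    )
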