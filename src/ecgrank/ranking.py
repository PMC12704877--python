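"""Model ranking: TOPSIS, an mRMR metric-selection adaptation, and paired
McNemar testing with Holm-Bonferroni correction.

TOPSIS (technique for order of preference by similarity to ideal solution)
ranks the m classifier variants by relative closeness to the ideal
alternative over the n = 3 benefit criteria (AUC, F1, accuracy):

    r_ij = x_ij / sqrt(sum_i x_ij^2)          (vector normalization)
    A+_j = max_i r_ij,   A-_j = min_i r_ij    (ideal / worst solutions)
    D+_i = ||r_i - A+||, D-_i = ||r_i - A-||  (Euclidean distances)
    C_i  = D-_i / (D+_i + D-_i)               (closeness, in [0, 1])

The highest closeness wins.  The default path is the unweighted computation
above; explicitly supplied non-equal weights are applied as v_ij = w_j r_ij.

The mRMR adaptation treats each model as a sample and each metric as a
feature: metric relevance is its absolute Pearson correlation with the
equal-weight mean of all metrics, redundancy its mean absolute correlation
with the metrics already selected, and metrics are greedily added while
relevance - redundancy stays positive (always keeping at least one).
TOPSIS closeness on the selected subset then ranks the models.

Tie conventions: TOPSIS ranks use max-position ties, the mRMR column uses
average-position ties (so a tied pair in sorted positions 4 and 5 is
reported as 4.5); closeness values within 1e-12 count as tied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import binomtest, chi2, rankdata

from .classifiers import PredictionSet
from .evaluation import METRIC_COLUMNS, MetricTable

__all__ = [
    "TopsisState", "RankVector", "MrmrSelection", "PairwiseTestResult",
    "topsis_closeness", "topsis_rank", "mrmr_select_metrics", "mrmr_rank",
    "rank_metric_table", "mcnemar_pair", "holm_adjust",
    "pairwise_comparison_suite",
]

CLOSENESS_TOL = 1e-12
#: discordant-count threshold below which the exact binomial test is used
EXACT_TEST_MAX = 25


@dataclass
class TopsisState:
    """All intermediates of one TOPSIS evaluation."""

    model_ids: list[str]
    x: np.ndarray          # m x n decision matrix
    w: np.ndarray          # n weights summing to 1
    r: np.ndarray          # normalized (and possibly weighted) matrix
    a_plus: np.ndarray     # ideal solution (column maxima)
    a_minus: np.ndarray    # worst solution (column minima)
    d_plus: np.ndarray     # distance to ideal
    d_minus: np.ndarray    # distance to worst
    c: np.ndarray          # closeness coefficients


@dataclass
class RankVector:
    """model_id -> rank; real-valued to allow tied ranks such as 4.5."""

    ranks: dict[str, float]
    tie_convention: str    # {"max", "average"}

    def __getitem__(self, model_id: str) -> float:
        return self.ranks[model_id]


@dataclass
class MrmrSelection:
    selected_metrics: list[str]
    relevance: dict[str, float]
    redundancy: dict[str, float]


@dataclass
class PairwiseTestResult:
    """McNemar result for one model pair.

    ``b`` counts rows where A is right and B wrong, ``c`` the reverse.
    """

    model_a: str
    model_b: str
    b: int
    c: int
    p_raw: float
    p_holm: float | None = None
    significant: bool | None = None


def _as_matrix(table: MetricTable | np.ndarray,
               columns: list[str] | None = None):
    if isinstance(table, MetricTable):
        ids = table.model_ids
        x = table.matrix
        names = list(METRIC_COLUMNS)
        if columns is not None:
            sel = [names.index(c) for c in columns]
            x = x[:, sel]
            names = list(columns)
        return ids, x, names
    x = np.asarray(table, dtype=float)
    ids = [f"row{i}" for i in range(x.shape[0])]
    return ids, x, [f"c{j}" for j in range(x.shape[1])]


def topsis_closeness(table: MetricTable | np.ndarray,
                     weights=None,
                     columns: list[str] | None = None) -> TopsisState:
    """Closeness coefficients C_i for every alternative.

    All criteria are benefit criteria; matrix entries must be non-negative
    (metrics are percentages).  When an alternative coincides with both the
    ideal and the worst solution (single row, or all rows identical) its
    closeness is defined as 0.5.
    """
    ids, x, names = _as_matrix(table, columns)
    m, n = x.shape
    if m < 1:
        raise ValueError("decision matrix needs at least one alternative")
    if np.any(x < 0):
        raise ValueError("decision matrix entries must be non-negative")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be n non-negative values")
        w = w / w.sum()
    norms = np.sqrt((x ** 2).sum(axis=0))
    if np.any(norms == 0):
        warnings.warn("all-zero criterion column contributes nothing "
                      "to the distances")
    safe = np.where(norms == 0, 1.0, norms)
    r = x / safe
    # default (equal-weight) path follows the unweighted printed equations;
    # explicit non-equal weights are applied multiplicatively
    if weights is not None and not np.allclose(w, 1.0 / n):
        r = w * r
    a_plus = r.max(axis=0)
    a_minus = r.min(axis=0)
    d_plus = np.sqrt(((r - a_plus) ** 2).sum(axis=1))
    d_minus = np.sqrt(((r - a_minus) ** 2).sum(axis=1))
    denom = d_plus + d_minus
    c = np.where(denom == 0, 0.5, d_minus / np.where(denom == 0, 1.0, denom))
    return TopsisState(model_ids=ids, x=x, w=w, r=r, a_plus=a_plus,
                       a_minus=a_minus, d_plus=d_plus, d_minus=d_minus, c=c)


def _tied_ranks(values: np.ndarray, method: str,
                tol: float = CLOSENESS_TOL) -> np.ndarray:
    """Descending ranks with tolerance-grouped ties (rank 1 = largest)."""
    order = np.argsort(-values, kind="stable")
    group = np.empty(len(values), dtype=int)
    gid = 0
    for k, idx in enumerate(order):
        if k > 0 and values[order[k - 1]] - values[idx] > tol:
            gid += 1
        group[idx] = gid
    return rankdata(group, method=method)


def topsis_rank(table: MetricTable | np.ndarray,
                weights=None) -> RankVector:
    """TOPSIS ranks, max-position tie convention (rank 1 = best)."""
    state = topsis_closeness(table, weights)
    ranks = _tied_ranks(state.c, "max")
    return RankVector(dict(zip(state.model_ids, ranks.astype(float))),
                      tie_convention="max")


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        warnings.warn("constant metric column: correlation treated as 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def mrmr_select_metrics(table: MetricTable) -> MrmrSelection:
    """Greedy metric subset maximizing relevance minus redundancy.

    Relevance of a metric is its absolute Pearson correlation with the
    equal-weight mean of all metrics; redundancy is its mean absolute
    correlation with the metrics already selected (0 for the first pick).
    Selection proceeds greedily by relevance - redundancy and stops once
    the best remaining score is non-positive; at least one metric (the
    most relevant) is always kept, and a metric perfectly correlated with
    a selected one (redundancy 1) is never added.
    """
    ids, x, names = _as_matrix(table)
    if x.shape[0] < 3:
        raise ValueError("mRMR selection needs at least 3 models "
                         "(correlations require variation)")
    target = x.mean(axis=1)
    relevance = {name: abs(_safe_corr(x[:, j], target))
                 for j, name in enumerate(names)}
    selected: list[str] = []
    redundancy: dict[str, float] = {}
    candidates = list(names)
    while candidates:
        best, best_score, best_red = None, -np.inf, 0.0
        for name in candidates:
            j = names.index(name)
            red = (0.0 if not selected else float(np.mean(
                [abs(_safe_corr(x[:, j], x[:, names.index(s)]))
                 for s in selected])))
            score = relevance[name] - red
            if score > best_score:
                best, best_score, best_red = name, score, red
        if selected and best_score <= 0:
            break
        selected.append(best)
        redundancy[best] = best_red
        candidates.remove(best)
    return MrmrSelection(selected_metrics=selected,
                         relevance=relevance, redundancy=redundancy)


def mrmr_rank(table: MetricTable) -> RankVector:
    """TOPSIS closeness on the mRMR-selected metric subset, ranked with
    average-position ties (tied pairs report ranks like 4.5)."""
    selection = mrmr_select_metrics(table)
    state = topsis_closeness(table, columns=selection.selected_metrics)
    ranks = _tied_ranks(state.c, "average")
    return RankVector(dict(zip(state.model_ids, ranks.astype(float))),
                      tie_convention="average")


def rank_metric_table(table: MetricTable, weights=None) -> pd.DataFrame:
    """Rank-table frame mirroring the reference layout: Method, Auc,
    f1-score, Accuracy, Rank_mRMR, Rank_TOPSIS, Closeness."""
    state = topsis_closeness(table, weights)
    t_ranks = _tied_ranks(state.c, "max")
    if len(table.rows) >= 3:
        m_ranks = [mrmr_rank(table)[m] for m in table.model_ids]
    else:
        m_ranks = _tied_ranks(state.c, "average").tolist()
    df = table.to_frame()
    df["Rank_mRMR"] = m_ranks
    df["Rank_TOPSIS"] = t_ranks.astype(float)
    df["Closeness"] = state.c
    return df


def mcnemar_pair(preds_a, preds_b, truth,
                 model_a: str = "A", model_b: str = "B") -> PairwiseTestResult:
    """McNemar's test on one model pair (raw p only).

    Exact two-sided binomial test when b + c < 25, otherwise chi-square
    with continuity correction, (|b - c| - 1)^2 / (b + c).  Symmetric in
    (b, c); p = 1 when b + c = 0.
    """
    a = np.asarray(getattr(preds_a, "labels", preds_a), dtype=int)
    b_arr = np.asarray(getattr(preds_b, "labels", preds_b), dtype=int)
    t = np.asarray(truth, dtype=int)
    if not (a.shape == b_arr.shape == t.shape):
        raise ValueError("prediction and truth vectors must have equal length")
    a_right = a == t
    b_right = b_arr == t
    b_count = int(np.sum(a_right & ~b_right))
    c_count = int(np.sum(~a_right & b_right))
    n_disc = b_count + c_count
    if n_disc == 0:
        p = 1.0
    elif n_disc < EXACT_TEST_MAX:
        p = float(binomtest(b_count, n_disc, 0.5).pvalue)
    else:
        stat = (abs(b_count - c_count) - 1) ** 2 / n_disc
        p = float(chi2.sf(stat, df=1))
    return PairwiseTestResult(model_a=model_a, model_b=model_b,
                              b=b_count, c=c_count, p_raw=min(p, 1.0))


def holm_adjust(raw_pvalues) -> np.ndarray:
    """Holm-Bonferroni step-down adjustment, input order preserved.

    adjusted_(k) = max_{j <= k} min(1, (K - j + 1) * p_(j)) over the
    ascending-sorted p-values.
    """
    p = np.asarray(raw_pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("raw p-values must be a 1-D sequence")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    k = p.size
    order = np.argsort(p, kind="stable")
    stepped = np.minimum((k - np.arange(k)) * p[order], 1.0)
    stepped = np.maximum.accumulate(stepped)
    out = np.empty(k)
    out[order] = stepped
    return out


def pairwise_comparison_suite(
        prediction_sets: list[PredictionSet], truth,
        alpha: float = 0.05,
) -> tuple[list[PairwiseTestResult], pd.DataFrame, list[list[str]]]:
    """All-pairs McNemar tests with a single Holm family.

    Models with bit-identical prediction vectors are collapsed first (the
    representative is the first of each group); returns the test results,
    a symmetric significance matrix (empty diagonal), and the collapsed
    groups for reporting.
    """
    if len(prediction_sets) < 2:
        raise ValueError("need at least 2 models to compare")
    t = np.asarray(truth, dtype=int)
    groups: list[list[PredictionSet]] = []
    for ps in prediction_sets:
        for g in groups:
            if np.array_equal(g[0].labels, ps.labels):
                g.append(ps)
                break
        else:
            groups.append([ps])
    reps = [g[0] for g in groups]
    group_ids = [[ps.model_id for ps in g] for g in groups]
    results = [mcnemar_pair(a, b, t, a.model_id, b.model_id)
               for a, b in combinations(reps, 2)]
    if results:
        adjusted = holm_adjust([r.p_raw for r in results])
        for r, p_adj in zip(results, adjusted):
            r.p_holm = float(p_adj)
            r.significant = bool(p_adj < alpha)
    ids = [ps.model_id for ps in reps]
    sig = pd.DataFrame("", index=ids, columns=ids)
    for r in results:
        mark = "yes" if r.significant else "no"
        sig.loc[r.model_a, r.model_b] = mark
        sig.loc[r.model_b, r.model_a] = mark
    return results, sig, group_ids


def pairwise_results_frame(results: list[PairwiseTestResult]) -> pd.DataFrame:
    """CSV-ready frame: model_a, model_b, b, c, p_raw, p_holm, significant."""
    return pd.DataFrame([{
        "model_a": r.model_a, "model_b": r.model_b, "b": r.b, "c": r.c,
        "p_raw": r.p_raw, "p_holm": r.p_holm, "significant": r.significant,
    } for r in results])
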