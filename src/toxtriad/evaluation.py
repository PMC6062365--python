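"""Performance, robustness, coverage, independence and interpretation
statistics for the cross-validated toxicity classifiers.

Metric conventions: sensitivity is the fraction of toxic compounds
correctly identified, selectivity the fraction of nontoxic compounds
correctly identified, and the correct classification rate (CCR) their
arithmetic mean (balanced accuracy). Cross-combination comparisons pair
cells trained and tested on the same split, removing split-to-split
variance. Applicability-domain coverage is profiled by binning external
predictions on the nearest-neighbor Euclidean distance to the modelling set
in chemical space. Domain independence is quantified by Mantel permutation
tests between the three descriptor-space distance matrices.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist, pdist, squareform

from .modeling import ModelResult, SplitPlan

__all__ = [
    "PerformanceSummary",
    "ImprovementRecord",
    "ADProfile",
    "MantelResult",
    "confusion_metrics",
    "summarize",
    "paired_improvement",
    "roc_auc",
    "ad_profile",
    "mantel_test",
    "aggregate_importance",
    "neighbor_contrast",
]


# ---------------------------------------------------------------------------
# performance
# ---------------------------------------------------------------------------

def confusion_metrics(
    truth: np.ndarray | pd.Series, predictions: np.ndarray | pd.Series
) -> tuple[float, float, float]:
    """(sensitivity, selectivity, CCR) for binary toxic(1)/nontoxic(0)."""
    t = np.asarray(truth)
    p = np.asarray(predictions)
    if t.shape != p.shape:
        raise ValueError("truth and predictions must be the same length")
    n_tox = int((t == 1).sum())
    n_non = int((t == 0).sum())
    if n_tox == 0 or n_non == 0:
        raise ValueError("both classes must be present in the truth labels")
    sensitivity = float((p[t == 1] == 1).sum() / n_tox)
    selectivity = float((p[t == 0] == 0).sum() / n_non)
    return sensitivity, selectivity, 0.5 * (sensitivity + selectivity)


@dataclass
class PerformanceSummary:
    combo: tuple[str, ...]
    per_cell: pd.DataFrame  # repeat, fold, sensitivity, selectivity, ccr
    mean: pd.Series
    sd: pd.Series


def summarize(results: list[ModelResult]) -> PerformanceSummary:
    """Per-cell metrics and their mean +/- SD over all cells of one combo."""
    ok = [r for r in results if r.error is None]
    if not ok:
        raise ValueError("no successful cells to summarize")
    combos = {r.combo for r in ok}
    if len(combos) > 1:
        raise ValueError(f"mixed combos in one summary: {sorted(combos)}")
    rows = []
    for r in ok:
        sens, sel, ccr = confusion_metrics(
            r.predictions["truth"], r.predictions["prediction"]
        )
        rows.append((r.repeat, r.fold, sens, sel, ccr))
    per_cell = pd.DataFrame(
        rows, columns=["repeat", "fold", "sensitivity", "selectivity", "ccr"]
    )
    metrics = per_cell[["sensitivity", "selectivity", "ccr"]]
    return PerformanceSummary(
        combo=ok[0].combo,
        per_cell=per_cell,
        mean=metrics.mean(),
        sd=metrics.std(ddof=1),
    )


@dataclass
class ImprovementRecord:
    combo_a: tuple[str, ...]
    combo_b: tuple[str, ...]
    delta_ccr: np.ndarray  # per shared (repeat, fold) cell, A - B
    mean: float
    se: float
    p_value: float


def paired_improvement(
    results_a: list[ModelResult], results_b: list[ModelResult]
) -> ImprovementRecord:
    """Per-split CCR difference A - B with a two-tailed paired t-test.

    Cells are paired on (repeat, fold); both runs must come from the same
    split plan, which is checked via identical held-out compound sets.
    """
    cells_a = {(r.repeat, r.fold): r for r in results_a if r.error is None}
    cells_b = {(r.repeat, r.fold): r for r in results_b if r.error is None}
    shared = sorted(set(cells_a) & set(cells_b))
    if not shared:
        raise ValueError("no shared (repeat, fold) cells to pair")
    deltas = []
    for key in shared:
        ra, rb = cells_a[key], cells_b[key]
        if list(ra.predictions.index) != list(rb.predictions.index):
            raise ValueError(
                f"cell {key}: held-out compounds differ; runs used different split plans"
            )
        ccr_a = confusion_metrics(ra.predictions["truth"], ra.predictions["prediction"])[2]
        ccr_b = confusion_metrics(rb.predictions["truth"], rb.predictions["prediction"])[2]
        deltas.append(ccr_a - ccr_b)
    d = np.asarray(deltas)
    sd = d.std(ddof=1) if len(d) > 1 else 0.0
    se = sd / math.sqrt(len(d))
    if sd == 0.0:
        p = 1.0 if d.mean() == 0 else 0.0
    else:
        p = float(stats.ttest_1samp(d, 0.0).pvalue)
    return ImprovementRecord(
        combo_a=results_a[0].combo,
        combo_b=results_b[0].combo,
        delta_ccr=d,
        mean=float(d.mean()),
        se=float(se),
        p_value=p,
    )


def roc_auc(truth: np.ndarray | pd.Series, p_toxic: np.ndarray | pd.Series) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve; ties count 1/2."""
    t = np.asarray(truth)
    s = np.asarray(p_toxic, dtype=float)
    pos = s[t == 1]
    neg = s[t == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


# ---------------------------------------------------------------------------
# applicability domain
# ---------------------------------------------------------------------------

@dataclass
class ADProfile:
    bin_edges: np.ndarray
    per_bin: pd.DataFrame  # combo, bin, n, ccr (NaN for empty/one-class bins)
    distances: pd.DataFrame  # combo, repeat, fold, compound_id, distance, truth, prediction


def ad_profile(
    results_by_combo: dict[tuple[str, ...], list[ModelResult]],
    chemical_block: pd.DataFrame,
    n_bins: int = 5,
) -> ADProfile:
    """CCR as a function of chemical-space distance to the modelling set.

    For each external prediction, the Euclidean nearest-neighbor distance to
    the *same fold's* final modelling compounds is computed in a shared,
    globally preprocessed chemical block. Distances are pooled over all
    combos to define shared quantile bin edges; per-bin CCR is then reported
    per combo. Bins lacking either class are reported as missing (NaN).
    """
    rows = []
    X = chemical_block
    for combo, results in results_by_combo.items():
        for r in results:
            if r.error is not None:
                continue
            model_ids = [cid for cid in r.state.kept_rows if cid in X.index]
            ext_ids = [cid for cid in r.predictions.index if cid in X.index]
            if not model_ids or not ext_ids:
                continue
            d = cdist(
                X.loc[ext_ids].to_numpy(dtype=float),
                X.loc[model_ids].to_numpy(dtype=float),
            ).min(axis=1)
            for cid, dist in zip(ext_ids, d):
                rows.append(
                    (
                        "+".join(combo),
                        r.repeat,
                        r.fold,
                        cid,
                        dist,
                        int(r.predictions.loc[cid, "truth"]),
                        int(r.predictions.loc[cid, "prediction"]),
                    )
                )
    distances = pd.DataFrame(
        rows,
        columns=["combo", "repeat", "fold", "compound_id", "distance", "truth", "prediction"],
    )
    if distances.empty:
        raise ValueError("no external predictions with chemical coordinates")
    edges = np.quantile(distances["distance"], np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    binned = np.digitize(distances["distance"], edges[1:-1])
    distances["bin"] = binned

    per_bin_rows = []
    for combo_name, group in distances.groupby("combo"):
        for b in range(n_bins):
            sub = group[group["bin"] == b]
            if sub.empty or sub["truth"].nunique() < 2:
                per_bin_rows.append((combo_name, b, len(sub), np.nan))
            else:
                _, _, ccr = confusion_metrics(sub["truth"], sub["prediction"])
                per_bin_rows.append((combo_name, b, len(sub), ccr))
    per_bin = pd.DataFrame(per_bin_rows, columns=["combo", "bin", "n", "ccr"])
    return ADProfile(bin_edges=edges, per_bin=per_bin, distances=distances)


# ---------------------------------------------------------------------------
# domain independence
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int


def mantel_test(
    dist_a: np.ndarray,
    dist_b: np.ndarray,
    n_perm: int = 9999,
    seed: int = 0,
    exhaustive: bool = False,
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    r is the Pearson correlation of the upper off-diagonal triangles; the
    one-sided p-value is (1 + #{permuted r >= observed r}) / (1 + n_perm),
    with rows and columns of B permuted jointly. ``exhaustive=True``
    enumerates all n! relabelings instead (small n only), with
    p = #{r_perm >= r_obs} / n! over the full group.
    """
    A = np.asarray(dist_a, dtype=float)
    B = np.asarray(dist_b, dtype=float)
    for name, M in (("A", A), ("B", B)):
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError(f"matrix {name} must be square")
        if not np.allclose(M, M.T):
            raise ValueError(f"matrix {name} must be symmetric")
        if not np.allclose(np.diag(M), 0):
            raise ValueError(f"matrix {name} must have a zero diagonal")
    if A.shape != B.shape:
        raise ValueError("matrices must have the same shape")
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)

    def corr(M: np.ndarray) -> float:
        return float(np.corrcoef(A[iu], M[iu])[0, 1])

    r_obs = corr(B)
    if exhaustive:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            p_idx = np.asarray(perm)
            if corr(B[np.ix_(p_idx, p_idx)]) >= r_obs - 1e-12:
                count += 1
            total += 1
        return MantelResult(r=r_obs, p_value=count / total, n_permutations=total)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p_idx = rng.permutation(n)
        if corr(B[np.ix_(p_idx, p_idx)]) >= r_obs - 1e-12:
            count += 1
    return MantelResult(
        r=r_obs, p_value=(1 + count) / (1 + n_perm), n_permutations=n_perm
    )


def domain_distance_matrices(
    blocks: dict[str, pd.DataFrame]
) -> dict[str, np.ndarray]:
    """Euclidean pairwise distance matrix per descriptor domain."""
    out = {}
    for domain, block in blocks.items():
        out[domain] = squareform(pdist(block.to_numpy(dtype=float)))
    return out


# ---------------------------------------------------------------------------
# interpretation
# ---------------------------------------------------------------------------

def aggregate_importance(
    results: list[ModelResult], domains: pd.Series, top_k: int = 10
) -> pd.DataFrame:
    """Average range-scaled variable importance over the tripartite models.

    Per model, raw importances are scaled to [0, 100]; per descriptor, the
    scaled values are averaged over the models in which the descriptor
    survived preprocessing (models where it was filtered out do not
    contribute). Returns one row per descriptor with its domain tag, average
    importance, number of contributing models, and rank within its domain.
    """
    ok = [r for r in results if r.error is None and len(r.importances)]
    if not ok:
        raise ValueError("no tripartite models with importances")
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for r in ok:
        imp = r.importances.to_numpy(dtype=float)
        lo, hi = imp.min(), imp.max()
        scaled = np.zeros_like(imp) if hi == lo else 100.0 * (imp - lo) / (hi - lo)
        for col, v in zip(r.importances.index, scaled):
            sums[col] = sums.get(col, 0.0) + v
            counts[col] = counts.get(col, 0) + 1
    rows = [
        (col, domains.get(col, "unknown"), sums[col] / counts[col], counts[col])
        for col in sums
    ]
    table = pd.DataFrame(
        rows, columns=["descriptor", "domain", "average_importance", "n_models"]
    ).sort_values("average_importance", ascending=False, ignore_index=True)
    table["rank_in_domain"] = (
        table.groupby("domain")["average_importance"].rank(
            ascending=False, method="first"
        ).astype(int)
    )
    return table


def neighbor_contrast(
    query_id: str,
    chemical_block: pd.DataFrame,
    target_block: pd.DataFrame,
    labels: pd.Series,
    k: int = 5,
    m: int = 5,
    max_distance: float | None = None,
    flag_threshold: int = 3,
) -> pd.DataFrame:
    """Target-score contrast between a toxic query and its nontoxic
    chemical-space neighbors.

    Finds the k nearest nontoxic neighbors of the query in the chemical
    block (optionally within ``max_distance``); for each neighbor, lists the
    m target descriptors with the largest numerical increase going from the
    neighbor to the query (ties by target id). Targets recurring in at least
    ``flag_threshold`` of the k lists are flagged as putative
    mode-of-action candidates.
    """
    if labels.get(query_id) != 1:
        raise ValueError(f"query compound {query_id!r} must be toxic")
    nontoxic = [cid for cid in labels.index if labels[cid] == 0 and cid in chemical_block.index]
    if not nontoxic:
        raise ValueError("no nontoxic compounds available")
    q = chemical_block.loc[[query_id]].to_numpy(dtype=float)
    d = cdist(q, chemical_block.loc[nontoxic].to_numpy(dtype=float))[0]
    order = np.lexsort((np.asarray(nontoxic, dtype=object), d))
    eligible = [
        (nontoxic[i], d[i])
        for i in order
        if max_distance is None or d[i] <= max_distance
    ]
    if len(eligible) < k:
        import warnings

        warnings.warn(
            f"only {len(eligible)} eligible neighbors (requested {k})", stacklevel=2
        )
    chosen = eligible[:k]

    q_scores = target_block.loc[query_id]
    rows = []
    per_neighbor_targets = []
    for cid, dist in chosen:
        diff = q_scores - target_block.loc[cid]
        # largest increase first; ties broken by target id
        ordered = diff.iloc[
            np.lexsort((diff.index.to_numpy(dtype=object), -diff.to_numpy()))
        ]
        top = ordered.iloc[:m]
        per_neighbor_targets.append(set(top.index))
        for rank, (tid, delta) in enumerate(top.items(), 1):
            rows.append((cid, dist, rank, tid, float(delta)))
    flag_counts: dict[str, int] = {}
    for tset in per_neighbor_targets:
        for tid in tset:
            flag_counts[tid] = flag_counts.get(tid, 0) + 1
    table = pd.DataFrame(
        rows, columns=["neighbor_id", "distance", "rank", "target_id", "score_increase"]
    )
    table["flagged"] = table["target_id"].map(
        lambda t: flag_counts.get(t, 0) >= flag_threshold
    )
    return table
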