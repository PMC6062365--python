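"""Fold-internal descriptor reduction, scaling and class balancing.

The four steps, applied per modelling set in this fixed order:

1. drop zero- and near-zero-variance descriptors;
2. greedy pairwise-correlation filtering at domain-specific cutoffs
   (calibrated once so the three domains end up similarly sized);
3. range scaling to [0, 1] using modelling-set minima/maxima (external
   values may fall outside and are not clipped);
4. downsampling of nontoxic compounds far from any toxic compound in
   chemical space, to an approximately class-balanced modelling set.

Everything is fitted on the modelling set only and applied uniformly to the
modelling and external sets; the fitted state is recorded for audit.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .featurization import DescriptorTable

__all__ = [
    "STEP_ORDER",
    "PreprocessConfig",
    "DomainCutoffs",
    "PreprocessState",
    "drop_near_zero_variance",
    "calibrate_cutoffs",
    "apply_correlation_filter",
    "fit_range_scaler",
    "apply_range_scaler",
    "downsample_modeling_set",
    "fit_preprocess",
    "transform",
    "validate_step_order",
]

STEP_ORDER = ("near_zero_variance", "correlation_filter", "range_scale", "downsample")


@dataclass(frozen=True)
class PreprocessConfig:
    nzv_freq_ratio: float = 19.0
    nzv_unique_cut: float = 10.0  # percent
    target_size: int | None = None  # None: smallest post-NZV domain width
    downsample_ratio: float = 1.0
    recalibrate_cutoffs_per_fold: bool = False
    step_order: tuple[str, ...] = STEP_ORDER


@dataclass(frozen=True)
class DomainCutoffs:
    """Maximum permitted absolute pairwise correlation per domain."""

    cutoffs: dict[str, float]

    def __post_init__(self) -> None:
        for domain, c in self.cutoffs.items():
            if not (0 < c <= 1):
                raise ValueError(f"cutoff for {domain!r} must be in (0, 1], got {c}")


@dataclass
class PreprocessState:
    """Record of everything fitted on one modelling set."""

    kept_columns: dict[str, list[str]]  # per domain
    scaler_bounds: dict[str, tuple[float, float]]  # column -> (min, max)
    kept_rows: list[str]  # modelling compounds surviving downsampling
    fitted_on: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "kept_columns": self.kept_columns,
                "scaler_bounds": {c: list(b) for c, b in self.scaler_bounds.items()},
                "kept_rows": self.kept_rows,
                "fitted_on": self.fitted_on,
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PreprocessState):
            return NotImplemented
        return (
            self.kept_columns == other.kept_columns
            and self.scaler_bounds == other.scaler_bounds
            and self.kept_rows == other.kept_rows
        )


def validate_step_order(order: tuple[str, ...] | list[str]) -> None:
    """The pipeline order is part of the contract; reject anything else."""
    if tuple(order) != STEP_ORDER:
        raise ValueError(
            f"preprocessing steps must run in the order {STEP_ORDER}, got {tuple(order)}"
        )


# ---------------------------------------------------------------------------
# step 1: near-zero variance
# ---------------------------------------------------------------------------

def drop_near_zero_variance(
    table: pd.DataFrame, freq_ratio: float = 19.0, unique_cut: float = 10.0
) -> tuple[pd.DataFrame, list[str]]:
    """Drop zero-variance columns and columns that are both highly
    imbalanced (top/second value frequency ratio > ``freq_ratio``) and
    low-cardinality (distinct fraction < ``unique_cut`` percent)."""
    if table.shape[1] == 0:
        raise ValueError("empty descriptor table")
    n = len(table)
    dropped = []
    for col in table.columns:
        values = table[col].to_numpy()
        counts = pd.Series(values).value_counts().to_numpy()
        if len(counts) == 1:
            dropped.append(col)
            continue
        ratio = counts[0] / counts[1]
        unique_pct = 100.0 * len(counts) / n
        if ratio > freq_ratio and unique_pct < unique_cut:
            dropped.append(col)
    kept = [c for c in table.columns if c not in set(dropped)]
    if not kept:
        raise ValueError("all columns dropped by near-zero-variance filter")
    return table[kept], dropped


# ---------------------------------------------------------------------------
# step 2: correlation filter
# ---------------------------------------------------------------------------

def _abs_corr(table: pd.DataFrame) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.abs(np.corrcoef(table.to_numpy(), rowvar=False))
    if C.ndim == 0:  # single column
        C = np.ones((1, 1))
    C = np.nan_to_num(C, nan=0.0)
    C = 0.5 * (C + C.T)  # BLAS matmul is not exactly symmetric
    np.fill_diagonal(C, 0.0)
    return C


def _greedy_survivors(C: np.ndarray, columns: list[str], cutoff: float) -> list[str]:
    """Greedy elimination on a precomputed |r| matrix.

    While some pair exceeds the cutoff, take the worst (largest |r|) pair and
    remove the member with the larger mean |r| to all other live columns;
    ties — within the pair, and among equally-bad pairs — break by column
    name order (the lexicographically later column is removed).
    """
    M = C.copy()
    alive = np.ones(len(columns), dtype=bool)
    order = np.argsort(columns)  # rank by name for deterministic ties
    rank = np.empty(len(columns), dtype=int)
    rank[order] = np.arange(len(columns))
    while alive.sum() > 1:
        worst = M.max()
        if worst <= cutoff:
            break
        ii, jj = np.nonzero(M == worst)
        # canonical worst pair: smallest (name-rank_i, name-rank_j)
        pairs = sorted(
            (min(rank[a], rank[b]), max(rank[a], rank[b]), a, b)
            for a, b in zip(ii, jj)
            if a < b
        )
        _, _, i, j = pairs[0]
        live = alive.copy()
        live[[i, j]] = False
        mean_i = M[i, live].mean() if live.any() else 0.0
        mean_j = M[j, live].mean() if live.any() else 0.0
        if mean_i > mean_j:
            out = i
        elif mean_j > mean_i:
            out = j
        else:
            out = i if rank[i] > rank[j] else j
        alive[out] = False
        M[out, :] = 0.0
        M[:, out] = 0.0
    return [c for c, a in zip(columns, alive) if a]


def apply_correlation_filter(table: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Remove columns until all pairwise |Pearson r| <= cutoff (greedy)."""
    if not (0 < cutoff <= 1):
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    if table.shape[1] <= 1 or cutoff >= 1.0:
        return table
    C = _abs_corr(table)
    survivors = _greedy_survivors(C, list(table.columns), cutoff)
    return table[survivors]


def calibrate_cutoffs(
    table: DescriptorTable,
    target_size: int | None = None,
    tolerance: float = 0.10,
    nzv_freq_ratio: float = 19.0,
    nzv_unique_cut: float = 10.0,
) -> DomainCutoffs:
    """Per-domain correlation cutoffs that reduce each block to a common size.

    Bisection over the cutoff such that greedy filtering leaves within
    +/-``tolerance`` of ``target_size`` columns; by default the target is the
    smallest post-near-zero-variance domain width. Domains already at or
    below the target band keep cutoff 1.0 (no-op). If even a cutoff near 0
    leaves too many mutually uncorrelated columns, the closest achievable
    size is used with a warning.
    """
    blocks: dict[str, pd.DataFrame] = {}
    for domain in table.domains.unique():
        block = table.block(domain)
        reduced, _ = drop_near_zero_variance(block, nzv_freq_ratio, nzv_unique_cut)
        blocks[domain] = reduced
    if target_size is None:
        target_size = min(b.shape[1] for b in blocks.values())

    cutoffs: dict[str, float] = {}
    for domain, block in blocks.items():
        p = block.shape[1]
        if p <= target_size * (1 + tolerance):
            cutoffs[domain] = 1.0
            continue
        C = _abs_corr(block)
        columns = list(block.columns)
        lo, hi = 0.0, 1.0
        best_c, best_gap = 1.0, math.inf
        for _ in range(40):
            mid = (lo + hi) / 2.0
            width = len(_greedy_survivors(C, columns, mid))
            gap = abs(width - target_size)
            if gap < best_gap:
                best_c, best_gap = mid, gap
            if abs(width - target_size) <= tolerance * target_size:
                best_c = mid
                break
            if width > target_size:
                hi = mid
            else:
                lo = mid
        else:
            if best_gap > tolerance * target_size:
                warnings.warn(
                    f"domain {domain!r}: target width {target_size} unreachable; "
                    f"using cutoff {best_c:.4f} (off by {best_gap:.0f} columns)",
                    stacklevel=2,
                )
        cutoffs[domain] = best_c
    return DomainCutoffs(cutoffs)


# ---------------------------------------------------------------------------
# step 3: range scaling
# ---------------------------------------------------------------------------

def fit_range_scaler(table: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Column (min, max) on the modelling set."""
    return {
        col: (float(table[col].min()), float(table[col].max())) for col in table.columns
    }


def apply_range_scaler(
    bounds: dict[str, tuple[float, float]], table: pd.DataFrame
) -> pd.DataFrame:
    """x' = (x - min) / (max - min); external values are not clipped and a
    constant column maps to 0."""
    out = {}
    for col in table.columns:
        lo, hi = bounds[col]
        x = table[col].to_numpy(dtype=float)
        out[col] = np.zeros_like(x) if hi == lo else (x - lo) / (hi - lo)
    return pd.DataFrame(out, index=table.index)


# ---------------------------------------------------------------------------
# step 4: downsampling
# ---------------------------------------------------------------------------

def downsample_modeling_set(
    table: pd.DataFrame,
    labels: pd.Series,
    distance_columns: list[str],
    ratio: float = 1.0,
) -> list[str]:
    """Kept compound ids after distance-based downsampling of nontoxics.

    Every nontoxic compound's Euclidean distance (over ``distance_columns``)
    to its nearest toxic compound is computed; the ceil(ratio * n_toxic)
    nearest nontoxics are kept (ties by compound id) and all toxics are kept.
    """
    toxic_ids = list(labels.index[labels == 1])
    nontoxic_ids = list(labels.index[labels == 0])
    if not toxic_ids:
        raise ValueError("downsampling requires at least one toxic compound")
    if not nontoxic_ids:
        raise ValueError("downsampling requires at least one nontoxic compound")
    n_keep = math.ceil(ratio * len(toxic_ids))
    if n_keep >= len(nontoxic_ids):
        return [cid for cid in labels.index]

    X_tox = table.loc[toxic_ids, distance_columns].to_numpy(dtype=float)
    X_non = table.loc[nontoxic_ids, distance_columns].to_numpy(dtype=float)
    d2 = ((X_non[:, None, :] - X_tox[None, :, :]) ** 2).sum(axis=2)
    nearest = np.sqrt(d2.min(axis=1))
    ranked = sorted(zip(nearest, nontoxic_ids))
    kept_non = {cid for _, cid in ranked[:n_keep]}
    return [cid for cid in labels.index if labels[cid] == 1 or cid in kept_non]


# ---------------------------------------------------------------------------
# fitted pipeline
# ---------------------------------------------------------------------------

def fit_preprocess(
    table: DescriptorTable,
    labels: pd.Series,
    cutoffs: DomainCutoffs,
    config: PreprocessConfig = PreprocessConfig(),
    fitted_on: str = "",
) -> PreprocessState:
    """Run steps 1-4 on a modelling set and record the fitted state."""
    validate_step_order(config.step_order)
    kept_columns: dict[str, list[str]] = {}
    scaled_parts = []
    for domain in table.domains.unique():
        block = table.block(domain)
        block, _ = drop_near_zero_variance(
            block, config.nzv_freq_ratio, config.nzv_unique_cut
        )
        cutoff = cutoffs.cutoffs.get(domain, 1.0)
        block = apply_correlation_filter(block, cutoff)
        kept_columns[domain] = list(block.columns)
        bounds = fit_range_scaler(block)
        scaled_parts.append((apply_range_scaler(bounds, block), bounds))

    scaler_bounds: dict[str, tuple[float, float]] = {}
    for _, bounds in scaled_parts:
        scaler_bounds.update(bounds)
    scaled = pd.concat([part for part, _ in scaled_parts], axis=1)

    domain_tags = table.domains
    chem_cols = [c for c in scaled.columns if domain_tags[c] == "chemical"]
    distance_cols = chem_cols if chem_cols else list(scaled.columns)
    kept_rows = downsample_modeling_set(
        scaled, labels, distance_cols, config.downsample_ratio
    )
    return PreprocessState(
        kept_columns=kept_columns,
        scaler_bounds=scaler_bounds,
        kept_rows=kept_rows,
        fitted_on=fitted_on,
    )


def transform(state: PreprocessState, table: DescriptorTable) -> pd.DataFrame:
    """Apply a fitted state (column selection + scaling) to any table.

    Row filtering (downsampling) is a modelling-set concern and is *not*
    applied here; callers subset rows with ``state.kept_rows`` themselves.
    """
    cols = [c for cols in state.kept_columns.values() for c in cols]
    missing = [c for c in cols if c not in table.data.columns]
    if missing:
        raise KeyError(f"table lacks fitted columns: {missing[:5]}")
    return apply_range_scaler(state.scaler_bounds, table.data[cols])
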