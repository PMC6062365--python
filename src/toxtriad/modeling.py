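"""Repeated stratified cross-validation of random forests over descriptor
domain combinations, with shared splits and y-scrambling robustness checks.

The evaluation design: 20 repeats of class-stratified 5-fold external cross
validation (100 models per descriptor combination), the identical splits
reused for every one of the 7 combinations so that per-split performance
differences isolate the effect of the descriptors. For each (repeat, fold)
cell the held-out fifth is removed before any preprocessing; the four
preprocessing steps are fitted on the remaining modelling set only. Forests
use n_trees = 500 and mtry = floor(sqrt(p)) with p the post-preprocessing
descriptor count; predictions are majority votes over trees with ties going
to the toxic class (false negatives are the costlier error in toxicology).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .featurization import DescriptorTable, DOMAINS
from .preprocessing import (
    DomainCutoffs,
    PreprocessConfig,
    PreprocessState,
    calibrate_cutoffs,
    fit_preprocess,
    transform,
)

__all__ = [
    "ALL_COMBOS",
    "SplitPlan",
    "RFParams",
    "ModelResult",
    "make_split_plan",
    "run_combination",
    "y_scramble_assess",
    "cell_seed",
]

logger = logging.getLogger("toxtriad")

#: the 7 non-empty descriptor-domain combinations.
ALL_COMBOS: tuple[tuple[str, ...], ...] = tuple(
    combo
    for r in (1, 2, 3)
    for combo in itertools.combinations(DOMAINS, r)
)


@dataclass(frozen=True)
class SplitPlan:
    """Shared fold assignment: ``assignment[r, i]`` is compound i's fold in
    repeat r."""

    compound_ids: tuple[str, ...]
    n_repeats: int
    n_folds: int
    assignment: np.ndarray  # (n_repeats, n_compounds) int fold labels
    seed: int

    def fold_mask(self, repeat: int, fold: int) -> np.ndarray:
        return self.assignment[repeat] == fold

    def cells(self):
        return itertools.product(range(self.n_repeats), range(self.n_folds))


@dataclass(frozen=True)
class RFParams:
    n_trees: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    @staticmethod
    def mtry(p: int) -> int:
        return max(1, min(p, int(math.isqrt(p))))


@dataclass
class ModelResult:
    repeat: int
    fold: int
    combo: tuple[str, ...]
    predictions: pd.DataFrame  # index compound_id: truth, prediction, p_toxic
    state: PreprocessState
    importances: pd.Series  # descriptor -> raw importance
    seed: int
    scramble_p: float | None = None
    error: str | None = None


def cell_seed(master_seed: int, *key: int) -> int:
    """Deterministic child seed for a (combo, repeat, fold, scramble) cell."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def make_split_plan(
    labels: pd.Series, n_repeats: int = 20, n_folds: int = 5, seed: int = 0
) -> SplitPlan:
    """Class-stratified fold assignments, one independent split per repeat."""
    counts = labels.value_counts()
    if (counts < n_folds).any():
        small = counts[counts < n_folds]
        raise ValueError(
            f"every class needs >= n_folds={n_folds} members; got {small.to_dict()}"
        )
    n = len(labels)
    assignment = np.empty((n_repeats, n), dtype=np.int64)
    y = labels.to_numpy()
    for r in range(n_repeats):
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True, random_state=cell_seed(seed, r)
        )
        for fold, (_, test_idx) in enumerate(skf.split(np.zeros((n, 1)), y)):
            assignment[r, test_idx] = fold
    return SplitPlan(
        compound_ids=tuple(labels.index),
        n_repeats=n_repeats,
        n_folds=n_folds,
        assignment=assignment,
        seed=seed,
    )


def _vote_predict(
    rf: RandomForestClassifier, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Majority vote over individual trees; p_toxic is the fraction of trees
    voting toxic and ties go to the toxic class."""
    votes = np.stack([tree.predict(X) for tree in rf.estimators_])
    p_toxic = (votes == 1).mean(axis=0)
    return (p_toxic >= 0.5).astype(int), p_toxic


def _fit_cell(
    table: DescriptorTable,
    labels: pd.Series,
    modeling_ids: list[str],
    cutoffs: DomainCutoffs,
    preprocess: PreprocessConfig,
    rf_params: RFParams,
    seed: int,
) -> tuple[RandomForestClassifier, PreprocessState, list[str]]:
    """Fit preprocessing and forest on one modelling set."""
    model_table = DescriptorTable(
        table.data.loc[modeling_ids], table.domains.copy()
    )
    if preprocess.recalibrate_cutoffs_per_fold:
        cutoffs = calibrate_cutoffs(
            model_table,
            preprocess.target_size,
            nzv_freq_ratio=preprocess.nzv_freq_ratio,
            nzv_unique_cut=preprocess.nzv_unique_cut,
        )
    state = fit_preprocess(
        model_table, labels.loc[modeling_ids], cutoffs, preprocess
    )
    X_model = transform(state, model_table).loc[state.kept_rows]
    y_model = labels.loc[state.kept_rows].to_numpy()
    p = X_model.shape[1]
    rf = RandomForestClassifier(
        n_estimators=rf_params.n_trees,
        max_features=RFParams.mtry(p),
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X_model.to_numpy(), y_model)
    return rf, state, list(X_model.columns)


def run_combination(
    table: DescriptorTable,
    labels: pd.Series,
    combo: tuple[str, ...],
    plan: SplitPlan,
    rf_params: RFParams = RFParams(),
    preprocess: PreprocessConfig = PreprocessConfig(),
    cutoffs: DomainCutoffs | None = None,
) -> list[ModelResult]:
    """One full repeated-CV pass for one descriptor-domain combination.

    Preprocessing failures in a fold abort that fold only, recorded as a
    ModelResult with ``error`` set.
    """
    if not combo or not set(combo) <= set(DOMAINS):
        raise ValueError(f"combo must be a non-empty subset of {DOMAINS}, got {combo}")
    if tuple(plan.compound_ids) != tuple(labels.index):
        raise ValueError("split plan does not match the label index")
    sub = table.restrict(combo)
    if cutoffs is None:
        try:
            cutoffs = calibrate_cutoffs(
                sub,
                preprocess.target_size,
                nzv_freq_ratio=preprocess.nzv_freq_ratio,
                nzv_unique_cut=preprocess.nzv_unique_cut,
            )
        except ValueError as exc:
            # degenerate block: let each fold fail with its own diagnostic
            logger.warning("combo=%s cutoff calibration failed: %s", "+".join(combo), exc)
            cutoffs = DomainCutoffs({d: 1.0 for d in combo})
    combo_idx = ALL_COMBOS.index(tuple(combo))

    results: list[ModelResult] = []
    ids = np.asarray(plan.compound_ids)
    for repeat, fold in plan.cells():
        seed = cell_seed(plan.seed, combo_idx, repeat, fold, 0)
        ext_mask = plan.fold_mask(repeat, fold)
        modeling_ids = list(ids[~ext_mask])
        external_ids = list(ids[ext_mask])
        logger.info(
            "stage=fit repeat=%d fold=%d combo=%s n_model=%d n_external=%d",
            repeat, fold, "+".join(combo), len(modeling_ids), len(external_ids),
        )
        try:
            rf, state, _ = _fit_cell(
                table=sub,
                labels=labels,
                modeling_ids=modeling_ids,
                cutoffs=cutoffs,
                preprocess=preprocess,
                rf_params=rf_params,
                seed=seed,
            )
        except ValueError as exc:
            logger.warning(
                "stage=fit repeat=%d fold=%d combo=%s failed: %s",
                repeat, fold, "+".join(combo), exc,
            )
            results.append(
                ModelResult(
                    repeat=repeat,
                    fold=fold,
                    combo=tuple(combo),
                    predictions=pd.DataFrame(
                        columns=["truth", "prediction", "p_toxic"]
                    ),
                    state=PreprocessState({}, {}, []),
                    importances=pd.Series(dtype=float),
                    seed=seed,
                    error=str(exc),
                )
            )
            continue
        ext_table = DescriptorTable(sub.data.loc[external_ids], sub.domains.copy())
        X_ext = transform(state, ext_table)
        pred, p_toxic = _vote_predict(rf, X_ext.to_numpy())
        predictions = pd.DataFrame(
            {
                "truth": labels.loc[external_ids].to_numpy(),
                "prediction": pred,
                "p_toxic": p_toxic,
            },
            index=pd.Index(external_ids, name="compound_id"),
        )
        importances = pd.Series(rf.feature_importances_, index=X_ext.columns)
        results.append(
            ModelResult(
                repeat=repeat,
                fold=fold,
                combo=tuple(combo),
                predictions=predictions,
                state=state,
                importances=importances,
                seed=seed,
            )
        )
    return results


def _ccr(truth: np.ndarray, pred: np.ndarray) -> float:
    sens = float((pred[truth == 1] == 1).mean())
    sel = float((pred[truth == 0] == 0).mean())
    return 0.5 * (sens + sel)


def y_scramble_assess(
    table: DescriptorTable,
    labels: pd.Series,
    result: ModelResult,
    plan: SplitPlan,
    rf_params: RFParams = RFParams(),
    preprocess: PreprocessConfig = PreprocessConfig(),
    cutoffs: DomainCutoffs | None = None,
    n_scrambles: int = 10,
) -> float:
    """One-tailed p-value that the real model's CCR sits inside the
    distribution of CCRs from label-scrambled retrains.

    The modelling-set labels are permuted uniformly ``n_scrambles`` times
    (external labels untouched), the full pipeline — preprocessing included —
    is refitted each time, and the real external CCR is compared against the
    scrambled CCRs with a predictive one-tailed t-test:
    t = (real - mean_scr) / (sd_scr * sqrt(1 + 1/n)). A model passes the
    robustness check when p < 0.05. With zero scrambled variance the
    degenerate rule applies: p = 0 if the real CCR exceeds the common value,
    else 1.
    """
    if n_scrambles < 2:
        raise ValueError("insufficient scrambles for t-test (need >= 2)")
    if result.error is not None:
        raise ValueError(f"cannot scramble a failed cell: {result.error}")
    sub = table.restrict(result.combo)
    if cutoffs is None:
        cutoffs = calibrate_cutoffs(
            sub,
            preprocess.target_size,
            nzv_freq_ratio=preprocess.nzv_freq_ratio,
            nzv_unique_cut=preprocess.nzv_unique_cut,
        )
    ids = np.asarray(plan.compound_ids)
    ext_mask = plan.fold_mask(result.repeat, result.fold)
    modeling_ids = list(ids[~ext_mask])
    external_ids = list(ids[ext_mask])
    truth = labels.loc[external_ids].to_numpy()
    real_ccr = _ccr(truth, result.predictions.loc[external_ids, "prediction"].to_numpy())

    combo_idx = ALL_COMBOS.index(tuple(result.combo))
    scrambled_ccrs = []
    for s in range(1, n_scrambles + 1):
        seed = cell_seed(plan.seed, combo_idx, result.repeat, result.fold, s)
        rng = np.random.default_rng(seed)
        scrambled = labels.copy()
        scrambled.loc[modeling_ids] = rng.permutation(
            labels.loc[modeling_ids].to_numpy()
        )
        logger.info(
            "stage=scramble repeat=%d fold=%d combo=%s scramble=%d",
            result.repeat, result.fold, "+".join(result.combo), s,
        )
        try:
            rf, state, _ = _fit_cell(
                table=sub,
                labels=scrambled,
                modeling_ids=modeling_ids,
                cutoffs=cutoffs,
                preprocess=preprocess,
                rf_params=rf_params,
                seed=seed,
            )
        except ValueError:
            # a scramble can wipe out one class after downsampling; a chance
            # model that cannot even train scores chance-level
            scrambled_ccrs.append(0.5)
            continue
        ext_table = DescriptorTable(sub.data.loc[external_ids], sub.domains.copy())
        pred, _ = _vote_predict(rf, transform(state, ext_table).to_numpy())
        scrambled_ccrs.append(_ccr(truth, pred))

    scr = np.asarray(scrambled_ccrs)
    sd = scr.std(ddof=1)
    if sd == 0:
        return 0.0 if real_ccr > scr[0] else 1.0
    t = (real_ccr - scr.mean()) / (sd * math.sqrt(1.0 + 1.0 / len(scr)))
    return float(stats.t.sf(t, df=len(scr) - 1))
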