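"""End-to-end orchestration: cohort -> descriptors -> models -> reports.

This is the library face of the command-line interface; each stage reads
and writes plain CSV/JSON artifacts so a run is resumable and auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic_data
from .featurization import DescriptorTable, assemble_table, qhts_block
from .modeling import (
    ALL_COMBOS,
    ModelResult,
    RFParams,
    SplitPlan,
    make_split_plan,
    run_combination,
    y_scramble_assess,
)
from .preprocessing import DomainCutoffs, PreprocessConfig, PreprocessState, calibrate_cutoffs
from .evaluation import (
    ad_profile,
    aggregate_importance,
    domain_distance_matrices,
    mantel_test,
    paired_improvement,
    summarize,
)
from .target_scorer import records_from_table, score_matrix, train_target_model

logger = logging.getLogger("toxtriad")

__all__ = [
    "RunConfig",
    "featurize_cohort",
    "run_models",
    "save_results",
    "load_results",
    "evaluate_results",
]

_KNOWN_KEYS = {
    "cohort_dir",
    "output_dir",
    "synthetic",
    "n_repeats",
    "n_folds",
    "n_trees",
    "n_scrambles",
    "master_seed",
    "combos",
    "preprocessing",
    "scramble_cells",
}

_PREPROCESS_KEYS = {
    "nzv_freq_ratio",
    "nzv_unique_cut",
    "target_size",
    "downsample_ratio",
    "recalibrate_cutoffs_per_fold",
}


@dataclass
class RunConfig:
    """Validated configuration for a full run."""

    cohort_dir: str = "cohort"
    output_dir: str = "results"
    synthetic: dict = field(default_factory=dict)
    n_repeats: int = 20
    n_folds: int = 5
    n_trees: int = 500
    n_scrambles: int = 10
    master_seed: int = 0
    combos: list[tuple[str, ...]] = field(default_factory=lambda: list(ALL_COMBOS))
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    scramble_cells: int | None = None  # None: assess every cell

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw = dict(raw)
        if "preprocessing" in raw:
            pp = raw["preprocessing"]
            bad = set(pp) - _PREPROCESS_KEYS
            if bad:
                raise ValueError(f"unknown preprocessing keys: {sorted(bad)}")
            raw["preprocessing"] = PreprocessConfig(**pp)
        if "combos" in raw:
            raw["combos"] = [tuple(c) for c in raw["combos"]]
        cfg = cls(**raw)
        for key in ("n_repeats", "n_folds", "n_trees", "n_scrambles"):
            if getattr(cfg, key) < 1:
                raise ValueError(f"config key {key} must be >= 1")
        return cfg


def simulate(config: RunConfig) -> Path:
    """Generate and write a synthetic cohort."""
    syn = synthetic_data.SyntheticConfig(
        **{**config.synthetic, "seed": config.synthetic.get("seed", config.master_seed)}
    )
    cohort = synthetic_data.generate_cohort(syn)
    out = Path(config.cohort_dir)
    synthetic_data.write_cohort(cohort, out)
    logger.info("stage=simulate n_compounds=%d dir=%s", syn.n_compounds, out)
    return out


def featurize_cohort(
    cohort_dir: str | Path, min_records: int = 50
) -> tuple[DescriptorTable, pd.Series, pd.DataFrame]:
    """Build the three descriptor blocks and labels from cohort files."""
    cohort = synthetic_data.read_cohort(cohort_dir)
    records = records_from_table(cohort.bioactivity_table, cohort.bioactivity_fingerprints)
    model = train_target_model(records, min_records=min_records)
    logger.info(
        "stage=featurize targets_retained=%d targets_dropped=%d",
        len(model.targets), len(model.dropped_targets),
    )
    scores = score_matrix(
        model, dict(zip(cohort.compound_ids, cohort.fingerprints))
    )
    cyto = qhts_block(cohort.qhts_raw)
    return assemble_table(cohort.chem_descriptors, scores, cyto, cohort.pld50)


def run_models(
    table: DescriptorTable,
    labels: pd.Series,
    config: RunConfig,
) -> tuple[dict[tuple[str, ...], list[ModelResult]], SplitPlan]:
    """Repeated CV for every configured combo over one shared split plan,
    plus y-scrambling on the configured number of cells per combo."""
    plan = make_split_plan(
        labels, n_repeats=config.n_repeats, n_folds=config.n_folds, seed=config.master_seed
    )
    rf = RFParams(n_trees=config.n_trees, seed=config.master_seed)
    results: dict[tuple[str, ...], list[ModelResult]] = {}
    for combo in config.combos:
        sub = table.restrict(combo)
        cutoffs = calibrate_cutoffs(
            sub,
            config.preprocessing.target_size,
            nzv_freq_ratio=config.preprocessing.nzv_freq_ratio,
            nzv_unique_cut=config.preprocessing.nzv_unique_cut,
        )
        combo_results = run_combination(
            table, labels, combo, plan, rf, config.preprocessing, cutoffs
        )
        n_cells = (
            len(combo_results) if config.scramble_cells is None else config.scramble_cells
        )
        for r in combo_results[:n_cells]:
            if r.error is None:
                r.scramble_p = y_scramble_assess(
                    table, labels, r, plan, rf, config.preprocessing, cutoffs,
                    n_scrambles=config.n_scrambles,
                )
        results[combo] = combo_results
    return results, plan


# ---------------------------------------------------------------------------
# persistence between CLI stages
# ---------------------------------------------------------------------------

def save_results(
    results: dict[tuple[str, ...], list[ModelResult]], directory: str | Path
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pred_rows, imp_rows, state_map = [], [], {}
    for combo, rs in results.items():
        combo_name = "+".join(combo)
        for r in rs:
            key = f"{combo_name}/{r.repeat}/{r.fold}"
            state_map[key] = {
                "kept_columns": r.state.kept_columns,
                "scaler_bounds": {c: list(b) for c, b in r.state.scaler_bounds.items()},
                "kept_rows": r.state.kept_rows,
                "seed": r.seed,
                "scramble_p": r.scramble_p,
                "error": r.error,
            }
            if r.error is not None:
                continue
            for cid, row in r.predictions.iterrows():
                pred_rows.append(
                    (combo_name, r.repeat, r.fold, cid,
                     int(row["truth"]), int(row["prediction"]), row["p_toxic"])
                )
            for col, v in r.importances.items():
                imp_rows.append((combo_name, r.repeat, r.fold, col, v))
    pd.DataFrame(
        pred_rows,
        columns=["combo", "repeat", "fold", "compound_id", "truth", "prediction", "p_toxic"],
    ).to_csv(directory / "predictions.csv", index=False)
    pd.DataFrame(
        imp_rows, columns=["combo", "repeat", "fold", "descriptor", "importance"]
    ).to_csv(directory / "importances.csv", index=False)
    with open(directory / "states.json", "w", encoding="utf-8") as fh:
        json.dump(state_map, fh)


def load_results(directory: str | Path) -> dict[tuple[str, ...], list[ModelResult]]:
    directory = Path(directory)
    preds = pd.read_csv(directory / "predictions.csv", dtype={"compound_id": str})
    imps = pd.read_csv(directory / "importances.csv")
    with open(directory / "states.json", encoding="utf-8") as fh:
        state_map = json.load(fh)
    pred_groups = dict(tuple(preds.groupby(["combo", "repeat", "fold"])))
    imp_groups = dict(tuple(imps.groupby(["combo", "repeat", "fold"])))
    results: dict[tuple[str, ...], list[ModelResult]] = {}
    for key, meta in state_map.items():
        combo_name, repeat, fold = key.rsplit("/", 2)
        combo = tuple(combo_name.split("+"))
        repeat, fold = int(repeat), int(fold)
        gkey = (combo_name, repeat, fold)
        if meta["error"] is not None:
            predictions = pd.DataFrame(columns=["truth", "prediction", "p_toxic"])
            importances = pd.Series(dtype=float)
        else:
            g = pred_groups[gkey]
            predictions = pd.DataFrame(
                {
                    "truth": g["truth"].to_numpy(),
                    "prediction": g["prediction"].to_numpy(),
                    "p_toxic": g["p_toxic"].to_numpy(),
                },
                index=pd.Index(g["compound_id"], name="compound_id"),
            )
            gi = imp_groups[gkey]
            importances = pd.Series(
                gi["importance"].to_numpy(), index=gi["descriptor"].tolist()
            )
        state = PreprocessState(
            kept_columns=meta["kept_columns"],
            scaler_bounds={c: tuple(b) for c, b in meta["scaler_bounds"].items()},
            kept_rows=meta["kept_rows"],
        )
        results.setdefault(combo, []).append(
            ModelResult(
                repeat=repeat,
                fold=fold,
                combo=combo,
                predictions=predictions,
                state=state,
                importances=importances,
                seed=meta["seed"],
                scramble_p=meta["scramble_p"],
                error=meta["error"],
            )
        )
    for rs in results.values():
        rs.sort(key=lambda r: (r.repeat, r.fold))
    return results


def evaluate_results(
    results: dict[tuple[str, ...], list[ModelResult]],
    table: DescriptorTable,
    labels: pd.Series,
    output_dir: str | Path,
    master_seed: int = 0,
    mantel_permutations: int = 999,
) -> dict[str, pd.DataFrame]:
    """Emit the performance, improvement, importance, AD-profile and
    Mantel reports as CSV files; returns them as DataFrames too."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    header = f"# master_seed={master_seed}\n"

    summaries = {combo: summarize(rs) for combo, rs in results.items()}
    perf = pd.DataFrame(
        [
            {
                "combo": "+".join(combo),
                "ccr_mean": s.mean["ccr"],
                "ccr_sd": s.sd["ccr"],
                "sensitivity_mean": s.mean["sensitivity"],
                "sensitivity_sd": s.sd["sensitivity"],
                "selectivity_mean": s.mean["selectivity"],
                "selectivity_sd": s.sd["selectivity"],
            }
            for combo, s in summaries.items()
        ]
    )

    imp_rows = []
    for combo_a, rs_a in results.items():
        for combo_b, rs_b in results.items():
            if set(combo_b) < set(combo_a):
                rec = paired_improvement(rs_a, rs_b)
                imp_rows.append(
                    {
                        "combo": "+".join(combo_a),
                        "comparison": "+".join(combo_b),
                        "ccr_improvement_mean": rec.mean,
                        "ccr_improvement_se": rec.se,
                        "p_value": rec.p_value,
                    }
                )
    improvements = pd.DataFrame(imp_rows)

    # shared chemical coordinates for AD and neighbor analyses: full-data
    # preprocessing of the chemical block
    from .preprocessing import apply_correlation_filter, apply_range_scaler, drop_near_zero_variance, fit_range_scaler

    blocks = {}
    cutoffs = calibrate_cutoffs(table)
    for domain in table.domains.unique():
        block, _ = drop_near_zero_variance(table.block(domain))
        block = apply_correlation_filter(block, cutoffs.cutoffs[domain])
        blocks[domain] = apply_range_scaler(fit_range_scaler(block), block)

    reports: dict[str, pd.DataFrame] = {
        "performance": perf,
        "improvements": improvements,
    }

    chem_combos = {c: rs for c, rs in results.items() if "chemical" in c}
    if chem_combos and "chemical" in blocks:
        profile = ad_profile(chem_combos, blocks["chemical"])
        reports["ad_profile"] = profile.per_bin

    mantel_rows = []
    mats = domain_distance_matrices(blocks)
    names = sorted(mats)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            res = mantel_test(mats[a], mats[b], n_perm=mantel_permutations, seed=master_seed)
            mantel_rows.append(
                {"domain_a": a, "domain_b": b, "r": res.r, "p_value": res.p_value,
                 "n_permutations": res.n_permutations}
            )
    if mantel_rows:
        reports["mantel"] = pd.DataFrame(mantel_rows)

    tri = results.get(("chemical", "target", "cytotox"))
    if tri:
        reports["importance"] = aggregate_importance(tri, table.domains)

    scramble_rows = []
    for combo, rs in results.items():
        ps = [r.scramble_p for r in rs if r.scramble_p is not None]
        if ps:
            scramble_rows.append(
                {
                    "combo": "+".join(combo),
                    "n_assessed": len(ps),
                    "n_passed": int(sum(p < 0.05 for p in ps)),
                }
            )
    if scramble_rows:
        reports["scramble"] = pd.DataFrame(scramble_rows)

    for name, frame in reports.items():
        path = output_dir / f"{name}.csv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header)
            frame.to_csv(fh, index=False)
    return reports
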