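"""Multi-target Laplacian-modified naive Bayesian interaction scorer.

Trained on a table of (compound fingerprint, target, active/inactive)
records, the model assigns every compound a per-target log-likelihood score

    score(t, x) = sum over features f in x of ln[(A_tf + 1) / (N_f * P_t + 1)]

where A_tf counts active training compounds for target t containing feature
f, N_f counts training compounds containing f, and P_t is the target's
active prior. The score measures the *expectation* of an interaction — a
relative-likelihood quantity, not a predicted affinity or potency — and the
vector of scores over all retained targets serves as the protein-target
descriptor block. Features never seen in training are Laplacian-neutral and
contribute ln(1/1) = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BioactivityRecord",
    "TargetModel",
    "train_target_model",
    "score_compound",
    "score_matrix",
    "records_from_table",
    "fingerprint_from_smiles",
]


@dataclass(frozen=True)
class BioactivityRecord:
    """One compound-target activity annotation.

    ``compound_id`` disambiguates repeated measurements of the same compound
    against different targets; when absent, the fingerprint itself is used
    as the compound's identity.
    """

    fingerprint: frozenset[int]
    target_id: str
    active: bool
    compound_id: str | None = None

    def __post_init__(self) -> None:
        if not self.fingerprint:
            raise ValueError("fingerprint must be non-empty")


@dataclass
class TargetModel:
    """Laplacian-corrected count statistics for every retained target."""

    targets: list[str]
    feature_index: dict[int, int]  # feature id -> row in active_counts
    active_counts: np.ndarray  # n_features x n_targets  (A_tf)
    n_active: np.ndarray  # per target
    n_records: np.ndarray  # per target
    priors: np.ndarray  # P_t = n_active_t / n_records_t
    feature_counts: np.ndarray  # N_f over distinct training compounds
    n_train: int
    min_records: int = 50
    dropped_targets: dict[str, str] = field(default_factory=dict)

    @property
    def log_ratios(self) -> np.ndarray:
        """ln[(A_tf + 1) / (N_f * P_t + 1)] for every seen feature and target."""
        return np.log(
            (self.active_counts + 1.0)
            / (self.feature_counts[:, None] * self.priors[None, :] + 1.0)
        )


def train_target_model(
    records: list[BioactivityRecord], min_records: int = 50
) -> TargetModel:
    """Tally activity counts and priors, dropping under-supported targets.

    Targets with fewer than ``min_records`` records, or with a degenerate
    prior (no actives, or no inactives), are dropped and listed in
    ``dropped_targets`` with the reason.
    """
    if not records:
        raise ValueError("no bioactivity records supplied")

    # distinct training compounds (by id if given, else by fingerprint)
    compound_fp: dict[object, frozenset[int]] = {}
    for rec in records:
        key = rec.compound_id if rec.compound_id is not None else rec.fingerprint
        compound_fp[key] = rec.fingerprint
    n_train = len(compound_fp)

    feature_counts_raw: dict[int, int] = {}
    for fp in compound_fp.values():
        for f in fp:
            feature_counts_raw[f] = feature_counts_raw.get(f, 0) + 1

    by_target: dict[str, list[BioactivityRecord]] = {}
    for rec in records:
        by_target.setdefault(rec.target_id, []).append(rec)

    dropped: dict[str, str] = {}
    retained: list[str] = []
    for tid in sorted(by_target):
        recs = by_target[tid]
        n_act = sum(r.active for r in recs)
        if len(recs) < min_records:
            dropped[tid] = f"only {len(recs)} records (< {min_records})"
        elif n_act == 0:
            dropped[tid] = "no active records (prior undefined)"
        elif n_act == len(recs):
            dropped[tid] = "no inactive records (prior degenerate)"
        else:
            retained.append(tid)
    if not retained:
        raise ValueError(
            f"no target has >= {min_records} records with both classes present"
        )

    feature_index = {f: i for i, f in enumerate(sorted(feature_counts_raw))}
    A = np.zeros((len(feature_index), len(retained)))
    n_active = np.zeros(len(retained))
    n_rec = np.zeros(len(retained))
    for t, tid in enumerate(retained):
        for rec in by_target[tid]:
            n_rec[t] += 1
            if rec.active:
                n_active[t] += 1
                for f in rec.fingerprint:
                    A[feature_index[f], t] += 1
    feature_counts = np.array([feature_counts_raw[f] for f in sorted(feature_counts_raw)], dtype=float)

    return TargetModel(
        targets=retained,
        feature_index=feature_index,
        active_counts=A,
        n_active=n_active,
        n_records=n_rec,
        priors=n_active / n_rec,
        feature_counts=feature_counts,
        n_train=n_train,
        min_records=min_records,
        dropped_targets=dropped,
    )


def score_compound(model: TargetModel, fingerprint: frozenset[int]) -> np.ndarray:
    """Per-target interaction-likelihood score for one fingerprint."""
    if not fingerprint:
        warnings.warn("empty fingerprint: returning zero scores", stacklevel=2)
        return np.zeros(len(model.targets))
    rows = [model.feature_index[f] for f in fingerprint if f in model.feature_index]
    if not rows:
        return np.zeros(len(model.targets))
    return model.log_ratios[rows, :].sum(axis=0)


def score_matrix(
    model: TargetModel, fingerprints: dict[str, frozenset[int]]
) -> pd.DataFrame:
    """Batch scoring; row i is exactly ``score_compound`` on fingerprint i."""
    L = model.log_ratios
    out = np.zeros((len(fingerprints), len(model.targets)))
    for i, fp in enumerate(fingerprints.values()):
        rows = [model.feature_index[f] for f in fp if f in model.feature_index]
        if rows:
            out[i] = L[rows, :].sum(axis=0)
    return pd.DataFrame(
        out, index=pd.Index(list(fingerprints), name="compound_id"), columns=model.targets
    )


def records_from_table(
    table: pd.DataFrame, fingerprints: dict[str, frozenset[int]]
) -> list[BioactivityRecord]:
    """Join a long bioactivity table (compound_id, target_id, active) with a
    fingerprint map into scoring records."""
    records = []
    for row in table.itertuples(index=False):
        fp = fingerprints.get(row.compound_id)
        if fp is None:
            raise KeyError(f"no fingerprint for compound {row.compound_id!r}")
        records.append(
            BioactivityRecord(
                fingerprint=fp,
                target_id=str(row.target_id),
                active=bool(row.active),
                compound_id=str(row.compound_id),
            )
        )
    return records


def fingerprint_from_smiles(smiles: str, radius: int = 2, n_bits: int = 1024) -> frozenset[int]:
    """Hashed circular (atom-environment) fingerprint for real structures.

    Requires RDKit; synthetic cohorts ship ready-made bit sets and do not
    use this path.
    """
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover
        raise ImportError("real-structure fingerprints require rdkit") from exc
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"could not parse SMILES {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    return frozenset(fp.GetOnBits())
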