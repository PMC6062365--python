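"""Assembly of the three domain-tagged descriptor blocks and class labels.

Toxicity classes follow the pLD50 thresholds used throughout: pLD50 < 2 is
nontoxic, pLD50 > 3 is toxic, and the band in between (boundaries included)
is marginal and excluded from modelling. Cytotoxicity descriptors are the
per-curve max-scaled qHTS responses, one column per (cell line,
concentration) pair — 13 x 14 = 182 at the benchmark shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DOMAINS",
    "DoseResponseProfile",
    "ToxicityRecord",
    "DescriptorTable",
    "classify_toxicity",
    "scale_qhts_profile",
    "qhts_block",
    "assemble_table",
]

DOMAINS = ("chemical", "target", "cytotox")


@dataclass(frozen=True)
class DoseResponseProfile:
    """One compound's concentration-response curve on one cell line."""

    compound_id: str
    cell_line: str
    points: tuple[tuple[float, float], ...]  # (concentration uM, response)

    def __post_init__(self) -> None:
        concs = [c for c, _ in self.points]
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise ValueError("concentrations must be strictly increasing")


@dataclass(frozen=True)
class ToxicityRecord:
    compound_id: str
    pld50: float
    tox_class: str

    def __post_init__(self) -> None:
        if classify_toxicity(self.pld50) != self.tox_class:
            raise ValueError(
                f"tox_class {self.tox_class!r} inconsistent with pLD50 {self.pld50}"
            )


@dataclass
class DescriptorTable:
    """Compounds x descriptors with a domain tag per column."""

    data: pd.DataFrame
    domains: pd.Series  # column -> domain tag

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise ValueError("descriptor column names must be unique")
        if self.data.isna().any().any():
            raise ValueError("descriptor table must have no missing values")
        unknown = set(self.domains.unique()) - set(DOMAINS)
        if unknown:
            raise ValueError(f"unknown domain tags: {sorted(unknown)}")
        if list(self.domains.index) != list(self.data.columns):
            raise ValueError("domain tags must cover exactly the data columns")

    def columns_for(self, domain: str) -> list[str]:
        return [c for c, d in self.domains.items() if d == domain]

    def block(self, domain: str) -> pd.DataFrame:
        return self.data[self.columns_for(domain)]

    def restrict(self, domains: tuple[str, ...] | list[str]) -> "DescriptorTable":
        cols = [c for c, d in self.domains.items() if d in domains]
        return DescriptorTable(self.data[cols], self.domains[cols])


def classify_toxicity(pld50: float, low: float = 2.0, high: float = 3.0) -> str:
    """Threshold a pLD50 value: < low -> nontoxic, > high -> toxic, else
    marginal (strict inequalities; exact boundary values are marginal)."""
    if not math.isfinite(pld50):
        raise ValueError(f"pLD50 must be finite, got {pld50}")
    if pld50 < low:
        return "nontoxic"
    if pld50 > high:
        return "toxic"
    return "marginal"


def scale_qhts_profile(responses: np.ndarray | list[float]) -> np.ndarray:
    """Scale a response curve so its maximum equals one.

    A profile whose maximum response is nonpositive shows no measurable
    cytotoxicity and maps to all zeros (dividing by a nonpositive maximum
    would flip signs).
    """
    r = np.asarray(responses, dtype=float)
    m = r.max() if r.size else 0.0
    if m <= 0:
        return np.zeros_like(r)
    return r / m


def qhts_block(qhts: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long qHTS table into max-scaled cytotoxicity descriptors.

    Input columns: compound_id, cell_line, concentration_um, response.
    Output: one row per compound, one column per (cell line, concentration),
    each curve scaled to unit maximum. Column names are
    ``cyto_<cell_line>_<concentration>``.
    """
    required = {"compound_id", "cell_line", "concentration_um", "response"}
    missing = required - set(qhts.columns)
    if missing:
        raise ValueError(f"qHTS table missing columns: {sorted(missing)}")
    wide = qhts.pivot_table(
        index="compound_id",
        columns=["cell_line", "concentration_um"],
        values="response",
        sort=True,
    )
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValueError(f"incomplete qHTS profiles for compounds: {bad[:5]}")
    scaled = np.empty_like(wide.to_numpy())
    lines = wide.columns.get_level_values(0)
    for line in lines.unique():
        cols = np.flatnonzero(lines == line)
        block = wide.to_numpy()[:, cols]
        maxima = block.max(axis=1)
        out = np.zeros_like(block)
        pos = maxima > 0
        out[pos] = block[pos] / maxima[pos, None]
        scaled[:, cols] = out
    names = [f"cyto_{line}_{conc:g}" for line, conc in wide.columns]
    return pd.DataFrame(scaled, index=wide.index.astype(str), columns=names)


def assemble_table(
    chem: pd.DataFrame,
    target_scores: pd.DataFrame,
    cytotox: pd.DataFrame,
    pld50: pd.Series,
) -> tuple[DescriptorTable, pd.Series, pd.DataFrame]:
    """Join the three blocks on shared compounds and derive binary labels.

    Marginal compounds are removed; compounds missing from any domain are
    excluded (intersection semantics). Returns the descriptor table, binary
    labels (1 = toxic), and a report of excluded compounds with reasons.
    """
    blocks = {"chemical": chem, "target": target_scores, "cytotox": cytotox}
    shared = set(pld50.index)
    for b in blocks.values():
        shared &= set(b.index)

    excluded = []
    for cid in pld50.index:
        missing = [name for name, b in blocks.items() if cid not in b.index]
        if missing:
            excluded.append((cid, f"missing from {', '.join(missing)} domain"))
    for name, b in blocks.items():
        for cid in b.index:
            if cid not in pld50.index:
                excluded.append((cid, "missing toxicity value"))
                shared.discard(cid)

    order = [cid for cid in pld50.index if cid in shared]
    classes = {cid: classify_toxicity(pld50[cid]) for cid in order}
    kept = [cid for cid in order if classes[cid] != "marginal"]
    excluded.extend((cid, "marginal toxicity") for cid in order if classes[cid] == "marginal")
    if not kept:
        raise ValueError("empty modeling table: no non-marginal compounds shared by all domains")

    parts, tags = [], []
    for name in DOMAINS:
        b = blocks[name].loc[kept]
        parts.append(b)
        tags.extend([name] * b.shape[1])
    data = pd.concat(parts, axis=1)
    data.index.name = "compound_id"
    table = DescriptorTable(data, pd.Series(tags, index=data.columns))
    labels = pd.Series(
        [1 if classes[cid] == "toxic" else 0 for cid in kept],
        index=data.index,
        name="toxic",
    )
    report = pd.DataFrame(excluded, columns=["compound_id", "reason"])
    return table, labels, report
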