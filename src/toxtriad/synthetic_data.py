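"""Synthetic cohort generator for the triply-heterogeneous toxicity pipeline.

Emulates the statistical structure of a rat acute-toxicity modelling cohort:
~367 compounds with a ~275:92 nontoxic:toxic imbalance, ~192 numeric chemical
descriptors, sparse binary circular-fingerprint bit sets, 13 cell-line qHTS
concentration-response profiles of 14 points each (0.6-92 uM), and a separate
bioactivity training table for the in-silico target-prediction model.

Toxicity signal is routed through a small set of latent "mechanisms", split
into three facets (chemical-facing, target-facing, cytotoxicity-facing).
pLD50 is a weighted sum of facet activations plus Gaussian noise, with the
weight of each facet set by ``domain_signal_weights``; each descriptor domain
observes only its own facet, so integrating domains is genuinely rewarded.
The latent matrix is stored for recovery tests only and is never consumed by
the modelling modules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticCohort",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

#: fraction of compounds deliberately left in the marginal (2 < pLD50 < 3)
#: band; the remaining probability mass is split to match the configured
#: class counts.
MARGINAL_MASS = 0.10

#: dedicated fingerprint bits per latent mechanism.
BITS_PER_MECHANISM = 40

#: fraction of chemical descriptors that load on mechanisms (rest are decoys).
CHEM_LINKED_FRACTION = 0.75

#: fraction of protein targets whose activity depends on mechanisms.
TARGET_LINKED_FRACTION = 0.35


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the benchmark dataset shape: 367 compounds (92 toxic),
    192 chemical descriptors, 477 protein targets, 13 cell lines x 14
    concentrations spanning 0.6-92 uM.
    """

    n_compounds: int = 367
    n_toxic: int = 92
    n_chem_descriptors: int = 192
    n_fingerprint_bits: int = 1024
    n_targets: int = 477
    n_cell_lines: int = 13
    n_concentrations: int = 14
    concentration_range: tuple[float, float] = (0.6, 92.0)
    n_latent_mechanisms: int = 12
    domain_signal_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    noise_sd: float = 0.6
    qhts_noise_sd: float = 0.05
    hill_emax_range: tuple[float, float] = (0.4, 1.0)
    hill_ec50_range: tuple[float, float] = (1.0, 60.0)
    hill_slope_range: tuple[float, float] = (0.8, 2.5)
    n_bioactivity_compounds: int = 1200
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_compounds": self.n_compounds,
            "n_toxic": self.n_toxic,
            "n_chem_descriptors": self.n_chem_descriptors,
            "n_fingerprint_bits": self.n_fingerprint_bits,
            "n_targets": self.n_targets,
            "n_cell_lines": self.n_cell_lines,
            "n_concentrations": self.n_concentrations,
            "n_latent_mechanisms": self.n_latent_mechanisms,
            "n_bioactivity_compounds": self.n_bioactivity_compounds,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        if self.n_toxic >= self.n_compounds:
            raise ValueError("n_toxic must be smaller than n_compounds")
        if abs(sum(self.domain_signal_weights) - 1.0) > 1e-9:
            raise ValueError("domain_signal_weights must sum to 1")
        if any(w < 0 for w in self.domain_signal_weights):
            raise ValueError("domain_signal_weights must be nonnegative")
        if self.noise_sd < 0 or self.qhts_noise_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        for name in ("concentration_range", "hill_emax_range", "hill_ec50_range", "hill_slope_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive (low, high) interval")


@dataclass
class GroundTruth:
    """Latent structure of a cohort; for recovery tests only.

    The modelling modules must never read this: they consume only the
    observable tables (descriptors, fingerprints, qHTS, pLD50, bioactivity).
    """

    latent_mechanisms: np.ndarray  # n_compounds x n_mechanisms
    facet_of_mechanism: np.ndarray  # 0=chemical, 1=target, 2=cytotox
    mechanism_bits: list[list[int]]  # dedicated fingerprint bits per mechanism
    chem_linked_columns: list[str]  # descriptor columns carrying signal
    linked_targets: list[str]  # targets with nonzero mechanism affinity
    target_affinity: np.ndarray  # n_targets x n_mechanisms loading matrix


@dataclass
class SyntheticCohort:
    compound_ids: list[str]
    fingerprints: list[frozenset[int]]
    chem_descriptors: pd.DataFrame  # index compound_id
    qhts_raw: pd.DataFrame  # long: compound_id, cell_line, concentration_um, response
    pld50: pd.Series  # index compound_id
    bioactivity_table: pd.DataFrame  # compound_id, target_id, active
    bioactivity_fingerprints: dict[str, frozenset[int]]
    ground_truth: GroundTruth
    config: SyntheticConfig

    @property
    def latent_mechanisms(self) -> np.ndarray:
        return self.ground_truth.latent_mechanisms

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SyntheticCohort):
            return NotImplemented
        return (
            self.compound_ids == other.compound_ids
            and self.fingerprints == other.fingerprints
            and self.chem_descriptors.equals(other.chem_descriptors)
            and self.qhts_raw.equals(other.qhts_raw)
            and self.pld50.equals(other.pld50)
            and self.bioactivity_table.equals(other.bioactivity_table)
            and self.bioactivity_fingerprints == other.bioactivity_fingerprints
            and np.array_equal(self.latent_mechanisms, other.latent_mechanisms)
        )


def _facet_assignment(n_mechanisms: int) -> np.ndarray:
    """Split mechanisms into three facets as evenly as possible."""
    return np.arange(n_mechanisms) % 3


def _solve_pld50_scale(q_toxic: float, low: float = 2.0, high: float = 3.0) -> tuple[float, float]:
    """Baseline and total sd of the Gaussian pLD50 model.

    Chosen so that P(pLD50 > high) = q_toxic*(1-m) and
    P(pLD50 < low) = (1-q_toxic)*(1-m) with marginal mass m = MARGINAL_MASS;
    the toxic fraction among classified compounds is then exactly q_toxic.
    """
    q_t = q_toxic * (1.0 - MARGINAL_MASS)
    q_n = (1.0 - q_toxic) * (1.0 - MARGINAL_MASS)
    z_hi = norm.ppf(1.0 - q_t)
    z_lo = norm.ppf(q_n)
    sigma = (high - low) / (z_hi - z_lo)
    mu = low - sigma * z_lo
    return mu, sigma


def _fingerprints_from_latent(
    Z: np.ndarray,
    mechanism_bits: list[list[int]],
    n_bits: int,
    rng: np.random.Generator,
) -> list[frozenset[int]]:
    """Mechanism-linked bits switch on with probability driven by activation.

    Half of each mechanism's bits respond to positive activation and half to
    negative (presence and absence of substructures are both informative);
    the symmetric design keeps total fingerprint density flat in activation,
    so the activation signal lives in *which* bits are on, not how many —
    without this, every target score would share one density factor and
    per-target interpretation would be meaningless.
    """
    n = Z.shape[0]
    on = rng.random((n, n_bits)) < 0.03  # background bits
    for m, bits in enumerate(mechanism_bits):
        half = len(bits) // 2
        for sign, group in ((1.0, bits[:half]), (-1.0, bits[half:])):
            if not group:
                continue
            p_on = 1.0 / (1.0 + np.exp(-(-2.2 + 2.2 * sign * Z[:, m])))
            on[:, group] = rng.random((n, len(group))) < p_on[:, None]
    fps = []
    for i in range(n):
        bits = np.flatnonzero(on[i])
        if bits.size == 0:  # fingerprints must be non-empty
            bits = np.array([int(rng.integers(n_bits))])
        fps.append(frozenset(int(b) for b in bits))
    return fps


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate one cohort; deterministic given ``config.seed``.

    Raises
    ------
    RuntimeError
        if after 100 pLD50-noise resamples the toxic and nontoxic class
        counts do not both land within +/-15% of the configured
        (n_toxic, n_compounds - n_toxic).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_compounds
    n_mech = config.n_latent_mechanisms
    ids = [f"CPD{i:05d}" for i in range(n)]

    facet = _facet_assignment(n_mech)
    Z = rng.standard_normal((n, n_mech))

    # facet activation: standardized mean over the facet's mechanisms
    weights = np.asarray(config.domain_signal_weights, dtype=float)
    signal = np.zeros(n)
    for d in range(3):
        mechs = np.flatnonzero(facet == d)
        if mechs.size:
            u = Z[:, mechs].sum(axis=1) / np.sqrt(mechs.size)
            signal += np.sqrt(weights[d]) * u

    q_toxic = config.n_toxic / config.n_compounds
    _, sigma_tot = _solve_pld50_scale(q_toxic)
    signal_scale = float(np.sqrt(max(sigma_tot**2 - config.noise_sd**2, 1e-12)))

    target_toxic = config.n_toxic
    target_nontoxic = config.n_compounds - config.n_toxic
    q_t = q_toxic * (1.0 - MARGINAL_MASS)
    pld50_values = None
    for _ in range(100):
        x = signal_scale * signal + config.noise_sd * rng.standard_normal(n)
        # center on the realized draw: with finite cohorts the analytic
        # baseline misses the band too often, so anchor the toxic threshold
        # at the realized (1 - q_t) quantile instead
        candidate = (3.0 - float(np.quantile(x, 1.0 - q_t))) + x
        n_tox = int(np.sum(candidate > 3.0))
        n_non = int(np.sum(candidate < 2.0))
        if (
            abs(n_tox - target_toxic) <= 0.15 * target_toxic
            and abs(n_non - target_nontoxic) <= 0.15 * target_nontoxic
        ):
            pld50_values = candidate
            break
    if pld50_values is None:
        raise RuntimeError(
            "could not realize class counts within +/-15% of "
            f"({target_toxic} toxic, {target_nontoxic} nontoxic) after 100 "
            "pLD50 noise resamples; adjust noise_sd or class counts"
        )
    pld50 = pd.Series(pld50_values, index=pd.Index(ids, name="compound_id"), name="pld50")

    # fingerprint bit allocation: disjoint dedicated bits per target-facing
    # mechanism. Fingerprints feed only the target scorer; linking them to
    # the other facets would leak chemical/cytotoxicity signal into the
    # target-score block through fingerprint density.
    bits_per = min(BITS_PER_MECHANISM, config.n_fingerprint_bits // n_mech)
    if bits_per == 0:
        raise ValueError("n_fingerprint_bits too small for the mechanism count")
    all_bits = rng.permutation(config.n_fingerprint_bits)
    mechanism_bits = [
        [int(b) for b in all_bits[m * bits_per : (m + 1) * bits_per]]
        if facet[m] == 1
        else []
        for m in range(n_mech)
    ]
    fingerprints = _fingerprints_from_latent(Z, mechanism_bits, config.n_fingerprint_bits, rng)

    # chemical descriptors: sparse linear mixtures of chemical-facing
    # mechanisms, plus pure-noise decoy columns. Each compound carries a
    # lognormal distortion factor on its descriptor noise: molecules whose
    # structures the descriptor set captures poorly sit far out in chemical
    # space and are predicted badly there, which is what applicability-
    # domain profiling measures.
    chem_mechs = np.flatnonzero(facet == 0)
    n_linked = int(round(CHEM_LINKED_FRACTION * config.n_chem_descriptors))
    distortion = np.exp(rng.normal(0.0, 0.6, size=n))
    X = np.empty((n, config.n_chem_descriptors))
    chem_cols = [f"chem_{j:04d}" for j in range(config.n_chem_descriptors)]
    linked_cols: list[str] = []
    for j in range(config.n_chem_descriptors):
        noise = distortion * rng.standard_normal(n)
        if j < n_linked and chem_mechs.size:
            k = int(rng.integers(1, min(3, chem_mechs.size) + 1))
            mechs = rng.choice(chem_mechs, size=k, replace=False)
            coefs = rng.standard_normal(k)
            mix = Z[:, mechs] @ coefs
            # saturating response: real descriptors have bounded ranges, so
            # extreme activations do not push compounds arbitrarily far out
            col = 2.0 * np.tanh(mix / 2.0) + 0.6 * noise
            linked_cols.append(chem_cols[j])
        else:
            col = noise
        scale = float(np.exp(rng.normal(0.0, 0.5)))
        offset = float(rng.normal(0.0, 2.0))
        X[:, j] = scale * col + offset
    chem_descriptors = pd.DataFrame(X, index=pd.Index(ids, name="compound_id"), columns=chem_cols)

    qhts_raw = _generate_qhts(config, Z, facet, ids, rng)

    (
        bioactivity_table,
        bioactivity_fingerprints,
        target_affinity,
        linked_targets,
    ) = _generate_bioactivity(config, facet, mechanism_bits, rng)

    truth = GroundTruth(
        latent_mechanisms=Z,
        facet_of_mechanism=facet,
        mechanism_bits=mechanism_bits,
        chem_linked_columns=linked_cols,
        linked_targets=linked_targets,
        target_affinity=target_affinity,
    )
    return SyntheticCohort(
        compound_ids=ids,
        fingerprints=fingerprints,
        chem_descriptors=chem_descriptors,
        qhts_raw=qhts_raw,
        pld50=pld50,
        bioactivity_table=bioactivity_table,
        bioactivity_fingerprints=bioactivity_fingerprints,
        ground_truth=truth,
        config=config,
    )


def hill_response(conc: np.ndarray, emax: float, ec50: float, slope: float) -> np.ndarray:
    """Noise-free Hill concentration-response: Emax*c^h / (EC50^h + c^h)."""
    c = np.asarray(conc, dtype=float)
    return emax * c**slope / (ec50**slope + c**slope)


def _generate_qhts(
    config: SyntheticConfig,
    Z: np.ndarray,
    facet: np.ndarray,
    ids: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(ids)
    concs = np.geomspace(*config.concentration_range, config.n_concentrations)
    cell_lines = [f"CL{j:02d}" for j in range(config.n_cell_lines)]
    cyto_mechs = np.flatnonzero(facet == 2)
    cyto = (
        Z[:, cyto_mechs].sum(axis=1) / np.sqrt(cyto_mechs.size) if cyto_mechs.size else np.zeros(n)
    )
    line_sensitivity = np.exp(rng.normal(0.0, 0.3, size=config.n_cell_lines))

    lo_e, hi_e = config.hill_emax_range
    lo_c, hi_c = config.hill_ec50_range
    lo_s, hi_s = config.hill_slope_range
    rows = []
    for j, line in enumerate(cell_lines):
        emax = rng.uniform(lo_e, hi_e, size=n)
        ec50_base = np.exp(rng.uniform(np.log(lo_c), np.log(hi_c), size=n))
        # cytotoxic mechanisms shift curves to lower EC50 (more potent)
        ec50 = np.clip(ec50_base * np.exp(-0.8 * cyto) / line_sensitivity[j], 0.05, 500.0)
        slope = rng.uniform(lo_s, hi_s, size=n)
        resp = emax[:, None] * concs[None, :] ** slope[:, None] / (
            ec50[:, None] ** slope[:, None] + concs[None, :] ** slope[:, None]
        )
        if config.qhts_noise_sd > 0:
            resp = resp + rng.normal(0.0, config.qhts_noise_sd, size=resp.shape)
        for i, cid in enumerate(ids):
            for k in range(config.n_concentrations):
                rows.append((cid, line, concs[k], resp[i, k]))
    return pd.DataFrame(rows, columns=["compound_id", "cell_line", "concentration_um", "response"])


def _generate_bioactivity(
    config: SyntheticConfig,
    facet: np.ndarray,
    mechanism_bits: list[list[int]],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict[str, frozenset[int]], np.ndarray, list[str]]:
    """Training table for the target model: mechanism-linked targets are
    active preferentially for compounds whose fingerprints carry the linked
    mechanisms' bits."""
    n_bio = config.n_bioactivity_compounds
    n_mech = config.n_latent_mechanisms
    bio_ids = [f"TRN{i:05d}" for i in range(n_bio)]
    Z_bio = rng.standard_normal((n_bio, n_mech))
    fps = _fingerprints_from_latent(Z_bio, mechanism_bits, config.n_fingerprint_bits, rng)

    # observed mechanism evidence: z-scored signed bit count (positive-half
    # presence minus negative-half presence, matching the fingerprint design)
    counts = np.zeros((n_bio, n_mech))
    for m, bits in enumerate(mechanism_bits):
        half = len(bits) // 2
        pos, neg = set(bits[:half]), set(bits[half:])
        counts[:, m] = [len(pos & fp) - len(neg & fp) for fp in fps]
    sd = counts.std(axis=0)
    sd[sd == 0] = 1.0
    evidence = (counts - counts.mean(axis=0)) / sd

    target_mechs = np.flatnonzero(facet == 1)
    n_linked = int(round(TARGET_LINKED_FRACTION * config.n_targets))
    target_ids = [f"TGT{t:04d}" for t in range(config.n_targets)]
    affinity = np.zeros((config.n_targets, n_mech))
    linked: list[str] = []
    for t in range(config.n_targets):
        if t < n_linked and target_mechs.size:
            k = int(rng.integers(1, min(2, target_mechs.size) + 1))
            mechs = rng.choice(target_mechs, size=k, replace=False)
            affinity[t, mechs] = rng.normal(0.0, 1.0, size=k)
            linked.append(target_ids[t])

    logits = -1.4 + 2.0 * evidence @ affinity.T  # n_bio x n_targets
    p_active = 1.0 / (1.0 + np.exp(-logits))
    active_all = rng.random((n_bio, config.n_targets)) < p_active

    min_subset = min(n_bio, 60)
    rows = []
    for t, tid in enumerate(target_ids):
        size = int(rng.integers(min_subset, n_bio + 1))
        members = rng.choice(n_bio, size=size, replace=False)
        members.sort()
        for i in members:
            rows.append((bio_ids[i], tid, bool(active_all[i, t])))
    table = pd.DataFrame(rows, columns=["compound_id", "target_id", "active"])
    return table, dict(zip(bio_ids, fps)), affinity, linked


# ---------------------------------------------------------------------------
# on-disk layout: one CSV per table plus a sparse fingerprint text format
# ---------------------------------------------------------------------------

_FILES = {
    "compounds": "compounds.csv",
    "chem": "chem_descriptors.csv",
    "qhts": "qhts.csv",
    "bioactivity": "bioactivity.csv",
    "fingerprints": "fingerprints.txt",
    "bio_fingerprints": "bioactivity_fingerprints.txt",
    "config": "config.json",
    "truth": "ground_truth.npz",
    "truth_meta": "ground_truth.json",
}


def _write_fingerprints(path: Path, ids: list[str], fps: list[frozenset[int]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for cid, fp in zip(ids, fps):
            fh.write(f"{cid}: {' '.join(str(b) for b in sorted(fp))}\n")


def _read_fingerprints(path: Path) -> tuple[list[str], list[frozenset[int]]]:
    ids, fps = [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                cid, _, rest = line.partition(":")
                fps.append(frozenset(int(b) for b in rest.split()))
                ids.append(cid.strip())
            except ValueError as exc:
                raise ValueError(f"{path.name} line {lineno}: malformed fingerprint") from exc
    return ids, fps


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> list[Path]:
    """Write a cohort as plain-text files; see module docstring for layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    comp = pd.DataFrame({"compound_id": cohort.compound_ids, "pld50": cohort.pld50.values})
    comp.to_csv(directory / _FILES["compounds"], index=False)
    cohort.chem_descriptors.to_csv(directory / _FILES["chem"])
    cohort.qhts_raw.to_csv(directory / _FILES["qhts"], index=False)
    bio = cohort.bioactivity_table.copy()
    bio["active"] = bio["active"].astype(int)
    bio.to_csv(directory / _FILES["bioactivity"], index=False)
    _write_fingerprints(directory / _FILES["fingerprints"], cohort.compound_ids, cohort.fingerprints)
    bio_ids = list(cohort.bioactivity_fingerprints)
    _write_fingerprints(
        directory / _FILES["bio_fingerprints"],
        bio_ids,
        [cohort.bioactivity_fingerprints[i] for i in bio_ids],
    )
    with open(directory / _FILES["config"], "w", encoding="utf-8") as fh:
        json.dump(asdict(cohort.config), fh, indent=1)
    truth = cohort.ground_truth
    np.savez(
        directory / _FILES["truth"],
        latent_mechanisms=truth.latent_mechanisms,
        facet_of_mechanism=truth.facet_of_mechanism,
        target_affinity=truth.target_affinity,
    )
    with open(directory / _FILES["truth_meta"], "w", encoding="utf-8") as fh:
        json.dump(
            {
                "mechanism_bits": truth.mechanism_bits,
                "chem_linked_columns": truth.chem_linked_columns,
                "linked_targets": truth.linked_targets,
            },
            fh,
        )
    for name in _FILES.values():
        written.append(directory / name)
    return written


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Read a cohort written by :func:`write_cohort`; numeric round trip is exact."""
    directory = Path(directory)
    for key in ("compounds", "chem", "qhts", "bioactivity", "fingerprints"):
        if not (directory / _FILES[key]).exists():
            raise FileNotFoundError(f"cohort directory is missing {_FILES[key]}")

    with open(directory / _FILES["config"], encoding="utf-8") as fh:
        raw = json.load(fh)
    for key in ("concentration_range", "domain_signal_weights", "hill_emax_range", "hill_ec50_range", "hill_slope_range"):
        raw[key] = tuple(raw[key])
    config = SyntheticConfig(**raw)

    comp = pd.read_csv(
        directory / _FILES["compounds"], dtype={"compound_id": str}, float_precision="round_trip"
    )
    ids = comp["compound_id"].tolist()
    pld50 = pd.Series(
        comp["pld50"].to_numpy(dtype=float), index=pd.Index(ids, name="compound_id"), name="pld50"
    )
    chem = pd.read_csv(
        directory / _FILES["chem"], index_col="compound_id", float_precision="round_trip"
    ).astype(float)
    chem.index = chem.index.astype(str)
    qhts = pd.read_csv(
        directory / _FILES["qhts"],
        dtype={"compound_id": str, "cell_line": str},
        float_precision="round_trip",
    )
    qhts = qhts.astype({"concentration_um": float, "response": float})
    bio = pd.read_csv(directory / _FILES["bioactivity"], dtype={"compound_id": str, "target_id": str})
    if not bio.empty and not set(bio["active"].unique()) <= {0, 1}:
        raise ValueError(f"{_FILES['bioactivity']}: active column must be 0/1")
    bio["active"] = bio["active"].astype(bool)

    fp_ids, fps = _read_fingerprints(directory / _FILES["fingerprints"])
    if fp_ids != ids:
        raise ValueError("fingerprints.txt compound ids disagree with compounds.csv")
    bio_fp_ids, bio_fps = _read_fingerprints(directory / _FILES["bio_fingerprints"])

    npz = np.load(directory / _FILES["truth"])
    with open(directory / _FILES["truth_meta"], encoding="utf-8") as fh:
        meta = json.load(fh)
    truth = GroundTruth(
        latent_mechanisms=npz["latent_mechanisms"],
        facet_of_mechanism=npz["facet_of_mechanism"],
        mechanism_bits=[list(map(int, bits)) for bits in meta["mechanism_bits"]],
        chem_linked_columns=list(meta["chem_linked_columns"]),
        linked_targets=list(meta["linked_targets"]),
        target_affinity=npz["target_affinity"],
    )
    return SyntheticCohort(
        compound_ids=ids,
        fingerprints=fps,
        chem_descriptors=chem,
        qhts_raw=qhts,
        pld50=pld50,
        bioactivity_table=bio,
        bioactivity_fingerprints=dict(zip(bio_fp_ids, bio_fps)),
        ground_truth=truth,
        config=config,
    )
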