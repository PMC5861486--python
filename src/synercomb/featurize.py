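"""Fixed-length feature encoding of (cell line, drug pair) samples.

Each sample is encoded as the concatenation of named blocks:

    [mutation | expression | cnv_amp | cnv_del | targets |
     mono(6) | addition(1) | similar(8) | sl(1)]

giving a vector of length 4*|panel| + |target universe| + 16. Genomic
blocks cover a gene panel (the sorted union of configured gene sets);
expression is z-scored per gene across the cell-line panel; copy-number
calls are split into amplification and deletion indicator blocks. The
target block marks the union of both drugs' targets, the mono block holds
sums and absolute differences of IC50/DSS/Einf, and the "similar" block
carries leakage-safe mean/median synergy aggregates over training-fold
samples sharing the cell line and/or a drug. All blocks are invariant
under swapping the two drugs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import MonoSummary

__all__ = [
    "CellLineProfile",
    "DrugInfo",
    "SLPairTable",
    "FeatureSchema",
    "build_panel",
    "mono_features",
    "similar_sample_features",
    "sl_score",
    "build_feature_vector",
    "build_feature_matrix",
]

logger = logging.getLogger(__name__)

CNV_STATES = ("AMP", "DEL", "NEUTRAL")
BINARY_BLOCKS = ("mutation", "cnv_amp", "cnv_del", "targets")


@dataclass
class CellLineProfile:
    """Genomic profile of one cell line over the gene panel.

    ``mutation`` maps gene -> {0,1} (1 = amino-acid variant present),
    ``expression`` maps gene -> normalized expression (z-score scale),
    ``cnv`` maps gene -> one of AMP / DEL / NEUTRAL.
    """

    cell_line_id: str
    mutation: dict[str, int] = field(default_factory=dict)
    expression: dict[str, float] = field(default_factory=dict)
    cnv: dict[str, str] = field(default_factory=dict)

    def is_perturbed(self, gene: str) -> bool:
        """Mutated or copy-number-altered (the SL 'perturbed' rule)."""
        return self.mutation.get(gene, 0) == 1 or self.cnv.get(gene, "NEUTRAL") != "NEUTRAL"


@dataclass(frozen=True)
class DrugInfo:
    drug_id: str
    targets: frozenset[str]


class SLPairTable:
    """Synthetic-lethality gene pairs with confidence scores in [0, 1].

    Pairs are unordered and stored canonically (sorted); the first
    occurrence of a duplicated pair wins.
    """

    def __init__(self, rows=()):
        self._conf: dict[tuple[str, str], float] = {}
        for g1, g2, conf in rows:
            self.add(g1, g2, conf)

    def add(self, gene_a: str, gene_b: str, confidence: float) -> None:
        if not np.isfinite(confidence):
            raise ValueError("SL confidence must be finite")
        key = tuple(sorted((gene_a, gene_b)))
        self._conf.setdefault(key, float(confidence))

    def pairs(self):
        return sorted(self._conf.items())

    def __len__(self) -> int:
        return len(self._conf)


def build_panel(gene_sets: dict[str, list[str]]) -> list[str]:
    """Sorted, de-duplicated union of the configured gene sets."""
    if not gene_sets or all(len(g) == 0 for g in gene_sets.values()):
        raise ValueError("gene-set collection is empty")
    union: set[str] = set()
    for genes in gene_sets.values():
        union.update(genes)
    return sorted(union)


@dataclass(frozen=True)
class FeatureSchema:
    """Named blocks with offsets; total length 4*|panel| + |targets| + 16."""

    panel: tuple[str, ...]
    target_universe: tuple[str, ...]

    @property
    def blocks(self) -> list[tuple[str, int, int]]:
        p, t = len(self.panel), len(self.target_universe)
        layout = [
            ("mutation", p),
            ("expression", p),
            ("cnv_amp", p),
            ("cnv_del", p),
            ("targets", t),
            ("mono", 6),
            ("addition", 1),
            ("similar", 8),
            ("sl", 1),
        ]
        out, off = [], 0
        for name, length in layout:
            out.append((name, off, length))
            off += length
        return out

    @property
    def length(self) -> int:
        return 4 * len(self.panel) + len(self.target_universe) + 16

    def block_slice(self, name: str) -> slice:
        for bname, off, length in self.blocks:
            if bname == name:
                return slice(off, off + length)
        raise KeyError(name)

    @property
    def feature_names(self) -> list[str]:
        mono_names = ["ic50_sum", "ic50_absdiff", "dss_sum", "dss_absdiff",
                      "einf_sum", "einf_absdiff"]
        sim_names = [f"{g}_{s}" for g in ("cell_line", "shared_drug", "pair",
                                          "shared_drug_cell_line")
                     for s in ("mean", "median")]
        names: list[str] = []
        for bname, _, _ in self.blocks:
            if bname in ("mutation", "expression", "cnv_amp", "cnv_del"):
                names += [f"{bname}:{g}" for g in self.panel]
            elif bname == "targets":
                names += [f"target:{g}" for g in self.target_universe]
            elif bname == "mono":
                names += [f"mono:{n}" for n in mono_names]
            elif bname == "addition":
                names += ["addition:score"]
            elif bname == "similar":
                names += [f"similar:{n}" for n in sim_names]
            else:
                names += ["sl:score"]
        return names

    def block_of(self, index: int) -> str:
        for bname, off, length in self.blocks:
            if off <= index < off + length:
                return bname
        raise IndexError(index)

    def is_binary(self, index: int) -> bool:
        return self.block_of(index) in BINARY_BLOCKS

    def to_dict(self) -> dict:
        return {
            "panel": list(self.panel),
            "target_universe": list(self.target_universe),
            "blocks": [{"name": n, "offset": o, "length": l} for n, o, l in self.blocks],
            "length": self.length,
        }

    @classmethod
    def from_panel(cls, panel, drugs: dict[str, DrugInfo]) -> "FeatureSchema":
        universe = sorted(set().union(*(d.targets for d in drugs.values())))
        return cls(panel=tuple(panel), target_universe=tuple(universe))


def mono_features(summary_a: MonoSummary, summary_b: MonoSummary) -> np.ndarray:
    """Sum and absolute difference of IC50, DSS and Einf (order-invariant)."""
    pairs = [(summary_a.ic50, summary_b.ic50), (summary_a.dss, summary_b.dss),
             (summary_a.e_inf, summary_b.e_inf)]
    out = []
    for a, b in pairs:
        if not (np.isfinite(a) and np.isfinite(b)):
            raise ValueError("mono summaries must be finite")
        out += [a + b, abs(a - b)]
    return np.array(out, dtype=float)


def similar_sample_features(
    key: tuple[str, str, str], training_scores: pd.DataFrame
) -> np.ndarray:
    """Mean and median training-fold synergy of four similarity groups.

    Groups: (i) same cell line; (ii) sharing at least one drug; (iii) same
    unordered drug pair; (iv) sharing at least one drug AND the cell line.
    The sample itself is excluded when it appears in the training table
    (leakage safety); an empty group falls back to the global training
    mean/median.
    """
    if training_scores.empty:
        raise ValueError("training score table is empty")
    cell, a, b = key
    df = training_scores
    self_mask = (df["cell_line"] == cell) & (df["drug_a"] == a) & (df["drug_b"] == b)
    df = df.loc[~self_mask]
    if df.empty:
        raise ValueError("training score table contains only the sample itself")
    scores = df["synergy_score"].to_numpy()
    g_mean, g_median = float(np.mean(scores)), float(np.median(scores))

    same_cell = df["cell_line"] == cell
    shares_drug = df["drug_a"].isin((a, b)) | df["drug_b"].isin((a, b))
    same_pair = (df["drug_a"] == a) & (df["drug_b"] == b)
    masks = [same_cell, shares_drug, same_pair, shares_drug & same_cell]

    out = []
    for m in masks:
        vals = df.loc[m, "synergy_score"].to_numpy()
        if len(vals):
            out += [float(np.mean(vals)), float(np.median(vals))]
        else:
            out += [g_mean, g_median]
    return np.array(out, dtype=float)


def sl_score(
    profile: CellLineProfile,
    drug_a: DrugInfo,
    drug_b: DrugInfo,
    sl: SLPairTable,
) -> float:
    """Confidence-sum over SL pairs linking a perturbed gene to a drug target.

    A pair (g1, g2) qualifies when one gene is perturbed in the cell line
    (mutated or copy-number-altered) and the other is targeted by either
    drug; each unordered pair is counted once.
    """
    targets = drug_a.targets | drug_b.targets
    total = 0.0
    for (g1, g2), conf in sl.pairs():
        if (profile.is_perturbed(g1) and g2 in targets) or (
            profile.is_perturbed(g2) and g1 in targets
        ):
            total += conf
    return total


def _zscore_expression(profiles: dict[str, CellLineProfile], panel) -> dict[str, dict[str, float]]:
    """Per-gene z-scores of expression across the cell-line panel."""
    cells = sorted(profiles)
    mat = np.array(
        [[profiles[c].expression.get(g, np.nan) for g in panel] for c in cells],
        dtype=float,
    )
    n_missing = int(np.isnan(mat).sum())
    if n_missing:
        logger.warning("imputing %d missing expression entries as 0", n_missing)
        mat = np.nan_to_num(mat, nan=0.0)
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0)
    sd[sd == 0] = 1.0
    z = (mat - mu) / sd
    return {c: dict(zip(panel, z[i])) for i, c in enumerate(cells)}


def build_feature_vector(
    key: tuple[str, str, str],
    profile: CellLineProfile,
    drug_a: DrugInfo,
    drug_b: DrugInfo,
    schema: FeatureSchema,
    summary_a: MonoSummary,
    summary_b: MonoSummary,
    addition: float,
    similar8: np.ndarray,
    sl_value: float,
    expression_z: dict[str, float] | None = None,
) -> np.ndarray:
    """Assemble one sample's feature vector per the schema.

    ``expression_z`` supplies pre-normalized expression; when omitted the
    profile's raw expression values are used as-is.
    """
    panel = schema.panel
    vec = np.zeros(schema.length, dtype=float)
    expr = expression_z if expression_z is not None else profile.expression

    # profile entries outside the panel are ignored (panel restriction);
    # drug targets outside the universe are a wiring error and are named
    for d in (drug_a, drug_b):
        unknown = d.targets - set(schema.target_universe)
        if unknown:
            raise ValueError(f"unknown target gene(s) for drug {d.drug_id!r}: {sorted(unknown)}")

    mut = vec[schema.block_slice("mutation")]
    exp_b = vec[schema.block_slice("expression")]
    amp = vec[schema.block_slice("cnv_amp")]
    dele = vec[schema.block_slice("cnv_del")]
    for i, g in enumerate(panel):
        mut[i] = 1.0 if profile.mutation.get(g, 0) == 1 else 0.0
        exp_b[i] = float(expr.get(g, 0.0))
        state = profile.cnv.get(g, "NEUTRAL")
        if state not in CNV_STATES:
            raise ValueError(f"unknown CNV state {state!r} for gene {g!r}")
        amp[i] = 1.0 if state == "AMP" else 0.0
        dele[i] = 1.0 if state == "DEL" else 0.0

    tgt = vec[schema.block_slice("targets")]
    t_index = {g: i for i, g in enumerate(schema.target_universe)}
    for g in drug_a.targets | drug_b.targets:
        tgt[t_index[g]] = 1.0

    vec[schema.block_slice("mono")] = mono_features(summary_a, summary_b)
    vec[schema.block_slice("addition")] = float(addition)
    similar8 = np.asarray(similar8, dtype=float)
    if similar8.shape != (8,):
        raise ValueError("similar-sample block must have exactly 8 entries")
    vec[schema.block_slice("similar")] = similar8
    vec[schema.block_slice("sl")] = float(sl_value)
    return vec


def build_feature_matrix(
    samples: pd.DataFrame,
    profiles: dict[str, CellLineProfile],
    drugs: dict[str, DrugInfo],
    schema: FeatureSchema,
    summaries: dict[tuple[str, str], MonoSummary],
    addition_scores: dict[tuple[str, str, str], float],
    sl_table: SLPairTable,
    train_mask: np.ndarray,
) -> np.ndarray:
    """Feature matrix for a scored sample table (leakage-safe).

    ``samples`` has columns cell_line, drug_a, drug_b, synergy_score in a
    fixed row order; ``train_mask`` flags the training fold. Similar-sample
    aggregates for every row are computed from training rows only, and a
    training row's own score never enters its own features.
    """
    samples = samples.reset_index(drop=True)
    train_tab = samples.loc[np.asarray(train_mask, dtype=bool),
                            ["cell_line", "drug_a", "drug_b", "synergy_score"]]
    expr_z = _zscore_expression(profiles, schema.panel)
    sl_cache: dict[tuple[str, str, str], float] = {}
    X = np.empty((len(samples), schema.length), dtype=float)
    for i, row in enumerate(samples.itertuples(index=False)):
        key = (row.cell_line, row.drug_a, row.drug_b)
        prof = profiles[row.cell_line]
        da, db = drugs[row.drug_a], drugs[row.drug_b]
        if key not in sl_cache:
            sl_cache[key] = sl_score(prof, da, db, sl_table)
        X[i] = build_feature_vector(
            key,
            prof,
            da,
            db,
            schema,
            summaries[(row.cell_line, row.drug_a)],
            summaries[(row.cell_line, row.drug_b)],
            addition_scores[key],
            similar_sample_features(key, train_tab),
            sl_cache[key],
            expression_z=expr_z[row.cell_line],
        )
    return X
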