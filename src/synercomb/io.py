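"""Readers and writers for the pipeline's file dialects.

All tabular files are UTF-8 with '.' decimal separators and a mandatory
header row. Dose-response data travel in long format (one well per row);
rows with a zero dose are the mono-therapy measurements. Gene sets use
the standard GMT dialect (set name, description, tab-separated genes).
Parsers reject malformed input with messages naming the offending line.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .dose_response import DoseResponseCurve
from .featurize import (
    CNV_STATES,
    CellLineProfile,
    DrugInfo,
    FeatureSchema,
    SLPairTable,
)
from .loewe import CombinationExperiment
from .simulate import SimulatedStudy

logger = logging.getLogger(__name__)

__all__ = [
    "read_mono_csv", "read_experiments", "write_experiments", "deduplicate",
    "read_scores", "write_scores", "read_gmt", "write_gmt",
    "read_profiles", "write_profiles", "read_drug_targets",
    "write_drug_targets", "read_sl_table", "write_sl_table",
    "write_feature_matrix", "read_feature_matrix", "write_study",
]

EXPERIMENT_COLUMNS = ["cell_line", "drug_a", "drug_b",
                      "dose_a_uM", "dose_b_uM", "response_frac"]


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def _require_numeric(df: pd.DataFrame, cols: list[str], path) -> None:
    for c in cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = vals.isna() & df[c].notna() | df[c].isna()
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(bad.idxmax()) + 2
            raise ValueError(f"{path}: non-numeric value in column {c!r} at line {line}")
        df[c] = vals


def read_mono_csv(path, percent: bool = False) -> list[DoseResponseCurve]:
    """Parse a mono-therapy CSV: ``cell_line,drug,dose_uM,response_frac``.

    One curve per (cell line, drug), rows sorted by dose. Responses are
    viability fractions of control; with ``percent`` they are given on
    a 0-100 scale and divided by 100 at read time.
    """
    df = _read_csv(path, ["cell_line", "drug", "dose_uM", "response_frac"])
    _require_numeric(df, ["dose_uM", "response_frac"], path)
    if percent:
        df["response_frac"] = df["response_frac"] / 100.0
    curves = []
    for (cell, drug), group in df.groupby(["cell_line", "drug"], sort=True):
        group = group.sort_values("dose_uM")
        curves.append(DoseResponseCurve(drug, cell,
                                        group["dose_uM"].to_numpy(),
                                        group["response_frac"].to_numpy()))
    return curves


def read_experiments(path, percent: bool = False) -> list[CombinationExperiment]:
    """Parse a long-format combination CSV into experiments.

    Zero-dose rows are routed to the mono-therapy curves; combination
    rows must form a complete dose grid. Pairs given as (B, A) are
    stored lexicographically with the matrix transposed. ``percent``
    rescales 0-100 viability inputs to fractions at read time.
    """
    df = _read_csv(path, EXPERIMENT_COLUMNS)
    _require_numeric(df, ["dose_a_uM", "dose_b_uM", "response_frac"], path)
    if percent:
        df["response_frac"] = df["response_frac"] / 100.0
    experiments = []
    for (cell, a, b), group in df.groupby(["cell_line", "drug_a", "drug_b"],
                                          sort=True):
        swap = a > b
        if swap:
            a, b = b, a
            group = group.rename(columns={"dose_a_uM": "dose_b_uM",
                                          "dose_b_uM": "dose_a_uM"})
        mono = {}
        for drug, dose_col, other_col in ((a, "dose_a_uM", "dose_b_uM"),
                                          (b, "dose_b_uM", "dose_a_uM")):
            rows = group[(group[other_col] == 0) & (group[dose_col] > 0)]
            rows = rows.sort_values(dose_col)
            if len(rows) < 4:
                raise ValueError(
                    f"{path}: experiment ({cell},{a},{b}) has fewer than 4 "
                    f"mono rows for drug {drug!r}")
            mono[drug] = DoseResponseCurve(
                drug, cell, rows[dose_col].to_numpy(),
                rows["response_frac"].to_numpy())
        combo = group[(group["dose_a_uM"] > 0) & (group["dose_b_uM"] > 0)]
        doses_a = np.sort(combo["dose_a_uM"].unique())
        doses_b = np.sort(combo["dose_b_uM"].unique())
        if len(combo) != len(doses_a) * len(doses_b):
            raise ValueError(
                f"{path}: ragged dose matrix for experiment ({cell},{a},{b}): "
                f"{len(combo)} wells vs {len(doses_a)}x{len(doses_b)} grid")
        pivot = combo.pivot_table(index="dose_a_uM", columns="dose_b_uM",
                                  values="response_frac", aggfunc="first")
        observed = pivot.loc[doses_a, doses_b].to_numpy()
        observed = np.clip(observed, 0.0, 1.5)
        experiments.append(CombinationExperiment(
            cell, a, b, doses_a, doses_b, observed, mono[a], mono[b]))
    return experiments


def write_experiments(experiments, path) -> None:
    """Inverse of :func:`read_experiments` (long format, mono rows at dose 0)."""
    rows = []
    for e in experiments:
        for d, r in zip(e.mono_a.doses, e.mono_a.responses):
            rows.append((e.cell_line_id, e.drug_a, e.drug_b, d, 0.0, r))
        for d, r in zip(e.mono_b.doses, e.mono_b.responses):
            rows.append((e.cell_line_id, e.drug_a, e.drug_b, 0.0, d, r))
        for i, da in enumerate(e.doses_a):
            for j, db in enumerate(e.doses_b):
                rows.append((e.cell_line_id, e.drug_a, e.drug_b, da, db,
                             e.observed[i, j]))
    pd.DataFrame(rows, columns=EXPERIMENT_COLUMNS).to_csv(path, index=False)


def deduplicate(experiments) -> list[CombinationExperiment]:
    """One experiment per (cell line, unordered pair); first occurrence kept."""
    seen, out = set(), []
    for e in experiments:
        if e.key in seen:
            continue
        seen.add(e.key)
        out.append(e)
    removed = len(experiments) - len(out)
    if removed:
        logger.info("deduplicate: removed %d duplicate experiment(s)", removed)
    return out


def write_scores(samples, path) -> None:
    pd.DataFrame([
        {"cell_line": s.cell_line_id, "drug_a": s.drug_a, "drug_b": s.drug_b,
         "synergy_score": s.synergy_score, "addition_score": s.addition_score}
        for s in samples
    ]).to_csv(path, index=False)


def read_scores(path) -> pd.DataFrame:
    df = _read_csv(path, ["cell_line", "drug_a", "drug_b",
                          "synergy_score", "addition_score"])
    _require_numeric(df, ["synergy_score", "addition_score"], path)
    return df


def read_gmt(path) -> dict[str, list[str]]:
    """Standard GMT: name <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    sets = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: GMT rows need "
                                 "name, description and at least one gene")
            sets[parts[0]] = parts[2:]
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(gene_sets):
            fh.write("\t".join([name, "synthetic"] + list(gene_sets[name])) + "\n")


def _read_matrix_tsv(path, value_name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    expected = ["gene", "cell_line", value_name]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def read_profiles(mutation_path, expression_path, cnv_path) -> dict[str, CellLineProfile]:
    """Assemble cell-line profiles from the three genomic TSV matrices."""
    mut = _read_matrix_tsv(mutation_path, "value")
    _require_numeric(mut, ["value"], mutation_path)
    expr = _read_matrix_tsv(expression_path, "value")
    _require_numeric(expr, ["value"], expression_path)
    cnv = _read_matrix_tsv(cnv_path, "value")
    bad = ~cnv["value"].isin(CNV_STATES)
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise ValueError(f"{cnv_path}: invalid CNV state at line {line} "
                         f"(expected one of {CNV_STATES})")
    cells = sorted(set(mut["cell_line"]) | set(expr["cell_line"]) | set(cnv["cell_line"]))
    profiles = {}
    for c in cells:
        profiles[c] = CellLineProfile(
            c,
            mutation=dict(zip(mut.loc[mut.cell_line == c, "gene"],
                              mut.loc[mut.cell_line == c, "value"].astype(int))),
            expression=dict(zip(expr.loc[expr.cell_line == c, "gene"],
                                expr.loc[expr.cell_line == c, "value"].astype(float))),
            cnv=dict(zip(cnv.loc[cnv.cell_line == c, "gene"],
                         cnv.loc[cnv.cell_line == c, "value"])),
        )
    return profiles


def write_profiles(profiles: dict[str, CellLineProfile], mutation_path,
                   expression_path, cnv_path) -> None:
    muts, exprs, cnvs = [], [], []
    for c in sorted(profiles):
        p = profiles[c]
        for g in sorted(p.mutation):
            muts.append((g, c, p.mutation[g]))
        for g in sorted(p.expression):
            exprs.append((g, c, p.expression[g]))
        for g in sorted(p.cnv):
            cnvs.append((g, c, p.cnv[g]))
    for rows, path in ((muts, mutation_path), (exprs, expression_path),
                       (cnvs, cnv_path)):
        pd.DataFrame(rows, columns=["gene", "cell_line", "value"]).to_csv(
            path, sep="\t", index=False)


def read_drug_targets(path) -> dict[str, DrugInfo]:
    df = pd.read_csv(path, sep="\t")
    for col in ("drug", "target_gene"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return {
        d: DrugInfo(d, frozenset(sub["target_gene"]))
        for d, sub in df.groupby("drug", sort=True)
    }


def write_drug_targets(drugs: dict[str, DrugInfo], path) -> None:
    rows = [(d, g) for d in sorted(drugs) for g in sorted(drugs[d].targets)]
    pd.DataFrame(rows, columns=["drug", "target_gene"]).to_csv(
        path, sep="\t", index=False)


def read_sl_table(path) -> SLPairTable:
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_a", "gene_b", "confidence"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    _require_numeric(df, ["confidence"], path)
    return SLPairTable(df[["gene_a", "gene_b", "confidence"]].itertuples(index=False))


def write_sl_table(sl: SLPairTable, path) -> None:
    rows = [(a, b, c) for (a, b), c in sl.pairs()]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "confidence"]).to_csv(
        path, sep="\t", index=False)


def write_feature_matrix(X: np.ndarray, schema: FeatureSchema,
                         meta: pd.DataFrame, path) -> None:
    """CSV with key columns + named feature columns, plus a sidecar
    ``<path>.schema.json`` describing the block layout."""
    path = Path(path)
    out = pd.concat(
        [meta.reset_index(drop=True)[["cell_line", "drug_a", "drug_b"]],
         pd.DataFrame(X, columns=schema.feature_names)], axis=1)
    out.to_csv(path, index=False)
    with open(path.with_suffix(path.suffix + ".schema.json"), "w") as fh:
        json.dump(schema.to_dict(), fh, indent=2, sort_keys=True)


def read_feature_matrix(path) -> tuple[np.ndarray, FeatureSchema, pd.DataFrame]:
    path = Path(path)
    df = pd.read_csv(path)
    with open(path.with_suffix(path.suffix + ".schema.json")) as fh:
        spec = json.load(fh)
    schema = FeatureSchema(panel=tuple(spec["panel"]),
                           target_universe=tuple(spec["target_universe"]))
    meta = df[["cell_line", "drug_a", "drug_b"]]
    X = df.drop(columns=["cell_line", "drug_a", "drug_b"]).to_numpy(dtype=float)
    if X.shape[1] != schema.length:
        raise ValueError(f"{path}: feature matrix width {X.shape[1]} does not "
                         f"match schema length {schema.length}")
    return X, schema, meta


def write_study(study: SimulatedStudy, outdir) -> dict[str, Path]:
    """Write a simulated study in the pipeline's file dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "experiments": outdir / "experiments.csv",
        "gene_sets": outdir / "gene_sets.gmt",
        "mutation": outdir / "mutation.tsv",
        "expression": outdir / "expression.tsv",
        "cnv": outdir / "cnv.tsv",
        "targets": outdir / "drug_targets.tsv",
        "sl": outdir / "sl_pairs.tsv",
        "truth": outdir / "truth.csv",
    }
    write_experiments(study.experiments, paths["experiments"])
    write_gmt(study.gene_sets, paths["gene_sets"])
    write_profiles(study.profiles, paths["mutation"], paths["expression"],
                   paths["cnv"])
    write_drug_targets(study.drugs, paths["targets"])
    write_sl_table(study.sl_table, paths["sl"])
    study.truth.to_csv(paths["truth"], index=False)
    return paths
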