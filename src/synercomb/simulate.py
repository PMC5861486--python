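"""Synthetic drug-combination study generator with planted mechanisms.

Generates a complete fake screen — gene panel and gene sets, cell-line
genomic profiles, a drug library with targets, a synthetic-lethality
pair table, and per-(cell line, drug pair) dose-response matrices — so
the whole pipeline is exercisable without any external download.

Two synergy mechanisms are planted on top of Loewe additivity:

* an SL coupling: planted synergy grows linearly (``beta_sl`` score
  units per unit) with the sample's synthetic-lethality score;
* a rule effect: combinations containing a drug that targets the gene
  ``g*`` gain ``rule_effect`` score units in cell lines where the
  expression of a second gene ``g'`` falls below a threshold.

The total planted score s_true (plus a residual N(0, tau) standing in
for unmodelled biology) enters each experiment as a uniform viability
shift on the combination wells, so the Loewe scoring stage recovers
s_true in expectation. Mono-therapy rows get i.i.d. well noise; each
(cell line, drug) mono curve is measured once and shared across that
drug's combinations, as in a screen with a single mono panel per plate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .dose_response import DoseResponseCurve, HillFit
from .featurize import CellLineProfile, DrugInfo, SLPairTable, sl_score
from .loewe import CombinationExperiment, loewe_surface

__all__ = ["SimulationConfig", "SimulatedStudy", "simulate_study",
           "simulate_shift_experiment", "truth_report"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic screen.

    Sizes default to a desk-scale study (20 cell lines x 15 drugs, all
    pairs, 5x5 dose matrices); rates and effect sizes are in the units
    of the quantities they perturb (synergy-score units for effects,
    viability fraction for well noise).
    """

    n_genes: int = 80
    panel_size: int = 60
    n_gene_sets: int = 6
    n_cell_lines: int = 20
    n_drugs: int = 15
    n_doses: int = 5
    dose_span_decades: float = 1.2
    mutation_rate: float = 0.05
    cnv_rate: float = 0.03          # each, for AMP and DEL
    einf_range: tuple[float, float] = (0.0, 0.6)
    log_ec50_range: tuple[float, float] = (-1.0, 1.0)
    hill_slope_range: tuple[float, float] = (0.8, 3.0)
    einf_sensitization: float = 0.2  # e_inf drop when a target is mut/amp
    targets_per_drug: tuple[int, int] = (1, 3)
    n_sl_pairs: int = 50
    sl_confidence_range: tuple[float, float] = (0.3, 1.0)
    beta_sl: float = 10.0            # score units per unit SL score
    rule_effect: float = 20.0        # score units when the planted rule fires
    rule_expr_threshold: float = -0.5
    well_sigma: float = 0.02         # viability-fraction well noise
    synergy_tau: float = 5.0         # unexplained synergy residual, score units
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_rate <= 1 or not 0 <= self.cnv_rate <= 1:
            raise ValueError("rates must lie in [0, 1]")
        if self.well_sigma < 0 or self.synergy_tau < 0:
            raise ValueError("noise levels must be non-negative")
        if self.panel_size > self.n_genes:
            raise ValueError("panel_size cannot exceed n_genes")
        if self.n_doses < 4:
            raise ValueError("need at least 4 doses for mono curve fitting")
        if self.n_drugs < 2 or self.n_cell_lines < 1:
            raise ValueError("need at least 2 drugs and 1 cell line")


@dataclass
class SimulatedStudy:
    """All artifacts of one simulated screen plus the planted ground truth."""

    config: SimulationConfig
    panel: list[str]
    gene_sets: dict[str, list[str]]
    profiles: dict[str, CellLineProfile]
    drugs: dict[str, DrugInfo]
    sl_table: SLPairTable
    experiments: list[CombinationExperiment]
    truth: pd.DataFrame
    g_star: str = ""
    g_prime: str = ""
    drug_params: dict = field(default_factory=dict)


def _gene_names(n: int) -> list[str]:
    return [f"G{i + 1:03d}" for i in range(n)]


def _make_gene_sets(panel: list[str], n_sets: int, rng) -> dict[str, list[str]]:
    """Overlapping gene sets whose union is exactly the panel."""
    chunks = np.array_split(np.array(panel), n_sets)
    sets = {}
    for i, chunk in enumerate(chunks):
        extra = rng.choice(panel, size=min(3, len(panel)), replace=False)
        genes = sorted(set(chunk.tolist()) | set(extra.tolist()))
        sets[f"PATHWAY_{i + 1}"] = genes
    return sets


def _cell_fit(base: tuple[float, float, float], drug: DrugInfo,
              profile: CellLineProfile, cfg: SimulationConfig) -> HillFit:
    """Cell-line-specific Hill curve: sensitized when a target is mut/amp."""
    e_inf, ec50, h = base
    hit = any(
        profile.mutation.get(g, 0) == 1 or profile.cnv.get(g) == "AMP"
        for g in drug.targets
    )
    if hit:
        e_inf = max(0.0, e_inf - cfg.einf_sensitization)
    return HillFit(e_inf=e_inf, ec50=ec50, h=h, rss=0.0)


def simulate_study(config: SimulationConfig | None = None) -> SimulatedStudy:
    """Generate the full study for ``config`` (reproducible per seed)."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)

    genes = _gene_names(cfg.n_genes)
    panel = sorted(rng.choice(genes, size=cfg.panel_size, replace=False).tolist())
    gene_sets = _make_gene_sets(panel, cfg.n_gene_sets, rng)

    cells = [f"CL{i + 1:02d}" for i in range(cfg.n_cell_lines)]
    profiles: dict[str, CellLineProfile] = {}
    for c in cells:
        mut = {g: int(rng.random() < cfg.mutation_rate) for g in genes}
        expr = {g: float(rng.normal()) for g in genes}
        cnv = {}
        for g in genes:
            u = rng.random()
            cnv[g] = "AMP" if u < cfg.cnv_rate else (
                "DEL" if u < 2 * cfg.cnv_rate else "NEUTRAL")
        profiles[c] = CellLineProfile(c, mut, expr, cnv)
    # the planted rule thresholds the NORMALIZED expression the pipeline
    # sees (z-score across the study's cell lines), so the planted
    # mechanism is exactly expressible in feature space
    expr_z: dict[str, dict[str, float]] = {}
    for g in genes:
        vals = np.array([profiles[c].expression[g] for c in cells])
        mu, sd = vals.mean(), vals.std()
        sd = sd if sd > 0 else 1.0
        for c, v in zip(cells, vals):
            expr_z.setdefault(c, {})[g] = float((v - mu) / sd)

    drug_ids = [f"DRUG{i + 1:02d}" for i in range(cfg.n_drugs)]
    g_star = panel[int(rng.integers(len(panel)))]
    drugs: dict[str, DrugInfo] = {}
    lo_t, hi_t = cfg.targets_per_drug
    for i, d in enumerate(drug_ids):
        k = int(rng.integers(lo_t, hi_t + 1))
        targets = set(rng.choice(panel, size=k, replace=False).tolist())
        if i < 3:  # the planted rule's target gene is hit by three drugs
            targets.add(g_star)
        else:
            targets.discard(g_star)
            if not targets:
                targets = {panel[int(rng.integers(len(panel)))] }
        drugs[d] = DrugInfo(d, frozenset(targets))
    targeted = set().union(*(drugs[d].targets for d in drug_ids))
    untargeted = [g for g in panel if g not in targeted]
    g_prime = untargeted[int(rng.integers(len(untargeted)))] if untargeted else panel[0]

    sl_rows = []
    seen_pairs: set[tuple[str, str]] = set()
    target_list = sorted(targeted)
    while len(sl_rows) < cfg.n_sl_pairs:
        # half the pairs link a drug-target gene (these carry the signal)
        if len(sl_rows) % 2 == 0 and target_list:
            g1 = target_list[int(rng.integers(len(target_list)))]
        else:
            g1 = panel[int(rng.integers(len(panel)))]
        g2 = panel[int(rng.integers(len(panel)))]
        if g1 == g2:
            continue
        key = tuple(sorted((g1, g2)))
        if key in seen_pairs:
            continue
        seen_pairs.add(key)
        sl_rows.append((key[0], key[1],
                        float(rng.uniform(*cfg.sl_confidence_range))))
    sl_table = SLPairTable(sl_rows)

    base_params = {
        d: (float(rng.uniform(*cfg.einf_range)),
            float(10.0 ** rng.uniform(*cfg.log_ec50_range)),
            float(rng.uniform(*cfg.hill_slope_range)))
        for d in drug_ids
    }
    doses = {
        d: base_params[d][1] * np.logspace(-cfg.dose_span_decades,
                                           cfg.dose_span_decades, cfg.n_doses)
        for d in drug_ids
    }

    # one mono measurement per (cell line, drug), shared across combinations
    mono_curves: dict[tuple[str, str], DoseResponseCurve] = {}
    cell_fits: dict[tuple[str, str], HillFit] = {}
    for c in cells:
        for d in drug_ids:
            fit = _cell_fit(base_params[d], drugs[d], profiles[c], cfg)
            cell_fits[(c, d)] = fit
            resp = fit.response(doses[d]) + rng.normal(0, cfg.well_sigma,
                                                       cfg.n_doses)
            mono_curves[(c, d)] = DoseResponseCurve(
                d, c, doses[d], np.clip(resp, 0.0, 1.5))

    experiments: list[CombinationExperiment] = []
    truth_rows = []
    for c in cells:
        prof = profiles[c]
        for a, b in combinations(drug_ids, 2):
            a, b = sorted((a, b))
            slv = sl_score(prof, drugs[a], drugs[b], sl_table)
            rule_on = (
                g_star in (drugs[a].targets | drugs[b].targets)
                and expr_z[c][g_prime] < cfg.rule_expr_threshold
            )
            s_true = (cfg.beta_sl * slv
                      + (cfg.rule_effect if rule_on else 0.0)
                      + float(rng.normal(0, cfg.synergy_tau)))
            surface = loewe_surface(cell_fits[(c, a)], cell_fits[(c, b)],
                                    doses[a], doses[b])
            observed = np.clip(
                surface - s_true / 100.0
                + rng.normal(0, cfg.well_sigma, surface.shape),
                0.0, 1.5)
            experiments.append(CombinationExperiment(
                c, a, b, doses[a], doses[b], observed,
                mono_curves[(c, a)], mono_curves[(c, b)]))
            truth_rows.append({"cell_line": c, "drug_a": a, "drug_b": b,
                               "s_true": s_true, "sl_score": slv,
                               "rule_on": bool(rule_on)})

    truth = pd.DataFrame(truth_rows)
    return SimulatedStudy(config=cfg, panel=panel, gene_sets=gene_sets,
                          profiles=profiles, drugs=drugs, sl_table=sl_table,
                          experiments=experiments, truth=truth,
                          g_star=g_star, g_prime=g_prime,
                          drug_params=base_params)


def simulate_shift_experiment(shift: float, sigma: float, rng,
                              cfg: SimulationConfig | None = None
                              ) -> CombinationExperiment:
    """One random experiment with a planted uniform synergy shift.

    The observed matrix is the Loewe surface of two random Hill curves
    minus ``shift``/100, with N(0, sigma) well noise; mono rows carry the
    same noise level.
    """
    cfg = cfg or SimulationConfig()
    fits, doses, curves = [], [], []
    for d in ("A", "B"):
        e_inf = float(rng.uniform(*cfg.einf_range))
        ec50 = float(10.0 ** rng.uniform(*cfg.log_ec50_range))
        h = float(rng.uniform(*cfg.hill_slope_range))
        fit = HillFit(e_inf, ec50, h, 0.0)
        dgrid = ec50 * np.logspace(-cfg.dose_span_decades,
                                   cfg.dose_span_decades, cfg.n_doses)
        resp = np.clip(fit.response(dgrid) + rng.normal(0, sigma, cfg.n_doses),
                       0.0, 1.5)
        fits.append(fit)
        doses.append(dgrid)
        curves.append(DoseResponseCurve(d, "CL", dgrid, resp))
    surface = loewe_surface(fits[0], fits[1], doses[0], doses[1])
    observed = np.clip(surface - shift / 100.0
                       + rng.normal(0, sigma, surface.shape), 0.0, 1.5)
    return CombinationExperiment("CL", "A", "B", doses[0], doses[1],
                                 observed, curves[0], curves[1])


def truth_report(truth: pd.DataFrame, recovered: pd.DataFrame,
                 value_column: str = "value") -> dict:
    """Recovery metrics of pipeline output against the planted truth.

    ``recovered`` must carry the experiment key columns plus
    ``value_column`` (a recovered synergy score or model prediction).
    Returns RMSE and Pearson r of value vs s_true over the matched keys;
    errors when the key sets differ.
    """
    keys = ["cell_line", "drug_a", "drug_b"]
    merged = truth.merge(recovered[keys + [value_column]], on=keys, how="outer",
                         indicator=True)
    if (merged["_merge"] != "both").any():
        raise ValueError("truth table and recovered table keys do not match")
    diff = merged[value_column].to_numpy() - merged["s_true"].to_numpy()
    rmse = float(np.sqrt(np.mean(diff ** 2)))
    s, v = merged["s_true"].to_numpy(), merged[value_column].to_numpy()
    if np.std(s) > 0 and np.std(v) > 0:
        r = float(np.corrcoef(s, v)[0, 1])
    else:
        r = float("nan")
    return {"rmse": rmse, "pearson_r": r, "n": int(len(merged))}
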