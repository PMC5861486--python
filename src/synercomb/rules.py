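"""Interpretable synergistic-rule mining from forest decision paths.

Every root-to-leaf path of a fitted tree-ensemble regressor whose leaf
predicts a synergy score >= ``s_min`` is collected and canonicalized:
repeated splits on one feature are merged to the tightest interval,
binary features (mutation / CNV / target blocks) render as ``=1`` /
``=0``, and expression features render as "underexpressed" (upper bound
below the z-score zero point) or "overexpressed" (lower bound at or above
it). Identical canonical signatures are counted across trees; the
frequency ranking surfaces conjunctions the forest rediscovers again and
again. Each surviving rule is evaluated by comparing the mean synergy of
samples satisfying the rule against the rest (two-sided Welch t-test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .featurize import FeatureSchema

__all__ = ["Condition", "Rule", "extract_paths", "evaluate_rule", "mine_rules",
           "subset_view", "rules_to_frame"]


class SchemaView:
    """Schema adapter for a forest trained on a column subset.

    Maps the subset's column indices back to the parent schema's blocks
    and feature names, so rule extraction works unchanged on forests
    trained on a restricted feature matrix.
    """

    def __init__(self, schema: FeatureSchema, columns: list[int]):
        self._names = [schema.feature_names[c] for c in columns]
        self._blocks = [schema.block_of(c) for c in columns]
        self.columns = list(columns)

    @property
    def feature_names(self) -> list[str]:
        return self._names

    def block_of(self, index: int) -> str:
        return self._blocks[index]


def subset_view(schema: FeatureSchema, columns) -> SchemaView:
    return SchemaView(schema, list(columns))


@dataclass(frozen=True)
class Condition:
    """One canonical feature condition.

    ``relation`` is one of '=1', '=0', 'under', 'over', '<=', '>'.
    'under'/'over' carry a representative numeric threshold on the
    z-scored expression axis (the median of the contributing tree-path
    thresholds); '=1'/'=0' need none.
    """

    feature: str
    relation: str
    threshold: float | None = None

    def render(self) -> str:
        if self.relation in ("=1", "=0"):
            return f"{self.feature}{self.relation}"
        if self.relation == "under":
            return f"underexpressed {self.feature.split(':', 1)[-1]}"
        if self.relation == "over":
            return f"overexpressed {self.feature.split(':', 1)[-1]}"
        return f"{self.feature} {self.relation} {self.threshold:.4g}"

    def mask(self, X: np.ndarray, col: int) -> np.ndarray:
        x = X[:, col]
        if self.relation == "=1":
            return x > 0.5
        if self.relation == "=0":
            return x <= 0.5
        if self.relation in ("under", "<="):
            return x <= self.threshold
        return x > self.threshold  # 'over', '>'


@dataclass
class Rule:
    """A mined conjunction with its support and two-group statistics."""

    conditions: tuple[Condition, ...]
    tree_support: int
    sample_support: int
    pos_mean: float
    neg_mean: float
    p_value: float

    def render(self) -> str:
        return ", ".join(c.render() for c in self.conditions)


# signature entry: (feature_index, relation, threshold_key)
# where threshold_key is None for canonicalized relations ('=1','=0',
# 'under','over') and the numeric threshold otherwise.


def _tree_paths(tree, s_min: float):
    """Yield (list of (feat, '<='|'>', thr), leaf_value) for qualifying leaves."""
    t = tree.tree_
    stack = [(0, [])]
    while stack:
        node, conds = stack.pop()
        if t.children_left[node] == -1:  # leaf
            value = float(t.value[node].ravel()[0])
            if value >= s_min:
                yield conds, value
            continue
        feat, thr = int(t.feature[node]), float(t.threshold[node])
        stack.append((t.children_right[node], conds + [(feat, ">", thr)]))
        stack.append((t.children_left[node], conds + [(feat, "<=", thr)]))


def _canonicalize(conds, schema: FeatureSchema, max_len: int):
    """Merge, canonicalize and truncate one path's conditions.

    Returns (signature, thresholds) where signature is a sorted tuple of
    (feature_index, relation, threshold_key) and thresholds maps signature
    entries to the path's numeric bound (for later aggregation).
    """
    # merge repeated splits to the tightest interval, in first-seen order
    order: list[int] = []
    lower: dict[int, float] = {}
    upper: dict[int, float] = {}
    for feat, op, thr in conds:
        if feat not in order:
            order.append(feat)
        if op == ">":
            lower[feat] = max(lower.get(feat, -np.inf), thr)
        else:
            upper[feat] = min(upper.get(feat, np.inf), thr)

    entries: list[tuple] = []
    thresholds: dict[tuple, float] = {}
    for feat in order:
        lo = lower.get(feat)
        hi = upper.get(feat)
        block = schema.block_of(feat)
        if block in ("mutation", "cnv_amp", "cnv_del", "targets"):
            # splits on {0,1} features always separate 0 from 1
            rel = "=1" if lo is not None else "=0"
            entries.append((feat, rel, None))
        elif block == "expression":
            if hi is not None and hi < 0:
                entries.append((feat, "under", None))
                thresholds[(feat, "under", None)] = hi
            elif lo is not None and lo >= 0:
                entries.append((feat, "over", None))
                thresholds[(feat, "over", None)] = lo
            else:
                if hi is not None:
                    entries.append((feat, "<=", round(hi, 10)))
                if lo is not None:
                    entries.append((feat, ">", round(lo, 10)))
        else:
            if hi is not None:
                entries.append((feat, "<=", round(hi, 10)))
            if lo is not None:
                entries.append((feat, ">", round(lo, 10)))
        if len(entries) >= max_len:
            break
    signature = tuple(sorted(entries[:max_len], key=lambda e: (e[0], e[1], e[2] or 0)))
    return signature, thresholds


def extract_paths(forest, schema: FeatureSchema, s_min: float,
                  max_len: int = 4) -> list[dict]:
    """Collect canonical high-synergy path signatures across a forest.

    Returns one record per distinct signature with its tree count and the
    per-condition threshold lists, sorted by descending tree count (ties:
    signature order, deterministically).
    """
    if not hasattr(forest, "estimators_"):
        raise TypeError("rule extraction needs a fitted tree-ensemble regressor")
    counts: dict[tuple, int] = {}
    thr_lists: dict[tuple, dict[tuple, list[float]]] = {}
    for tree in forest.estimators_:
        seen_in_tree: set[tuple] = set()
        for conds, _value in _tree_paths(tree, s_min):
            sig, thrs = _canonicalize(conds, schema, max_len)
            if not sig:
                continue
            if sig not in seen_in_tree:
                counts[sig] = counts.get(sig, 0) + 1
                seen_in_tree.add(sig)
            slot = thr_lists.setdefault(sig, {})
            for entry, t in thrs.items():
                slot.setdefault(entry, []).append(t)
    records = []
    for sig in sorted(counts, key=lambda s: (-counts[s], s)):
        records.append({
            "signature": sig,
            "tree_support": counts[sig],
            "thresholds": {e: float(np.median(v)) for e, v in thr_lists.get(sig, {}).items()},
        })
    return records


def _conditions_from_record(record: dict, schema: FeatureSchema) -> tuple[Condition, ...]:
    names = schema.feature_names
    conds = []
    for feat, rel, thr_key in record["signature"]:
        thr = record["thresholds"].get((feat, rel, thr_key))
        if thr is None and thr_key is not None:
            thr = float(thr_key)
        conds.append(Condition(feature=names[feat], relation=rel, threshold=thr))
    return tuple(conds)


def evaluate_rule(conditions, columns: list[int], X: np.ndarray,
                  y: np.ndarray) -> tuple[float, float, float, int]:
    """Two-group comparison of a rule on scored samples.

    Returns (pos_mean, neg_mean, p_value, sample_support) where the
    p-value is a two-sided Welch t-test (Satterthwaite df) between
    satisfying and non-satisfying samples; errors when either group is
    empty (the rule is untestable).
    """
    mask = np.ones(len(X), dtype=bool)
    for cond, col in zip(conditions, columns):
        mask &= cond.mask(X, col)
    n_pos = int(mask.sum())
    if n_pos == 0 or n_pos == len(X):
        raise ValueError("rule is untestable: one group is empty")
    pos, neg = y[mask], y[~mask]
    res = stats.ttest_ind(pos, neg, equal_var=False)
    return float(np.mean(pos)), float(np.mean(neg)), float(res.pvalue), n_pos


_CANONICAL_RELATIONS = ("=1", "=0", "under", "over")


def mine_rules(forest, schema: FeatureSchema, X: np.ndarray, y: np.ndarray,
               s_min: float = 15.0, max_len: int = 4, min_support: int = 20,
               top_k: int = 10, interpretable_only: bool = False) -> list[Rule]:
    """Top-K frequent synergism rules from a fitted forest.

    Pipeline: extract canonical high-prediction path signatures, drop
    those satisfied by fewer than ``min_support`` training samples,
    evaluate each by the two-group Welch comparison, rank by tree
    frequency (ties: smaller p first) and return the top K.

    With ``interpretable_only`` the mining keeps only fully canonical
    signatures (binary =1/=0 and under/over-expression conditions),
    discarding paths that retain raw numeric thresholds; the forest
    still uses all its features to grow, so continuous covariates shape
    the trees without contaminating the reported rules.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    records = extract_paths(forest, schema, s_min, max_len)
    if interpretable_only:
        records = [r for r in records
                   if all(rel in _CANONICAL_RELATIONS
                          for _, rel, _ in r["signature"])]
    rules: list[Rule] = []
    for rec in records:
        cols = [feat for feat, _, _ in rec["signature"]]
        conds = _conditions_from_record(rec, schema)
        mask = np.ones(len(X), dtype=bool)
        for cond, col in zip(conds, cols):
            mask &= cond.mask(X, col)
        support = int(mask.sum())
        if support < min_support or support == len(X):
            continue
        pos_mean, neg_mean, p, _ = evaluate_rule(conds, cols, X, y)
        rules.append(Rule(conditions=conds, tree_support=rec["tree_support"],
                          sample_support=support, pos_mean=pos_mean,
                          neg_mean=neg_mean, p_value=p))
    if not rules:
        warnings.warn("no qualifying rule signature found", stacklevel=2)
        return []
    rules.sort(key=lambda r: (-r.tree_support, r.p_value))
    return rules[:top_k]


def rules_to_frame(rules: list[Rule]) -> pd.DataFrame:
    """Table 4-style TSV-ready frame of mined rules."""
    return pd.DataFrame([
        {
            "conditions": r.render(),
            "tree_support": r.tree_support,
            "sample_support": r.sample_support,
            "pos_mean": r.pos_mean,
            "neg_mean": r.neg_mean,
            "p_value": r.p_value,
        }
        for r in rules
    ])
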