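import numpy as np
import pandas as pd
import pytest

from synercomb.dose_response import MonoSummary
from synercomb.featurize import (
    CellLineProfile,
    DrugInfo,
    FeatureSchema,
    SLPairTable,
    build_feature_matrix,
    build_feature_vector,
    build_panel,
    mono_features,
    similar_sample_features,
    sl_score,
)


class TestPanel:
    def test_union_is_sorted_and_unique(self):
        assert build_panel({"s1": ["A", "B"], "s2": ["B", "C"]}) == ["A", "B", "C"]

    def test_single_set_keeps_length(self):
        genes = [f"G{i}" for i in range(14)]
        assert len(build_panel({"s": genes})) == 14

    def test_matches_brute_force_union(self, rng):
        pool = [f"G{i}" for i in range(30)]
        sets = {f"s{j}": list(rng.choice(pool, size=rng.integers(1, 10),
                                         replace=False)) for j in range(5)}
        expected = sorted(set().union(*sets.values()))
        assert build_panel(sets) == expected

    def test_rejects_empty_collection(self):
        with pytest.raises(ValueError):
            build_panel({})


class TestMonoFeatures:
    def test_direct_arithmetic(self):
        a = MonoSummary(2.0, 30.0, 0.2)
        b = MonoSummary(6.0, 10.0, 0.6)
        assert mono_features(a, b) == pytest.approx([8, 4, 40, 20, 0.8, 0.4])

    def test_identical_summaries_zero_differences(self):
        a = MonoSummary(3.0, 20.0, 0.5)
        out = mono_features(a, a)
        assert out[1] == out[3] == out[5] == 0

    def test_order_invariance(self):
        a = MonoSummary(2.0, 30.0, 0.2)
        b = MonoSummary(6.0, 10.0, 0.6)
        assert np.array_equal(mono_features(a, b), mono_features(b, a))


def score_table(rows):
    return pd.DataFrame(rows, columns=["cell_line", "drug_a", "drug_b",
                                       "synergy_score"])


class TestSimilarSampleFeatures:
    KEY = ("HT29", "AZD", "MK8")

    def test_single_same_cell_line_sample(self):
        tab = score_table([("HT29", "D1", "D2", 7.0), ("OTHER", "D1", "D2", 99.0)])
        out = similar_sample_features(self.KEY, tab)
        assert out[0] == out[1] == 7.0

    def test_empty_pair_group_falls_back_to_global(self):
        tab = score_table([("HT29", "D1", "D2", 4.0), ("C2", "D3", "D4", 8.0)])
        out = similar_sample_features(self.KEY, tab)
        assert out[4] == pytest.approx(6.0)   # pair-group mean -> global mean
        assert out[5] == pytest.approx(6.0)

    def test_self_sample_is_excluded(self):
        tab = score_table([self.KEY + (50.0,), ("HT29", "D1", "D2", 7.0)])
        out = similar_sample_features(self.KEY, tab)
        assert out[0] == 7.0  # own score never contributes

    def test_matches_brute_force_group_by(self, rng):
        cells = [f"C{i}" for i in range(4)]
        drugs = [f"D{i}" for i in range(5)]
        rows = []
        for _ in range(60):
            a, b = sorted(rng.choice(drugs, size=2, replace=False))
            rows.append((rng.choice(cells), a, b, float(rng.normal(0, 20))))
        tab = score_table(rows)
        for _ in range(20):
            a, b = sorted(rng.choice(drugs, size=2, replace=False))
            key = (str(rng.choice(cells)), a, b)
            out = similar_sample_features(key, tab)
            others = [r for r in rows if (r[0], r[1], r[2]) != key]
            groups = [
                [r[3] for r in others if r[0] == key[0]],
                [r[3] for r in others if r[1] in key[1:] or r[2] in key[1:]],
                [r[3] for r in others if (r[1], r[2]) == (key[1], key[2])],
                [r[3] for r in others if (r[1] in key[1:] or r[2] in key[1:])
                 and r[0] == key[0]],
            ]
            all_scores = [r[3] for r in others]
            expected = []
            for g in groups:
                vals = g if g else all_scores
                expected += [np.mean(vals), np.median(vals)]
            assert out == pytest.approx(expected)

    def test_rejects_empty_table(self):
        with pytest.raises(ValueError):
            similar_sample_features(self.KEY, score_table([]))


class TestSLScore:
    PROFILE = CellLineProfile("c", mutation={"g1": 1}, expression={},
                              cnv={"g5": "AMP"})

    def test_empty_table_scores_zero(self):
        a, b = DrugInfo("a", frozenset({"g2"})), DrugInfo("b", frozenset())
        assert sl_score(self.PROFILE, a, b, SLPairTable()) == 0.0

    def test_counts_qualifying_pairs_only(self):
        sl = SLPairTable([("g1", "g2", 0.8), ("g3", "g4", 0.5)])
        a = DrugInfo("a", frozenset({"g2"}))
        b = DrugInfo("b", frozenset())
        assert sl_score(self.PROFILE, a, b, sl) == pytest.approx(0.8)

    def test_double_orientation_counted_once(self):
        # g1 mutated AND targeted; g5 amplified AND targeted: both
        # orientations of (g1, g5) qualify but the pair counts once
        sl = SLPairTable([("g1", "g5", 0.6)])
        a = DrugInfo("a", frozenset({"g1", "g5"}))
        b = DrugInfo("b", frozenset())
        assert sl_score(self.PROFILE, a, b, sl) == pytest.approx(0.6)

    def test_matches_brute_force_enumeration(self, rng):
        genes = [f"g{i}" for i in range(12)]
        for _ in range(30):
            prof = CellLineProfile(
                "c",
                mutation={g: int(rng.random() < 0.3) for g in genes},
                expression={},
                cnv={g: rng.choice(["AMP", "DEL", "NEUTRAL"]) for g in genes})
            a = DrugInfo("a", frozenset(rng.choice(genes, 2, replace=False)))
            b = DrugInfo("b", frozenset(rng.choice(genes, 2, replace=False)))
            pairs = []
            seen = set()
            for _ in range(8):
                g1, g2 = rng.choice(genes, 2, replace=False)
                if tuple(sorted((g1, g2))) in seen:
                    continue
                seen.add(tuple(sorted((g1, g2))))
                pairs.append((g1, g2, float(rng.uniform(0, 1))))
            sl = SLPairTable(pairs)
            targets = a.targets | b.targets
            expected = sum(
                c for (g1, g2), c in sl.pairs()
                if (prof.is_perturbed(g1) and g2 in targets)
                or (prof.is_perturbed(g2) and g1 in targets))
            assert sl_score(prof, a, b, sl) == pytest.approx(expected)


class TestSchemaAndVector:
    def test_schema_length_formula(self, small_pipeline):
        schema = small_pipeline["schema"]
        assert schema.length == 4 * len(schema.panel) + len(schema.target_universe) + 16

    def test_full_cancer_panel_schema_is_1028(self):
        panel = tuple(f"G{i:03d}" for i in range(239))
        universe = tuple(f"T{i:02d}" for i in range(56))
        assert FeatureSchema(panel, universe).length == 1028

    def test_target_positions_marked(self):
        panel = ("EGFR", "HES5", "MTOR")
        schema = FeatureSchema(panel, ("EGFR", "MTOR", "TOP1"))
        prof = CellLineProfile("c")
        a = DrugInfo("a", frozenset({"MTOR"}))
        b = DrugInfo("b", frozenset({"EGFR"}))
        vec = build_feature_vector(("c", "a", "b"), prof, a, b, schema,
                                   MonoSummary(1, 1, 0.1), MonoSummary(1, 1, 0.1),
                                   addition=0.0, similar8=np.zeros(8), sl_value=0.0)
        tgt = vec[schema.block_slice("targets")]
        assert list(tgt) == [1.0, 1.0, 0.0]

    def test_drug_swap_is_bitwise_identical(self):
        panel = ("A1", "B2", "C3")
        schema = FeatureSchema(panel, ("A1", "C3"))
        prof = CellLineProfile("c", {"A1": 1}, {"B2": 0.5}, {"C3": "DEL"})
        d1 = DrugInfo("d1", frozenset({"A1"}))
        d2 = DrugInfo("d2", frozenset({"C3"}))
        s1, s2 = MonoSummary(2, 30, 0.2), MonoSummary(6, 10, 0.6)
        kw = dict(schema=schema, addition=12.0, similar8=np.arange(8.0), sl_value=0.3)
        v1 = build_feature_vector(("c", "d1", "d2"), prof, d1, d2,
                                  summary_a=s1, summary_b=s2, **kw)
        v2 = build_feature_vector(("c", "d1", "d2"), prof, d2, d1,
                                  summary_a=s2, summary_b=s1, **kw)
        assert np.array_equal(v1, v2)

    def test_unknown_target_named_in_error(self):
        schema = FeatureSchema(("A1",), ("A1",))
        with pytest.raises(ValueError, match="ZZZ"):
            build_feature_vector(("c", "d1", "d2"), CellLineProfile("c"),
                                 DrugInfo("d1", frozenset({"ZZZ"})),
                                 DrugInfo("d2", frozenset()), schema,
                                 MonoSummary(1, 1, 1), MonoSummary(1, 1, 1),
                                 0.0, np.zeros(8), 0.0)


class TestMatrixContracts:
    def test_leakage_test_fold_scores_never_enter_features(self, small_pipeline):
        """Perturbing every test-fold synergy score changes no feature."""
        sp = small_pipeline
        cfg, schema, split = sp["config"], sp["schema"], sp["split"]
        scores = sp["scores"]
        from synercomb.pipeline import _load_featurize_inputs
        panel, profiles, drugs, sl, scores_df, summaries = _load_featurize_inputs(cfg)
        train_mask = np.zeros(len(scores_df), dtype=bool)
        train_mask[split.train_idx] = True
        addition = {(r.cell_line, r.drug_a, r.drug_b): r.addition_score
                    for r in scores_df.itertuples(index=False)}
        perturbed = scores_df.copy()
        perturbed.loc[split.test_idx, "synergy_score"] += 1000.0
        X1 = build_feature_matrix(scores_df, profiles, drugs, schema, summaries,
                                  addition, sl, train_mask)
        X2 = build_feature_matrix(perturbed, profiles, drugs, schema, summaries,
                                  addition, sl, train_mask)
        assert np.array_equal(X1, X2)

    def test_matrix_is_deterministic(self, small_pipeline):
        sp = small_pipeline
        from synercomb.pipeline import _load_featurize_inputs
        panel, profiles, drugs, sl, scores_df, summaries = _load_featurize_inputs(sp["config"])
        train_mask = np.zeros(len(scores_df), dtype=bool)
        train_mask[sp["split"].train_idx] = True
        addition = {(r.cell_line, r.drug_a, r.drug_b): r.addition_score
                    for r in scores_df.itertuples(index=False)}
        X1 = build_feature_matrix(scores_df, profiles, drugs, sp["schema"],
                                  summaries, addition, sl, train_mask)
        assert np.array_equal(X1, sp["X"])

    def test_zeroing_mutations_touches_only_mutation_block(self, small_pipeline):
        sp = small_pipeline
        from synercomb.pipeline import _load_featurize_inputs
        panel, profiles, drugs, sl, scores_df, summaries = _load_featurize_inputs(sp["config"])
        train_mask = np.zeros(len(scores_df), dtype=bool)
        train_mask[sp["split"].train_idx] = True
        addition = {(r.cell_line, r.drug_a, r.drug_b): r.addition_score
                    for r in scores_df.itertuples(index=False)}
        wiped = {c: CellLineProfile(c, {g: 0 for g in p.mutation},
                                    p.expression, p.cnv)
                 for c, p in profiles.items()}
        X2 = build_feature_matrix(scores_df, wiped, drugs, sp["schema"],
                                  summaries, addition, sl, train_mask)
        schema = sp["schema"]
        mut = schema.block_slice("mutation")
        sl_b = schema.block_slice("sl")
        diff_cols = np.flatnonzero((sp["X"] != X2).any(axis=0))
        # only the mutation block and the mutation-dependent SL score move
        allowed = set(range(mut.start, mut.stop)) | set(range(sl_b.start, sl_b.stop))
        assert set(diff_cols) <= allowed
        assert (X2[:, mut] == 0).all()
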