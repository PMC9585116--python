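"""Blank filtering, formula matching, detection calls, dedup, harmonisation."""

import numpy as np
import pandas as pd
import pytest

from exposcreen.errors import ValidationError
from exposcreen.features import (
    average_replicates,
    call_detections,
    collapse_duplicates,
    filter_blank_features,
    find_duplicate_groups,
    harmonize_batches,
    match_formulas,
    merge_modes,
    pairwise_match,
)
from conftest import make_feature_rows


def _samples(batches=(1,), with_blank=True):
    rows = []
    for b in batches:
        rows.append((f"S{b}a", f"P{b}a", "maternal", b))
        rows.append((f"S{b}b", f"P{b}b", "maternal", b))
        if with_blank:
            rows.append((f"WB{b}", None, "water_blank", b))
    return pd.DataFrame(rows, columns=["sample_id", "participant_id", "matrix", "batch"])


def _blank_case(sample_ab, blank_ab):
    feats = make_feature_rows(
        [("f1", 300.0, 5.0, {"S1a": sample_ab, "S1b": sample_ab, "WB1": blank_ab})],
        samples=("S1a", "S1b", "WB1"),
    )
    return feats, _samples()


class TestBlankFilter:
    @pytest.mark.parametrize(
        "sample_ab,blank_ab,kept",
        [
            (10000, 5000, True),   # exactly two times qualifies
            (9999, 5000, False),   # strictly below the ratio is zeroed
            (100, 0, True),        # zero blank reference filters nothing
            (10001, 5000, True),
        ],
    )
    def test_two_times_rule_boundaries(self, sample_ab, blank_ab, kept):
        feats, samples = _blank_case(sample_ab, blank_ab)
        out = filter_blank_features(feats, samples, ratio=2.0)
        study = out[out["sample_id"] == "S1a"]
        if kept:
            assert (study["abundance"] == sample_ab).all()
        else:
            assert len(out) == 0 or (study["abundance"] == 0).all()

    def test_feature_dropped_when_all_cells_fail(self):
        feats, samples = _blank_case(9000, 5000)
        out = filter_blank_features(feats, samples, ratio=2.0)
        assert "f1" not in set(out["feature_id"])

    def test_blank_reference_is_batchwise(self):
        # blank signal in batch 1 must not filter the batch-2 feature
        f1 = make_feature_rows(
            [("f1", 300.0, 5.0, {"S1a": 6000, "WB1": 5000})],
            batch=1, samples=("S1a", "S1b", "WB1"),
        )
        f2 = make_feature_rows(
            [("f2", 300.0, 5.0, {"S2a": 6000})],
            batch=2, samples=("S2a", "S2b", "WB2"),
        )
        feats = pd.concat([f1, f2], ignore_index=True)
        out = filter_blank_features(feats, _samples(batches=(1, 2)), ratio=2.0)
        assert "f2" in set(out["feature_id"])
        assert "f1" not in set(out["feature_id"])

    def test_missing_water_blank_names_batch(self):
        feats = make_feature_rows([("f1", 300.0, 5.0, {"S1a": 100})], samples=("S1a",))
        samples = _samples(with_blank=False)
        with pytest.raises(ValidationError, match="1"):
            filter_blank_features(feats, samples)

    def test_raising_ratio_only_zeroes_more(self, small_study):
        feats, samples = small_study["features"], small_study["samples"]
        lo = filter_blank_features(feats, samples, ratio=2.0)
        hi = filter_blank_features(feats, samples, ratio=4.0)
        key = ["feature_id", "sample_id", "replicate"]
        merged = lo.merge(hi, on=key, how="left", suffixes=("_lo", "_hi"))
        ab_hi = merged["abundance_hi"].fillna(0.0)
        assert ((ab_hi <= merged["abundance_lo"]) | np.isclose(
            ab_hi, merged["abundance_lo"])).all()
        assert set(hi["feature_id"]) <= set(lo["feature_id"])


class TestFormulaMatching:
    def test_exact_mass_scores_100(self, tiny_db):
        feats = make_feature_rows([("f1", 300.0, 5.0, {"S1": 1})], samples=("S1",))
        m = match_formulas(feats, tiny_db)
        assert len(m) == 1
        assert m.iloc[0]["formula"] == "C10H10O2"
        assert m.iloc[0]["ppm_error"] == 0.0
        assert m.iloc[0]["score"] == 100.0

    def test_20ppm_off_is_unmatched(self, tiny_db):
        feats = make_feature_rows([("f1", 300.006, 5.0, {"S1": 1})], samples=("S1",))
        m = match_formulas(feats, tiny_db, ppm_tol=5.0)
        assert len(m) == 0
        assert m.attrs["n_unmatched"] == 1

    def test_score_threshold_gates_match(self, tiny_db):
        # 2 ppm error -> score 60 < 70 with the default mapping
        feats = make_feature_rows(
            [("f1", 300.0 * (1 + 2e-6), 5.0, {"S1": 1})], samples=("S1",)
        )
        assert len(match_formulas(feats, tiny_db, score_threshold=70.0)) == 0
        assert len(match_formulas(feats, tiny_db, score_threshold=50.0)) == 1

    def test_nearer_of_two_formulas_wins(self):
        from exposcreen.types import ChemicalDatabase, FormulaEntry, IsomerEntry

        db = ChemicalDatabase(
            [
                FormulaEntry("A1", 300.0000, (IsomerEntry("a", "A1", 0, 0, 0),)),
                FormulaEntry("B1", 300.0006, (IsomerEntry("b", "B1", 0, 0, 0),)),
            ]
        )
        feats = make_feature_rows(
            [("f1", 300.0004, 5.0, {"S1": 1})], samples=("S1",)
        )
        m = match_formulas(feats, db, score_threshold=0.0)
        assert m.iloc[0]["formula"] == "B1"


class TestDetections:
    @pytest.mark.parametrize("ab,expected", [(5000.0, True), (4999.0, False), (0.0, False)])
    def test_inclusive_threshold(self, ab, expected):
        mat = pd.DataFrame({"s1": [ab]}, index=["c1"])
        det = call_detections(mat, 5000.0)
        assert bool(det.detected.iloc[0, 0]) is expected

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValidationError):
            call_detections(pd.DataFrame({"s1": [-1.0]}, index=["c1"]))

    def test_frequency_is_mean_over_samples(self):
        mat = pd.DataFrame({"a": [6000.0], "b": [0.0], "c": [7000.0], "d": [1.0]},
                           index=["c1"])
        assert call_detections(mat).frequency["c1"] == 0.5


def _meta(rows):
    return pd.DataFrame(
        rows, columns=["feature_id", "formula", "neutral_mass", "rt"]
    )


class TestDuplicateGroups:
    @pytest.mark.parametrize(
        "dppm,drt,together",
        [
            (10.0, 0.3, True),
            (15.0, 0.5, True),    # inclusive boundary on both axes
            (15.01, 0.5, False),
            (15.0, 0.51, False),
            (10.0, 0.6, False),
        ],
    )
    def test_pair_boundaries(self, dppm, drt, together):
        m1 = 300.0
        m2 = m1 * (1 + dppm * 1e-6)
        meta = _meta([("a", "X", m1, 5.0), ("b", "X", m2, 5.0 + drt)])
        groups = find_duplicate_groups(meta)
        assert ({"a", "b"} in groups) is together

    def test_ppm_uses_smaller_mass_denominator(self):
        # 15 ppm of the smaller mass: inclusive exactly at the boundary
        m1 = 500.0
        m2 = m1 * (1 + 15e-6)
        meta = _meta([("a", "X", m1, 1.0), ("b", "X", m2, 1.0)])
        assert {"a", "b"} in find_duplicate_groups(meta)

    def test_shared_match_transitivity(self):
        # a-b and b-c match, a-c does not: one group of three
        m = 300.0
        meta = _meta(
            [
                ("a", "X", m, 5.0),
                ("b", "X", m * (1 + 10e-6), 5.0),
                ("c", "X", m * (1 + 20e-6), 5.0),
            ]
        )
        groups = find_duplicate_groups(meta)
        assert {"a", "b", "c"} in groups

    def test_different_formulas_never_grouped(self):
        meta = _meta([("a", "X", 300.0, 5.0), ("b", "Y", 300.0, 5.0)])
        groups = find_duplicate_groups(meta)
        assert {"a"} in groups and {"b"} in groups

    def test_matches_bfs_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(2, 120))
            formulas = rng.choice(["X", "Y", "Z"], n)
            masses = rng.uniform(100, 1000, n) * (1 + rng.normal(0, 8e-6, n))
            rts = rng.uniform(0, 19, n)
            meta = _meta(
                [(f"f{i}", formulas[i], masses[i], rts[i]) for i in range(n)]
            )
            got = set(map(frozenset, find_duplicate_groups(meta)))
            assert got == _bfs_oracle(meta)


class TestCollapse:
    def test_highest_detection_frequency_retained(self):
        stats = pd.DataFrame(
            {"detection_frequency": [0.8, 0.5], "ppm_error": [1.0, 0.1]},
            index=["a", "b"],
        )
        retained, groups = collapse_duplicates([{"a", "b"}], stats)
        assert retained == ["a"]
        assert groups[0].retained_id == "a"

    def test_tie_breaks_on_ppm_then_id(self):
        stats = pd.DataFrame(
            {"detection_frequency": [0.5, 0.5, 0.5], "ppm_error": [1.0, -0.2, 0.2]},
            index=["a", "b", "c"],
        )
        retained, _ = collapse_duplicates([{"a", "b", "c"}], stats)
        assert retained == ["b"]
        stats2 = stats.copy()
        stats2["ppm_error"] = [0.2, 0.2, 0.2]
        retained2, _ = collapse_duplicates([{"a", "b", "c"}], stats2)
        assert retained2 == ["a"]

    def test_singleton_retains_itself(self):
        stats = pd.DataFrame(
            {"detection_frequency": [0.1], "ppm_error": [2.0]}, index=["a"]
        )
        assert collapse_duplicates([{"a"}], stats)[0] == ["a"]

    def test_empty_group_is_internal_error(self):
        with pytest.raises(ValidationError):
            collapse_duplicates([set()], pd.DataFrame())

    def test_order_invariance_of_retained_set(self):
        rng = np.random.default_rng(3)
        n = 60
        meta = _meta(
            [
                (
                    f"f{i}",
                    rng.choice(["X", "Y"]),
                    float(rng.uniform(100, 200) * (1 + rng.normal(0, 5e-6))),
                    float(rng.uniform(0, 10)),
                )
                for i in range(n)
            ]
        )
        stats = pd.DataFrame(
            {
                "detection_frequency": rng.choice([0.2, 0.5, 0.5, 0.8], n),
                "ppm_error": rng.normal(0, 1, n),
            },
            index=meta["feature_id"],
        )
        base = collapse_duplicates(find_duplicate_groups(meta), stats)[0]
        for seed in range(3):
            perm = meta.sample(frac=1.0, random_state=seed).reset_index(drop=True)
            got = collapse_duplicates(find_duplicate_groups(perm), stats)[0]
            assert got == base

    def test_idempotence(self):
        rng = np.random.default_rng(9)
        n = 40
        meta = _meta(
            [
                (
                    f"f{i}",
                    "X",
                    float(rng.uniform(100, 100.01)),
                    float(rng.uniform(0, 3)),
                )
                for i in range(n)
            ]
        )
        stats = pd.DataFrame(
            {"detection_frequency": rng.random(n), "ppm_error": rng.normal(0, 1, n)},
            index=meta["feature_id"],
        )
        retained, _ = collapse_duplicates(find_duplicate_groups(meta), stats)
        meta2 = meta[meta["feature_id"].isin(retained)]
        retained2, _ = collapse_duplicates(find_duplicate_groups(meta2), stats)
        assert retained2 == retained


class TestMergeModes:
    def _tables(self):
        pos = _meta([("p1", "X", 300.0, 5.0)]).assign(ppm_error=0.5, mode="positive")
        neg = _meta([("n1", "X", 300.0 * (1 + 5e-6), 5.1)]).assign(
            ppm_error=1.0, mode="negative"
        )
        return pos, neg

    def test_same_chemical_in_both_modes_collapses(self):
        pos, neg = self._tables()
        freq = pd.Series({"p1": 0.8, "n1": 0.4})
        merged, groups = merge_modes({"positive": pos, "negative": neg}, freq)
        assert list(merged["feature_id"]) == ["p1"]

    def test_mode_exclusive_chemicals_both_kept(self):
        pos, neg = self._tables()
        neg["formula"] = "Y"
        freq = pd.Series({"p1": 0.8, "n1": 0.4})
        merged, _ = merge_modes({"positive": pos, "negative": neg}, freq)
        assert set(merged["feature_id"]) == {"p1", "n1"}

    def test_empty_negative_table_passes_positive_through(self):
        pos, _ = self._tables()
        merged, groups = merge_modes(
            {"positive": pos, "negative": pos.iloc[:0]}, pd.Series({"p1": 0.8})
        )
        assert list(merged["feature_id"]) == ["p1"]
        assert all(len(g.members) == 1 for g in groups)


class TestReplicates:
    def test_mean_of_two_replicates(self):
        feats = make_feature_rows([("f1", 300.0, 5.0, {"S1": 1})], samples=("S1",))
        feats.loc[feats["replicate"] == 1, "abundance"] = 4000.0
        feats.loc[feats["replicate"] == 2, "abundance"] = 6000.0
        out = average_replicates(feats)
        assert out["abundance"].iloc[0] == 5000.0

    def test_singleton_extraction_zeroed(self):
        feats = make_feature_rows([("f1", 300.0, 5.0, {"S1": 1})], samples=("S1",))
        feats.loc[feats["replicate"] == 1, "abundance"] = 8000.0
        feats.loc[feats["replicate"] == 2, "abundance"] = 0.0
        out = average_replicates(feats)
        assert out["abundance"].iloc[0] == 0.0

    def test_equal_replicates_unchanged(self):
        feats = make_feature_rows([("f1", 300.0, 5.0, {"S1": 7000.0})], samples=("S1",))
        out = average_replicates(feats)
        assert out["abundance"].iloc[0] == 7000.0

    def test_three_replicates_rejected(self):
        feats = make_feature_rows([("f1", 300.0, 5.0, {"S1": 1})], samples=("S1",))
        extra = feats.iloc[[0]].assign(replicate=3)
        with pytest.raises(ValidationError):
            average_replicates(pd.concat([feats, extra], ignore_index=True))


class TestHarmonize:
    def _abund(self, fid, cols, val=6000.0):
        return pd.DataFrame({c: [val] for c in cols}, index=[fid])

    def test_chained_batches_become_one_chemical(self):
        # A1-A2 match, A2-A3 match, A1-A3 RT drifted beyond the window
        m = 300.0
        t1 = _meta([("A1", "X", m, 5.0)]).assign(ppm_error=0.1)
        t2 = _meta([("A2", "X", m, 5.4)]).assign(ppm_error=0.1)
        t3 = _meta([("A3", "X", m, 5.8)]).assign(ppm_error=0.1)
        per_batch = {
            1: (t1, self._abund("A1", ["s1"])),
            2: (t2, self._abund("A2", ["s2"])),
            3: (t3, self._abund("A3", ["s3"])),
        }
        freq = pd.Series({"A1": 0.5, "A2": 0.5, "A3": 0.5})
        table = harmonize_batches(per_batch, freq)
        assert len(table.meta) == 1
        assert table.meta.iloc[0]["n_batches"] == 3
        assert (table.abundance.loc[table.meta.iloc[0]["chemical"]] == 6000.0).all()

    def test_batch_exclusive_chemical_keeps_zero_elsewhere(self):
        t1 = _meta([("A1", "X", 300.0, 5.0)]).assign(ppm_error=0.1)
        t2 = _meta([("B1", "Y", 400.0, 8.0)]).assign(ppm_error=0.1)
        per_batch = {1: (t1, self._abund("A1", ["s1"])),
                     2: (t2, self._abund("B1", ["s2"]))}
        freq = pd.Series({"A1": 0.5, "B1": 0.5})
        table = harmonize_batches(per_batch, freq)
        assert len(table.meta) == 2
        row = table.abundance.loc[table.meta.set_index("formula").loc["X", "chemical"]]
        assert row["s1"] == 6000.0 and row["s2"] == 0.0

    def test_same_batch_conflict_keeps_higher_frequency_and_warns(self):
        # A1 and A1b in batch 1 are not duplicates of each other, but both
        # match the batch-2 bridge A2
        m = 300.0
        t1 = _meta(
            [("A1", "X", m, 4.8), ("A1b", "X", m, 5.8)]
        ).assign(ppm_error=0.1)
        t2 = _meta([("A2", "X", m, 5.3)]).assign(ppm_error=0.1)
        ab1 = pd.DataFrame({"s1": [6000.0, 9000.0]}, index=["A1", "A1b"])
        per_batch = {1: (t1, ab1), 2: (t2, self._abund("A2", ["s2"]))}
        freq = pd.Series({"A1": 0.2, "A1b": 0.9, "A2": 0.5})
        with pytest.warns(UserWarning, match="batch 1"):
            table = harmonize_batches(per_batch, freq)
        assert len(table.meta) == 1
        chem = table.meta.iloc[0]["chemical"]
        assert table.abundance.loc[chem, "s1"] == 9000.0

    def test_known_chemical_count_recovered_on_clean_input(self, gen_db):
        from exposcreen.config import PipelineConfig
        from exposcreen.pipeline import run_feature_pipeline
        from exposcreen.synth import (
            EffectsConfig, FeatureGenConfig, generate_cohort,
            generate_feature_tables, make_ground_truth,
        )

        cohort = generate_cohort(12, seed=21)
        k = 25
        eff = EffectsConfig(n_chemicals=k, differential_fraction=0.2,
                            null_df_range=(0.5, 0.9))
        truth = make_ground_truth(gen_db, eff, seed=21)
        cfg = FeatureGenConfig(
            mass_ppm_sd=0.3, mass_ppm_max=1.0, rt_within_sd=0.02,
            rt_between_sd=0.05, duplicate_fraction=0.0, dual_mode_fraction=0.3,
            blank_fail_fraction=0.0, singleton_fraction=0.0,
        )
        feats, samples = generate_feature_tables(
            gen_db, cohort, truth=truth, seed=21, config=cfg
        )
        pcfg = PipelineConfig()
        table, detections, dedup, qc = run_feature_pipeline(
            feats, samples, gen_db, pcfg
        )
        assert len(table.meta) == k


def _bfs_oracle(meta, ppm_tol=15.0, rt_tol=0.5):
    """Independent grouping oracle: BFS over the pairwise match matrix."""
    ids = list(meta["feature_id"])
    formulas = list(meta["formula"])
    masses = list(meta["neutral_mass"])
    rts = list(meta["rt"])
    n = len(ids)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j or formulas[i] != formulas[j]:
                continue
            ppm = abs(masses[i] - masses[j]) / min(masses[i], masses[j]) * 1e6
            if ppm <= ppm_tol * (1 + 1e-9) and abs(rts[i] - rts[j]) <= rt_tol + 1e-12:
                adj[i][j] = True
    seen = [False] * n
    comps = set()
    for start in range(n):
        if seen[start]:
            continue
        queue = [start]
        seen[start] = True
        comp = []
        while queue:
            u = queue.pop(0)
            comp.append(ids[u])
            for v in range(n):
                if adj[u][v] and not seen[v]:
                    seen[v] = True
                    queue.append(v)
        comps.add(frozenset(comp))
    return comps
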