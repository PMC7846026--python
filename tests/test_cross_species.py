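"""Cross-species set construction and the metrics over it."""

import numpy as np
import pytest

from tcrshare.cross_species import (
    Quantifier,
    build_cross_species_set,
    cohort_mean_frequency,
    cross_rank_area,
    enumerate_peptide_pairs,
    exclusive_vs_cohort_overlap,
    rank_area_profile,
    rank_clones,
    resampling_null,
    select_highly_abundant,
    stage_similarity,
    tumor_associated_filter,
    vj_usage_correlation,
    weighted_jaccard,
)
from tcrshare.errors import ConfigError, CoverageError, EmptyInputError, TcrShareError
from tcrshare.io import Clone, RepertoireSample

from conftest import make_sample
from oracles import pearson_oracle, weighted_jaccard_oracle


class TestBuildCrossSpeciesSet:
    def _world(self):
        mouse = [
            make_sample({"CAF": 2, "CBF": 1}, sample_id="m1", timepoint=1),
            make_sample({"CAF": 1, "CCF": 1}, sample_id="m2", timepoint=2),
        ]
        human = {
            "d1": [make_sample({"CAF": 1, "CBF": 1}, sample_id="h1")],
            "d2": [make_sample({"CAF": 3}, sample_id="h2")],
        }
        return mouse, human

    def test_present_everywhere_is_member(self):
        mouse, human = self._world()
        cs = build_cross_species_set(mouse, human, Quantifier(human_requirement="all"))
        assert "CAF" in cs.members

    def test_absent_from_one_required_dataset_excluded(self):
        mouse, human = self._world()
        cs = build_cross_species_set(mouse, human, Quantifier(human_requirement="all"))
        assert "CBF" not in cs.members  # missing from d2

    def test_all_timepoints_requirement(self):
        mouse, human = self._world()
        cs = build_cross_species_set(
            mouse, human, Quantifier(require_all_mouse_timepoints=True, human_requirement="any")
        )
        assert cs.members == {"CAF"}

    def test_unknown_dataset_name_rejected(self):
        mouse, human = self._world()
        with pytest.raises(ConfigError):
            build_cross_species_set(mouse, human, Quantifier(datasets=("nope",)))

    def test_random_world_matches_nested_loop_oracle(self, rng):
        aas = [f"C{chr(65 + i)}F" for i in range(20)]
        for _ in range(20):
            mouse = [
                make_sample({aa: 1 for aa in aas if rng.random() < 0.4} or {aas[0]: 1},
                            sample_id=f"m{i}", timepoint=i + 1)
                for i in range(3)
            ]
            human = {
                name: [
                    make_sample({aa: 1 for aa in aas if rng.random() < 0.4} or {aas[1]: 1},
                                sample_id=f"{name}_s{j}")
                    for j in range(2)
                ]
                for name in ("d1", "d2")
            }
            q = Quantifier(min_mouse_samples=2, human_requirement="all")
            got = build_cross_species_set(mouse, human, q).members
            expected = set()
            for aa in aas:
                n_mouse = sum(1 for m in mouse if aa in m.aa_set())
                in_all = all(
                    any(aa in s.aa_set() for s in cohort) for cohort in human.values()
                )
                if n_mouse >= 2 and in_all:
                    expected.add(aa)
            assert got == expected
            # monotonicity: relaxing the quantifier never removes members
            relaxed = build_cross_species_set(
                mouse, human, Quantifier(min_mouse_samples=1, human_requirement="any")
            ).members
            assert got <= relaxed


class TestTumorAssociatedFilter:
    tumor = [make_sample({"CAF": 1, "CBF": 1}, sample_id="t", tissue="tumor")]
    normal = [make_sample({"CBF": 1}, sample_id="n", tissue="normal")]

    def test_tumor_only_kept(self):
        assert tumor_associated_filter({"CAF", "CBF"}, self.tumor, self.normal) == {"CAF"}

    def test_no_normals_degenerates_with_warning(self, caplog):
        out = tumor_associated_filter({"CAF", "CBF"}, self.tumor, [])
        assert out == {"CAF", "CBF"}


class TestRanking:
    def test_descending_count_ranks(self):
        s = make_sample({"a": 10, "b": 5, "c": 1})
        assert rank_clones(s) == {"a": 1, "b": 2, "c": 3}

    def test_lexicographic_tie_break(self):
        s = make_sample({"b": 5, "a": 5})
        assert rank_clones(s) == {"a": 1, "b": 2}

    def test_random_counts_agree_with_sort_oracle(self, rng):
        counts = {f"C{i:02d}F": int(rng.integers(1, 50)) for i in range(30)}
        ranks = rank_clones(make_sample(counts))
        order = sorted(counts, key=lambda aa: (-counts[aa], aa))
        assert ranks == {aa: i + 1 for i, aa in enumerate(order)}
        assert sorted(ranks.values()) == list(range(1, 31))


class TestCrossRankArea:
    def test_top_ranked_in_both_species(self):
        assert cross_rank_area(1, 1) == 1.0

    def test_last_of_258_in_both_species(self):
        assert round(cross_rank_area(258, 258), 6) == 0.000015

    def test_direct_arithmetic(self):
        assert cross_rank_area(2, 3) == pytest.approx(1 / 6)

    def test_rank_below_one_rejected(self):
        with pytest.raises(TcrShareError):
            cross_rank_area(0, 3)

    def test_strictly_decreasing_in_each_argument(self):
        for r in range(1, 20):
            assert cross_rank_area(r + 1, 5) < cross_rank_area(r, 5)
            assert cross_rank_area(5, r + 1) < cross_rank_area(5, r)


class TestRankAreaProfile:
    def test_concordant_top_member_dominates(self):
        mouse = {1: make_sample({"a": 10, "b": 1}, sample_id="m1")}
        human = make_sample({"a": 20, "b": 2}, sample_id="h")
        prof = rank_area_profile({"a", "b"}, mouse, human)
        share_a = prof.loc[prof["junction_aa"] == "a", "share"].item()
        assert share_a > 0.5  # area 1 vs 1/4

    def test_shares_normalise_per_timepoint(self):
        s = make_sample({"a": 5, "b": 3, "c": 1}, sample_id="m")
        prof = rank_area_profile({"a", "b", "c"}, {1: s, 2: s}, s)
        sums = prof.groupby("timepoint")["share"].sum()
        assert np.allclose(sums, 1.0)

    def test_matches_rank_recomputation_oracle(self, rng):
        aas = [f"C{i}F" for i in range(12)]
        mouse = {
            tp: make_sample({aa: int(rng.integers(1, 99)) for aa in aas}, sample_id=f"m{tp}")
            for tp in (1, 2, 3)
        }
        human = make_sample({aa: int(rng.integers(1, 99)) for aa in aas}, sample_id="h")
        prof = rank_area_profile(set(aas), mouse, human)
        hranks = rank_clones(human)
        for tp, sample in mouse.items():
            mranks = rank_clones(sample)
            sub = prof[prof["timepoint"] == tp]
            for row in sub.itertuples(index=False):
                assert row.area == pytest.approx(
                    1.0 / (mranks[row.junction_aa] * hranks[row.junction_aa])
                )

    def test_missing_member_named(self):
        mouse = {1: make_sample({"a": 1}, sample_id="m")}
        human = make_sample({"a": 1, "b": 1}, sample_id="h")
        with pytest.raises(CoverageError, match="b"):
            rank_area_profile({"a", "b"}, mouse, human)


class TestWeightedJaccard:
    def test_self_is_one(self):
        f = {"a": 0.5, "b": 0.5}
        assert weighted_jaccard(f, f) == pytest.approx(1.0)

    def test_disjoint_is_zero(self):
        assert weighted_jaccard({"a": 1.0}, {"b": 1.0}) == 0.0

    def test_hand_evaluation(self):
        got = weighted_jaccard({"a": 0.5, "b": 0.5}, {"a": 0.25, "c": 0.75})
        assert got == pytest.approx(0.25 / 1.75)

    def test_random_pairs_match_oracle_and_bounds(self, rng):
        for _ in range(50):
            a = {f"k{i}": float(rng.random()) for i in rng.choice(15, 6, replace=False)}
            b = {f"k{i}": float(rng.random()) for i in rng.choice(15, 6, replace=False)}
            got = weighted_jaccard(a, b)
            assert got == pytest.approx(weighted_jaccard_oracle(a, b), abs=1e-12)
            assert 0.0 <= got <= 1.0
            assert got == pytest.approx(weighted_jaccard(b, a))

    def test_all_zero_side_rejected(self):
        with pytest.raises(EmptyInputError):
            weighted_jaccard({"a": 0.0}, {"a": 1.0})


class TestExclusiveVsCohortOverlap:
    def test_empty_exclusive_set_gives_zero_overlaps(self, rng):
        mice = [make_sample({f"C{i}F": 5 for i in range(10)}, sample_id="m1")]
        cohorts = {"h": [make_sample({f"C{i}F": 5 for i in range(10)}, sample_id="h1")]}
        res = exclusive_vs_cohort_overlap(
            {"case": set(), "control": set()}, mice, cohorts, subsample_n=20, seed=0
        )
        assert all(v == 0.0 for v in res["means"].values())

    def test_planted_enrichment_detected(self):
        """Case-exclusive AAs injected into the 'breast' cohort only:
        their overlap with that cohort exceeds the control set's."""
        case_set = {f"CASE{i}F" for i in range(8)}
        ctrl_set = {f"CTRL{i}F" for i in range(8)}
        mice = [
            make_sample(
                {**{aa: 10 for aa in case_set}, **{aa: 10 for aa in ctrl_set}},
                sample_id=f"m{i}",
            )
            for i in range(3)
        ]
        breast = [
            make_sample({**{aa: 10 for aa in case_set}, "CXF": 10}, sample_id=f"h{i}")
            for i in range(3)
        ]
        res = exclusive_vs_cohort_overlap(
            {"case": case_set, "control": ctrl_set},
            mice,
            {"breast": breast},
            subsample_n=40,
            seed=1,
        )
        assert res["means"][("case", "breast")] > res["means"][("control", "breast")]
        assert res["tests"]["breast"]["p_value"] < 0.05


class TestStageSimilarity:
    def test_formula(self):
        sample = make_sample({f"C{i}F": 1 for i in range(10)})
        cohort = {"i": [{"C0F", "C1F"}, set(), set(), set(), set()]}
        recs = stage_similarity(sample, cohort)
        assert recs[0].shared_count == 2
        assert recs[0].similarity == pytest.approx(2 / (10 * 5))

    def test_no_shared_clones_zero(self):
        recs = stage_similarity(make_sample({"CAF": 1}), {"i": [{"CXF"}]})
        assert recs[0].similarity == 0.0

    def test_invariant_under_relabeling(self, rng):
        aas = [f"C{i}F" for i in range(12)]
        relabel = {aa: f"Z{i}" for i, aa in enumerate(aas)}
        sample_aas = aas[:8]
        cohort = {"ii": [set(aas[4:10]), set(aas[2:5])]}
        a = stage_similarity(make_sample({aa: 1 for aa in sample_aas}), cohort)
        b = stage_similarity(
            make_sample({relabel[aa]: 1 for aa in sample_aas}),
            {"ii": [{relabel[aa] for aa in s} for s in cohort["ii"]]},
        )
        assert a[0].similarity == b[0].similarity

    def test_empty_stage_excluded_with_warning(self):
        recs = stage_similarity(make_sample({"CAF": 1}), {"i": [], "ii": [{"CAF"}]})
        assert [r.stage for r in recs] == ["ii"]


class TestSelectHighlyAbundant:
    def _epoch(self, n, counts_by_aa):
        return [
            make_sample(
                {aa: c for aa, c in counts_by_aa(i).items() if c > 0},
                sample_id=f"s{i}",
            )
            for i in range(n)
        ]

    def test_presence_threshold(self):
        young = self._epoch(12, lambda i: {"CAF": 1, "CBF": 1 if i < 3 else 0})
        old = self._epoch(12, lambda i: {"CAF": 1, "CBF": 1 if i < 3 else 0})
        candidates, _ = select_highly_abundant(young, old, min_samples=10)
        assert "CAF" in candidates and "CBF" not in candidates

    def test_planted_old_enrichment_recovered(self, rng):
        young = self._epoch(
            12, lambda i: {"CAF": int(rng.integers(1, 5)), "CBF": int(rng.integers(8, 12))}
        )
        old = self._epoch(
            12, lambda i: {"CAF": int(rng.integers(15, 25)), "CBF": int(rng.integers(8, 12))}
        )
        candidates, significant = select_highly_abundant(young, old, min_samples=10)
        assert "CAF" in significant
        assert "CBF" not in significant

    def test_alpha_zero_empties_significant(self):
        young = self._epoch(10, lambda i: {"CAF": 1 + i})
        old = self._epoch(10, lambda i: {"CAF": 20 + i})
        _, significant = select_highly_abundant(young, old, min_samples=10, alpha=0.0)
        assert significant == set()

    def test_min_samples_exceeding_epoch_rejected(self):
        with pytest.raises(ConfigError):
            select_highly_abundant(self._epoch(3, lambda i: {"CAF": 1}),
                                   self._epoch(3, lambda i: {"CAF": 1}), min_samples=10)


class TestResamplingNull:
    cohort = [make_sample({f"C{i}F": (20 - i) for i in range(20)}, sample_id="h")]
    candidates = {f"C{i}F" for i in range(20)}

    def test_reproducible_bit_exact(self):
        a = resampling_null({"C0F", "C1F"}, self.candidates, self.cohort, n_iter=10, seed=3)
        b = resampling_null({"C0F", "C1F"}, self.candidates, self.cohort, n_iter=10, seed=3)
        assert np.array_equal(a["null"], b["null"]) and a["p_value"] == b["p_value"]

    def test_most_frequent_selection_minimal_p(self):
        selected = {"C0F", "C1F", "C2F"}  # the three most frequent
        res = resampling_null(selected, self.candidates, self.cohort, n_iter=200, seed=0)
        assert res["p_value"] == pytest.approx(1 / 201)

    def test_p_bounds(self, rng):
        for seed in range(5):
            sel = {f"C{i}F" for i in rng.choice(20, 4, replace=False)}
            res = resampling_null(sel, self.candidates, self.cohort, n_iter=50, seed=seed)
            assert 1 / 51 <= res["p_value"] <= 1.0

    def test_observed_matches_frequency_definition(self):
        obs = cohort_mean_frequency({"C0F"}, self.cohort)
        depth = sum(20 - i for i in range(20))
        assert obs == pytest.approx(20 / depth)


class TestPeptidePairs:
    def test_full_cartesian_size(self):
        cdr3s = [f"CASS{i:03d}F" for i in range(258)]
        peptides = [f"PEP{i:03d}" for i in range(257)]
        assert len(enumerate_peptide_pairs(cdr3s, peptides)) == 66_306

    @pytest.mark.parametrize("n_c, n_p", [(1, 1), (3, 4)])
    def test_small_products(self, n_c, n_p):
        df = enumerate_peptide_pairs(
            [f"C{i}F" for i in range(n_c)], [f"P{i}" for i in range(n_p)]
        )
        assert len(df) == n_c * n_p

    def test_duplicates_deduplicated(self):
        df = enumerate_peptide_pairs(["CAF", "CAF"], ["P1"])
        assert len(df) == 1

    def test_table_scorer_lookup_with_missing(self):
        import pandas as pd

        table = pd.DataFrame(
            {"cdr3": ["CAF"], "peptide": ["P1"], "score": [0.7]}
        )
        df = enumerate_peptide_pairs(["CAF", "CBF"], ["P1"], scorer=table)
        scores = dict(zip(zip(df["cdr3"], df["peptide"]), df["score"]))
        assert scores[("CAF", "P1")] == 0.7
        assert np.isnan(scores[("CBF", "P1")])


class TestVJUsage:
    def _samples(self, usage_rows):
        out = []
        for i, row in enumerate(usage_rows):
            s = RepertoireSample(f"s{i}", f"s{i}")
            for j, (gene, cnt) in enumerate(row.items()):
                s.add_clone(
                    Clone(f"NT{i}_{j}", f"C{j}F", cnt, v_calls=frozenset({gene}))
                )
            out.append(s)
        return out

    def test_proportional_usage_correlates_plus_one(self):
        # V1 and V2 frequency vectors proportional across samples; V3 varies
        samples = self._samples([
            {"V1": 1, "V2": 2, "V3": 7}, {"V1": 2, "V2": 4, "V3": 4},
            {"V1": 3, "V2": 6, "V3": 1},
        ])
        corr = vj_usage_correlation(samples, which="v")
        assert corr.loc["V1", "V2"] == pytest.approx(1.0)

    def test_antiproportional_usage_correlates_minus_one(self):
        samples = self._samples([
            {"V1": 1, "V2": 3}, {"V1": 2, "V2": 2}, {"V1": 3, "V2": 1},
        ])
        corr = vj_usage_correlation(samples, which="v")
        assert corr.loc["V1", "V2"] == pytest.approx(-1.0)

    def test_random_usage_matches_direct_summation_pearson(self, rng):
        rows = [
            {f"V{g}": int(rng.integers(1, 30)) for g in range(4)} for _ in range(6)
        ]
        samples = self._samples(rows)
        corr = vj_usage_correlation(samples, which="v")
        freq = {
            g: [row[g] / sum(row.values()) for row in rows]
            for g in rows[0]
        }
        for ga in freq:
            for gb in freq:
                assert corr.loc[ga, gb] == pytest.approx(
                    pearson_oracle(freq[ga], freq[gb]), abs=1e-10
                )
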