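"""Fixed-variant classification, Venn arithmetic, distribution scans."""

import numpy as np
import pytest
from scipy import stats

from conftest import make_callset, make_site

from indelfinger.comparison import (
    DISTINCT_CLASSES,
    FixedClass,
    arm_counts,
    arm_distribution_test,
    call_clusters,
    classify_fixed,
    coding_effect,
    count_in_features,
    percent,
    sliding_windows,
    venn_summary,
    window_spans,
)
from indelfinger.models import FeatureInterval, FeatureSet, GenomeReference, VariantSite


class TestClassify:
    @pytest.mark.parametrize(
        "ga,gb,expected",
        [
            ((1, 1), (0, 0), FixedClass.UNIQUE_A),
            ((0, 0), (1, 1), FixedClass.UNIQUE_B),
            ((1, 1), (1, 1), FixedClass.SHARED_ALT),
            ((0, 1), (1, 1), FixedClass.NOT_FIXED),
            ((0, 0), (0, 0), FixedClass.REF_BOTH),
            (None, (1, 1), FixedClass.NOT_FIXED),
        ],
    )
    def test_definitions(self, ga, gb, expected):
        cs = make_callset(["a", "b"], [(make_site(), {"a": ga, "b": gb})])
        assert classify_fixed(cs, "a", "b") == [expected]

    def test_multiallelic_rejected(self):
        cs = make_callset(["a", "b"], [(make_site(alts=("G", "T")), {"a": (1, 1), "b": (0, 0)})])
        with pytest.raises(ValueError):
            classify_fixed(cs, "a", "b")

    def test_classes_conserve_input(self, classified):
        callset, classes = classified
        assert len(classes) == len(callset)

    def test_recovers_planted_classes(self, scenario, classified):
        """Every filtered site's class matches the generator's ground truth."""
        callset, classes = classified
        truth = {
            (v["contig"], v["pos"]): v for v in scenario.truth["variants"]
        }
        checked = 0
        for site, cls in zip(callset.sites, classes):
            t = truth[(site.contig, site.pos)]
            if t["role"] != "variant":
                continue
            a, b = scenario.truth["focal_pair"]
            ga, gb = t["genotypes"][a], t["genotypes"][b]
            if ga is None or gb is None or ga[0] != ga[1] or gb[0] != gb[1]:
                expected = FixedClass.NOT_FIXED
            elif ga == [1, 1] and gb == [1, 1]:
                expected = FixedClass.SHARED_ALT
            elif ga == [1, 1]:
                expected = FixedClass.UNIQUE_A
            elif gb == [1, 1]:
                expected = FixedClass.UNIQUE_B
            else:
                expected = FixedClass.REF_BOTH
            assert cls == expected, f"{site.contig}:{site.pos}"
            checked += 1
        assert checked > 1000


class TestPercent:
    @pytest.mark.parametrize(
        "count,total,expected",
        [
            (314, 331, 95),
            (118, 124, 95),
            (207_249, 289_475, 72),
            (915_720, 1_244_056, 74),
            (67_193, 289_475, 23),
            (15_033, 289_475, 5),
            (1, 1, 100),
            (1, 200, 1),  # 0.5 rounds away from zero
        ],
    )
    def test_rounding_half_away_from_zero(self, count, total, expected):
        assert percent(count, total) == expected

    def test_zero_total_raises(self):
        with pytest.raises(ZeroDivisionError):
            percent(1, 0)


class TestVenn:
    def test_small_constructed_summary(self):
        rows = []
        plan = [((1, 1), (1, 1))] * 5 + [((1, 1), (0, 0))] * 2 + [((0, 0), (1, 1))] * 3
        for i, (ga, gb) in enumerate(plan):
            rows.append((make_site(pos=100 + 10 * i), {"a": ga, "b": gb}))
        rows.append((make_site(pos=995, ref="AT", alts=("A",)), {"a": (1, 1), "b": (0, 0)}))
        cs = make_callset(["a", "b"], rows)
        summary = venn_summary(cs, classify_fixed(cs, "a", "b"))
        snp = summary["SNP"]
        assert snp["fixed_total"] == 10
        assert snp["counts"]["SHARED_ALT"] == 5
        assert snp["percent"] == {"SHARED_ALT": 50, "UNIQUE_A": 20, "UNIQUE_B": 30}
        assert summary["INDEL"]["fixed_total"] == 1
        assert summary["INDEL"]["percent"]["UNIQUE_A"] == 100

    def test_single_shared_variant(self):
        cs = make_callset(["a", "b"], [(make_site(), {"a": (1, 1), "b": (1, 1)})])
        s = venn_summary(cs, classify_fixed(cs, "a", "b"))
        assert s["SNP"]["percent"]["SHARED_ALT"] == 100


def _textbook_chi2(observed, expected):
    return sum((o - e) ** 2 / e for o, e in zip(observed, expected))


class TestArmChi2:
    def test_null_case(self):
        res = arm_distribution_test({"a": 50, "b": 50}, {"a": 1000, "b": 1000})
        assert res["chi2"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_two_equal_arms_closed_form(self):
        # (10-5)^2/5 + (0-5)^2/5 = 10
        res = arm_distribution_test({"a": 10, "b": 0}, {"a": 500, "b": 500})
        assert res["chi2"] == pytest.approx(10.0)
        assert res["df"] == 1

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_textbook_formula(self, seed):
        rng = np.random.default_rng(seed)
        lengths = {f"arm{i}": int(rng.integers(10_000, 100_000)) for i in range(5)}
        total = 5000
        probs = np.array(list(lengths.values()), dtype=float)
        probs /= probs.sum()
        counts = rng.multinomial(total, probs)
        observed = dict(zip(lengths, (int(c) for c in counts)))
        res = arm_distribution_test(observed, lengths)
        expected = [total * l / sum(lengths.values()) for l in lengths.values()]
        assert res["chi2"] == pytest.approx(_textbook_chi2(counts, expected), abs=1e-9)

    def test_p_uniform_under_null(self):
        """Uniform variant placement -> uniform p-values (KS at alpha 0.01)."""
        rng = np.random.default_rng(7)
        lengths = {"a": 40_000, "b": 60_000, "c": 100_000}
        pvals = []
        probs = np.array([0.2, 0.3, 0.5])
        for _ in range(300):
            counts = rng.multinomial(10_000, probs)
            res = arm_distribution_test(dict(zip(lengths, map(int, counts))), lengths)
            pvals.append(res["p"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError):
            arm_distribution_test({"a": 5}, {"a": 100})

    def test_scenario_blocks_make_distribution_nonrandom(self, scenario, classified):
        callset, classes = classified
        obs = arm_counts(callset, classes, DISTINCT_CLASSES)
        res = arm_distribution_test(obs, scenario.genome.lengths)
        assert res["p"] < 1e-4


class TestWindows:
    def test_span_enumeration(self):
        spans = window_spans(20_000, 10_000, 2_500)
        assert [s for s, _, _ in spans] == [1, 2501, 5001, 7501, 10001]
        assert all(not t for _, _, t in spans)

    def test_tail_window_truncated(self):
        # full windows end at start 10001 (covering ..20000); the uncovered
        # tail yields one truncated window at the next step position
        spans = window_spans(22_000, 10_000, 2_500)
        assert spans[-1] == (12501, 22000, True)
        assert [s for s, _, t in spans if not t][-1] == 10001

    def test_short_contig_single_truncated_window(self):
        assert window_spans(5_000, 10_000, 2_500) == [(1, 5000, True)]

    def test_step_larger_than_window_rejected(self):
        with pytest.raises(ValueError):
            window_spans(10_000, 100, 200)

    def test_interior_variant_in_expected_windows(self):
        cs = make_callset(["a", "b"], [(make_site(pos=5000), {"a": (1, 1), "b": (0, 0)})])
        classes = classify_fixed(cs, "a", "b")
        windows = sliding_windows(cs, classes, {"c1": 20_000})
        hits = [w for w in windows if w.distinct_count]
        assert [(w.start, w.end) for w in hits] == [(1, 10_000), (2501, 12_500)]

    def test_empty_callset_all_zero(self):
        cs = make_callset(["a", "b"], [])
        windows = sliding_windows(cs, [], {"c1": 20_000})
        assert windows and all(w.distinct_count == 0 for w in windows)

    def test_interior_multiplicity_property(self):
        """With step < window, each interior variant lands in window/step windows."""
        rows = [
            (make_site(pos=p), {"a": (1, 1), "b": (0, 0)})
            for p in range(15_000, 25_001, 500)
        ]
        cs = make_callset(["a", "b"], rows)
        classes = classify_fixed(cs, "a", "b")
        windows = sliding_windows(cs, classes, {"c1": 50_000})
        total = sum(w.distinct_count for w in windows)
        assert total == len(rows) * 4  # window 10k / step 2.5k


class TestClusters:
    def _clustered_callset(self, blocks, background=0, length=1_000_000, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        pos_used = set()
        for start, end, owner in blocks:
            for p in sorted(rng.integers(start, end, size=(end - start) // 500)):
                p = int(p)
                if p in pos_used:
                    continue
                pos_used.add(p)
                gts = {"a": (1, 1), "b": (0, 0)} if owner == "a" else {"a": (0, 0), "b": (1, 1)}
                rows.append((make_site(pos=p), gts))
        for p in rng.integers(1, length, size=background):
            p = int(p)
            if p in pos_used:
                continue
            pos_used.add(p)
            rows.append((make_site(pos=p), {"a": (1, 1), "b": (0, 0)}))
        cs = make_callset(["a", "b"], rows)
        return cs, classify_fixed(cs, "a", "b")

    def test_planted_block_recovered_with_owner(self):
        cs, classes = self._clustered_callset([(500_000, 550_000, "b")], background=50)
        windows = sliding_windows(cs, classes, {"c1": 1_000_000})
        calls = call_clusters(windows, cs, classes)
        assert len(calls) == 1
        c = calls[0]
        assert c.dominant_class == "UNIQUE_B"
        assert c.start <= 500_000 and c.end >= 545_000

    def test_uniform_background_no_clusters(self):
        cs, classes = self._clustered_callset([], background=200)
        windows = sliding_windows(cs, classes, {"c1": 1_000_000})
        assert call_clusters(windows, cs, classes) == []

    def test_distant_blocks_stay_separate(self):
        cs, classes = self._clustered_callset(
            [(100_000, 150_000, "a"), (700_000, 750_000, "b")], background=20
        )
        windows = sliding_windows(cs, classes, {"c1": 1_000_000})
        calls = call_clusters(windows, cs, classes)
        assert len(calls) == 2
        assert {c.dominant_class for c in calls} == {"UNIQUE_A", "UNIQUE_B"}


class TestFeatures:
    FEATURES = FeatureSet([
        FeatureInterval("c1", 10, 20, "exon1", "exon"),
        FeatureInterval("c1", 20, 40, "intron1", "intron"),
        FeatureInterval("c1", 100, 200, "enh1", "enhancer"),
    ])

    def _classified(self, positions):
        rows = [(make_site(pos=p), {"a": (1, 1), "b": (0, 0)}) for p in positions]
        cs = make_callset(["a", "b"], rows)
        return cs, classify_fixed(cs, "a", "b")

    def test_position_inside_exon(self):
        cs, classes = self._classified([15])
        out = count_in_features(cs, classes, self.FEATURES)
        assert out["per_feature"]["exon1"]["SNP"] == 1

    def test_boundary_follows_half_open_rule(self):
        # 1-based pos 21 -> 0-based 20: first base of the intron, not the exon
        cs, classes = self._classified([21])
        out = count_in_features(cs, classes, self.FEATURES)
        assert "exon1" not in out["per_feature"]
        assert out["per_feature"]["intron1"]["SNP"] == 1

    def test_planted_enhancer_count(self):
        cs, classes = self._classified([110, 120, 130, 140, 150])
        out = count_in_features(cs, classes, self.FEATURES)
        assert out["per_category"]["enhancer"] == 5

    def test_outside_everything_is_intergenic(self):
        cs, classes = self._classified([5000])
        out = count_in_features(cs, classes, self.FEATURES)
        assert out["per_category"] == {"intergenic": 1}


class TestCodingEffect:
    GENOME = GenomeReference({"c1": "ATGCTTTAAGGG"})
    CDS = [(0, 9)]  # ATG CTT TAA

    def test_synonymous_third_position(self):
        site = VariantSite("c1", 6, "T", ("C",))  # CTT -> CTC, Leu -> Leu
        assert coding_effect(site, self.CDS, "+", self.GENOME) == "synonymous"

    def test_nonsynonymous(self):
        site = VariantSite("c1", 3, "G", ("A",))  # ATG -> ATA, Met -> Ile
        assert coding_effect(site, self.CDS, "+", self.GENOME) == "nonsynonymous"

    def test_outside_cds_noncoding(self):
        site = VariantSite("c1", 11, "G", ("T",))
        assert coding_effect(site, self.CDS, "+", self.GENOME) == "noncoding"

    def test_minus_strand(self):
        # gene on minus strand of c2: revcomp(CATTTTCAT) = ATG AAA ATG
        genome = GenomeReference({"c2": "CATTTTCATGGG"})
        # pos 5 (T) -> C: revcomp codon AAA -> AGA? check: plus CATTTTCAT,
        # edit pos5 T->C gives CATTCTCAT? no: pos 5 0-based 4 -> CATTCTCAT;
        # revcomp = ATGAGAATG: AAA->AGA (Lys->Arg), nonsynonymous
        site = VariantSite("c2", 5, "T", ("C",))
        assert coding_effect(site, [(0, 9)], "-", genome) == "nonsynonymous"

    def test_indel_rejected(self):
        site = VariantSite("c1", 3, "GC", ("G",))
        with pytest.raises(ValueError):
            coding_effect(site, self.CDS, "+", self.GENOME)

    def test_partial_codon_cds_rejected(self):
        site = VariantSite("c1", 3, "G", ("A",))
        with pytest.raises(ValueError):
            coding_effect(site, [(0, 8)], "+", self.GENOME)
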