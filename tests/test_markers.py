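"""Marker selection criteria, in-silico PCR, fingerprints, contamination."""

import numpy as np
import pytest

from conftest import make_callset, make_site

from indelfinger.comparison import classify_fixed
from indelfinger.markers import (
    MarkerCriteria,
    apply_variants_to_sequence,
    collapse_bands,
    detect_contamination,
    distinguishability,
    fingerprint,
    in_silico_pcr,
    longest_tandem_run,
    sample_haplotypes,
    select_candidates,
    shannon_entropy_dinucleotide,
    simulate_mixture,
)
from indelfinger.models import GenomeReference, PrimerPair, revcomp


def _rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


# ---------------------------------------------------------------------------
# sequence complexity helpers

class TestComplexity:
    def test_random_sequence_is_complex(self):
        rng = np.random.default_rng(5)
        seq = _rand_seq(rng, 120)
        assert shannon_entropy_dinucleotide(seq) > 1.5
        assert longest_tandem_run(seq) <= 10

    def test_microsatellite_is_low_complexity(self):
        assert shannon_entropy_dinucleotide("AT" * 50) < 1.0
        assert longest_tandem_run("AT" * 50) == 100

    def test_homopolymer_run(self):
        assert longest_tandem_run("ACGT" + "A" * 12 + "CGTA") == 12


# ---------------------------------------------------------------------------
# selection criteria on a planted fixture

def _planted_selection_fixture(seed=17):
    """Genome + Distinct-GT indel set where exactly 3 candidates pass all
    criteria; every other candidate fails a known criterion."""
    rng = np.random.default_rng(seed)
    genome = GenomeReference({
        "c1": _rand_seq(rng, 60_000) + "AT" * 60 + _rand_seq(rng, 20_000),
        "c2": _rand_seq(rng, 80_000),
    })
    rows = []
    expected_pass = []

    def add_del(contig, pos, length, a=(1, 1), b=(0, 0)):
        ref = genome.fetch(contig, pos - 1, pos + length)
        rows.append((make_site(contig=contig, pos=pos, ref=ref, alts=(ref[0],)),
                     {"A": a, "B": b}))

    def add_ins(contig, pos, seq, a=(1, 1), b=(0, 0)):
        ref = genome.fetch(contig, pos - 1, pos)
        rows.append((make_site(contig=contig, pos=pos, ref=ref, alts=(ref + seq,)),
                     {"A": a, "B": b}))

    # three valid markers, far apart
    add_del("c1", 5_000, 100)
    expected_pass.append("c1.5000")
    add_ins("c1", 40_000, _rand_seq(rng, 150))
    expected_pass.append("c1.40000")
    add_del("c2", 30_000, 120)
    expected_pass.append("c2.30000")
    # fails criterion 2: exactly 79 bp (strictly greater required)
    add_del("c2", 60_000, 79)
    # fails criterion 1: het in sample A
    add_del("c1", 20_000, 100, a=(0, 1))
    # fails criterion 3: inserted sequence copied from elsewhere in the genome
    add_ins("c1", 25_000, genome.fetch("c2", 10_000, 10_150))
    # fails criterion 4: microsatellite insertion (also present-in-genome safe: AT-run)
    add_ins("c2", 45_000, "AT" * 60)
    # fails criterion 5: two long indels 100 bp apart
    add_del("c1", 70_000, 90)
    add_del("c1", 70_190, 90)
    # short background indels (fail criterion 2 only)
    for pos in (12_000, 55_000):
        add_del("c1", pos, 4)
    cs = make_callset(["A", "B"], rows)
    return genome, cs, expected_pass


class TestSelection:
    def test_planted_fixture_exact_recovery(self):
        genome, cs, expected = _planted_selection_fixture()
        classes = classify_fixed(cs, "A", "B")
        out = select_candidates(cs, classes, "A", "B", genome, MarkerCriteria())
        passed = sorted(m.name for m in out if m.passed_all)
        assert passed == sorted(expected)

    def test_exclusion_reasons_recorded(self):
        genome, cs, _ = _planted_selection_fixture()
        classes = classify_fixed(cs, "A", "B")
        out = {m.name: m for m in select_candidates(cs, classes, "A", "B", genome)}
        assert not out["c2.60000"].criteria_flags[2]  # 79 bp, needs > 79
        assert not out["c1.25000"].criteria_flags[3]  # insertion found in genome
        assert not out["c2.45000"].criteria_flags[4]  # microsatellite
        assert not out["c1.70000"].criteria_flags[5]  # flanked by another indel
        assert "c1.20000" not in out  # het: not a Distinct-GT fixed indel

    def test_input_order_invariance(self):
        genome, cs, _ = _planted_selection_fixture()
        classes = classify_fixed(cs, "A", "B")
        ref = [m.name for m in select_candidates(cs, classes, "A", "B", genome)]
        idx = list(range(len(cs)))[::-1]
        shuffled = cs.subset([True] * len(cs))
        shuffled.sites = [cs.sites[i] for i in idx]
        shuffled.genotypes = [cs.genotypes[i] for i in idx]
        shuffled.sort()
        again = [m.name for m in select_candidates(
            shuffled, classify_fixed(shuffled, "A", "B"), "A", "B", genome)]
        assert again == ref

    def test_per_contig_cap(self):
        genome, cs, _ = _planted_selection_fixture()
        classes = classify_fixed(cs, "A", "B")
        out = select_candidates(cs, classes, "A", "B", genome,
                                MarkerCriteria(max_per_contig=1))
        passed = [m for m in out if m.passed_all]
        contigs = [m.contig for m in passed]
        assert len(contigs) == len(set(contigs))

    def test_scenario_recovers_planted_markers(self, scenario, classified):
        callset, classes = classified
        a, b = scenario.truth["focal_pair"]
        out = select_candidates(callset, classes, a, b, scenario.genome)
        passed = {m.name for m in out if m.passed_all}
        planted = {
            name for name, t in scenario.truth["markers"].items()
            if t["diagnostic_pair_distinct"]
        }
        assert planted <= passed


# ---------------------------------------------------------------------------
# in-silico PCR and haplotypes

def _template_with_primers(rng, insert_len=300):
    fwd = _rand_seq(rng, 21)
    rev = _rand_seq(rng, 20)
    middle = _rand_seq(rng, insert_len - len(fwd) - len(rev))
    template = _rand_seq(rng, 150) + fwd + middle + revcomp(rev) + _rand_seq(rng, 150)
    return template, PrimerPair("m", fwd, rev)


class TestPcr:
    def test_reference_and_deletion_products(self):
        rng = np.random.default_rng(3)
        template, pp = _template_with_primers(rng, insert_len=361)
        assert in_silico_pcr(template, pp) == [361]
        # delete 79 bp between the primers -> 282 bp product
        cut = 150 + 30
        deleted = template[:cut] + template[cut + 79:]
        assert in_silico_pcr(deleted, pp) == [282]

    def test_insertion_grows_product(self):
        rng = np.random.default_rng(4)
        template, pp = _template_with_primers(rng, insert_len=532)
        ins_at = 150 + 100
        grown = template[:ins_at] + _rand_seq(rng, 204) + template[ins_at:]
        assert in_silico_pcr(grown, pp) == [736]

    def test_absent_primers_no_product(self):
        rng = np.random.default_rng(5)
        _, pp = _template_with_primers(rng)
        assert in_silico_pcr(_rand_seq(rng, 2000), pp) == []

    def test_oversized_product_ignored(self):
        rng = np.random.default_rng(6)
        template, pp = _template_with_primers(rng, insert_len=2500)
        assert in_silico_pcr(template, pp, max_amplicon=2000) == []

    @pytest.mark.parametrize("length", [50, 117, 204, 300])
    def test_amplicon_difference_equals_indel_length(self, length):
        rng = np.random.default_rng(length)
        template, pp = _template_with_primers(rng, insert_len=500)
        cut = 150 + 60
        shorter = template[:cut] + template[cut + length:]
        (a,), (b,) = in_silico_pcr(template, pp), in_silico_pcr(shorter, pp)
        assert a - b == length


class TestHaplotypes:
    def test_snp_edit(self):
        assert apply_variants_to_sequence("AACCGG", [(3, "C", "T")]) == "AATCGG"

    def test_deletion_edit(self):
        assert apply_variants_to_sequence("AACCGG", [(3, "CCG", "C")]) == "AACG"

    def test_ref_mismatch_rejected(self):
        with pytest.raises(ValueError):
            apply_variants_to_sequence("AACCGG", [(3, "G", "T")])

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            apply_variants_to_sequence("AACCGGTT", [(2, "ACC", "A"), (4, "C", "T")])

    def test_length_change_is_signed_indel_sum(self):
        rng = np.random.default_rng(9)
        seq = _rand_seq(rng, 5000)
        edits, delta, pos = [], 0, 10
        while pos < 4500:
            if rng.random() < 0.5:
                n = int(rng.integers(1, 20))
                ref = seq[pos - 1: pos + n]
                edits.append((pos, ref, ref[0]))
                delta -= n
                pos += n + int(rng.integers(5, 50))
            else:
                ins = _rand_seq(rng, int(rng.integers(1, 20)))
                edits.append((pos, seq[pos - 1], seq[pos - 1] + ins))
                delta += len(ins)
                pos += int(rng.integers(5, 50))
        assert len(apply_variants_to_sequence(seq, edits)) == 5000 + delta

    def test_het_edits_one_haplotype(self):
        genome = GenomeReference({"c1": "AAACCCGGGTTT"})
        cs = make_callset(["s"], [(make_site(contig="c1", pos=4, ref="CCC", alts=("C",)),
                                   {"s": (0, 1)})])
        h0, h1 = sample_haplotypes(genome, cs, "s")["c1"]
        assert h0 == "AAACCCGGGTTT" and h1 == "AAACGGGTTT"


# ---------------------------------------------------------------------------
# fingerprints

class TestFingerprint:
    def test_scenario_matrix_matches_truth(self, scenario, filtered):
        callset, _ = filtered
        matrix = fingerprint(scenario.genome, callset, list(callset.samples),
                             scenario.primers)
        for name, t in scenario.truth["markers"].items():
            for sample, expected in t["expected_bands"].items():
                assert list(matrix.bands[sample][name]) == expected, (name, sample)

    def test_identical_samples_identical_rows(self, scenario, filtered):
        callset, _ = filtered
        matrix = fingerprint(scenario.genome, callset, ["lineA", "lineA"],
                             scenario.primers)
        assert matrix.row("lineA") == matrix.row("lineA")

    def test_heterozygous_marker_two_bands(self, scenario, filtered):
        callset, _ = filtered
        het_markers = [
            (name, s)
            for name, t in scenario.truth["markers"].items()
            for s, g in t["genotypes"].items() if g == "het"
        ]
        assert het_markers, "scenario should plant a heterozygous marker"
        matrix = fingerprint(scenario.genome, callset, list(callset.samples),
                             scenario.primers)
        for name, s in het_markers:
            assert len(matrix.bands[s][name]) == 2

    def test_band_collapse(self):
        assert collapse_bands([361, 363, 500], 5) == (361, 500)


def _matrix(rows, markers=None):
    from indelfinger.markers import FingerprintMatrix

    samples = [f"s{i}" for i in range(len(rows))]
    markers = markers or [f"m{j}" for j in range(len(rows[0]))]
    bands = {
        s: {m: (v if isinstance(v, tuple) else (v,)) for m, v in zip(markers, row)}
        for s, row in zip(samples, rows)
    }
    return FingerprintMatrix(samples, markers, bands)


class TestDistinguishability:
    def test_published_style_matrix_needs_all_three(self):
        m = _matrix([(282, 736, 263), (361, 384, 157), (361, 384, 263), (361, 736, 262)])
        rep = distinguishability(m, tolerance_bp=5)
        assert rep["all_distinct"]
        # 263 vs 262 and shared cells defeat every 1- and 2-marker subset
        assert rep["minimal_subsets"] == [["m0", "m1", "m2"]]

    def test_identical_rows_not_distinguishable(self):
        m = _matrix([(100, 200), (100, 200)])
        rep = distinguishability(m)
        assert not rep["all_distinct"] and rep["minimal_subsets"] == []

    def test_single_informative_marker_suffices(self):
        m = _matrix([(100, 500), (200, 500), (300, 500), (400, 500)])
        rep = distinguishability(m)
        assert ["m0"] in rep["minimal_subsets"]
        assert "m1" in rep["redundant_markers"]

    def test_monotone_in_markers(self):
        """Adding a marker never decreases the distinguished pair count."""
        from indelfinger.markers import _n_distinguished_pairs

        m = _matrix([(282, 736, 263), (361, 736, 157), (361, 736, 263), (361, 736, 262)])
        for k in range(1, 3):
            a = _n_distinguished_pairs(m, m.markers[:k], 5)
            b = _n_distinguished_pairs(m, m.markers[:k + 1], 5)
            assert b >= a


class TestContamination:
    EXPECTED = {"mA": (361,), "mB": (509,)}
    CONTAMINANT = {"mA": (276,), "mB": (509,)}

    def test_ten_percent_mixture_detected(self):
        mix = simulate_mixture(self.EXPECTED, self.CONTAMINANT, 0.10)
        v = detect_contamination("host", self.EXPECTED, band_fractions=mix,
                                 min_fraction=0.10)
        assert v.detected
        assert any(e["marker"] == "mA" for e in v.evidence)

    def test_pure_sample_clean(self):
        mix = simulate_mixture(self.EXPECTED, self.EXPECTED, 0.5)
        v = detect_contamination("host", self.EXPECTED, band_fractions=mix)
        assert not v.detected and v.evidence == []

    def test_below_threshold_not_detected(self):
        mix = simulate_mixture(self.EXPECTED, self.CONTAMINANT, 0.05)
        v = detect_contamination("host", self.EXPECTED, band_fractions=mix,
                                 min_fraction=0.10)
        assert not v.detected

    def test_band_mode(self):
        v = detect_contamination("host", self.EXPECTED,
                                 observed_bands={"mA": [361, 276], "mB": [509]})
        assert v.detected

    def test_uninformative_pair_reported(self):
        v = detect_contamination(
            "host", self.EXPECTED,
            observed_bands={"mA": [361], "mB": [509]},
            contaminant="twin", contaminant_expected=self.EXPECTED,
        )
        assert not v.informative and not v.detected
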