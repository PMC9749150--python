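"""Diagnostic indel markers: selection, in-silico PCR, fingerprints, contamination.

Candidate markers are indels fixed with a distinct genotype between two
cell lines.  Six criteria prioritize them for a PCR + agarose assay:

1. distinct fixed genotype between the two lines (re-checked on input);
2. indel length strictly greater than ``min_size`` (default 79 bp) so the
   allele difference resolves on a gel;
3. the distinguishing sequence maps uniquely — the deleted reference
   segment plus flanks occurs exactly once in the reference, an inserted
   sequence occurs zero times (exact search on both strands);
4. the distinguishing sequence is not low-complexity (dinucleotide
   entropy and maximum 1–2-mer tandem-run caps);
5. no other predicted indel within ``isolation_window`` bp;
6. markers are spatially spread — greedy max-min-distance selection with
   a per-contig cap.

Amplicons are predicted by exact primer matching on sample haplotypes
(the reference with the sample's fixed variants applied), giving each
line a band-size vector — its molecular fingerprint.  Fingerprints feed
distinguishability analysis (minimal marker subsets, redundant markers)
and cross-contamination detection from unexpected bands or minor-allele
fractions.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field

from .comparison import FixedClass
from .models import CallSet, GenomeReference, PrimerPair, VariantSite, revcomp

CRITERIA_NAMES = {
    1: "distinct_genotype",
    2: "size",
    3: "unique_mapping",
    4: "complexity",
    5: "isolation",
    6: "spacing",
}


@dataclass
class MarkerCriteria:
    """Thresholds for the six selection criteria."""

    min_size: int = 79  # criterion 2: indel length must be strictly greater
    flank_pad: int = 20  # criterion 3: flanking bases around a deletion segment
    entropy_min: float = 1.5  # criterion 4: dinucleotide entropy, bits/base
    max_repeat_run: int = 10  # criterion 4: longest 1-2-mer tandem run, bases
    isolation_window: int = 200  # criterion 5: bp to nearest other indel
    max_per_contig: int = 2  # criterion 6: per-contig cap in greedy selection
    max_markers: int | None = None  # optional overall cap


@dataclass
class IndelMarker:
    """A candidate diagnostic indel named ``<contig>.<1-based left pos>``."""

    contig: str
    pos: int
    ref_allele: str
    alt_allele: str
    genotypes: dict[str, str]  # sample -> "hom_ref" | "hom_alt" | "het" | "missing"
    criteria_flags: dict[int, bool] = field(default_factory=dict)

    @property
    def name(self) -> str:
        return f"{self.contig}.{self.pos}"

    @property
    def indel_length(self) -> int:
        return abs(len(self.alt_allele) - len(self.ref_allele))

    @property
    def is_deletion(self) -> bool:
        return len(self.alt_allele) < len(self.ref_allele)

    @property
    def passed_all(self) -> bool:
        return all(self.criteria_flags.get(i, False) for i in range(1, 7))

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "contig": self.contig,
            "pos": self.pos,
            "indel_length": self.indel_length,
            "type": "deletion" if self.is_deletion else "insertion",
            "genotypes": self.genotypes,
            "criteria": {CRITERIA_NAMES[i]: bool(v) for i, v in sorted(self.criteria_flags.items())},
            "passed_all": self.passed_all,
        }


def shannon_entropy_dinucleotide(seq: str) -> float:
    """Entropy of the overlapping-dinucleotide distribution, in bits per base.

    A random sequence approaches 2 bits/base; microsatellite-like repeats
    fall well below (an AT-repeat scores 0.5, a homopolymer 0).
    """
    if len(seq) < 2:
        return 0.0
    counts = Counter(seq[i:i + 2] for i in range(len(seq) - 1))
    n = sum(counts.values())
    h = -sum((c / n) * math.log2(c / n) for c in counts.values())
    return h / 2.0


def longest_tandem_run(seq: str) -> int:
    """Longest run, in bases, of a tandemly repeated 1- or 2-mer."""
    best = 0
    for unit in (1, 2):
        i = 0
        while i < len(seq):
            j = i + unit
            while j + unit <= len(seq) and seq[j:j + unit] == seq[i:i + unit]:
                j += unit
            run = j - i
            if run > unit:  # at least two copies
                best = max(best, run)
            i += 1
    return best


def count_occurrences_both_strands(genome: GenomeReference, query: str) -> int:
    """Exact occurrences of *query* in the reference, counting both strands."""
    total = 0
    rc = revcomp(query)
    for seq in genome.contigs.values():
        total += seq.count(query)
        if rc != query:
            total += seq.count(rc)
    return total


def distinguishing_sequence(marker: IndelMarker, genome: GenomeReference, flank_pad: int) -> str:
    """The sequence whose genomic uniqueness criterion 3 tests.

    For a deletion: the deleted reference segment with ``flank_pad``
    flanks (present once in the reference at the marker locus).  For an
    insertion: the inserted bases alone (absent from the reference).
    """
    if marker.is_deletion:
        # VCF convention: ref = anchor + deleted bases
        del_start0 = marker.pos  # first deleted base, 0-based
        del_end0 = marker.pos - 1 + len(marker.ref_allele)
        lo = max(0, del_start0 - flank_pad)
        hi = min(len(genome.contigs[marker.contig]), del_end0 + flank_pad)
        return genome.fetch(marker.contig, lo, hi)
    return marker.alt_allele[len(marker.ref_allele):] if marker.alt_allele.startswith(marker.ref_allele) else marker.alt_allele[1:]


def _genotype_label(gt) -> str:
    if gt.is_missing:
        return "missing"
    if gt.is_het:
        return "het"
    return "hom_alt" if gt.gt == (1, 1) else "hom_ref"


def select_candidates(callset: CallSet, classes: list[FixedClass],
                      sample_a: str, sample_b: str,
                      genome: GenomeReference,
                      criteria: MarkerCriteria | None = None) -> list[IndelMarker]:
    """Apply the six selection criteria to Distinct-GT fixed indels.

    Returns every candidate with its per-criterion flags; markers passing
    all six come first, in greedy spatial-selection order.  Deterministic
    and input-order invariant (candidates are sorted by contig, pos).
    """
    criteria = criteria or MarkerCriteria()
    all_indel_pos: dict[str, list[int]] = {}
    for site in callset.sites:
        if site.variant_class == "INDEL":
            all_indel_pos.setdefault(site.contig, []).append(site.pos)
    for v in all_indel_pos.values():
        v.sort()

    contig_order = {c: i for i, c in enumerate(genome.contigs)}
    rebuilt: list[IndelMarker] = []
    for i, (site, gts) in enumerate(callset):
        cls = classes[i]
        if site.variant_class != "INDEL" or cls not in (FixedClass.UNIQUE_A, FixedClass.UNIQUE_B):
            continue
        m = IndelMarker(
            contig=site.contig,
            pos=site.pos,
            ref_allele=site.ref_allele,
            alt_allele=site.alt_alleles[0],
            genotypes={s: _genotype_label(g) for s, g in gts.items()},
        )
        m.criteria_flags[1] = (
            m.genotypes.get(sample_a) in ("hom_ref", "hom_alt")
            and m.genotypes.get(sample_b) in ("hom_ref", "hom_alt")
            and m.genotypes[sample_a] != m.genotypes[sample_b]
        )
        m.criteria_flags[2] = m.indel_length > criteria.min_size
        dseq = distinguishing_sequence(m, genome, criteria.flank_pad)
        occ = count_occurrences_both_strands(genome, dseq)
        m.criteria_flags[3] = (occ == 1) if m.is_deletion else (occ == 0)
        m.criteria_flags[4] = (
            shannon_entropy_dinucleotide(dseq) >= criteria.entropy_min
            and longest_tandem_run(dseq) <= criteria.max_repeat_run
        )
        near = all_indel_pos.get(m.contig, [])
        m.criteria_flags[5] = not any(
            p != m.pos and abs(p - m.pos) <= criteria.isolation_window for p in near
        )
        rebuilt.append(m)
    rebuilt.sort(key=lambda m: (contig_order.get(m.contig, 10**9), m.pos))

    eligible = [m for m in rebuilt if all(m.criteria_flags[i] for i in range(1, 6))]
    selected = _greedy_spacing(eligible, criteria)
    sel_names = {m.name for m in selected}
    for m in rebuilt:
        m.criteria_flags[6] = m.name in sel_names
    rest = [m for m in rebuilt if m.name not in sel_names]
    return selected + rest


def _greedy_spacing(eligible: list[IndelMarker], criteria: MarkerCriteria) -> list[IndelMarker]:
    """Criterion 6: greedy max-min-distance pick with a per-contig cap.

    Different contigs count as infinitely far apart; within a contig the
    distance is |pos difference|.  Seeded with the first eligible marker
    in (contig, pos) order; ties favour earlier genomic order.
    """
    if not eligible:
        return []
    selected: list[IndelMarker] = [eligible[0]]
    remaining = eligible[1:]
    per_contig = Counter(m.contig for m in selected)

    def min_dist(m: IndelMarker) -> float:
        ds = [
            abs(m.pos - s.pos) if m.contig == s.contig else math.inf
            for s in selected
        ]
        return min(ds)

    while remaining:
        if criteria.max_markers is not None and len(selected) >= criteria.max_markers:
            break
        viable = [m for m in remaining if per_contig[m.contig] < criteria.max_per_contig]
        if not viable:
            break
        best = max(viable, key=lambda m: (min_dist(m), -m.pos))
        if min_dist(best) <= 0:
            break
        selected.append(best)
        per_contig[best.contig] += 1
        remaining = [m for m in remaining if m.name != best.name]
    selected.sort(key=lambda m: (m.contig, m.pos))
    return selected


# ---------------------------------------------------------------------------
# In-silico PCR

class AmbiguousPCRError(RuntimeError):
    pass


def _find_all(hay: str, needle: str) -> list[int]:
    out = []
    i = hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def in_silico_pcr(template: str, primers: PrimerPair,
                  max_amplicon: int = 3000, max_products: int = 10) -> list[int]:
    """Predicted amplicon lengths from exact primer matches on *template*.

    The forward primer must match the plus strand and the reverse
    complement of the reverse primer must occur downstream; the amplicon
    runs from the forward primer's 5' start to the reverse primer's 5'
    start inclusive.  Products longer than ``max_amplicon`` are ignored;
    more than ``max_products`` raises an ambiguity error.
    """
    fwd_hits = _find_all(template, primers.forward)
    rev_hits = _find_all(template, revcomp(primers.reverse))
    products = []
    for i in fwd_hits:
        for j in rev_hits:
            length = j + len(primers.reverse) - i
            if length >= len(primers.forward) + len(primers.reverse) and j >= i and length <= max_amplicon:
                products.append(length)
    if len(products) > max_products:
        raise AmbiguousPCRError(
            f"{primers.marker}: {len(products)} products (> {max_products})"
        )
    return sorted(products)


# ---------------------------------------------------------------------------
# Haplotype construction

def apply_variants_to_sequence(seq: str, edits: list[tuple[int, str, str]]) -> str:
    """Apply VCF-style edits (1-based pos, ref, alt) to one contig sequence.

    Edits must be sorted and non-overlapping; each is validated against
    the current reference text before splicing.
    """
    out = []
    cursor = 0  # 0-based position in seq
    last_end = -1
    for pos, ref, alt in edits:
        start0 = pos - 1
        if start0 < last_end:
            raise ValueError(f"overlapping variants at pos {pos}")
        if seq[start0:start0 + len(ref)] != ref:
            raise ValueError(
                f"ref mismatch at pos {pos}: expected {ref!r}, "
                f"found {seq[start0:start0 + len(ref)]!r}"
            )
        out.append(seq[cursor:start0])
        out.append(alt)
        cursor = start0 + len(ref)
        last_end = cursor
    out.append(seq[cursor:])
    return "".join(out)


def sample_haplotypes(genome: GenomeReference, callset: CallSet, sample: str,
                      contigs: list[str] | None = None) -> dict[str, tuple[str, str]]:
    """Two haplotype sequences per contig for one sample.

    Homozygous-alt variants edit both haplotypes; heterozygous variants
    edit the second haplotype only (an arbitrary but deterministic
    phasing — sufficient for fragment-size prediction, where phase across
    distant amplicons is irrelevant).  Missing and hom-ref calls leave
    the reference untouched.
    """
    wanted = contigs or list(genome.contigs)
    edits: dict[str, tuple[list, list]] = {c: ([], []) for c in wanted}
    for site, gts in callset:
        if site.contig not in edits:
            continue
        g = gts[sample]
        if g.is_missing or g.gt == (0, 0):
            continue
        alt = site.alt_alleles[g.gt[1] - 1] if g.gt[1] >= 1 else site.alt_alleles[0]
        edit = (site.pos, site.ref_allele, alt)
        if g.is_hom:
            edits[site.contig][0].append(edit)
            edits[site.contig][1].append(edit)
        else:
            edits[site.contig][1].append(edit)
    out: dict[str, tuple[str, str]] = {}
    for c in wanted:
        h0 = apply_variants_to_sequence(genome.contigs[c], sorted(edits[c][0]))
        h1 = apply_variants_to_sequence(genome.contigs[c], sorted(edits[c][1]))
        out[c] = (h0, h1)
    return out


# ---------------------------------------------------------------------------
# Fingerprints

def collapse_bands(sizes: list[int], tolerance: int) -> tuple[int, ...]:
    """Collapse band sizes within gel tolerance (keep the smallest of a group)."""
    out: list[int] = []
    for s in sorted(set(sizes)):
        if out and s - out[-1] <= tolerance:
            continue
        out.append(s)
    return tuple(out)


@dataclass
class FingerprintMatrix:
    samples: list[str]
    markers: list[str]
    bands: dict[str, dict[str, tuple[int, ...]]]  # sample -> marker -> sizes
    failures: list[tuple[str, str]] = field(default_factory=list)

    def row(self, sample: str) -> tuple[tuple[int, ...], ...]:
        return tuple(self.bands[sample].get(m, ()) for m in self.markers)

    def as_dict(self) -> dict:
        return {
            "samples": self.samples,
            "markers": self.markers,
            "bands": {
                s: {m: list(self.bands[s].get(m, ())) for m in self.markers}
                for s in self.samples
            },
            "non_amplifiable": [list(x) for x in self.failures],
        }

    def to_tsv(self, path) -> None:
        import pandas as pd

        rows = []
        for s in self.samples:
            row = {"sample": s}
            for m in self.markers:
                row[m] = ",".join(str(b) for b in self.bands[s].get(m, ())) or "NA"
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def fingerprint(genome: GenomeReference, callset: CallSet, samples: list[str],
                primer_pairs: list[PrimerPair], gel_tolerance: int = 5,
                max_amplicon: int = 3000) -> FingerprintMatrix:
    """Predict each sample's band-size set at every marker assay.

    Both haplotypes are amplified, so heterozygous indels yield two bands;
    bands within ``gel_tolerance`` collapse into one.  Assays with no
    product for a sample are recorded as failures, not fatal.
    """
    markers = [p.marker for p in primer_pairs]
    bands: dict[str, dict[str, tuple[int, ...]]] = {}
    failures: list[tuple[str, str]] = []
    for sample in samples:
        haps = sample_haplotypes(genome, callset, sample)
        bands[sample] = {}
        for pp in primer_pairs:
            sizes: list[int] = []
            for contig_haps in haps.values():
                for hap in contig_haps:
                    sizes.extend(in_silico_pcr(hap, pp, max_amplicon=max_amplicon))
            if sizes:
                bands[sample][pp.marker] = collapse_bands(sizes, gel_tolerance)
            else:
                failures.append((sample, pp.marker))
    return FingerprintMatrix(list(samples), markers, bands, failures)


# ---------------------------------------------------------------------------
# Distinguishability

def _cells_match(a: tuple[int, ...], b: tuple[int, ...], tol: int) -> bool:
    if len(a) != len(b):
        return False
    return all(abs(x - y) <= tol for x, y in zip(sorted(a), sorted(b)))


def _rows_distinct(matrix: FingerprintMatrix, marker_subset: list[str], tol: int) -> bool:
    rows = []
    for s in matrix.samples:
        rows.append(tuple(matrix.bands[s].get(m, ()) for m in marker_subset))
    for i, j in itertools.combinations(range(len(rows)), 2):
        if all(_cells_match(a, b, tol) for a, b in zip(rows[i], rows[j])):
            return False
    return True


def _n_distinguished_pairs(matrix: FingerprintMatrix, marker_subset: list[str], tol: int) -> int:
    n = 0
    for i, j in itertools.combinations(range(len(matrix.samples)), 2):
        si, sj = matrix.samples[i], matrix.samples[j]
        cells_i = [matrix.bands[si].get(m, ()) for m in marker_subset]
        cells_j = [matrix.bands[sj].get(m, ()) for m in marker_subset]
        if not all(_cells_match(a, b, tol) for a, b in zip(cells_i, cells_j)):
            n += 1
    return n


def distinguishability(matrix: FingerprintMatrix, tolerance_bp: int = 5) -> dict:
    """Fingerprint discrimination report.

    Reports whether all sample rows are pairwise distinct at the gel
    tolerance, every minimal marker subset achieving full discrimination,
    and markers that are redundant (dropping them keeps discrimination
    unchanged).
    """
    all_distinct = _rows_distinct(matrix, matrix.markers, tolerance_bp)
    minimal_subsets: list[list[str]] = []
    if all_distinct:
        for k in range(1, len(matrix.markers) + 1):
            for combo in itertools.combinations(matrix.markers, k):
                if _rows_distinct(matrix, list(combo), tolerance_bp):
                    minimal_subsets.append(list(combo))
            if minimal_subsets:
                break
    full = _n_distinguished_pairs(matrix, matrix.markers, tolerance_bp)
    redundant = []
    for m in matrix.markers:
        others = [x for x in matrix.markers if x != m]
        if _n_distinguished_pairs(matrix, others, tolerance_bp) == full:
            redundant.append(m)
    return {
        "all_distinct": all_distinct,
        "n_distinguished_pairs": full,
        "n_sample_pairs": len(matrix.samples) * (len(matrix.samples) - 1) // 2,
        "minimal_subsets": minimal_subsets,
        "redundant_markers": redundant,
    }


# ---------------------------------------------------------------------------
# Contamination

@dataclass
class ContaminationVerdict:
    tested_sample: str
    contaminant: str | None
    detected: bool
    evidence: list[dict] = field(default_factory=list)
    estimated_minor_fraction: float | None = None
    informative: bool = True

    def as_dict(self) -> dict:
        return {
            "tested_sample": self.tested_sample,
            "contaminant": self.contaminant,
            "detected": self.detected,
            "informative": self.informative,
            "evidence": self.evidence,
            "estimated_minor_fraction": self.estimated_minor_fraction,
        }


def simulate_mixture(expected: dict[str, tuple[int, ...]],
                     contaminant: dict[str, tuple[int, ...]],
                     fraction: float) -> dict[str, dict[int, float]]:
    """Per-marker band -> template-fraction map for a host/contaminant mix.

    Bands from the host carry fraction ``1 - f``, bands from the
    contaminant carry ``f``; shared bands accumulate both.  This is the
    idealised gel of a mixed-template PCR (no amplification bias).
    """
    out: dict[str, dict[int, float]] = {}
    for marker in set(expected) | set(contaminant):
        fracs: dict[int, float] = {}
        for b in expected.get(marker, ()):
            fracs[b] = fracs.get(b, 0.0) + (1.0 - fraction)
        for b in contaminant.get(marker, ()):
            fracs[b] = fracs.get(b, 0.0) + fraction
        out[marker] = fracs
    return out


def detect_contamination(tested_sample: str,
                         expected: dict[str, tuple[int, ...]],
                         observed_bands: dict[str, list[int]] | None = None,
                         band_fractions: dict[str, dict[int, float]] | None = None,
                         min_fraction: float = 0.10,
                         tolerance_bp: int = 5,
                         contaminant: str | None = None,
                         contaminant_expected: dict[str, tuple[int, ...]] | None = None) -> ContaminationVerdict:
    """Flag contamination from unexpected bands or minor-allele fractions.

    Band mode (``observed_bands``): any band not explained by the expected
    fingerprint at the gel tolerance is evidence.  Fraction mode
    (``band_fractions``): an unexpected band is evidence only when its
    template fraction reaches ``min_fraction`` (bands below the threshold
    are treated as invisible, mirroring the assay's detection limit).

    When the putative contaminant's fingerprint is supplied and no marker
    differs between the pair, the verdict is marked non-informative.
    """
    if (observed_bands is None) == (band_fractions is None):
        raise ValueError("provide exactly one of observed_bands / band_fractions")
    informative = True
    if contaminant_expected is not None:
        informative = any(
            not _cells_match(tuple(expected.get(m, ())), tuple(contaminant_expected.get(m, ())), tolerance_bp)
            for m in expected
        )
    evidence: list[dict] = []
    est: float | None = None
    if observed_bands is not None:
        for marker, obs in observed_bands.items():
            exp = expected.get(marker, ())
            unexpected = [
                b for b in obs if not any(abs(b - e) <= tolerance_bp for e in exp)
            ]
            if unexpected:
                evidence.append({"marker": marker, "unexpected_bands": unexpected})
    else:
        assert band_fractions is not None
        for marker, fracs in band_fractions.items():
            exp = expected.get(marker, ())
            for b, f in fracs.items():
                if f >= min_fraction and not any(abs(b - e) <= tolerance_bp for e in exp):
                    evidence.append({"marker": marker, "unexpected_bands": [b], "fraction": f})
                    est = f if est is None else max(est, f)
    return ContaminationVerdict(
        tested_sample=tested_sample,
        contaminant=contaminant,
        detected=bool(evidence) and informative,
        evidence=evidence,
        estimated_minor_fraction=est,
        informative=informative,
    )
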