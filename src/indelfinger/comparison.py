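"""Two-sample comparison of fixed variants and their genomic distribution.

"Fixed" means homozygous within a cell line: at a biallelic site each of
the two focal samples is either homozygous reference or homozygous
alternate.  Sites are classified as

* ``SHARED_ALT`` — both lines hom-alt ("Same GT": same in both lines but
  different from the reference assembly),
* ``UNIQUE_A`` / ``UNIQUE_B`` — hom-alt in one line, hom-ref in the other
  (together the "Distinct GT" set that distinguishes the lines),
* ``NOT_FIXED`` — any heterozygous call,
* ``REF_BOTH`` — both hom-ref (excluded from variant totals).

Downstream summaries: Venn totals and percentages, a chi-square test of
variant placement against chromosome-arm lengths, a sliding-window scan
(default 10 kb windows, 2.5 kb step), merged cluster calls from enriched
windows, per-feature counts and synonymous/nonsynonymous classification
of coding SNPs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from Bio.Seq import Seq
from scipy import stats

from .models import CallSet, FeatureSet, GenomeReference, INTERGENIC, VariantSite


class FixedClass(str, Enum):
    SHARED_ALT = "SHARED_ALT"
    UNIQUE_A = "UNIQUE_A"
    UNIQUE_B = "UNIQUE_B"
    NOT_FIXED = "NOT_FIXED"
    REF_BOTH = "REF_BOTH"


#: The two classes making up the "Distinct GT" set.
DISTINCT_CLASSES = (FixedClass.UNIQUE_A, FixedClass.UNIQUE_B)


def classify_fixed(callset: CallSet, sample_a: str, sample_b: str) -> list[FixedClass]:
    """Classify every (biallelic) site by the two samples' fixed genotypes."""
    out: list[FixedClass] = []
    for site, gts in callset:
        if not site.is_biallelic:
            raise ValueError(
                f"classify_fixed requires biallelic sites; {site.contig}:{site.pos} "
                f"has {len(site.alt_alleles)} alt alleles"
            )
        ga, gb = gts[sample_a], gts[sample_b]
        if ga.is_missing or gb.is_missing or ga.is_het or gb.is_het:
            out.append(FixedClass.NOT_FIXED)
            continue
        a_alt = ga.is_hom_for(1)
        b_alt = gb.is_hom_for(1)
        if a_alt and b_alt:
            out.append(FixedClass.SHARED_ALT)
        elif a_alt:
            out.append(FixedClass.UNIQUE_A)
        elif b_alt:
            out.append(FixedClass.UNIQUE_B)
        else:
            out.append(FixedClass.REF_BOTH)
    return out


def percent(count: float, total: float) -> int:
    """Integer percentage, rounding half away from zero.

    Used for every printed percentage in the reports (e.g. 314 diploid
    cells out of 331 -> 95).
    """
    if total == 0:
        raise ZeroDivisionError("percent() with zero total")
    x = 100.0 * count / total
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def venn_summary(callset: CallSet, classes: list[FixedClass]) -> dict:
    """Venn-structure totals per variant class (SNP / INDEL).

    Percentages are of the variant total SHARED_ALT + UNIQUE_A + UNIQUE_B;
    REF_BOTH and NOT_FIXED sites are tallied but excluded from that total.
    """
    out: dict = {}
    for vc in ("SNP", "INDEL"):
        counts = {c.value: 0 for c in FixedClass}
        for site, cls in zip(callset.sites, classes):
            if site.variant_class == vc:
                counts[cls.value] += 1
        total = (
            counts["SHARED_ALT"] + counts["UNIQUE_A"] + counts["UNIQUE_B"]
        )
        entry: dict = {"counts": counts, "fixed_total": total}
        if total > 0:
            entry["percent"] = {
                "SHARED_ALT": percent(counts["SHARED_ALT"], total),
                "UNIQUE_A": percent(counts["UNIQUE_A"], total),
                "UNIQUE_B": percent(counts["UNIQUE_B"], total),
            }
        else:
            entry["percent"] = {}
        out[vc] = entry
    return out


def arm_counts(callset: CallSet, classes: list[FixedClass],
               which: tuple[FixedClass, ...], variant_class: str | None = None) -> dict[str, int]:
    """Observed variant counts per contig for the given class set."""
    counts: dict[str, int] = {}
    for site, cls in zip(callset.sites, classes):
        if cls not in which:
            continue
        if variant_class and site.variant_class != variant_class:
            continue
        counts[site.contig] = counts.get(site.contig, 0) + 1
    return counts


def arm_distribution_test(observed: dict[str, int], arm_lengths: dict[str, int]) -> dict:
    """Pearson chi-square of observed arm counts against arm-length proportions.

    Expected counts are total x (arm length / genome length) — i.e. the
    null model that variants land uniformly across the chromosome arms.
    """
    arms = list(arm_lengths)
    if len(arms) < 2:
        raise ValueError("need at least 2 arms")
    genome_len = sum(arm_lengths.values())
    total = sum(observed.get(a, 0) for a in arms)
    expected = np.array([total * arm_lengths[a] / genome_len for a in arms], dtype=float)
    if np.any(expected == 0):
        raise ValueError("expected count of zero on an arm")
    obs = np.array([observed.get(a, 0) for a in arms], dtype=float)
    chi2, p = stats.chisquare(obs, f_exp=expected)
    return {
        "arms": arms,
        "observed": obs.tolist(),
        "expected": expected.tolist(),
        "chi2": float(chi2),
        "df": len(arms) - 1,
        "p": float(p),
    }


@dataclass
class WindowCounts:
    contig: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    truncated: bool = False
    by_class: dict[str, int] = field(default_factory=dict)
    by_variant_class: dict[str, int] = field(default_factory=dict)

    @property
    def distinct_count(self) -> int:
        return self.by_class.get("UNIQUE_A", 0) + self.by_class.get("UNIQUE_B", 0)


def window_spans(contig_length: int, window_size: int, step: int) -> list[tuple[int, int, bool]]:
    """Deterministic (start, end, truncated) spans, 1-based closed.

    Full windows are emitted while ``start <= L - window + 1``; if the last
    full window does not reach the contig end one truncated window covers
    the tail.  Contigs shorter than one window yield a single truncated
    window.
    """
    if step > window_size:
        raise ValueError("step must not exceed window size")
    spans: list[tuple[int, int, bool]] = []
    start = 1
    last_end = 0
    while start <= contig_length - window_size + 1:
        spans.append((start, start + window_size - 1, False))
        last_end = start + window_size - 1
        start += step
    if last_end < contig_length:
        spans.append((start, contig_length, True))
    return spans


def sliding_windows(callset: CallSet, classes: list[FixedClass],
                    contig_lengths: dict[str, int],
                    window_size: int = 10_000, step: int = 2_500) -> list[WindowCounts]:
    """Count variants per class in overlapping windows along each contig.

    With step < window a variant is counted in every window covering it
    (up to window/step windows for interior positions).
    """
    # gather positions per contig, per class, per variant class
    per_contig: dict[str, list[tuple[int, FixedClass, str]]] = {c: [] for c in contig_lengths}
    for site, cls in zip(callset.sites, classes):
        if site.contig in per_contig:
            per_contig[site.contig].append((site.pos, cls, site.variant_class))
    out: list[WindowCounts] = []
    for contig, length in contig_lengths.items():
        entries = sorted(per_contig[contig])
        positions = np.array([e[0] for e in entries], dtype=np.int64)
        for start, end, truncated in window_spans(length, window_size, step):
            lo = int(np.searchsorted(positions, start, side="left"))
            hi = int(np.searchsorted(positions, end, side="right"))
            wc = WindowCounts(contig, start, end, truncated)
            for pos, cls, vc in entries[lo:hi]:
                wc.by_class[cls.value] = wc.by_class.get(cls.value, 0) + 1
                wc.by_variant_class[vc] = wc.by_variant_class.get(vc, 0) + 1
            out.append(wc)
    return out


@dataclass
class ClusterCall:
    contig: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    dominant_class: str
    n_unique_a: int
    n_unique_b: int

    @property
    def variant_count(self) -> int:
        return self.n_unique_a + self.n_unique_b


def call_clusters(windows: list[WindowCounts], callset: CallSet, classes: list[FixedClass],
                  min_density: float | None = None,
                  merge_gap: int | None = None,
                  min_cluster_variants: int = 20,
                  step: int = 2_500) -> list[ClusterCall]:
    """Merge runs of Distinct-GT-enriched windows into cluster calls.

    ``min_density`` defaults to median + 3 x 1.4826 MAD of the Distinct-GT
    window counts (a robust analogue of mean + 3 SD: with inversion-sized
    enriched regions covering a non-trivial fraction of the genome, the
    plain SD is inflated by the very signal being sought and the mean+3SD
    cut then sits above the enriched level itself).  ``merge_gap``
    defaults to twice the step.  The dominant class is the majority of
    UNIQUE_A vs UNIQUE_B sites within the merged span (ties go to
    UNIQUE_A), and clusters with fewer than ``min_cluster_variants``
    Distinct-GT variants are dropped.
    """
    counts = np.array([w.distinct_count for w in windows], dtype=float)
    if min_density is None:
        if len(counts):
            med = float(np.median(counts))
            mad = float(np.median(np.abs(counts - med)))
            min_density = max(med + 3.0 * 1.4826 * mad, med + 3.0)
        else:
            min_density = 0.0
    if merge_gap is None:
        merge_gap = 2 * step
    enriched = [w for w in windows if w.distinct_count >= min_density and w.distinct_count > 0]
    # merge per contig
    spans: list[tuple[str, int, int]] = []
    for w in sorted(enriched, key=lambda w: (w.contig, w.start)):
        if spans and spans[-1][0] == w.contig and w.start - spans[-1][2] - 1 <= merge_gap:
            spans[-1] = (w.contig, spans[-1][1], max(spans[-1][2], w.end))
        else:
            spans.append((w.contig, w.start, w.end))
    # tally distinct variants inside each merged span
    out: list[ClusterCall] = []
    for contig, start, end in spans:
        na = nb = 0
        for site, cls in zip(callset.sites, classes):
            if site.contig == contig and start <= site.pos <= end:
                if cls is FixedClass.UNIQUE_A:
                    na += 1
                elif cls is FixedClass.UNIQUE_B:
                    nb += 1
        if na + nb < min_cluster_variants:
            continue
        dominant = FixedClass.UNIQUE_A.value if na >= nb else FixedClass.UNIQUE_B.value
        out.append(ClusterCall(contig, start, end, dominant, na, nb))
    return out


def count_in_features(callset: CallSet, classes: list[FixedClass],
                      features: FeatureSet,
                      which: tuple[FixedClass, ...] = DISTINCT_CLASSES) -> dict:
    """Count selected variants per feature and per category.

    Variants map by their 1-based position (indels by the left-most
    reference base); feature intervals are 0-based half-open, so a variant
    at pos p lands in intervals containing p-1.  Variants outside every
    interval count as intergenic.
    """
    per_feature: dict[str, dict[str, int]] = {}
    per_category: dict[str, int] = {}
    for site, cls in zip(callset.sites, classes):
        if cls not in which:
            continue
        pos0 = site.pos - 1
        hits = [iv for iv in features if iv.contig == site.contig and iv.contains(pos0)]
        if not hits:
            per_category[INTERGENIC] = per_category.get(INTERGENIC, 0) + 1
            continue
        for iv in hits:
            f = per_feature.setdefault(iv.name, {})
            f[site.variant_class] = f.get(site.variant_class, 0) + 1
            per_category[iv.category] = per_category.get(iv.category, 0) + 1
    return {"per_feature": per_feature, "per_category": per_category}


def coding_effect(site: VariantSite, cds_intervals: list[tuple[int, int]],
                  strand: str, genome: GenomeReference) -> str:
    """Classify a biallelic SNP as synonymous / nonsynonymous / noncoding.

    ``cds_intervals`` are 0-based half-open genomic intervals in genomic
    order; their concatenation (reverse-complemented for '-') must be a
    whole number of codons.
    """
    if not site.is_snp:
        raise ValueError("coding_effect is defined for SNPs only")
    if not site.is_biallelic:
        raise ValueError("coding_effect requires a biallelic site")
    cds_len = sum(e - s for s, e in cds_intervals)
    if cds_len % 3 != 0:
        raise ValueError(f"CDS length {cds_len} not divisible by 3")
    pos0 = site.pos - 1
    offset = 0
    in_cds = None
    for s, e in cds_intervals:
        if s <= pos0 < e:
            in_cds = offset + (pos0 - s)
            break
        offset += e - s
    if in_cds is None:
        return "noncoding"
    cds_seq = "".join(genome.fetch(site.contig, s, e) for s, e in cds_intervals)
    alt_seq = cds_seq[:in_cds] + site.alt_alleles[0] + cds_seq[in_cds + 1:]
    if strand == "-":
        from .models import revcomp

        cds_seq, alt_seq = revcomp(cds_seq), revcomp(alt_seq)
    aa_ref = str(Seq(cds_seq).translate())
    aa_alt = str(Seq(alt_seq).translate())
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"
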