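"""Inversion karyotyping and species-ancestry typing from diagnostic SNP panels.

A diagnostic panel lists SNPs whose two alleles tag alternative states —
an inverted vs. standard chromosomal arrangement (e.g. 2Rb vs 2R+b), or
two sibling species (*An. gambiae* vs *An. coluzzii*).  Typing walks the
panel positions in a call set, counts diploid alleles concordant with
each state, and calls the karyotype from the allele majority.  Ancestry
scoring averages 1 / 0.5 / 0 per SNP for hom-first-state / het /
hom-second-state genotypes.  Gel-band interpretation maps observed PCR
product sizes onto genotype labels within a size tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .models import CallSet, DiagnosticPanel


@dataclass
class KaryotypeCall:
    inversion: str
    n_state1: int
    n_state2: int
    n_typed: int
    coverage: float
    call: str  # homozygous_state1 | homozygous_state2 | heterozygous | undetermined
    state1_label: str = ""
    state2_label: str = ""

    def as_dict(self) -> dict:
        return {
            "inversion": self.inversion,
            "state1_label": self.state1_label,
            "state2_label": self.state2_label,
            "n_state1": self.n_state1,
            "n_state2": self.n_state2,
            "n_typed_snps": self.n_typed,
            "coverage": round(self.coverage, 4),
            "call": self.call,
        }


def _typed_alleles(callset: CallSet, sample: str, panel: DiagnosticPanel):
    """Yield (n1, n2) allele-concordance counts for each typed panel SNP.

    A panel SNP is typed when its position is present in the call set and
    the sample's genotype is non-missing.  Each diploid genotype
    contributes two allele observations; alleles matching neither state
    allele contribute nothing.
    """
    index = callset.site_index()
    for snp in panel.snps:
        i = index.get((snp.contig, snp.pos))
        if i is None:
            continue
        site = callset.sites[i]
        g = callset.genotypes[i][sample]
        if g.is_missing:
            continue
        alleles = site.alleles
        n1 = n2 = 0
        for ai in g.gt:  # type: ignore[union-attr]
            if ai >= len(alleles):
                continue
            base = alleles[ai]
            if base == snp.state1_allele:
                n1 += 1
            elif base == snp.state2_allele:
                n2 += 1
        yield n1, n2


def karyotype(callset: CallSet, sample: str, panel: DiagnosticPanel,
              min_coverage_fraction: float = 0.25,
              majority_fraction: float = 0.9,
              het_min_fraction: float = 0.25) -> KaryotypeCall:
    """Call an inversion karyotype from diagnostic-SNP allele counts.

    The call is ``homozygous_stateX`` when state X holds at least
    ``majority_fraction`` of counted alleles, ``heterozygous`` when both
    states hold at least ``het_min_fraction``, and ``undetermined`` when
    panel coverage (typed SNPs / total published panel size) falls below
    ``min_coverage_fraction`` or no rule fires.
    """
    n1 = n2 = typed = 0
    for a, b in _typed_alleles(callset, sample, panel):
        if a + b > 0:
            typed += 1
        n1 += a
        n2 += b
    coverage = typed / panel.total_panel_size  # type: ignore[operator]
    if coverage < min_coverage_fraction or n1 + n2 == 0:
        call = "undetermined"
    else:
        f1 = n1 / (n1 + n2)
        f2 = 1.0 - f1
        if f1 >= majority_fraction:
            call = "homozygous_state1"
        elif f2 >= majority_fraction:
            call = "homozygous_state2"
        elif min(f1, f2) >= het_min_fraction:
            call = "heterozygous"
        else:
            call = "undetermined"
    return KaryotypeCall(
        inversion=panel.panel_id,
        n_state1=n1,
        n_state2=n2,
        n_typed=typed,
        coverage=coverage,
        call=call,
        state1_label=panel.state1_label,
        state2_label=panel.state2_label,
    )


@dataclass
class AncestryScore:
    sample: str
    panel_id: str
    n_state1_hom: int
    n_het: int
    n_state2_hom: int
    mean_score: float
    label: str
    state1_label: str = ""
    state2_label: str = ""

    @property
    def n_typed(self) -> int:
        return self.n_state1_hom + self.n_het + self.n_state2_hom

    def as_dict(self) -> dict:
        return {
            "sample": self.sample,
            "panel": self.panel_id,
            "n_state1_hom": self.n_state1_hom,
            "n_het": self.n_het,
            "n_state2_hom": self.n_state2_hom,
            "n_typed": self.n_typed,
            "mean_score": self.mean_score,
            "label": self.label,
        }


#: default label bins: >= 0.8 first species, <= 0.2 second species, else hybrid
DEFAULT_ANCESTRY_BINS = (0.8, 0.2)


def ancestry_label(mean_score: float, state1_label: str, state2_label: str,
                   bins: tuple[float, float] = DEFAULT_ANCESTRY_BINS) -> str:
    hi, lo = bins
    if mean_score >= hi:
        return state1_label
    if mean_score <= lo:
        return state2_label
    return f"{state1_label}/{state2_label} hybrid"


def ancestry_score(callset: CallSet, sample: str, panel: DiagnosticPanel,
                   bins: tuple[float, float] = DEFAULT_ANCESTRY_BINS) -> AncestryScore:
    """Mean ancestry score over typed panel SNPs (1 / 0.5 / 0 scoring).

    A SNP scores 1 when the sample is homozygous for the first-state
    allele, 0.5 when heterozygous for the two state alleles, and 0 when
    homozygous for the second-state allele.  Untyped SNPs (absent sites,
    missing genotypes, or alleles matching neither state) are excluded
    from the mean.
    """
    n1h = nh = n2h = 0
    for a, b in _typed_alleles(callset, sample, panel):
        if a == 2 and b == 0:
            n1h += 1
        elif a == 1 and b == 1:
            nh += 1
        elif a == 0 and b == 2:
            n2h += 1
    n_typed = n1h + nh + n2h
    if n_typed == 0:
        raise ValueError(f"no panel SNPs typed for sample {sample!r}")
    mean = (n1h * 1.0 + nh * 0.5) / n_typed
    return AncestryScore(
        sample=sample,
        panel_id=panel.panel_id,
        n_state1_hom=n1h,
        n_het=nh,
        n_state2_hom=n2h,
        mean_score=mean,
        label=ancestry_label(mean, panel.state1_label, panel.state2_label, bins),
        state1_label=panel.state1_label,
        state2_label=panel.state2_label,
    )


def ancestry_score_from_composition(n_state1_hom: int, n_het: int, n_state2_hom: int) -> float:
    """Mean score from a (hom1, het, hom2) composition — the same arithmetic
    ancestry_score applies to typed genotypes."""
    n = n_state1_hom + n_het + n_state2_hom
    if n == 0:
        raise ValueError("empty composition")
    return (n_state1_hom + 0.5 * n_het) / n


@dataclass
class BandAssay:
    """A gel diagnostic: genotype label -> expected band size(s) in bp.

    Distinct genotypes must remain distinguishable at the stated size
    tolerance (the default 20 bp reflects agarose resolution — products a
    single base apart are not resolvable on a gel).
    """

    name: str
    bands: dict[str, tuple[int, ...]]
    tolerance: int = 20

    def __post_init__(self) -> None:
        norm: dict[str, tuple[int, ...]] = {}
        for label, sizes in self.bands.items():
            sizes = tuple(sizes) if isinstance(sizes, (tuple, list)) else (sizes,)
            if any(s <= 0 for s in sizes):
                raise ValueError(f"assay {self.name!r}: non-positive band size")
            norm[label] = sizes
        self.bands = norm
        labels = list(norm)
        for i, la in enumerate(labels):
            for lb in labels[i + 1:]:
                if self._sets_match(norm[la], norm[lb]):
                    raise ValueError(
                        f"assay {self.name!r}: genotypes {la!r} and {lb!r} are "
                        f"indistinguishable at tolerance {self.tolerance} bp"
                    )

    def _sets_match(self, a: tuple[int, ...], b: tuple[int, ...]) -> bool:
        if len(a) != len(b):
            return False
        return all(abs(x - y) <= self.tolerance for x, y in zip(sorted(a), sorted(b)))


def interpret_bands(assay: BandAssay, observed: list[int] | tuple[int, ...]) -> str:
    """Map observed gel band sizes onto a genotype label.

    One label's band set fully observed -> that homozygous label; the
    band sets of two labels both present -> "label1/label2" (a
    heterozygote or template mixture); anything else -> "unknown".
    """
    if not observed:
        raise ValueError("no observed bands")
    matched = []
    for label, sizes in assay.bands.items():
        if all(any(abs(o - s) <= assay.tolerance for o in observed) for s in sizes):
            matched.append(label)
    if len(matched) == 1:
        # every observed band must be accounted for by the single label
        sizes = assay.bands[matched[0]]
        if all(any(abs(o - s) <= assay.tolerance for s in sizes) for o in observed):
            return matched[0]
        return "unknown"
    if len(matched) >= 2:
        return "/".join(matched[:2])
    return "unknown"
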