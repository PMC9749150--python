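"""Shared variant data model.

The pipeline operates downstream of variant calling: its inputs are a
multi-sample VCF, a reference genome and small TSV panels.  These classes
are the in-memory forms of those inputs.  Coordinate conventions follow
the source formats — VCF positions are 1-based, interval features are
stored 0-based half-open — and every conversion happens at the I/O layer,
never inside an analysis routine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

_VALID_BASES = frozenset("ACGTN")

#: Sentinel category for variants falling outside every annotated feature.
INTERGENIC = "intergenic"

FEATURE_CATEGORIES = (
    "exon",
    "intron",
    "five_prime_utr",
    "three_prime_utr",
    "enhancer",
    "other",
)


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class GenomeReference:
    """An ordered collection of named contig sequences (uppercase A/C/G/T/N)."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise FormatError(f"contig {name!r} has an empty sequence")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise FormatError(
                    f"contig {name!r} contains invalid characters: {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Return the 0-based half-open slice ``[start, end)`` of *contig*."""
        return self.contigs[contig][start:end]

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs


@dataclass
class VariantSite:
    """One VCF record: position, alleles and site-level annotations.

    ``pos`` is the 1-based position of the first reference base, as in the
    VCF.  ``annotations`` holds the hard-filter annotations (FS, SOR, MQ,
    MQRankSum, ReadPosRankSum, ...); absent keys mean the caller did not
    emit that annotation, which the filters must tolerate.
    """

    contig: str
    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    qual: float = 0.0
    annotations: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref_allele:
            raise ValueError("ref allele must be non-empty")
        if not self.alt_alleles:
            raise ValueError("at least one alt allele required")
        self.alt_alleles = tuple(self.alt_alleles)

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref_allele,) + self.alt_alleles

    @property
    def is_snp(self) -> bool:
        """True iff every allele is a single base."""
        return all(len(a) == 1 for a in self.alleles)

    @property
    def variant_class(self) -> str:
        return "SNP" if self.is_snp else "INDEL"

    @property
    def is_biallelic(self) -> bool:
        return len(self.alt_alleles) == 1

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref_allele, ",".join(self.alt_alleles))


#: Genotype value for calls containing "." (any missing allele).
MISSING = None


@dataclass
class SampleGenotype:
    """Per-sample diploid call with depth and quality.

    ``gt`` is an unordered pair of allele indices (stored sorted), or
    ``None`` for a missing call.  ``ad`` lists per-allele read depths in
    allele order.
    """

    sample_id: str
    gt: tuple[int, int] | None
    dp: int | None = None
    gq: int | None = None
    ad: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.gt is not None:
            self.gt = tuple(sorted(self.gt))  # type: ignore[assignment]

    @property
    def is_missing(self) -> bool:
        return self.gt is None

    @property
    def is_het(self) -> bool:
        return self.gt is not None and self.gt[0] != self.gt[1]

    @property
    def is_hom(self) -> bool:
        return self.gt is not None and self.gt[0] == self.gt[1]

    def is_hom_for(self, allele_index: int) -> bool:
        return self.gt == (allele_index, allele_index)


@dataclass
class CallSet:
    """Sites plus per-site, per-sample genotypes with a fixed sample order.

    Invariant: every site carries a genotype entry (possibly missing) for
    every sample, and sites are sorted by (contig, pos) with contig order
    taken from first appearance.
    """

    samples: tuple[str, ...]
    sites: list[VariantSite]
    genotypes: list[dict[str, SampleGenotype]]

    def __post_init__(self) -> None:
        self.samples = tuple(self.samples)
        if len(self.sites) != len(self.genotypes):
            raise ValueError("sites and genotypes length mismatch")
        for gts in self.genotypes:
            for s in self.samples:
                if s not in gts:
                    raise ValueError(f"missing genotype entry for sample {s!r}")

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[tuple[VariantSite, dict[str, SampleGenotype]]]:
        return iter(zip(self.sites, self.genotypes))

    def subset(self, keep: Sequence[bool]) -> "CallSet":
        """New CallSet containing sites where *keep* is true (order kept)."""
        if len(keep) != len(self.sites):
            raise ValueError("mask length mismatch")
        sites = [s for s, k in zip(self.sites, keep) if k]
        gts = [g for g, k in zip(self.genotypes, keep) if k]
        return CallSet(self.samples, sites, gts)

    def sort(self) -> None:
        """Sort sites by (contig-first-appearance, pos) in place."""
        order = {c: i for i, c in enumerate(dict.fromkeys(s.contig for s in self.sites))}
        idx = sorted(range(len(self.sites)), key=lambda i: (order[self.sites[i].contig], self.sites[i].pos))
        self.sites = [self.sites[i] for i in idx]
        self.genotypes = [self.genotypes[i] for i in idx]

    def site_index(self) -> dict[tuple[str, int], int]:
        """Lookup (contig, pos) -> site list index (first site wins on dup)."""
        out: dict[tuple[str, int], int] = {}
        for i, s in enumerate(self.sites):
            out.setdefault((s.contig, s.pos), i)
        return out


@dataclass
class FeatureInterval:
    contig: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    name: str
    category: str = "other"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"interval {self.name!r}: start {self.start} >= end {self.end}"
            )

    def contains(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end


@dataclass
class FeatureSet:
    """Genomic intervals (exon/intron/UTR/enhancer/...), 0-based half-open."""

    intervals: list[FeatureInterval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[FeatureInterval]:
        return iter(self.intervals)

    def validate_against(self, genome: GenomeReference) -> None:
        lengths = genome.lengths
        for iv in self.intervals:
            if iv.contig not in lengths:
                raise FormatError(f"interval contig {iv.contig!r} not in reference")
            if iv.end > lengths[iv.contig]:
                raise FormatError(
                    f"interval {iv.name!r} extends past end of {iv.contig}"
                )


@dataclass
class PanelSNP:
    """One diagnostic SNP: two labeled alleles at a fixed position."""

    contig: str
    pos: int  # 1-based
    state1_allele: str
    state2_allele: str

    def __post_init__(self) -> None:
        for a in (self.state1_allele, self.state2_allele):
            if len(a) != 1 or a not in "ACGT":
                raise FormatError(f"panel allele must be a single base, got {a!r}")
        if self.state1_allele == self.state2_allele:
            raise FormatError(
                f"panel SNP {self.contig}:{self.pos} has identical state alleles"
            )


@dataclass
class DiagnosticPanel:
    """A curated SNP panel diagnostic for an inversion arrangement or species.

    ``total_panel_size`` is the size of the full published panel; the SNPs
    actually present may be fewer, and the ratio is the typing coverage.
    """

    panel_id: str
    snps: list[PanelSNP]
    state1_label: str
    state2_label: str
    total_panel_size: int | None = None

    def __post_init__(self) -> None:
        if not self.snps:
            raise FormatError(f"panel {self.panel_id!r} is empty")
        seen: set[tuple[str, int]] = set()
        for snp in self.snps:
            k = (snp.contig, snp.pos)
            if k in seen:
                raise FormatError(
                    f"panel {self.panel_id!r}: duplicate position {k[0]}:{k[1]}"
                )
            seen.add(k)
        if self.total_panel_size is None:
            self.total_panel_size = len(self.snps)
        if self.total_panel_size < len(self.snps):
            raise FormatError("total_panel_size smaller than observed panel")

    def __len__(self) -> int:
        return len(self.snps)


@dataclass
class PrimerPair:
    """Forward/reverse primer sequences for one marker assay."""

    marker: str
    forward: str
    reverse: str
    annealing_tag: str = ""

    def __post_init__(self) -> None:
        for p in (self.forward, self.reverse):
            if len(p) < 15:
                raise FormatError(
                    f"primer for {self.marker!r} shorter than 15 nt: {p!r}"
                )
            bad = set(p.upper()) - set("ACGT")
            if bad:
                raise FormatError(f"primer for {self.marker!r} has non-ACGT: {bad}")
        self.forward = self.forward.upper()
        self.reverse = self.reverse.upper()


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_RC_TABLE)[::-1]


_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")
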