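"""Synthetic diploid cell-line scenario generator.

Builds a small multi-line genome with the statistical structure the
analysis assumes, so every pipeline stage is testable without any
sequencing data: a random reference of a few chromosome "arms", a
multi-sample VCF with

* shared homozygous divergence from the reference in all lines,
* inversion-mimicking blocks of line-specific fixed variants,
* a sparse background of line-specific variants,
* planted site- and genotype-level filter failures at configurable rates
  (each labelled in the ground truth, so filter reports can be checked
  rule by rule),
* diagnostic SNP panels (an inversion panel inside a planted block and a
  20-SNP species panel with per-line score compositions), and
* diagnostic indel markers spanned by primer pairs with a fixed
  reference amplicon size.

Everything derives from one numpy Generator, so a seeded run is
byte-reproducible.  Noise (stray heterozygotes, missing calls) is kept
off the designed assay loci; it models caller error on ordinary sites.
"""

from __future__ import annotations

import json
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as ifio
from .models import (
    CallSet,
    DiagnosticPanel,
    GenomeReference,
    PanelSNP,
    PrimerPair,
    SampleGenotype,
    VariantSite,
    revcomp,
)

_BASES = "ACGT"

DEFAULT_CONTIGS = {
    "2R": 1_000_000,
    "2L": 600_000,
    "3R": 800_000,
    "3L": 700_000,
    "X": 500_000,
}

DEFAULT_SAMPLES = ("lineA", "lineB", "lineC", "lineD")

#: line-specific variant blocks mimicking fixed chromosomal inversions
DEFAULT_BLOCKS = (
    ("2R", 300_000, 500_000, "lineB"),
    ("2R", 650_000, 700_000, "lineA"),
    ("3R", 200_000, 260_000, "lineB"),
    ("3L", 400_000, 450_000, "lineA"),
)

#: per-rule planted failure rates on ordinary (non-assay) sites
DEFAULT_FAILURE_RATES = {
    "QUAL": 0.004,
    "FS": 0.004,
    "SOR": 0.003,
    "MQ": 0.003,
    "MQRankSum": 0.002,
    "ReadPosRankSum": 0.002,
    "missing": 0.004,
    "multiallelic": 0.003,
    "min_dp": 0.003,
    "min_gq": 0.003,
    "allele_balance": 0.003,
    "depth_cap": 0.004,
}

# marker plan: (name stem contig, offset from a spread position, type, length,
#               hom carriers, het carriers)
DEFAULT_MARKER_PLAN = (
    {"contig": "2R", "pos": 560_000, "kind": "del", "length": 85,
     "hom": ("lineA",), "het": ()},
    {"contig": "3R", "pos": 600_000, "kind": "ins", "length": 148,
     "hom": ("lineA", "lineD"), "het": ()},
    {"contig": "3L", "pos": 600_000, "kind": "ins", "length": 106,
     "hom": ("lineA", "lineC", "lineD"), "het": ()},
    {"contig": "2L", "pos": 300_000, "kind": "del", "length": 90,
     "hom": ("lineA",), "het": ()},
    {"contig": "X", "pos": 250_000, "kind": "ins", "length": 120,
     "hom": (), "het": ("lineC",)},
)

#: species-panel composition per line: (hom first-species, het, hom second-species)
DEFAULT_SPECIES_COMPOSITION = {
    "lineA": (1, 6, 13),
    "lineB": (1, 6, 13),
    "lineC": (3, 0, 17),
    "lineD": (0, 0, 20),
}

REF_AMPLICON = 361  # reference-allele product size of every planted assay
PRIMER_LEN = 20
MARKER_OFFSET = 100  # indel start offset inside the amplicon


@dataclass
class ScenarioConfig:
    seed: int = 0
    contigs: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CONTIGS))
    samples: tuple[str, ...] = DEFAULT_SAMPLES
    sample_a: str = "lineA"
    sample_b: str = "lineB"
    shared_alt_rate: float = 3e-3
    background_distinct_rate: float = 1e-4
    block_rate: float = 2e-3
    distinct_blocks: tuple = DEFAULT_BLOCKS
    indel_fraction: float = 0.15
    indel_geom_p: float = 0.3
    indel_long_fraction: float = 0.03  # heavy tail: lengths 80-250
    het_rate: float = 0.01
    failure_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FAILURE_RATES))
    depth_mean: float = 40.0
    marker_plan: tuple = DEFAULT_MARKER_PLAN
    inversion_panel_size: int = 300
    inversion_panel_total: int = 349
    species_composition: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_COMPOSITION)
    )

    def validate(self) -> None:
        for rate in (self.shared_alt_rate, self.background_distinct_rate,
                     self.block_rate, self.indel_fraction, self.het_rate):
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"rate out of [0,1]: {rate}")
        for contig, start, end, owner in self.distinct_blocks:
            if contig not in self.contigs:
                raise ValueError(f"block contig {contig!r} not in contigs")
            if not (0 <= start < end <= self.contigs[contig]):
                raise ValueError(f"block ({contig},{start},{end}) out of bounds")
            if owner not in self.samples:
                raise ValueError(f"block owner {owner!r} not a sample")
        for s, c in self.species_composition.items():
            if sum(c) != 20:
                raise ValueError(f"species composition for {s!r} must sum to 20")
        for plan in self.marker_plan:
            lo, hi = plan["pos"], plan["pos"] + REF_AMPLICON
            for contig, start, end, _ in self.distinct_blocks:
                if contig == plan["contig"] and lo < end and start < hi:
                    raise ValueError(
                        f"planted marker amplicon on {contig} overlaps block "
                        f"({start},{end})"
                    )


@dataclass
class Scenario:
    config: ScenarioConfig
    genome: GenomeReference
    callset: CallSet  # annotated, with noise and planted failures
    truth_callset: CallSet  # clean genotypes, no noise, passing annotations
    inversion_panel: DiagnosticPanel | None
    species_panel: DiagnosticPanel
    primers: list[PrimerPair]
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "reference": outdir / "reference.fa",
            "vcf": outdir / "calls.vcf",
            "truth_vcf": outdir / "truth.vcf",
            "inversion_panel": outdir / "inversion_panel.tsv",
            "species_panel": outdir / "species_panel.tsv",
            "primers": outdir / "primers.tsv",
            "truth": outdir / "ground_truth.json",
        }
        ifio.write_fasta(self.genome, paths["reference"])
        ifio.write_vcf(self.callset, paths["vcf"], self.genome.lengths)
        ifio.write_vcf(self.truth_callset, paths["truth_vcf"], self.genome.lengths)
        if self.inversion_panel is not None:
            ifio.write_panel(self.inversion_panel, paths["inversion_panel"])
        else:
            del paths["inversion_panel"]
        ifio.write_panel(self.species_panel, paths["species_panel"])
        ifio.write_primers(self.primers, paths["primers"])
        paths["truth"].write_text(json.dumps(self.truth, indent=2) + "\n")
        return paths


class _Reservations:
    """Per-contig reserved half-open intervals with overlap queries."""

    def __init__(self) -> None:
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}

    def overlaps(self, contig: str, start: int, end: int) -> bool:
        starts = self._starts.get(contig, [])
        ends = self._ends.get(contig, [])
        i = bisect_left(starts, end)
        return i > 0 and ends[i - 1] > start

    def reserve(self, contig: str, start: int, end: int) -> bool:
        if self.overlaps(contig, start, end):
            return False
        starts = self._starts.setdefault(contig, [])
        ends = self._ends.setdefault(contig, [])
        i = bisect_left(starts, start)
        starts.insert(i, start)
        ends.insert(i, end)
        return True


def _random_genome(rng: np.random.Generator, contigs: dict[str, int]) -> GenomeReference:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = {}
    for name, length in contigs.items():
        idx = rng.integers(0, 4, size=length, dtype=np.uint8)
        seqs[name] = lut[idx].tobytes().decode("ascii")
    return GenomeReference(seqs)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[rng.integers(0, 4, size=length, dtype=np.uint8)].tobytes().decode("ascii")


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in _BASES if b != base]
    return choices[int(rng.integers(0, 3))]


@dataclass
class _Planted:
    contig: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    gts: dict[str, tuple[int, int] | None]
    planted_class: str  # SHARED_ALT / UNIQUE_<owner> / panel / marker
    block: str | None = None
    failure: str | None = None
    role: str = "variant"  # variant | panel | marker
    fail_sample: str | None = None
    clean_gts: dict[str, tuple[int, int] | None] | None = None
    clean_alts: tuple[str, ...] | None = None


def plant_block(rng: np.random.Generator, genome: GenomeReference,
                samples: tuple[str, ...], block: tuple[str, int, int, str],
                rate: float, reservations: _Reservations,
                indel_fraction: float = 0.15, indel_geom_p: float = 0.3,
                indel_long_fraction: float = 0.03) -> list[_Planted]:
    """Plant dense owner-specific fixed variants inside one block interval.

    The owner is homozygous-alt at every planted site, every other line
    homozygous-ref, so downstream classification sees a UNIQUE_owner run
    — the footprint a fixed chromosomal inversion leaves in a two-line
    comparison.
    """
    contig, start, end, owner = block
    n = int(rng.poisson(rate * (end - start)))
    records: list[_Planted] = []
    positions = np.sort(rng.integers(start, end, size=n))
    for p in positions:
        rec = _make_variant_record(
            rng, genome, samples, contig, int(p),
            owner_samples=(owner,), shared=False, reservations=reservations,
            indel_fraction=indel_fraction, indel_geom_p=indel_geom_p,
            indel_long_fraction=indel_long_fraction,
        )
        if rec is not None:
            rec.block = f"{contig}:{start}-{end}:{owner}"
            records.append(rec)
    return records


def _make_variant_record(rng, genome, samples, contig, pos0, owner_samples,
                         shared, reservations, indel_fraction, indel_geom_p,
                         indel_long_fraction) -> _Planted | None:
    """One random variant at 0-based pos0, or None if the spot is taken."""
    length = genome.lengths[contig]
    is_indel = rng.random() < indel_fraction
    if is_indel:
        if rng.random() < indel_long_fraction:
            ilen = int(rng.integers(80, 251))
        else:
            ilen = 1 + int(rng.geometric(indel_geom_p))
        is_del = rng.random() < 0.5
        if is_del:
            if pos0 + 1 + ilen >= length:
                return None
            ref = genome.fetch(contig, pos0, pos0 + 1 + ilen)
            alt = ref[0]
            span = 1 + ilen
        else:
            ref = genome.fetch(contig, pos0, pos0 + 1)
            alt = ref + _random_seq(rng, ilen)
            span = 1
    else:
        ref = genome.fetch(contig, pos0, pos0 + 1)
        alt = _other_base(rng, ref)
        span = 1
    if not reservations.reserve(contig, pos0 - 12, pos0 + span + 12):
        return None
    if shared:
        gts = {s: (1, 1) for s in samples}
        cls = "SHARED_ALT"
    else:
        gts = {s: ((1, 1) if s in owner_samples else (0, 0)) for s in samples}
        cls = f"UNIQUE_{owner_samples[0]}"
    return _Planted(contig, pos0 + 1, ref, (alt,), gts, cls)


def _apply_failures_and_noise(rng: np.random.Generator, records: list[_Planted],
                              failure_rates: dict[str, float], het_rate: float,
                              samples: tuple[str, ...]) -> None:
    """Assign at most one planted failure (or het noise) per ordinary record.

    Pre-noise genotypes are stashed on each record (``clean_gts``) so the
    truth call set can be materialised without noise.
    """
    rules = list(failure_rates)
    probs = np.array([failure_rates[r] for r in rules])
    cum = np.cumsum(probs)
    for rec in records:
        rec.clean_gts = dict(rec.gts)
        rec.clean_alts = rec.alts
        if rec.role != "variant":
            continue
        u = rng.random()
        idx = int(np.searchsorted(cum, u))
        if idx < len(rules):
            rule = rules[idx]
            is_snp = all(len(a) == 1 for a in (rec.ref,) + rec.alts)
            if rule in ("SOR", "MQ", "MQRankSum", "multiallelic") and not is_snp:
                rule = None  # inapplicable to indels: no failure planted
            if rule is not None:
                rec.failure = rule
                victim = samples[int(rng.integers(0, len(samples)))]
                rec.fail_sample = victim
                if rule == "missing":
                    rec.gts[victim] = None
                elif rule == "multiallelic":
                    extra = _other_base(rng, rec.alts[0])
                    if extra == rec.ref:
                        extra = _other_base(rng, extra)
                    rec.alts = rec.alts + (extra,)
                elif rule == "allele_balance":
                    rec.gts[victim] = (0, 1)
                continue
        if rng.random() < het_rate:
            victim = samples[int(rng.integers(0, len(samples)))]
            if rec.gts[victim] is not None:
                rec.gts[victim] = (0, 1)


def _annotations_for(rng: np.random.Generator, rec: _Planted) -> tuple[float, dict[str, float]]:
    """QUAL and INFO annotations — failing for the planted rule, passing else."""
    is_snp = all(len(a) == 1 for a in (rec.ref,) + rec.alts)
    qual = float(np.round(rng.uniform(100, 1000), 1))
    ann = {
        "FS": float(np.round(rng.uniform(0.0, 5.0), 3)),
        "ReadPosRankSum": float(np.round(rng.normal(0.0, 1.0), 3)),
    }
    if is_snp:
        ann["SOR"] = float(np.round(rng.uniform(0.3, 1.5), 3))
        ann["MQ"] = float(np.round(rng.uniform(55.0, 60.0), 2))
        ann["MQRankSum"] = float(np.round(rng.normal(0.0, 1.0), 3))
    f = rec.failure
    if f == "QUAL":
        qual = float(np.round(rng.uniform(2.0, 25.0), 1))
    elif f == "FS":
        ann["FS"] = float(np.round(rng.uniform(70.0, 120.0) if is_snp else rng.uniform(210.0, 300.0), 3))
    elif f == "SOR":
        ann["SOR"] = float(np.round(rng.uniform(3.5, 6.0), 3))
    elif f == "MQ":
        ann["MQ"] = float(np.round(rng.uniform(20.0, 35.0), 2))
    elif f == "MQRankSum":
        ann["MQRankSum"] = float(np.round(rng.uniform(-20.0, -13.0), 3))
    elif f == "ReadPosRankSum":
        ann["ReadPosRankSum"] = float(
            np.round(rng.uniform(-15.0, -9.0) if is_snp else rng.uniform(-30.0, -21.0), 3)
        )
    return qual, ann


def _genotype_fields(rng: np.random.Generator, rec: _Planted, sample: str,
                     depth_mean: float) -> SampleGenotype:
    gt = rec.gts[sample]
    high_depth = rec.failure == "depth_cap"
    dp = int(rng.poisson(depth_mean * (3.0 if high_depth else 1.0)))
    dp = max(dp, 12)
    gq = int(rng.integers(60, 100))
    fail = rec.failure
    if fail == "min_dp" and sample == rec.fail_sample:
        dp = int(rng.integers(1, 8))
    if fail == "min_gq" and sample == rec.fail_sample:
        gq = int(rng.integers(1, 15))
    n_alleles = 1 + len(rec.alts)
    ad = [0] * n_alleles
    if gt is None:
        return SampleGenotype(sample, None, dp=0, gq=0, ad=None)
    if gt[0] == gt[1]:
        ad[gt[0]] = dp
    else:
        if fail == "allele_balance" and sample == rec.fail_sample:
            minor = max(1, int(0.08 * dp))
        else:
            minor = int(rng.binomial(dp, 0.5))
            lo = int(np.ceil(0.3 * dp))
            minor = min(max(minor, lo), dp - lo)
        ad[gt[0]] = dp - minor
        ad[gt[1]] = minor
    return SampleGenotype(sample, gt, dp=dp, gq=gq, ad=tuple(ad))


def generate(config: ScenarioConfig | None = None, outdir: str | Path | None = None) -> Scenario:
    """Build the full scenario; optionally write its files to *outdir*."""
    config = config or ScenarioConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    genome = _random_genome(rng, config.contigs)
    reservations = _Reservations()
    samples = tuple(config.samples)

    # ---- markers first: they reserve their amplicon footprints
    primers: list[PrimerPair] = []
    marker_records: list[_Planted] = []
    marker_truth: dict[str, dict] = {}
    for plan in config.marker_plan:
        contig, p0 = plan["contig"], plan["pos"]
        if not reservations.reserve(contig, p0 - 50, p0 + REF_AMPLICON + 50):
            raise ValueError(f"marker region on {contig} at {p0} is not free")
        fwd = genome.fetch(contig, p0, p0 + PRIMER_LEN)
        rev = revcomp(genome.fetch(contig, p0 + REF_AMPLICON - PRIMER_LEN, p0 + REF_AMPLICON))
        ilen = plan["length"]
        ipos0 = p0 + MARKER_OFFSET  # anchor base, 0-based
        if plan["kind"] == "del":
            ref = genome.fetch(contig, ipos0, ipos0 + 1 + ilen)
            alt = ref[0]
        else:
            ref = genome.fetch(contig, ipos0, ipos0 + 1)
            ins = _random_seq(rng, ilen)
            # inserted sequence must be absent from the reference
            while any(ins in seq or revcomp(ins) in seq for seq in genome.contigs.values()):
                ins = _random_seq(rng, ilen)  # pragma: no cover - vanishingly rare
            alt = ref + ins
        gts: dict[str, tuple[int, int] | None] = {}
        for s in samples:
            if s in plan["hom"]:
                gts[s] = (1, 1)
            elif s in plan["het"]:
                gts[s] = (0, 1)
            else:
                gts[s] = (0, 0)
        rec = _Planted(contig, ipos0 + 1, ref, (alt,), gts, "marker", role="marker")
        marker_records.append(rec)
        name = f"{contig}.{ipos0 + 1}"
        primers.append(PrimerPair(name, fwd, rev, "60C"))
        delta = -ilen if plan["kind"] == "del" else ilen
        bands = {}
        for s in samples:
            if gts[s] == (1, 1):
                bands[s] = [REF_AMPLICON + delta]
            elif gts[s] == (0, 1):
                bands[s] = sorted({REF_AMPLICON, REF_AMPLICON + delta})
            else:
                bands[s] = [REF_AMPLICON]
        marker_truth[name] = {
            "contig": contig,
            "pos": ipos0 + 1,
            "kind": plan["kind"],
            "length": ilen,
            "genotypes": {s: ("hom_alt" if gts[s] == (1, 1) else "het" if gts[s] == (0, 1) else "hom_ref") for s in samples},
            "expected_bands": bands,
            "diagnostic_pair_distinct": gts[config.sample_a] != gts[config.sample_b]
            and gts[config.sample_a][0] == gts[config.sample_a][1]  # type: ignore[index]
            and gts[config.sample_b][0] == gts[config.sample_b][1],  # type: ignore[index]
        }

    # ---- inversion panel inside the first block (owner = hom state1)
    inv_snps: list[PanelSNP] = []
    panel_records: list[_Planted] = []
    b_owner = None
    if config.distinct_blocks and config.inversion_panel_size > 0:
        b_contig, b_start, b_end, b_owner = config.distinct_blocks[0]
        panel_positions: list[int] = []
        spacing = (b_end - b_start) // (config.inversion_panel_size + 1)
        p = b_start + spacing
        while len(panel_positions) < config.inversion_panel_size and p < b_end:
            if reservations.reserve(b_contig, p - 6, p + 6):
                panel_positions.append(p)
                p += spacing
            else:
                p += 17
        for p0 in panel_positions:
            ref = genome.fetch(b_contig, p0, p0 + 1)
            alt = _other_base(rng, ref)
            gts = {s: ((1, 1) if s == b_owner else (0, 0)) for s in samples}
            panel_records.append(_Planted(b_contig, p0 + 1, ref, (alt,), gts, "panel", role="panel"))
            inv_snps.append(PanelSNP(b_contig, p0 + 1, alt, ref))  # state1 = inverted allele
    inversion_panel = DiagnosticPanel(
        panel_id="2Rb_like",
        snps=inv_snps,
        state1_label="inverted",
        state2_label="standard",
        total_panel_size=config.inversion_panel_total,
    ) if inv_snps else None

    # ---- species panel: 20 SNPs spread over X, 2L and 3L
    species_contigs = [c for c in ("X", "2L", "3L") if c in config.contigs] or list(config.contigs)
    sp_snps: list[PanelSNP] = []
    sp_records: list[_Planted] = []
    n_species = 20
    per = [n_species // len(species_contigs)] * len(species_contigs)
    for i in range(n_species - sum(per)):
        per[i] += 1
    comp = {s: list(config.species_composition.get(s, (0, 0, 20))) for s in samples}
    # per-sample genotype sequence over the 20 SNPs, order: hom1, het, hom2
    gt_seq = {
        s: [(1, 1)] * comp[s][0] + [(0, 1)] * comp[s][1] + [(0, 0)] * comp[s][2]
        for s in samples
    }
    k = 0
    for contig, n_here in zip(species_contigs, per):
        length = config.contigs[contig]
        spacing = length // (n_here + 1)
        placed = 0
        p0 = spacing
        while placed < n_here and p0 < length - 10:
            if reservations.reserve(contig, p0 - 6, p0 + 6):
                ref = genome.fetch(contig, p0, p0 + 1)
                alt = _other_base(rng, ref)  # alt = first-species (state1) allele
                gts = {s: gt_seq[s][k] for s in samples}
                sp_records.append(_Planted(contig, p0 + 1, ref, (alt,), gts, "panel", role="panel"))
                sp_snps.append(PanelSNP(contig, p0 + 1, alt, ref))
                placed += 1
                k += 1
                p0 += spacing
            else:
                p0 += 17  # spot taken (e.g. a marker amplicon): probe nearby
    species_panel = DiagnosticPanel(
        panel_id="species_20snp",
        snps=sp_snps,
        state1_label="gambiae",
        state2_label="coluzzii",
        total_panel_size=20,
    )

    # ---- block, shared and background variants
    records: list[_Planted] = []
    for block in config.distinct_blocks:
        records.extend(
            plant_block(rng, genome, samples, block, config.block_rate, reservations,
                        config.indel_fraction, config.indel_geom_p, config.indel_long_fraction)
        )
    for contig, length in config.contigs.items():
        n_shared = int(rng.poisson(config.shared_alt_rate * length))
        for p in np.sort(rng.integers(0, length - 300, size=n_shared)):
            rec = _make_variant_record(
                rng, genome, samples, contig, int(p), (), True, reservations,
                config.indel_fraction, config.indel_geom_p, config.indel_long_fraction,
            )
            if rec is not None:
                records.append(rec)
        n_bg = int(rng.poisson(config.background_distinct_rate * length))
        for p in np.sort(rng.integers(0, length - 300, size=n_bg)):
            owner = config.sample_a if rng.random() < 0.5 else config.sample_b
            rec = _make_variant_record(
                rng, genome, samples, contig, int(p), (owner,), False, reservations,
                config.indel_fraction, config.indel_geom_p, config.indel_long_fraction,
            )
            if rec is not None:
                records.append(rec)

    all_records = records + panel_records + sp_records + marker_records
    _apply_failures_and_noise(rng, all_records, config.failure_rates, config.het_rate, samples)

    # ---- materialise the two call sets
    def build(clean: bool) -> CallSet:
        sites: list[VariantSite] = []
        genotypes: list[dict[str, SampleGenotype]] = []
        sub = np.random.default_rng(config.seed + (1 if clean else 2))
        for rec in all_records:
            if clean:
                view = _Planted(rec.contig, rec.pos, rec.ref,
                                rec.clean_alts or rec.alts,
                                dict(rec.clean_gts or rec.gts), rec.planted_class)
            else:
                view = rec
            qual, ann = _annotations_for(sub, view)
            sites.append(VariantSite(view.contig, view.pos, view.ref, view.alts, qual, ann))
            genotypes.append(
                {s: _genotype_fields(sub, view, s, config.depth_mean) for s in samples}
            )
        cs = CallSet(samples, sites, genotypes)
        cs.sort()
        return cs

    callset = build(clean=False)
    truth_callset = build(clean=True)

    truth = {
        "seed": config.seed,
        "samples": list(samples),
        "focal_pair": [config.sample_a, config.sample_b],
        "contig_lengths": dict(config.contigs),
        "blocks": [
            {"contig": c, "start": s + 1, "end": e, "owner": o}
            for c, s, e, o in config.distinct_blocks
        ],
        "variants": [
            {
                "contig": r.contig,
                "pos": r.pos,
                "ref": r.ref,
                "alts": list(r.alts),
                "planted_class": r.planted_class,
                "block": r.block,
                "failure": r.failure,
                "role": r.role,
                "genotypes": {
                    s: (None if r.gts[s] is None else list(r.gts[s])) for s in samples
                },
            }
            for r in all_records
        ],
        "filter_failures": _failure_index(all_records),
        "karyotypes": (
            {
                s: ("homozygous_state1" if s == b_owner else "homozygous_state2")
                for s in samples
            }
            if b_owner is not None
            else {}
        ),
        "ancestry_compositions": {s: list(comp[s]) for s in samples},
        "markers": marker_truth,
        "panels": {
            "inversion": {"id": "2Rb_like", "n_snps": len(inv_snps),
                          "total_panel_size": config.inversion_panel_total},
            "species": {"id": "species_20snp", "n_snps": len(sp_snps)},
        },
    }

    scenario = Scenario(
        config=config,
        genome=genome,
        callset=callset,
        truth_callset=truth_callset,
        inversion_panel=inversion_panel,
        species_panel=species_panel,
        primers=primers,
        truth=truth,
    )
    if outdir is not None:
        scenario.write(outdir)
    return scenario


def _failure_index(records: list[_Planted]) -> dict[str, list]:
    out: dict[str, list] = {}
    for r in records:
        if r.failure:
            out.setdefault(r.failure, []).append([r.contig, r.pos])
    return out
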