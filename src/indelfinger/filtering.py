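"""Variant- and genotype-level filtering cascade.

The cascade mirrors the hard-filtering scheme used for short-read
genotype calls from cultured cell lines:

1. **Site hard filters** — SNPs judged on QUAL, SOR, FS, MQ, MQRankSum and
   ReadPosRankSum; indels on QUAL, FS and ReadPosRankSum.  A site fails if
   any *present* annotation violates its threshold; absent annotations are
   never held against a site.
2. **Genotype filters** — drop sites with any missing call, multiallelic
   sites, sites where any sample fails minimum depth (MIN_DP) or genotype
   quality (MIN_GQ), and sites where any heterozygote has minor-allele
   balance below MIN_AB.
3. **Depth cap** — per variant class, site mean depth must not exceed
   ``max_depth_multiplier`` x the mode of rounded site mean depths
   (boundary inclusive: mean depth equal to the cap passes).

Each stage reports input/passed/removed counts split by SNP/INDEL, plus a
per-rule breakdown, and the cascade is idempotent: re-running it on its
own output changes nothing.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .models import CallSet, SampleGenotype, VariantSite

logger = logging.getLogger(__name__)

# Defaults follow the standard hard-filter recommendations for germline
# short variants; every threshold is configurable.
DEFAULT_SNP_THRESHOLDS = {
    "qual_min": 30.0,
    "sor_max": 3.0,
    "fs_max": 60.0,
    "mq_min": 40.0,
    "mqranksum_min": -12.5,
    "readposranksum_min": -8.0,
}
DEFAULT_INDEL_THRESHOLDS = {
    "qual_min": 30.0,
    "fs_max": 200.0,
    "readposranksum_min": -20.0,
}


@dataclass
class FilterConfig:
    snp_thresholds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SNP_THRESHOLDS))
    indel_thresholds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_INDEL_THRESHOLDS))
    min_ab: float = 0.2
    min_dp: int = 10
    min_gq: int = 20
    max_depth_multiplier: float = 2.0
    require_biallelic: bool = True
    drop_any_missing: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.min_ab <= 0.5):
            raise ValueError(f"min_ab must be in (0, 0.5], got {self.min_ab}")
        if self.max_depth_multiplier <= 1.0:
            raise ValueError("max_depth_multiplier must exceed 1")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "FilterConfig":
        cfg = cls()
        for k, v in d.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown filter config key {k!r}")
            if k in ("snp_thresholds", "indel_thresholds"):
                getattr(cfg, k).update(v)
            else:
                setattr(cfg, k, v)
        cfg.__post_init__()
        return cfg

    @classmethod
    def from_json(cls, path: str | Path) -> "FilterConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class StageReport:
    stage: str
    input_snps: int
    input_indels: int
    passed_snps: int
    passed_indels: int
    rule_failures: dict[str, int] = field(default_factory=dict)
    #: site keys removed at this stage, by first failing rule
    removed_by_rule: dict[str, list] = field(default_factory=dict)

    @property
    def removed_snps(self) -> int:
        return self.input_snps - self.passed_snps

    @property
    def removed_indels(self) -> int:
        return self.input_indels - self.passed_indels


@dataclass
class FilterReport:
    stages: list[StageReport] = field(default_factory=list)

    def summary(self) -> list[dict]:
        out = []
        for st in self.stages:
            out.append(
                {
                    "stage": st.stage,
                    "input_snps": st.input_snps,
                    "passed_snps": st.passed_snps,
                    "removed_snps": st.removed_snps,
                    "input_indels": st.input_indels,
                    "passed_indels": st.passed_indels,
                    "removed_indels": st.removed_indels,
                    "rule_failures": st.rule_failures,
                }
            )
        return out

    def retained_fraction(self, variant_class: str) -> float:
        if not self.stages:
            return 1.0
        first, last = self.stages[0], self.stages[-1]
        if variant_class == "SNP":
            return last.passed_snps / first.input_snps if first.input_snps else 1.0
        return last.passed_indels / first.input_indels if first.input_indels else 1.0

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.summary()).drop(columns=["rule_failures"]).to_csv(
            path, sep="\t", index=False
        )


def _class_counts(sites: list[VariantSite]) -> tuple[int, int]:
    n_snp = sum(1 for s in sites if s.is_snp)
    return n_snp, len(sites) - n_snp


def site_hard_filter_failures(site: VariantSite, config: FilterConfig) -> list[str]:
    """Names of hard-filter rules the site violates (absent annotations skip)."""
    th = config.snp_thresholds if site.is_snp else config.indel_thresholds
    ann = site.annotations
    failures: list[str] = []
    if "qual_min" in th and site.qual < th["qual_min"]:
        failures.append("QUAL")
    checks = [
        ("fs_max", "FS", lambda v, t: v > t),
        ("sor_max", "SOR", lambda v, t: v > t),
        ("mq_min", "MQ", lambda v, t: v < t),
        ("mqranksum_min", "MQRankSum", lambda v, t: v < t),
        ("readposranksum_min", "ReadPosRankSum", lambda v, t: v < t),
    ]
    for key, ann_key, violates in checks:
        if key in th and ann_key in ann and isinstance(ann[ann_key], (int, float)):
            if violates(float(ann[ann_key]), th[key]):
                failures.append(ann_key)
    return failures


def hard_filter_sites(callset: CallSet, config: FilterConfig) -> tuple[CallSet, StageReport]:
    """Apply the site-level hard filters; return survivors and a stage report."""
    n_snp, n_indel = _class_counts(callset.sites)
    keep = []
    rule_failures: Counter[str] = Counter()
    removed_by_rule: dict[str, list] = {}
    for site in callset.sites:
        failures = site_hard_filter_failures(site, config)
        keep.append(not failures)
        for f in failures:
            rule_failures[f] += 1
        if failures:
            removed_by_rule.setdefault(failures[0], []).append(list(site.key))
    out = callset.subset(keep)
    p_snp, p_indel = _class_counts(out.sites)
    report = StageReport(
        "hard_filter", n_snp, n_indel, p_snp, p_indel,
        dict(rule_failures), removed_by_rule,
    )
    return out, report


def _genotype_failure(site: VariantSite, gts: dict[str, SampleGenotype],
                      config: FilterConfig) -> str | None:
    """First genotype-level rule the site fails, or None.

    Check order: missing data, biallelic requirement, MIN_DP/MIN_GQ,
    allele balance.  A heterozygote with no AD is treated as failing the
    allele-balance rule (conservative).
    """
    if config.drop_any_missing and any(g.is_missing for g in gts.values()):
        return "missing"
    if config.require_biallelic and not site.is_biallelic:
        return "multiallelic"
    for g in gts.values():
        if g.is_missing:
            continue
        if g.dp is not None and g.dp < config.min_dp:
            return "min_dp"
        if g.dp is None:
            return "min_dp"
        if g.gq is not None and g.gq < config.min_gq:
            return "min_gq"
        if g.gq is None:
            return "min_gq"
    for g in gts.values():
        if g.is_het:
            if g.ad is None:
                logger.warning(
                    "het at %s:%d sample %s lacks AD; failing allele balance",
                    site.contig, site.pos, g.sample_id,
                )
                return "allele_balance"
            a, b = g.gt  # type: ignore[misc]
            da, db = g.ad[a], g.ad[b]
            tot = da + db
            if tot == 0 or min(da, db) / tot < config.min_ab:
                return "allele_balance"
    return None


def genotype_filter(callset: CallSet, config: FilterConfig) -> tuple[CallSet, StageReport]:
    """Drop sites failing missing-data, biallelic, DP/GQ or allele-balance rules."""
    n_snp, n_indel = _class_counts(callset.sites)
    keep = []
    rule_failures: Counter[str] = Counter()
    removed_by_rule: dict[str, list] = {}
    for site, gts in callset:
        rule = _genotype_failure(site, gts, config)
        keep.append(rule is None)
        if rule is not None:
            rule_failures[rule] += 1
            removed_by_rule.setdefault(rule, []).append(list(site.key))
    out = callset.subset(keep)
    p_snp, p_indel = _class_counts(out.sites)
    report = StageReport(
        "genotype_filter", n_snp, n_indel, p_snp, p_indel,
        dict(rule_failures), removed_by_rule,
    )
    return out, report


def site_mean_depth(gts: dict[str, SampleGenotype]) -> float:
    """Mean of per-sample DP over all samples (missing DP counts as 0)."""
    depths = [(g.dp or 0) for g in gts.values()]
    return sum(depths) / len(depths)


def mode_mean_depth(callset: CallSet, variant_class: str) -> int:
    """Mode of per-site mean depths for one variant class.

    Site mean depths are rounded half-up to integers before taking the
    mode; ties break toward the smaller depth.
    """
    counts: Counter[int] = Counter()
    for site, gts in callset:
        if site.variant_class != variant_class:
            continue
        counts[int(site_mean_depth(gts) + 0.5)] += 1
    if not counts:
        raise ValueError(f"no sites of class {variant_class!r}")
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return best[0]


def depth_cap_filter(callset: CallSet, config: FilterConfig) -> tuple[CallSet, StageReport]:
    """Remove sites whose mean depth exceeds multiplier x class mode depth."""
    n_snp, n_indel = _class_counts(callset.sites)
    caps: dict[str, float] = {}
    for vc in ("SNP", "INDEL"):
        if any(s.variant_class == vc for s in callset.sites):
            caps[vc] = config.max_depth_multiplier * mode_mean_depth(callset, vc)
    keep = []
    rule_failures: Counter[str] = Counter()
    removed_by_rule: dict[str, list] = {}
    for site, gts in callset:
        ok = site_mean_depth(gts) <= caps[site.variant_class]
        keep.append(ok)
        if not ok:
            rule_failures["depth_cap"] += 1
            removed_by_rule.setdefault("depth_cap", []).append(list(site.key))
    out = callset.subset(keep)
    p_snp, p_indel = _class_counts(out.sites)
    report = StageReport(
        "depth_cap", n_snp, n_indel, p_snp, p_indel,
        dict(rule_failures), removed_by_rule,
    )
    return out, report


def run_filter_cascade(callset: CallSet, config: FilterConfig | None = None) -> tuple[CallSet, FilterReport]:
    """Full cascade: hard filters, then genotype filters, then depth cap."""
    config = config or FilterConfig()
    report = FilterReport()
    cs, st = hard_filter_sites(callset, config)
    report.stages.append(st)
    cs, st = genotype_filter(cs, config)
    report.stages.append(st)
    if len(cs):
        cs, st = depth_cap_filter(cs, config)
        report.stages.append(st)
    return cs, report
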