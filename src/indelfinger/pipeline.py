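"""High-level pipeline stages tying the modules into reproducible runs.

Each stage reads standard-format inputs, calls into the library, and
writes TSV/JSON artifacts plus a manifest (input hashes, resolved
parameters, seed) sufficient to reproduce the outputs.  The CLI is a
thin wrapper over these functions; tests call them directly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

from . import io as ifio
from .comparison import (
    DISTINCT_CLASSES,
    FixedClass,
    arm_counts,
    arm_distribution_test,
    call_clusters,
    classify_fixed,
    sliding_windows,
    venn_summary,
)
from .filtering import FilterConfig, run_filter_cascade
from .markers import (
    MarkerCriteria,
    detect_contamination,
    distinguishability,
    fingerprint,
    select_candidates,
    simulate_mixture,
)
from .models import CallSet, GenomeReference
from .typing import ancestry_score, karyotype


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: Path, inputs: dict[str, Path | str], params: dict,
                   seed: int | None = None) -> None:
    manifest = {
        "inputs": {
            k: {"path": str(p), "sha256": _sha256(Path(p))}
            for k, p in inputs.items()
            if p is not None and Path(p).exists()
        },
        "parameters": params,
        "seed": seed,
    }
    ifio.write_json(manifest, outdir / "manifest.json")


def stage_filter(vcf: Path, outdir: Path, config: FilterConfig | None = None) -> CallSet:
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or FilterConfig()
    callset = ifio.read_vcf(vcf)
    filtered, report = run_filter_cascade(callset, config)
    ifio.write_vcf(filtered, outdir / "filtered.vcf")
    report.to_tsv(outdir / "filter_report.tsv")
    ifio.write_json(
        {
            "stages": report.summary(),
            "retained_fraction": {
                "SNP": report.retained_fraction("SNP"),
                "INDEL": report.retained_fraction("INDEL"),
            },
        },
        outdir / "filter_report.json",
    )
    write_manifest(outdir, {"vcf": vcf}, {"filter": asdict(config)})
    return filtered


def stage_classify(filtered: CallSet, sample_a: str, sample_b: str, outdir: Path) -> list[FixedClass]:
    outdir.mkdir(parents=True, exist_ok=True)
    classes = classify_fixed(filtered, sample_a, sample_b)
    summary = venn_summary(filtered, classes)
    ifio.write_json(summary, outdir / "venn.json")
    with open(outdir / "venn.tsv", "w") as fh:
        fh.write("variant_class\tfixed_class\tcount\tpercent\n")
        for vc, entry in summary.items():
            for cls, n in entry["counts"].items():
                pct = entry["percent"].get(cls, "")
                fh.write(f"{vc}\t{cls}\t{n}\t{pct}\n")
    with open(outdir / "classified.tsv", "w") as fh:
        fh.write("contig\tpos\tvariant_class\tfixed_class\n")
        for site, cls in zip(filtered.sites, classes):
            fh.write(f"{site.contig}\t{site.pos}\t{site.variant_class}\t{cls.value}\n")
    return classes


def stage_distribution(filtered: CallSet, classes: list[FixedClass],
                       contig_lengths: dict[str, int], outdir: Path,
                       window_size: int = 10_000, step: int = 2_500,
                       min_cluster_variants: int = 20) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    chi2_results = {}
    for label, which in (("distinct", DISTINCT_CLASSES), ("same", (FixedClass.SHARED_ALT,))):
        for vc in ("SNP", "INDEL"):
            observed = arm_counts(filtered, classes, which, vc)
            if sum(observed.values()) == 0:
                continue
            chi2_results[f"{label}_{vc}"] = arm_distribution_test(observed, contig_lengths)
    windows = sliding_windows(filtered, classes, contig_lengths, window_size, step)
    clusters = call_clusters(windows, filtered, classes, step=step,
                             min_cluster_variants=min_cluster_variants)
    ifio.write_json(chi2_results, outdir / "arm_chi2.json")
    with open(outdir / "windows.tsv", "w") as fh:
        fh.write("contig\tstart\tend\ttruncated\tdistinct\tshared\tsnp\tindel\n")
        for w in windows:
            fh.write(
                f"{w.contig}\t{w.start}\t{w.end}\t{int(w.truncated)}\t"
                f"{w.distinct_count}\t{w.by_class.get('SHARED_ALT', 0)}\t"
                f"{w.by_variant_class.get('SNP', 0)}\t{w.by_variant_class.get('INDEL', 0)}\n"
            )
    cluster_dicts = [
        {
            "contig": c.contig, "start": c.start, "end": c.end,
            "dominant_class": c.dominant_class, "n_unique_a": c.n_unique_a,
            "n_unique_b": c.n_unique_b, "variant_count": c.variant_count,
        }
        for c in clusters
    ]
    ifio.write_json(cluster_dicts, outdir / "clusters.json")
    with open(outdir / "clusters.tsv", "w") as fh:
        fh.write("contig\tstart\tend\tdominant_class\tn_unique_a\tn_unique_b\n")
        for c in clusters:
            fh.write(f"{c.contig}\t{c.start}\t{c.end}\t{c.dominant_class}\t"
                     f"{c.n_unique_a}\t{c.n_unique_b}\n")
    ifio.write_bed(
        [(c.contig, c.start - 1, c.end, c.dominant_class) for c in clusters],
        outdir / "clusters.bed",
    )
    return {"chi2": chi2_results, "windows": windows, "clusters": clusters}


def stage_typing(filtered: CallSet, inversion_panel, species_panel, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    karyotypes = {
        s: karyotype(filtered, s, inversion_panel).as_dict() for s in filtered.samples
    }
    ancestry = {
        s: ancestry_score(filtered, s, species_panel).as_dict() for s in filtered.samples
    }
    ifio.write_json(karyotypes, outdir / "karyotypes.json")
    ifio.write_json(ancestry, outdir / "ancestry.json")
    return {"karyotypes": karyotypes, "ancestry": ancestry}


def stage_markers(filtered: CallSet, classes: list[FixedClass], genome: GenomeReference,
                  sample_a: str, sample_b: str, primers, outdir: Path,
                  criteria: MarkerCriteria | None = None,
                  gel_tolerance: int = 5) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    candidates = select_candidates(filtered, classes, sample_a, sample_b, genome, criteria)
    ifio.write_json([m.as_dict() for m in candidates], outdir / "marker_candidates.json")
    matrix = fingerprint(genome, filtered, list(filtered.samples), primers,
                         gel_tolerance=gel_tolerance)
    matrix.to_tsv(outdir / "fingerprints.tsv")
    ifio.write_json(matrix.as_dict(), outdir / "fingerprints.json")
    report = distinguishability(matrix, gel_tolerance)
    ifio.write_json(report, outdir / "distinguishability.json")
    return {"candidates": candidates, "matrix": matrix, "distinguishability": report}


def stage_contamination(matrix, host: str, contaminant: str, fraction: float,
                        outdir: Path, min_fraction: float = 0.10,
                        gel_tolerance: int = 5) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    expected = {m: matrix.bands[host].get(m, ()) for m in matrix.markers}
    cont = {m: matrix.bands[contaminant].get(m, ()) for m in matrix.markers}
    mixture = simulate_mixture(expected, cont, fraction)
    verdict = detect_contamination(
        host, expected, band_fractions=mixture, min_fraction=min_fraction,
        tolerance_bp=gel_tolerance, contaminant=contaminant,
        contaminant_expected=cont,
    )
    out = verdict.as_dict()
    out["simulated_fraction"] = fraction
    ifio.write_json(out, outdir / "contamination.json")
    return out


def authenticate(matrix, observed: dict[str, list[int]], tolerance_bp: int = 5) -> dict:
    """Match an observed band table against stored line fingerprints.

    Returns the best-matching line and the per-line mismatch counts
    (number of marker assays whose band sets disagree at the tolerance).
    """
    from .markers import _cells_match

    mismatches = {}
    for s in matrix.samples:
        n = 0
        for m in matrix.markers:
            exp = tuple(matrix.bands[s].get(m, ()))
            obs = tuple(observed.get(m, ()))
            if not _cells_match(exp, obs, tolerance_bp):
                n += 1
        mismatches[s] = n
    best = min(matrix.samples, key=lambda s: (mismatches[s], s))
    ties = [s for s in matrix.samples if mismatches[s] == mismatches[best]]
    return {
        "best_match": best,
        "mismatches": mismatches,
        "ambiguous": len(ties) > 1,
        "exact": mismatches[best] == 0,
    }


def run_all(scenario_dir: Path, outdir: Path, sample_a: str, sample_b: str,
            filter_config: FilterConfig | None = None, seed: int | None = None,
            contamination_fraction: float = 0.10,
            inversion_panel_total: int | None = None) -> dict:
    """Chain every stage on a scenario directory (as written by ``simulate``)."""
    scenario_dir = Path(scenario_dir)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = ifio.read_fasta(scenario_dir / "reference.fa")
    inv_panel = ifio.read_panel(scenario_dir / "inversion_panel.tsv",
                                total_panel_size=inversion_panel_total)
    sp_panel = ifio.read_panel(scenario_dir / "species_panel.tsv")
    primers = ifio.read_primers(scenario_dir / "primers.tsv")

    filtered = stage_filter(scenario_dir / "calls.vcf", outdir, filter_config)
    classes = stage_classify(filtered, sample_a, sample_b, outdir)
    dist = stage_distribution(filtered, classes, genome.lengths, outdir)
    typing_out = stage_typing(filtered, inv_panel, sp_panel, outdir)
    markers_out = stage_markers(filtered, classes, genome, sample_a, sample_b,
                                primers, outdir)
    contamination = stage_contamination(
        markers_out["matrix"], sample_b, sample_a, contamination_fraction, outdir
    )
    write_manifest(
        outdir,
        {
            "reference": scenario_dir / "reference.fa",
            "vcf": scenario_dir / "calls.vcf",
            "inversion_panel": scenario_dir / "inversion_panel.tsv",
            "species_panel": scenario_dir / "species_panel.tsv",
            "primers": scenario_dir / "primers.tsv",
        },
        {
            "sample_a": sample_a,
            "sample_b": sample_b,
            "filter": asdict(filter_config or FilterConfig()),
            "contamination_fraction": contamination_fraction,
        },
        seed=seed,
    )
    return {
        "filtered": filtered,
        "classes": classes,
        "distribution": dist,
        "typing": typing_out,
        "markers": markers_out,
        "contamination": contamination,
    }
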