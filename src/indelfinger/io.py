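"""Readers and writers for the formats the pipeline touches.

FASTA goes through Biopython.  The VCF reader/writer is a deliberately
small dialect handler for the fields the pipeline uses (FORMAT GT/AD/DP/GQ,
INFO FS/SOR/MQ/MQRankSum/ReadPosRankSum); unknown INFO keys are carried
through untouched so round trips are lossless for everything we model.
Multiallelic records are preserved as-is — splitting is never performed,
downstream filters drop them.  Intervals are accepted as BED (0-based
half-open) or GFF3 (1-based closed) and normalised to 0-based half-open
on read.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    CallSet,
    DiagnosticPanel,
    FeatureInterval,
    FeatureSet,
    FormatError,
    GenomeReference,
    PanelSNP,
    PrimerPair,
    SampleGenotype,
    VariantSite,
)

# INFO keys parsed as floats; anything else is passed through verbatim.
_FLOAT_INFO_KEYS = ("FS", "SOR", "MQ", "MQRankSum", "ReadPosRankSum")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> GenomeReference:
    """Load a FASTA file into a :class:`GenomeReference` (uppercased)."""
    path = Path(path)
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise FormatError(f"{path}: duplicate contig {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: contig {rec.id!r} has empty sequence")
        contigs[rec.id] = seq
    if not contigs:
        raise FormatError(f"{path}: no FASTA records found")
    return GenomeReference(contigs)


def write_fasta(genome: GenomeReference, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.contigs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# VCF

def _parse_gt(token: str, n_alleles: int, sample: str, line_no: int) -> tuple[int, int] | None:
    sep = "|" if "|" in token else "/"
    parts = token.split(sep)
    if any(p == "." for p in parts):
        return None
    try:
        alleles = tuple(int(p) for p in parts)
    except ValueError as exc:
        raise FormatError(f"line {line_no}: bad GT {token!r} for {sample}") from exc
    if len(alleles) != 2:
        raise FormatError(f"line {line_no}: non-diploid GT {token!r} for {sample}")
    if any(a < 0 or a >= n_alleles for a in alleles):
        raise FormatError(f"line {line_no}: GT allele out of range in {token!r}")
    return alleles  # type: ignore[return-value]


def _fmt_float(x: float) -> str:
    """Compact float formatting, stable across write/read cycles."""
    s = f"{x:.6g}"
    return s


def read_vcf(path: str | Path) -> CallSet:
    """Parse a VCF 4.x text file into a :class:`CallSet`.

    "./." (or any GT containing ".") parses as a missing call.  INFO keys
    in the hard-filter set are parsed as floats; other keys are kept as
    strings in the annotations map.
    """
    path = Path(path)
    samples: list[str] | None = None
    sites: list[VariantSite] = []
    genotypes: list[dict[str, SampleGenotype]] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 10:
                    raise FormatError(f"{path} line {line_no}: no samples in header")
                samples = cols[9:]
                continue
            if samples is None:
                raise FormatError(f"{path} line {line_no}: record before #CHROM header")
            cols = line.split("\t")
            if len(cols) < 9 + len(samples):
                raise FormatError(f"{path} line {line_no}: truncated record")
            contig, pos_s, _id, ref, alt, qual_s, _filt, info_s, format_s = cols[:9]
            alt_alleles = tuple(alt.split(","))
            qual = 0.0 if qual_s == "." else float(qual_s)
            annotations: dict[str, float | str] = {}
            if info_s not in (".", ""):
                for item in info_s.split(";"):
                    if "=" in item:
                        k, v = item.split("=", 1)
                        if k in _FLOAT_INFO_KEYS:
                            annotations[k] = float(v)
                        else:
                            annotations[k] = v
                    else:
                        annotations[item] = ""
            site = VariantSite(
                contig=contig,
                pos=int(pos_s),
                ref_allele=ref,
                alt_alleles=alt_alleles,
                qual=qual,
                annotations=annotations,  # type: ignore[arg-type]
            )
            fmt_keys = format_s.split(":")
            if "GT" not in fmt_keys:
                raise FormatError(f"{path} line {line_no}: FORMAT lacks GT")
            row: dict[str, SampleGenotype] = {}
            n_alleles = 1 + len(alt_alleles)
            for sample, token in zip(samples, cols[9:]):
                fields = dict(zip(fmt_keys, token.split(":")))
                gt = _parse_gt(fields["GT"], n_alleles, sample, line_no)
                dp = None
                gq = None
                ad = None
                if fields.get("DP") not in (None, "."):
                    dp = int(fields["DP"])
                if fields.get("GQ") not in (None, "."):
                    gq = int(fields["GQ"])
                if fields.get("AD") not in (None, "."):
                    ad = tuple(int(x) for x in fields["AD"].split(","))
                row[sample] = SampleGenotype(sample, gt, dp=dp, gq=gq, ad=ad)
            sites.append(site)
            genotypes.append(row)
    if samples is None:
        raise FormatError(f"{path}: missing #CHROM header line")
    cs = CallSet(tuple(samples), sites, genotypes)
    cs.sort()
    return cs


def write_vcf(callset: CallSet, path: str | Path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write a CallSet as a VCF 4.2 text file (FORMAT GT:AD:DP:GQ)."""
    lines = ["##fileformat=VCFv4.2"]
    if contig_lengths:
        for name, length in contig_lengths.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    for key in _FLOAT_INFO_KEYS:
        lines.append(f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">')
    lines.append('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(callset.samples)
    )
    for site, gts in callset:
        info_items = []
        for k, v in site.annotations.items():
            if v == "":
                info_items.append(k)
            elif isinstance(v, float):
                info_items.append(f"{k}={_fmt_float(v)}")
            else:
                info_items.append(f"{k}={v}")
        info = ";".join(info_items) if info_items else "."
        sample_cols = []
        for s in callset.samples:
            g = gts[s]
            gt_s = "./." if g.gt is None else f"{g.gt[0]}/{g.gt[1]}"
            ad_s = "." if g.ad is None else ",".join(str(x) for x in g.ad)
            dp_s = "." if g.dp is None else str(g.dp)
            gq_s = "." if g.gq is None else str(g.gq)
            sample_cols.append(f"{gt_s}:{ad_s}:{dp_s}:{gq_s}")
        lines.append(
            "\t".join(
                [
                    site.contig,
                    str(site.pos),
                    ".",
                    site.ref_allele,
                    ",".join(site.alt_alleles),
                    _fmt_float(site.qual),
                    ".",
                    info,
                    "GT:AD:DP:GQ",
                ]
                + sample_cols
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Intervals (BED / GFF3)

def read_intervals(path: str | Path, format: str = "bed") -> FeatureSet:
    """Read BED or GFF3 intervals into 0-based half-open FeatureIntervals.

    BED is 0-based half-open already; GFF3 start/end are 1-based closed and
    are converted on read.  For GFF3 the feature ``type`` column is mapped
    onto the category vocabulary where it matches (exon, intron,
    five_prime_utr, three_prime_utr, enhancer); anything else is "other".
    """
    path = Path(path)
    fmt = format.lower()
    if fmt not in ("bed", "gff3"):
        raise ValueError(f"unknown interval format {format!r}")
    intervals: list[FeatureInterval] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            try:
                if fmt == "bed":
                    contig, start, end = cols[0], int(cols[1]), int(cols[2])
                    name = cols[3] if len(cols) > 3 else f"bed_{line_no}"
                    category = cols[6] if len(cols) > 6 else "other"
                else:
                    contig = cols[0]
                    ftype = cols[2]
                    start = int(cols[3]) - 1
                    end = int(cols[4])
                    name = f"{ftype}_{line_no}"
                    for item in cols[8].split(";") if len(cols) > 8 else []:
                        if item.startswith(("ID=", "Name=")):
                            name = item.split("=", 1)[1]
                            break
                    category = ftype.lower() if ftype.lower() in (
                        "exon", "intron", "five_prime_utr", "three_prime_utr", "enhancer"
                    ) else "other"
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path} line {line_no}: malformed record") from exc
            if start >= end:
                raise FormatError(f"{path} line {line_no}: start >= end")
            intervals.append(FeatureInterval(contig, start, end, name, category))
    return FeatureSet(intervals)


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for contig, start, end, name in intervals:
            fh.write(f"{contig}\t{start}\t{end}\t{name}\n")


# ---------------------------------------------------------------------------
# TSV panels and primer tables

def read_panel(path: str | Path, panel_id: str | None = None,
               total_panel_size: int | None = None) -> DiagnosticPanel:
    """Read a diagnostic-SNP panel TSV.

    Expected columns: contig, pos, allele_state1, allele_state2,
    state1_label, state2_label.  Labels must be constant within a file.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["contig", "pos", "allele_state1", "allele_state2",
                "state1_label", "state2_label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df.empty:
        raise FormatError(f"{path}: empty panel")
    labels1 = df["state1_label"].unique()
    labels2 = df["state2_label"].unique()
    if len(labels1) != 1 or len(labels2) != 1:
        raise FormatError(f"{path}: state labels must be constant within a panel")
    snps = [
        PanelSNP(r.contig, int(r.pos), r.allele_state1, r.allele_state2)
        for r in df.itertuples()
    ]
    return DiagnosticPanel(
        panel_id=panel_id or path.stem,
        snps=snps,
        state1_label=str(labels1[0]),
        state2_label=str(labels2[0]),
        total_panel_size=total_panel_size,
    )


def write_panel(panel: DiagnosticPanel, path: str | Path) -> None:
    rows = [
        {
            "contig": s.contig,
            "pos": s.pos,
            "allele_state1": s.state1_allele,
            "allele_state2": s.state2_allele,
            "state1_label": panel.state1_label,
            "state2_label": panel.state2_label,
        }
        for s in panel.snps
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_primers(path: str | Path) -> list[PrimerPair]:
    """Read a primer table TSV with columns marker, forward, reverse[, tm_tag]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["marker", "forward", "reverse"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out = []
    for r in df.itertuples():
        tag = getattr(r, "tm_tag", "") or ""
        out.append(PrimerPair(r.marker, r.forward, r.reverse, str(tag)))
    return out


def write_primers(primers: Iterable[PrimerPair], path: str | Path) -> None:
    rows = [
        {"marker": p.marker, "forward": p.forward, "reverse": p.reverse, "tm_tag": p.annealing_tag}
        for p in primers
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# JSON reports

def write_json(obj: object, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=False, default=_json_default) + "\n")


def _json_default(o: object):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (set, frozenset, tuple)):
        return sorted(o) if isinstance(o, (set, frozenset)) else list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
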