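"""Readers and writers for the pipeline's on-disk formats.

Plain-text formats throughout: BED for the microsatellite panel, TSV for
histograms / exon depth / clipped reads / PCR profiles, VCF (via pysam)
with a TSV mirror for variants, JSON for baselines and truth sidecars.
Writers emit rows in a deterministic order so identical inputs give
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .hypermutation import SomaticVariant
from .mmr_lesions import ClippedRead, Rearrangement
from .msi_ngs import LengthHistogram, LocusBaseline, MicrosatelliteLocus
from .msi_pcr import MarkerProfile

__all__ = [
    "write_panel_bed", "read_panel_bed",
    "write_histograms_tsv", "read_histograms_tsv",
    "write_baseline_json", "read_baseline_json",
    "write_variants_vcf", "read_variants_vcf",
    "write_variants_tsv", "read_variants_tsv",
    "write_clipped_reads_tsv", "read_clipped_reads_tsv",
    "write_pcr_profiles_tsv", "read_pcr_profiles_tsv",
    "write_rearrangements_bedpe",
    "write_truth_json", "read_truth_json",
]


# -- panel BED --------------------------------------------------------

def write_panel_bed(loci: Sequence[MicrosatelliteLocus], path: str | Path) -> None:
    """BED6+2: name=locus_id, score=reference repeat count, then repeat unit."""
    with open(path, "w") as fh:
        for locus in loci:
            fh.write(
                f"{locus.chrom}\t{locus.start}\t{locus.end}\t{locus.locus_id}"
                f"\t{locus.reference_repeat_count}\t+\t{locus.repeat_unit}\n"
            )


def read_panel_bed(path: str | Path) -> list[MicrosatelliteLocus]:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "locus_id", "score", "strand", "unit"],
    )
    return [
        MicrosatelliteLocus(
            locus_id=row.locus_id, chrom=row.chrom, start=int(row.start),
            end=int(row.end), repeat_unit=row.unit,
            reference_repeat_count=int(row.score),
        )
        for row in df.itertuples(index=False)
    ]


# -- repeat-length histograms -----------------------------------------

def write_histograms_tsv(
    histograms: Mapping[str, LengthHistogram], specimen_id: str, path: str | Path
) -> None:
    rows = []
    for locus_id in sorted(histograms):
        hist = histograms[locus_id]
        for length in sorted(hist.counts):
            rows.append((specimen_id, locus_id, length, hist.counts[length]))
    df = pd.DataFrame(
        rows, columns=["specimen_id", "locus_id", "repeat_length", "read_count"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_histograms_tsv(path: str | Path) -> dict[str, LengthHistogram]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, LengthHistogram] = {}
    for locus_id, group in df.groupby("locus_id", sort=True):
        out[str(locus_id)] = LengthHistogram(
            locus_id=str(locus_id),
            counts={
                int(r.repeat_length): int(r.read_count)
                for r in group.itertuples(index=False)
            },
        )
    return out


# -- baselines --------------------------------------------------------

def write_baseline_json(
    baselines: Mapping[str, LocusBaseline], path: str | Path
) -> None:
    payload = {
        locus_id: {
            "mean_allele_count": b.mean_allele_count,
            "sd_allele_count": b.sd_allele_count,
            "n_controls": b.n_controls,
        }
        for locus_id, b in sorted(baselines.items())
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_baseline_json(path: str | Path) -> dict[str, LocusBaseline]:
    payload = json.loads(Path(path).read_text())
    return {
        locus_id: LocusBaseline(locus_id=locus_id, **fields)
        for locus_id, fields in payload.items()
    }


# -- somatic variants -------------------------------------------------

_VCF_INFO = (
    ("VAF", "1", "Float", "Tumor variant allele fraction"),
    ("NAB", "1", "Float", "Max allele balance across germline samples"),
    ("COMMON", "0", "Flag", "Present in common-variant database"),
    ("PALT", "0", "Flag", "Protein-altering consequence"),
    ("CSQ", "1", "String", "Consequence class"),
)


def write_variants_vcf(
    variants: Sequence[SomaticVariant], path: str | Path
) -> None:
    """Write a VCF with VAF/NAB/COMMON/PALT/CSQ INFO keys (1-based POS)."""
    header = pysam.VariantHeader()
    for name, number, vtype, desc in _VCF_INFO:
        header.info.add(name, number, vtype, desc)
    for chrom in sorted({v.chrom for v in variants}):
        header.contigs.add(chrom, length=250_000_000)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            rec = vcf.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            rec.info["VAF"] = v.tumor_vaf
            rec.info["NAB"] = v.normal_allele_balance
            if v.common_variant:
                rec.info["COMMON"] = True
            if v.protein_altering:
                rec.info["PALT"] = True
            if v.consequence:
                rec.info["CSQ"] = v.consequence
            vcf.write(rec)


def read_variants_vcf(path: str | Path) -> list[SomaticVariant]:
    out: list[SomaticVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            out.append(
                SomaticVariant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    tumor_vaf=round(float(rec.info["VAF"]), 4),
                    normal_allele_balance=round(float(rec.info["NAB"]), 4),
                    common_variant="COMMON" in rec.info,
                    protein_altering="PALT" in rec.info,
                    consequence=str(rec.info.get("CSQ", "")),
                )
            )
    return out


_VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "tumor_vaf", "normal_allele_balance",
    "common_variant", "protein_altering", "consequence",
]


def write_variants_tsv(
    variants: Sequence[SomaticVariant], path: str | Path
) -> None:
    df = pd.DataFrame([vars(v) for v in variants], columns=_VARIANT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_variants_tsv(path: str | Path) -> list[SomaticVariant]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        SomaticVariant(
            chrom=str(r.chrom), pos=int(r.pos), ref=str(r.ref), alt=str(r.alt),
            tumor_vaf=float(r.tumor_vaf),
            normal_allele_balance=float(r.normal_allele_balance),
            common_variant=bool(r.common_variant),
            protein_altering=bool(r.protein_altering),
            consequence=str(r.consequence),
        )
        for r in df.itertuples(index=False)
    ]


# -- clipped reads ----------------------------------------------------

_CLIP_COLUMNS = [
    "chrom", "pos", "clip_side", "strand",
    "partner_chrom", "partner_pos", "partner_strand",
]


def write_clipped_reads_tsv(
    reads: Sequence[ClippedRead], path: str | Path
) -> None:
    df = pd.DataFrame([vars(r) for r in reads], columns=_CLIP_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_clipped_reads_tsv(path: str | Path) -> list[ClippedRead]:
    df = pd.read_csv(path, sep="\t")
    return [
        ClippedRead(
            chrom=str(r.chrom), pos=int(r.pos), clip_side=str(r.clip_side),
            strand=str(r.strand), partner_chrom=str(r.partner_chrom),
            partner_pos=int(r.partner_pos), partner_strand=str(r.partner_strand),
        )
        for r in df.itertuples(index=False)
    ]


# -- PCR profiles -----------------------------------------------------

def write_pcr_profiles_tsv(
    profiles: Mapping[str, MarkerProfile], path: str | Path
) -> None:
    rows = []
    for marker in sorted(profiles):
        p = profiles[marker]
        for sample, table in (("tumor", p.tumor), ("normal", p.normal)):
            for length in sorted(table):
                rows.append((marker, sample, length, table[length]))
    df = pd.DataFrame(rows, columns=["marker", "sample", "length", "intensity"])
    df.to_csv(path, sep="\t", index=False)


def read_pcr_profiles_tsv(path: str | Path) -> dict[str, MarkerProfile]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, MarkerProfile] = {}
    for marker, group in df.groupby("marker", sort=True):
        tables: dict[str, dict[int, float]] = {"tumor": {}, "normal": {}}
        for r in group.itertuples(index=False):
            tables[str(r.sample)][int(r.length)] = float(r.intensity)
        out[str(marker)] = MarkerProfile(
            marker=str(marker), tumor=tables["tumor"], normal=tables["normal"]
        )
    return out


# -- rearrangements ---------------------------------------------------

def write_rearrangements_bedpe(
    rearrangements: Sequence[Rearrangement], path: str | Path
) -> None:
    """BEDPE: both breakpoints as 1-bp intervals, name=type, score=support."""
    with open(path, "w") as fh:
        for r in rearrangements:
            fh.write(
                f"{r.bp1.chrom}\t{r.bp1.pos}\t{r.bp1.pos + 1}"
                f"\t{r.bp2.chrom}\t{r.bp2.pos}\t{r.bp2.pos + 1}"
                f"\t{r.type}\t{r.n_support}\t.\t.\t{','.join(r.genes_hit) or '.'}\n"
            )


# -- truth sidecars ---------------------------------------------------

def write_truth_json(truth, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(truth.to_dict(), indent=1, sort_keys=True) + "\n"
    )


def read_truth_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
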