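"""Minimal exon-level gene model for the mismatch-repair genes.

Gene spans follow hg19 locations of MSH2 and MSH6 (chr2) and MLH1 (chr3);
the per-exon intervals are SYNTHETIC — evenly spaced boxes inside the gene
span, adequate for exon-indexed copy-number calling and for locating
planted lesions, not for annotating real alignments.

Also hosts the homopolymer-tract catalog used to set aside mosaic MSH6
frameshifts (poly-G tract in exon 5, c.3261; poly-A tract in exon 7,
c.3573) that arise as a downstream consequence of MSI rather than as
driver lesions.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "Exon",
    "Gene",
    "GeneModel",
    "Tract",
    "default_mmr_model",
    "msi_artifact_catalog",
]


@dataclass(frozen=True)
class Exon:
    index: int  # 1-based exon number
    chrom: str
    start: int  # 0-based half-open
    end: int


@dataclass(frozen=True)
class Gene:
    name: str
    chrom: str
    start: int
    end: int
    exons: tuple[Exon, ...]

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class Tract:
    """A homopolymer tract whose indels are treated as MSI artifacts."""

    label: str
    gene: str
    chrom: str
    start: int
    end: int

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


class GeneModel:
    """Lookup container for a handful of genes with exon intervals."""

    def __init__(self, genes: dict[str, Gene]):
        self.genes = genes

    def __contains__(self, name: str) -> bool:
        return name in self.genes

    def __getitem__(self, name: str) -> Gene:
        return self.genes[name]

    def genes_at(self, chrom: str, pos: int) -> list[str]:
        return [g.name for g in self.genes.values() if g.contains(chrom, pos)]


def _make_gene(name: str, chrom: str, start: int, end: int, n_exons: int) -> Gene:
    exon_len = 200
    gap = (end - start - n_exons * exon_len) // max(n_exons - 1, 1)
    exons = tuple(
        Exon(
            index=i + 1,
            chrom=chrom,
            start=start + i * (exon_len + gap),
            end=start + i * (exon_len + gap) + exon_len,
        )
        for i in range(n_exons)
    )
    return Gene(name=name, chrom=chrom, start=start, end=end, exons=exons)


def default_mmr_model() -> GeneModel:
    """MSH2 (16 exons), MSH6 (10 exons) and MLH1 (19 exons), hg19-like spans."""
    genes = {
        "MSH2": _make_gene("MSH2", "chr2", 47_630_206, 47_710_367, 16),
        "MSH6": _make_gene("MSH6", "chr2", 48_010_221, 48_034_092, 10),
        "MLH1": _make_gene("MLH1", "chr3", 37_034_841, 37_092_337, 19),
    }
    return GeneModel(genes)


def msi_artifact_catalog(model: GeneModel | None = None) -> tuple[Tract, ...]:
    """Homopolymer tracts inside MSH6 exons 5 and 7 (mosaic-frameshift sites)."""
    model = model or default_mmr_model()
    msh6 = model["MSH6"]
    exon5 = msh6.exons[4]
    exon7 = msh6.exons[6]
    return (
        Tract(
            label="MSH6_exon5_polyG_c.3261",
            gene="MSH6",
            chrom=exon5.chrom,
            start=exon5.start + 90,
            end=exon5.start + 100,
        ),
        Tract(
            label="MSH6_exon7_polyA_c.3573",
            gene="MSH6",
            chrom=exon7.chrom,
            start=exon7.start + 90,
            end=exon7.start + 100,
        ),
    )
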