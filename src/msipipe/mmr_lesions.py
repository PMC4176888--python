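"""Mismatch-repair gene lesion detection and bi-allelic inactivation calls.

Three evidence streams are integrated per gene:

* truncating small variants (frameshift/nonsense) from the somatic table,
  after setting aside known homopolymer-tract mosaic frameshifts that are
  a consequence of MSI rather than a cause;
* structural rearrangements reconstructed from clipped-read (split-read)
  evidence by clustering clip points and pairing clusters through their
  partner coordinates;
* exon-level copy-number losses from capture depth ratios, merged into
  contiguous segments ("exon i-j del").

A gene with a homozygous copy loss, or with two or more distinct
inactivating events, is called bi-allelically inactivated — the state that
abolishes mismatch repair and licenses hypermutation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd

from .genemodel import GeneModel, Tract, default_mmr_model, msi_artifact_catalog
from .hypermutation import SomaticVariant

__all__ = [
    "ClippedRead",
    "Breakpoint",
    "Rearrangement",
    "ExonCall",
    "CnvSegment",
    "LesionEvent",
    "GeneLesionSet",
    "cluster_breakpoints",
    "call_exon_cnv",
    "exclude_msi_artifacts",
    "assess_biallelic",
    "call_gene_lesions",
    "DEFAULT_MIN_SUPPORT",
    "DEFAULT_WINDOW",
    "DEFAULT_LOSS_MAX",
    "DEFAULT_HOMOZYGOUS_MAX",
    "DEFAULT_MIN_CONSECUTIVE",
]

#: minimum clipped reads supporting each breakpoint of an emitted rearrangement
DEFAULT_MIN_SUPPORT = 4
#: clip points within this many bp merge into one breakpoint cluster
DEFAULT_WINDOW = 10
#: depth ratio at or below this is a (heterozygous) loss
DEFAULT_LOSS_MAX = 0.70
#: depth ratio at or below this is a homozygous loss
DEFAULT_HOMOZYGOUS_MAX = 0.15
#: minimum run of like-state exons merged into a reported segment
DEFAULT_MIN_CONSECUTIVE = 2

RearrangementType = Literal["inversion", "deletion", "translocation", "tandem-dup"]
ExonState = Literal["neutral", "loss", "homozygous-loss"]
Zygosity = Literal["biallelic", "monoallelic", "none"]


@dataclass(frozen=True)
class ClippedRead:
    """Minimal split-read evidence: where a read is clipped and where the
    clipped sequence maps (the partner breakpoint)."""

    chrom: str
    pos: int  # 0-based clip point
    clip_side: Literal["left", "right"]
    strand: Literal["+", "-"]
    partner_chrom: str
    partner_pos: int
    partner_strand: Literal["+", "-"]

    def __post_init__(self) -> None:
        if self.pos < 0 or self.partner_pos < 0:
            raise ValueError("positions must be >= 0")


@dataclass(frozen=True)
class Breakpoint:
    chrom: str
    pos: int
    clip_side: str


@dataclass(frozen=True)
class Rearrangement:
    bp1: Breakpoint
    bp2: Breakpoint
    type: RearrangementType
    n_support: int
    genes_hit: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        inter = self.bp1.chrom != self.bp2.chrom
        if inter != (self.type == "translocation"):
            raise ValueError("translocation iff breakpoints on different chromosomes")


@dataclass(frozen=True)
class ExonCall:
    gene: str
    exon: int
    depth_ratio: float
    state: ExonState


@dataclass(frozen=True)
class CnvSegment:
    gene: str
    exon_start: int  # 1-based exon indices, inclusive
    exon_end: int
    state: ExonState

    @property
    def label(self) -> str:
        kind = "homozygous del" if self.state == "homozygous-loss" else "del"
        return f"{self.gene} exon {self.exon_start}-{self.exon_end} {kind}"


@dataclass(frozen=True)
class LesionEvent:
    kind: Literal[
        "frameshift", "nonsense", "rearrangement", "copy-loss", "homozygous-loss"
    ]
    description: str


@dataclass
class GeneLesionSet:
    gene: str
    events: list[LesionEvent]
    zygosity_verdict: Zygosity


@dataclass
class _Cluster:
    chrom: str
    clip_side: str
    positions: list[int]
    partner: list[tuple[str, int, str]]
    strands: list[str]

    @property
    def support(self) -> int:
        return len(self.positions)

    @property
    def pos(self) -> int:
        # modal clip point; ties resolved toward the smaller coordinate
        counts = Counter(self.positions)
        best = max(counts.values())
        return min(p for p, c in counts.items() if c == best)

    @property
    def partner_modal(self) -> tuple[str, int, str]:
        chrom = Counter(p[0] for p in self.partner).most_common(1)[0][0]
        positions = [p[1] for p in self.partner if p[0] == chrom]
        counts = Counter(positions)
        best = max(counts.values())
        pos = min(p for p, c in counts.items() if c == best)
        strand = Counter(p[2] for p in self.partner).most_common(1)[0][0]
        return chrom, pos, strand


def _build_clusters(reads: Iterable[ClippedRead], window: int) -> list[_Cluster]:
    by_key: dict[tuple[str, str], list[ClippedRead]] = {}
    for r in reads:
        by_key.setdefault((r.chrom, r.clip_side), []).append(r)
    clusters: list[_Cluster] = []
    for (chrom, side), group in sorted(by_key.items()):
        group.sort(key=lambda r: r.pos)
        current: list[ClippedRead] = []
        for r in group:
            if current and r.pos - current[-1].pos > window:
                clusters.append(_finish(chrom, side, current))
                current = []
            current.append(r)
        if current:
            clusters.append(_finish(chrom, side, current))
    return clusters


def _finish(chrom: str, side: str, reads: list[ClippedRead]) -> _Cluster:
    return _Cluster(
        chrom=chrom,
        clip_side=side,
        positions=[r.pos for r in reads],
        partner=[(r.partner_chrom, r.partner_pos, r.partner_strand) for r in reads],
        strands=[r.strand for r in reads],
    )


def _classify(a: _Cluster, b: _Cluster) -> RearrangementType:
    if a.chrom != b.chrom:
        return "translocation"
    if a.clip_side == b.clip_side:
        return "inversion"
    low, high = (a, b) if a.pos <= b.pos else (b, a)
    return "deletion" if low.clip_side == "right" else "tandem-dup"


def cluster_breakpoints(
    reads: Sequence[ClippedRead],
    min_support: int = DEFAULT_MIN_SUPPORT,
    window: int = DEFAULT_WINDOW,
    gene_model: GeneModel | None = None,
) -> list[Rearrangement]:
    """Reconstruct rearrangements from clipped-read evidence.

    Clip points on the same chromosome and clip side within ``window`` bp
    form a cluster whose breakpoint is the modal clip point.  Two clusters
    are paired when each one's modal partner coordinate falls within
    ``window`` of the other's breakpoint; only reciprocally supported pairs
    with at least ``min_support`` reads on *both* sides are emitted.
    ``n_support`` is the weaker side's read count.
    """
    clusters = _build_clusters(reads, window)
    used = [False] * len(clusters)
    out: list[Rearrangement] = []
    for i, a in enumerate(clusters):
        if used[i] or a.support < min_support:
            continue
        pa_chrom, pa_pos, _ = a.partner_modal
        for j in range(i + 1, len(clusters)):
            b = clusters[j]
            if used[j] or b.support < min_support:
                continue
            pb_chrom, pb_pos, _ = b.partner_modal
            if (
                b.chrom == pa_chrom
                and abs(b.pos - pa_pos) <= window
                and a.chrom == pb_chrom
                and abs(a.pos - pb_pos) <= window
            ):
                used[i] = used[j] = True
                first, second = sorted(
                    (a, b), key=lambda c: (c.chrom, c.pos, c.clip_side)
                )
                bp1 = Breakpoint(first.chrom, first.pos, first.clip_side)
                bp2 = Breakpoint(second.chrom, second.pos, second.clip_side)
                genes: tuple[str, ...] = ()
                if gene_model is not None:
                    hit = set(gene_model.genes_at(bp1.chrom, bp1.pos))
                    hit |= set(gene_model.genes_at(bp2.chrom, bp2.pos))
                    genes = tuple(sorted(hit))
                out.append(
                    Rearrangement(
                        bp1=bp1,
                        bp2=bp2,
                        type=_classify(a, b),
                        n_support=min(a.support, b.support),
                        genes_hit=genes,
                    )
                )
                break
    out.sort(key=lambda r: (r.bp1.chrom, r.bp1.pos, r.bp2.chrom, r.bp2.pos))
    return out


def call_exon_cnv(
    depth_ratios: pd.DataFrame,
    loss_max: float = DEFAULT_LOSS_MAX,
    homozygous_max: float = DEFAULT_HOMOZYGOUS_MAX,
    min_consecutive: int = DEFAULT_MIN_CONSECUTIVE,
) -> tuple[list[ExonCall], list[CnvSegment]]:
    """Call per-exon copy state from depth ratios and merge loss segments.

    ``depth_ratios`` needs columns ``gene``, ``exon`` (1-based index) and
    ``depth_ratio`` (tumor/normal normalized depth).  Exon state is
    homozygous-loss at ratio <= ``homozygous_max``, loss at ratio <=
    ``loss_max``, neutral otherwise.  Runs of at least ``min_consecutive``
    consecutive like-state exons merge into reported segments; the calls
    and segments are invariant to input row order.
    """
    if (depth_ratios["depth_ratio"] < 0).any():
        raise ValueError("depth ratios must be >= 0")
    df = depth_ratios.sort_values(["gene", "exon"], kind="mergesort")
    calls: list[ExonCall] = []
    for row in df.itertuples(index=False):
        ratio = float(row.depth_ratio)
        if ratio <= homozygous_max:
            state: ExonState = "homozygous-loss"
        elif ratio <= loss_max:
            state = "loss"
        else:
            state = "neutral"
        calls.append(ExonCall(gene=str(row.gene), exon=int(row.exon),
                              depth_ratio=ratio, state=state))
    segments: list[CnvSegment] = []
    run: list[ExonCall] = []
    for call in calls + [ExonCall("", -1, 0.0, "neutral")]:  # sentinel flush
        if (
            run
            and call.gene == run[-1].gene
            and call.state == run[-1].state
            and call.exon == run[-1].exon + 1
        ):
            run.append(call)
            continue
        if run and run[0].state != "neutral" and len(run) >= min_consecutive:
            segments.append(
                CnvSegment(
                    gene=run[0].gene,
                    exon_start=run[0].exon,
                    exon_end=run[-1].exon,
                    state=run[0].state,
                )
            )
        run = [call]
    return calls, segments


def exclude_msi_artifacts(
    variants: Iterable[SomaticVariant],
    artifact_catalog: Sequence[Tract] | None = None,
) -> tuple[list[SomaticVariant], list[SomaticVariant]]:
    """Partition variants into (retained, artifacts).

    Variants inside a cataloged homopolymer tract are presumed MSI-driven
    mosaic events and never count toward zygosity.  The exclusion is
    catalog-based and independent of the specimen's MSI status.
    """
    catalog = msi_artifact_catalog() if artifact_catalog is None else artifact_catalog
    retained: list[SomaticVariant] = []
    artifacts: list[SomaticVariant] = []
    for v in variants:
        # VCF-style positions are 1-based; tracts are 0-based half-open
        if any(t.contains(v.chrom, v.pos - 1) for t in catalog):
            artifacts.append(v)
        else:
            retained.append(v)
    return retained, artifacts


def assess_biallelic(events: Sequence[LesionEvent]) -> Zygosity:
    """Zygosity verdict: homozygous loss alone is bi-allelic; otherwise two
    or more distinct inactivating events are required."""
    distinct = list(dict.fromkeys(events))  # de-duplicate, order-preserving
    if any(e.kind == "homozygous-loss" for e in distinct):
        return "biallelic"
    if len(distinct) >= 2:
        return "biallelic"
    if len(distinct) == 1:
        return "monoallelic"
    return "none"


TRUNCATING = ("frameshift", "nonsense")


def call_gene_lesions(
    gene: str,
    variants: Sequence[SomaticVariant],
    rearrangements: Sequence[Rearrangement] = (),
    segments: Sequence[CnvSegment] = (),
    gene_model: GeneModel | None = None,
    artifact_catalog: Sequence[Tract] | None = None,
) -> GeneLesionSet:
    """Integrate all evidence for one gene into a GeneLesionSet.

    Counts truncating small variants inside the gene (after artifact-tract
    exclusion), rearrangements with at least one breakpoint inside the gene
    (each rearrangement counted once even when both breakpoints hit), and
    copy-loss segments overlapping the gene.
    """
    model = gene_model or default_mmr_model()
    g = model[gene]
    retained, _ = exclude_msi_artifacts(variants, artifact_catalog)
    events: list[LesionEvent] = []
    for v in retained:
        if v.consequence in TRUNCATING and g.contains(v.chrom, v.pos - 1):
            events.append(
                LesionEvent(kind=v.consequence,
                            description=f"{v.chrom}:{v.pos}:{v.ref}>{v.alt}")
            )
    for r in rearrangements:
        if g.contains(r.bp1.chrom, r.bp1.pos) or g.contains(r.bp2.chrom, r.bp2.pos):
            events.append(
                LesionEvent(
                    kind="rearrangement",
                    description=(
                        f"{r.type} {r.bp1.chrom}:{r.bp1.pos}-"
                        f"{r.bp2.chrom}:{r.bp2.pos}"
                    ),
                )
            )
    for s in segments:
        if s.gene != gene:
            continue
        kind = "homozygous-loss" if s.state == "homozygous-loss" else "copy-loss"
        events.append(LesionEvent(kind=kind, description=s.label))
    events = list(dict.fromkeys(events))
    return GeneLesionSet(gene=gene, events=events,
                         zygosity_verdict=assess_biallelic(events))
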