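"""Synthetic-data generator for the whole pipeline.

Emits every input the callers consume, with the statistical structure the
analysis assumes, plus a truth sidecar for oracle comparison:

* per-locus repeat-length read histograms with geometric PCR-stutter noise,
  and extra shifted allele modes at destabilized loci in MMR-deficient
  specimens;
* somatic variant tables with the planted protein-altering burden plus
  germline and low-VAF contaminant records that the somatic filters must
  remove;
* clipped-read (split-read) evidence at planted rearrangement breakpoints;
* per-exon capture depth ratios with planted heterozygous (~0.5) and
  homozygous (~0.03) copy losses;
* five-marker PCR fragment-length profiles with planted novel alleles;
* cohort fixtures mirroring the study design: 15 PDX lines (3 hypermutated)
  and 50 rapid-autopsy patients (5 hypermutated) with 5 PDX lines derived
  from autopsy patients, one of them hypermutated in both cohorts.

All randomness flows from ``SimulationConfig.seed`` plus stable per-entity
hashes, so identical seed and config reproduce byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .genemodel import GeneModel, default_mmr_model, msi_artifact_catalog
from .hypermutation import SomaticVariant
from .mmr_lesions import ClippedRead
from .msi_ngs import LengthHistogram, MicrosatelliteLocus
from .msi_pcr import PROMEGA_MARKERS, MarkerProfile

__all__ = [
    "SimulationConfig",
    "SpecimenTruth",
    "LesionSpec",
    "SpecimenData",
    "PatientSpec",
    "CohortData",
    "stutter_pmf",
    "make_panel",
    "simulate_locus_histogram",
    "simulate_specimen",
    "simulate_controls",
    "simulate_pcr_profile",
    "simulate_marker_panel",
    "simulate_cohort",
    "paper_cohort",
    "LUCAP58_UNSTABLE_MARKERS",
    "MARKER_REF_LENGTH",
]

#: markers with planted instability in the LuCaP 58 PCR fixture
LUCAP58_UNSTABLE_MARKERS = ("MONO-27", "BAT-25", "NR-24")

#: modal fragment length (in length units) of each marker's normal profile
MARKER_REF_LENGTH = {
    "NR-21": 103,
    "BAT-26": 116,
    "BAT-25": 124,
    "NR-24": 132,
    "MONO-27": 142,
}


def _crc(text: str) -> int:
    return zlib.crc32(text.encode()) & 0x7FFFFFFF


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults are the study conditions simulated.

    ``stutter_prob`` is the per-replication probability that a read's
    observed repeat length slips one unit shorter; repeated slips give the
    geometric tail.  ``msi_locus_fraction`` of panel loci are destabilized
    in an MMR-deficient specimen, each gaining 1-2 extra allele modes
    shifted ``1 + Poisson(msi_shift_mean)`` units below the reference.
    ``contamination_germline_rate`` is the germline fraction among injected
    contaminant variant records (the remainder are low-VAF artifacts).
    """

    seed: int = 0
    n_loci: int = 146
    depth_mean: float = 200.0
    stutter_prob: float = 0.10
    msi_locus_fraction: float = 0.5
    msi_shift_mean: float = 1.0
    contamination_germline_rate: float = 0.30

    def __post_init__(self) -> None:
        for name in ("stutter_prob", "msi_locus_fraction",
                     "contamination_germline_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if self.seed < 0:
            raise ValueError("seed must be >= 0")
        if self.msi_shift_mean < 0:
            raise ValueError("msi_shift_mean must be >= 0")


@dataclass(frozen=True)
class LesionSpec:
    """A planted MMR-gene event with exact coordinates.

    ``sites`` restricts the lesion to named tumor sites of a patient;
    empty means present at every site.
    """

    kind: Literal["frameshift", "rearrangement", "copy_loss"]
    gene: str
    label: str
    pos_offset: int = 0                      # frameshift: offset into gene span
    sv_type: str = ""                        # rearrangement type
    bp1: tuple[str, int] | None = None       # (chrom, 0-based pos)
    bp2: tuple[str, int] | None = None
    exon_start: int = 0                      # copy loss: 1-based inclusive
    exon_end: int = 0
    zygosity: Literal["het", "hom"] = "het"
    sites: tuple[str, ...] = ()


@dataclass(frozen=True)
class SpecimenTruth:
    specimen_id: str
    msi_status: Literal["MSI-high", "MSS"]
    hypermutated: bool
    true_burden: int
    lesions: tuple[LesionSpec, ...] = ()
    destabilized_loci: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "specimen_id": self.specimen_id,
            "msi_status": self.msi_status,
            "hypermutated": self.hypermutated,
            "true_burden": self.true_burden,
            "lesions": [l.label for l in self.lesions],
            "destabilized_loci": list(self.destabilized_loci),
        }


@dataclass
class SpecimenData:
    """Everything the pipeline consumes for one specimen, plus truth."""

    truth: SpecimenTruth
    histograms: dict[str, LengthHistogram]
    variants: list[SomaticVariant]
    exon_depth: pd.DataFrame
    clipped_reads: list[ClippedRead]


def stutter_pmf(stutter_prob: float, max_k: int) -> np.ndarray:
    """P(read slips k units), k = 0..max_k: geometric (1-p) p^k with the
    truncated tail folded into the last bin so the mass sums to one."""
    p = stutter_prob
    pmf = np.array([(1.0 - p) * p**k for k in range(max_k + 1)])
    pmf[-1] += 1.0 - pmf.sum()
    return pmf


def make_panel(n_loci: int = 146) -> list[MicrosatelliteLocus]:
    """Deterministic mononucleotide panel: ``n_loci`` A/T runs of 12-27
    units spread over several chromosomes."""
    loci = []
    chroms = ["chr1", "chr2", "chr3", "chr5", "chr11", "chr13", "chr17", "chr19"]
    for i in range(n_loci):
        repeat = 12 + i % 16
        chrom = chroms[i % len(chroms)]
        start = 10_000_000 + (i // len(chroms)) * 100_000
        loci.append(
            MicrosatelliteLocus(
                locus_id=f"MSI_{i + 1:04d}",
                chrom=chrom,
                start=start,
                end=start + repeat,
                repeat_unit="A" if i % 2 == 0 else "T",
                reference_repeat_count=repeat,
            )
        )
    return loci


def _draw_unstable_modes(
    ref_len: int, config: SimulationConfig, rng: np.random.Generator
) -> list[tuple[int, float]]:
    """Allele modes of a destabilized locus: the reference allele keeps half
    the mass; 1-2 shifted modes at reference - (1 + Poisson) share the rest."""
    n_modes = 1 + int(rng.random() < 0.5)
    shifts = sorted({1 + int(rng.poisson(config.msi_shift_mean))
                     for _ in range(n_modes)})
    weight = 0.5 / len(shifts)
    modes = [(ref_len, 0.5)]
    modes += [(max(ref_len - k, 1), weight) for k in shifts]
    return modes


def simulate_locus_histogram(
    locus: MicrosatelliteLocus,
    unstable: bool,
    depth: int,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> LengthHistogram:
    """Draw a read-length histogram for one locus.

    Stable loci concentrate mass at the reference length with the
    geometric one-directional stutter tail; unstable loci additionally
    carry shifted allele modes.  Histogram mass equals ``depth`` exactly.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng([config.seed, _crc(locus.locus_id)]) if rng is None else rng
    if depth == 0:
        return LengthHistogram(locus_id=locus.locus_id, counts={})
    ref = locus.reference_repeat_count
    modes = (
        _draw_unstable_modes(ref, config, rng)
        if unstable
        else [(ref, 1.0)]
    )
    max_k = max(ref - 1, 1)
    slip = stutter_pmf(config.stutter_prob, max_k)
    prob: dict[int, float] = {}
    for length, weight in modes:
        for k in range(min(max_k, length - 1) + 1):
            obs = length - k
            prob[obs] = prob.get(obs, 0.0) + weight * slip[k]
        # fold any truncated mass onto length 1
        residual = weight - weight * slip[: min(max_k, length - 1) + 1].sum()
        if residual > 0:
            prob[1] = prob.get(1, 0.0) + residual
    lengths = sorted(prob)
    probs = np.array([prob[l] for l in lengths])
    probs = probs / probs.sum()
    draws = rng.multinomial(depth, probs)
    counts = {l: int(c) for l, c in zip(lengths, draws) if c > 0}
    return LengthHistogram(locus_id=locus.locus_id, counts=counts)


def _lesions_at_site(truth: SpecimenTruth, site: str | None) -> list[LesionSpec]:
    if site is None:
        return list(truth.lesions)
    return [l for l in truth.lesions if not l.sites or site in l.sites]


_SV_CLIP_SIDES = {
    "inversion": ("right", "right"),
    "deletion": ("right", "left"),
    "tandem-dup": ("left", "right"),
    "translocation": ("right", "left"),
}


def _rearrangement_reads(
    lesion: LesionSpec,
    n_support: int,
    jitter: int,
    rng: np.random.Generator,
) -> list[ClippedRead]:
    assert lesion.bp1 is not None and lesion.bp2 is not None
    (c1, p1), (c2, p2) = sorted([lesion.bp1, lesion.bp2])
    side1, side2 = _SV_CLIP_SIDES[lesion.sv_type]
    strand1, strand2 = ("+", "+") if lesion.sv_type == "inversion" else ("+", "-")
    reads: list[ClippedRead] = []
    for _ in range(n_support):
        off = int(rng.integers(-jitter, jitter + 1)) if jitter > 0 else 0
        reads.append(ClippedRead(c1, p1 + off, side1, strand1, c2, p2, strand2))
    for _ in range(n_support):
        off = int(rng.integers(-jitter, jitter + 1)) if jitter > 0 else 0
        reads.append(ClippedRead(c2, p2 + off, side2, strand2, c1, p1, strand1))
    return reads


def _variant(
    chrom: str, pos: int, rng: np.random.Generator,
    vaf: float, nab: float, common: bool, palt: bool, consequence: str,
) -> SomaticVariant:
    bases = "ACGT"
    ref = bases[int(rng.integers(4))]
    alt = bases[(bases.index(ref) + 1 + int(rng.integers(3))) % 4]
    if consequence == "frameshift":
        ref, alt = ref, ref + alt  # 1-bp insertion representation
    return SomaticVariant(
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        tumor_vaf=round(vaf, 4), normal_allele_balance=round(nab, 4),
        common_variant=common, protein_altering=palt, consequence=consequence,
    )


def simulate_specimen(
    truth: SpecimenTruth,
    panel: Sequence[MicrosatelliteLocus],
    config: SimulationConfig,
    gene_model: GeneModel | None = None,
    site: str | None = None,
    n_support: int = 12,
    breakpoint_jitter: int = 0,
) -> SpecimenData:
    """Emit all pipeline inputs for one specimen, consistent with truth.

    MSI-high specimens destabilize exactly ``round(msi_locus_fraction *
    n_loci)`` loci (recorded in the returned truth sidecar).  The variant
    table carries exactly ``true_burden`` protein-altering somatic records
    that pass the somatic filters, plus contaminants built to be removed:
    germline records with normal allele balance drawn at or above 0.40, and
    low-VAF artifacts below the 10% threshold.  In MSI-high specimens
    mosaic homopolymer-tract frameshifts are injected at low VAF.  Planted
    rearrangements produce reciprocal clipped-read clusters; planted copy
    losses pull exon depth ratios to ~0.5 (het) or ~0.03 (hom).
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    model = gene_model or default_mmr_model()
    lesions = _lesions_at_site(truth, site)
    for lesion in lesions:
        if lesion.gene and lesion.gene not in model:
            raise ValueError(f"lesion gene {lesion.gene!r} absent from gene model")
    truth = replace(truth, lesions=tuple(lesions))
    rng = np.random.default_rng([config.seed, _crc(truth.specimen_id)])

    # -- microsatellite histograms -------------------------------------
    if truth.msi_status == "MSI-high":
        if truth.destabilized_loci:
            destabilized = set(truth.destabilized_loci)
        else:
            n_unstable = round(config.msi_locus_fraction * len(panel))
            picked = rng.choice(len(panel), size=n_unstable, replace=False)
            destabilized = {panel[i].locus_id for i in sorted(picked)}
    else:
        destabilized = set()
    truth = replace(truth, destabilized_loci=tuple(sorted(destabilized)))
    histograms: dict[str, LengthHistogram] = {}
    for locus in panel:
        depth = int(rng.poisson(config.depth_mean))
        histograms[locus.locus_id] = simulate_locus_histogram(
            locus, locus.locus_id in destabilized, depth, config, rng
        )

    # -- somatic variant table -----------------------------------------
    variants: list[SomaticVariant] = []
    fs_lesions = [l for l in lesions if l.kind == "frameshift"]
    if truth.true_burden < len(fs_lesions):
        raise ValueError("true_burden smaller than planted frameshift count")
    for lesion in fs_lesions:
        gene = model[lesion.gene]
        # alleles derived from the lesion label so the same planted event is
        # byte-identical at every tumor site of a patient
        h = _crc(lesion.label)
        ref = "ACGT"[h % 4]
        variants.append(
            SomaticVariant(
                chrom=gene.chrom, pos=gene.start + lesion.pos_offset + 1,
                ref=ref, alt=ref + "ACGT"[(h >> 2) % 4],
                tumor_vaf=round(rng.uniform(0.20, 0.50), 4),
                normal_allele_balance=round(rng.uniform(0.0, 0.05), 4),
                common_variant=False, protein_altering=True,
                consequence="frameshift",
            )
        )
    n_background = truth.true_burden - len(fs_lesions)
    for _ in range(n_background):
        chrom = f"chr{int(rng.integers(1, 23))}"
        pos = int(rng.integers(1_000_000, 200_000_000))
        variants.append(
            _variant(chrom, pos, rng,
                     vaf=rng.uniform(0.15, 0.60), nab=rng.uniform(0.0, 0.05),
                     common=False, palt=True, consequence="missense")
        )
    if truth.msi_status == "MSI-high":
        # mosaic MSI-driven frameshifts in cataloged homopolymer tracts,
        # subclonal (low VAF) so the burden filter removes them
        for tract in msi_artifact_catalog(model):
            variants.append(
                _variant(tract.chrom, tract.start + 6, rng,
                         vaf=rng.uniform(0.02, 0.08), nab=rng.uniform(0.0, 0.05),
                         common=False, palt=True, consequence="frameshift")
            )
    n_contaminants = max(3, round(0.5 * truth.true_burden))
    n_germline = round(config.contamination_germline_rate * n_contaminants)
    for i in range(n_contaminants):
        chrom = f"chr{int(rng.integers(1, 23))}"
        pos = int(rng.integers(1_000_000, 200_000_000))
        if i < n_germline:
            variants.append(
                _variant(chrom, pos, rng,
                         vaf=rng.uniform(0.30, 0.70),
                         nab=rng.uniform(0.40, 0.60),
                         common=bool(rng.random() < 0.7),
                         palt=bool(rng.random() < 0.6),
                         consequence="missense")
            )
        else:
            variants.append(
                _variant(chrom, pos, rng,
                         vaf=rng.uniform(0.01, 0.095),
                         nab=rng.uniform(0.0, 0.05),
                         common=False, palt=True, consequence="missense")
            )

    # -- exon depth ratios ---------------------------------------------
    loss_by_exon: dict[tuple[str, int], str] = {}
    for lesion in lesions:
        if lesion.kind != "copy_loss":
            continue
        for exon_idx in range(lesion.exon_start, lesion.exon_end + 1):
            loss_by_exon[(lesion.gene, exon_idx)] = lesion.zygosity
    rows = []
    for gene in model.genes.values():
        for exon in gene.exons:
            zyg = loss_by_exon.get((gene.name, exon.index))
            if zyg == "hom":
                ratio = max(0.0, rng.normal(0.03, 0.008))
            elif zyg == "het":
                ratio = max(0.0, rng.normal(0.50, 0.04))
            else:
                ratio = max(0.0, rng.normal(1.00, 0.04))
            rows.append(
                {"gene": gene.name, "exon": exon.index, "chrom": exon.chrom,
                 "start": exon.start, "end": exon.end,
                 "depth_ratio": round(ratio, 4)}
            )
    exon_depth = pd.DataFrame(rows)

    # -- clipped-read evidence -----------------------------------------
    clipped: list[ClippedRead] = []
    for lesion in lesions:
        if lesion.kind == "rearrangement":
            clipped.extend(
                _rearrangement_reads(lesion, n_support, breakpoint_jitter, rng)
            )

    return SpecimenData(
        truth=truth,
        histograms=histograms,
        variants=variants,
        exon_depth=exon_depth,
        clipped_reads=clipped,
    )


def simulate_controls(
    panel: Sequence[MicrosatelliteLocus],
    config: SimulationConfig,
    n_controls: int = 10,
) -> list[dict[str, LengthHistogram]]:
    """Simulate normal-control specimens (all loci stable) for baselines."""
    controls = []
    for i in range(n_controls):
        rng = np.random.default_rng([config.seed, _crc(f"control_{i:03d}")])
        control = {}
        for locus in panel:
            depth = int(rng.poisson(config.depth_mean))
            control[locus.locus_id] = simulate_locus_histogram(
                locus, False, depth, config, rng
            )
        controls.append(control)
    return controls


# ---------------------------------------------------------------------
# PCR fragment profiles
# ---------------------------------------------------------------------

#: relative stutter-ladder intensities at mode, mode-1, mode-2, mode-3
_PCR_LADDER = (1000.0, 250.0, 60.0, 15.0)


def _pcr_shape(mode: int, scale: float, rng: np.random.Generator) -> dict[int, float]:
    shape = {}
    for k, base in enumerate(_PCR_LADDER):
        inten = scale * base * max(0.0, 1.0 + rng.normal(0.0, 0.05))
        shape[mode - k] = shape.get(mode - k, 0.0) + round(inten, 2)
    return shape


def simulate_pcr_profile(
    marker: str,
    unstable: bool,
    seed: int,
    shift: int | None = None,
) -> tuple[MarkerProfile, int | None]:
    """Simulate one marker's tumor/normal fragment profiles.

    Stable markers give tumor and normal the same modal length (independent
    intensity noise).  Unstable markers mix in a tumor allele shifted
    ``shift`` (default: 5-8, drawn) units below the normal mode — beyond
    stutter range, so the caller must flag it.  Returns the profile and the
    planted shift (None when stable) as the truth sidecar.
    """
    if marker not in MARKER_REF_LENGTH:
        raise ValueError(f"unknown marker {marker!r}")
    rng = np.random.default_rng([seed, _crc(marker)])
    ref = MARKER_REF_LENGTH[marker]
    normal = _pcr_shape(ref, 1.0, rng)
    if not unstable:
        return MarkerProfile(marker=marker, tumor=_pcr_shape(ref, 1.0, rng),
                             normal=normal), None
    planted = int(rng.integers(5, 9)) if shift is None else int(shift)
    tumor = _pcr_shape(ref, 0.5, rng)
    for length, inten in _pcr_shape(ref - planted, 0.5, rng).items():
        tumor[length] = tumor.get(length, 0.0) + inten
    return MarkerProfile(marker=marker, tumor=tumor, normal=normal), planted


def simulate_marker_panel(
    unstable_markers: Iterable[str], seed: int
) -> tuple[dict[str, MarkerProfile], dict[str, int | None]]:
    """Simulate all five markers; returns profiles and planted-shift truth."""
    unstable = set(unstable_markers)
    unknown = unstable - set(PROMEGA_MARKERS)
    if unknown:
        raise ValueError(f"unknown markers: {sorted(unknown)}")
    profiles: dict[str, MarkerProfile] = {}
    truth: dict[str, int | None] = {}
    for marker in PROMEGA_MARKERS:
        profiles[marker], truth[marker] = simulate_pcr_profile(
            marker, marker in unstable, seed
        )
    return profiles, truth


# ---------------------------------------------------------------------
# Cohort fixtures
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class PatientSpec:
    """Ground-truth description of one cohort entry (a PDX line or an
    autopsy patient); ``link`` names the autopsy patient a PDX line was
    derived from."""

    patient_id: str
    cohort: Literal["PDX", "autopsy"]
    sites: tuple[str, ...]
    hypermutated: bool
    msi_high: bool
    burden: int
    lesions: tuple[LesionSpec, ...] = ()
    link: str | None = None


@dataclass
class CohortData:
    specimens: dict[str, SpecimenData]
    truths: dict[str, SpecimenTruth]
    specimen_to_patient: dict[str, str]
    specs: list[PatientSpec]
    pcr_profiles: dict[str, dict[str, MarkerProfile]] = field(default_factory=dict)
    pcr_truth: dict[str, dict[str, int | None]] = field(default_factory=dict)


def _inv(gene: str, label: str, p1: int, p2: int) -> LesionSpec:
    return LesionSpec(kind="rearrangement", gene=gene, label=label,
                      sv_type="inversion", bp1=("chr2", p1), bp2=("chr2", p2))


_MSH2_INVERSIONS = (
    _inv("MSH2", "MSH2-C2orf61 343 kb inversion", 47_640_000, 47_297_000),
    _inv("MSH2", "MSH2-KCNK12 74 kb inversion", 47_670_000, 47_744_000),
    _inv("MSH2", "MSH2-KCNK12 40 kb inversion", 47_700_000, 47_740_000),
)

_MSH6_TESC_T212 = LesionSpec(
    kind="rearrangement", gene="MSH6", label="MSH6-TESC t(2;12)",
    sv_type="translocation", bp1=("chr2", 48_020_000), bp2=("chr12", 117_476_000),
)

_LUCAP145_LESIONS = (
    LesionSpec(kind="copy_loss", gene="MSH2", label="MSH2 exon 8-16 del",
               exon_start=8, exon_end=16, zygosity="het"),
    _MSH6_TESC_T212,
)


def paper_cohort() -> list[PatientSpec]:
    """The study-design fixture: 15 PDX lines (3 hypermutated) and 50
    autopsy patients (5 hypermutated), with five PDX lines linked to their
    source autopsy patients (one link joins two hypermutated entries), so
    65 entries collapse to 60 unique patients of whom 7 are hypermutated."""
    pdx: list[PatientSpec] = [
        PatientSpec(
            "LuCaP 58", "PDX", ("xenograft",), True, True, 620,
            lesions=(
                LesionSpec(kind="copy_loss", gene="MSH6",
                           label="MSH6 del exon 8 to 3'UTR",
                           exon_start=8, exon_end=10, zygosity="het"),
                LesionSpec(kind="frameshift", gene="MSH6",
                           label="MSH6 frameshift (c.3799_3800del)",
                           pos_offset=21_000),
            ),
        ),
        PatientSpec(
            "LuCaP 73", "PDX", ("xenograft",), True, True, 540,
            lesions=(
                LesionSpec(kind="copy_loss", gene="MSH2",
                           label="MSH2 copy loss (del 3 Mb)",
                           exon_start=1, exon_end=16, zygosity="het"),
                LesionSpec(kind="copy_loss", gene="MSH6",
                           label="MSH6 copy loss (del 3 Mb)",
                           exon_start=1, exon_end=10, zygosity="het"),
                LesionSpec(kind="rearrangement", gene="MSH2",
                           label="MSH2-FBXO11 inversion", sv_type="inversion",
                           bp1=("chr2", 47_650_000), bp2=("chr2", 48_400_000)),
            ),
        ),
        PatientSpec("LuCaP 147", "PDX", ("xenograft",), True, True, 855,
                    lesions=_MSH2_INVERSIONS, link="05-165"),
        PatientSpec("LuCaP 23.1", "PDX", ("xenograft",), False, False, 45),
        PatientSpec("LuCaP 35", "PDX", ("xenograft",), False, False, 52),
        PatientSpec("LuCaP 70", "PDX", ("xenograft",), False, False, 61),
        PatientSpec("LuCaP 77", "PDX", ("xenograft",), False, False, 49),
        PatientSpec("LuCaP 78", "PDX", ("xenograft",), False, False, 58,
                    link="98-328"),
        PatientSpec("LuCaP 81", "PDX", ("xenograft",), False, False, 66,
                    link="98-362"),
        PatientSpec("LuCaP 86.2", "PDX", ("xenograft",), False, False, 43),
        PatientSpec("LuCaP 92", "PDX", ("xenograft",), False, False, 71,
                    link="99-069"),
        PatientSpec("LuCaP 96", "PDX", ("xenograft",), False, False, 55),
        PatientSpec("LuCaP 105", "PDX", ("xenograft",), False, False, 48),
        PatientSpec("LuCaP 141", "PDX", ("xenograft",), False, False, 63),
        PatientSpec("LuCaP 145", "PDX", ("xenograft",), False, False, 57,
                    lesions=_LUCAP145_LESIONS, link="05-144"),
    ]
    autopsy: list[PatientSpec] = [
        PatientSpec("05-165", "autopsy",
                    ("bone", "adrenal", "liver", "lymph node"),
                    True, True, 855, lesions=_MSH2_INVERSIONS),
        PatientSpec(
            "03-130", "autopsy", ("lymph node",), True, True, 647,
            lesions=(
                LesionSpec(kind="rearrangement", gene="MSH2",
                           label="MSH2 translocation splits the gene t(2;18)",
                           sv_type="translocation",
                           bp1=("chr2", 47_660_000), bp2=("chr18", 48_000_000)),
                LesionSpec(kind="copy_loss", gene="MSH2", label="MSH2 copy loss",
                           exon_start=1, exon_end=16, zygosity="het"),
                LesionSpec(kind="frameshift", gene="MSH6",
                           label="MSH6 frameshift (c.2690del)", pos_offset=12_000),
                LesionSpec(kind="copy_loss", gene="MSH6", label="MSH6 copy loss",
                           exon_start=1, exon_end=10, zygosity="het"),
            ),
        ),
        PatientSpec(
            "06-134", "autopsy", ("kidney", "lymph node"), True, True, 314,
            lesions=(
                LesionSpec(kind="copy_loss", gene="MLH1",
                           label="MLH1 homozygous copy loss",
                           exon_start=1, exon_end=19, zygosity="hom"),
            ),
        ),
        PatientSpec(
            "00-010", "autopsy", ("prostate", "liver"), True, True, 673,
            lesions=(
                LesionSpec(kind="frameshift", gene="MSH2",
                           label="MSH2 frameshift (c.2364_2365insTACA)",
                           pos_offset=50_000),
            ),
        ),
        PatientSpec(
            "05-123", "autopsy", ("prostate", "lymph node"), True, True, 807,
            lesions=(
                LesionSpec(kind="frameshift", gene="MSH2",
                           label="MSH2 frameshift (c.1124_1125insG)",
                           pos_offset=20_000),
                LesionSpec(kind="frameshift", gene="MSH2",
                           label="MSH2 frameshift (c.1082del)", pos_offset=19_000),
                LesionSpec(kind="frameshift", gene="MLH1",
                           label="MLH1 frameshift (c.1310del), lymph node only",
                           pos_offset=25_000, sites=("lymph node",)),
            ),
        ),
        PatientSpec("01-095", "autopsy", ("liver", "lymph node"),
                    False, False, 149),
        PatientSpec("05-144", "autopsy",
                    ("bone", "adrenal", "liver", "lymph node"),
                    False, False, 57, lesions=_LUCAP145_LESIONS),
        PatientSpec("05-214", "autopsy",
                    ("bone", "liver", "lymph node 1", "lymph node 2"),
                    False, False, 46),
        PatientSpec("05-116", "autopsy", ("bone", "adrenal", "liver", "lung"),
                    False, False, 47),
        PatientSpec("00-029", "autopsy", ("liver",), False, False, 37),
        PatientSpec("00-090", "autopsy", ("lymph node",), False, False, 69),
        PatientSpec("98-328", "autopsy", ("lymph node",), False, False, 58),
        PatientSpec("98-362", "autopsy", ("bone",), False, False, 66),
        PatientSpec("99-069", "autopsy", ("liver",), False, False, 71),
    ]
    # exome-only autopsy patients (no targeted follow-up, all non-hypermutated)
    for i in range(36):
        autopsy.append(
            PatientSpec(f"RA-{i + 1:02d}", "autopsy", ("metastasis",),
                        False, False, 30 + (i * 7) % 120)
        )
    return pdx + autopsy


def simulate_cohort(
    specs: Sequence[PatientSpec],
    config: SimulationConfig,
    panel: Sequence[MicrosatelliteLocus] | None = None,
    gene_model: GeneModel | None = None,
) -> CohortData:
    """Simulate every specimen of a cohort; truth is shared across a
    patient's sites except for explicitly site-restricted lesions."""
    panel = make_panel(config.n_loci) if panel is None else list(panel)
    model = gene_model or default_mmr_model()
    specimens: dict[str, SpecimenData] = {}
    truths: dict[str, SpecimenTruth] = {}
    spec_to_patient: dict[str, str] = {}
    for spec in specs:
        # patient-level truth (destabilized locus set shared across sites)
        if spec.msi_high:
            patient_rng = np.random.default_rng(
                [config.seed, _crc(spec.patient_id), 1]
            )
            n_unstable = round(config.msi_locus_fraction * len(panel))
            picked = patient_rng.choice(len(panel), size=n_unstable, replace=False)
            destabilized = tuple(sorted(panel[i].locus_id for i in picked))
        else:
            destabilized = ()
        for site in spec.sites:
            specimen_id = f"{spec.patient_id}|{site}"
            if specimen_id in specimens:
                raise ValueError(f"duplicate specimen id {specimen_id!r}")
            truth = SpecimenTruth(
                specimen_id=specimen_id,
                msi_status="MSI-high" if spec.msi_high else "MSS",
                hypermutated=spec.hypermutated,
                true_burden=spec.burden,
                lesions=spec.lesions,
                destabilized_loci=destabilized,
            )
            data = simulate_specimen(truth, panel, config, model, site=site)
            specimens[specimen_id] = data
            truths[specimen_id] = data.truth
            spec_to_patient[specimen_id] = spec.patient_id
    # one five-marker PCR run per patient; MSI-high patients carry planted
    # instability at three markers (LuCaP 58 keeps its canonical trio)
    pcr_profiles: dict[str, dict[str, MarkerProfile]] = {}
    pcr_truth: dict[str, dict[str, int | None]] = {}
    for spec in specs:
        if not spec.msi_high:
            unstable_markers: tuple[str, ...] = ()
        elif spec.patient_id == "LuCaP 58":
            unstable_markers = LUCAP58_UNSTABLE_MARKERS
        else:
            marker_rng = np.random.default_rng(
                [config.seed, _crc(spec.patient_id), 2]
            )
            picked = marker_rng.choice(len(PROMEGA_MARKERS), size=3, replace=False)
            unstable_markers = tuple(PROMEGA_MARKERS[i] for i in sorted(picked))
        seed = (config.seed * 1_000_003 + _crc(spec.patient_id)) % (2**31 - 1)
        pcr_profiles[spec.patient_id], pcr_truth[spec.patient_id] = (
            simulate_marker_panel(unstable_markers, seed)
        )
    return CohortData(
        specimens=specimens,
        truths=truths,
        specimen_to_patient=spec_to_patient,
        specs=list(specs),
        pcr_profiles=pcr_profiles,
        pcr_truth=pcr_truth,
    )
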