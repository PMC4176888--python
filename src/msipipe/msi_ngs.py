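"""Microsatellite instability calling from targeted-sequencing read data.

This module scores MSI the way mSINGS-style callers do: for each captured
mononucleotide microsatellite locus, the distribution of observed repeat
lengths in a specimen is summarized as a *distinct-allele count* (the number
of repeat lengths carrying at least a minimum fraction of the reads) and
compared against a baseline built from a population of normal controls.  A
locus is unstable when its allele count exceeds the control mean by more
than ``k_sd`` control standard deviations.  The specimen-level call is the
fraction of evaluable loci that are unstable; a fraction strictly greater
than 0.20 is reported as MSI-high.

Loci covered by fewer than 30 reads are excluded from both numerator and
denominator, mirroring clinical quality filtering for targeted panels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "MicrosatelliteLocus",
    "LengthHistogram",
    "LocusBaseline",
    "MsiResult",
    "count_alleles",
    "train_baseline",
    "evaluate_locus",
    "call_specimen",
    "DEFAULT_SUPPORT_FRACTION",
    "DEFAULT_MIN_DEPTH",
    "DEFAULT_K_SD",
    "DEFAULT_MSI_THRESHOLD",
    "DEFAULT_MIN_EVALUABLE",
]

#: minimum fraction of a locus's reads a repeat length needs to count as an allele
DEFAULT_SUPPORT_FRACTION = 0.05
#: loci with fewer reads than this are excluded as failing quality filter
DEFAULT_MIN_DEPTH = 30
#: number of control standard deviations above the control mean that defines "unstable"
DEFAULT_K_SD = 3.0
#: unstable-locus fraction strictly above this is MSI-high
DEFAULT_MSI_THRESHOLD = 0.20
#: minimum evaluable loci required for a confident specimen-level call
DEFAULT_MIN_EVALUABLE = 20

LocusStatus = Literal["unstable", "stable", "filtered-low-depth"]
MsiCall = Literal["MSI-high", "MSI-negative", "indeterminate"]


@dataclass(frozen=True)
class MicrosatelliteLocus:
    """One mononucleotide repeat site on the capture panel.

    Coordinates are 0-based half-open.  ``reference_repeat_count`` is the
    number of repeat units in the reference genome.
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    repeat_unit: str
    reference_repeat_count: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.locus_id}: end must be > start")
        if len(self.repeat_unit) != 1:
            raise ValueError(
                f"{self.locus_id}: mononucleotide panel requires a 1-base repeat unit"
            )
        if self.reference_repeat_count < 1:
            raise ValueError(f"{self.locus_id}: reference_repeat_count must be >= 1")


@dataclass
class LengthHistogram:
    """Read counts by observed repeat length for one locus in one specimen."""

    locus_id: str
    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for length, count in self.counts.items():
            if count < 0:
                raise ValueError(f"{self.locus_id}: negative count at length {length}")

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class LocusBaseline:
    """Normal-control allele-count statistics for one locus."""

    locus_id: str
    mean_allele_count: float
    sd_allele_count: float
    n_controls: int

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise ValueError(f"{self.locus_id}: baseline requires >= 2 controls")
        if self.sd_allele_count < 0:
            raise ValueError(f"{self.locus_id}: sd must be >= 0")


@dataclass
class MsiResult:
    """Specimen-level MSI call with per-locus statuses."""

    locus_status: dict[str, LocusStatus]
    n_evaluated: int
    n_unstable: int
    fraction_unstable: float
    call: MsiCall


def count_alleles(
    hist: LengthHistogram, support_fraction: float = DEFAULT_SUPPORT_FRACTION
) -> int:
    """Count distinct repeat lengths supported by ``support_fraction`` of reads.

    A repeat length counts as an allele when its read count is at least
    ``support_fraction * depth`` (inclusive).  Undefined at zero depth —
    callers must depth-filter first.
    """
    depth = hist.depth
    if depth <= 0:
        raise ValueError(f"{hist.locus_id}: count_alleles undefined at zero depth")
    if not 0.0 < support_fraction < 1.0:
        raise ValueError("support_fraction must be in (0, 1)")
    threshold = support_fraction * depth
    return sum(1 for c in hist.counts.values() if c >= threshold)


def train_baseline(
    controls: Sequence[Mapping[str, LengthHistogram]],
    support_fraction: float = DEFAULT_SUPPORT_FRACTION,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> dict[str, LocusBaseline]:
    """Build per-locus allele-count baselines from normal-control specimens.

    ``controls`` holds one locus→histogram mapping per control specimen.
    For each locus, controls failing the depth filter are dropped; loci with
    fewer than two passing controls are untrainable and omitted from the
    returned mapping (and so excluded from evaluation downstream).

    The standard deviation is the population SD (``ddof=0``): the controls
    are treated as the reference population itself.
    """
    per_locus: dict[str, list[int]] = {}
    for control in controls:
        for locus_id, hist in control.items():
            if hist.depth < min_depth:
                continue
            per_locus.setdefault(locus_id, []).append(
                count_alleles(hist, support_fraction)
            )
    baselines: dict[str, LocusBaseline] = {}
    for locus_id, allele_counts in per_locus.items():
        if len(allele_counts) < 2:
            continue
        arr = np.asarray(allele_counts, dtype=float)
        baselines[locus_id] = LocusBaseline(
            locus_id=locus_id,
            mean_allele_count=float(arr.mean()),
            sd_allele_count=float(arr.std(ddof=0)),
            n_controls=len(allele_counts),
        )
    return baselines


def evaluate_locus(
    hist: LengthHistogram,
    baseline: LocusBaseline,
    min_depth: int = DEFAULT_MIN_DEPTH,
    k_sd: float = DEFAULT_K_SD,
    support_fraction: float = DEFAULT_SUPPORT_FRACTION,
) -> LocusStatus:
    """Classify one locus as unstable/stable/filtered against its baseline.

    Unstable means the allele count is *strictly* greater than
    ``mean + k_sd * sd``; a tie is stable.
    """
    if hist.locus_id != baseline.locus_id:
        raise ValueError(
            f"locus/baseline mismatch: {hist.locus_id} vs {baseline.locus_id}"
        )
    if hist.depth < min_depth:
        return "filtered-low-depth"
    alleles = count_alleles(hist, support_fraction)
    cutoff = baseline.mean_allele_count + k_sd * baseline.sd_allele_count
    return "unstable" if alleles > cutoff else "stable"


def call_specimen(
    locus_status: Mapping[str, LocusStatus],
    msi_threshold: float = DEFAULT_MSI_THRESHOLD,
    min_evaluable: int = DEFAULT_MIN_EVALUABLE,
) -> MsiResult:
    """Aggregate per-locus statuses into a specimen-level MSI call.

    Depth-filtered loci are excluded from both numerator and denominator.
    The call is MSI-high iff ``fraction_unstable > msi_threshold`` (strict
    inequality), MSI-negative otherwise, and indeterminate when fewer than
    ``min_evaluable`` loci were evaluable.
    """
    evaluated = {
        lid: s for lid, s in locus_status.items() if s != "filtered-low-depth"
    }
    n_evaluated = len(evaluated)
    n_unstable = sum(1 for s in evaluated.values() if s == "unstable")
    fraction = n_unstable / n_evaluated if n_evaluated > 0 else math.nan
    if n_evaluated < min_evaluable:
        call: MsiCall = "indeterminate"
    elif fraction > msi_threshold:
        call = "MSI-high"
    else:
        call = "MSI-negative"
    return MsiResult(
        locus_status=dict(locus_status),
        n_evaluated=n_evaluated,
        n_unstable=n_unstable,
        fraction_unstable=fraction,
        call=call,
    )
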